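"""Genotype QC, sporadic-missing imputation, per-SNP additive association
testing, genomic-inflation diagnostics, and clinical univariate tests.

The additive SNP test is the Cochran-Armitage trend test with scores (0,1,2),
which is the standard "chi-square test under an additive model" and is
algebraically identical to the Rao score test of a univariate logistic
regression of case status on dosage.  QC thresholds default to the usual
array-QC settings: MAF >= 0.01, per-SNP and per-sample missing rate <= 0.05,
HWE p > 1e-5 (1-df chi-square goodness of fit, cases and controls pooled).

Association tests exclude missing dosages pairwise (run them pre-imputation);
model fitting expects a complete matrix (run it post-imputation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix, PhenotypeTable

logger = logging.getLogger("prfr")

#: median of the 1-df chi-square distribution, the null calibration constant
#: for the genomic inflation factor
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclass
class QCThresholds:
    maf_min: float = 0.01
    snp_missing_max: float = 0.05
    sample_missing_max: float = 0.05
    hwe_p_min: float = 1e-5


@dataclass
class QCReport:
    n_snps_in: int
    n_snps_out: int
    n_samples_in: int
    n_samples_out: int
    removed: dict[str, int] = field(default_factory=dict)
    lambda_gc: float | None = None

    def as_dict(self) -> dict:
        return {
            "n_snps_in": self.n_snps_in,
            "n_snps_out": self.n_snps_out,
            "n_samples_in": self.n_samples_in,
            "n_samples_out": self.n_samples_out,
            "removed": dict(self.removed),
            "lambda_gc": self.lambda_gc,
        }


# ---------------------------------------------------------------------------
# Per-SNP summary statistics
# ---------------------------------------------------------------------------


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency of one SNP, missing excluded.

    The counted-allele frequency is sum(dosage)/(2 * n_nonmissing); the MAF
    is the smaller of it and its complement.
    """
    d = np.asarray(dosages, dtype=float)
    n = np.count_nonzero(~np.isnan(d))
    if n == 0:
        raise ValueError("all-missing SNP: MAF undefined")
    f = np.nansum(d) / (2 * n)
    return float(min(f, 1 - f))


def hwe_test(counts: tuple[int, int, int]) -> float:
    """1-df chi-square goodness-of-fit p-value against HWE proportions.

    ``counts`` are genotype counts (n_AA, n_Aa, n_aa) for dosage 0/1/2.
    Monomorphic SNPs are in trivial equilibrium (p = 1).
    """
    n0, n1, n2 = counts
    if min(n0, n1, n2) < 0:
        raise ValueError("negative genotype count")
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("empty genotype counts")
    f = (n1 + 2 * n2) / (2 * n)  # counted-allele frequency
    if f == 0.0 or f == 1.0:
        return 1.0
    expected = np.array([n * (1 - f) ** 2, n * 2 * f * (1 - f), n * f**2])
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def _snp_missing_rates(dosages: np.ndarray) -> np.ndarray:
    return np.isnan(dosages).mean(axis=0)


def _genotype_counts(column: np.ndarray) -> tuple[int, int, int]:
    d = column[~np.isnan(column)]
    return (
        int(np.count_nonzero(d == 0)),
        int(np.count_nonzero(d == 1)),
        int(np.count_nonzero(d == 2)),
    )


# ---------------------------------------------------------------------------
# QC filtering and imputation
# ---------------------------------------------------------------------------


def qc_filter(
    genotypes: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply sample-missing, SNP-missing, MAF and HWE filters, in that order.

    Keep rules: sample missing <= max, SNP missing <= max, MAF >= min (all
    inclusive), HWE p strictly > min.  HWE is computed on all samples pooled.
    """
    thresholds = thresholds or QCThresholds()
    if genotypes.n_snps == 0 or genotypes.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    report = QCReport(
        n_snps_in=genotypes.n_snps,
        n_snps_out=0,
        n_samples_in=genotypes.n_individuals,
        n_samples_out=0,
    )
    # (1) sample missing rate
    sample_miss = np.isnan(genotypes.dosages).mean(axis=1)
    keep_samples = sample_miss <= thresholds.sample_missing_max
    report.removed["sample_missing"] = int((~keep_samples).sum())
    kept_ids = [s for s, k in zip(genotypes.sample_ids, keep_samples) if k]
    if not kept_ids:
        raise ValueError(f"all samples removed by QC; report={report.as_dict()}")
    gm = genotypes.subset_samples(kept_ids)

    # (2) SNP missing rate
    snp_miss = _snp_missing_rates(gm.dosages)
    keep = snp_miss <= thresholds.snp_missing_max
    report.removed["snp_missing"] = int((~keep).sum())

    # (3) MAF (on SNPs surviving the missing filter)
    with np.errstate(invalid="ignore"):
        nonmiss = np.count_nonzero(~np.isnan(gm.dosages), axis=0)
        freq = np.where(nonmiss > 0, np.nansum(gm.dosages, axis=0) / (2 * np.maximum(nonmiss, 1)), np.nan)
    maf = np.minimum(freq, 1 - freq)
    fail_maf = keep & ~(maf >= thresholds.maf_min)
    report.removed["maf"] = int(fail_maf.sum())
    keep &= maf >= thresholds.maf_min

    # (4) HWE, pooled samples (vectorized; equals hwe_test per SNP)
    n_col = np.stack([(gm.dosages == g).sum(axis=0) for g in (0.0, 1.0, 2.0)]).astype(
        float
    )
    n_tot = n_col.sum(axis=0)
    freq = np.where(n_tot > 0, (n_col[1] + 2 * n_col[2]) / (2 * np.maximum(n_tot, 1)), 0.5)
    poly = (freq > 0) & (freq < 1)
    f = np.where(poly, freq, 0.5)
    expected = np.stack([n_tot * (1 - f) ** 2, n_tot * 2 * f * (1 - f), n_tot * f**2])
    with np.errstate(divide="ignore", invalid="ignore"):
        hwe_chi2 = ((n_col - expected) ** 2 / np.maximum(expected, 1e-300)).sum(axis=0)
    hwe_p = np.where(poly, stats.chi2.sf(hwe_chi2, df=1), 1.0)
    fail_hwe = keep & ~(hwe_p > thresholds.hwe_p_min)
    report.removed["hwe"] = int(fail_hwe.sum())
    keep &= ~fail_hwe

    if not keep.any():
        raise ValueError(f"all SNPs removed by QC; report={report.as_dict()}")
    out = gm.subset_snps([s for s, k in zip(gm.snp_ids, keep) if k])
    report.n_snps_out = out.n_snps
    report.n_samples_out = out.n_individuals
    return out, report


def impute_sporadic_missing(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Fill missing cells with the per-SNP modal dosage (ties -> smaller dosage).

    A deliberately simple stand-in for reference-panel genotype imputation,
    adequate for sporadic (low-rate) missingness.
    """
    if not np.isnan(genotypes.dosages).any():
        return genotypes
    dosages = genotypes.dosages.copy()
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        if miss.all():
            raise ValueError(
                f"SNP {genotypes.snps[j].snp_id} is entirely missing; cannot impute"
            )
        counts = np.array([np.count_nonzero(col == g) for g in (0.0, 1.0, 2.0)])
        mode = float(np.argmax(counts))  # argmax takes the first max: tie -> smaller
        col[miss] = mode
    return GenotypeMatrix(dosages, genotypes.snps, genotypes.sample_ids)


# ---------------------------------------------------------------------------
# Additive association (Cochran-Armitage trend)
# ---------------------------------------------------------------------------


def trend_test(counts: np.ndarray) -> tuple[float, float]:
    """Cochran-Armitage trend test with scores (0,1,2) on a 2x3 table.

    ``counts[0]`` are case genotype counts, ``counts[1]`` controls, columns
    ordered by dosage 0/1/2.  Returns (chi2, p); degenerate variance (all
    samples in one genotype column) gives (0, 1).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 3):
        raise ValueError("counts must be a 2x3 case/control x genotype table")
    if counts[0].sum() == 0 or counts[1].sum() == 0:
        raise ValueError("trend test requires at least one case and one control")
    scores = np.array([0.0, 1.0, 2.0])
    n_col = counts.sum(axis=0)
    n = n_col.sum()
    r = counts[0].sum()  # cases
    num = n * np.dot(scores, counts[0]) - r * np.dot(scores, n_col)
    var_term = n * np.dot(scores**2, n_col) - np.dot(scores, n_col) ** 2
    denom = r * (n - r) * var_term
    if denom <= 0:
        return 0.0, 1.0
    chi2 = float(n * num**2 / denom)
    return chi2, float(stats.chi2.sf(chi2, df=1))


def association_table(
    genotypes: GenotypeMatrix, phenotypes: PhenotypeTable
) -> pd.DataFrame:
    """Per-SNP MAF, missing rate, HWE p, and additive trend test vs case status.

    Missing dosages are excluded per SNP (pairwise deletion).  Returns a
    DataFrame with columns snp_id, chrom, pos, maf, missing_rate, hwe_p,
    chi2, p — one row per SNP, in matrix order.  All statistics are computed
    vectorized across SNPs; they agree with the scalar :func:`trend_test` and
    :func:`hwe_test` applied per SNP.
    """
    y = phenotypes.outcomes_for(genotypes.sample_ids)
    case = (y == 1).astype(float)
    ctrl = (y == 0).astype(float)
    if case.sum() == 0 or ctrl.sum() == 0:
        raise ValueError("association requires both cases and controls")
    D = genotypes.dosages
    miss = np.isnan(D)
    if miss.all(axis=0).any():
        bad = genotypes.snp_ids[int(np.argmax(miss.all(axis=0)))]
        raise ValueError(f"SNP {bad} is entirely missing")
    missing_rate = miss.mean(axis=0)

    # per-SNP genotype counts split by outcome, missing excluded
    case_counts = np.stack([case @ (D == g) for g in (0.0, 1.0, 2.0)])  # 3 x p
    ctrl_counts = np.stack([ctrl @ (D == g) for g in (0.0, 1.0, 2.0)])
    scores = np.array([0.0, 1.0, 2.0])

    n_col = case_counts + ctrl_counts  # pooled genotype counts, 3 x p
    n = n_col.sum(axis=0)
    r = case_counts.sum(axis=0)

    # Cochran-Armitage trend statistic (identical to the logistic score test)
    num = n * (scores @ case_counts) - r * (scores @ n_col)
    var_term = n * (scores**2 @ n_col) - (scores @ n_col) ** 2
    denom = r * (n - r) * var_term
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, n * num**2 / np.where(denom > 0, denom, 1.0), 0.0)
    p = np.where(denom > 0, stats.chi2.sf(chi2, df=1), 1.0)

    # MAF of the counted allele, folded to the minor allele
    freq = (n_col[1] + 2 * n_col[2]) / (2 * n)
    maf = np.minimum(freq, 1 - freq)

    # HWE goodness of fit on pooled samples; monomorphic -> p = 1
    poly = (freq > 0) & (freq < 1)
    f = np.where(poly, freq, 0.5)
    expected = np.stack([n * (1 - f) ** 2, n * 2 * f * (1 - f), n * f**2])
    hwe_chi2 = ((n_col - expected) ** 2 / expected).sum(axis=0)
    hwe_p = np.where(poly, stats.chi2.sf(hwe_chi2, df=1), 1.0)

    return pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids,
            "chrom": [s.chrom for s in genotypes.snps],
            "pos": [s.pos for s in genotypes.snps],
            "maf": maf,
            "missing_rate": missing_rate,
            "hwe_p": hwe_p,
            "chi2": chi2,
            "p": p,
        }
    )


def filter_snps_by_p(assoc: pd.DataFrame, cutoff: float = 0.001) -> list[str]:
    """SNP ids with association p strictly below ``cutoff``, ordered by
    ascending p then snp_id."""
    hits = assoc[assoc["p"] < cutoff]
    if hits.empty:
        logger.warning("no SNPs pass the p<%g filter", cutoff)
        return []
    hits = hits.sort_values(["p", "snp_id"], kind="mergesort")
    return hits["snp_id"].tolist()


# ---------------------------------------------------------------------------
# Inflation diagnostics
# ---------------------------------------------------------------------------


def genomic_inflation(chi2_values: np.ndarray) -> float:
    """Genomic inflation factor: median observed chi2 over the 1-df null median."""
    chi2_values = np.asarray(chi2_values, dtype=float)
    if chi2_values.size == 0:
        raise ValueError("empty chi-square vector")
    return float(np.median(chi2_values) / CHI2_1DF_MEDIAN)


def qq_points(p_values: np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10 p quantiles plus a 95% null band.

    Expected quantiles use (i - 0.5)/n; the band comes from Beta(i, n-i+1)
    order-statistic quantiles of uniform p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any():
        raise ValueError("p-values must be > 0 (floor at machine epsilon upstream)")
    if (p > 1).any():
        raise ValueError("p-values must be <= 1")
    n = p.size
    observed = np.sort(p)
    i = np.arange(1, n + 1)
    expected = (i - 0.5) / n
    lower = stats.beta.ppf(0.025, i, n - i + 1)
    upper = stats.beta.ppf(0.975, i, n - i + 1)
    return pd.DataFrame(
        {
            "expected_neglog10": -np.log10(expected),
            "observed_neglog10": -np.log10(observed),
            "band_low_neglog10": -np.log10(upper),
            "band_high_neglog10": -np.log10(lower),
        }
    )


# ---------------------------------------------------------------------------
# Clinical univariate tests
# ---------------------------------------------------------------------------


def univariate_clinical_tests(phenotypes: PhenotypeTable) -> pd.DataFrame:
    """Case/control tests for each clinical covariate.

    Categorical variables: chi-square test of the full contingency table for
    the p-value, plus per-level odds ratios against the declared reference
    level with Woolf (log-OR +/- 1.96 SE) confidence intervals; zero cells
    get the Haldane-Anscombe 0.5 correction for the OR/CI only.  Continuous
    variables: single-predictor logistic regression Wald p and per-unit OR.

    Returns a long DataFrame: variable, level, odds_ratio, ci_low, ci_high, p.
    """
    import statsmodels.api as sm

    y = phenotypes.outcome
    rows = []
    for var in phenotypes.covariates:
        values = phenotypes.data[var]
        kind = phenotypes.covariate_types[var]
        if kind == "categorical":
            values = values.astype(str)
            levels = sorted(values.unique())
            if len(levels) < 2:
                raise ValueError(f"covariate {var!r} is constant")
            ref = phenotypes.reference_level(var)
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from {var!r}")
            table = pd.crosstab(values, y).reindex(levels).fillna(0)
            chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
            ref_case = float(table.loc[ref].get(1, 0))
            ref_ctrl = float(table.loc[ref].get(0, 0))
            rows.append((var, f"{ref} (ref)", 1.0, np.nan, np.nan, float(p)))
            for lev in levels:
                if lev == ref:
                    continue
                a = float(table.loc[lev].get(1, 0))  # level cases
                b = float(table.loc[lev].get(0, 0))  # level controls
                c, d = ref_case, ref_ctrl
                if min(a, b, c, d) == 0:
                    a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
                or_ = (a * d) / (b * c)
                se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
                lo = np.exp(np.log(or_) - 1.96 * se)
                hi = np.exp(np.log(or_) + 1.96 * se)
                rows.append((var, lev, float(or_), float(lo), float(hi), float(p)))
        else:
            x = values.to_numpy(dtype=float)
            if np.allclose(x, x[0]):
                raise ValueError(f"covariate {var!r} is constant")
            X = sm.add_constant(x)
            fit = sm.Logit(y, X).fit(disp=0)
            beta = fit.params[1]
            se = fit.bse[1]
            rows.append(
                (
                    var,
                    "per_unit",
                    float(np.exp(beta)),
                    float(np.exp(beta - 1.96 * se)),
                    float(np.exp(beta + 1.96 * se)),
                    float(fit.pvalues[1]),
                )
            )
    return pd.DataFrame(
        rows, columns=["variable", "level", "odds_ratio", "ci_low", "ci_high", "p"]
    )


def filter_clinical_by_p(
    clinical: pd.DataFrame, cutoff: float = 0.05
) -> list[str]:
    """Clinical variables whose test p is strictly below ``cutoff``."""
    per_var = clinical.groupby("variable")["p"].min()
    return sorted(per_var[per_var < cutoff].index)
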