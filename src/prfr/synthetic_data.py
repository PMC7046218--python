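"""Seeded synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes: a small
case-control cohort (defaults: 205 individuals, ~25% cases, mirroring a
radiation-exposed contralateral-breast-cancer study population) genotyped at a
configurable number of biallelic SNPs in Hardy-Weinberg equilibrium, with
optional LD blocks, a sparse logistic causal architecture on centered dosages,
sporadic missingness, and clinical covariates drawn independently of the
outcome (none of the six clinical variables carried signal in the motivating
cohort, so the default covariates are pure noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import GenotypeMatrix, PhenotypeTable, SNPInfo

import pandas as pd


@dataclass
class SimulationConfig:
    """Parameters of a simulated cohort.

    ``causal_effects`` are per-causal-SNP log odds ratios applied to dosages
    centered at their expectation 2*MAF; the intercept is solved numerically
    so the mean case probability matches ``intercept_target_prevalence``.
    ``ld_block_size`` = 1 gives independent SNPs; larger blocks use an
    exchangeable latent-Gaussian correlation ``ld_rho`` within each block.
    """

    n_individuals: int = 205
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 0
    causal_effects: list[float] | None = None
    intercept_target_prevalence: float = 52 / 205
    ld_block_size: int = 1
    ld_rho: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    causal_snp_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_snps <= 0:
            raise ValueError("n_individuals and n_snps must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if not (0 < self.intercept_target_prevalence < 1):
            raise ValueError("target prevalence must lie in (0,1)")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must lie in [0,1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0,1)")
        if self.causal_effects is None:
            self.causal_effects = [np.log(1.5)] * self.n_causal
        if len(self.causal_effects) != self.n_causal:
            raise ValueError("causal_effects length must equal n_causal")


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    causal_snp_ids: list[str]
    true_effects: list[float]
    true_mafs: np.ndarray = field(repr=False, default=None)


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw HWE genotypes, independent or in exchangeable-correlation LD blocks.

    Per SNP j a MAF is drawn uniformly on ``maf_range``.  Independent SNPs are
    the sum of two Bernoulli(MAF) allele draws.  With ``ld_block_size`` > 1,
    correlated standard-normal latents (exchangeable correlation ``ld_rho``
    within a block) are thresholded at the HWE genotype-frequency quantiles,
    preserving per-SNP HWE margins while inducing dosage correlation.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_individuals, config.n_snps
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=p)
    if config.ld_block_size == 1 or config.ld_rho == 0.0:
        dosages = rng.binomial(2, mafs[None, :], size=(n, p)).astype(float)
    else:
        dosages = np.empty((n, p))
        b = config.ld_block_size
        rho = config.ld_rho
        for start in range(0, p, b):
            width = min(b, p - start)
            shared = rng.standard_normal((n, 1))
            noise = rng.standard_normal((n, width))
            latent = np.sqrt(rho) * shared + np.sqrt(1 - rho) * noise
            u = stats.norm.cdf(latent)
            m = mafs[start : start + width]
            # HWE cumulative genotype frequencies: P(0)=(1-m)^2, P(0 or 1)=1-m^2
            c0 = (1 - m) ** 2
            c1 = 1 - m**2
            dosages[:, start : start + width] = (u >= c0).astype(float) + (
                u >= c1
            ).astype(float)
    width_id = len(str(p))
    snps = [
        SNPInfo(f"snp{j + 1:0{width_id}d}", str((j % 22) + 1), 10_000 + 1000 * j)
        for j in range(p)
    ]
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    gm = GenotypeMatrix(dosages, snps, sample_ids)
    gm.true_mafs = mafs  # type: ignore[attr-defined]  # carried for calibration
    return gm


def _solve_intercept(eta: np.ndarray, target: float, tol: float = 1e-4) -> float:
    """Bisect for b0 such that mean sigmoid(b0 + eta) == target."""

    def mean_p(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + eta)))))

    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    b0 = 0.5 * (lo + hi)
    if abs(mean_p(b0) - target) > tol:
        raise RuntimeError("intercept calibration failed to reach tolerance")
    return b0


def simulate_phenotype(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> PhenotypeTable:
    """Draw binary outcomes from a sparse logistic model on centered dosages.

    logit P(case) = b0 + sum_j beta_j (dosage_j - 2*MAF_j), with b0 solved by
    bisection so the mean case probability matches the target prevalence
    (tolerance 1e-4).  Clinical covariates are simulated independently of the
    outcome.  Dosages must be complete (inject missingness afterwards).
    """
    rng = np.random.default_rng(config.seed + 1)
    n = genotypes.n_individuals
    causal_ids = config.causal_snp_ids or genotypes.snp_ids[: config.n_causal]
    for cid in causal_ids:
        if cid not in genotypes.snp_ids:
            raise KeyError(f"causal SNP {cid!r} not in genotype matrix")
    eta = np.zeros(n)
    if causal_ids:
        X = genotypes.subset_snps(causal_ids).dosages
        if np.isnan(X).any():
            raise ValueError("causal dosages contain missing values")
        mafs = getattr(genotypes, "true_mafs", None)
        if mafs is not None:
            idx = [genotypes.snp_ids.index(c) for c in causal_ids]
            centers = 2 * mafs[idx]
        else:
            centers = X.mean(axis=0)
        beta = np.asarray(config.causal_effects, dtype=float)
        eta = (X - centers) @ beta
    b0 = _solve_intercept(eta, config.intercept_target_prevalence)
    prob = 1.0 / (1.0 + np.exp(-(b0 + eta)))
    outcome = rng.binomial(1, prob)
    covs = _simulate_covariates(n, rng)
    df = pd.DataFrame({"sample_id": genotypes.sample_ids, "outcome": outcome})
    for name, values in covs.items():
        df[name] = values
    return PhenotypeTable(
        df,
        covariate_types={
            "age_menarche": "categorical",
            "family_history": "categorical",
            "treatment": "categorical",
            "n_pregnancies": "categorical",
            "registry": "categorical",
            "age_dx": "continuous",
            "rt_dose": "continuous",
        },
        reference_levels={
            "age_menarche": "before13",
            "family_history": "none",
            "treatment": "none",
            "n_pregnancies": "0",
            "registry": "R1",
        },
    )


def _simulate_covariates(n: int, rng: np.random.Generator) -> dict:
    """Clinical covariates with realistic marginals but no outcome effect."""
    return {
        "age_menarche": rng.choice(["before13", "after13"], size=n, p=[0.5, 0.5]),
        "family_history": rng.choice(["none", "1plus"], size=n, p=[0.73, 0.27]),
        "treatment": rng.choice(
            ["none", "chemo", "hormone", "both"], size=n, p=[0.21, 0.03, 0.54, 0.22]
        ),
        "n_pregnancies": rng.choice(
            ["0", "1", "2", "3", "gt3"], size=n, p=[0.33, 0.21, 0.34, 0.09, 0.03]
        ),
        "registry": rng.choice(
            ["R1", "R2", "R3", "R4", "R5"], size=n, p=[0.11, 0.23, 0.17, 0.42, 0.07]
        ),
        "age_dx": np.round(rng.uniform(23, 40, size=n), 1),
        "rt_dose": np.round(rng.uniform(1.0, 3.8, size=n), 2),
    }


def inject_missingness(
    genotypes: GenotypeMatrix, rate: float, seed: int
) -> GenotypeMatrix:
    """Set each genotype cell missing independently with probability ``rate``."""
    if not (0 <= rate < 1):
        raise ValueError("missing rate must lie in [0,1)")
    if rate == 0:
        return genotypes
    rng = np.random.default_rng(seed)
    mask = rng.random(genotypes.dosages.shape) < rate
    dosages = genotypes.dosages.copy()
    dosages[mask] = np.nan
    out = GenotypeMatrix(dosages, genotypes.snps, genotypes.sample_ids)
    mafs = getattr(genotypes, "true_mafs", None)
    if mafs is not None:
        out.true_mafs = mafs  # type: ignore[attr-defined]
    return out


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Full cohort draw: genotypes, phenotypes, then sporadic missingness."""
    genotypes = simulate_genotypes(config)
    phenotypes = simulate_phenotype(genotypes, config)
    if (phenotypes.outcome == 1).sum() == 0 or (phenotypes.outcome == 0).sum() == 0:
        raise RuntimeError(
            "simulated cohort has a single outcome class; "
            "increase n_individuals or adjust prevalence"
        )
    causal_ids = config.causal_snp_ids or genotypes.snp_ids[: config.n_causal]
    if config.missing_rate > 0:
        genotypes = inject_missingness(genotypes, config.missing_rate, config.seed + 2)
    return SimulatedCohort(
        genotypes=genotypes,
        phenotypes=phenotypes,
        causal_snp_ids=list(causal_ids),
        true_effects=list(config.causal_effects or []),
        true_mafs=getattr(genotypes, "true_mafs", None),
    )
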