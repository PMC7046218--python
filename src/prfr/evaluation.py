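"""Train/validation splitting, AUC machinery, and the repeated 5-fold x 100
hold-out evaluation protocol.

The headline protocol: the cohort is split once into training and validation
sets stratified by case/control status (greedily balanced on further clinical
variables in priority order).  Within the training set, a shuffled 5-fold
process is repeated 100 times; in every fold the *entire* pipeline —
univariate association filter, supervised-PCA preconditioning, model fit —
is refit on the fold's 80% training portion, and the resulting model scores
the untouched hold-out validation set.  At the defaults this yields 500
hold-out AUCs per model family, whose distributions are compared by Welch's
t-test.

A deliberately leaky variant (association filter fitted once on all training
data instead of per fold) is retained for testing: with out-of-fold scoring
it demonstrates the selection bias the per-fold refit avoids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import association_table, filter_snps_by_p
from .io_formats import GenotypeMatrix, PhenotypeTable
from .modeling import (
    ForestSpec,
    fit_lasso,
    fit_preconditioned_lasso,
    fit_prfr,
    fit_rf_classifier,
)
from .preconditioning import fit_supervised_pca, precondition_outcomes

logger = logging.getLogger("prfr")

MODEL_FAMILIES = ("prfr", "rf_classifier", "lasso", "preconditioned_lasso")


# ---------------------------------------------------------------------------
# Train/validation split
# ---------------------------------------------------------------------------


@dataclass
class SplitAssignment:
    training: list[str]
    validation: list[str]
    balance: dict[str, float] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.training + self.validation,
                "split": ["training"] * len(self.training)
                + ["validation"] * len(self.validation),
            }
        )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _imbalance(
    phenotypes: PhenotypeTable, train: list[str], valid: list[str], var: str
) -> float:
    """Standardized mean difference (continuous) or total-variation distance
    (categorical) between the two sides of a split."""
    col = phenotypes.data[var]
    a, b = col.loc[train], col.loc[valid]
    if phenotypes.covariate_types.get(var) == "continuous":
        pooled = np.sqrt(0.5 * (a.var(ddof=1) + b.var(ddof=1)))
        if pooled == 0 or np.isnan(pooled):
            return 0.0
        return float(abs(a.mean() - b.mean()) / pooled)
    pa = a.astype(str).value_counts(normalize=True)
    pb = b.astype(str).value_counts(normalize=True)
    levels = pa.index.union(pb.index)
    return float(
        0.5 * sum(abs(pa.get(l, 0.0) - pb.get(l, 0.0)) for l in levels)
    )


def stratified_split(
    phenotypes: PhenotypeTable,
    fraction_train: float = 2 / 3,
    priority: list[str] | None = None,
    seed: int = 0,
    n_candidates: int = 1000,
) -> SplitAssignment:
    """Case/control-stratified train/validation split, greedily balanced.

    Stratification on outcome is exact (counts rounded half-up).  Among
    ``n_candidates`` seeded random draws, the one minimizing the
    lexicographic imbalance vector over ``priority`` variables is chosen —
    a perfect split on every variable is generally unattainable, so earlier
    variables win.
    """
    priority = priority or []
    for var in priority:
        if var not in phenotypes.covariates:
            raise KeyError(f"priority variable {var!r} not in phenotype table")
    ids = np.array(phenotypes.sample_ids)
    y = phenotypes.outcome
    cases, controls = ids[y == 1], ids[y == 0]
    n_tc = _round_half_up(fraction_train * len(cases))
    n_tk = _round_half_up(fraction_train * len(controls))
    if (
        n_tc < 1
        or n_tk < 1
        or len(cases) - n_tc < 1
        or len(controls) - n_tk < 1
    ):
        raise ValueError(
            "split fraction leaves a side without both outcome classes"
        )
    rng = np.random.default_rng(seed)
    if not priority:
        n_candidates = 1
    best: tuple | None = None
    best_split: tuple[list[str], list[str]] | None = None
    for _ in range(max(1, n_candidates)):
        pc = rng.permutation(cases)
        pk = rng.permutation(controls)
        train = sorted(np.concatenate([pc[:n_tc], pk[:n_tk]]).tolist())
        valid = sorted(np.concatenate([pc[n_tc:], pk[n_tk:]]).tolist())
        vec = tuple(_imbalance(phenotypes, train, valid, v) for v in priority)
        if best is None or vec < best:
            best, best_split = vec, (train, valid)
    train, valid = best_split
    balance = {v: m for v, m in zip(priority, best or ())}
    return SplitAssignment(training=train, validation=valid, balance=balance)


# ---------------------------------------------------------------------------
# AUC machinery
# ---------------------------------------------------------------------------


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney concordance: probability a random case outscores a random
    control, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes")
    ranks = stats.rankdata(scores)  # midranks handle ties as 1/2
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


def auc_pvalue(scores: np.ndarray, labels: np.ndarray) -> float:
    """One-sided p-value for AUC > 0.5 via the Mann-Whitney U test.

    Exact enumeration for small tie-free samples, otherwise the normal
    approximation with tie correction (scipy's "auto" policy).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not ((labels == 1).any() and (labels == 0).any()):
        raise ValueError("p-value requires both classes")
    res = stats.mannwhitneyu(
        scores[labels == 1], scores[labels == 0], alternative="greater", method="auto"
    )
    return float(res.pvalue)


def bootstrap_auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified percentile bootstrap 95% CI for the AUC.

    Cases and controls are resampled separately, so every replicate retains
    both classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    case_scores = scores[labels == 1]
    ctrl_scores = scores[labels == 0]
    if case_scores.size == 0 or ctrl_scores.size == 0:
        raise ValueError("bootstrap CI requires both classes")
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        cs = rng.choice(case_scores, size=case_scores.size, replace=True)
        ks = rng.choice(ctrl_scores, size=ctrl_scores.size, replace=True)
        s = np.concatenate([cs, ks])
        l = np.concatenate([np.ones(cs.size, int), np.zeros(ks.size, int)])
        reps[b] = auc(s, l)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass
class AUCDistribution:
    kind: str
    aucs: np.ndarray
    oof_aucs: np.ndarray | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def ci(self) -> tuple[float, float]:
        """95% t-interval for the mean of the AUC distribution."""
        n = self.aucs.size
        if n < 2:
            return (self.mean, self.mean)
        se = float(np.std(self.aucs, ddof=1) / np.sqrt(n))
        t = stats.t.ppf(0.975, df=n - 1)
        return (self.mean - t * se, self.mean + t * se)

    def as_frame(self, n_folds: int) -> pd.DataFrame:
        reps = np.arange(self.aucs.size) // n_folds
        folds = np.arange(self.aucs.size) % n_folds
        return pd.DataFrame(
            {"model": self.kind, "repeat": reps, "fold": folds, "auc": self.aucs}
        )


def compare_auc_distributions(a: AUCDistribution, b: AUCDistribution) -> float:
    """Two-sided Welch t-test p-value between two AUC distributions."""
    if a.aucs.size < 2 or b.aucs.size < 2:
        raise ValueError("need >= 2 AUCs per distribution")
    if np.array_equal(a.aucs, b.aucs) or (
        np.std(a.aucs) == 0 and np.std(b.aucs) == 0 and a.mean == b.mean
    ):
        return 1.0
    t, p = stats.ttest_ind(a.aucs, b.aucs, equal_var=False)
    return float(p)


# ---------------------------------------------------------------------------
# Per-fold pipeline and the repeated-CV protocol
# ---------------------------------------------------------------------------


def fit_pipeline_model(
    genotypes: GenotypeMatrix,
    outcomes: np.ndarray,
    family: str,
    snp_p_cutoff: float = 1e-3,
    n_pc: int = 2,
    forest_spec: ForestSpec | None = None,
    seed: int = 0,
    filtered_snp_ids: list[str] | None = None,
):
    """Fit one model family end to end on one training subset.

    Runs the univariate association filter (unless ``filtered_snp_ids`` is
    supplied — the leaky variant), restricts to the filtered SNPs, applies
    preconditioning where the family needs it, and fits the model.  If fewer
    than ``n_pc`` SNPs pass the filter, the ``n_pc`` most associated SNPs are
    used so the fit stays defined.
    """
    if family not in MODEL_FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    pheno = pd.DataFrame({"sample_id": genotypes.sample_ids, "outcome": outcomes})
    if filtered_snp_ids is None:
        assoc = association_table(
            genotypes, PhenotypeTable(pheno)
        )
        filtered = filter_snps_by_p(assoc, snp_p_cutoff)
        if len(filtered) < n_pc:
            fallback = assoc.sort_values(["p", "snp_id"], kind="mergesort")
            filtered = fallback["snp_id"].head(n_pc).tolist()
            logger.warning(
                "only %d SNP(s) passed p<%g; falling back to the %d most associated",
                len(filtered),
                snp_p_cutoff,
                n_pc,
            )
    else:
        filtered = list(filtered_snp_ids)
    sub = genotypes.subset_snps(filtered)
    spec = forest_spec or ForestSpec()
    spec = ForestSpec(spec.n_trees, spec.min_node_size, seed)
    if family == "prfr":
        spca = fit_supervised_pca(sub, outcomes, n_pc=n_pc)
        pre = precondition_outcomes(spca, sub, outcomes)
        return fit_prfr(sub, pre, spec)
    if family == "rf_classifier":
        return fit_rf_classifier(sub, outcomes, spec)
    if family == "lasso":
        return fit_lasso(sub, outcomes, seed=seed)
    spca = fit_supervised_pca(sub, outcomes, n_pc=n_pc)
    pre = precondition_outcomes(spca, sub, outcomes)
    return fit_preconditioned_lasso(sub, pre, seed=seed)


def repeated_cv_auc(
    genotypes_train: GenotypeMatrix,
    outcomes_train: np.ndarray,
    genotypes_valid: GenotypeMatrix,
    outcomes_valid: np.ndarray,
    family: str,
    n_repeats: int = 100,
    n_folds: int = 5,
    seed: int = 0,
    snp_p_cutoff: float = 1e-3,
    n_pc: int = 2,
    forest_spec: ForestSpec | None = None,
    eval_on: str = "validation",
    leak_filter: bool = False,
) -> AUCDistribution:
    """Repeated shuffled k-fold training with fixed hold-out scoring.

    Per repeat the training set is shuffled and partitioned into ``n_folds``
    folds; per fold the entire pipeline is refit on the fold's training
    portion (80% at 5 folds) and the fitted model scores either the fixed
    hold-out validation set (``eval_on="validation"``) or the out-of-fold
    samples (``eval_on="oof"``).  Defaults give n_repeats x n_folds = 500
    models/AUCs.

    ``leak_filter=True`` fits the association filter once on the full
    training set — a test fixture demonstrating feature-selection leakage,
    not an analysis option.
    """
    if eval_on not in ("validation", "oof"):
        raise ValueError("eval_on must be 'validation' or 'oof'")
    y_train = np.asarray(outcomes_train, dtype=int)
    y_valid = np.asarray(outcomes_valid, dtype=int)
    n = y_train.size
    leak_ids = None
    if leak_filter:
        pheno = pd.DataFrame(
            {"sample_id": genotypes_train.sample_ids, "outcome": y_train}
        )
        assoc = association_table(genotypes_train, PhenotypeTable(pheno))
        leak_ids = filter_snps_by_p(assoc, snp_p_cutoff)
        if len(leak_ids) < n_pc:
            leak_ids = (
                assoc.sort_values(["p", "snp_id"], kind="mergesort")["snp_id"]
                .head(n_pc)
                .tolist()
            )
    aucs: list[float] = []
    for rep in range(n_repeats):
        rng = np.random.default_rng([seed, rep])
        for _attempt in range(100):
            perm = rng.permutation(n)
            folds = np.array_split(perm, n_folds)
            ok = all(len(np.unique(y_train[np.setdiff1d(perm, f)])) == 2 for f in folds)
            if eval_on == "oof":
                ok = ok and all(len(np.unique(y_train[f])) == 2 for f in folds)
            if ok:
                break
            logger.info("repeat %d: single-class fold, reshuffling", rep)
        else:
            raise RuntimeError("could not draw folds with both classes present")
        for k, fold in enumerate(folds):
            train_idx = np.setdiff1d(perm, fold)
            sub = genotypes_train.subset_samples(
                [genotypes_train.sample_ids[i] for i in train_idx]
            )
            fold_seed = int(
                np.random.default_rng([seed, rep, k]).integers(0, 2**31 - 1)
            )
            model = fit_pipeline_model(
                sub,
                y_train[train_idx],
                family,
                snp_p_cutoff=snp_p_cutoff,
                n_pc=n_pc,
                forest_spec=forest_spec,
                seed=fold_seed,
                filtered_snp_ids=leak_ids,
            )
            if eval_on == "validation":
                scores = model.predict(genotypes_valid)
                aucs.append(auc(scores, y_valid))
            else:
                oof = genotypes_train.subset_samples(
                    [genotypes_train.sample_ids[i] for i in fold]
                )
                scores = model.predict(oof)
                aucs.append(auc(scores, y_train[fold]))
    return AUCDistribution(kind=family, aucs=np.array(aucs))


# ---------------------------------------------------------------------------
# Ancestry-PC baseline
# ---------------------------------------------------------------------------


def ancestry_pc_baseline(
    genotypes_train: GenotypeMatrix,
    outcomes_train: np.ndarray,
    genotypes_valid: GenotypeMatrix,
    outcomes_valid: np.ndarray,
    n_pc: int = 3,
) -> tuple[dict, float]:
    """Logistic model on the first ``n_pc`` unsupervised (ancestry) PCs.

    PCA runs on all QC-passing SNPs of the training set (standardized
    dosages); the model is a plain logistic regression of case status on the
    PC scores, scored on the validation set.  Returns the coefficient record
    and the validation AUC — the dotted-line baseline of the model-comparison
    figure.
    """
    from sklearn.linear_model import LogisticRegression

    if genotypes_train.n_snps < n_pc:
        raise ValueError(f"need >= {n_pc} SNPs for the ancestry baseline")
    y = np.asarray(outcomes_train, dtype=int)
    X = genotypes_train.dosages
    if np.isnan(X).any():
        raise ValueError("genotypes contain missing dosages; impute first")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    sds[sds == 0] = 1.0
    Z = (X - means) / sds
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt[:n_pc].T.copy()
    for k in range(n_pc):
        col = loadings[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, k] = -col
    clf = LogisticRegression(max_iter=10_000)
    clf.fit(Z @ loadings, y)
    Xv = genotypes_valid.subset_snps(genotypes_train.snp_ids).dosages
    Zv = (Xv - means) / sds
    scores = clf.predict_proba(Zv @ loadings)[:, 1]
    model = {
        "n_pc": n_pc,
        "intercept": float(clf.intercept_[0]),
        "coefficients": [float(c) for c in clf.coef_[0]],
    }
    return model, auc(scores, np.asarray(outcomes_valid, dtype=int))
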