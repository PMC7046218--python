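"""Model fitting: the preconditioned random forest regressor (PRFR), its
out-of-bag permutation variable importance, and the comparator families
(conventional RF classification, LASSO logistic, preconditioned LASSO).

The forest is an ensemble of CART trees (scikit-learn base trees) grown on
explicit bootstrap samples drawn here, so that each tree's out-of-bag (OOB)
membership is retained for the permutation importance computation.  Default
hyperparameters: 1000 trees, minimum terminal-leaf size 5, and
mtry = floor(sqrt(n_features)) candidate features per split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV, LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .io_formats import GenotypeMatrix


@dataclass
class ForestSpec:
    n_trees: int = 1000
    min_node_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")

    @staticmethod
    def mtry(n_features: int) -> int:
        return max(1, math.floor(math.sqrt(n_features)))


@dataclass
class FittedForest:
    """A fitted forest plus everything needed to score and to compute VIM."""

    kind: str  # "prfr" or "rf_classifier"
    snp_ids: list[str]
    trees: list = field(repr=False, default_factory=list)
    bootstrap_indices: list[np.ndarray] = field(repr=False, default_factory=list)
    oob_masks: list[np.ndarray] = field(repr=False, default_factory=list)
    training_X: np.ndarray = field(repr=False, default=None)
    training_y: np.ndarray = field(repr=False, default=None)
    spec: ForestSpec = field(default_factory=ForestSpec)

    def predict(self, genotypes: GenotypeMatrix) -> np.ndarray:
        """Continuous risk score: mean tree prediction (regression) or mean
        case probability (classification).  No thresholding."""
        X = _feature_matrix(genotypes, self.snp_ids)
        return self._predict_matrix(X)

    def _predict_matrix(self, X: np.ndarray) -> np.ndarray:
        total = np.zeros(X.shape[0])
        for tree in self.trees:
            total += _tree_score(tree, X, self.kind)
        return total / len(self.trees)


def _feature_matrix(genotypes: GenotypeMatrix, snp_ids: list[str]) -> np.ndarray:
    missing = [s for s in snp_ids if s not in set(genotypes.snp_ids)]
    if missing:
        raise KeyError(f"genotypes lack model feature SNPs: {missing[:5]}")
    X = genotypes.subset_snps(snp_ids).dosages
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing dosages; impute first")
    return X


def _tree_score(tree, X: np.ndarray, kind: str) -> np.ndarray:
    if kind == "rf_classifier":
        proba = tree.predict_proba(X)
        case_col = np.flatnonzero(tree.classes_ == 1)
        return proba[:, case_col[0]] if case_col.size else np.zeros(X.shape[0])
    return tree.predict(X)


def _fit_forest(
    X: np.ndarray, y: np.ndarray, spec: ForestSpec, kind: str, snp_ids: list[str]
) -> FittedForest:
    n = X.shape[0]
    rng = np.random.default_rng(spec.seed)
    mtry = ForestSpec.mtry(X.shape[1])
    trees, boots, oobs = [], [], []
    tree_cls = DecisionTreeClassifier if kind == "rf_classifier" else DecisionTreeRegressor
    for _ in range(spec.n_trees):
        idx = rng.integers(0, n, size=n)  # bootstrap of size n, with replacement
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        tree = tree_cls(
            max_features=mtry,
            min_samples_leaf=spec.min_node_size,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
        boots.append(idx)
        oobs.append(oob)
    return FittedForest(
        kind=kind,
        snp_ids=list(snp_ids),
        trees=trees,
        bootstrap_indices=boots,
        oob_masks=oobs,
        training_X=X,
        training_y=np.asarray(y, dtype=float),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# PRFR and the conventional RF classifier
# ---------------------------------------------------------------------------


def fit_prfr(
    genotypes: GenotypeMatrix,
    preconditioned: dict[str, float],
    spec: ForestSpec | None = None,
) -> FittedForest:
    """Regression forest on the continuous preconditioned outcomes.

    Each tree is grown on a bootstrap sample; a tree's prediction for a new
    sample is the mean preconditioned outcome in the terminal leaf it reaches,
    and the forest prediction is the average over trees.
    """
    spec = spec or ForestSpec()
    if genotypes.n_snps == 0:
        raise ValueError("no feature SNPs")
    y = np.array([preconditioned[s] for s in genotypes.sample_ids], dtype=float)
    if ((y < 0) | (y > 1)).any():
        raise ValueError("preconditioned outcomes must lie in [0,1]")
    X = _feature_matrix(genotypes, genotypes.snp_ids)
    return _fit_forest(X, y, spec, "prfr", genotypes.snp_ids)


def fit_rf_classifier(
    genotypes: GenotypeMatrix, outcomes: np.ndarray, spec: ForestSpec | None = None
) -> FittedForest:
    """Classification forest on the raw binary outcomes; the score is the
    mean per-tree case probability."""
    spec = spec or ForestSpec()
    y = np.asarray(outcomes, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training outcomes are single-class")
    X = _feature_matrix(genotypes, genotypes.snp_ids)
    return _fit_forest(X, y, spec, "rf_classifier", genotypes.snp_ids)


# ---------------------------------------------------------------------------
# Permutation variable importance (OOB)
# ---------------------------------------------------------------------------


def compute_vim(model: FittedForest, seed: int = 0) -> pd.DataFrame:
    """Out-of-bag permutation importance for every feature of a PRFR model.

    Per tree and feature: shuffle the feature's values across that tree's OOB
    samples (others fixed), and take the increase in OOB mean squared error
    over the unshuffled baseline.  The VIM is the raw mean increase over
    trees (unscaled); ranks descend by VIM with ties broken by snp_id.

    Returns a DataFrame (snp_id, vim, rank) sorted by rank.
    """
    if model.kind != "prfr":
        raise ValueError("VIM is defined for the PRFR regression forest")
    X, y = model.training_X, model.training_y
    p = X.shape[1]
    rng = np.random.default_rng(seed)
    totals = np.zeros(p)
    counts = np.zeros(p, dtype=int)
    for tree, oob in zip(model.trees, model.oob_masks):
        if not oob.any():
            continue
        Xo = X[oob]
        yo = y[oob]
        base_mse = float(np.mean((tree.predict(Xo) - yo) ** 2))
        for j in range(p):
            perm = rng.permutation(Xo.shape[0])
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            mse = float(np.mean((tree.predict(Xp) - yo) ** 2))
            totals[j] += mse - base_mse
            counts[j] += 1
    if (counts == 0).any():
        raise ValueError("a feature had no tree with OOB samples; VIM undefined")
    vim = totals / counts
    df = pd.DataFrame({"snp_id": model.snp_ids, "vim": vim})
    df = df.sort_values(["vim", "snp_id"], ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, p + 1)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# LASSO comparators
# ---------------------------------------------------------------------------


@dataclass
class LassoResult:
    shrinkage: float
    nonzero_coefficients: dict[str, float]
    kind: str


@dataclass
class FittedLinear:
    """Intercept + sparse linear scores from a LASSO-family fit."""

    kind: str  # "lasso" or "preconditioned_lasso"
    snp_ids: list[str]
    intercept: float
    coefficients: np.ndarray
    link: str  # "logit" or "identity"
    result: LassoResult | None = None

    def predict(self, genotypes: GenotypeMatrix) -> np.ndarray:
        X = _feature_matrix(genotypes, self.snp_ids)
        eta = self.intercept + X @ self.coefficients
        if self.link == "logit":
            return 1.0 / (1.0 + np.exp(-eta))
        return eta


def fit_lasso(
    genotypes: GenotypeMatrix,
    outcomes: np.ndarray,
    n_cv_folds: int = 5,
    seed: int = 0,
) -> FittedLinear:
    """L1-penalized logistic regression with the penalty chosen at minimum
    cross-validated deviance (log loss)."""
    y = np.asarray(outcomes, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes required")
    X = _feature_matrix(genotypes, genotypes.snp_ids)
    keep = X.std(axis=0) > 0
    if not keep.all():
        import logging

        logging.getLogger("prfr").warning(
            "dropping %d constant feature(s) before LASSO", int((~keep).sum())
        )
    snp_ids = [s for s, k in zip(genotypes.snp_ids, keep) if k]
    Xk = X[:, keep]
    n_cv_folds = min(n_cv_folds, int(np.bincount(y).min()))
    if n_cv_folds >= 2:
        from sklearn.linear_model import LogisticRegressionCV

        cv = StratifiedKFold(n_splits=n_cv_folds, shuffle=True, random_state=seed)
        clf = LogisticRegressionCV(
            l1_ratios=[1.0],
            solver="liblinear",
            Cs=20,
            cv=cv,
            scoring="neg_log_loss",
            max_iter=5000,
            random_state=seed,
            use_legacy_attributes=False,
        )
        clf.fit(Xk, y)
        c_chosen = float(np.atleast_1d(clf.C_)[0])
    else:  # too few per-class samples for CV: fall back to a fixed penalty
        clf = LogisticRegression(
            l1_ratio=1, solver="liblinear", C=1.0, max_iter=5000, random_state=seed
        )
        clf.fit(Xk, y)
        c_chosen = 1.0
    coefs = clf.coef_[0]
    nonzero = {s: float(c) for s, c in zip(snp_ids, coefs) if c != 0.0}
    full = np.zeros(len(genotypes.snp_ids))
    full[np.flatnonzero(keep)] = coefs
    return FittedLinear(
        kind="lasso",
        snp_ids=list(genotypes.snp_ids),
        intercept=float(clf.intercept_[0]),
        coefficients=full,
        link="logit",
        # report shrinkage on the penalty scale (inverse of sklearn's C)
        result=LassoResult(1.0 / c_chosen, nonzero, "lasso"),
    )


def fit_preconditioned_lasso(
    genotypes: GenotypeMatrix,
    preconditioned: dict[str, float],
    n_cv_folds: int = 5,
    seed: int = 0,
) -> FittedLinear:
    """L1-penalized least squares on the continuous preconditioned outcomes."""
    y = np.array([preconditioned[s] for s in genotypes.sample_ids], dtype=float)
    X = _feature_matrix(genotypes, genotypes.snp_ids)
    keep = X.std(axis=0) > 0
    snp_ids = [s for s, k in zip(genotypes.snp_ids, keep) if k]
    Xk = X[:, keep]
    if np.allclose(y, y[0]) or not snp_ids:
        return FittedLinear(
            kind="preconditioned_lasso",
            snp_ids=list(genotypes.snp_ids),
            intercept=float(y.mean()),
            coefficients=np.zeros(len(genotypes.snp_ids)),
            link="identity",
            result=LassoResult(float("inf"), {}, "preconditioned_lasso"),
        )
    reg = LassoCV(alphas=50, cv=min(n_cv_folds, len(y)), random_state=seed, tol=1e-6)
    reg.fit(Xk, y)
    coefs = reg.coef_
    nonzero = {s: float(c) for s, c in zip(snp_ids, coefs) if c != 0.0}
    full = np.zeros(len(genotypes.snp_ids))
    full[np.flatnonzero(keep)] = coefs
    return FittedLinear(
        kind="preconditioned_lasso",
        snp_ids=list(genotypes.snp_ids),
        intercept=float(reg.intercept_),
        coefficients=full,
        link="identity",
        result=LassoResult(float(reg.alpha_), nonzero, "preconditioned_lasso"),
    )


def lasso_selection_frequency(
    genotypes: GenotypeMatrix,
    outcomes: np.ndarray,
    n_iterations: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Fraction of resampled LASSO refits in which each SNP gets a nonzero
    coefficient.

    Each iteration refits the LASSO on a random 80% (4/5) subset of the
    training samples — the same shuffled 5-fold scheme the evaluation module
    uses, taking one fold's training portion per iteration.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    y = np.asarray(outcomes, dtype=int)
    n = len(y)
    rng = np.random.default_rng(seed)
    counts = pd.Series(0.0, index=genotypes.snp_ids)
    done = 0
    while done < n_iterations:
        perm = rng.permutation(n)
        folds = np.array_split(perm, 5)
        for fold in folds:
            if done >= n_iterations:
                break
            train_idx = np.setdiff1d(perm, fold)
            if len(np.unique(y[train_idx])) < 2:
                continue
            sub = genotypes.subset_samples(
                [genotypes.sample_ids[i] for i in train_idx]
            )
            fit = fit_lasso(sub, y[train_idx], seed=int(rng.integers(0, 2**31 - 1)))
            for s in fit.result.nonzero_coefficients:
                counts[s] += 1
            done += 1
    freq = (counts / n_iterations).rename("frequency")
    df = freq.reset_index().rename(columns={"index": "snp_id"})
    df = df.sort_values(
        ["frequency", "snp_id"], ascending=[False, True], kind="mergesort"
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)
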