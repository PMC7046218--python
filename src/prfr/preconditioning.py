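"""Supervised-PCA preconditioning of binary outcomes.

The preconditioning step replaces binary training labels with continuous
fitted probabilities so that a regression forest can learn a smooth target:
(1) restrict the genotype matrix to the association-filtered SNPs, (2)
center and scale each dosage column to unit variance, (3) take the first
``n_pc`` principal components (right singular vectors), (4) fit a logistic
regression of the binary outcomes on the component scores with a small ridge
penalty, and (5) emit the fitted probabilities — the preconditioned outcomes
— for the training samples only.  Validation outcomes stay binary.

PC signs are fixed by making the largest-magnitude loading entry positive,
so the whole pipeline is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .io_formats import GenotypeMatrix


@dataclass
class SupervisedPCAModel:
    """Frozen state of a fitted preconditioning transform."""

    snp_ids: list[str]
    means: np.ndarray  # per-SNP centering means
    sds: np.ndarray  # per-SNP scaling SDs (>0)
    loadings: np.ndarray  # n_snps x n_pc, orthonormal columns
    intercept: float
    coefficients: np.ndarray  # length n_pc
    training_sample_ids: list[str]

    @property
    def n_pc(self) -> int:
        return self.loadings.shape[1]


def _standardize(X: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    return (X - means) / sds


def fit_supervised_pca(
    genotypes: GenotypeMatrix,
    outcomes: np.ndarray,
    n_pc: int = 2,
    ridge_penalty: float = 1e-6,
) -> SupervisedPCAModel:
    """Fit the sPCA + penalized-logistic preconditioning model.

    ``genotypes`` must already be restricted to the association-filtered SNPs
    and be complete (no missing dosages).  Both outcome classes must be
    present.  The ridge penalty keeps the logistic fit finite under
    quasi-separation, which n_pc=2 fits on small samples can produce.
    """
    X = genotypes.dosages
    y = np.asarray(outcomes, dtype=int)
    if X.shape[0] != y.size:
        raise ValueError("outcome length does not match genotype rows")
    if np.isnan(X).any():
        raise ValueError("genotypes contain missing dosages; impute first")
    if X.shape[1] < n_pc:
        raise ValueError(f"need at least n_pc={n_pc} SNPs, got {X.shape[1]}")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    if (sds == 0).any():
        bad = genotypes.snp_ids[int(np.argmax(sds == 0))]
        raise ValueError(f"zero-variance SNP column {bad!r} (run QC first)")
    Z = _standardize(X, means, sds)
    # right singular vectors = PC loadings
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt[:n_pc].T.copy()
    # deterministic sign: largest-magnitude entry of each loading positive
    for k in range(n_pc):
        col = loadings[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, k] = -col
    scores = Z @ loadings
    # sklearn's C is the inverse of the L2 penalty weight
    clf = LogisticRegression(
        l1_ratio=0, C=1.0 / ridge_penalty, solver="lbfgs", max_iter=50_000, tol=1e-12
    )
    clf.fit(scores, y)
    return SupervisedPCAModel(
        snp_ids=list(genotypes.snp_ids),
        means=means,
        sds=sds,
        loadings=loadings,
        intercept=float(clf.intercept_[0]),
        coefficients=clf.coef_[0].copy(),
        training_sample_ids=list(genotypes.sample_ids),
    )


def project_pcs(model: SupervisedPCAModel, genotypes: GenotypeMatrix) -> np.ndarray:
    """Project samples onto the stored PC loadings (n_samples x n_pc)."""
    missing = [s for s in model.snp_ids if s not in set(genotypes.snp_ids)]
    if missing:
        raise KeyError(f"genotypes lack model SNPs: {missing[:5]}")
    X = genotypes.subset_snps(model.snp_ids).dosages
    if np.isnan(X).any():
        raise ValueError("genotypes contain missing dosages; impute first")
    return _standardize(X, model.means, model.sds) @ model.loadings


def precondition_outcomes(
    model: SupervisedPCAModel,
    genotypes: GenotypeMatrix,
    outcomes: np.ndarray,
) -> dict[str, float]:
    """Fitted logistic probabilities for the training samples.

    The sample set must equal the one the model was fitted on — the transform
    is defined for training outcomes only.
    """
    if list(genotypes.sample_ids) != model.training_sample_ids:
        raise ValueError(
            "precondition_outcomes must be called with the samples the model "
            "was fitted on (validation outcomes stay binary)"
        )
    y = np.asarray(outcomes, dtype=int)
    if y.size != len(model.training_sample_ids):
        raise ValueError("outcome length mismatch")
    scores = project_pcs(model, genotypes)
    eta = model.intercept + scores @ model.coefficients
    prob = 1.0 / (1.0 + np.exp(-eta))
    return dict(zip(genotypes.sample_ids, prob.astype(float)))
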