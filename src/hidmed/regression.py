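"""Step 1: mediation regressions.

Per-SNP effects on each known mediator (a*) come from an OLS fit of that
mediator on all SNPs jointly (plus covariates and any declared parent
mediators); direct SNP effects on the outcome (c*) come from an OLS fit of
the outcome on all SNPs, all known mediators and covariates.  SNPs are
first sign-oriented so every SNP has a non-negative marginal effect on the
outcome, and SNPs with outlying estimated effects (beyond k x IQR fences)
are removed jointly from all downstream vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .exceptions import RankDeficiencyError
from .simulate import GenotypeMatrix


@dataclass
class EffectVector:
    """A per-SNP vector of (estimated or true) effects."""

    values: np.ndarray
    snp_ids: list[str]
    role: str = "a_star"
    standard_errors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.snp_ids):
            raise ValueError("values and snp_ids must be aligned")

    def restrict(self, idx: np.ndarray) -> "EffectVector":
        se = None if self.standard_errors is None else self.standard_errors[idx]
        return EffectVector(self.values[idx],
                            [self.snp_ids[i] for i in idx],
                            self.role, se)


@dataclass
class RegressionResult:
    """All Step-1 outputs: per-mediator a* vectors, c*, the mediator and
    covariate coefficients of the outcome fit, the kept-SNP index set after
    outlier filtering and the orientation signs applied."""

    a_star: list[EffectVector]
    c_star: EffectVector
    mediator_coefficients: np.ndarray
    covariate_coefficients: np.ndarray
    kept_snps: np.ndarray
    sign_flips: np.ndarray

    @property
    def a_star_joint(self) -> np.ndarray:
        """Concatenated a* over kept SNPs (the Step-2 input)."""
        return np.concatenate([v.values[self.kept_snps] for v in self.a_star])

    @property
    def c_star_kept(self) -> EffectVector:
        return self.c_star.restrict(self.kept_snps)

    def effects_frame(self) -> pd.DataFrame:
        rows = []
        for k, vec in enumerate(self.a_star):
            for j, sid in enumerate(vec.snp_ids):
                rows.append((sid, f"a_star_{k + 1}", vec.values[j],
                             vec.standard_errors[j]))
        for j, sid in enumerate(self.c_star.snp_ids):
            rows.append((sid, "c_star", self.c_star.values[j],
                         self.c_star.standard_errors[j]))
        return pd.DataFrame(rows, columns=["snp_id", "role", "estimate", "se"])


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS via Cholesky-factored normal equations.

    ``y`` may be (n,) or (n, q) for multi-response fits with a shared design.
    Returns (coef, se) of matching shape.  Raises RankDeficiencyError when
    X'X is singular (e.g. more predictors than samples).
    """
    X = np.asarray(X, dtype=float)
    y1 = np.asarray(y, dtype=float)
    n, k = X.shape
    if k >= n:
        raise RankDeficiencyError(
            f"design has {k} columns but only {n} rows; cannot fit OLS")
    xtx = X.T @ X
    try:
        cf = linalg.cho_factor(xtx)
    except linalg.LinAlgError as exc:
        raise RankDeficiencyError(
            f"singular design ({n} rows x {k} columns)") from exc
    coef = linalg.cho_solve(cf, X.T @ y1)
    resid = y1 - X @ coef
    dof = n - k
    if y1.ndim == 1:
        sigma2 = resid @ resid / dof
    else:
        sigma2 = (resid * resid).sum(axis=0) / dof
    xtx_inv_diag = np.diag(linalg.cho_solve(cf, np.eye(k)))
    se = np.sqrt(np.multiply.outer(xtx_inv_diag, sigma2)) if y1.ndim > 1 \
        else np.sqrt(xtx_inv_diag * sigma2)
    return coef, se


def _design(G: np.ndarray, *blocks: np.ndarray | None) -> np.ndarray:
    cols = [np.ones((G.shape[0], 1)), G]
    for b in blocks:
        if b is not None and b.size:
            cols.append(b if b.ndim == 2 else b[:, None])
    return np.hstack(cols)


def _as_array(x) -> np.ndarray | None:
    if x is None:
        return None
    a = np.asarray(x, dtype=float)
    return a


def orient_snps(G: GenotypeMatrix, Y: np.ndarray,
                covariates=None) -> GenotypeMatrix:
    """Recode SNPs so every SNP has a non-negative effect on the outcome.

    Fits one multiple regression of Y on all SNPs (+ covariates); columns
    with negative coefficients are recoded dosage -> 2 - dosage and their
    sign recorded, so a refit yields all non-negative SNP coefficients.
    """
    Gd = G.dosages.astype(float)
    X = _design(Gd, _as_array(covariates))
    coef, _ = _ols(X, np.asarray(Y, dtype=float))
    snp_coef = coef[1:1 + G.p]
    flips = snp_coef < 0
    signs = np.where(flips, -1, 1)
    dosages = G.dosages.copy()
    dosages[:, flips] = 2 - dosages[:, flips]
    return GenotypeMatrix(dosages=dosages, snp_ids=list(G.snp_ids),
                          mafs=None if G.mafs is None else G.mafs.copy(),
                          signs=G.signs * signs)


def estimate_mediator_effects(G: GenotypeMatrix, M_k: np.ndarray,
                              mediator_parents=None, covariates=None,
                              role: str = "a_star") -> EffectVector:
    """Per-SNP effects on one mediator: OLS of M_k on all SNPs jointly,
    plus covariates and declared parent mediators (the adjustment needed
    when some known mediators cause others)."""
    Gd = G.dosages.astype(float)
    X = _design(Gd, _as_array(covariates), _as_array(mediator_parents))
    coef, se = _ols(X, np.asarray(M_k, dtype=float))
    return EffectVector(coef[1:1 + G.p], list(G.snp_ids), role,
                        se[1:1 + G.p])


def estimate_direct_effects(G: GenotypeMatrix, M, covariates,
                            Y: np.ndarray):
    """Direct SNP effects on the outcome: OLS of Y on SNPs + mediators +
    covariates.  Returns (c_star, mediator_coefficients,
    covariate_coefficients)."""
    Gd = G.dosages.astype(float)
    Ma = _as_array(M)
    Ca = _as_array(covariates)
    X = _design(Gd, Ma, Ca)
    coef, se = _ols(X, np.asarray(Y, dtype=float))
    c_star = EffectVector(coef[1:1 + G.p], list(G.snp_ids), "c_star",
                          se[1:1 + G.p])
    k_med = 0 if Ma is None else (Ma.shape[1] if Ma.ndim == 2 else 1)
    med_coef = coef[1 + G.p:1 + G.p + k_med]
    cov_coef = coef[1 + G.p + k_med:]
    return c_star, med_coef, cov_coef


def filter_outlier_snps(vectors, k: float = 3.0, joint: bool = True):
    """IQR outlier filter across effect vectors.

    For each vector, entries outside [Q1 - k*IQR, Q3 + k*IQR] are flagged
    (linear-interpolation quartiles).  With ``joint`` (the default) a SNP
    flagged in any vector is removed from all and the shared kept index set
    is returned; otherwise one kept index set per vector is returned.
    """
    arrays = [v.values if isinstance(v, EffectVector) else np.asarray(v, float)
              for v in vectors]
    if not arrays or any(a.size == 0 for a in arrays):
        raise ValueError("filter_outlier_snps requires non-empty vectors")
    p = len(arrays[0])
    if any(len(a) != p for a in arrays):
        raise ValueError("all vectors must have the same length")
    flags = []
    for a in arrays:
        q1, q3 = np.percentile(a, [25, 75])
        iqr = q3 - q1
        flags.append((a > q3 + k * iqr) | (a < q1 - k * iqr))
    if not joint:
        return [np.flatnonzero(~f) for f in flags]
    return np.flatnonzero(~np.logical_or.reduce(flags))


def run_step1(G: GenotypeMatrix, mediators, covariates, Y,
              mediator_parent_idx: dict[int, list[int]] | None = None,
              outlier_k: float = 3.0, orient: bool = True,
              covariates_in_mediator_fits: bool = True) -> RegressionResult:
    """The complete Step 1: orientation, mediator fits, outcome fit and the
    joint outlier filter.

    ``mediator_parent_idx`` maps mediator column index -> list of parent
    mediator column indices to adjust for in that mediator's regression.
    Mediators with the same design are fitted together (shared factorization).
    """
    Ma = np.asarray(mediators, dtype=float)
    if Ma.ndim == 1:
        Ma = Ma[:, None]
    Ca = _as_array(covariates)
    Ya = np.asarray(Y, dtype=float)
    if orient:
        G = orient_snps(G, Ya, Ca)
    Gd = G.dosages.astype(float)
    K = Ma.shape[1]
    parents = mediator_parent_idx or {}
    med_cov = Ca if covariates_in_mediator_fits else None

    a_star: list[EffectVector | None] = [None] * K
    groups: dict[tuple[int, ...], list[int]] = {}
    for k in range(K):
        groups.setdefault(tuple(sorted(parents.get(k, []))), []).append(k)
    for parent_key, ks in groups.items():
        pa = Ma[:, list(parent_key)] if parent_key else None
        X = _design(Gd, med_cov, pa)
        coef, se = _ols(X, Ma[:, ks])
        for col, k in enumerate(ks):
            a_star[k] = EffectVector(coef[1:1 + G.p, col], list(G.snp_ids),
                                     f"a_star_{k + 1}", se[1:1 + G.p, col])

    c_star, med_coef, cov_coef = estimate_direct_effects(G, Ma, Ca, Ya)
    kept = filter_outlier_snps([*a_star, c_star], k=outlier_k)
    return RegressionResult(a_star=a_star, c_star=c_star,
                            mediator_coefficients=med_coef,
                            covariate_coefficients=cov_coef,
                            kept_snps=kept, sign_flips=G.signs)
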