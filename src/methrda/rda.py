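"""Redundancy analysis (RDA) of a region's M-values on a design matrix.

RDA is constrained ordination: a multivariate multiple regression of the
(column-centered) outcome matrix Y on the predictors X, followed by a PCA
of the fitted values.  The constrained axes are the RDA components.  Two
statistics summarize the association:

* **R2** — the fraction of total centered outcome variance captured by
  the fitted (constrained) matrix, ``ss_fitted / ss_total``.
* **pseudo-F** — the ratio of constrained to residual mean squares,
  ``(ss_fitted / m) / (ss_residual / (n - m - q - 1))``, used as the
  statistic of the sample-permutation test.

When conditioning covariates are present both Y and X are residualized on
them first (partial RDA).  By default R2 keeps the *total* centered
variance in the denominator, so conditioning can only shrink R2; the
post-conditioning denominator is available via ``r2_denominator``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import DesignMatrix
from .exceptions import (
    FormatError,
    InsufficientSamplesError,
    ParameterError,
    RankError,
)

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-10


@dataclass
class RDAFit:
    """Result of one RDA fit (one region x one design)."""

    r2: float
    ss_total: float
    ss_fitted: float
    ss_residual: float
    ss_conditioned: float
    sample_scores: np.ndarray  # n x c
    cpg_loadings: np.ndarray  # k x c
    eigenvalues: np.ndarray  # c
    m: int
    n: int
    k: int
    q: int = 0
    probe_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def _center_scale(y_samples_by_cpgs: np.ndarray, scale: bool) -> np.ndarray:
    yc = y_samples_by_cpgs - y_samples_by_cpgs.mean(axis=0, keepdims=True)
    if scale:
        sd = yc.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            raise FormatError("cannot scale: at least one CpG is constant")
        yc = yc / sd
    return yc


def _orthonormal_basis(x: np.ndarray, what: str) -> np.ndarray:
    """QR basis of a full-column-rank matrix; raises RankError otherwise."""
    if x.shape[1] == 0:
        return np.empty((x.shape[0], 0))
    qmat, rmat = np.linalg.qr(x)
    diag = np.abs(np.diag(rmat))
    if diag.min() < _RANK_TOL * max(diag.max(), 1.0):
        raise RankError(f"{what} is rank deficient")
    return qmat


def _decompose(
    y_cpgs_by_samples: np.ndarray,
    x: DesignMatrix,
    scale: bool,
) -> dict:
    """Shared regression/decomposition step used by fit and permutation."""
    y = np.asarray(y_cpgs_by_samples, dtype=float).T  # n x k
    if not np.isfinite(y).all():
        raise FormatError("outcome matrix contains non-finite values")
    n, k = y.shape
    m, q = x.m, x.q
    if x.n_samples != n:
        raise FormatError(
            f"design has {x.n_samples} samples but outcome has {n}"
        )
    if n < m + q + 2:
        raise InsufficientSamplesError(
            f"n={n} samples cannot support m={m} predictors + q={q} covariates"
        )
    yc = _center_scale(y, scale)
    xc = x.values - x.values.mean(axis=0, keepdims=True)
    ss_grand = float(np.sum(yc * yc))
    if q:
        zc = x.conditioning - x.conditioning.mean(axis=0, keepdims=True)
        qz = _orthonormal_basis(zc, "conditioning block")
        yr = yc - qz @ (qz.T @ yc)
        xr = xc - qz @ (qz.T @ xc)
    else:
        yr, xr = yc, xc
    ss_conditioned = max(ss_grand - float(np.sum(yr * yr)), 0.0)
    qx = _orthonormal_basis(xr, "design matrix")
    if m:
        fitted = qx @ (qx.T @ yr)
    else:
        fitted = np.zeros_like(yr)
    ss_fitted = float(np.sum(fitted * fitted))
    resid = yr - fitted
    ss_residual = float(np.sum(resid * resid))
    return {
        "yc": yc,
        "yr": yr,
        "qx": qx,
        "fitted": fitted,
        "n": n,
        "k": k,
        "m": m,
        "q": q,
        "ss_total": ss_grand,
        "ss_conditioned": ss_conditioned,
        "ss_fitted": ss_fitted,
        "ss_residual": ss_residual,
    }


def fit_rda(
    y,
    x: DesignMatrix,
    *,
    scale: bool = False,
    r2_denominator: str = "total",
) -> RDAFit:
    """Fit RDA of a region's M-values (k CpGs x n samples) on a design.

    Parameters
    ----------
    y
        Region M-value submatrix, CpGs x samples (DataFrame or array).
    x
        Centered design matrix, optionally with a conditioning block.
    scale
        Scale each CpG to unit variance before fitting (correlation-based
        RDA).  Default is centering only (covariance-based).
    r2_denominator
        ``"total"`` (default): R2 = ss_fitted / total centered variance,
        so conditioned-out variance counts in the denominator.
        ``"conditioned"``: R2 = ss_fitted / (ss_fitted + ss_residual).
    """
    if r2_denominator not in ("total", "conditioned"):
        raise ParameterError(f"unknown r2_denominator {r2_denominator!r}")
    probe_ids: list[str] = []
    sample_ids: list[str] = []
    if isinstance(y, pd.DataFrame):
        probe_ids = list(map(str, y.index))
        sample_ids = list(map(str, y.columns))
        y = y.to_numpy()
    parts = _decompose(y, x, scale)
    n, k, m, q = parts["n"], parts["k"], parts["m"], parts["q"]
    denom = (
        parts["ss_total"]
        if r2_denominator == "total"
        else parts["ss_fitted"] + parts["ss_residual"]
    )
    r2 = parts["ss_fitted"] / denom if denom > 0 else 0.0

    c = min(m, k, n - 1)
    if c:
        u, s, vt = np.linalg.svd(parts["fitted"], full_matrices=False)
        u, s, vt = u[:, :c], s[:c], vt[:c]
        # reproducible sign: largest-|loading| entry of each component positive
        for j in range(c):
            idx = np.argmax(np.abs(vt[j]))
            if vt[j, idx] < 0:
                vt[j] *= -1.0
                u[:, j] *= -1.0
        sample_scores = u * s
        cpg_loadings = vt.T
        eigenvalues = s**2 / (n - 1)
    else:
        sample_scores = np.empty((n, 0))
        cpg_loadings = np.empty((k, 0))
        eigenvalues = np.empty(0)

    return RDAFit(
        r2=float(r2),
        ss_total=parts["ss_total"],
        ss_fitted=parts["ss_fitted"],
        ss_residual=parts["ss_residual"],
        ss_conditioned=parts["ss_conditioned"],
        sample_scores=sample_scores,
        cpg_loadings=cpg_loadings,
        eigenvalues=eigenvalues,
        m=m,
        n=n,
        k=k,
        q=q,
        probe_ids=probe_ids,
        sample_ids=sample_ids,
    )


def pseudo_f(fit: RDAFit) -> float:
    """Pseudo-F statistic: constrained vs residual mean square."""
    if fit.m < 1:
        raise ParameterError("pseudo-F requires at least one predictor")
    df_resid = fit.n - fit.m - fit.q - 1
    if df_resid < 1:
        raise InsufficientSamplesError("no residual degrees of freedom")
    if fit.ss_residual <= 0:
        warnings.warn("zero residual sum of squares; pseudo-F is infinite")
        return float("inf")
    return (fit.ss_fitted / fit.m) / (fit.ss_residual / df_resid)


@dataclass
class PermutationResult:
    """Sample-permutation test of the RDA pseudo-F."""

    f_obs: float
    f_null: np.ndarray
    p_value: float
    b: int
    seed: int

    @property
    def min_attainable_p(self) -> float:
        return 1.0 / (self.b + 1)


def _permute_design(x: DesignMatrix, order: np.ndarray) -> DesignMatrix:
    return DesignMatrix(
        values=x.values[order],
        column_names=x.column_names,
        sample_ids=x.sample_ids,
        conditioning=x.conditioning,
        conditioning_names=x.conditioning_names,
    )


def permutation_test(
    y,
    x: DesignMatrix,
    b: int = 10_000,
    seed: int = 0,
    *,
    scale: bool = False,
) -> PermutationResult:
    """Permutation test of the region-design association.

    Samples are treated as freely exchangeable: the predictor rows are
    permuted jointly (all predictor columns together) while the outcome
    and any conditioning covariates stay attached to their samples; the
    pseudo-F is recomputed for each of ``b`` permutations.  The p-value
    uses the add-one formula ``(1 + #{F_perm >= F_obs}) / (b + 1)``, so
    the smallest attainable p is ``1/(b+1)``.
    """
    if b < 1:
        raise ParameterError(f"permutation count must be >= 1, got {b}")
    if isinstance(y, pd.DataFrame):
        y = y.to_numpy()
    y = np.asarray(y, dtype=float)
    parts = _decompose(y, x, scale)
    n, m, q = parts["n"], parts["m"], parts["q"]
    if m < 1:
        raise ParameterError("permutation test requires at least one predictor")
    df_resid = n - m - q - 1
    f_obs = (parts["ss_fitted"] / m) / (parts["ss_residual"] / df_resid)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(b)])

    if q == 0:
        # Permuting rows of the centered X permutes the rows of its
        # orthonormal basis Q, so ss_fitted per permutation is
        # ||Q[perm].T @ Yc||^2 and ss_residual = ss_total - ss_fitted.
        yc = parts["yc"]
        qx = parts["qx"]
        ss_total = parts["ss_total"]
        ss_f = np.empty(b)
        chunk = max(1, int(2e7 // max(n * m, 1)))
        for lo in range(0, b, chunk):
            sub = perms[lo : lo + chunk]
            qp = qx[sub]  # (cb, n, m)
            proj = np.einsum("bnm,nk->bmk", qp, yc)
            ss_f[lo : lo + len(sub)] = np.einsum("bmk,bmk->b", proj, proj)
        ss_r = ss_total - ss_f
        with np.errstate(divide="ignore"):
            f_null = (ss_f / m) / (ss_r / df_resid)
    else:
        f_null = np.empty(b)
        for i, order in enumerate(perms):
            p = _decompose(y, _permute_design(x, order), scale)
            f_null[i] = (p["ss_fitted"] / m) / (p["ss_residual"] / df_resid)

    p_value = (1 + int(np.count_nonzero(f_null >= f_obs))) / (b + 1)
    return PermutationResult(
        f_obs=float(f_obs), f_null=f_null, p_value=p_value, b=b, seed=seed
    )


@dataclass
class BiplotCoordinates:
    """Coordinates for an RDA biplot (samples, group centroids, top CpGs)."""

    sample_scores: pd.DataFrame
    group_centroids: pd.DataFrame | None
    cpg_coordinates: pd.DataFrame


def biplot_coordinates(
    fit: RDAFit,
    n_components: int = 2,
    n_labeled_cpgs: int = 10,
    groups=None,
) -> BiplotCoordinates:
    """Sample scores, per-level centroids, and strongest-loading CpGs.

    ``groups``, if given, is a length-n sequence of factor levels; the
    centroid of each level's member samples is returned for labelling.
    The ``n_labeled_cpgs`` CpGs with the largest loading magnitude across
    the retained components are returned for labelling in the biplot.
    """
    if n_components < 1 or n_components > fit.n_components:
        raise ParameterError(
            f"n_components={n_components} not in [1, {fit.n_components}]"
        )
    axes = [f"RDA{i + 1}" for i in range(n_components)]
    sample_index = fit.sample_ids or list(range(fit.n))
    scores = pd.DataFrame(
        fit.sample_scores[:, :n_components], index=sample_index, columns=axes
    )
    centroids = None
    if groups is not None:
        centroids = scores.groupby(np.asarray(groups, dtype=object)).mean()
        centroids.index.name = "group"
    probe_index = fit.probe_ids or list(range(fit.k))
    loadings = pd.DataFrame(
        fit.cpg_loadings[:, :n_components], index=probe_index, columns=axes
    )
    magnitude = np.sqrt((loadings.to_numpy() ** 2).sum(axis=1))
    n_top = min(max(n_labeled_cpgs, 0), fit.k)
    top = loadings.iloc[np.argsort(magnitude)[::-1][:n_top]]
    return BiplotCoordinates(
        sample_scores=scores, group_centroids=centroids, cpg_coordinates=top
    )
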