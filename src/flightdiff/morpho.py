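"""Landmark-based geometric morphometrics.

Generalized Procrustes superimposition (partial Procrustes: translation,
unit-centroid-size scaling, rotation-only fitting with no reflection),
allometry correction by multivariate regression of shape on centroid size,
covariance PCA of the residuals, canonical variate analysis, permutation
tests of pairwise Procrustes distances between group means, and confidence
ellipses of group means.

All analyses operate on 12-landmark, 2-D configurations.  Left/right wing
sides are mirrored explicitly (``reflect_sides``) before superimposition;
the Procrustes rotation itself never reflects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.stats import chi2

from .popstruct import OrdinationResult

logger = logging.getLogger(__name__)

N_LANDMARKS = 12

__all__ = [
    "LandmarkSet",
    "AlignedShapes",
    "ShapeResiduals",
    "CvaResult",
    "MeanEllipse",
    "centroid_size",
    "generalized_procrustes",
    "allometry_correction",
    "shape_pca",
    "canonical_variates",
    "procrustes_distances",
    "mean_confidence_ellipse",
    "group_mean_ellipses",
    "reflect_sides",
]


@dataclass
class LandmarkSet:
    """Specimen × 12-landmark coordinate sets with group labels.

    Coordinates are expected in consistent units (``scale``, when present,
    records the per-specimen digitization factor already applied, as a TPS
    SCALE line would).  ``side_flag`` optionally marks 'L'/'R' wings.
    """

    specimens: np.ndarray
    groups: np.ndarray
    coords: np.ndarray  # (n, 12, 2)
    scale: Optional[np.ndarray] = None
    side_flag: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (N_LANDMARKS, 2):
            raise ValueError(
                f"coords must have shape (n, {N_LANDMARKS}, 2), got {self.coords.shape}"
            )
        if len(set(self.specimens)) != len(self.specimens):
            raise ValueError("specimen identifiers must be unique")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]


@dataclass
class AlignedShapes:
    """Procrustes-superimposed configurations and pre-scaling centroid sizes."""

    procrustes_coords: np.ndarray  # (n, 12, 2)
    centroid_size: np.ndarray      # (n,)
    mean_shape: np.ndarray         # (12, 2), unit centroid size
    specimens: np.ndarray
    groups: np.ndarray
    iterations_used: int = 0
    converged: bool = True


@dataclass
class ShapeResiduals:
    """Allometry-corrected Procrustes coordinates (flattened 24-vectors)."""

    residual_coords: np.ndarray    # (n, 24)
    percent_predicted: float       # fraction of shape variance explained by size
    regression_vector: np.ndarray  # (24,), shape change per unit centroid size
    centroid_size: np.ndarray
    specimens: np.ndarray
    groups: np.ndarray


@dataclass
class CvaResult:
    cv_scores: np.ndarray          # (n, axes)
    eigenvalues: np.ndarray
    percent_among_variance: np.ndarray
    group_means: pd.DataFrame      # group × axis
    groups: np.ndarray


@dataclass
class MeanEllipse:
    """Confidence ellipse of a group mean in a 2-D score plane."""

    center: np.ndarray
    semi_axes: np.ndarray  # (2,), major then minor
    angle_rad: float
    n: int
    confidence: float = 0.95


def reflect_sides(lms: LandmarkSet, mirror_flag: str = "L") -> LandmarkSet:
    """Mirror configurations whose side_flag equals ``mirror_flag`` (x -> -x)."""
    if lms.side_flag is None:
        return lms
    coords = lms.coords.copy()
    mask = np.asarray([s == mirror_flag for s in lms.side_flag])
    coords[mask, :, 0] *= -1.0
    return LandmarkSet(
        specimens=lms.specimens, groups=lms.groups, coords=coords,
        scale=lms.scale, side_flag=np.array(["R"] * lms.n_specimens, dtype=object),
    )


def centroid_size(config: np.ndarray) -> np.ndarray:
    """Square root of summed squared landmark distances to the centroid.

    Accepts one configuration (12, 2) or a stack (n, 12, 2); degenerate
    configurations (all landmarks identical) yield size 0.
    """
    c = np.asarray(config, dtype=np.float64)
    single = c.ndim == 2
    if single:
        c = c[None]
    centered = c - c.mean(axis=1, keepdims=True)
    cs = np.sqrt((centered**2).sum(axis=(1, 2)))
    if (cs == 0).any():
        logger.warning("degenerate configuration: all landmarks identical")
    return float(cs[0]) if single else cs


def _rotation_onto(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation (no reflection) carrying x onto target."""
    u, _, vt = np.linalg.svd(x.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1.0
        r = u @ vt
    return r


def generalized_procrustes(
    lms: LandmarkSet,
    tol: float = 1e-10,
    max_iter: int = 100,
    tangent_projection: bool = True,
) -> AlignedShapes:
    """Generalized Procrustes analysis (partial Procrustes).

    Iteratively centers each configuration, scales it to unit centroid
    size, rotates it onto the current mean by rotation-only orthogonal
    Procrustes, then updates and renormalizes the mean, until the mean
    shape moves by less than ``tol``.  Pre-scaling centroid sizes are
    recorded.

    By default aligned shapes are then projected onto the tangent plane at
    the mean: this makes the unit-size constraint linear, so shape
    variation spans at most 2·12 − 4 = 20 dimensions exactly (centering
    and the 2-D rotation criterion are already linear constraints).
    Disable with ``tangent_projection=False`` to stay on the curved
    pre-shape sphere.
    """
    n = lms.n_specimens
    if n < 2:
        raise ValueError("GPA requires at least 2 specimens")
    X = lms.coords - lms.coords.mean(axis=1, keepdims=True)
    cs = centroid_size(lms.coords)
    if (cs == 0).any():
        bad = lms.specimens[cs == 0]
        raise ValueError(f"degenerate (zero-size) configurations: {list(bad)}")
    X = X / cs[:, None, None]
    mean = X[0].copy()
    mean /= np.sqrt((mean**2).sum())
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            X[i] = X[i] @ _rotation_onto(X[i], mean)
        new_mean = X.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        new_mean /= np.sqrt((new_mean**2).sum())
        # keep the mean's orientation stable across iterations
        change = np.sqrt(((new_mean - mean) ** 2).sum())
        mean = new_mean
        if change < tol:
            converged = True
            break
    if not converged:
        logger.warning("GPA did not converge within %d iterations", max_iter)
    if tangent_projection:
        m = mean.reshape(-1)
        flat = X.reshape(n, -1)
        X = (flat - ((flat @ m) - 1.0)[:, None] * m[None, :]).reshape(n, N_LANDMARKS, 2)
    return AlignedShapes(
        procrustes_coords=X,
        centroid_size=cs,
        mean_shape=mean,
        specimens=lms.specimens,
        groups=lms.groups,
        iterations_used=it,
        converged=converged,
    )


def allometry_correction(aligned: AlignedShapes) -> ShapeResiduals:
    """Regress Procrustes coordinates on centroid size; keep the residuals.

    Ordinary least squares of each of the 24 coordinates on centroid size.
    ``percent_predicted`` is the regression sum of squares over the total
    shape sum of squares.  With constant centroid size the regression is
    undefined: residuals are the centered coordinates and
    percent_predicted is 0 (a warning is logged).
    """
    n = aligned.procrustes_coords.shape[0]
    if n < 3:
        raise ValueError("allometry regression requires at least 3 specimens")
    Y = aligned.procrustes_coords.reshape(n, -1)
    x = aligned.centroid_size.astype(np.float64)
    Yc = Y - Y.mean(axis=0)
    xc = x - x.mean()
    sxx = float((xc**2).sum())
    if sxx <= 1e-20 * float((x**2).mean()) * len(x):
        logger.warning("constant centroid size: allometry regression undefined")
        return ShapeResiduals(
            residual_coords=Yc,
            percent_predicted=0.0,
            regression_vector=np.zeros(Y.shape[1]),
            centroid_size=aligned.centroid_size,
            specimens=aligned.specimens,
            groups=aligned.groups,
        )
    beta = (xc @ Yc) / sxx  # (24,)
    fitted = np.outer(xc, beta)
    resid = Yc - fitted
    ss_total = float((Yc**2).sum())
    ss_reg = float((fitted**2).sum())
    return ShapeResiduals(
        residual_coords=resid,
        percent_predicted=(ss_reg / ss_total) if ss_total > 0 else 0.0,
        regression_vector=beta,
        centroid_size=aligned.centroid_size,
        specimens=aligned.specimens,
        groups=aligned.groups,
    )


def shape_pca(res: ShapeResiduals) -> OrdinationResult:
    """Covariance PCA of the allometry-corrected shape residuals.

    After superimposition at most 2·12 − 4 = 20 eigenvalues are nonzero
    (2 translations, 1 rotation, 1 scale removed).
    """
    X = res.residual_coords
    n = X.shape[0]
    if n < 3:
        raise ValueError("shape PCA requires at least 3 specimens")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    tot = eig.sum()
    return OrdinationResult(
        scores=U * s,
        variance_fraction=eig / tot if tot > 0 else np.zeros_like(eig),
        eigenvalues=eig,
        components=Vt,
        axis_count=len(eig),
        method="pca_shape_covariance",
    )


def canonical_variates(res: ShapeResiduals, groups=None) -> CvaResult:
    """Canonical variate analysis of shape residuals by group.

    Data are first projected onto principal components with nonzero
    variance (eigenvalue > 1e-12 × largest), then the generalized
    eigenproblem of among-group versus pooled within-group covariance is
    solved there.  Scores are scaled so the pooled within-group variance is
    1 per axis; at most g − 1 axes are returned.
    """
    X = res.residual_coords
    g_labels = np.asarray(res.groups if groups is None else groups, dtype=object)
    uniq = list(dict.fromkeys(g_labels))
    if len(uniq) < 2:
        raise ValueError("CVA requires at least 2 groups")
    for g in uniq:
        if (g_labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 specimens")
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    # rank guard: project onto non-null principal components
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2
    keep = eig > 1e-12 * eig.max()
    P = Vt[keep].T
    Z = Xc @ P
    d = Z.shape[1]
    k = len(uniq)
    W = np.zeros((d, d))
    B = np.zeros((d, d))
    grand = Z.mean(axis=0)
    means = {}
    for g in uniq:
        zg = Z[g_labels == g]
        mg = zg.mean(axis=0)
        means[g] = mg
        W += (zg - mg).T @ (zg - mg)
        B += len(zg) * np.outer(mg - grand, mg - grand)
    W /= n - k
    B /= k - 1
    vals, vecs = scipy.linalg.eigh(B, W)  # vecs are W-orthonormal
    idx = np.argsort(vals)[::-1]
    n_axes = min(k - 1, d)
    vals = vals[idx][:n_axes]
    A = vecs[:, idx][:, :n_axes]
    vals = np.maximum(vals, 0.0)
    scores = Z @ A
    tot = vals.sum()
    pct = 100.0 * vals / tot if tot > 0 else np.zeros_like(vals)
    gm = pd.DataFrame(
        {f"CV{a + 1}": [float(means[g] @ A[:, a]) for g in uniq] for a in range(n_axes)},
        index=uniq,
    )
    return CvaResult(
        cv_scores=scores,
        eigenvalues=vals,
        percent_among_variance=pct,
        group_means=gm,
        groups=g_labels,
    )


def procrustes_distances(
    aligned: AlignedShapes,
    groups=None,
    permutations: int = 10_000,
    seed: int = 0,
):
    """Pairwise distances between group mean shapes, with permutation tests.

    Distance = root summed squared difference between group mean aligned
    configurations.  The p-value is the proportion of label permutations
    with distance >= observed, with the +1/(N+1) continuity correction.
    Returns (distance DataFrame, p-value DataFrame).
    """
    if permutations < 100:
        logger.warning("fewer than 100 permutations: p-values are coarse")
    g_labels = np.asarray(aligned.groups if groups is None else groups, dtype=object)
    uniq = list(dict.fromkeys(g_labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    X = aligned.procrustes_coords.reshape(len(g_labels), -1)
    rng = np.random.default_rng(seed)
    dist = pd.DataFrame(0.0, index=uniq, columns=uniq)
    pval = pd.DataFrame(np.nan, index=uniq, columns=uniq)
    for ga, gb in combinations(uniq, 2):
        xa = X[g_labels == ga]
        xb = X[g_labels == gb]
        na, nb = len(xa), len(xb)
        pool = np.vstack([xa, xb])
        obs = float(np.linalg.norm(xa.mean(axis=0) - xb.mean(axis=0)))
        total = pool.sum(axis=0)
        # vectorized permutations: random subsets of size na
        keys = rng.random((permutations, na + nb))
        idx = np.argsort(keys, axis=1)[:, :na]
        sum_a = pool[idx].sum(axis=1)
        mean_a = sum_a / na
        mean_b = (total - sum_a) / nb
        d_perm = np.linalg.norm(mean_a - mean_b, axis=1)
        p = (np.count_nonzero(d_perm >= obs - 1e-15) + 1) / (permutations + 1)
        dist.loc[ga, gb] = dist.loc[gb, ga] = obs
        pval.loc[ga, gb] = pval.loc[gb, ga] = p
    return dist, pval


def mean_confidence_ellipse(
    scores: np.ndarray, confidence: float = 0.95
) -> MeanEllipse:
    """Confidence ellipse of the mean of 2-D scores.

    Eigendecomposition of (sample covariance / n); semi-axes are scaled by
    the square root of the chi-square 2-df quantile (5.991 at 95%).
    """
    pts = np.asarray(scores, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("scores must be (n, 2)")
    n = pts.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a mean ellipse")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False) / n
    vals, vecs = np.linalg.eigh(cov)
    orderd = np.argsort(vals)[::-1]
    vals = np.maximum(vals[orderd], 0.0)
    vecs = vecs[:, orderd]
    q = chi2.ppf(confidence, df=2)
    semi = np.sqrt(q * vals)
    angle = float(np.arctan2(vecs[1, 0], vecs[0, 0]))
    return MeanEllipse(center=center, semi_axes=semi, angle_rad=angle, n=n,
                       confidence=confidence)


def group_mean_ellipses(scores: np.ndarray, groups, confidence: float = 0.95) -> dict:
    """Mean confidence ellipse per group for a 2-D score plane."""
    g_labels = np.asarray(groups, dtype=object)
    out = {}
    for g in dict.fromkeys(g_labels):
        out[g] = mean_confidence_ellipse(scores[g_labels == g], confidence)
    return out
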