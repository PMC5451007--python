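"""Dataset filtering, ordination, and population differentiation.

Implements the SNP filtering rules (site coverage, biallelic-only,
per-population read minimum, per-individual missingness), PCA on genotype
posterior probabilities, Nei's G_ST with Bayesian credible intervals from
posterior allele-frequency draws, non-metric multidimensional scaling of
the resulting distance matrix, and pseudo-haploid single-read sampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .genomod import AlleleFrequencyPosterior, GenotypePosterior, ReadCountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "GstMatrix",
    "PseudoHaploidMatrix",
    "OrdinationResult",
    "filter_dataset",
    "genotype_pca",
    "pairwise_gst",
    "nmds_embed",
    "pseudo_haploid_sample",
]

MISSING = -9


@dataclass
class FilterSpec:
    """SNP / individual filtering thresholds.

    Defaults: a site must be covered (>=1 read) in at least 25% of
    individuals, be biallelic, and carry at least 15 reads in every
    population sample; individuals missing more than 98% of loci are
    dropped.
    """

    min_site_coverage_fraction: float = 0.25
    biallelic_only: bool = True
    min_reads_per_population: int = 15
    max_individual_missing_fraction: float = 0.98

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_site_coverage_fraction <= 1.0:
            raise ValueError("min_site_coverage_fraction must lie in [0, 1]")
        if not 0.0 <= self.max_individual_missing_fraction <= 1.0:
            raise ValueError("max_individual_missing_fraction must lie in [0, 1]")
        if self.min_reads_per_population < 0:
            raise ValueError("min_reads_per_population must be >= 0")


@dataclass
class GstMatrix:
    """Pairwise multi-locus G_ST with 95% credible bounds."""

    populations: list
    estimate: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    status: np.ndarray  # str per pair: "ok" or "undefined"

    def __post_init__(self) -> None:
        k = len(self.populations)
        for m in (self.estimate, self.ci_low, self.ci_high):
            if m.shape != (k, k):
                raise ValueError("G_ST matrices must be square over populations")

    def to_table2_frame(self) -> pd.DataFrame:
        """Lower triangle: estimates; upper triangle: 'lo–hi' CI strings."""
        k = len(self.populations)
        out = pd.DataFrame(
            "", index=self.populations, columns=self.populations, dtype=object
        )
        for i in range(k):
            out.iloc[i, i] = "0"
            for j in range(k):
                if i > j:
                    out.iloc[i, j] = f"{self.estimate[i, j]:.4f}"
                elif i < j:
                    out.iloc[i, j] = f"{self.ci_low[i, j]:.4f}-{self.ci_high[i, j]:.4f}"
        return out

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, j in combinations(range(len(self.populations)), 2):
            rows.append(
                {
                    "pop_a": self.populations[i],
                    "pop_b": self.populations[j],
                    "gst": self.estimate[i, j],
                    "ci_low": self.ci_low[i, j],
                    "ci_high": self.ci_high[i, j],
                    "status": self.status[i, j],
                }
            )
        return pd.DataFrame(rows)


@dataclass
class PseudoHaploidMatrix:
    """One sampled allele per individual-locus: 1 (ref), 2 (alt), -9 missing."""

    calls: np.ndarray  # (n, L) int8
    individuals: np.ndarray
    populations: np.ndarray
    loci: np.ndarray


@dataclass
class OrdinationResult:
    """Scores per item × axis, with variance fractions (PCA) or stress (NMDS)."""

    scores: np.ndarray
    variance_fraction: Optional[np.ndarray] = None
    eigenvalues: Optional[np.ndarray] = None
    components: Optional[np.ndarray] = None
    stress: Optional[float] = None
    stress_trace: Optional[np.ndarray] = None
    axis_count: int = 0
    method: str = ""
    meta: dict = field(default_factory=dict)


def filter_dataset(
    rcm: ReadCountMatrix,
    spec: FilterSpec = FilterSpec(),
    allele_count_per_site: Optional[np.ndarray] = None,
):
    """Apply the SNP and individual filters in their fixed order.

    Order: (1) multiallelic sites (when per-site allele counts are given),
    (2) sites covered in fewer than ``min_site_coverage_fraction`` of
    individuals, (3) sites with total reads below
    ``min_reads_per_population`` in any retained population, (4)
    individuals missing more than ``max_individual_missing_fraction`` of
    the retained loci.  Returns the filtered matrix plus a removal log
    recording each dropped site/individual and the rule that fired.
    """
    log_rows = []
    locus_keep = np.ones(rcm.n_loci, dtype=bool)
    depth = rcm.depth

    if spec.biallelic_only and allele_count_per_site is not None:
        ac = np.asarray(allele_count_per_site)
        if ac.shape != (rcm.n_loci,):
            raise ValueError("allele_count_per_site must align with loci")
        bad = ac > 2
        for j in np.flatnonzero(bad):
            log_rows.append(
                {"kind": "site", "id": rcm.loci[j], "rule": "multiallelic",
                 "detail": f"{ac[j]} alleles"}
            )
        locus_keep &= ~bad

    cov_frac = (depth > 0).mean(axis=0)
    bad = locus_keep & (cov_frac < spec.min_site_coverage_fraction)
    for j in np.flatnonzero(bad):
        log_rows.append(
            {"kind": "site", "id": rcm.loci[j], "rule": "site_coverage",
             "detail": f"covered in {cov_frac[j]:.3f} of individuals"}
        )
    locus_keep &= ~bad

    pidx = rcm.pop_indices()
    n_pops = len(rcm.pop_labels)
    pop_reads = np.zeros((n_pops, rcm.n_loci), dtype=np.int64)
    for k in range(n_pops):
        pop_reads[k] = depth[pidx == k].sum(axis=0)
    bad = locus_keep & (pop_reads.min(axis=0) < spec.min_reads_per_population)
    for j in np.flatnonzero(bad):
        k = int(pop_reads[:, j].argmin())
        log_rows.append(
            {"kind": "site", "id": rcm.loci[j], "rule": "min_reads_per_population",
             "detail": f"{pop_reads[k, j]} reads in {rcm.pop_labels[k]}"}
        )
    locus_keep &= ~bad

    ind_keep = np.ones(rcm.n_individuals, dtype=bool)
    if locus_keep.any():
        miss_frac = (depth[:, locus_keep] == 0).mean(axis=1)
        bad_ind = miss_frac > spec.max_individual_missing_fraction
        for i in np.flatnonzero(bad_ind):
            log_rows.append(
                {"kind": "individual", "id": rcm.individuals[i],
                 "rule": "individual_missingness",
                 "detail": f"missing {miss_frac[i]:.3f} of retained loci"}
            )
        ind_keep &= ~bad_ind
    else:
        logger.warning("all sites removed by filtering; empty result")

    log = pd.DataFrame(log_rows, columns=["kind", "id", "rule", "detail"])
    return rcm.subset(ind_mask=ind_keep, locus_mask=locus_keep), log


def genotype_pca(gp: GenotypePosterior, n_axes: Optional[int] = None) -> OrdinationResult:
    """PCA of the individuals × (3·loci) genotype-posterior matrix.

    Columns are mean-centered, unscaled; missing cells (NaN) are imputed
    with the column mean before centering.  Scores and variance fractions
    come from the covariance eigendecomposition (via SVD).
    """
    n, L, _ = gp.prob.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 individuals")
    X = gp.prob.reshape(n, 3 * L).astype(np.float64).copy()
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(np.isnan(X))
        X[idx] = col_mean[idx[1]]
    scale = max(float((X**2).mean()), 1e-300)
    X -= X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eig = s**2 / (n - 1)
    # kill pure floating-point fuzz from the centering of constant columns
    eig[eig <= 1e-20 * scale] = 0.0
    s = np.where(eig > 0, s, 0.0)
    tot = eig.sum()
    frac = eig / tot if tot > 0 else np.zeros_like(eig)
    m = len(eig) if n_axes is None else min(n_axes, len(eig))
    return OrdinationResult(
        scores=U[:, :m] * s[:m],
        variance_fraction=frac[:m],
        eigenvalues=eig[:m],
        components=Vt[:m],
        axis_count=m,
        method="pca_genotype_posterior",
        meta={"imputation": "column-mean", "centering": "mean", "scaling": "none"},
    )


def pairwise_gst(afp: AlleleFrequencyPosterior) -> GstMatrix:
    """Nei's multi-locus G_ST per population pair, with credible intervals.

    For each retained MCMC draw and pair: per-locus H_S is the mean of
    2p_k(1−p_k) over the two populations and H_T = 2p̄(1−p̄) with p̄ their
    mean; the multi-locus statistic is Σ_loci(H_T − H_S) / Σ_loci H_T
    (ratio of sums).  The point estimate is the posterior mean over draws;
    the credible bounds are the 2.5 and 97.5 percentiles.  Draws are paired
    across populations at matched MCMC iterations.
    """
    K = len(afp.populations)
    if K < 2:
        raise ValueError("at least two populations required")
    est = np.zeros((K, K))
    lo = np.zeros((K, K))
    hi = np.zeros((K, K))
    status = np.full((K, K), "ok", dtype=object)
    for i, j in combinations(range(K), 2):
        pa = afp.draws[i]  # (L, D)
        pb = afp.draws[j]
        hs = pa * (1 - pa) + pb * (1 - pb)  # mean of 2p(1-p) over the pair
        pbar = 0.5 * (pa + pb)
        ht = 2 * pbar * (1 - pbar)
        num = (ht - hs).sum(axis=0)
        den = ht.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            g = np.where(den > 0, num / den, np.nan)
        if np.isnan(g).all():
            status[i, j] = status[j, i] = "undefined"
            est[i, j] = est[j, i] = np.nan
            lo[i, j] = lo[j, i] = np.nan
            hi[i, j] = hi[j, i] = np.nan
            continue
        est[i, j] = est[j, i] = np.nanmean(g)
        lo[i, j] = lo[j, i] = np.nanpercentile(g, 2.5)
        hi[i, j] = hi[j, i] = np.nanpercentile(g, 97.5)
    return GstMatrix(
        populations=list(afp.populations), estimate=est, ci_low=lo, ci_high=hi,
        status=status,
    )


def _kruskal_stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    den = float((d**2).sum())
    if den == 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / den))


def _smacof_single(delta_flat, order, m, dims, rng, max_iter, tol, x0=None):
    n_pairs = len(delta_flat)
    X = rng.normal(size=(m, dims)) if x0 is None else x0.copy()
    trace = []
    prev = np.inf
    for _ in range(max_iter):
        d = pdist(X)
        # monotone regression of distances on the rank order of dissimilarity
        dhat = np.empty_like(d)
        dhat[order] = isotonic_regression(d[order]).x
        # scale disparities to the configuration's distance norm
        ssd = (d**2).sum()
        ssdh = (dhat**2).sum()
        if ssdh > 0:
            dhat = dhat * np.sqrt(ssd / ssdh)
        stress = _kruskal_stress1(d, dhat)
        trace.append(stress)
        if prev - stress < tol:
            break
        prev = stress
        # Guttman transform
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dhat / d, 0.0)
        B = -squareform(ratio)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = B @ X / m
    return X, trace[-1], np.array(trace)


def nmds_embed(
    dissimilarity: np.ndarray,
    dims: int = 3,
    restarts: int = 8,
    max_iter: int = 500,
    tol: float = 1e-9,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS by iterative majorization (SMACOF) with monotone
    regression of configuration distances on dissimilarity ranks.

    The first start is the classical (metric) scaling solution; the
    remaining ``restarts − 1`` are random.  The best configuration by
    Kruskal stress-1 is returned, with the per-iteration stress trace of
    the winning start.
    """
    D = np.asarray(dissimilarity, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("dissimilarity must be symmetric")
    if (D < 0).any():
        raise ValueError("dissimilarities must be non-negative")
    m = D.shape[0]
    if m <= dims:
        raise ValueError("need more objects than embedding dimensions")
    delta = squareform(D, checks=False)
    order = np.argsort(delta, kind="stable")
    rng = np.random.default_rng(seed)

    # classical scaling start
    J = np.eye(m) - np.ones((m, m)) / m
    Bc = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(Bc)
    idx = np.argsort(w)[::-1][:dims]
    x0 = V[:, idx] * np.sqrt(np.maximum(w[idx], 0.0))

    best = None
    for r in range(max(1, restarts)):
        start = x0 if r == 0 else None
        X, stress, trace = _smacof_single(
            delta, order, m, dims, rng, max_iter, tol, x0=start
        )
        if best is None or stress < best[1]:
            best = (X, stress, trace)
    X, stress, trace = best
    X = X - X.mean(axis=0)
    return OrdinationResult(
        scores=X,
        stress=stress,
        stress_trace=trace,
        axis_count=dims,
        method="nmds_smacof",
        meta={"restarts": restarts, "max_iter": max_iter, "tol": tol, "seed": seed},
    )


def pseudo_haploid_sample(rcm: ReadCountMatrix, seed: int = 0) -> PseudoHaploidMatrix:
    """Sample one read per individual-locus in proportion to read counts.

    Cells with depth > 0 get call 2 with probability alt/(ref+alt), else
    call 1; zero-depth cells are missing (-9).
    """
    rng = np.random.default_rng(seed)
    depth = rcm.depth
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(depth > 0, rcm.alt / np.maximum(depth, 1), 0.0)
    u = rng.random(depth.shape)
    calls = np.where(u < p_alt, 2, 1).astype(np.int8)
    calls[depth == 0] = MISSING
    return PseudoHaploidMatrix(
        calls=calls,
        individuals=rcm.individuals,
        populations=rcm.populations,
        loci=rcm.loci,
    )
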