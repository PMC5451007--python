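"""Synthetic inputs with the statistical structure the analyses assume.

Generators produce read-count matrices, admixed genotype data, 12-landmark
wing shapes, and melanization tables, each paired with the generating truth
so downstream estimators can be checked for parameter recovery.

Genetic divergence follows an F-model: population allele frequencies are
Beta-distributed around an ancestral frequency p0 with variance
F·p0·(1−p0), so F sets the expected among-population differentiation.
Reads are a Poisson-depth binomial channel over Hardy–Weinberg genotypes.
Wing shapes are built in shape space as base + group effect + allometric
term + digitization noise, then hit with a random similarity transform.
Melanization is linear in wing area with group offsets.

Every generator is a pure function of its integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genomod import ReadCountMatrix
from .morpho import LandmarkSet

__all__ = [
    "TruePopFrequencies",
    "SyntheticTruth",
    "sim_pop_frequencies",
    "sim_read_counts",
    "sim_admixed_read_counts",
    "sim_landmarks",
    "sim_melanization",
    "DEFAULT_BASE_SHAPE",
]


@dataclass
class TruePopFrequencies:
    """Ancestral and per-population allele frequencies under the F-model."""

    loci: int
    populations: list
    p0: np.ndarray          # (L,)
    F: float
    p: np.ndarray           # (n_pops, L)

    def __post_init__(self) -> None:
        for arr in (self.p0, self.p):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError("allele frequencies must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Generating parameters retained for parameter-recovery testing."""

    frequencies: Optional[TruePopFrequencies] = None
    genotypes: Optional[np.ndarray] = None          # (n, L) in {0,1,2}
    q_true: Optional[np.ndarray] = None             # (n, K), rows sum to 1
    shape_effects: Optional[dict] = None            # group -> (24,) offsets
    allometric_vector: Optional[np.ndarray] = None  # (24,)
    base_shape: Optional[np.ndarray] = None         # (12, 2)
    centroid_sizes: Optional[np.ndarray] = None
    melanization_slope: Optional[float] = None
    group_offsets: Optional[dict] = None
    seeds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.q_true is not None:
            if not np.allclose(self.q_true.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError("each row of q_true must sum to 1")


def sim_pop_frequencies(
    loci: int,
    populations: Sequence[str],
    F: float,
    p0_range: tuple = (0.05, 0.95),
    seed: int = 0,
) -> TruePopFrequencies:
    """Draw per-population allele frequencies under the F-model.

    p0 ~ Uniform(p0_range); each population's p ~ Beta with mean p0 and
    variance F·p0·(1−p0), i.e. parameters (p0(1−F)/F, (1−p0)(1−F)/F).
    """
    if not 0.0 < F < 1.0:
        raise ValueError(f"F must lie strictly in (0, 1), got {F}")
    if loci < 1:
        raise ValueError("at least one locus required")
    lo, hi = p0_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError("p0_range must be an interval inside (0, 1)")
    pops = list(populations)
    if not pops:
        raise ValueError("at least one population required")
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(lo, hi, size=loci)
    a = p0 * (1.0 - F) / F
    b = (1.0 - p0) * (1.0 - F) / F
    p = rng.beta(a, b, size=(len(pops), loci))
    return TruePopFrequencies(loci=loci, populations=pops, p0=p0, F=F, p=p)


def _reads_from_genotypes(
    genotypes: np.ndarray,
    coverage: float,
    err: float,
    missing_rate: float,
    rng: np.random.Generator,
):
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not 0.0 <= err < 0.5:
        raise ValueError("err must lie in [0, 0.5)")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    n, L = genotypes.shape
    depth = rng.poisson(coverage, size=(n, L))
    depth[rng.random((n, L)) < missing_rate] = 0
    e = np.array([err, 0.5, 1.0 - err])[genotypes]
    alt = rng.binomial(depth, e)
    ref = depth - alt
    return ref, alt


def sim_read_counts(
    freqs: TruePopFrequencies,
    n_per_pop,
    coverage: float = 8.0,
    err: float = 0.005,
    missing_rate: float = 0.1,
    seed: int = 0,
):
    """Simulate GBS-style read counts over HWE genotypes.

    Genotypes are Binomial(2, p) per individual-locus; depth is
    Poisson(coverage) zeroed with probability ``missing_rate``; alternate
    reads are Binomial(depth, e(g)) with e(0)=err, e(1)=0.5, e(2)=1−err.

    Returns (ReadCountMatrix, SyntheticTruth).
    """
    if np.isscalar(n_per_pop):
        n_per_pop = [int(n_per_pop)] * len(freqs.populations)
    n_per_pop = [int(x) for x in n_per_pop]
    if len(n_per_pop) != len(freqs.populations) or any(x < 1 for x in n_per_pop):
        raise ValueError("n_per_pop must give a positive size for every population")
    rng = np.random.default_rng(seed)
    pop_of_ind = np.repeat(np.arange(len(n_per_pop)), n_per_pop)
    n = len(pop_of_ind)
    genotypes = rng.binomial(2, freqs.p[pop_of_ind, :]).astype(np.int8)
    ref, alt = _reads_from_genotypes(genotypes, coverage, err, missing_rate, rng)
    loci = np.array([f"L{j:06d}" for j in range(freqs.loci)], dtype=object)
    inds, pops = [], []
    for k, pop in enumerate(freqs.populations):
        for i in range(n_per_pop[k]):
            inds.append(f"{pop}_{i:03d}")
            pops.append(pop)
    rcm = ReadCountMatrix(
        loci=loci,
        individuals=np.array(inds, dtype=object),
        populations=np.array(pops, dtype=object),
        ref=ref,
        alt=alt,
    )
    truth = SyntheticTruth(
        frequencies=freqs, genotypes=genotypes, seeds={"read_counts": int(seed)}
    )
    return rcm, truth


def sim_admixed_read_counts(
    K: int,
    loci: int,
    F: float,
    q_spec,
    coverage: float = 8.0,
    err: float = 0.005,
    missing_rate: float = 0.1,
    p0_range: tuple = (0.05, 0.95),
    seed: int = 0,
):
    """Simulate read counts for admixed individuals.

    ``q_spec`` is either an (n, K) array of admixture proportions (rows on
    the simplex) or a tuple ``(n, alpha)`` drawing q rows from a symmetric
    Dirichlet(alpha).  Each of the two allele copies per individual-locus
    picks its cluster of origin from q, then its allele from that cluster's
    frequency; reads then follow the same channel as :func:`sim_read_counts`.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(q_spec, tuple) and len(q_spec) == 2 and np.isscalar(q_spec[0]):
        n, alpha = int(q_spec[0]), float(q_spec[1])
        q = rng.dirichlet(np.full(K, alpha), size=n)
    else:
        q = np.asarray(q_spec, dtype=np.float64)
        if q.ndim != 2 or q.shape[1] != K:
            raise ValueError("q_spec must be an (n, K) array")
        if not np.allclose(q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each q row must sum to 1 within 1e-9")
    n = q.shape[0]
    clusters = [f"anc{k + 1}" for k in range(K)]
    freqs = sim_pop_frequencies(
        loci, clusters, F, p0_range=p0_range, seed=int(rng.integers(2**31 - 1))
    )
    # two allele copies, each drawing its own cluster of origin per locus
    g = np.zeros((n, loci), dtype=np.int8)
    cum = np.cumsum(q, axis=1)
    for _copy in range(2):
        u = rng.random((n, loci))
        origin = (u[..., None] > cum[:, None, :-1]).sum(axis=2)
        allele = rng.random((n, loci)) < freqs.p[origin, np.arange(loci)[None, :]]
        g += allele.astype(np.int8)
    ref, alt = _reads_from_genotypes(g, coverage, err, missing_rate, rng)
    dominant = q.argmax(axis=1)
    labels = np.array(
        [
            clusters[dominant[i]] if q[i].max() > 0.8 else "admixed"
            for i in range(n)
        ],
        dtype=object,
    )
    rcm = ReadCountMatrix(
        loci=np.array([f"L{j:06d}" for j in range(loci)], dtype=object),
        individuals=np.array([f"ind_{i:03d}" for i in range(n)], dtype=object),
        populations=labels,
        ref=ref,
        alt=alt,
    )
    truth = SyntheticTruth(
        frequencies=freqs, genotypes=g, q_true=q, seeds={"admixed": int(seed)}
    )
    return rcm, truth


# A 12-landmark wing-like template: vein convergence points and vein/margin
# intersections along an elongated forewing outline, unit centroid size.
_RAW_BASE = np.array(
    [
        [0.00, 0.10],   # wing base
        [0.35, 0.32],   # subcostal/radial fork
        [0.70, 0.42],   # radial fork
        [1.00, 0.40],   # apex-ward margin intersection
        [1.20, 0.28],   # apex
        [1.10, 0.10],   # outer margin vein tip
        [0.95, -0.02],  # outer margin vein tip
        [0.75, -0.12],  # tornus-ward margin
        [0.50, -0.16],  # anal margin vein tip
        [0.25, -0.12],  # anal margin
        [0.45, 0.10],   # discal cell crossvein
        [0.70, 0.16],   # discal cell apex
    ]
)


def _unit_size(config: np.ndarray) -> np.ndarray:
    c = config - config.mean(axis=0)
    return c / np.sqrt((c**2).sum())


DEFAULT_BASE_SHAPE = _unit_size(_RAW_BASE)


def sim_landmarks(
    groups,
    base_shape: Optional[np.ndarray] = None,
    shape_effects: Optional[dict] = None,
    allometric_vector: Optional[np.ndarray] = None,
    cs_range: tuple = (22.0, 28.0),
    noise_sd: float = 0.005,
    seed: int = 0,
):
    """Simulate 12-landmark wing configurations.

    ``groups`` maps group label to specimen count.  In shape space (unit
    centroid size) each specimen is base + group effect + allometric_vector
    · (cs − mean cs) + iid Gaussian noise; the configuration is then scaled
    to its centroid size (mm) and hit with a random rotation and
    translation; a random digitization scale factor is recorded in
    ``scale`` so coordinates stay in consistent units (the TPS writer
    reapplies it).  Reflections are never applied.

    Returns (LandmarkSet, SyntheticTruth).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    base = DEFAULT_BASE_SHAPE if base_shape is None else np.asarray(base_shape, float)
    if base.shape != (12, 2):
        raise ValueError("base_shape must be 12 x 2")
    if np.allclose(base, base[0]):
        raise ValueError("degenerate base shape: all landmarks identical")
    base = _unit_size(base)
    groups = dict(groups)
    labels = [g for g, size in groups.items() for _ in range(int(size))]
    n = len(labels)
    if n == 0:
        raise ValueError("at least one specimen required")
    rng = np.random.default_rng(seed)
    eff = {g: np.zeros(24) for g in groups}
    if shape_effects:
        for g, v in shape_effects.items():
            eff[g] = np.asarray(v, float).reshape(24)
    allo = (
        np.zeros(24)
        if allometric_vector is None
        else np.asarray(allometric_vector, float).reshape(24)
    )
    cs = rng.uniform(cs_range[0], cs_range[1], size=n)
    cs_mean = cs.mean()
    coords = np.empty((n, 12, 2))
    digit_scale = rng.uniform(0.8, 1.25, size=n)  # px-per-mm jitter
    for i, g in enumerate(labels):
        shp = base.reshape(24) + eff[g] + allo * (cs[i] - cs_mean)
        shp = shp + rng.normal(0.0, noise_sd, size=24)
        cfg = shp.reshape(12, 2) * cs[i]
        th = rng.uniform(0.0, 2.0 * np.pi)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        cfg = cfg @ rot.T + rng.uniform(-10.0, 10.0, size=2)
        coords[i] = cfg
    lmt = LandmarkSet(
        specimens=np.array([f"spec_{i:03d}" for i in range(n)], dtype=object),
        groups=np.array(labels, dtype=object),
        coords=coords,
        scale=1.0 / digit_scale,
    )
    truth = SyntheticTruth(
        shape_effects=eff,
        allometric_vector=allo,
        base_shape=base,
        centroid_sizes=cs,
        seeds={"landmarks": int(seed)},
    )
    return lmt, truth


def sim_melanization(
    groups,
    area_range: tuple = (90.0, 150.0),
    slope: float = 0.2,
    group_offsets: Optional[dict] = None,
    noise_sd: float = 1.0,
    measurement_sd: float = 0.2,
    seed: int = 0,
    render_images: bool = False,
    px_per_mm: int = 20,
):
    """Simulate wing melanization tables (and optionally binary images).

    Melanization (mm²) = slope·area + offset(group) + Gaussian noise,
    truncated at 0.  Each quantity is "measured" twice with small
    measurement noise, mimicking duplicated tracing.  With
    ``render_images`` each specimen also gets a binary raster: a black blob
    of known filled pixel count enclosing white holes, plus a scale bar in
    a bottom strip outside the measurement region.

    Returns (DataFrame, SyntheticTruth[, images]) where ``images`` is a
    list of dicts with keys image, px_per_mm, roi, filled_px, hole_px.
    """
    import pandas as pd

    if area_range[0] <= 0 or area_range[1] <= 0:
        raise ValueError("area_range must be positive")
    groups = dict(groups)
    offsets = {g: 0.0 for g in groups}
    if group_offsets:
        offsets.update({g: float(v) for g, v in group_offsets.items()})
    rng = np.random.default_rng(seed)
    rows = []
    labels = [g for g, size in groups.items() for _ in range(int(size))]
    areas = rng.uniform(area_range[0], area_range[1], size=len(labels))
    melan = np.maximum(
        0.0,
        slope * areas
        + np.array([offsets[g] for g in labels])
        + rng.normal(0.0, noise_sd, size=len(labels)),
    )
    for i, g in enumerate(labels):
        a1, a2 = areas[i] + rng.normal(0.0, measurement_sd, 2)
        m1, m2 = melan[i] + rng.normal(0.0, measurement_sd, 2)
        rows.append(
            {
                "specimen": f"spec_{i:03d}",
                "group": g,
                "area_1": a1,
                "area_2": a2,
                "melanization_1": m1,
                "melanization_2": m2,
            }
        )
    df = pd.DataFrame(rows)
    truth = SyntheticTruth(
        melanization_slope=slope,
        group_offsets=offsets,
        seeds={"melanization": int(seed)},
    )
    if not render_images:
        return df, truth
    images = [
        render_wing_blob(
            filled_px=int(round(a * px_per_mm**2)),
            hole_px=int(round(max(0.0, a * px_per_mm**2 * 0.15))),
            px_per_mm=px_per_mm,
        )
        for a in melan
    ]
    return df, truth, images


def render_wing_blob(filled_px: int, hole_px: int, px_per_mm: int = 100):
    """Render a black blob with exactly known filled and hole pixel counts.

    The blob is a solid rectangle of ``filled_px`` pixels whose interior
    contains white rectangular holes totalling ``hole_px`` pixels; a scale
    bar of length ``px_per_mm`` pixels sits in a bottom strip outside the
    region of interest.  Returns a dict with the uint8 image (white=255),
    the ROI slice covering the wing region only, and the truth counts.
    """
    if hole_px and hole_px >= filled_px:
        raise ValueError("holes must fit strictly inside the filled region")
    w = max(8, int(np.ceil(np.sqrt(filled_px * 1.6))))
    h = (filled_px + w - 1) // w
    rem = filled_px - (h - 1) * w  # last, possibly partial, row
    pad = 10
    img = np.full((h + 2 * pad + 30, w + 2 * pad), 255, dtype=np.uint8)
    img[pad : pad + h - 1, pad : pad + w] = 0
    img[pad + h - 1, pad : pad + rem] = 0
    # carve interior holes (never touching the blob boundary)
    remaining = hole_px
    row = pad + 2
    while remaining > 0 and row < pad + h - 3:
        run = min(remaining, w - 6)
        img[row, pad + 3 : pad + 3 + run] = 255
        remaining -= run
        row += 2
    if remaining:
        raise ValueError("hole_px too large for the blob interior")
    bar_row = img.shape[0] - 15
    img[bar_row : bar_row + 3, pad : pad + px_per_mm] = 0
    roi = (slice(0, h + 2 * pad), slice(0, img.shape[1]))
    return {
        "image": img,
        "roi": roi,
        "px_per_mm": px_per_mm,
        "filled_px": filled_px,
        "hole_px": hole_px,
    }
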