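"""Wing melanization measurement and shared univariate statistics.

Melanization is measured from binary wing rasters: the wing's black region
is filled, enclosed white holes are counted separately, and total
melanization is the filled black area minus the enclosed white area (i.e.
the raw black pixel area).  Because melanization scales with wing size, it
is regressed on wing area and the residuals carry into a one-way ANOVA
with Tukey's HSD across populations.  The ANOVA/Tukey routines are shared
with the shape analyses (per-PC score tests).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import f as f_dist
from scipy.stats import studentized_range, t as t_dist

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaTable",
    "MelanizationFit",
    "measure_melanization",
    "prepare_melanization_table",
    "melanization_residuals",
    "one_way_anova",
    "tukey_hsd",
    "anova_with_tukey",
]


@dataclass
class AnovaTable:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: pd.Series
    ss_between: float
    ss_within: float
    ms_within: float
    tukey: Optional[pd.DataFrame] = None


@dataclass
class MelanizationFit:
    """Size-corrected melanization records plus the area regression."""

    records: pd.DataFrame          # adds total_melanization/residual columns
    R: float
    p_value: float
    slope: float
    intercept: float
    status: str = "ok"


def measure_melanization(
    image: np.ndarray,
    px_per_mm: float,
    threshold: Union[str, float] = "isodata",
):
    """Measure black area, enclosed white area, and total melanization (mm²).

    The single-channel image is binarized (isodata/intermeans threshold by
    default, or a fixed value); pixels at or below the threshold count as
    black.  ``black_area`` is the area of the black regions with their
    interior holes filled; ``enclosed_white_area`` is the area of white
    pixels not connected to the image border (the holes); total
    melanization is their difference.  Returns a (black_area,
    enclosed_white_area, total_melanization) tuple.
    """
    if px_per_mm <= 0:
        raise ValueError("px_per_mm must be positive")
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if img.min() == img.max():
        logger.warning("blank image: no melanized area detected")
        return 0.0, 0.0, 0.0
    if isinstance(threshold, str):
        if threshold != "isodata":
            raise ValueError(f"unknown threshold method {threshold!r}")
        from skimage.filters import threshold_isodata

        thr = threshold_isodata(img)
    else:
        thr = float(threshold)
    black = img <= thr
    if not black.any():
        logger.warning("no pixels below threshold: blank measurement")
        return 0.0, 0.0, 0.0
    filled = ndimage.binary_fill_holes(black)
    scale = float(px_per_mm) ** 2
    black_area = filled.sum() / scale
    enclosed_white = (filled & ~black).sum() / scale
    return black_area, enclosed_white, black_area - enclosed_white


def prepare_melanization_table(df: pd.DataFrame) -> pd.DataFrame:
    """Average duplicate area/melanization measurements into single columns."""
    out = df.copy()
    if {"area_1", "area_2"} <= set(out.columns):
        out["wing_area"] = out[["area_1", "area_2"]].mean(axis=1)
    if {"melanization_1", "melanization_2"} <= set(out.columns):
        out["total_melanization"] = out[["melanization_1", "melanization_2"]].mean(axis=1)
    if "wing_area" not in out.columns or "total_melanization" not in out.columns:
        raise ValueError(
            "table must provide wing_area/total_melanization or duplicate columns"
        )
    return out


def melanization_residuals(records: pd.DataFrame) -> MelanizationFit:
    """Correlate melanization with wing area and attach OLS residuals.

    Pearson R between total melanization and wing area with a two-sided
    t-test p-value; OLS of melanization on area; residuals appended as
    ``residual_melanization``.  With constant wing area the correlation is
    undefined and the fit is returned with status ``"undefined"`` and
    mean-centered melanization as residuals.
    """
    df = prepare_melanization_table(records)
    if len(df) < 3:
        raise ValueError("need at least 3 records")
    x = df["wing_area"].to_numpy(dtype=np.float64)
    y = df["total_melanization"].to_numpy(dtype=np.float64)
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        logger.warning("constant wing area: correlation undefined")
        df = df.assign(residual_melanization=yc)
        return MelanizationFit(
            records=df, R=np.nan, p_value=np.nan, slope=np.nan,
            intercept=np.nan, status="undefined",
        )
    syy = float(yc @ yc)
    sxy = float(xc @ yc)
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    if syy == 0.0:
        r, p = 0.0, 1.0
    else:
        r = sxy / np.sqrt(sxx * syy)
        if abs(r) >= 1.0:
            p = 0.0
        else:
            tstat = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * t_dist.sf(abs(tstat), n - 2)
    resid = y - (intercept + slope * x)
    df = df.assign(residual_melanization=resid)
    return MelanizationFit(
        records=df, R=float(r), p_value=float(p), slope=float(slope),
        intercept=intercept,
    )


def _group_arrays(values, groups):
    v = np.asarray(values, dtype=np.float64)
    g = np.asarray(groups, dtype=object)
    if v.shape != g.shape:
        raise ValueError("values and groups must align")
    uniq = list(dict.fromkeys(g))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    parts = {}
    for lab in uniq:
        arr = v[g == lab]
        if len(arr) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 values")
        parts[lab] = arr
    return parts


def one_way_anova(values, groups) -> AnovaTable:
    """Standard one-way fixed-effects ANOVA (between/within decomposition)."""
    parts = _group_arrays(values, groups)
    v = np.asarray(values, dtype=np.float64)
    grand = v.mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in parts.values())
    ssw = sum(((a - a.mean()) ** 2).sum() for a in parts.values())
    dfb = len(parts) - 1
    dfw = len(v) - len(parts)
    msb = ssb / dfb
    msw = ssw / dfw
    if msw == 0.0:
        F = np.inf if msb > 0 else 0.0
        p = 0.0 if msb > 0 else 1.0
    else:
        F = msb / msw
        p = float(f_dist.sf(F, dfb, dfw))
    means = pd.Series({lab: a.mean() for lab, a in parts.items()})
    return AnovaTable(
        F=float(F), df_between=dfb, df_within=dfw, p=p, group_means=means,
        ss_between=float(ssb), ss_within=float(ssw), ms_within=float(msw),
    )


def tukey_hsd(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey–Kramer HSD pairwise comparisons.

    q = |mean_i − mean_j| / sqrt(MSW·(1/n_i + 1/n_j)/2); adjusted p from
    the studentized-range distribution with (n_groups, df_within) degrees
    of freedom; significance flagged at ``alpha``.
    """
    parts = _group_arrays(values, groups)
    anova = one_way_anova(values, groups)
    k = len(parts)
    rows = []
    for ga, gb in combinations(parts, 2):
        a, b = parts[ga], parts[gb]
        diff = a.mean() - b.mean()
        se = np.sqrt(anova.ms_within * (1.0 / len(a) + 1.0 / len(b)) / 2.0)
        if se == 0.0:
            q = 0.0 if diff == 0 else np.inf
            p = 1.0 if diff == 0 else 0.0
        else:
            q = abs(diff) / se
            p = float(studentized_range.sf(q, k, anova.df_within))
        rows.append(
            {"group_a": ga, "group_b": gb, "difference": float(diff),
             "q": float(q), "p_adj": min(1.0, p), "significant": p < alpha}
        )
    return pd.DataFrame(rows)


def anova_with_tukey(values, groups, alpha: float = 0.05) -> AnovaTable:
    """One-way ANOVA with the Tukey HSD table attached."""
    table = one_way_anova(values, groups)
    table.tukey = tukey_hsd(values, groups, alpha=alpha)
    return table
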