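"""Plantar-pressure gait analytics.

Regional peak/mean pressures, vertical ground reaction force (GRF), and
center-of-pressure (CoP) trajectories from stance-phase pressure grids, plus a
non-parametric permutation cluster test that localises %-stance intervals
where two groups of 1-D curves differ.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    ParameterError,
    PressureSeries,
    REGION_SCHEMES,
    region_band,
)

#: Total force (N) below which a frame is considered unloaded and its CoP
#: undefined.
FORCE_THRESHOLD_N = 10.0

#: Number of samples of a time-normalised stance curve (0..100 % inclusive).
STANCE_SAMPLES = 101


class InputError(ValueError):
    """Raised for malformed analysis inputs."""


# ---------------------------------------------------------------------------
# Region map
# ---------------------------------------------------------------------------

@dataclass
class RegionMap:
    """Assignment of sensor cells to anatomical plantar regions.

    ``labels[i, j]`` is the region of cell (row i, col j) or ``""`` for cells
    outside the archetype's scheme (e.g. toe and midfoot cells of the bound
    feet, which never contact the ground).
    """

    labels: np.ndarray            # (R, C) of str
    scheme: str
    foot_length: float
    foot_width: float

    @property
    def regions(self) -> tuple[str, ...]:
        return REGION_SCHEMES[self.scheme]

    @classmethod
    def for_archetype(
        cls,
        scheme: str,
        grid_shape: tuple[int, int],
        foot_length: float,
        foot_width: float,
    ) -> "RegionMap":
        """Build the scheme's region mask on a grid tiling the footprint.

        Rows split into rearfoot/midfoot/forefoot/toe bands along the foot
        length; columns split medial/lateral at the midline (medial = larger
        x, i.e. higher column index). In the toe band the hallux occupies the
        medial 40% of the width; the NF keeps the remaining toes, the bound
        feet do not.
        """
        if scheme not in REGION_SCHEMES:
            raise ParameterError(f"unknown region scheme {scheme!r}")
        rows, cols = grid_shape
        dy = foot_length / rows
        dx = foot_width / cols
        present = set(REGION_SCHEMES[scheme])
        labels = np.full(grid_shape, "", dtype=object)
        for i in range(rows):
            yfrac = (i + 0.5) * dy / foot_length
            for j in range(cols):
                xfrac = (j + 0.5) * dx / foot_width  # 0 lateral -> 1 medial
                medial = xfrac >= 0.5
                if yfrac >= 0.85:
                    name = "hallux" if xfrac >= 0.6 else "other_toes"
                elif yfrac >= 0.60:
                    name = ("medial_" if medial else "lateral_") + "forefoot"
                elif yfrac >= 0.30:
                    name = ("medial_" if medial else "lateral_") + "midfoot"
                else:
                    name = ("medial_" if medial else "lateral_") + "rearfoot"
                if name in present:
                    labels[i, j] = name
        return cls(labels, scheme, foot_length, foot_width)

    def cells(self, region: str) -> np.ndarray:
        """Boolean cell mask of one region."""
        return self.labels == region


# ---------------------------------------------------------------------------
# GRF and CoP
# ---------------------------------------------------------------------------

def compute_grf(series: PressureSeries) -> np.ndarray:
    """Vertical GRF (N) per frame: sum of pressure x cell area.

    1 kPa over 1 mm^2 is 1e-3 N.
    """
    area = series.cell_area
    if not np.isfinite(area) or area <= 0:
        raise InputError("pressure series lacks valid cell-area metadata")
    return series.pressures.sum(axis=(1, 2)) * area * 1e-3


def compute_cop(
    frame: np.ndarray,
    series: PressureSeries,
    force_threshold: float = FORCE_THRESHOLD_N,
) -> tuple[float, float]:
    """Pressure-weighted CoP (x mm, y mm) of a single frame.

    Returns ``(nan, nan)`` when the total force is at or below the threshold.
    The CoP always lies inside the convex hull of the loaded cells.
    """
    frame = np.asarray(frame, float)
    force = frame.sum() * series.cell_area * 1e-3
    if force <= force_threshold:
        return (np.nan, np.nan)
    y, x = series.cell_centers()
    w = frame / frame.sum()
    return float((w.sum(axis=0) * x).sum()), float((w.sum(axis=1) * y).sum())


def stance_frames(
    series: PressureSeries, force_threshold: float = FORCE_THRESHOLD_N
) -> tuple[int, int]:
    """First and last frame (inclusive) with GRF above threshold."""
    grf = compute_grf(series)
    loaded = np.flatnonzero(grf > force_threshold)
    if loaded.size == 0:
        raise InputError("no frame exceeds the force threshold")
    return int(loaded[0]), int(loaded[-1])


def cop_trajectory(
    series: PressureSeries, force_threshold: float = FORCE_THRESHOLD_N
) -> np.ndarray:
    """(F, 2) CoP (x, y) in mm per frame; NaN where unloaded."""
    return np.array(
        [compute_cop(f, series, force_threshold) for f in series.pressures]
    )


@dataclass
class CoPTrajectory:
    """Normalised CoP over stance: x as % of foot width, y as % of length,
    resampled to 101 points of % stance."""

    stance_pct: np.ndarray   # (101,) 0..100
    x_pct: np.ndarray        # (101,)
    y_pct: np.ndarray        # (101,)


def normalize_cop(
    series: PressureSeries,
    foot_length: float,
    foot_width: float,
    force_threshold: float = FORCE_THRESHOLD_N,
) -> CoPTrajectory:
    """Normalise a CoP trajectory to the subject-specific foot dimensions.

    x% = 100 (x - footprint x_min)/width, y% likewise by length, then linear
    resampling of the loaded stance interval onto 101 % -stance points.
    """
    if foot_length <= 0 or foot_width <= 0:
        raise ParameterError("foot dimensions must be positive")
    xy = cop_trajectory(series, force_threshold)
    first, last = stance_frames(series, force_threshold)
    xy = xy[first : last + 1]
    valid = ~np.isnan(xy[:, 0])
    if valid.sum() < 2:
        raise InputError("fewer than two loaded frames in stance")
    # footprint origin: the grid's lower corner, recorded by the series
    x0 = series.origin[1]
    y0 = series.origin[0]
    x_pct = 100.0 * (xy[:, 0] - x0) / foot_width
    y_pct = 100.0 * (xy[:, 1] - y0) / foot_length
    src = np.linspace(0.0, 100.0, len(xy))
    pct = np.linspace(0.0, 100.0, STANCE_SAMPLES)
    # interpolate across any interior masked samples using the valid ones
    xi = np.interp(pct, src[valid], x_pct[valid])
    yi = np.interp(pct, src[valid], y_pct[valid])
    return CoPTrajectory(pct, xi, yi)


# ---------------------------------------------------------------------------
# Regional statistics
# ---------------------------------------------------------------------------

def regional_stats(series: PressureSeries, regions: RegionMap) -> pd.DataFrame:
    """Peak and mean pressure (kPa) per anatomical region.

    Peak: maximum over the region's cells and all frames. Mean: time-and-area
    weighted average over stance (zeros included). Empty regions report 0.
    """
    rows = []
    for name in regions.regions:
        mask = regions.cells(name)
        if not mask.any():
            rows.append({"region": name, "peak_kpa": 0.0, "mean_kpa": 0.0})
            continue
        vals = series.pressures[:, mask]
        rows.append(
            {
                "region": name,
                "peak_kpa": float(vals.max()),
                "mean_kpa": float(vals.mean()),
            }
        )
    return pd.DataFrame(rows).set_index("region")


# ---------------------------------------------------------------------------
# Permutation cluster comparison of stance curves
# ---------------------------------------------------------------------------

@dataclass
class IntervalReport:
    """Clusters of %-stance where two groups of curves differ."""

    intervals: list[tuple[float, float]] = field(default_factory=list)
    p_values: list[float] = field(default_factory=list)
    threshold: float = np.nan
    t_stat: np.ndarray | None = None

    def __bool__(self) -> bool:
        return bool(self.intervals)


def _t_statistic(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = len(a), len(b)
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (ma - mb) / denom, 0.0)
    return t


def _clusters(t: np.ndarray, thresh: float) -> list[tuple[int, int, float]]:
    """Contiguous runs of |t| > thresh as (start, end inclusive, mass)."""
    above = np.abs(t) > thresh
    out = []
    i = 0
    n = len(t)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            out.append((i, j, float(np.abs(t[i : j + 1]).sum())))
            i = j + 1
        else:
            i += 1
    return out


def compare_curves(
    trials_a: list[np.ndarray] | np.ndarray,
    trials_b: list[np.ndarray] | np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 500,
    seed: int = 0,
) -> IntervalReport:
    """Cluster-based permutation test for two groups of stance curves.

    Point-wise two-sample t statistics are thresholded at the two-tailed
    critical value; contiguous supra-threshold runs form clusters scored by
    their summed |t| mass. The null distribution of the maximum cluster mass
    is built by relabelling trials: exhaustively when the number of distinct
    relabelings is at most 500, otherwise by ``n_perm`` seeded Monte-Carlo
    draws. Clusters with p <= alpha are reported as %-stance intervals.

    With tiny groups the attainable p is bounded below by 1/#relabelings
    (e.g. 3+3 trials admit only 20 relabelings, so min p = 0.05).
    """
    a = np.atleast_2d(np.asarray(trials_a, float))
    b = np.atleast_2d(np.asarray(trials_b, float))
    if a.shape[1] != b.shape[1]:
        raise InputError("curve groups must share a common time base")
    if len(a) < 2 or len(b) < 2:
        raise InputError("need at least two trials per group")
    na, nb = len(a), len(b)
    npts = a.shape[1]
    pct = np.linspace(0.0, 100.0, npts)

    df = na + nb - 2
    thresh = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    t_obs = _t_statistic(a, b)
    obs_clusters = _clusters(t_obs, thresh)
    report = IntervalReport(threshold=thresh, t_stat=t_obs)
    if not obs_clusters:
        return report

    pooled = np.vstack([a, b])
    n_total = na + nb
    n_exact = comb(n_total, na)

    def max_mass(idx_a: np.ndarray) -> float:
        sel = np.zeros(n_total, bool)
        sel[idx_a] = True
        cl = _clusters(_t_statistic(pooled[sel], pooled[~sel]), thresh)
        return max((m for _, _, m in cl), default=0.0)

    if n_exact <= 500:
        # exhaustive: the observed labelling is in the null set, so count it
        # once and other relabelings only when strictly more extreme (the
        # complement labelling always ties; with 3+3 trials min p = 1/20)
        null = np.array(
            [max_mass(np.array(c)) for c in itertools.combinations(range(n_total), na)]
        )
        strict = True
        denom = n_exact
    else:
        rng = np.random.default_rng(seed)
        null = np.array(
            [max_mass(rng.permutation(n_total)[:na]) for _ in range(n_perm)]
        )
        strict = False
        denom = n_perm + 1

    for start, end, mass in obs_clusters:
        if strict:
            p = (np.sum(null > mass + 1e-12) + 1) / denom
        else:
            p = (np.sum(null >= mass - 1e-12) + 1) / denom
        if p <= alpha:
            report.intervals.append((float(pct[start]), float(pct[end])))
            report.p_values.append(float(p))
    return report
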