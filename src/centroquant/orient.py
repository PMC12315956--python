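"""Centrosome-orientation statistics: sector rule, rose histogram,
circular summaries, Kuiper's uniformity test and the two-proportion test.

The orientation angle of a cell is the signed angle (counterclockwise
positive, degrees in (−180, 180]) between its nucleus→centrosome vector
and its wound normal; 0° means the centrosome faces the wound.  A
centrosome is "properly located" when its angle lies within a 150°
circular sector facing the wound, i.e. |θ| ≤ 75° (boundary inclusive).
The rose histogram uses 24 bins of exactly 15°, edge-aligned at multiples
of 15° so the sector boundary ±75° falls on bin edges.

Kuiper's test is the rotation-invariant analogue of the Kolmogorov–
Smirnov uniformity test: V = D⁺ + D⁻ computed on the angles mapped to
(0, 1].  The p-value uses Stephens' finite-sample modification
V* = V(√n + 0.155 + 0.24/√n) and the asymptotic series
p = 2 Σ_{j≥1} (4j²V*² − 1) e^{−2j²V*²}.

The between-condition comparison of "properly located" fractions is the
classical two-sample test for equality of proportions with the Yates
half-unit continuity correction; its squared z equals the Yates χ².
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DegenerateDataError, ParameterError

__all__ = [
    "RoseHistogram",
    "OrientationResult",
    "StatTestResult",
    "orientation_angle",
    "classify_sector",
    "rose_histogram",
    "circular_summary",
    "kuiper_uniformity",
    "two_proportion_test",
    "orientation_pipeline",
    "plot_rose",
]

ROSE_BIN_DEG = 15.0
SECTOR_HALFWIDTH_DEG = 75.0


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class RoseHistogram:
    """Angular histogram with 15° bins covering (−180, 180].

    ``bin_edges`` holds the 25 edge values −180, −165, …, 180; bin k
    covers [edges[k], edges[k+1]) with +180 folded into the top bin.
    ``relative_radius`` is each count divided by the maximum count (the
    plotted rose radius), all zero for an empty histogram.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    relative_radius: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class StatTestResult:
    """Generic hypothesis-test output."""

    method: str
    statistic: float
    df: Optional[float]
    n1: Optional[int]
    n2: Optional[int]
    p_two_sided: float
    p_one_sided: float
    direction: str

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class OrientationResult:
    """Per-condition orientation summary (the statistical core of the
    wound-assay readout)."""

    condition: str
    angles_deg: np.ndarray
    n: int
    n_in_sector: int
    prop_in_sector: float
    rose: RoseHistogram
    circ_mean_deg: Optional[float]
    resultant_R: float
    kuiper_V: float
    kuiper_p: float
    sector_halfwidth_deg: float = SECTOR_HALFWIDTH_DEG

    def summary_dict(self) -> dict:
        return {
            "condition": self.condition,
            "n": self.n,
            "n_in_sector": self.n_in_sector,
            "prop_in_sector": self.prop_in_sector,
            "rose_counts": self.rose.counts.tolist(),
            "circ_mean_deg": self.circ_mean_deg,
            "resultant_R": self.resultant_R,
            "kuiper_V": self.kuiper_V,
            "kuiper_p": self.kuiper_p,
            "sector_halfwidth_deg": self.sector_halfwidth_deg,
        }


# ---------------------------------------------------------------------------
# Angles
# ---------------------------------------------------------------------------

def orientation_angle(
    nucleus_yx_um: Sequence[float],
    centrosome_yx_um: Sequence[float],
    wound_normal_yx: Sequence[float],
) -> float:
    """Signed angle (degrees, CCW positive) from wound normal to the
    nucleus→centrosome direction, in (−180, 180].  Z is ignored.

    Raises :class:`DegenerateDataError` when the centrosome coincides with
    the nucleus centroid (the direction is undefined).
    """
    ny, nx = float(wound_normal_yx[0]), float(wound_normal_yx[1])
    vy = float(centrosome_yx_um[0]) - float(nucleus_yx_um[0])
    vx = float(centrosome_yx_um[1]) - float(nucleus_yx_um[1])
    if vy == 0.0 and vx == 0.0:
        raise DegenerateDataError("centrosome coincides with nucleus centroid")
    cross = nx * vy - ny * vx
    dot = nx * vx + ny * vy
    ang = math.degrees(math.atan2(cross, dot))
    return 180.0 if ang == -180.0 else ang


def classify_sector(angle_deg: float,
                    halfwidth_deg: float = SECTOR_HALFWIDTH_DEG) -> bool:
    """True iff the centrosome is properly located: |angle| ≤ halfwidth
    (boundary inclusive)."""
    return abs(angle_deg) <= halfwidth_deg


def rose_histogram(angles_deg: Sequence[float]) -> RoseHistogram:
    """24-bin, 15°-wide angular histogram over (−180, 180].

    +180° is folded into the top bin [165, 180); total counts always
    equal the number of input angles.
    """
    edges = np.arange(-180.0, 180.0 + ROSE_BIN_DEG, ROSE_BIN_DEG)
    angles = np.asarray(angles_deg, float)
    if angles.size == 0:
        zero = np.zeros(24)
        return RoseHistogram(bin_edges=edges, counts=zero.astype(int),
                             relative_radius=zero)
    idx = np.floor((angles + 180.0) / ROSE_BIN_DEG).astype(int)
    idx = np.clip(idx, 0, 23)  # +180 → top bin
    counts = np.bincount(idx, minlength=24)
    rel = counts / counts.max() if counts.max() > 0 else np.zeros(24)
    return RoseHistogram(bin_edges=edges, counts=counts,
                         relative_radius=rel.astype(float))


def circular_summary(angles_deg: Sequence[float]) -> tuple[Optional[float], float]:
    """Circular mean direction and resultant length R.

    Mean = atan2(Σ sin θ, Σ cos θ); R = |Σ e^{iθ}| / n ∈ [0, 1].  When
    R = 0 the mean direction is undefined and returned as ``None``.
    """
    theta = np.radians(np.asarray(angles_deg, float))
    if theta.size == 0:
        raise ParameterError("circular_summary needs at least one angle")
    s, c = np.sum(np.sin(theta)), np.sum(np.cos(theta))
    r = math.hypot(s, c) / theta.size
    if r < 1e-12:
        return None, 0.0
    return math.degrees(math.atan2(s, c)), float(r)


# ---------------------------------------------------------------------------
# Kuiper's test
# ---------------------------------------------------------------------------

def kuiper_uniformity(angles_deg: Sequence[float]) -> tuple[float, float]:
    """Kuiper's V statistic and p-value against circular uniformity.

    Angles are mapped to u = (θ + 180)/360 ∈ (0, 1] and sorted;
    V = D⁺ + D⁻ with D⁺ = max(i/n − u_(i)), D⁻ = max(u_(i) − (i−1)/n).
    The p-value uses Stephens' modified statistic
    V* = V (√n + 0.155 + 0.24/√n) and the series
    p = 2 Σ_{j≥1} (4j²V*² − 1) e^{−2j²V*²}, truncated when terms fall
    below 1e-10 and clamped to [0, 1].  For n < 8 the approximation is
    coarse (the caller should treat p as indicative only).
    """
    angles = np.asarray(angles_deg, float)
    if angles.size == 0:
        raise ParameterError("kuiper_uniformity needs at least one angle")
    n = angles.size
    u = np.sort((angles + 180.0) / 360.0)
    i = np.arange(1, n + 1)
    d_plus = float(np.max(i / n - u))
    d_minus = float(np.max(u - (i - 1) / n))
    v = d_plus + d_minus

    v_star = v * (math.sqrt(n) + 0.155 + 0.24 / math.sqrt(n))
    p = 0.0
    for j in range(1, 1000):
        a = 2.0 * (j * v_star) ** 2
        term = 2.0 * (2.0 * a - 1.0) * math.exp(-a)
        p += term
        if abs(term) < 1e-10:
            break
    return v, float(min(max(p, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Two-proportion test
# ---------------------------------------------------------------------------

def two_proportion_test(
    x1: int, n1: int, x2: int, n2: int, continuity: bool = True,
) -> StatTestResult:
    """Two-sample test for equality of proportions (normal approximation).

    z = (|p̂₁ − p̂₂| − CC) / √(p̂(1 − p̂)(1/n₁ + 1/n₂)) with pooled p̂ and
    the Yates continuity correction CC = ½(1/n₁ + 1/n₂) when requested
    (the corrected difference is clamped at 0).  The statistic reported
    is χ² = z²; without the correction it equals the Pearson χ² of the
    2×2 table.  One-sided p is taken in the observed direction.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1 or not 0 <= x <= n:
            raise ParameterError("need 0 <= x <= n and n >= 1 in both groups")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    direction = "p1_greater" if p1 >= p2 else "p2_greater"
    if pooled in (0.0, 1.0):
        return StatTestResult(
            method="two-sample proportion test"
                   + (" (continuity corrected)" if continuity else ""),
            statistic=0.0, df=1.0, n1=n1, n2=n2,
            p_two_sided=1.0, p_one_sided=0.5, direction=direction,
        )
    diff = abs(p1 - p2)
    if continuity:
        diff = max(diff - 0.5 * (1.0 / n1 + 1.0 / n2), 0.0)
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = diff / se
    p_one = float(norm.sf(z))
    return StatTestResult(
        method="two-sample proportion test"
               + (" (continuity corrected)" if continuity else ""),
        statistic=z * z, df=1.0, n1=n1, n2=n2,
        p_two_sided=min(2.0 * p_one, 1.0), p_one_sided=p_one,
        direction=direction,
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def orientation_pipeline(
    cells: pd.DataFrame,
    condition: str = "",
    sector_halfwidth_deg: float = SECTOR_HALFWIDTH_DEG,
    zone_filter: Optional[str] = "outer",
) -> tuple[OrientationResult, pd.DataFrame]:
    """Angles, sector calls and circular statistics for one condition.

    Filters to ``zone_filter`` cells (default outer — the headline
    readout concerns cells next to the wound) that have an assigned
    centrosome, computes each cell's orientation angle against its own
    wound normal, and assembles the :class:`OrientationResult` plus a
    per-cell table (cell_id, angle_deg, in_sector, zone).

    Raises :class:`DegenerateDataError` when no cell passes the filters.
    """
    df = cells
    if zone_filter is not None:
        df = df[df["zone"] == zone_filter]
        if len(df) == 0:
            raise DegenerateDataError(
                f"no cells in zone {zone_filter!r} (of {len(cells)} total)"
            )
    df = df[df["centrosome_y_um"].notna() & df["centrosome_x_um"].notna()]
    if len(df) == 0:
        raise DegenerateDataError(
            "no cells with an assigned centrosome after zone filtering"
        )
    angles, ids, zones = [], [], []
    skipped = 0
    for row in df.itertuples(index=False):
        try:
            ang = orientation_angle(
                (row.nucleus_y_um, row.nucleus_x_um),
                (row.centrosome_y_um, row.centrosome_x_um),
                (row.wound_normal_y, row.wound_normal_x),
            )
        except DegenerateDataError:
            skipped += 1
            continue
        angles.append(ang)
        ids.append(row.cell_id)
        zones.append(row.zone)
    if not angles:
        raise DegenerateDataError("all centrosome-nucleus vectors degenerate")
    angles_arr = np.asarray(angles)
    in_sector = np.array([classify_sector(a, sector_halfwidth_deg)
                          for a in angles_arr])
    rose = rose_histogram(angles_arr)
    mean_deg, r = circular_summary(angles_arr)
    v, p = kuiper_uniformity(angles_arr)
    result = OrientationResult(
        condition=condition,
        angles_deg=angles_arr,
        n=len(angles_arr),
        n_in_sector=int(in_sector.sum()),
        prop_in_sector=float(in_sector.mean()),
        rose=rose,
        circ_mean_deg=mean_deg,
        resultant_R=r,
        kuiper_V=v,
        kuiper_p=p,
        sector_halfwidth_deg=sector_halfwidth_deg,
    )
    table = pd.DataFrame({
        "cell_id": ids,
        "angle_deg": angles_arr,
        "in_sector": in_sector,
        "zone": zones,
    })
    return result, table


def plot_rose(result: OrientationResult, ax=None):
    """Polar rose plot of an orientation result (radius = relative count,
    0° = wound normal, counterclockwise positive)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    edges = np.radians(result.rose.bin_edges[:-1] + ROSE_BIN_DEG / 2.0)
    ax.bar(edges, result.rose.relative_radius,
           width=np.radians(ROSE_BIN_DEG), edgecolor="k", alpha=0.7)
    ax.set_theta_zero_location("E")
    ax.set_title(f"{result.condition} (n={result.n}, "
                 f"{100 * result.prop_in_sector:.1f}% in sector)")
    return ax
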