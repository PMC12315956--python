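"""smFISH spot-to-centrosome proximity and the between-condition Welch test.

For every cell with at least one smFISH spot and an assigned centrosome,
the readout is the proportion of its spots lying within a fixed radius
(default 2 µm, boundary inclusive) of the nearest centrosome of that
cell.  Distances are 3D Euclidean in µm — voxel indices must be converted
using the anisotropic voxel size before reaching this module — and drop
to 2D automatically when either object lacks a z-coordinate.

Cells with zero spots are excluded (a proportion is undefined), not
scored as zero; the exclusion count is reported.  Conditions are compared
with a one-sided Welch's t test on the per-cell proportions, defaulting
to the "control greater" alternative (depletion is hypothesised to
reduce centrosomal mRNA localisation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ParameterError
from .orient import StatTestResult

__all__ = [
    "ColocRecord",
    "proximity_fraction",
    "welch_t_one_sided",
    "coloc_pipeline",
]

DEFAULT_COLOC_RADIUS_UM = 2.0


@dataclass
class ColocRecord:
    """Per-cell spot-to-centrosome proximity summary."""

    cell_id: int
    n_spots: int
    n_near: int
    radius_um: float

    @property
    def proportion(self) -> float:
        if self.n_spots == 0:
            raise DegenerateDataError("proportion undefined for 0 spots")
        return self.n_near / self.n_spots


def _distances_to_nearest(spots_zyx: np.ndarray,
                          centrosomes_zyx: np.ndarray) -> np.ndarray:
    """Distance from each spot to its nearest centrosome; 2D when either
    side lacks finite z."""
    spots = np.atleast_2d(np.asarray(spots_zyx, float))
    cents = np.atleast_2d(np.asarray(centrosomes_zyx, float))
    use_3d = (np.isfinite(spots[:, 0]).all() and np.isfinite(cents[:, 0]).all())
    if not use_3d:
        spots = spots[:, 1:]
        cents = cents[:, 1:]
    diff = spots[:, None, :] - cents[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=2)).min(axis=1)


def proximity_fraction(
    spots: pd.DataFrame,
    cells: pd.DataFrame,
    radius_um: float = DEFAULT_COLOC_RADIUS_UM,
) -> tuple[list[ColocRecord], dict]:
    """Per-cell proportion of spots within ``radius_um`` of a centrosome.

    ``spots`` needs columns ``cell_id, z_um, y_um, x_um`` (z may be NaN
    for 2D data); ``cells`` needs ``cell_id`` and centrosome coordinates
    (NaN centrosome = no centrosome).  A spot counts as *near* when its
    distance to the nearest centrosome of its own cell is ≤ radius
    (inclusive at exactly the radius).  Cells with zero spots or no
    centrosome are excluded; the tally is returned alongside the records.
    """
    if radius_um <= 0:
        raise ParameterError("radius must be > 0")
    records: list[ColocRecord] = []
    excluded = {"no_spots": 0, "no_centrosome": 0}
    spots_by_cell = dict(iter(spots.groupby("cell_id"))) if len(spots) else {}
    for row in cells.itertuples(index=False):
        has_centrosome = (
            np.isfinite(row.centrosome_y_um) and np.isfinite(row.centrosome_x_um)
        )
        cell_spots = spots_by_cell.get(row.cell_id)
        if cell_spots is None or len(cell_spots) == 0:
            excluded["no_spots"] += 1
            continue
        if not has_centrosome:
            excluded["no_centrosome"] += 1
            continue
        cz = getattr(row, "centrosome_z_um", float("nan"))
        d = _distances_to_nearest(
            cell_spots[["z_um", "y_um", "x_um"]].to_numpy(float),
            np.array([[cz, row.centrosome_y_um, row.centrosome_x_um]]),
        )
        n_near = int(np.sum(d <= radius_um))
        records.append(ColocRecord(cell_id=row.cell_id,
                                   n_spots=len(cell_spots),
                                   n_near=n_near, radius_um=radius_um))
    return records, excluded


def welch_t_one_sided(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "A_greater",
) -> StatTestResult:
    """Welch's unequal-variance t test between two groups of proportions.

    t = (x̄_A − x̄_B) / √(s²_A/n_A + s²_B/n_B) with Welch–Satterthwaite
    degrees of freedom; one-sided p against the requested alternative
    (``A_greater`` or ``B_greater``).
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each group needs n >= 2 for Welch's t test")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise DegenerateDataError("both groups have zero variance")
    if alternative not in ("A_greater", "B_greater"):
        raise ParameterError("alternative must be 'A_greater' or 'B_greater'")
    scipy_alt = "greater" if alternative == "A_greater" else "less"
    res_one = stats.ttest_ind(a, b, equal_var=False, alternative=scipy_alt)
    res_two = stats.ttest_ind(a, b, equal_var=False, alternative="two-sided")
    return StatTestResult(
        method="Welch two-sample t test",
        statistic=float(res_one.statistic),
        df=float(res_one.df),
        n1=len(a), n2=len(b),
        p_two_sided=float(res_two.pvalue),
        p_one_sided=float(res_one.pvalue),
        direction=alternative,
    )


def coloc_pipeline(
    condition_data: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    radius_um: float = DEFAULT_COLOC_RADIUS_UM,
    alternative: str = "A_greater",
    compare: Optional[tuple[str, str]] = None,
) -> tuple[pd.DataFrame, Optional[StatTestResult], dict]:
    """Proximity proportions per condition plus the Welch comparison.

    ``condition_data`` maps condition label → (spots table, cells table).
    ``compare`` names the (A, B) pair to test; with exactly two
    conditions it defaults to their insertion order.  Returns a long
    per-cell table (condition, cell_id, n_spots, n_near, proportion), the
    test result (``None`` if no pair to compare), and the per-condition
    exclusion tallies.
    """
    frames = []
    exclusions: dict[str, dict] = {}
    for label, (spots, cells) in condition_data.items():
        records, excluded = proximity_fraction(spots, cells, radius_um)
        if not records:
            raise DegenerateDataError(
                f"condition {label!r} has no eligible cells "
                f"(excluded: {excluded})"
            )
        frames.append(pd.DataFrame({
            "condition": label,
            "cell_id": [r.cell_id for r in records],
            "n_spots": [r.n_spots for r in records],
            "n_near": [r.n_near for r in records],
            "proportion": [r.proportion for r in records],
        }))
        exclusions[label] = excluded
    table = pd.concat(frames, ignore_index=True)

    test = None
    labels = list(condition_data)
    if compare is None and len(labels) == 2:
        compare = (labels[0], labels[1])
    if compare is not None:
        a = table.loc[table["condition"] == compare[0], "proportion"]
        b = table.loc[table["condition"] == compare[1], "proportion"]
        try:
            test = welch_t_one_sided(a.to_numpy(), b.to_numpy(),
                                     alternative=alternative)
        except DegenerateDataError:
            # e.g. every proportion identical in both groups; the per-cell
            # table is still informative, so report the test as undefined
            test = None
    return table, test, exclusions
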