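"""Synthetic wound-healing fields with coordinate ground truth and rendering.

The generator emulates the geometry of a scratch / insert-gap migration
assay: a confluent monolayer with a straight cell-free band (the wound),
nuclei packed without overlap on both sides, and one centrosome per cell
displaced from the nucleus centroid by a fixed distance at an angle drawn
from a von Mises distribution centred on that cell's wound normal.  smFISH
puncta are scattered in the cytoplasm with a configurable fraction placed
within the colocalization radius of the cell's centrosome.

The angular model is the von Mises family: ``f(θ) ∝ exp(κ cos(θ − µ))``,
the minimal unimodal circular distribution.  ``κ = 0`` is the circular
uniform; the concentration κ is the single dial controlling how strongly
centrosomes face the wound.  :func:`calibrate_kappa` inverts the sector
probability so a preset can be pinned to a target fraction of "properly
located" centrosomes (e.g. 70% within ±75°).

Everything is deterministic given the master seed: per-stage child
generators are derived with :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import integrate, special
from scipy.optimize import brentq

from .errors import GenerationError, ParameterError, RenderError
from .stacks import ImageStack

__all__ = [
    "WoundGeometry",
    "SynthConfig",
    "Optics",
    "SyntheticField",
    "sample_orientation_angles",
    "sector_probability",
    "calibrate_kappa",
    "generate_field",
    "render_stack",
    "control_kappa",
    "depleted_kappa",
    "preset_config",
]

UNIFORM_SECTOR_75 = 150.0 / 360.0  # sector measure of ±75° under uniformity


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WoundGeometry:
    """A straight cell-free band in the monolayer plane.

    ``axis`` runs along the band, ``normal`` is perpendicular to it; both
    are unit 2-vectors in ``(y, x)`` order.  A point ``p`` lies inside the
    wound iff ``band[0] <= p·normal <= band[1]`` (signed offsets in µm).
    The per-cell wound normal (the 0° reference for orientation angles)
    points from the cell toward the nearer band edge, so it equals
    ``+normal`` on one side of the band and ``-normal`` on the other.
    """

    axis: tuple[float, float]
    normal: tuple[float, float]
    band: tuple[float, float]

    def __post_init__(self) -> None:
        a = np.asarray(self.axis, float)
        n = np.asarray(self.normal, float)
        if not (math.isclose(np.linalg.norm(a), 1.0, abs_tol=1e-9)
                and math.isclose(np.linalg.norm(n), 1.0, abs_tol=1e-9)):
            raise ParameterError("axis and normal must be unit vectors")
        if abs(float(a @ n)) > 1e-9:
            raise ParameterError("axis must be perpendicular to normal")
        if not self.band[0] < self.band[1]:
            raise ParameterError("band lower offset must be < upper offset")

    def signed_offset(self, points_yx: np.ndarray) -> np.ndarray:
        """Coordinate of each (y, x) point along the band normal."""
        pts = np.atleast_2d(np.asarray(points_yx, float))
        return pts @ np.asarray(self.normal, float)

    def edge_distance(self, points_yx: np.ndarray) -> np.ndarray:
        """Distance from each point to the nearer band-edge line (0 inside)."""
        s = self.signed_offset(points_yx)
        lo, hi = self.band
        return np.where(s < lo, lo - s, np.where(s > hi, s - hi, 0.0))

    def cell_normals(self, points_yx: np.ndarray) -> np.ndarray:
        """Per-point unit vector toward the wound band, shape (n, 2)."""
        s = self.signed_offset(points_yx)
        n = np.asarray(self.normal, float)
        mid = 0.5 * (self.band[0] + self.band[1])
        sign = np.where(s <= mid, 1.0, -1.0)
        return sign[:, None] * n[None, :]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _default_wound() -> WoundGeometry:
    return WoundGeometry(axis=(0.0, 1.0), normal=(1.0, 0.0), band=(-20.0, 20.0))


@dataclass
class SynthConfig:
    """Parameters of one synthetic field.

    Lengths in µm, angles in degrees.  ``mu_deg`` is the mean centrosome
    direction *relative to each cell's wound normal* (0° = facing the
    wound); ``kappa`` is the von Mises concentration (0 = uniform).
    ``centrosome_spot_fraction`` is the expected fraction of each cell's
    smFISH spots placed within ``coloc_radius_um`` of its centrosome.
    ``noise`` is ``(poisson_scale, gaussian_sd)``: photon shot noise is
    Poisson on the signal scaled by ``poisson_scale`` and read noise is
    additive Gaussian.
    """

    n_cells: int = 200
    kappa: float = 0.0
    mu_deg: float = 0.0
    wound: WoundGeometry = field(default_factory=_default_wound)
    nucleus_radius_um: float = 5.0
    centrosome_offset_um: float = 5.0  # juxtanuclear: one nucleus radius
    spots_per_cell: int = 20
    centrosome_spot_fraction: float = 0.3
    coloc_radius_um: float = 2.0
    voxel_um: tuple[float, float, float] = (0.6, 0.2841, 0.2841)
    noise: tuple[float, float] = (1.0, 2.0)
    seed: int = 0
    # Packing details.  min-centre-distance factor 2.2 × nucleus radius keeps
    # nuclei disjoint; zone_margin_um keeps nuclei off the outer/inner
    # boundary line so ground-truth zone labels are unambiguous.
    min_spacing_factor: float = 2.2
    zone_margin_um: float = 3.0
    field_size_um: Optional[tuple[float, float]] = None  # (extent along axis, strip depth)
    max_retries: int = 10_000

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ParameterError("n_cells must be >= 0")
        if self.kappa < 0:
            raise ParameterError("kappa must be >= 0")
        if not 0.0 <= self.centrosome_spot_fraction <= 1.0:
            raise ParameterError("centrosome_spot_fraction must be in [0, 1]")
        if self.spots_per_cell < 0:
            raise ParameterError("spots_per_cell must be >= 0")
        for name in ("nucleus_radius_um", "centrosome_offset_um", "coloc_radius_um"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if any(v <= 0 for v in self.voxel_um):
            raise ParameterError("voxel sizes must be > 0")
        if any(v < 0 for v in self.noise):
            raise ParameterError("noise terms must be >= 0")

    @property
    def d_outer_um(self) -> float:
        """Ground-truth outer-zone depth: 1.5 × nucleus equivalent diameter."""
        return 1.5 * 2.0 * self.nucleus_radius_um


@dataclass
class Optics:
    """Rendering parameters: PSF widths and nominal amplitudes per channel.

    Point sources are rendered as anisotropic 3D Gaussians whose *total*
    (integrated) intensity equals the nominal amplitude; nuclei are
    rendered as smoothed disks (top-hat of the nucleus radius convolved
    with a small Gaussian) with a Gaussian axial profile.  Default
    amplitudes give a centrosome-spot peak SNR of roughly 10 against the
    default Poisson + read noise on a background of 20 counts.
    """

    psf_sigma_um: tuple[float, float, float] = (0.7, 0.3, 0.3)  # (z, y, x)
    nucleus_edge_sigma_um: float = 0.5
    nucleus_z_sigma_um: float = 1.5
    nucleus_peak: float = 150.0
    centrosome_amplitude: float = 1000.0
    fish_amplitude: float = 600.0
    background: float = 20.0
    pad_um: float = 4.0


# ---------------------------------------------------------------------------
# Ground-truth records
# ---------------------------------------------------------------------------

@dataclass
class SyntheticField:
    """Ground truth of one generated field.

    ``cells`` has one row per cell: nucleus centroid, centrosome position
    (the angle recorded in ``true_angle_deg`` is exactly the angle used to
    place the centrosome), zone label and per-cell wound normal.
    ``spots`` has one row per smFISH punctum with its placement flag.
    """

    cells: pd.DataFrame
    spots: pd.DataFrame
    wound: WoundGeometry
    config: SynthConfig

    def write_csv(self, out_dir: Union[str, Path]) -> tuple[Path, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cells_path = out / "cells.csv"
        spots_path = out / "spots.csv"
        self.cells.to_csv(cells_path, index=False)
        self.spots.to_csv(spots_path, index=False)
        return cells_path, spots_path


_CELL_COLUMNS = [
    "cell_id", "nucleus_y_um", "nucleus_x_um",
    "centrosome_z_um", "centrosome_y_um", "centrosome_x_um",
    "zone", "true_angle_deg", "wound_normal_y", "wound_normal_x",
    "centrosome_rel_amp",
]
_SPOT_COLUMNS = [
    "spot_id", "cell_id", "channel", "z_um", "y_um", "x_um",
    "near_centrosome_flag",
]


# ---------------------------------------------------------------------------
# Angular model
# ---------------------------------------------------------------------------

def _wrap_deg(angles: np.ndarray) -> np.ndarray:
    """Wrap to the half-open interval (−180, 180]."""
    wrapped = np.mod(np.asarray(angles, float) + 180.0, 360.0) - 180.0
    return np.where(wrapped == -180.0, 180.0, wrapped)


def sample_orientation_angles(
    n: int,
    kappa: float,
    mu_deg: float = 0.0,
    seed: Union[int, np.random.Generator] = 0,
) -> np.ndarray:
    """Draw ``n`` i.i.d. von Mises angles, in degrees in (−180, 180].

    ``kappa = 0`` reduces to the circular uniform distribution.
    """
    if n < 0:
        raise ParameterError("n must be >= 0")
    if kappa < 0:
        raise ParameterError("kappa must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = rng.vonmises(math.radians(mu_deg), kappa, size=int(n))
    return _wrap_deg(np.degrees(theta))


def sector_probability(kappa: float, halfwidth_deg: float = 75.0) -> float:
    """P(|θ| ≤ halfwidth) under von Mises(0, κ), by adaptive quadrature.

    The integrand uses the exponentially scaled Bessel normalisation
    ``exp(κ(cos θ − 1)) / (2π I0e(κ))`` so large κ stays finite.
    Absolute error below 1e-8.
    """
    if kappa < 0:
        raise ParameterError("kappa must be >= 0")
    if not 0.0 < halfwidth_deg <= 180.0:
        raise ParameterError("halfwidth must be in (0, 180]")
    if halfwidth_deg == 180.0:
        return 1.0
    hw = math.radians(halfwidth_deg)
    norm = 2.0 * math.pi * special.i0e(kappa)

    def density(t: float) -> float:
        return math.exp(kappa * (math.cos(t) - 1.0)) / norm

    value, _ = integrate.quad(density, -hw, hw, epsabs=1e-12, limit=200)
    return float(min(value, 1.0))


def calibrate_kappa(target_prob: float, halfwidth_deg: float = 75.0) -> float:
    """Concentration κ whose ±halfwidth sector probability equals the target.

    Solved by monotone bracketing + Brent root-finding against
    :func:`sector_probability`; |sector_probability(κ) − target| < 1e-6.
    Raises if the target is below the uniform sector measure or ≥ 1.
    """
    baseline = halfwidth_deg * 2.0 / 360.0  # uniform sector measure
    if not baseline <= target_prob < 1.0:
        raise ParameterError(
            f"target probability must be in [{baseline:.5f}, 1); got {target_prob}"
        )
    if math.isclose(target_prob, baseline, abs_tol=1e-12):
        return 0.0
    hi = 1.0
    while sector_probability(hi, halfwidth_deg) < target_prob:
        hi *= 2.0
        if hi > 1e8:  # pragma: no cover - unreachable for target < 1
            raise ParameterError("target probability too close to 1")
    kappa = brentq(
        lambda k: sector_probability(k, halfwidth_deg) - target_prob,
        0.0, hi, xtol=1e-10,
    )
    return float(kappa)


def control_kappa() -> float:
    """κ calibrated so 70% of angles fall in the ±75° sector (≈ 0.98)."""
    return calibrate_kappa(0.70, 75.0)


def depleted_kappa() -> float:
    """κ calibrated so 54% of angles fall in the ±75° sector (≈ 0.40)."""
    return calibrate_kappa(0.54, 75.0)


def preset_config(preset: str, **overrides) -> SynthConfig:
    """Named condition presets: ``control`` (70% in-sector), ``depleted``
    (54%), ``uniform`` (κ=0)."""
    presets = {
        "control": control_kappa,
        "depleted": depleted_kappa,
        "uniform": lambda: 0.0,
    }
    if preset not in presets:
        raise ParameterError(f"unknown preset {preset!r}; choose {sorted(presets)}")
    overrides.setdefault("kappa", presets[preset]())
    return SynthConfig(**overrides)


# ---------------------------------------------------------------------------
# Field generation
# ---------------------------------------------------------------------------

def _field_extent(config: SynthConfig) -> tuple[float, float]:
    """(length along wound axis, monolayer strip depth), both µm."""
    if config.field_size_um is not None:
        return config.field_size_um
    dmin = config.min_spacing_factor * config.nucleus_radius_um
    # rejection sampling saturates well below RSA density; 2.6 dmin² per
    # cell keeps packing failures out of reach at the default retry budget
    area = max(config.n_cells, 1) * 2.6 * dmin * dmin
    length = math.sqrt(area)
    depth = area / (2.0 * length)
    return (length, depth)


def generate_field(config: SynthConfig) -> SyntheticField:
    """Generate one field: packed nuclei, centrosomes, smFISH spots.

    Nuclei are placed by rejection sampling on both monolayer strips with
    minimum centre distance ``min_spacing_factor × nucleus_radius``
    (default 2.2 radii, i.e. just-disjoint nuclei).  Each cell's centrosome sits at ``nucleus + offset · R(θ) n̂`` where n̂
    is that cell's wound normal and θ its sampled von Mises angle —
    ``true_angle_deg`` records θ exactly.  Fails with
    :class:`GenerationError` if packing stalls for ``max_retries``
    consecutive rejections.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_pos, rng_ang, rng_spot, rng_amp = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    wound = config.wound
    r = config.nucleus_radius_um
    dmin = config.min_spacing_factor * r
    length, depth = _field_extent(config)
    lo, hi = wound.band
    axis = np.asarray(wound.axis, float)
    normal = np.asarray(wound.normal, float)

    # admissible normal-offsets: outside the band by at least one radius,
    # within the strips, and off the zone-boundary line by the margin
    d_outer = config.d_outer_um
    margin = config.zone_margin_um

    def admissible(s_off: float) -> bool:
        d = min(abs(s_off - lo), abs(s_off - hi))
        if lo - r < s_off < hi + r:
            return False
        edge = (lo - s_off) if s_off < lo else (s_off - hi)
        return abs(edge - d_outer) > margin

    centers: list[np.ndarray] = []
    fails = 0
    while len(centers) < config.n_cells:
        t = rng_pos.uniform(0.0, length)
        side = 1.0 if rng_pos.uniform() < 0.5 else -1.0
        s_off = (hi + r + rng_pos.uniform(0.0, depth)) if side > 0 else (
            lo - r - rng_pos.uniform(0.0, depth))
        if not admissible(s_off):
            fails += 1
            if fails > config.max_retries:
                raise GenerationError(
                    f"nucleus packing failed after {config.max_retries} retries "
                    f"({len(centers)}/{config.n_cells} placed); enlarge the field"
                )
            continue
        pos = t * axis + s_off * normal  # (y, x)
        if centers and np.min(
            np.linalg.norm(np.asarray(centers) - pos, axis=1)
        ) < dmin:
            fails += 1
            if fails > config.max_retries:
                raise GenerationError(
                    f"nucleus packing failed after {config.max_retries} retries "
                    f"({len(centers)}/{config.n_cells} placed); enlarge the field"
                )
            continue
        centers.append(pos)
        fails = 0

    if config.n_cells == 0:
        cells = pd.DataFrame(columns=_CELL_COLUMNS)
        spots = pd.DataFrame(columns=_SPOT_COLUMNS)
        return SyntheticField(cells=cells, spots=spots, wound=wound, config=config)

    centers_arr = np.asarray(centers)
    normals = wound.cell_normals(centers_arr)
    edge_d = wound.edge_distance(centers_arr)
    zones = np.where(edge_d <= d_outer, "outer", "inner")

    angles = sample_orientation_angles(
        config.n_cells, config.kappa, config.mu_deg, seed=rng_ang
    )
    theta = np.radians(angles)
    # rotate each cell's wound normal by θ counterclockwise (x right, y up)
    ny, nx = normals[:, 0], normals[:, 1]
    dir_x = nx * np.cos(theta) - ny * np.sin(theta)
    dir_y = nx * np.sin(theta) + ny * np.cos(theta)
    cent_yx = centers_arr + config.centrosome_offset_um * np.stack(
        [dir_y, dir_x], axis=1
    )
    z_mid = 0.0
    cent_z = z_mid + np.clip(rng_pos.normal(0.0, 0.4, config.n_cells), -1.0, 1.0)
    rel_amp = np.exp(rng_amp.normal(0.0, 0.15, config.n_cells))

    cells = pd.DataFrame({
        "cell_id": np.arange(config.n_cells),
        "nucleus_y_um": centers_arr[:, 0],
        "nucleus_x_um": centers_arr[:, 1],
        "centrosome_z_um": cent_z,
        "centrosome_y_um": cent_yx[:, 0],
        "centrosome_x_um": cent_yx[:, 1],
        "zone": zones,
        "true_angle_deg": angles,
        "wound_normal_y": normals[:, 0],
        "wound_normal_x": normals[:, 1],
        "centrosome_rel_amp": rel_amp,
    })

    spots = _place_spots(config, cells, rng_spot)
    return SyntheticField(cells=cells, spots=spots, wound=wound, config=config)


def _place_spots(config: SynthConfig, cells: pd.DataFrame,
                 rng: np.random.Generator) -> pd.DataFrame:
    """smFISH ground truth: per cell, Binomial(spots_per_cell, fraction)
    spots inside 0.9 × coloc radius of the centrosome, the rest in the
    cytoplasm strictly outside 1.1 × coloc radius."""
    rows = []
    n_spots = config.spots_per_cell
    if n_spots == 0 or len(cells) == 0:
        return pd.DataFrame(columns=_SPOT_COLUMNS)
    rad = config.coloc_radius_um
    cell_extent = config.min_spacing_factor * config.nucleus_radius_um
    spot_id = 0
    for row in cells.itertuples(index=False):
        cz, cy, cx = row.centrosome_z_um, row.centrosome_y_um, row.centrosome_x_um
        k_near = rng.binomial(n_spots, config.centrosome_spot_fraction)
        for _ in range(k_near):
            # uniform in a 3D ball of radius 0.9 rad around the centrosome
            while True:
                off = rng.uniform(-1.0, 1.0, 3)
                if np.sum(off * off) <= 1.0:
                    break
            off *= 0.9 * rad
            rows.append((spot_id, row.cell_id, "fish",
                         cz + off[0], cy + off[1], cx + off[2], True))
            spot_id += 1
        placed = 0
        while placed < n_spots - k_near:
            yx = rng.uniform(-cell_extent, cell_extent, 2)
            z = rng.uniform(-1.5, 1.5)
            pos = np.array([z, row.nucleus_y_um + yx[0], row.nucleus_x_um + yx[1]])
            d = np.linalg.norm(pos - np.array([cz, cy, cx]))
            if d <= 1.1 * rad:
                continue
            rows.append((spot_id, row.cell_id, "fish",
                         pos[0], pos[1], pos[2], False))
            spot_id += 1
            placed += 1
    return pd.DataFrame(rows, columns=_SPOT_COLUMNS)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _gaussian_kernel_window(shape_zyx, center_vox, half_extent):
    """Local window slices plus voxel-centre offsets for one punctum."""
    slices, grids = [], []
    for ax in range(3):
        c = center_vox[ax]
        h = half_extent[ax]
        a = max(int(math.floor(c - h)), 0)
        b = min(int(math.ceil(c + h)) + 1, shape_zyx[ax])
        if a >= b:
            return None, None
        slices.append(slice(a, b))
        grids.append(np.arange(a, b, dtype=float) - c)
    return tuple(slices), grids


def render_stack(field: SyntheticField, optics: Optional[Optics] = None,
                 rng: Optional[np.random.Generator] = None) -> ImageStack:
    """Render a field as a noisy multi-channel stack with voxel metadata.

    Channels: ``dapi`` (nuclei as smoothed disks), ``centrosome``
    (puncta, one per cell, total intensity = ``centrosome_amplitude`` ×
    the cell's relative amplitude), and ``fish`` when the field has
    spots.  Each punctum's kernel is normalised over its rendering window
    so its integrated (pre-noise) intensity equals its nominal amplitude
    to well within 1%.  Noise follows the config: Poisson on the scaled
    signal plus additive Gaussian read noise.
    """
    optics = optics or Optics()
    config = field.config
    vz, vy, vx = config.voxel_um
    cells, spots = field.cells, field.spots

    pts = [np.zeros((0, 3))]
    if len(cells):
        pts.append(cells[["centrosome_z_um", "centrosome_y_um",
                          "centrosome_x_um"]].to_numpy(float))
        nuc = cells[["nucleus_y_um", "nucleus_x_um"]].to_numpy(float)
        pts.append(np.column_stack([np.zeros(len(nuc)), nuc]))
    if len(spots):
        pts.append(spots[["z_um", "y_um", "x_um"]].to_numpy(float))
    allpts = np.vstack(pts)
    if len(allpts) == 0:
        allpts = np.zeros((1, 3))

    pad = optics.pad_um
    rpad = config.nucleus_radius_um + pad
    z_lo = allpts[:, 0].min() - 3.0 * optics.psf_sigma_um[0] - 0.5
    z_hi = allpts[:, 0].max() + 3.0 * optics.psf_sigma_um[0] + 0.5
    y_lo, y_hi = allpts[:, 1].min() - rpad, allpts[:, 1].max() + rpad
    x_lo, x_hi = allpts[:, 2].min() - rpad, allpts[:, 2].max() + rpad
    origin = np.array([z_lo, y_lo, x_lo])
    nzyx = (
        int(math.ceil((z_hi - z_lo) / vz)) + 1,
        int(math.ceil((y_hi - y_lo) / vy)) + 1,
        int(math.ceil((x_hi - x_lo) / vx)) + 1,
    )
    if any(n <= 0 for n in nzyx) or np.prod(nzyx) > 5e8:
        raise RenderError(f"field extent yields unreasonable stack shape {nzyx}")

    names = ["dapi", "centrosome"] + (["fish"] if len(spots) else [])
    data = np.full((len(names),) + nzyx, optics.background, dtype=np.float64)

    def to_vox(p_um: np.ndarray) -> np.ndarray:
        return (np.asarray(p_um, float) - origin) / np.array([vz, vy, vx])

    sigma_vox = np.array(optics.psf_sigma_um) / np.array([vz, vy, vx])

    # --- nuclei: smoothed disk, Gaussian axial profile ---
    if len(cells):
        ch = data[0]
        edge_s = optics.nucleus_edge_sigma_um
        rad = config.nucleus_radius_um
        zsig_vox = optics.nucleus_z_sigma_um / vz
        half = (3.0 * zsig_vox, (rad + 3 * edge_s) / vy + 1, (rad + 3 * edge_s) / vx + 1)
        for row in cells.itertuples(index=False):
            cvox = to_vox([0.0, row.nucleus_y_um, row.nucleus_x_um])
            win, grids = _gaussian_kernel_window(nzyx, cvox, half)
            if win is None:
                continue
            gz, gy, gx = grids
            rho = np.sqrt((gy[:, None] * vy) ** 2 + (gx[None, :] * vx) ** 2)
            lateral = 0.5 * special.erfc((rho - rad) / (math.sqrt(2.0) * edge_s))
            zprof = np.exp(-0.5 * (gz / zsig_vox) ** 2)
            ch[win] += optics.nucleus_peak * zprof[:, None, None] * lateral[None, :, :]

    # --- puncta: normalised anisotropic Gaussians ---
    def add_puncta(ch: np.ndarray, positions_um: np.ndarray, amps: np.ndarray):
        half = tuple(5.0 * s + 1 for s in sigma_vox)
        for p, amp in zip(positions_um, amps):
            cvox = to_vox(p)
            win, grids = _gaussian_kernel_window(nzyx, cvox, half)
            if win is None:
                raise RenderError(f"punctum at {p} falls outside the stack")
            k = np.exp(-0.5 * (grids[0] / sigma_vox[0]) ** 2)[:, None, None] \
                * np.exp(-0.5 * (grids[1] / sigma_vox[1]) ** 2)[None, :, None] \
                * np.exp(-0.5 * (grids[2] / sigma_vox[2]) ** 2)[None, None, :]
            ch[win] += amp * k / k.sum()

    if len(cells):
        add_puncta(
            data[1],
            cells[["centrosome_z_um", "centrosome_y_um", "centrosome_x_um"]]
            .to_numpy(float),
            optics.centrosome_amplitude
            * cells["centrosome_rel_amp"].to_numpy(float),
        )
    if len(spots):
        add_puncta(
            data[2],
            spots[["z_um", "y_um", "x_um"]].to_numpy(float),
            np.full(len(spots), optics.fish_amplitude),
        )

    poisson_scale, gaussian_sd = config.noise
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    if poisson_scale > 0:
        data = rng.poisson(np.clip(data, 0, None) * poisson_scale) / poisson_scale
    if gaussian_sd > 0:
        data = data + rng.normal(0.0, gaussian_sd, data.shape)

    stack = ImageStack(
        pixels=data.astype(np.float32),
        voxel_um=(vz, vy, vx),
        channel_names=names,
    )
    # record the physical origin so detected voxel coordinates can be
    # mapped back onto the ground-truth frame
    stack.origin_um = tuple(origin)  # type: ignore[attr-defined]
    return stack
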