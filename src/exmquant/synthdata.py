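"""Synthetic ground-truth generators for every analysis stage.

All generators are deterministic given their seed (``numpy`` Generator,
PCG64). Physical frame: nm coordinates, pixel ``(i, j)`` centered at
``((j + 0.5) * pixel_size, (i + 0.5) * pixel_size)``.

The defaults for quantities the underlying imaging experiments do not pin
down (spots per corner, localization jitter) are modeling assumptions, not
measured values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import skimage.draw

from exmquant.npc_symmetry import PointCloud
from exmquant.profiles import LineProfile

__all__ = [
    "NPCSimParams",
    "ChainSimParams",
    "NucleusSimParams",
    "FieldError",
    "gen_npc_pointcloud",
    "gen_npc_cohort",
    "render_image",
    "gen_sideview_profile",
    "gen_periodic_chain",
    "gen_nuclei_mask",
    "gen_ring_image",
    "gen_striped_profile",
]


class FieldError(ValueError):
    """A generated object does not fit in the requested field."""


def _rng(seed, rng):
    return rng if rng is not None else np.random.default_rng(seed)


@dataclass
class NPCSimParams:
    """Top-view ring particle: s corners on a circle, incomplete labeling."""

    ring_diameter: float = 107.0  # nm, corrected (true) scale
    symmetry: int = 8
    p_label: float = 1.0  # per-corner labeling probability
    points_per_corner: float = 20.0  # Poisson mean per labeled corner
    loc_noise_sd: float = 0.0  # nm, isotropic localization jitter
    rotation: Union[float, str] = "random"  # radians, or "random"
    expansion_factor: float = 1.0  # physical diameter = ring_diameter * EF
    pixel_size: float = 10.0  # nm / pixel (rendering)
    spot_sigma: float = 10.0  # nm (rendering blur)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_label <= 1:
            raise ValueError("p_label must be in [0, 1]")
        if self.ring_diameter <= 0:
            raise ValueError("ring_diameter must be positive")
        if self.symmetry < 2:
            raise ValueError("symmetry must be >= 2")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.points_per_corner < 0 or self.loc_noise_sd < 0:
            raise ValueError("points_per_corner and loc_noise_sd must be >= 0")


@dataclass
class ChainSimParams:
    """Periodic dot chain along a line (missed dots, interval jitter)."""

    period: float = 58.0  # nm
    n_dots: int = 34
    jitter_sd: float = 0.0  # nm, per-dot displacement about the lattice
    miss_prob: float = 0.0
    dot_sigma: float = 6.0  # nm, rendered dot width
    render_step_nm: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.n_dots < 2:
            raise ValueError("n_dots must be >= 2")
        if not 0 <= self.miss_prob <= 1:
            raise ValueError("miss_prob must be in [0, 1]")


@dataclass
class NucleusSimParams:
    """Elliptical nucleus masks with a stated cross-section distribution.

    sqrt(area) of each nucleus is drawn from
    N(ncs_mean * gel_expansion, (ncs_sd * gel_expansion)^2), resampled if
    non-positive (keeps the stated mean unbiased versus clipping).
    """

    n_nuclei: int = 10
    ncs_mean: float = 16.7  # um
    ncs_sd: float = 2.0  # um
    ellipticity_range: tuple[float, float] = (0.7, 1.0)  # minor/major axis ratio
    gel_expansion: float = 1.0
    pixel_size: float = 400.0  # nm / pixel
    field_px: tuple[int, int] = (1024, 1024)  # (rows, cols)
    max_attempts: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ncs_mean <= 0:
            raise ValueError("ncs_mean must be positive")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        a, b = self.ellipticity_range
        if not 0 < a <= b <= 1:
            raise ValueError("ellipticity_range must satisfy 0 < a <= b <= 1")


def gen_npc_pointcloud(
    params: NPCSimParams, rng: np.random.Generator | None = None
) -> tuple[PointCloud, dict]:
    """One simulated particle: each corner is labeled independently with
    probability ``p_label``; a labeled corner contributes Poisson-many points
    on the ring at its corner angle, displaced by isotropic Gaussian jitter.

    Returns the point cloud (centered at the true particle center, which is
    the origin of its nm frame) and a ground-truth dict with the labeled
    mask, rotation, and per-corner point counts.
    """
    rng = _rng(params.seed, rng)
    s = params.symmetry
    rotation = (
        float(rng.uniform(0, 2 * np.pi / s))
        if isinstance(params.rotation, str)
        else float(params.rotation)
    )
    labeled = rng.random(s) < params.p_label
    n_points = np.where(labeled, rng.poisson(params.points_per_corner, size=s), 0)
    radius = params.ring_diameter * params.expansion_factor / 2.0
    xs, ys = [], []
    for k in range(s):
        if n_points[k] == 0:
            continue
        ang = rotation + 2 * np.pi * k / s
        x0, y0 = radius * np.cos(ang), radius * np.sin(ang)
        xs.append(x0 + rng.normal(0, params.loc_noise_sd, n_points[k]))
        ys.append(y0 + rng.normal(0, params.loc_noise_sd, n_points[k]))
    if xs:
        pts = np.column_stack([np.concatenate(xs), np.concatenate(ys)])
    else:
        pts = np.zeros((0, 2))
    truth = {
        "labeled": labeled,
        "rotation": rotation,
        "points_per_corner": n_points,
        "radius_nm": radius,
    }
    return PointCloud(pts, (0.0, 0.0)), truth


def gen_npc_cohort(
    params: NPCSimParams, n_particles: int, rng: np.random.Generator | None = None
) -> list[tuple[PointCloud, dict]]:
    """Independent particles drawn from one generator stream."""
    rng = _rng(params.seed, rng)
    return [gen_npc_pointcloud(params, rng=rng) for _ in range(n_particles)]


def render_image(
    cloud: PointCloud,
    pixel_size: float,
    spot_sigma: float,
    field_px: tuple[int, int],
) -> np.ndarray:
    """Render each point as a unit-integral Gaussian spot onto a pixel grid.

    ``field_px`` is (rows, cols); the cloud's nm coordinates must fall inside
    the field, otherwise the offending coordinate is named in the error.
    Total integrated intensity is proportional to the point count.
    """
    ny, nx = field_px
    img = np.zeros((ny, nx), dtype=float)
    if len(cloud) == 0:
        return img
    pts = cloud.points
    fx, fy = nx * pixel_size, ny * pixel_size
    bad = (pts[:, 0] < 0) | (pts[:, 0] > fx) | (pts[:, 1] < 0) | (pts[:, 1] > fy)
    if bad.any():
        i = int(np.nonzero(bad)[0][0])
        raise FieldError(
            f"point ({pts[i, 0]:.1f}, {pts[i, 1]:.1f}) nm outside the "
            f"{fx:.0f} x {fy:.0f} nm field"
        )
    half_px = int(np.ceil(5 * spot_sigma / pixel_size)) + 1
    norm = pixel_size**2 / (2 * np.pi * spot_sigma**2)
    for x, y in pts:
        jc = int(x / pixel_size)
        ic = int(y / pixel_size)
        j0, j1 = max(jc - half_px, 0), min(jc + half_px + 1, nx)
        i0, i1 = max(ic - half_px, 0), min(ic + half_px + 1, ny)
        jj = (np.arange(j0, j1) + 0.5) * pixel_size
        ii = (np.arange(i0, i1) + 0.5) * pixel_size
        gx = np.exp(-((jj - x) ** 2) / (2 * spot_sigma**2))
        gy = np.exp(-((ii - y) ** 2) / (2 * spot_sigma**2))
        img[i0:i1, j0:j1] += norm * np.outer(gy, gx)
    return img


def gen_sideview_profile(
    separation: float,
    peak_sigma: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
    step_nm: float = 1.0,
    margin_sigmas: float = 6.0,
    rng: np.random.Generator | None = None,
) -> LineProfile:
    """Two Gaussian peaks at +/- separation/2 about the profile midpoint,
    plus additive Gaussian noise. separation=0 degenerates to one peak."""
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = _rng(seed, rng)
    half_len = separation / 2.0 + margin_sigmas * peak_sigma
    positions = np.arange(-half_len, half_len + step_nm / 2, step_nm)
    y = np.exp(-((positions - separation / 2) ** 2) / (2 * peak_sigma**2))
    y += np.exp(-((positions + separation / 2) ** 2) / (2 * peak_sigma**2))
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, y.size)
    return LineProfile(
        positions - positions[0],
        y,
        meta={"true_separation_nm": separation, "peak_sigma_nm": peak_sigma,
              "midpoint_nm": -positions[0]},
    )


def gen_periodic_chain(
    params: ChainSimParams, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, LineProfile]:
    """Dot positions ``k * period + N(0, jitter^2)`` with independent misses,
    sorted ascending, plus a rendered profile (sum of Gaussian dots)."""
    rng = _rng(params.seed, rng)
    lattice = np.arange(params.n_dots) * params.period
    positions = lattice + rng.normal(0, params.jitter_sd, params.n_dots)
    kept = rng.random(params.n_dots) >= params.miss_prob
    positions = np.sort(positions[kept])
    margin = 5 * params.dot_sigma + 3 * params.jitter_sd
    lo = (positions.min() if positions.size else 0.0) - margin
    hi = (positions.max() if positions.size else 0.0) + margin
    axis = np.arange(lo, hi + params.render_step_nm / 2, params.render_step_nm)
    y = np.zeros_like(axis)
    for p in positions:
        y += np.exp(-((axis - p) ** 2) / (2 * params.dot_sigma**2))
    profile = LineProfile(
        axis - axis[0],
        y,
        meta={"dot_positions_nm": (positions - axis[0]).tolist(),
              "period_nm": params.period},
    )
    return positions, profile


def gen_nuclei_mask(
    params: NucleusSimParams, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping ellipses in a label image (reject-and-resample).

    Returns the int label image (0 = background, 1..n = nuclei) and the
    analytic true areas in um^2. Raises :class:`FieldError` when placement
    fails after ``max_attempts``.
    """
    rng = _rng(params.seed, rng)
    px_um = params.pixel_size / 1000.0
    ny, nx = params.field_px
    labels = np.zeros((ny, nx), dtype=np.int32)
    placed: list[tuple[float, float, float]] = []  # (row, col, bounding radius px)
    true_areas = np.zeros(params.n_nuclei)
    lo_e, hi_e = params.ellipticity_range
    for i in range(params.n_nuclei):
        for _ in range(params.max_attempts):
            L = rng.normal(params.ncs_mean * params.gel_expansion,
                           params.ncs_sd * params.gel_expansion)
            if L <= 0:
                continue  # resample a non-positive draw
            area_um2 = L**2
            e = rng.uniform(lo_e, hi_e)
            a_um = np.sqrt(area_um2 / (np.pi * e))  # semi-major
            b_um = a_um * e
            a_px, b_px = a_um / px_um, b_um / px_um
            theta = rng.uniform(0, np.pi)
            r0 = rng.uniform(a_px + 1, ny - a_px - 1) if ny > 2 * a_px + 2 else None
            c0 = rng.uniform(a_px + 1, nx - a_px - 1) if nx > 2 * a_px + 2 else None
            if r0 is None or c0 is None:
                continue
            if any(np.hypot(r0 - r, c0 - c) < a_px + rad for r, c, rad in placed):
                continue
            rr, cc = skimage.draw.ellipse(
                r0, c0, b_px, a_px, shape=labels.shape, rotation=theta
            )
            labels[rr, cc] = i + 1
            placed.append((r0, c0, a_px))
            true_areas[i] = area_um2
            break
        else:
            raise FieldError(
                f"could not place nucleus {i + 1}/{params.n_nuclei} after "
                f"{params.max_attempts} attempts; enlarge field_px"
            )
    return labels, true_areas


def gen_ring_image(
    diameter: float,
    symmetry: int,
    unit_sigma: float,
    expansion_factor: float = 1.0,
    pixel_size: float = 10.0,
    seed: int | None = None,
    rotation: Union[float, str] = "random",
    field_px: tuple[int, int] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """n Gaussian units evenly spaced on a circle of physical diameter
    ``diameter * expansion_factor``, centered in the field."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    rng = _rng(seed, rng)
    rot = (
        float(rng.uniform(0, 2 * np.pi / symmetry))
        if isinstance(rotation, str)
        else float(rotation)
    )
    radius = diameter * expansion_factor / 2.0
    if field_px is None:
        extent = 2 * (radius + 5 * unit_sigma)
        n = int(np.ceil(extent / pixel_size)) + 1
        field_px = (n, n)
    cy = field_px[0] * pixel_size / 2.0
    cx = field_px[1] * pixel_size / 2.0
    ang = rot + 2 * np.pi * np.arange(symmetry) / symmetry
    pts = np.column_stack([cx + radius * np.cos(ang), cy + radius * np.sin(ang)])
    cloud = PointCloud(pts, (cx, cy))
    return render_image(cloud, pixel_size, unit_sigma, field_px)


def gen_striped_profile(
    spacing: float,
    n_stripes: int,
    sigma: float,
    noise_sd: float = 0.0,
    jitter_sd: float = 0.0,
    seed: int | None = None,
    step_nm: float = 1.0,
    rng: np.random.Generator | None = None,
) -> LineProfile:
    """1D profile of ``n_stripes`` Gaussian stripes ``spacing`` nm apart
    (optionally jittered), for inter-peak distance analyses.

    When ``spacing`` is not well above ``2 * sigma`` neighbouring stripes merge
    into single peaks, and downstream peak finding will report fewer
    intervals; that is deliberate, documented behavior.
    """
    if spacing <= 0 or n_stripes < 1:
        raise ValueError("spacing must be > 0 and n_stripes >= 1")
    rng = _rng(seed, rng)
    centers = np.arange(n_stripes) * spacing + rng.normal(0, jitter_sd, n_stripes)
    margin = 5 * sigma + 3 * jitter_sd
    axis = np.arange(centers.min() - margin, centers.max() + margin + step_nm / 2,
                     step_nm)
    y = np.zeros_like(axis)
    for c in centers:
        y += np.exp(-((axis - c) ** 2) / (2 * sigma**2))
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, y.size)
    return LineProfile(
        axis - axis[0],
        y,
        meta={"stripe_positions_nm": (centers - axis[0]).tolist(),
              "spacing_nm": spacing},
    )
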