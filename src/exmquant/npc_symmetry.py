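"""Corner counting for ring-shaped particles with n-fold symmetry.

The pipeline turns a single-particle crop into a point cloud, trims radial
outliers, estimates the particle orientation from the circular mean of the
s-folded polar angles, partitions the plane into s equal sectors around that
orientation, and reports how many sectors hold more than a given fraction of
the points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import scipy.optimize
from skimage.filters import threshold_otsu

__all__ = [
    "PointCloud",
    "OrientationEstimate",
    "SectorPartition",
    "NPCDetection",
    "CornerHistogram",
    "EmptyParticleError",
    "image_to_pointcloud",
    "trim_outliers",
    "wrapped_angle_diff",
    "fold_angle",
    "estimate_orientation",
    "assign_sectors",
    "count_active_corners",
    "detect_corners",
    "corner_histogram",
    "fit_gaussian_histogram",
]


class EmptyParticleError(ValueError):
    """No pixels above threshold / empty point cloud."""


@dataclass
class PointCloud:
    """Planar points (nm) with a fixed center.

    The center is defined once (intensity-weighted centroid at construction
    from an image) and deliberately NOT recomputed by :func:`trim_outliers`,
    so that trimming and centering cannot feed back on each other.
    """

    points: np.ndarray  # (N, 2) float, nm
    center: tuple[float, float]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.center = (float(self.center[0]), float(self.center[1]))

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def radii(self) -> np.ndarray:
        return np.hypot(
            self.points[:, 0] - self.center[0], self.points[:, 1] - self.center[1]
        )

    @property
    def R(self) -> float:
        """Distance from the center to the furthest point (0 if empty)."""
        return float(self.radii.max()) if len(self) else 0.0

    @property
    def angles(self) -> np.ndarray:
        """Polar angle of each point about the center, in [0, 2*pi)."""
        a = np.arctan2(
            self.points[:, 1] - self.center[1], self.points[:, 0] - self.center[0]
        )
        return np.mod(a, 2 * np.pi)


@dataclass(frozen=True)
class OrientationEstimate:
    theta_star: float  # radians, in [0, 2*pi/s)
    s: int
    objective_value: float  # sum of squared wrapped residuals at theta_star
    method: str  # "closed_form" | "grid_search"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.theta_star < 2 * np.pi / self.s + 1e-12):
            raise ValueError("theta_star must lie in [0, 2*pi/s)")


@dataclass
class SectorPartition:
    borders: np.ndarray  # s border angles (radians)
    per_sector_counts: np.ndarray  # s nonnegative ints
    sector_of_point: np.ndarray  # sector index per point
    R: float  # radial extent of the partition (furthest kept point)

    @property
    def s(self) -> int:
        return self.per_sector_counts.size

    @property
    def n_points(self) -> int:
        return int(self.per_sector_counts.sum())


@dataclass
class NPCDetection:
    """Full result for one particle."""

    orientation: OrientationEstimate
    partition: SectorPartition
    active_corners: int
    n_points: int


@dataclass
class CornerHistogram:
    counts: np.ndarray  # length s + 1, index = number of active corners
    n_particles: int
    gauss_mu: float | None = None
    gauss_sigma: float | None = None
    gauss_amp: float | None = None
    r_squared: float | None = None

    @property
    def fit_defined(self) -> bool:
        return self.gauss_mu is not None

    @property
    def mode(self) -> int:
        return int(np.argmax(self.counts))


def _parse_threshold(image: np.ndarray, threshold_spec) -> float:
    if isinstance(threshold_spec, str):
        if threshold_spec == "otsu":
            return float(threshold_otsu(image))
        if threshold_spec.startswith("frac:"):
            return float(threshold_spec[5:]) * float(image.max())
        if threshold_spec.startswith("abs:"):
            return float(threshold_spec[4:])
        raise ValueError(f"unknown threshold spec {threshold_spec!r}")
    return float(threshold_spec)  # absolute intensity


def image_to_pointcloud(
    image: np.ndarray, pixel_size_nm: float, threshold_spec="otsu"
) -> PointCloud:
    """Supra-threshold pixel coordinates (nm) of a single-particle crop.

    The center is the intensity-weighted centroid of the selected pixels.
    Raises :class:`EmptyParticleError` when nothing is above threshold.
    """
    image = np.asarray(image, dtype=float)
    thr = _parse_threshold(image, threshold_spec)
    rows, cols = np.nonzero(image > thr)
    if rows.size == 0:
        raise EmptyParticleError(f"no pixels above threshold {thr}")
    xs = (cols + 0.5) * pixel_size_nm
    ys = (rows + 0.5) * pixel_size_nm
    w = image[rows, cols]
    center = (float(np.average(xs, weights=w)), float(np.average(ys, weights=w)))
    return PointCloud(np.column_stack([xs, ys]), center)


def trim_outliers(cloud: PointCloud, keep_frac: float = 0.9) -> PointCloud:
    """Keep the ``ceil(keep_frac * N)`` points nearest to the (fixed) center.

    Ties at the cut radius resolve by insertion order (stable sort). The
    center is carried over unchanged.
    """
    if not 0 < keep_frac <= 1:
        raise ValueError("keep_frac must be in (0, 1]")
    n = len(cloud)
    if n == 0:
        raise EmptyParticleError("cannot trim an empty point cloud")
    n_keep = int(np.ceil(keep_frac * n))
    order = np.argsort(cloud.radii, kind="stable")[:n_keep]
    order.sort()  # preserve insertion order of the survivors
    return PointCloud(cloud.points[order], cloud.center)


def wrapped_angle_diff(theta1, theta2):
    """Signed angular difference wrapped into (-pi, pi].

    Computed as ``(theta1 - theta2 + pi) mod 2*pi - pi``; the single boundary
    value -pi is mapped to +pi so the result lies in the half-open interval
    (-pi, pi].
    """
    d = np.mod(np.asarray(theta1, dtype=float) - np.asarray(theta2, dtype=float) + np.pi,
               2 * np.pi) - np.pi
    d = np.where(d == -np.pi, np.pi, d)
    return d if d.ndim else float(d)


def fold_angle(theta, s: int):
    """Reduce an angle modulo the symmetry period 2*pi/s."""
    return np.mod(theta, 2 * np.pi / s)


def _wrapped_diff_period(a, b, period: float):
    half = period / 2.0
    return np.mod(a - b + half, period) - half


def _squared_objective(folded: np.ndarray, theta: float, s: int) -> float:
    return float(np.sum(_wrapped_diff_period(folded, theta, 2 * np.pi / s) ** 2))


def estimate_orientation(
    cloud: PointCloud,
    s: int = 8,
    method: str = "closed_form",
    grid_resolution: float = 1e-3,
) -> OrientationEstimate:
    """Particle orientation from the s-folded polar angles of the points.

    closed_form (default): circular mean of the folded angles,
    ``theta* = atan2(sum sin(s*ang), sum cos(s*ang)) / s`` reduced to
    [0, 2*pi/s). grid_search: argmin of the sum of squared wrapped residuals
    over a uniform grid of the stated resolution.

    A cloud whose folded angles cancel (resultant length below tolerance) has
    no defined orientation: theta*=0 is returned with ``degenerate=True`` and
    a warning, so downstream sector assignment can still proceed.
    """
    if s < 2:
        raise ValueError("symmetry order s must be >= 2")
    if len(cloud) == 0:
        raise EmptyParticleError("cannot orient an empty point cloud")
    ang = cloud.angles
    folded = fold_angle(ang, s)
    period = 2 * np.pi / s

    C = float(np.cos(s * ang).sum())
    S = float(np.sin(s * ang).sum())
    resultant = np.hypot(C, S) / len(cloud)
    if resultant < 1e-9:
        warnings.warn("orientation undefined: folded angles cancel; using theta*=0")
        return OrientationEstimate(0.0, s, _squared_objective(folded, 0.0, s),
                                   method, degenerate=True)

    if method == "closed_form":
        theta = float(np.mod(np.arctan2(S, C) / s, period))
        return OrientationEstimate(theta, s, _squared_objective(folded, theta, s),
                                   "closed_form")
    if method == "grid_search":
        grid = np.arange(0.0, period, grid_resolution)
        diffs = _wrapped_diff_period(folded[None, :], grid[:, None], period)
        obj = np.sum(diffs**2, axis=1)
        i = int(np.argmin(obj))
        return OrientationEstimate(float(grid[i]), s, float(obj[i]), "grid_search")
    raise ValueError(f"unknown method {method!r}")


def assign_sectors(cloud: PointCloud, orient: OrientationEstimate) -> SectorPartition:
    """Partition points into s equal sectors with borders at
    ``theta* - pi/s + 2*pi*k/s``; each sector is half-open (border belongs to
    the lower sector boundary, i.e. starts a sector)."""
    s = orient.s
    period = 2 * np.pi / s
    base = orient.theta_star - np.pi / s
    borders = np.mod(base + period * np.arange(s), 2 * np.pi)
    if len(cloud) == 0:
        return SectorPartition(borders, np.zeros(s, dtype=int),
                               np.zeros(0, dtype=int), 0.0)
    rel = np.mod(cloud.angles - base, 2 * np.pi)
    sector = np.floor(rel / period).astype(int)
    sector = np.clip(sector, 0, s - 1)  # guard the rel == 2*pi float edge
    counts = np.bincount(sector, minlength=s)
    return SectorPartition(borders, counts, sector, cloud.R)


def count_active_corners(partition: SectorPartition, activation_frac: float = 0.05) -> int:
    """Number of sectors holding strictly more than ``activation_frac`` of the
    points."""
    if not 0 <= activation_frac < 1:
        raise ValueError("activation_frac must be in [0, 1)")
    total = partition.n_points
    return int(np.sum(partition.per_sector_counts > activation_frac * total))


def detect_corners(
    cloud: PointCloud,
    s: int = 8,
    keep_frac: float = 0.9,
    activation_frac: float = 0.05,
    method: str = "closed_form",
) -> NPCDetection:
    """Run the full trimming -> orientation -> sector -> activation pipeline
    on one particle's point cloud."""
    kept = trim_outliers(cloud, keep_frac)
    orient = estimate_orientation(kept, s=s, method=method)
    partition = assign_sectors(kept, orient)
    active = count_active_corners(partition, activation_frac)
    return NPCDetection(orient, partition, active, len(kept))


def corner_histogram(detections: Iterable[NPCDetection | int], s: int = 8,
                     fit: bool = True) -> CornerHistogram:
    """Histogram of active-corner counts over a cohort, with an optional
    unweighted Gaussian least-squares fit."""
    corners = [d.active_corners if isinstance(d, NPCDetection) else int(d)
               for d in detections]
    counts = np.bincount(corners, minlength=s + 1)
    if counts.size > s + 1:
        raise ValueError("active-corner count exceeds symmetry order")
    hist = CornerHistogram(counts, int(counts.sum()))
    if fit:
        fit_gaussian_histogram(hist)
    return hist


def fit_gaussian_histogram(hist: CornerHistogram) -> CornerHistogram:
    """Least-squares fit of ``A * exp(-(k - mu)^2 / (2 sigma^2))`` to the
    (k, counts) pairs; fills the fit fields in place.

    Requires at least 3 distinct occupied bins; on failure the fit fields stay
    None (histogram flagged undefined) rather than raising.
    """
    k = np.arange(hist.counts.size, dtype=float)
    y = hist.counts.astype(float)
    if np.count_nonzero(y) < 3:
        return hist

    def gauss(x, amp, mu, sigma):
        return amp * np.exp(-((x - mu) ** 2) / (2 * sigma**2))

    mu0 = float(np.average(k, weights=np.maximum(y, 1e-12)))
    sigma0 = max(float(np.sqrt(np.average((k - mu0) ** 2, weights=np.maximum(y, 1e-12)))), 0.3)
    try:
        popt, _ = scipy.optimize.curve_fit(
            gauss, k, y, p0=[float(y.max()), mu0, sigma0], maxfev=10000
        )
    except (RuntimeError, scipy.optimize.OptimizeWarning):
        return hist
    residuals = y - gauss(k, *popt)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    hist.gauss_amp, hist.gauss_mu, hist.gauss_sigma = (
        float(popt[0]), float(popt[1]), abs(float(popt[2])))
    hist.r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else None
    return hist
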