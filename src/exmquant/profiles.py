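"""Line and polar intensity profiling.

Physical conventions used throughout the package:

* images are 2D arrays indexed ``[row, col]``;
* the physical coordinate of pixel ``(i, j)`` is ``((j + 0.5) * px,
  (i + 0.5) * px)`` in ``(x, y)`` nm, i.e. x runs along columns;
* all profile positions are in nm and uniformly spaced;
* angles are measured from +x, counterclockwise, in radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi
import scipy.signal

__all__ = [
    "LineProfile",
    "PolarProfile",
    "ProfileError",
    "extract_line_profile",
    "fwhm",
    "find_peaks",
    "two_peak_separation",
    "polar_transform",
    "angular_offset",
    "radial_offset",
    "fiber_angle",
]


class ProfileError(ValueError):
    """Raised when a profile does not satisfy an operation's preconditions."""


@dataclass
class LineProfile:
    """A 1D intensity trace on a uniform physical axis (nm)."""

    positions: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.intensities.shape:
            raise ProfileError("positions and intensities must be matching 1D arrays")
        if self.positions.size >= 2:
            steps = np.diff(self.positions)
            if np.any(steps <= 0):
                raise ProfileError("positions must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9 * abs(steps[0])):
                raise ProfileError("positions must be uniformly spaced")

    @property
    def step(self) -> float:
        if self.positions.size < 2:
            raise ProfileError("profile has fewer than 2 samples")
        return float(self.positions[1] - self.positions[0])

    def __len__(self) -> int:
        return self.positions.size


@dataclass
class PolarProfile:
    """Intensity resampled on an (angle, radius) grid about a center.

    ``intensity`` has shape ``(n_angle, n_radius)``; ``angular_profile`` is
    the mean over the selected radial band, one value per angle bin.
    """

    angle_bins: np.ndarray  # bin centers, radians in [0, 2*pi)
    radius_bins: np.ndarray  # bin centers, nm
    intensity: np.ndarray
    angular_profile: np.ndarray

    def __post_init__(self) -> None:
        if self.intensity.shape != (self.angle_bins.size, self.radius_bins.size):
            raise ProfileError("intensity map shape must be (n_angle, n_radius)")

    @property
    def angle_step(self) -> float:
        return float(self.angle_bins[1] - self.angle_bins[0])


def extract_line_profile(
    image: np.ndarray,
    p0: Sequence[float],
    p1: Sequence[float],
    pixel_size_nm: float,
    width_px: int = 1,
    n_samples: int | None = None,
) -> LineProfile:
    """Bilinear plot profile along the segment ``p0 -> p1``.

    ``p0``/``p1`` are (x, y) pixel coordinates. The profile is averaged over
    ``width_px`` parallel lines offset along the transverse direction.
    """
    image = np.asarray(image, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    for name, p in (("p0", p0), ("p1", p1)):
        if not (0 <= p[0] <= image.shape[1] - 1 and 0 <= p[1] <= image.shape[0] - 1):
            raise ProfileError(f"endpoint {name}={tuple(p)} outside image {image.shape}")
    length_px = float(np.hypot(*(p1 - p0)))
    if n_samples is None:
        n_samples = max(int(np.ceil(length_px)) + 1, 2)
    t = np.linspace(0.0, 1.0, n_samples)
    xs = p0[0] + t * (p1[0] - p0[0])
    ys = p0[1] + t * (p1[1] - p0[1])
    direction = (p1 - p0) / max(length_px, 1e-12)
    normal = np.array([-direction[1], direction[0]])
    offsets = np.arange(width_px, dtype=float) - (width_px - 1) / 2.0
    acc = np.zeros(n_samples)
    for off in offsets:
        acc += ndi.map_coordinates(
            image, [ys + off * normal[1], xs + off * normal[0]], order=1, mode="nearest"
        )
    intensities = acc / width_px
    positions = t * length_px * pixel_size_nm
    return LineProfile(
        positions,
        intensities,
        meta={"p0": tuple(p0), "p1": tuple(p1), "width_px": width_px,
              "pixel_size_nm": pixel_size_nm},
    )


def _half_crossing(x: np.ndarray, y: np.ndarray, i_peak: int, half: float, side: int) -> float:
    """Linearly interpolated position where y crosses `half`, walking from the
    peak towards lower (side=-1) or higher (side=+1) indices."""
    i = i_peak
    while 0 <= i + side < len(y):
        j = i + side
        if y[j] <= half:
            # interpolate between i (above) and j (at/below)
            frac = (y[i] - half) / (y[i] - y[j])
            return float(x[i] + frac * (x[j] - x[i]))
        i = j
    raise ProfileError("half-maximum crossing not found (peak at profile boundary)")


def fwhm(profile: LineProfile, baseline: str = "local_min") -> float:
    """Full width at half maximum of the dominant peak, in nm.

    baseline="local_min" subtracts the lower of the two minima flanking the
    global maximum before taking the half level; baseline="raw" uses the raw
    intensities (half level = max/2).
    """
    y = profile.intensities.astype(float)
    x = profile.positions
    if y.size < 3:
        raise ProfileError("profile too short for FWHM")
    i_peak = int(np.argmax(y))
    if baseline == "local_min":
        left = y[: i_peak + 1].min() if i_peak > 0 else y[0]
        right = y[i_peak:].min()
        base = min(left, right)
    elif baseline == "raw":
        base = 0.0
    else:
        raise ValueError(f"unknown baseline mode {baseline!r}")
    peak = y[i_peak]
    if peak <= base:
        raise ProfileError("no peak above baseline")
    half = base + 0.5 * (peak - base)
    left_x = _half_crossing(x, y, i_peak, half, -1)
    right_x = _half_crossing(x, y, i_peak, half, +1)
    return right_x - left_x


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """3-point parabolic sub-sample refinement of a local-maximum index."""
    if i <= 0 or i >= len(y) - 1:
        return float(x[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return float(x[i] + delta * (x[1] - x[0]))


def find_peaks(
    profile: LineProfile,
    min_prominence_frac: float = 0.1,
    min_separation_nm: float = 0.0,
) -> np.ndarray:
    """Local maxima passing prominence and separation filters.

    Prominence threshold is ``min_prominence_frac`` of the profile's dynamic
    range; returned positions (nm) are refined by 3-point parabolic
    interpolation.
    """
    y = profile.intensities
    if y.size == 0:
        raise ProfileError("empty profile")
    span = float(y.max() - y.min())
    if span == 0:
        return np.array([])
    distance = max(int(round(min_separation_nm / profile.step)), 1) if y.size > 1 else 1
    idx, _ = scipy.signal.find_peaks(
        y, prominence=min_prominence_frac * span, distance=distance
    )
    return np.array([_parabolic_refine(profile.positions, y, i) for i in idx])


def two_peak_separation(profile: LineProfile, **peak_kwargs) -> float:
    """Distance (nm) between exactly two detected peaks."""
    peak_kwargs.setdefault("min_prominence_frac", 0.1)
    peaks = find_peaks(profile, **peak_kwargs)
    if len(peaks) != 2:
        raise ProfileError(
            f"expected exactly 2 peaks, found {len(peaks)} at {np.round(peaks, 2).tolist()}"
        )
    return float(abs(peaks[1] - peaks[0]))


def polar_transform(
    image: np.ndarray,
    center_px: Sequence[float],
    pixel_size_nm: float,
    n_angle_bins: int = 360,
    radial_band_nm: tuple[float, float] | None = None,
    radial_step_px: float = 1.0,
) -> PolarProfile:
    """Resample ``image`` on an (angle, radius) grid about ``center_px`` (x, y).

    ``angular_profile`` is the mean intensity over the radial band (the whole
    radial range if no band is given).
    """
    image = np.asarray(image, dtype=float)
    cx, cy = float(center_px[0]), float(center_px[1])
    if not (0 <= cx <= image.shape[1] - 1 and 0 <= cy <= image.shape[0] - 1):
        raise ProfileError(f"center {center_px} outside image {image.shape}")
    r_max_px = min(cx, cy, image.shape[1] - 1 - cx, image.shape[0] - 1 - cy)
    if radial_band_nm is not None:
        lo, hi = radial_band_nm
        if hi / pixel_size_nm > r_max_px + 1e-9:
            raise ProfileError(
                f"radial band up to {hi} nm exceeds the largest inscribed radius "
                f"{r_max_px * pixel_size_nm:.1f} nm"
            )
    r_px = np.arange(radial_step_px / 2.0, r_max_px + 1e-9, radial_step_px)
    if r_px.size == 0:
        raise ProfileError("center too close to the border for a polar transform")
    ang = (np.arange(n_angle_bins) + 0.5) * (2 * np.pi / n_angle_bins)
    aa, rr = np.meshgrid(ang, r_px, indexing="ij")
    xs = cx + rr * np.cos(aa)
    ys = cy + rr * np.sin(aa)
    intensity = ndi.map_coordinates(image, [ys, xs], order=1, mode="constant")
    radius_nm = r_px * pixel_size_nm
    if radial_band_nm is None:
        band_mask = np.ones_like(radius_nm, dtype=bool)
    else:
        band_mask = (radius_nm >= radial_band_nm[0]) & (radius_nm <= radial_band_nm[1])
        if not band_mask.any():
            raise ProfileError("radial band contains no radial bins")
    angular = intensity[:, band_mask].mean(axis=1)
    return PolarProfile(ang, radius_nm, intensity, angular)


def angular_offset(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """Circular cross-correlation lag of B relative to A, in radians (-pi, pi].

    Both inputs are angular profiles on identical uniform [0, 2*pi) binnings.
    Positive means B is A rotated counterclockwise. For signals with n-fold
    periodicity the answer is only defined modulo 2*pi/n.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ProfileError("angular profiles must be 1D with equal binning")
    a = a - a.mean()
    b = b - b.mean()
    if np.allclose(a, 0) or np.allclose(b, 0):
        raise ProfileError("flat profile: angular offset undefined")
    corr = np.fft.irfft(np.fft.rfft(b) * np.conj(np.fft.rfft(a)), n=a.size)
    i = int(np.argmax(corr))
    # parabolic sub-bin refinement on the circular correlogram
    y0, y1, y2 = corr[(i - 1) % a.size], corr[i], corr[(i + 1) % a.size]
    denom = y0 - 2 * y1 + y2
    delta = 0.0 if denom == 0 else float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
    bin_width = 2 * np.pi / a.size
    lag = (i + delta) * bin_width
    return float((lag + np.pi) % (2 * np.pi) - np.pi)


def radial_offset(
    positions_a: np.ndarray, positions_b: np.ndarray
) -> tuple[float, float, int]:
    """Mean signed difference B - A (nm) over paired positions, with SD and n."""
    a = np.asarray(positions_a, dtype=float)
    b = np.asarray(positions_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ProfileError("radial_offset requires nonempty paired 1D position arrays")
    diff = b - a
    sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    return float(diff.mean()), sd, int(diff.size)


def fiber_angle(points: np.ndarray, base_axis: Sequence[float] = (1.0, 0.0)) -> float:
    """Unsigned acute angle (degrees) between a total-least-squares line fit
    through ``points`` (N x 2) and ``base_axis``."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ProfileError("fiber_angle needs at least 2 points of shape (N, 2)")
    centered = pts - pts.mean(axis=0)
    if np.allclose(centered, 0):
        raise ProfileError("collapsed points: fiber direction undefined")
    # principal axis = TLS line direction
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    base = np.asarray(base_axis, dtype=float)
    base = base / np.linalg.norm(base)
    cosang = abs(float(np.dot(direction, base)))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
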