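"""Functional maps from per-focal-spot decoded amplitudes, and their metrics.

A scan yields one decoded amplitude per focal spot; this module assembles the
amplitudes into a 2-D map on the scan grid, upsamples it onto a fine lattice
(0.01 mm by default) for display and profiling, converts to a floored dB
scale, and computes the two summary metrics used to compare decoders:
image SNR (signal power at the source peaks over background power, in dB) and
the −3 dB source width of a line profile (the resolution metric).

dB conventions: map and profile values are amplitudes, so the dB map and the
−3 dB width criterion use 20·log10; the SNR ratio is formed from powers
(squared amplitudes) and uses 10·log10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import RectBivariateSpline

from .phantom import ScanGrid

__all__ = [
    "ImageMap",
    "LineProfile",
    "build_image",
    "interpolate_image",
    "to_db",
    "compute_snr",
    "line_profile",
    "source_width_3db",
]


@dataclass
class ImageMap:
    """Gridded amplitude map: ``values[iy, ix]`` at ``(x_coords[ix], y_coords[iy])`` mm."""

    values: np.ndarray
    x_coords: np.ndarray
    y_coords: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.x_coords = np.asarray(self.x_coords, dtype=float)
        self.y_coords = np.asarray(self.y_coords, dtype=float)
        if self.values.shape != (self.y_coords.size, self.x_coords.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match coordinates "
                f"({self.y_coords.size}, {self.x_coords.size})"
            )
        if np.any(self.values < 0):
            raise ValueError("amplitude map values must be >= 0")

    @property
    def x_step(self) -> float:
        return float(self.x_coords[1] - self.x_coords[0]) if self.x_coords.size > 1 else 0.0

    @property
    def y_step(self) -> float:
        return float(self.y_coords[1] - self.y_coords[0]) if self.y_coords.size > 1 else 0.0


@dataclass
class LineProfile:
    """Amplitudes along one grid line of a map, at ``fixed_coordinate`` on the other axis."""

    positions: np.ndarray
    values: np.ndarray
    axis: str
    fixed_coordinate: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.axis not in ("x", "y"):
            raise ValueError(f"axis must be 'x' or 'y', got {self.axis!r}")
        if self.positions.size != self.values.size:
            raise ValueError("positions and values must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


def build_image(grid: ScanGrid, amplitudes: Sequence[float] | np.ndarray) -> ImageMap:
    """Arrange per-spot amplitudes (in ``simulate_scan`` order) on the grid."""
    amps = np.asarray(amplitudes, dtype=float)
    if amps.size != grid.n_spots:
        raise ValueError(
            f"expected {grid.n_spots} amplitudes for a {grid.nx}x{grid.ny} grid, "
            f"got {amps.size}"
        )
    values = amps.reshape(grid.nx, grid.ny).T  # scan order: x outer, y inner
    return ImageMap(values=values, x_coords=grid.x_coords, y_coords=grid.y_coords)


def interpolate_image(
    img: ImageMap, step: float = 0.01, method: str = "cubic"
) -> ImageMap:
    """Spline-upsample a map onto a ``step``-mm lattice over the same extent.

    Bicubic by default (``method='linear'`` for bilinear); original grid nodes
    are reproduced exactly.  Cubic undershoot below zero is clipped to keep
    the amplitude-map invariant.
    """
    if step <= 0:
        raise ValueError(f"step must be > 0 mm, got {step}")
    if img.x_coords.size < 2 or img.y_coords.size < 2:
        raise ValueError("need at least 2 grid points per axis to interpolate")
    orders = {"cubic": 3, "linear": 1}
    if method not in orders:
        raise ValueError(f"method must be one of {sorted(orders)}, got {method!r}")
    k = orders[method]
    kx = min(k, img.x_coords.size - 1)
    ky = min(k, img.y_coords.size - 1)
    spline = RectBivariateSpline(img.y_coords, img.x_coords, img.values, kx=ky, ky=kx)
    xs = img.x_coords[0] + step * np.arange(
        int(round((img.x_coords[-1] - img.x_coords[0]) / step)) + 1
    )
    ys = img.y_coords[0] + step * np.arange(
        int(round((img.y_coords[-1] - img.y_coords[0]) / step)) + 1
    )
    vals = spline(ys, xs)
    np.clip(vals, 0.0, None, out=vals)
    return ImageMap(values=vals, x_coords=xs, y_coords=ys)


def to_db(img: ImageMap, dynamic_range: float = 5.0) -> np.ndarray:
    """Amplitude map in dB re. its peak, floored at ``-dynamic_range``."""
    peak = img.values.max()
    if peak <= 0:
        raise ValueError("cannot convert an all-zero image to dB")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(img.values / peak)
    return np.maximum(db, -float(dynamic_range))


def compute_snr(
    img: ImageMap,
    source_positions: Sequence[tuple[float, float]],
    roi_radius: float = 1.5,
) -> float:
    """Image SNR in dB: 10·log10(P_signal / P_noise).

    P_signal is the mean squared amplitude over the per-source ROI peak pixels
    (one peak per circular ROI of ``roi_radius`` mm); P_noise the mean squared
    amplitude over all pixels outside every ROI.
    """
    if len(source_positions) == 0:
        raise ValueError("need at least one source position")
    X, Y = np.meshgrid(img.x_coords, img.y_coords)
    union = np.zeros(img.values.shape, dtype=bool)
    peaks = []
    for sx, sy in source_positions:
        mask = (X - sx) ** 2 + (Y - sy) ** 2 <= roi_radius**2
        if not mask.any():
            raise ValueError(f"ROI at ({sx}, {sy}) mm contains no pixels")
        peaks.append(img.values[mask].max())
        union |= mask
    background = ~union
    if not background.any():
        raise ValueError("background region is empty; shrink roi_radius")
    p_signal = float(np.mean(np.square(peaks)))
    p_noise = float(np.mean(img.values[background] ** 2))
    if p_noise == 0.0:
        warnings.warn("zero background power; SNR is unbounded", RuntimeWarning)
        return float("inf")
    return float(10.0 * np.log10(p_signal / p_noise))


def line_profile(img: ImageMap, axis: str, fixed: float) -> LineProfile:
    """Nearest-row/column amplitude profile.

    ``axis='x'`` varies x at the map row nearest to ``y = fixed``;
    ``axis='y'`` varies y at the column nearest to ``x = fixed``.
    """
    if axis == "x":
        if not img.y_coords[0] <= fixed <= img.y_coords[-1]:
            raise ValueError(
                f"fixed y = {fixed} mm outside extent "
                f"[{img.y_coords[0]}, {img.y_coords[-1]}]"
            )
        iy = int(np.argmin(np.abs(img.y_coords - fixed)))
        return LineProfile(
            positions=img.x_coords.copy(), values=img.values[iy, :].copy(),
            axis="x", fixed_coordinate=float(img.y_coords[iy]),
        )
    if axis == "y":
        if not img.x_coords[0] <= fixed <= img.x_coords[-1]:
            raise ValueError(
                f"fixed x = {fixed} mm outside extent "
                f"[{img.x_coords[0]}, {img.x_coords[-1]}]"
            )
        ix = int(np.argmin(np.abs(img.x_coords - fixed)))
        return LineProfile(
            positions=img.y_coords.copy(), values=img.values[:, ix].copy(),
            axis="y", fixed_coordinate=float(img.x_coords[ix]),
        )
    raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")


def source_width_3db(profile: LineProfile) -> float:
    """Width (mm) of the contiguous interval around the profile peak where the
    amplitude stays at or above peak·10^(−3/20), with linear sub-step boundary
    interpolation.  The peak must be interior and the profile must fall below
    the threshold on both sides."""
    v = profile.values
    pos = profile.positions
    i = int(np.argmax(v))
    if i == 0 or i == v.size - 1:
        raise ValueError("profile peak lies on the boundary; width not measurable")
    thr = v[i] * 10.0 ** (-3.0 / 20.0)

    def crossing(j_inside: int, j_outside: int) -> float:
        # linear interpolation of the threshold crossing between two samples
        v0, v1 = v[j_inside], v[j_outside]
        frac = (v0 - thr) / (v0 - v1)
        return float(pos[j_inside] + frac * (pos[j_outside] - pos[j_inside]))

    j = i
    while j > 0 and v[j - 1] >= thr:
        j -= 1
    if j == 0 and v[0] >= thr:
        raise ValueError("profile does not fall below −3 dB left of the peak")
    left = crossing(j, j - 1)

    j = i
    while j < v.size - 1 and v[j + 1] >= thr:
        j += 1
    if j == v.size - 1 and v[-1] >= thr:
        raise ValueError("profile does not fall below −3 dB right of the peak")
    right = crossing(j, j + 1)
    return right - left
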