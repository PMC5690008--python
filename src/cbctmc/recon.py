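"""Projection preprocessing, partial-arc weighting and FDK cone-beam
reconstruction with a Shepp-Logan convolution filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import _kernels
from .geometry import ConeBeamGeometry, ProjectionImage, ProjectionSet, arc_angles

__all__ = [
    "LogProjection",
    "ReconVolume",
    "ReconGrid",
    "preprocess",
    "air_normalize",
    "partial_arc_weights",
    "shepp_logan_kernel",
    "fdk_reconstruct",
    "resample",
]

logger = logging.getLogger(__name__)

HU_WATER = 1024.0  # CT-number convention: water = 1024, vacuum = 0

INTENSITY_FLOOR_FRACTION = 1e-6


@dataclass
class LogProjection:
    """Line-integral (log-normalized) projection raster."""

    pixels: np.ndarray
    angle: float
    kind: str = "raw"  # raw r | simulated r | corrected p

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("non-finite log projection values")


@dataclass
class ReconGrid:
    shape: tuple[int, int, int]  # (nx, ny, nz)
    voxel_size: tuple[float, float, float]  # cm
    origin: tuple[float, float, float] | None = None  # corner, cm

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if self.origin is None:
            self.origin = tuple(
                -0.5 * n * v for n, v in zip(self.shape, self.voxel_size)
            )


@dataclass
class ReconVolume:
    """Reconstructed attenuation volume (1/cm), indexed [ix, iy, iz]."""

    mu: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]
    hu_scale: float  # water-equivalent mu defining 1024 HU

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.mu)):
            raise ValueError("non-finite attenuation values")
        if any(v <= 0 for v in self.voxel_size) or self.hu_scale <= 0:
            raise ValueError("voxel_size and hu_scale must be positive")


def preprocess(raw: ProjectionImage, monitor_value: float,
               median_size: int = 3) -> ProjectionImage:
    """Normalize to the tube output monitor, then median filter."""
    if monitor_value <= 0:
        raise ValueError("monitor value must be positive")
    out = ndimage.median_filter(raw.pixels / monitor_value, size=median_size,
                                mode="nearest")
    return ProjectionImage(out, raw.component, raw.angle)


def _floored(pixels: np.ndarray, floor: float) -> tuple[np.ndarray, int]:
    n = int(np.count_nonzero(pixels < floor))
    return np.maximum(pixels, floor), n


def air_normalize(R: ProjectionImage, B: ProjectionImage) -> LogProjection:
    """Log air normalization r = ln(B / R), with intensity flooring so
    Monte Carlo zeros cannot produce infinities."""
    if R.pixels.shape != B.pixels.shape:
        raise ValueError("R and B shapes differ")
    floor = INTENSITY_FLOOR_FRACTION * float(B.pixels.max())
    if floor <= 0:
        raise ValueError("blank scan is identically zero")
    b, nb = _floored(B.pixels, floor)
    r, nr = _floored(R.pixels, floor)
    if nb or nr:
        logger.info("floored %d blank and %d raw pixels", nb, nr)
    return LogProjection(np.log(b / r), R.angle, kind="raw")


def _column_fan_angles(geometry: ConeBeamGeometry) -> np.ndarray:
    """In-plane fan angle gamma of each detector column, radians."""
    nu = geometry.det_pixels[0]
    pu = geometry.det_size[0] / nu
    u = (np.arange(nu) + 0.5) * pu - geometry.det_size[0] / 2
    return np.arctan(u / geometry.sdd)


def partial_arc_weights(geometry: ConeBeamGeometry,
                        feather_deg: float | None = None) -> np.ndarray:
    """Redundancy weights w(angle, u) in [0, 1] for partial-arc scans.

    A ray at (beta, gamma) is conjugate to (beta + pi + 2 gamma, -gamma).
    Each projection angle gets a smooth arc-end taper c(beta); the weight
    is c(beta) / (c(beta) + c(beta_conjugate)), so replicated rays sum to
    exactly 1 and singly measured rays get weight 1.
    """
    gam = _column_fan_angles(geometry)
    full_fan = 2 * geometry.half_fan_angle
    extent = np.deg2rad(geometry.arc_extent)
    if extent < np.pi + full_fan - 1e-9:
        raise ValueError("arc shorter than 180 degrees plus the fan angle")
    betas = np.deg2rad(arc_angles(geometry) - geometry.arc_start)
    if feather_deg is None:
        feather = geometry.half_fan_angle
    else:
        feather = np.deg2rad(feather_deg)
    full_circle = abs(extent - 2 * np.pi) < 1e-9

    def taper(b):
        if full_circle:
            return np.ones_like(b)
        c = np.ones_like(b)
        inside = (b >= 0) & (b <= extent)
        lo = inside & (b < feather)
        hi = inside & (b > extent - feather)
        c = np.where(inside, c, 0.0)
        c = np.where(lo, 0.5 - 0.5 * np.cos(np.pi * b / feather), c)
        c = np.where(hi, 0.5 - 0.5 * np.cos(np.pi * (extent - b) / feather), c)
        return c

    B, G = np.meshgrid(betas, gam, indexing="ij")
    conj = B + np.pi + 2 * G
    if full_circle:
        conj = np.mod(conj, 2 * np.pi)
    else:
        # conjugate angle may wrap only within the covered arc
        conj = np.where(conj > extent, conj - 2 * np.pi, conj)
        conj = np.where(conj < 0, conj + 2 * np.pi, conj)
    c_self = taper(B)
    c_conj = taper(conj)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(c_self + c_conj > 0, c_self / (c_self + c_conj), 0.0)
    return w


def shepp_logan_kernel(n_taps: int, pitch: float) -> np.ndarray:
    """Discrete spatial-domain Shepp-Logan convolution kernel,
    h[n] = 2 / (pi^2 pitch^2 (1 - 4 n^2))."""
    n = np.arange(-n_taps, n_taps + 1)
    return 2.0 / (np.pi ** 2 * pitch ** 2 * (1.0 - 4.0 * n ** 2))


def _filter_rows(proj: np.ndarray, pitch: float) -> np.ndarray:
    """Row-wise ramp filtering via FFT convolution with zero padding to at
    least twice the row length."""
    nv, nu = proj.shape
    kern = shepp_logan_kernel(nu, pitch)
    nfft = int(2 ** np.ceil(np.log2(2 * nu + kern.size)))
    K = np.fft.rfft(kern, nfft)
    P = np.fft.rfft(proj, nfft, axis=1)
    out = np.fft.irfft(P * K, nfft, axis=1)
    return out[:, nu : 2 * nu] * pitch


def fdk_reconstruct(log_projections: ProjectionSet | list[LogProjection],
                    geometry: ConeBeamGeometry, recon_grid: ReconGrid,
                    hu_scale: float = 0.2059) -> ReconVolume:
    """Shepp-Logan filtered FDK reconstruction of log projections.

    Steps: cosine (obliquity) weighting, partial-arc redundancy weighting,
    row-wise ramp convolution on the virtual detector through the
    isocenter, then distance-weighted cone-beam backprojection.
    """
    angles = arc_angles(geometry)
    if isinstance(log_projections, ProjectionSet):
        stack = log_projections.stack("log")
        have = log_projections.angles("log")
    else:
        have = sorted(p.angle for p in log_projections)
        order = np.argsort([p.angle for p in log_projections])
        stack = np.stack([log_projections[i].pixels for i in order])
    missing = [a for a in np.round(angles, 9) if a not in np.round(have, 9)]
    if missing:
        raise ValueError(f"missing projection angles: {missing[:10]}")
    na, nv, nu = stack.shape
    if (nu, nv) != geometry.det_pixels:
        raise ValueError("projection raster does not match geometry")

    scale = geometry.sad / geometry.sdd
    pu = geometry.det_size[0] * scale / nu
    pv = geometry.det_size[1] * scale / nv
    u = (np.arange(nu) + 0.5) * pu - geometry.det_size[0] * scale / 2
    v = (np.arange(nv) + 0.5) * pv - geometry.det_size[1] * scale / 2
    U, V = np.meshgrid(u, v)
    cosw = geometry.sad / np.sqrt(geometry.sad ** 2 + U ** 2 + V ** 2)
    arc_w = partial_arc_weights(geometry)  # (na, nu)

    filtered = np.empty_like(stack)
    for i in range(na):
        weighted = stack[i] * cosw * arc_w[i][None, :]
        filtered[i] = _filter_rows(weighted, pu)

    g = recon_grid
    vol = _kernels.fdk_backproject(
        filtered, np.deg2rad(angles), geometry.sad, geometry.sdd,
        geometry.det_size[0], geometry.det_size[1],
        g.shape[0], g.shape[1], g.shape[2],
        g.voxel_size[0], g.voxel_size[1], g.voxel_size[2],
        g.origin[0], g.origin[1], g.origin[2],
    )
    return ReconVolume(vol, g.voxel_size, g.origin, hu_scale)


def resample(data: np.ndarray, target_shape: tuple[int, ...],
             method: str = "bicubic") -> np.ndarray:
    """Resample a raster to a new shape.

    ``bicubic`` (for projection upsampling) uses cubic spline
    interpolation; ``block-average`` (for reconstruction downsampling)
    requires integer shape ratios and preserves the mean exactly.
    """
    data = np.asarray(data, dtype=np.float64)
    if tuple(target_shape) == data.shape:
        return data.copy()
    if method == "bicubic":
        factors = [t / s for t, s in zip(target_shape, data.shape)]
        out = ndimage.zoom(data, factors, order=3, mode="nearest",
                           grid_mode=True)
        if out.shape != tuple(target_shape):
            raise ValueError("bicubic resampling produced wrong shape")
        return out
    if method == "block-average":
        ratios = []
        for s, t in zip(data.shape, target_shape):
            if s % t:
                raise ValueError("block-average requires integer decimation")
            ratios.append(s // t)
        view_shape = []
        for t, r in zip(target_shape, ratios):
            view_shape.extend([t, r])
        view = data.reshape(view_shape)
        axes = tuple(range(1, 2 * len(ratios), 2))
        return view.mean(axis=axes)
    raise ValueError(f"unknown resampling method {method!r}")
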