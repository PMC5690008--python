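"""Cone-beam scan geometry and the projection-image data model.

Coordinate convention (right-handed): isocenter at the origin, rotation
axis along +z.  At angle 0 the source sits on +y at distance ``sad``; the
flat detector is perpendicular to the source-isocenter line at distance
``sdd`` from the source.  Detector ``u`` increases with +x at angle 0,
``v`` along +z.  Angles rotate the source counterclockwise about +z.
Pixel centers are at ``(index + 0.5) * pitch`` from the detector corner,
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = [
    "ConeBeamGeometry",
    "ProjectionImage",
    "ProjectionSet",
    "make_obi_geometry",
    "arc_angles",
    "pixel_ray",
]

COMPONENTS = ("total", "primary", "scatter", "blank", "log", "corrected")


@dataclass(frozen=True)
class ConeBeamGeometry:
    sad: float  # source-to-axis distance, cm
    sdd: float  # source-to-detector distance, cm
    det_size: tuple[float, float]  # (width, height) cm
    det_pixels: tuple[int, int]  # (nu, nv)
    arc_start: float = 0.0  # degrees
    arc_extent: float = 360.0  # degrees
    n_projections: int = 360

    def __post_init__(self) -> None:
        if not (0 < self.sad < self.sdd):
            raise ValueError("require 0 < sad < sdd")
        if min(self.det_pixels) < 1:
            raise ValueError("det_pixels must be positive")
        if not (0 < self.arc_extent <= 360):
            raise ValueError("arc_extent must be in (0, 360]")
        if self.n_projections < 1:
            raise ValueError("need at least one projection")

    @property
    def pixel_pitch(self) -> tuple[float, float]:
        return (self.det_size[0] / self.det_pixels[0],
                self.det_size[1] / self.det_pixels[1])

    @property
    def magnification(self) -> float:
        return self.sdd / self.sad

    @property
    def half_fan_angle(self) -> float:
        """Half the in-plane fan angle, radians."""
        return float(np.arctan(0.5 * self.det_size[0] / self.sdd))

    def with_detector(self, det_pixels: tuple[int, int]) -> "ConeBeamGeometry":
        """Same physical geometry with a different detector sampling."""
        return replace(self, det_pixels=det_pixels)

    def source_position(self, angle_deg: float) -> np.ndarray:
        b = np.deg2rad(angle_deg)
        return np.array([-self.sad * np.sin(b), self.sad * np.cos(b), 0.0])

    def detector_frame(self, angle_deg: float):
        """(center, e_u, e_v) of the detector plane at a given angle."""
        b = np.deg2rad(angle_deg)
        e_u = np.array([np.cos(b), np.sin(b), 0.0])
        e_v = np.array([0.0, 0.0, 1.0])
        center = np.array(
            [-(self.sad - self.sdd) * np.sin(b),
             (self.sad - self.sdd) * np.cos(b), 0.0]
        )
        return center, e_u, e_v


def make_obi_geometry(scoring: bool = False) -> ConeBeamGeometry:
    """Clinical on-board-imager preset: SAD 100 cm, SDD 149.88 cm,
    39.7 x 29.8 cm flat panel, 200-degree arc with 372 projections.

    With ``scoring=True`` the detector is sampled on the coarse
    256 x 192 scoring grid (1.552 mm pixels) used for simulation.
    """
    det_pixels = (256, 192) if scoring else (1024, 768)
    det_size = (39.7312, 29.7984) if scoring else (39.7, 29.8)
    return ConeBeamGeometry(
        sad=100.0,
        sdd=149.88,
        det_size=det_size,
        det_pixels=det_pixels,
        arc_start=0.0,
        arc_extent=200.0,
        n_projections=372,
    )


def arc_angles(geometry: ConeBeamGeometry) -> np.ndarray:
    """Uniform projection-center angles over the half-open arc, degrees."""
    step = geometry.arc_extent / geometry.n_projections
    return geometry.arc_start + step * np.arange(geometry.n_projections)


def pixel_ray(geometry: ConeBeamGeometry, angle_deg: float,
              u_index: int, v_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Ray (source point, unit direction) through a detector pixel center."""
    nu, nv = geometry.det_pixels
    if not (0 <= u_index < nu and 0 <= v_index < nv):
        raise IndexError("pixel index outside detector grid")
    src = geometry.source_position(angle_deg)
    center, e_u, e_v = geometry.detector_frame(angle_deg)
    pu, pv = geometry.pixel_pitch
    w, h = geometry.det_size
    target = (
        center
        + ((u_index + 0.5) * pu - w / 2) * e_u
        + ((v_index + 0.5) * pv - h / 2) * e_v
    )
    d = target - src
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("degenerate ray")
    return src, d / n


@dataclass
class ProjectionImage:
    """Detector-plane raster for one projection angle.

    ``component`` is one of 'total', 'primary', 'scatter', 'blank',
    'log' or 'corrected'.  Intensity components must be non-negative.
    ``rel_uncertainty`` is an optional fractional 1-sigma map.
    """

    pixels: np.ndarray
    component: str
    angle: float
    rel_uncertainty: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise ValueError(f"unknown component {self.component!r}")
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2D (nv, nu)")
        if self.component in ("total", "primary", "scatter", "blank"):
            if np.any(self.pixels < 0):
                raise ValueError("negative intensity pixels")
        if self.rel_uncertainty is not None:
            self.rel_uncertainty = np.asarray(self.rel_uncertainty, dtype=np.float64)
            if self.rel_uncertainty.shape != self.pixels.shape:
                raise ValueError("uncertainty map shape mismatch")
            if np.any(self.rel_uncertainty < 0):
                raise ValueError("negative uncertainties")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


class ProjectionSet:
    """Collection of projection images keyed by (angle, component), all
    sharing one detector sampling and one geometry."""

    def __init__(self, geometry: ConeBeamGeometry,
                 images: Iterable[ProjectionImage] = ()):
        self.geometry = geometry
        self._images: dict[tuple[float, str], ProjectionImage] = {}
        for im in images:
            self.add(im)

    def add(self, image: ProjectionImage) -> None:
        if self._images:
            ref = next(iter(self._images.values()))
            if image.shape != ref.shape:
                raise ValueError("detector pixel dimensions differ")
        self._images[(float(image.angle), image.component)] = image

    def get(self, angle: float, component: str) -> ProjectionImage:
        return self._images[(float(angle), component)]

    def __contains__(self, key: tuple[float, str]) -> bool:
        return (float(key[0]), key[1]) in self._images

    def angles(self, component: str | None = None) -> list[float]:
        seen = []
        for (a, c) in self._images:
            if (component is None or c == component) and a not in seen:
                seen.append(a)
        return sorted(seen)

    def stack(self, component: str) -> np.ndarray:
        """(n_angles, nv, nu) array for one component, angle-ordered."""
        angles = self.angles(component)
        return np.stack([self._images[(a, component)].pixels for a in angles])

    def __len__(self) -> int:
        return len(self._images)
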