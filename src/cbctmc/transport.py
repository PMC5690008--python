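"""Monte Carlo photon transport with variance reduction, plus a
deterministic Siddon-style ray tracer for primary and blank projections.

Transport physics: photoelectric absorption (no electron transport),
free-electron Klein-Nishina Compton scattering and tabulated coherent
scattering with an independent-atom form-factor angular model.  Photons
are followed down to a configurable cutoff (default 10 keV).  Variance
reduction: forced detection scoring, fixed interaction splitting with
Russian roulette, Woodcock (delta) tracking and an optional isotropic
exponential path-length transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .geometry import ConeBeamGeometry, ProjectionImage
from .materials import MaterialCatalog, VoxelPhantom, load_default_catalog, _data_path

__all__ = [
    "Spectrum",
    "VRTParams",
    "PhotonState",
    "TransportTables",
    "siddon_primary",
    "simulate_projection",
    "woodcock_free_path",
    "accept_real",
    "split_and_roulette",
    "adaptive_smooth",
]


@dataclass(frozen=True)
class Spectrum:
    """Discrete line spectrum; weights are positive and sum to one."""

    energies: np.ndarray
    weights: np.ndarray
    mode: str = "sampled"

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=np.float64)
        w = np.asarray(self.weights, dtype=np.float64)
        if e.size == 0:
            raise ValueError("empty spectrum")
        if np.any(w <= 0):
            raise ValueError("spectrum weights must be positive")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("spectrum weights must sum to 1")
        if np.any(e < 10.0) or np.any(e > 150.0):
            raise ValueError("energies outside the 10-150 keV table range")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w)

    @classmethod
    def monoenergetic(cls, energy_kev: float) -> "Spectrum":
        return cls(np.array([energy_kev]), np.array([1.0]), mode="monoenergetic")

    @property
    def cdf(self) -> np.ndarray:
        return np.cumsum(self.weights)

    @property
    def mean_energy(self) -> float:
        return float(np.dot(self.energies, self.weights))


@dataclass(frozen=True)
class VRTParams:
    """Variance-reduction controls: splitting number, Russian-roulette
    factor, path-stretch parameter and the photon energy cutoff."""

    n_split: int = 16
    rr_factor: int = 8
    path_stretch: float = 0.0
    forced_detection: bool = True
    photon_cutoff: float = 10.0
    coherent: bool = True

    def __post_init__(self) -> None:
        if self.n_split < 1 or self.rr_factor < 1:
            raise ValueError("n_split and rr_factor must be >= 1")
        if self.path_stretch < 0:
            raise ValueError("path_stretch must be >= 0")
        if self.photon_cutoff < 10.0:
            raise ValueError("cutoff below the 10 keV table minimum")


@dataclass
class PhotonState:
    position: np.ndarray
    direction: np.ndarray
    energy: float
    weight: float
    scatter_order: int = 0
    aimed: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.weight <= 0:
            raise ValueError("non-positive weight")
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("direction must be unit-norm")


class TransportTables:
    """Flattened per-material cross-section arrays for the kernels."""

    def __init__(self, catalog: MaterialCatalog | None = None):
        catalog = catalog or load_default_catalog()
        self.names = catalog.names
        mats = [catalog[n] for n in self.names]
        self.e_grid = mats[0].xs_energy.astype(np.float64)
        ne = self.e_grid.size
        nm = len(mats)
        self.matt_total = np.zeros((nm, ne))
        self.matt_photo = np.zeros((nm, ne))
        self.matt_incoh = np.zeros((nm, ne))
        self.matt_coh = np.zeros((nm, ne))
        for i, m in enumerate(mats):
            self.matt_total[i] = m.xs_total
            self.matt_photo[i] = m.xs_photo
            self.matt_incoh[i] = m.xs_incoh
            self.matt_coh[i] = m.xs_coh
        ff = pd.read_csv(_data_path("rayleigh_ff.csv"))
        x = np.sort(ff.x_invA.unique())
        x2 = (x ** 2).astype(np.float64)
        self.rayl_x2 = x2
        self.rayl_cum = np.zeros((nm, x2.size))
        for i, name in enumerate(self.names):
            sub = ff[ff.material == name].sort_values("x_invA")
            if len(sub) == 0:  # vacuum
                continue
            f2 = sub.f2.to_numpy()
            # cumulative integral of F^2 over x^2 (trapezoid)
            cum = np.concatenate(
                [[0.0], np.cumsum(0.5 * (f2[1:] + f2[:-1]) * np.diff(x2))]
            )
            self.rayl_cum[i] = cum

    @property
    def e0(self) -> float:
        return float(self.e_grid[0])

    @property
    def de(self) -> float:
        return float(self.e_grid[1] - self.e_grid[0])


_TABLES: TransportTables | None = None


def default_tables() -> TransportTables:
    global _TABLES
    if _TABLES is None:
        _TABLES = TransportTables()
    return _TABLES


def _phantom_arrays(phantom: VoxelPhantom, tables: TransportTables):
    # map phantom material names onto the table ordering
    if phantom.material_names == tables.names:
        mat = phantom.material_index
    else:
        lut = np.array([tables.names.index(n) for n in phantom.material_names],
                       dtype=np.int8)
        mat = lut[phantom.material_index]
    origin = np.asarray(phantom.origin, dtype=np.float64)
    voxel = np.asarray(phantom.voxel_size, dtype=np.float64)
    return np.ascontiguousarray(mat), phantom.density, origin, voxel


def _frame(geometry: ConeBeamGeometry, angle: float):
    src = geometry.source_position(angle)
    det_c, e_u, e_v = geometry.detector_frame(angle)
    b = np.deg2rad(angle)
    e_n = np.array([-np.sin(b), np.cos(b), 0.0])  # detector normal, toward source
    return src, det_c, e_u, e_v, e_n


def siddon_primary(phantom: VoxelPhantom, geometry: ConeBeamGeometry,
                   spectrum: Spectrum, angle: float,
                   tables: TransportTables | None = None
                   ) -> tuple[ProjectionImage, ProjectionImage]:
    """Noiseless primary and blank projection at one angle by exact voxel
    traversal (radiological path through pixel centers)."""
    tables = tables or default_tables()
    mat, rho, origin, voxel = _phantom_arrays(phantom, tables)
    src, det_c, e_u, e_v, e_n = _frame(geometry, angle)
    nu, nv = geometry.det_pixels
    prim, blank = _kernels.siddon_primary_kernel(
        mat, rho, origin, voxel, src, det_c, e_u, e_v, e_n,
        geometry.det_size[0], geometry.det_size[1], nu, nv,
        spectrum.energies, spectrum.weights,
        tables.e0, tables.de, tables.matt_total,
    )
    return (ProjectionImage(prim, "primary", angle),
            ProjectionImage(blank, "blank", angle))


def simulate_projection(phantom: VoxelPhantom, geometry: ConeBeamGeometry,
                        spectrum: Spectrum, angle: float, n_histories: int,
                        vrt: VRTParams | None = None, seed: int = 0,
                        tables: TransportTables | None = None
                        ) -> tuple[ProjectionImage, ProjectionImage]:
    """Monte Carlo estimate of the primary and scatter detector signal at
    one projection angle, with per-pixel relative 1-sigma maps.

    Values are normalized so a vacuum phantom yields the analytic blank
    field in expectation (energy-fluence units; absolute calibration
    cancels in the log normalization).
    """
    if n_histories < 1:
        raise ValueError("need at least one history")
    vrt = vrt or VRTParams()
    tables = tables or default_tables()
    mat, rho, origin, voxel = _phantom_arrays(phantom, tables)
    src, det_c, e_u, e_v, e_n = _frame(geometry, angle)
    nu, nv = geometry.det_pixels
    # per-material maximum density present, for the Woodcock majorant
    nm = len(tables.names)
    rho_max = np.zeros(nm)
    for m in range(nm):
        sel = mat == m
        if np.any(sel):
            rho_max[m] = float(rho[sel].max())
    prim, prim_sq, scat, scat_sq = _kernels.mc_projection_kernel(
        mat, rho, origin, voxel, src, det_c, e_u, e_v, e_n,
        geometry.det_size[0], geometry.det_size[1], nu, nv,
        spectrum.energies, spectrum.cdf,
        tables.e0, tables.de, tables.matt_total, tables.matt_photo,
        tables.matt_incoh, tables.matt_coh,
        tables.rayl_x2, tables.rayl_cum, rho_max,
        int(n_histories), int(vrt.n_split), int(vrt.rr_factor),
        float(vrt.path_stretch), float(vrt.photon_cutoff),
        vrt.coherent, int(seed) & 0x7FFFFFFF,
    )
    scale = nu * nv / float(n_histories)

    def _finish(s1, s2, component):
        with np.errstate(invalid="ignore", divide="ignore"):
            var = np.maximum(s2 - s1 ** 2 / n_histories, 0.0)
            rel = np.where(s1 > 0, np.sqrt(var) / np.where(s1 > 0, s1, 1.0), 0.0)
        return ProjectionImage(s1 * scale, component, angle, rel_uncertainty=rel)

    return _finish(prim, prim_sq, "primary"), _finish(scat, scat_sq, "scatter")


def woodcock_free_path(rng: np.random.Generator, mu_max: float) -> float:
    """Free path in the homogenized majorant medium: Exponential(mu_max)."""
    if mu_max <= 0:
        raise ValueError("mu_max must be positive")
    return float(rng.exponential(1.0 / mu_max))


def accept_real(local_mu: float, mu_max: float,
                rng: np.random.Generator) -> bool:
    """True when a Woodcock candidate interaction is real (probability
    local_mu / mu_max), else fictitious."""
    if mu_max <= 0:
        raise ValueError("mu_max must be positive")
    if not (0.0 <= local_mu <= mu_max):
        raise ValueError("require 0 <= local_mu <= mu_max")
    return bool(rng.random() < local_mu / mu_max)


def split_and_roulette(photon: PhotonState, vrt: VRTParams,
                       rng: np.random.Generator,
                       sample_direction: Callable[[np.random.Generator],
                                                  tuple[np.ndarray, float]],
                       is_aimed: Callable[[np.ndarray], bool]
                       ) -> list[PhotonState]:
    """Split a photon at an interaction into ``n_split`` daughters (weight
    1/n_split each); detector-aimed daughters are kept for forced-detection
    scoring, the rest survive Russian roulette with probability
    1/rr_factor and weight rr_factor/n_split.  The expected total daughter
    weight equals the parent weight."""
    out: list[PhotonState] = []
    n = vrt.n_split
    for _ in range(n):
        d, e = sample_direction(rng)
        w = photon.weight / n
        if is_aimed(d):
            out.append(PhotonState(photon.position.copy(), d, e, w,
                                   photon.scatter_order + 1, aimed=True))
        elif rng.random() * vrt.rr_factor < 1.0:
            out.append(PhotonState(photon.position.copy(), d, e,
                                   w * vrt.rr_factor,
                                   photon.scatter_order + 1, aimed=False))
    return out


# ---------------------------------------------------------------------------
# locally adaptive scatter smoothing

_WINDOWS = (3, 5, 7, 11, 15, 21, 31, 41)


def _savgol2d(img: np.ndarray, window: int, order: int = 2) -> tuple[np.ndarray, float]:
    """Separable Savitzky-Golay smoothing; returns the smoothed image and
    the variance-reduction factor (sum of squared effective weights)."""
    from scipy.signal import savgol_coeffs
    from scipy.ndimage import correlate1d

    c = savgol_coeffs(window, min(order, window - 1))
    out = correlate1d(img, c, axis=0, mode="nearest")
    out = correlate1d(out, c, axis=1, mode="nearest")
    var_factor = float((c ** 2).sum()) ** 2
    return out, var_factor


def adaptive_smooth(scatter: ProjectionImage,
                    windows: Sequence[int] = _WINDOWS,
                    chi2_margin: float = 3.0) -> ProjectionImage:
    """Locally adaptive smoothing of a noisy scatter projection.

    At every pixel the widest smoothing window whose local quadratic fit
    is statistically consistent with the data (normalized residual test
    against the pixel uncertainty map) is selected; windows shrink at
    genuine gradients.  The propagated relative uncertainty reflects the
    variance reduction of the selected window.
    """
    from scipy.ndimage import uniform_filter

    if scatter.rel_uncertainty is None:
        raise ValueError("adaptive smoothing requires an uncertainty map")
    img = scatter.pixels
    sigma = scatter.rel_uncertainty * np.abs(img)
    smoothed = [img]
    factors = [1.0]
    for w in windows:
        s, f = _savgol2d(img, w)
        smoothed.append(s)
        factors.append(f)
    sig2 = np.where(sigma > 0, sigma, np.inf) ** 2
    best = img.copy()
    best_rel = scatter.rel_uncertainty.copy()
    chosen = np.zeros(img.shape, dtype=np.int64)
    for k in range(1, len(smoothed)):
        w = windows[k - 1]
        resid = (img - smoothed[k]) ** 2 / sig2
        chi2 = uniform_filter(resid, size=w, mode="nearest")
        nwin = w * w
        ok = chi2 <= 1.0 + chi2_margin * np.sqrt(2.0 / nwin)
        best = np.where(ok, smoothed[k], best)
        chosen = np.where(ok, k, chosen)
    factor_map = np.asarray(factors)[chosen]
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(
            best != 0,
            np.sqrt(factor_map) * sigma / np.abs(np.where(best != 0, best, 1.0)),
            0.0,
        )
    out = np.maximum(best, 0.0)
    return ProjectionImage(out, scatter.component, scatter.angle,
                           rel_uncertainty=rel)
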