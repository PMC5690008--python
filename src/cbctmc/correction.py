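"""Projection-domain scatter correction and the iterative loop:
reconstruct, convert to materials/densities, simulate, correct,
reconstruct again, until convergence.

The per-pixel correction of the measured log projection r is

    p = (1 + alpha) r - alpha r_sim - ln( P_sim / (P_sim + beta S_sim) )

with P_sim and S_sim the simulated primary and scatter intensities,
alpha a relaxation parameter and beta the antiscatter-grid parameter
(the ratio of scatter-to-primary ratios with and without a grid).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ConeBeamGeometry, ProjectionImage, ProjectionSet, arc_angles
from .materials import MaterialRamp, default_ramp, load_default_catalog, volume_from_mu
from .recon import (
    INTENSITY_FLOOR_FRACTION,
    HU_WATER,
    LogProjection,
    ReconGrid,
    ReconVolume,
    air_normalize,
    fdk_reconstruct,
    resample,
)
from .transport import (
    Spectrum,
    VRTParams,
    adaptive_smooth,
    siddon_primary,
    simulate_projection,
)

__all__ = [
    "CorrectionParams",
    "CorrectionConfig",
    "IterationState",
    "corrected_log_projection",
    "grid_beta",
    "run_iteration",
    "run_correction",
    "simulate_scan",
    "scatter_free_reference",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrectionParams:
    alpha: float = 0.0
    beta: float = 1.0
    max_iter: int = 3
    conv_tol: float = 0.01  # relative change of the inter-iteration RMSE

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")
        if self.conv_tol <= 0:
            raise ValueError("conv_tol must be positive")


@dataclass
class IterationState:
    iteration: int
    volume: ReconVolume
    corrected_projections: list[LogProjection] | None = None
    convergence_metric: float = np.nan  # HU RMSE vs previous iteration

    def __post_init__(self) -> None:
        if self.iteration < 0:
            raise ValueError("iteration must be >= 0")


@dataclass
class CorrectionConfig:
    """Everything the loop needs besides the raw scan itself."""

    geometry: ConeBeamGeometry
    spectrum: Spectrum
    recon_grid: ReconGrid
    scoring_geometry: ConeBeamGeometry | None = None
    vrt: VRTParams = field(default_factory=VRTParams)
    ramp: MaterialRamp | None = None
    n_histories: int = 100_000
    replicate_symmetric: bool = False
    smooth_scatter: bool = True
    seed: int = 0
    r_sim_includes_beta: bool = True
    # reuse the same MC seed every iteration (common random numbers): the
    # convergence trace then measures the phantom update, not seed noise
    common_rng: bool = True

    def __post_init__(self) -> None:
        if self.scoring_geometry is None:
            self.scoring_geometry = self.geometry
        if self.ramp is None:
            self.ramp = default_ramp()

    @property
    def mu_water(self) -> float:
        catalog = load_default_catalog()
        return float(
            catalog["Water"].mass_atten(self.spectrum.mean_energy)
        )


def grid_beta(spr_grid: float, spr_no_grid: float) -> float:
    """Grid parameter: the ratio of scatter-to-primary ratios measured
    with and without an antiscatter grid."""
    if spr_no_grid <= 0:
        raise ValueError("spr_no_grid must be positive")
    return spr_grid / spr_no_grid


def corrected_log_projection(r: LogProjection, r_sim: LogProjection,
                             P_sim: ProjectionImage, S_sim: ProjectionImage,
                             params: CorrectionParams) -> LogProjection:
    """Apply the relaxed, grid-aware scatter correction to one projection."""
    shapes = {r.pixels.shape, r_sim.pixels.shape, P_sim.pixels.shape,
              S_sim.pixels.shape}
    if len(shapes) != 1:
        raise ValueError("projection shapes differ")
    floor = INTENSITY_FLOOR_FRACTION * float(max(P_sim.pixels.max(), 1e-300))
    P = np.maximum(P_sim.pixels, floor)
    if np.any(P <= 0):
        raise ValueError("non-positive simulated primary after flooring")
    S = np.maximum(S_sim.pixels, 0.0)
    a = params.alpha
    p = (1.0 + a) * r.pixels - a * r_sim.pixels \
        - np.log(P / (P + params.beta * S))
    return LogProjection(p, r.angle, kind="corrected")


def _analytic_blank(geometry: ConeBeamGeometry, spectrum: Spectrum,
                    angle: float) -> ProjectionImage:
    """Unattenuated detector field (inverse square and obliquity)."""
    nu, nv = geometry.det_pixels
    pu, pv = geometry.pixel_pitch
    u = (np.arange(nu) + 0.5) * pu - geometry.det_size[0] / 2
    v = (np.arange(nv) + 0.5) * pv - geometry.det_size[1] / 2
    U, V = np.meshgrid(u, v)
    d2 = geometry.sdd ** 2 + U ** 2 + V ** 2
    cosobl = geometry.sdd / np.sqrt(d2)
    val = cosobl * geometry.sdd ** 2 / d2
    b = float(np.dot(spectrum.weights, spectrum.energies)) * val
    return ProjectionImage(b, "blank", angle)


def _simulate_components(phantom, config: CorrectionConfig, angle: float,
                         seed: int):
    """Ray-traced primary plus Monte Carlo scatter (smoothed) on the
    scoring grid, upsampled to the reconstruction detector grid."""
    sg = config.scoring_geometry
    prim_s, _blank_s = siddon_primary(phantom, sg, config.spectrum, angle)
    _p_mc, scat_s = simulate_projection(
        phantom, sg, config.spectrum, angle, config.n_histories,
        vrt=config.vrt, seed=seed,
    )
    if config.smooth_scatter:
        scat_s = adaptive_smooth(scat_s)
    nu, nv = config.geometry.det_pixels
    if (nu, nv) != sg.det_pixels:
        prim = resample(prim_s.pixels, (nv, nu), "bicubic")
        scat = np.maximum(resample(scat_s.pixels, (nv, nu), "bicubic"), 0.0)
    else:
        prim, scat = prim_s.pixels, scat_s.pixels
    return (ProjectionImage(np.maximum(prim, 0.0), "primary", angle),
            ProjectionImage(scat, "scatter", angle))


def _measured_logs(raw: ProjectionSet) -> dict[float, LogProjection]:
    out = {}
    for a in raw.angles("total"):
        R = raw.get(a, "total")
        B = raw.get(a, "blank")
        out[a] = air_normalize(R, B)
    return out


def _volume_rmse_hu(a: ReconVolume, b: ReconVolume) -> float:
    """HU RMSE between two volumes over the central slice, restricted to
    the inscribed field-of-view cylinder."""
    nx, ny, nz = a.mu.shape
    iz = nz // 2
    xs = (np.arange(nx) + 0.5) / nx - 0.5
    ys = (np.arange(ny) + 0.5) / ny - 0.5
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    mask = X ** 2 + Y ** 2 <= 0.45 ** 2
    da = HU_WATER * a.mu[:, :, iz] / a.hu_scale
    db = HU_WATER * b.mu[:, :, iz] / b.hu_scale
    return float(np.sqrt(np.mean((da[mask] - db[mask]) ** 2)))


def run_iteration(state: IterationState, raw: ProjectionSet,
                  params: CorrectionParams,
                  config: CorrectionConfig) -> IterationState:
    """One loop of the iterative correction: convert the current volume to
    a material/density phantom, simulate primary and scatter for every
    projection angle, correct the measured log projections, reconstruct."""
    if state.volume is None:
        raise ValueError("iteration state carries no volume")
    vol = state.volume
    phantom = volume_from_mu(vol.mu, config.ramp,
                             voxel_size=vol.voxel_size, origin=vol.origin)
    angles = arc_angles(config.geometry)
    sim_angles = angles[:1] if config.replicate_symmetric else angles
    if config.common_rng:
        iter_seed = config.seed
    else:
        iter_seed = config.seed ^ (0x9E3779B9 * (state.iteration + 1)) & 0x7FFFFFFF

    logs = _measured_logs(raw)
    beta = params.beta
    corrected: list[LogProjection] = []
    sims: dict[float, tuple[ProjectionImage, ProjectionImage]] = {}
    for k, a in enumerate(sim_angles):
        try:
            sims[a] = _simulate_components(phantom, config, a,
                                           seed=iter_seed + 7919 * k)
        except Exception as err:  # pragma: no cover - context decoration
            raise RuntimeError(
                f"simulation failed at iteration {state.iteration + 1}, "
                f"angle {a:.2f}") from err
    blank0 = _analytic_blank(config.geometry, config.spectrum, angles[0])
    for a in angles:
        prim, scat = sims[sim_angles[0]] if config.replicate_symmetric else sims[a]
        floor = INTENSITY_FLOOR_FRACTION * float(blank0.pixels.max())
        P = np.maximum(prim.pixels, floor)
        b_eff = beta if config.r_sim_includes_beta else 1.0
        r_sim = LogProjection(
            np.log(blank0.pixels / (P + b_eff * scat.pixels)), a, kind="simulated"
        )
        corrected.append(
            corrected_log_projection(
                logs[a], r_sim,
                ProjectionImage(P, "primary", a),
                ProjectionImage(scat.pixels, "scatter", a),
                params,
            )
        )
    try:
        new_vol = fdk_reconstruct(corrected, config.geometry,
                                  config.recon_grid, hu_scale=config.mu_water)
    except Exception as err:  # pragma: no cover
        raise RuntimeError(
            f"reconstruction failed at iteration {state.iteration + 1}") from err
    metric = _volume_rmse_hu(new_vol, vol)
    return IterationState(state.iteration + 1, new_vol, corrected, metric)


def run_correction(raw: ProjectionSet, params: CorrectionParams,
                   config: CorrectionConfig,
                   reference: ReconVolume | None = None
                   ) -> tuple[list[IterationState], pd.DataFrame]:
    """Run the full iterative correction on a raw scan.

    Returns every iteration state (index 0 is the uncorrected
    reconstruction) plus a convergence trace.  Stops when the relative
    change of the inter-iteration volume RMSE drops below ``conv_tol``,
    when ``max_iter`` is reached, or (with a warning) when the metric
    increases in two consecutive iterations.
    """
    logs = _measured_logs(raw)
    lps = [LogProjection(lp.pixels, a, "raw") for a, lp in logs.items()]
    vol0 = fdk_reconstruct(lps, config.geometry, config.recon_grid,
                           hu_scale=config.mu_water)
    states = [IterationState(0, vol0, None, np.nan)]
    rows = []

    def _log_row(st):
        ref_rmse = (_volume_rmse_hu(st.volume, reference)
                    if reference is not None else np.nan)
        rows.append({"iteration": st.iteration,
                     "rmse_vs_prev_hu": st.convergence_metric,
                     "rmse_vs_reference_hu": ref_rmse})
        logger.info("iteration %d: rmse_vs_prev=%.2f HU rmse_vs_ref=%.2f HU",
                    st.iteration, st.convergence_metric, ref_rmse)

    _log_row(states[0])
    increases = 0
    for _ in range(params.max_iter):
        st = run_iteration(states[-1], raw, params, config)
        _log_row(st)
        prev_metric = states[-1].convergence_metric
        states.append(st)
        if np.isfinite(prev_metric):
            if st.convergence_metric > prev_metric:
                increases += 1
                if increases >= 2:
                    warnings.warn("correction diverging: inter-iteration RMSE "
                                  "increased twice; halting", RuntimeWarning)
                    break
            else:
                increases = 0
            rel = abs(st.convergence_metric - prev_metric) / prev_metric
            if rel < params.conv_tol:
                break
    return states, pd.DataFrame(rows)


def simulate_scan(phantom, config: CorrectionConfig, params: CorrectionParams
                  | None = None, include_scatter: bool = True,
                  seed: int | None = None,
                  noise_rel: float = 0.0) -> ProjectionSet:
    """Generate a synthetic raw scan (total + blank, optionally with the
    scatter contribution) of a known phantom, on the reconstruction
    detector grid.  Used for end-to-end tests and fixtures.

    ``noise_rel`` adds multiplicative Gaussian detector noise to the
    measured total signal (emulating the per-pixel statistical
    uncertainty of an acquired scan); the stored primary component stays
    noiseless so it can serve as an ideal scatter-free reference.
    """
    seed = config.seed if seed is None else seed
    angles = arc_angles(config.geometry)
    sim_angles = angles[:1] if config.replicate_symmetric else angles
    pset = ProjectionSet(config.geometry)
    comps = {}
    rng = np.random.default_rng(seed)
    for k, a in enumerate(sim_angles):
        prim, scat = _simulate_components(phantom, config, a, seed=seed + 104729 * k)
        comps[a] = (prim, scat)
    noise = {a: 1.0 + noise_rel * rng.standard_normal(
        comps[sim_angles[0]][0].pixels.shape) for a in sim_angles} \
        if noise_rel > 0 else None
    for a in angles:
        prim, scat = comps[sim_angles[0]] if config.replicate_symmetric else comps[a]
        total = prim.pixels + (scat.pixels if include_scatter else 0.0)
        if noise is not None:
            total = np.maximum(
                total * noise[sim_angles[0] if config.replicate_symmetric else a],
                0.0)
        pset.add(ProjectionImage(total, "total", a))
        pset.add(ProjectionImage(prim.pixels, "primary", a))
        pset.add(ProjectionImage(scat.pixels if include_scatter
                                 else np.zeros_like(prim.pixels), "scatter", a))
        pset.add(_analytic_blank(config.geometry, config.spectrum, a))
    return pset


def scatter_free_reference(raw: ProjectionSet,
                           config: CorrectionConfig) -> ReconVolume:
    """Reconstruction from the primary-only component of a synthetic scan."""
    lps = []
    for a in raw.angles("primary"):
        P = raw.get(a, "primary")
        B = raw.get(a, "blank")
        lps.append(LogProjection(air_normalize(P, B).pixels, a, "raw"))
    return fdk_reconstruct(lps, config.geometry, config.recon_grid,
                           hu_scale=config.mu_water)
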