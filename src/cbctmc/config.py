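"""YAML run configuration with strict validation.

All physical quantities carry explicit units in key names (``sad_cm``,
``energy_kev``, ...).  Unknown keys are rejected.  Defaults follow the
clinical partial-arc preset (alpha=0, beta=0.5, 372 projections over
200 degrees) unless a water-phantom preset is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .correction import CorrectionConfig, CorrectionParams
from .geometry import ConeBeamGeometry
from .materials import MaterialRamp, default_ramp, load_ramp
from .recon import ReconGrid
from .transport import Spectrum, VRTParams

__all__ = ["RunConfig", "load_run_config"]

_GEOM_KEYS = {"sad_cm", "sdd_cm", "det_width_cm", "det_height_cm",
              "det_pixels_u", "det_pixels_v", "arc_start_deg",
              "arc_extent_deg", "n_projections"}
_SPEC_KEYS = {"energies_kev", "weights", "monoenergetic_kev"}
_VRT_KEYS = {"n_split", "rr_factor", "path_stretch", "photon_cutoff_kev",
             "coherent"}
_CORR_KEYS = {"alpha", "beta", "max_iter", "conv_tol"}
_RECON_KEYS = {"shape", "voxel_size_cm", "scoring_pixels_u",
               "scoring_pixels_v"}
_TOP_KEYS = {"geometry", "spectrum", "vrt", "correction", "recon",
             "ramp_file", "seed", "n_histories", "replicate_symmetric",
             "output_dir"}


def _check_keys(block: dict, allowed: set[str], name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {name}: {sorted(unknown)}")


@dataclass
class RunConfig:
    geometry: ConeBeamGeometry
    spectrum: Spectrum
    vrt: VRTParams
    correction: CorrectionParams
    recon_grid: ReconGrid
    scoring_pixels: tuple[int, int]
    ramp: MaterialRamp
    seed: int = 0
    n_histories: int = 100_000
    replicate_symmetric: bool = False
    output_dir: Path = field(default_factory=lambda: Path("out"))

    def correction_config(self) -> CorrectionConfig:
        return CorrectionConfig(
            geometry=self.geometry,
            spectrum=self.spectrum,
            recon_grid=self.recon_grid,
            scoring_geometry=self.geometry.with_detector(self.scoring_pixels),
            vrt=self.vrt,
            ramp=self.ramp,
            n_histories=self.n_histories,
            replicate_symmetric=self.replicate_symmetric,
            seed=self.seed,
        )


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")

    g = raw.get("geometry", {})
    _check_keys(g, _GEOM_KEYS, "geometry")
    geometry = ConeBeamGeometry(
        sad=float(g.get("sad_cm", 100.0)),
        sdd=float(g.get("sdd_cm", 149.88)),
        det_size=(float(g.get("det_width_cm", 39.7)),
                  float(g.get("det_height_cm", 29.8))),
        det_pixels=(int(g.get("det_pixels_u", 1024)),
                    int(g.get("det_pixels_v", 768))),
        arc_start=float(g.get("arc_start_deg", 0.0)),
        arc_extent=float(g.get("arc_extent_deg", 200.0)),
        n_projections=int(g.get("n_projections", 372)),
    )

    s = raw.get("spectrum", {})
    _check_keys(s, _SPEC_KEYS, "spectrum")
    if "monoenergetic_kev" in s:
        spectrum = Spectrum.monoenergetic(float(s["monoenergetic_kev"]))
    elif "energies_kev" in s:
        spectrum = Spectrum(np.asarray(s["energies_kev"], float),
                            np.asarray(s["weights"], float))
    else:
        spectrum = Spectrum.monoenergetic(60.0)

    v = raw.get("vrt", {})
    _check_keys(v, _VRT_KEYS, "vrt")
    vrt = VRTParams(
        n_split=int(v.get("n_split", 16)),
        rr_factor=int(v.get("rr_factor", 8)),
        path_stretch=float(v.get("path_stretch", 0.0)),
        photon_cutoff=float(v.get("photon_cutoff_kev", 10.0)),
        coherent=bool(v.get("coherent", True)),
    )

    c = raw.get("correction", {})
    _check_keys(c, _CORR_KEYS, "correction")
    correction = CorrectionParams(
        alpha=float(c.get("alpha", 0.0)),
        beta=float(c.get("beta", 0.5)),
        max_iter=int(c.get("max_iter", 3)),
        conv_tol=float(c.get("conv_tol", 0.01)),
    )

    r = raw.get("recon", {})
    _check_keys(r, _RECON_KEYS, "recon")
    recon_grid = ReconGrid(
        shape=tuple(r.get("shape", [512, 512, 128])),
        voxel_size=tuple(r.get("voxel_size_cm", [0.051, 0.051, 0.27])),
    )
    scoring = (int(r.get("scoring_pixels_u", 256)),
               int(r.get("scoring_pixels_v", 192)))

    ramp = load_ramp(raw["ramp_file"]) if "ramp_file" in raw else default_ramp()
    return RunConfig(
        geometry=geometry, spectrum=spectrum, vrt=vrt, correction=correction,
        recon_grid=recon_grid, scoring_pixels=scoring, ramp=ramp,
        seed=int(raw.get("seed", 0)),
        n_histories=int(raw.get("n_histories", 100_000)),
        replicate_symmetric=bool(raw.get("replicate_symmetric", False)),
        output_dir=Path(raw.get("output_dir", "out")),
    )
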