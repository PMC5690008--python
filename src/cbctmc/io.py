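"""File formats and the synthetic fixture generator.

Volumes are stored as MetaImage (.mha, single-file, uncompressed raw) or
HDF5; voxel phantoms additionally in the egsphant-style plain-text layout
(material list, grid dimensions, boundary lists, material-index block,
density block).  Projection stacks go to HDF5 with per-angle and
per-component channels.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import h5py
import numpy as np

from .geometry import ConeBeamGeometry, ProjectionImage, ProjectionSet
from .materials import (
    MaterialRamp,
    VoxelPhantom,
    load_default_catalog,
    make_catphan_like_phantom,
    make_ramp,
    make_water_air_phantom,
)
from .recon import ReconGrid, ReconVolume

__all__ = [
    "write_volume",
    "read_volume",
    "write_projection_set",
    "read_projection_set",
    "write_egsphant",
    "read_egsphant",
    "generate_fixture",
    "FixtureBundle",
]

_MHA_TYPES = {"MET_FLOAT": np.float32, "MET_DOUBLE": np.float64,
              "MET_SHORT": np.int16, "MET_UCHAR": np.uint8}


def write_volume(path: str | Path, volume: ReconVolume) -> None:
    """Write a reconstruction volume as an uncompressed local MetaImage."""
    path = Path(path)
    if path.suffix != ".mha":
        raise ValueError("unsupported container; use .mha")
    mu = np.asarray(volume.mu, dtype=np.float64)
    nx, ny, nz = mu.shape
    header = (
        "ObjectType = Image\n"
        "NDims = 3\n"
        "BinaryData = True\n"
        "BinaryDataByteOrderMSB = False\n"
        f"DimSize = {nx} {ny} {nz}\n"
        f"ElementSpacing = {volume.voxel_size[0]} {volume.voxel_size[1]} {volume.voxel_size[2]}\n"
        f"Offset = {volume.origin[0]} {volume.origin[1]} {volume.origin[2]}\n"
        f"HUScale = {volume.hu_scale!r}\n"
        "ElementType = MET_DOUBLE\n"
        "ElementDataFile = LOCAL\n"
    )
    with open(path, "wb") as f:
        f.write(header.encode())
        # MetaImage raw block is x-fastest
        f.write(np.ascontiguousarray(mu.transpose(2, 1, 0)).tobytes())


def read_volume(path: str | Path) -> ReconVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header: dict[str, str] = {}
    with open(path, "rb") as f:
        while True:
            line = f.readline()
            if not line:
                raise ValueError("corrupt MetaImage header: no data section")
            key, _, val = line.decode().partition("=")
            header[key.strip()] = val.strip()
            if key.strip() == "ElementDataFile":
                break
        if header.get("ElementDataFile") != "LOCAL":
            raise ValueError("only single-file (LOCAL) MetaImage supported")
        dtype = _MHA_TYPES.get(header.get("ElementType", ""))
        if dtype is None:
            raise ValueError(f"unsupported ElementType {header.get('ElementType')}")
        nx, ny, nz = (int(x) for x in header["DimSize"].split())
        data = np.frombuffer(f.read(), dtype=dtype)
    if data.size != nx * ny * nz:
        raise ValueError("corrupt MetaImage: truncated data block")
    mu = data.reshape(nz, ny, nx).transpose(2, 1, 0).astype(np.float64)
    spacing = tuple(float(x) for x in header["ElementSpacing"].split())
    origin = tuple(float(x) for x in header.get("Offset", "0 0 0").split())
    hu_scale = float(header.get("HUScale", 0.2059))
    return ReconVolume(mu, spacing, origin, hu_scale)


def write_projection_set(path: str | Path, pset: ProjectionSet) -> None:
    """Projection stacks as HDF5: one (angle, v, u) dataset per component
    with angle and geometry metadata."""
    g = pset.geometry
    with h5py.File(path, "w") as f:
        f.attrs["sad"] = g.sad
        f.attrs["sdd"] = g.sdd
        f.attrs["det_size"] = g.det_size
        f.attrs["det_pixels"] = g.det_pixels
        f.attrs["arc_start"] = g.arc_start
        f.attrs["arc_extent"] = g.arc_extent
        f.attrs["n_projections"] = g.n_projections
        comps = sorted({c for (_, c) in pset._images})
        for comp in comps:
            angles = pset.angles(comp)
            grp = f.create_group(comp)
            grp.create_dataset("angles", data=np.asarray(angles))
            grp.create_dataset("pixels", data=pset.stack(comp))
            uncs = [pset.get(a, comp).rel_uncertainty for a in angles]
            if all(u is not None for u in uncs):
                grp.create_dataset("rel_uncertainty", data=np.stack(uncs))


def read_projection_set(path: str | Path) -> ProjectionSet:
    with h5py.File(path, "r") as f:
        geom = ConeBeamGeometry(
            sad=float(f.attrs["sad"]), sdd=float(f.attrs["sdd"]),
            det_size=tuple(f.attrs["det_size"]),
            det_pixels=tuple(int(x) for x in f.attrs["det_pixels"]),
            arc_start=float(f.attrs["arc_start"]),
            arc_extent=float(f.attrs["arc_extent"]),
            n_projections=int(f.attrs["n_projections"]),
        )
        pset = ProjectionSet(geom)
        for comp in f:
            grp = f[comp]
            angles = grp["angles"][()]
            pix = grp["pixels"][()]
            unc = grp["rel_uncertainty"][()] if "rel_uncertainty" in grp else None
            for i, a in enumerate(angles):
                pset.add(ProjectionImage(
                    pix[i], comp, float(a),
                    rel_uncertainty=None if unc is None else unc[i]))
    return pset


def write_egsphant(phantom: VoxelPhantom, path: str | Path) -> None:
    """egsphant-style text export: material count and names, grid
    dimensions, voxel boundary lists, material-index block (one digit per
    voxel, z-slices of y-rows), then the density block."""
    nx, ny, nz = phantom.shape
    lines = [str(len(phantom.material_names))]
    lines += phantom.material_names
    lines.append(" ".join("0.0" for _ in phantom.material_names))  # dummy ESTEPE
    lines.append(f"{nx} {ny} {nz}")
    for axis in range(3):
        n = phantom.shape[axis]
        o = phantom.origin[axis]
        d = phantom.voxel_size[axis]
        bounds = [o + i * d for i in range(n + 1)]
        lines.append(" ".join(f"{b:.6g}" for b in bounds))
    for iz in range(nz):
        for iy in range(ny):
            # egsphant media indices are 1-based
            lines.append("".join(str(int(phantom.material_index[ix, iy, iz]) + 1)
                                 for ix in range(nx)))
        lines.append("")
    for iz in range(nz):
        for iy in range(ny):
            lines.append(" ".join(f"{phantom.density[ix, iy, iz]:.6g}"
                                  for ix in range(nx)))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def read_egsphant(path: str | Path) -> VoxelPhantom:
    tok_lines = [l for l in Path(path).read_text().splitlines()]
    it = iter([l for l in tok_lines])
    nmat = int(next(it).strip())
    names = [next(it).strip() for _ in range(nmat)]
    next(it)  # ESTEPE dummies
    nx, ny, nz = (int(x) for x in next(it).split())
    bounds = [np.array([float(x) for x in next(it).split()]) for _ in range(3)]
    voxel_size = tuple(float(b[1] - b[0]) for b in bounds)
    origin = tuple(float(b[0]) for b in bounds)
    idx = np.zeros((nx, ny, nz), dtype=np.int8)
    for iz in range(nz):
        for iy in range(ny):
            row = next(it).strip()
            idx[:, iy, iz] = [int(c) - 1 for c in row]
        nxt = next(it, "")
    rho = np.zeros((nx, ny, nz), dtype=np.float32)
    for iz in range(nz):
        for iy in range(ny):
            row = next(it).split()
            rho[:, iy, iz] = [float(x) for x in row]
        next(it, "")
    return VoxelPhantom(idx, rho, voxel_size, origin, names)


@dataclass
class FixtureBundle:
    name: str
    scale: str
    phantom: VoxelPhantom
    geometry: ConeBeamGeometry
    scoring_geometry: ConeBeamGeometry
    recon_grid: ReconGrid
    spectrum_kev: float
    beta: float
    seed: int
    ramp: MaterialRamp | None = None

    def manifest(self) -> dict:
        d = {"name": self.name, "scale": self.scale, "seed": self.seed,
             "spectrum_kev": self.spectrum_kev, "beta": self.beta,
             "geometry": asdict(self.geometry),
             "phantom_shape": list(self.phantom.shape)}
        d["hash"] = hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]
        return d


def generate_fixture(name: str, scale: str = "desk", seed: int = 0
                     ) -> FixtureBundle:
    """Deterministic synthetic scan setups.

    ``water_phantom``: water cylinder with a central air cavity scanned
    over a full circle with a monoenergetic 60 keV source (full scale:
    20/20/2/10 cm, 360 projections; desk scale: 128-cube grid, 90
    projections).  ``catphan_like``: eight-insert sensitometry cylinder
    under the clinical partial-arc preset.
    """
    if scale not in ("full", "desk"):
        raise ValueError("scale must be 'full' or 'desk'")
    if name == "water_phantom":
        if scale == "full":
            phantom = make_water_air_phantom(20, 20, 2, 10, voxel_size=0.1)
            geom = ConeBeamGeometry(100.0, 149.88, (39.7, 29.8), (512, 384),
                                    0.0, 360.0, 360)
            sgeom = geom.with_detector((256, 192))
            grid = ReconGrid((512, 512, 128), (0.051, 0.051, 0.27))
        else:
            vox = 22.0 / 128
            phantom = make_water_air_phantom(
                20, 20, 2, 10, voxel_size=vox, shape=(128, 128, 128))
            geom = ConeBeamGeometry(100.0, 149.88, (39.7, 29.8), (128, 96),
                                    0.0, 360.0, 90)
            sgeom = geom.with_detector((64, 48))
            grid = ReconGrid((128, 128, 128), (vox, vox, vox))
        ramp = make_ramp(["Vacuum", "Air", "Water"], 60.0)
        return FixtureBundle(name, scale, phantom, geom, sgeom, grid,
                             spectrum_kev=60.0, beta=1.0, seed=seed, ramp=ramp)
    if name == "catphan_like":
        if scale == "full":
            phantom = make_catphan_like_phantom(voxel_size=0.1)
            geom = ConeBeamGeometry(100.0, 149.88, (39.7, 29.8), (1024, 768),
                                    0.0, 200.0, 372)
            sgeom = geom.with_detector((256, 192))
            grid = ReconGrid((512, 512, 16), (0.051, 0.051, 0.27))
        else:
            vox = 22.0 / 96
            phantom = make_catphan_like_phantom(
                voxel_size=(vox, vox, vox), shape=(96, 96, 24))
            geom = ConeBeamGeometry(100.0, 149.88, (39.7, 29.8), (96, 24),
                                    0.0, 200.0, 93)
            sgeom = geom.with_detector((48, 12))
            grid = ReconGrid((96, 96, 8), (vox, vox, 0.6))
        ramp = make_ramp(load_default_catalog().names, 60.0)
        return FixtureBundle(name, scale, phantom, geom, sgeom, grid,
                             spectrum_kev=60.0, beta=0.5, seed=seed, ramp=ramp)
    raise ValueError(
        f"unknown fixture {name!r}; options: water_phantom, catphan_like")
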