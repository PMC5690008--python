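"""Material catalogue, attenuation-to-material ramp and voxel phantoms.

The catalogue ships with a static photon cross-section table (10--150 keV,
1 keV grid) for the nine materials used in Catphan-style sensitometry:
Vacuum, Air, PMP, LDPE, Polystyrene, Water, Acrylic, Delrin and Teflon.
Mass attenuation coefficients were tabulated once from an XCOM-equivalent
source; no network access is needed at runtime.

Voxel phantoms carry a material-index grid plus a mass-density grid.  The
density of a voxel with reconstructed attenuation ``mu`` assigned to a
material with nominal attenuation ``mu_mat`` and nominal density
``rho_mat`` is the fractional value ``mu / mu_mat * rho_mat``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Material",
    "MaterialCatalog",
    "MaterialRamp",
    "VoxelPhantom",
    "load_default_catalog",
    "load_ramp",
    "default_ramp",
    "make_ramp",
    "assign_material",
    "mu_to_density",
    "volume_from_mu",
    "make_water_air_phantom",
    "make_catphan_like_phantom",
    "material_mu",
]

logger = logging.getLogger(__name__)

# electrons per gram (Z/A weighted, Avogadro folded in); used by the
# transport module for free-electron Compton sampling
ELECTRONS_PER_G = {
    "Vacuum": 0.0,
    "Air": 3.005637e23,
    "PMP": 3.433865e23,
    "LDPE": 3.433865e23,
    "Polystyrene": 3.237710e23,
    "Water": 3.341921e23,
    "Acrylic": 3.247734e23,
    "Delrin": 3.208600e23,
    "Teflon": 2.890050e23,
}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("cbctmc").joinpath("data", name)))


@dataclass(frozen=True)
class Material:
    """A catalogued material with nominal properties and cross sections.

    ``xs_table`` holds mass attenuation coefficients in cm^2/g over a
    strictly increasing energy grid in keV, with columns total,
    photoelectric, incoherent and coherent.
    """

    name: str
    mu_nominal: float  # 1/cm at the reference spectrum
    rho_nominal: float  # g/cm^3
    xs_energy: np.ndarray = field(repr=False)
    xs_total: np.ndarray = field(repr=False)
    xs_photo: np.ndarray = field(repr=False)
    xs_incoh: np.ndarray = field(repr=False)
    xs_coh: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.mu_nominal < 0 or self.rho_nominal < 0:
            raise ValueError(f"{self.name}: negative nominal properties")
        e = np.asarray(self.xs_energy, float)
        if e.size and np.any(np.diff(e) <= 0):
            raise ValueError(f"{self.name}: energies not strictly increasing")
        for arr in (self.xs_total, self.xs_photo, self.xs_incoh, self.xs_coh):
            if np.any(np.asarray(arr) < 0):
                raise ValueError(f"{self.name}: negative cross section")
        parts = self.xs_photo + self.xs_incoh + self.xs_coh
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.abs(parts - self.xs_total) / np.where(
                self.xs_total > 0, self.xs_total, 1.0
            )
        if np.any(rel > 0.01):
            raise ValueError(f"{self.name}: partials do not sum to total within 1%")

    @property
    def electrons_per_g(self) -> float:
        return ELECTRONS_PER_G.get(self.name, 0.0)

    def mass_atten(self, energy_kev: float | np.ndarray, kind: str = "total") -> np.ndarray:
        """Log-log interpolated mass attenuation coefficient, cm^2/g."""
        e = np.asarray(energy_kev, dtype=float)
        lo, hi = self.xs_energy[0], self.xs_energy[-1]
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(
                f"energy outside tabulated range [{lo}, {hi}] keV"
            )
        table = {
            "total": self.xs_total,
            "photo": self.xs_photo,
            "incoh": self.xs_incoh,
            "coh": self.xs_coh,
        }[kind]
        if np.all(table == 0):  # vacuum
            return np.zeros_like(e) if e.ndim else 0.0
        with np.errstate(divide="ignore"):
            logt = np.log(np.maximum(table, 1e-300))
        out = np.exp(np.interp(np.log(e), np.log(self.xs_energy), logt))
        return out if e.ndim else float(out)


class MaterialCatalog:
    """Ordered mapping of material name -> :class:`Material`."""

    def __init__(self, materials: Sequence[Material]):
        self._by_name = {m.name: m for m in materials}
        self._order = [m.name for m in materials]

    def __getitem__(self, name: str) -> Material:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    @property
    def names(self) -> list[str]:
        return list(self._order)

    def index(self, name: str) -> int:
        return self._order.index(name)


_DEFAULT_CATALOG: MaterialCatalog | None = None

# nominal (mu_mat, rho_mat) pairs of the reference ramp
_NOMINALS = {
    "Vacuum": (0.0, 0.0),
    "Air": (5.18e-4, 1.205e-3),
    "PMP": (0.178, 0.83),
    "LDPE": (0.200, 0.93),
    "Polystyrene": (0.217, 1.06),
    "Water": (0.243, 1.00),
    "Acrylic": (0.259, 1.19),
    "Delrin": (0.315, 1.41),
    "Teflon": (0.485, 2.10),
}


def load_default_catalog() -> MaterialCatalog:
    """Load the embedded nine-material catalogue (cached)."""
    global _DEFAULT_CATALOG
    if _DEFAULT_CATALOG is not None:
        return _DEFAULT_CATALOG
    df = pd.read_csv(_data_path("xs_tables.csv"))
    mats = []
    for name, (mu_mat, rho_mat) in _NOMINALS.items():
        sub = df[df.material == name].sort_values("energy_kev")
        mats.append(
            Material(
                name=name,
                mu_nominal=mu_mat,
                rho_nominal=rho_mat,
                xs_energy=sub.energy_kev.to_numpy(),
                xs_total=sub.total_cm2_g.to_numpy(),
                xs_photo=sub.photo_cm2_g.to_numpy(),
                xs_incoh=sub.incoh_cm2_g.to_numpy(),
                xs_coh=sub.coh_cm2_g.to_numpy(),
            )
        )
    _DEFAULT_CATALOG = MaterialCatalog(mats)
    return _DEFAULT_CATALOG


@dataclass(frozen=True)
class MaterialRamp:
    """Contiguous half-open attenuation intervals [mu_low, mu_high) mapping
    reconstructed attenuation to a material name.

    ``nominals`` optionally overrides the per-entry (mu_mat, rho_mat)
    pairs used for fractional density conversion; by default the
    catalogue nominals apply.
    """

    entries: tuple[tuple[float, float, str], ...]
    nominals: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.nominals is not None and len(self.nominals) != len(self.entries):
            raise ValueError("nominals must match entries")
        if not self.entries:
            raise ValueError("empty ramp")
        lows = [e[0] for e in self.entries]
        highs = [e[1] for e in self.entries]
        if lows[0] != 0.0:
            raise ValueError("first interval must start at 0")
        if not np.isinf(highs[-1]):
            raise ValueError("last interval must be unbounded above")
        for i in range(1, len(self.entries)):
            if lows[i] != highs[i - 1]:
                raise ValueError("intervals must be contiguous and non-overlapping")
        if any(h <= l for l, h in zip(lows, highs)):
            raise ValueError("empty interval in ramp")

    @property
    def lows(self) -> np.ndarray:
        return np.array([e[0] for e in self.entries])

    @property
    def names(self) -> list[str]:
        return [e[2] for e in self.entries]

    def assign(self, mu: float | np.ndarray) -> np.ndarray | str:
        """Material name(s) for attenuation value(s); lower bound inclusive."""
        arr = np.asarray(mu, dtype=float)
        if np.any(arr < 0):
            raise ValueError("negative attenuation coefficient")
        idx = np.searchsorted(self.lows[1:], arr, side="right")
        names = np.array(self.names)
        out = names[idx]
        return out if arr.ndim else str(out)

    def assign_index(self, mu: np.ndarray) -> np.ndarray:
        arr = np.asarray(mu, dtype=float)
        if np.any(arr < 0):
            raise ValueError("negative attenuation coefficient")
        return np.searchsorted(self.lows[1:], arr, side="right").astype(np.int8)


def load_ramp(path: str | Path) -> MaterialRamp:
    """Read a ramp CSV (mu_low, mu_high, material, mu_mat, rho_mat) and
    validate the partition property."""
    df = pd.read_csv(path)
    entries = tuple(
        (float(r.mu_low), float(r.mu_high), str(r.material)) for r in df.itertuples()
    )
    nominals = None
    if "mu_mat" in df.columns and "rho_mat" in df.columns:
        nominals = tuple(
            (float(r.mu_mat), float(r.rho_mat)) for r in df.itertuples()
        )
    return MaterialRamp(entries, nominals)


_DEFAULT_RAMP: MaterialRamp | None = None


def default_ramp() -> MaterialRamp:
    global _DEFAULT_RAMP
    if _DEFAULT_RAMP is None:
        _DEFAULT_RAMP = load_ramp(_data_path("catphan_ramp.csv"))
    return _DEFAULT_RAMP


def make_ramp(names: Sequence[str], energy_kev: float,
              catalog: MaterialCatalog | None = None) -> MaterialRamp:
    """Build an attenuation ramp for a specific scan energy.

    A ramp is defined per scanned object: nominal attenuations are taken
    from the catalogue at ``energy_kev`` and interval boundaries placed at
    arithmetic midpoints between consecutive nominal values (vacuum, when
    present, keeps its conventional 2.5e-4 threshold).
    """
    catalog = catalog or load_default_catalog()
    mats = sorted((catalog[n] for n in names),
                  key=lambda m: material_mu(m, energy_kev))
    mus = [material_mu(m, energy_kev) for m in mats]
    entries = []
    low = 0.0
    for i, m in enumerate(mats):
        if i + 1 < len(mats):
            if m.name == "Vacuum":
                high = min(2.5e-4, 0.5 * (mus[i] + mus[i + 1]))
            else:
                high = 0.5 * (mus[i] + mus[i + 1])
        else:
            high = np.inf
        entries.append((low, high, m.name))
        low = high
    nominals = tuple((material_mu(m, energy_kev), m.rho_nominal) for m in mats)
    return MaterialRamp(tuple(entries), nominals)


def assign_material(mu: float, ramp: MaterialRamp | None = None,
                    catalog: MaterialCatalog | None = None) -> Material:
    """Return the unique catalogued material whose ramp interval contains
    ``mu`` (intervals are half-open, lower bound inclusive)."""
    if mu < 0:
        raise ValueError("negative attenuation coefficient")
    ramp = ramp or default_ramp()
    catalog = catalog or load_default_catalog()
    return catalog[str(ramp.assign(mu))]


def mu_to_density(mu: float, material: Material) -> float:
    """Fractional density: mu / mu_nominal * rho_nominal; vacuum maps to 0."""
    if mu < 0:
        raise ValueError("negative attenuation coefficient")
    if material.mu_nominal == 0.0:
        return 0.0
    return mu / material.mu_nominal * material.rho_nominal


def material_mu(material: Material, energy_kev: float) -> float:
    """Linear attenuation (1/cm) at nominal density for a given energy."""
    return float(material.mass_atten(energy_kev)) * material.rho_nominal


@dataclass
class VoxelPhantom:
    """Voxelized object: material indices plus per-voxel mass density.

    Arrays are indexed ``[ix, iy, iz]``; ``voxel_size`` is (dx, dy, dz)
    in cm and ``origin`` the position of the grid corner (low edge of
    voxel ``[0, 0, 0]``) in cm.
    """

    material_index: np.ndarray
    density: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]
    material_names: list[str]

    def __post_init__(self) -> None:
        if self.material_index.shape != self.density.shape:
            raise ValueError("material and density grids differ in shape")
        if np.any(self.density < 0):
            raise ValueError("negative density")
        if self.material_index.min() < 0 or self.material_index.max() >= len(
            self.material_names
        ):
            raise ValueError("material index out of range")
        self.material_index = np.ascontiguousarray(self.material_index, dtype=np.int8)
        self.density = np.ascontiguousarray(self.density, dtype=np.float32)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.material_index.shape

    def voxel_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size[axis]

    def mu_volume(self, energy_kev: float,
                  catalog: MaterialCatalog | None = None) -> np.ndarray:
        """Linear attenuation map (1/cm) at the given energy."""
        catalog = catalog or load_default_catalog()
        matt = np.array(
            [float(catalog[n].mass_atten(energy_kev)) for n in self.material_names],
            dtype=np.float32,
        )
        return matt[self.material_index] * self.density


def volume_from_mu(mu_volume: np.ndarray, ramp: MaterialRamp | None = None,
                   catalog: MaterialCatalog | None = None,
                   voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1),
                   origin: tuple[float, float, float] | None = None) -> VoxelPhantom:
    """Convert a reconstructed attenuation volume to a material/density
    phantom via ramp assignment and fractional density conversion.

    Small negative voxels (reconstruction noise) are clamped to zero with
    a logged count; non-finite voxels raise.
    """
    mu = np.asarray(mu_volume, dtype=np.float64)
    if not np.all(np.isfinite(mu)):
        bad = np.argwhere(~np.isfinite(mu))
        raise ValueError(f"non-finite attenuation at {len(bad)} voxels, first {bad[:5].tolist()}")
    n_neg = int(np.count_nonzero(mu < 0))
    if n_neg:
        logger.info("clamping %d negative attenuation voxels to 0", n_neg)
        mu = np.maximum(mu, 0.0)
    ramp = ramp or default_ramp()
    catalog = catalog or load_default_catalog()
    names = ramp.names
    idx = ramp.assign_index(mu)
    if ramp.nominals is not None:
        mu_mat = np.array([n[0] for n in ramp.nominals])
        rho_mat = np.array([n[1] for n in ramp.nominals])
    else:
        mu_mat = np.array([catalog[n].mu_nominal for n in names])
        rho_mat = np.array([catalog[n].rho_nominal for n in names])
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(mu_mat > 0, rho_mat / np.where(mu_mat > 0, mu_mat, 1.0), 0.0)
    density = mu * scale[idx]
    if origin is None:
        origin = tuple(-0.5 * n * d for n, d in zip(mu.shape, voxel_size))
    return VoxelPhantom(idx, density.astype(np.float32), voxel_size, origin, names)


def _cylinder_mask(shape, voxel_size, origin, radius, half_length, axis=2):
    xs = origin[0] + (np.arange(shape[0]) + 0.5) * voxel_size[0]
    ys = origin[1] + (np.arange(shape[1]) + 0.5) * voxel_size[1]
    zs = origin[2] + (np.arange(shape[2]) + 0.5) * voxel_size[2]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    return (X**2 + Y**2 <= radius**2) & (np.abs(Z) <= half_length)


def make_water_air_phantom(
    diameter: float = 20.0,
    length: float = 20.0,
    cavity_diameter: float = 2.0,
    cavity_length: float = 10.0,
    voxel_size: float | tuple[float, float, float] = 0.2,
    shape: tuple[int, int, int] | None = None,
) -> VoxelPhantom:
    """Water cylinder with a coaxial central air cavity, vacuum outside.

    The cylinder axis is the rotation (z) axis and the phantom is centred
    on the isocenter.
    """
    if cavity_diameter > diameter or cavity_length > length:
        raise ValueError("cavity does not fit inside the cylinder")
    if np.isscalar(voxel_size):
        voxel_size = (float(voxel_size),) * 3
    if any(v <= 0 for v in voxel_size):
        raise ValueError("voxel_size must be positive")
    if shape is None:
        margin = 1.1
        shape = tuple(
            int(np.ceil(margin * ext / v))
            for ext, v in zip((diameter, diameter, length), voxel_size)
        )
    origin = tuple(-0.5 * n * v for n, v in zip(shape, voxel_size))
    catalog = load_default_catalog()
    names = catalog.names
    idx = np.zeros(shape, dtype=np.int8)  # vacuum
    rho = np.zeros(shape, dtype=np.float32)
    water = _cylinder_mask(shape, voxel_size, origin, diameter / 2, length / 2)
    idx[water] = names.index("Water")
    rho[water] = catalog["Water"].rho_nominal
    if cavity_diameter > 0 and cavity_length > 0:
        cav = _cylinder_mask(shape, voxel_size, origin, cavity_diameter / 2,
                             cavity_length / 2)
        idx[cav] = names.index("Air")
        rho[cav] = catalog["Air"].rho_nominal
    return VoxelPhantom(idx, rho, voxel_size, origin, names)


# insert materials of a Catphan-style sensitometry section (background is
# water-equivalent; two air inserts)
CATPHAN_INSERTS = ["Air", "Air", "PMP", "LDPE", "Polystyrene", "Acrylic",
                   "Delrin", "Teflon"]


def make_catphan_like_phantom(
    diameter: float = 20.0,
    length: float = 4.0,
    insert_diameter: float = 1.2,
    insert_ring_radius: float = 6.0,
    voxel_size: float | tuple[float, float, float] = 0.2,
    shape: tuple[int, int, int] | None = None,
) -> VoxelPhantom:
    """Water-equivalent cylinder with eight sensitometry inserts arranged
    on a ring, mimicking a Catphan sensitometry module."""
    if np.isscalar(voxel_size):
        voxel_size = (float(voxel_size),) * 3
    phantom = make_water_air_phantom(
        diameter, length, 0.0, 0.0, voxel_size, shape
    )
    catalog = load_default_catalog()
    names = phantom.material_names
    xs = phantom.voxel_centers(0)
    ys = phantom.voxel_centers(1)
    zs = phantom.voxel_centers(2)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    inside_z = np.abs(Z) <= length / 2
    for k, mat in enumerate(CATPHAN_INSERTS):
        ang = 2 * np.pi * k / len(CATPHAN_INSERTS)
        cx, cy = insert_ring_radius * np.cos(ang), insert_ring_radius * np.sin(ang)
        m = ((X - cx) ** 2 + (Y - cy) ** 2 <= (insert_diameter / 2) ** 2) & inside_z
        phantom.material_index[m] = names.index(mat)
        phantom.density[m] = catalog[mat].rho_nominal
    return phantom
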