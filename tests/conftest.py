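import numpy as np
import pytest

from cbctmc.geometry import ConeBeamGeometry, arc_angles
from cbctmc.materials import load_default_catalog, make_water_air_phantom
from cbctmc.recon import LogProjection
from cbctmc.transport import Spectrum


@pytest.fixture(scope="session")
def catalog():
    return load_default_catalog()


@pytest.fixture(scope="session")
def mono60():
    return Spectrum.monoenergetic(60.0)


@pytest.fixture(scope="session")
def small_geometry():
    """Coarse full-circle scan used by the MC unit tests."""
    return ConeBeamGeometry(100.0, 149.88, (39.7, 29.8), (32, 24), 0, 360, 90)


@pytest.fixture(scope="session")
def water_cylinder_64():
    """20 cm water cylinder (no cavity) on a 64-cube grid."""
    return make_water_air_phantom(20, 20, 0, 0, voxel_size=22 / 64,
                                  shape=(64, 64, 64))


@pytest.fixture(scope="session")
def water_air_64():
    """20 cm water cylinder with the 2 x 10 cm air cavity, 64-cube grid."""
    return make_water_air_phantom(20, 20, 2, 10, voxel_size=22 / 64,
                                  shape=(64, 64, 64))


def analytic_cylinder_logs(geometry: ConeBeamGeometry, mu: float,
                           radius: float) -> list[LogProjection]:
    """Noiseless log projections of an infinite uniform cylinder about the
    rotation axis: closed-form chord lengths, independent of the FDK code."""
    nu, nv = geometry.det_pixels
    pu, pv = geometry.pixel_pitch
    out = []
    for a in arc_angles(geometry):
        b = np.deg2rad(a)
        src = geometry.source_position(a)
        center, e_u, e_v = geometry.detector_frame(a)
        u = (np.arange(nu) + 0.5) * pu - geometry.det_size[0] / 2
        v = (np.arange(nv) + 0.5) * pv - geometry.det_size[1] / 2
        U, V = np.meshgrid(u, v)
        tgt = center[None, None, :] + U[..., None] * e_u + V[..., None] * e_v
        d = tgt - src
        dn = d / np.linalg.norm(d, axis=-1, keepdims=True)
        p2 = src[:2]
        d2 = dn[..., :2]
        a2 = (d2 ** 2).sum(-1)
        b2 = 2 * (p2 * d2).sum(-1)
        c2 = (p2 ** 2).sum() - radius ** 2
        disc = b2 * b2 - 4 * a2 * c2
        chord = np.where(disc > 0, np.sqrt(np.maximum(disc, 0)) / a2, 0.0)
        out.append(LogProjection(mu * chord, a, "raw"))
    return out
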