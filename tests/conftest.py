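import numpy as np
import pytest

from culmforce import presets
from culmforce.geometry import FibreSet, build_cylindrical_grid, extract_bundle_centerlines
from culmforce.synthetic_data import (
    ComponentLibrary,
    FibreCenterline,
    StemParams,
    generate_stem_geometry,
    rasterize_label_volume,
)


@pytest.fixture(scope="session")
def resistant_params() -> StemParams:
    return presets.stem_params("rye_resistant", seed=1)


@pytest.fixture(scope="session")
def resistant_geometry(resistant_params):
    return generate_stem_geometry(resistant_params)


@pytest.fixture(scope="session")
def resistant_volume(resistant_geometry):
    return rasterize_label_volume(resistant_geometry, presets.volume_spec("rye_resistant"))


@pytest.fixture(scope="session")
def resistant_fibres(resistant_volume):
    return extract_bundle_centerlines(resistant_volume)


@pytest.fixture(scope="session")
def default_grid(resistant_geometry):
    return build_cylindrical_grid(resistant_geometry)


@pytest.fixture(scope="session")
def component_library() -> ComponentLibrary:
    return ComponentLibrary.default()


@pytest.fixture
def no_bundle_params() -> StemParams:
    return StemParams(
        outer_radius=1.8, inner_radius=1.3, length=20.0,
        n_outer_bundles=0, n_inner_bundles=0,
        ring_radius_outer=1.65, ring_radius_inner=1.42, bundle_radius=0.07,
    )


def straight_fibre(incline_deg: float, phi_deg: float, x0=1.5, y0=0.0,
                   length=15.0, z_step=1.0) -> FibreCenterline:
    """Straight inclined centerline: drift dz/tan(incline) along azimuth phi."""
    z = np.arange(0.0, length + z_step / 2, z_step)
    drift = 0.0 if incline_deg >= 90 else 1.0 / np.tan(np.deg2rad(incline_deg))
    p = np.deg2rad(phi_deg)
    pts = np.column_stack([x0 + drift * np.cos(p) * z, y0 + drift * np.sin(p) * z, z])
    return FibreCenterline(pts, phi_deg, incline_deg)


@pytest.fixture
def single_fibre_set():
    def make(incline_deg, phi_deg, **kwargs) -> FibreSet:
        return FibreSet([straight_fibre(incline_deg, phi_deg, **kwargs)], ["outer"])
    return make
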