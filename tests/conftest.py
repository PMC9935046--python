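import numpy as np
import pytest

import vtexit as vx
from vtexit.library import BeatLibrary, LibraryConfig, build_pacing_library, build_vt_library, make_cohort


@pytest.fixture(scope="session")
def mesh_default():
    """Default-resolution (3 mm) ventricle with fibers."""
    return vx.build_ventricle_mesh(vx.GeometryParams())


@pytest.fixture(scope="session")
def uvc_default(mesh_default):
    return vx.compute_uvc(mesh_default)


@pytest.fixture(scope="session")
def mesh_coarse():
    """Coarse (4.5 mm) ventricle used by the heavier simulation tests."""
    return vx.build_ventricle_mesh(vx.GeometryParams(target_edge_length=4.5))


@pytest.fixture(scope="session")
def uvc_coarse(mesh_coarse):
    return vx.compute_uvc(mesh_coarse)


@pytest.fixture(scope="session")
def conduction():
    return vx.ConductionModel()


@pytest.fixture(scope="session")
def tiny_library_config():
    """2 small anatomies, 25 paced + 16 VT beats each."""
    return LibraryConfig(
        n_paced_per_anatomy=25,
        n_vt_per_anatomy=16,
        n_anatomies=2,
        global_seed=11,
        anatomies=tuple(
            vx.perturb_geometry_params(vx.GeometryParams(target_edge_length=4.5), 2, seed=5)
        ),
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_library_config):
    return make_cohort(tiny_library_config)


@pytest.fixture(scope="session")
def tiny_paced_library(tiny_library_config, tiny_cohort, tmp_path_factory) -> BeatLibrary:
    out = tmp_path_factory.mktemp("lib") / "paced"
    return build_pacing_library(tiny_library_config, out, cohort=tiny_cohort)


@pytest.fixture(scope="session")
def tiny_vt_library(tiny_library_config, tiny_cohort, tmp_path_factory) -> BeatLibrary:
    out = tmp_path_factory.mktemp("lib") / "vt"
    return build_vt_library(tiny_library_config, out, cohort=tiny_cohort)
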