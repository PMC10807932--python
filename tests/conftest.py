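import numpy as np
import pytest

import corochar as cc


@pytest.fixture(scope="session")
def straight_phantom():
    """60 mm straight vessel, radius 2 mm, 0.4 mm isotropic grid."""
    spec = cc.PhantomSpec(
        vessels=[cc.VesselSpec(kind="straight", length_mm=60.0,
                               radius_start_mm=2.0, radius_end_mm=2.0)],
        seed=1,
    )
    return cc.generate_phantom(spec)


@pytest.fixture(scope="session")
def straight_tree(straight_phantom):
    _, coronary, aorta, _ = straight_phantom
    return cc.build_tree(coronary, aorta)


@pytest.fixture(scope="session")
def branched_phantom():
    """Main vessel with two daughter branches (three leaf tips)."""
    main = cc.VesselSpec(kind="straight", length_mm=60.0,
                         radius_start_mm=2.5, radius_end_mm=2.0)
    d1 = cc.VesselSpec(kind="straight", length_mm=35.0, radius_start_mm=2.0,
                       radius_end_mm=1.6, start=(20.0, 0.0, 0.0),
                       direction=(0.8, 0.6, 0.0))
    d2 = cc.VesselSpec(kind="straight", length_mm=28.0, radius_start_mm=1.8,
                       radius_end_mm=1.5, start=(40.0, 0.0, 0.0),
                       direction=(0.8, -0.5, 0.3))
    spec = cc.PhantomSpec(vessels=[main, d1, d2], seed=33)
    return cc.generate_phantom(spec)


@pytest.fixture(scope="session")
def lesion_phantom():
    """Two-vessel tree with one 2.5 x 2 x 2 mm lesion at abscissa 25 mm."""
    v1 = cc.VesselSpec(kind="straight", length_mm=70.0,
                       radius_start_mm=3.0, radius_end_mm=2.0)
    v2 = cc.VesselSpec(kind="straight", length_mm=50.0, radius_start_mm=2.5,
                       radius_end_mm=1.8, start=(20.0, 0.0, 0.0),
                       direction=(0.8, 0.6, 0.0))
    les = cc.LesionSpec(center_abscissa_mm=25.0, axis_lengths_mm=(2.5, 2.0, 2.0))
    spec = cc.PhantomSpec(vessels=[v1, v2], lesions=[les], seed=7)
    return cc.generate_phantom(spec)


@pytest.fixture(scope="session")
def lesion_tree(lesion_phantom):
    _, coronary, aorta, _ = lesion_phantom
    return cc.build_tree(coronary, aorta)
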