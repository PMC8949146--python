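import numpy as np
import pytest

from memdrug import (
    BindingPairSpec,
    Frame,
    SiteRef,
    SyntheticConfig,
    SystemMap,
    Trajectory,
    build_system,
)


@pytest.fixture(scope="session")
def default_system():
    """Full-composition system (100 lipid+chol per leaflet), built once."""
    system, frame0 = build_system(SyntheticConfig(seed=7))
    return system, frame0


@pytest.fixture()
def small_config():
    return SyntheticConfig(
        seed=11,
        n_lipid_per_leaflet=16,
        box=(40.0, 40.0, 95.7),
        dt=0.1,
        n_frames=101,
    )


@pytest.fixture()
def tiny_bilayer():
    """Hand-built 2-lipid bilayer plus one drug molecule, for exact checks."""
    atoms = [
        SiteRef(0, "DOPC", "P"),
        SiteRef(0, "DOPC", "O13"),
        SiteRef(1, "DOPC", "P"),
        SiteRef(1, "DOPC", "O13"),
        SiteRef(2, "DBD1", "H2"),
        SiteRef(2, "DBD1", "H4"),
    ]
    system = SystemMap(atoms=atoms, leaflet={0: "upper", 1: "lower"})
    pos = np.array(
        [
            [5.0, 5.0, 21.5],
            [5.0, 6.0, 20.5],
            [5.0, 5.0, -21.5],
            [5.0, 6.0, -20.5],
            [8.0, 8.0, 23.0],
            [9.8, 8.0, 23.0],
        ]
    )
    frame = Frame(time=0.0, positions=pos, box=(20.0, 20.0, 60.0))
    return system, frame


def constant_trajectory(system, frame, n_frames=3, dt=0.1):
    frames = [
        Frame(time=i * dt, positions=frame.positions.copy(), box=frame.box.copy())
        for i in range(n_frames)
    ]
    return Trajectory(system=system, frames=frames, dt=dt)
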