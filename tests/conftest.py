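import numpy as np
import pytest

from embotrace import hemodynamics as hemo
from embotrace import transport as tp
from embotrace import vasculature as vas


@pytest.fixture(scope="session")
def fluid():
    return hemo.FluidProperties()


@pytest.fixture(scope="session")
def waveform():
    return hemo.CardiacWaveform()


@pytest.fixture(scope="session")
def baseline():
    return vas.build_baseline_network()


@pytest.fixture(scope="session")
def tuned_resistances(baseline, waveform, fluid):
    targets = hemo.target_flow_splits(baseline)
    return hemo.tune_outlet_resistances(baseline, targets, waveform, fluid)


@pytest.fixture(scope="session")
def baseline_solution(baseline, waveform, tuned_resistances, fluid):
    return hemo.solve_unsteady(baseline, waveform, tuned_resistances, fluid)


@pytest.fixture(scope="session")
def baseline_field(baseline_solution, baseline, fluid):
    return hemo.segment_velocity_field(baseline_solution, baseline, fluid)


def straight_tube_network(radius=3.0, length=100.0, n=51):
    """A single straight vessel from inlet to one outlet."""
    pts = np.column_stack(
        [np.zeros(n), np.zeros(n), np.linspace(0.0, length, n)]
    )
    seg = vas.SegmentGeometry(
        id="tube", name="tube", points=pts, radii=np.full(n, radius),
        proximal_node="inlet", distal_node="out",
    )
    return vas.NetworkTopology(
        segments={"tube": seg}, inlet="inlet",
        outlets={"tube_out": "out"}, hemisphere_map={"tube_out": "none"},
    )


def y_network(radius=3.0):
    """Inlet trunk splitting into two identical straight branches."""
    n = 31

    def seg(sid, p0, p1, prox, dist):
        pts = np.linspace(p0, p1, n)
        return vas.SegmentGeometry(
            id=sid, name=sid, points=pts, radii=np.full(n, radius),
            proximal_node=prox, distal_node=dist,
        )

    trunk = seg("trunk", np.array([0.0, 0, 0]), np.array([0.0, 0, 60]),
                "inlet", "bif")
    left = seg("left", np.array([0.0, 0, 60]), np.array([40.0, 0, 120]),
               "bif", "out_l")
    right = seg("right", np.array([0.0, 0, 60]), np.array([-40.0, 0, 120]),
                "bif", "out_r")
    return vas.NetworkTopology(
        segments={"trunk": trunk, "left": left, "right": right},
        inlet="inlet",
        outlets={"left_out": "out_l", "right_out": "out_r"},
        hemisphere_map={"left_out": "none", "right_out": "none"},
    )


@pytest.fixture()
def tube_network():
    return straight_tube_network()


@pytest.fixture()
def tube_field(tube_network, fluid):
    wave = hemo.CardiacWaveform(mean_flow=10.0, shape=lambda ph: np.ones_like(ph))
    res = hemo.OutletResistanceSet(resistances={"tube_out": 1.0})
    sol = hemo.solve_unsteady(tube_network, wave, res, fluid)
    return hemo.segment_velocity_field(sol, tube_network, fluid)
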