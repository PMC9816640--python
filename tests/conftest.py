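import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from spindlemorph import graph_io, synthetic_spindle as ss

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def control_spindle():
    """A control-like synthetic spindle with observations, shared read-only."""
    cfg = ss.scenario_presets()["control-like"]
    recon, truth = ss.generate_spindle(cfg)
    obs = ss.generate_observations(recon, truth, cfg)
    return recon, truth, obs


@pytest.fixture()
def tiny_recon():
    """A minimal hand-built reconstruction: one KMT, one non-KMT, two poles."""
    kmt = graph_io.MicrotubuleTrack(
        "t1",
        "KMT",
        "f1",
        np.array([[0.0, 0.0, 0.0], [1000.0, 0.0, 0.0], [2000.0, 0.0, 0.0]]),
        end_a=graph_io.EndAnnotation(True, {"o1": "open"}),
        end_b=graph_io.EndAnnotation(False, {"o1": "closed", "o2": "open"}),
    )
    non = graph_io.MicrotubuleTrack(
        "t2",
        "non-KMT",
        None,
        np.array([[-4000.0, 500.0, 0.0], [0.0, 1000.0, 0.0]]),
        end_a=graph_io.EndAnnotation(False, {"o1": "undefined"}),
    )
    poles = [
        graph_io.Pole("P1", np.array([-5000.0, 0.0, 0.0]), np.array([-5200.0, 100.0, 0.0])),
        graph_io.Pole("P2", np.array([5000.0, 0.0, 0.0]), np.array([5200.0, -100.0, 0.0])),
    ]
    kin = graph_io.Kinetochore("k1", None, ["t1"])
    return graph_io.SpindleReconstruction(
        condition="control",
        cell_id="cell0",
        tracks=[kmt, non],
        poles=poles,
        kinetochores=[kin],
        observers=["o1", "o2"],
    )


def make_obs_frame(d, morphology, observer="o1", mt_class="KMT", fiber="f1", condition="c"):
    """Tidy observation records from parallel sequences."""
    d = np.atleast_1d(d)
    morphology = np.atleast_1d(morphology)
    k = max(len(d), len(morphology))
    return pd.DataFrame(
        {
            "track_id": [f"t{i}" for i in range(k)],
            "mt_class": mt_class,
            "fiber_id": fiber,
            "condition": condition,
            "observer_id": observer,
            "D": np.resize(d, k),
            "morphology": np.resize(morphology, k),
        }
    )
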