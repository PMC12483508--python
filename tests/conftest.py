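import numpy as np
import pytest

import popcode as pc
from popcode.protocols import Presentation, StimulusProtocol


@pytest.fixture(scope="session")
def gratings_session():
    """Small control gratings session shared across tests (30 neurons)."""
    return pc.simulate_session(pc.SimulationConfig.control(30, seed=3), "gratings")


@pytest.fixture(scope="session")
def gratings_dff(gratings_session):
    return pc.compute_dff(gratings_session.recording)


@pytest.fixture(scope="session")
def movie_session():
    return pc.simulate_session(pc.SimulationConfig.control(20, seed=5), "movies")


def short_gratings_protocol(n_trials: int, frame_rate_hz: float = 16.0) -> StimulusProtocol:
    """A gratings protocol with fewer trial repetitions, for fast calibration."""
    on = int(round(2 * frame_rate_hz))
    off = int(round(3 * frame_rate_hz))
    pres, t = [], 0
    for _ in range(n_trials):
        for d in range(8):
            t += off
            pres.append(Presentation(d, t, on))
            t += on
    return StimulusProtocol("gratings", pres, n_trials, 8, frame_rate_hz, t)


@pytest.fixture(scope="session")
def small_design():
    """Design matrix + shared CV folds on a 4-trial gratings session."""
    from popcode.encoding import _LassoCV, contiguous_folds

    proto = short_gratings_protocol(4)
    behavior = pc.simulate_behavior(proto.total_frames, seed=3)
    design = pc.build_design_matrix(proto, behavior)
    cv = _LassoCV(design.X, contiguous_folds(proto.total_frames, 10), 1e-3)
    return proto, design, cv
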