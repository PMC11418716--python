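import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import stairreach as sr

settings.register_profile("stable", deadline=None, derandomize=True)
settings.load_profile("stable")


@pytest.fixture(scope="session")
def chamber():
    return sr.default_config()


@pytest.fixture(scope="session")
def right_layout(chamber):
    return chamber.layout("right")


@pytest.fixture(scope="session")
def default_session():
    """One default synthetic session plus its pipeline result."""
    spec = sr.default_session_spec(11)
    table, truth = sr.generate_session(spec)
    result = sr.run_session(table, sr.default_config())
    return spec, table, truth, result


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_clean(x, y, fps=100.0, likelihood=None, landmark="paw_right"):
    """Wrap bare coordinate arrays into a CleanTrajectory (no cleaning)."""
    n = len(x)
    lik = np.full((n, 1), 0.99) if likelihood is None else likelihood[:, None]
    table = sr.TrajectoryTable(
        landmarks=[landmark],
        x=np.asarray(x, float)[:, None],
        y=np.asarray(y, float)[:, None],
        likelihood=lik,
        fps=fps,
    )
    return sr.CleanTrajectory(
        table=table,
        usable=table.valid.copy(),
        jump_rejected=np.zeros_like(table.valid),
        gap_filled=np.zeros_like(table.valid),
    )
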