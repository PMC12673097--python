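import numpy as np
import pandas as pd
import pytest

import sitpheno as sp


def make_track(
    center_xy: np.ndarray,
    nose_xy: np.ndarray | None = None,
    likelihood: np.ndarray | None = None,
    fps: float = 30.0,
    session: str = "S1",
    animal_id: str = "a1",
) -> sp.KeypointTrack:
    """Build a two-bodypart track directly from coordinate arrays."""
    center_xy = np.asarray(center_xy, dtype=float)
    n = len(center_xy)
    if nose_xy is None:
        nose_xy = center_xy
    nose_xy = np.asarray(nose_xy, dtype=float)
    lik = np.ones(n) if likelihood is None else np.asarray(likelihood, dtype=float)
    data = pd.concat(
        {
            "nose": pd.DataFrame(
                {"x": nose_xy[:, 0], "y": nose_xy[:, 1], "likelihood": lik}
            ),
            "center": pd.DataFrame(
                {"x": center_xy[:, 0], "y": center_xy[:, 1], "likelihood": lik}
            ),
        },
        axis=1,
    )
    data.columns.names = ["bodyparts", "coords"]
    return sp.KeypointTrack(
        animal_id=animal_id,
        session=session,
        fps=fps,
        data=data,
        bodypart_map={"nose": "nose", "center": "center"},
    )


@pytest.fixture(scope="session")
def arena() -> sp.ArenaSpec:
    """Square 42 cm arena imaged at 10 px/cm with the cage on the top wall."""
    return sp.default_arena()


@pytest.fixture(scope="session")
def small_cohort(arena):
    """A 4+4+4 cohort at full session length, shared across tests."""
    design = sp.CohortDesign(
        n_control=4, n_resilient_like=4, n_susceptible_like=4, seed=11, arena=arena
    )
    return design, sp.simulate_cohort(design)
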