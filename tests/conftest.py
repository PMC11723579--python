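import warnings

import numpy as np
import pytest

from mdesmap.design import assign_orders, build_probe_orders
from mdesmap.simulate import StudyConfig, generate_study

PAPER_DESIGN = dict(n_orders=16, n_probes=5, clip_len_s=660, first_probe_s=75,
                    grid_s=15, window_s=120)


@pytest.fixture(scope="session")
def paper_schedules():
    return build_probe_orders(**PAPER_DESIGN, seed=42)


@pytest.fixture(scope="session")
def paper_assignments(paper_schedules):
    movies = {m: paper_schedules for m in ("m1", "m2", "m3")}
    pids = [f"p{i + 1:03d}" for i in range(120)]
    return assign_orders(pids, movies, seed=7)


@pytest.fixture(scope="session")
def small_study():
    """Reduced-size synthetic study used by pipeline-level tests."""
    cfg = StudyConfig(seed=314, n_participants_mdes=48, n_subjects_fmri=8,
                      n_parcels=60)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_study(cfg)


@pytest.fixture(autouse=True)
def _quiet_model_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
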