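import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fieldstring as fs
from fieldstring.pmf import integrate_mean_force
from fieldstring.string_fts import FTSConfig, run_fts

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

E_MAX = 41.14e8


@pytest.fixture(scope="session")
def default_landscape():
    return fs.build_default_landscape()


@pytest.fixture(scope="session")
def fts_runs(default_landscape):
    """Full default-config FTS runs (no field) for seeds 1-3.

    Seed 1 keeps the final window samples (with trajectories) for the WHAM
    cross-check.  Each entry: (FTSResult, PMFProfile).
    """
    out = {}
    for seed in (1, 2, 3):
        res = run_fts(default_landscape, None, FTSConfig(), seed,
                      keep_final_samples=(seed == 1))
        prof = integrate_mean_force(res.string, res.mean_forces)
        out[seed] = (res, prof)
    return out


@pytest.fixture(scope="session")
def fts_runs_field(default_landscape):
    """Same pipeline at the maximum +x field strength."""
    field = fs.FieldSpec("x", 1, E_MAX)
    out = {}
    for seed in (1, 2, 3):
        res = run_fts(default_landscape, field, FTSConfig(), seed)
        prof = integrate_mean_force(res.string, res.mean_forces)
        out[seed] = (res, prof)
    return out
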