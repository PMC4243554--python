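import numpy as np
import pytest

from fabas.core import BeatIntervalSeries
from fabas.simulate import GeneratorConfig, generate_recording


def series_from_nn(nn, valid=None, t0=0.0, **meta) -> BeatIntervalSeries:
    """Build a series from interval values (ms); onset times follow from the
    intervals themselves, so timing consistency holds by construction."""
    nn = np.asarray(nn, dtype=float)
    times = t0 + np.concatenate([[0.0], np.cumsum(nn[:-1]) / 1000.0])
    return BeatIntervalSeries(
        beat_times=times,
        nn_intervals=nn,
        valid=np.ones(len(nn), dtype=bool) if valid is None else np.asarray(valid, bool),
        **meta,
    )


@pytest.fixture(scope="session")
def default_recording():
    """One 30-min synthetic recording at 30 weeks (quiet then active)."""
    return generate_recording(GeneratorConfig(wga=30.0, seed=11))


@pytest.fixture(scope="session")
def quiet_recording():
    """A 30-min recording that is quiet sleep throughout, artifact-free."""
    cfg = GeneratorConfig(
        wga=32.0, seed=13, schedule=(("quiet", 1800.0),), artifact_fraction=0.0
    )
    return generate_recording(cfg)
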