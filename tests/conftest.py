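import numpy as np
import pytest

from meadev.spike_io import Recording, SpikeTrain, default_positions


def train(times, t_start=0.0, t_stop=900.0):
    return SpikeTrain(np.asarray(times, dtype=float), t_start=t_start, t_stop=t_stop)


@pytest.fixture
def make_recording():
    """Factory building a Recording from a list of spike-time arrays."""

    def _make(list_of_times, t_stop=900.0, region="CTX", age_div=14, array_id="test"):
        trains = [train(t, 0.0, t_stop) for t in list_of_times]
        n = len(trains)
        return Recording(
            trains=trains,
            positions=default_positions(n),
            labels=[f"E{i + 1:02d}" for i in range(n)],
            region=region,
            age_div=age_div,
            array_id=array_id,
        )

    return _make


@pytest.fixture
def poisson_train():
    """Factory for homogeneous Poisson trains (sorted, deduplicated)."""

    def _make(rate_hz, duration, seed, t_start=0.0):
        rng = np.random.default_rng(seed)
        n = rng.poisson(rate_hz * duration)
        times = np.unique(rng.uniform(t_start, t_start + duration, n))
        return SpikeTrain(times, t_start=t_start, t_stop=t_start + duration)

    return _make
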