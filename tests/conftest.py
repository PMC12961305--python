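import numpy as np
import pytest

import jierp


@pytest.fixture(scope="session")
def template():
    return jierp.erp_template()


@pytest.fixture(scope="session")
def loguniform_train():
    """A typical stimulation train: 400 events, log-uniform ISIs, seeded."""
    return jierp.generate_train(400, seed=11)


@pytest.fixture(scope="session")
def noiseless_recording(loguniform_train, template):
    return jierp.synthesize_recording(
        loguniform_train, template=template, spec="none", noise_sd=0.0, seed=3
    )


@pytest.fixture()
def epochs_noiseless(noiseless_recording):
    ep = jierp.epoch_events(noiseless_recording)
    return jierp.reject_amplitude(ep)


def make_zjierp(z, valid=None, time_ms=None, source="individual"):
    """Assemble a ZJierp from a raw (b, b, T) z array for statistics tests."""
    z = np.asarray(z, dtype=float)
    if valid is None:
        valid = ~np.isnan(z[..., 0])
    if time_ms is None:
        time_ms = np.arange(1, z.shape[-1] + 1)
    return jierp.ZJierp(
        z=z,
        valid=np.asarray(valid, dtype=bool),
        time_ms=np.asarray(time_ms),
        source=source,
        degenerate_latencies=np.zeros(z.shape[-1], dtype=bool),
    )
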