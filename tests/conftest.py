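import pytest

import gonadotrace as gt


@pytest.fixture(scope="session")
def protocol():
    return gt.make_protocol()


@pytest.fixture(scope="session")
def noise_free_control(protocol):
    """Noise-free, bleach-free control parameters (all cells gonadotrophs)."""
    return gt.default_group_params("control").with_(
        noise_sd=0.0, bleach_rate=0.0, frac_nonviable=0.0, frac_responder=1.0
    )


@pytest.fixture(scope="session")
def control_recording(protocol):
    """A realistic control recording with its ground truth (default noise)."""
    rec, truth = gt.synth_recording("control", 120, seed=11, protocol=protocol)
    return rec, truth


@pytest.fixture(scope="session")
def long_lasting_trace_140(protocol):
    """Noise-free, bleach-free long-lasting oscillatory trace with exactly
    140 ground-truth spikes, as dF/F (detrended + normalized)."""
    from gonadotrace.preprocess import detrend_bleach, normalize_dff

    trace, n_true = make_long_lasting_trace(protocol, n_spikes=140, seed=1)
    dff = normalize_dff(detrend_bleach(trace, protocol))
    return dff, n_true


def make_long_lasting_trace(protocol, n_spikes=140, seed=1, noise_sd=0.0):
    """Build one long-lasting oscillatory cell with a fixed spike count."""
    from gonadotrace.synth import long_lasting_fixture

    return long_lasting_fixture(n_spikes, seed=seed, protocol=protocol, noise_sd=noise_sd), n_spikes
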