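import numpy as np
import pytest

from imgdecouple.detector import fit
from imgdecouple.features import extract_features
from imgdecouple.signals import ChannelSignal, process_event
from imgdecouple.simulate import (
    ArtifactSpec,
    ImpactScenario,
    SimConfig,
    generate_dataset,
    inject_decoupling,
    simulate_coupled_event,
)

FS = 3200.0


@pytest.fixture
def quiet_cfg():
    """Acquisition config without sensor noise (analytic checks)."""
    return SimConfig(noise_sd_lin_g=0.0, noise_sd_gyro=0.0)


@pytest.fixture
def coupled_event(quiet_cfg):
    scenario = ImpactScenario(peak_lin_g=50.0, lin_duration_ms=10.0,
                              direction=(0.6, 0.3, 0.74))
    return simulate_coupled_event(scenario, quiet_cfg, seed=42)


@pytest.fixture
def decoupled_twin(coupled_event):
    """Same impact with a late artifact strong enough to survive the
    175/250 Hz acquisition filters and inflate the processed peak."""
    record, truth = coupled_event
    spec = ArtifactSpec(onset_ms=15.0, freq_hz=180.0, amplitude_ratio=3.0,
                        gyro_amplitude_ratio=0.4)
    return inject_decoupling(record, truth, spec, seed=43), truth


@pytest.fixture(scope="session")
def small_dataset():
    """60 noisy events, 25% decoupled — shared across detector tests."""
    return generate_dataset(60, 0.25, SimConfig(), seed=1234)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    fvs = [extract_features(process_event(ev.record),
                            event_id=ev.record.event_id)
           for ev in small_dataset]
    labels = [ev.record.label for ev in small_dataset]
    return fvs, labels


@pytest.fixture(scope="session")
def trained_model(small_features):
    fvs, labels = small_features
    return fit(fvs, labels, event_ids=[f.event_id for f in fvs])


def tone(freq_hz, n=161, fs=FS, trigger_index=32, amplitude=1.0):
    t = np.arange(n) / fs
    return ChannelSignal(amplitude * np.sin(2 * np.pi * freq_hz * t), fs,
                         trigger_index)
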