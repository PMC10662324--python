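import numpy as np
import pytest

from hrvcam.beats_hrv import beats_to_ibi, detrend_tachogram, resample_tachogram
from hrvcam.synth_ecg import (ModulationSignal, NoiseConfig, ScenarioConfig,
                              generate_modulation, ipfm_beats, make_cohort,
                              render_ecg)


def constant_modulation(duration_s: float, dt: float = 0.004) -> ModulationSignal:
    t = np.arange(0.0, duration_s + dt / 2, dt)
    return ModulationSignal(t=t, m=np.zeros_like(t))


@pytest.fixture(scope="session")
def clean_record_60bpm():
    """Noise-free 60-bpm ECG, 60 s, with exact beat annotations."""
    beats = ipfm_beats(constant_modulation(60.0), 1000.0)
    return render_ecg(beats, fs=250.0, noise=NoiseConfig.none(), seed=0,
                      duration=61.0)


@pytest.fixture(scope="session")
def modulated_tachogram():
    """4-Hz tachogram of a 300-s IPFM simulation with 0.25 Hz HF modulation."""
    cfg = ScenarioConfig(a_lf=0.0, a_hf=0.08, f_hf=0.25, noise_sigma=0.0)
    mod = generate_modulation(cfg, 300.0, "baseline", seed=11)
    beats = ipfm_beats(mod, 850.0)
    return detrend_tachogram(resample_tachogram(beats_to_ibi(beats)))


@pytest.fixture(scope="session")
def tiny_cohort():
    """One-subject rendered cohort (baseline + 3 gameplay records)."""
    cfg = ScenarioConfig(seed=5)
    return make_cohort(cfg, (1, 0, 0, 0), seed=5)
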