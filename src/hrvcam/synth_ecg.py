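"""Synthetic annotated ECG cohorts with known autonomic modulation.

Every downstream stage of the pipeline (filtering, QRS detection, ectopic
rejection, time-frequency analysis, classification) is validated against
signals generated here, because the ground truth — beat times, LF/HF
modulation amplitudes, ectopic positions, severity class — is known exactly.

The generative chain is the standard one for HRV simulation studies:

1. an instantaneous-rate modulation ``m(t)`` made of an LF sinusoid, an HF
   sinusoid and band-limited broadband noise (all fractional, dimensionless);
2. the integral pulse frequency modulation (IPFM) model, which emits beat
   ``k`` when ``(1/T) * integral_0^t (1 + m(tau)) dtau`` crosses the integer
   ``k`` (``T`` = mean RR interval) — so the RR series encodes ``m`` and the
   tachogram spectrum has known peaks;
3. occasional ectopic beats (a beat advanced by 25–40 % of the local RR with
   a compensatory pause), giving ground truth for the 20 % ectopic filter;
4. a Gaussian-template P-QRS-T waveform rendered per beat plus baseline
   wander, 60 Hz powerline and EMG-like noise.

A cohort emulates the cue-reactivity study design: per subject one 5-min
resting ("baseline") record and three >=5-min "gameplay" records, with the
gameplay LF/HF modulation amplitudes scaled by per-severity-class
reactivity multipliers, and an IAT severity score drawn from the class band.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

SEVERITY_CLASSES = ("normal", "mild", "moderate", "severe")

#: IAT score band (inclusive) per severity class.
IAT_BANDS = {
    "normal": (0, 30),
    "mild": (31, 50),
    "moderate": (51, 80),
    "severe": (81, 100),
}

#: Gaussian wave templates (offset from R in s, amplitude in mV, width sigma in s).
_PQRST = (
    (-0.200, 0.12, 0.028),   # P
    (-0.028, -0.14, 0.010),  # Q
    (0.000, 1.10, 0.013),    # R
    (0.030, -0.22, 0.012),   # S
    (0.260, 0.32, 0.055),    # T
)


@dataclass
class ModulationSignal:
    """Fractional modulation of the instantaneous heart rate on a uniform grid."""

    t: np.ndarray          # seconds
    m: np.ndarray          # dimensionless, 1 + m > 0 everywhere
    components: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        if self.t.shape != self.m.shape:
            raise ValueError("t and m must have the same length")
        if np.any(1.0 + self.m <= 0):
            raise ValueError("modulation drives 1 + m(t) <= 0: rate would go negative")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class BeatTimes:
    """Strictly increasing beat times with normal/ectopic labels."""

    times: np.ndarray      # seconds
    labels: np.ndarray     # 'normal' | 'ectopic'

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != self.times.shape:
            raise ValueError("labels must match times")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class ECGRecord:
    """Single-lead ECG samples in mV with optional ground-truth annotations."""

    fs: float
    samples: np.ndarray | None
    annotations: BeatTimes | None = None
    phase: str = "baseline"          # 'baseline' | 'gameplay'
    subject_id: str = ""
    episode_index: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.fs < 100:
            raise ValueError("sampling rate must be >= 100 Hz")
        if self.samples is not None:
            self.samples = np.asarray(self.samples, dtype=float)
            if not np.all(np.isfinite(self.samples)):
                raise ValueError("ECG samples must be finite")
            if self.annotations is not None and self.annotations.times.size:
                if self.annotations.times[-1] >= self.duration:
                    raise ValueError("annotation beyond record duration")

    @property
    def duration(self) -> float:
        if self.samples is None:
            return float(self.meta.get("duration_s", 0.0))
        return self.samples.size / self.fs


@dataclass
class ScenarioConfig:
    """Study-design parameters of a synthetic cue-reactivity cohort.

    Reactivity multipliers scale the gameplay-phase modulation amplitudes
    relative to baseline, per severity class.  The defaults encode the
    qualitative pattern the pipeline is meant to recover — HF (vagal)
    reactivity separates all four classes, while an LF increase additionally
    marks the severe class — as a learnable synthetic signal; they are
    configuration, not measured physiology.
    """

    mean_rr_ms: float = 850.0
    mean_rr_jitter_ms: float = 75.0       # per-subject uniform +/- jitter
    a_lf: float = 0.05                    # baseline LF modulation amplitude
    a_hf: float = 0.06                    # baseline HF modulation amplitude
    f_lf: float = 0.10                    # Hz, inside the 0.04-0.15 LF band
    f_hf: float = 0.25                    # Hz, inside the 0.15-0.4 HF band
    noise_sigma: float = 0.01             # broadband modulation noise (RMS)
    reactivity_hf: dict = field(default_factory=lambda: {
        "normal": 1.0, "mild": 0.8, "moderate": 0.6, "severe": 0.45})
    reactivity_lf: dict = field(default_factory=lambda: {
        "normal": 1.0, "mild": 1.0, "moderate": 1.0, "severe": 1.5})
    reactivity_jitter_sd: float = 0.05    # lognormal sigma on per-subject multipliers
    fs: float = 250.0                     # ECG sampling rate, Hz
    wander_mv: float = 0.10               # baseline wander amplitude
    powerline_mv: float = 0.05            # 60 Hz line amplitude
    powerline_hz: float = 60.0
    emg_sigma_mv: float = 0.02            # white EMG-like noise
    ectopic_rate_per_min: float = 2.0
    baseline_s: float = 300.0
    gameplay_s: float = 312.0
    iat_bands: dict = field(default_factory=lambda: dict(IAT_BANDS))
    seed: int = 0

    def __post_init__(self):
        for d in (self.reactivity_hf, self.reactivity_lf):
            if any(v <= 0 for v in d.values()):
                raise ValueError("reactivity multipliers must be > 0")
        if self.ectopic_rate_per_min < 0:
            raise ValueError("ectopic rate must be >= 0")
        if not (250 < self.mean_rr_ms < 2000):
            raise ValueError("mean RR must lie in (250, 2000) ms")
        for cls, (lo, hi) in self.iat_bands.items():
            ref = IAT_BANDS[cls]
            if not (lo >= 0 and hi <= 100 and lo <= hi):
                raise ValueError(f"invalid IAT band for {cls}")
            if (lo, hi) != ref:
                raise ValueError(f"IAT band for {cls} must match the label bands {ref}")


def generate_modulation(config: ScenarioConfig, duration: float, phase: str,
                        seed: int, severity: str = "normal",
                        dt: float = 0.004) -> ModulationSignal:
    """Build the fractional rate modulation for one record.

    ``m(t) = a_LF sin(2 pi f_LF t + phi1) + a_HF sin(2 pi f_HF t + phi2) + n(t)``
    with ``n`` band-limited (< ~0.5 Hz) Gaussian noise of RMS ``noise_sigma``.
    In the gameplay phase the class reactivity multipliers scale the two
    amplitudes; the baseline phase uses them unscaled.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if phase not in ("baseline", "gameplay"):
        raise ValueError(f"unknown phase {phase!r}")
    if severity not in SEVERITY_CLASSES:
        raise ValueError(f"unknown severity {severity!r}")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + dt / 2, dt)
    a_lf, a_hf = config.a_lf, config.a_hf
    if phase == "gameplay":
        a_lf *= config.reactivity_lf[severity]
        a_hf *= config.reactivity_hf[severity]
    phi1, phi2 = rng.uniform(0, 2 * np.pi, size=2)
    m = a_lf * np.sin(2 * np.pi * config.f_lf * t + phi1)
    m = m + a_hf * np.sin(2 * np.pi * config.f_hf * t + phi2)
    if config.noise_sigma > 0:
        # white noise on a 4 Hz grid, Gaussian-smoothed to ~<0.5 Hz, unit RMS
        coarse = rng.standard_normal(int(np.ceil(duration * 4)) + 8)
        coarse = gaussian_filter1d(coarse, sigma=2.0, mode="reflect")
        coarse /= max(np.sqrt(np.mean(coarse**2)), 1e-12)
        tc = (np.arange(coarse.size) - 4) * 0.25
        m = m + config.noise_sigma * np.interp(t, tc, coarse)
    return ModulationSignal(t=t, m=m, components={
        "lf": (a_lf, config.f_lf), "hf": (a_hf, config.f_hf),
        "noise_sigma": config.noise_sigma})


def ipfm_beats(mod: ModulationSignal, mean_rr_ms: float) -> BeatTimes:
    """Emit beats by the IPFM model.

    Beat ``k`` fires when ``(1000 / mean_rr_ms) * integral (1 + m)`` crosses
    the integer ``k``; the crossing is located by linear interpolation on the
    modulation grid (grid step must be <= 10 ms).
    """
    if not (250 < mean_rr_ms < 2000):
        raise ValueError("mean RR must lie in (250, 2000) ms")
    dt = mod.dt
    if dt > 0.010 + 1e-12:
        raise ValueError("modulation grid too coarse for beat localization (need <= 10 ms)")
    rate = 1000.0 / mean_rr_ms  # beats per second
    integ = np.concatenate([[0.0], np.cumsum((1.0 + mod.m[:-1]) * dt)]) * rate
    n_beats = int(np.floor(integ[-1] + 1e-9))
    if n_beats < 1:
        return BeatTimes(times=np.empty(0), labels=np.empty(0, dtype=object))
    ks = np.arange(1, n_beats + 1, dtype=float)
    idx = np.searchsorted(integ, ks)
    idx = np.clip(idx, 1, integ.size - 1)
    frac = (ks - integ[idx - 1]) / (integ[idx] - integ[idx - 1])
    times = mod.t[idx - 1] + frac * dt
    return BeatTimes(times=times, labels=np.array(["normal"] * n_beats, dtype=object))


def inject_ectopics(beats: BeatTimes, rate_per_min: float, seed: int) -> BeatTimes:
    """Advance randomly chosen beats by 25-40 % of the local RR (compensatory pause).

    The following beat is left in place, so each ectopic shortens one interval
    by 25-40 % and lengthens the next by the same amount — both exceed the
    20 % rejection threshold of the ectopic filter, giving it clean ground
    truth.  Expected count is ``rate * duration / 60`` (binomial over beats).
    """
    if rate_per_min < 0:
        raise ValueError("ectopic rate must be >= 0")
    if rate_per_min == 0 or len(beats) < 5:
        return BeatTimes(times=beats.times.copy(), labels=beats.labels.copy())
    rng = np.random.default_rng(seed)
    times = beats.times.copy()
    labels = beats.labels.copy()
    duration = times[-1] - times[0]
    candidates = np.arange(2, len(beats) - 2)
    p = min(1.0, (rate_per_min * duration / 60.0) / candidates.size)
    picked = candidates[rng.random(candidates.size) < p]
    # no adjacent ectopics: keep the first of any adjacent pair
    keep, last = [], -10
    for i in picked:
        if i - last > 1:
            keep.append(i)
            last = i
    for i in keep:
        rr = times[i] - times[i - 1]
        shift = rng.uniform(0.25, 0.40) * rr
        times[i] -= shift
        labels[i] = "ectopic"
    return BeatTimes(times=times, labels=labels)


@dataclass
class NoiseConfig:
    wander_mv: float = 0.10
    powerline_mv: float = 0.05
    powerline_hz: float = 60.0
    emg_sigma_mv: float = 0.02

    @classmethod
    def from_scenario(cls, config: ScenarioConfig) -> "NoiseConfig":
        return cls(wander_mv=config.wander_mv, powerline_mv=config.powerline_mv,
                   powerline_hz=config.powerline_hz, emg_sigma_mv=config.emg_sigma_mv)

    @classmethod
    def none(cls) -> "NoiseConfig":
        return cls(wander_mv=0.0, powerline_mv=0.0, emg_sigma_mv=0.0)


def render_ecg(beats: BeatTimes, fs: float = 250.0,
               noise: NoiseConfig | None = None, seed: int = 0,
               duration: float | None = None, phase: str = "baseline",
               subject_id: str = "", episode_index: int = 0) -> ECGRecord:
    """Render a Gaussian-template P-QRS-T waveform per beat plus noise.

    In the noise-free case the R-wave sample maximum coincides with the beat
    time to within half a sample.  Ectopic beats are rendered without a P
    wave and with a slightly reduced R amplitude.
    """
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    if duration is None:
        duration = (beats.times[-1] + 0.5) if len(beats) else 1.0
    n = int(round(duration * fs))
    if len(beats) and beats.times[-1] >= duration:
        raise ValueError("beats extend beyond the requested duration")
    sig = np.zeros(n)
    t = np.arange(n) / fs
    for tb, lab in zip(beats.times, beats.labels):
        for off, amp, sigma in _PQRST:
            if lab == "ectopic":
                if off == -0.200:    # ectopics: no P wave
                    continue
                if off == 0.0:
                    amp = amp * 0.9
            c = tb + off
            lo = max(0, int((c - 4 * sigma) * fs))
            hi = min(n, int((c + 4 * sigma) * fs) + 1)
            if hi <= lo:
                continue
            tt = t[lo:hi]
            sig[lo:hi] += amp * np.exp(-0.5 * ((tt - c) / sigma) ** 2)
    noise = noise if noise is not None else NoiseConfig.none()
    rng = np.random.default_rng(seed)
    if noise.wander_mv > 0:
        ph = rng.uniform(0, 2 * np.pi, size=2)
        sig += noise.wander_mv * (0.7 * np.sin(2 * np.pi * 0.21 * t + ph[0])
                                  + 0.3 * np.sin(2 * np.pi * 0.33 * t + ph[1]))
    if noise.powerline_mv > 0:
        sig += noise.powerline_mv * np.sin(
            2 * np.pi * noise.powerline_hz * t + rng.uniform(0, 2 * np.pi))
    if noise.emg_sigma_mv > 0:
        sig += noise.emg_sigma_mv * rng.standard_normal(n)
    return ECGRecord(fs=fs, samples=sig, annotations=beats, phase=phase,
                     subject_id=subject_id, episode_index=episode_index,
                     meta={"seed": seed, "duration_s": duration})


@dataclass
class Subject:
    subject_id: str
    severity: str
    iat_score: int
    mean_rr_ms: float
    records: list  # ECGRecord: one baseline + three gameplay


@dataclass
class Cohort:
    config: ScenarioConfig
    subjects: list

    @property
    def n_records(self) -> int:
        return sum(len(s.records) for s in self.subjects)

    def manifest(self) -> dict:
        return {
            "n_subjects": len(self.subjects),
            "n_records": self.n_records,
            "subjects": [
                {
                    "subject_id": s.subject_id,
                    "severity": s.severity,
                    "iat_score": s.iat_score,
                    "mean_rr_ms": s.mean_rr_ms,
                    "records": [
                        {"phase": r.phase, "episode": r.episode_index,
                         "duration_s": r.duration, "fs": r.fs,
                         "seed": r.meta.get("seed")}
                        for r in s.records
                    ],
                }
                for s in self.subjects
            ],
        }


def make_cohort(config: ScenarioConfig, n_per_class, seed: int,
                render: bool = True) -> Cohort:
    """Generate a full synthetic cohort.

    Per subject: one ``baseline_s`` resting record and three ``gameplay_s``
    gameplay records, with per-subject mean-RR and reactivity jitter, an IAT
    score drawn uniformly from the class band, and ectopics injected at the
    configured rate.  With ``render=False`` the waveform synthesis is skipped
    (beat annotations and the manifest are still exact), which is enough for
    design/counting checks.
    """
    n_per_class = tuple(int(v) for v in n_per_class)
    if len(n_per_class) != 4 or any(v < 0 for v in n_per_class):
        raise ValueError("n_per_class must be four non-negative counts")
    root = np.random.SeedSequence(seed)
    subjects = []
    sid = 0
    for cls, n_cls in zip(SEVERITY_CLASSES, n_per_class):
        for _ in range(n_cls):
            sid += 1
            ss = root.spawn(1)[0]
            rng = np.random.default_rng(ss)
            subject_id = f"S{sid:03d}"
            lo, hi = config.iat_bands[cls]
            iat = int(rng.integers(lo, hi + 1))
            mean_rr = config.mean_rr_ms + rng.uniform(-1, 1) * config.mean_rr_jitter_ms
            jit = float(np.exp(rng.normal(0.0, config.reactivity_jitter_sd)))
            subj_cfg = dataclasses.replace(
                config,
                reactivity_hf={k: v * jit for k, v in config.reactivity_hf.items()},
                reactivity_lf={k: v * jit for k, v in config.reactivity_lf.items()},
            )
            records = []
            specs = [("baseline", 0, config.baseline_s)] + [
                ("gameplay", ep, config.gameplay_s) for ep in (1, 2, 3)]
            for phase, ep, dur in specs:
                rec_seed = int(rng.integers(0, 2**31 - 1))
                mod = generate_modulation(subj_cfg, dur, phase, rec_seed, severity=cls)
                beats = ipfm_beats(mod, mean_rr)
                beats = inject_ectopics(beats, config.ectopic_rate_per_min, rec_seed + 1)
                if render:
                    rec = render_ecg(beats, fs=config.fs,
                                     noise=NoiseConfig.from_scenario(config),
                                     seed=rec_seed + 2, duration=dur, phase=phase,
                                     subject_id=subject_id, episode_index=ep)
                else:
                    rec = ECGRecord(fs=config.fs, samples=None, annotations=beats,
                                    phase=phase, subject_id=subject_id,
                                    episode_index=ep,
                                    meta={"seed": rec_seed, "duration_s": dur})
                records.append(rec)
            subjects.append(Subject(subject_id=subject_id, severity=cls,
                                    iat_score=iat, mean_rr_ms=mean_rr,
                                    records=records))
    return Cohort(config=config, subjects=subjects)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write a cohort to disk: per-record CSV + JSON sidecar, beat-time CSV, manifest."""
    from pathlib import Path

    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        for r in s.records:
            stem = f"{s.subject_id}_{r.phase}{r.episode_index}"
            if r.samples is not None:
                t = np.arange(r.samples.size) / r.fs
                pd.DataFrame({"time_s": t, "mv": r.samples}).to_csv(
                    outdir / f"{stem}.csv", index=False)
            if r.annotations is not None:
                pd.DataFrame({"beat_time_s": r.annotations.times}).to_csv(
                    outdir / f"{stem}.beats.csv", index=False)
            sidecar = {"fs": r.fs, "subject": s.subject_id, "phase": r.phase,
                       "episode": r.episode_index, "seed": r.meta.get("seed")}
            (outdir / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    (outdir / "manifest.json").write_text(json.dumps(cohort.manifest(), indent=1))
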