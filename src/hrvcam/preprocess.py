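"""ECG denoising filter chain.

Three zero-phase Butterworth stages: a 3rd-order 1 Hz high-pass (baseline
wander from movement/respiration), a 3rd-order 15 Hz low-pass (EMG), and a
6th-order 58-62 Hz band-stop (powerline).  All filters are designed as
second-order sections and applied forward-backward (``sosfiltfilt``) so the
R-peak timing that feeds the inter-beat-interval series is not shifted; the
price is that the effective magnitude response is the square of the design
(the -3 dB points quoted below refer to the single-pass design).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synth_ecg import ECGRecord


@dataclass(frozen=True)
class FilterSpec:
    """One Butterworth stage. ``cutoff_hz`` is a scalar, or a (low, high) pair
    for the notch (band-stop); ``order`` is the per-design order (a band-stop
    of design order 3 has overall order 6)."""

    kind: str               # 'highpass' | 'lowpass' | 'notch'
    order: int
    cutoff_hz: float | tuple

    def __post_init__(self):
        if self.kind not in ("highpass", "lowpass", "notch"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def design_sos(self, fs: float) -> np.ndarray:
        cut = self.cutoff_hz
        nyq = fs / 2.0
        if self.kind == "notch":
            lo, hi = cut
            if not (0 < lo < hi < nyq):
                raise ValueError("notch band must lie inside (0, fs/2)")
            return signal.butter(self.order, [lo, hi], btype="bandstop",
                                 output="sos", fs=fs)
        if not (0 < float(cut) < nyq):
            raise ValueError("cutoff must lie inside (0, fs/2)")
        btype = "highpass" if self.kind == "highpass" else "lowpass"
        return signal.butter(self.order, float(cut), btype=btype, output="sos", fs=fs)


#: the standard chain: HP 1 Hz (order 3) -> LP 15 Hz (order 3) -> notch 58-62 Hz
#: (band-stop design order 3, i.e. 6th order overall).
DEFAULT_CHAIN = (
    FilterSpec("highpass", 3, 1.0),
    FilterSpec("lowpass", 3, 15.0),
    FilterSpec("notch", 3, (58.0, 62.0)),
)


def apply_filter(record: ECGRecord, spec: FilterSpec) -> ECGRecord:
    """Apply one zero-phase Butterworth stage; length, fs and annotations kept."""
    x = record.samples
    if x is None:
        raise ValueError("record has no samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples in input")
    sos = spec.design_sos(record.fs)
    y = signal.sosfiltfilt(sos, x)
    meta = dict(record.meta)
    meta.setdefault("filters", [])
    meta["filters"] = list(meta["filters"]) + [dataclasses.asdict(spec)]
    return ECGRecord(fs=record.fs, samples=y, annotations=record.annotations,
                     phase=record.phase, subject_id=record.subject_id,
                     episode_index=record.episode_index, meta=meta)


def preprocess_ecg(record: ECGRecord, chain=DEFAULT_CHAIN) -> ECGRecord:
    """Run the full denoising chain in sequence (requires fs > 120 Hz so the
    60 Hz band is representable)."""
    if record.fs <= 120:
        raise ValueError("preprocess_ecg requires fs > 120 Hz")
    out = record
    for spec in chain:
        out = apply_filter(out, spec)
    return out
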