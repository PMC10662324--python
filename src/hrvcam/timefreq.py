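"""Time-frequency scalograms of 30-s tachogram segments.

Each 30-s, 4-Hz tachogram segment (120 samples) is mapped to a 304 x 30
power matrix: 304 frequency bins linearly spaced over (0, 0.4] Hz and 30
one-second time bins.  Two window families are provided:

* ``stft`` — a 10-s Hann window centered on each 1-s time bin;
* ``cwt``  — an analytic Morlet (omega0 = 6) wavelet, i.e. a Gaussian
  window whose width scales with the analysis frequency, with the classic
  scale rectification (power divided by scale) so a tone's response is
  symmetric about its frequency instead of tilted toward low frequencies.

Both are evaluated as *weighted least-squares sinusoid projections*: for
each (frequency bin, time bin) the segment is projected onto
``{cos 2 pi f t, sin 2 pi f t}`` under the window weights, truncated at the
segment boundary, and the projection power is normalized per-cell by the
window's actual mass inside the segment.  This formulation has two
properties a padded FFT does not: a pure tone's projection power is
maximal exactly at its own frequency for any non-negative window (so the
argmax row is unbiased at the +/- 1-bin level, which matters on a grid
with 1.3 mHz spacing), and boundary cells need no reflection padding —
phase-discontinuous junctions introduced by padding are what drags
spectral peaks off by several millihertz.  For interior cells the ``stft``
power coincides with the ordinary one-sided Hann periodogram density
(ms^2/Hz); the ``cwt`` power is in relative units (its calibration cancels
in baseline normalization and band ratios).

Gameplay scalograms are normalized against a per-subject resting profile:
the per-frequency-bin mean PSD of the baseline recording, so each ratio
row expresses gameplay power relative to that subject's own resting power
and between-subject scale factors (fitness, BMI, electrode gain) drop out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beats_hrv import TachogramUniform
from .dataset import segment_windows

N_FREQ = 304
N_TIME = 30
F_MAX = 0.4
SEGMENT_S = 30.0
TACH_FS = 4.0
MORLET_W0 = 6.0
MORLET_B = 2.0      # psi(t) ~ exp(-t^2/B) exp(i w0 t): B=2 is the unit-width Morlet
BANDS = {"vlf": (0.0, 0.04), "lf": (0.04, 0.15), "hf": (0.15, 0.4)}


@dataclass(frozen=True)
class FrequencyGrid:
    """304 bin centers f_k = (k+1) * 0.4 / 304, k = 0..303, with band masks
    VLF [0, 0.04), LF [0.04, 0.15), HF [0.15, 0.4] partitioning the grid."""

    freqs: np.ndarray = field(
        default_factory=lambda: (np.arange(N_FREQ) + 1) * F_MAX / N_FREQ)

    def mask(self, band: str) -> np.ndarray:
        if band not in BANDS:
            raise ValueError(f"unknown band {band!r}")
        lo, hi = BANDS[band]
        if band == "hf":
            return (self.freqs >= lo) & (self.freqs <= hi + 1e-12)
        return (self.freqs >= lo) & (self.freqs < hi)

    @property
    def df(self) -> float:
        return F_MAX / N_FREQ


GRID = FrequencyGrid()


@dataclass
class Scalogram:
    power: np.ndarray            # (304, 30), >= 0
    freqs: np.ndarray
    times: np.ndarray            # 30 bin centers, s from segment start
    method: str                  # 'stft' | 'cwt'
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (N_FREQ, N_TIME):
            raise ValueError(f"scalogram must be {N_FREQ}x{N_TIME}")
        if not np.all(np.isfinite(self.power)) or np.any(self.power < 0):
            raise ValueError("scalogram power must be finite and non-negative")


@dataclass
class BaselineProfile:
    mean_psd: np.ndarray         # (304,), strictly positive (floored)
    n_windows: int = 0
    degenerate: bool = False

    def __post_init__(self):
        self.mean_psd = np.asarray(self.mean_psd, dtype=float)
        if self.mean_psd.shape != (N_FREQ,):
            raise ValueError(f"profile must have {N_FREQ} values")
        if np.any(self.mean_psd <= 0):
            raise ValueError("profile must be strictly positive (apply the floor)")


@dataclass
class NormalizedScalogram:
    ratio: np.ndarray            # (304, 30), dimensionless
    freqs: np.ndarray
    times: np.ndarray
    method: str
    meta: dict = field(default_factory=dict)


class _LSDesign:
    """Precomputed projection design for one window family.

    For every (frequency bin k, time bin p): the window-weighted cos/sin
    load vectors over the 120 segment samples, the 2x2 Gram matrix of the
    weighted sinusoid pair, and the window mass/energy inside the segment.
    Projection power of segment ``x`` is the Gram-solved quadratic form,
    scaled to a one-sided density by sum(w) / (fs * sum(w^2)) per cell.
    """

    def __init__(self, weights: np.ndarray, rectify_scale: bool):
        # weights: (n_samples, N_FREQ, N_TIME) window values, >= 0
        n = weights.shape[0]
        t = np.arange(n) / TACH_FS
        cos = np.cos(2 * np.pi * t[:, None] * GRID.freqs[None, :])   # (n, K)
        sin = np.sin(2 * np.pi * t[:, None] * GRID.freqs[None, :])
        wc = weights * cos[:, :, None]
        ws = weights * sin[:, :, None]
        self.g11 = np.einsum("nkp,nk->kp", wc, cos)
        self.g22 = np.einsum("nkp,nk->kp", ws, sin)
        self.g12 = np.einsum("nkp,nk->kp", wc, sin)
        self.det = np.maximum(self.g11 * self.g22 - self.g12 ** 2, 1e-30)
        sw = weights.sum(axis=0)
        sw2 = np.maximum((weights ** 2).sum(axis=0), 1e-30)
        self.scale = sw / (TACH_FS * sw2)
        if rectify_scale:
            # rectified wavelet power (divide by scale, i.e. multiply by f):
            # removes the 1/f tilt that biases tone peaks low by ~1/(2 w0^2)
            self.scale = self.scale * (GRID.freqs[:, None] / F_MAX)
        self.wc = wc.reshape(n, -1)
        self.ws = ws.reshape(n, -1)

    def power(self, x: np.ndarray) -> np.ndarray:
        a = (x @ self.wc).reshape(N_FREQ, N_TIME)
        b = (x @ self.ws).reshape(N_FREQ, N_TIME)
        quad = (self.g22 * a * a - 2 * self.g12 * a * b + self.g11 * b * b) / self.det
        return np.maximum(quad * self.scale, 0.0)


def _stft_design() -> _LSDesign:
    n = int(SEGMENT_S * TACH_FS)
    nwin = int(10.0 * TACH_FS)
    hann = np.hanning(nwin + 1)[:-1]
    w = np.zeros((n, N_TIME))
    for p in range(N_TIME):
        start = int((p + 0.5) * TACH_FS) - nwin // 2
        lo, hi = max(0, start), min(n, start + nwin)
        w[lo:hi, p] = hann[lo - start:hi - start]
    return _LSDesign(np.repeat(w[:, None, :], N_FREQ, axis=1), rectify_scale=False)


def _cwt_design() -> _LSDesign:
    n = int(SEGMENT_S * TACH_FS)
    t = np.arange(n) / TACH_FS
    centers = np.arange(N_TIME) + 0.5
    s_sec = (MORLET_W0 / (2 * np.pi)) / GRID.freqs          # Morlet scale, s
    env = np.exp(-((t[:, None, None] - centers[None, None, :]) ** 2)
                 / (MORLET_B * s_sec[None, :, None] ** 2))
    return _LSDesign(env, rectify_scale=True)


_DESIGNS: dict[str, _LSDesign] = {}


def _design(method: str) -> _LSDesign:
    if method not in ("stft", "cwt"):
        raise ValueError(f"unknown method {method!r}")
    if method not in _DESIGNS:
        _DESIGNS[method] = _stft_design() if method == "stft" else _cwt_design()
    return _DESIGNS[method]


def _check_segment(values: np.ndarray) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.size != int(SEGMENT_S * TACH_FS):
        raise ValueError(f"segment must be exactly {int(SEGMENT_S * TACH_FS)} "
                         f"samples at {TACH_FS} Hz")
    if not np.all(np.isfinite(x)):
        raise ValueError("segment contains non-finite values")
    return x - x.mean()


def compute_scalogram(seg, method: str = "stft", meta: dict | None = None) -> Scalogram:
    values = seg.values if isinstance(seg, TachogramUniform) else seg
    x = _check_segment(values)
    power = _design(method).power(x)
    return Scalogram(power=power, freqs=GRID.freqs.copy(),
                     times=np.arange(N_TIME) + 0.5, method=method,
                     meta=meta or {})


def scalogram_stft(seg, meta: dict | None = None) -> Scalogram:
    """Hann-windowed (10 s) scalogram; interior cells match the one-sided
    Hann periodogram density in ms^2/Hz."""
    return compute_scalogram(seg, method="stft", meta=meta)


def scalogram_cwt(seg, meta: dict | None = None) -> Scalogram:
    """Analytic Morlet (omega0 = 6) scalogram with rectified (scale-
    normalized) power; relative units."""
    return compute_scalogram(seg, method="cwt", meta=meta)


def band_power(s: Scalogram, band: str) -> float:
    """Mean over time bins of the band-integrated power (midpoint rule on
    the uniform grid, so vlf + lf + hf equals the total 0-0.4 Hz integral
    exactly), in ms^2 for the STFT method."""
    mask = GRID.mask(band)
    return float(s.power[mask, :].sum(axis=0).mean() * GRID.df)


def baseline_profile(baseline_tach: TachogramUniform, method: str = "stft",
                     window_s: float = 30.0, hop_s: float = 10.0) -> BaselineProfile:
    """Per-frequency-bin mean PSD of a resting recording.

    The baseline tachogram is cut into 30-s windows every 10 s; all time
    bins of all window scalograms are averaged per frequency row.  The
    result is floored at 1e-8 x max so later division is safe; an all-zero
    baseline yields a flat floored profile flagged degenerate.
    """
    span = baseline_tach.values.size / baseline_tach.fs
    if span < 60.0:
        raise ValueError("baseline must provide at least 60 s")
    offsets = segment_windows(span, window=window_s, hop=hop_s)
    nseg = int(window_s * baseline_tach.fs)
    acc = np.zeros(N_FREQ)
    for off in offsets:
        i0 = int(round(off * baseline_tach.fs))
        seg = baseline_tach.values[i0:i0 + nseg]
        s = compute_scalogram(seg, method=method)
        acc += s.power.mean(axis=1)
    mean_psd = acc / len(offsets)
    peak = float(mean_psd.max())
    if peak <= 0:
        return BaselineProfile(mean_psd=np.full(N_FREQ, 1e-12),
                               n_windows=len(offsets), degenerate=True)
    return BaselineProfile(mean_psd=np.maximum(mean_psd, 1e-8 * peak),
                           n_windows=len(offsets), degenerate=False)


def normalize(s: Scalogram, p: BaselineProfile,
              mode: str = "ratio") -> NormalizedScalogram:
    """ratio[f, t] = power[f, t] / mean_psd[f] (row-wise division);
    ``mode='log'`` returns log1p of the ratio instead."""
    if s.freqs.shape != p.mean_psd.shape:
        raise ValueError("frequency grid mismatch")
    ratio = s.power / p.mean_psd[:, None]
    if mode == "log":
        ratio = np.log1p(ratio)
    elif mode != "ratio":
        raise ValueError(f"unknown mode {mode!r}")
    return NormalizedScalogram(ratio=ratio, freqs=s.freqs, times=s.times,
                               method=s.method, meta=dict(s.meta))
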