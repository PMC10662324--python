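"""R-peak detection and inter-beat-interval (IBI) conditioning.

The detector is the classic Pan-Tompkins pipeline: 5-15 Hz band-pass,
five-point derivative, squaring, 150 ms moving-window integration, then
dual adaptive thresholds over the integrated signal with a 200 ms
refractory period, a 360 ms T-wave slope check and a search-back pass at
1.66x the running RR.  Detected fiducials are refined to the local maximum
of the (zero-phase) band-passed ECG.

The IBI series is cleaned with a 20 % ectopic filter — an interval is
rejected when it deviates from the running median of the five preceding
accepted intervals by more than 20 % — then polynomial-detrended and
resampled to a uniform 4 Hz tachogram by a natural cubic spline, the form
expected by the spectral analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .synth_ecg import BeatTimes, ECGRecord


@dataclass
class IBISeries:
    beat_time: np.ndarray   # s, time of the later beat of each pair
    ibi: np.ndarray         # ms
    flags: np.ndarray       # 'ok' | 'ectopic_removed' | 'interpolated'

    def __post_init__(self):
        self.beat_time = np.asarray(self.beat_time, dtype=float)
        self.ibi = np.asarray(self.ibi, dtype=float)
        if self.flags is None:
            self.flags = np.array(["ok"] * self.ibi.size, dtype=object)
        self.flags = np.asarray(self.flags, dtype=object)
        if np.any(self.ibi <= 0):
            raise ValueError("IBI values must be positive")
        if self.beat_time.size > 1 and np.any(np.diff(self.beat_time) <= 0):
            raise ValueError("beat times must be strictly increasing")


@dataclass
class TachogramUniform:
    fs: float               # Hz, 4 by convention
    t0: float               # s, time of the first sample
    values: np.ndarray      # ms

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tachogram values must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs


@dataclass
class DetectionMetrics:
    sensitivity: float
    ppv: float
    n_matched: int
    offsets_ms: np.ndarray = field(default_factory=lambda: np.empty(0))


def pan_tompkins(record: ECGRecord, refractory_s: float = 0.200,
                 twave_window_s: float = 0.360, mwi_s: float = 0.150) -> BeatTimes:
    """Detect R-peaks. Returns an empty result (no error) on a flat signal."""
    x = record.samples
    if x is None or record.duration < 5.0:
        raise ValueError("record must carry samples and last at least 5 s")
    if record.fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    fs = record.fs
    sos = signal.butter(3, [5.0, 15.0], btype="bandpass", output="sos", fs=fs)
    bp = signal.sosfiltfilt(sos, x)
    # centered five-point derivative (zero group delay)
    kern = np.array([2, 1, 0, -1, -2]) / 8.0 * fs
    der = np.convolve(bp, kern[::-1], mode="same")
    sq = der ** 2
    nwin = max(1, int(round(mwi_s * fs)))
    mwi = np.convolve(sq, np.ones(nwin) / nwin, mode="same")
    if np.max(mwi) <= 0:
        return BeatTimes(times=np.empty(0), labels=np.empty(0, dtype=object))

    # candidate fiducials: local maxima of the integrated signal
    cand, _ = signal.find_peaks(mwi, distance=max(1, int(0.150 * fs)))
    if cand.size == 0:
        return BeatTimes(times=np.empty(0), labels=np.empty(0, dtype=object))

    init = mwi[: int(2 * fs)]
    spki = float(np.max(init)) / 2.0
    npki = float(np.mean(init)) / 2.0
    refr = int(refractory_s * fs)
    beats: list[int] = []
    rr_buf: list[float] = []
    slope_at: dict[int, float] = {}

    def slope(i: int) -> float:
        lo, hi = max(0, i - int(0.075 * fs)), min(der.size, i + int(0.075 * fs))
        return float(np.max(np.abs(der[lo:hi]))) if hi > lo else 0.0

    def accept(i: int, searchback: bool) -> None:
        nonlocal spki
        w = 0.25 if searchback else 0.125
        spki = w * mwi[i] + (1 - w) * spki
        if beats:
            rr_buf.append((i - beats[-1]) / fs)
            if len(rr_buf) > 8:
                rr_buf.pop(0)
        beats.append(i)
        slope_at[i] = slope(i)

    for i in cand:
        thr1 = npki + 0.25 * (spki - npki)
        is_beat = False
        if beats and i - beats[-1] < refr:
            npki = 0.125 * mwi[i] + 0.875 * npki
            continue
        if mwi[i] > thr1:
            is_beat = True
            # T-wave discrimination: close to the last beat and much flatter
            if beats and (i - beats[-1]) / fs < twave_window_s:
                if slope(i) < 0.5 * slope_at.get(beats[-1], np.inf):
                    is_beat = False
        if is_beat:
            accept(i, searchback=False)
        else:
            npki = 0.125 * mwi[i] + 0.875 * npki
            # search-back: a long gap suggests a missed beat
            if beats and rr_buf:
                rr_avg = float(np.mean(rr_buf))
                if (i - beats[-1]) / fs > 1.66 * rr_avg:
                    seg = cand[(cand > beats[-1] + refr) & (cand < i)]
                    seg = seg[mwi[seg] > 0.5 * thr1]
                    if seg.size:
                        accept(int(seg[np.argmax(mwi[seg])]), searchback=True)

    if not beats:
        return BeatTimes(times=np.empty(0), labels=np.empty(0, dtype=object))

    # refine each fiducial to the local max of the band-passed ECG (+/- 50 ms)
    half = int(0.050 * fs)
    refined = []
    for i in beats:
        lo, hi = max(0, i - half), min(bp.size, i + half + 1)
        refined.append(lo + int(np.argmax(bp[lo:hi])))
    refined = np.unique(refined)
    keep = [int(refined[0])]
    for i in refined[1:]:
        if i - keep[-1] >= refr:
            keep.append(int(i))
    times = np.asarray(keep, dtype=float) / fs
    return BeatTimes(times=times, labels=np.array(["normal"] * len(keep), dtype=object))


def match_beats(detected: BeatTimes, truth: BeatTimes,
                tol_ms: float = 50.0) -> DetectionMetrics:
    """Greedy one-to-one nearest matching within ``tol_ms``."""
    d, t = detected.times, truth.times
    if d.size == 0 or t.size == 0:
        return DetectionMetrics(sensitivity=0.0 if t.size else 1.0,
                                ppv=0.0 if d.size else 1.0, n_matched=0)
    tol = tol_ms / 1000.0
    pairs = []
    idx = np.searchsorted(t, d)
    for i, j in enumerate(idx):
        for jj in (j - 1, j):
            if 0 <= jj < t.size:
                delta = abs(d[i] - t[jj])
                if delta <= tol:
                    pairs.append((delta, i, jj))
    pairs.sort()
    used_d, used_t, offsets = set(), set(), []
    for delta, i, jj in pairs:
        if i in used_d or jj in used_t:
            continue
        used_d.add(i)
        used_t.add(jj)
        offsets.append((d[i] - t[jj]) * 1000.0)
    m = len(offsets)
    return DetectionMetrics(sensitivity=m / t.size, ppv=m / d.size, n_matched=m,
                            offsets_ms=np.asarray(offsets))


def beats_to_ibi(beats: BeatTimes) -> IBISeries:
    """IBI_k = (t_{k+1} - t_k) in ms, stamped at t_{k+1}."""
    if len(beats) < 2:
        raise ValueError("need at least 2 beats")
    ibi = np.diff(beats.times) * 1000.0
    return IBISeries(beat_time=beats.times[1:], ibi=ibi,
                     flags=np.array(["ok"] * ibi.size, dtype=object))


def ectopic_filter(ibi: IBISeries, threshold: float = 0.20) -> IBISeries:
    """Reject intervals deviating > ``threshold`` from the running median.

    The reference is the median of the five preceding *accepted* intervals
    (the first five are compared against the whole-series median).  Rejected
    intervals are replaced by cubic interpolation of the accepted intervals
    over time and flagged; edge intervals that cannot be interpolated keep
    the flag ``ectopic_removed`` with a nearest-value fill.
    """
    n = ibi.ibi.size
    if n < 5:
        raise ValueError("need at least 5 intervals")
    series_med = float(np.median(ibi.ibi))
    accepted: list[float] = []
    flagged = np.zeros(n, dtype=bool)
    for k in range(n):
        med = float(np.median(accepted[-5:])) if len(accepted) >= 5 else series_med
        if abs(ibi.ibi[k] - med) / med > threshold:
            flagged[k] = True
        else:
            accepted.append(float(ibi.ibi[k]))
    if flagged.mean() > 0.5:
        raise ValueError("more than half of the intervals rejected: record unusable")
    out = ibi.ibi.copy()
    flags = np.array(["ok"] * n, dtype=object)
    if flagged.any():
        good = ~flagged
        interior = flagged & (ibi.beat_time >= ibi.beat_time[good][0]) \
                           & (ibi.beat_time <= ibi.beat_time[good][-1])
        if good.sum() >= 4 and interior.any():
            cs = CubicSpline(ibi.beat_time[good], ibi.ibi[good], bc_type="natural")
            out[interior] = cs(ibi.beat_time[interior])
            flags[interior] = "interpolated"
        edge = flagged & ~interior
        if edge.any():
            out[edge] = np.interp(ibi.beat_time[edge], ibi.beat_time[good],
                                  ibi.ibi[good])
            flags[edge] = "ectopic_removed"
    out = np.maximum(out, 1.0)  # interpolation guard: intervals stay positive
    return IBISeries(beat_time=ibi.beat_time.copy(), ibi=out, flags=flags)


def detrend_poly(times: np.ndarray, values: np.ndarray, order: int = 3):
    """Least-squares polynomial detrend (mean included); returns
    (detrended values, fitted trend, coefficients)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if not (1 <= order <= 6):
        raise ValueError("order must be in 1..6")
    if values.size < order + 2:
        raise ValueError("need at least order+2 points")
    if np.ptp(times) <= 0:
        raise ValueError("degenerate time axis")
    poly = np.polynomial.Polynomial.fit(times, values, deg=order)
    trend = poly(times)
    resid = values - trend
    resid = resid - resid.mean()
    return resid, trend, poly.convert().coef


def detrend_tachogram(tach: TachogramUniform, order: int = 3) -> TachogramUniform:
    resid, _, _ = detrend_poly(tach.times, tach.values, order=order)
    return TachogramUniform(fs=tach.fs, t0=tach.t0, values=resid)


def detrend_ibi(ibi: IBISeries, order: int = 3) -> IBISeries:
    resid, _, _ = detrend_poly(ibi.beat_time, ibi.ibi, order=order)
    # shifted to keep intervals positive in the container; spectral content unchanged
    return IBISeries(beat_time=ibi.beat_time, ibi=resid - resid.min() + 1.0,
                     flags=ibi.flags)


def resample_tachogram(ibi: IBISeries, fs: float = 4.0) -> TachogramUniform:
    """Natural cubic spline through (beat_time, ibi) on a uniform ``fs`` grid
    over [first, last] beat time."""
    if ibi.ibi.size < 4:
        raise ValueError("need at least 4 intervals")
    span = ibi.beat_time[-1] - ibi.beat_time[0]
    if span < 1.0:
        raise ValueError("IBI span must be at least 1 s")
    cs = CubicSpline(ibi.beat_time, ibi.ibi, bc_type="natural")
    n = int(np.floor(span * fs)) + 1
    t = ibi.beat_time[0] + np.arange(n) / fs
    return TachogramUniform(fs=fs, t0=float(ibi.beat_time[0]), values=cs(t))


def record_to_tachogram(record: ECGRecord, detrend_order: int = 3,
                        preprocessed: bool = False,
                        detrend_on: str = "tachogram") -> TachogramUniform:
    """Convenience pipeline: preprocess -> Pan-Tompkins -> IBI -> 20 % filter
    -> 4 Hz tachogram -> polynomial detrend (on the tachogram by default,
    ``detrend_on='ibi'`` to detrend the irregular series instead)."""
    from .preprocess import preprocess_ecg

    rec = record if preprocessed else preprocess_ecg(record)
    beats = pan_tompkins(rec)
    ibi = ectopic_filter(beats_to_ibi(beats))
    if detrend_on == "ibi":
        ibi = detrend_ibi(ibi, order=detrend_order)
        return resample_tachogram(ibi)
    tach = resample_tachogram(ibi)
    return detrend_tachogram(tach, order=detrend_order)
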