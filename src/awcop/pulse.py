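"""Radial pulse preprocessing and the 15-parameter fiducial set.

Processing chain: moving-average smoothing and baseline-drift removal, then
extraction of the most stable 6-s window (300 samples at 50 Hz), cycle
segmentation at diastolic minima, and per-cycle computation of the classic
pulse-graph parameters::

    h1 h3 h4 h5 t t1 t4 t5 h3/h1 h1/t1 h4/h1 t1/t t4/t5 w1/t w2/t

h1/h3/h5 are the percussion, tidal and dicrotic wave heights above the
cycle-onset baseline, h4 the dicrotic-notch height, t1/t4 the times of the
main peak and notch, t the cycle length and t5 = t - t4. w1 and w2 are the
widths of the main wave at (2/3)h1 and (4/5)h1 above baseline ("top third"
and "top fifth" of the primary wave), so w2 <= w1 by construction.

Peak and crossing locations use parabolic / linear sub-sample interpolation:
at 50 Hz a systolic upstroke spans only ~7 samples, and grid-resolution
timing would dominate the error budget otherwise.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CohortManifest, PulseRecording, read_pulse_csv

SEGMENT_SECONDS = 6.0
FEATURE_COLUMNS = ["h1", "h3", "h4", "h5", "t", "t1", "t4", "t5",
                   "h3_over_h1", "h1_over_t1", "h4_over_h1",
                   "t1_over_t", "t4_over_t5", "w1_over_t", "w2_over_t"]
MIN_PEAK_DISTANCE_S = 0.4  # bounds heart rate at 150 bpm


@dataclasses.dataclass
class PulseSegment:
    pressure: np.ndarray
    sampling_interval: float
    start_index: int = 0

    @property
    def duration(self) -> float:
        return len(self.pressure) * self.sampling_interval


@dataclasses.dataclass
class PulseCycle:
    pressure: np.ndarray      # onset-to-onset, onset sample included
    sampling_interval: float
    onset_index: int          # index into parent segment

    @property
    def duration(self) -> float:
        return len(self.pressure) * self.sampling_interval


@dataclasses.dataclass
class PulseFeatures:
    """The 15 per-cycle parameters; NaN where the notch is undetectable."""

    h1: float
    h3: float
    h4: float
    h5: float
    t: float
    t1: float
    t4: float
    t5: float
    h3_over_h1: float
    h1_over_t1: float
    h4_over_h1: float
    t1_over_t: float
    t4_over_t5: float
    w1_over_t: float
    w2_over_t: float
    degenerate: bool = False
    tidal_fallback: bool = False

    def as_series(self) -> pd.Series:
        return pd.Series({k: getattr(self, k) for k in FEATURE_COLUMNS})


# --------------------------------------------------------------------------

def preprocess(recording: PulseRecording, smooth_window: int = 3,
               drift_cutoff: float = 0.5) -> PulseRecording:
    """Moving-average smoothing then baseline-drift removal.

    Drift is estimated as the low-pass component below ``drift_cutoff`` Hz
    (zero-phase Butterworth) and subtracted; ``drift_cutoff=0`` disables
    removal, ``smooth_window=1`` disables smoothing. Length is preserved.
    """
    x = recording.pressure
    if smooth_window >= len(x):
        raise ValueError("smoothing window must be shorter than the recording")
    if recording.duration < SEGMENT_SECONDS:
        raise ValueError("recording shorter than the 6-s analysis window")
    if smooth_window > 1:
        pad = smooth_window // 2
        xp = np.pad(x, (pad, smooth_window - 1 - pad), mode="reflect")
        x = np.convolve(xp, np.ones(smooth_window) / smooth_window, mode="valid")
    if drift_cutoff > 0:
        fs = 1.0 / recording.sampling_interval
        b, a = signal.butter(2, drift_cutoff / (fs / 2.0), btype="low")
        trend = signal.filtfilt(b, a, x)
        x = x - trend
    return PulseRecording(pressure=x, sampling_interval=recording.sampling_interval)


def _systolic_peaks(x: np.ndarray, dt: float) -> np.ndarray:
    dist = max(int(round(MIN_PEAK_DISTANCE_S / dt)), 1)
    # prominence threshold from a robust range so isolated artifacts cannot
    # mask the regular systolic peaks
    q10, q90 = np.percentile(x, [10, 90])
    span = float(q90 - q10)
    if span <= 0:
        return np.array([], dtype=int)
    peaks, _ = signal.find_peaks(x, distance=dist, prominence=0.5 * span)
    return peaks


def extract_stable_segment(recording: PulseRecording) -> PulseSegment:
    """The 6-s window whose systolic peak amplitudes are most stable.

    Stability score = variance of peak heights inside the window (windows
    with <2 peaks are ineligible); ties resolved to the earliest onset.
    """
    x = recording.pressure
    dt = recording.sampling_interval
    n_seg = int(round(SEGMENT_SECONDS / dt))
    if len(x) < n_seg:
        raise ValueError("recording shorter than the 6-s analysis window")
    peaks = _systolic_peaks(x, dt)
    heights = x[peaks]
    best_score, best_start = np.inf, 0
    for start in range(len(x) - n_seg + 1):
        inside = heights[(peaks >= start) & (peaks < start + n_seg)]
        if len(inside) < 2:
            continue
        score = float(np.var(inside))
        if score < best_score - 1e-15:
            best_score, best_start = score, start
    if not np.isfinite(best_score):
        raise ValueError("no stable 6-s window: fewer than 2 systolic peaks")
    return PulseSegment(pressure=x[best_start:best_start + n_seg].copy(),
                        sampling_interval=dt, start_index=best_start)


def segment_cycles(segment: PulseSegment) -> list[PulseCycle]:
    """Split a segment into full cycles delimited at diastolic minima."""
    x = segment.pressure
    dt = segment.sampling_interval
    peaks = _systolic_peaks(x, dt)
    if len(peaks) < 2:
        raise ValueError("cycle extraction needs at least 2 systolic peaks")
    onsets = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        onsets.append(a + int(np.argmin(x[a:b])))
    cycles = []
    for a, b in zip(onsets[:-1], onsets[1:]):
        cycles.append(PulseCycle(pressure=x[a:b + 1].copy(),
                                 sampling_interval=dt, onset_index=a))
    if not cycles:
        raise ValueError("segment contains no complete cycle")
    return cycles


# --------------------------------------------------------------------------
# sub-sample helpers

def _refine_peak(x: np.ndarray, i: int) -> tuple[float, float]:
    """Parabolic interpolation of a local extremum at index i -> (pos, value)."""
    if i <= 0 or i >= len(x) - 1:
        return float(i), float(x[i])
    denom = x[i - 1] - 2 * x[i] + x[i + 1]
    if abs(denom) < 1e-15:
        return float(i), float(x[i])
    delta = 0.5 * (x[i - 1] - x[i + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    value = x[i] - 0.25 * (x[i - 1] - x[i + 1]) * delta
    return i + delta, float(value)


def _width_at(x: np.ndarray, peak_idx: int, level: float, dt: float) -> float:
    """Contiguous time around ``peak_idx`` where x exceeds ``level``."""
    left = peak_idx
    while left > 0 and x[left - 1] > level:
        left -= 1
    right = peak_idx
    while right < len(x) - 1 and x[right + 1] > level:
        right += 1
    # linear interpolation of the two crossings
    lpos = float(left)
    if left > 0 and x[left] != x[left - 1]:
        lpos = left - (x[left] - level) / (x[left] - x[left - 1])
    rpos = float(right)
    if right < len(x) - 1 and x[right] != x[right + 1]:
        rpos = right + (x[right] - level) / (x[right] - x[right + 1])
    return max(rpos - lpos, 0.0) * dt


def compute_features(cycle: PulseCycle) -> PulseFeatures:
    """Fiducial parameters of a single cycle (see module docstring)."""
    x = cycle.pressure
    dt = cycle.sampling_interval
    n = len(x)
    baseline = float(x[0])  # cycle-onset value: robust to residual drift
    t = (n - 1) * dt
    i_peak = int(np.argmax(x))
    p_pos, p_val = _refine_peak(x, i_peak)
    h1 = p_val - baseline
    t1 = p_pos * dt
    if h1 <= 0:
        raise ValueError("non-positive main-wave amplitude")

    # dicrotic notch: deepest local minimum after the main peak
    tail = x[i_peak:]
    minima, _ = signal.find_peaks(-tail)
    h4 = h5 = t4 = t5 = np.nan
    t4_over_t5 = np.nan
    degenerate = True
    i_notch = None
    if len(minima) > 0:
        i_notch = i_peak + int(minima[np.argmin(tail[minima])])
        n_pos, n_val = _refine_peak(x, i_notch)
        h4 = n_val - baseline
        t4 = n_pos * dt
        t5 = t - t4
        t4_over_t5 = t4 / t5 if t5 > 0 else np.nan
        degenerate = False
        # dicrotic wave: first local maximum after the notch
        after = x[i_notch:]
        maxima, _ = signal.find_peaks(after)
        if len(maxima) > 0:
            _, d_val = _refine_peak(x, i_notch + int(maxima[0]))
            h5 = d_val - baseline

    # tidal wave: local maximum between main peak and notch; fallback is the
    # steepest-negative-curvature point on the descending limb
    tidal_fallback = False
    end = i_notch if i_notch is not None else n - 1
    h3 = np.nan
    if end - i_peak >= 2:
        mid = x[i_peak:end + 1]
        tmax, _ = signal.find_peaks(mid)
        if len(tmax) > 0:
            _, t_val = _refine_peak(x, i_peak + int(tmax[0]))
            h3 = t_val - baseline
        else:
            curv = np.diff(mid, 2)
            if len(curv) > 0:
                j = int(np.argmin(curv)) + 1
                h3 = float(mid[j]) - baseline
                tidal_fallback = True
    if not np.isfinite(h3):
        h3 = h1  # single-bump morphology: tidal merged into the main wave
        tidal_fallback = True

    w1 = _width_at(x, i_peak, baseline + (2.0 / 3.0) * h1, dt)
    w2 = _width_at(x, i_peak, baseline + (4.0 / 5.0) * h1, dt)
    return PulseFeatures(
        h1=h1, h3=h3, h4=h4, h5=h5, t=t, t1=t1, t4=t4, t5=t5,
        h3_over_h1=h3 / h1, h1_over_t1=h1 / t1 if t1 > 0 else np.nan,
        h4_over_h1=h4 / h1, t1_over_t=t1 / t, t4_over_t5=t4_over_t5,
        w1_over_t=w1 / t, w2_over_t=w2 / t,
        degenerate=degenerate, tidal_fallback=tidal_fallback)


# --------------------------------------------------------------------------

class PulseFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer: raw recordings -> per-recording mean of the 15 parameters.

    ``transform`` accepts a list of :class:`PulseRecording` and returns an
    ``(n, 15)`` array (column order :data:`FEATURE_COLUMNS`); ratios whose
    notch was undetectable in a cycle are nan-averaged over the remaining
    cycles. Stateless (``fit`` is a no-op) but follows the scikit-learn
    transformer protocol so it can sit in a Pipeline.
    """

    def __init__(self, smooth_window: int = 3, drift_cutoff: float = 0.5):
        self.smooth_window = smooth_window
        self.drift_cutoff = drift_cutoff

    def fit(self, X, y=None):
        self.n_features_out_ = len(FEATURE_COLUMNS)
        return self

    def transform(self, X) -> np.ndarray:
        rows = []
        for rec in X:
            pre = preprocess(rec, self.smooth_window, self.drift_cutoff)
            seg = extract_stable_segment(pre)
            feats = [compute_features(c).as_series() for c in segment_cycles(seg)]
            with np.errstate(invalid="ignore"):
                rows.append(pd.DataFrame(feats).mean(axis=0, skipna=True).to_numpy())
        return np.asarray(rows)

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


def features_table(manifest: CohortManifest, smooth_window: int = 3,
                   drift_cutoff: float = 0.5) -> pd.DataFrame:
    """Per-patient mean pulse parameters, 15 columns, indexed by patient_id."""
    extractor = PulseFeatureExtractor(smooth_window, drift_cutoff)
    recs = [read_pulse_csv(manifest.root / p) for p in manifest.rows["pulse_path"]]
    table = pd.DataFrame(extractor.fit_transform(recs), columns=FEATURE_COLUMNS)
    table.index = pd.Index(manifest.patient_ids, name="patient_id")
    return table
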