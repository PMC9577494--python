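"""Raw-signal preprocessing: ECG filtering and R-peak detection, NN-interval
cleaning, tonic/phasic EDA decomposition, breath-cycle segmentation, and
per-subject baseline compensation.

Conventions: event times in seconds from trial start; sample indices 0-based;
all filters zero-phase (forward-backward application).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import sparse

from .exceptions import InsufficientDataError, InvalidParameterError, ShapeError
from .simulate import bateman_kernel

__all__ = [
    "FilterSpec",
    "RPeakSeries",
    "NNIntervalSeries",
    "EdaDecomposition",
    "BreathCycleSet",
    "fir_bandpass",
    "detect_r_peaks",
    "nn_intervals",
    "eda_decompose",
    "segment_breaths",
    "baseline_compensate",
]

# NN-interval artifact rejection bounds (ms) and running-median deviation rule
NN_MIN_MS = 250.0
NN_MAX_MS = 3000.0
NN_MEDIAN_DEVIATION = 0.30
REFRACTORY_S = 0.200


@dataclass
class FilterSpec:
    """Linear-phase windowed-sinc FIR band-pass specification.

    The ECG default (3-45 Hz) keeps the QRS complex while suppressing baseline
    wander and mains interference.  ``numtaps`` of 0 means "half a second of
    taps", resolved against the sampling rate at design time.
    """

    low_hz: float = 3.0
    high_hz: float = 45.0
    numtaps: int = 0
    kind: str = "bandpass"
    design: str = "windowed-sinc FIR"

    def resolve_numtaps(self, fs: float) -> int:
        n = self.numtaps if self.numtaps > 0 else int(0.5 * fs) + 1
        return n + 1 if n % 2 == 0 else n  # odd taps -> symmetric, type-I FIR

    def validate(self, fs: float) -> None:
        if not (0.0 < self.low_hz < self.high_hz < fs / 2.0):
            raise InvalidParameterError(
                f"band edges must satisfy 0 < low < high < fs/2; got "
                f"({self.low_hz}, {self.high_hz}) at fs={fs}"
            )


@dataclass
class RPeakSeries:
    """Detected R-peak sample indices (strictly increasing) at sampling rate fs."""

    sample_indices: np.ndarray
    fs: float
    warning: str | None = None

    def __post_init__(self) -> None:
        self.sample_indices = np.asarray(self.sample_indices, dtype=int)
        if len(self.sample_indices) > 1 and np.any(np.diff(self.sample_indices) <= 0):
            raise InvalidParameterError("R-peak indices must be strictly increasing")

    @property
    def times_s(self) -> np.ndarray:
        return self.sample_indices / self.fs

    def __len__(self) -> int:
        return len(self.sample_indices)


@dataclass
class NNIntervalSeries:
    """Normal-to-normal intervals (ms) with their onset anchor times (s)."""

    intervals_ms: np.ndarray
    t_anchor_s: np.ndarray

    def __post_init__(self) -> None:
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        self.t_anchor_s = np.asarray(self.t_anchor_s, dtype=float)
        if len(self.intervals_ms) != len(self.t_anchor_s):
            raise ShapeError("intervals and anchors must have equal length")

    def __len__(self) -> int:
        return len(self.intervals_ms)

    @property
    def span_s(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(self.t_anchor_s[-1] + self.intervals_ms[-1] / 1000.0 - self.t_anchor_s[0])


@dataclass
class EdaDecomposition:
    tonic: np.ndarray
    phasic: np.ndarray
    scr_events: list  # (onset_s, amplitude_uS)
    fs: float
    warning: str | None = None


@dataclass
class BreathCycleSet:
    """Trough-to-trough breathing cycles: (start_s, peak_s, end_s, amplitude)."""

    cycles: list
    warning: str | None = None

    def __post_init__(self) -> None:
        for (s, p, e, _a) in self.cycles:
            if not (s < p < e):
                raise InvalidParameterError("each cycle must satisfy start < peak < end")

    def __len__(self) -> int:
        return len(self.cycles)

    @property
    def durations_s(self) -> np.ndarray:
        return np.asarray([e - s for (s, _p, e, _a) in self.cycles])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.asarray([a for (_s, _p, _e, a) in self.cycles])


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

def fir_bandpass(x: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase FIR band-pass; output length equals input length.

    Designed with :func:`scipy.signal.firwin` (Hamming window) and applied
    forward-backward so R-peak latency is preserved.
    """
    spec = spec or FilterSpec()
    spec.validate(fs)
    numtaps = spec.resolve_numtaps(fs)
    x = np.asarray(x, dtype=float)
    min_len = 3 * numtaps
    if len(x) <= min_len:
        raise InsufficientDataError(
            f"signal too short for filtering: need > {min_len} samples "
            f"({numtaps} taps), got {len(x)}"
        )
    taps = sps.firwin(numtaps, [spec.low_hz, spec.high_hz], pass_zero=False, fs=fs,
                      window="hamming")
    return sps.filtfilt(taps, [1.0], x)


def detect_r_peaks(filtered_ecg: np.ndarray, fs: float) -> RPeakSeries:
    """Hamilton-style QRS detection on band-passed ECG.

    Chain: differentiate -> rectify -> 80 ms moving-average envelope ->
    adaptive threshold tracking running signal/noise peak estimates with a
    200 ms refractory period -> back-search for the local maximum of the
    filtered ECG as the R point.  Never raises on empty output; returns an
    empty series with a warning instead.
    """
    x = np.asarray(filtered_ecg, dtype=float)
    if len(x) < int(0.5 * fs) or np.ptp(x) == 0:
        return RPeakSeries(np.array([], dtype=int), fs, warning="no QRS candidates")

    env = np.abs(np.diff(x, prepend=x[0]))
    win = max(int(round(0.08 * fs)), 1)
    env = np.convolve(env, np.ones(win) / win, mode="same")

    refractory = int(round(REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(env, distance=refractory)
    if len(cand) == 0:
        return RPeakSeries(np.array([], dtype=int), fs, warning="no QRS candidates")

    # adaptive threshold: npk/spk are running noise/signal peak estimates
    spk = float(np.percentile(env[cand], 90))
    npk = float(np.percentile(env[cand], 10))
    accepted = []
    for idx in cand:
        thr = npk + 0.3125 * (spk - npk)
        if env[idx] > thr:
            if accepted and idx - accepted[-1] < refractory:
                continue
            accepted.append(idx)
            spk = 0.875 * spk + 0.125 * env[idx]
        else:
            npk = 0.875 * npk + 0.125 * env[idx]
    if not accepted:
        return RPeakSeries(np.array([], dtype=int), fs, warning="no peaks above threshold")

    # back-search the filtered ECG for the true R point near each envelope peak
    back = int(round(0.10 * fs))
    fwd = int(round(0.06 * fs))
    r_idx = []
    for idx in accepted:
        lo, hi = max(idx - back, 0), min(idx + fwd + 1, len(x))
        r_idx.append(lo + int(np.argmax(x[lo:hi])))
    r_idx = np.asarray(sorted(set(r_idx)), dtype=int)
    keep = [0]
    for i in range(1, len(r_idx)):
        if r_idx[i] - r_idx[keep[-1]] >= refractory:
            keep.append(i)
    return RPeakSeries(r_idx[keep], fs)


def nn_intervals(rpeaks: RPeakSeries) -> NNIntervalSeries:
    """Successive R-R differences (ms) with artifact rejection.

    Intervals outside (250, 3000) ms or deviating more than 30% from the
    running median of the last 11 accepted intervals are removed.
    """
    if len(rpeaks) < 3:
        raise InsufficientDataError(f"need >= 3 R-peaks, got {len(rpeaks)}")
    times = rpeaks.times_s
    raw = np.diff(times) * 1000.0
    anchors = times[:-1]

    kept_vals, kept_anchors, window = [], [], []
    for val, anc in zip(raw, anchors):
        if not (NN_MIN_MS < val < NN_MAX_MS):
            continue
        if window:
            med = float(np.median(window))
            if abs(val - med) > NN_MEDIAN_DEVIATION * med:
                continue
        kept_vals.append(val)
        kept_anchors.append(anc)
        window.append(val)
        if len(window) > 11:
            window.pop(0)
    if len(kept_vals) < 2:
        raise InsufficientDataError(
            f"fewer than 2 NN intervals survive artifact rejection ({len(kept_vals)})"
        )
    return NNIntervalSeries(np.asarray(kept_vals), np.asarray(kept_anchors))


# ---------------------------------------------------------------------------
# EDA
# ---------------------------------------------------------------------------

def _lowpass(x: np.ndarray, fs: float, cutoff_hz: float, order: int = 2) -> np.ndarray:
    b, a = sps.butter(order, cutoff_hz, btype="low", fs=fs)
    padlen = min(3 * max(len(a), len(b)), len(x) - 1)
    return sps.filtfilt(b, a, x, padlen=padlen)


def eda_decompose(eda: np.ndarray, fs: float, driver_fs: float = 4.0,
                  alpha: float = 5e-4, min_amp_uS: float = 0.01) -> EdaDecomposition:
    """Tonic/phasic split by sparse nonnegative deconvolution.

    The skin-conductance model is ``y = tonic + K d`` with ``K`` the Bateman
    kernel matrix and ``d`` a sparse nonnegative sudomotor driver on a
    ``driver_fs`` grid.  The tonic level is initialised from a smoothed rolling
    low percentile, the driver is fit with an L1-penalised nonnegative least
    squares (coordinate descent), and SCR events are driver local maxima whose
    resulting conductance deflection exceeds ``min_amp_uS``.

    Falls back to a plain high-/low-pass split (with a warning) if the
    optimisation fails.
    """
    y = np.asarray(eda, dtype=float)
    if len(y) / fs < 30.0:
        raise InsufficientDataError("EDA segment must be at least 30 s long")
    if np.any(y < -1e-9):
        raise InvalidParameterError("EDA must be nonnegative (microsiemens)")
    try:
        return _eda_deconvolve(y, fs, driver_fs, alpha, min_amp_uS)
    except Exception as exc:  # pragma: no cover - defensive fallback
        warnings.warn(f"EDA deconvolution failed ({exc}); falling back to band split")
        tonic = _lowpass(y, fs, 0.05)
        phasic = y - tonic
        return EdaDecomposition(tonic, phasic, [], fs,
                                warning="deconvolution failed; band-split fallback")


def _eda_deconvolve(y, fs, driver_fs, alpha, min_amp_uS) -> EdaDecomposition:
    from sklearn.linear_model import Lasso

    n = len(y)
    t = np.arange(n) / fs
    # deconvolve on a coarse working grid, then interpolate back to fs
    tw = np.arange(0.0, t[-1] + 0.5 / driver_fs, 1.0 / driver_fs)
    yw = np.interp(tw, t, y)
    nw = len(yw)

    # rolling low-percentile tonic initialisation (8 s window)
    win = max(int(8.0 * driver_fs), 3)
    pad = win // 2
    ypad = np.pad(yw, pad, mode="edge")
    base = np.array([np.percentile(ypad[i:i + win], 10) for i in range(nw)])
    tonic0w = _lowpass(base, driver_fs, 0.05)

    resid = yw - tonic0w
    # kernel matrix: column j = Bateman response to a unit driver at tw[j]
    kern = bateman_kernel(np.arange(0.0, 12.0, 1.0 / driver_fs))
    K = np.zeros((nw, nw))
    for j in range(nw):
        hi = min(j + len(kern), nw)
        K[j:hi, j] = kern[:hi - j]

    lasso = Lasso(alpha=alpha, positive=True, fit_intercept=False, max_iter=3000)
    lasso.fit(K, resid)
    d = lasso.coef_.copy()
    # debias: unpenalised nonnegative refit on the selected support
    support = np.flatnonzero(d > 1e-9)
    if len(support):
        from scipy.optimize import nnls
        d_sup, _ = nnls(K[:, support], resid)
        d[:] = 0.0
        d[support] = d_sup
    phasic = np.interp(t, tw, K @ d)
    tonic0 = np.interp(t, tw, tonic0w)
    tonic = tonic0 + _lowpass(y - tonic0 - phasic, fs, 0.05)

    # SCR events: local maxima of the sparse driver (>= 0.5 s apart); the
    # event amplitude is the conductance deflection of the local driver mass
    events = []
    dpad = np.concatenate([[0.0], d, [0.0]])
    pk, _ = sps.find_peaks(dpad, distance=max(int(0.5 * driver_fs), 1))
    half = max(int(0.5 * driver_fs), 1)
    for j in pk - 1:
        lo, hi = max(j - half, 0), min(j + half + 1, nw)
        peak_amp = float(d[lo:hi].sum() * kern.max())
        if peak_amp >= min_amp_uS:
            events.append((float(tw[j]), peak_amp))
    return EdaDecomposition(tonic, phasic, events, fs)


# ---------------------------------------------------------------------------
# Respiration
# ---------------------------------------------------------------------------

def segment_breaths(rsp: np.ndarray, fs: float, min_period_s: float = 1.0,
                    prominence_frac: float = 0.1) -> BreathCycleSet:
    """Trough-to-trough breath segmentation on the detrended, smoothed signal.

    Peaks and troughs are alternating extrema with a minimum spacing of
    ``min_period_s`` and a minimum prominence of ``prominence_frac`` times the
    signal SD.  A cycle is (trough, following peak, next trough).
    """
    x = np.asarray(rsp, dtype=float)
    if len(x) / fs < 10.0:
        raise InsufficientDataError("RSP segment must be at least 10 s long")
    sd = float(np.std(x))
    if sd == 0.0:
        return BreathCycleSet([], warning="constant signal; no breathing cycles")
    smooth = _lowpass(sps.detrend(x), fs, 1.0)
    dist = max(int(min_period_s * fs), 1)
    prom = prominence_frac * sd
    peaks, _ = sps.find_peaks(smooth, distance=dist, prominence=prom)
    # pad so troughs at the very edges of the record are still found
    pad_val = smooth.max() + 10 * sd
    padded = np.concatenate([[pad_val], smooth, [pad_val]])
    troughs, _ = sps.find_peaks(-padded, distance=dist, prominence=prom)
    troughs = np.clip(troughs - 1, 0, len(smooth) - 1)
    if len(peaks) == 0 or len(troughs) < 2:
        return BreathCycleSet([], warning="no breathing cycles found")

    cycles = []
    for i in range(len(troughs) - 1)    :
        s, e = troughs[i], troughs[i + 1]
        inner = peaks[(peaks > s) & (peaks < e)]
        if len(inner) == 0:
            continue
        p = inner[int(np.argmax(smooth[inner]))]
        amp = float(smooth[p] - 0.5 * (smooth[s] + smooth[e]))
        cycles.append((s / fs, p / fs, e / fs, amp))
    if not cycles:
        return BreathCycleSet([], warning="no breathing cycles found")
    return BreathCycleSet(cycles)


# ---------------------------------------------------------------------------
# Baseline compensation
# ---------------------------------------------------------------------------

def baseline_compensate(trial_features, baseline_features, mode: str = "subtract"):
    """Remove per-subject offsets using the neutral baseline recording.

    ``mode``: "off" returns the trial vector unchanged, "subtract" removes the
    baseline value per feature, "divide" scales by it (values with |baseline|
    below 1e-12 are passed through unchanged and flagged).
    """
    from .features import FeatureVector  # local import avoids a cycle

    if list(trial_features.values.keys()) != list(baseline_features.values.keys()):
        raise InvalidParameterError("trial and baseline feature names must match")
    if mode == "off":
        return trial_features
    if mode not in ("subtract", "divide"):
        raise InvalidParameterError(f"unknown compensation mode {mode!r}")
    out, flags = {}, set(trial_features.flags)
    for name, val in trial_features.values.items():
        b = baseline_features.values[name]
        if mode == "subtract":
            out[name] = val - b
        else:
            if abs(b) < 1e-12:
                out[name] = val
                flags.add(f"divide-by-zero-baseline:{name}")
            else:
                out[name] = val / b
    return FeatureVector(values=out, subject_id=trial_features.subject_id,
                         trial_id=trial_features.trial_id, flags=flags)
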