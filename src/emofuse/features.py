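"""The 58-feature vector: 47 ECG/HRV features, 4 EDA features, 7 RSP features.

The HRV set spans three domains:

* time (14): RMSSD, MeanNN, SDNN, SDSD, CVNN, CVSD, MedianNN, MadNN, MCVNN,
  IQRNN, pNN50, pNN20, TINN, HTI;
* frequency (4): HF, VHF, HFn, LnHF (high-frequency band powers of the
  resampled tachogram; low-frequency summaries deliberately omitted);
* non-linear (29): Poincare geometry (SD1, SD2, ...), heart-rate fragmentation
  (PIP, IALS, PSS, PAS), heart-rate asymmetry (Guzik/Porta/area/slope indices
  and the deceleration/acceleration variance partitions), and the regularity
  statistics ApEn and SampEn.

Formula conventions for the ambiguous entries are pinned in each docstring;
degenerate inputs (zero-variance series, empty event sets) map to documented
sentinels rather than exceptions wherever a value can still be defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate as spi
from scipy import signal as sps

from .exceptions import InsufficientDataError, InvalidParameterError
from .preprocess import (BreathCycleSet, EdaDecomposition, NNIntervalSeries,
                         detect_r_peaks, eda_decompose, fir_bandpass,
                         nn_intervals, segment_breaths)

__all__ = [
    "ECG_TIME_FEATURES", "ECG_FREQUENCY_FEATURES", "ECG_NONLINEAR_FEATURES",
    "ECG_FEATURES", "EDA_FEATURES", "RSP_FEATURES", "ALL_FEATURES",
    "feature_domain", "FeatureVector",
    "hrv_time", "hrv_frequency", "hrv_nonlinear",
    "eda_features", "rsp_features", "extract_all", "features_table",
]

# ---------------------------------------------------------------------------
# Registry (closed world: extraction may only emit these names)
# ---------------------------------------------------------------------------

ECG_TIME_FEATURES = (
    "RMSSD", "MeanNN", "SDNN", "SDSD", "CVNN", "CVSD", "MedianNN", "MadNN",
    "MCVNN", "IQRNN", "pNN50", "pNN20", "TINN", "HTI",
)
ECG_FREQUENCY_FEATURES = ("HF", "VHF", "HFn", "LnHF")
ECG_NONLINEAR_FEATURES = (
    "SD1", "SD2", "SD1SD2", "S", "CSI", "CVI", "CSI_Modified",
    "PIP", "IALS", "PSS", "PAS",
    "GI", "SI", "AI", "PI",
    "C1d", "C1a", "SD1d", "SD1a", "C2d", "C2a", "SD2d", "SD2a",
    "Cd", "Ca", "SDNNd", "SDNNa",
    "ApEn", "SampEn",
)
ECG_FEATURES = ECG_TIME_FEATURES + ECG_FREQUENCY_FEATURES + ECG_NONLINEAR_FEATURES
EDA_FEATURES = ("SCR_count_per_min", "SCR_mean_amplitude", "tonic_mean", "phasic_sd")
RSP_FEATURES = (
    "amplitude_mean", "amplitude_max", "amplitude_var",
    "breath_rate_mean", "cycle_duration_mean", "cycle_duration_sd", "amplitude_cv",
)
ALL_FEATURES = ECG_FEATURES + EDA_FEATURES + RSP_FEATURES

assert len(ECG_FEATURES) == 47 and len(ALL_FEATURES) == 58

# sentinel for log of a vanishing band power
LNHF_FLOOR = 1e-12


def feature_domain(name: str) -> str:
    if name in ECG_TIME_FEATURES:
        return "ecg-time"
    if name in ECG_FREQUENCY_FEATURES:
        return "ecg-frequency"
    if name in ECG_NONLINEAR_FEATURES:
        return "ecg-nonlinear"
    if name in EDA_FEATURES:
        return "eda"
    if name in RSP_FEATURES:
        return "rsp"
    raise KeyError(f"{name!r} is not a registered feature")


@dataclass
class FeatureVector:
    """Named 58-element feature vector for one trial.

    ``flags`` records non-fatal problems (sentinel values, failed channels);
    flagged vectors are excluded from model training downstream.
    """

    values: dict
    subject_id: int = -1
    trial_id: int = -1
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = [k for k in self.values if k not in ALL_FEATURES]
        if bad:
            raise InvalidParameterError(f"names outside the feature registry: {bad}")
        for name, v in self.values.items():
            if not np.isfinite(v):
                self.flags.add(f"non-finite:{name}")

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self, names=ALL_FEATURES) -> np.ndarray:
        return np.asarray([self.values[n] for n in names], dtype=float)


# ---------------------------------------------------------------------------
# Time domain
# ---------------------------------------------------------------------------

HIST_BIN_MS = 7.8125  # 1/128 s, the standard NN-histogram bin width


def _nn_array(nn) -> np.ndarray:
    if isinstance(nn, NNIntervalSeries):
        return np.asarray(nn.intervals_ms, dtype=float)
    return np.asarray(nn, dtype=float)


def _tinn_hti(x: np.ndarray) -> tuple[float, float]:
    """Triangular interpolation width (TINN, ms) and HRV triangular index.

    The NN histogram uses 7.8125 ms bins.  TINN fits a triangle with apex at
    the modal bin, scanning all (N, M) bin pairs around it for the least-squares
    best fit; HTI is total count over modal count.
    """
    lo = np.floor(x.min() / HIST_BIN_MS) * HIST_BIN_MS
    hi = np.ceil(x.max() / HIST_BIN_MS) * HIST_BIN_MS + HIST_BIN_MS
    edges = np.arange(lo, hi + HIST_BIN_MS / 2, HIST_BIN_MS)
    h, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    k = int(np.argmax(h))
    hti = float(len(x) / h[k])
    if len(h) == 1:
        return 0.0, hti
    best = (math.inf, 0.0)
    peak = h[k]
    for n_i in range(0, k + 1):
        for m_i in range(k, len(h)):
            if m_i == n_i:
                continue
            tri = np.zeros_like(h, dtype=float)
            left = np.arange(n_i, k + 1)
            if k > n_i:
                tri[left] = peak * (left - n_i) / (k - n_i)
            else:
                tri[k] = peak
            right = np.arange(k, m_i + 1)
            if m_i > k:
                tri[right] = peak * (m_i - right) / (m_i - k)
            tri[k] = peak
            err = float(np.sum((h - tri) ** 2))
            if err < best[0]:
                best = (err, centers[m_i] - centers[n_i])
    return float(best[1]), hti


def hrv_time(nn) -> dict:
    """The 14 time-domain HRV features from an NN series (ms)."""
    x = _nn_array(nn)
    if len(x) < 4:
        raise InsufficientDataError(f"time-domain HRV needs >= 4 intervals, got {len(x)}")
    d = np.diff(x)
    mean_nn = float(np.mean(x))
    sdnn = float(np.std(x, ddof=1))
    rmssd = float(np.sqrt(np.mean(d**2)))
    sdsd = float(np.std(d, ddof=1))
    median_nn = float(np.median(x))
    mad_nn = float(np.median(np.abs(x - median_nn)) * 1.4826)
    q75, q25 = np.percentile(x, [75, 25])
    tinn, hti = _tinn_hti(x)
    return {
        "RMSSD": rmssd,
        "MeanNN": mean_nn,
        "SDNN": sdnn,
        "SDSD": sdsd,
        "CVNN": sdnn / mean_nn,
        "CVSD": rmssd / mean_nn,
        "MedianNN": median_nn,
        "MadNN": mad_nn,
        "MCVNN": mad_nn / median_nn,
        "IQRNN": float(q75 - q25),
        "pNN50": float(100.0 * np.mean(np.abs(d) > 50.0)),
        "pNN20": float(100.0 * np.mean(np.abs(d) > 20.0)),
        "TINN": tinn,
        "HTI": hti,
    }


# ---------------------------------------------------------------------------
# Frequency domain
# ---------------------------------------------------------------------------

HF_BAND = (0.15, 0.40)
VHF_BAND = (0.40, 0.50)
TOTAL_BAND = (0.04, 0.50)
TACHOGRAM_FS = 4.0


def hrv_frequency(nn: NNIntervalSeries) -> dict:
    """HF/VHF band powers (ms^2) of the evenly resampled tachogram.

    The NN series is cubic-interpolated to 4 Hz, mean-removed, and a Welch
    periodogram integrated over HF = [0.15, 0.4] Hz and VHF = [0.4, 0.5] Hz.
    HFn normalises HF by the total power in [0.04, 0.5] Hz; LnHF is ln(HF)
    with the power floored at 1e-12 ms^2 to keep the logarithm finite.
    """
    if not isinstance(nn, NNIntervalSeries):
        nn = NNIntervalSeries(np.asarray(nn, float),
                              np.concatenate([[0.0], np.cumsum(nn)[:-1] / 1000.0]))
    if nn.span_s < 30.0:
        raise InsufficientDataError(
            f"frequency-domain HRV needs >= 30 s of NN data, got {nn.span_s:.1f} s"
        )
    t = nn.t_anchor_s
    x = nn.intervals_ms
    tt = np.arange(t[0], t[-1], 1.0 / TACHOGRAM_FS)
    interp = spi.interp1d(t, x, kind="cubic" if len(x) > 3 else "linear",
                          fill_value="extrapolate")
    xs = interp(tt)
    xs = xs - np.mean(xs)
    nperseg = min(256, len(xs))
    f, pxx = sps.welch(xs, fs=TACHOGRAM_FS, nperseg=nperseg)

    def band_power(lo, hi):
        m = (f >= lo) & (f < hi)
        return float(np.trapezoid(pxx[m], f[m])) if m.sum() > 1 else 0.0

    hf = band_power(*HF_BAND)
    vhf = band_power(*VHF_BAND)
    total = band_power(*TOTAL_BAND)
    hfn = hf / total if total > 0 else 0.0
    return {"HF": hf, "VHF": vhf, "HFn": hfn, "LnHF": float(np.log(max(hf, LNHF_FLOOR)))}


# ---------------------------------------------------------------------------
# Non-linear domain
# ---------------------------------------------------------------------------

def _sign_runs(s: np.ndarray) -> list:
    """Lengths of maximal constant-sign runs of a nonzero-sign sequence."""
    runs, cur = [], 0
    prev = 0
    for v in s:
        if v == 0:
            if cur:
                runs.append(cur)
            cur, prev = 0, 0
            continue
        if v == prev:
            cur += 1
        else:
            if cur:
                runs.append(cur)
            cur, prev = 1, v
    if cur:
        runs.append(cur)
    return runs


def _fragmentation(x: np.ndarray) -> dict:
    """Heart-rate fragmentation (Costa-style) from the NN difference signs.

    PIP: percentage of internal points where the difference changes sign;
    IALS: inverse of the mean acceleration/deceleration segment length;
    PSS: percentage of NN intervals lying in short (< 3) segments;
    PAS: percentage of NN intervals lying in alternation segments of length >= 4.
    Constant series have no sign changes: PIP = PSS = PAS = 0, IALS = 0.
    """
    d = np.diff(x)
    s = np.sign(d)
    n_internal = len(x) - 2
    if n_internal <= 0 or np.all(s == 0):
        return {"PIP": 0.0, "IALS": 0.0, "PSS": 0.0, "PAS": 0.0}
    changes = np.diff(s) != 0
    pip = 100.0 * float(np.sum(changes)) / n_internal

    runs = _sign_runs(s)
    ials = 1.0 / float(np.mean(runs)) if runs else 0.0
    pss = 100.0 * float(sum(r for r in runs if r < 3)) / len(d)

    # alternation segments: maximal stretches of consecutive sign flips
    alt_len, alt_total = 1, 0
    for i in range(1, len(s)):
        if s[i] != 0 and s[i - 1] != 0 and s[i] == -s[i - 1]:
            alt_len += 1
        else:
            if alt_len >= 4:
                alt_total += alt_len
            alt_len = 1
    if alt_len >= 4:
        alt_total += alt_len
    pas = 100.0 * alt_total / len(d)
    return {"PIP": pip, "IALS": ials, "PSS": pss, "PAS": pas}


def _asymmetry(x: np.ndarray) -> dict:
    """Heart-rate asymmetry from the Poincare plot (x_i, x_{i+1}).

    Decelerations are points above the identity line (x_{i+1} > x_i).  GI/SI/AI
    weight each off-diagonal point by its distance, angle, and sector area;
    PI is the percentage of accelerations among off-diagonal points.  The
    short- and long-term variance partitions (SD1d/SD1a, SD2d/SD2a, SDNNd/
    SDNNa) and their normalised contributions (C1d/C1a, C2d/C2a, Cd/Ca) follow
    the standard deceleration/acceleration decomposition of SD1/SD2/SDNN.
    Zero-variance series return 0 for all indices (50/50 shares become 0.5).
    """
    xi, xj = x[:-1], x[1:]
    delta = xj - xi
    n = len(delta)
    dec = delta > 0
    acc = delta < 0
    nz = delta != 0

    out = {}
    dist = np.abs(delta) / math.sqrt(2.0)
    tot_dist = float(np.sum(dist[nz]))
    out["GI"] = 100.0 * float(np.sum(dist[dec])) / tot_dist if tot_dist > 0 else 0.0

    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.abs(np.arctan2(xj, xi) - math.pi / 4.0)
    tot_theta = float(np.sum(theta[nz]))
    out["SI"] = 100.0 * float(np.sum(theta[dec])) / tot_theta if tot_theta > 0 else 0.0

    r2 = xi**2 + xj**2
    sector = 0.5 * r2 * theta
    tot_sector = float(np.sum(sector[nz]))
    out["AI"] = 100.0 * float(np.sum(sector[dec])) / tot_sector if tot_sector > 0 else 0.0

    n_nz = int(np.sum(nz))
    out["PI"] = 100.0 * float(np.sum(acc)) / n_nz if n_nz else 0.0

    # variance partitions
    sd1d = math.sqrt(float(np.sum(delta[dec] ** 2)) / (2.0 * n)) if n else 0.0
    sd1a = math.sqrt(float(np.sum(delta[acc] ** 2)) / (2.0 * n)) if n else 0.0
    sd1i2 = sd1d**2 + sd1a**2
    out["SD1d"], out["SD1a"] = sd1d, sd1a
    out["C1d"] = sd1d**2 / sd1i2 if sd1i2 > 0 else 0.0
    out["C1a"] = sd1a**2 / sd1i2 if sd1i2 > 0 else 0.0

    m = float(np.mean(x))
    along = (xi - m) + (xj - m)  # projection on the identity line
    sd2d = math.sqrt(float(np.sum(along[dec] ** 2) + 0.5 * np.sum(along[~nz] ** 2)) / (2.0 * n)) if n else 0.0
    sd2a = math.sqrt(float(np.sum(along[acc] ** 2) + 0.5 * np.sum(along[~nz] ** 2)) / (2.0 * n)) if n else 0.0
    sd2i2 = sd2d**2 + sd2a**2
    out["SD2d"], out["SD2a"] = sd2d, sd2a
    out["C2d"] = sd2d**2 / sd2i2 if sd2i2 > 0 else 0.0
    out["C2a"] = sd2a**2 / sd2i2 if sd2i2 > 0 else 0.0

    sdnnd = math.sqrt((sd1d**2 + sd2d**2) / 2.0)
    sdnna = math.sqrt((sd1a**2 + sd2a**2) / 2.0)
    tot = sdnnd**2 + sdnna**2
    out["SDNNd"], out["SDNNa"] = sdnnd, sdnna
    out["Cd"] = sdnnd**2 / tot if tot > 0 else 0.0
    out["Ca"] = sdnna**2 / tot if tot > 0 else 0.0
    return out


def _phi_apen(x: np.ndarray, m: int, r: float) -> float:
    n = len(x)
    templ = np.lib.stride_tricks.sliding_window_view(x, m)
    # Chebyshev distances between all template pairs (self-matches included)
    d = np.max(np.abs(templ[:, None, :] - templ[None, :, :]), axis=-1)
    c = np.mean(d <= r, axis=1)
    return float(np.mean(np.log(c)))


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """ApEn(m, r): phi(m) - phi(m+1) with self-matches, Chebyshev distance."""
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * float(np.std(x, ddof=1))
    if len(x) < m + 2:
        raise InsufficientDataError("ApEn needs at least m + 2 samples")
    if r <= 0:
        return 0.0
    return _phi_apen(x, m, r) - _phi_apen(x, m + 1, r)


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r) = -ln(A/B) without self-matches, Chebyshev distance.

    Both template sets use the first N-m windows so that a series whose
    m-matches are always (m+1)-matches (e.g. a constant-increment ramp)
    scores exactly 0.  B = 0 or A = 0 returns the documented sentinel 0.0
    (perfect regularity) and inf respectively.
    """
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * float(np.std(x, ddof=1))
    n = len(x)
    if n < m + 2:
        raise InsufficientDataError("SampEn needs at least m + 2 samples")
    if r <= 0:
        return 0.0

    def count(mm: int) -> int:
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)[: n - m]
        d = np.max(np.abs(templ[:, None, :] - templ[None, :, :]), axis=-1)
        iu = np.triu_indices(len(templ), k=1)
        return int(np.sum(d[iu] <= r))

    b = count(m)
    a = count(m + 1)
    if b == 0:
        return 0.0
    if a == 0:
        return float("inf")
    return float(-math.log(a / b))


def hrv_nonlinear(nn) -> dict:
    """The 29 non-linear HRV features (Poincare, fragmentation, asymmetry, entropy)."""
    x = _nn_array(nn)
    if len(x) < 10:
        raise InsufficientDataError(f"non-linear HRV needs >= 10 intervals, got {len(x)}")
    d = np.diff(x)
    sdnn = float(np.std(x, ddof=1))
    var_d = float(np.var(d, ddof=1))
    sd1 = math.sqrt(var_d / 2.0)
    sd2 = math.sqrt(max(2.0 * sdnn**2 - sd1**2, 0.0))
    out = {
        "SD1": sd1,
        "SD2": sd2,
        "SD1SD2": sd1 / sd2 if sd2 > 0 else 0.0,
        "S": math.pi * sd1 * sd2,
        "CSI": sd2 / sd1 if sd1 > 0 else 0.0,
        # CVI and CSI_Modified use the 4-SD axis convention T = 4*SD1, L = 4*SD2
        "CVI": math.log10(16.0 * sd1 * sd2) if sd1 * sd2 > 0 else 0.0,
        "CSI_Modified": (16.0 * sd2**2) / (4.0 * sd1) if sd1 > 0 else 0.0,
    }
    out.update(_fragmentation(x))
    out.update(_asymmetry(x))
    if sdnn == 0.0:
        out["ApEn"] = 0.0
        out["SampEn"] = 0.0
    else:
        r = 0.2 * sdnn
        out["ApEn"] = approximate_entropy(x, 2, r)
        se = sample_entropy(x, 2, r)
        out["SampEn"] = se if np.isfinite(se) else 10.0  # capped sentinel
    return out


# ---------------------------------------------------------------------------
# EDA and RSP features
# ---------------------------------------------------------------------------

def eda_features(d: EdaDecomposition, duration_s: float) -> dict:
    """SCR rate and amplitude plus tonic level and phasic variability."""
    if duration_s <= 0:
        raise InvalidParameterError("duration_s must be > 0")
    n_ev = len(d.scr_events)
    amps = [a for (_t, a) in d.scr_events]
    return {
        "SCR_count_per_min": 60.0 * n_ev / duration_s,
        "SCR_mean_amplitude": float(np.mean(amps)) if amps else 0.0,
        "tonic_mean": float(np.mean(d.tonic)),
        "phasic_sd": float(np.std(d.phasic)),
    }


def rsp_features(c: BreathCycleSet, duration_s: float) -> tuple[dict, bool]:
    """Breath-cycle amplitude and timing statistics.

    Returns ``(values, ok)``; with an empty cycle set all values are 0 and
    ``ok`` is False so the caller can flag the vector.
    """
    if len(c) == 0:
        return {name: 0.0 for name in RSP_FEATURES}, False
    amps = c.amplitudes
    durs = c.durations_s
    amp_mean = float(np.mean(amps))
    mean_dur = float(np.mean(durs))
    return {
        "amplitude_mean": amp_mean,
        "amplitude_max": float(np.max(amps)),
        "amplitude_var": float(np.var(amps)),
        "breath_rate_mean": 60.0 / mean_dur,
        "cycle_duration_mean": mean_dur,
        "cycle_duration_sd": float(np.std(durs)),
        "amplitude_cv": float(np.std(amps)) / amp_mean if amp_mean != 0 else 0.0,
    }, True


# ---------------------------------------------------------------------------
# Whole-trial extraction
# ---------------------------------------------------------------------------

def extract_all(trial, max_nn_for_entropy: int = 400) -> FeatureVector:
    """Run the full preprocessing chain on one trial and emit the 58 features.

    Channel failures never raise: the affected features are set to 0 and the
    vector is flagged so downstream model fitting can exclude it.
    """
    values = {name: 0.0 for name in ALL_FEATURES}
    flags: set = set()

    try:
        filtered = fir_bandpass(trial.ecg, trial.fs_ecg)
        rpeaks = detect_r_peaks(filtered, trial.fs_ecg)
        nn = nn_intervals(rpeaks)
        values.update(hrv_time(nn))
        try:
            values.update(hrv_frequency(nn))
        except InsufficientDataError:
            flags.add("ecg-frequency-failed")
        x = nn.intervals_ms
        if len(x) > max_nn_for_entropy:
            nn_ent = NNIntervalSeries(x[:max_nn_for_entropy],
                                      nn.t_anchor_s[:max_nn_for_entropy])
        else:
            nn_ent = nn
        values.update(hrv_nonlinear(nn_ent))
    except (InsufficientDataError, InvalidParameterError):
        flags.add("ecg-failed")

    try:
        dec = eda_decompose(trial.eda, trial.fs_eda)
        if dec.warning:
            flags.add("eda-fallback")
        values.update(eda_features(dec, len(trial.eda) / trial.fs_eda))
    except (InsufficientDataError, InvalidParameterError):
        flags.add("eda-failed")

    try:
        cycles = segment_breaths(trial.rsp, trial.fs_rsp)
        rsp_vals, ok = rsp_features(cycles, len(trial.rsp) / trial.fs_rsp)
        values.update(rsp_vals)
        if not ok:
            flags.add("rsp-empty")
    except (InsufficientDataError, InvalidParameterError):
        flags.add("rsp-failed")

    ordered = {name: values[name] for name in ALL_FEATURES}
    return FeatureVector(values=ordered, subject_id=trial.subject_id,
                         trial_id=trial.trial_id, flags=flags)


def features_table(trials, baseline_mode: str = "subtract"):
    """Extract features for a list of trials into a tidy DataFrame.

    Baseline recordings (``is_baseline``) supply the per-subject reference
    vector; their own rows are not included in the output.  Rows whose
    extraction raised flags keep an ``ok = False`` marker.
    """
    import pandas as pd

    from .preprocess import baseline_compensate

    baselines = {}
    trial_vectors = []
    for tr in trials:
        fv = extract_all(tr)
        if tr.is_baseline:
            baselines[tr.subject_id] = fv
        else:
            trial_vectors.append((tr, fv))

    rows = []
    for tr, fv in trial_vectors:
        if baseline_mode != "off" and tr.subject_id in baselines:
            fv = baseline_compensate(fv, baselines[tr.subject_id], mode=baseline_mode)
        row = {
            "subject_id": tr.subject_id, "trial_id": tr.trial_id,
            "arousal": tr.arousal_score, "valence": tr.valence_score,
            "familiarity": tr.familiarity,
            "ok": not any(f.endswith("-failed") or f.startswith("non-finite")
                          for f in fv.flags),
        }
        row.update(fv.values)
        rows.append(row)
    return pd.DataFrame(rows)
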