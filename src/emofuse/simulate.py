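"""Synthetic multi-modal physiological trial generator.

Emulates an affective-computing study in which subjects watch emotion-eliciting
videos while ECG, electrodermal activity (EDA) and respiration (RSP) are recorded,
and rate arousal and valence on a 1-9 scale afterwards.  Each simulated trial
carries exact ground truth (R-peak times, SCR event times, breath-cycle bounds)
so that every downstream detector can be scored against a known answer.

Emotion enters through a linear score-to-parameter mapping: arousal raises mean
heart rate, skin-conductance level and response rate, and breathing rate;
valence perturbs the RR short-term/long-term variability balance and breathing
regularity.  Subject-level Gaussian offsets create between-subject variability,
and a 60-s neutral baseline recording per subject supports baseline compensation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError

__all__ = [
    "SimulationConfig",
    "MultiModalTrial",
    "TrialGroundTruth",
    "simulate_ecg",
    "simulate_eda",
    "simulate_rsp",
    "simulate_trial",
    "simulate_dataset",
    "write_dataset",
    "read_dataset",
]

# AR(1) coefficient of the correlated RR component; fixed so that the
# (SDNN, RMSSD) target pair maps uniquely onto the two variance scales.
_RR_AR1_PHI = 0.9


# ---------------------------------------------------------------------------
# Configuration and containers
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study-level simulation parameters.

    Durations are seconds, rates Hz.  ``arousal_effect`` and ``valence_effect``
    are dimensionless multipliers on the linear score-to-parameter slopes
    (0 switches the emotional modulation off entirely).  ``seed`` fully
    determines the generated dataset.
    """

    n_subjects: int = 20
    trials_per_subject: int = 12
    trial_duration_s: float = 60.0
    baseline_duration_s: float = 60.0
    fs_ecg: float = 250.0
    fs_eda: float = 25.0
    fs_rsp: float = 25.0
    arousal_effect: float = 1.0
    valence_effect: float = 0.5
    noise_sd_ecg: float = 0.03
    noise_sd_eda: float = 0.01
    noise_sd_rsp: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trials_per_subject < 1:
            raise InvalidParameterError("n_subjects and trials_per_subject must be >= 1")
        if not (34.0 <= self.trial_duration_s <= 201.0):
            raise InvalidParameterError(
                f"trial_duration_s must lie in [34, 201] s, got {self.trial_duration_s}"
            )
        if self.baseline_duration_s <= 0:
            raise InvalidParameterError("baseline_duration_s must be > 0")
        for name in ("fs_ecg", "fs_eda", "fs_rsp"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.arousal_effect < 0 or self.valence_effect < 0:
            raise InvalidParameterError("effect sizes must be >= 0")


@dataclass
class TrialGroundTruth:
    """Exact event times (seconds from trial start) known to the simulator."""

    r_times_s: np.ndarray
    scr_times_s: np.ndarray
    breath_bounds_s: np.ndarray

    def to_json_dict(self) -> dict:
        return {
            "r_times_s": np.asarray(self.r_times_s, dtype=float).tolist(),
            "scr_times_s": np.asarray(self.scr_times_s, dtype=float).tolist(),
            "breath_bounds_s": np.asarray(self.breath_bounds_s, dtype=float).tolist(),
        }


@dataclass
class MultiModalTrial:
    """One trial: three synchronously started channels plus self-report scores."""

    subject_id: int
    trial_id: int
    ecg: np.ndarray
    eda: np.ndarray
    rsp: np.ndarray
    fs_ecg: float
    fs_eda: float
    fs_rsp: float
    arousal_score: int
    valence_score: int
    familiarity: int = 0
    is_baseline: bool = False
    ground_truth: TrialGroundTruth | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.arousal_score <= 9) or not (1 <= self.valence_score <= 9):
            raise InvalidParameterError("arousal/valence scores must be integers in 1-9")
        if self.familiarity not in (-1, 0, 1):
            raise InvalidParameterError("familiarity must be one of {-1, 0, 1}")

    @property
    def duration_s(self) -> float:
        return len(self.ecg) / self.fs_ecg


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Channel simulators
# ---------------------------------------------------------------------------

def _rr_tachogram(n_beats: int, mean_rr_s: float, sdnn_target_ms: float,
                  rmssd_target_ms: float, rng: np.random.Generator) -> np.ndarray:
    """RR series (seconds) as white + AR(1) mixture scaled to hit SDNN/RMSSD.

    With white variance c1^2 and an AR(1) component (coefficient phi) of
    variance c2^2, the series variance is c1^2 + c2^2 and the variance of
    successive differences is 2*(c1^2 + (1 - phi) * c2^2).  Solving for the
    targets and clipping to the feasible cone gives the two scales.
    """
    if sdnn_target_ms < 0 or rmssd_target_ms < 0:
        raise InvalidParameterError("sdnn/rmssd targets must be >= 0")
    if sdnn_target_ms > 0 and rmssd_target_ms > 2.0 * sdnn_target_ms * np.sqrt(2.0):
        raise InvalidParameterError(
            "infeasible variability targets: rmssd_target > 2*sdnn_target*sqrt(2)"
        )
    s2 = sdnn_target_ms**2
    c2_sq = np.clip((s2 - rmssd_target_ms**2 / 2.0) / _RR_AR1_PHI, 0.0, s2)
    c1_sq = s2 - c2_sq
    white = rng.normal(0.0, 1.0, n_beats) * np.sqrt(c1_sq)
    # stationary AR(1) with unit marginal variance
    innov = rng.normal(0.0, 1.0, n_beats)
    ar = np.empty(n_beats)
    if n_beats:
        ar[0] = innov[0]
        sig_innov = np.sqrt(1.0 - _RR_AR1_PHI**2)
        for i in range(1, n_beats):
            ar[i] = _RR_AR1_PHI * ar[i - 1] + sig_innov * innov[i]
    rr_ms = mean_rr_s * 1000.0 + white + np.sqrt(c2_sq) * ar
    return np.clip(rr_ms, 300.0, 2500.0) / 1000.0


def _pqrst_template(fs: float) -> tuple[np.ndarray, int]:
    """Gaussian-bump PQRST beat template; returns (template, index of R)."""
    t = np.arange(-0.35, 0.45, 1.0 / fs)
    beat = (
        0.08 * np.exp(-((t + 0.22) ** 2) / (2 * 0.025**2))   # P
        - 0.12 * np.exp(-((t + 0.035) ** 2) / (2 * 0.010**2))  # Q
        + 1.00 * np.exp(-(t**2) / (2 * 0.008**2))              # R
        - 0.18 * np.exp(-((t - 0.035) ** 2) / (2 * 0.012**2))  # S
        + 0.22 * np.exp(-((t - 0.22) ** 2) / (2 * 0.045**2))   # T
    )
    r_idx = int(np.argmin(np.abs(t)))
    return beat, r_idx


def simulate_ecg(duration_s: float, fs: float, mean_hr_bpm: float,
                 sdnn_target_ms: float = 50.0, rmssd_target_ms: float = 35.0,
                 noise_sd: float = 0.03, seed=0,
                 baseline_wander_amp: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a single-lead ECG as a template beat train on a stochastic RR process.

    Returns ``(waveform, true_r_times_s)``; the R times are exact by construction.
    Amplitudes are in mV with a unit R wave.
    """
    if not (30.0 <= mean_hr_bpm <= 200.0):
        raise InvalidParameterError(f"mean_hr_bpm must lie in [30, 200], got {mean_hr_bpm}")
    if duration_s < 10.0:
        raise InvalidParameterError("duration_s must be >= 10 s")
    rng = _as_rng(seed)
    mean_rr = 60.0 / mean_hr_bpm
    n_beats = int(np.ceil(duration_s / mean_rr)) + 10
    rr = _rr_tachogram(n_beats, mean_rr, sdnn_target_ms, rmssd_target_ms, rng)
    r_times = 0.5 * mean_rr + np.concatenate([[0.0], np.cumsum(rr)])
    r_times = r_times[r_times < duration_s]

    n = int(round(duration_s * fs))
    wave = np.zeros(n)
    beat, r_idx = _pqrst_template(fs)
    for rt in r_times:
        start = int(round(rt * fs)) - r_idx
        lo, hi = max(start, 0), min(start + len(beat), n)
        if hi > lo:
            wave[lo:hi] += beat[lo - start:hi - start]
    t = np.arange(n) / fs
    wave += baseline_wander_amp * np.sin(2 * np.pi * 0.15 * t + rng.uniform(0, 2 * np.pi))
    if noise_sd > 0:
        wave += rng.normal(0.0, noise_sd, n)
    return wave, r_times


def bateman_kernel(t: np.ndarray, tau_rise: float = 0.75, tau_decay: float = 2.0) -> np.ndarray:
    """Two-exponential SCR impulse response; peak amplitude < 1 for a unit driver."""
    h = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    return np.where(t >= 0, h, 0.0)


def simulate_eda(duration_s: float, fs: float, tonic_level_uS: float = 2.0,
                 scr_rate_per_min: float = 4.0, scr_amp_uS: float = 0.5,
                 seed=0, noise_sd: float = 0.0,
                 amp_jitter: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Simulate skin conductance: slow tonic drift plus Poisson SCR events.

    Each event contributes ``amp * (exp(-t/2.0) - exp(-t/0.75))`` microsiemens,
    so the per-event peak stays below the driver amplitude.
    """
    if tonic_level_uS < 0:
        raise InvalidParameterError("tonic_level_uS must be >= 0")
    if scr_rate_per_min < 0:
        raise InvalidParameterError("scr_rate_per_min must be >= 0")
    rng = _as_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    drift_phase = rng.uniform(0, 2 * np.pi)
    tonic = tonic_level_uS * (1.0 + 0.02 * np.sin(2 * np.pi * t / max(duration_s, 60.0) + drift_phase))
    wave = tonic.copy()

    n_events = rng.poisson(scr_rate_per_min * duration_s / 60.0)
    event_times = np.sort(rng.uniform(0.0, max(duration_s - 3.0, 0.0), n_events))
    for et in event_times:
        amps = scr_amp_uS
        if amp_jitter > 0:
            amps = scr_amp_uS * rng.lognormal(0.0, amp_jitter)
        tail = t[t >= et] - et
        wave[n - len(tail):] += amps * bateman_kernel(tail)
    if noise_sd > 0:
        wave += rng.normal(0.0, noise_sd, n)
    return wave, event_times


def simulate_rsp(duration_s: float, fs: float, breath_rate_bpm: float = 14.0,
                 amp: float = 1.0, amp_var: float = 0.1, seed=0,
                 period_jitter: float = 0.05,
                 noise_sd: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Simulate respiration as cycle-wise cosine arcs (trough to trough).

    Returns ``(waveform, cycle_bounds_s)`` where the bounds delimit completed
    cycles (``len(bounds) - 1`` cycles).
    """
    if not (4.0 <= breath_rate_bpm <= 60.0):
        raise InvalidParameterError(f"breath_rate_bpm must lie in [4, 60], got {breath_rate_bpm}")
    if amp_var < 0 or period_jitter < 0:
        raise InvalidParameterError("amp_var and period_jitter must be >= 0")
    rng = _as_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    wave = np.zeros(n)
    mean_period = 60.0 / breath_rate_bpm

    bounds = [0.0]
    pos = 0.0
    while pos < duration_s + mean_period:
        period = mean_period * float(np.clip(1.0 + period_jitter * rng.normal(), 0.5, 1.8))
        cyc_amp = amp * float(np.clip(1.0 + amp_var * rng.normal(), 0.2, 2.5))
        mask = (t >= pos) & (t < pos + period)
        wave[mask] = -cyc_amp * np.cos(2 * np.pi * (t[mask] - pos) / period)
        pos += period
        bounds.append(pos)
    complete = [b for b in bounds if b <= duration_s + 0.5 / fs]
    if noise_sd > 0:
        wave += rng.normal(0.0, noise_sd, n)
    return wave, np.asarray(complete)


# ---------------------------------------------------------------------------
# Score -> parameter mapping and trial assembly
# ---------------------------------------------------------------------------

@dataclass
class SubjectProfile:
    """Per-subject additive offsets, drawn once from the dataset seed."""

    hr_offset_bpm: float
    tonic_offset_uS: float
    scr_rate_offset: float
    breath_rate_offset: float

    @classmethod
    def draw(cls, config: SimulationConfig, subject_id: int) -> "SubjectProfile":
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1000 + subject_id]))
        return cls(
            hr_offset_bpm=rng.normal(0.0, 5.0),
            tonic_offset_uS=rng.normal(0.0, 0.4),
            scr_rate_offset=rng.normal(0.0, 0.8),
            breath_rate_offset=rng.normal(0.0, 1.0),
        )


def trial_parameters(config: SimulationConfig, profile: SubjectProfile,
                     arousal_score: int, valence_score: int) -> dict:
    """Linear mapping from (score - 5) to channel parameters.

    Arousal raises mean heart rate, tonic skin conductance, SCR rate and
    breathing rate; valence tilts the RMSSD/SDNN balance (heart-rate-asymmetry
    proxy) and breathing regularity.  Slopes are per score point at effect 1.
    """
    a = (arousal_score - 5) * config.arousal_effect
    v = (valence_score - 5) * config.valence_effect
    return {
        "mean_hr_bpm": float(np.clip(70.0 + 5.0 * a + profile.hr_offset_bpm, 40.0, 180.0)),
        "sdnn_ms": float(np.clip(50.0 * (1.0 - 0.06 * a), 5.0, 150.0)),
        "rmssd_ms": float(np.clip(35.0 * (1.0 - 0.06 * a) * (1.0 + 0.04 * v), 3.0, 120.0)),
        "tonic_uS": float(np.clip(3.0 + 0.3 * a + profile.tonic_offset_uS, 0.05, 20.0)),
        "scr_rate_per_min": float(np.clip(4.0 + 1.5 * a + profile.scr_rate_offset, 0.0, 30.0)),
        "breath_rate_bpm": float(np.clip(14.0 + 1.2 * a + profile.breath_rate_offset, 5.0, 40.0)),
        "rsp_period_jitter": float(np.clip(0.05 * (1.0 - 0.08 * v), 0.005, 0.3)),
    }


def simulate_trial(config: SimulationConfig, subject_id: int, trial_id: int,
                   arousal_score: int, valence_score: int,
                   familiarity: int = 0, is_baseline: bool = False) -> MultiModalTrial:
    """Simulate one trial (or, with ``is_baseline``, a 60-s neutral recording).

    The per-trial random stream is derived from ``(config.seed, subject_id,
    trial_id)`` so the full dataset is reproducible bit-exactly.
    """
    if not (1 <= arousal_score <= 9) or not (1 <= valence_score <= 9):
        raise InvalidParameterError("scores must be in 1-9")
    profile = SubjectProfile.draw(config, subject_id)
    if is_baseline:
        params = trial_parameters(config, profile, 5, 5)
        duration = config.baseline_duration_s
    else:
        params = trial_parameters(config, profile, arousal_score, valence_score)
        duration = config.trial_duration_s

    # trial_id -1 marks the baseline recording; shift so the seed entries stay non-negative
    ss = np.random.SeedSequence([config.seed, subject_id, trial_id + 1, int(is_baseline)])
    s_ecg, s_eda, s_rsp = [np.random.default_rng(c) for c in ss.spawn(3)]

    ecg, r_times = simulate_ecg(
        duration, config.fs_ecg, params["mean_hr_bpm"],
        sdnn_target_ms=params["sdnn_ms"], rmssd_target_ms=params["rmssd_ms"],
        noise_sd=config.noise_sd_ecg, seed=s_ecg,
    )
    eda, scr_times = simulate_eda(
        duration, config.fs_eda, tonic_level_uS=params["tonic_uS"],
        scr_rate_per_min=params["scr_rate_per_min"], scr_amp_uS=0.5,
        seed=s_eda, noise_sd=config.noise_sd_eda, amp_jitter=0.2,
    )
    rsp, bounds = simulate_rsp(
        duration, config.fs_rsp, breath_rate_bpm=params["breath_rate_bpm"],
        amp=1.0, amp_var=0.1, seed=s_rsp,
        period_jitter=params["rsp_period_jitter"], noise_sd=config.noise_sd_rsp,
    )
    return MultiModalTrial(
        subject_id=subject_id, trial_id=trial_id,
        ecg=ecg, eda=eda, rsp=rsp,
        fs_ecg=config.fs_ecg, fs_eda=config.fs_eda, fs_rsp=config.fs_rsp,
        arousal_score=arousal_score, valence_score=valence_score,
        familiarity=familiarity, is_baseline=is_baseline,
        ground_truth=TrialGroundTruth(r_times, scr_times, bounds),
    )


def simulate_dataset(config: SimulationConfig) -> list[MultiModalTrial]:
    """Simulate the full study: per subject, one neutral baseline plus the trials.

    Scores are drawn uniformly from 1-9 (mid-scale binarization therefore yields
    unbalanced classes, as in real self-report data); familiarity uniform on
    {-1, 0, 1}.  Baseline recordings carry ``trial_id = -1``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 77]))
    trials: list[MultiModalTrial] = []
    for subj in range(config.n_subjects):
        trials.append(simulate_trial(config, subj, -1, 5, 5, is_baseline=True))
        for tid in range(config.trials_per_subject):
            arousal = int(rng.integers(1, 10))
            valence = int(rng.integers(1, 10))
            fam = int(rng.integers(-1, 2))
            trials.append(simulate_trial(config, subj, tid, arousal, valence, familiarity=fam))
    return trials


def dataset_manifest(trials: Sequence[MultiModalTrial]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": tr.subject_id,
            "trial_id": tr.trial_id,
            "arousal": tr.arousal_score,
            "valence": tr.valence_score,
            "familiarity": tr.familiarity,
            "is_baseline": int(tr.is_baseline),
        }
        for tr in trials
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# On-disk dataset layout: manifest.csv + per-trial per-channel CSVs + GT JSON
# ---------------------------------------------------------------------------

def _trial_stem(tr: MultiModalTrial) -> str:
    tag = "baseline" if tr.is_baseline else f"trial{tr.trial_id:03d}"
    return f"sub{tr.subject_id:03d}_{tag}"

def write_dataset(trials: Sequence[MultiModalTrial], outdir) -> Path:
    """Write manifest.csv, per-channel `time_s,value` CSVs and ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = dataset_manifest(trials)
    paths = []
    for tr in trials:
        stem = _trial_stem(tr)
        for chan, fs in (("ecg", tr.fs_ecg), ("eda", tr.fs_eda), ("rsp", tr.fs_rsp)):
            sig = getattr(tr, chan)
            t = np.arange(len(sig)) / fs
            df = pd.DataFrame({"time_s": t, "value": sig})
            df.to_csv(outdir / f"{stem}_{chan}.csv", index=False, float_format="%.7g")
        if tr.ground_truth is not None:
            with open(outdir / f"{stem}_truth.json", "w") as fh:
                json.dump(tr.ground_truth.to_json_dict(), fh)
        paths.append(stem)
    manifest["path_stem"] = paths
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return outdir


def read_dataset(indir) -> list[MultiModalTrial]:
    """Load a dataset directory written by :func:`write_dataset`."""
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    trials = []
    for _, row in manifest.iterrows():
        stem = row["path_stem"]
        chans, rates = {}, {}
        for chan in ("ecg", "eda", "rsp"):
            df = pd.read_csv(indir / f"{stem}_{chan}.csv")
            chans[chan] = df["value"].to_numpy()
            tt = df["time_s"].to_numpy()
            rates[chan] = 1.0 / (tt[1] - tt[0]) if len(tt) > 1 else 1.0
        gt = None
        gt_path = indir / f"{stem}_truth.json"
        if gt_path.exists():
            with open(gt_path) as fh:
                d = json.load(fh)
            gt = TrialGroundTruth(
                np.asarray(d["r_times_s"]), np.asarray(d["scr_times_s"]),
                np.asarray(d["breath_bounds_s"]),
            )
        trials.append(MultiModalTrial(
            subject_id=int(row["subject_id"]), trial_id=int(row["trial_id"]),
            ecg=chans["ecg"], eda=chans["eda"], rsp=chans["rsp"],
            fs_ecg=round(rates["ecg"], 6), fs_eda=round(rates["eda"], 6),
            fs_rsp=round(rates["rsp"], 6),
            arousal_score=int(row["arousal"]), valence_score=int(row["valence"]),
            familiarity=int(row["familiarity"]), is_baseline=bool(row["is_baseline"]),
            ground_truth=gt,
        ))
    return trials
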