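"""Study orchestration: simulate -> preprocess/features -> ML baselines and the
five deep-learning schemes -> metrics tables and statistical comparisons.

Arousal and valence are always trained as separate binary problems.  Every
artifact written by :func:`run_study` is stamped with the configuration hash
and the seeds, and every reported mean/sd is recomputable from the stored
subset-level values.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .baselines import (EvalResult, binarize, dummy_classifiers,
                        make_balanced_subsets, paired_t_test, run_ml)
from .exceptions import InvalidParameterError
from .features import features_table
from .nn import (ArchitectureSpec, build_midcnn, build_single_input_dcnn,
                 default_architecture, small_architecture, stacked_input,
                 train, trials_to_inputs)
from .simulate import SimulationConfig, simulate_dataset

__all__ = [
    "ConfusionMatrix", "metrics", "MetricsResult",
    "ExperimentConfig", "run_dcnn_scheme", "run_study",
]

logger = logging.getLogger("emofuse")

DCNN_SCHEMES = ("single-ecg", "single-eda", "single-rsp", "single-stacked", "mi")


@dataclass
class ConfusionMatrix:
    """2x2 counts; rows are actual labels, columns predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2) or np.any(self.counts < 0):
            raise InvalidParameterError("confusion matrix must be 2x2 with counts >= 0")

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / float(self.counts.sum())

    def precision(self, cls: int) -> float:
        col = self.counts[:, cls].sum()
        return float(self.counts[cls, cls]) / col if col else 0.0

    def recall(self, cls: int) -> float:
        row = self.counts[cls].sum()
        return float(self.counts[cls, cls]) / row if row else 0.0


@dataclass
class MetricsResult:
    accuracy: float
    macro_f1: float
    precision: tuple
    recall: tuple
    confusion: ConfusionMatrix
    zero_division_flag: bool = False


def metrics(y_true, y_pred) -> MetricsResult:
    """Accuracy, macro F1 and per-class precision/recall from binary labels.

    Macro F1 is the unweighted mean of the per-class F1 scores; any
    zero-division (a class never predicted or never present) contributes an
    F1 of 0 and raises the flag.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise InvalidParameterError("inputs must be equal-length and non-empty")
    counts = np.zeros((2, 2), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[t, p] += 1
    cm = ConfusionMatrix(counts)
    precs, recs, f1s = [], [], []
    flag = False
    for cls in (0, 1):
        p, r = cm.precision(cls), cm.recall(cls)
        if p + r == 0:
            f1s.append(0.0)
            flag = True
        else:
            f1s.append(2 * p * r / (p + r))
        precs.append(p)
        recs.append(r)
    return MetricsResult(cm.accuracy, float(np.mean(f1s)), tuple(precs), tuple(recs),
                         cm, flag)


# ---------------------------------------------------------------------------
# Deep-learning scheme evaluation
# ---------------------------------------------------------------------------

def _scheme_inputs(trials, scheme: str, spec: ArchitectureSpec):
    if scheme == "mi":
        return trials_to_inputs(trials, spec)
    if scheme == "single-stacked":
        return [stacked_input(trials, spec)]
    if scheme.startswith("single-"):
        mod = scheme.split("-", 1)[1]
        return [stacked_input(trials, spec, modalities=(mod,))]
    raise InvalidParameterError(f"unknown scheme {scheme!r}")


def _scheme_model(scheme: str, spec: ArchitectureSpec, seed: int):
    if scheme == "mi":
        return build_midcnn(spec, seed=seed)
    if scheme == "single-stacked":
        return build_single_input_dcnn(spec, ("ecg", "eda", "rsp"), seed=seed)
    mod = scheme.split("-", 1)[1]
    return build_single_input_dcnn(spec, (mod,), seed=seed)


def run_dcnn_scheme(trials, labels, scheme: str = "mi",
                    spec: ArchitectureSpec | None = None, seed: int = 0,
                    epochs: int = 15, batch_size: int = 8, lr: float = 2e-3,
                    n_subsets: int = 5, n_folds: int = 5, groups=None,
                    collect_predictions: bool = False):
    """Balanced-subset cross-validated evaluation of one deep-learning scheme.

    Mirrors the ML protocol: per balanced subset, a stratified k-fold split
    realises the 80/20 train/test division; a fresh network is trained per
    fold and scored on the held-out fold.  ``groups`` switches to
    subject-disjoint folds (see :func:`emofuse.baselines.run_ml`).  Returns an
    :class:`EvalResult` (and the pooled test predictions when requested).
    """
    from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

    spec = spec or small_architecture()
    y = np.asarray(labels, dtype=int)
    groups = None if groups is None else np.asarray(groups)
    inputs = _scheme_inputs(trials, scheme, spec)
    subsets = make_balanced_subsets(y, n_subsets=n_subsets, seed=seed)
    subset_accs, subset_f1s, fold_accs = [], [], []
    pooled_true, pooled_pred = [], []
    for sub in subsets:
        ys = y[sub.indices]
        xs = [x[sub.indices] for x in inputs]
        if groups is None:
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                  random_state=seed + sub.subset_id)
            splits = skf.split(np.zeros(len(ys)), ys)
        else:
            skf = StratifiedGroupKFold(n_splits=n_folds, shuffle=True,
                                       random_state=seed + sub.subset_id)
            splits = skf.split(np.zeros(len(ys)), ys, groups[sub.indices])
        accs, f1s = [], []
        for fold_i, (tr_idx, te_idx) in enumerate(splits):
            model = _scheme_model(scheme, spec, seed=seed * 1000 + sub.subset_id * 10 + fold_i)
            train(model, [x[tr_idx] for x in xs], ys[tr_idx], epochs=epochs,
                  batch_size=batch_size, lr=lr, seed=seed + fold_i)
            pred = model.predict([x[te_idx] for x in xs])
            m = metrics(ys[te_idx], pred)
            accs.append(m.accuracy)
            f1s.append(m.macro_f1)
            pooled_true.extend(ys[te_idx].tolist())
            pooled_pred.extend(pred.tolist())
        subset_accs.append(float(np.mean(accs)))
        subset_f1s.append(float(np.mean(f1s)))
        fold_accs.append(accs)
    subset_accs = np.asarray(subset_accs)
    subset_f1s = np.asarray(subset_f1s)
    result = EvalResult(
        classifier=f"dcnn-{scheme}", modality="fusion" if "ecg&" not in scheme else scheme,
        accuracy_mean=float(np.mean(subset_accs)), accuracy_sd=float(np.std(subset_accs)),
        f1_mean=float(np.mean(subset_f1s)), f1_sd=float(np.std(subset_f1s)),
        subset_accuracies=subset_accs, subset_f1s=subset_f1s, fold_accuracies=fold_accs,
    )
    if collect_predictions:
        return result, (np.asarray(pooled_true), np.asarray(pooled_pred))
    return result


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Desk-scale study configuration (simulation + evaluation settings)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    tasks: tuple = ("arousal",)
    ml_classifiers: tuple = ("svm", "rfc", "knn")
    ml_modalities: tuple = ("ecg", "eda", "rsp", "fusion")
    dcnn_schemes: tuple = DCNN_SCHEMES
    architecture: str = "small"  # "small" or "default"
    n_subsets: int = 5
    n_folds: int = 5
    epochs: int = 15
    batch_size: int = 8
    seed: int = 0
    baseline_mode: str = "subtract"

    def arch_spec(self) -> ArchitectureSpec:
        return default_architecture() if self.architecture == "default" else small_architecture()

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        for key in ("tasks", "ml_classifiers", "ml_modalities", "dcnn_schemes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(simulation=sim, **raw)


def _plot_confusion(cm: ConfusionMatrix, title: str, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3.2, 3.0))
    ax.imshow(cm.counts, cmap="Blues")
    for i in range(2):
        for j in range(2):
            ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center")
    ax.set_xticks([0, 1], ["pred low", "pred high"])
    ax.set_yticks([0, 1], ["low", "high"])
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_study(config: ExperimentConfig, out_dir) -> dict:
    """Run the full pipeline and write the report bundle.

    Outputs in ``out_dir``: ``baseline_results.csv`` (classifier x modality x
    task), ``dcnn_results.csv`` (the five schemes), per-task confusion-matrix
    CSV + PNG for the multi-input network, ``stats.json`` with the paired
    t-tests (multi-input vs best ML baseline, multi-input vs stacked
    single-input), and ``run_info.json`` with the config hash and seeds.
    Individual stage failures are recorded in a failure manifest instead of
    aborting the whole study.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(filename=out / "study.log", level=logging.INFO,
                        format="%(asctime)s %(levelname)s %(message)s", force=True)
    failures = []
    info = {"config_hash": config.config_hash(), "seed": config.seed,
            "simulation_seed": config.simulation.seed, "config": asdict(config)}

    logger.info("simulating dataset (hash %s)", info["config_hash"])
    trials = simulate_dataset(config.simulation)
    study_trials = [t for t in trials if not t.is_baseline]

    logger.info("extracting features for %d trials", len(study_trials))
    feats = features_table(trials, baseline_mode=config.baseline_mode)
    feats_ok = feats[feats["ok"]].reset_index(drop=True)
    feats_ok.to_csv(out / "features.csv", index=False)
    keep_ids = set(zip(feats_ok["subject_id"], feats_ok["trial_id"]))
    kept_trials = [t for t in study_trials if (t.subject_id, t.trial_id) in keep_ids]

    baseline_rows, dcnn_rows, stats = [], [], {}
    spec = config.arch_spec()
    for task in config.tasks:
        y = binarize(feats_ok[task].to_numpy())
        ml_results = {}
        for clf in config.ml_classifiers:
            for mod in config.ml_modalities:
                try:
                    res = run_ml(feats_ok, y, classifier=clf, modality=mod,
                                 seed=config.seed, n_subsets=config.n_subsets,
                                 n_folds=config.n_folds)
                    ml_results[(clf, mod)] = res
                    baseline_rows.append(_result_row(task, res))
                except Exception as exc:
                    failures.append({"stage": f"ml:{clf}:{mod}:{task}", "error": str(exc)})
                    logger.exception("ML stage failed")
        # dummy classifiers on one balanced subset split 80/20
        try:
            sub = make_balanced_subsets(y, n_subsets=1, seed=config.seed)[0]
            ys = y[sub.indices]
            cut = int(0.8 * len(ys))
            rnd, maj = dummy_classifiers(ys[:cut], ys[cut:], seed=config.seed)
            baseline_rows.append(_result_row(task, rnd))
            baseline_rows.append(_result_row(task, maj))
        except Exception as exc:
            failures.append({"stage": f"dummies:{task}", "error": str(exc)})

        dcnn_results = {}
        for scheme in config.dcnn_schemes:
            try:
                if scheme == "mi":
                    res, (yt, yp) = run_dcnn_scheme(
                        kept_trials, y, scheme=scheme, spec=spec, seed=config.seed,
                        epochs=config.epochs, batch_size=config.batch_size,
                        n_subsets=config.n_subsets, n_folds=config.n_folds,
                        collect_predictions=True)
                    m = metrics(yt, yp)
                    pd.DataFrame(m.confusion.counts,
                                 index=["actual_low", "actual_high"],
                                 columns=["pred_low", "pred_high"]
                                 ).to_csv(out / f"confusion_{task}.csv")
                    _plot_confusion(m.confusion, f"multi-input DCNN ({task})",
                                    out / f"confusion_{task}.png")
                else:
                    res = run_dcnn_scheme(
                        kept_trials, y, scheme=scheme, spec=spec, seed=config.seed,
                        epochs=config.epochs, batch_size=config.batch_size,
                        n_subsets=config.n_subsets, n_folds=config.n_folds)
                dcnn_results[scheme] = res
                dcnn_rows.append(_result_row(task, res))
            except Exception as exc:
                failures.append({"stage": f"dcnn:{scheme}:{task}", "error": str(exc)})
                logger.exception("DCNN stage failed")

        # paired comparisons on matched fold-level values (robust to n_subsets = 1)
        def fold_vec(res):
            return np.concatenate([np.atleast_1d(f) for f in res.fold_accuracies])

        task_stats = {}
        if "mi" in dcnn_results and ml_results:
            best_ml = max(ml_results.values(), key=lambda r: r.accuracy_mean)
            t, p = paired_t_test(fold_vec(dcnn_results["mi"]), fold_vec(best_ml))
            task_stats["mi_vs_best_ml"] = {
                "best_ml": f"{best_ml.classifier}/{best_ml.modality}",
                "t": t, "p": p,
            }
        if "mi" in dcnn_results and "single-stacked" in dcnn_results:
            t, p = paired_t_test(fold_vec(dcnn_results["mi"]),
                                 fold_vec(dcnn_results["single-stacked"]))
            task_stats["mi_vs_stacked"] = {"t": t, "p": p}
        stats[task] = task_stats

    pd.DataFrame(baseline_rows).to_csv(out / "baseline_results.csv", index=False)
    pd.DataFrame(dcnn_rows).to_csv(out / "dcnn_results.csv", index=False)
    with open(out / "stats.json", "w") as fh:
        json.dump(stats, fh, indent=2)
    info["failures"] = failures
    with open(out / "run_info.json", "w") as fh:
        json.dump(info, fh, indent=2, default=str)
    logger.info("study complete: %d failures", len(failures))
    return {"stats": stats, "failures": failures, "out_dir": str(out)}


def _result_row(task: str, res: EvalResult) -> dict:
    return {
        "task": task,
        "classifier": res.classifier,
        "modality": res.modality,
        "accuracy_mean": res.accuracy_mean,
        "accuracy_sd": res.accuracy_sd,
        "f1_mean": res.f1_mean,
        "f1_sd": res.f1_sd,
        "subset_accuracies": ";".join(f"{a:.6f}" for a in np.atleast_1d(res.subset_accuracies)),
    }
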