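"""Metric suite, training-percentage protocol, and pipeline orchestration.

Metrics are computed from micro-pooled confusion counts (TP/TN/FP/FN
summed over classes before the formula is applied):

    accuracy  = (TP+TN) / (TP+TN+FP+FN)
    precision = TP / (TP+FP)
    recall    = TP / (TP+FN)
    F         = 2·precision·recall / (precision+recall)
    MCC       = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    MAE       = mean |y − ŷ| over all (sample, class) pairs, with ŷ the
                predicted probability (hard-label MAE by flag)

Any ratio with a zero denominator is reported as 0 and flagged, never NaN.
Macro averaging is available by flag; micro is the default for the
multi-label case.

The evaluation protocol trains at a configurable list of training
percentages (50–90) with stratified seeded splits and reports the six
metrics per split, plus an everything-selected ablation so the value of
the optimizer-chosen feature subset is visible.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .augment import AugmentPolicy, augment_epoch
from .chwo import ChwoConfig, SelectionMask, chwo_minimize, select_features, woa_minimize
from .enae import EnaeConfig, extract_features, train_enae
from .imstrans import SwinConfig, features_to_grids, imstrans_forward, train_classifier
from .prep import PrepConfig, preprocess
from .synthpack import LabeledDataset, SynthConfig, generate_dataset, read_dataset

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "precision", "recall", "f_measure", "mcc", "mae")
STANDARD_PCTS = (50, 60, 70, 80, 90)


# ---------------------------------------------------------------------------
# confusion counts and metrics


@dataclass
class ConfusionCounts:
    """Micro-pooled totals plus per-class counts."""

    TP: int
    TN: int
    FP: int
    FN: int
    per_class: np.ndarray | None = None  # (C, 4) rows TP, TN, FP, FN

    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f_measure: float
    mcc: float
    mae: float
    split: str = ""
    seed: int = 0
    zero_division_flags: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_NAMES}


def confusion_counts(y_true: np.ndarray, y_pred_binary: np.ndarray) -> ConfusionCounts:
    """Tally decisions; inputs are (N,) or (N, C) binary arrays."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred_binary)
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch between truth and prediction")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("confusion_counts requires binary entries")
    if y_true.ndim == 1:
        y_true = y_true[:, None]
        y_pred = y_pred[:, None]
    per_class = np.stack(
        [
            ((y_true == 1) & (y_pred == 1)).sum(axis=0),
            ((y_true == 0) & (y_pred == 0)).sum(axis=0),
            ((y_true == 0) & (y_pred == 1)).sum(axis=0),
            ((y_true == 1) & (y_pred == 0)).sum(axis=0),
        ],
        axis=1,
    )
    tp, tn, fp, fn = per_class.sum(axis=0)
    return ConfusionCounts(int(tp), int(tn), int(fp), int(fn), per_class)


def _safe_div(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def metrics_from_counts(tp: float, tn: float, fp: float, fn: float,
                        flags: list[str], prefix: str = "") -> tuple[float, float, float, float, float]:
    accuracy = _safe_div(tp + tn, tp + tn + fp + fn, prefix + "accuracy", flags)
    precision = _safe_div(tp, tp + fp, prefix + "precision", flags)
    recall = _safe_div(tp, tp + fn, prefix + "recall", flags)
    f_measure = _safe_div(2 * precision * recall, precision + recall, prefix + "f_measure", flags)
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, prefix + "mcc", flags)
    return accuracy, precision, recall, f_measure, mcc


def compute_metrics(
    counts: ConfusionCounts,
    y_prob: np.ndarray | None = None,
    y_true: np.ndarray | None = None,
    *,
    averaging: str = "micro",
    hard_label_mae: bool = False,
    split: str = "",
    seed: int = 0,
) -> MetricsReport:
    """Evaluate the metric suite on pooled counts (+ probabilities for MAE)."""
    flags: list[str] = []
    if averaging == "micro" or counts.per_class is None:
        acc, prec, rec, f1, mcc = metrics_from_counts(counts.TP, counts.TN, counts.FP, counts.FN, flags)
    elif averaging == "macro":
        rows = [metrics_from_counts(*row, flags, prefix=f"class{i}_") for i, row in enumerate(counts.per_class)]
        acc, prec, rec, f1, mcc = (float(np.mean([r[k] for r in rows])) for k in range(5))
    else:
        raise ValueError("averaging must be 'micro' or 'macro'")
    if y_prob is None or y_true is None:
        flags.append("mae")
        mae = 0.0
    else:
        y_prob = np.asarray(y_prob, dtype=np.float64)
        y_hat = (y_prob >= 0.5).astype(np.float64) if hard_label_mae else y_prob
        mae = float(np.abs(np.asarray(y_true, dtype=np.float64) - y_hat).mean())
    return MetricsReport(acc, prec, rec, f1, mcc, mae, split=split, seed=seed,
                         zero_division_flags=tuple(flags))


# ---------------------------------------------------------------------------
# split protocol


def split_protocol(ds: LabeledDataset, training_pct: float, seed: int) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified (by primary label) seeded split; sizes within ±1 of target."""
    if training_pct not in STANDARD_PCTS:
        warnings.warn(f"training percentage {training_pct} outside the standard grid {STANDARD_PCTS}",
                      stacklevel=2)
    strata = ds.primary_labels()
    values, counts = np.unique(strata, return_counts=True)
    if (counts < 2).any():
        tiny = values[counts < 2]
        raise ValueError(f"cannot stratify: class {tiny.tolist()} has fewer than 2 members")
    idx = np.arange(len(ds))
    train_idx, test_idx = train_test_split(
        idx, train_size=training_pct / 100.0, random_state=seed, stratify=strata
    )

    def subset(indices: np.ndarray) -> LabeledDataset:
        return LabeledDataset(
            [ds.images[i] for i in indices],
            ds.labels[indices],
            [dict(ds.records[i]) for i in indices],
            ds.class_names,
        )

    return subset(np.sort(train_idx)), subset(np.sort(test_idx))


# ---------------------------------------------------------------------------
# end-to-end experiment


@dataclass
class ExperimentConfig:
    """Study conditions for one full pipeline run (all stages, desk scale)."""

    synth: SynthConfig = field(default_factory=lambda: SynthConfig(n_images=300, image_side=32))
    data_dir: str | None = None  # read PNG+CSV instead of generating
    prep: PrepConfig = field(default_factory=lambda: PrepConfig(smoothing_Z=0.8, target_size=16))
    augment: AugmentPolicy = field(default_factory=lambda: AugmentPolicy(max_rotation_deg=15.0))
    augment_train: bool = True
    enae: EnaeConfig = field(default_factory=lambda: EnaeConfig(
        layer_dims=(64, 32), epochs=12, finetune_epochs=12, learning_rate=1e-3))
    selection: ChwoConfig = field(default_factory=lambda: ChwoConfig(pop_size=12, max_iters=15))
    fs_alpha: float = 0.9
    swin: SwinConfig = field(default_factory=lambda: SwinConfig(
        patch_size=1, embed_dim=16, window_P=3, num_heads=2,
        epochs=60, learning_rate=3e-3))
    training_pcts: tuple[int, ...] = (90,)
    seeds: tuple[int, ...] = (0,)
    run_ablation: bool = True
    run_random_mask: bool = False


def _predict(model, grids: np.ndarray, head_mode: str) -> tuple[np.ndarray, np.ndarray]:
    probs = imstrans_forward(model, grids)
    if head_mode == "softmax":
        pred = np.zeros_like(probs, dtype=np.int8)
        pred[np.arange(len(probs)), probs.argmax(axis=1)] = 1
    else:
        pred = (probs >= 0.5).astype(np.int8)
    return probs, pred


def _fit_and_score(F_train, F_test, train_labels, test_labels, mask: SelectionMask,
                   swin_cfg: SwinConfig, split: str, seed: int) -> tuple[MetricsReport, ConfusionCounts, object]:
    cols = mask.indices()
    # per-column standardization with training statistics: latent features
    # land on arbitrary scales and the classifier expects unit-order inputs
    mu = F_train[:, cols].mean(axis=0)
    sd = F_train[:, cols].std(axis=0)
    sd[sd == 0] = 1.0
    grids_train = features_to_grids((F_train[:, cols] - mu) / sd)
    grids_test = features_to_grids((F_test[:, cols] - mu) / sd)
    cfg = replace(swin_cfg, input_side=grids_train.shape[1], patch_size=1,
                  n_classes=train_labels.shape[1], seed=seed)
    y_train = train_labels.argmax(axis=1) if cfg.head_mode == "softmax" else train_labels
    model = train_classifier(grids_train, y_train, cfg,
                             val_inputs=grids_test,
                             val_labels=test_labels.argmax(axis=1) if cfg.head_mode == "softmax" else test_labels)
    probs, pred = _predict(model, grids_test, cfg.head_mode)
    counts = confusion_counts(test_labels, pred)
    report = compute_metrics(counts, probs, test_labels, split=split, seed=seed)
    return report, counts, model


def run_experiment(config: ExperimentConfig, out_dir: str | None = None) -> dict:
    """Full pipeline per (training percentage, seed); JSON/CSV-ready report.

    Stage order: preprocess → augment (train only) → train EnAE on the
    stacked original+augmented rows → extract features → ChWO selection →
    reshape the selected features to a grid → train IMSTrans → metrics on
    the held-out split. An everything-selected ablation (and optionally a
    random equal-size mask) is scored for comparison.
    """
    if config.data_dir is not None:
        ds = read_dataset(config.data_dir)
    else:
        ds = generate_dataset(config.synth)
    report: dict = {"per_run": [], "config_seeds": list(config.seeds)}
    for pct in config.training_pcts:
        for seed in config.seeds:
            logger.info("experiment: pct=%s seed=%s", pct, seed)
            train_ds, test_ds = split_protocol(ds, pct, seed)
            prep_rng = np.random.default_rng(seed)
            X_train = np.stack([preprocess(im, config.prep, prep_rng).values for im in train_ds.images])
            X_test = np.stack([preprocess(im, config.prep, prep_rng).values for im in test_ds.images])

            enae_rows = X_train.reshape(len(X_train), -1)
            if config.augment_train:
                policy = replace(config.augment, seed=seed)
                aug = augment_epoch(train_ds, policy, epoch=0)
                X_aug = np.stack([preprocess(im, config.prep, prep_rng).values for im in aug.images])
                enae_rows = np.concatenate([enae_rows, X_aug.reshape(len(X_aug), -1)])

            enae_cfg = replace(config.enae, seed=seed)
            enae_model = train_enae(enae_rows, enae_cfg)
            F_train = extract_features(enae_model, X_train.reshape(len(X_train), -1))
            F_test = extract_features(enae_model, X_test.reshape(len(X_test), -1))

            sel_cfg = replace(config.selection, seed=seed)
            mask = select_features(F_train, train_ds.labels, sel_cfg, fs_alpha=config.fs_alpha)

            split_tag = f"{pct}pct"
            metrics, counts, model = _fit_and_score(
                F_train, F_test, train_ds.labels, test_ds.labels, mask, config.swin, split_tag, seed
            )
            run = {
                "pct": pct,
                "seed": seed,
                "mask_size": mask.selected_count,
                "n_features": F_train.shape[1],
                "metrics": metrics.as_dict(),
                "confusion_per_class": counts.per_class.tolist(),
                "enae_loss_first": enae_model.loss_history[0],
                "enae_loss_final": enae_model.loss_history[-1],
                "classifier_history": model.history,
            }
            if config.run_ablation:
                all_mask = SelectionMask(np.ones(F_train.shape[1], dtype=np.int8))
                abl, _, _ = _fit_and_score(
                    F_train, F_test, train_ds.labels, test_ds.labels, all_mask, config.swin, split_tag, seed
                )
                run["ablation_metrics"] = abl.as_dict()
            if config.run_random_mask:
                rng = np.random.default_rng(seed + 7919)
                rand = np.zeros(F_train.shape[1], dtype=np.int8)
                rand[rng.choice(F_train.shape[1], size=max(1, mask.selected_count), replace=False)] = 1
                rnd, _, _ = _fit_and_score(
                    F_train, F_test, train_ds.labels, test_ds.labels, SelectionMask(rand),
                    config.swin, split_tag, seed
                )
                run["random_mask_metrics"] = rnd.as_dict()
            report["per_run"].append(run)

    report["table"] = summarize_table(report["per_run"])
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "experiment_report.json").write_text(json.dumps(report, indent=2))
        pd.DataFrame(report["table"]).to_csv(out / "metrics_table.csv")
    return report


def summarize_table(per_run: list[dict]) -> dict:
    """Metric rows × training-percentage columns (mean over seeds)."""
    table: dict[str, dict[str, float]] = {m: {} for m in METRIC_NAMES}
    pcts = sorted({r["pct"] for r in per_run})
    for pct in pcts:
        runs = [r for r in per_run if r["pct"] == pct]
        for m in METRIC_NAMES:
            table[m][str(pct)] = float(np.mean([r["metrics"][m] for r in runs]))
    return table


# ---------------------------------------------------------------------------
# optimizer convergence reporting


def default_benchmarks() -> dict:
    return {
        "sphere": {"fn": lambda x: float(np.sum(x**2)), "dim": 5, "bounds": (-1.0, 1.0)},
        "rastrigin": {
            "fn": lambda x: float(10 * len(x) + np.sum(x**2 - 10 * np.cos(2 * np.pi * x))),
            "dim": 5,
            "bounds": (-5.12, 5.12),
        },
    }


def convergence_report(
    objectives: dict | None = None,
    cfg: ChwoConfig | None = None,
    seeds: tuple[int, ...] = tuple(range(10)),
) -> pd.DataFrame:
    """Best-fitness-vs-iteration curves for ChWO and vanilla WOA, paired seeds."""
    objectives = objectives or default_benchmarks()
    cfg = cfg or ChwoConfig(pop_size=20, max_iters=100)
    rows = []
    for name, spec in objectives.items():
        for seed in seeds:
            run_cfg = replace(cfg, seed=seed, bounds=spec["bounds"])
            for algo, minimize in (("chwo", chwo_minimize), ("woa", woa_minimize)):
                _, _, history = minimize(spec["fn"], spec["dim"], run_cfg)
                rows.extend(
                    {"objective": name, "algorithm": algo, "seed": seed,
                     "iteration": i, "best_fitness": f}
                    for i, f in enumerate(history)
                )
    return pd.DataFrame(rows)


def final_fitness_summary(curves: pd.DataFrame) -> pd.DataFrame:
    """Median final best fitness per (objective, algorithm)."""
    last = curves.loc[curves.groupby(["objective", "algorithm", "seed"])["iteration"].idxmax()]
    return last.groupby(["objective", "algorithm"])["best_fitness"].median().reset_index()
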