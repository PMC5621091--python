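"""End-to-end pipeline wiring and evaluation metrics.

The pipeline mirrors how the recognition system runs on a device: window the
sensor stream, extract per-window features, classify each window with the
hierarchical SVM, correct the label sequence with the context smoother, and
score raw vs corrected predictions.  "Average accuracy" throughout is the
unweighted macro mean of per-class accuracies (per-class recall), so every
activity counts equally regardless of how long it was performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParameterError, PipelineStageError
from .features import feature_table
from .hsvm import DEFAULT_FEATURE_COSTS, HierarchicalSVMClassifier
from .signals import SensorStream, decimate, segment_windows
from .smoother import smooth_sequence
from .synth import SyntheticConfig, default_config, generate_session, generate_training_set

__all__ = [
    "ConfusionMatrix",
    "PipelineConfig",
    "PipelineReport",
    "evaluate",
    "run_pipeline",
    "run_synthetic_pipeline",
    "rate_sweep",
    "make_test_stream",
]


@dataclass
class ConfusionMatrix:
    """Integer count matrix: rows = truth, columns = prediction."""

    classes: tuple
    counts: np.ndarray

    @classmethod
    def from_labels(cls, truth, predicted, classes=None) -> "ConfusionMatrix":
        truth = list(truth)
        predicted = list(predicted)
        if len(truth) != len(predicted):
            raise ParameterError(
                f"truth ({len(truth)}) and predicted ({len(predicted)}) lengths differ"
            )
        if classes is None:
            classes = tuple(sorted(set(truth) | set(predicted)))
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(truth, predicted):
            counts[index[t], index[p]] += 1
        return cls(classes=tuple(classes), counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def per_class_accuracy(self) -> dict:
        """Diagonal over row sum — per-class recall."""
        out = {}
        for i, c in enumerate(self.classes):
            row = self.counts[i].sum()
            out[c] = float(self.counts[i, i] / row) if row else float("nan")
        return out

    @property
    def macro_accuracy(self) -> float:
        accs = [a for a in self.per_class_accuracy().values() if not np.isnan(a)]
        return float(np.mean(accs)) if accs else float("nan")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def evaluate(truth, predicted, classes=None) -> ConfusionMatrix:
    """Confusion matrix + accuracies for a truth/prediction label pair."""
    return ConfusionMatrix.from_labels(truth, predicted, classes=classes)


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of the full recognition pipeline."""

    rate_hz: float = 1.0
    window_s: float = 5.0
    overlap_s: float = 0.0
    k: int = 1
    purity_threshold: float = 0.95
    svm_c: float = 1.0
    seed: int = 0
    windows_per_class: int = 15
    feature_costs: tuple = DEFAULT_FEATURE_COSTS

    def __post_init__(self) -> None:
        if self.window_s <= self.overlap_s or self.overlap_s < 0:
            raise ParameterError("need window_s > overlap_s >= 0")
        if self.k < 0:
            raise ParameterError("k must be >= 0")


@dataclass
class PipelineReport:
    """Raw and smoothed evaluation of one train/test run."""

    config: PipelineConfig
    raw_cm: ConfusionMatrix
    smoothed_cm: ConfusionMatrix
    truth: list = field(repr=False)
    raw_predictions: list = field(repr=False)
    smoothed_predictions: list = field(repr=False)
    n_nodes: int = 0
    tree_json: str = field(default="", repr=False)

    @property
    def raw_macro_accuracy(self) -> float:
        return self.raw_cm.macro_accuracy

    @property
    def smoothed_macro_accuracy(self) -> float:
        return self.smoothed_cm.macro_accuracy

    def improvement(self) -> dict:
        """Per-class and average accuracy gain of smoothing over raw output."""
        raw = self.raw_cm.per_class_accuracy()
        smo = self.smoothed_cm.per_class_accuracy()
        out = {c: smo[c] - raw[c] for c in self.raw_cm.classes}
        out["average"] = self.smoothed_macro_accuracy - self.raw_macro_accuracy
        return out

    def to_json(self) -> str:
        payload = {
            "config": {
                "rate_hz": self.config.rate_hz,
                "window_s": self.config.window_s,
                "overlap_s": self.config.overlap_s,
                "k": self.config.k,
                "purity_threshold": self.config.purity_threshold,
                "svm_c": self.config.svm_c,
                "seed": self.config.seed,
                "windows_per_class": self.config.windows_per_class,
            },
            "n_nodes": self.n_nodes,
            "n_windows": self.raw_cm.total,
            "raw": {
                "per_class_accuracy": self.raw_cm.per_class_accuracy(),
                "macro_accuracy": self.raw_macro_accuracy,
                "confusion": self.raw_cm.counts.tolist(),
            },
            "smoothed": {
                "per_class_accuracy": self.smoothed_cm.per_class_accuracy(),
                "macro_accuracy": self.smoothed_macro_accuracy,
                "confusion": self.smoothed_cm.counts.tolist(),
            },
            "improvement": self.improvement(),
            "classes": list(self.raw_cm.classes),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineStageError(f"stage '{name}' failed: {exc}") from exc

    return wrap


def run_pipeline(
    config: PipelineConfig,
    train_stream: SensorStream,
    test_stream: SensorStream,
) -> PipelineReport:
    """window -> features -> train tree -> classify -> smooth -> evaluate.

    Both streams are windowed per contiguous activity segment with the first
    and last window of each segment dropped, mirroring how labelled sessions
    are collected (boundary windows mix activities).  The training stream
    must carry labels.
    """
    if train_stream.labels is None:
        raise ParameterError("training stream must carry per-sample labels")
    train_windows = _stage("windowing")(
        segment_windows, train_stream, config.window_s, config.overlap_s
    )
    test_windows = _stage("windowing")(
        segment_windows, test_stream, config.window_s, config.overlap_s
    )
    train_tab = _stage("feature extraction")(feature_table, train_windows)
    test_tab = _stage("feature extraction")(feature_table, test_windows)
    return _fit_and_score(config, train_tab, test_tab)


def _fit_and_score(
    config: PipelineConfig, train_tab: pd.DataFrame, test_tab: pd.DataFrame
) -> PipelineReport:
    feature_cols = [c for c in train_tab.columns if c not in ("t_start", "label")]
    model = HierarchicalSVMClassifier(
        feature_costs=config.feature_costs,
        purity_threshold=config.purity_threshold,
        C=config.svm_c,
        random_state=config.seed,
    )
    _stage("training")(model.fit, train_tab[feature_cols], train_tab["label"])
    raw = list(_stage("classification")(model.predict, test_tab[feature_cols]))
    smoothed = _stage("smoothing")(smooth_sequence, raw, config.k)
    truth = list(test_tab["label"])
    classes = tuple(model.classes_)
    return PipelineReport(
        config=config,
        raw_cm=evaluate(truth, raw, classes=classes),
        smoothed_cm=evaluate(truth, smoothed, classes=classes),
        truth=truth,
        raw_predictions=raw,
        smoothed_predictions=smoothed,
        n_nodes=model.n_nodes_,
        tree_json=model.to_json(),
    )


def make_test_stream(
    synth_config: SyntheticConfig | None = None,
    seconds_per_activity: float = 300.0,
    seed: int = 1,
    rate_hz: float = 1.0,
) -> SensorStream:
    """One continuous session visiting every activity once, for testing."""
    if synth_config is None:
        synth_config = default_config(rate_hz=rate_hz, seed=seed)
    schedule = tuple((name, seconds_per_activity) for name in synth_config.activities)
    return generate_session(replace(synth_config, schedule=schedule, seed=seed, rate_hz=rate_hz))


def run_synthetic_pipeline(
    config: PipelineConfig,
    seconds_per_activity: float = 300.0,
) -> PipelineReport:
    """Full pipeline on generated data: balanced training set + one session.

    Training uses ``windows_per_class`` windows per activity (the 90-window
    default); testing uses one continuous session with every activity
    performed for ``seconds_per_activity``.  Seeds derive from the pipeline
    seed, so the whole report is reproducible.
    """
    synth_cfg = default_config(rate_hz=config.rate_hz, seed=config.seed)
    train_windows = generate_training_set(
        synth_cfg, windows_per_class=config.windows_per_class, window_s=config.window_s
    )
    test_stream = make_test_stream(
        synth_cfg,
        seconds_per_activity=seconds_per_activity,
        seed=config.seed + 1,
        rate_hz=config.rate_hz,
    )
    test_windows = segment_windows(test_stream, config.window_s, config.overlap_s)
    return _fit_and_score(config, feature_table(train_windows), feature_table(test_windows))


def rate_sweep(
    config: PipelineConfig,
    rates=(1.0, 5.0, 10.0, 50.0),
    base_rate_hz: float = 50.0,
    seconds_per_activity: float = 300.0,
) -> dict[float, PipelineReport]:
    """Train and evaluate at several sampling rates decimated from one recording.

    One training recording and one test session are generated at
    ``base_rate_hz``; each target rate sees exactly the samples a sensor
    polled at that rate would have recorded (pure point decimation).  Window
    length is held fixed, so lower rates simply carry fewer samples per
    window.
    """
    synth_cfg = default_config(rate_hz=base_rate_hz, seed=config.seed)
    train_schedule = tuple(
        (name, (config.windows_per_class + 2) * config.window_s)
        for name in synth_cfg.activities
    )
    train_stream = generate_session(
        replace(synth_cfg, schedule=train_schedule, seed=config.seed)
    )
    test_stream = make_test_stream(
        synth_cfg,
        seconds_per_activity=seconds_per_activity,
        seed=config.seed + 1,
        rate_hz=base_rate_hz,
    )
    reports = {}
    for rate in rates:
        sub_cfg = replace(config, rate_hz=rate)
        reports[rate] = run_pipeline(
            sub_cfg, decimate(train_stream, rate), decimate(test_stream, rate)
        )
    return reports
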