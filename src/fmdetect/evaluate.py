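"""Evaluation protocol: confusion matrices, metric averaging, experiments.

Metrics treat movement as the positive class:

    precision = TP / (TP + FP)        recall = TP / (TP + FN)
    F1 = 2 P R / (P + R)              specificity = TN / (TN + FP)

Aggregation follows the study protocol: for model input 1 the six
per-sensor confusion matrices of a scan are averaged element-wise into
per-scan counts; for model inputs 2 and 3 each scan yields a single
matrix.  Per-scan counts are then averaged element-wise across scans and
precision/recall are computed from the averaged counts, with F1 taken as
the harmonic mean of that precision and recall.

The train/test split is chronological within each scan (first 70% of
windows train): STFT windows overlap in time, so a random split would leak
test information into training.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .features import (SpectralConfig, compute_stft, fuse_concatenated, fuse_individual,
                       fuse_summed, label_windows, WindowedDataset)
from .models import (BoostConfig, DecisionTree, KnnConfig, KNNClassifier, RusConfig,
                     AdaBoostClassifier, RUSBoostClassifier, TreeConfig)
from .preprocess import FilterConfig, NoiseCancelConfig, preprocess_pipeline
from .synthgen import AnnotationTrack, Recording

logger = logging.getLogger(__name__)

CLASSIFIERS = ("knn", "tree", "adaboost", "rusboost")


# ---------------------------------------------------------------------------
# confusion counts and metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    """TP/TN/FP/FN; fractional values arise from averaging."""

    tp: float = 0.0
    tn: float = 0.0
    fp: float = 0.0
    fn: float = 0.0

    @property
    def total(self) -> float:
        return self.tp + self.tn + self.fp + self.fn

    def scaled(self, factor: float) -> "ConfusionCounts":
        return ConfusionCounts(self.tp * factor, self.tn * factor,
                               self.fp * factor, self.fn * factor)


@dataclass
class MetricsReport:
    """Derived metrics; ``None`` flags an undefined (0/0) quantity."""

    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    specificity: float | None = None
    accuracy: float | None = None
    counts: ConfusionCounts | None = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("precision", "recall", "f1", "specificity", "accuracy")}


def confusion(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    return ConfusionCounts(
        tp=float(np.sum((y_true == 1) & (y_pred == 1))),
        tn=float(np.sum((y_true == 0) & (y_pred == 0))),
        fp=float(np.sum((y_true == 0) & (y_pred == 1))),
        fn=float(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: float, den: float, name: str) -> float | None:
    if den == 0:
        logger.info("%s undefined (zero denominator); flagged as None", name)
        return None
    return num / den


def f1_score(precision: float | None, recall: float | None) -> float | None:
    """Harmonic mean of precision and recall; None when either is undefined."""
    if precision is None or recall is None:
        return None
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def metrics(counts: ConfusionCounts) -> MetricsReport:
    if counts.total <= 0:
        raise ValueError("confusion counts sum to zero; no metrics to compute")
    p = _ratio(counts.tp, counts.tp + counts.fp, "precision")
    r = _ratio(counts.tp, counts.tp + counts.fn, "recall")
    return MetricsReport(
        precision=p,
        recall=r,
        f1=f1_score(p, r),
        specificity=_ratio(counts.tn, counts.tn + counts.fp, "specificity"),
        accuracy=(counts.tp + counts.tn) / counts.total,
        counts=counts,
    )


def mean_counts(items: Sequence[ConfusionCounts]) -> ConfusionCounts:
    if not items:
        raise ValueError("cannot average an empty list of confusion counts")
    n = len(items)
    return ConfusionCounts(
        tp=sum(c.tp for c in items) / n,
        tn=sum(c.tn for c in items) / n,
        fp=sum(c.fp for c in items) / n,
        fn=sum(c.fn for c in items) / n,
    )


def aggregate_model1(per_scan_sensor_counts: Sequence[Sequence[ConfusionCounts]]) -> MetricsReport:
    """Average over sensors within each scan, then over scans; metrics at the end."""
    if not per_scan_sensor_counts:
        raise ValueError("no scans to aggregate")
    per_scan = [mean_counts(list(sensor_counts)) for sensor_counts in per_scan_sensor_counts]
    return metrics(mean_counts(per_scan))


def aggregate_model23(per_scan_counts: Sequence[ConfusionCounts]) -> MetricsReport:
    """Average the single per-scan matrices over scans; metrics from the mean."""
    if not per_scan_counts:
        raise ValueError("no scans to aggregate")
    return metrics(mean_counts(list(per_scan_counts)))


# ---------------------------------------------------------------------------
# experiment protocol
# ---------------------------------------------------------------------------

def split_train_test(dataset: WindowedDataset, fraction: float = 0.7,
                     seed: int | None = None) -> tuple[WindowedDataset, WindowedDataset]:
    """Chronological split: the first ceil(fraction*n) windows train.

    ``seed`` is accepted for interface compatibility but unused — the split
    is deterministic because temporally overlapping windows would leak
    across a random split.  Clamped so at least one window lands on each side.
    """
    n = dataset.n_windows
    if n < 2:
        raise ValueError("need at least 2 windows to split")
    if not 0.0 < fraction < 1.0:
        raise ConfigurationError("train fraction must lie in (0, 1)")
    n_train = min(max(int(math.ceil(fraction * n)), 1), n - 1)

    def take(sl: slice) -> WindowedDataset:
        return WindowedDataset(X=dataset.X[sl], y=dataset.y[sl],
                               window_starts_s=dataset.window_starts_s[sl],
                               scan_id=dataset.scan_id, fusion=dataset.fusion,
                               sensor_id=dataset.sensor_id)

    return take(slice(0, n_train)), take(slice(n_train, n))


@dataclass
class ExperimentConfig:
    """One experiment cell: model input x classifier plus stage configs."""

    train_fraction: float = 0.7
    model_input: int = 2  # 1 individual | 2 concatenated | 3 summed
    classifier: str = "rusboost"
    classifier_params: dict = field(default_factory=dict)
    noise_cfg: NoiseCancelConfig = field(default_factory=NoiseCancelConfig)
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)
    spectral_cfg: SpectralConfig = field(default_factory=SpectralConfig)
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must lie in (0, 1)")
        if self.model_input not in (1, 2, 3):
            raise ConfigurationError("model_input must be 1, 2 or 3")
        if self.classifier not in CLASSIFIERS:
            raise ConfigurationError(f"classifier must be one of {CLASSIFIERS}")


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2 ** 31))


def make_classifier(name: str, seed: int = 0, params: dict | None = None):
    """Build a classifier honouring the shared fit/predict contract."""
    params = dict(params or {})
    weak_depth = params.pop("weak_learner_depth", 1)
    if name == "knn":
        return KNNClassifier(KnnConfig(**params))
    if name == "tree":
        return DecisionTree(TreeConfig(**params))
    if name == "adaboost":
        return AdaBoostClassifier(BoostConfig(weak_learner=TreeConfig(max_depth=weak_depth),
                                              seed=seed, **params))
    if name == "rusboost":
        ratio = params.pop("target_majority_ratio", 1.0)
        base = BoostConfig(weak_learner=TreeConfig(max_depth=weak_depth), seed=seed, **params)
        return RUSBoostClassifier(RusConfig(base=base, target_majority_ratio=ratio))
    raise ConfigurationError(f"unknown classifier {name!r}")


@dataclass
class ExperimentResult:
    """Aggregated report plus the per-scan confusion table."""

    report: MetricsReport
    per_scan: pd.DataFrame
    config: ExperimentConfig
    skipped_scans: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"model input {self.config.model_input} / {self.config.classifier} "
            f"on {len(self.per_scan)} scan(s)",
        ]
        for key, value in self.report.as_dict().items():
            lines.append(f"  {key:>12}: " + ("undefined" if value is None else f"{value:.3f}"))
        if self.skipped_scans:
            lines.append(f"  skipped scans: {', '.join(self.skipped_scans)}")
        return "\n".join(lines)


def _scan_counts(recording: Recording, track: AnnotationTrack, config: ExperimentConfig,
                 scan_index: int) -> tuple[list[ConfusionCounts], int]:
    """Run the full per-scan pipeline; returns per-sensor or single-matrix counts."""
    rec, trk = preprocess_pipeline(recording, track, config.noise_cfg, config.filter_cfg)
    spectral = replace(config.spectral_cfg, fs=rec.fs)
    spectrograms = [compute_stft(rec.sensors[ch], spectral, channel_id=name)
                    for ch, name in enumerate(rec.channel_names)]
    y = label_windows(spectrograms[0].window_starts_s, spectral, trk)
    scan_id = recording.scan_id or f"scan{scan_index}"
    counts: list[ConfusionCounts] = []
    if config.model_input == 1:
        datasets = fuse_individual(spectrograms, y, scan_id)
    elif config.model_input == 2:
        datasets = [fuse_concatenated(spectrograms, y, scan_id)]
    else:
        datasets = [fuse_summed(spectrograms, y, scan_id)]
    for k, ds in enumerate(datasets):
        train, test = split_train_test(ds, config.train_fraction)
        if np.unique(train.y).size < 2:
            # untrainable scan portion: predict the only class seen in training
            only = int(train.y[0]) if train.y.size else 0
            logger.warning("scan %s: single-class training windows; predicting class %d",
                           scan_id, only)
            pred = np.full(test.y.shape, only, dtype=int)
        else:
            clf = make_classifier(config.classifier, _derive_seed(config.seed, scan_index, k),
                                  config.classifier_params)
            clf.fit(train.X, train.y)
            pred = clf.predict(test.X)
        counts.append(confusion(test.y, pred))
    return counts, len(trk.events)


def run_experiment(scans: Sequence[tuple[Recording, AnnotationTrack]],
                   config: ExperimentConfig | None = None,
                   skip_errors: bool = False) -> ExperimentResult:
    """Full protocol over a set of scans for one (model input, classifier) cell.

    Per scan: preprocess -> per-sensor STFT -> fusion -> chronological 70/30
    split -> fit -> predict -> confusion matrix; then the model-input-specific
    averaging.  With ``skip_errors`` a failing scan is logged and skipped.
    """
    config = config or ExperimentConfig()
    config.validate()
    if not scans:
        raise ValueError("no scans given")
    per_scan_counts: list[list[ConfusionCounts]] = []
    rows = []
    skipped: list[str] = []
    for s, (recording, track) in enumerate(scans):
        scan_id = recording.scan_id or f"scan{s}"
        try:
            counts, n_events = _scan_counts(recording, track, config, s)
        except Exception as exc:  # noqa: BLE001 - per-scan isolation is the contract
            if not skip_errors:
                raise
            logger.warning("skipping scan %s: %s", scan_id, exc)
            skipped.append(scan_id)
            continue
        per_scan_counts.append(counts)
        scan_mean = mean_counts(counts)
        p = _ratio(scan_mean.tp, scan_mean.tp + scan_mean.fp, f"{scan_id} precision")
        r = _ratio(scan_mean.tp, scan_mean.tp + scan_mean.fn, f"{scan_id} recall")
        rows.append({"scan_id": scan_id, "n_udfm": n_events,
                     "tp": scan_mean.tp, "tn": scan_mean.tn,
                     "fp": scan_mean.fp, "fn": scan_mean.fn,
                     "precision": p, "recall": r, "f1": f1_score(p, r)})
    if not per_scan_counts:
        raise ValueError("all scans failed; nothing to aggregate")
    if config.model_input == 1:
        report = aggregate_model1(per_scan_counts)
    else:
        report = aggregate_model23([c[0] for c in per_scan_counts])
    return ExperimentResult(report=report, per_scan=pd.DataFrame(rows),
                            config=config, skipped_scans=skipped)


# ---------------------------------------------------------------------------
# searches
# ---------------------------------------------------------------------------

def imu_threshold_search(scans: Sequence[tuple[Recording, AnnotationTrack]],
                         thresholds: Iterable[float] = (4.0, 5.0, 6.0),
                         config: ExperimentConfig | None = None,
                         ) -> tuple[pd.DataFrame, float]:
    """Evaluate IMU gating thresholds on the scan with the most UDFM events.

    Returns the (threshold, precision, recall, mean_pr) table and the
    threshold maximising mean(precision, recall); undefined metrics count
    as zero for the selection.
    """
    config = config or ExperimentConfig()
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("no thresholds to search")
    busiest = max(range(len(scans)), key=lambda i: len(scans[i][1].events))
    rows = []
    for thr in thresholds:
        cfg = replace(config, noise_cfg=NoiseCancelConfig(imu_threshold=thr,
                                                          guard_s=config.noise_cfg.guard_s))
        rep = run_experiment([scans[busiest]], cfg).report
        p = rep.precision if rep.precision is not None else 0.0
        r = rep.recall if rep.recall is not None else 0.0
        rows.append({"threshold": thr, "precision": p, "recall": r,
                     "mean_pr": 0.5 * (p + r)})
    table = pd.DataFrame(rows)
    best = float(table.loc[table["mean_pr"].idxmax(), "threshold"])
    return table, best


def valid_grid_pairs(windows: Iterable[float] = range(2, 11),
                     overlaps: Iterable[float] = range(1, 5)) -> list[tuple[float, float]]:
    """All (window_s, overlap_s) pairs with overlap strictly inside the window."""
    return [(w, o) for w in windows for o in overlaps if 0 < o < w]


def stft_grid_search(scans: Sequence[tuple[Recording, AnnotationTrack]],
                     windows: Iterable[float] = range(2, 11),
                     overlaps: Iterable[float] = range(1, 5),
                     config: ExperimentConfig | None = None,
                     ) -> tuple[tuple[float, float], pd.DataFrame]:
    """Grid search over STFT window/overlap; selects the pair maximising F1.

    Invalid pairs (overlap >= window) are skipped; ties break toward the
    larger window, then the smaller overlap.
    """
    config = config or ExperimentConfig()
    pairs = valid_grid_pairs(windows, overlaps)
    if not pairs:
        raise ValueError("no valid (window, overlap) pairs in the grid")
    rows = []
    for w, o in pairs:
        cfg = replace(config, spectral_cfg=replace(config.spectral_cfg,
                                                   window_s=float(w), overlap_s=float(o)))
        rep = run_experiment(scans, cfg).report
        rows.append({"window_s": float(w), "overlap_s": float(o),
                     "precision": rep.precision, "recall": rep.recall,
                     "f1": rep.f1 if rep.f1 is not None else float("-inf")})
    table = pd.DataFrame(rows)
    best_row = max(rows, key=lambda r: (r["f1"], r["window_s"], -r["overlap_s"]))
    table["f1"] = table["f1"].replace(float("-inf"), np.nan)
    return (best_row["window_s"], best_row["overlap_s"]), table


# ---------------------------------------------------------------------------
# discussion-style analyses
# ---------------------------------------------------------------------------

def performance_vs_event_count(per_scan: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Sort per-scan metrics by UDFM count; Spearman correlation with count.

    Correlations are ``None`` when undefined (fewer than 2 distinct counts).
    """
    table = per_scan.sort_values("n_udfm", kind="stable").reset_index(drop=True)
    corr: dict[str, float | None] = {}
    for metric_name in ("precision", "recall"):
        values = table[metric_name].astype(float)
        ok = values.notna()
        if ok.sum() < 2 or table.loc[ok, "n_udfm"].nunique() < 2:
            corr[metric_name] = None
            continue
        rho = stats.spearmanr(table.loc[ok, "n_udfm"], values[ok]).statistic
        corr[metric_name] = None if np.isnan(rho) else float(rho)
    return table, corr


def mpm_vs_udfm_agreement(track: AnnotationTrack, window_s: float = 8.0,
                          duration_s: float | None = None,
                          latency_s: float = 2.0) -> MetricsReport:
    """Window-level agreement between ultrasound events and maternal presses.

    The session is discretised into non-overlapping windows of ``window_s``.
    Each press is attributed to the latest UDFM event starting within
    ``latency_s`` before it (the perception latency); presses with no such
    event are spurious.  A window is UDFM-positive when an event overlaps
    it and MPM-positive when it holds a matched event or a spurious press.

    Following the study's agreement analysis, "precision" is the fraction
    of UDFM-positive windows that are MPM-positive (the maternally
    perceived fraction), "recall" the fraction of MPM-positive windows
    that are UDFM-positive, and specificity/accuracy are computed from the
    window 2x2 table.
    """
    if duration_s is None:
        ends = [ev.end_s for ev in track.events] + list(track.mpm_press_s)
        if not ends:
            raise ValueError("empty session: no events or presses and no duration given")
        duration_s = max(ends)
    n_win = max(int(math.ceil(duration_s / window_s)), 1)
    udfm = np.zeros(n_win, dtype=bool)
    mpm = np.zeros(n_win, dtype=bool)

    def windows_of(start: float, end: float) -> slice:
        i0 = min(int(start // window_s), n_win - 1)
        i1 = min(int(max(end - 1e-9, start) // window_s), n_win - 1)
        return slice(i0, i1 + 1)

    for ev in track.events:
        udfm[windows_of(ev.onset_s, ev.end_s)] = True
    matched = [False] * len(track.events)
    onsets = [ev.onset_s for ev in track.events]
    for press in track.mpm_press_s:
        candidates = [i for i, o in enumerate(onsets) if press - latency_s <= o <= press]
        if candidates:
            matched[candidates[-1]] = True
        else:  # spurious press
            mpm[min(int(press // window_s), n_win - 1)] = True
    for ev, hit in zip(track.events, matched):
        if hit:
            mpm[windows_of(ev.onset_s, ev.end_s)] = True

    tp = float(np.sum(udfm & mpm))
    fn = float(np.sum(udfm & ~mpm))   # unperceived movement windows
    fp = float(np.sum(~udfm & mpm))   # spurious-press windows
    tn = float(np.sum(~udfm & ~mpm))
    p = _ratio(tp, tp + fn, "agreement precision")
    r = _ratio(tp, tp + fp, "agreement recall")
    return MetricsReport(precision=p, recall=r, f1=f1_score(p, r),
                         specificity=_ratio(tn, tn + fp, "agreement specificity"),
                         accuracy=(tp + tn) / n_win,
                         counts=ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
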