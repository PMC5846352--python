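"""Adaptive training-set calibration: the self-labeling update loop.

The decoder starts from a supervised training set (36 target/standard
pairs).  As the test session proceeds in segments of ``k`` blocks, each
just-classified segment is self-labeled twice — by the current SVM
(posterior probability P_svm) and by fuzzy C-means on the same CSP
features (membership probability P_fcm, clusters mapped to task labels by
center matching).  A candidate is harvested as *reliable* only if both
labelers agree and both confidences strictly exceed the threshold delta
(fusion strategy; single-labeler variants use one confidence alone).
Reliable samples are appended with fresh recency timestamps, samples
whose timestamp exceeds the capacity M are clipped away, and the SVM is
retrained on the updated set before the next segment is decoded.

Timestamps count recency: the last added sample is 1, the one before 2,
and so on; clipping keeps the M most recent, except that a class about to
vanish keeps its newest ``min_per_class`` members (a guard the retraining
step needs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .classifiers import (SVMModel, compute_class_centers, fcm_label, fit_fcm,
                          match_clusters, predict_posterior, train_svm)
from .csp import CSPModel, csp_features, fit_csp
from .preprocess import (AveragedSample, PreprocessConfig, build_training_pairs,
                         preprocess_session)
from .simulator import SessionData

__all__ = [
    "TimedSample",
    "TrainingSet",
    "CalibrationConfig",
    "AdaptiveRunResult",
    "select_reliable",
    "clip_training_set",
    "calibrate_cycle",
    "run_adaptive_session",
    "run_adaptive_from_averaged",
]

logger = logging.getLogger(__name__)

TARGET, STANDARD = 1, 0


@dataclass(eq=False)
class TimedSample:
    """A feature vector in the training set with provenance and recency."""

    features: np.ndarray
    assigned_label: int
    timestamp: int
    true_label: int | None = None
    p_svm: float | None = None
    p_fcm: float | None = None
    raw: np.ndarray | None = None  # channels x window samples, for CSP refit


@dataclass
class TrainingSet:
    """Ordered, capacity-bounded collection of timed samples."""

    samples: list[TimedSample] = field(default_factory=list)
    capacity: int = 250

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def features(self) -> np.ndarray:
        return np.vstack([s.features for s in self.samples])

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.assigned_label for s in self.samples])

    def class_counts(self) -> dict[int, int]:
        y = self.labels
        return {TARGET: int(np.sum(y == TARGET)),
                STANDARD: int(np.sum(y == STANDARD))}

    def add_batch(self, new: list[TimedSample]) -> None:
        """Append samples; existing timestamps age by ``len(new)`` and the
        batch gets timestamps len(new)..1 in arrival order (last added = 1)."""
        n = len(new)
        if n == 0:
            return
        for s in self.samples:
            s.timestamp += n
        for i, s in enumerate(new):
            s.timestamp = n - i
        self.samples.extend(new)

    def timestamps(self) -> list[int]:
        return [s.timestamp for s in self.samples]


@dataclass(frozen=True)
class CalibrationConfig:
    interval_blocks: int = 4         # k: blocks between calibrations
    delta: float = 0.75              # reliability threshold
    capacity: int = 250              # M: training-set size cap
    strategy: str = "fusion"         # none | svm_only | fcm_only | fusion
    refit_csp: bool = False
    min_per_class: int = 2
    seed: int = 0
    fcm_m: float = 2.0
    fcm_tol: float = 1e-6
    fcm_max_iter: int = 300

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if self.interval_blocks < 1:
            raise ValueError("interval_blocks must be >= 1")
        if self.capacity < 1:
            raise ValueError("capacity must be >= 1")
        if self.strategy not in ("none", "svm_only", "fcm_only", "fusion"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


def select_reliable(candidates: list[TimedSample], delta: float,
                    strategy: str = "fusion",
                    fcm_labels: np.ndarray | None = None,
                    svm_labels: np.ndarray | None = None) -> list[TimedSample]:
    """Reliable-candidate selection, order-preserving.

    fusion: both labels agree AND P_svm > delta AND P_fcm > delta (strict);
    svm_only: P_svm > delta; fcm_only: P_fcm > delta.  Each candidate's
    ``assigned_label`` must already reflect the strategy's labeler.
    """
    out = []
    for i, c in enumerate(candidates):
        if strategy == "fusion":
            agree = (svm_labels is None or fcm_labels is None
                     or svm_labels[i] == fcm_labels[i])
            if (agree and c.p_svm is not None and c.p_fcm is not None
                    and c.p_svm > delta and c.p_fcm > delta):
                out.append(c)
        elif strategy == "svm_only":
            if c.p_svm is not None and c.p_svm > delta:
                out.append(c)
        elif strategy == "fcm_only":
            if c.p_fcm is not None and c.p_fcm > delta:
                out.append(c)
        else:
            raise ValueError(f"no selection for strategy {strategy!r}")
    return out


def clip_training_set(ts: TrainingSet, min_per_class: int = 2) -> int:
    """Drop samples older than the capacity; renumber timestamps 1..size.

    A class that clipping would reduce below ``min_per_class`` keeps its
    newest members instead, displacing the oldest kept samples of the
    other class.  Returns the number of samples removed.
    """
    m = ts.capacity
    before = len(ts)
    if before > m:
        kept = [s for s in ts.samples if s.timestamp <= m]
        removed = [s for s in ts.samples if s.timestamp > m]
        for cls in (TARGET, STANDARD):
            have = sum(1 for s in kept if s.assigned_label == cls)
            if have < min_per_class:
                rescue = sorted((s for s in removed if s.assigned_label == cls),
                                key=lambda s: s.timestamp)[: min_per_class - have]
                kept.extend(rescue)
                for s in rescue:
                    removed.remove(s)
        # displace oldest overrepresented samples if the rescue overfilled
        while len(kept) > m:
            counts = {c: sum(1 for s in kept if s.assigned_label == c)
                      for c in (TARGET, STANDARD)}
            evictable = [s for s in kept
                         if counts[s.assigned_label] > min_per_class]
            victim = max(evictable, key=lambda s: s.timestamp)
            kept.remove(victim)
        ts.samples = kept
    # compress timestamps to ranks 1..size, preserving recency order
    order = sorted(ts.samples, key=lambda s: s.timestamp)
    for rank, s in enumerate(order, start=1):
        s.timestamp = rank
    return before - len(ts)


def _segment_candidates(segment: list[AveragedSample], csp_model: CSPModel
                        ) -> list[TimedSample]:
    out = []
    for s in segment:
        out.append(TimedSample(
            features=csp_features(csp_model, s),
            assigned_label=-1, timestamp=0,
            true_label=None if s.is_target is None else int(s.is_target),
            raw=s.data))
    return out


def calibrate_cycle(training_set: TrainingSet, csp_model: CSPModel,
                    svm_model: SVMModel, segment: list[AveragedSample],
                    cfg: CalibrationConfig, cycle_index: int = 0
                    ) -> tuple[TrainingSet, CSPModel, SVMModel, dict]:
    """One calibration cycle on the just-classified segment.

    Runs the SVM labeler, the fCM labeler with cluster-to-class matching,
    dual-threshold reliable selection, timestamped insertion, capacity
    clipping and classifier retraining.  The audit record counts the
    candidates, the additions (column B), the correctly labeled additions
    when truth is known (column A), and the set size before/after.
    """
    candidates = _segment_candidates(segment, csp_model)
    X = np.vstack([c.features for c in candidates])

    svm_labels, p_svm = predict_posterior(svm_model, X)
    for c, lab, p in zip(candidates, svm_labels, p_svm):
        c.p_svm = float(p)

    fcm_labels = None
    fcm_failed = False
    if cfg.strategy in ("fusion", "fcm_only"):
        try:
            centers = compute_class_centers(training_set.features,
                                            training_set.labels,
                                            positive_label=TARGET)
            fcm = fit_fcm(X, m=cfg.fcm_m, init_centers=centers,
                          tol=cfg.fcm_tol, max_iter=cfg.fcm_max_iter)
            mapping = match_clusters(fcm, centers, labels=(TARGET, STANDARD))
            fcm_labels, p_fcm = fcm_label(fcm, mapping)
            for c, p in zip(candidates, p_fcm):
                c.p_fcm = float(p)
        except ValueError as exc:
            fcm_failed = True
            logger.warning("fCM degenerate in cycle %d (%s); no fusion "
                           "selections this cycle", cycle_index, exc)

    if fcm_failed and cfg.strategy in ("fusion", "fcm_only"):
        selected: list[TimedSample] = []
    else:
        label_source = {"fusion": svm_labels, "svm_only": svm_labels,
                        "fcm_only": fcm_labels}[cfg.strategy]
        for c, lab in zip(candidates, label_source):
            c.assigned_label = int(lab)
        selected = select_reliable(candidates, cfg.delta, cfg.strategy,
                                   fcm_labels=fcm_labels,
                                   svm_labels=svm_labels)

    size_before = len(training_set)
    training_set.add_batch([replace_ts(s) for s in selected])
    n_removed = clip_training_set(training_set, cfg.min_per_class)

    if selected or n_removed:
        if cfg.refit_csp and selected:
            csp_model = _refit_csp_from_set(training_set, csp_model)
        svm_model = train_svm(training_set.features, training_set.labels,
                              seed=cfg.seed + cycle_index + 1)
    # else: nothing changed, so the decoder is left untouched

    n_correct = sum(1 for s in selected
                    if s.true_label is not None
                    and s.assigned_label == s.true_label)
    audit = {
        "cycle": cycle_index,
        "n_candidates": len(candidates),
        "n_selected": len(selected),        # column B
        "n_correct": n_correct,             # column A
        "size_before": size_before,
        "size_after": len(training_set),
        "n_removed": n_removed,
        "fcm_failed": fcm_failed,
    }
    return training_set, csp_model, svm_model, audit


def replace_ts(s: TimedSample) -> TimedSample:
    """Fresh copy so the training set owns its samples."""
    return TimedSample(features=np.array(s.features, copy=True),
                       assigned_label=s.assigned_label, timestamp=0,
                       true_label=s.true_label, p_svm=s.p_svm, p_fcm=s.p_fcm,
                       raw=None if s.raw is None else np.array(s.raw, copy=True))


def _refit_csp_from_set(ts: TrainingSet, old: CSPModel) -> CSPModel:
    """Refit CSP on the stored raw windows grouped by assigned label, then
    recompute every stored feature vector under the new filters."""
    raws = {TARGET: [], STANDARD: []}
    for s in ts.samples:
        if s.raw is None:
            return old  # raw windows unavailable: keep current filters
        raws[s.assigned_label].append(s.raw)
    if len(raws[TARGET]) < 2 or len(raws[STANDARD]) < 2:
        return old
    model = fit_csp(raws[TARGET], raws[STANDARD])
    for s in ts.samples:
        s.features = csp_features(model, s.raw)
    return model


@dataclass
class AdaptiveRunResult:
    predicted_buttons: list[int]
    true_buttons: list[int]
    scores: list[np.ndarray]           # per block: 6 target-posteriors
    audit_trail: list[dict]
    segment_bounds: list[tuple[int, int]]

    @property
    def n_correct(self) -> int:
        return sum(p == t for p, t in zip(self.predicted_buttons,
                                          self.true_buttons))


def _initial_models(averaged_train: list[list[AveragedSample]],
                    cfg: CalibrationConfig):
    pairs = build_training_pairs(averaged_train, seed=cfg.seed)
    targets = [s for s in pairs if s.is_target]
    standards = [s for s in pairs if not s.is_target]
    csp_model = fit_csp(targets, standards)
    ts = TrainingSet(capacity=cfg.capacity)
    batch = [TimedSample(features=csp_features(csp_model, s),
                         assigned_label=int(s.is_target),
                         timestamp=0, true_label=int(s.is_target),
                         raw=s.data)
             for s in pairs]
    if cfg.capacity < len(batch):
        raise ValueError("capacity M must be at least the initial training size")
    # recording order: later blocks are more recent
    ts.add_batch(batch)
    clip_training_set(ts)
    svm_model = train_svm(ts.features, ts.labels, seed=cfg.seed)
    return ts, csp_model, svm_model


def run_adaptive_from_averaged(averaged_train: list[list[AveragedSample]],
                               averaged_test: list[list[AveragedSample]],
                               test_targets: list[int],
                               cfg: CalibrationConfig) -> AdaptiveRunResult:
    """Adaptive decoding given already-preprocessed block averages.

    Blocks are decoded in segments of ``interval_blocks``; every segment
    except the last then feeds a calibration cycle (unless strategy is
    ``none``), so each block is always decoded by a model that never saw
    its own segment.
    """
    from .evaluate import decode_block  # late import to avoid a cycle

    ts, csp_model, svm_model = _initial_models(averaged_train, cfg)
    k = cfg.interval_blocks
    n_blocks = len(averaged_test)
    preds, scores = [], []
    audit: list[dict] = []
    bounds = [(i, min(i + k, n_blocks)) for i in range(0, n_blocks, k)]
    for seg_idx, (lo, hi) in enumerate(bounds):
        for b in range(lo, hi):
            decision = decode_block(svm_model, csp_model, averaged_test[b])
            preds.append(decision.predicted_button)
            scores.append(decision.scores)
        if cfg.strategy != "none" and hi < n_blocks:
            segment = [s for b in range(lo, hi) for s in averaged_test[b]]
            ts, csp_model, svm_model, rec = calibrate_cycle(
                ts, csp_model, svm_model, segment, cfg, cycle_index=seg_idx)
            rec["segment"] = seg_idx
            audit.append(rec)
    return AdaptiveRunResult(predicted_buttons=preds, true_buttons=test_targets,
                             scores=scores, audit_trail=audit,
                             segment_bounds=bounds)


def run_adaptive_session(train_session: SessionData, test_session: SessionData,
                         cfg: CalibrationConfig,
                         pre_cfg: PreprocessConfig | None = None
                         ) -> AdaptiveRunResult:
    """End-to-end adaptive run: preprocess both sessions, build the initial
    supervised models from the training session, then decode the test
    session with interval-scheduled calibration."""
    if train_session.paradigm != test_session.paradigm:
        raise ValueError("train and test sessions must share a paradigm")
    pre_cfg = pre_cfg or PreprocessConfig()
    averaged_train, _ = preprocess_session(train_session, pre_cfg)
    averaged_test, _ = preprocess_session(test_session, pre_cfg)
    return run_adaptive_from_averaged(averaged_train, averaged_test,
                                      test_session.target_buttons, cfg)
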