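"""Block decoding, accuracy, information transfer rate and strategy tables.

A block is decoded by scoring each of its six button-averages with the
binary classifier's target-class posterior and taking the argmax (ties to
the lowest button index).  Session accuracy is the percentage of blocks
whose predicted button equals the true one.  The information transfer
rate per selection is the standard noisy-channel bound

    bits = log2 N + P log2 P + (1 - P) log2((1 - P) / (N - 1)),

with x log2 x := 0 at x = 0, scaled by 60/T to bits per minute; at the
paradigm defaults N = 6 selectable buttons and T = 7.5 s per block.
Strategy comparisons across subjects use the two-sided paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classifiers import SVMModel, predict_posterior
from .csp import CSPModel, csp_features
from .preprocess import AveragedSample

__all__ = [
    "BlockDecision",
    "EvaluationResult",
    "decode_block",
    "itr",
    "itr_per_selection",
    "session_accuracy",
    "segment_accuracies",
    "compare_strategies",
    "round_half_up",
]

TARGET = 1


@dataclass
class BlockDecision:
    scores: np.ndarray       # 6 target-class posteriors
    predicted_button: int
    true_button: int | None = None


@dataclass
class EvaluationResult:
    n_blocks: int
    n_correct: int
    accuracy: float          # percent
    itr: float               # bits/min
    itr_per_selection: float # bits
    per_segment_accuracy: list[float] | None = None


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero, the convention of printed report tables."""
    factor = 10.0 ** decimals
    return np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor


def decode_block(model: SVMModel, csp_model: CSPModel,
                 block: list[AveragedSample]) -> BlockDecision:
    """Six binary classifications, then argmax of the target posteriors."""
    if len(block) == 0:
        raise ValueError("empty block")
    if sorted(s.button for s in block) != list(range(len(block))):
        raise ValueError("block is missing a button sample")
    feats = np.vstack([csp_features(csp_model, s) for s in block])
    proba = model.posterior(feats)
    target_col = int(np.where(model.classes_ == TARGET)[0][0])
    scores = proba[:, target_col]
    return BlockDecision(scores=scores,
                         predicted_button=int(np.argmax(scores)),
                         true_button=None)


def itr_per_selection(p: float, n: int) -> float:
    """Bits per selection for accuracy ``p`` among ``n`` items."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"accuracy must lie in [0, 1], got {p}")
    if n < 2:
        raise ValueError("need at least 2 selectable items")
    def xlog2x(x: float) -> float:
        return 0.0 if x <= 0.0 else x * np.log2(x)
    return float(np.log2(n) + xlog2x(p)
                 + (0.0 if p >= 1.0 else (1 - p) * np.log2((1 - p) / (n - 1))))


def itr(p: float, n: int = 6, t: float = 7.5) -> float:
    """Information transfer rate in bits per minute (T seconds/selection)."""
    if t <= 0:
        raise ValueError("selection time must be positive")
    return itr_per_selection(p, n) * 60.0 / t


def session_accuracy(predicted: list[int], true: list[int],
                     n_items: int = 6, selection_time_s: float = 7.5,
                     segment_bounds: list[tuple[int, int]] | None = None
                     ) -> EvaluationResult:
    """Percent of correctly decoded blocks plus the matching ITR."""
    if len(predicted) == 0:
        raise ValueError("need at least one block decision")
    if len(predicted) != len(true):
        raise ValueError("prediction/truth length mismatch")
    correct = [int(p == t) for p, t in zip(predicted, true)]
    n_correct = sum(correct)
    acc = 100.0 * n_correct / len(predicted)
    per_seg = None
    if segment_bounds is not None:
        per_seg = [100.0 * sum(correct[lo:hi]) / (hi - lo)
                   for lo, hi in segment_bounds if hi > lo]
    return EvaluationResult(
        n_blocks=len(predicted), n_correct=n_correct, accuracy=acc,
        itr=itr(acc / 100.0, n_items, selection_time_s),
        itr_per_selection=itr_per_selection(acc / 100.0, n_items),
        per_segment_accuracy=per_seg)


def segment_accuracies(result) -> list[float]:
    """Per-segment accuracies from an AdaptiveRunResult."""
    correct = [int(p == t) for p, t in zip(result.predicted_buttons,
                                           result.true_buttons)]
    return [100.0 * sum(correct[lo:hi]) / (hi - lo)
            for lo, hi in result.segment_bounds if hi > lo]


def compare_strategies(results: dict[str, list[float]],
                       baseline: str = "none", alpha: float = 0.05
                       ) -> pd.DataFrame:
    """Mean +/- std per strategy and paired t-test flags against a baseline.

    ``results`` maps strategy name to a per-subject (or per-seed) accuracy
    vector; all vectors must be paired (same length, same order).  A
    strategy is flagged significant when the two-sided paired t-test
    against the baseline gives p < alpha; degenerate cases (zero paired
    difference variance) are never flagged.
    """
    if baseline not in results:
        raise ValueError(f"baseline {baseline!r} missing from results")
    lengths = {len(v) for v in results.values()}
    if len(lengths) != 1:
        raise ValueError("all strategies need the same number of subjects")
    if lengths.pop() < 2:
        raise ValueError("need at least 2 subjects for a paired comparison")
    base = np.asarray(results[baseline], dtype=float)
    rows = []
    for name, vals in results.items():
        v = np.asarray(vals, dtype=float)
        if name == baseline or np.allclose(v, base):
            p = np.nan
            tstat = np.nan
        else:
            tstat, p = stats.ttest_rel(v, base)
        rows.append({
            "strategy": name,
            "mean": v.mean(),
            "std": v.std(ddof=1),
            "t_stat": tstat,
            "p_value": p,
            "significant": bool(np.isfinite(p) and p < alpha),
        })
    return pd.DataFrame(rows).set_index("strategy")
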