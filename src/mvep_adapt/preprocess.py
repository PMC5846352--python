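"""Epoch conditioning: artifact rejection, bandpass, windowing, averaging.

The pipeline follows the standard mVEP decoding chain: raw epochs with any
sample exceeding the rejection threshold (50 uV) are discarded, survivors
are zero-phase bandpass filtered (0.5-10 Hz, 4th-order Butterworth applied
forward-backward), the feature window (150-300 ms after stimulus onset,
half-open) is cut out, the surviving trials of each virtual button within
a block are averaged, and the initial supervised training set is built by
pairing each block's target average with one randomly chosen standard
average from the same block (36 pairs for a 36-block training session).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .simulator import Epoch, SessionData

__all__ = [
    "PreprocessConfig",
    "AveragedSample",
    "DegenerateBlockError",
    "reject_artifacts",
    "bandpass",
    "extract_window",
    "average_block",
    "preprocess_session",
    "build_training_pairs",
]

logger = logging.getLogger(__name__)


class DegenerateBlockError(ValueError):
    """A button lost every trial of a block to artifact rejection."""


@dataclass(frozen=True)
class PreprocessConfig:
    reject_threshold: float = 50.0  # uV
    band_low: float = 0.5  # Hz
    band_high: float = 10.0  # Hz
    window_start: float = 150.0  # ms
    window_end: float = 300.0  # ms
    filter_order: int = 4

    def __post_init__(self) -> None:
        if self.reject_threshold <= 0:
            raise ValueError("reject_threshold must be positive")
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")
        if not self.window_start < self.window_end:
            raise ValueError("need window_start < window_end")


@dataclass(eq=False)
class AveragedSample:
    """Mean over a button's surviving trials within one block.

    ``data`` is channels x window-samples (uV); ``is_target`` is the true
    label when known (simulation / supervised training), None otherwise.
    """

    data: np.ndarray
    button: int
    is_target: bool | None
    block_index: int


def reject_artifacts(epochs: list[Epoch], threshold: float = 50.0
                     ) -> tuple[list[Epoch], int]:
    """Drop epochs whose absolute amplitude exceeds ``threshold`` anywhere.

    The comparison is strict: a peak exactly at the threshold is kept.
    Order is preserved.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    kept = [e for e in epochs if np.abs(e.data).max() <= threshold]
    return kept, len(epochs) - len(kept)


def _band_sos(cfg: PreprocessConfig, rate: float):
    nyq = rate / 2.0
    if cfg.band_high >= nyq:
        raise ValueError(
            f"band_high {cfg.band_high} Hz must be below Nyquist {nyq} Hz"
        )
    # second-order sections: the band is a tiny fraction of Nyquist, where
    # the transfer-function form of the filter is numerically unstable
    return butter(cfg.filter_order, [cfg.band_low / nyq, cfg.band_high / nyq],
                  btype="bandpass", output="sos")


def bandpass(epoch: Epoch, cfg: PreprocessConfig, rate: float = 1000.0) -> Epoch:
    """Zero-phase Butterworth bandpass; same shape, linear in the input."""
    sos = _band_sos(cfg, rate)
    return Epoch(data=sosfiltfilt(sos, epoch.data, axis=-1),
                 button=epoch.button, is_target=epoch.is_target,
                 block_index=epoch.block_index, trial_index=epoch.trial_index)


def bandpass_array(data: np.ndarray, cfg: PreprocessConfig,
                   rate: float = 1000.0) -> np.ndarray:
    """Vectorised zero-phase bandpass along the last axis."""
    return sosfiltfilt(_band_sos(cfg, rate), data, axis=-1)


def extract_window(epoch_or_data, cfg: PreprocessConfig,
                   rate: float = 1000.0) -> np.ndarray:
    """Cut the half-open feature window [window_start, window_end) ms.

    Sample indexing is 0-based with stimulus onset at 0 ms, so 150-300 ms
    at 1000 Hz yields exactly 150 samples per channel.
    """
    data = epoch_or_data.data if isinstance(epoch_or_data, Epoch) else epoch_or_data
    i0 = int(round(cfg.window_start * rate / 1000.0))
    i1 = int(round(cfg.window_end * rate / 1000.0))
    if i0 < 0 or i1 > data.shape[-1]:
        raise ValueError(
            f"window [{cfg.window_start}, {cfg.window_end}) ms outside epoch "
            f"of {data.shape[-1]} samples"
        )
    return data[..., i0:i1]


def average_block(block_epochs: list[Epoch], n_buttons: int = 6
                  ) -> list[AveragedSample]:
    """Element-wise mean per button over its surviving trials.

    Raises :class:`DegenerateBlockError` if any button has no epochs left.
    Epoch ``is_target`` flags must agree within a button; the averaged
    sample inherits them.
    """
    by_button: dict[int, list[Epoch]] = {b: [] for b in range(n_buttons)}
    for e in block_epochs:
        by_button[e.button].append(e)
    out: list[AveragedSample] = []
    for btn in range(n_buttons):
        eps = by_button[btn]
        if not eps:
            raise DegenerateBlockError(
                f"button {btn} has no surviving epochs in block "
                f"{block_epochs[0].block_index if block_epochs else '?'}"
            )
        flags = {e.is_target for e in eps}
        out.append(AveragedSample(
            data=np.mean([e.data for e in eps], axis=0),
            button=btn,
            is_target=flags.pop() if len(flags) == 1 else None,
            block_index=eps[0].block_index,
        ))
    return out


def preprocess_session(session: SessionData, cfg: PreprocessConfig
                       ) -> tuple[list[list[AveragedSample]], dict]:
    """Full conditioning of a session: reject -> filter -> window -> average.

    Returns one list of ``n_buttons`` :class:`AveragedSample` per surviving
    block (degenerate blocks are skipped with a logged warning) and a log
    dict with rejection counts and skipped block indices.
    """
    rate = session.paradigm.sampling_rate
    n_buttons = session.paradigm.n_buttons
    blocks_out: list[list[AveragedSample]] = []
    log = {"n_rejected": 0, "skipped_blocks": [], "rejections": []}
    for block in session.blocks:
        kept, n_rej = reject_artifacts(block.epochs, cfg.reject_threshold)
        log["n_rejected"] += n_rej
        for e in block.epochs:
            peak = float(np.abs(e.data).max())
            if peak > cfg.reject_threshold:
                log["rejections"].append(
                    (e.block_index, e.trial_index, e.button, peak))
        if not kept:
            log["skipped_blocks"].append(block.epochs[0].block_index)
            logger.warning("block %d lost all epochs to rejection",
                           block.epochs[0].block_index)
            continue
        stack = np.stack([e.data for e in kept])
        filtered = bandpass_array(stack, cfg, rate)
        windowed = extract_window(filtered, cfg, rate)
        processed = [
            Epoch(data=windowed[i], button=e.button, is_target=e.is_target,
                  block_index=e.block_index, trial_index=e.trial_index)
            for i, e in enumerate(kept)
        ]
        try:
            blocks_out.append(average_block(processed, n_buttons))
        except DegenerateBlockError:
            log["skipped_blocks"].append(kept[0].block_index)
            logger.warning("block %d degenerate after rejection, skipped",
                           kept[0].block_index)
    return blocks_out, log


def build_training_pairs(averaged_blocks: list[list[AveragedSample]],
                         seed: int) -> list[AveragedSample]:
    """Target + one seeded-random standard sample per block (1:1 balance)."""
    out: list[AveragedSample] = []
    for blk in averaged_blocks:
        targets = [s for s in blk if s.is_target]
        standards = [s for s in blk if not s.is_target]
        if len(targets) != 1 or not standards:
            raise ValueError(
                f"block {blk[0].block_index} does not have exactly one target "
                "and at least one standard sample"
            )
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, blk[0].block_index]))
        out.append(targets[0])
        out.append(standards[rng.integers(len(standards))])
    return out
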