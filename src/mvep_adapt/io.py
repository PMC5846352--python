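"""Plain-text session fixtures and run reports.

A session is stored as a directory holding ``meta.json`` (paradigm,
per-block target buttons, provenance) and ``epochs.csv`` in long format
(block, trial, button, is_target, channel, sample_index, value_uV).  The
round trip is bit-exact: floats are written with ``repr`` (shortest
exactly-round-tripping decimal form).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .simulator import Block, Epoch, ParadigmConfig, SessionData

__all__ = ["save_session", "load_session", "write_audit_csv",
           "write_segment_accuracy_csv"]


def save_session(session: SessionData, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "paradigm": asdict(session.paradigm),
        "target_buttons": session.target_buttons,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))
    rows = []
    for block in session.blocks:
        for e in block.epochs:
            n_ch, n_s = e.data.shape
            rows.append(pd.DataFrame({
                "block": e.block_index,
                "trial": e.trial_index,
                "button": e.button,
                "is_target": int(e.is_target),
                "channel": np.repeat(np.arange(n_ch), n_s),
                "sample_index": np.tile(np.arange(n_s), n_ch),
                "value_uV": e.data.ravel(),
            }))
    pd.concat(rows, ignore_index=True).to_csv(directory / "epochs.csv",
                                              index=False)
    return directory


def load_session(directory: str | Path) -> SessionData:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    pdm = dict(meta["paradigm"])
    paradigm = ParadigmConfig(**pdm)
    # round_trip parsing: the fast float parser loses the last bit
    df = pd.read_csv(directory / "epochs.csv", float_precision="round_trip")
    blocks: list[Block] = []
    for b, target in enumerate(meta["target_buttons"]):
        sub = df[df["block"] == b]
        epochs: list[Epoch] = []
        for (trial, button), grp in sub.groupby(["trial", "button"], sort=True):
            grp = grp.sort_values(["channel", "sample_index"])
            n_ch = grp["channel"].nunique()
            data = grp["value_uV"].to_numpy().reshape(n_ch, -1)
            epochs.append(Epoch(data=data, button=int(button),
                                is_target=bool(grp["is_target"].iloc[0]),
                                block_index=b, trial_index=int(trial)))
        # restore recording order: trial-major, button within trial
        epochs.sort(key=lambda e: (e.trial_index, e.button))
        blocks.append(Block(target_button=int(target), epochs=epochs))
    return SessionData(blocks=blocks, paradigm=paradigm)


def write_audit_csv(audit_trail: list[dict], path: str | Path) -> Path:
    """Per-cycle harvest accounting: columns A (correct additions),
    B (total additions) and C = A/B where defined."""
    rows = []
    for rec in audit_trail:
        a, b = rec["n_correct"], rec["n_selected"]
        rows.append({
            "segment": rec.get("segment", rec["cycle"]),
            "n_candidates": rec["n_candidates"],
            "A": a, "B": b,
            "C": (a / b) if b else float("nan"),
            "size_before": rec["size_before"],
            "size_after": rec["size_after"],
            "n_removed": rec["n_removed"],
        })
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_segment_accuracy_csv(per_segment: list[float],
                               path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"segment": range(len(per_segment)),
                  "accuracy_percent": per_segment}).to_csv(path, index=False)
    return path
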