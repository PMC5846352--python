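"""Two-class common spatial patterns with one-pair log-variance features.

CSP finds spatial filters w maximizing the ratio of projected variance
between two classes.  Per-sample covariances are trace-normalized (removing
per-trial gain), averaged per class into S1 and S2, and the generalized
eigenproblem S1 w = lambda (S1 + S2) w is solved; eigenvalues lie in [0, 1]
and the selected pair are the eigenvectors of the largest and smallest
eigenvalue.  The feature of a sample X under filter w is log var(w^T X).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import eigh

from .preprocess import AveragedSample

__all__ = ["CSPModel", "fit_csp", "csp_features"]


@dataclass
class CSPModel:
    filters: np.ndarray        # n_filters x channels, sorted by eigenvalue desc
    eigenvalues: np.ndarray    # descending, in [0, 1]
    selected_pair: tuple[int, int] = (0, -1)

    @property
    def pair_filters(self) -> np.ndarray:
        first, last = self.selected_pair
        return self.filters[[first, last]]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "filters": self.filters.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "selected_pair": list(self.selected_pair),
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CSPModel":
        d = json.loads(Path(path).read_text())
        return cls(filters=np.asarray(d["filters"]),
                   eigenvalues=np.asarray(d["eigenvalues"]),
                   selected_pair=tuple(d["selected_pair"]))


def _normalized_cov(data: np.ndarray) -> np.ndarray:
    """Sample covariance over time, normalized to unit trace."""
    x = data - data.mean(axis=1, keepdims=True)
    c = x @ x.T
    tr = np.trace(c)
    if tr <= 0:
        raise ValueError("sample has zero variance; cannot form covariance")
    return c / tr


def _extract(sample) -> np.ndarray:
    return sample.data if isinstance(sample, AveragedSample) else np.asarray(sample)


def fit_csp(class1, class2, regularization: float = 1e-6) -> CSPModel:
    """Fit CSP from two lists of samples (AveragedSample or arrays).

    ``regularization`` adds eps * trace/n_channels * I to the composite
    covariance before solving, guarding against rank deficiency from few
    samples.  Filter signs are fixed so each filter's largest-magnitude
    coefficient is positive.
    """
    if len(class1) < 2 or len(class2) < 2:
        raise ValueError("need at least 2 samples per class")
    s1 = np.mean([_normalized_cov(_extract(s)) for s in class1], axis=0)
    s2 = np.mean([_normalized_cov(_extract(s)) for s in class2], axis=0)
    if s1.shape != s2.shape:
        raise ValueError("channel counts of the two classes disagree")
    n_ch = s1.shape[0]
    composite = s1 + s2
    composite = composite + regularization * np.trace(composite) / n_ch * np.eye(n_ch)
    try:
        vals, vecs = eigh(s1, composite)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - diagnostic path
        raise np.linalg.LinAlgError(
            "generalized eigenproblem failed; composite covariance singular "
            f"despite regularization {regularization}"
        ) from exc
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, 1.0)
    filters = vecs[:, order].T
    # deterministic sign: largest-|coefficient| entry positive
    for i, w in enumerate(filters):
        j = np.argmax(np.abs(w))
        if w[j] < 0:
            filters[i] = -w
    return CSPModel(filters=filters, eigenvalues=vals, selected_pair=(0, -1))


def csp_features(model: CSPModel, sample) -> np.ndarray:
    """Log-variance of the sample projected through the selected filter pair."""
    data = _extract(sample)
    if data.shape[0] != model.filters.shape[1]:
        raise ValueError(
            f"sample has {data.shape[0]} channels, model expects "
            f"{model.filters.shape[1]}"
        )
    proj = model.pair_filters @ data
    var = proj.var(axis=1, ddof=1)
    if np.any(var <= 0):
        raise ValueError("zero projected variance; degenerate sample")
    return np.log(var)
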