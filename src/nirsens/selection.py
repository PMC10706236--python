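"""Calibration/prediction partitioning: Kennard-Stone and SPXY.

Kennard-Stone is the classical deterministic max-min selection: start from
the pair of samples at maximal Euclidean distance, then repeatedly add the
sample maximizing the minimum distance to the already-selected set.  SPXY
runs the same procedure on a joint distance that sums X-space and Y-space
Euclidean distances, each normalized by its own maximum, so the calibration
subset spans both the instrumental and the reference-value space.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = ["SplitResult", "kennard_stone", "spxy", "round_half_up"]


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (documented rule)."""
    return int(np.floor(x + 0.5))


@dataclasses.dataclass
class SplitResult:
    """Disjoint calibration/prediction index sets covering all samples."""

    calibration_idx: np.ndarray
    prediction_idx: np.ndarray
    fraction: float = 0.67

    def __post_init__(self) -> None:
        self.calibration_idx = np.asarray(self.calibration_idx, dtype=int)
        self.prediction_idx = np.asarray(self.prediction_idx, dtype=int)
        cal, pred = set(self.calibration_idx.tolist()), set(self.prediction_idx.tolist())
        if cal & pred:
            raise ValueError("calibration and prediction sets overlap")
        n = len(cal) + len(pred)
        if cal | pred != set(range(n)):
            raise ValueError("split does not cover indices 0..n-1 exactly once")

    @property
    def n(self) -> int:
        return len(self.calibration_idx) + len(self.prediction_idx)

    def to_json(self) -> str:
        return json.dumps(
            {
                "calibration_idx": self.calibration_idx.tolist(),
                "prediction_idx": self.prediction_idx.tolist(),
                "fraction": self.fraction,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitResult":
        d = json.loads(text)
        return cls(
            calibration_idx=np.asarray(d["calibration_idx"], dtype=int),
            prediction_idx=np.asarray(d["prediction_idx"], dtype=int),
            fraction=d.get("fraction", 0.67),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "SplitResult":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def _kennard_stone_on_distance(D: np.ndarray, k: int) -> np.ndarray:
    """Max-min selection on a precomputed distance matrix.

    Ties break to the lowest index (argmax returns the first maximum; the
    initial pair is the row-major-first maximal entry, lower index first).
    """
    n = D.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must satisfy 2 <= k <= {n}, got {k}")
    i, j = np.unravel_index(np.argmax(D), D.shape)
    first, second = (i, j) if i < j else (j, i)
    selected = [int(first), int(second)]
    remaining = np.ones(n, dtype=bool)
    remaining[selected] = False
    min_dist = np.minimum(D[first], D[second])
    while len(selected) < k:
        cand = np.where(remaining, min_dist, -np.inf)
        nxt = int(np.argmax(cand))
        selected.append(nxt)
        remaining[nxt] = False
        min_dist = np.minimum(min_dist, D[nxt])
    return np.asarray(selected, dtype=int)


def kennard_stone(X: np.ndarray, k: int) -> np.ndarray:
    """Select ``k`` samples by the Kennard-Stone max-min criterion.

    Returns indices in selection order.  Deterministic; ties break to the
    lowest index.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    D = squareform(pdist(X, metric="euclidean"))
    if D.max() == 0:
        raise ValueError("all samples identical in X space; selection undefined")
    return _kennard_stone_on_distance(D, k)


def spxy(
    X: np.ndarray,
    y: np.ndarray,
    fraction: float = 0.67,
    y_weight: float = 1.0,
) -> SplitResult:
    """SPXY partition into calibration and prediction subsets.

    The joint distance is ``dx/max(dx) + y_weight * dy/max(dy)`` with
    Euclidean distances in each space; Kennard-Stone selection on this
    distance yields the calibration set of size ``round_half_up(fraction*n)``.
    ``y_weight=0`` reduces exactly to Kennard-Stone on X alone.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).reshape(len(X), -1)
    n = X.shape[0]
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n_cal = round_half_up(fraction * n)
    n_cal = max(2, min(n_cal, n - 1))
    dx = squareform(pdist(X, metric="euclidean"))
    if dx.max() == 0:
        raise ValueError("all samples identical in X space; SPXY undefined")
    D = dx / dx.max()
    if y_weight != 0.0:
        dy = squareform(pdist(y, metric="euclidean"))
        if dy.max() == 0:
            raise ValueError(
                "all y values identical: Y-space distance degenerate; "
                "fall back to kennard_stone on X"
            )
        D = D + y_weight * dy / dy.max()
    cal = _kennard_stone_on_distance(D, n_cal)
    pred = np.setdiff1d(np.arange(n), cal)
    return SplitResult(
        calibration_idx=np.sort(cal), prediction_idx=pred, fraction=fraction
    )
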