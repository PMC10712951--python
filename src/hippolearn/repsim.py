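"""Representational similarity analysis of hidden-layer activity.

For each probe item we capture the activity pattern evoked in DG, CA3 and
CA1, in two modes: the *initial* response — activity after it has spread
through the circuit but before EC_out output recirculates back into EC_in
(big-loop recurrence structurally disabled by gating the EC_out→EC_in
projection at 0) — and the *settled* response, the fully converged state
including big-loop influence.  Item x item Pearson correlations of these
patterns expose whether a layer separates items or represents shared
category structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .netcore import Network
from .scoring import probe

__all__ = [
    "ResponseSnapshot",
    "SimilarityMatrix",
    "capture_responses",
    "similarity_matrix",
    "within_between_summary",
]

HIDDEN_LAYERS = ("DG", "CA3", "CA1")


@dataclass
class ResponseSnapshot:
    """Evoked activity of one layer for one probe item."""

    item_id: str
    layer: str
    activations: np.ndarray
    mode: str  # "initial" | "settled"
    category: str | None = None


@dataclass
class SimilarityMatrix:
    """Item x item Pearson correlations for one layer and mode."""

    values: np.ndarray
    item_ids: list
    labels: list
    layer: str
    mode: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.item_ids, columns=self.item_ids)


def capture_responses(network: Network, probes, mode: str = "settled",
                      layers=HIDDEN_LAYERS) -> list:
    """Evoke each probe and snapshot the hidden layers (no weight changes)."""
    if mode not in ("initial", "settled"):
        raise ValueError("mode must be 'initial' or 'settled'")
    out = []
    for spec in probes:
        state = probe(network, spec.input, mode=mode)
        for layer in layers:
            out.append(ResponseSnapshot(spec.id, layer,
                                        state[layer].copy(), mode,
                                        spec.category))
    return out


def _pearson_rows(x: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation with constant rows defined as 0."""
    x = np.asarray(x, dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    constant = norms == 0
    if constant.any():
        warnings.warn("constant activity vector(s); their correlations are "
                      "defined as 0", stacklevel=2)
        norms = np.where(constant, 1.0, norms)
    c = (centered / norms[:, None]) @ (centered / norms[:, None]).T
    c = np.clip(c, -1.0, 1.0)
    c[constant, :] = 0.0
    c[:, constant] = 0.0
    np.fill_diagonal(c, 1.0)
    return c


def similarity_matrix(snapshots) -> dict:
    """Pearson-correlation matrices from :func:`capture_responses` output.

    Returns ``{(layer, mode): SimilarityMatrix}``; the diagonal is always 1
    (an item correlated with itself) and matrices are symmetric.
    """
    groups: dict = {}
    for s in snapshots:
        groups.setdefault((s.layer, s.mode), []).append(s)
    result = {}
    for key, snaps in groups.items():
        if len(snaps) < 2:
            raise ValueError("need at least two items for a similarity matrix")
        mat = _pearson_rows(np.stack([s.activations for s in snaps]))
        result[key] = SimilarityMatrix(mat, [s.item_id for s in snaps],
                                       [s.category for s in snaps], *key)
    return result


def within_between_summary(matrix: SimilarityMatrix, labels=None,
                           excluded_items=()) -> tuple:
    """Mean off-diagonal similarity within and between categories.

    ``excluded_items`` are dropped entirely (e.g. the equiprobable card
    combinations of the probabilistic task).  A category with a single item
    contributes no within-category pairs.
    """
    labels = list(matrix.labels if labels is None else labels)
    keep = [i for i, item in enumerate(matrix.item_ids)
            if item not in set(excluded_items)]
    vals = matrix.values[np.ix_(keep, keep)]
    labs = np.asarray([labels[i] for i in keep])
    same = labs[:, None] == labs[None, :]
    off = ~np.eye(len(keep), dtype=bool)
    within = vals[same & off]
    between = vals[~same & off]
    mean_within = float(within.mean()) if within.size else float("nan")
    mean_between = float(between.mean()) if between.size else float("nan")
    return mean_within, mean_between
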