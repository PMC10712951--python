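"""Test protocol and behavioural scores.

Testing never changes connection weights: a probe pattern is clamped on the
Input layer, the network settles with both pathways gated on (lesioned
networks keep their lesion), and scores are read off the settled EC_out
activations.

Score kinds
-----------
* ``unique-feature`` / ``categorization-sat`` / ``generalization-sat`` —
  activation of the correct unit divided by the summed activation of a small
  competitor set (chance = 1 / set size).
* ``recognition-weather`` — mean activation of the correct card units over
  the mean across all card units (the literal definition; can exceed 1, and
  equals 1 for an undifferentiated output).  A sum-normalized variant
  (summed correct over summed card activation, bounded in [0, 1]) is
  reported alongside it.
* ``categorization-weather`` / ``generalization-typ`` — summed activation of
  the correct outcome/label units over the summed activation of both
  outcome/label sets (chance 0.5).  The literal mean-over-means variant of
  the label score is also available.
* ``atypical-feature`` — summed activation of an item's atypical feature
  units over the 10 feature units on its atypical (opposite-prototype) side;
  chance is 0.1 per atypical feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .netcore import ActivityState, Network, settle

__all__ = [
    "ProbeSpec",
    "probe",
    "ratio_score",
    "mean_ratio_score",
    "atypical_feature_score",
    "generalization_typ_score",
    "score_probe",
    "run_test_battery",
]


@dataclass
class ProbeSpec:
    """One test probe: input pattern, scored unit sets, chance level."""

    id: str
    kind: str
    input: np.ndarray
    correct: list
    denominator: list
    chance: float
    category: str | None = None
    meta: dict = field(default_factory=dict)


def probe(network: Network, probe_input: np.ndarray, mode: str = "settled",
          max_cycles: int = 100, tolerance: float = 1e-4) -> ActivityState:
    """Settle the network on a probe with no learning.

    ``mode="settled"`` runs a normal test settle (both pathways gated on,
    big-loop recirculation active); ``mode="initial"`` silences the
    EC_out→EC_in recirculation so the state reflects the first feedforward
    spread of activity only.
    """
    phase = "test" if mode == "settled" else "test_initial"
    vec = np.asarray(probe_input, dtype=float)
    if vec.shape[0] != network.layer("Input").size:
        raise ValueError(
            f"probe length {vec.shape[0]} != Input size {network.layer('Input').size}")
    return settle(network, {"Input": vec}, phase, max_cycles, tolerance)


def ratio_score(outputs, correct_units, denominator_units, chance=None) -> float:
    """sum(activation over correct) / sum(activation over denominator).

    The denominator set includes the correct set.  A silent denominator
    (total activation 0) carries no evidence either way and returns the
    chance level.
    """
    outputs = np.asarray(outputs, dtype=float)
    num = outputs[list(correct_units)].sum()
    den = outputs[list(denominator_units)].sum()
    if den == 0.0:
        return float(chance) if chance is not None else \
            len(correct_units) / len(denominator_units)
    return float(num / den)


def mean_ratio_score(outputs, correct_units, all_units) -> float:
    """mean(activation over correct) / mean(activation over all units).

    The literal recognition measure of the probabilistic task; an
    undifferentiated (or silent) output yields 1.0.
    """
    outputs = np.asarray(outputs, dtype=float)
    den = outputs[list(all_units)].mean()
    if den == 0.0:
        return 1.0
    return float(outputs[list(correct_units)].mean() / den)


def atypical_feature_score(outputs, atypical_correct_units, atypical_side_units):
    """Proportion of atypical-side activation on the item's own atypical
    features.  Returns ``(score, chance)`` with chance = k * 0.1 for an item
    with k atypical features (k in 1..4 for training items)."""
    k = len(atypical_correct_units)
    if not 1 <= k <= 4:
        raise ValueError(f"training items have 1-4 atypical features, got {k}")
    chance = 0.1 * k
    return ratio_score(outputs, atypical_correct_units, atypical_side_units,
                       chance=chance), chance


def generalization_typ_score(outputs, correct_label_units, all_label_units,
                             variant: str = "sum") -> float:
    """Label score for novel typicality-continuum items (chance 0.5).

    ``variant="sum"`` (default) divides summed correct-label activation by
    the summed activation over both labels, bounded in [0, 1].
    ``variant="mean"`` is the literal mean-over-means phrasing, which equals
    1.0 for an undifferentiated output.
    """
    if variant == "mean":
        return mean_ratio_score(outputs, correct_label_units, all_label_units)
    return ratio_score(outputs, correct_label_units, all_label_units, chance=0.5)


def score_probe(outputs: np.ndarray, spec: ProbeSpec) -> dict:
    """Score one probe's settled EC_out activations.

    Returns a record dict with the probe's primary ``score`` (sum-normalized
    where the literal definition is unbounded) and, for weather recognition,
    the literal mean-ratio value under ``score_literal``.
    """
    rec = {"probe": spec.id, "kind": spec.kind, "category": spec.category,
           "chance": spec.chance}
    rec.update({k: v for k, v in spec.meta.items()
                if k in ("excluded", "typicality", "n_atypical")})
    if spec.kind == "recognition-weather":
        rec["score_literal"] = mean_ratio_score(outputs, spec.correct, spec.denominator)
        rec["score"] = ratio_score(outputs, spec.correct, spec.denominator,
                                   chance=len(spec.correct) / len(spec.denominator))
        rec["chance"] = len(spec.correct) / len(spec.denominator)
    elif spec.kind == "atypical-feature":
        rec["score"], rec["chance"] = atypical_feature_score(
            outputs, spec.correct, spec.denominator)
    else:
        rec["score"] = ratio_score(outputs, spec.correct, spec.denominator,
                                   chance=spec.chance)
    return rec


def run_test_battery(network: Network, dataset, probe_sets=None,
                     trial: int | None = None) -> pd.DataFrame:
    """Run every probe of the requested probe sets (weights untouched).

    Returns a long-format table with one row per probe.
    """
    names = probe_sets if probe_sets is not None else \
        [k for k in dataset.probes if k != "rsa"]
    rows = []
    for name in names:
        for spec in dataset.probes[name]:
            state = probe(network, spec.input)
            rec = score_probe(state["EC_out"], spec)
            rec["probe_set"] = name
            if trial is not None:
                rec["trial"] = trial
            rows.append(rec)
    return pd.DataFrame(rows)
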