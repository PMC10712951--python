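"""Theta-phase Contrastive Hebbian Learning, lesions and trial schedules.

The network is trained as an autoencoder: the pattern clamped on the Input
layer must be reproduced on EC_out.  An intact learning trial has three
settled phases — two *minus* phases, corresponding to the trough and peak
of the theta rhythm, and one *plus* phase with the target clamped on
EC_out.  At the trough EC_in drives CA1 while CA3→CA1 is suppressed; at the
peak CA3 drives CA1 while EC_in→CA1 is suppressed, letting the two pathways
learn more independently.  After the trial, every learnable projection
moves its weights to reduce the difference between plus-phase and (mean)
minus-phase unit coactivities.

Lesioned networks (one pathway removed) use a single minus phase, since the
two-minus scheme exists to separate the two pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .netcore import ActivityState, Network, settle

__all__ = [
    "PhaseSchedule",
    "TrainingSchedule",
    "StoppingRule",
    "TrialRecord",
    "LESION_CONDITIONS",
    "INTACT_SCHEDULE",
    "LESIONED_SCHEDULE",
    "chl_delta",
    "hebbian_delta",
    "run_trial",
    "apply_lesion",
    "check_stop",
    "train",
    "schedule_for",
]

LESION_CONDITIONS = ("intact", "MSP-only", "TSP-only")

#: lesion condition -> projection whose strength is set to 0.  "MSP-only"
#: removes the trisynaptic route into CA1 (CA3→CA1); "TSP-only" removes the
#: direct monosynaptic route (EC_in→CA1).  CA1↔EC_out is never lesioned —
#: it is needed to produce output.
LESION_TARGET = {"MSP-only": ("CA3", "CA1"), "TSP-only": ("EC_in", "CA1")}


@dataclass(frozen=True)
class PhaseSchedule:
    """Ordered phases of one learning trial.

    ``minus_phases`` are settled with the input clamped and EC_out free;
    the plus phase additionally clamps the target on EC_out.
    """

    minus_phases: tuple
    plus_phase: str = "plus"

    def __post_init__(self):
        if not 1 <= len(self.minus_phases) <= 2:
            raise ValueError("a trial has one or two minus phases")


INTACT_SCHEDULE = PhaseSchedule(("trough", "peak"))
LESIONED_SCHEDULE = PhaseSchedule(("minus",), "plus_lesion")


def schedule_for(condition: str) -> PhaseSchedule:
    if condition not in LESION_CONDITIONS:
        raise ValueError(f"unknown lesion condition {condition!r}")
    return INTACT_SCHEDULE if condition == "intact" else LESIONED_SCHEDULE


@dataclass(frozen=True)
class StoppingRule:
    """Stop once, after at least ``min_trials`` trials, the last ``window``
    trials all have sum squared error below ``sse_threshold`` (used for the
    probabilistic task, where error cannot be driven to zero)."""

    min_trials: int = 25
    window: int = 5
    sse_threshold: float = 1.2


@dataclass
class TrainingSchedule:
    """How many trials to run, in what order, with which interim tests."""

    total_trials: int
    interim_test_trials: tuple = ()
    stopping_rule: StoppingRule | None = None
    max_cycles: int = 100
    tolerance: float = 1e-4


@dataclass
class TrialRecord:
    """Bookkeeping for one learning trial."""

    trial: int
    item_id: str
    sse: float
    mean_abs_delta: dict
    phase_states: dict | None = None


def chl_delta(plus_coproduct: np.ndarray, minus_coproducts,
              learning_rate: float, weights: np.ndarray,
              mask: np.ndarray) -> np.ndarray:
    """Contrastive Hebbian weight change for one projection.

    delta = lr * (plus coactivity − mean of the minus coactivities), applied
    only inside the connectivity mask and soft-bounded into [0, 1]: weight
    increases are scaled by (1 − w), decreases by w, so weights approach the
    bounds asymptotically instead of being clipped.
    """
    minus = np.mean(minus_coproducts, axis=0)
    if plus_coproduct.shape != weights.shape or minus.shape != weights.shape:
        raise ValueError("coactivity products do not match the projection shape")
    raw = learning_rate * (plus_coproduct - minus)
    bounded = np.where(raw > 0, raw * (1.0 - weights), raw * weights)
    return bounded * mask


def hebbian_delta(pre: np.ndarray, post: np.ndarray, learning_rate: float,
                  weights: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Self-organizing (CPCA-style) Hebbian weight change.

    For each connection, delta = lr * post * (pre − w): weights of active
    destination units move toward their presynaptic activity, strengthening
    the links that drove the winners and decaying unused ones.  Naturally
    bounded in [0, 1]; used for the input-side trisynaptic projections,
    whose pre/post activity carries no phase contrast.
    """
    return (learning_rate * post[None, :] * (pre[:, None] - weights)) * mask


def run_trial(network: Network, input_pattern: np.ndarray,
              target_pattern: np.ndarray | None = None,
              phase_schedule: PhaseSchedule = INTACT_SCHEDULE,
              max_cycles: int = 100, tolerance: float = 1e-4,
              keep_states: bool = False, item_id: str = "",
              trial: int = 0) -> TrialRecord:
    """Settle all phases of one trial, then apply CHL updates once.

    The input pattern is clamped on Input throughout; the target (equal to
    the input for autoencoder training unless given) is clamped on EC_out in
    the plus phase only.  Sum squared error is measured between the first
    minus phase's settled EC_out and the target.
    """
    x = np.asarray(input_pattern, dtype=float)
    if x.shape[0] != network.layer("Input").size:
        raise ValueError("pattern length does not match Input layer size")
    target = x if target_pattern is None else np.asarray(target_pattern, dtype=float)

    states: dict[str, ActivityState] = {}
    for ph in phase_schedule.minus_phases:
        states[ph] = settle(network, {"Input": x}, ph, max_cycles, tolerance)
    states[phase_schedule.plus_phase] = settle(
        network, {"Input": x, "EC_out": target}, phase_schedule.plus_phase,
        max_cycles, tolerance)

    last_minus = states[phase_schedule.minus_phases[-1]]
    sse = float(np.sum((last_minus["EC_out"] - target) ** 2))

    mean_abs = {}
    plus_state = states[phase_schedule.plus_phase]
    for p in network.learnable_projections():
        hebb = p.spec.hebbian
        delta = 0.0
        if hebb < 1.0:
            plus_cop = np.outer(plus_state[p.src], plus_state[p.dst])
            # phase-matched contrast: a projection only learns from minus
            # phases in which it was transmitting (its gate open) — a
            # silenced synapse has no credit for that phase's coactivity
            phases = [ph for ph in phase_schedule.minus_phases
                      if p.spec.gate(ph) > 0.0]
            if not phases:
                phases = list(phase_schedule.minus_phases)
            minus_cops = [np.outer(states[ph][p.src], states[ph][p.dst])
                          for ph in phases]
            delta = (1.0 - hebb) * chl_delta(
                plus_cop, minus_cops, p.spec.learning_rate, p.weights, p.mask)
        if hebb > 0.0:
            hrate = p.spec.hebbian_rate
            if hrate is None:
                hrate = p.spec.learning_rate
            delta = delta + hebb * hebbian_delta(
                plus_state[p.src], plus_state[p.dst], hrate,
                p.weights, p.mask)
        if p.spec.decay > 0.0:
            lo, hi = p.spec.weight_init
            delta = delta - p.spec.decay * (p.weights - 0.5 * (lo + hi)) * p.mask
        p.weights += delta
        mean_abs[f"{p.src}->{p.dst}"] = float(np.abs(delta).mean())
    return TrialRecord(trial, item_id, sse, mean_abs,
                       states if keep_states else None)


def apply_lesion(network: Network, condition: str) -> Network:
    """Return a copy of the network with the condition's pathway silenced.

    The lesioned projection contributes zero drive in every phase and is
    excluded from learning, for the entire run (training and test).
    ``intact`` returns an unmodified copy.
    """
    if condition not in LESION_CONDITIONS:
        raise ValueError(f"unknown lesion condition {condition!r}")
    out = network.copy()
    if condition != "intact":
        src, dst = LESION_TARGET[condition]
        out.projection(src, dst).lesioned = True
    return out


def check_stop(sse_history, rule: StoppingRule | None) -> bool:
    """True iff the stopping rule is configured and satisfied.

    The decision can only fire at or after ``min_trials`` trials; the
    qualifying window is the most recent ``window`` trials (it may have
    begun earlier).
    """
    if rule is None:
        return False
    n = len(sse_history)
    if n < rule.min_trials or n < rule.window:
        return False
    recent = sse_history[-rule.window:]
    return all(s < rule.sse_threshold for s in recent)


def _trial_order(dataset, schedule: TrainingSchedule, rng: np.random.Generator):
    """Yield item indices for each trial according to the dataset's policy."""
    n = len(dataset.items)
    if dataset.trial_policy == "replacement":
        yield from rng.integers(0, n, size=schedule.total_trials)
    elif dataset.trial_policy == "weighted":
        yield from rng.choice(n, size=schedule.total_trials,
                              p=dataset.sample_weights)
    elif dataset.trial_policy == "epochs":
        if schedule.total_trials % n:
            raise ValueError("epoch policy needs total_trials divisible by "
                             "the number of items")
        order = np.concatenate([rng.permutation(n)
                                for _ in range(schedule.total_trials // n)])
        yield from order
    else:
        raise ValueError(f"unknown trial policy {dataset.trial_policy!r}")


def train(network: Network, dataset, schedule: TrainingSchedule,
          condition: str = "intact", seed: int = 0,
          interim_test=None):
    """Run a full training schedule on a (possibly lesioned) network.

    ``interim_test(trial, network)`` is called, with weights frozen, at
    every trial index in ``schedule.interim_test_trials`` (trial 0 = before
    any training) and after the final trial.  The stopping rule, when
    configured, ends training early.  Returns ``(network, records)`` —
    the trained network and the per-trial :class:`TrialRecord` list.
    """
    if not dataset.items:
        raise ValueError("empty dataset")
    phase_schedule = schedule_for(condition)
    rng = np.random.default_rng(seed)
    interim = set(schedule.interim_test_trials)
    if interim_test is not None and 0 in interim:
        interim_test(0, network)
    records = []
    sse_history = []
    for t, idx in enumerate(_trial_order(dataset, schedule, rng), start=1):
        item = dataset.items[int(idx)]
        rec = run_trial(network, item.vector,
                        phase_schedule=phase_schedule,
                        max_cycles=schedule.max_cycles,
                        tolerance=schedule.tolerance,
                        item_id=item.id, trial=t)
        records.append(rec)
        sse_history.append(rec.sse)
        stopped = check_stop(sse_history, schedule.stopping_rule)
        if interim_test is not None and (t in interim or stopped
                                         or t == schedule.total_trials):
            interim_test(t, network)
        if stopped:
            break
    return network, records
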