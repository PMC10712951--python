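"""Scikit-learn style estimator wrapping the hippocampal circuit.

:class:`HippocampusAutoencoder` packages network construction, optional
pathway lesioning and Contrastive Hebbian training behind the familiar
``fit`` / ``predict`` / ``transform`` surface, so the model composes with
sklearn tooling (cloning, ``get_params``/``set_params``, pipelines whose
final step reconstructs patterns or exposes hidden-layer codes).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted, check_random_state

from . import netcore, plasticity
from .plasticity import StoppingRule, TrainingSchedule
from .scoring import probe
from .tasks import CategoryDataset, Exemplar

__all__ = ["HippocampusAutoencoder"]


class HippocampusAutoencoder(TransformerMixin, BaseEstimator):
    """Rate-coded hippocampal autoencoder with TSP and MSP pathways.

    The circuit reproduces input patterns on its output layer, learning
    through theta-phase Contrastive Hebbian Learning.  The sparse,
    fast-learning trisynaptic pathway (EC→DG→CA3→CA1) pattern-separates
    exemplars while the dense, slow-learning monosynaptic pathway
    (EC→CA1) extracts the statistical regularities that define category
    structure; either can be lesioned.

    Parameters
    ----------
    lesion : {"intact", "MSP-only", "TSP-only"}
        "MSP-only" silences CA3→CA1 (removing the trisynaptic route),
        "TSP-only" silences EC_in→CA1.  Lesioned models train with a single
        minus phase.
    n_trials : int
        Number of learning trials (each trial presents one pattern).
    trial_policy : {"replacement", "epochs", "weighted"}
        How trials are drawn from the training patterns.
    tsp_learning_rate, msp_learning_rate : float
        Per-weight contrastive step sizes; the trisynaptic pathway learns
        an order of magnitude faster than the monosynaptic one (10:1).
    input_k : int or None
        kWTA set-point for the Input/EC layers; default is the typical
        number of active units in the training patterns.
    dg_size, ca3_size, ca1_size / dg_k, ca3_k, ca1_k
        Hidden layer sizes and inhibition set-points.  DG and CA3 carry
        high inhibition (sparse codes), CA1 lower inhibition.
    gain, inhib_floor : float
        Transfer-function slope and minimum inhibition level.
    stopping_rule : StoppingRule or None
        Optional early stopping on a run of low-error trials.
    random_state : int, RandomState or None
        Seeds connection topography, initial weights and trial order.

    Attributes
    ----------
    network_ : the trained :class:`~hippolearn.netcore.Network`.
    sse_history_ : per-trial sum squared reconstruction error.
    n_trials_ : number of trials actually run (may stop early).
    n_features_in_ : input pattern length.
    """

    def __init__(self, lesion="intact", n_trials=140, trial_policy="replacement",
                 tsp_learning_rate=0.1, msp_learning_rate=0.01,
                 output_learning_rate=None, input_k=None, dg_size=400, ca3_size=80, ca1_size=100,
                 dg_k=8, ca3_k=16, ca1_k=20, gain=80.0, inhib_floor=0.02,
                 rel_floor=0.25, dt=0.4,
                 stopping_rule=None, max_cycles=100, tolerance=1e-4,
                 random_state=None):
        self.lesion = lesion
        self.n_trials = n_trials
        self.trial_policy = trial_policy
        self.tsp_learning_rate = tsp_learning_rate
        self.msp_learning_rate = msp_learning_rate
        self.output_learning_rate = output_learning_rate
        self.input_k = input_k
        self.dg_size = dg_size
        self.ca3_size = ca3_size
        self.ca1_size = ca1_size
        self.dg_k = dg_k
        self.ca3_k = ca3_k
        self.ca1_k = ca1_k
        self.gain = gain
        self.inhib_floor = inhib_floor
        self.rel_floor = rel_floor
        self.dt = dt
        self.stopping_rule = stopping_rule
        self.max_cycles = max_cycles
        self.tolerance = tolerance
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _seed(self) -> int:
        if isinstance(self.random_state, (int, np.integer)):
            return int(self.random_state)
        rs = check_random_state(self.random_state)
        return int(rs.randint(0, 2**31 - 1))

    def _as_dataset(self, X, sample_weight) -> CategoryDataset:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2d (n_patterns, n_units)")
        items = [Exemplar(f"item{i}", "item", row) for i, row in enumerate(X)]
        policy = self.trial_policy
        w = None
        if sample_weight is not None:
            w = np.asarray(sample_weight, dtype=float)
            w = w / w.sum()
            policy = "weighted"
        k = self.input_k
        if k is None:
            k = max(1, int(round(float((X > 0.5).sum(axis=1).mean()))))
        return CategoryDataset("adhoc", X.shape[1], k, items, {},
                               trial_policy=policy, sample_weights=w)

    def fit(self, X, y=None, sample_weight=None):
        """Train the circuit to reconstruct the patterns in ``X``.

        ``y`` is ignored (the model is an autoencoder); ``sample_weight``
        sets per-pattern presentation probabilities.
        """
        return self.fit_dataset(self._as_dataset(X, sample_weight))

    def fit_dataset(self, dataset: CategoryDataset, interim_test=None):
        """Train on a task dataset (satellites / weather / typicality).

        ``interim_test(trial, network)`` is invoked, weights frozen, at
        trial 0 and after each scheduled interim trial.
        """
        seed = self._seed()
        layers = netcore.default_layer_specs(
            dataset.input_size, self.input_k or dataset.input_k,
            dg_size=self.dg_size, ca3_size=self.ca3_size, ca1_size=self.ca1_size,
            dg_k=self.dg_k, ca3_k=self.ca3_k, ca1_k=self.ca1_k,
            gain=self.gain, inhib_floor=self.inhib_floor,
            rel_floor=self.rel_floor, dt=self.dt)
        projections = netcore.default_projection_specs(
            self.tsp_learning_rate, self.msp_learning_rate,
            self.output_learning_rate)
        net = netcore.build_network(layers, projections, seed=seed)
        net = plasticity.apply_lesion(net, self.lesion)
        schedule = TrainingSchedule(
            total_trials=self.n_trials,
            interim_test_trials=(0,) if interim_test else (),
            stopping_rule=self.stopping_rule,
            max_cycles=self.max_cycles, tolerance=self.tolerance)
        net, records = plasticity.train(net, dataset, schedule,
                                        condition=self.lesion, seed=seed,
                                        interim_test=interim_test)
        self.network_ = net
        self.records_ = records
        self.sse_history_ = np.array([r.sse for r in records])
        self.n_trials_ = len(records)
        self.n_features_in_ = dataset.input_size
        return self

    # ------------------------------------------------------------------
    def _check_X(self, X):
        check_is_fitted(self, "network_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"X has {X.shape[1]} features, expected "
                             f"{self.n_features_in_}")
        return X

    def predict(self, X) -> np.ndarray:
        """Settled EC_out reconstruction for each input pattern."""
        X = self._check_X(X)
        return np.stack([probe(self.network_, row)["EC_out"] for row in X])

    def transform(self, X, layer: str = "CA1", mode: str = "settled") -> np.ndarray:
        """Hidden-layer representation evoked by each pattern.

        ``mode="initial"`` disables big-loop recirculation during settling.
        """
        X = self._check_X(X)
        m = "settled" if mode == "settled" else "initial"
        return np.stack([probe(self.network_, row, mode=m)[layer] for row in X])

    def score(self, X, y=None) -> float:
        """Mean reconstruction accuracy: 1 − SSE / n_units, averaged over X."""
        X = self._check_X(X)
        out = self.predict(X)
        sse = ((out - X) ** 2).sum(axis=1)
        return float(np.mean(1.0 - sse / X.shape[1]))
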