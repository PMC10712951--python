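"""Hippocampal circuit core: layers, projections, k-winner-take-all settling.

The circuit is a rate-coded network with five functional layers — superficial
and deep entorhinal cortex (``EC_in``, ``EC_out``) plus the hippocampal
subfields ``DG``, ``CA3`` and ``CA1`` — and a separate ``Input`` layer, the
same size as ``EC_in``, on which external patterns are clamped.  Two routes
link EC to CA1: the sparse, fast-learning trisynaptic pathway (TSP:
EC_in→DG→CA3→CA1) and the dense, slow-learning monosynaptic pathway (MSP:
EC_in→CA1).  CA1 talks bidirectionally to EC_out, and EC_out recirculates
one-to-one back into EC_in (the "big loop").

Unit activities are rates in [0, 1].  Within-layer inhibition is a set-point
k-winner-take-all (kWTA) current: the inhibition level is placed between the
k-th and (k+1)-th largest excitatory drives so that roughly ``k_active``
units of a layer can be strongly active, and activity is a saturating
logistic function of (drive − inhibition).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

__all__ = [
    "LayerSpec",
    "ProjectionSpec",
    "Projection",
    "Network",
    "ActivityState",
    "build_network",
    "net_input",
    "apply_kwta",
    "settle",
    "save_network",
    "load_network",
]

#: order in which free layers are updated within one settling cycle —
#: the anatomical feedforward sweep.
LAYER_UPDATE_ORDER = ("EC_in", "DG", "CA3", "CA1", "EC_out")

LAYER_NAMES = ("Input", "EC_in", "EC_out", "DG", "CA3", "CA1")

#: canonical phase labels
PHASES = ("trough", "peak", "minus", "plus", "plus_lesion", "test", "test_initial")

#: strong-activity threshold used when counting kWTA winners
STRONG_ACTIVITY = 0.5


@dataclass(frozen=True)
class LayerSpec:
    """One pool of rate-coded units.

    Parameters
    ----------
    name : layer name, one of ``LAYER_NAMES``.
    size : number of units (> 0).
    k_active : set-point of the kWTA inhibition, 1 <= k_active <= size.
    gain : slope of the logistic transfer of (drive - inhibition).
    inhib_floor : minimum inhibition level; keeps zero-drive units silent
        when fewer than ``k_active`` units receive any excitation.
    rel_floor : inhibition floor relative to the strongest drive in the
        layer (set-point inhibition scales with overall excitation), so a
        weakly driven layer still resolves a competition among its
        best-driven units instead of falling silent.
    """

    name: str
    size: int
    k_active: int
    gain: float = 80.0
    inhib_floor: float = 0.02
    rel_floor: float = 0.25
    #: step size of the graded activation update, in (0, 1]: activity moves
    #: this fraction of the way toward its instantaneous target each cycle.
    #: Values < 1 give units temporal integration, letting an attractor
    #: seeded by the external cue establish itself before slower recurrent
    #: signals (e.g. big-loop recirculation) arrive.
    dt: float = 0.4

    def __post_init__(self):
        if self.name not in LAYER_NAMES:
            raise ValueError(f"unknown layer name {self.name!r}")
        if self.size <= 0:
            raise ValueError("layer size must be positive")
        if not 1 <= self.k_active <= self.size:
            raise ValueError("k_active must be in [1, size]")


@dataclass(frozen=True)
class ProjectionSpec:
    """Wiring rule for one projection between layers.

    ``connectivity_fraction`` is the proportion of source units each
    destination unit receives from (fan-in is ``round(fraction * src_size)``,
    at least 1).  ``phase_gates`` maps a phase label to a multiplicative
    strength in [0, 1]; unlisted phases default to 1.  ``identity`` wires
    unit i to unit i with fixed weight 1 (layers must be the same size).
    """

    src: str
    dst: str
    connectivity_fraction: float = 1.0
    learnable: bool = True
    learning_rate: float = 0.0
    pathway_tag: str = "fixed"  # {"TSP", "MSP", "fixed"}
    phase_gates: dict = field(default_factory=dict)
    weight_init: tuple = (0.25, 0.75)
    identity: bool = False
    exclude_self: bool = False  # for recurrent projections
    #: constant relative strength of this projection (multiplies the phase
    #: gate): >1 for the "detonator" mossy-fiber drive that lets sparse DG
    #: activity dictate CA3 winner choice at encoding, <1 for big-loop
    #: recirculation so external input keeps priority over retrieved output.
    strength: float = 1.0
    #: mixing coefficient for a self-organizing Hebbian (CPCA-style)
    #: component of learning, in [0, 1].  The input-side trisynaptic
    #: projections learn purely this way (their pre/post activity is
    #: identical across theta phases, so the contrastive term carries no
    #: signal there); error-driven projections use 0.
    hebbian: float = 0.0
    #: step size of the Hebbian component (defaults to learning_rate).
    #: Episodic binding in the trisynaptic pathway is effectively one-shot,
    #: so the binding rate is larger than the contrastive rates.
    hebbian_rate: float | None = None
    #: columnar (topographic) wiring: unit j of the larger layer connects
    #: to unit j mod n of the smaller layer, giving each EC unit its own
    #: small CA1 column.  Used for the CA1↔EC_out interface.
    columnar: bool = False
    #: drop connections from each source unit onto its own destination
    #: column (see ``columnar``).  Used for EC_in→CA1: the direct pathway
    #: then carries cross-feature statistical structure — a unit's own
    #: output column is reachable only through correlated features or
    #: through CA3 — instead of a trivial identity map.
    exclude_own_column: bool = False
    #: per-trial decay of learned weight change back toward the initial
    #: mean.  Acts as a rate filter: associations reinforced often reach a
    #: high steady state, rare (item-specific) ones decay away between
    #: reinforcements — how the slow pathway keeps category statistics
    #: without retaining single exemplars.
    decay: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.connectivity_fraction <= 1.0:
            raise ValueError(
                f"connectivity fraction must be in (0, 1], got "
                f"{self.connectivity_fraction} for {self.src}->{self.dst}"
            )

    def gate(self, phase: str) -> float:
        return float(self.phase_gates.get(phase, 1.0))


class Projection:
    """A realized projection: binary mask, weight matrix, fan-in counts.

    Weights are stored as an (src_size, dst_size) array; entries outside the
    mask are exactly 0 and stay 0 under learning.  ``lesioned`` zeroes the
    projection's effective strength without touching the stored weights.

    ``norm`` is the drive normalizer: the number of incoming connections a
    destination unit can expect to be *active* (source k_active scaled by
    the connection fraction, at least 1), so winner drives are O(1) for
    sparse and dense projections alike.
    """

    __slots__ = ("spec", "mask", "weights", "fan_in", "norm", "lesioned")

    def __init__(self, spec, mask, weights, src_k_active=None):
        self.spec = spec
        self.mask = mask
        self.weights = weights
        self.fan_in = mask.sum(axis=0).astype(float)
        if np.any(self.fan_in == 0):
            raise ValueError(f"projection {spec.src}->{spec.dst} has a dst unit with no inputs")
        src_size = mask.shape[0]
        k = src_size if src_k_active is None else src_k_active
        self.norm = np.maximum(k * self.fan_in / src_size, 1.0)
        self.lesioned = False

    @property
    def src(self):
        return self.spec.src

    @property
    def dst(self):
        return self.spec.dst

    def effective_weights(self, phase: str) -> np.ndarray | None:
        """Gated, fan-in-normalized weight matrix for ``phase``.

        Returns None when the projection contributes nothing (gate 0 or
        lesioned), letting the settling loop skip it.
        """
        if self.lesioned:
            return None
        g = self.spec.gate(phase) * self.spec.strength
        if g == 0.0:
            return None
        return self.weights * (g / self.norm)

    def copy(self) -> "Projection":
        p = Projection.__new__(Projection)
        p.spec = self.spec
        p.mask = self.mask
        p.weights = self.weights.copy()
        p.fan_in = self.fan_in
        p.norm = self.norm
        p.lesioned = self.lesioned
        return p


def default_projection_specs(tsp_lr: float = 0.1, msp_lr: float = 0.01,
                             output_lr: float | None = None) -> list:
    """The canonical wiring of the circuit.

    TSP: EC_in→DG and EC_in→CA3 at 25% connectivity, DG→CA3 at 5%, a full
    CA3 recurrent collateral system (no self-connections) and full CA3→CA1.
    MSP: full EC_in→CA1 plus bidirectional CA1↔EC_out.  Input→EC_in and
    EC_out→EC_in are fixed one-to-one links; the latter carries big-loop
    recirculation and is the projection silenced in "initial-response" mode.

    The input-side TSP projections self-organize (pure Hebbian, forming
    pattern-separated codes and CA3 attractors); CA3→CA1 and the MSP learn
    by the contrastive rule.  The trisynaptic learning rate is 10x the
    monosynaptic one (0.02 vs 0.002).  ``output_lr`` sets the CA1↔EC_out
    rate (default: the fast rate, since these links carry all output
    regardless of pathway).

    Theta-phase gates: at the simulated trough CA3→CA1 is suppressed, at the
    simulated peak EC_in→CA1 is suppressed; both are open in the plus phase
    and at test.
    """
    if output_lr is None:
        output_lr = tsp_lr
    return [
        ProjectionSpec("Input", "EC_in", identity=True, learnable=False),
        ProjectionSpec("EC_out", "EC_in", identity=True, learnable=False,
                       strength=0.5, phase_gates={"test_initial": 0.0}),
        ProjectionSpec("EC_in", "DG", 0.25, False, 0.0, "TSP",
                       weight_init=(0.0, 0.2)),
        ProjectionSpec("EC_in", "CA3", 0.25, True, tsp_lr, "TSP",
                       weight_init=(0.0, 0.2), hebbian=1.0, hebbian_rate=0.4),
        ProjectionSpec("DG", "CA3", 0.05, False, 0.0, "TSP", strength=32.0,
                       weight_init=(0.0, 0.2),
                       phase_gates={"test": 0.0, "test_initial": 0.0}),
        ProjectionSpec("CA3", "CA3", 1.0, True, tsp_lr, "TSP",
                       weight_init=(0.0, 0.2), exclude_self=True,
                       hebbian=1.0, hebbian_rate=0.4),
        ProjectionSpec("CA3", "CA1", 1.0, True, tsp_lr, "TSP", strength=2.0,
                       weight_init=(0.0, 0.2), phase_gates={"trough": 0.0}),
        ProjectionSpec("EC_in", "CA1", 1.0, True, msp_lr, "MSP",
                       weight_init=(0.0, 0.2),
                       phase_gates={"peak": 0.0, "plus": 0.0},
                       exclude_own_column=True),
        ProjectionSpec("CA1", "EC_out", 1.0, True, output_lr, "MSP",
                       weight_init=(0.3, 0.7), columnar=True),
        ProjectionSpec("EC_out", "CA1", 1.0, True, output_lr, "MSP",
                       weight_init=(0.3, 0.7), columnar=True),
    ]


def default_layer_specs(input_size: int, input_k: int, *, dg_size: int = 400,
                        ca3_size: int = 80, ca1_size: int = 100, dg_k: int = 8,
                        ca3_k: int = 16, ca1_k: int = 20, gain: float = 80.0,
                        inhib_floor: float = 0.02, rel_floor: float = 0.25,
                        dt: float = 0.4) -> list:
    """Default layer table: DG 400, CA3 80, CA1 100 units; EC/Input layers
    sized by the task.  DG and CA3 carry high within-layer inhibition
    (sparse codes: 2% of DG, 20% of CA3), CA1 lower inhibition (20% of a
    layer 4x smaller than DG); EC layers allow as many winners as a typical
    pattern has active units."""
    mk = lambda name, size, k: LayerSpec(name, size, k, gain=gain,
                                         inhib_floor=inhib_floor,
                                         rel_floor=rel_floor, dt=dt)
    return [
        mk("Input", input_size, input_k),
        mk("EC_in", input_size, input_k),
        mk("EC_out", input_size, input_k),
        mk("DG", dg_size, dg_k),
        mk("CA3", ca3_size, ca3_k),
        mk("CA1", ca1_size, ca1_k),
    ]


class Network:
    """The simulated hippocampal circuit: layers, projections, weights."""

    def __init__(self, layers, projections, rng_seed):
        self.layers = {sp.name: sp for sp in layers}
        self.projections = list(projections)
        self.rng_seed = rng_seed
        self._incoming = {}
        for p in self.projections:
            self._incoming.setdefault(p.dst, []).append(p)

    def layer(self, name: str) -> LayerSpec:
        return self.layers[name]

    def incoming(self, dst: str) -> list:
        return self._incoming.get(dst, [])

    def projection(self, src: str, dst: str) -> Projection:
        for p in self.projections:
            if p.src == src and p.dst == dst:
                return p
        raise KeyError(f"no projection {src}->{dst}")

    def copy(self) -> "Network":
        return Network(self.layers.values(), [p.copy() for p in self.projections],
                       self.rng_seed)

    def weights_hash(self) -> str:
        h = hashlib.sha256()
        for p in self.projections:
            h.update(p.weights.tobytes())
        return h.hexdigest()

    def learnable_projections(self) -> list:
        return [p for p in self.projections
                if p.spec.learnable and not p.lesioned]


@dataclass
class ActivityState:
    """Per-layer activations for one settled phase."""

    activations: dict
    phase: str
    cycles: int
    converged: bool

    def __getitem__(self, layer: str) -> np.ndarray:
        return self.activations[layer]


def _columnar_mask(src_size: int, dst_size: int) -> np.ndarray:
    mask = np.zeros((src_size, dst_size), dtype=bool)
    if src_size <= dst_size:  # e.g. EC_out -> CA1 columns
        for j in range(dst_size):
            mask[j % src_size, j] = True
    else:
        for i in range(src_size):
            mask[i, i % dst_size] = True
    return mask


def _realize_projection(spec: ProjectionSpec, src_size: int, dst_size: int,
                        rng: np.random.Generator, src_k_active=None) -> Projection:
    if spec.columnar:
        mask = _columnar_mask(src_size, dst_size)
        lo, hi = spec.weight_init
        weights = rng.uniform(lo, hi, size=(src_size, dst_size)) * mask
        return Projection(spec, mask, weights, src_k_active)
    if spec.identity:
        if src_size != dst_size:
            raise ValueError(
                f"identity projection {spec.src}->{spec.dst} requires equal "
                f"layer sizes ({src_size} vs {dst_size})")
        eye = np.eye(src_size)
        return Projection(spec, eye.astype(bool), eye.copy(), src_k_active)
    mask = np.zeros((src_size, dst_size), dtype=bool)
    if spec.connectivity_fraction >= 1.0:
        mask[:] = True
        if spec.exclude_own_column:
            cols = np.arange(dst_size) % src_size
            mask[cols, np.arange(dst_size)] = False
    else:
        fan = max(1, round(spec.connectivity_fraction * src_size))
        for j in range(dst_size):  # independent draw per destination unit
            mask[rng.choice(src_size, size=fan, replace=False), j] = True
    if spec.exclude_self:
        np.fill_diagonal(mask, False)
    lo, hi = spec.weight_init
    weights = rng.uniform(lo, hi, size=(src_size, dst_size)) * mask
    return Projection(spec, mask, weights, src_k_active)


def build_network(layer_specs, projection_specs=None, seed: int = 0) -> Network:
    """Construct the circuit with seeded masks and initial weights.

    Both the topography of sparse connections and the individual weight
    values are drawn from ``seed``; the same (specs, seed) pair always yields
    a bit-identical network.
    """
    if projection_specs is None:
        projection_specs = default_projection_specs()
    layer_specs = list(layer_specs)
    sizes = {sp.name: sp.size for sp in layer_specs}
    ks = {sp.name: sp.k_active for sp in layer_specs}
    rng = np.random.default_rng(seed)
    projections = []
    for ps in projection_specs:
        if ps.src not in sizes or ps.dst not in sizes:
            raise ValueError(f"projection {ps.src}->{ps.dst} names an unknown layer")
        projections.append(_realize_projection(ps, sizes[ps.src], sizes[ps.dst],
                                               rng, ks[ps.src]))
    return Network(layer_specs, projections, seed)


def apply_kwta(drives: np.ndarray, k_active: int, gain: float = 80.0,
               inhib_floor: float = 0.02, rel_floor: float = 0.25) -> np.ndarray:
    """Set-point kWTA inhibition followed by a saturating transfer.

    The layer-wide inhibition level is the midpoint of the k-th and (k+1)-th
    largest drives (floored at ``inhib_floor``), so approximately ``k_active``
    units end up above the strong-activity threshold of 0.5.  The transfer is
    a logistic of gain * (drive - inhibition): monotone in drive, bounded in
    [0, 1], and symmetric under permutations and ties.
    """
    drives = np.asarray(drives, dtype=float)
    if not np.all(np.isfinite(drives)):
        raise ValueError("non-finite drives")
    n = drives.shape[0]
    if not 1 <= k_active <= n:
        raise ValueError("k_active must be in [1, len(drives)]")
    floor = inhib_floor
    dmax = drives.max()
    if rel_floor * dmax > floor:
        floor = rel_floor * dmax
    thr = _kwta_threshold(drives, k_active, floor)
    # hard threshold: units below the inhibition level are silent (not
    # merely exponentially small), as in threshold-linear rate units; above
    # it, activity rises saturating toward 1
    out = 2.0 * expit(gain * (drives - thr)) - 1.0
    np.clip(out, 0.0, 1.0, out=out)
    return out


#: drives closer than this are treated as tied (saturated rate units often
#: tie exactly; a tie spanning the k-boundary admits the whole tied class,
#: keeping the inhibition symmetric instead of silencing all tied units)
TIE_TOL = 1e-6


def _kwta_threshold(drives: np.ndarray, k_active: int, floor: float) -> float:
    """Set-point inhibition level: midpoint of the k-th largest drive and
    the next *distinct* drive below it, floored at ``floor``."""
    n = drives.shape[0]
    if k_active >= n:
        return floor
    d_k = np.partition(drives, n - k_active)[n - k_active]
    below = drives[drives < d_k - TIE_TOL]
    thr = 0.5 * (d_k + below.max()) if below.size else floor
    return thr if thr > floor else floor


def net_input(dst_layer: str, network: Network, activations: dict,
              phase: str = "test") -> np.ndarray:
    """Excitatory drive of each unit in ``dst_layer``.

    Per projection, the masked weighted sum of presynaptic activity is
    normalized by the projection's fan-in (keeping sparse and full
    projections on a common scale) and scaled by its phase gate; the
    contributions of all incoming projections are summed.
    """
    drive = np.zeros(network.layer(dst_layer).size)
    for p in network.incoming(dst_layer):
        W = p.effective_weights(phase)
        if W is None:
            continue
        try:
            src_act = activations[p.src]
        except KeyError:
            raise KeyError(f"no activations for source layer {p.src!r}") from None
        drive += src_act @ W
    return drive


def settle(network: Network, clamps: dict, phase: str, max_cycles: int = 100,
           tolerance: float = 1e-4) -> ActivityState:
    """Iterate net-input + kWTA over free layers until activity stabilizes.

    Layers named in ``clamps`` hold their clamped values exactly throughout.
    Free layers start silent and are updated in the anatomical sweep order
    (EC_in, DG, CA3, CA1, EC_out), each update seeing the most recent
    activity of the others.  Settling stops when the largest absolute
    activation change in a cycle drops below ``tolerance``; hitting
    ``max_cycles`` first is not an error — the state is returned flagged
    unconverged.
    """
    acts = {}
    for name, spec in network.layers.items():
        if name in clamps:
            v = np.asarray(clamps[name], dtype=float)
            if v.shape[0] != spec.size:
                raise ValueError(f"clamp for {name} has length {v.shape[0]}, "
                                 f"expected {spec.size}")
            acts[name] = v
        else:
            acts[name] = np.zeros(spec.size)

    free = [n for n in LAYER_UPDATE_ORDER if n not in clamps and n in network.layers]
    # fold gates / fan-in into the weights once per settle (weights are
    # static within a phase)
    incoming = {}
    for name in free:
        rows = []
        for p in network.incoming(name):
            W = p.effective_weights(phase)
            if W is not None:
                rows.append((p.src, W))
        incoming[name] = rows
    specs = {name: network.layer(name) for name in free}

    converged = False
    cycle = 0
    for cycle in range(1, max_cycles + 1):
        max_delta = 0.0
        for name in free:
            spec = specs[name]
            rows = incoming[name]
            if rows:
                src, W = rows[0]
                drive = acts[src] @ W
                for src, W in rows[1:]:
                    drive += acts[src] @ W
            else:
                drive = np.zeros(spec.size)
            floor = spec.inhib_floor
            dmax = drive[np.argmax(drive)]
            if spec.rel_floor * dmax > floor:
                floor = spec.rel_floor * dmax
            thr = _kwta_threshold(drive, spec.k_active, floor)
            target = 2.0 * expit(spec.gain * (drive - thr)) - 1.0
            np.clip(target, 0.0, 1.0, out=target)
            prev = acts[name]
            new = prev + spec.dt * (target - prev)
            d = float(np.max(np.abs(new - prev)))
            if d > max_delta:
                max_delta = d
            acts[name] = new
        if max_delta < tolerance:
            converged = True
            break
    return ActivityState(acts, phase, cycle, converged)


def save_network(network: Network, path) -> None:
    """Serialize masks, weights and seed to an .npz archive (bit-exact)."""
    arrays = {"rng_seed": np.asarray(network.rng_seed)}
    meta = []
    for i, p in enumerate(network.projections):
        arrays[f"mask_{i}"] = p.mask
        arrays[f"weights_{i}"] = p.weights
        arrays[f"lesioned_{i}"] = np.asarray(p.lesioned)
        meta.append((p.src, p.dst))
    arrays["edges"] = np.asarray(meta)
    layer_rows = [(sp.name, sp.size, sp.k_active, sp.gain, sp.inhib_floor)
                  for sp in network.layers.values()]
    arrays["layers"] = np.asarray([[str(x) for x in r] for r in layer_rows])
    np.savez(path, **arrays)


def load_network(path, projection_specs=None) -> Network:
    """Load a network saved by :func:`save_network`.

    ``projection_specs`` restores learning rates and gates (defaults to the
    canonical wiring); masks, weights and lesion flags come from the file.
    """
    with np.load(path, allow_pickle=False) as z:
        layers = [LayerSpec(r[0], int(r[1]), int(r[2]), float(r[3]), float(r[4]))
                  for r in z["layers"]]
        edges = [tuple(e) for e in z["edges"]]
        if projection_specs is None:
            projection_specs = default_projection_specs()
        spec_by_edge = {(ps.src, ps.dst): ps for ps in projection_specs}
        ks = {sp.name: sp.k_active for sp in layers}
        projections = []
        for i, edge in enumerate(edges):
            spec = spec_by_edge[edge]
            p = Projection(spec, z[f"mask_{i}"], z[f"weights_{i}"],
                           src_k_active=ks[spec.src])
            p.lesioned = bool(z[f"lesioned_{i}"])
            projections.append(p)
        seed = int(z["rng_seed"])
    return Network(layers, projections, seed)
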