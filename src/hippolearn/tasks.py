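"""Synthetic category-learning paradigms.

Three stimulus sets exercise different kinds of category structure:

* **Satellites** — three deterministic categories of five "satellite"
  exemplars over 27 binary input units (9 per category: 5 shared features,
  one of which is category-prototypical and present in every exemplar, plus
  4 unique features, each belonging to a single exemplar).
* **Weather prediction** — four cards, presented in combinations of one to
  three, probabilistically predict one of two outcomes (sun / rain); cards
  and outcome are encoded on 8 input units (4 cards + 2 units per outcome).
* **Typicality continuum** — two categories of creatures with 10 binary
  features; the prototypes share no features and exemplars vary in how many
  features they share with their prototype; inputs are 30 units (2 per
  feature + 5 label units per category).

Every dataset is generated from a seed; counts and structure are fixed,
only arbitrary assignments (which features swap, which novel combinations
are drawn) vary across seeds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .scoring import ProbeSpec

__all__ = [
    "Exemplar",
    "CategoryDataset",
    "ProbabilisticContingency",
    "build_satellite_dataset",
    "build_weather_dataset",
    "build_typicality_dataset",
    "load_contingency",
    "export_patterns",
]


@dataclass
class Exemplar:
    """One training item: binary input vector plus metadata."""

    id: str
    category: str
    vector: np.ndarray
    typicality: int | None = None  # shared-feature count with own prototype
    meta: dict = field(default_factory=dict)


@dataclass
class CategoryDataset:
    """Training exemplars, probe sets and layer-sizing metadata.

    ``input_k`` is the kWTA set-point used for the Input/EC layers (the
    typical number of active units in a training pattern).  ``trial_policy``
    names how training trials are drawn: "replacement" (uniform with
    replacement), "epochs" (shuffled passes through the item list) or
    "weighted" (per-item sampling weights, for the probabilistic task).
    """

    name: str
    input_size: int
    input_k: int
    items: list
    probes: dict
    trial_policy: str = "replacement"
    sample_weights: np.ndarray | None = None
    unit_roles: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def training_vectors(self) -> np.ndarray:
        return np.stack([it.vector for it in self.items])


@dataclass
class ProbabilisticContingency:
    """Card-combination frequency table for the probabilistic task."""

    combos: list          # list of tuples of card indices (1-based)
    frequencies: np.ndarray
    p_sun: np.ndarray
    excluded: np.ndarray  # True for equiprobable combinations

    def __post_init__(self):
        if np.any((self.p_sun < 0) | (self.p_sun > 1)):
            raise ValueError("outcome probabilities must lie in [0, 1]")
        if not np.isclose(self.frequencies.sum(), 1.0, atol=1e-6):
            raise ValueError("combination frequencies must sum to 1")

    @property
    def n_combos(self) -> int:
        return len(self.combos)

    def category(self, i: int) -> str:
        return "sun" if self.p_sun[i] > 0.5 else "rain"


def load_contingency(path=None) -> ProbabilisticContingency:
    """Load the contingency table (the packaged default when path is None)."""
    if path is None:
        text = resources.files("hippolearn.data").joinpath(
            "weather_contingency.yaml").read_text()
        raw = yaml.safe_load(text)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    combos = [tuple(row["cards"]) for row in raw["combinations"]]
    freq = np.array([row["frequency"] for row in raw["combinations"]], dtype=float)
    p_sun = np.array([row["p_sun"] for row in raw["combinations"]], dtype=float)
    excluded = np.isclose(p_sun, 0.5)
    return ProbabilisticContingency(combos, freq, p_sun, excluded)


# ---------------------------------------------------------------------------
# Satellites

N_CATEGORIES = 3
UNITS_PER_CATEGORY = 9  # 5 shared (first is category-prototypical) + 4 unique


def _sat_units(category: int):
    base = category * UNITS_PER_CATEGORY
    proto = base                      # category-prototypical feature
    shared = list(range(base, base + 5))
    swappable = shared[1:]            # shared features that exemplars may lose
    unique = list(range(base + 5, base + 9))
    return proto, shared, swappable, unique


def build_satellite_dataset(seed: int = 0) -> CategoryDataset:
    """Three categories x five satellites over 27 binary input units.

    Per category the prototype activates the 5 shared units; each of the 4
    other exemplars swaps one non-prototypical shared feature for its own
    unique feature (so every unique unit appears in exactly one exemplar).
    Probe sets: "unique" and "categorization" present a single unique
    feature; "generalization" presents 18 novel satellites (6 per category)
    built from two non-prototypical shared features plus two unique features
    in combinations never seen in training.
    """
    rng = np.random.default_rng(seed)
    input_size = N_CATEGORIES * UNITS_PER_CATEGORY
    cats = ["Alpha", "Beta", "Gamma"]
    items, probes = [], {"unique": [], "categorization": [], "generalization": [],
                         "rsa": []}
    proto_units = [_sat_units(c)[0] for c in range(N_CATEGORIES)]

    for c, cat in enumerate(cats):
        proto, shared, swappable, unique = _sat_units(c)
        vec = np.zeros(input_size)
        vec[shared] = 1.0
        items.append(Exemplar(f"{cat}_proto", cat, vec, typicality=5))
        dropped = rng.permutation(4)  # which shared feature each exemplar loses
        for j in range(4):
            vec = np.zeros(input_size)
            vec[shared] = 1.0
            vec[swappable[dropped[j]]] = 0.0
            vec[unique[j]] = 1.0
            items.append(Exemplar(f"{cat}_ex{j + 1}", cat, vec, typicality=4,
                                  meta={"unique_unit": unique[j],
                                        "dropped_shared": swappable[dropped[j]]}))
            probe_in = np.zeros(input_size)
            probe_in[unique[j]] = 1.0
            probes["unique"].append(ProbeSpec(
                id=f"{cat}_ex{j + 1}", kind="unique-feature", input=probe_in,
                correct=[unique[j]], denominator=list(unique), chance=0.25,
                category=cat))
            probes["categorization"].append(ProbeSpec(
                id=f"{cat}_ex{j + 1}", kind="categorization-sat", input=probe_in,
                correct=[proto], denominator=list(proto_units), chance=1 / 3,
                category=cat))
            probes["rsa"].append(ProbeSpec(
                id=f"{cat}_ex{j + 1}", kind="rsa", input=probe_in,
                correct=[proto], denominator=list(proto_units), chance=1 / 3,
                category=cat))
        # novel satellites: 2 of the 4 swappable shared + 2 of the 4 unique
        combos = list(itertools.product(itertools.combinations(range(4), 2),
                                        itertools.combinations(range(4), 2)))
        for g, idx in enumerate(rng.choice(len(combos), size=6, replace=False)):
            (s1, s2), (u1, u2) = combos[idx]
            vec = np.zeros(input_size)
            vec[[swappable[s1], swappable[s2], unique[u1], unique[u2]]] = 1.0
            probes["generalization"].append(ProbeSpec(
                id=f"{cat}_novel{g + 1}", kind="generalization-sat", input=vec,
                correct=[proto], denominator=list(proto_units), chance=1 / 3,
                category=cat))

    roles = {}
    for c, cat in enumerate(cats):
        proto, shared, _, unique = _sat_units(c)
        roles[proto] = (cat, "category-prototypical")
        for u in shared[1:]:
            roles[u] = (cat, "shared")
        for u in unique:
            roles[u] = (cat, "unique")
    return CategoryDataset("satellites", input_size, 5, items, probes,
                           trial_policy="replacement", unit_roles=roles)


# ---------------------------------------------------------------------------
# Weather prediction

N_CARDS = 4
SUN_UNITS = (4, 5)
RAIN_UNITS = (6, 7)
WEATHER_INPUT_SIZE = 8


def _weather_vector(cards, outcome=None) -> np.ndarray:
    vec = np.zeros(WEATHER_INPUT_SIZE)
    for c in cards:
        vec[c - 1] = 1.0
    if outcome == "sun":
        vec[list(SUN_UNITS)] = 1.0
    elif outcome == "rain":
        vec[list(RAIN_UNITS)] = 1.0
    return vec


def build_weather_dataset(seed: int = 0, contingency: ProbabilisticContingency | None = None):
    """Probabilistic weather task: items are (combination, outcome) pairs.

    Training items enumerate every card combination with each outcome,
    weighted by frequency(combination) x P(outcome | combination); a trial
    presents cards *and* outcome as input (observational training) and the
    target equals the input.  Probes present cards only: "recognition"
    scores reconstruction of the card units, "categorization" the outcome
    units.  The two equiprobable combinations are flagged ``excluded`` and
    dropped from analysis, not from training.

    Returns ``(dataset, contingency)``.
    """
    del seed  # structure is fully determined; kept for interface symmetry
    if contingency is None:
        contingency = load_contingency()
    items = []
    weights = []
    for i, cards in enumerate(contingency.combos):
        for outcome, p in (("sun", contingency.p_sun[i]),
                           ("rain", 1.0 - contingency.p_sun[i])):
            w = contingency.frequencies[i] * p
            if w <= 0:
                continue
            name = "".join(str(c) for c in cards)
            items.append(Exemplar(f"c{name}_{outcome}", contingency.category(i),
                                  _weather_vector(cards, outcome),
                                  meta={"cards": cards, "outcome": outcome,
                                        "combo_index": i}))
            weights.append(w)
    probes = {"recognition": [], "categorization": [], "rsa": []}
    card_units = list(range(N_CARDS))
    outcome_units = list(SUN_UNITS) + list(RAIN_UNITS)
    for i, cards in enumerate(contingency.combos):
        name = "".join(str(c) for c in cards)
        cat = contingency.category(i)
        excl = bool(contingency.excluded[i])
        vec = _weather_vector(cards)
        correct_cards = [c - 1 for c in cards]
        probes["recognition"].append(ProbeSpec(
            id=f"c{name}", kind="recognition-weather", input=vec,
            correct=correct_cards, denominator=card_units, chance=1.0,
            category=cat, meta={"excluded": excl}))
        correct_outcome = list(SUN_UNITS if cat == "sun" else RAIN_UNITS)
        probes["categorization"].append(ProbeSpec(
            id=f"c{name}", kind="categorization-weather", input=vec,
            correct=correct_outcome, denominator=outcome_units, chance=0.5,
            category=cat, meta={"excluded": excl}))
        probes["rsa"].append(ProbeSpec(
            id=f"c{name}", kind="rsa", input=vec, correct=correct_outcome,
            denominator=outcome_units, chance=0.5, category=cat,
            meta={"excluded": excl, "p_sun": float(contingency.p_sun[i])}))
    ds = CategoryDataset("weather", WEATHER_INPUT_SIZE, 4, items, probes,
                         trial_policy="weighted",
                         sample_weights=np.asarray(weights) / np.sum(weights),
                         extra={"contingency": contingency})
    return ds, contingency


# ---------------------------------------------------------------------------
# Typicality continuum

N_FEATURES = 10
LABEL_UNITS = {"A": list(range(20, 25)), "B": list(range(25, 30))}
TYP_INPUT_SIZE = 2 * N_FEATURES + 10
#: shared-feature count -> number of training items per category
TYP_TRAIN_DISTRIBUTION = {9: 2, 8: 3, 7: 3, 6: 2}
TYP_TEST_PER_LEVEL = 5


def _typ_vector(flips, category, with_label):
    """Feature encoding: unit 2f codes value 0 (prototype A), 2f+1 value 1
    (prototype B); ``flips`` lists the features taking the opposite
    prototype's value."""
    vec = np.zeros(TYP_INPUT_SIZE)
    for f in range(N_FEATURES):
        own = 1 if category == "B" else 0
        value = own ^ (1 if f in flips else 0)
        vec[2 * f + value] = 1.0
    if with_label:
        vec[LABEL_UNITS[category]] = 1.0
    return vec


def _atypical_side_units(category):
    """The 10 feature units carrying the opposite prototype's values."""
    other = 1 if category == "A" else 0
    return [2 * f + other for f in range(N_FEATURES)]


def build_typicality_dataset(seed: int = 0) -> CategoryDataset:
    """Two intermixed categories with graded typicality.

    20 training items (10 per category) whose shared-feature counts with
    their prototype follow {9: 2, 8: 3, 7: 3, 6: 2}; the prototypes are not
    trained.  Training inputs carry the 5-unit category label; all probes
    omit labels.  Probe sets: "generalization" (42 novel items: the two
    prototypes plus five per remaining typicality level, scored on label
    units) and "atypical" (the 20 training items, scored on the atypical
    feature units, chance 0.1 x number of atypical features).
    """
    rng = np.random.default_rng(seed)
    items = []
    used = {"A": set(), "B": set()}
    for cat in ("A", "B"):
        n = 0
        for shared, count in TYP_TRAIN_DISTRIBUTION.items():
            d = N_FEATURES - shared  # number of atypical features, 1..4
            for _ in range(count):
                while True:
                    flips = tuple(sorted(rng.choice(N_FEATURES, size=d, replace=False)))
                    if flips not in used[cat]:
                        used[cat].add(flips)
                        break
                n += 1
                items.append(Exemplar(
                    f"{cat}{n}", cat, _typ_vector(flips, cat, with_label=True),
                    typicality=shared,
                    meta={"flips": flips,
                          "atypical_units": [2 * f + (0 if cat == "B" else 1)
                                             for f in flips]}))

    probes = {"generalization": [], "atypical": [], "rsa": []}
    label_all = LABEL_UNITS["A"] + LABEL_UNITS["B"]
    for cat in ("A", "B"):
        probes["generalization"].append(ProbeSpec(
            id=f"{cat}_prototype", kind="generalization-typ",
            input=_typ_vector((), cat, with_label=False),
            correct=LABEL_UNITS[cat], denominator=label_all, chance=0.5,
            category=cat, meta={"typicality": 10}))
        for shared in TYP_TRAIN_DISTRIBUTION:
            d = N_FEATURES - shared
            chosen = set()
            while len(chosen) < TYP_TEST_PER_LEVEL:
                flips = tuple(sorted(rng.choice(N_FEATURES, size=d, replace=False)))
                if flips not in used[cat] and flips not in chosen:
                    chosen.add(flips)
            for t, flips in enumerate(sorted(chosen)):
                probes["generalization"].append(ProbeSpec(
                    id=f"{cat}_novel_s{shared}_{t + 1}", kind="generalization-typ",
                    input=_typ_vector(flips, cat, with_label=False),
                    correct=LABEL_UNITS[cat], denominator=label_all, chance=0.5,
                    category=cat, meta={"typicality": shared, "flips": flips}))
    for it in items:
        k = len(it.meta["flips"])
        probes["atypical"].append(ProbeSpec(
            id=it.id, kind="atypical-feature",
            input=_typ_vector(it.meta["flips"], it.category, with_label=False),
            correct=it.meta["atypical_units"],
            denominator=_atypical_side_units(it.category), chance=0.1 * k,
            category=it.category, meta={"typicality": it.typicality,
                                        "n_atypical": k}))
        probes["rsa"].append(ProbeSpec(
            id=it.id, kind="rsa",
            input=_typ_vector(it.meta["flips"], it.category, with_label=False),
            correct=LABEL_UNITS[it.category], denominator=label_all, chance=0.5,
            category=it.category, meta={"typicality": it.typicality}))
    return CategoryDataset("typicality", TYP_INPUT_SIZE, 15, items, probes,
                           trial_policy="epochs")


def export_patterns(dataset: CategoryDataset, path) -> pd.DataFrame:
    """Write the training patterns as a delimited table (one row per item)."""
    rows = []
    for it in dataset.items:
        row = {"id": it.id, "category": it.category, "typicality": it.typicality}
        row.update({f"u{i}": int(v) for i, v in enumerate(it.vector)})
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(path, sep="\t", index=False)
    return frame
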