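"""Experiment orchestration: many seeded networks x lesion conditions.

Reproduces the simulation protocol at desk scale: for each condition a
population of networks with randomly initialized weights (topography and
values both seeded) is built, lesioned, trained with interim tests, scored
on the full probe battery and analyzed with representational similarity.
Network initialization is the random-effects unit: summary tables report
mean ± s.e.m. across networks, and condition contrasts compare per-network
means.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .model import HippocampusAutoencoder
from .plasticity import LESION_CONDITIONS, StoppingRule
from .repsim import HIDDEN_LAYERS, capture_responses, similarity_matrix, \
    within_between_summary
from .scoring import run_test_battery
from .tasks import build_satellite_dataset, build_typicality_dataset, \
    build_weather_dataset

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "run_single_network",
    "aggregate",
    "condition_contrasts",
    "SIM_DEFAULTS",
]

#: per-simulation defaults: trial counts and learning rates follow the
#: modelled paradigms (140 satellite trials; 50 weather trials with the
#: 25-trial / 5-below-1.2 stopping rule; 100 typicality trials = 5 epochs
#: of 20 items, with a reduced MSP rate for these highly overlapping items)
SIM_DEFAULTS = {
    "satellites": dict(n_trials=140, trial_policy="replacement",
                       msp_learning_rate=0.01, stopping=False,
                       interim=(0, 20, 40, 60, 80, 100, 120, 140)),
    "weather": dict(n_trials=50, trial_policy="weighted",
                    msp_learning_rate=0.01, stopping=True,
                    interim=(0, 10, 20, 30, 40, 50)),
    "typicality": dict(n_trials=100, trial_policy="epochs",
                       msp_learning_rate=0.0025, stopping=False,
                       interim=(0, 20, 40, 60, 80, 100)),
}


@dataclass
class ExperimentConfig:
    """Configuration of one simulation campaign."""

    simulation: str
    n_networks: int = 100
    conditions: tuple = LESION_CONDITIONS
    seed_base: int = 0
    dataset_seed: int | None = None  # defaults to seed_base
    n_trials: int | None = None
    interim_test_trials: tuple | None = None
    rsa: bool = True
    rsa_modes: tuple = ("initial", "settled")
    out_dir: str | None = None
    estimator_params: dict = field(default_factory=dict)
    #: for the stopping-rule task: keep adding networks until ``n_networks``
    #: reach the final trial without stopping early (stopped networks still
    #: contribute up to their stop trial, then drop out of later averages)
    replenish_final: bool = False
    max_attempts_factor: int = 10

    def __post_init__(self):
        if self.simulation not in SIM_DEFAULTS:
            raise ValueError(f"unknown simulation {self.simulation!r}")
        for c in self.conditions:
            if c not in LESION_CONDITIONS:
                raise ValueError(f"unknown condition {c!r}")


@dataclass
class ExperimentResult:
    scores: pd.DataFrame          # long format, one row per probe x test
    curves: pd.DataFrame          # per-trial training log
    rsa: pd.DataFrame | None      # per-network within/between summaries
    rsa_matrices: dict            # (layer, mode) -> mean similarity matrix
    summary: pd.DataFrame
    manifest: dict


def _build_dataset(simulation: str, seed: int):
    if simulation == "satellites":
        return build_satellite_dataset(seed)
    if simulation == "weather":
        return build_weather_dataset(seed)[0]
    return build_typicality_dataset(seed)


def _make_estimator(config: ExperimentConfig, condition: str, seed: int):
    d = SIM_DEFAULTS[config.simulation]
    params = dict(
        lesion=condition,
        n_trials=config.n_trials or d["n_trials"],
        trial_policy=d["trial_policy"],
        msp_learning_rate=d["msp_learning_rate"],
        stopping_rule=StoppingRule() if d["stopping"] else None,
        random_state=seed,
    )
    params.update(config.estimator_params)
    return HippocampusAutoencoder(**params)


def run_single_network(config: ExperimentConfig, condition: str, seed: int,
                       dataset=None):
    """Build→lesion→train→test one network; returns per-network tables."""
    if dataset is None:
        dataset = _build_dataset(config.simulation,
                                 config.dataset_seed if config.dataset_seed
                                 is not None else config.seed_base)
    est = _make_estimator(config, condition, seed)
    d = SIM_DEFAULTS[config.simulation]
    interim = config.interim_test_trials
    if interim is None:
        interim = d["interim"]
    batteries = []

    def interim_test(trial, network):
        batteries.append(run_test_battery(network, dataset, trial=trial))

    # interim schedule is handled here (trial 0 + listed trials + final)
    schedule_interims = tuple(sorted(set(interim) | {0}))

    from . import netcore
    from .plasticity import TrainingSchedule, apply_lesion, train
    layers = netcore.default_layer_specs(
        dataset.input_size, est.input_k or dataset.input_k,
        dg_size=est.dg_size, ca3_size=est.ca3_size, ca1_size=est.ca1_size,
        dg_k=est.dg_k, ca3_k=est.ca3_k, ca1_k=est.ca1_k,
        gain=est.gain, inhib_floor=est.inhib_floor,
        rel_floor=est.rel_floor, dt=est.dt)
    projections = netcore.default_projection_specs(
        est.tsp_learning_rate, est.msp_learning_rate, est.output_learning_rate)
    net = netcore.build_network(layers, projections, seed=seed)
    net = apply_lesion(net, condition)
    schedule = TrainingSchedule(
        total_trials=est.n_trials,
        interim_test_trials=schedule_interims,
        stopping_rule=est.stopping_rule,
        max_cycles=est.max_cycles, tolerance=est.tolerance)
    net, records = train(net, dataset, schedule, condition=condition,
                         seed=seed, interim_test=interim_test)

    scores = pd.concat(batteries, ignore_index=True)
    scores["network"] = seed
    scores["condition"] = condition
    curves = pd.DataFrame(
        {"trial": [r.trial for r in records],
         "item": [r.item_id for r in records],
         "sse": [r.sse for r in records]})
    curves["network"] = seed
    curves["condition"] = condition
    curves["stopped_early"] = len(records) < est.n_trials

    rsa_rows, mats = [], {}
    if config.rsa and "rsa" in dataset.probes:
        excluded = [p.id for p in dataset.probes["rsa"]
                    if p.meta.get("excluded")]
        snaps = []
        for mode in config.rsa_modes:
            snaps.extend(capture_responses(net, dataset.probes["rsa"], mode))
        mats = similarity_matrix(snaps)
        for (layer, mode), sm in mats.items():
            w, b = within_between_summary(sm, excluded_items=excluded)
            rsa_rows.append({"network": seed, "condition": condition,
                             "layer": layer, "mode": mode,
                             "within": w, "between": b})
    return scores, curves, pd.DataFrame(rsa_rows), mats, net


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full campaign and (optionally) write delimited artifacts.

    Per-network pipelines are independent and fully seeded (seed_base +
    network index, shared across conditions), so two invocations with the
    same config produce byte-identical tables regardless of run order.
    """
    dataset = _build_dataset(config.simulation,
                             config.dataset_seed if config.dataset_seed
                             is not None else config.seed_base)
    all_scores, all_curves, all_rsa = [], [], []
    mat_sums: dict = {}
    mat_counts: dict = {}
    seeds_used: dict = {}
    for condition in config.conditions:
        done = attempt = 0
        seeds_used[condition] = []
        max_attempts = config.n_networks * config.max_attempts_factor
        while done < config.n_networks and attempt < max_attempts:
            seed = config.seed_base + attempt
            attempt += 1
            scores, curves, rsa, mats, _ = run_single_network(
                config, condition, seed, dataset)
            reached_final = not bool(curves["stopped_early"].iloc[0])
            keep = reached_final or not config.replenish_final
            all_scores.append(scores)
            all_curves.append(curves)
            if keep:
                done += 1
                seeds_used[condition].append(seed)
                if len(rsa):
                    all_rsa.append(rsa)
                for key, sm in mats.items():
                    mat_sums[key] = mat_sums.get(key, 0) + sm.values
                    mat_counts[key] = mat_counts.get(key, 0) + 1
                    mat_items = sm.item_ids
        if done < config.n_networks:
            raise RuntimeError(
                f"could not complete {config.n_networks} networks for "
                f"{condition} within {max_attempts} attempts")

    scores = pd.concat(all_scores, ignore_index=True)
    curves = pd.concat(all_curves, ignore_index=True)
    rsa = pd.concat(all_rsa, ignore_index=True) if all_rsa else None
    rsa_matrices = {key: pd.DataFrame(mat_sums[key] / mat_counts[key],
                                      index=mat_items, columns=mat_items)
                    for key in mat_sums}
    summary = aggregate(scores)
    manifest = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in dataclasses.asdict(config).items()},
                "seeds": seeds_used,
                "package": "hippolearn 0.1.0"}

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        scores.to_csv(out / "scores.tsv", sep="\t", index=False)
        curves.to_csv(out / "learning_curves.tsv", sep="\t", index=False)
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        if rsa is not None:
            rsa.to_csv(out / "rsa_summary.tsv", sep="\t", index=False)
        for (layer, mode), frame in rsa_matrices.items():
            frame.to_csv(out / f"rsa_{layer}_{mode}.tsv", sep="\t")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return ExperimentResult(scores, curves, rsa, rsa_matrices, summary, manifest)


def aggregate(score_records: pd.DataFrame) -> pd.DataFrame:
    """Mean, s.e.m. (across networks) and n per condition/trial/score kind.

    Excluded probes (equiprobable card combinations) are dropped; an empty
    cell simply does not appear.  Cells with a single network get an
    undefined (NaN) s.e.m., not zero.
    """
    df = score_records
    if "excluded" in df.columns:
        df = df[~df["excluded"].fillna(False).astype(bool)]
    keys = [k for k in ("condition", "trial", "kind", "typicality")
            if k in df.columns and df[k].notna().any()]
    # first average over probes within a network, then across networks
    per_net = (df.groupby(keys + ["network"], dropna=False)["score"]
                 .mean().reset_index())
    g = per_net.groupby(keys, dropna=False)["score"]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    chance = df.groupby(keys, dropna=False)["chance"].mean().reset_index()
    return out.merge(chance, on=keys).drop(columns="sd")


def condition_contrasts(score_records: pd.DataFrame, kind: str,
                        trial=None) -> pd.DataFrame:
    """Pairwise condition comparisons on per-network mean scores.

    Welch t-tests between every pair of conditions (network initialization
    as the sampling unit), at the final test trial unless ``trial`` given.
    """
    df = score_records[score_records["kind"] == kind]
    if "excluded" in df.columns:
        df = df[~df["excluded"].fillna(False).astype(bool)]
    t = trial if trial is not None else df["trial"].max()
    df = df[df["trial"] == t]
    per_net = df.groupby(["condition", "network"])["score"].mean().reset_index()
    conds = sorted(per_net["condition"].unique())
    rows = []
    for i, a in enumerate(conds):
        for b in conds[i + 1:]:
            xa = per_net.loc[per_net["condition"] == a, "score"]
            xb = per_net.loc[per_net["condition"] == b, "score"]
            res = stats.ttest_ind(xa, xb, equal_var=False)
            rows.append({"kind": kind, "trial": t, "condition_a": a,
                         "condition_b": b, "mean_a": xa.mean(),
                         "mean_b": xb.mean(), "t": res.statistic,
                         "p": res.pvalue})
    return pd.DataFrame(rows)
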