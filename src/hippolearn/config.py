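"""Plain-text architecture configuration (YAML layer/projection/gate tables).

The packaged ``data/default_architecture.yaml`` reproduces the canonical
wiring for the 27-unit satellite task; :func:`load_architecture` turns any
such file back into layer and projection specs for
:func:`hippolearn.netcore.build_network`.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .netcore import (LayerSpec, Network, ProjectionSpec, build_network,
                      default_layer_specs, default_projection_specs)

__all__ = ["save_architecture", "load_architecture", "build_from_config",
           "default_architecture_dict"]


def _layer_row(sp: LayerSpec) -> dict:
    return dict(name=sp.name, size=sp.size, k_active=sp.k_active,
                gain=sp.gain, inhib_floor=sp.inhib_floor,
                rel_floor=sp.rel_floor, dt=sp.dt)


def _projection_row(ps: ProjectionSpec) -> dict:
    return dict(src=ps.src, dst=ps.dst,
                connectivity_fraction=ps.connectivity_fraction,
                learnable=ps.learnable, learning_rate=ps.learning_rate,
                pathway=ps.pathway_tag, phase_gates=dict(ps.phase_gates),
                weight_init=list(ps.weight_init), identity=ps.identity,
                exclude_self=ps.exclude_self, strength=ps.strength,
                hebbian=ps.hebbian, hebbian_rate=ps.hebbian_rate,
                columnar=ps.columnar,
                exclude_own_column=ps.exclude_own_column, decay=ps.decay)


def default_architecture_dict(input_size: int = 27, input_k: int = 5) -> dict:
    return {"layers": [_layer_row(sp) for sp in
                       default_layer_specs(input_size, input_k)],
            "projections": [_projection_row(ps) for ps in
                            default_projection_specs()]}


def save_architecture(path, layer_specs=None, projection_specs=None,
                      input_size: int = 27, input_k: int = 5) -> None:
    if layer_specs is None:
        cfg = default_architecture_dict(input_size, input_k)
    else:
        cfg = {"layers": [_layer_row(sp) for sp in layer_specs],
               "projections": [_projection_row(ps) for ps in projection_specs]}
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def _parse(cfg: dict):
    layers = [LayerSpec(d["name"], int(d["size"]), int(d["k_active"]),
                        float(d.get("gain", 80.0)),
                        float(d.get("inhib_floor", 0.02)),
                        float(d.get("rel_floor", 0.25)),
                        float(d.get("dt", 0.4)))
              for d in cfg["layers"]]
    projections = []
    for d in cfg["projections"]:
        hr = d.get("hebbian_rate")
        projections.append(ProjectionSpec(
            d["src"], d["dst"],
            connectivity_fraction=float(d.get("connectivity_fraction", 1.0)),
            learnable=bool(d.get("learnable", True)),
            learning_rate=float(d.get("learning_rate", 0.0)),
            pathway_tag=d.get("pathway", "fixed"),
            phase_gates=dict(d.get("phase_gates", {})),
            weight_init=tuple(d.get("weight_init", (0.0, 0.2))),
            identity=bool(d.get("identity", False)),
            exclude_self=bool(d.get("exclude_self", False)),
            strength=float(d.get("strength", 1.0)),
            hebbian=float(d.get("hebbian", 0.0)),
            hebbian_rate=None if hr is None else float(hr),
            columnar=bool(d.get("columnar", False)),
            exclude_own_column=bool(d.get("exclude_own_column", False)),
            decay=float(d.get("decay", 0.0))))
    return layers, projections


def load_architecture(path=None):
    """Load (layer_specs, projection_specs) from a YAML architecture file
    (the packaged default when ``path`` is None)."""
    if path is None:
        text = resources.files("hippolearn.data").joinpath(
            "default_architecture.yaml").read_text()
        cfg = yaml.safe_load(text)
    else:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    return _parse(cfg)


def build_from_config(path=None, seed: int = 0) -> Network:
    layers, projections = load_architecture(path)
    return build_network(layers, projections, seed=seed)
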