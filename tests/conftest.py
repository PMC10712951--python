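import numpy as np
import pytest

from hippolearn.netcore import (LayerSpec, ProjectionSpec, build_network,
                                default_layer_specs, default_projection_specs)
from hippolearn.tasks import (build_satellite_dataset, build_typicality_dataset,
                              build_weather_dataset)


@pytest.fixture(scope="session")
def sat_dataset():
    return build_satellite_dataset(0)


@pytest.fixture(scope="session")
def weather_dataset():
    return build_weather_dataset(0)


@pytest.fixture(scope="session")
def typ_dataset():
    return build_typicality_dataset(0)


@pytest.fixture
def default_net():
    """Fresh default circuit sized for the satellite task."""
    return build_network(default_layer_specs(27, 5),
                         default_projection_specs(), seed=0)


def tiny_layers(n_input=6, k=2):
    """A miniature circuit for oracle tests (all layers small)."""
    return [
        LayerSpec("Input", n_input, k),
        LayerSpec("EC_in", n_input, k),
        LayerSpec("EC_out", n_input, k),
        LayerSpec("DG", 20, 2),
        LayerSpec("CA3", 10, 2),
        LayerSpec("CA1", 12, 3),
    ]


@pytest.fixture
def tiny_net():
    return build_network(tiny_layers(), default_projection_specs(), seed=3)


def per_network_means(scores, kind, value="score"):
    """Mean score per network for one score kind (excluded probes dropped)."""
    df = scores[scores["kind"] == kind]
    if "excluded" in df.columns:
        df = df[~df["excluded"].fillna(False).astype(bool)]
    return df.groupby(["condition", "network"])[value].mean().unstack(0)


def ci95(values):
    values = np.asarray(values, dtype=float)
    m = values.mean()
    half = 1.96 * values.std(ddof=1) / np.sqrt(len(values))
    return m - half, m + half
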