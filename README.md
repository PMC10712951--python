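# hippolearn

A rate-coded neural-circuit model of how the hippocampus learns new
categories in minutes rather than months. The package is aimed at
computational-neuroscience and category-learning researchers who want a
desk-scale, fully seeded simulation of the hippocampal division of labour:

* the **trisynaptic pathway** (TSP, EC→DG→CA3→CA1) — sparse, fast-learning,
  pattern-separating; the circuit's episodic channel, responsible for
  remembering the arbitrary details of individual exemplars;
* the **monosynaptic pathway** (MSP, EC→CA1) — dense, slow-learning,
  overlap-preserving; a miniature semantic system that extracts the
  regularities defining category structure.

The circuit is trained as an autoencoder (reproduce the pattern presented
to superficial entorhinal cortex, EC_in, on the deep layer, EC_out) with
theta-phase Contrastive Hebbian Learning: each trial contrasts two free
(minus) phases — a theta *trough* in which EC drives CA1 with CA3→CA1
suppressed, and a theta *peak* in which CA3 drives CA1 with EC_in→CA1
suppressed — against one plus phase with the target clamped on EC_out:

&nbsp;&nbsp;&nbsp;&nbsp;Δw = ε · ( ⟨x·y⟩⁺ − ⟨x·y⟩⁻ ),&nbsp;&nbsp; ε_TSP = 10 · ε_MSP

Within-layer inhibition is set-point k-winner-take-all; unit activities are
rates in [0, 1]. Lesion conditions (`intact`, `TSP-only`, `MSP-only`)
silence one input route to CA1 during both learning and test. Three
category-learning paradigms are generated programmatically: satellite
categories with shared and unique features, the probabilistic
weather-prediction task, and a typicality continuum of two intermixed
categories. Behavioural scores (unique-feature recognition, categorization,
generalization, atypical-feature recognition) and representational
similarity analyses (initial vs. settled responses of DG, CA3, CA1) follow
the published protocols. See `docs/methods.md` for the full model account.

## Worked example

Train one network per lesion condition on the satellite task (three
categories × five satellites over 27 binary features, 140 trials) and run
the behavioural test battery:

```python
from hippolearn import HippocampusAutoencoder, build_satellite_dataset
from hippolearn.scoring import run_test_battery

dataset = build_satellite_dataset(seed=0)
for lesion in ("TSP-only", "MSP-only"):
    model = HippocampusAutoencoder(lesion=lesion, random_state=0)
    model.fit_dataset(dataset)
    scores = run_test_battery(model.network_, dataset)
    print(lesion)
    print(scores.groupby("kind")["score"].mean().round(2).to_string())
```

```
TSP-only
kind
categorization-sat    0.74
generalization-sat    0.97
unique-feature        0.85
MSP-only
kind
categorization-sat    0.64
generalization-sat    1.00
unique-feature        0.17
```

The network with only the trisynaptic pathway recalls each satellite's
unique feature from a single-feature cue (0.85; chance 0.25) — episodic
binding. The network with only the monosynaptic pathway is at chance on
unique features (0.17) yet generalizes the category-prototypical feature
to novel satellites perfectly (1.00; chance 0.33) — statistical
regularity extraction. `HippocampusAutoencoder` is a scikit-learn style
estimator: `fit(X)` trains on arbitrary binary pattern matrices,
`predict(X)` returns settled EC_out reconstructions, and
`transform(X, layer="CA1", mode="initial")` exposes hidden-layer codes.

Full campaigns (100 seeded networks × 3 lesion conditions, interim tests,
RSA matrices, delimited outputs and a run manifest) run through
`hippolearn.run_experiment` or the CLI:

```bash
hippolearn run --sim satellites --n-networks 100 --seed 0 --out runs/sat
hippolearn make-dataset --sim weather --out weather_patterns.tsv
```

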