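# Model and methods

`hippolearn` simulates rapid category learning in a rate-coded model of the
hippocampal circuit. The package's central claim, inherited from the
complementary-learning-systems tradition, is that the two anatomical routes
from entorhinal cortex (EC) into CA1 implement complementary learning
channels: the **trisynaptic pathway** (TSP: EC→DG→CA3→CA1) is sparse and
fast-learning and encodes individual exemplars, while the **monosynaptic
pathway** (MSP: EC→CA1) is dense and slow-learning and extracts the
statistical regularities that define category structure. Lesioning either
pathway in the model dissociates memory for exemplar-specific detail from
categorization and generalization.

## Circuit

Six unit pools: `Input` (clamp layer), `EC_in`, `EC_out` (sized by the
task), `DG` (400 units), `CA3` (80), `CA1` (100). Activities are rates in
[0, 1]. Projections:

| projection | connectivity | learning | notes |
|---|---|---|---|
| Input→EC_in | one-to-one, fixed | — | external clamp |
| EC_out→EC_in | one-to-one, fixed, strength 0.5 | — | big-loop recirculation; gated off in "initial-response" probes |
| EC_in→DG | 25% sparse, fixed random | — | structural pattern separation |
| EC_in→CA3 | 25% sparse | Hebbian (CPCA), rate 0.4 | content-addressable retrieval path |
| DG→CA3 | 5% sparse, fixed random, strength 32 | — | "detonator" mossy drive; dictates CA3 winner choice at encoding, silenced at test |
| CA3→CA3 | full (no self) | Hebbian (CPCA), rate 0.4 | attractor completion |
| CA3→CA1 | full, strength 2 | contrastive, rate 0.1 | suppressed at theta trough |
| EC_in→CA1 | full **minus own column** | contrastive, rate 0.01 | suppressed at theta peak and in the plus phase |
| CA1↔EC_out | columnar | contrastive, rate 0.1 | CA1 unit *j* exchanges with EC unit *j* mod *n* |

Two wiring choices deserve emphasis because they carry the pathway
dissociation:

* **Columnar CA1↔EC_out.** Output decoding is topographic: each EC unit
  owns a small CA1 column. Producing a specific output feature requires
  activating its column.
* **Own-column exclusion in EC_in→CA1.** The direct pathway connects each
  EC_in unit to every CA1 column *except* the one belonging to its own
  slot. The MSP therefore cannot implement an identity map; it can only
  carry cross-feature statistical structure. Item-specific output (e.g. a
  satellite's unique feature) is reachable only through CA3 — which is
  exactly the division of labour the model is meant to express. A side
  effect is that untrained networks score slightly *below* chance on
  unique-feature probes (the cue's own column is the one column random
  input weights cannot drive).

## Dynamics

A unit's drive is the gated, masked weighted sum of presynaptic activity,
normalized per projection by the **expected number of active inputs**
(source k_active × fan-in / source size, at least 1), so winner drives are
O(1) whether the source is 4-of-80 sparse or fully active. Within-layer
inhibition is set-point k-winner-take-all: the inhibition level θ sits
between the k-th largest drive and the next *distinct* drive below it
(ties at the boundary all pass — saturated rate units tie exactly, and a
tie straddling k must not silence the whole class), floored at
max(0.02, 0.25·max drive) so weakly driven layers still resolve their
competition rather than falling silent. Activity is a hard-thresholded
saturating transfer, 2σ(g·(drive−θ))−1 clipped to [0, 1] with gain g = 80:
units below inhibition are exactly silent, not exponentially small —
ratio scores over sub-threshold activity would otherwise read out rank
information no downstream structure could see.

Settling sweeps layers in anatomical order (EC_in, DG, CA3, CA1, EC_out),
each update moving a fraction dt = 0.4 toward its instantaneous target.
The graded step gives the cue-seeded CA3 attractor time to establish
itself before big-loop recirculation arrives. Settling stops when the
largest activation change falls below 1e-4 (typically ~20 cycles) or at
100 cycles, in which case the state is returned flagged unconverged.
k-winner-take-all set-points: DG 8, CA3 16, CA1 20, EC layers = the
typical number of active units in a training pattern.

## Learning

Training is autoencoding: the pattern clamped on `Input` must be
reproduced on `EC_out`. An intact trial settles three phases — a *trough*
minus phase (CA3→CA1 suppressed), a *peak* minus phase (EC_in→CA1
suppressed) and a *plus* phase with the target clamped on `EC_out`
(EC_in→CA1 suppressed, so the CA1 plus-state inherits CA3's pattern
separation). Error-driven projections update by Contrastive Hebbian
Learning, Δw = lr·(plus coactivity − minus coactivity), contrasting only
the minus phase **in which the projection was transmitting** (a synapse
gated off has no credit for that phase), soft-bounded into [0, 1].
Lesioned networks run a single minus phase with all surviving gates open.

The input-side trisynaptic projections (EC_in→CA3, CA3→CA3) carry no
phase contrast — with the input clamped, their pre/post activity is
identical in every phase — and instead learn by a self-organizing CPCA
rule, Δw = rate·post·(pre − w), at a fast binding rate (0.4) befitting
near-one-shot episodic encoding. EC_in→DG and DG→CA3 are fixed: granule
pattern separation here is structural, and mossy winner assignment must
stay stable across repetitions for binding to accumulate.

Learning rates are 0.1 (TSP and output) versus 0.01 (MSP), preserving the
10:1 fast/slow ratio that defines the two channels; the absolute scale is
calibrated to this package's update rule and drive normalization (a given
nominal rate moves reconstruction error several-fold slower here than in
conductance-based frameworks with weight contrast enhancement).

## Tasks, lesions, scoring, RSA

The three paradigms (satellite categories, probabilistic weather
prediction, typicality continuum) are generated programmatically from a
seed; counts and structure are fixed, only arbitrary assignments vary.
The weather contingency table ships as an editable YAML file: three
printed anchor probabilities are exact (0.90, 0.79, 0.15) and the
remaining rows are a synthetic reconstruction in the style of the classic
task (mirror-symmetric sun/rain structure, exactly two equiprobable
combinations, frequencies summing to 1). The weather task uses the
stopping rule (minimum 25 trials, then five consecutive trials with sum
squared error below 1.2); the error is measured on the *last* minus phase
of a trial (the peak phase for intact networks), where reconstruction
flows through the trisynaptic route — trough-phase reconstruction passes
through the cross-feature MSP alone and can never reach threshold.

Lesions zero the effective strength of EC_in→CA1 (TSP-only condition) or
CA3→CA1 (MSP-only) for training and test alike, and exclude the
projection from learning. Testing clamps a probe on `Input`, settles with
both surviving pathways open and never touches weights. Scores are
activation ratios over designated output unit sets (sum-based by default;
the literal mean-over-means weather recognition measure is reported
alongside a sum-normalized variant); a silent denominator returns the
chance level. Representational similarity uses Pearson correlations of
DG/CA3/CA1 patterns evoked per item, in *initial* mode (EC_out→EC_in
structurally gated off, so no big-loop influence) and *settled* mode.

## What the simulations show — and known departures

With 100 seeded initializations per condition the package reproduces the
core dissociation pattern: MSP-lesioned (TSP-only) networks remember
unique/atypical exemplar features well above chance while MSP-only
networks sit at chance on them; MSP-only networks categorize and
generalize well; weather recognition survives MSP lesions but suffers
without the TSP, while categorization shows the opposite dependence;
generalization rises monotonically with typicality; and representational
similarity shows category structure in the initial response of CA1 only,
with big-loop recurrence spreading it into DG and CA3 in the settled
response.

Departures we know about and deliberately did not tune away:

* **TSP-only satellite generalization** stays near 0.95 rather than
  degrading toward ~0.5: our CA3 retrieval of novel feature
  recombinations lands in category-consistent exemplar attractors, whose
  output always contains the correct prototypical feature.
* **Intact unique-feature recognition** runs below the lesioned TSP-only
  networks (≈0.3 vs ≈0.7): at test the MSP's categorical drive displaces
  the unique-feature column from CA1's winner set more aggressively than
  in the reference behaviour, where the intact network loses only a few
  points.
* **Weather settled-CA1 within-category similarity** sits near 0.55
  rather than 0.38: with columnar decoding, retrieved outcome columns
  dominate the settled CA1 state for same-category card combinations.
* Intact satellite categorization plateaus near 0.85 rather than 1.0.

The synthetic generators emulate the published stimulus structures
exactly (counts, feature roles, contingencies) but not, of course, any
perceptual front-end; passing tests demonstrate circuit-level
dissociations under binary feature codes, not predictions about image- or
text-derived stimuli.

## Problem sizes and determinism

The test suite and the acceptance script train full populations — 100
networks per lesion condition per paradigm (140 satellite trials, ≤50
weather trials under the stopping rule, 100 typicality trials) — the same
population size used for the reported statistics. Every random element
(mask topography, initial weights, trial order) derives from a single
integer seed per network; identical seeds yield bit-identical weight
trajectories, and experiment outputs are byte-identical across reruns.
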