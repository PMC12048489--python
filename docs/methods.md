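# Methods

This note documents the models and procedures `fecomap` implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Data model

A connectome is two flat tables. The **neuron table** carries one row per
neuron: a morphological class (`sensory`, `motor`, `local`,
`intersegmental`, `ascending`, `descending`, or `fragment` for unproofread
objects), a sensory subtype (the five FeCO subtypes or `none`), a
hemilineage label, a fast transmitter (`ACh`, `GABA`, `Glu`, `unknown`), a
segment label, and a motor-module id (set exactly for motor neurons). The
**synapse table** carries one row per synaptic contact with pre/post ids and
x/y/z in nm. All analyses run on the aggregated edge list: counts per
ordered (pre, post) pair, plus each neuron's **total input count** over all
rows — including autapses, fragments and sub-threshold edges — which is the
denominator of every impact ratio. Autapses are excluded from edges by
default but retained in input totals, since the denominator is a neuron's
full predicted input, not its proofread partner graph; whether fragment
input belongs in the denominator is genuinely open for real exports, so it
is a config switch (default on).

## Partner inclusion thresholds

A neuron counts as a downstream partner when it receives at least
`out_threshold` = 4 synapses from a *single* seed axon, and as an upstream
partner at `in_threshold` = 3; these thresholds mitigate false positives
from automated synapse detection and bias analyses toward stereotyped
connections. Inclusion is per seed neuron, but once a partner qualifies its
counts are summed over all seeds, sub-threshold contributions included.
Pooled inclusion (summed counts reaching threshold) is available as an
option. Raising the threshold can only shrink a partner set — this
monotonicity is a tested invariant.

## Connectivity similarity and clustering

Each seed is represented by its vector of raw synapse counts onto the
thresholded partner set. Similarity is the cosine of two weight vectors
(computed with scikit-learn, then symmetrized exactly and clipped to
[-1, 1]); it is invariant to scaling any seed's whole vector, so differences
in total output do not masquerade as differences in connectivity. Seeds with
all-zero vectors get undefined entries and are excluded from clustering
(label −1) rather than imputed. Clustering is agglomerative on the distance
1 − S with **average linkage** — the conventional choice for similarity
matrices; the linkage is a config knob because nothing in the scientific
definition pins it down. The tree is cut either at a requested cluster count
or at a distance threshold (default 0.5); labels are renumbered by first
appearance along the dendrogram leaf order so results are deterministic.
Cross-population clustering aligns two populations' partner columns to their
union (absent counts are zero) and reports per-cluster composition by
population of origin.

## Signed multi-hop motor impact

The monosynaptic impact of neuron A onto neuron B is
`count(A→B) / input_total(B)`, signed by A's transmitter: ACh excitatory,
GABA inhibitory, Glu inhibitory (VNC convention, acting through GluCl; the
sign map is overridable for neuromuscular contexts). Sensory afferents are
assumed cholinergic, so a sensory source is always positive. The motor
impact of a sensory seed onto a motor module is the sum of three terms over
the module's motor neurons (MNs):

1. **monosynaptic** — direct seed→MN ratios, forced positive;
2. **disynaptic** — for every interneuron I that is postsynaptic to the
   seed and presynaptic to a module MN, |seed→I| · |I→MN| signed by I;
3. **trisynaptic** — for every ordered pair (P, Q) of distinct
   hemilineage-identified interneurons on a seed→P→Q→MN path,
   |seed→P| · |P→Q| · |Q→MN|, positive when P and Q agree in sign.

Rules and their rationale:

* An edge participates only if its count passed the reconstruction
  threshold (default 4). Thresholding is a *partner-graph selection* step;
  the score itself uses raw counts and is therefore exactly invariant to a
  global rescaling of all synapse counts on a fixed graph (a tested
  property).
* Intermediates exclude motor neurons (premotor neurons are interneurons by
  definition) and the seed itself. Disynaptic intermediates need an
  identified transmitter; trisynaptic intermediates need an identified
  hemilineage. Excluded intermediates are tallied in a per-score coverage
  report rather than silently dropped.
* The P = Q term is excluded from the trisynaptic sum (the neuron that is
  both post-seed and pre-MN is already the disynaptic term); with autapses
  excluded this term would be zero anyway, so the switch is safe either way.
* Sums run over distinct intermediate neurons/pairs, not anatomical paths.

The implementation is dense matrix algebra over the neuron index (the
trisynaptic term is a bilinear form with a zeroed diagonal); the test suite
checks it against an independent loop-based enumeration of all signed paths
of length ≤ 3 to 1e−12 on random graphs. The score summarizes multi-layer
connectivity trends; it deliberately ignores circuit dynamics, intrinsic
properties and synaptic weights beyond counts, and is not a predictor of
activity.

**Preference scores.** A premotor neuron's module preference is its synapse
count onto each module's MNs over its synapses onto all MNs; a neuron's
subtype preference is the count received from each FeCO subtype over all
FeCO input. Both are simple fractions summing to 1 (raw counts, no
threshold) and are computed only for eligible neurons (≥ 1 MN synapse, ≥ 1
FeCO synapse respectively).

## Spatial branches

All output synapses of one subtype are partitioned by K-means (k = 3, the
number of major axon branches) on Euclidean distance in raw nm — no
per-axis scaling or normalization, matching the anatomical definition.
k-means++ with 10 restarts and a fixed seed makes the partition
deterministic; branch labels are canonicalized by ascending centroid
coordinate along a declared axis (default z, the dorsal–ventral axis), so
branch 1 is always the most ventral. A partner's branch preference is the
fraction of its synapses coming from each branch; subsampling draws a
uniform fraction of synapse rows without replacement while holding the
fitted branch labels fixed, and reports each partner's strongest preference
(partners emptied by the subsample are dropped with a logged count).

## Saturation (novel partners)

Seeds are accumulated one at a time in random order, recording the
cumulative number of distinct partners; the ordering is redrawn 50 times
(default) from per-resample RNG streams spawned from one master seed, and
the curve is summarized by mean and population s.d. per step. The terminal
value equals the union size in every resample by construction — tested, not
assumed. The mean curve is fitted by least squares (scipy `curve_fit`) with
`y = a·ln(1 + b·t)`, chosen to force y(0) = 0; `y = a·ln t + c` is
available by flag since the logarithmic family is not otherwise pinned
down. The fit uses the mean curve (not pooled per-resample points), and the
extrapolation target defaults to 152 neurons, the full sensory organ. A
flat curve cannot be represented with y(0) = 0 except as b → 0 and is
flagged degenerate (prediction falls back to the terminal value);
non-convergence raises with diagnostics.

## Synthetic connectome generator

The generator emulates the statistical structure the analyses assume, with
every planted label recorded for recovery tests. Study conditions (the
defaults): sensory seeds 8/13/9/13/37 per subtype for the front-left leg
plus 14 second-leg clubs; three club frequency groups; motor modules named
after the 18 front-leg muscles (2–4 MNs each, 44 total), with the tibia
extensor/flexor pair as the planted antagonists and the long tendon muscle
as the club pathway's faint motor target; club interneuron pools of
hemilineages 10B (38, ACh), 8B (15, ACh), 0A/0B (18, GABA) and 9A (19,
GABA); dedicated premotor neurons per (proprioceptive subtype × antagonist
module) with transmitters chosen so flexion-tuned seeds excite the extensor
module and inhibit the flexor module (and conversely), a 0.9 dedication
probability; GABAergic 9A "gate" neurons that inhibit hook axons and
premotor neurons (providing trisynaptic paths and upstream FeCO partners);
small hair-plate/campaniform populations converging on proprioceptive
pools and wing/neck populations converging on club pools; recurrent
wiring among the club interneuron classes with fixed block probabilities.

Synapse counts per connected pair are zero-truncated negative binomial
(mean 6, dispersion 2; strong blocks mean 10) because connectome edge
weights are overdispersed; noise conditions are a 10% cross-block edge rate
and multiplicative log-normal count jitter (σ = 0.2). Club terminals are
drawn from three z-stratified Gaussian clouds (centers 15/30/45 µm,
σ = 3 µm); proprioceptive output synapses come from three branch clouds
(±7 µm offsets, σ = 2 µm) with each partner preferring one branch at 0.8
fidelity. Roughly half of every interneuron's and MN's input synapses are
backfilled from `fragment` objects, emulating the unproofread remainder of
a real reconstruction, so impact denominators are realistic. Sizes: `tiny`
(~20 neurons, hand-checkable), `small` (~150), `paper_scale` (~600 neurons,
~55k synapse rows; generates in well under a second).

What the generator does **not** emulate: realistic degree or weight
distributions of any specific dataset, morphology, electrical synapses,
descending control, or inter-subtype convergence beyond the planted noise.
Passing recovery tests therefore shows the analyses are correct and
sensitive at the planted effect sizes — not that any particular biological
claim holds in real data.

## Pipeline and determinism

`circuit run` executes partners → similarity → branches → impact →
saturation; inputs are validated before any output is written, and a stage
failure halts with the stage name (exit codes: 2 validation, 3 stage
failure). All writers use fixed column order and 17-significant-digit
floats, readers parse floats in round-trip mode, and every RNG stream
derives from the config seed, so a rerun on identical inputs is
byte-identical — including `report.json` (config echo, input SHA-256
checksums, per-stage counts, collected warnings, output manifest). The test
suite pins this with shipped golden outputs for the tiny fixture.

## Problem sizes used in tests

Unit and property tests run on `tiny`/`small` fixtures and random graphs of
≤ 60 neurons (where exhaustive path enumeration is the oracle); recovery
tests use 10–20 `paper_scale` replicates. The acceptance script mirrors
these sizes: 60 random oracle graphs, 50 oracle cosine matrices, 10
`paper_scale` replicates for clustering recovery, and one replicate for the
saturation, normalization, sign-structure and determinism checks.

## Known limitations

* The impact score is a connectivity summary, not a dynamical prediction.
* Hemilineage→transmitter inference is taken as input; neurons violating
  the one-hemilineage-one-transmitter rule will carry the wrong sign.
* The cosine/agglomerative pipeline has no significance model; cluster
  counts are user choices (k or a distance cut), not inferred.
* The logarithmic extrapolation is a smooth-curve heuristic, not a
  statistical richness estimator (Chao-type estimators are out of scope).
* Electrical synapses are invisible to count-based tables and ignored.
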