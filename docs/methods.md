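# Methods

This note documents the models, the procedure, the tunable parameters and the
numerical choices behind `molscope`, and what the synthetic benchmark does and
does not demonstrate.

## Model

A feedforward network on hashed circular fingerprints: input of `n_bits`
(default 2048, Morgan radius 1), one or two ReLU hidden layers of
`hidden_size` (default 512) and a single logistic output trained with binary
cross-entropy and Adam (batch size 16, at most 10 epochs). Two reference
configurations are provided: one hidden layer (learning rate 1e-3, dropout
0.5, L2 1e-3) and two hidden layers (learning rate 1e-4, dropout 0.2, no L2).
L2 applies to hidden-layer weights only; dropout is inverted and disabled at
inference, so the forward pass is deterministic. Early stopping keeps the
parameter snapshot of the epoch with the highest validation ROC-AUC, ties
resolved toward the earlier epoch (less drift from initialization). Weights
are initialized He-normal (hidden) / Glorot-normal (output) from a seeded
generator; the scheme, seed and split membership are stored in the
checkpoint, making every training bit-reproducible.

The implementation is plain NumPy. The networks involved are small enough
that a hand-written forward/backward pass is both faster to set up and more
transparent than a deep-learning framework, and it gives the interpretability
code exact analytic gradients and direct access to weights and activations.

## Substructure mining

Per first-layer neuron:

1. **Compound selection.** Training compounds whose activation strictly
   exceeds mean + `thresh_compound`·SD (default 2; population SD — the
   difference to the sample SD is negligible at training-set sizes but must
   be fixed for exact tests). A zero-variance neuron selects nothing.
2. **Bit selection.** The top `thresh_bits` fraction (default 0.1) of input
   bits by *signed* weight — only positively weighted bits can push a
   rectified activation up; ranking by magnitude is available behind a flag.
   The cut keeps the `⌈f·n⌉` largest weights, ties at the cut included.
3. **FCA.** The compound × bit context is enumerated into all closed
   (extent, intent) concepts using the intersection-closure construction
   (every intent is an intersection of object intents), with attribute
   bitmasks; guards abort on oversized contexts (500×300) or concept
   explosions rather than hang. Concepts are processed in order of
   decreasing support, ties toward smaller, lexicographically earlier
   intents (the more generic chemical concept first).
4. **Concept filtering.** A concept is used only if its intent's summed
   weight reaches `thresh_weight` (default 1) times the activation
   threshold; the bias is not part of the comparison. Once every bit of a
   concept has appeared in previously used concepts, the concept is skipped.
5. **Fragments.** Per extent compound, all atoms inside any environment of
   any intent bit are marked and split into connected fragments; a bit
   contributes its weight to a fragment only if at least one of its
   environments lies entirely inside it (a fragment must actually contain a
   feature to claim its weight), counted once regardless of occurrences.
   Only the best-scoring fragment per compound is kept, and only if its own
   summed weight clears the same threshold. A fragment is discarded when an
   already accepted strictly smaller fragment has the identical summed
   weight (the generic fragment explains the activation equally well).
6. **Hierarchy.** Accepted fragments (at most `max_substructures` = 200 per
   neuron) are deduplicated by canonical form and arranged into a DAG by
   strict subgraph containment, transitively reduced, generic fragments at
   the roots.

Fragment identity and matching use element, aromatic flag, formal charge and
bond order/aromaticity, hydrogens implicit, no stereochemistry. The canonical
form is the canonical SMILES of the induced subgraph *copied out as a
standalone graph* — canonicalizing inside the source molecule can give two
different strings for isomorphic fragments from different compounds, which
would corrupt deduplication and create cycles in the containment DAG.

Mining is restricted to the first hidden layer. In two-layer networks the
second layer's neurons largely aggregate first-layer features rather than
detect new chemistry; the evaluation module provides the diagnostics that
support this reading (pairwise activation correlations within/between
layers, and per-neuron ROC-AUC with the activation used as a classifier
score).

## Integrated gradients

Attributions integrate gradients along the straight path from the all-zeros
baseline (the empty fingerprint) to the input; path points are fractional bit
vectors, which the network accepts by construction. The differentiated output
F is the post-logistic probability by default (logit space is an option).
Layer attributions use the exact chain form — the gradient of F with respect
to the layer activations times the analytic path-derivative of those
activations — so the per-neuron sums telescope to F(x) − F(x′) rather than
relying on an averaged-gradient × activation-difference approximation.

Quadrature (`IGConfig.method`): the default `segmented` rule exploits that
every ReLU pre-activation is piecewise linear in the path parameter, so all
kink locations are found analytically and each smooth segment is integrated
with Gauss–Legendre; the completeness identity then holds to ~1e-13 at the
default m = 50. A single global Gauss–Legendre rule (`gausslegendre`, the
default of mainstream attribution libraries) and the textbook right-endpoint
sum (`right`, error O(1/m)) are available for comparison; the step-doubling
behavior of the latter is part of the test suite.

## Atom-level sharing

IG_input: bits below 1% of the strongest bit's attribution magnitude are
dropped; each surviving bit's attribution is split equally over its distinct
environments (hash collisions), and each distinct environment's share is
split equally over the atoms of all its occurrences. IG_hidden: each neuron's
attribution is shared equally among the most specific matched fragments of
its network (matched nodes with no matched child; a node is only tested once
all its parents matched), then equally among the embeddings of each fragment
— multiple embeddings of one fragment share, mirroring the environment rule —
then onto atoms, by default in proportion to the summed weight of the
covering bits (normalized to 1; uniform fallback when deduplication across
source compounds leaves no covered atom). Neurons with no match are ignored;
the fraction of positive attribution carried by matched neurons is reported
(`accounted_positive_fraction`). Both routes conserve attribution mass
exactly, which the test suite asserts to 1e-10.

Attribution ROC-AUC uses midrank tie handling (equal-sharing produces many
tied atoms) and is undefined — signaled, not silently zeroed — when the
ground truth covers no atoms or all atoms. Scores are computed for
true-positive predictions only: a false negative's explanation cannot be
expected to recover a toxicophore the model did not act on. Per-alert
aggregation restricts to compounds matching a single alert after an optional
alert-merge map for systematically co-occurring alerts.

## Synthetic benchmark

The generator assembles compounds by bonding 1–3 decorations onto a scaffold
(aromatic and aliphatic rings, a chain); the label is 1 iff at least one
configured SMARTS alert matches, and matched atoms are the per-compound
ground truth. The default study: 2000 compounds, four planted alerts
(aromatic nitro, epoxide, aziridine, nitrosamine), ~50% positives, no label
noise. Positive compounds carry one alert decoration, with a 5% chance of a
second — in real alert-labeled mutagenicity data most actives match a single
alert, and this matters scientifically: activations add, so if multi-alert
compounds were common they would dominate every neuron's
mean + 2·SD tail and the mined concepts would become chimeras joining two
toxicophores through scaffold atoms. The same failure mode appears when the
hidden layer is made much smaller than the reference 512: neurons stop
specializing, single-motif concepts no longer clear the relevance threshold,
and explanation quality collapses — an instructive sensitivity of the method
to representation width. Alert rules can carry exception SMARTS (a match
silences the rule) to emulate deactivating contexts for negative-prediction
explanations.

What the benchmark does *not* emulate: realistic property and size
distributions, assay noise (unless `label_noise` is set), alert-ambiguous
chemistry, and toxicophores defined by anything beyond a substructure match.
Passing the end-to-end tests shows the machinery is correct and that the
pipeline recovers planted causal substructures; it does not certify
explanation quality on experimental data, where labels are noisy and the
model's own errors propagate into the explanations.

Problem sizes used by the automated end-to-end study: 2000 compounds
(80/10/10 split), 512 hidden neurons, full extraction over all neurons,
explanations at m = 50 for the 200 test compounds. Fixed seeds (library 11,
split 5, network 5) make the whole chain reproducible.

## Depiction

Atom attributions map to RGB: white at zero, red hue for positive (toward
the toxic class), blue for negative, intensity proportional to |value|
relative to the data-set maximum and clipped to full intensity at 70% of it,
so the lower range stays discriminable. Input-level and hidden-level
explanations use separate scales — unmatched neurons systematically shrink
hidden-level magnitudes, so the two are not directly comparable. Only the
color computation is part of the library; structure rendering is left to the
user's RDKit drawing pipeline.

## Known limitations

- Mined fragments are literal subgraphs; no SMARTS generalization is
  attempted, so a slightly different variant of a motif (e.g. an aromatic
  nitroso where only nitro-containing fragments were mined) can fail to
  match and its neuron's attribution is then dropped.
- Large matched fragments dilute attribution over many atoms, lowering
  atom-ranking scores even when the right region is found.
- FCA enumeration is exponential in the worst case; the guards make this an
  explicit error rather than a hang, but pathological contexts are possible.
- Only first-layer neurons are mined; deeper layers are characterized
  diagnostically, not structurally.
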