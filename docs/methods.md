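# Methods

## Data model

A reconstruction is compared with ground truth purely at the level of the
brain graph: neurons are opaque string ids, and each synapse is a directed
edge with one 3-D centroid. Coordinates are treated as nanometres on an
isotropic grid; nothing in the package ever touches voxels. The same
abstraction is used for both inputs, and no correspondence between the two
id spaces is assumed anywhere — that is the point of the metric.

For the geometric error models a network also carries a morphology: each
neuron is a rooted tree of short cylindrical segments (id, parent, start
and end points, diameter, and a process-kind tag soma/axon/dendrite), and
each synapse is anchored on one presynaptic and one postsynaptic segment.

## Synapse correspondence

Synapse ids are reconciled by a minimum-cost one-to-one assignment on
Euclidean centroid distance, with a cap (default 300 nm, configurable)
beyond which assignment is forbidden. The cap is realised exactly by the
standard augmented construction: every synapse receives a private
"unassigned" slot at cost equal to the cap, pairs beyond the cap are
forbidden, and the solver minimises total paired distance plus cap times
the number of unassigned synapses. Post-filtering an uncapped optimum is
deliberately *not* used; it can produce a different (non-optimal) result.

For scalability the problem is solved sparsely: candidate pairs within the
cap are found with a k-d tree and each connected component of the candidate
graph is solved independently with `scipy.optimize.linear_sum_assignment`.
The objective is separable over components, so the decomposition is exact;
a brute-force enumeration oracle over all capped partial assignments
verifies optimality on small random instances in the test suite.
Determinism: inputs are processed in synapse-id order and the solver is
deterministic; among exactly tied optima any optimum is acceptable, and the
same one is always returned for the same input.

## Count table and tallies

For every matched synapse pair the ground-truth presynaptic terminal is
counted with the reconstruction presynaptic terminal, and likewise for the
postsynaptic terminals, incrementing c[gt_neuron, recon_fragment] for each.
Unmatched ground-truth synapses put both terminals in the reserved deletion
column, unmatched reconstruction synapses in the insertion row; a
`segmentation_only` mode instead discards unmatched synapses entirely, so a
sparse gold standard with missed synapses does not unjustly penalise the
reconstruction. A synapse whose direction is flipped in the reconstruction
lands in cross cells under this pairing and is therefore penalised with
both false-positive and false-negative paths — no explicit reversal
detection is needed (nor would it be possible with opaque ids).

True positives, false negatives and false positives are closed-form sums
over the table (see README). Two exact conservation laws are enforced by
property tests: per neuron, TP + FN equals C(row total, 2); and the
per-neuron false-positive attribution — merge pairs halved between the two
neurons involved, insertion-vs-neuron pairs assigned to the neuron, pure
insertion pairs kept in a reserved network-level term — sums to the global
FP exactly on every instance.

Per-neuron scores support two false-positive conventions: `attributed`
(the halving scheme above; the default, because it decomposes the global
count) and `incident` (every false-positive pair containing one of the
neuron's matched terminals at full weight, the convention under which the
worked toy example's green neuron scores 0.333). Score conventions at the
boundaries: an empty problem (no paths at all) scores 1; zero true
positives with any error present scores 0; an undefined precision or recall
is reported as NaN unless the other error count is also zero.

## Comparison metrics

The adapted Rand index and the NVI are computed from the same count table
with the insertion row and deletion column treated as additional neurons.
The published double sum for Rand-index true negatives restricts both
indices to increasing pairs, which silently drops pairs with i < i' but
j > j'; the default implementation counts true negatives as all unordered
terminal pairs in a different row *and* a different column — the only
definition under which TP + TN + FP + FN exhausts all C(total, 2) pairs,
as verified against a brute-force enumeration — and an `as_printed` mode
reproduces the literal formula. The NVI uses natural logarithms (the
normalized ratio is base-invariant), defines 0·log 0 = 0, and returns 0 for
a single-cell table, whose two one-block partitions are identical.

The undirected variant cannot be built from the count table without an
arbitrary per-synapse orientation choice, so it enumerates terminal pairs
directly on the matched edge lists (the line-graph f1 construction): a
ground-truth pair is a true positive when its two reconstruction partners
share a fragment at either end. On reversal-free inputs this equals the
directed tallies exactly (property-tested); with reversals it forgives
direction errors that the directed score penalises. In degenerate cases
where a pair of synapses shares *both* endpoints the gt-side and
recon-side enumerations can differ slightly; this is accepted and
documented rather than hidden behind an orientation heuristic.

## Synthetic networks

The generator aims at statistical plausibility as a substrate for the error
models, not at morphometric realism. Each neuron grows one axonal and four
dendritic trees from a uniformly placed soma; growth is a random walk with
2 µm segments, Gaussian turning noise (sd 0.35 rad), branching probability
0.08 per segment, and diameters tapering geometrically (axons from 600 nm,
dendrites from 1600 nm, floor 200 nm). Synapses follow Peter's rule on the
surface-to-surface distance between cross-neuron axon–dendrite segment
pairs: probability p_max below d1, zero above d2, linear in between, with a
greedy minimum-spacing rejection to prevent clustering. Cell types share
the growth model and only set counts and ids.

Defaults target the test-scale study condition of roughly 100–300 synaptic
terminals per neuron on a 50-neuron network: a 25×25×25 µm volume with
p_max = 0.6, d1 = 500 nm, d2 = 2000 nm, min_spacing = 300 nm yields ≈2800
synapses (mean ≈113 terminals per neuron). A `paper_scale_config` (872
neurons of five cortical types in 79×79×1300 µm) is provided for larger
runs but is not exercised by the tests. Everything is reproducible from a
single integer seed.

What the generator does *not* emulate: cortical layering and type-specific
morphometry, distance-dependent connection specificity beyond proximity,
bouton/spine geometry, and annotation noise in centroids. Passing tests on
these networks therefore demonstrate the metric's algebra and the error
models' behaviour, not performance on real electron-microscopy data.

## Error models

* **delete** removes exactly round(fraction·N) synapses (half-up), chosen
  uniformly without replacement.
* **insert** visits every cross-neuron segment pair within d2 and adds a
  spurious synapse with the linear kernel probability on surface distance;
  inserted synapses are flagged (`ins:` id prefix) and their centroids are
  jittered by ≤10 nm so they never collide exactly with a real synapse.
* **split** visits every process segment and, with the kernel probability
  on its *diameter*, detaches the segment together with its subtree as a
  new fragment; the parent side keeps the original id, and nested selections
  compose into fragments of fragments. Thin structures (spine necks) are
  the natural split sites.
* **merge** samples merge events on close cross-neuron segment pairs and
  unifies whole neurons by connected components (union–find, smallest id as
  representative), so every ground-truth neuron is a subset of one
  reconstructed neuron.

Split, merge and delete leave centroids untouched, so matching remains
exact and the measured degradation isolates the modelled error — mirroring
a simulation design in which the graph, not the geometry, is perturbed.

Per-neuron diagnostics are computed from the count table: the deleted
fraction (share of a neuron's terminals in the deletion column), the
foreign fraction (share of the hosting fragment's terminals not belonging
to the neuron; equals (n_B+n_C)/(n_A+n_B+n_C) when A is merged with B and
C), and the split entropy — the Shannon entropy of the neuron's matched
terminals across fragments divided by the log of its matched terminal
count, which is 0 for an unsplit neuron and bounded by 1 since a neuron
cannot occupy more fragments than it has terminals. The normalisation
choice was genuinely open (entropy could also be normalised by the log of
the fragment count); dividing by the terminal count's log was chosen so
that heavier fragmentation of the same neuron always scores higher.

## Crop-and-relabel preprocessing

When ground truth is a densely annotated box inside a larger volume, a
reconstruction that correctly joins two branches through a branch point
*outside* the box would be unjustly penalised as a merge. `crop_relabel`
clips segments to the box (Liang–Barsky), drops synapses whose centroid or
anchors leave it, and relabels each neuron's surviving segments one
fragment per connected component of the restricted parent-link graph.
Applying the same crop to both sides restores a perfect score for a
perfect reconstruction, which the tests verify on generated networks.

## Experiment sweeps

The default sweep applies each error model at three intensities to
50-neuron networks generated from three seeds (delete fractions
0.1/0.3/0.6; insert p_max 0.05/0.2/0.6 over d1=500, d2=1500 nm; split
p_max 0.05/0.3/0.9 over diameters d1=300, d2=800 nm; merge p_max
0.001/0.004/0.02 over d1=200, d2=600 nm — merge probabilities are small
because events compose transitively across thousands of close segment
pairs). The grids were chosen to produce clearly graded degradation from
mild to severe within each model. Within one model and seed the same
random stream is used at every intensity, so the smaller error set is
nested in the larger one and degradation is monotone by construction, not
merely in expectation. Problem sizes throughout (50 neurons, ~2800
synapses, 3 seeds) are the package's test-scale study condition; the
generator and sweep scale to much larger settings via configuration.

## Known limitations

* Polysynaptic junctions (one presynaptic, many postsynaptic partners) are
  outside the data model: every record has exactly one pre and one post id.
* Tie-breaking between exactly equal-cost matchings follows the solver's
  deterministic choice rather than a documented lexicographic rule.
* The undirected score's gt-side/recon-side asymmetry in multi-shared-
  endpoint cases, noted above.
* Generator realism is untested against any reference morphometry; it is
  fixture machinery with physiologically plausible scales, not a NeuGen
  replacement.
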