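# Methods

This note records the modelling choices behind `relrna`, the parameters
that matter, what the synthetic-structure generator does and does not
emulate, and the numerical conventions a maintainer needs.

## Problem and representation

Fixed-backbone RNA inverse design: given one or more 3D structures that
a single sequence must adopt, predict a per-position distribution over
{A, C, G, U} and sample candidate sequences. Multi-state inputs matter
for regulatory RNAs such as riboswitches, whose function depends on two
mutually exclusive secondary structures; the architecture therefore
keeps the K conformations separate through the encoder and merges them
late (embedding average for the one-shot decoder, probability average
for the autoregressive one) rather than merging their edge sets up
front.

Each nucleotide is reduced to the P, C4′ and N1/N9 (pyrimidine/purine)
atoms, with C4′ as the node position. Typed edges:

| type | definition | count |
|---|---|---|
| primary | backbone neighbours, both directions | 2(L−1) |
| secondary | annotated base pairs (canonical + non-canonical), both directions | 2·\|BP\| |
| spatial | DBSCAN co-cluster of unpaired nts, 2 Å ≤ d < 2·eps, \|j−i\| ≥ 500 | ≤ 4·L |

The types are disjoint by construction; a base pair annotated between
backbone neighbours (biologically dubious, occasionally emitted by
annotation tools) is dropped from the secondary list so the invariant
holds. Base-pair detection itself is out of scope: annotations are
consumed from DSSR-style JSON or a 1-based pair-list TSV.

Spatial-edge parameters (eps = 20 Å, min_samples = 5, minimum sequence
separation 500 nt, 2 Å minimum length, 4·L cap) are the defaults of the
method this package implements; DBSCAN runs with the Euclidean metric
on C4′ coordinates of unpaired nucleotides only, positions lacking a
C4′ atom are excluded from clustering, and "down-sampling to the cap"
means seeded uniform sampling of *undirected* pairs without
replacement, keeping the directed set symmetric. Candidate generation
loops within clusters via a KD-tree rather than over all L² pairs.

## Features

Node scalars (15): sin/cos of three inter-atom angles
(P–C4′–N, C4′ᵢ₋₁–C4′ᵢ–C4′ᵢ₊₁, N–C4′–C4′ᵢ₊₁) and three dihedrals
(P–C4′–Pᵢ₊₁–C4′ᵢ₊₁, C4′ᵢ₋₁–Pᵢ–C4′ᵢ–Pᵢ₊₁, Nᵢ₋₁–C4′ᵢ₋₁–C4′ᵢ–Nᵢ), then
three distances (P–C4′, C4′–N, C4′–C4′ᵢ₊₁). Node vectors (4): unit
C4′→P (same residue), C4′→Pᵢ₊₁, C4′→N (same residue), C4′→Nᵢ₋₁. The
"forward/backward C4′–N" pair is ambiguous in prose descriptions of
this feature family; the same-residue/previous-residue reading used
here is isolated in `features.node_features`. Any term referencing a
missing atom or running off a terminus is zero-filled (not NaN, not
imputed) so tensors stay dense and indexing stays aligned with the
sequence.

Edge features: unit displacement x⃗ⱼ−x⃗ᵢ plus the C4′ distance encoded by
16 Gaussian RBFs with centers evenly spaced on [0, 40 Å] and width equal
to the spacing; 40 Å covers the maximal spatial edge length (2·eps).
All edge types share this featurization, and there are no positional
encodings — removing them is a deliberate property of the architecture
(sequence position should not leak into a geometry-only encoder).

## Network

GVP units keep scalar and 3-vector channels separate; vectors are mixed
only by linear maps over the channel axis and rescaled by sigmoid gates
computed from invariants, which is what makes the network equivariant.
Default widths: node 128 scalar / 16 vector, edge 32 scalar / 1 vector
(standard GVP-GNN conventions). A linear GVP embeds raw features; each
of the `num_layers` (2 by default, 4 supported) relational layers runs
one two-GVP message function per edge type, aggregates messages by
summation over each type's neighbourhood, pools the per-type aggregates
with learned scalar weights w_p, w_s, w_t (one triple per layer,
initialized to 1, unconstrained), and applies a residual update:
message-add → LayerNorm → two-GVP feed-forward → residual → LayerNorm.
The scalar channel uses standard layer normalization with learned
gain/bias; the vector channel is divided by the RMS of its channel
norms (no learned parameters, preserving equivariance). Early versions
without normalization trained but diverged after a few hundred epochs;
the normalization follows the reference GVP-GNN design.

With a single populated edge type and unit weight a relational layer is
mathematically identical to a plain single-component GVP-GNN layer; the
test suite asserts this bitwise against an independently written
single-component forward path sharing the same parameters.

Multi-state pooling over K structures is a position-wise **mean** of the
per-structure final embeddings (a mean rather than an unnormalized sum
so the embedding scale is K-invariant, and duplicate-structure inputs
collapse exactly to the K=1 case).

Decoders:

* **NAR**: two node-wise GVPs on the pooled embedding, linear 4-way
  head, softmax. No graph edges are used at decode time; the union of
  the K edge sets is never formed.
* **AR** (5′→3′): per structure k, position i is conditioned on the
  letter at i−1 through a learned 5-row embedding table (A, C, G, U,
  and a start/unknown token used at i = 0 and for masked letters),
  concatenated with the node embedding and passed through a one-hidden-
  layer MLP. Training teacher-forces the true previous letter; design
  time feeds each structure its own sampled trajectory and pools the
  per-structure probabilities per position only after full decoding
  (pooling per step would couple the trajectories). The exact
  conditioning mechanism is the package's own choice; only the causal
  5′→3′ contract and the probability-average pooling are contractual.

Training: masked cross-entropy of the native letters (positions with
letter N excluded from loss and metric denominators), Adam with
lr = 1e-3, dropout 0.1 (whole vector channels dropped together),
gradient clipping at global norm 1, seeded group-order shuffling. The
learning rate was chosen for stable convergence of the CPU-scale
configurations in this package; higher rates (≥ 2e-3) oscillate on the
small-graph regime. Checkpoints (npz: parameters + config) reload to
bit-identical evaluation.

The network, including reverse-mode automatic differentiation, is
implemented directly on NumPy (`relrna.nn.autodiff`); gradients of
every primitive are verified against finite differences in the test
suite.

### Invariances

Output probabilities are invariant under proper rigid motions
(rotations + translations) of all input coordinates; tests assert
< 1e-4 relative deviation and observe ~1e-15. Under *improper*
operations (reflections) strict invariance is impossible with this
feature set: the sin of a dihedral changes sign under reflection, so a
mirrored backbone is a genuinely different (opposite-chirality) input.
Translation invariance of the scalar features is asserted at machine
precision — bitwise equality is not meaningful because translating
float coordinates rounds the inputs themselves.

## Metrics

Perplexity, accuracy, recovery (16 samples by default) and sc score as
fractions; the CLI reports fractions and table-style percentages are
fractions × 100. Argmax ties in accuracy resolve to the first letter in
A<C<G<U order. The sc score's similarity between predicted and
reference pair sets is fixed as the Matthews correlation over all
C(L,2) unordered position pairs (both-empty defined as 1.0, undefined
denominator as 0.0); the secondary-structure predictor is a pluggable
adapter. Two adapters ship: a ViennaRNA `RNAfold` subprocess wrapper,
and a maximum-matching Nussinov folder used by the tests — the latter
is a deliberately simple stand-in, not a thermodynamic model, and
should not be used for real design decisions.

## Data splits

Sequence-identity splitting emulates CD-HIT's greedy longest-first
representative clustering at 90% identity (identity = matches /
alignment length under global alignment via edlib); an adapter also
reads real CD-HIT `.clstr` files. Structure-similarity splitting
consumes cluster labels from an external TM-score clusterer via a
tool-agnostic TSV; the built-in RMSD-threshold fallback is labelled an
approximation (global C4′ RMSD, equal lengths only). Whole clusters go
to one side; clusters are ranked by mean intra-group pairwise Kabsch
RMSD and validation/test (default 100 groups each) are filled from the
high-RMSD end with seeded tie-breaking, so conformationally redundant
groups concentrate in training. Tie-break order in the original
protocol is unknown; the seeded shuffle makes ours explicit and
reproducible.

## Synthetic structure generator

`synthetic` provides the study conditions for every test: an idealized
A-form helix (rise 2.81 Å, twist 32.7°, radius 9.4 Å, partner-strand
phase 150°), hairpins (helix stem + smooth loop arc), a toy riboswitch
(S1–loop–S2–loop–S1 with S2 pairable either way, K = 2 with distinct
coordinates and pair sets), and compact unpaired random-walk coils
(6 Å step, confining radius ∝ L^1/3) long enough to produce spatial
edges. All generators are pure functions of parameters + seed and
round-trip through the PDB writer/reader.

Hairpins carry 0.3 Å seeded Gaussian coordinate jitter by default. This
emulates the coordinate heterogeneity of experimental structures and is
load-bearing: noise-free ideal stems make every mid-stem nucleotide
geometrically *identical*, so distinct training sequences become
unrecoverable in principle — a degeneracy real data does not have. The
helix generator stays exact (jitter 0) so its symmetry properties can
be asserted. Consequently, passing tests demonstrate that the pipeline
learns geometry→sequence mappings when geometry carries signal; they do
not demonstrate recovery rates on experimental RNA, which has
sequence-dependent backbone geometry, modified residues, missing atoms
and crystal contacts the generator does not model.

The overfit sanity experiment uses five hairpins with distinct
stem/loop sizes ((3,4), (3,5), (4,6), (4,7), (3,8)): under a 2-layer
receptive field, same-shaped loops atop identical stems alias across
fixtures, which would make memorization impossible for reasons
unrelated to implementation correctness.

## Problem sizes

Test-suite and acceptance runs use 10–31 nt fixtures, 1100–1500 nt
coils for spatial edges, 300-epoch training runs of the default-width
2-layer model, and 200-epoch runs for the AR riboswitch demonstration —
sizes chosen so the whole pipeline (including brute-force oracles)
reruns from scratch in about a minute on one CPU core. Full-scale
training on public RNA structure repositories is explicitly out of
scope here; nothing in the implementation is specific to small inputs
(the spatial-edge construction is the only superlinear step and is
KD-tree-indexed).

## Known limitations

* The AR conditioning is first-order (previous letter only); deeper
  causal context would require an attention- or RNN-style decoder.
* The Nussinov stand-in folder overpredicts base pairs; sc scores from
  it are only comparable within a run that uses it consistently.
* The structsim fallback clusterer is not TM-score based.
* Reflection (chirality) invariance is intentionally absent (see
  Invariances).
* NumPy training is single-core; wall-time is fine for package-scale
  experiments and prohibitive for repository-scale training.
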