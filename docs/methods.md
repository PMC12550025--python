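# Methods

## Problem setting

`catgen` models homogeneous-catalysis reaction records: each record is a
set of role-tagged molecules (reactants, optional reagents, one product,
one catalyst complex — ligands and metal fragments are part of a single,
possibly dot-separated catalyst SMILES), a reaction time in hours, and a
scalar catalytic performance target (percent yield by default; other
endpoints such as binding energies in kcal/mol are carried through a
`target_kind` tag). The package jointly learns to *reconstruct/generate*
catalysts conditioned on the reaction context and to *predict* the target,
so that the latent space can later be searched for catalysts predicted to
perform well under a fixed condition.

## Catalyst representation

A catalyst is a one-hot triple **M** = (*T*, *A*, *B*) over a fixed node
budget *S*: *T* ∈ {0,1}^S marks the number of occupied nodes (index 0 is
the reserved empty state, so the largest encodable molecule has S−1
atoms), *A* ∈ {0,1}^(S×At) the atom type per node (channel 0 = "no atom"),
and *B* ∈ {0,1}^(S×S×Bt) the bond type per node pair (channel 0 =
"no bond"; *B* is symmetric in its node indices and its diagonal is
no-bond). At the default sizing S=100, At=68, Bt=6 the flattened
representation has 100 + 100·68 + 100·100·6 = 66 900 entries.

Design choices the representation leaves open and how they are fixed here:

* **Atom-type membership.** The channel count is fixed (68 including
  no-atom) but membership is data-dependent: `build_vocabulary` orders the
  observed elements by frequency (ties alphabetical) and pads with unused
  slots, and the vocabulary is serialized with every checkpoint so decoding
  is reproducible. A default 67-element palette (organic subset + metals
  common in homogeneous catalysis) is provided for the full-size setting.
* **Bond types.** {no-bond, single, double, triple, aromatic, other};
  "other" absorbs dative/unspecified bonds so organometallic inputs encode
  without growing the channel count.
* **Node order.** Encoding uses the toolkit's canonical atom order
  (fragments occupy consecutive blocks); training augmentation
  (`shuffle_augment`) randomizes the order of occupied nodes, five
  orderings per record by default. Five *total* copies replace the
  canonical single copy.
* **Charges and stereochemistry are not channels.** Formal charges are
  re-derived (where legal) during reconstruction; chirality is not
  represented at all. Round-trip identity therefore holds for neutral,
  achiral structures, which is what the synthetic generator emits.

## Model

All neural components run on a small reverse-mode autodiff engine written
for this package (`catgen/_autodiff.py`); no GPU framework is required.

* **Catalyst embedding** x: three MLPs (for T, A, B), outputs summed.
  The embedding is deliberately order-sensitive; node-order augmentation
  supplies the invariance pressure during training.
* **Condition embedding** c: a shared 2-layer graph-attention encoder with
  mean pooling embeds each reactant/reagent/product molecule (mean over
  multiple molecules within a role; a learned "no reagent" token when the
  reagent list is empty), concatenated with log(time/h) and a one-hot over
  catalyst molecular-weight clusters. Cluster edges default to
  training-set quantiles (8 bins) and are stored in the checkpoint. The
  attention layers consume node features and connectivity; the declared
  edge features are available to alternative encoders but not used by the
  default one.
* **Encoder** Q(z|x,c): MLP with mean and log-variance heads,
  reparameterized sampling z = μ + exp(½ log σ²) ⊙ ε.
* **Decoder** P(M|z,c), three sequential stages: (1) a length head on
  (z‖c); (2) an annotation head on (z‖c‖T-block); (3) a per-node linear
  map of (A-block‖z‖c) to node vectors u_i whose per-channel bilinear
  products u_i W_t u_j form the initial adjacency, refined by a small
  per-pair MLP and symmetrized. During training each stage independently
  consumes the true upstream block with probability 0.25 (teacher
  forcing; one Bernoulli draw per stage, not per sample).
* **Predictor** f(z,c): MLP on the *mean* latent concatenated with the
  condition; trained on standardized targets, reported on the original
  scale (clipped to [0,100] for yield).
* **Loss** L = α·L_recons + β·L_KL + L_pred with α=1, β=0.01 by default.
  L_recons sums categorical cross-entropies over the T fiber, the S rows
  of A and the S² fibers of B; because almost all of B is no-bond, fibers
  whose true class is no-bond are down-weighted by the observed
  bond/no-bond ratio (floored at 0.02), computed from the training split
  and stored with the results. L_KL is the closed-form Gaussian KL to
  N(0,I); L_pred the squared error on the standardized target.

Architecture defaults (d_x=256, D=64, graph width 64) are config-driven;
`TrainingConfig.desk()` (d_x=64, D=16, graph width 16) is the CPU-scale
setting used throughout the tests. Optimizer: Adam, lr 2·10⁻³, batch 16.

## Reconstruction with validity correction

Decoder logits are converted to molecules by: reading the size from
argmax T; typing occupied nodes by row-argmax of A (nodes argmaxing to
no-atom or padding channels are treated as absent); collecting all
non-no-bond candidate pairs (i<j, fibers symmetrized by averaging),
sorting by probability descending (ties broken lexicographically on
(i, j, channel)) and adding bonds in that order; after each addition the
valence of both endpoints is checked against a standard table — a bond
that would exceed the maximum legal valence is rejected, except where a
single formal charge legalizes it (quaternary N⁺, O⁺/P⁺/B⁻; carbon is
never charged; metals and unlisted elements get a permissive cap of 6).
A rejected pair becomes no-bond; it is not re-offered a lower-probability
bond channel. Finalization attempts sanitization; on kekulization failure
aromatic flags are cleared (aromatic bonds fall back to single) and
sanitization is retried; irreparable structures yield an empty output,
which is a legal result counted as invalid downstream. Finally, fragments
consisting of exactly one uncharged carbon atom are removed (single
heteroatoms and metals are kept). With correction off the raw argmax
structure is returned, possibly invalid.

## Data curation

`parse_reaction_table` reads a SURF-like CSV/TSV (columns reactant_1..n,
product, catalyst, reagent_1..n, time_h, yield), canonicalizes all
SMILES and drops rows with missing roles, non-positive times or
unparseable SMILES, logging a machine-readable reason per drop. Curation
then proceeds: duplicate averaging over the order-insensitive key
(reactants multiset, product, catalyst, reagents multiset, time); IQR
outlier removal (keep iff inside [Q1−1.5·IQR, Q3+1.5·IQR] on catalyst
molecular weight, catalyst atom count and target; quartiles by linear
interpolation, the numpy default; fewer than 4 records → no-op with a
warning); clipping of yield-kind targets to [0,100]; downsampling of
overrepresented catalysts (default cap: 1% of the input, at least 1);
and a seeded 90:5:5 train/validation/test split.

## Generation and metrics

Three sampling schemes: *random latent + random condition* draws
uniformly inside the per-dimension integer bounding box
[floor(min), ceil(max)] of the training latent means and pairs it with a
random training condition; *around sample + random condition* perturbs an
anchor catalyst's latent mean with Gaussian noise (σ = 0.5 latent units
by default); *around sample + sample condition* uses the anchor's own
condition. Metrics over a generated set: Valid (sanitizable fraction),
Valid(Task) (dataset-specific predicate), Unique (distinct canonical
structures), Novel (distinct structures absent from the training set),
IntDiv (mean pairwise Tanimoto *distance* among distinct valid
structures) and SNN (mean over valid molecules of the maximum Tanimoto
*similarity* to any training molecule), all on 2048-bit ECFP4
fingerprints. Valid/Unique/Novel all use the number of generation
attempts as denominator (nested, MOSES-style), which makes
Novel ≤ Unique ≤ Valid an identity rather than an empirical observation;
SNN averages over valid molecules. Task rules shipped: single fragment
(L-SM/PS), Pd(OAc)₂ presence (SM), and the L₁-M-L₂ motif — exactly three
fragments of which exactly one is a lone metal atom (CC). The ligand
filter requires N or P, exactly three covalent bonds on every P, no P–H
bond and no P in a three-membered ring. Fréchet ChemNet Distance needs an
external trained network and is exposed only as an optional report field,
never fabricated.

## Inverse design

The optimization objective decodes a latent point under a fixed
condition, re-embeds and re-encodes the decoded molecule, predicts from
the re-encoded mean, and adjusts the prediction with structural
penalties/rewards and an optional similarity term
(−w·(1 − max Tanimoto to a reference set)). In match-value mode the base
score is −|prediction − target|; the C–C cross-coupling case targets the
midpoint (−27.55 kcal/mol) of the −32.1 to −23.0 kcal/mol binding-energy
window and uses 50 rounds × top-10 = 500 candidates. Failed decodes get a
finite worst-case score (min observed − 3·IQR, floor-capped) so the
search continues. The search itself is sequential model-based
optimization: uniform exploration for the first 10 points, then a
Gaussian process (Matérn ν=2.5 + white noise, fixed hyperparameters,
refit on at most 256 subsampled points for O(n³) control) with expected
improvement maximized over 256 random candidates, constrained to the
training-latent integer box or to a declared ball around an anchor
latent. Duplicate decoded molecules within a round are collapsed before
the top-k selection.

## Synthetic data

`make_reaction_dataset` assembles molecules from a fixed library of
chemically safe fragments (alkyl, aryl, amine, phosphine, carbonyl,
halide pieces) joined by single bonds within an atom budget (default 12),
guaranteeing sanitizable, neutral, vocabulary-covered structures and
plausible phosphine cases for the ligand filters; catalysts gain a lone
metal fragment ([Pd]/[Ni]/[Pt]) with probability 0.2. The target is
100·sigmoid(w·[MW/100, heteroatom count, ring count, log time] + b) plus
Gaussian noise (σ=5 by default), clipped to [0,100]; (w, b) are drawn
from the dataset seed and returned, so recovery experiments have a known
ground truth. What the generator does *not* emulate: real reaction-class
distributions, chemically meaningful reactant→product relationships,
charged species, stereochemistry, and condition–yield mechanisms beyond
the declared descriptor function — so green tests demonstrate protocol
and codec correctness and learnability of a known signal, not chemical
accuracy on real reactions.

## Problem sizes used in the test and acceptance runs

Chosen as desk-scale defaults: codec round-trip on 500 generated
catalysts; post-processing sanitization on 10⁴ random logit tensors
(node budget 12); valence-oracle agreement on ≥100 randomized conflict
cases; learning sanity on 200 records (≤12 atoms, ×5 node-order
augmentation, 20–25 epochs with the desk architecture), where total loss
and training prediction RMSE both fall by well over 50 %; surrogate
recovery at n=2000 (noise-free, held-out R² ≥ 0.99) and n=500 (σ=5,
held-out RMSE ≤ 2σ); mock-objective optimization at the CC budget
(50×12 calls). Longer training continues to improve reconstruction
fidelity; exact end-to-end memorization of full structures (decode of a
record's own latent mean reproducing its exact canonical SMILES) remains
below 50 % for 200 records at these sizes — adjacency decoding through a
rank-limited bilinear head is the bottleneck — and is reported honestly
by `CVAEResults.reconstruct_records` rather than asserted as a test.

## Known limitations

* No charge or stereochemistry channels; charged/chiral catalysts
  round-trip only up to those attributes.
* The graph-attention condition encoder ignores declared edge features.
* The GP surrogate uses fixed kernel hyperparameters; for rugged
  objectives the expected-improvement search degrades toward random
  search rather than failing.
* Pre-training at the scale of public reaction corpora (10⁴–10⁵
  reactions, S=100) is architecturally supported but not exercised by the
  test suite, which runs entirely at desk scale.
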