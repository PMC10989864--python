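# Methods

## Problem and labels

Ready biodegradability is a binary screening property: under the MITI-I
test a compound is readily biodegradable (RB) when its biochemical
oxygen demand reaches at least 60% of the theoretical demand within
four weeks, otherwise not readily biodegradable (NRB). The package
treats RB as the positive class throughout (Sn = recall of RB,
Sp = recall of NRB). Model output is a probability p(RB); the decision
rule mirrors the assay's threshold — RB iff 100·p ≥ 60, boundary
inclusive. BA and ER are invariant to the positive-class choice, so the
headline numbers do not depend on this convention.

## Graph construction

Molecules are parsed with RDKit over heavy atoms only; hydrogens enter
via the total-H one-hot feature. Parsing canonicalizes first and builds
the graph in canonical atom order, so chemically identical inputs
("CCO", "OCC") produce bit-identical graphs — this makes duplicate
detection exact string matching on canonical SMILES, and graph
identity trivially stable across runs. The adjacency matrix is
symmetric with zero diagonal: bonds are undirected, and the sum
aggregation assumes symmetric neighbourhoods. Bond features are not
used; bond order reaches the model only through the aromaticity and
hybridization atom features. Multi-fragment (dotted) SMILES are
accepted as disconnected graphs with a logged warning, because
rejecting salts silently would surprise users; stereochemistry is
parsed but not featurized.

The atom-feature layout (element list with a trailing "other" slot,
degree 0–10, implicit valence 0–6, formal charge, radical electrons,
hybridization SP/SP2/SP3/SP3D/SP3D2, aromaticity, total H 0–4;
d0 = 75) is frozen in `constants.py` under a version string that
checkpoints record and verify on load. If a different canonical feature
list is ever adopted, only that file changes and the version bumps.

## Architecture

Per layer t: messages are a linear perceptron with nonlinearity σ
(default ReLU, configurable), aggregation is the neighbour sum, and the
update feeds the concatenation [(1+ε)·h_v^(t−1) ‖ h_N(v)] into a GRU.
Design choices where the scheme is genuinely open:

* **GRU state.** A single GRU step needs a recurrent state; we use the
  node's previous representation h_v^(t−1), so the update combines the
  GIN-style (1+ε) self-term (through the input) with a gated carry of
  the node's own history (through the state).
* **ε** is per-layer and learnable, initialized 0; a config switch can
  fix it. Per-layer is the safer default since nothing forces the
  self-weighting to be depth-independent.
* **Readout.** Weighted-sum-and-max: z_t = [Σ_v w_v h_v ‖ max_v h_v]
  with w_v = logistic(a·h_v + b), a one-layer scalar gate (softmax-free,
  the conventional parameterization of this readout). Readouts are taken
  after every layer t = 1..T (layer 0, a plain affine projection of raw
  features, carries no neighbourhood information and is excluded).
* **Fingerprint.** z_G is the final hidden state of an LSTM with width
  2d run over (z_1, …, z_T) in layer order; the final state is the
  natural summary of the whole depth sequence.
* **Input projection.** One affine map lifts d0 = 75 atom features to
  the hidden width d, required for GRU dimensional consistency.
* **Head.** One affine map from z_G to a logit, logistic squashing.

Defaults T = 3, d = 64 are conventional for small-molecule property
prediction and fully config-exposed; the architecture nowhere depends
on them. All initialization randomness flows from a single integer
seed (Glorot-normal matrices, zero biases), and initialization is
bit-reproducible given (config, seed). Dropout is not implemented.

Sum and max pooling with shared per-node maps make the forward pass
invariant under atom relabelling; the suite checks this to 1e−5 over
random permutations, and checks one full layer against a brute-force
per-node loop to 1e−9.

## Implementation note

The forward pass, backpropagation and Adam are implemented on NumPy
with a small reverse-mode autodiff engine (`autodiff.py`): elementwise
arithmetic with broadcasting, 2-D matmul, concat, row reductions and
the needed nonlinearities. Gradients of every primitive and of full
gated-cell composites are verified against central finite differences.
Max-pooling ties route gradient to the first-occurring argmax row.

## Training

Loss: focal loss, −α(1−p)^γ log p for RB and −(1−α)p^γ log(1−p) for
NRB, mean-reduced over the batch; defaults γ = 2, α = 0.25 (the focal
loss literature's defaults — the choice matters only under strong
imbalance and both are config-exposed). `alpha: null` selects the
unweighted form, whose γ = 0 limit is exactly binary cross-entropy
(tested to 1e−9). Probabilities exactly 0 or 1 are clamped to
[1e−7, 1−1e−7] with a warning before the logarithm.

Optimizer: Adam, lr 1e−3, β = (0.9, 0.999), batch 32, at most 100
epochs — field-standard defaults, all in `TrainConfig` / the YAML
config file. When a validation set is supplied, training early-stops
on its balanced accuracy with patience 10 and returns the best-scoring
weights. Training is bitwise reproducible given (config, seed, data):
the only randomness is the epoch shuffling and parameter init, both
seeded.

Cross-validation: stratified fivefold on the training split
(stratification because the published benchmark is 547/1178
imbalanced; unstratified folds would make fold metrics noisy), shuffled
with the config seed; each fold trains a freshly initialized model,
early-stopping on its held-out fold. Selection takes the highest
test-split BA, ties broken by external-split BA then lower fold index.
Caveat: selecting on the test split means the test metrics of the
selected model are mildly optimistic; the external split is the honest
generalization estimate.

## Synthetic benchmark

The generator emulates the *shape* of the real benchmark — a CSV of
labelled SMILES with stratified 60/20/20 train/test/external splits —
not its chemistry. Molecules come from a fixed grammar (alkyl chains
C1–C6, optional benzene core, hydroxyl/amine/carboxyl decorations, 0–3
chlorines); the default label rule is NRB iff ≥ 1 chlorine. The rule is
deliberately linearly separable in the atom-type features: if the model
fails to learn it, the failure is in the implementation, not the data.
A harder rule (NRB iff ≥ 2 Cl AND aromatic) ships for nonlinearity
regression tests. Default class balance is 0.5 (the separability test
should not also depend on imbalance handling); the generator takes a
target balance parameter for imbalanced fixtures. Generation is a pure
function of its spec and every emitted SMILES parses.

What passing on this fixture shows: the full pipeline (featurization →
message passing → readout → fingerprint → focal training → CV →
selection → 60% rule) can extract a substructure-determined label from
graphs. What it does not show: performance on real biodegradation
data, where labels are noisy, the decision boundary is not a single
substructure, and the chemistry is far more diverse.

## Problem sizes and tolerances

The learnability check runs fivefold CV on the 400-molecule fixture
with a compact network (T = 2, d = 32, lr 3e−3, ≤ 30 epochs, patience
5) — ample capacity for a separable rule and small enough that the
whole check runs in well under a minute on one CPU; the selected model
must reach held-out BA ≥ 0.95. Numerical tolerances: permutation
invariance 1e−5 (float summation-order effects only), layer-vs-oracle
1e−9, metric identities 1e−12, focal/cross-entropy agreement 1e−9.

## Known limitations

* No bond/edge features, no 3D information, no stereochemistry.
* Selection on the test split (see caveat above).
* Training is CPU-bound pure NumPy: fine for the benchmark scale
  (thousands of molecules), not for millions.
* The external 1725-chemical benchmark must be supplied by the user;
  the loader then reports its composition (1725 total; 547 RB / 1178
  NRB) and duplicate structure, but no network access is attempted.
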