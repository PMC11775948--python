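# Methods

## Model

A molecule is an undirected graph: nodes are heavy atoms labeled by
element, edges are bonds weighted by multiplicity. Aromatic systems are
**kekulized** so every bond carries an integer multiplicity in {1, 2, 3};
the propagation rule needs a single numeric adjacency and alternating
single/double bonds are the standard integer-valued reading of an aromatic
ring. Hydrogens are implicit. Disconnected SMILES (salts written with `.`)
are kept as one graph; the self-loop added during normalization guarantees
strictly positive degrees, so propagation and mean pooling remain well
defined for every component, including isolated atoms.

Initial node features encode the *r*-radius subgraph of each atom. Because
"all distinct possible r-radius subgraphs" need a concrete index, we use
iterative Weisfeiler–Lehman relabeling: round 0 is the element symbol, and
each of the *r* subsequent rounds hashes the node's current label together
with the sorted multiset of (bond multiplicity, neighbor label) pairs.
This is deterministic, isomorphism-invariant at radius *r* for molecular
graphs in practice (verified against brute-force neighborhood-isomorphism
search on small molecules), and linear-time. Each identifier maps to a
random unit-norm vector in **R**^d derived from a cryptographic hash of
(master seed, identifier): an identifier first seen at inference time gets
exactly the vector it would have received during training, with no
dependence on vocabulary insertion order and no stored state needed for
reproducibility.

Propagation uses the symmetric-normalized, self-looped adjacency
Ã = D̂^(−1/2)(A + I)D̂^(−1/2) with D̂ taken from **weighted** row sums —
bond multiplicities enter the normalization, consistent with
multiplicity-weighted edges (a 0/1-binarized mode is available via
configuration). There are no bias terms inside the propagation layers;
each layer is X⁽ᵗ⁺¹⁾ = ReLU(Ã X⁽ᵗ⁾ W⁽ᵗ⁾) with W⁽ᵗ⁾ ∈ **R**^(d×d).
Final node embeddings are mean-pooled into the graph embedding v⃗_G.

The feed-forward head is deliberately small: one hidden layer of width *d*
with ReLU and biases, then a linear map to 11 outputs. The head
architecture is a genuinely open design point — the published description
("fully connected feed-forward discriminative network") does not pin down
a shape, and the quoted overall weight count is not reconstructible from
any obvious head, so we chose the smallest head consistent with the
description and made it the documented default. SoftMax over the 11
outputs gives single-class probabilities; element-wise sigmoids give
independent membership probabilities, thresholded at ½ **inclusive** (a
probability of exactly one half declares membership).

## Training

Cross-entropy (softmax) or the sum of 11 binary cross-entropies (sigmoid)
is minimized with Adam at learning rate 10⁻³ (otherwise standard Adam
constants), 100 epochs by default, taking one gradient step per molecule
and visiting the training set in a seeded shuffled order each epoch.
Mini-batching is a free parameter of the method; batch size 1 keeps the
implementation simple and exactly reproducible. When a validation set is
supplied, the parameters of the epoch with lowest validation loss are
returned (best-epoch checkpoint); final metrics are always computed on the
untouched test split. All gradients are hand-derived (for both heads the
logit gradient reduces to *probabilities − targets*), and the whole model
lives in numpy: with ~10⁴ weights and molecular graphs of tens of nodes,
dense BLAS is faster than framework overhead, there is no GPU requirement,
and two runs with the same seed agree bitwise at a fixed thread count.

Default hyperparameters: embedding dimension d = 50, l = 3 propagation
layers, subgraph radius r = 2, 100 epochs. The random forest uses 300
trees, maximum depth 60, Gini impurity. The multi-label baselines are
kNN with k = 5 (per-class vote fractions among the neighbors), bagged
logistic regression with 25 base learners (the "ensemble logistic
regression" baseline is described only by name in the literature; bagging
with averaged probabilities is our concrete reading), and 11 independently
trained binary forests. All of these are configurable.

## Global molecular features

The 173-entry vector w⃗ is 166 public MACCS substructure keys (vector slot
*i* holds key *i* + 1) plus seven physicochemical descriptors: molecular
weight (g/mol), Crippen logP, Crippen molar refractivity, rotatable-bond
count, ring count, aromatic-ring count, and topological polar surface area
(Å²). The first six follow the published notions of size, lipophilicity,
rigidity and polarizability; the exact seventh descriptor is not
enumerated in the literature we follow, and TPSA is this package's choice
(it is the most widely used polarity descriptor in bioavailability work).
The descriptor list is held in one tuple and is straightforward to swap.

## Evaluation

Top-n accuracy ranks classes by predicted probability with ties broken
toward the lower class index. Multi-label metrics accumulate bit-wise
TP/TN/FP/FN over all compound–class pairs: accuracy is the fraction of
correct bits (×100), precision and recall are the micro (cumulative-count)
ratios, Hamming loss is the mean fraction of mismatched bits per compound,
exact match the fraction of compounds with a perfect 11-bit string.
Undefined ratios (zero denominators) are reported as null/`None` flags,
never coerced to 0; per-class tables print "–" for them. Classifier pairs
are compared with McNemar's test on paired correctness indicators; the
default is the **exact** two-sided binomial form because test sets here
are a few hundred items (the chi-squared-with-correction form is available
via a flag).

## Synthetic benchmark

The planted-motif generator builds each molecule as a random alkyl/ether
scaffold chain with the characteristic functional-group motif of each
assigned class attached as a branch (carboxyl, phosphate, amide, nitrile,
thiol, pyridine, phenol, furan, sulfonate, trifluoromethyl, nitro). Labels
follow the planted motifs exactly unless label noise is switched on. The
KEGG-shaped spec (`kegg_like_spec`) emits 1200 molecules in 11 classes
with linearly skewed class sizes (largest ≈ 5× smallest), ~8%
mixed-membership compounds (matching a compound set in which 4539 of 4935
entries are single-class), and scaffold sizes of 12–45 chain atoms giving
metabolite-scale molecules of roughly 15–50 heavy atoms (mean ≈ 30).
Molecule size matters for the benchmark's discriminative structure: with
fragment-sized molecules (< 15 atoms) the flattened per-node "local graph
feature" encoding is nearly lossless and its random forest becomes
artificially competitive, whereas at metabolite scale the position
dependence and truncation of that encoding bite — as they do on real
compounds — and the expected ordering (embedding forest ≫ local-feature
forest) emerges.

What the generator does **not** emulate: real biochemical scaffolds
(sugars, steroids, nucleotides), stereochemistry, charge states, motif
co-occurrence correlations, or classes defined by global shape rather than
a single functional group. Consequently the synthetic task is much easier
than real pathway-class prediction — near-100% hybrid accuracy here
demonstrates that the pipeline is wired correctly and that the qualitative
model ordering holds, not that these accuracies transfer to curated
compound sets.

## Numerical and degenerate-input choices

- Softmax is computed with max-shift; sigmoid as ½(1 + tanh(z/2)); the
  binary cross-entropy uses `logaddexp` — no probability ever reaches an
  un-loggable 0 or 1 during training.
- Self-loops make every degree ≥ 1, so adjacency normalization needs no
  epsilon.
- Weight initialization is He-style normal scaled by √(2/fan-in), biases
  zero, from a generator seeded by the model seed.
- Single-atom molecules: Ã = [[1]], pooling is the identity; the pipeline
  treats them like any other graph.
- Classes with fewer than 3 members cannot seed all three partitions and
  fall back to unstratified assignment with a warning.
- A multi-label class with zero positive training examples gets its
  predicted probability pinned to 0, with a warning.
- Local graph features pad or truncate to `max_atoms` = 60 atoms in
  canonical order (truncation logged).
- Probe: adjusted R² is computed on the full fit for continuous features;
  binary features are scored on a seeded holdout of fraction 0.2 (the
  holdout fraction for the binary probes is our default; it is exposed as
  a flag), with non-convergent logistic fits falling back to
  majority-class accuracy under a flag.

## Problem sizes of the bundled runs

The bundled benchmark and the acceptance run use a single 80/10/10 split
of the 1200-molecule synthetic set with the default 100-epoch training —
a desk-scale analogue chosen so a complete from-scratch run finishes in a
few minutes on one CPU. The repeated-splits protocol (10 repeats with
across-repeat standard deviations) is implemented and available through
`pathgcn benchmark --repeats 10` for full-scale studies on user-supplied
data.

## Known limitations

- WL relabeling can in principle merge non-isomorphic neighborhoods;
  no molecular counterexample arises in our tests, but pathological graphs
  exist.
- Kekulization makes aromatic bond weights resonance-structure-dependent
  in rings where RDKit's kekulization is not unique; embeddings are still
  deterministic for a given SMILES string.
- The exact-duplicate-id truncation of subgraph identifiers to 128 hash
  bits makes collisions astronomically unlikely but not impossible.
- Full-scale accuracy claims require a curated compound download that
  cannot be bundled; the package reproduces protocol and qualitative
  ordering, not the published headline numbers, out of the box.
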