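# Methods

## Problem setting

A reaction is given as atom-mapped reaction SMILES,
`reactants>reagents>products`, with integer map numbers linking reactant
atoms to product atoms. The *reaction center* set TR(p) is the set of mapped
atom pairs whose bond changes between the two sides, each written as a tuple
`(atom1, atom2, new_bond)` with `new_bond` one of {none, single, double,
aromatic} (an optional triple-bond outcome can be enabled for corpora that
need it). Because the mapping is given, TR(p) is computed exactly by diffing
the mapped bond tables of reactants and product; a pair bonded on only one
side contributes a center with the product-side type (`none` when the bond
disappears, including when an atom leaves the product entirely). A labeled
reaction with an empty diff is rejected: identity "reactions" carry no
training signal and usually indicate a mapping error.

Reagents (the unmapped middle field) are merged into the reactant graph.
They participate in message passing — a nucleophilic solvent can matter —
but, having no map numbers, they are excluded from center candidacy and can
never appear in a predicted edit. This inclusion is a deliberate choice; the
alternative (dropping reagents) is a one-line change at parse time.

## Featurization

Atoms: one-hot element over a 40-element organic vocabulary plus an "other"
bucket, atomic mass scaled by 1/100 for numeric conditioning, aromaticity
flag, one-hot connectivity (all bonded neighbors including hydrogens, capped
at 5) and one-hot total valence (capped at 6) — 56 dimensions. Bonds:
one-hot type (single/double/triple/aromatic), conjugation and ring flags — 6
dimensions. Feature vectors have fixed length for every atom and bond.

## Center model (WLN with global attention)

Atom embeddings are computed by `depth` rounds (default 3) of
Weisfeiler–Lehman-style refinement: each round, atom *a* receives
`m_a = Σ_{b∈N(a)} relu(h_b W_nei + f_ab W_bond)` and updates
`h_a ← relu(h_a W_self + m_a W_msg)`, after an initial projection
`h = relu(x W_in)`. All activations are ReLU; hidden width defaults to 300.
The layer equations are this package's own design within the WLN lineage;
depth-0 is permitted as a diagnostic (the embedding is then the bare input
projection).

Reactivity often depends on atoms far from the changing bond, so a global
attention layer forms, for every atom, a context vector
`c_a = Σ_b α_ab h_b` with bilinear sigmoid weights
`α_ab = σ(h_a W_att h_b)` confined to atoms of the same reaction. Each
unordered mapped pair (i, j) is scored per bond type by

    z_ij = relu(h_i U_loc + h_j U_loc + c_i U_ctx + c_j U_ctx + f_ij U_bf + b)
    s_ij = σ(z_ij W_out + b_out)

which is symmetric in (i, j) by construction; `f_ij` is the existing-bond
feature vector (zeros for non-bonded pairs). The logistic squashing keeps
scores in (0, 1) so the cross-entropy below is well defined. The per-pair
attention weights can be dumped as TSV for visualization.

**Top-k selection.** For each pair only the argmax bond type is admitted, so
top-k selection returns k distinct atom pairs — this is what makes the
candidate count exactly 2^k − 1 downstream. Ties break by ascending
(atom1, atom2, bond-type index), so selection is deterministic.

## Mean-teacher training

The perturbation zeroes each atom's feature vector independently with
probability λ (default 0.1); topology, bond features and map numbers are
untouched. The student is trained on perturbed graphs, the teacher scores
clean graphs, and the loss is `L_CEL + ω·L_MSE` with L_CEL summed over all
(pair, bond-type) slots of the labeled batch (normalized by batch size) and
L_MSE the mean squared student–teacher score gap over labeled *and*
unlabeled graphs. Teacher scores are constants in the gradient; the teacher
is modified only by the EMA step, never by backpropagation (verified by
test).

Choices the reference protocol leaves open, fixed here as defaults:

| parameter | default | rationale |
|---|---|---|
| ω schedule | sigmoid ramp `ω_max·exp(−5(1−p)²)` over the first 10% of steps, ω_max = 1 | standard mean-teacher practice; protects the student from an untrained teacher |
| α (EMA) | 0.99 | conventional smoothing constant |
| λ | 0.1 | mild perturbation; swept values behave smoothly |
| optimizer | Adam | robust default for this loss surface |
| batch | 16 labeled + 16 unlabeled per step | balanced consistency signal |

The learning-rate schedule is `lr = lr0 · 0.95^⌊step/10000⌋` with lr0
defaulting to 0.01 and both factors configurable; the schedule is logged per
step. At desk scale we train with lr0 = 0.002 — Adam at 0.01 on this
objective collapses to a flat scorer, while 0.002 converges quickly and
stably.

**The EMA equation has two readings.** The conventional mean-teacher update
blends the previous *teacher* with the current student
(`θ_t ← α θ_t + (1−α) θ_s`); a literal reading of the update as sometimes
printed blends the two most recent *student* iterates
(`θ_t ← α θ_s^{i−1} + (1−α) θ_s^i`), which is a one-step smoother with no
long memory. Both are implemented (`ema_mode = standard | literal`),
standard is the default, and both are covered by hand-traced tests.

**Degenerate configuration.** With ω = 0, λ = 0 and an empty unlabeled pool
the loop reproduces a supervised-only run bit for bit: initialization, batch
order and perturbation draw from independent seeded streams, so disabling
one component does not shift the others.

## Candidate enumeration

All 2^k − 1 non-empty subsets of the k selected centers are applied as bond
edits (deterministic order: subset size, then lexicographic). An edit
removes the bond (`none`) or sets/creates it at the given order; hydrogen
counts of edited atoms are recomputed from default valence tables during
sanitization, and making a bond aromatic marks both atoms aromatic so
aromaticity perception can complete the ring. Candidates failing
sanitization are kept with `valid=False` and excluded from ranking by
default — the literal 31-candidate set is preserved, nothing is silently
dropped. Charge changes and stereochemistry are out of scope.

The true product is located by canonical-structure comparison with atom maps
stripped. Fragments consisting entirely of unmapped atoms (merged-in
reagents) are removed from the candidate's comparison form, since unmapped
species cannot appear in a product field; mapped spectators and leaving
groups are retained. A `fragments` comparison mode accepts corpora whose
product field omits leaving groups.

## Ranker (WLDN)

Each candidate is embedded by a WLN tower of the same layer form (by default
with its own weights — weight sharing with the center model is possible but
off, as the two tasks differ). For every atom matched through the map, the
difference vector `Δ_a = h_a^cand − h_a^reac` is computed; atoms within one
bond of any edited pair (radius configurable) are pooled by summation and a
two-layer head maps the pooled vector to the scalar s(p_i). A candidate
identical to the reactants therefore scores exactly the head's zero-input
output, and atoms far from every edit contribute nothing — the "difference"
in difference network. Training minimizes `−log softmax` of the true
product's score, computed with max subtraction; records whose true product
does not survive into the valid candidate set are excluded from the loss,
counted, and scored as failures in evaluation. Ranker updates are taken per
reaction, so gradients are clipped to a global norm of 5 — without clipping
an occasional spiky example can knock a converged model off its solution.

## Synthetic corpus generator

The generator emulates the input format and center-count structure of patent
reaction corpora without any external data. Six grammar rules span 1–5
edits and the full bond vocabulary: alkene reduction (1), halide amination
(2), HBr elimination (2), substitution+reduction (3),
substitution+elimination (4), and 2,5-dihydrofuran → furan aromatization (5
aromatic edits). The default center-count distribution (0.35, 0.35, 0.12,
0.12, 0.06) concentrates mass at 1–2 edits, as real corpora do. Scaffolds
are random 6–16-heavy-atom carbon trees with ether/alcohol oxygens
sprinkled on uninvolved positions; substitution uses Cl and elimination Br
so the reactant determines which elementary step applies at which site, and
sprinkled heteroatoms are oxygen only so the nucleophilic amine nitrogen is
unambiguous — without these choices the task would be unidentifiable from
the reactant side and no model could reach high coverage. A spectator
reagent (water, methanol, ethanol or acetone) is added unmapped with
probability 0.2.

Each sample is built by applying the rule's edits with the package's own
edit machinery and then re-parsed from its serialized line, so every emitted
record has, by construction *and* by assertion, TR(p) equal to the
generating edits under bond-diff extraction. Unlabeled pools are the same
reactions with products stripped; the hidden truth goes to a sidecar TSV,
and the labeled and unlabeled pools are checked to share no canonical
reaction.

What the generator does **not** emulate: reagent- and condition-dependent
selectivity, competing reaction pathways, stereochemistry, charged species,
and the long-tailed template diversity of real patent data. Passing tests on
these corpora demonstrates that the machinery — extraction, training
dynamics, enumeration, ranking — is correct and that the semi-supervised
signal behaves as designed; it does not certify accuracy on real corpora.

## Numerical core

The models run on a small reverse-mode automatic-differentiation engine over
float64 numpy arrays (dense linear algebra, elementwise nonlinearities,
gather/segment-sum for message passing), with Adam. Gradients are verified
against central finite differences. Determinism: all randomness flows
through seeded `numpy` generators split into independent streams
(initialization, batch order, perturbation, unlabeled sampling), so a run is
exactly reproducible from its config and seed.

## Problem sizes used in tests and the acceptance script

Training experiments use 800 labeled + 2,000 unlabeled reactions with a
200-reaction held-out set, hidden width 64, depth 3, 700 steps (500 for the
20%-labels comparison), batch 16+16, lr0 = 0.002 — a configuration at which
both arms of every comparison have converged on this task; the ranker trains
on 400 reactions for 5 epochs. Larger widths and longer schedules change
nothing qualitatively here.

## Known limitations

* Center candidacy is all-pairs over mapped atoms (O(n²) per reaction);
  fine at small-molecule scale, wasteful for very large reactants.
* Hydrogen rebalancing covers neutral closed-shell chemistry only; edits
  implying charge or radical changes are flagged invalid rather than
  modeled.
* The "improved" difference-pooling neighborhood (radius 1) is a declared
  design choice; widening it is a config flag, not a researched optimum.
* No 3-D or stereochemical information is used anywhere.
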