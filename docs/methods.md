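# Methods

## Model

A protein–ligand complex is reduced to its binding area: every ligand
atom plus every protein atom within 4.0 Å (inclusive) of some ligand
atom. Atoms are nodes; the only edges in the default scheme are
inter-molecular contacts, i.e. protein-atom–ligand-atom pairs whose
distance falls in one of K ordered, disjoint, half-open ranges (lo, hi].
The defaults are (2, 3] and (3, 4] Å: pairs closer than ~2 Å are almost
always covalent and are excluded, while 4 Å bounds the binding area
itself. The two bins loosely separate strong short contacts (e.g.
short hydrogen bonds) from weaker long ones, and keeping them distinct is
the point of the tensor representation — the single-range ablation
(`AGIMA_SAM`, one slice on (2, 4]) and the intra-molecular-inclusive
schemes (`GRAPHBAR_2AM`, `GRAPHBAR_3AM`) exist to test exactly that.

Each slice A_k is normalized with self-loops, N_k = D̃^(−1/2)(A_k +
I)D̃^(−1/2), and convolved **once**: F_k = σ(N_k F W_k), no bias. One hop
confines the receptive field to direct inter-molecular neighborhoods;
stacking hops would mix in second-order paths that run through the same
molecule, which the representation deliberately avoids. Sum pooling
h_k = Σ_i f_ik makes the graph readout permutation-invariant, and the
whole pipeline depends on coordinates only through the distance matrix,
so scores are invariant under rigid motion by construction. The
concatenated h = h₁‖…‖h_K feeds a dense head: two hidden layers (width
128 by default) with activation and train-time inverted dropout, then a
linear scalar output. The h_k returned by `forward` are taken right
before the dense head (the last-but-two layer) and are the quantities
the embedding-PCA interpretation examines.

The network is small, so it is implemented directly on NumPy with
analytic gradients and Adam; a test verifies backprop against central
differences to 1e-5. Training minimizes MSE over mini-batches, monitors
validation RMSE each epoch, and returns the best-epoch parameters.
Training is bit-deterministic for a fixed config seed (one generator
drives initialization, shuffling and dropout).

## Node features

`F18`: 9-way one-hot atom type (B, C, N, O, P, S, Se, halogen, metal),
hybridization code (1/2/3 for sp/sp²/sp³, 0 otherwise, a single integer
column), heavy- and hetero-neighbor counts, five binary pharmacophoric
flags (hydrophobic, aromatic, H-bond acceptor, H-bond donor, ring
membership), Gasteiger partial charge. `F13` drops the five flags.
`F8`: the flags plus metallicity, the positive and negative parts of the
partial charge, and the excluded volume (4/3)πr³ from Bondi-type van der
Waals radii. `F21` is the non-redundant union: `F18` plus those three
`F8`-only columns — F13 ⊂ F18, and the remaining F8 members duplicate
F18's pharmacophoric/metal columns, which is how the width 21 arises.

Chemistry perception uses RDKit: Gasteiger–Marsili charges computed on
the fly for both molecules (input MOL2 charges ignored by default;
undefined charges fall back to 0 with a warning), aromaticity and ring
membership from sanitization, protein connectivity from proximity
bonding. Pharmacophore typing is rule-based and documented rather than
SMARTS-driven: donors/acceptors are N/O with/without attached hydrogens
(acceptors excluding positively charged centers), hydrophobic atoms are
carbons with no N/O neighbor plus thioether sulfur. Hydrogens are
stripped by default, so the graphs are heavy-atom graphs; the 4 Å
neighbor search therefore also runs on heavy atoms.

## Evaluation and screening

Scoring is summarized by Pearson correlation and RMSE. Leakage control
follows an OR rule: an evaluation complex survives only if, against every
training complex, the protein-sequence similarity stays below 0.3 **or**
the ligand similarity stays below 0.7 (both strict; equality removes).
The similarity functions are injected; defaults are global-alignment
BLOSUM62 sequence identity (Biopython) and Tanimoto over hashed atom-pair
fingerprints (RDKit), both in [0, 1].

Enrichment factor: EF_X = (actives found in the top X% / all actives) /
(X/100), with n_top = round(N·X/100) floored at 1 and score ties broken
by stable input order. The alternative "precision" reading
(hits/n_top)/(X/100) is available behind a flag; the recall reading is
the default because its ceiling is the library's total/active ratio,
which is how reported EF magnitudes behave under heavy imbalance. The
subsampling protocol keeps all actives, draws n_actives·r decoys without
replacement per repeat (10 repeats by default), and averages EF per
(X, r) cell; r_DTA_max of a full library is the nearest integer of
decoys/actives.

## Synthetic fixtures

The generator emulates the one geometric property the method cares
about: a controlled number of inter-molecular contacts per distance
range. Ligand atoms (carbon) form a compact cluster with ≥2.2 Å
separation; each requested contact places a protein atom (nitrogen) at a
sampled distance inside its range from one randomly chosen ligand atom
while staying >4 Å from every other ligand atom, so each protein atom
realizes exactly one contact; remaining protein atoms are placed beyond
the cutoff. Several protein atoms may share a ligand atom, so node
degrees vary — without that variation, symmetric isolated pairs make the
pooled linear response of the normalized convolution invariant to the
contact count, and the task would be artificially hard. Every generated
complex is verified against the graph builder before being returned.

Labeled tasks set label = 1.0·c₁ + 0.2·c₂ + N(0, 0.1) by default (counts
uniform on 0..8 per range, 6 ligand atoms, 3 distant protein atoms);
sum pooling over one-hop convolutions can represent count-linear
functions, so weight recovery is a fair end-to-end check. The
charge-modulated variant holds the counts fixed and lets each contact
contribute its ligand atom's charge (uniform on 0.5–1.5), making the
charge column the only label-relevant feature for the importance
experiment. What these fixtures do **not** emulate: real fold geometry,
covalent structure, charge distributions, or label noise structure — a
pass on them validates the learning machinery and the graph semantics,
not chemical accuracy on real complexes, which would require training on
curated affinity data.

## Experiment sizing and numerical choices

The validation experiments (`agima.experiments`, driven by
`scripts/acceptance.py` and the acceptance tests) use 400-complex tasks,
conv_dim 32, dense widths (64, 64), dropout 0.1, 60–80 epochs, Adam at
3e-3 — sized so a full run takes seconds per training on one CPU while
leaving ample capacity for the count-linear targets. Production defaults
(conv_dim 128, dense 128/128, dropout 0.2, lr 1e-3) remain the
`ModelConfig` defaults. Other numerical conventions: distance intervals
are half-open (lo, hi] everywhere, including the GraphBAR-style (0, 2]
bin; the binding-area boundary d ≤ 4.0 Å is inclusive; raw adjacency
keeps a zero diagonal (self-loops appear only in the normalized form, so
slice disjointness stays checkable); degrees after self-loops are ≥1, so
normalization never divides by zero; PCA signs are fixed by making the
largest-magnitude loading positive; ΔPC is reported signed, and can be
negative when masking helps.

## Known limitations

No protonation, structure repair or docking; mmCIF unsupported. Charges
are Gasteiger only. The alternative ionizable-group reading of the F8
charge features is not implemented (the sign-split reading matches their
float type). Real-data headline numbers require the external affinity
benchmarks and a docking engine and are out of scope here; the code path
(index files of PDB/SDF-MOL2 pairs with labels) supports them unchanged.
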