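# agima

Scoring protein–ligand binding structures by learning **a**tomic **g**raphs
with **i**nter-**m**olecular **a**djacency.

## The problem

Predicting the binding strength (−log K_d/i) of a protein–ligand complex
from its 3D structure is the *scoring* step of structure-based drug
discovery. Binding strength is dominated by short-range, non-covalent
contacts between the two molecules — hydrogen bonds, hydrophobic packing,
π-stacking. `agima` represents the binding area of a complex as an atomic
graph whose **only** edges are inter-molecular contacts, binned by distance
range, and learns that graph with a deliberately shallow network.

For a complex with binding-site atoms V = {nd₁, …, ndₙ} (all ligand atoms
plus protein atoms within 4 Å of any ligand atom), the adjacency tensor
**A** ∈ {0,1}ⁿˣⁿˣᴷ has slices

    A_ijk = 1  iff  (nd_i, nd_j) is a protein–ligand pair and d_ij ∈ δ_k

with default ranges δ₁ = (2 Å, 3 Å], δ₂ = (3 Å, 4 Å]. Each slice is
convolved once:

    F_k = σ( D̃_k^(−1/2) (A_::k + I) D̃_k^(−1/2) F W_k )

where F ∈ ℝⁿˣᵐ is the node-feature matrix, then sum-pooled into per-slice
embeddings h_k = Σᵢ f_ik, concatenated (h = h₁ ‖ h₂) and mapped to the
score by a small dense head with dropout. A single hop keeps the model
focused on direct inter-molecular neighborhoods; intra-molecular edges
never enter the default scheme.

Four node-feature sets are built in (`F18`, `F8`, `F13`, `F21` — atom-type
one-hots, hybridization, neighbor counts, pharmacophoric flags, Gasteiger
charges, excluded volume), along with ablation adjacency schemes: a merged
single range (`AGIMA_SAM`, (2, 4] Å) and GraphBAR-style schemes that also
admit intra-molecular contacts (`GRAPHBAR_2AM`/`GRAPHBAR_3AM`).

Also included: PC/RMSE evaluation with a sequence/ligand-similarity
leakage filter, the decoy-ratio-swept enrichment-factor (EF) screening
protocol, and two post-hoc interpretation tools (masked-feature importance
and PCA of the per-slice embeddings).

## Worked example

Labels of a 400-complex synthetic benchmark are linear in the per-range
contact counts — 1.0 per (2, 3] Å contact, 0.2 per (3, 4] Å contact, plus
N(0, 0.1) noise — so a model that can separate the two ranges has a real
advantage over one that sees only their union:

```bash
$ python examples/train_and_recover_weights.py
AGIMA_2    held-out PC = 0.9987
AGIMA_SAM  held-out PC = 0.8422
```

The two-range model recovers the planted structure almost to the noise
ceiling; the merged-range model is capped near the correlation achievable
from c₁+c₂ alone. Interpretation of a model trained on a charge-modulated
task (`examples/interpret_trained_model.py`):

```
baseline: PC = 0.968, RMSE = 0.220
top 3 features by PC drop when masked:
  partial_charge       dPC = +0.934 dRMSE = +2.023
  atom_type_N          dPC = +0.139 dRMSE = +0.671
  hydrophobic          dPC = +0.102 dRMSE = +0.290
```

Masking the feature that actually generates the labels collapses the
correlation; everything else is a perturbation. The other example scripts
(`examples/build_contact_graph.py`, `examples/screening_enrichment.py`)
walk through graph construction and the EF sweep the same way.

A thin CLI mirrors the library (`agima simulate | featurize | train |
score | screen | explain | config-dump`); every run writes a YAML manifest
with the resolved configuration, seed and library versions.

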