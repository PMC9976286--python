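# Methods

## Scope and conventions

Coordinates are Ångström throughout, atom indices 0-based, RDKit molecules
the in-memory chemistry container. The package reproduces the computational
stages of a pharmacophore screening campaign; everything wet-lab (enzymatic
assays, IC50 determination, inhibition-mode experiments) and everything tied
to licensed data (the commercial screening library, the original models' 3D
coordinates, which were never published machine-readably) is out of scope.
Published summary numbers — confusion-count columns, per-model hit
accounting — are treated as *inputs* where a stage needs them.

## Feature perception

Perception is a deterministic rule table, not a pKa calculation. Ionization
follows fixed physiological-pH rules: carboxylic acids (and phosphonates,
sulfonates, tetrazoles, acyl sulfonamides) count as negatively ionizable
whether drawn neutral or charged; aliphatic amines, amidines and guanidines
as positively ionizable. NI features sit at the centroid of the acidic
oxygens (tetrazole: ring centroid), PI on the basic centre, HBD/HBA on the
donor/acceptor heavy atom with an approximate H/lone-pair direction,
aromatic features at ring centroids with the ring normal as direction.
Hydrophobic features are centroids of connected clusters (≥ 3 atoms) of
carbons with no heteroatom neighbour; clusters of ≥ 6 atoms are split per
aromatic ring and residual chain fragment so each lipophilic moiety gets its
own feature. The default tolerance is 1.5 Å for every kind, overridable per
feature. The exact pattern definitions of commercial tools are proprietary;
this table is a documented approximation and nothing downstream depends on
perceiving any specific literature ligand exactly.

## Structure-based models

A perceived ligand feature becomes a model feature iff a complementary
protein partner satisfies the geometry criteria (defaults: donor–acceptor
heavy-atom distance 2.5–3.8 Å with a ≥ 120° D–H···A angle applied only when
an explicit hydrogen is present; charged-group centroid distance ≤ 5.5 Å;
cluster-centroid to apolar side-chain atom 1.0–5.0 Å; ring-centroid to
ring-centroid ≤ 5.0 Å; ligand atom to metal ≤ 2.8 Å). These are consensus
crystallographic contact criteria; the vendor tool's internal thresholds are
unpublished. Protein partners are recognised by residue/atom-name
vocabulary (arginine/lysine/histidine cations, aspartate/glutamate
carboxylates, backbone and side-chain donors/acceptors, aromatic side-chain
rings, whitelisted metals such as the catalytic zinc). Exclusion volumes of
radius 1.0 Å are placed on every protein heavy atom within a 5 Å shell of
the ligand, deduplicated at 0.5 Å.

## Shared-feature (ligand-based) models

The reference molecule's first conformer fixes the frame. For every other
training compound and conformer, the largest kind-compatible correspondence
to the reference features is found by clique search (pair pre-filter: model
and ligand inter-feature distances agree within summed tolerances), the
correspondence is superposed rigidly (Kabsch), and reference features whose
partner lands within the summed tolerances count as matched; ties between
equally large correspondences break on lower RMSD. Only reference features
matched in *every* training compound survive. Consequence: the output is
always a subset of the reference's perceived features, and identical
training molecules return the full set.

## Matching and the fit score

Matching is rigid per conformer; flexibility enters only through the
conformer ensemble. Candidate correspondences are cliques in the graph whose
nodes are kind-compatible (model, ligand) feature pairs and whose edges
require inter-feature distance agreement within summed tolerances — a
necessary condition for any rigid pose that places both features inside
their spheres, which keeps the search tractable without losing solutions.
Every model feature is mandatory (shared-feature models contain only
universally present features, so optional-feature semantics would add
nothing here); the tolerance check after superposition is strict
(d ≤ tol), an Xvol violation is a ligand heavy atom strictly inside the
sphere (hydrogens ignored), and the accepted pose with the highest
fit = Σ(1 − d/tol) wins, ties broken by the lexicographically smallest
correspondence. The score is documented and monotone in geometric quality;
it is not the (unpublished) score of any commercial tool, so only
rank-order-free decisions depend on it. Degenerate superpositions (1 or 2
matched features) use the same SVD solution, which is a valid least-squares
minimiser; the brute-force oracle in the tests uses the identical primitive,
so the comparison isolates the search strategy.

## Validation metrics

sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), YoA = TP/(TP+FP)
(defined 0 for an empty hit list), accuracy = (TP+TN)/N,
EF = YoA·N/A with N = A + D, EF_max = N/A, decoy hit rate = 100·FP/D.
Display rounding is half-up to two decimals (so 0.625 prints as 0.63 and
336.125 as 336.13), full precision is kept internally; the two-decimal
agreement of all 8 × 8 published derived values with these definitions is
what pins them down, since the source renders the equations as images. ROC
AUC uses the rank-sum (Mann–Whitney) formulation with midranks; molecules a
model does not retrieve enter at score 0, below every hit — the original
tool's ranking of non-hits is unknown, which is why the published AUC column
is not reproduced. Only actives of a model's own binding-mode subset enter
its confusion counts; decoys always all count.

## Decoy selection

Known actives are removed from the pool by canonical-SMILES identity. Pool
compounds whose property vector (molecular weight, heavy atoms, rings,
NI/PI group counts, logP bin) lies inside the actives' per-property
[min − 10 %, max + 10 %] envelope survive, are leader-clustered by Morgan
fingerprint Tanimoto at 0.6 in seeded order, and are drawn one per cluster
(then round-robin within clusters) until the requested count. The envelope
width, the clustering cutoff and the property list are documented choices;
the original selection protocol names only the intent (similar properties,
structural diversity).

## Triage

The substrate-moiety filter ships an editable SMARTS for the
α-amino/N-acyl-glutamate motif. The keep-all rule selects every hit of any
model with fewer than 10 total hits. The published visual similarity
assessment is replaced by automated single-linkage grouping at ECFP4
Tanimoto ≥ 0.8 with the lowest identifier as representative — reproducible,
but it cannot recreate manual choices among similar compounds, so only the
rule-based part of the published 82 → 50 funnel is automated.

## Synthetic data: what it emulates and what it does not

The generators produce provable ground truth rather than realistic
chemistry. Planted molecules are assembled from a fragment vocabulary
(carboxylate, amine, hydroxyl, ether, thiol, benzene/pyrimidine, alkyl
clusters) wired by ether-type linkers with deterministic coordinates — the
linker oxygens deliberately break apolar clusters so no stray hydrophobic
feature appears, at the price of extra acceptor candidates, which are
harmless because extra ligand features never hurt a match. Actives are rigid
copies of the template under a random rigid motion plus optional per-atom
Gaussian jitter (`noise_sd`, modelling perception/experimental scatter; no
chemistry-aware noise). Decoys alter the scaffold so matching is impossible
by construction: `displace_one_feature` moves a uniquely realised
NI/PI/AI/HC/MB fragment so far that its distance to every remaining feature
exceeds the largest model inter-feature distance plus summed tolerances
(violating the distance-compatibility condition any rigid pose implies, for
every correspondence — checked numerically at build time);
`wrong_kind` mutates the fragment's chemistry so the kind disappears from
the molecule entirely; `xvol_clash` bonds a carbon exactly at an exclusion
volume centre, so such decoys match precisely when the Xvol check is off
(guaranteed at zero noise, where the matched pose is exact). Toy complexes
place one ligand fragment per requested interaction plus a minimal protein
partner at mid-range distances (e.g. salt bridge at 4.5–5.0 Å of a 5.5 Å
cutoff, H-bond at 3.1 Å of a 2.5–3.8 Å window), with spacings chosen so no
unintended contact falls inside any criterion; structure-based perception
on them recovers exactly the requested kinds. Passing these tests shows the
machinery is correct under known geometry; it does not show that the
perception table or the contact criteria match any particular experimental
complex.

## Problem sizes and numerical choices

The test and analysis screens use libraries of ~110 single-conformer
molecules of ~21 atoms, 20 seeds per noise level in the jitter sweep, 200
random instances for the matcher/oracle comparison and 50 random
model/library pairs for the monotonicity properties — sizes at which every
result is exactly checkable while the whole suite runs in well under a
minute. Floating-point guards of 1e-9 are applied on tolerance and Xvol
boundaries; rigid-motion invariance holds to 1e-6 Å. Conformer generation
is ETKDG with a fixed seed, duplicates pruned at 0.5 Å heavy-atom RMSD
(the generator presets cap ensembles at 25 conformers in "fast" and 500 in
"best" mode, following the original screening setup).

## Known limitations

Feature directions are perceived but not used as matching constraints (the
tolerance spheres carry the geometry); protonation is rule-based; tautomers
are not enumerated; matching has no partial/optional-feature mode; the
enrichment AUC depends on the documented fit score and is therefore not
comparable to tool-specific published AUCs; and the synthetic libraries do
not emulate medicinal-chemistry diversity, so enrichment numbers on them
characterise correctness, not prospective performance.
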