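# Methods

`depthsite` predicts protein–ligand binding residues from structure and
sequence, and reranks externally detected pockets with those predictions.
This note records the model, its assumptions, the parameters that matter,
and the design decisions taken where more than one reasonable choice existed.

## Half-space depth on atom clouds

The geometric core is the half-space (Tukey) depth of a point `x` with
respect to the finite cloud of protein heavy atoms. We use the
open-half-space counting convention:

    HD(x) = min over hyperplanes h through x of #{atoms strictly on one side of h}

Under this convention a point on the convex hull boundary has depth exactly
0 (a supporting hyperplane leaves an empty strict side), and the centre of a
symmetric cloud attains the maximum `floor(n/2)`. Points lining a surface
pocket have small positive depth — they are "indented" relative to the hull
without being buried — which is exactly the signal used to separate concave
from convex surface.

Two evaluators are provided:

* `exact_depth` enumerates candidate hyperplane normals. The direction count
  is piecewise constant on the sphere of directions, with cells bounded by
  the great circles orthogonal to each atom offset; its minimum is attained
  at arrangement vertices, i.e. directions orthogonal to two offsets
  (cross products) in 3-D, perpendiculars in 2-D, the two directions in 1-D.
  Coordinate axes and single-offset perpendiculars are added as candidates
  so collinear/coplanar (degenerate) clouds are handled. The enumeration is
  cubic in `n` and guarded to `n <= 500`.
* `approx_depth` minimises the strict-side count over `n_dirs` seeded random
  unit directions, in memory-bounded chunks. Sampling directions can only
  miss the minimiser, so the approximation never under-reports the true
  depth; on clouds in general position it converges to the exact value as
  `n_dirs` grows (symmetric clouds, e.g. perfect lattices, are the known
  exception: the minimising direction there can be an isolated arrangement
  vertex that random directions hit with probability zero).

Per-residue depth is the depth of the residue's Cα (heavy-atom centroid when
Cα is absent) within the pooled heavy-atom cloud of all protein chains.
Protein-scale default is the sampled evaluator with `n_dirs = 1000`,
`seed = 0`; exact enumeration is practical for the small structures used in
testing. Points within `1e-9 · max|offset|` of a candidate hyperplane count
for neither side, which realises strict inequalities at machine precision.

## Surface, patches, and the three-way sample labeling

Residues are the unit of prediction. A residue is *surface* when its
relative solvent accessibility (RSA) is strictly above 10%. RSA is the
Shrake–Rupley accessible surface area of the residue's heavy atoms (probe
1.4 Å, 960 sphere points, ligand stripped first so labeling never peeks at
the answer), divided by the residue type's theoretical maximum ASA
(Tien et al. 2013 table, overridable), clipped to [0, 1]. A *patch* is a
surface residue plus every surface residue within 10 Å of it; residue–residue
distance is the minimum heavy-atom distance (a Cα mode is available),
matching the atom-level phrasing of the ligand-contact rule.

Labels are assigned in two stages, every comparison strict:

1. *Candidates.* A surface residue whose nearest heavy atom lies < 7 Å from
   any ligand atom (hydrogens included on the ligand side) is a positive
   candidate; otherwise a negative candidate. With several ligands, contact
   with any one suffices.
2. *Confirmation.* A positive candidate becomes POSITIVE iff strictly more
   than 30% of its patch neighbours are positive candidates (isolated
   contacts are noise). A negative candidate is discarded when its own depth
   exceeds 5; otherwise it becomes NEGATIVE iff its patch has strictly more
   than 5 neighbours with mean depth below 8. Everything else is NP&NN
   ("not positive and not negative").

The deliberately strict negative definition keeps only residues on
unambiguous convex surface — residues the depth criterion says cannot sit in
a pocket — which both purifies the negative class and roughly balances the
two classes without reweighting. NP&NN samples are excluded from training by
default but still receive predictions; a config flag can fold the
depth-rejected candidates into the negative class for ablation (the flag
never relabels ligand-contacting residues, so "no NEGATIVE residue touches
the ligand" holds under either setting).

## Feature vector (330 dimensions)

Each sample is the concatenation of three blocks (layout frozen; a golden
fixture vector in the test suite guards the order):

* **Global, 35**: chain length, distance to the N-terminus and distance to
  the C-terminus, each one-hot over the intervals [0, 60), [60, 120),
  [120, 240), ≥ 240 (12); whole-protein amino-acid composition (20);
  whole-protein helix/strand/coil content (3).
* **Window, 270**: a sliding window of length 9 centred on the residue,
  30 features per position — 20 PSSM log-odds, the conservation score,
  a 3-bit secondary-structure one-hot, positive charge, negative charge,
  isoelectric point, polarity, hydrophobicity, and an out-of-chain
  indicator. Positions off either chain end contribute 29 zeros and
  indicator 1.
* **Patch, 25**: hydrogen-bond tendency (min, max, mean over patch members,
  plus the centre's own value: 4); min/max/mean of positive charge, negative
  charge, isoelectric point, polarity, hydrophobicity and conservation (18);
  patch secondary-structure content (3). Statistics include the centre.

Conservation is `1 − H/log2(20)` where `H` is the Shannon entropy of the
renormalised 20 observed-frequency entries of the profile column, so 1 means
fully conserved; an `entropy` orientation switch is provided since either
convention appears in the literature. Window PSSM features use the log-odds
columns of the PSI-BLAST ASCII profile; min-max normalisation downstream
makes the integer scale immaterial.

Property scales are bundled config tables, overridable per entry: charges as
binary indicators (R/K/H positive, D/E negative), Zimmerman isoelectric
points, Grantham polarity, Kyte–Doolittle hydropathy, and a hydrogen-bond
tendency column reflecting relative side-chain donor/acceptor propensity.
These are standard choices, not a claim about which scales any particular
prior study used; swapping tables changes feature values but not the layout.
Unknown residue types (X) take zero for every property. An optional flag
appends the residue's integer depth as a 331st feature for ablation; it is
off by default.

## Classifier and evaluation

Features are min-max normalised to [0, 1] per column on the training split;
constant columns map to 0 and test values are clipped into the training
range. The classifier is an RBF-kernel SVM with Platt-scaled probability
output (scikit-learn `SVC(probability=True)`); the decision threshold for
confusion-matrix metrics is 0.5. `(C, γ)` come from an exhaustive grid
search — default log₂ grid C ∈ 2^[−5,15], γ ∈ 2^[−15,3], step 2 — scored by
pooled out-of-fold Matthews correlation on a seeded random subset of
training proteins (30 by default, fewer when fewer exist).

Cross-validation always partitions *proteins*, never residues of one protein
across folds: residues of one structure are highly correlated, and splitting
them would leak identity. The fold builder shuffles protein ids with the
given seed and asserts that the pooled out-of-fold predictions cover every
sample exactly once. Reported metrics: accuracy, precision, sensitivity,
specificity, MCC (zero-denominator cases reported as 0 and flagged), ROC by
threshold sweep and AUC by the trapezoid rule.

## Pocket reranking

Geometry-based detectors emit ranked pockets; the classifier supplies an
orthogonal signal. Each pocket is scored by the number of its residues with
predicted probability ≥ 0.5, and pockets are reordered by that count
(descending, ties keeping detector order). For detectors that report only a
geometric centre, the pocket's residues are the surface residues with any
heavy atom within a configurable radius of the centre (default 8 Å, the
same value as the functional cutoff); sweeping that radius yields the nested
residue sets used for detector ROC curves. A pocket is *functional* when its
centre lies strictly within 8 Å of any ligand atom, and the top-n success
rate over a protein set is the fraction of proteins with a functional pocket
among the first n — by construction invariant, at n = 3, under any rerank of
the same three pockets. Unranked detector tables are pre-ranked by volume
descending before the top 3 are taken; the centre of a residue-list pocket
is the centroid of its residues' heavy atoms.

## Synthetic benchmark

The fixture generator emulates everything the pipeline consumes without any
downloads: PDB complexes, DSSP-like secondary-structure files, PSI-BLAST
ASCII profiles, pocket tables and truth labels, all byte-reproducible from a
seed. A toy protein is `n` residues (default 64) on a sphere whose radius
targets a 5.5 Å nearest-neighbour spacing, with a hemispherical dimple: the
cap of directions nearest +z is pulled inward by up to 45% of the radius
with a smooth falloff. Each residue carries a Cα plus three pseudo-backbone
heavy atoms (N, C, O with jitter) so atom-level distance rules and
Shrake–Rupley areas behave sensibly; sequence order is shuffled relative to
geometry so chain position carries no pocket information. A four-atom
ligand sits at the centroid of the meaningfully indented residues, making
dimple-bottom residues ligand contacts; truth labels mark binders (atoms
< 7 Å from the ligand) and pocket lining (indented by more than a quarter of
the falloff, or in ligand contact). Profile columns at binder positions mix
a point mass on the residue's own amino acid into Dirichlet noise with
weight `s/(1+s)` for signal strength `s` (default 4), so conservation and
log-odds carry label signal at high `s` and nothing is learnable at `s = 0`.

What the fixtures deliberately do not model: real backbone connectivity and
dihedral statistics, side chains, physical packing densities, sequence
redundancy, and any realistic relation between structure and evolutionary
profile. Green tests therefore demonstrate that the implementation is
faithful to its rules and that the pipeline recovers plantable signal — not
field performance on crystallographic data, which requires a curated complex
set and real PSI-BLAST profiles.

The default benchmark (12 proteins × 64 residues) keeps exact depth
enumeration and a full grid-searched 5-fold CV inside a couple of minutes on
one core; these sizes are the package's study conditions for the acceptance
script, which reports cross-validated AUC ≈ 1 at signal 4, AUC ≈ 0.5 at
signal 0, and top-1 success rising from 0 to 1 when the planted rank-3
functional pocket is reranked by out-of-fold predictions.

## Numerical and degenerate-input conventions

* Strict inequalities exactly as the selection rules state them; depth is an
  integer, mean neighbour depth a real compared against 8.
* First NMR model only; one altloc conformer kept; waters never ligands;
  non-canonical residues map to X with zeroed properties and a logged
  warning; unknown residue types use the glycine maximum ASA.
* RSA is computed on the apo protein (ligand stripped). Finite sphere-point
  Shrake–Rupley is exactly translation invariant but only ~1–2% rotation
  invariant at 960 points; tests assert accordingly.
* Patches with no neighbours give singleton statistics (min = max = mean =
  centre value); a positive candidate with zero neighbours cannot be
  confirmed and falls to NP&NN.
* The DSSP fallback assigner uses backbone dihedrals (helix for φ ∈
  [−100°, −30°], ψ ∈ [−80°, −5°]; strand for φ ≤ −45° with extended ψ;
  else coil) and labels residues with incomplete backbones coil.
* Model archives store the fitted SVM, the normaliser and a feature-layout
  fingerprint; loading verifies the format tag and reproduces predictions
  bit-for-bit.

## Known limitations

* Exact depth enumeration is O(n³) and unusable beyond a few hundred points;
  the sampled evaluator's error is one-sided (over-estimation) and worst for
  deeply buried queries.
* Property scales and the hydrogen-bond tendency table are package defaults;
  studies tied to specific AAindex accessions should override them.
* The predictor itself does not detect pockets; reranking requires an
  external detector's output.
* Multi-chain support pools all protein chains for depth, RSA and patches,
  and treats sequence features per chain; inter-chain interface effects are
  otherwise not modelled.
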