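# depthsite

Protein–ligand binding-site prediction on protein surfaces, built around a
statistical-depth definition of the negative class.

Knowing *where* a small molecule binds a protein is central to functional
annotation and structure-based drug discovery. Positive examples are easy —
residues in contact with a crystallised ligand — but "this residue does not
bind" is rarely knowable, which makes training data for residue classifiers
noisy. `depthsite` addresses that with the half-space (Tukey) depth of each
residue within the protein's heavy-atom cloud,

    HD(x) = min over hyperplanes h through x of #{atoms strictly on one side of h},

under an open-half-space convention where convex-hull points have depth 0.
Surface residues on strictly convex surface (low depth, shallow
neighbourhood) are geometrically unable to sit in a pocket and become
high-confidence negatives; ligand-contacting residues whose neighbourhood
agrees become positives; everything ambiguous is held out of training.
An RBF-kernel SVM over a 330-dimensional feature vector (35 global +
270 sliding-window + 25 surface-patch features from PSSM profiles,
conservation entropy, secondary structure and physicochemical scales) then
predicts a per-residue binding probability, and a post-processor reranks
pockets from external geometric detectors by how many predicted binders
each contains.

The package is a library plus a `depthsite` command line: PDB in, per-residue
depth/label/probability tables and reranked pocket lists out. A deterministic
synthetic-fixture generator (spherical toy proteins with a planted pocket,
ligand and profile signal) makes the whole pipeline buildable and testable
offline.

## Worked example

Generate three toy complexes, inspect depth and labels, train, and predict
on a held-out structure:

```console
$ depthsite simulate --out-dir sim --n-proteins 3 --seed 5
$ depthsite depth sim/prot00.pdb --out depth.tsv && head -3 depth.tsv
chain	seq_index	aa	depth
A	1	K	6
A	2	Q	1

$ depthsite label sim/prot00.pdb --out labels.tsv && head -3 labels.tsv
chain	seq_index	aa	rsa	depth	n_neighbors	candidate	label
A	1	K	0.2082	6	18	POS_CAND	POSITIVE
A	2	Q	0.3173	1	14	NEG_CAND	NEGATIVE
```

Residue A:1 sits in the planted pocket: depth 6 (indented relative to the
convex hull), within 7 Å of the ligand, and confirmed POSITIVE by its
neighbourhood. A:2 is on convex shell — depth 1, no ligand contact, and its
patch passes the depth screen, so it is a confident NEGATIVE.

```console
$ depthsite train sim/manifest.json --out model.joblib
trained on 192 samples (33 positive); C=8.0 gamma=0.03125

$ depthsite predict sim/prot01.pdb --model model.joblib \
      --pssm A=sim/prot01_A.pssm --ss sim/prot01.ss --out pred.tsv
$ head -3 pred.tsv
structure_id	chain	seq_index	probability	predicted
prot01	A	1	0.0023	0
prot01	A	2	0.0023	0

$ depthsite cv sim/manifest.json --k 3 --out cv.json && cat cv.json
{
  "accuracy": 1.0,
  "precision": 1.0,
  "sensitivity": 1.0,
  "specificity": 1.0,
  "mcc": 1.0,
  "auc": 1.0,
  "n_positive": 33,
  "n_negative": 159
}
```

The toy profiles carry strong planted signal, so protein-grouped 3-fold
cross-validation separates the classes perfectly; with
`--signal-strength 0` fixtures the same pipeline scores AUC ≈ 0.5. The
probability column feeds `depthsite rerank`, which reorders a detector's
pocket table by predicted-binder counts.

The Python API mirrors the CLI: `read_pdb`, `compute_rsa`, `residue_depths`,
`label_samples`, `featurize_structure`, `train`/`cross_validate`, `rerank` —
see `docs/methods.md` for the model, parameter defaults, and the fixture
generator's scope and limits.

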