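# fapocket

Prediction of fatty-acid (FA)-binding pockets on protein structures.

Soluble proteins such as the nucleoporins Nic96 and Nup157 can bury an acyl
chain in a hydrophobic cavity; finding candidate cavities and deciding
whether they look like genuine FA-binding sites is a structure-only
classification problem.  `fapocket` implements that workflow end to end:

1. **Cavity detection.** Heavy atoms of a PDB structure are Delaunay-
   triangulated; the circumsphere of each tetrahedron is an *alpha sphere*
   (tangent to four atoms, containing no atom center).  Spheres with radius
   in [4.0, 6.2] Å are kept — the window that selects cleft- and
   cavity-lining spheres while rejecting packing interstices and bulk
   solvent — and single-linkage clustered at 6.0 Å into pockets.
2. **Featurization.** Each pocket becomes a fixed-order 14-descriptor
   vector: sphere count, mean/max radius, apolar-sphere fraction,
   Monte-Carlo union volume, compactness, Kyte–Doolittle hydrophobicity of
   the lining, polar/charged/aromatic lining fractions, H/E/C
   secondary-structure composition (from a backbone-dihedral assigner), and
   lining size.
3. **Classification.** A multilayer perceptron (one hidden layer of 32
   logistic units) maps the descriptor vector to a score in [0, 1].  Two
   models are trained — one from an all-species curated set, one
   human-only — with stratified 5-fold cross-validation.  A pocket is
   called positive only when its score is **strictly** greater than 0.5,
   and a *consensus* hit must be positive under **both** models, which
   bounds the consensus false-positive rate by the smaller per-model rate.
4. **FPR estimation.** A negative pool of ligand-bound structures whose
   ligands are not FAs (exclusion list applied) is sampled, scored, and the
   percentage of positive calls reported per model and for the consensus.

Because the curated structure sets and negative pools are external
databases, the package ships a **synthetic generator** that emulates every
input: cavity-bearing pseudo-protein "cages" with optional acyl or ring
pseudo-ligands, labeled feature matrices with controllable class
separation, and stand-in curated tables with the real sets' shape (340
human rows; 70 rows across 52 species).  The entire pipeline therefore runs
and is tested with no downloads.

## Worked example

Generate a cage with a buried 8-carbon acyl pseudo-ligand and detect its
cavity:

```sh
$ fapocket simulate cage --out cage.pdb --seed 1 --ligand acyl
$ fapocket detect cage.pdb
structure_id  pocket_id  n_spheres  mean_radius  apolar_fraction  chain  span_start  span_end  ...
cage          1          100        4.87         1.0              A      1           39        ...
```

One pocket: 100 alpha spheres of mean radius 4.87 Å, entirely apolar, lined
by residues 1–39 of chain A — the built-in cavity.

Run the full synthetic workflow (60 training cages, two models, 5-fold CV,
10 held-out cages, 40-cage ring-decoy pool):

```sh
$ fapocket demo --seed 42
cv_mean_all_species     1.000
cv_mean_human           1.000
holdout_consensus_rate  1.000
fpr_all_species         2.4
fpr_human               2.4
fpr_consensus           2.4
```

Both models cross-validate perfectly on the cage dataset, every held-out
acyl-cage cavity is recovered by the consensus call, and 2.4% of
ring-decoy pockets are falsely called positive — with the consensus rate,
as always, no larger than either per-model rate.

To predict on real structures, train models from your own feature tables
(`fapocket train`), then:

```sh
fapocket predict my_structure.pdb --model-all-species A.joblib --model-human B.joblib
```

which emits one row per pocket with both scores, the consensus flag, and
the author-numbered residue span of the pocket lining.

## Layout

- `src/fapocket/structure.py` — PDB I/O (gemmi-backed), Atom/Residue/Structure model
- `src/fapocket/detect.py` — alpha spheres, clustering, pocket finalization
- `src/fapocket/ss.py` — backbone dihedrals and H/E/C assignment
- `src/fapocket/features.py` — the 14-descriptor contract and normalization
- `src/fapocket/curation.py` — training tables, ligand-contact labeling, datasets
- `src/fapocket/classifier.py` — MLP training, CV, threshold, consensus
- `src/fapocket/fpr.py` — negative pools and FPR reports
- `src/fapocket/synthetic.py` — cages, feature simulation, table stand-ins
- `src/fapocket/pipeline.py`, `cli.py` — orchestration and the `fapocket` CLI

See `docs/methods.md` for the model details, parameter choices, and the
limits of what the synthetic benchmarks demonstrate.
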