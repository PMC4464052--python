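# poseguide

Knowledge-guided docking toolkit: machinery for exploiting previously
solved ligand structures of a protein target when predicting how a new
ligand binds.  In prospective ("cross-docking") pose prediction the
search engine usually *finds* near-native poses but *ranks* them below
decoys; poseguide provides the engine-agnostic pieces that fix this by
fusing prior structural knowledge with docking scores:

* **Substructure hints** — mine positioned common substructures (≥ 4
  heavy atoms, budgeted depth-first search, top 50 by 2D similarity)
  between a ligand and known bound ligands, as 3D fragments an engine can
  use to focus its search.
* **Similarity rescoring** — convert each pose's mean 3D similarity
  s_i to the m known bound poses into an upper-tail probability
  p_i = 1 − ½(1 + erf((s_i − μ)/(σ′√2))), σ′ = σ/√m, and add the
  energy-derived bonus w_i = log10(1/p_i) (floored at p = 1e-6, so at
  most +6 pKd) to the docking score.
* **Boltzmann pose families** — cluster rescored poses by
  symmetry-corrected RMSD and rank families by normalised 10^score
  weights, read as the probability that the true binding mode falls in
  each family.
* **Ensemble selection** — pick K representative protein structures from
  a pocket-similarity matrix by exact/K-medoid partitioning (plus the
  "diverse" and "random" comparison strategies and a single-linkage
  similarity tree with Newick export).
* **Benchmark protocol** — curation filters (element whitelist, MW <
  1000, protein contact, buriedness), earliest-25% temporal split,
  success-at-top-k evaluation with symmetry-corrected RMSD (including
  site C2 symmetry), cumulative histograms, novelty fractions, KS and
  exact binomial tests.
* **Synthetic fixtures** — a seeded generator producing ligand series,
  pose clouds with planted native/decoy structure, and clustered
  similarity matrices, so everything runs without downloads.

It is aimed at structural bioinformaticians building or evaluating pose
prediction pipelines around an existing docking engine.

## Worked example

Generate a synthetic target (8 known bound ligands, one test ligand, a
100-pose docking-like cloud whose decoys outscore the natives by 0.5
pKd), then rescore and evaluate:

```bash
poseguide simulate --seed 3 -o fx/
poseguide rescore --poses fx/docked.sdf --posehints fx/EarlyHints.mol2 -o families.json
poseguide eval --families families.json --poses fx/docked.sdf --ref fx/TestRef.mol2
```

which prints

```
top-1   1.000
top-2   1.000
top-5   1.000
top-10  1.000
top-all 1.000
```

the fraction of ligands (here one) whose best pose among the top-k
ranked families lies within 2.0 Å symmetry-corrected RMSD of the
crystallographic reference.  Without `--posehints` decoy families fill
the top ranks (`top-1` through `top-10` print `0.000`; only `top-all`
reaches `1.000`): the pool contains the native pose, but it is the
rescoring, not the docking score, that identifies it.  The same pipeline is available in
Python:

```python
from poseguide.fixtures import FixtureSpec, make_pose_cloud, reference_poses
from poseguide.knowledge_rescoring import rescore_and_rank

spec = FixtureSpec(seed=3)
refs = reference_poses(spec)
poses = make_pose_cloud(refs[0], spec)
corrections, families = rescore_and_rank(poses, knowns=refs[1:])
print(families[0].probability)   # ~1.0 for the recovered native family
```

Other entry points: `poseguide hints` (substructure hint fragments),
`poseguide select --matrix psim.tsv --k 5 --strategy kmedoid|diverse|random`
(protein ensemble choice), `poseguide gsim` / `poseguide sim3d`
(similarity matrices), and `poseguide curate` (filters + temporal split).

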