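# Methods

`poseguide` re-implements, in a docking-engine-agnostic form, the
knowledge-guided machinery that surrounds a pose-prediction engine:
exploiting previously solved ligand structures of a target to (i) mine
positioned substructure hints, (ii) re-rank candidate docked poses, and
(iii) choose representative protein structures for ensemble docking —
together with the curation and evaluation protocol of a temporally
partitioned cross-docking benchmark.  The docking engine itself (search,
scoring, conformer enumeration) and the computation of protein
binding-pocket similarity are out of scope; poses arrive as files in one
shared site frame, and pocket similarity arrives as a precomputed matrix.

## Data model and conventions

A `Molecule` is a chemical graph (element, formal charge, aromatic flag
per atom; order + aromatic flag per bond).  A `Pose` adds per-atom 3D
coordinates in Å in the common site frame and, for docked candidates, a
docking score in pKd units (higher = tighter predicted binding).  All
geometric comparisons are performed in place: no superposition is ever
applied, because the methods are only meaningful for poses that already
live in one frame.

SDF (V2000) and SYBYL MOL2 are the interchange formats; docking scores
travel in an SDF data field / MOL2 header comment named `SCORE_PKD`.
Aromatic bonds compare as aromatic regardless of Kekulé assignment, so
round-tripping through either format preserves the graph up to that
equivalence.

## Symmetry-corrected RMSD

Deviation between a predicted and a reference pose is the minimum
heavy-atom RMSD over (a) all element- and bond-preserving automorphisms
of the ligand's heavy-atom graph and (b) an optional set of proper rigid
site-symmetry operations (e.g. a C2 axis for a homodimeric protease
site), including the identity.  Hydrogens are excluded because
crystallographic references rarely constrain them.  Automorphisms are
enumerated by iterative colour refinement (element, charge, aromaticity,
degree, then neighbourhood colours) followed by backtracking; a hard cap
(default 10,000, with a warning) bounds pathological highly symmetric
graphs.  By construction the corrected value never exceeds the plain
identity-mapping RMSD.

When a reference structure provides several modelled alternates, the
deviation is the minimum over alternates.

## 2D graph similarity (GSIM)

Each molecule is summarised by canonical keys of rooted neighbourhood
balls: for every heavy atom and every radius 0–3, the induced subgraph of
atoms within that graph distance, with the root marked.  Emission stops
for a root once its ball stops growing, so saturated neighbourhoods are
not double-counted.  Keys are canonicalised with a Weisfeiler–Lehman
graph hash over typed nodes and edges, which makes the multiset invariant
to atom input order.  Similarity is the weighted multiset overlap taken
bidirectionally,

    gsim(A, B) = 2 * w(matched) / (w(A) + w(B)),

with keys rooted at non-carbon heavy atoms weighted 2.0 (configurable) to
favour pharmacophore-bearing substructure.  The score is symmetric,
bounded in [0, 1], and exactly 1 for identical graphs.  The subgraph
definition (balls vs. paths) and the heteroatom weight are conventions of
this package; they are exposed as parameters rather than asserted as the
original values.

## Substructure hints

Common connected substructures between the ligand to dock and each known
bound ligand are found by depth-first search over atom pairings.  Atom
compatibility requires equal element and aromatic flag; bond
compatibility requires equal aromatic flag and, for non-aromatic bonds,
equal order; agreement on bond presence is enforced between all mapped
pairs (induced matching).  The search branches on the smallest frontier
atom with an explicit exclude branch and roots each candidate atom set at
its minimum ligand atom, so each connected set is visited once — this
keeps exhaustive enumeration tractable on small molecules while
preserving completeness.

The search is budgeted: it halts either by exhaustion or once 10,000
recursive extension steps have elapsed since the last discovery of a
larger match (budget exhaustion is a flagged, non-fatal outcome).
Matches need at least 4 heavy atoms; per known molecule, matches with
identical ligand atom sets are de-duplicated and subsets of a retained
match are pruned.  Each surviving fragment takes its coordinates verbatim
from the known bound pose, is scored by `gsim(fragment, whole ligand)`,
and the pooled matches across all knowns are ranked (similarity desc,
size desc, known id asc) and truncated at 50 by default.  Hints are
emitted as data files; injecting them into an engine's search is the
engine's job.

## 3D similarity surrogate

The rescoring mathematics needs a bounded, normalised, frame-aware 3D
similarity S.  The one provided is a Gaussian-overlap score over two
channels: per-heavy-atom shape densities whose widths are tied to van der
Waals radii (decay chosen so two identical atoms separated by twice the
vdW radius overlap at ~1% of self-overlap), and typed polar points
(donor, acceptor, positive, negative; width 1 Å) matched within type
only.  Donors are N/O carrying a hydrogen (explicit or inferred from
standard valence), acceptors are neutral-or-anionic N/O, and charge
features come from formal charges.  With O the weighted overlap
(shape:polar = 2:1),

    S(a, b) = O(a, b) / sqrt(O(a, a) * O(b, b)),

which by Cauchy–Schwarz lies in [0, 1], equals 1 at identity, is
symmetric, is invariant under a joint rigid transform, and vanishes with
separation.  No conformer search or mutual alignment is performed.

## Similarity-to-probability rescoring

For n candidate poses L_1..n and m known bound poses K_1..m, the n×m
similarity table yields mean μ and population standard deviation σ.  The
per-pose mean similarity s_i = (1/m) Σ_j S(L_i, K_j) is, under the pool
distribution, approximately normal with standard error σ′ = σ/√m, and

    p_i = 1 − ½(1 + erf((s_i − μ)/(σ′√2)))

is the upper-tail probability of a similarity that native-like arising by
chance within the pool.  The statistical-potential analogy maps this
likelihood ratio to an energy; on the pKd score scale, identifying
RT·ln 10 with one pKd unit, the correction becomes the positive bonus
w_i = log10(1/p_i) added to the docking score.  Probabilities are floored
at 1e-6, capping the bonus at 6 pKd.  Degenerate cases degrade to no
correction: fewer than two poses, an empty known set, or σ = 0 (where p
steps to 0.5/floor/1 around the mean).  Note σ′ = σ/√m is applied even
when the knowns are highly redundant; this is statistically optimistic
and is documented rather than patched.

## Pose families

Poses sorted by descending adjusted score are leader-clustered: a pose
joins the first family whose representative lies within 2.0 Å
symmetry-corrected RMSD (configurable), else founds a new family.  Family
weight is 10^(representative score − best score) — representative rather
than member-sum weighting avoids rewarding densely resampled minima — and
the normalised weights, which sum to 1 by construction, are reported as
the probability that the experimentally observed binding mode falls
within the family.  The leader linkage and the threshold are this
package's conventions (the upstream literature does not pin them down);
both are exposed.

## Ensemble selection

Given an N×N pocket-similarity matrix (symmetric, unit diagonal),
structures are partitioned on distance d = 1 − similarity:

* **kmedoid** — K-medoid partitioning, with each cluster represented by
  the member of maximal mean similarity to its co-members.  When the
  number of candidate medoid sets C(N, k) is at most 5000 the optimum is
  found exactly by enumeration; beyond that, seeded multi-restart
  PAM-style alternation (default 100 restarts) is used.  The exact branch
  makes the selection provably optimal in the regime where the
  oracle-equivalence tests operate.
* **diverse** — greedy max-min-distance selection seeded at the structure
  of lowest mean similarity to all others.  This deliberately reproduces
  the known failure mode of diversity-driven selection: it returns
  outliers, which rarely represent the relevant pocket configurations.
* **random** — seeded uniform sampling, the baseline.

A single-linkage agglomeration over the same matrix yields the mutual
similarity tree, exported as Newick with the similarity at each merge as
the internal node annotation; merge similarities are non-increasing
toward the root.

## Benchmark curation and evaluation

Curation applies four independent rules to each liganded complex record:
elements restricted to H/C/N/O/S/P/F/Cl/Br/I; molecular weight under
1000; at least three ligand heavy atoms within 1.0 Å vdW
surface-to-surface distance of the protein; and a buriedness ratio
(protein atoms within a 4.0 Å shell ÷ ligand heavy atoms) of at least
0.3.  The shell and ratio defaults are this package's choices — the
source protocol references an external definition without printing
values — and both are parameters.  Records without a protein shell are
evaluated on the two ligand-intrinsic rules only, flagged.

The temporal split sorts by deposition date (ties by id) and assigns the
earliest ⌈0.25·N⌉ complexes to the known set (ceiling chosen and
documented for non-integer quarters).  A centroid filter drops ligands
whose heavy-atom centroid deviates more than 10 Å (closed threshold) from
the mean centroid.

Evaluation computes, per ranked pose family, the minimum
symmetry-corrected RMSD of any member to the reference, and derives
success-at-top-k (k ∈ {1, 2, 5, 10, all}) at a given RMSD threshold;
best-at-top-k is non-increasing in k.  Cumulative histograms, novelty
fractions (fraction of test items whose maximal similarity to the knowns
falls strictly below a threshold; default threshold the 10th percentile
of the pooled similarity distribution when not supplied), the two-sample
Kolmogorov–Smirnov comparison, and the exact binomial test complete the
reporting toolkit; the latter two delegate to scipy.

## Synthetic fixtures and what they show

The generator emulates the statistical situation that makes knowledge
guidance valuable, not the physics of docking.  A series of ligands
shares a rigid aromatic 6-ring scaffold with seeded heteroatom-bearing
decorations; reference poses place the scaffold at one canonical site
location, so the series' bound poses overlap.  A pose cloud per ligand
(default 100 poses) mixes near-native poses (≤ 1 Å from the reference;
default spread 0.6 Å) with decoys (flipped 180° and displaced 4.5–7 Å,
hence ≥ 4 Å RMSD) whose scores exceed every native score by a 0.5 pKd gap
around a 6.0 pKd anchor.  Default conditions: 8 known ligands, 20%
native fraction.  Geometry is idealised (fixed bond lengths, no force
field, no minimisation); torsion randomisation rotates rigid sub-trees
about acyclic single bonds, preserving bond lengths exactly.

Because decoys outscore natives by construction, unguided family ranking
fails in 100% of trials; the end-to-end experiment (100 seeded ligands)
checks that similarity rescoring recovers the native family at rank 1 in
at least 90% of them, with family probabilities summing to 1 within
1e-9.  What passing shows: the rescoring pipeline moves well-separated
native-like poses to the top whenever the 3D similarity signal separates
them from decoys.  What it does not show: performance on real docking
decoys, which are not rigid flips, can partially overlap the native pose,
and sit in a continuous score landscape; nor robustness to preparation
errors, protonation variation, or pocket flexibility.

## Numerical choices and limitations

* Population (ddof = 0) standard deviation over the similarity table.
* Ties broken deterministically everywhere (score then index for pose
  ordering; identifier sort for structure selection); all stochastic
  steps consume an explicit seed.
* Automorphism truncation, budget exhaustion, and skipped filter rules
  are warnings/flags, never silent.
* Problem sizes in the test suite and the acceptance script (≤ 12 heavy
  atoms where exhaustive oracles run, 100-trial experiments, N ≤ 8
  exhaustive selection checks) are chosen so independent brute-force
  verification is feasible at every step.
* The 3D similarity is a surrogate with the same contract as the
  proprietary function it stands in for, not a numerical reproduction;
  published headline success rates on real benchmarks depend on the
  docking engine and corpus and are outside what this package computes.
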