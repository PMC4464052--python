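"""Deterministic synthetic fixtures for every module and for the
end-to-end guided-vs-unguided rescoring experiment.

The generator emulates the statistical situation that makes knowledge
guidance valuable: a docking run produces a pool of candidate poses in
which the near-native poses are present but *outscored* by decoys, while
previously solved ligands of the same chemical series occupy the same
region of the site.  Concretely:

* a series of ligands shares a rigid aromatic scaffold (>= 6 heavy atoms)
  with varied, heteroatom-containing decorations;
* the reference pose of each ligand places the scaffold at one canonical
  location, so the series' bound poses overlap in space;
* a pose cloud mixes near-native poses (<= 1 Å RMSD from the reference)
  with decoys (>= 4 Å, flipped and displaced) whose docking scores beat
  the natives by a configured gap.

Geometry is idealised (fixed bond lengths, planar ring, no force field):
none of the downstream machinery requires physically minimised
structures.  Every fixture is a pure function of its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from poseguide.chemcore import Atom, Bond, Molecule, Pose
from poseguide.ensemble_selection import PocketSimMatrix
from poseguide.knowledge_rescoring import build_pose_families, rescore

RING_BOND = 1.39  # aromatic C-C, Å
CHAIN_BOND = 1.48  # generic single bond, Å


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic rescoring experiment."""

    seed: int = 0
    n_knowns: int = 8
    n_poses: int = 100
    native_fraction: float = 0.2
    rmsd_spread: float = 0.6  # Å, target perturbation of native poses
    score_gap: float = 0.5  # pKd by which decoys beat natives
    scaffold_size: int = 6
    base_score: float = 6.0  # pKd scale anchor for docking scores
    family_rmsd: float = 2.0

    def __post_init__(self) -> None:
        if min(self.n_knowns, self.n_poses, self.scaffold_size) < 1:
            raise ValueError("counts must be >= 1")
        if self.rmsd_spread <= 0:
            raise ValueError("rmsd_spread must be > 0")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# ligand series
# ---------------------------------------------------------------------------

_DECORATIONS = ("O", "N", "C", "OC", "NC", "CC", "CO", "CN")


def _build_ligand(spec: FixtureSpec, index: int) -> tuple[Molecule, np.ndarray]:
    """Scaffold ring plus seeded decorations; coordinates are the canonical
    reference placement shared by the series."""
    rng = np.random.default_rng((spec.seed, 1, index))
    n_ring = max(6, spec.scaffold_size)
    atoms = [Atom("C", aromatic=True) for _ in range(n_ring)]
    bonds = [Bond(i, (i + 1) % n_ring, 1, True) for i in range(n_ring)]
    radius = RING_BOND / (2 * math.sin(math.pi / n_ring))
    ang = 2 * math.pi * np.arange(n_ring) / n_ring
    coords = [
        np.array([radius * math.cos(a), radius * math.sin(a), 0.0]) for a in ang
    ]
    # decorations: 2-3 substituents, at least one heteroatom-initial
    n_sub = int(rng.integers(2, 4))
    sites = rng.choice(n_ring, size=n_sub, replace=False)
    decos = [str(rng.choice(_DECORATIONS)) for _ in range(n_sub)]
    if not any(d[0] in "ON" for d in decos):
        decos[0] = "O" + decos[0][1:]
    for site, deco in zip(sites, decos):
        parent = int(site)
        out = coords[parent] / np.linalg.norm(coords[parent])
        for depth, el in enumerate(deco):
            atoms.append(Atom(el))
            child = len(atoms) - 1
            bonds.append(Bond(parent, child, 1, False))
            zig = np.array([0.0, 0.0, 0.45 if depth % 2 else -0.45])
            step = out * CHAIN_BOND * 0.95 + zig
            coords.append(coords[parent] + step * (CHAIN_BOND / np.linalg.norm(step)))
            parent = child
    return Molecule(atoms, bonds, f"lig{spec.seed}_{index}"), np.array(coords)


def make_ligand_series(spec: FixtureSpec, n_ligands: int | None = None) -> list[Molecule]:
    """Ligands sharing a connected >= ``scaffold_size``-atom scaffold."""
    n = n_ligands if n_ligands is not None else spec.n_knowns + 1
    return [_build_ligand(spec, i)[0] for i in range(n)]


def reference_poses(spec: FixtureSpec, n_ligands: int | None = None) -> list[Pose]:
    """Reference poses of the series in the shared site frame."""
    n = n_ligands if n_ligands is not None else spec.n_knowns + 1
    out = []
    for i in range(n):
        mol, coords = _build_ligand(spec, i)
        out.append(Pose(mol, coords))
    return out


# ---------------------------------------------------------------------------
# pose clouds
# ---------------------------------------------------------------------------

def make_pose_cloud(reference: Pose, spec: FixtureSpec) -> list[Pose]:
    """Scored candidate poses: perturbed natives outscored by flipped and
    displaced decoys.

    Native poses deviate from the reference by at most
    ``min(rmsd_spread, 1.0)`` Å (plain heavy-atom RMSD); decoys by at
    least 4 Å.  Decoy scores exceed every native score by at least
    ``score_gap``.  The pose order is a seeded shuffle.
    """
    rng = np.random.default_rng((spec.seed, 2))
    n_native = max(1, round(spec.native_fraction * spec.n_poses))
    cap = min(spec.rmsd_spread, 1.0)
    center = reference.heavy_coords.mean(axis=0)
    poses = []
    for _ in range(n_native):
        target = cap * rng.uniform(0.3, 0.999)
        angle = rng.uniform(0.02, 0.25)
        axis = _random_unit(rng)
        trans = _random_unit(rng) * target * 0.7
        for _ in range(8):
            rot = _rotation(axis, angle)
            new = (reference.coords - center) @ rot.T + center + trans
            d = new[list(reference.molecule.heavy_indices)] - reference.heavy_coords
            r = float(np.sqrt((d * d).sum(axis=1).mean()))
            if r <= cap:
                break
            shrink = target / r
            angle *= shrink
            trans = trans * shrink
        score = spec.base_score - rng.uniform(0.0, 0.3)
        poses.append(Pose(reference.molecule, new, float(score)))
    for _ in range(spec.n_poses - n_native):
        rot = _rotation(_random_unit(rng), math.pi)
        trans = _random_unit(rng) * rng.uniform(4.5, 7.0)
        new = (reference.coords - center) @ rot.T + center + trans
        score = spec.base_score + spec.score_gap + rng.uniform(0.0, 0.3)
        poses.append(Pose(reference.molecule, new, float(score)))
    order = rng.permutation(len(poses))
    return [poses[i] for i in order]


# ---------------------------------------------------------------------------
# pocket-similarity matrices
# ---------------------------------------------------------------------------

def make_clustered_simmatrix(
    block_sizes: list[int],
    within: float = 0.9,
    between: float = 0.1,
    noise: float = 0.0,
    seed: int = 0,
) -> PocketSimMatrix:
    """Symmetric unit-diagonal matrix with planted blocks plus seeded
    symmetric noise, clipped to [0, 1]."""
    rng = np.random.default_rng(seed)
    n = sum(block_sizes)
    values = np.full((n, n), between)
    start = 0
    for size in block_sizes:
        values[start : start + size, start : start + size] = within
        start += size
    if noise > 0:
        pert = rng.normal(scale=noise, size=(n, n))
        pert = (pert + pert.T) / 2
        values = np.clip(values + pert, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    ids = [f"s{i:03d}" for i in range(n)]
    return PocketSimMatrix(ids, values)


# ---------------------------------------------------------------------------
# torsion randomization
# ---------------------------------------------------------------------------

def rotatable_bonds(mol: Molecule) -> list[Bond]:
    """Single, non-aromatic, acyclic bonds between non-terminal heavy atoms."""
    import networkx as nx

    g = mol.heavy_graph()
    bridges = set(frozenset(e) for e in nx.bridges(g))
    out = []
    for b in mol.bonds:
        if b.order != 1 or b.aromatic:
            continue
        if not (mol.atoms[b.i].is_heavy and mol.atoms[b.j].is_heavy):
            continue
        if frozenset((b.i, b.j)) not in bridges:
            continue
        if g.degree[b.i] < 2 or g.degree[b.j] < 2:
            continue
        out.append(b)
    return out


def randomize_torsions(pose: Pose, seed: int = 0) -> Pose:
    """Assign seeded random dihedral angles to all rotatable bonds.

    Rigid-body geometry is preserved exactly: for each rotatable bond the
    atoms on the far side are rotated about the bond axis, leaving all
    bond lengths and angles unchanged.  A molecule with no rotatable bonds
    is returned unchanged.
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    coords = pose.coords.copy()
    g = pose.molecule.heavy_graph()
    # include hydrogens in the moving side by attaching them to their heavy atom
    full = nx.Graph()
    full.add_nodes_from(range(pose.molecule.n_atoms))
    for b in pose.molecule.bonds:
        full.add_edge(b.i, b.j)
    for b in rotatable_bonds(pose.molecule):
        angle = rng.uniform(0.0, 2 * math.pi)
        cut = full.copy()
        cut.remove_edge(b.i, b.j)
        moving = nx.node_connected_component(cut, b.j)
        axis = coords[b.j] - coords[b.i]
        rot = _rotation(axis, angle)
        origin = coords[b.i]
        idx = sorted(moving)
        coords[idx] = (coords[idx] - origin) @ rot.T + origin
    return Pose(pose.molecule, coords, pose.score)


# ---------------------------------------------------------------------------
# random molecules (for property tests and oracles)
# ---------------------------------------------------------------------------

_RAND_ELEMENTS = ("C", "C", "C", "C", "N", "O", "S")
_MAX_DEGREE = {"C": 4, "N": 3, "O": 2, "S": 2}


def make_random_molecule(n_heavy: int, seed: int = 0) -> Molecule:
    """Random connected heavy-atom molecule: a spanning tree with element
    degree caps, occasionally closed into a ring."""
    rng = np.random.default_rng(seed)
    if n_heavy < 1:
        raise ValueError("need at least one atom")
    atoms = [Atom(str(rng.choice(_RAND_ELEMENTS))) for _ in range(n_heavy)]
    degree = [0] * n_heavy
    bonds = []
    for i in range(1, n_heavy):
        candidates = [
            j for j in range(i) if degree[j] < _MAX_DEGREE[atoms[j].element]
        ]
        if not candidates:
            candidates = list(range(i))
        j = int(rng.choice(candidates))
        bonds.append(Bond(j, i, 1, False))
        degree[i] += 1
        degree[j] += 1
    # one optional ring closure
    if n_heavy >= 4 and rng.random() < 0.5:
        closable = [
            (i, j)
            for i in range(n_heavy)
            for j in range(i + 2, n_heavy)
            if degree[i] < _MAX_DEGREE[atoms[i].element]
            and degree[j] < _MAX_DEGREE[atoms[j].element]
            and not any({b.i, b.j} == {i, j} for b in bonds)
        ]
        if closable:
            i, j = closable[int(rng.integers(len(closable)))]
            bonds.append(Bond(i, j, 1, False))
    return Molecule(atoms, bonds, f"rand{seed}")


# ---------------------------------------------------------------------------
# end-to-end guided vs unguided experiment
# ---------------------------------------------------------------------------

@dataclass
class TrialResult:
    unguided_native_top: bool
    guided_native_top: bool
    unguided_prob_sum: float
    guided_prob_sum: float
    best_native_rmsd: float


def run_trial(spec: FixtureSpec, success_rmsd: float = 2.0) -> TrialResult:
    """One ligand: dock-like pose cloud, rescore against the series'
    known bound poses, compare unguided vs guided top-family correctness.

    The top family is 'native' when its best member lies within
    ``success_rmsd`` (symmetry-corrected) of the reference pose.
    """
    from poseguide.chemcore import symmetry_rmsd

    refs = reference_poses(spec)
    test_ref, knowns = refs[0], refs[1:]
    poses = make_pose_cloud(test_ref, spec)

    def top_family_rmsd(adjusted):
        fams = build_pose_families(poses, adjusted, rmsd_threshold=spec.family_rmsd)
        top = fams[0]
        rmsd = min(symmetry_rmsd(poses[i], test_ref) for i in top.member_poses)
        return rmsd, sum(f.probability for f in fams)

    raw = [p.score for p in poses]
    un_rmsd, un_sum = top_family_rmsd(raw)
    corrections = rescore(poses, knowns)
    g_rmsd, g_sum = top_family_rmsd([c.adjusted_score for c in corrections])
    return TrialResult(
        unguided_native_top=un_rmsd <= success_rmsd,
        guided_native_top=g_rmsd <= success_rmsd,
        unguided_prob_sum=un_sum,
        guided_prob_sum=g_sum,
        best_native_rmsd=g_rmsd,
    )


def run_guided_experiment(
    n_trials: int = 100, seed: int = 0, **spec_overrides
) -> dict:
    """Guided-vs-unguided success over seeded trials.

    Returns unguided and guided top-family success fractions and the
    largest deviation of any run's family-probability sum from 1.
    """
    results = []
    for t in range(n_trials):
        spec = FixtureSpec(seed=seed * 100003 + t, **spec_overrides)
        results.append(run_trial(spec))
    prob_err = max(
        max(abs(r.unguided_prob_sum - 1.0), abs(r.guided_prob_sum - 1.0))
        for r in results
    )
    return {
        "n_trials": n_trials,
        "unguided_success": sum(r.unguided_native_top for r in results) / n_trials,
        "guided_success": sum(r.guided_native_top for r in results) / n_trials,
        "max_probability_sum_error": prob_err,
    }
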