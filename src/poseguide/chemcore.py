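"""Chemical graph and pose primitives.

This module provides the data model shared by the whole toolkit: a
:class:`Molecule` (a chemical graph without coordinates), a :class:`Pose`
(a molecule placed in the common binding-site frame, optionally carrying a
docking score in pKd units), structure file I/O (SDF V2000 and SYBYL MOL2),
graph-automorphism enumeration, and symmetry-corrected RMSD.

All poses handled here are assumed to live in one shared site coordinate
frame; RMSD is therefore computed *in place*, with no superposition, over
heavy atoms only. Symmetry correction minimises the deviation over the
ligand's graph automorphisms and, optionally, over rigid site symmetry
operations (e.g. the C2 axis of a homodimeric protease site).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: SDF data field / MOL2 comment carrying the docking score in pKd units.
SCORE_FIELD = "SCORE_PKD"

_PT = Chem.GetPeriodicTable()


class StructureParseError(ValueError):
    """Raised when a structure record cannot be parsed."""


def _check_element(symbol: str) -> None:
    try:
        if _PT.GetAtomicNumber(symbol) <= 0:
            raise ValueError
    except Exception:
        raise StructureParseError(f"unsupported element symbol: {symbol!r}") from None


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """One atom: element symbol, formal charge, aromaticity flag."""

    element: str
    formal_charge: int = 0
    aromatic: bool = False

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    @property
    def is_hetero(self) -> bool:
        """Heavy atom that is not carbon."""
        return self.is_heavy and self.element != "C"

    def type_key(self) -> tuple:
        return (self.element, self.formal_charge, self.aromatic)


@dataclass(frozen=True)
class Bond:
    """Undirected bond between atom indices ``i < j``."""

    i: int
    j: int
    order: int = 1
    aromatic: bool = False

    def type_key(self) -> tuple:
        # Aromatic bonds compare as aromatic regardless of Kekulé order.
        return ("ar",) if self.aromatic else (self.order,)


@dataclass
class Molecule:
    """A chemical graph: ordered atoms plus undirected bonds.

    Invariants enforced at construction: bond endpoints reference existing
    distinct atoms, no duplicate bonds, and at least one heavy atom.
    """

    atoms: list[Atom]
    bonds: list[Bond]
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[frozenset[int]] = set()
        norm: list[Bond] = []
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n) or b.i == b.j:
                raise ValueError(f"bond ({b.i},{b.j}) references invalid atoms (n={n})")
            key = frozenset((b.i, b.j))
            if key in seen:
                raise ValueError(f"duplicate bond ({b.i},{b.j})")
            seen.add(key)
            if b.i > b.j:
                b = Bond(b.j, b.i, b.order, b.aromatic)
            norm.append(b)
        self.bonds = norm
        for a in self.atoms:
            _check_element(a.element)
        if not any(a.is_heavy for a in self.atoms):
            raise ValueError("molecule must contain at least one heavy atom")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def heavy_indices(self) -> tuple[int, ...]:
        return tuple(i for i, a in enumerate(self.atoms) if a.is_heavy)

    def adjacency(self) -> dict[int, dict[int, Bond]]:
        adj: dict[int, dict[int, Bond]] = {i: {} for i in range(self.n_atoms)}
        for b in self.bonds:
            adj[b.i][b.j] = b
            adj[b.j][b.i] = b
        return adj

    def heavy_graph(self):
        """Heavy-atom graph as networkx, nodes labelled by atom index."""
        import networkx as nx

        g = nx.Graph()
        for i in self.heavy_indices:
            g.add_node(i, type=self.atoms[i].type_key())
        for b in self.bonds:
            if self.atoms[b.i].is_heavy and self.atoms[b.j].is_heavy:
                g.add_edge(b.i, b.j, type=b.type_key())
        return g

    def molecular_weight(self) -> float:
        return sum(_PT.GetAtomicWeight(a.element) for a in self.atoms)

    def graph_signature(self) -> tuple:
        return (
            tuple(a.type_key() for a in self.atoms),
            tuple(sorted((b.i, b.j) + b.type_key() for b in self.bonds)),
        )


def graphs_equal(a: Molecule, b: Molecule) -> bool:
    """Identical chemical graphs under identical atom ordering."""
    return a.graph_signature() == b.graph_signature()


@dataclass
class Pose:
    """A molecule with 3D coordinates in the shared site frame.

    ``score`` is a docking score in pKd units (higher is better); it is
    ``None`` for reference crystallographic poses.
    """

    molecule: Molecule
    coords: np.ndarray
    score: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.molecule.n_atoms, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{self.molecule.n_atoms} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def heavy_coords(self) -> np.ndarray:
        return self.coords[list(self.molecule.heavy_indices)]

    def centroid(self) -> np.ndarray:
        return self.heavy_coords.mean(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Pose":
        """Return a copy rigidly transformed by ``x -> R x + t``."""
        new = self.coords @ np.asarray(rotation, float).T + np.asarray(translation, float)
        return Pose(self.molecule, new, self.score)


# ---------------------------------------------------------------------------
# Site symmetry
# ---------------------------------------------------------------------------

@dataclass
class SymmetryOps:
    """Symmetry operations used when comparing poses.

    ``automorphisms`` are atom-index permutations over the heavy atoms of a
    molecule (identity first); when ``None`` they are derived from the
    molecule at evaluation time.  ``site_ops`` are proper rigid transforms
    ``(R, t)`` expressing binding-site symmetry (the identity is implicit and
    need not be listed).
    """

    automorphisms: list[tuple[int, ...]] | None = None
    site_ops: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ops = []
        for rot, trans in self.site_ops:
            rot = np.asarray(rot, float)
            trans = np.asarray(trans, float)
            if rot.shape != (3, 3) or trans.shape != (3,):
                raise ValueError("site op must be a (3,3) rotation and length-3 translation")
            if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-8):
                raise ValueError("site rotation must be orthonormal")
            if np.linalg.det(rot) < 0:
                raise ValueError("site rotation must be proper (det +1)")
            ops.append((rot, trans))
        self.site_ops = ops

    @staticmethod
    def c2(axis, center) -> "SymmetryOps":
        """Two-fold rotation about ``axis`` through ``center`` (e.g. the
        HIV-protease active-site C2 axis)."""
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        center = np.asarray(center, float)
        rot = 2.0 * np.outer(axis, axis) - np.eye(3)  # rotation by pi
        trans = center - rot @ center
        return SymmetryOps(site_ops=[(rot, trans)])


# ---------------------------------------------------------------------------
# Automorphisms
# ---------------------------------------------------------------------------

class AutomorphismTruncation(UserWarning):
    """Signalled when automorphism enumeration hits its hard cap."""


def enumerate_automorphisms(mol: Molecule, max_count: int = 10000) -> list[tuple[int, ...]]:
    """All element- and bond-preserving automorphisms of the heavy-atom graph.

    Permutations are expressed over heavy atoms in heavy-atom order: entry
    ``k`` is the heavy position onto which heavy position ``k`` is mapped.
    Uses iterative colour refinement (element, charge, aromaticity, degree,
    then neighbourhood colours) followed by backtracking.  The identity is
    always first.  Enumeration is truncated, with a warning, at
    ``max_count`` permutations.
    """
    heavy = mol.heavy_indices
    n = len(heavy)
    pos = {a: k for k, a in enumerate(heavy)}
    adj: list[dict[int, tuple]] = [{} for _ in range(n)]
    for b in mol.bonds:
        if b.i in pos and b.j in pos:
            ki, kj = pos[b.i], pos[b.j]
            adj[ki][kj] = b.type_key()
            adj[kj][ki] = b.type_key()

    # connectivity check (spec precondition)
    if n == 0:
        raise ValueError("molecule has no heavy atoms")
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    if len(seen) != n:
        raise ValueError("heavy-atom graph must be connected")

    # colour refinement
    colors = [mol.atoms[heavy[k]].type_key() + (len(adj[k]),) for k in range(n)]
    while True:
        new = [
            (colors[k], tuple(sorted(((adj[k][v], colors[v]) for v in adj[k]), key=repr)))
            for k in range(n)
        ]
        # compress
        palette = {c: i for i, c in enumerate(sorted(set(new), key=repr))}
        new_ids = [palette[c] for c in new]
        if len(set(new_ids)) == len(set(map(repr, colors))):
            colors = new_ids
            break
        colors = new_ids

    # backtracking order: DFS so each atom (after the first) has a mapped neighbour
    order: list[int] = []
    visited = [False] * n
    stack = [0]
    while stack:
        u = stack.pop()
        if visited[u]:
            continue
        visited[u] = True
        order.append(u)
        for v in sorted(adj[u], reverse=True):
            if not visited[v]:
                stack.append(v)

    results: list[tuple[int, ...]] = []
    truncated = False
    mapping = [-1] * n
    used = [False] * n

    def extend(depth: int) -> bool:
        nonlocal truncated
        if depth == n:
            if len(results) >= max_count:
                truncated = True
                return False
            results.append(tuple(mapping))
            return True
        a = order[depth]
        for b in range(n):
            if used[b] or colors[b] != colors[a]:
                continue
            ok = True
            for u in order[:depth]:
                if adj[a].get(u) != adj[b].get(mapping[u]):
                    ok = False
                    break
            if ok:
                mapping[a] = b
                used[b] = True
                if not extend(depth + 1):
                    used[b] = False
                    mapping[a] = -1
                    return False
                used[b] = False
                mapping[a] = -1
        return True

    extend(0)
    if truncated:
        warnings.warn(
            f"automorphism enumeration truncated at {max_count}",
            AutomorphismTruncation,
        )
    identity = tuple(range(n))
    results.sort()
    if identity in results:
        results.remove(identity)
    results.insert(0, identity)
    return results


# ---------------------------------------------------------------------------
# Symmetry-corrected RMSD
# ---------------------------------------------------------------------------

def plain_rmsd(pred: Pose, ref: Pose) -> float:
    """Identity-mapping heavy-atom RMSD in the shared frame (no fitting)."""
    d = pred.heavy_coords - ref.heavy_coords
    return float(np.sqrt((d * d).sum(axis=1).mean()))


def symmetry_rmsd(
    pred: Pose,
    ref: Pose,
    site_ops: SymmetryOps | None = None,
    max_automorphisms: int = 10000,
) -> float:
    """Minimum in-place heavy-atom RMSD over graph automorphisms x site ops.

    ``pred`` and ``ref`` must share the same molecular graph (same atom
    ordering).  No rotational/translational fitting is performed; poses are
    compared in the shared site frame.
    """
    if not graphs_equal(pred.molecule, ref.molecule):
        raise ValueError("pred and ref must share the same molecular graph")
    if site_ops is not None and site_ops.automorphisms is not None:
        autos = site_ops.automorphisms
    else:
        autos = enumerate_automorphisms(pred.molecule, max_count=max_automorphisms)
    perms = np.array(autos, dtype=int)
    p = pred.heavy_coords
    q = ref.heavy_coords
    ops = [(np.eye(3), np.zeros(3))]
    if site_ops is not None:
        ops.extend(site_ops.site_ops)
    best = math.inf
    for rot, trans in ops:
        q_op = q @ rot.T + trans
        # diff[k] for perm pi: p[k] - q_op[pi[k]]
        diffs = p[None, :, :] - q_op[perms]
        rms = np.sqrt((diffs * diffs).sum(axis=2).mean(axis=1))
        best = min(best, float(rms.min()))
    return best


# ---------------------------------------------------------------------------
# Structure file I/O
# ---------------------------------------------------------------------------

_BOND_TYPES = {
    Chem.BondType.SINGLE: (1, False),
    Chem.BondType.DOUBLE: (2, False),
    Chem.BondType.TRIPLE: (3, False),
    Chem.BondType.AROMATIC: (1, True),
}
_ORDER_TO_RD = {
    (1, False): Chem.BondType.SINGLE,
    (2, False): Chem.BondType.DOUBLE,
    (3, False): Chem.BondType.TRIPLE,
}


def pose_from_rdkit(mol: Chem.Mol) -> Pose:
    atoms = [
        Atom(a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic())
        for a in mol.GetAtoms()
    ]
    bonds = []
    for b in mol.GetBonds():
        order, aro = _BOND_TYPES.get(b.GetBondType(), (1, False))
        if b.GetIsAromatic():
            aro = True
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order, aro))
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    conf = mol.GetConformer()
    coords = np.array(conf.GetPositions(), dtype=float)
    score = None
    if mol.HasProp(SCORE_FIELD):
        score = float(mol.GetProp(SCORE_FIELD))
    return Pose(Molecule(atoms, bonds, name), coords, score)


def pose_to_rdkit(pose: Pose) -> Chem.Mol:
    m = Chem.RWMol()
    for a in pose.molecule.atoms:
        try:
            ra = Chem.Atom(a.element)
        except Exception:
            raise StructureParseError(f"unsupported element symbol: {a.element!r}")
        ra.SetFormalCharge(a.formal_charge)
        ra.SetIsAromatic(a.aromatic)
        ra.SetNoImplicit(True)
        m.AddAtom(ra)
    for b in pose.molecule.bonds:
        if b.aromatic:
            bt = Chem.BondType.AROMATIC
        else:
            bt = _ORDER_TO_RD[(b.order, False)]
        m.AddBond(b.i, b.j, bt)
    conf = Chem.Conformer(pose.molecule.n_atoms)
    for i, xyz in enumerate(pose.coords):
        conf.SetAtomPosition(i, [float(x) for x in xyz])
    m.AddConformer(conf)
    mol = m.GetMol()
    mol.SetProp("_Name", pose.molecule.name)
    if pose.score is not None:
        mol.SetProp(SCORE_FIELD, repr(float(pose.score)))
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        Chem.FastFindRings(mol)
    return mol


def _read_sdf(path: str) -> list[Pose]:
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    poses = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise StructureParseError(f"malformed SDF record at index {i} in {path}")
        poses.append(pose_from_rdkit(mol))
    return poses


def _write_sdf(path: str, poses: list[Pose]) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for pose in poses:
            writer.write(pose_to_rdkit(pose))
    finally:
        writer.close()


def _read_mol2(path: str) -> list[Pose]:
    with open(path) as fh:
        text = fh.read()
    chunks = [c for c in text.split("@<TRIPOS>MOLECULE") if c.strip()]
    poses = []
    for idx, chunk in enumerate(chunks):
        try:
            poses.append(_parse_mol2_record(chunk))
        except StructureParseError:
            raise
        except Exception as exc:
            raise StructureParseError(
                f"malformed MOL2 record at index {idx} in {path}: {exc}"
            ) from exc
    return poses


def _parse_mol2_record(chunk: str) -> Pose:
    lines = chunk.splitlines()
    # header: name, counts, mol type, charge type, then optional comments
    header = [ln for ln in lines if not ln.startswith("@<TRIPOS>")]
    name = header[1].strip() if len(header) > 1 else ""
    score = None
    for ln in header[:8]:
        if SCORE_FIELD + "=" in ln:
            score = float(ln.split("=", 1)[1])
            break
    sections: dict[str, list[str]] = {}
    current = None
    for ln in chunk.splitlines():
        if ln.startswith("@<TRIPOS>"):
            current = ln.strip()[9:]
            sections[current] = []
        elif current is not None and ln.strip():
            sections[current].append(ln)
    atoms, coords = [], []
    for ln in sections.get("ATOM", []):
        parts = ln.split()
        x, y, z = map(float, parts[2:5])
        atype = parts[5]
        element = atype.split(".")[0]
        element = element[0].upper() + element[1:].lower() if element else element
        _check_element(element)
        aromatic = atype.endswith(".ar")
        charge = int(round(float(parts[8]))) if len(parts) > 8 else 0
        atoms.append(Atom(element, charge, aromatic))
        coords.append((x, y, z))
    bonds = []
    for ln in sections.get("BOND", []):
        parts = ln.split()
        i, j = int(parts[1]) - 1, int(parts[2]) - 1
        btype = parts[3]
        if btype == "ar":
            bonds.append(Bond(i, j, 1, True))
        elif btype == "am":
            bonds.append(Bond(i, j, 1, False))
        else:
            bonds.append(Bond(i, j, int(btype), False))
    return Pose(Molecule(atoms, bonds, name), np.array(coords), score)


def _sybyl_type(atom: Atom) -> str:
    return f"{atom.element}.ar" if atom.aromatic else atom.element


def _write_mol2(path: str, poses: list[Pose]) -> None:
    out = []
    for pose in poses:
        mol = pose.molecule
        out.append("@<TRIPOS>MOLECULE")
        out.append(mol.name or "UNNAMED")
        out.append(f" {mol.n_atoms} {len(mol.bonds)} 0 0 0")
        out.append("SMALL")
        out.append("USER_CHARGES")
        if pose.score is not None:
            out.append(f"{SCORE_FIELD}={pose.score!r}")
        out.append("@<TRIPOS>ATOM")
        for i, (a, xyz) in enumerate(zip(mol.atoms, pose.coords), start=1):
            out.append(
                f"{i:>7} {a.element}{i:<4} {xyz[0]:>12.4f} {xyz[1]:>12.4f} "
                f"{xyz[2]:>12.4f} {_sybyl_type(a):<6} 1 LIG {float(a.formal_charge):>8.4f}"
            )
        out.append("@<TRIPOS>BOND")
        for i, b in enumerate(mol.bonds, start=1):
            btype = "ar" if b.aromatic else str(b.order)
            out.append(f"{i:>6} {b.i + 1:>5} {b.j + 1:>5} {btype}")
        out.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(out))


def read_structures(path, fmt: str = "sdf") -> list[Pose]:
    """Read all poses from an SDF (V2000) or MOL2 (SYBYL) file.

    Scores are taken from the ``SCORE_PKD`` SDF data field or MOL2 header
    comment when present.  Atom order follows the file.
    """
    fmt = fmt.lower()
    if fmt == "sdf":
        return _read_sdf(path)
    if fmt == "mol2":
        return _read_mol2(path)
    raise ValueError(f"unknown format {fmt!r}; expected 'sdf' or 'mol2'")


def write_structures(path, poses: list[Pose], fmt: str = "sdf") -> None:
    """Write poses to SDF or MOL2 (inverse of :func:`read_structures`)."""
    fmt = fmt.lower()
    if fmt == "sdf":
        _write_sdf(path, poses)
    elif fmt == "mol2":
        _write_mol2(path, poses)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'sdf' or 'mol2'")
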