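"""Mining positioned common substructures from known bound ligands.

Given a ligand to dock and a set of ligands whose bound poses are known,
this module finds connected common substructures (at least four heavy
atoms), copies their 3D coordinates from the known bound poses, and ranks
the resulting "hint" fragments by 2D similarity of the fragment to the
whole ligand.  The hints are emitted as data; feeding them into a docking
engine's configurational search is the engine's job, not this module's.

The search is depth-first over pairs of compatible atoms and is bounded by
a recurrence budget: it stops either by exhaustion or once a fixed number
of recursive extension steps have elapsed since the last time a larger
common substructure was discovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from poseguide.chemcore import Atom, Bond, Molecule, Pose
from poseguide.gsim2d import enumerate_subgraphs, gsim

MIN_MATCH_ATOMS = 4
DEFAULT_MAX_HINTS = 50
DEFAULT_RECURRENCE_LIMIT = 10000


@dataclass
class SearchBudget:
    """Depth-first search budget.

    The search halts when more than ``recurrence_limit`` extension-step
    initiations have occurred since the last discovery of a larger matching
    substructure.  ``exhausted`` records whether a search it was used for
    ran out of budget (a normal, non-fatal outcome).
    """

    recurrence_limit: int = DEFAULT_RECURRENCE_LIMIT
    recurrences_since_best: int = 0
    best_size: int = 0
    exhausted: bool = False

    def tick(self) -> bool:
        """Register one recurrence initiation; True while budget remains."""
        self.recurrences_since_best += 1
        if self.recurrences_since_best > self.recurrence_limit:
            self.exhausted = True
            return False
        return True

    def record_size(self, size: int) -> None:
        if size > self.best_size:
            self.best_size = size
            self.recurrences_since_best = 0


@dataclass
class SubstructureMatch:
    """A positioned common substructure between a ligand and a known pose.

    ``mapping`` pairs ligand atom indices with known-pose atom indices;
    ``fragment`` carries the matched subgraph with coordinates copied from
    the known bound pose.
    """

    known_id: str
    mapping: list[tuple[int, int]]
    fragment: Pose
    gsim_to_whole: float = 0.0

    @property
    def size(self) -> int:
        return len(self.mapping)

    @property
    def ligand_atoms(self) -> frozenset[int]:
        return frozenset(i for i, _ in self.mapping)


def _atoms_compatible(a: Atom, b: Atom) -> bool:
    return a.element == b.element and a.aromatic == b.aromatic


def _bonds_compatible(a: Bond | None, b: Bond | None) -> bool:
    if (a is None) != (b is None):
        return False
    if a is None:
        return True
    if a.aromatic != b.aromatic:
        return False
    if not a.aromatic and a.order != b.order:
        return False
    return True


def common_substructures(
    ligand: Molecule, known: Pose, budget: SearchBudget | None = None
) -> list[SubstructureMatch]:
    """Connected common substructure matches of >=4 heavy atoms.

    Atom compatibility requires equal element and aromatic flag; bond
    compatibility requires equal aromatic flag and, for non-aromatic bonds,
    equal order; mapped atom pairs must agree on bond presence (induced
    matching).  Maximal matches are collected depth-first; matches with
    identical ligand atom sets, or whose ligand atom set is a subset of
    another match on the same known, are pruned.  The search stops early if
    the budget runs out (``budget.exhausted`` is then set).
    """
    if budget is None:
        budget = SearchBudget()
    lig_heavy = list(ligand.heavy_indices)
    kn_mol = known.molecule
    kn_heavy = list(kn_mol.heavy_indices)
    ladj = ligand.adjacency()
    kadj = kn_mol.adjacency()

    raw: dict[frozenset[int], dict[int, int]] = {}

    def emit(mapping: dict[int, int]) -> None:
        if len(mapping) < MIN_MATCH_ATOMS:
            return
        key = frozenset(mapping)
        if key not in raw:
            raw[key] = dict(mapping)

    def extend(mapping: dict[int, int], used_k: set[int], forbidden: set[int]) -> None:
        """Branch on the smallest frontier ligand atom: map it to each
        compatible known atom, or exclude it.  Each connected ligand atom
        set is thus visited at most once per root."""
        if not budget.tick():
            return
        frontier = [
            v
            for u in mapping
            for v in ladj[u]
            if v not in mapping and v not in forbidden and ligand.atoms[v].is_heavy
        ]
        if not frontier:
            emit(mapping)
            return
        v = min(frontier)
        for w in kn_heavy:
            if w in used_k or not _atoms_compatible(ligand.atoms[v], kn_mol.atoms[w]):
                continue
            ok = all(
                _bonds_compatible(ladj[v].get(u), kadj[w].get(x))
                for u, x in mapping.items()
            )
            # the known-side image must stay connected as well
            if ok and not any(kadj[w].get(x) is not None for x in mapping.values()):
                ok = False
            if ok:
                mapping[v] = w
                used_k.add(w)
                budget.record_size(len(mapping))
                extend(mapping, used_k, forbidden)
                del mapping[v]
                used_k.discard(w)
                if budget.exhausted:
                    return
        forbidden.add(v)
        extend(mapping, used_k, forbidden)
        forbidden.discard(v)

    for u in lig_heavy:
        # root each atom set at its minimum ligand atom: smaller atoms excluded
        root_forbidden = {a for a in lig_heavy if a < u}
        for w in kn_heavy:
            if _atoms_compatible(ligand.atoms[u], kn_mol.atoms[w]):
                extend({u: w}, {w}, set(root_forbidden))
                if budget.exhausted:
                    break
        if budget.exhausted:
            break

    # prune subsets (per known molecule)
    keys = sorted(raw, key=len, reverse=True)
    kept: list[frozenset[int]] = []
    for key in keys:
        if not any(key < other for other in kept):
            kept.append(key)

    matches = []
    for key in sorted(kept, key=lambda k: (-len(k), sorted(k))):
        mapping = raw[key]
        matches.append(_build_match(ligand, known, mapping))
    return matches


def _build_match(ligand: Molecule, known: Pose, mapping: dict[int, int]) -> SubstructureMatch:
    lig_atoms = sorted(mapping)
    local = {a: i for i, a in enumerate(lig_atoms)}
    atoms = [ligand.atoms[a] for a in lig_atoms]
    bonds = []
    ladj = ligand.adjacency()
    for i, a in enumerate(lig_atoms):
        for b, bond in ladj[a].items():
            if b in local and a < b:
                bonds.append(Bond(local[a], local[b], bond.order, bond.aromatic))
    frag_mol = Molecule(atoms, bonds, f"{known.molecule.name}:frag{len(lig_atoms)}")
    coords = np.array([known.coords[mapping[a]] for a in lig_atoms])
    frag = Pose(frag_mol, coords)
    return SubstructureMatch(
        known_id=known.molecule.name,
        mapping=[(a, mapping[a]) for a in lig_atoms],
        fragment=frag,
    )


def extract_hints(
    ligand: Molecule,
    knowns: list[Pose],
    max_hints: int = DEFAULT_MAX_HINTS,
    recurrence_limit: int = DEFAULT_RECURRENCE_LIMIT,
) -> list[SubstructureMatch]:
    """Ranked hint fragments mined from all known bound poses.

    Matches from every known are pooled, scored by 2D similarity of the
    fragment graph to the whole ligand, sorted (similarity desc, size desc,
    known id asc) and truncated at ``max_hints``.  An empty known set
    yields an empty result.
    """
    lig_keys = enumerate_subgraphs(ligand)
    pooled: list[SubstructureMatch] = []
    for known in knowns:
        budget = SearchBudget(recurrence_limit=recurrence_limit)
        for match in common_substructures(ligand, known, budget):
            match.gsim_to_whole = gsim(
                enumerate_subgraphs(match.fragment.molecule), lig_keys
            )
            pooled.append(match)
    pooled.sort(
        key=lambda m: (
            -m.gsim_to_whole,
            -m.size,
            m.known_id,
            sorted(m.ligand_atoms),
        )
    )
    return pooled[:max_hints]
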