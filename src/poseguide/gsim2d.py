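"""2D graph similarity from rooted subgraphs (GSIM).

A molecule is summarised as a multiset of canonical keys, one per heavy
atom and per neighbourhood radius 0..``max_depth``: the key encodes the
induced subgraph ("ball") of all heavy atoms within that graph distance of
the root, with the root marked.  Similarity between two molecules is the
weighted fraction of keys shared in both directions, with keys rooted at
heteroatoms up-weighted, normalised to [0, 1] so that self-similarity is
exactly 1.

This similarity drives the ranking of substructural hints and the ligand
novelty analyses; it is deliberately insensitive to 3D geometry.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx

from poseguide.chemcore import Molecule

DEFAULT_DEPTH = 3
DEFAULT_HETERO_WEIGHT = 2.0


@dataclass(frozen=True)
class SubgraphKey:
    """Canonical encoding of a rooted neighbourhood ball."""

    encoding: str
    root_is_heteroatom: bool
    depth: int


def _ball_key(g: nx.Graph, root: int, members: frozenset[int], depth: int) -> str:
    sub = g.subgraph(members).copy()
    for node in sub.nodes:
        sub.nodes[node]["label"] = repr(
            (sub.nodes[node]["type"], node == root)
        )
    for u, v in sub.edges:
        sub.edges[u, v]["label"] = repr(sub.edges[u, v]["type"])
    return nx.weisfeiler_lehman_graph_hash(
        sub, edge_attr="label", node_attr="label", iterations=max(3, depth + 1)
    )


def enumerate_subgraphs(mol: Molecule, max_depth: int = DEFAULT_DEPTH) -> Counter:
    """Multiset of canonical rooted-ball keys for every heavy atom.

    For each root, one key per radius 0..``max_depth``; a radius whose ball
    equals the previous radius' ball (the neighbourhood is exhausted) emits
    no further key for that root.
    """
    g = mol.heavy_graph()
    if g.number_of_nodes() == 0:
        raise ValueError("molecule has no heavy atoms")
    keys: Counter = Counter()
    for root in g.nodes:
        lengths = nx.single_source_shortest_path_length(g, root, cutoff=max_depth)
        prev_members: frozenset[int] | None = None
        for depth in range(max_depth + 1):
            members = frozenset(n for n, d in lengths.items() if d <= depth)
            if members == prev_members:
                break
            prev_members = members
            keys[
                SubgraphKey(
                    _ball_key(g, root, members, depth),
                    mol.atoms[root].is_hetero,
                    depth,
                )
            ] += 1
    return keys


def _weight(key: SubgraphKey, hetero_weight: float) -> float:
    return hetero_weight if key.root_is_heteroatom else 1.0


def gsim(
    a: Molecule | Counter,
    b: Molecule | Counter,
    max_depth: int = DEFAULT_DEPTH,
    hetero_weight: float = DEFAULT_HETERO_WEIGHT,
) -> float:
    """Bidirectional weighted rooted-subgraph similarity in [0, 1].

    ``(w-matched A->B + w-matched B->A) / (w-total A + w-total B)``, where
    matching is multiset intersection of canonical keys and keys rooted at
    non-carbon heavy atoms carry ``hetero_weight``.  Symmetric, equal to 1
    for identical graphs.  Precomputed key multisets may be passed directly
    in place of molecules.
    """
    ka = a if isinstance(a, Counter) else enumerate_subgraphs(a, max_depth)
    kb = b if isinstance(b, Counter) else enumerate_subgraphs(b, max_depth)
    matched = sum(
        min(ca, kb[key]) * _weight(key, hetero_weight)
        for key, ca in ka.items()
        if key in kb
    )
    total = sum(c * _weight(k, hetero_weight) for k, c in ka.items()) + sum(
        c * _weight(k, hetero_weight) for k, c in kb.items()
    )
    if total == 0:
        return 0.0
    return 2.0 * matched / total
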