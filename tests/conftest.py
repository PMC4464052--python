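"""Shared molecule/pose builders for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from poseguide.chemcore import Atom, Bond, Molecule, Pose


def chain(elements: str, name: str = "") -> Molecule:
    """Linear single-bonded heavy-atom chain, e.g. chain('CCO') = ethanol
    heavy skeleton."""
    return Molecule(
        [Atom(e) for e in elements],
        [Bond(i, i + 1) for i in range(len(elements) - 1)],
        name or elements,
    )


def chain_pose(elements: str, spacing: float = 1.5, score=None) -> Pose:
    mol = chain(elements)
    coords = np.zeros((len(elements), 3))
    coords[:, 0] = spacing * np.arange(len(elements))
    return Pose(mol, coords, score)


def hexagon_coords(radius: float = 1.39) -> np.ndarray:
    ang = 2 * math.pi * np.arange(6) / 6
    return np.stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)], axis=1)


@pytest.fixture
def benzene() -> Molecule:
    return Molecule(
        [Atom("C", aromatic=True) for _ in range(6)],
        [Bond(i, (i + 1) % 6, 1, True) for i in range(6)],
        "benzene",
    )


@pytest.fixture
def benzene_pose(benzene) -> Pose:
    return Pose(benzene, hexagon_coords())


def ring_with_substituent(element: str, name: str = "") -> tuple[Molecule, np.ndarray]:
    """Aromatic 6-ring with one exocyclic single-bonded atom (toluene for
    'C', phenol heavy skeleton for 'O')."""
    atoms = [Atom("C", aromatic=True) for _ in range(6)] + [Atom(element)]
    bonds = [Bond(i, (i + 1) % 6, 1, True) for i in range(6)] + [Bond(0, 6)]
    coords = np.vstack([hexagon_coords(), [[2.87, 0.0, 0.0]]])
    return Molecule(atoms, bonds, name or f"ring-{element}"), coords
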