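"""In-frame 3D molecular similarity (shape + polar features).

Poses already placed in a common binding-site frame are compared by
Gaussian overlap of (a) per-heavy-atom shape densities with widths tied to
van der Waals radii and (b) typed polar points (hydrogen-bond donor,
acceptor, positive, negative) of fixed 1 Å width, matched within type
only.  The raw overlap is normalised by the geometric mean of the
self-overlaps, so the score lies in [0, 1], equals 1 for a pose compared
with itself, is symmetric, is invariant under a common rigid transform of
both poses, and vanishes as the poses separate.  No mutual alignment or
conformer search is performed.

The functional form is an openly documented surrogate for proprietary
shape/electrostatic similarity functions: the downstream rescoring
mathematics only requires a bounded, normalised, frame-aware similarity,
which this satisfies by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from poseguide.chemcore import Molecule, Pose

_PT = Chem.GetPeriodicTable()

#: shape Gaussian decay: two identical atoms separated by twice the vdW
#: radius overlap at ~1% of their self-overlap -> alpha = ln(100) / (2 r^2)
_SHAPE_LN = math.log(100.0) / 2.0
#: polar point Gaussian width (Å)
POLAR_SIGMA = 1.0
#: relative weight of shape vs polar overlap
SHAPE_WEIGHT = 2.0
POLAR_WEIGHT = 1.0

#: default valences used to infer implicit hydrogens on N/O donors
_DEFAULT_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3, "F": 1, "Cl": 1, "Br": 1, "I": 1}

POLAR_TYPES = ("donor", "acceptor", "positive", "negative")


@dataclass
class FeatureSet:
    """Shape centres (positions + vdW radii) and typed polar points."""

    shape_centers: np.ndarray  # (n, 3)
    shape_radii: np.ndarray  # (n,)
    polar_points: dict[str, np.ndarray] = field(default_factory=dict)  # type -> (k, 3)


def _implicit_hydrogens(mol: Molecule, idx: int) -> int:
    a = mol.atoms[idx]
    val = _DEFAULT_VALENCE.get(a.element)
    if val is None:
        return 0
    adj = mol.adjacency()[idx]
    order_sum = sum(1.5 if b.aromatic else b.order for b in adj.values())
    return max(0, int(round(val + a.formal_charge - order_sum)))


def features(pose: Pose) -> FeatureSet:
    """Deterministic feature extraction from graph plus geometry.

    Donors are N/O bearing at least one hydrogen (explicit neighbour or
    inferred from valence); acceptors are neutral-or-anionic N/O; charge
    features come from formal charges on heavy atoms.
    """
    mol = pose.molecule
    heavy = list(mol.heavy_indices)
    centers = pose.coords[heavy]
    radii = np.array([_PT.GetRvdw(mol.atoms[i].element) for i in heavy])
    adj = mol.adjacency()
    polar: dict[str, list[np.ndarray]] = {t: [] for t in POLAR_TYPES}
    for i in heavy:
        a = mol.atoms[i]
        xyz = pose.coords[i]
        if a.formal_charge > 0:
            polar["positive"].append(xyz)
        elif a.formal_charge < 0:
            polar["negative"].append(xyz)
        if a.element in ("N", "O"):
            n_h = sum(1 for j in adj[i] if mol.atoms[j].element == "H")
            n_h += _implicit_hydrogens(mol, i)
            if n_h > 0 and a.formal_charge >= 0:
                polar["donor"].append(xyz)
            if a.formal_charge <= 0:
                polar["acceptor"].append(xyz)
    return FeatureSet(
        shape_centers=centers,
        shape_radii=radii,
        polar_points={t: np.array(p) for t, p in polar.items() if p},
    )


def _gaussian_overlap(xa, alpha_a, xb, alpha_b) -> float:
    """Sum over pairs of the closed-form product-Gaussian integral."""
    d2 = ((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=2)
    asum = alpha_a[:, None] + alpha_b[None, :]
    pref = (math.pi / asum) ** 1.5
    expo = np.exp(-(alpha_a[:, None] * alpha_b[None, :] / asum) * d2)
    return float((pref * expo).sum())


def _overlap(fa: FeatureSet, fb: FeatureSet) -> float:
    alpha_a = _SHAPE_LN / fa.shape_radii**2
    alpha_b = _SHAPE_LN / fb.shape_radii**2
    total = SHAPE_WEIGHT * _gaussian_overlap(
        fa.shape_centers, alpha_a, fb.shape_centers, alpha_b
    )
    alpha_p = 1.0 / (2.0 * POLAR_SIGMA**2)
    for t in POLAR_TYPES:
        pa = fa.polar_points.get(t)
        pb = fb.polar_points.get(t)
        if pa is not None and pb is not None:
            total += POLAR_WEIGHT * _gaussian_overlap(
                pa, np.full(len(pa), alpha_p), pb, np.full(len(pb), alpha_p)
            )
    return total


def sim3d(a: Pose | FeatureSet, b: Pose | FeatureSet) -> float:
    """Normalised 3D similarity in [0, 1] between poses in one frame.

    ``O(a,b) / sqrt(O(a,a) * O(b,b))`` with ``O`` the weighted Gaussian
    overlap; precomputed :class:`FeatureSet` objects are accepted in place
    of poses.
    """
    fa = a if isinstance(a, FeatureSet) else features(a)
    fb = b if isinstance(b, FeatureSet) else features(b)
    oab = _overlap(fa, fb)
    oaa = _overlap(fa, fa)
    obb = _overlap(fb, fb)
    if oaa <= 0 or obb <= 0:
        return 0.0
    return min(1.0, oab / math.sqrt(oaa * obb))


def similarity_matrix(poses_a: list[Pose], poses_b: list[Pose]) -> np.ndarray:
    """n x m matrix of pairwise similarities (features cached per pose)."""
    fas = [features(p) for p in poses_a]
    fbs = [features(p) for p in poses_b]
    self_a = np.array([_overlap(f, f) for f in fas])
    self_b = np.array([_overlap(f, f) for f in fbs])
    out = np.empty((len(fas), len(fbs)))
    for i, fa in enumerate(fas):
        for j, fb in enumerate(fbs):
            norm = math.sqrt(self_a[i] * self_b[j])
            out[i, j] = min(1.0, _overlap(fa, fb) / norm) if norm > 0 else 0.0
    return out
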