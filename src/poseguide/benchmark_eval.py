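"""Benchmark curation, docking-success evaluation, and statistics.

Implements the curation filters used to build temporally partitioned
cross-docking benchmarks from liganded complex records (element whitelist,
molecular weight, protein contact, buriedness), the earliest-25% temporal
split, the ligand centroid sanity filter, per-ligand pose-family
evaluation with symmetry-corrected RMSD and success-at-top-k,
cumulative-histogram summaries, novelty fractions, and the two statistical
comparisons used to report results (two-sample Kolmogorov–Smirnov and the
exact binomial test).
"""

from __future__ import annotations

import datetime as _dt
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from scipy import stats as _stats

from poseguide.chemcore import Pose, SymmetryOps, symmetry_rmsd
from poseguide.knowledge_rescoring import PoseFamily

_PT = Chem.GetPeriodicTable()

#: elements permitted in benchmark ligands
ELEMENT_WHITELIST = frozenset("H C N O S P F Cl Br I".split())
MAX_MOLECULAR_WEIGHT = 1000.0
#: at least this many ligand heavy atoms must touch the protein...
MIN_CONTACT_ATOMS = 3
#: ...within this vdW surface-to-surface distance (Å)
CONTACT_SURFACE_DIST = 1.0
#: buriedness: protein atoms within this centre-to-centre shell (Å)
BURIEDNESS_SHELL = 4.0
#: ...divided by ligand heavy atoms must reach this ratio
BURIEDNESS_RATIO = 0.3

TOP_K_LEVELS = (1, 2, 5, 10, None)  # None = all families


@dataclass
class ComplexRecord:
    """One liganded complex: id, deposition date, ligand pose, and the
    protein contact shell (positions + elements)."""

    id: str
    deposition_date: str  # ISO date
    ligand: Pose
    protein_positions: np.ndarray | None = None  # (p, 3)
    protein_elements: list[str] | None = None

    def date(self) -> _dt.date:
        try:
            return _dt.date.fromisoformat(self.deposition_date)
        except ValueError as exc:
            raise ValueError(
                f"record {self.id}: unparseable date {self.deposition_date!r}"
            ) from exc


@dataclass
class FilterResult:
    passed: bool
    reasons: list[str]  # names of failed rules
    evaluated: list[str]  # rules actually evaluated


def ligand_passes_filters(
    rec: ComplexRecord,
    max_weight: float = MAX_MOLECULAR_WEIGHT,
    min_contacts: int = MIN_CONTACT_ATOMS,
    contact_dist: float = CONTACT_SURFACE_DIST,
    buriedness_shell: float = BURIEDNESS_SHELL,
    buriedness_ratio: float = BURIEDNESS_RATIO,
) -> FilterResult:
    """Four independent curation rules; any failure rejects the record.

    ``element``: all atoms drawn from the H/C/N/O/S/P/halogen whitelist;
    ``weight``: molecular weight below 1000; ``contacts``: at least three
    ligand heavy atoms within 1 Å vdW surface-to-surface distance of the
    protein; ``buriedness``: nearby-protein-atom to ligand-heavy-atom
    ratio at least the threshold.  Without a protein shell only the two
    ligand-intrinsic rules are evaluated (flagged via ``evaluated``).
    """
    mol = rec.ligand.molecule
    failed: list[str] = []
    evaluated = ["element", "weight"]
    if any(a.element not in ELEMENT_WHITELIST for a in mol.atoms):
        failed.append("element")
    if mol.molecular_weight() >= max_weight:
        failed.append("weight")
    if rec.protein_positions is not None and len(rec.protein_positions):
        evaluated += ["contacts", "buriedness"]
        lig_xyz = rec.ligand.heavy_coords
        lig_r = np.array(
            [_PT.GetRvdw(mol.atoms[i].element) for i in mol.heavy_indices]
        )
        prot_xyz = np.asarray(rec.protein_positions, float)
        prot_r = np.array([_PT.GetRvdw(e) for e in rec.protein_elements])
        d = np.linalg.norm(lig_xyz[:, None, :] - prot_xyz[None, :, :], axis=2)
        surface = d - lig_r[:, None] - prot_r[None, :]
        n_contact = int((surface.min(axis=1) < contact_dist).sum())
        if n_contact < min_contacts:
            failed.append("contacts")
        nearby = int((d.min(axis=0) <= buriedness_shell).sum())
        if nearby / len(lig_xyz) < buriedness_ratio:
            failed.append("buriedness")
    else:
        warnings.warn(
            f"record {rec.id}: no protein shell; contact/buriedness rules skipped"
        )
    return FilterResult(passed=not failed, reasons=failed, evaluated=evaluated)


def temporal_split(
    records: list[ComplexRecord], early_fraction: float = 0.25
) -> tuple[list[ComplexRecord], list[ComplexRecord]]:
    """Partition by deposition date: earliest ceil(fraction*N) records form
    the known ('early') set, the rest the test set.  Date ties broken by id.
    """
    if len(records) < 4:
        raise ValueError("need at least 4 records for a temporal split")
    ordered = sorted(records, key=lambda r: (r.date(), r.id))
    n_early = math.ceil(early_fraction * len(ordered))
    return ordered[:n_early], ordered[n_early:]


def centroid_filter(ligands: list[Pose], max_dist: float = 10.0) -> list[Pose]:
    """Drop ligands whose heavy-atom centroid deviates by more than
    ``max_dist`` from the centroid of all ligand centroids (closed
    threshold: exactly ``max_dist`` is retained)."""
    if not ligands:
        return []
    centroids = np.array([p.centroid() for p in ligands])
    overall = centroids.mean(axis=0)
    dev = np.linalg.norm(centroids - overall, axis=1)
    return [p for p, d in zip(ligands, dev) if d <= max_dist]


@dataclass
class EvalRecord:
    """Per-ligand evaluation: family RMSDs in rank order and best-at-top-k."""

    ligand_id: str
    family_rmsds: list[float]  # min member RMSD per family, by family rank
    best_at_top_k: dict[int | None, float] = field(default_factory=dict)


def evaluate(
    families_per_ligand: dict[str, list[PoseFamily]],
    poses_per_ligand: dict[str, list[Pose]],
    references: dict[str, Pose | list[Pose]],
    site_ops: SymmetryOps | None = None,
) -> list[EvalRecord]:
    """Per family, the minimum symmetry-corrected RMSD over member poses to
    the reference (minimum over reference alternates when several are
    given); best-at-top-k for k in {1, 2, 5, 10, all}."""
    out = []
    for lig_id, families in families_per_ligand.items():
        poses = poses_per_ligand[lig_id]
        refs = references[lig_id]
        if isinstance(refs, Pose):
            refs = [refs]
        fam_rmsds = []
        for fam in families:
            rmsd = min(
                symmetry_rmsd(poses[i], ref, site_ops)
                for i in fam.member_poses
                for ref in refs
            )
            fam.min_rmsd_to_ref = rmsd
            fam_rmsds.append(rmsd)
        best = {}
        for k in TOP_K_LEVELS:
            top = fam_rmsds if k is None else fam_rmsds[:k]
            best[k] = min(top) if top else math.inf
        out.append(EvalRecord(ligand_id=lig_id, family_rmsds=fam_rmsds, best_at_top_k=best))
    return out


def success_rate(
    records: list[EvalRecord], k: int | None = 1, threshold: float = 2.0
) -> float:
    """Fraction of ligands whose best family among the top k is within the
    RMSD threshold."""
    if not records:
        raise ValueError("no evaluation records")
    hits = sum(1 for r in records if r.best_at_top_k[k] <= threshold)
    return hits / len(records)


def cumulative_histogram(values, edges) -> np.ndarray:
    """Cumulative proportion of values <= each edge (non-decreasing,
    reaching 1.0 once the largest value is passed)."""
    values = np.asarray(list(values), float)
    if values.size == 0:
        raise ValueError("no values to histogram")
    edges = np.asarray(list(edges), float)
    return np.array([(values <= e).mean() for e in edges])


def novelty_fraction(test_items, knowns, similarity, threshold: float) -> float:
    """Fraction of test items whose *maximal* similarity to the knowns is
    strictly below the threshold.  With no knowns every item is novel
    (flagged with a warning)."""
    test_items = list(test_items)
    if not test_items:
        raise ValueError("no test items")
    if not knowns:
        warnings.warn("no known items: novelty fraction is vacuously 1.0")
        return 1.0
    novel = sum(
        1 for t in test_items if max(similarity(t, k) for k in knowns) < threshold
    )
    return novel / len(test_items)


def ks_compare(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov D statistic and asymptotic p-value."""
    res = _stats.ks_2samp(np.asarray(list(a), float), np.asarray(list(b), float),
                          method="asymp")
    return float(res.statistic), float(res.pvalue)


def exact_binomial(successes: int, n: int, p0: float) -> float:
    """Exact two-sided binomial test p-value for ``successes`` of ``n``
    trials against success probability ``p0``."""
    return float(_stats.binomtest(successes, n, p0, alternative="two-sided").pvalue)


def write_eval_report(records: list[EvalRecord], path) -> None:
    """JSON export of per-ligand family RMSDs and top-k summaries."""
    payload = [
        {
            "ligand_id": r.ligand_id,
            "family_rmsds": r.family_rmsds,
            "best_at_top_k": {
                ("all" if k is None else str(k)): (None if math.isinf(v) else v)
                for k, v in r.best_at_top_k.items()
            },
        }
        for r in records
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
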