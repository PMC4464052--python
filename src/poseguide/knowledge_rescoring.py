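"""Similarity-to-probability pose rescoring and Boltzmann pose families.

Given n candidate docked poses of a ligand and the bound poses of m
previously solved ligands in the same site frame, the full n x m table of
3D similarities is summarised by its mean mu and standard deviation sigma.
For pose i with mean similarity s_i to the knowns, the mean of m draws has
standard error sigma' = sigma / sqrt(m), and the upper-tail probability

    p_i = 1 - (1/2) * (1 + erf((s_i - mu) / (sigma' * sqrt(2))))

measures how unusually native-like the pose is relative to the pool.  The
statistical-potential analogy (an observed-to-reference likelihood ratio
mapped to an energy) converts this into a score adjustment; on the pKd
scale, with RT*ln(10) identified with one pKd unit, the adjustment is the
positive bonus

    w_i = log10(1 / p_i),

added to the docking score.  Probabilities are floored at 1e-6, capping
the bonus at 6 pKd.  A pose much less native-like than the pool gets
p ~ 1 and a correction near zero; an unusually native-like pose gets a
small p and a large favourable correction.

Rescored poses are grouped into pose families by greedy leader clustering
on symmetry-corrected RMSD, and families are ranked by normalised
Boltzmann weights 10^(score difference), interpreted as the probability
that the experimentally observed binding mode falls within the family.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from poseguide.chemcore import Pose, SymmetryOps, symmetry_rmsd
from poseguide.sim3d import similarity_matrix

PROBABILITY_FLOOR = 1e-6
MAX_ADJUSTMENT = -math.log10(PROBABILITY_FLOOR)  # 6 pKd
DEFAULT_FAMILY_RMSD = 2.0


@dataclass
class SimilarityStats:
    """Moments of the n x m pose-to-known similarity table."""

    mu: float
    sigma: float
    m: int
    n: int

    @property
    def sigma_prime(self) -> float:
        """Standard error of a mean of m similarities: sigma / sqrt(m)."""
        return self.sigma / math.sqrt(self.m)


@dataclass
class PoseCorrection:
    """Per-pose rescoring record."""

    s_i: float
    p_i: float
    w_i: float
    score: float
    adjusted_score: float


@dataclass
class PoseFamily:
    """RMSD-clustered group of poses with a normalised probability score."""

    member_poses: list[int]
    representative: int
    probability: float
    representative_score: float
    min_rmsd_to_ref: float | None = None


def similarity_stats(poses: list[Pose], knowns: list[Pose]) -> SimilarityStats:
    """Mean and (population) SD of all n x m pairwise 3D similarities."""
    n, m = len(poses), len(knowns)
    if m < 1:
        raise ValueError("need at least one known bound pose")
    if n < 2:
        raise ValueError(
            "need at least two candidate poses to estimate the similarity "
            "distribution; skip the correction (w_i = 0) instead"
        )
    table = similarity_matrix(poses, knowns)
    return SimilarityStats(
        mu=float(table.mean()), sigma=float(table.std(ddof=0)), m=m, n=n
    )


def pose_probability(s_i: float, stats: SimilarityStats) -> float:
    """Upper-tail probability of observing mean similarity >= s_i.

    Floored at 1e-6.  A degenerate pool (sigma' = 0) yields 0.5 at the
    mean and a step to the floor/1 on either side.
    """
    sp = stats.sigma_prime
    if sp <= 0:
        if s_i == stats.mu:
            return 0.5
        return PROBABILITY_FLOOR if s_i > stats.mu else 1.0
    z = (s_i - stats.mu) / (sp * math.sqrt(2.0))
    p = 1.0 - 0.5 * (1.0 + math.erf(z))
    return max(p, PROBABILITY_FLOOR)


def score_adjustment(p_i: float) -> float:
    """Score bonus w_i = log10(1/p_i) in pKd units, in [0, 6]."""
    if p_i < PROBABILITY_FLOOR:
        warnings.warn(
            f"probability {p_i:g} below floor {PROBABILITY_FLOOR:g}; clamped"
        )
        p_i = PROBABILITY_FLOOR
    if p_i > 1.0:
        raise ValueError(f"probability {p_i} > 1")
    return math.log10(1.0 / p_i)


def rescore(poses: list[Pose], knowns: list[Pose]) -> list[PoseCorrection]:
    """One :class:`PoseCorrection` per pose; unguided identity when no knowns.

    With an empty known set, or with too few poses to estimate the
    similarity distribution, adjusted scores equal the input scores.
    """
    scores = []
    for i, p in enumerate(poses):
        if p.score is None:
            raise ValueError(f"pose {i} has no docking score")
        scores.append(float(p.score))
    if not knowns or len(poses) < 2:
        return [
            PoseCorrection(s_i=math.nan, p_i=1.0, w_i=0.0, score=s, adjusted_score=s)
            for s in scores
        ]
    stats = similarity_stats(poses, knowns)
    table = similarity_matrix(poses, knowns)
    out = []
    for i, s in enumerate(scores):
        s_i = float(table[i].mean())
        p_i = pose_probability(s_i, stats)
        w_i = score_adjustment(p_i)
        out.append(
            PoseCorrection(
                s_i=s_i, p_i=p_i, w_i=w_i, score=s, adjusted_score=s + w_i
            )
        )
    return out


def build_pose_families(
    poses: list[Pose],
    adjusted_scores: list[float] | np.ndarray,
    rmsd_threshold: float = DEFAULT_FAMILY_RMSD,
    site_ops: SymmetryOps | None = None,
) -> list[PoseFamily]:
    """Greedy leader clustering into Boltzmann-ranked pose families.

    Poses are visited in order of descending adjusted score; each joins the
    first existing family whose representative (leader) lies within
    ``rmsd_threshold`` symmetry-corrected RMSD, else founds a new family.
    Family weight is ``10^(representative score - best score)``; the
    normalised weights sum to 1 and are reported as family probabilities.
    """
    if len(poses) == 0:
        return []
    adjusted = np.asarray(adjusted_scores, dtype=float)
    if adjusted.shape != (len(poses),):
        raise ValueError("one adjusted score per pose required")
    # all poses share one graph: enumerate automorphisms once
    from poseguide.chemcore import enumerate_automorphisms

    if site_ops is None or site_ops.automorphisms is None:
        autos = enumerate_automorphisms(poses[0].molecule)
        site_ops = SymmetryOps(autos, site_ops.site_ops if site_ops else [])
    order = sorted(range(len(poses)), key=lambda i: (-adjusted[i], i))
    leaders: list[int] = []
    members: list[list[int]] = []
    for i in order:
        placed = False
        for fam, leader in enumerate(leaders):
            if symmetry_rmsd(poses[i], poses[leader], site_ops) <= rmsd_threshold:
                members[fam].append(i)
                placed = True
                break
        if not placed:
            leaders.append(i)
            members.append([i])
    best = adjusted[leaders[0]]
    weights = np.array([10.0 ** (adjusted[l] - best) for l in leaders])
    probs = weights / weights.sum()
    fams = [
        PoseFamily(
            member_poses=mem,
            representative=leader,
            probability=float(p),
            representative_score=float(adjusted[leader]),
        )
        for leader, mem, p in zip(leaders, members, probs)
    ]
    fams.sort(key=lambda f: -f.probability)
    return fams


def rescore_and_rank(
    poses: list[Pose],
    knowns: list[Pose],
    rmsd_threshold: float = DEFAULT_FAMILY_RMSD,
    site_ops: SymmetryOps | None = None,
) -> tuple[list[PoseCorrection], list[PoseFamily]]:
    """Full pipeline: rescore against knowns, then build ranked families."""
    corrections = rescore(poses, knowns)
    families = build_pose_families(
        poses,
        [c.adjusted_score for c in corrections],
        rmsd_threshold=rmsd_threshold,
        site_ops=site_ops,
    )
    return corrections, families
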