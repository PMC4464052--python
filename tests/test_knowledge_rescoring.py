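"""Similarity statistics, probability mapping, rescoring, pose families."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from poseguide.chemcore import Pose
from poseguide.knowledge_rescoring import (
    PROBABILITY_FLOOR,
    SimilarityStats,
    build_pose_families,
    pose_probability,
    rescore,
    rescore_and_rank,
    score_adjustment,
    similarity_stats,
)
from tests.conftest import chain, chain_pose


def _shifted(base: Pose, dx: float, score=None) -> Pose:
    return Pose(base.molecule, base.coords + [dx, 0.0, 0.0], score)


class TestSimilarityStats:
    def test_degenerate_equal_similarities(self):
        base = chain_pose("CCO")
        poses = [_shifted(base, 0.0), _shifted(base, 0.0)]
        stats = similarity_stats(poses, [base])
        assert stats.mu == pytest.approx(1.0)
        assert stats.sigma == pytest.approx(0.0)

    def test_sigma_prime_equals_sigma_for_single_known(self):
        base = chain_pose("CCO")
        poses = [_shifted(base, d) for d in (0.0, 1.0, 3.0)]
        stats = similarity_stats(poses, [base])
        assert stats.m == 1
        assert stats.sigma_prime == stats.sigma

    def test_moments_match_direct_summation(self):
        base = chain_pose("CCO")
        poses = [_shifted(base, d) for d in (0.0, 0.7, 2.5)]
        knowns = [_shifted(base, d) for d in (0.1, 4.0)]
        stats = similarity_stats(poses, knowns)
        from poseguide.sim3d import sim3d

        table = [[sim3d(p, k) for k in knowns] for p in poses]
        flat = [v for row in table for v in row]
        mu = sum(flat) / len(flat)
        var = sum((v - mu) ** 2 for v in flat) / len(flat)
        assert stats.mu == pytest.approx(mu, abs=1e-12)
        assert stats.sigma == pytest.approx(math.sqrt(var), abs=1e-12)
        assert stats.sigma_prime == pytest.approx(stats.sigma / math.sqrt(2), abs=1e-15)

    def test_single_pose_is_an_error(self):
        base = chain_pose("CCO")
        with pytest.raises(ValueError, match="skip the correction"):
            similarity_stats([base], [base])


class TestProbabilityAndAdjustment:
    def test_probability_half_at_the_mean(self):
        stats = SimilarityStats(mu=0.4, sigma=0.2, m=3, n=10)
        assert pose_probability(0.4, stats) == 0.5

    @pytest.mark.parametrize("z", [-3.0, -1.0, 0.5, 2.0, 3.5])
    def test_matches_normal_upper_tail(self, z):
        stats = SimilarityStats(mu=0.5, sigma=0.1, m=4, n=50)
        s_i = stats.mu + z * stats.sigma_prime
        assert pose_probability(s_i, stats) == pytest.approx(
            sps.norm.sf(z), abs=1e-12
        )

    def test_floor_applied_for_extreme_similarity(self):
        stats = SimilarityStats(mu=0.5, sigma=0.01, m=9, n=50)
        assert pose_probability(0.99, stats) == PROBABILITY_FLOOR

    def test_strictly_decreasing_in_similarity(self):
        stats = SimilarityStats(mu=0.5, sigma=0.1, m=4, n=50)
        s_grid = np.linspace(0.3, 0.65, 30)
        p = [pose_probability(s, stats) for s in s_grid]
        assert all(a > b for a, b in zip(p, p[1:]))

    def test_degenerate_sigma_steps(self):
        stats = SimilarityStats(mu=0.5, sigma=0.0, m=4, n=10)
        assert pose_probability(0.5, stats) == 0.5
        assert pose_probability(0.6, stats) == PROBABILITY_FLOOR
        assert pose_probability(0.4, stats) == 1.0

    def test_adjustment_units(self):
        assert score_adjustment(1.0) == 0.0
        assert score_adjustment(1e-6) == pytest.approx(6.0)
        # the pKd magnitude of the published worked example
        assert score_adjustment(10 ** (-3.1)) == pytest.approx(3.1)

    def test_below_floor_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert score_adjustment(1e-9) == pytest.approx(6.0)


class TestRescore:
    def test_no_knowns_is_identity(self):
        base = chain_pose("CCO")
        poses = [_shifted(base, d, score=5.0 + d) for d in (0.0, 1.0, 2.0)]
        out = rescore(poses, [])
        assert [c.adjusted_score for c in out] == [c.score for c in out]
        assert all(c.w_i == 0.0 for c in out)

    def test_constant_similarity_preserves_ranking(self):
        base = chain_pose("CCO")
        # all poses identical geometry, different scores: equal s_i
        poses = [_shifted(base, 0.0, score=s) for s in (6.0, 5.0, 4.0)]
        out = rescore(poses, [base])
        order = np.argsort([-c.adjusted_score for c in out])
        assert list(order) == [0, 1, 2]

    def test_similarity_flip_promotes_native_like_pose(self):
        """A pose overlapping the knowns but scored 0.5 pKd below the
        decoys must outrank them after correction."""
        base = chain_pose("CCNO")
        natives = [_shifted(base, 0.05, score=6.0), _shifted(base, -0.05, score=6.0)]
        decoys = [_shifted(base, 8.0 + d, score=6.5) for d in (0.0, 0.3, 0.6)]
        poses = natives + decoys
        knowns = [_shifted(base, 0.0), _shifted(base, 0.1)]
        out = rescore(poses, knowns)
        best = max(range(len(poses)), key=lambda i: out[i].adjusted_score)
        assert best < len(natives)
        assert out[0].w_i > out[-1].w_i


class TestPoseFamilies:
    def test_single_pose_single_family(self):
        p = chain_pose("CCO", score=5.0)
        fams = build_pose_families([p], [5.0])
        assert len(fams) == 1
        assert fams[0].probability == pytest.approx(1.0)

    def test_equal_scores_split_evenly(self):
        base = chain_pose("CCO")
        poses = [_shifted(base, 0.0, 5.0), _shifted(base, 9.0, 5.0)]
        fams = build_pose_families(poses, [5.0, 5.0])
        assert [f.probability for f in fams] == pytest.approx([0.5, 0.5])

    def test_one_pkd_gap_gives_ten_to_one(self):
        base = chain_pose("CCO")
        poses = [_shifted(base, 0.0, 7.0), _shifted(base, 9.0, 6.0)]
        fams = build_pose_families(poses, [7.0, 6.0])
        assert fams[0].probability == pytest.approx(10 / 11)
        assert fams[1].probability == pytest.approx(1 / 11)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(17)
        base = chain_pose("CCNO")
        poses = [
            _shifted(base, float(rng.uniform(0, 20)), float(rng.uniform(4, 8)))
            for _ in range(40)
        ]
        fams = build_pose_families(poses, [p.score for p in poses])
        assert sum(f.probability for f in fams) == pytest.approx(1.0, abs=1e-9)
        probs = [f.probability for f in fams]
        assert probs == sorted(probs, reverse=True)

    def test_members_within_threshold_of_leader(self):
        base = chain_pose("CCO")
        poses = [_shifted(base, d, 5.0 - 0.01 * i) for i, d in enumerate((0, 0.5, 1.0, 9.0))]
        fams = build_pose_families(poses, [p.score for p in poses], rmsd_threshold=2.0)
        assert len(fams) == 2
        assert sorted(fams[0].member_poses) == [0, 1, 2]

    def test_families_partition_the_pool(self):
        base = chain_pose("CCO")
        poses = [_shifted(base, 3.0 * i, 5.0) for i in range(5)]
        fams = build_pose_families(poses, [5.0] * 5)
        seen = sorted(i for f in fams for i in f.member_poses)
        assert seen == list(range(5))

    def test_empty_pool_empty_result(self):
        assert build_pose_families([], []) == []

    def test_pipeline_runs_end_to_end(self):
        base = chain_pose("CCNO")
        poses = [_shifted(base, 0.1, 6.0), _shifted(base, 7.0, 6.4), _shifted(base, 7.2, 6.5)]
        corrections, fams = rescore_and_rank(poses, [base])
        assert len(corrections) == 3
        assert sum(f.probability for f in fams) == pytest.approx(1.0, abs=1e-9)
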