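"""Curation filters, temporal split, evaluation, and statistics."""

import datetime
import math

import numpy as np
import pytest
from scipy import stats as sps

from poseguide.benchmark_eval import (
    ComplexRecord,
    centroid_filter,
    cumulative_histogram,
    evaluate,
    exact_binomial,
    ks_compare,
    ligand_passes_filters,
    novelty_fraction,
    success_rate,
    temporal_split,
)
from poseguide.chemcore import Atom, Bond, Molecule, Pose
from poseguide.knowledge_rescoring import PoseFamily, build_pose_families
from tests.conftest import chain, chain_pose


def _record(
    rec_id="rec",
    date="2003-06-27",
    elements="CCO",
    with_protein=True,
    lig_offset=0.0,
):
    pose = chain_pose(elements)
    pose = Pose(pose.molecule, pose.coords + [0, 0, lig_offset])
    protein = None
    prot_el = None
    if with_protein:
        # a slab of carbon atoms right below the ligand
        xs, ys = np.meshgrid(np.linspace(-2, 5, 6), np.linspace(-2, 2, 4))
        protein = np.stack([xs.ravel(), ys.ravel(), np.full(xs.size, -3.3)], axis=1)
        prot_el = ["C"] * len(protein)
    return ComplexRecord(rec_id, date, pose, protein, prot_el)


class TestFilters:
    def test_clean_record_passes(self):
        res = ligand_passes_filters(_record())
        assert res.passed and res.reasons == []
        assert set(res.evaluated) == {"element", "weight", "contacts", "buriedness"}

    def test_selenium_fails_element_rule(self):
        rec = _record(elements="CCSe".replace("Se", "C"))  # baseline passes
        assert ligand_passes_filters(rec).passed
        bad = _record()
        bad.ligand = Pose(
            Molecule([Atom("C"), Atom("Se")], [Bond(0, 1)]), np.zeros((2, 3)) + [[0, 0, 0], [1.8, 0, 0]]
        )
        res = ligand_passes_filters(bad)
        assert not res.passed and "element" in res.reasons

    def test_heavy_ligand_fails_weight_rule(self):
        heavy = _record(elements="I" * 8 + "C")  # 8 iodines ~ MW 1027
        res = ligand_passes_filters(heavy)
        assert "weight" in res.reasons

    def test_floating_ligand_fails_contact_rule(self):
        res = ligand_passes_filters(_record(lig_offset=10.0))
        assert "contacts" in res.reasons

    def test_missing_protein_shell_skips_geometric_rules(self):
        with pytest.warns(UserWarning, match="skipped"):
            res = ligand_passes_filters(_record(with_protein=False))
        assert set(res.evaluated) == {"element", "weight"}


class TestTemporalSplit:
    def _records(self, n, start=2000):
        return [
            _record(rec_id=f"r{i:03d}", date=f"{start + i // 12}-{i % 12 + 1:02d}-01",
                    with_protein=False)
            for i in range(n)
        ]

    def test_forty_records_split_ten_thirty(self):
        early, test = temporal_split(self._records(40))
        assert (len(early), len(test)) == (10, 30)
        latest_early = max(r.date() for r in early)
        earliest_test = min(r.date() for r in test)
        assert latest_early <= earliest_test

    def test_ceiling_rule_on_169_records(self):
        early, test = temporal_split(self._records(169))
        assert (len(early), len(test)) == (math.ceil(0.25 * 169), 169 - 43)
        assert len(early) == 43

    def test_equal_dates_tie_break_by_id(self):
        recs = [
            _record(rec_id=f"r{i}", date="2001-01-01", with_protein=False)
            for i in (3, 1, 0, 2)
        ]
        early, test = temporal_split(recs, early_fraction=0.25)
        assert [r.id for r in early] == ["r0"]

    def test_unparseable_date_names_record(self):
        recs = self._records(4)
        recs[2].deposition_date = "not-a-date"
        with pytest.raises(ValueError, match="r002"):
            temporal_split(recs)

    def test_too_few_records(self):
        with pytest.raises(ValueError, match="at least 4"):
            temporal_split(self._records(3))


class TestCentroidFilter:
    def test_coincident_ligands_all_retained(self):
        ligs = [chain_pose("CCO") for _ in range(5)]
        assert len(centroid_filter(ligs)) == 5

    def test_planted_outlier_dropped(self):
        ligs = [chain_pose("CCO") for _ in range(5)]
        outlier = Pose(ligs[0].molecule, ligs[0].coords + [50.0, 0, 0])
        kept = centroid_filter(ligs + [outlier])
        assert all(p is not outlier for p in kept) and len(kept) == 5

    def test_boundary_exactly_at_threshold_retained(self):
        a = chain_pose("CCO")
        b = Pose(a.molecule, a.coords + [4.0, 0, 0])  # centroids 2.0 from mean
        assert len(centroid_filter([a, b], max_dist=2.0)) == 2


class TestEvaluate:
    def _setup(self):
        ref = chain_pose("CCO")
        near = Pose(ref.molecule, ref.coords + [0.3, 0, 0], 6.0)
        far = Pose(ref.molecule, ref.coords + [8.0, 0, 0], 7.0)
        poses = [far, near]
        fams = build_pose_families(poses, [7.0, 6.0])
        return ref, poses, fams

    def test_family_containing_reference_scores_zero(self):
        ref = chain_pose("CCO")
        poses = [Pose(ref.molecule, ref.coords, 5.0)]
        fams = build_pose_families(poses, [5.0])
        (rec,) = evaluate({"lig": fams}, {"lig": poses}, {"lig": ref})
        assert rec.best_at_top_k[1] == pytest.approx(0.0)

    def test_counting_success_rate(self):
        records = []
        for i, rmsd in enumerate((0.5, 1.0, 1.5, 3.0)):
            ref = chain_pose("CCO")
            pose = Pose(ref.molecule, ref.coords + [rmsd, 0, 0], 5.0)
            fams = build_pose_families([pose], [5.0])
            records += evaluate({f"l{i}": fams}, {f"l{i}": [pose]}, {f"l{i}": ref})
        assert success_rate(records, 1, threshold=2.0) == pytest.approx(0.75)

    def test_top_k_curve_matches_brute_force_over_pool(self):
        ref, poses, fams = self._setup()
        (rec,) = evaluate({"lig": fams}, {"lig": poses}, {"lig": ref})
        from poseguide.chemcore import symmetry_rmsd

        all_rmsds = [symmetry_rmsd(p, ref) for p in poses]
        assert rec.best_at_top_k[None] == pytest.approx(min(all_rmsds))
        ks = [1, 2, 5, 10]
        vals = [rec.best_at_top_k[k] for k in ks]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_reference_alternates_take_minimum(self):
        ref, poses, fams = self._setup()
        alt = Pose(ref.molecule, ref.coords + [8.0, 0, 0])
        (only_alt,) = evaluate({"lig": fams}, {"lig": poses}, {"lig": [alt]})
        (both,) = evaluate({"lig": fams}, {"lig": poses}, {"lig": [ref, alt]})
        assert both.best_at_top_k[1] <= only_alt.best_at_top_k[1]
        assert both.best_at_top_k[1] == pytest.approx(0.0)


class TestStatistics:
    def test_cumulative_histogram_counts(self):
        values = [0.4, 1.2, 1.4, 2.5, 6.0]
        out = cumulative_histogram(values, [0.5, 1.5, 2.0, 3.0, 10.0])
        assert out == pytest.approx([0.2, 0.6, 0.6, 0.8, 1.0])
        assert all(a <= b for a, b in zip(out, out[1:]))

    def test_value_below_first_edge(self):
        assert cumulative_histogram([0.1], [0.5, 1.0]) == pytest.approx([1.0, 1.0])

    def test_empty_values_error(self):
        with pytest.raises(ValueError, match="no values"):
            cumulative_histogram([], [1.0])

    def test_novelty_zero_when_all_known(self):
        items = ["a", "b"]
        sim = lambda x, y: 1.0 if x == y else 0.0
        assert novelty_fraction(items, items, sim, threshold=0.5) == 0.0

    def test_novelty_vacuous_without_knowns(self):
        with pytest.warns(UserWarning, match="vacuously"):
            assert novelty_fraction(["a"], [], lambda x, y: 0.0, 0.5) == 1.0

    def test_novelty_half_on_planted_fixture(self):
        knowns = [0.0, 1.0]
        items = [0.0, 1.0, 10.0, 20.0]
        sim = lambda x, y: 1.0 / (1.0 + abs(x - y))
        assert novelty_fraction(items, knowns, sim, threshold=0.5) == 0.5

    def test_ks_identical_samples(self):
        d, p = ks_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == pytest.approx(0.0)

    def test_ks_disjoint_supports(self):
        d, _ = ks_compare([0.0, 0.1, 0.2], [5.0, 5.1, 5.2])
        assert d == pytest.approx(1.0)

    def test_ks_matches_ecdf_difference_oracle(self):
        a = [0.2, 0.5, 1.1, 2.0]
        b = [0.4, 0.9, 1.5]
        d, _ = ks_compare(a, b)
        grid = sorted(a + b)
        ecdf = lambda xs, t: sum(1 for x in xs if x <= t) / len(xs)
        oracle = max(abs(ecdf(a, t) - ecdf(b, t)) for t in grid)
        assert d == pytest.approx(oracle)

    def test_binomial_null_consistent(self):
        assert exact_binomial(5, 10, 0.5) == pytest.approx(1.0)

    def test_binomial_zero_of_ten(self):
        # two-sided tail: 2 * (1/2)^10
        assert exact_binomial(0, 10, 0.5) == pytest.approx(2 / 1024)

    def test_binomial_monotone_in_deviation(self):
        ps = [exact_binomial(k, 20, 0.5) for k in range(10, 21)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))
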