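"""Abundance matrix, heuristic grouping, Bray-Curtis, NMDS, ANOSIM."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from pgsr.enterotypes import (
    SampleAbundanceMatrix,
    anosim,
    bray_curtis,
    build_abundance_matrix,
    heuristic_group,
    nmds,
)
from pgsr.phylogeny import DistanceMatrix
from pgsr.profiles import AlignmentHit
from pgsr.simulate import make_enterotype_cohort

from .oracles import exact_anosim_two_groups


def hit(query, pid=90.0, scov=0.8, e=1e-10):
    return AlignmentHit(query, "contig", pid, 500, e, 100.0, subject_coverage=scov)


class TestBuildAbundanceMatrix:
    def test_inclusive_thresholds_and_normalization(self):
        tables = {
            "s1": [
                hit("p1", pid=80.0, scov=0.50),  # exactly at both: counted
                hit("p1", pid=79.9, scov=0.80),  # identity fails
                hit("p1", pid=90.0, scov=0.49),  # coverage fails
                hit("p1", e=1.1e-5),             # e-value fails
            ],
            "s2": [hit("p2"), hit("p2")],
        }
        m = build_abundance_matrix(tables, {"s1": 2.0, "s2": 1.0}, ["p1", "p2"])
        assert m.values[0, 0] == pytest.approx(0.5)  # 1 hit / 2 Mb
        assert m.values[1, 1] == pytest.approx(2.0)

    def test_incidence_percentage(self):
        tables = {f"s{i}": [hit("p1")] for i in range(6)}
        tables.update({f"s{i}": [] for i in range(6, 10)})
        m = build_abundance_matrix(tables, {f"s{i}": 1.0 for i in range(10)}, ["p1"])
        assert m.incidence[0] == pytest.approx(60.0)

    def test_scaffold_rows_merge_additively(self):
        tables = {"s1": [hit("p1"), hit("p1"), hit("p2")]}
        m = build_abundance_matrix(
            tables, {"s1": 2.0}, ["p1", "p2", "p3"],
            scaffold_groups={"scaf1": frozenset({"p1", "p2"})},
        )
        assert m.phage_ids == ("scaf1", "p3")
        assert m.values[0, 0] == pytest.approx(1.5)

    def test_missing_sample_warns_with_zero_column(self):
        with pytest.warns(UserWarning, match="no hit table"):
            m = build_abundance_matrix({"s1": [hit("p1")]}, {"s1": 1.0, "s2": 1.0}, ["p1"])
        assert m.values[0, m.sample_ids.index("s2")] == 0.0


class TestHeuristicGroup:
    def test_identical_samples_share_a_group(self):
        v = np.array([[1.0, 1.0], [3.0, 3.0], [0.5, 0.5]])
        m = SampleAbundanceMatrix(("p1", "p2", "p3"), ("s1", "s2"), v)
        # with two samples every present row exceeds the 40% incidence rule,
        # so the noise filter is lifted for this micro-example
        a = heuristic_group(m, noise_incidence=101.0, tau=0.9, seed=0)
        assert a.assignments["s1"] == a.assignments["s2"]

    def test_planted_cohort_recovered(self, cohort):
        matrix, truth = cohort
        a = heuristic_group(matrix, seed=5)
        ari = adjusted_rand_score(
            [truth[s] for s in matrix.sample_ids],
            [a.assignments[s] for s in matrix.sample_ids],
        )
        assert ari >= 0.8

    def test_fifth_template_lands_in_uc(self):
        matrix, truth = make_enterotype_cohort(
            n_samples=40, n_groups=5, n_phage=60, n_shared=0, seed=2
        )
        a = heuristic_group(matrix, max_groups=4, seed=3)
        letters = {a.assignments[s] for s in matrix.sample_ids}
        assert letters <= {"A", "B", "C", "D", "UC"}
        assert "UC" in letters

    def test_sample_order_invariance_up_to_relabeling(self, cohort):
        matrix, _ = cohort
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(matrix.sample_ids))
        shuffled = SampleAbundanceMatrix(
            matrix.phage_ids,
            tuple(matrix.sample_ids[i] for i in perm),
            matrix.values[:, perm],
        )
        a = heuristic_group(matrix, seed=5)
        b = heuristic_group(shuffled, seed=5)
        ids = matrix.sample_ids
        ari = adjusted_rand_score(
            [a.assignments[s] for s in ids], [b.assignments[s] for s in ids]
        )
        assert ari == 1.0

    def test_all_noise_rows_is_an_error(self):
        v = np.ones((3, 4))
        m = SampleAbundanceMatrix(("p1", "p2", "p3"), tuple("abcd"), v)
        with pytest.raises(ValueError, match="noise"):
            heuristic_group(m, seed=0)

    def test_seed_is_mandatory(self, cohort):
        with pytest.raises(ValueError, match="seed"):
            heuristic_group(cohort[0])


class TestBrayCurtis:
    def test_hand_computed_value(self):
        v = np.array([[1.0, 0.0], [2.0, 2.0], [0.0, 2.0]])
        m = SampleAbundanceMatrix(("p1", "p2", "p3"), ("x", "y"), v)
        d = bray_curtis(m)
        assert d.value("x", "y") == pytest.approx(3 / 7)

    def test_identical_and_disjoint_columns(self):
        v = np.array([[1.0, 1.0, 0.0], [2.0, 2.0, 0.0], [0.0, 0.0, 5.0]])
        m = SampleAbundanceMatrix(("p1", "p2", "p3"), ("x", "y", "z"), v)
        d = bray_curtis(m)
        assert d.value("x", "y") == 0.0
        assert d.value("x", "z") == 1.0

    def test_entries_in_unit_interval_and_scale_invariance(self, cohort):
        matrix, _ = cohort
        d = bray_curtis(matrix)
        assert np.all(d.d >= 0) and np.all(d.d <= 1)
        scaled = SampleAbundanceMatrix(
            matrix.phage_ids, matrix.sample_ids, matrix.values * 3.0
        )
        np.testing.assert_allclose(bray_curtis(scaled).d, d.d, atol=1e-12)

    def test_all_zero_pair_is_zero_by_convention(self):
        v = np.zeros((2, 2))
        m = SampleAbundanceMatrix(("p1", "p2"), ("x", "y"), v)
        assert bray_curtis(m).value("x", "y") == 0.0


class TestNmds:
    def test_equilateral_triangle_embeds_exactly(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = nmds(DistanceMatrix(("a", "b", "c"), d), n_restarts=5, seed=1)
        assert res.stress == pytest.approx(0.0, abs=1e-4)

    def test_known_planar_configuration_recovered(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(size=(12, 2))
        diff = pts[:, None, :] - pts[None, :, :]
        d = np.sqrt((diff**2).sum(-1))
        D = DistanceMatrix(tuple(f"p{i}" for i in range(12)), d)
        res = nmds(D, n_restarts=20, seed=2)
        assert res.stress <= 0.01
        got = np.sqrt(
            ((res.coordinates[:, None, :] - res.coordinates[None, :, :]) ** 2).sum(-1)
        )
        iu = np.triu_indices(12, 1)
        from scipy.stats import spearmanr

        assert spearmanr(got[iu], d[iu]).statistic >= 0.995

    def test_coordinates_centered_and_deterministic(self, cohort):
        D = bray_curtis(cohort[0])
        a = nmds(D, n_restarts=4, seed=9)
        b = nmds(D, n_restarts=4, seed=9)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)
        np.testing.assert_allclose(a.coordinates.mean(axis=0), 0.0, atol=1e-10)

    def test_planted_cohort_stress_acceptable(self, cohort):
        res = nmds(bray_curtis(cohort[0]), seed=7)
        assert res.stress <= 0.15


class TestAnosim:
    def separated_matrix(self):
        # two tight clusters far apart: every between > every within
        d = np.array(
            [
                [0.0, 0.1, 0.2, 0.9, 1.0, 0.95],
                [0.1, 0.0, 0.15, 0.92, 0.97, 0.96],
                [0.2, 0.15, 0.0, 0.91, 0.99, 0.93],
                [0.9, 0.92, 0.91, 0.0, 0.12, 0.18],
                [1.0, 0.97, 0.99, 0.12, 0.0, 0.16],
                [0.95, 0.96, 0.93, 0.18, 0.16, 0.0],
            ]
        )
        labels = ("a", "b", "c", "d", "e", "f")
        groups = {"a": "G1", "b": "G1", "c": "G1", "d": "G2", "e": "G2", "f": "G2"}
        return DistanceMatrix(labels, d), groups

    def test_perfect_separation_gives_r_one(self):
        D, groups = self.separated_matrix()
        res = anosim(D, groups, seed=0)
        assert res.R == pytest.approx(1.0)

    def test_exact_enumeration_matches_oracle(self):
        D, groups = self.separated_matrix()
        res = anosim(D, groups, n_permutations=999, seed=0)
        assert res.exact
        r_oracle, p_oracle = exact_anosim_two_groups(
            D.d.tolist(), [groups[l] for l in D.labels]
        )
        assert res.R == pytest.approx(r_oracle, abs=1e-12)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)
        assert res.p_value == pytest.approx(1 / 10)  # unique best separation

    def test_r_invariant_to_monotone_transform(self):
        D, groups = self.separated_matrix()
        transformed = DistanceMatrix(D.labels, np.sqrt(D.d) * 3.0)
        a = anosim(D, groups, seed=1)
        b = anosim(transformed, groups, seed=1)
        assert a.R == pytest.approx(b.R, abs=1e-12)

    def test_null_calibration_type_i_error(self):
        """On structureless data the test rejects at roughly its alpha level."""
        rng = np.random.default_rng(0)
        n = 12
        labels = tuple(f"s{i}" for i in range(n))
        groups = {l: ("G1" if i < n // 2 else "G2") for i, l in enumerate(labels)}
        rejections = 0
        n_sims = 200
        for sim_i in range(n_sims):
            x = rng.uniform(size=(n, 5))
            diff = x[:, None, :] - x[None, :, :]
            d = np.sqrt((diff**2).sum(-1))
            D = DistanceMatrix(labels, d)
            res = anosim(D, groups, n_permutations=199, seed=int(rng.integers(2**31)))
            if res.p_value <= 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sims <= 0.07

    def test_planted_cohort_strongly_separated(self, cohort):
        matrix, truth = cohort
        res = anosim(bray_curtis(matrix), truth, n_permutations=999, seed=3)
        assert res.R >= 0.75 and res.p_value <= 0.01

    def test_group_of_one_rejected(self):
        D, groups = self.separated_matrix()
        bad = dict(groups, f="G3")
        with pytest.raises(ValueError):
            anosim(D, bad, seed=0)

    def test_uc_samples_excluded(self):
        D, groups = self.separated_matrix()
        with_uc = dict(groups)
        res_full = anosim(D, groups, seed=0)
        # relabeling one member of each group as UC drops them from the test
        smaller = dict(groups, c="UC", f="UC")
        res_small = anosim(D, smaller, seed=0)
        assert res_small.group_sizes == {"G1": 2, "G2": 2}
        assert res_full.group_sizes == {"G1": 3, "G2": 3}
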