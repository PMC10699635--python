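"""AMOVA against a brute-force oracle; MCA against closed-form identities."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ylineage import (
    GenealogySpec,
    STRModel,
    amova_two_level,
    mca,
    pairwise_distance_matrix,
    simulate_structured_populations,
)

from conftest import genotype_table, make_profile


def labelled_profiles(vectors, pops, groups, loci=("L1", "L2", "L3")):
    return [
        make_profile(f"s{i}", dict(zip(loci, v)), population=p, group=g)
        for i, (v, p, g) in enumerate(zip(vectors, pops, groups))
    ]


def naive_amova(profiles, metric="pairwise_difference"):
    """Independent oracle: SSD identities via explicit loops, variance
    components by solving the expected-mean-square equations with numpy."""
    loci = profiles[0].active_loci()

    def d(a, b):
        if metric == "pairwise_difference":
            return sum(a.alleles[l] != b.alleles[l] for l in loci)
        return sum((a.alleles[l] - b.alleles[l]) ** 2 for l in loci)

    def ss(subset):
        tot = 0.0
        for i in range(len(subset)):
            for j in range(i + 1, len(subset)):
                tot += d(subset[i], subset[j])
        return tot / len(subset)

    N = len(profiles)
    pops = sorted({p.population for p in profiles})
    groups = sorted({p.group for p in profiles})
    by_pop = {q: [p for p in profiles if p.population == q] for q in pops}
    by_grp = {g: [p for p in profiles if p.group == g] for g in groups}
    group_of = {q: by_pop[q][0].group for q in pops}
    P, G = len(pops), len(groups)

    ss_total = ss(profiles)
    ss_wp = sum(ss(by_pop[q]) for q in pops)
    ss_grp = sum(ss(by_grp[g]) for g in groups)
    ssd_ag, ssd_ap, ssd_wp = ss_total - ss_grp, ss_grp - ss_wp, ss_wp

    n_p = {q: len(by_pop[q]) for q in pops}
    n_g = {g: len(by_grp[g]) for g in groups}
    sum_np2_over_ng = sum(
        sum(n_p[q] ** 2 for q in pops if group_of[q] == g) / n_g[g] for g in groups
    )
    n1 = (N - sum_np2_over_ng) / (P - G)
    n2 = (sum_np2_over_ng - sum(n_p[q] ** 2 for q in pops) / N) / (G - 1)
    n3 = (N - sum(n_g[g] ** 2 for g in groups) / N) / (G - 1)
    # E[MS] equations: solve the triangular system for (Va, Vb, Vc)
    A = np.array([[n3, n2, 1.0], [0.0, n1, 1.0], [0.0, 0.0, 1.0]])
    ms = np.array([ssd_ag / (G - 1), ssd_ap / (P - G), ssd_wp / (N - P)])
    Va, Vb, Vc = np.linalg.solve(A, ms)
    return (ssd_ag, ssd_ap, ssd_wp), (Va, Vb, Vc)


class TestAmova:
    def test_identical_haplotypes_degenerate(self):
        profs = labelled_profiles(
            [(10, 10, 10)] * 8,
            ["P1"] * 4 + ["P2"] * 4,
            ["G1"] * 4 + ["G2"] * 4,
        )
        with pytest.warns(UserWarning, match="degenerate"):
            res = amova_two_level(profs, n_permutations=0)
        assert all(l.variance == 0 for l in res.levels)
        assert res.degenerate

    def test_pure_between_group_variation_gives_100_percent(self):
        profs = labelled_profiles(
            [(10, 10, 10)] * 4 + [(14, 14, 14)] * 4,
            ["P1"] * 4 + ["P2"] * 4,
            ["G1"] * 4 + ["G2"] * 4,
        )
        res = amova_two_level(profs, n_permutations=0)
        among = next(l for l in res.levels if l.source == "Among groups")
        assert among.percent == pytest.approx(100.0)
        within = next(l for l in res.levels if l.source == "Within populations")
        assert within.variance == 0.0

    @pytest.mark.parametrize("metric", ["pairwise_difference", "sum_squared_size_difference"])
    def test_twelve_sample_toy_matches_bruteforce_oracle(self, metric):
        rng = np.random.default_rng(11)
        vecs = [tuple(int(x) for x in rng.integers(10, 15, size=3)) for _ in range(12)]
        pops = ["P1"] * 3 + ["P2"] * 3 + ["P3"] * 3 + ["P4"] * 3
        grps = ["G1"] * 6 + ["G2"] * 6
        profs = labelled_profiles(vecs, pops, grps)
        res = amova_two_level(profs, metric=metric, n_permutations=0)
        (ssd_ag, ssd_ap, ssd_wp), (Va, Vb, Vc) = naive_amova(profs, metric)
        by_source = {l.source: l for l in res.levels}
        assert by_source["Among groups"].ss == pytest.approx(ssd_ag)
        assert by_source["Among populations within groups"].ss == pytest.approx(ssd_ap)
        assert by_source["Within populations"].ss == pytest.approx(ssd_wp)
        assert by_source["Among groups"].variance == pytest.approx(Va)
        assert by_source["Among populations within groups"].variance == pytest.approx(Vb)
        assert by_source["Within populations"].variance == pytest.approx(Vc)

    def test_unbalanced_design_matches_oracle(self):
        rng = np.random.default_rng(13)
        sizes = {"P1": 5, "P2": 2, "P3": 7, "P4": 3, "P5": 4}
        group_of = {"P1": "G1", "P2": "G1", "P3": "G2", "P4": "G2", "P5": "G2"}
        vecs, pops, grps = [], [], []
        for q, n in sizes.items():
            for _ in range(n):
                vecs.append(tuple(int(x) for x in rng.integers(9, 16, size=3)))
                pops.append(q)
                grps.append(group_of[q])
        profs = labelled_profiles(vecs, pops, grps)
        res = amova_two_level(profs, n_permutations=0)
        _, (Va, Vb, Vc) = naive_amova(profs)
        got = {l.source: l.variance for l in res.levels}
        assert got["Among groups"] == pytest.approx(Va)
        assert got["Among populations within groups"] == pytest.approx(Vb)
        assert got["Within populations"] == pytest.approx(Vc)

    def test_percents_sum_to_100_and_df_identity(self):
        rng = np.random.default_rng(5)
        for trial in range(20):
            spec = GenealogySpec(
                "two_level_hierarchy", 24, 60.0,
                group_sizes=[[6, 6], [6, 6]],
                divergence_generations=(30.0, 15.0), seed=int(rng.integers(2**31)),
            )
            profs = simulate_structured_populations(
                spec, STRModel(mu_per_locus_per_gen=5e-3)
            )
            res = amova_two_level(profs, n_permutations=0)
            if res.degenerate:
                continue
            assert res.percent_total() == pytest.approx(100.0, abs=0.01)
            assert sum(l.df for l in res.levels) == len(profs) - 1

    def test_negative_components_reported_unmodified(self):
        """Groups crossing population labels can drive Vb below zero; the
        component and its percentage are reported as-is, not truncated."""
        found_negative = False
        for seed in range(30):
            rng = np.random.default_rng(seed)
            vecs = [tuple(int(x) for x in rng.integers(10, 14, size=3)) for _ in range(16)]
            pops = ["P1"] * 4 + ["P2"] * 4 + ["P3"] * 4 + ["P4"] * 4
            grps = ["G1"] * 8 + ["G2"] * 8
            res = amova_two_level(labelled_profiles(vecs, pops, grps), n_permutations=0)
            vb = next(l for l in res.levels if "within groups" in l.source)
            if vb.variance < 0:
                found_negative = True
                assert vb.percent < 0
                assert res.percent_total() == pytest.approx(100.0, abs=0.01)
        assert found_negative

    def test_each_population_its_own_group_collapses_to_one_level(self):
        rng = np.random.default_rng(21)
        vecs = [tuple(int(x) for x in rng.integers(10, 14, size=3)) for _ in range(12)]
        pops = ["P1"] * 4 + ["P2"] * 4 + ["P3"] * 4
        own_group = amova_two_level(
            labelled_profiles(vecs, pops, pops), n_permutations=0
        )
        single_group = amova_two_level(
            labelled_profiles(vecs, pops, ["G"] * 12), n_permutations=0
        )
        # among-group Va (pops as groups) equals among-population Vb (one group)
        va = next(l for l in own_group.levels if l.source == "Among groups").variance
        vb = next(l for l in single_group.levels if l.source == "Among populations").variance
        assert va == pytest.approx(vb)
        vc1 = own_group.levels[-1].variance
        vc2 = single_group.levels[-1].variance
        assert vc1 == pytest.approx(vc2)

    def test_permutation_pvalues_uniform_under_null(self):
        """Exchangeable data: the Phi_ST permutation p-value must be uniform
        (KS test at alpha=0.01 over 500 null datasets, B=99)."""
        rng = np.random.default_rng(99)
        pvals = []
        pops = ["P1"] * 6 + ["P2"] * 6 + ["P3"] * 6
        grps = ["G1"] * 6 + ["G1"] * 6 + ["G2"] * 6
        for _ in range(500):
            vecs = [tuple(int(x) for x in rng.integers(8, 16, size=3)) for _ in range(18)]
            res = amova_two_level(
                labelled_profiles(vecs, pops, grps),
                n_permutations=99,
                seed=int(rng.integers(2**31)),
            )
            pvals.append(res.p_values["Phi_ST"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_single_population_rejected(self):
        profs = labelled_profiles([(10, 10, 10)] * 4, ["P1"] * 4, ["G1"] * 4)
        with pytest.raises(ValueError):
            amova_two_level(profs)

    def test_distance_metrics_differ_as_documented(self):
        profs = labelled_profiles(
            [(10, 10, 10), (13, 10, 10)], ["P1", "P2"], ["G1", "G2"]
        )
        d_diff = pairwise_distance_matrix(profs, "pairwise_difference")
        d_sq = pairwise_distance_matrix(profs, "sum_squared_size_difference")
        assert d_diff[0, 1] == 1 and d_sq[0, 1] == 9


class TestMca:
    def anticorrelated_table(self, n_per_block=10):
        records = {}
        for i in range(n_per_block):
            records[f"a{i}"] = {"m1": "D", "m2": "A"}
        for i in range(n_per_block):
            records[f"b{i}"] = {"m1": "A", "m2": "D"}
        pops = {s: ("X" if s.startswith("a") else "Y") for s in records}
        return genotype_table(records, markers=["m1", "m2"], populations=pops)

    def test_identical_samples_have_zero_inertia(self):
        table = genotype_table(
            {f"s{i}": {"m1": "D", "m2": "A"} for i in range(5)}, markers=["m1", "m2"]
        )
        with pytest.warns(UserWarning):
            res = mca(table)
        assert res.total_inertia == 0.0

    def test_perfectly_anticorrelated_markers_load_on_one_dimension(self):
        res = mca(self.anticorrelated_table())
        assert res.eigenvalues[0] == pytest.approx(1.0)
        assert res.percent_inertia[0] == pytest.approx(100.0)
        assert res.total_inertia == pytest.approx(1.0)

    def test_eigenvalue_sum_equals_total_inertia(self):
        rng = np.random.default_rng(7)
        records = {
            f"s{i}": {
                m: rng.choice(["A", "D", "."], p=[0.5, 0.4, 0.1])
                for m in ["m1", "m2", "m3", "m4"]
            }
            for i in range(30)
        }
        table = genotype_table(records, markers=["m1", "m2", "m3", "m4"])
        res = mca(table)
        assert res.eigenvalues.sum() == pytest.approx(res.total_inertia)

    def test_eigenvalues_non_increasing_and_percents_bounded(self):
        res = mca(self.anticorrelated_table())
        assert all(np.diff(res.eigenvalues) <= 1e-12)
        assert 0 < res.cumulative_percent_dims12 <= 100 + 1e-9

    def test_supplementary_variable_does_not_influence_axes(self):
        table = self.anticorrelated_table()
        base = mca(table, supplementary=None)
        with_supp = mca(table, supplementary="population")
        pd.testing.assert_frame_equal(base.col_coords, with_supp.col_coords)
        assert with_supp.supp_coords is not None
        shuffled = genotype_table(
            {s: {"m1": table.states.at[s, "m1"], "m2": table.states.at[s, "m2"]}
             for s in table.samples},
            markers=["m1", "m2"],
            populations={s: ("Y" if i % 2 else "X") for i, s in enumerate(table.samples)},
        )
        res = mca(shuffled, supplementary="population")
        pd.testing.assert_frame_equal(base.col_coords, res.col_coords)

    def test_constant_marker_excluded_with_warning(self):
        records = {f"s{i}": {"m1": "D", "m2": "A" if i < 5 else "D",
                             "m3": "D" if i % 2 else "A"} for i in range(10)}
        table = genotype_table(records, markers=["m1", "m2", "m3"])
        with pytest.warns(UserWarning, match="constant"):
            res = mca(table)
        assert res.excluded_markers == ["m1"]
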