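"""DEG criterion, BH adjustment, fold changes and the signature partition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import cardiosig as cs
from helpers_oracles import brute_bh, pooled_t_p


class TestTwoGroupTest:
    def test_identical_groups_give_p_one(self):
        a = np.array([[1.0, 2.0, 3.0]])
        p = cs.test_two_groups(a, a)
        assert p[0] == pytest.approx(1.0)

    def test_matches_hand_computed_pooled_t(self):
        """Toy a=[1,1,2,2], b=[5,5,6,6]: pooled t = -9.798 with 6 df, p = 6.51e-5."""
        a = np.array([[1.0, 1, 2, 2]])
        b = np.array([[5.0, 5, 6, 6]])
        p = cs.test_two_groups(a, b)
        assert p[0] == pytest.approx(6.506148515315591e-05, rel=1e-9)
        assert p[0] == pytest.approx(pooled_t_p(a[0], b[0]), rel=1e-12)

    def test_degenerate_constant_groups(self):
        equal = cs.test_two_groups(np.array([[2.0, 2]]), np.array([[2.0, 2]]))
        assert equal[0] == 1.0
        unequal = cs.test_two_groups(np.array([[2.0, 2]]), np.array([[3.0, 3]]))
        assert unequal[0] == 0.0

    def test_single_sample_group_rejected(self):
        with pytest.raises(cs.ValidationError):
            cs.test_two_groups(np.array([[1.0]]), np.array([[1.0, 2.0]]))

    def test_null_pvalues_are_uniform(self):
        """Under exchangeable groups p-values pass a KS sanity bound."""
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, (3000, 10))
        b = rng.normal(0, 1, (3000, 12))
        p = cs.test_two_groups(a, b)
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 1e-3


class TestBHAdjust:
    def test_hand_applied_step_up(self):
        q = cs.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_and_all_ones(self):
        assert cs.bh_adjust(np.array([0.37]))[0] == pytest.approx(0.37)
        assert np.allclose(cs.bh_adjust(np.ones(5)), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(cs.ValidationError):
            cs.bh_adjust(np.array([0.5, 1.2]))

    @given(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=20)
    )
    def test_matches_brute_force_step_up(self, pvals):
        """Oracle equivalence on every vector up to length 20."""
        p = np.array(pvals)
        assert np.allclose(cs.bh_adjust(p), brute_bh(p), atol=1e-12)

    def test_q_never_below_p_and_monotone(self):
        rng = np.random.default_rng(5)
        p = rng.random(200)
        q = cs.bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestFoldChange:
    @pytest.mark.parametrize(
        "m1,m2,expected", [(10, 5, 2.0), (5, 10, -2.0), (18, 18, 1.0)]
    )
    def test_signed_convention(self, m1, m2, expected):
        assert cs.fold_change(m1, m2) == pytest.approx(expected)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(cs.ValidationError):
            cs.fold_change(0.0, 5.0)

    @given(
        m1=st.floats(0.1, 1e4), m2=st.floats(0.1, 1e4)
    )
    def test_antisymmetry_and_magnitude(self, m1, m2):
        fc = cs.fold_change(m1, m2)
        assert abs(fc) >= 1.0
        if m1 != m2:
            assert fc == pytest.approx(-cs.fold_change(m2, m1))


class TestCallDegs:
    def test_joint_criterion_blocks_single_condition_genes(self):
        """Significant-but-small and large-but-noisy genes are both rejected."""
        rng = np.random.default_rng(2)
        n1, n2 = 10, 10
        # gene A: tiny but ultra-consistent difference (q small, diff 3 < 5)
        gene_a = np.r_[np.full(n1, 20.0), np.full(n2, 17.0)] + rng.normal(0, 0.01, 20)
        # gene B: big but wildly noisy difference (diff 8, q large)
        gene_b = np.r_[np.tile([45.0, 15.0], 5), np.tile([37.0, 7.0], 5)]
        # gene C: clean DEG
        gene_c = np.r_[np.full(n1, 30.0), np.full(n2, 10.0)] + rng.normal(0, 0.5, 20)
        matrix = pd.DataFrame(
            [gene_a, gene_b, gene_c],
            index=["small_diff", "noisy", "clean"],
            columns=[f"s{i}" for i in range(20)],
        ).clip(lower=5.1)
        meta = pd.DataFrame(
            {"phenotype": ["DCM"] * n1 + ["NF"] * n2}, index=matrix.columns
        )
        res = cs.call_degs(matrix, meta, ("DCM", "NF"))
        assert bool(res.loc["clean", "is_deg"])
        assert not bool(res.loc["small_diff", "is_deg"])
        assert not bool(res.loc["noisy", "is_deg"])
        # joint-criterion invariant over all genes
        flagged = res[res["is_deg"]]
        assert (flagged["expressed"]).all()
        assert (flagged["diff"].abs() >= 5).all()
        assert (flagged["q"] <= 0.05).all()

    def test_planted_genes_recovered_with_calibrated_false_positives(self, small_cohort):
        _, matrix, samples, truth = small_cohort
        res = cs.call_degs(matrix, samples, ("DCM", "NF"))
        planted = truth.gene_truth["effect_dcm"] != 0
        sens = res.loc[planted[planted].index, "is_deg"].mean()
        assert sens >= 0.9
        nulls = truth.genes_of_class("null")
        assert res.loc[nulls, "is_deg"].mean() <= 0.01

    def test_empirical_fdr_across_replicates(self):
        """Empirical FDR of called DEGs stays <= 0.10 at nominal 0.05 over 20 seeds."""
        fps, calls = 0, 0
        for seed in range(20):
            config = cs.SimConfig(n_dcm=12, n_icm=8, n_nf=10, n_genes=1000, seed=seed)
            matrix, samples, truth = cs.generate_cohort(config)
            res = cs.call_degs(matrix, samples, ("DCM", "NF"))
            called = res.index[res["is_deg"]]
            true_dcm = truth.gene_truth["effect_dcm"] != 0
            # confounders count as false for the disease contrast only after
            # adjustment; on raw data exclude them from the FDR numerator
            confounded = truth.gene_truth["class"].isin(["sex_linked", "age_linked"])
            eligible = called[~confounded.loc[called]]
            fps += (~true_dcm.loc[eligible]).sum()
            calls += len(eligible)
        assert calls > 0
        assert fps / calls <= 0.10


class TestPartition:
    @staticmethod
    def result_from_sets(universe, degs, diffs=None):
        diffs = diffs or {}
        df = pd.DataFrame(
            {
                "mean_1": 10.0,
                "mean_2": 8.0,
                "diff": [diffs.get(g, 6.0) for g in universe],
                "p": 0.001,
                "q": 0.01,
                "expressed": True,
                "is_deg": [g in degs for g in universe],
            },
            index=pd.Index(universe, name="gene_id"),
        )
        return df

    def test_set_algebra_example(self):
        universe = list("abcde")
        dcm = self.result_from_sets(universe, {"a", "b", "c"})
        icm = self.result_from_sets(universe, {"b", "c", "d"})
        sets = cs.partition_signatures(dcm, icm)
        assert set(sets.hf.index) == {"b", "c"}
        assert set(sets.dcm_specific.index) == {"a"}
        assert set(sets.icm_specific.index) == {"d"}

    def test_empty_overlap(self):
        universe = list("abcd")
        dcm = self.result_from_sets(universe, {"a"})
        icm = self.result_from_sets(universe, {"b"})
        sets = cs.partition_signatures(dcm, icm)
        assert len(sets.hf) == 0
        assert set(sets.dcm_specific.index) == {"a"}
        assert set(sets.icm_specific.index) == {"b"}

    def test_mismatched_universe_rejected(self):
        dcm = self.result_from_sets(list("abc"), {"a"})
        icm = self.result_from_sets(list("abd"), {"a"})
        with pytest.raises(cs.ValidationError):
            cs.partition_signatures(dcm, icm)

    def test_partition_identities_on_synthetic_run(self, small_cohort):
        _, matrix, samples, _ = small_cohort
        dcm = cs.call_degs(matrix, samples, ("DCM", "NF"))
        icm = cs.call_degs(matrix, samples, ("ICM", "NF"))
        direct = cs.call_degs(matrix, samples, ("ICM", "DCM"))
        sets = cs.partition_signatures(dcm, icm, direct)
        assert len(sets.hf) + len(sets.dcm_specific) == int(dcm["is_deg"].sum())
        assert len(sets.hf) + len(sets.icm_specific) == int(icm["is_deg"].sum())
        assert len(sets.hf.index.intersection(sets.dcm_specific.index)) == 0
        assert len(sets.hf.index.intersection(sets.icm_specific.index)) == 0


class TestConcordance:
    def test_identical_mean_vectors_give_r2_one_and_full_concordance(self):
        universe = list("abcdef")
        diffs = {g: (6.0 if i % 2 else -6.0) for i, g in enumerate(universe)}
        base = TestPartition.result_from_sets(universe, set(universe), diffs)
        base["mean_1"] = [10.0, 20, 40, 80, 160, 320]
        sets = cs.partition_signatures(base, base)
        diag = cs.concordance_diagnostics(sets, base, base)
        assert diag["direction_concordance"] == 1.0
        assert diag["log_mean_r2"] == pytest.approx(1.0)

    def test_empty_hf_set_rejected(self):
        universe = list("ab")
        dcm = TestPartition.result_from_sets(universe, {"a"})
        icm = TestPartition.result_from_sets(universe, {"b"})
        sets = cs.partition_signatures(dcm, icm)
        with pytest.raises(cs.ValidationError):
            cs.concordance_diagnostics(sets, dcm, icm)

    def test_synthetic_hf_genes_fully_concordant(self, default_run):
        """Recovered planted-shared genes are same-sign by construction; the
        empirical HF set may add rare same-q false intersections."""
        sets = default_run["signatures"]
        truth = default_run["truth"]
        dcm = default_run["results"][("DCM", "NF")]
        icm = default_run["results"][("ICM", "NF")]
        planted = truth.genes_of_class("hf_shared_up", "hf_shared_down")
        recovered = sets.hf.index.intersection(planted)
        assert len(recovered) > 0
        assert (
            np.sign(dcm.loc[recovered, "diff"]) == np.sign(icm.loc[recovered, "diff"])
        ).all()
        diag = cs.concordance_diagnostics(sets, dcm, icm)
        assert diag["direction_concordance"] >= 0.99
        assert diag["log_mean_r2"] > 0.9


def test_deg_table_round_trip(tmp_path, small_cohort):
    _, matrix, samples, _ = small_cohort
    res = cs.call_degs(matrix, samples, ("DCM", "NF"))
    cs.write_deg_table(res, tmp_path / "dcm_vs_nf.tsv")
    back = cs.read_deg_table(tmp_path / "dcm_vs_nf.tsv")
    assert back.attrs["comparison"] == "DCM_vs_NF"
    assert set(back.index[back["is_deg"]]) == set(res.index[res["is_deg"]])
    overlap = cs.deg_list_overlap(back.index[back["is_deg"]], res.index[res["is_deg"]])
    assert overlap["fraction_of_b"] == pytest.approx(1.0)
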