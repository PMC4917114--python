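"""Module membership, meta statistics and trait correlation contracts."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from coexseed.datatypes import ModuleAssignment
from coexseed.membership import (
    assign_final_modules,
    meta_membership,
    module_eigengene,
    module_membership,
    module_trait_correlation,
    null_membership_pvalues,
    within_module_connectivity,
)


def assignment_of(labels: dict) -> ModuleAssignment:
    return ModuleAssignment(pd.Series(labels))


class TestConnectivity:
    def test_singleton_module_has_zero_kin(self):
        adj = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        kin = within_module_connectivity(adj, assignment_of({"a": 1, "b": 0, "c": 0}))
        assert kin["a"] == 0.0

    def test_three_gene_module_kin(self):
        A = np.full((3, 3), 0.5)
        np.fill_diagonal(A, 1.0)
        adj = pd.DataFrame(A, index=list("abc"), columns=list("abc"))
        kin = within_module_connectivity(adj, assignment_of({"a": 1, "b": 1, "c": 1}))
        assert np.allclose(kin.to_numpy(), 1.0)

    def test_matches_bruteforce_sum(self, rng):
        n = 20
        A = rng.uniform(size=(n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        ids = [f"g{i}" for i in range(n)]
        adj = pd.DataFrame(A, index=ids, columns=ids)
        labels = {g: 1 if i < 12 else 2 for i, g in enumerate(ids)}
        kin = within_module_connectivity(adj, assignment_of(labels))
        for i, g in enumerate(ids):
            expect = sum(
                A[i, j] for j, h in enumerate(ids) if h != g and labels[h] == labels[g]
            )
            assert kin[g] == pytest.approx(expect)


class TestModuleMembership:
    def test_identical_profiles_give_mm_one(self, rng):
        base = rng.normal(size=10)
        v = pd.DataFrame([base + i * 1e-9 for i in range(6)], index=[f"g{i}" for i in range(6)])
        asg = assignment_of({f"g{i}": 1 for i in range(6)})
        adj = pd.DataFrame(np.ones((6, 6)), index=v.index, columns=v.index)
        mm = module_membership(v, asg, adj)
        assert np.allclose(mm[1].to_numpy(), 1.0, atol=1e-6)

    def test_orthogonal_gene_has_mm_zero(self):
        ref = np.array([1.0, -1.0, 1.0, -1.0])
        orth = np.array([1.0, 1.0, -1.0, -1.0])
        rows = [ref, ref * 2, ref * 3 + 0.1, ref + 0.2, ref * 1.5, orth]
        ids = [f"g{i}" for i in range(6)]
        v = pd.DataFrame(rows, index=ids)
        asg = assignment_of({g: 1 for g in ids})
        adj = pd.DataFrame(np.ones((6, 6)), index=ids, columns=ids)
        mm = module_membership(v, asg, adj)
        assert abs(mm.loc["g5", 1]) < 1e-9

    def test_members_score_higher_than_nonmembers(self, rng):
        factor = rng.normal(size=30)
        members = [factor * 1.0 + rng.normal(0, 0.05, 30) for _ in range(10)]
        outsiders = [rng.normal(size=30) for _ in range(10)]
        ids = [f"m{i}" for i in range(10)] + [f"o{i}" for i in range(10)]
        v = pd.DataFrame(members + outsiders, index=ids)
        asg = assignment_of({g: (1 if g.startswith("m") else 0) for g in ids})
        adj = pd.DataFrame(
            np.abs(np.corrcoef(v.to_numpy())) ** 6, index=ids, columns=ids
        )
        mm = module_membership(v, asg, adj)
        member_mm = mm.loc[[g for g in ids if g.startswith("m")], 1]
        outsider_mm = mm.loc[[g for g in ids if g.startswith("o")], 1]
        assert member_mm.min() > outsider_mm.max()


class TestMetaMembership:
    def test_zero_correlation_gives_p_one(self):
        mm = pd.DataFrame({1: [0.0]}, index=["g"])
        meta = meta_membership([(mm, 10), (mm, 12)])
        row = meta.loc[("g", 1)]
        assert row["t_bar"] == 0.0
        assert row["P"] == pytest.approx(1.0)

    def test_single_dataset_closed_form(self):
        mm = pd.DataFrame({1: [0.5]}, index=["g"])
        meta = meta_membership([(mm, 11)])
        assert meta.loc[("g", 1), "T_scaled"] == pytest.approx(np.sqrt(3.0))

    def test_identical_datasets_scale_with_sqrt_d(self):
        mm = pd.DataFrame({1: [0.6]}, index=["g"])
        one = meta_membership([(mm, 20)])
        four = meta_membership([(mm, 20)] * 4)
        assert four.loc[("g", 1), "T_scaled"] == pytest.approx(
            2.0 * one.loc[("g", 1), "T_scaled"]
        )

    def test_invariant_to_dataset_order(self, rng):
        ids = [f"g{i}" for i in range(8)]
        t1 = pd.DataFrame({1: rng.uniform(-0.9, 0.9, 8)}, index=ids)
        t2 = pd.DataFrame({1: rng.uniform(-0.9, 0.9, 8)}, index=ids)
        a = meta_membership([(t1, 10), (t2, 14)])
        b = meta_membership([(t2, 14), (t1, 10)])
        pd.testing.assert_frame_equal(a, b)

    def test_partial_coverage_uses_covering_datasets(self):
        t1 = pd.DataFrame({1: [0.5, np.nan]}, index=["g1", "g2"])
        t2 = pd.DataFrame({1: [0.5, 0.5]}, index=["g1", "g2"])
        meta = meta_membership([(t1, 10), (t2, 10)])
        assert meta.loc[("g1", 1), "D"] == 2
        assert meta.loc[("g2", 1), "D"] == 1
        assert meta.loc[("g2", 1), "df"] == 8

    def test_perfect_correlation_clamped_with_warning(self):
        mm = pd.DataFrame({1: [1.0]}, index=["g"])
        with pytest.warns(UserWarning, match="clamp"):
            meta = meta_membership([(mm, 10)])
        assert np.isfinite(meta.loc[("g", 1), "T_scaled"])


class TestFinalAssignment:
    def _meta(self, rows):
        idx = pd.MultiIndex.from_tuples(
            [(g, m) for g, m, _, _ in rows], names=["gene", "module"]
        )
        return pd.DataFrame(
            {"R": [r for _, _, r, _ in rows], "P": [p for _, _, _, p in rows]}, index=idx
        )

    def test_threshold_rules(self):
        meta = self._meta(
            [("a", 1, 0.19, 1e-20), ("b", 1, 0.5, 1e-14), ("c", 1, 0.5, 1e-10)]
        )
        final = assign_final_modules(meta)
        assert final.labels["a"] == 0  # fails R
        assert final.labels["b"] == 1  # passes both
        assert final.labels["c"] == 0  # fails P

    def test_gene_goes_to_module_with_max_r(self):
        meta = self._meta([("a", 1, 0.5, 1e-20), ("a", 2, 0.8, 1e-20)])
        assert assign_final_modules(meta).labels["a"] == 2

    def test_null_data_nearly_nothing_assigned(self):
        P = null_membership_pvalues(n_genes=1000, seed=3)
        assert (P < 1e-13).mean() <= 0.01


class TestEigengene:
    def test_identical_profiles_give_r_one(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        v = pd.DataFrame([base, base * 2 + 1], index=["a", "b"])
        asg = assignment_of({"a": 1, "b": 1})
        me = module_eigengene(v, asg)[1].to_numpy()
        r = np.corrcoef(base, me)[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert r > 0  # orientation

    def test_sign_flip_restores_positive_orientation(self, rng):
        v = pd.DataFrame(rng.normal(size=(5, 8)), index=[f"g{i}" for i in range(5)])
        asg = assignment_of({f"g{i}": 1 for i in range(5)})
        me1 = module_eigengene(v, asg)[1]
        me2 = module_eigengene(-v, asg)[1]
        genes_r1 = np.mean([np.corrcoef(v.loc[g], me1)[0, 1] for g in v.index])
        genes_r2 = np.mean([np.corrcoef(-v.loc[g], me2)[0, 1] for g in v.index])
        assert genes_r1 > 0 and genes_r2 > 0

    def test_recovers_planted_factor(self, rng):
        factor = rng.normal(size=40)
        v = pd.DataFrame(
            [factor + rng.normal(0, 0.3, 40) for _ in range(20)],
            index=[f"g{i}" for i in range(20)],
        )
        asg = assignment_of({f"g{i}": 1 for i in range(20)})
        me = module_eigengene(v, asg)[1].to_numpy()
        assert abs(np.corrcoef(me, factor)[0, 1]) >= 0.95

    def test_zero_variance_module_errors(self):
        v = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["a", "b"])
        with pytest.raises(ValueError, match="zero-variance"):
            module_eigengene(v, assignment_of({"a": 1, "b": 1}))


class TestTraitCorrelation:
    def test_perfect_separation(self):
        me = pd.DataFrame({1: [1.0, 1.2, -1.0, -1.1]}, index=list("abcd"))
        trait = pd.Series([1, 1, 0, 0], index=list("abcd"), dtype=float)
        stats = module_trait_correlation(me, trait)
        assert stats["abs_r"].iloc[0] == pytest.approx(1.0, abs=1e-2)

    def test_constant_trait_errors(self):
        me = pd.DataFrame({1: [1.0, 2.0, 3.0]}, index=list("abc"))
        with pytest.raises(ValueError, match="constant"):
            module_trait_correlation(me, pd.Series([1.0, 1.0, 1.0], index=list("abc")))

    def test_permutation_reduces_correlation(self, rng):
        n = 40
        trait = pd.Series([1.0] * (n // 2) + [0.0] * (n // 2), index=range(n))
        me = pd.DataFrame({1: trait + rng.normal(0, 0.5, n)}, index=range(n))
        observed = module_trait_correlation(me, trait)["abs_r"].iloc[0]
        perms = []
        for _ in range(100):
            p = trait.to_numpy().copy()
            rng.shuffle(p)
            perms.append(
                module_trait_correlation(me, pd.Series(p, index=range(n)))["abs_r"].iloc[0]
            )
        assert np.mean(perms) < observed


class TestNullCalibration:
    def test_meta_p_uniform_under_global_null(self):
        P = null_membership_pvalues(seed=0)
        assert len(P) >= 2000
        assert kstest(P, "uniform").pvalue > 0.01
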