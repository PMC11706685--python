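import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import rootposture as rp


def random_groups(seed, k=3, n=12, ties=False):
    rng = np.random.default_rng(seed)
    gs = [rng.normal(i * 0.5, 1.0, n) for i in range(k)]
    if ties:
        gs = [np.round(g, 1) for g in gs]
    return gs


class TestKruskalWallis:
    def test_identical_constant_groups(self):
        H, p = rp.kruskal_wallis([np.ones(5), np.ones(7)])
        assert H == 0.0
        assert p == 1.0

    def test_separated_groups_match_rank_formula(self):
        groups = [np.array([1.0, 2, 3]), np.array([4.0, 5, 6]), np.array([7.0, 8, 9])]
        H, p = rp.kruskal_wallis(groups)
        # brute-force rank-sum formula (no ties)
        N = 9
        rank_sums = [6.0, 15.0, 24.0]
        H_ref = 12 / (N * (N + 1)) * sum(R**2 / 3 for R in rank_sums) - 3 * (N + 1)
        assert H == pytest.approx(H_ref, abs=1e-12)

    def test_label_order_invariance(self):
        gs = random_groups(5)
        assert rp.kruskal_wallis(gs) == pytest.approx(
            rp.kruskal_wallis(gs[::-1]), abs=1e-12
        )

    @pytest.mark.parametrize("seed,ties", [(0, False), (1, True), (2, True)])
    def test_matches_scipy_reference(self, seed, ties):
        gs = random_groups(seed, ties=ties)
        H, p = rp.kruskal_wallis(gs)
        ref = sps.kruskal(*gs)
        assert H == pytest.approx(ref.statistic, abs=1e-8)
        assert p == pytest.approx(ref.pvalue, abs=1e-8)


class TestSteelDwass:
    def test_symmetry(self):
        gs = random_groups(3)
        P = rp.steel_dwass(gs)
        M = P.to_numpy()
        np.testing.assert_allclose(M, M.T, equal_nan=True)
        assert np.isnan(np.diag(M)).all()

    def test_widely_separated_pair(self):
        a = np.arange(1.0, 11.0)
        b = np.arange(101.0, 111.0)
        P = rp.steel_dwass([a, b])
        assert P.iloc[0, 1] < 0.01

    def test_k2_reduces_to_wilcoxon_normal_approximation(self):
        rng = np.random.default_rng(7)
        a = np.round(rng.normal(0, 1, 15), 1)  # include ties
        b = np.round(rng.normal(0.8, 1, 12), 1)
        P = rp.steel_dwass([a, b])
        # tie-corrected normal approximation, two-sided
        pooled = np.concatenate([a, b])
        N = pooled.size
        ranks = sps.rankdata(pooled)
        W = ranks[a.size :].sum()
        E = b.size * (N + 1) / 2
        V = a.size * b.size / (N * (N - 1)) * ((ranks**2).sum() - N * (N + 1) ** 2 / 4)
        p_ref = 2 * sps.norm.sf(abs(W - E) / np.sqrt(V))
        assert P.iloc[0, 1] == pytest.approx(p_ref, abs=1e-6)

    @settings(deadline=None, max_examples=15)
    @given(seed=st.integers(0, 10_000), k=st.integers(2, 4))
    def test_never_smaller_than_unadjusted_wilcoxon(self, seed, k):
        gs = random_groups(seed, k=k, n=8, ties=True)
        P = rp.steel_dwass(gs).to_numpy()
        for i in range(k):
            for j in range(i + 1, k):
                pooled = np.concatenate([gs[i], gs[j]])
                N = pooled.size
                ranks = sps.rankdata(pooled)
                W = ranks[gs[i].size :].sum()
                E = gs[j].size * (N + 1) / 2
                V = (
                    gs[i].size
                    * gs[j].size
                    / (N * (N - 1))
                    * ((ranks**2).sum() - N * (N + 1) ** 2 / 4)
                )
                if V <= 0:
                    continue
                p_wilcox = 2 * sps.norm.sf(abs(W - E) / np.sqrt(V))
                assert P[i, j] >= p_wilcox - 1e-12

    def test_small_group_rejected(self):
        with pytest.raises(rp.ParameterError):
            rp.steel_dwass([np.array([1.0]), np.array([1.0, 2.0])])


class TestBrunnerMunzel:
    def test_identical_samples_relative_effect_half(self):
        a = np.array([1.0, 2, 3, 4, 5])
        res = rp.brunner_munzel(a, a.copy())
        assert res.relative_effect == pytest.approx(0.5)

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 14)
        r1 = rp.brunner_munzel(a, b)
        r2 = rp.brunner_munzel(b, a)
        assert r1.relative_effect == pytest.approx(1 - r2.relative_effect)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.pvalue == pytest.approx(r2.pvalue)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scipy_reference(self, seed):
        rng = np.random.default_rng(seed)
        a = np.round(rng.normal(0, 1, 13), 1)
        b = np.round(rng.normal(0.6, 2, 17), 1)
        mine = rp.brunner_munzel(a, b)
        ref = sps.brunnermunzel(a, b)
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-8)
        assert mine.pvalue == pytest.approx(ref.pvalue, abs=1e-8)

    def test_bonferroni_multiplication(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 20), rng.normal(0.7, 1, 20)
        res = rp.brunner_munzel(a, b, correction_family_size=4)
        assert res.pvalue_bonferroni == pytest.approx(min(1.0, res.pvalue * 4))

    def test_all_tied_degenerate(self):
        res = rp.brunner_munzel(np.ones(5), np.ones(6))
        assert res.degenerate
        assert res.pvalue == 1.0
        assert res.relative_effect == pytest.approx(0.5)

    def test_complete_separation(self):
        res = rp.brunner_munzel(np.zeros(5), np.ones(6))
        assert res.degenerate
        assert res.pvalue == 0.0
        assert res.relative_effect == pytest.approx(1.0)


class TestBonferroni:
    def test_printed_family_of_nine(self):
        assert rp.bonferroni_threshold(0.05, 9) == pytest.approx(0.0056, abs=5e-5)

    def test_single_test(self):
        assert rp.bonferroni_threshold(0.05, 1) == 0.05

    def test_quarter(self):
        assert rp.bonferroni_threshold(0.01, 4) == pytest.approx(0.0025)

    def test_invalid(self):
        with pytest.raises(rp.ParameterError):
            rp.bonferroni_threshold(0.05, 0)
        with pytest.raises(rp.ParameterError):
            rp.bonferroni_threshold(1.5, 2)


class TestCompactLetters:
    @staticmethod
    def check_iff(P, letters, labels, alpha=0.05):
        for i, li in enumerate(labels):
            for j, lj in enumerate(labels):
                if i >= j:
                    continue
                share = bool(set(letters[li]) & set(letters[lj]))
                significant = P[i, j] < alpha
                assert share != significant, (
                    f"{li}({letters[li]}) vs {lj}({letters[lj]}), p={P[i, j]}"
                )

    def test_no_differences_single_letter(self):
        P = np.full((4, 4), 0.9)
        np.fill_diagonal(P, np.nan)
        letters = rp.compact_letters(P)
        assert all(v == "a" for v in letters.values())

    def test_all_different_distinct_letters(self):
        P = np.full((3, 3), 0.001)
        np.fill_diagonal(P, np.nan)
        letters = rp.compact_letters(P)
        vals = list(letters.values())
        assert len(set(vals)) == 3
        assert all(len(v) == 1 for v in vals)

    def test_chain_pattern(self):
        # only pair (0, 2) significant -> a, ab, b
        P = np.array(
            [[np.nan, 0.5, 0.01], [0.5, np.nan, 0.2], [0.01, 0.2, np.nan]]
        )
        letters = rp.compact_letters(P, labels=["g0", "g1", "g2"])
        assert letters == {"g0": "a", "g1": "ab", "g2": "b"}

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 100_000), k=st.integers(2, 6))
    def test_iff_sharing_property(self, seed, k):
        rng = np.random.default_rng(seed)
        P = np.full((k, k), np.nan)
        iu = np.triu_indices(k, 1)
        vals = rng.uniform(0, 1, iu[0].size) ** 2  # skew toward significance
        P[iu] = vals
        P[(iu[1], iu[0])] = vals
        labels = [f"g{i}" for i in range(k)]
        letters = rp.compact_letters(P, labels=labels)
        assert all(letters[lab] for lab in labels)  # every group lettered
        self.check_iff(P, letters, labels)


class TestCompareGroups:
    def test_steel_dwass_report(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "group": ["a"] * 15 + ["b"] * 15 + ["c"] * 15,
                "SI": np.concatenate(
                    [
                        rng.uniform(0.9, 1.0, 15),
                        rng.uniform(0.9, 1.0, 15),
                        rng.uniform(0.5, 0.6, 15),
                    ]
                ),
            }
        )
        cmp_res = rp.compare_groups(df, "SI")
        assert cmp_res.omnibus_p < 0.01
        assert cmp_res.letters["a"] == cmp_res.letters["b"]
        assert not set(cmp_res.letters["a"]) & set(cmp_res.letters["c"])

    def test_brunner_munzel_family_correction(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "group": ["a"] * 20 + ["b"] * 20,
                "x": np.concatenate([rng.normal(0, 1, 20), rng.normal(0.4, 1, 20)]),
            }
        )
        res = rp.compare_groups(df, "x", method="brunner_munzel", family_size=4)
        raw = rp.brunner_munzel(
            df.x[df.group == "a"].to_numpy(), df.x[df.group == "b"].to_numpy()
        )
        assert res.pairwise_p.loc["a", "b"] == pytest.approx(
            min(1.0, raw.pvalue * 4)
        )
        assert res.correction == "bonferroni"
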