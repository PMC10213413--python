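"""Screening statistics: exact Wilcoxon, BH-FDR, effect sizes, diversity, ddCt."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ammonet.data_model import FeatureTable
from ammonet.screen import (
    GateConfig,
    ace_index,
    bh_adjust,
    ddct_fold_change,
    log2_fold_change,
    screen_table,
    shannon_index,
    wilcoxon_rank_sum,
)


def enumeration_oracle(x, y):
    """Independent exact two-sided p: enumerate every rank split directly."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    sums = [sum(c) for c in combinations(ranks, n1)]
    total = len(sums)
    lo = sum(1 for s in sums if s <= w_obs + 1e-9) / total
    hi = sum(1 for s in sums if s >= w_obs - 1e-9) / total
    return min(1.0, 2.0 * min(lo, hi))


class TestWilcoxon:
    def test_fully_separated_triples(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="exact")
        assert p == pytest.approx(0.1)

    def test_fully_separated_pairs(self):
        _, p = wilcoxon_rank_sum([1, 2], [3, 4], mode="exact")
        assert p == pytest.approx(1.0 / 3.0)

    def test_identical_constant_groups(self):
        _, p = wilcoxon_rank_sum([5, 5, 5], [5, 5, 5], mode="exact")
        assert p == pytest.approx(1.0)

    def test_requires_two_observations(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1], [2, 3])

    def test_matches_enumeration_oracle_tie_free(self):
        rng = np.random.default_rng(5)
        for _ in range(80):
            n1 = int(rng.integers(2, 7))
            n2 = int(rng.integers(2, 13 - n1))
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            _, p = wilcoxon_rank_sum(x, y, mode="exact")
            assert p == pytest.approx(enumeration_oracle(x, y), abs=1e-12)

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(6)
        for _ in range(40):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            _, p = wilcoxon_rank_sum(x, y, mode="exact")
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_tied_inputs_use_seeded_permutations(self):
        x, y = [1, 1, 2], [2, 3, 3]
        _, p1 = wilcoxon_rank_sum(x, y, mode="exact", seed=3)
        _, p2 = wilcoxon_rank_sum(x, y, mode="exact", seed=3)
        assert p1 == p2
        assert 0 < p1 <= 1

    def test_approx_close_to_exact_for_moderate_n(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=7)
        y = rng.normal(size=7) + 1.0
        _, p_exact = wilcoxon_rank_sum(x, y, mode="exact")
        _, p_approx = wilcoxon_rank_sum(x, y, mode="approx")
        assert p_approx == pytest.approx(p_exact, abs=0.05)


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ((0.005, 0.01, 0.03), (0.015, 0.015, 0.03)),
            ((0.01, 0.04), (0.02, 0.04)),
            ((0.5, 0.5, 0.5), (0.5, 0.5, 0.5)),
        ],
    )
    def test_hand_computed_vectors(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected, abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_statsmodels_and_is_monotone(self, p):
        q = bh_adjust(p)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert q == pytest.approx(q_ref, abs=1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= np.asarray(p) - 1e-12)

    def test_constant_vector_unchanged(self):
        assert bh_adjust([0.2] * 5) == pytest.approx([0.2] * 5, abs=1e-12)


class TestLog2FoldChange:
    def test_closed_form(self):
        assert log2_fold_change([8, 8], [2, 2]) == pytest.approx(2.0)

    def test_identity(self):
        assert log2_fold_change([3, 5], [3, 5]) == pytest.approx(0.0)

    def test_zero_mean_regularised(self):
        v = log2_fold_change([1, 1], [0, 0], pseudocount=1e-6)
        assert np.isfinite(v) and v > 0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            log2_fold_change([-1, 2], [1, 2])

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(st.floats(min_value=0.01, max_value=100), min_size=2, max_size=6),
        st.lists(st.floats(min_value=0.01, max_value=100), min_size=2, max_size=6),
    )
    def test_antisymmetric_under_group_swap(self, x, y):
        assert log2_fold_change(x, y) == pytest.approx(-log2_fold_change(y, x), abs=1e-9)


class TestDiversity:
    def test_shannon_uniform(self):
        assert shannon_index([1, 1, 1, 1]) == pytest.approx(np.log(4), abs=1e-12)

    def test_shannon_single_taxon(self):
        assert shannon_index([0, 7, 0]) == 0.0

    def test_shannon_hand_value(self):
        assert shannon_index([0.5, 0.25, 0.25]) == pytest.approx(1.039721, abs=1e-6)

    def test_shannon_rejects_all_zero(self):
        with pytest.raises(ValueError):
            shannon_index([0, 0])

    def test_shannon_maximal_at_uniform(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            k = int(rng.integers(2, 10))
            assert shannon_index(rng.dirichlet(np.ones(k))) <= np.log(k) + 1e-12

    def test_ace_no_rare_species(self):
        assert ace_index([20, 15, 12]).ace == pytest.approx(3.0)

    def test_ace_all_singletons_falls_back_to_chao1(self):
        res = ace_index([1, 1])
        assert res.chao1_fallback
        # bias-corrected Chao1: 2 + 1*0/... = 2 + 1*(1-... F1=2,F2=0 -> 2+2*1/2=3
        assert res.ace == pytest.approx(2 + 2 * 1 / 2)

    def test_ace_hand_derived_value(self):
        # counts (1,2,3,25), cutoff 10: S_abund=1, rare={1,2,3}: S_rare=3,
        # N_rare=6, F1=1, C_ace=5/6; sum i(i-1)F_i = 2+6 = 8;
        # gamma^2 = max(3/(5/6) * 8/30 - 1, 0) = max(0.96-1,0) = 0
        # ACE = 1 + 3/(5/6) + 0 = 4.6
        res = ace_index([1, 2, 3, 25])
        assert res.ace == pytest.approx(4.6, abs=1e-12)
        assert res.gamma_sq == 0.0

    def test_ace_requires_integers(self):
        with pytest.raises(ValueError):
            ace_index([0.5, 1.2])


class TestDdct:
    def test_hand_arithmetic(self):
        res = ddct_fold_change(20, 15, 22, 15)
        assert res.ddct == pytest.approx(-2.0)
        assert res.fold_change == pytest.approx(4.0)

    def test_equal_deltas_give_unity(self):
        assert ddct_fold_change(21, 16, 25, 20).fold_change == pytest.approx(1.0)

    def test_positive_ddct_halves(self):
        assert ddct_fold_change(22, 15, 21, 15).fold_change == pytest.approx(0.5)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ddct_fold_change(float("nan"), 15, 22, 15)


def _table_from(values, layer="muscle_metabolome", level="metabolite", n=6):
    cols = [f"s{i:02d}" for i in range(1, 2 * n + 1)]
    return FeatureTable(layer=layer, level=level,
                        data=pd.DataFrame(values, columns=cols,
                                          index=[f"f{i}" for i in range(len(values))]))


def _meta(n=6):
    from ammonet.data_model import SampleMetadata

    rows = [
        {"sample_id": f"s{i:02d}", "subject_id": f"R{i:02d}",
         "group": "high" if i <= n else "low", "sex": ""}
        for i in range(1, 2 * n + 1)
    ]
    return SampleMetadata(pd.DataFrame(rows))


class TestScreenTable:
    def _mixed_table(self, seed=0, n=6):
        rng = np.random.default_rng(seed)
        base = rng.lognormal(3, 0.4, size=(30, 2 * n))
        base[0, :n] *= 16.0  # strongly shifted feature
        return _table_from(base, layer="lung_transcriptome", level="gene", n=n)

    def test_gene_gate_needs_both_q_and_fold(self):
        # a clear fold change with a weak q must not pass the gene gate
        res = screen_table(self._mixed_table(), _meta(),
                           gate=GateConfig(max_q=1e-6, min_abs_log2fc=1.0))
        assert not res["is_biomarker"].any()

    def test_shifted_feature_flagged_with_default_gene_gate(self):
        res = screen_table(self._mixed_table(), _meta())
        row = res.set_index("feature_id").loc["f0"]
        assert row["log2fc"] > 1.0
        assert row["p_raw"] == pytest.approx(2.0 / 924.0)

    def test_group_swap_negates_log2fc_keeps_p(self):
        table = self._mixed_table()
        meta = _meta()
        flipped = meta.data.copy()
        flipped["group"] = flipped["group"].map({"high": "low", "low": "high"})
        from ammonet.data_model import SampleMetadata

        res_a = screen_table(table, meta)
        res_b = screen_table(table, SampleMetadata(flipped))
        assert np.allclose(res_a["log2fc"], -res_b["log2fc"])
        assert np.allclose(res_a["p_raw"], res_b["p_raw"])
        assert (res_a["direction"] != res_b["direction"]).all()

    def test_invariant_to_sample_column_order(self):
        table = self._mixed_table()
        meta = _meta()
        rng = np.random.default_rng(1)
        perm = rng.permutation(table.sample_ids)
        shuffled = FeatureTable(table.layer, table.level, table.data[list(perm)])
        res_a = screen_table(table, meta).set_index("feature_id")
        res_b = screen_table(shuffled, meta).set_index("feature_id")
        assert np.allclose(res_a["p_raw"], res_b["p_raw"])
        assert np.allclose(res_a["log2fc"], res_b["log2fc"])

    def test_requires_three_per_group(self):
        table = self._mixed_table(n=2)
        with pytest.raises(ValueError):
            screen_table(table, _meta(n=2))

    def test_vip_gate(self):
        table = self._mixed_table()
        vip = pd.Series(0.0, index=table.feature_ids)
        vip["f0"] = 1.5
        res = screen_table(table, _meta(),
                           gate=GateConfig(max_q=1.01, min_vip=1.0), vip=vip)
        assert res.set_index("feature_id")["is_biomarker"]["f0"]
        assert res["is_biomarker"].sum() == 1
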