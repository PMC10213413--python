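"""Spearman networks: correlation, permutation inference, edge gating, I/O."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ammonet.data_model import FeatureTable, SampleMetadata, align_samples
from ammonet.netbuild import (
    EdgeGate,
    build_network,
    permutation_pvalue,
    read_graphml,
    spearman_rho,
    write_edges_tsv,
    write_graphml,
)


class TestSpearman:
    def test_monotone_identity(self):
        assert spearman_rho([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_reversal(self):
        assert spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_mid_rank_hand_value(self):
        # tied mid-ranks: Pearson of ranks = 4.5 / sqrt(22.5)
        rho = spearman_rho([1, 2, 2, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(4.5 / np.sqrt(22.5), abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            x, y = rng.normal(size=(2, 10))
            assert spearman_rho(x, y) == pytest.approx(
                stats.spearmanr(x, y).statistic, abs=1e-12
            )

    def test_constant_vector_returns_nan(self):
        assert np.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))


class TestPermutationP:
    def test_exhaustive_three_points(self):
        assert permutation_pvalue([1, 2, 3], [10, 20, 30]) == pytest.approx(2.0 / 6.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(2, 10))
        assert permutation_pvalue(x, y, seed=9) == permutation_pvalue(x, y, seed=9)

    def test_null_p_approximately_uniform_exhaustive(self):
        # exhaustive enumeration at n = 6 gives exact p-values, which are
        # uniform under independence up to the permutation lattice
        rng = np.random.default_rng(2)
        ps = [
            permutation_pvalue(rng.normal(size=6), rng.normal(size=6))
            for _ in range(200)
        ]
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_null_monte_carlo_p_is_valid(self):
        # the (1+k)/(n_perm+1) convention must not anti-conservatively
        # exceed the nominal level under independence
        rng = np.random.default_rng(12)
        ps = np.array([
            permutation_pvalue(rng.normal(size=10), rng.normal(size=10),
                               n_perm=199, seed=s)
            for s in range(200)
        ])
        for alpha in (0.05, 0.1, 0.25):
            se = np.sqrt(alpha * (1 - alpha) / ps.size)
            assert (ps <= alpha).mean() <= alpha + 3 * se

    def test_rejects_tiny_n_perm(self):
        with pytest.raises(ValueError):
            permutation_pvalue([1, 2, 3], [1, 2, 3], n_perm=10)


def dataset_from_matrix(matrix, layer="muscle_metabolome", level="metabolite",
                        n_high=6, n_low=6):
    n = n_high + n_low
    subjects = [f"R{i:02d}" for i in range(1, n + 1)]
    cols = [f"m-{s}" for s in subjects]
    meta = SampleMetadata(pd.DataFrame(
        [{"sample_id": c, "subject_id": s,
          "group": "high" if i < n_high else "low", "sex": ""}
         for i, (c, s) in enumerate(zip(cols, subjects))]
    ))
    table = FeatureTable(layer, level, pd.DataFrame(
        matrix, columns=cols, index=[f"f{i:03d}" for i in range(len(matrix))]
    ))
    return align_samples([table], meta), [f"f{i:03d}" for i in range(len(matrix))]


class TestBuildNetwork:
    def test_duplicated_feature_forces_edge(self):
        rng = np.random.default_rng(3)
        row = rng.normal(size=12)
        matrix = np.vstack([row, row + 100.0, rng.normal(size=(3, 12))])
        ds, feats = dataset_from_matrix(np.exp(matrix))
        net = build_network(
            ds, {("muscle_metabolome", "metabolite"): feats},
            gate=EdgeGate(min_abs_rho=0.8, max_q=0.05), scope="all_pairs",
            group_filter="both", seed=0,
        )
        assert ("f000", "f001") in net.edges
        assert net.rho("f000", "f001") == pytest.approx(1.0)

    def test_unsatisfiable_gate_keeps_nodes_but_no_edges(self):
        rng = np.random.default_rng(4)
        ds, feats = dataset_from_matrix(rng.lognormal(size=(4, 12)))
        net = build_network(
            ds, {("muscle_metabolome", "metabolite"): feats},
            gate=EdgeGate(min_abs_rho=1.01), scope="all_pairs",
            group_filter="both",
        )
        assert net.edges == []
        assert net.nodes == sorted(feats)

    def test_gate_is_monotone(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=12)
        matrix = np.exp(base + rng.normal(scale=0.4, size=(6, 12)))
        ds, feats = dataset_from_matrix(matrix)
        key = ("muscle_metabolome", "metabolite")
        loose = build_network(ds, {key: feats}, gate=EdgeGate(min_abs_rho=0.3, max_q=0.3),
                              scope="all_pairs", group_filter="both", seed=1)
        tight = build_network(ds, {key: feats}, gate=EdgeGate(min_abs_rho=0.7, max_q=0.05),
                              scope="all_pairs", group_filter="both", seed=1)
        assert set(tight.edges) <= set(loose.edges)

    def test_fdr_contract_under_null(self):
        # independent features: kept-edge fraction stays near the BH level
        rng = np.random.default_rng(6)
        kept = tested = 0
        for s in range(5):
            ds, feats = dataset_from_matrix(
                np.exp(np.random.default_rng(s).normal(size=(12, 12))))
            net = build_network(
                ds, {("muscle_metabolome", "metabolite"): feats},
                gate=EdgeGate(min_abs_rho=0.0, max_q=0.05), scope="all_pairs",
                group_filter="both", seed=s,
            )
            kept += net.graph.n_edges
            tested += net.n_pairs_tested
        assert kept / tested <= 0.05

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(7)
        ds, feats = dataset_from_matrix(rng.lognormal(size=(3, 8)), n_high=4, n_low=4)
        with pytest.raises(ValueError, match="matched subjects"):
            build_network(ds, {("muscle_metabolome", "metabolite"): feats},
                          gate=EdgeGate(min_n=6), group_filter="high")

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        ds, feats = dataset_from_matrix(rng.lognormal(size=(6, 12)))
        key = ("muscle_metabolome", "metabolite")
        a = build_network(ds, {key: feats}, scope="all_pairs",
                          group_filter="both", seed=3)
        b = build_network(ds, {key: feats}, scope="all_pairs",
                          group_filter="both", seed=3)
        assert a.edges == b.edges
        assert a.edge_attrs == b.edge_attrs


class TestSerialisation:
    def _network(self):
        rng = np.random.default_rng(9)
        row = rng.normal(size=12)
        matrix = np.exp(np.vstack([row, row * 2 + 1, rng.normal(size=(2, 12))]))
        ds, feats = dataset_from_matrix(matrix)
        return build_network(ds, {("muscle_metabolome", "metabolite"): feats},
                             gate=EdgeGate(min_abs_rho=0.5), scope="all_pairs",
                             group_filter="both", seed=0)

    def test_graphml_round_trip(self, tmp_path):
        net = self._network()
        p = tmp_path / "net.graphml"
        write_graphml(net, p)
        back = read_graphml(p)
        assert back.nodes == net.nodes
        assert back.edges == net.edges
        for e, attrs in net.edge_attrs.items():
            for k, v in attrs.items():
                assert back.edge_attrs[e][k] == pytest.approx(v, abs=0, rel=0)
        assert back.node_attrs == net.node_attrs

    def test_edges_tsv_columns(self, tmp_path):
        net = self._network()
        p = tmp_path / "edges.tsv"
        write_edges_tsv(net, p)
        df = pd.read_csv(p, sep="\t")
        assert list(df.columns) == ["node_a", "node_b", "rho", "p_perm",
                                    "q_fdr", "layer_a", "layer_b"]
        assert len(df) == net.graph.n_edges
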