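"""Core-community extraction, integration and the end-to-end pipeline."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ammonet.graphcore import Graph
from ammonet.integrate import (
    PipelineConfig,
    build_integrated_network,
    extract_core_community,
    rank_key_features,
    run_pipeline,
)
from ammonet.netbuild import EdgeGate, OmicsNetwork
from ammonet.synthetic_data import SimConfig, generate_dataset


def network_from(edges, rhos=None, nodes=(), layer="lung_transcriptome",
                 level="gene"):
    g = Graph(nodes=nodes, edges=edges)
    attrs = {n: {"layer": layer, "level": level} for n in g.nodes}
    edge_attrs = {}
    for i, (u, v) in enumerate(g.edges):
        rho = 0.9 if rhos is None else rhos[(u, v)]
        edge_attrs[(u, v)] = {"rho": rho, "p_perm": 0.001, "q_fdr": 0.01}
    return OmicsNetwork(g, attrs, edge_attrs)


class TestExtractCore:
    def test_two_triangles_tie_broken_by_mean_abs_rho(self):
        edges = [("a", "b"), ("a", "c"), ("b", "c"),
                 ("d", "e"), ("d", "f"), ("e", "f"), ("c", "d")]
        rhos = {e: 0.85 for e in [("a", "b"), ("a", "c"), ("b", "c"), ("c", "d")]}
        rhos.update({e: 0.95 for e in [("d", "e"), ("d", "f"), ("e", "f")]})
        net = network_from(edges, rhos)
        assert extract_core_community(net) == ["d", "e", "f"]

    def test_connected_clique_returns_everything(self):
        edges = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")]
        net = network_from(edges)
        assert extract_core_community(net) == ["a", "b", "c", "d"]

    def test_single_node(self):
        net = network_from([], nodes=["only"])
        assert extract_core_community(net) == ["only"]

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            extract_core_community(network_from([]))

    def test_remaining_tie_lexicographic(self):
        # two disjoint edges with identical rho: the lexicographically
        # smallest member set wins
        net = network_from([("c", "d"), ("a", "b")],
                           rhos={("a", "b"): 0.9, ("c", "d"): 0.9})
        assert extract_core_community(net) == ["a", "b"]


class TestRankKeyFeatures:
    def test_star_centre_under_top_k(self):
        edges = [("hub", f"leaf{i}") for i in range(5)]
        net = network_from(edges)
        df = rank_key_features(net, rule=("top_k", 1))
        assert df.iloc[0]["node_id"] == "hub"
        assert df.iloc[0]["mcc"] == 5
        assert list(df.loc[df["selected"], "node_id"]) == ["hub"]

    def test_all_isolated_quantile_selects_all(self):
        net = network_from([], nodes=["a", "b", "c", "d"])
        df = rank_key_features(net, rule=("mcc_quantile", 0.90))
        assert df["selected"].all()
        assert (df["mcc"] == 1).all()

    def test_bridge_nodes_outrank_triangle_interiors(self):
        edges = [("a", "b"), ("a", "c"), ("b", "c"),
                 ("d", "e"), ("d", "f"), ("e", "f"), ("c", "d")]
        df = rank_key_features(network_from(edges), rule=("top_k", 2))
        selected = set(df.loc[df["selected"], "node_id"])
        assert selected == {"c", "d"}
        assert df.set_index("node_id")["mcc"]["c"] == 3  # 2! + 1!

    def test_boundary_ties_all_included(self):
        # top_k=1 on a symmetric triangle keeps all three tied nodes
        df = rank_key_features(network_from([("a", "b"), ("b", "c"), ("a", "c")]),
                               rule=("top_k", 1))
        assert df["selected"].all()


class TestBuildIntegrated:
    def test_needs_two_contributing_layers(self):
        ds, truth = generate_dataset(SimConfig(seed=0))
        cores = {("lung_transcriptome", "gene"): ["lung_gene0001", "lung_gene0002"]}
        with pytest.raises(ValueError, match=">= 2 layers"):
            build_integrated_network(ds, cores)

    def test_empty_core_layer_absent_from_nodes(self):
        ds, truth = generate_dataset(SimConfig(seed=0))
        cores = {
            ("lung_transcriptome", "gene"): ["lung_gene0001", "lung_gene0002"],
            ("muscle_metabolome", "metabolite"): ["muscle_met0001"],
            ("nasal_microbiome", "genus"): [],
        }
        net = build_integrated_network(ds, cores, gate=EdgeGate(min_abs_rho=0.99))
        assert all(not n.startswith("nasal") for n in net.nodes)
        assert set(net.nodes) == {"lung_gene0001", "lung_gene0002", "muscle_met0001"}

    def test_shared_factor_creates_cross_layer_edges(self):
        # block members of different layers share a latent factor at
        # loading 0.95 over 12 subjects -> cross-layer edges survive the gate
        cfg = SimConfig(seed=3, taxon_log2fc=0.0, gene_log2fc=0.0,
                        metabolite_shift_sd=0.0)
        ds, truth = generate_dataset(cfg)
        blocks = truth.features[truth.features["block_id"] > 0]
        cores = {
            (layer, level): sorted(sub["feature_id"])
            for (layer, level), sub in blocks.groupby(["layer", "level"])
        }
        net = build_integrated_network(
            ds, cores, gate=EdgeGate(min_abs_rho=0.6), group_filter="both", seed=3
        )
        cross = [
            (u, v) for u, v in net.edges
            if net.node_attrs[u]["layer"] != net.node_attrs[v]["layer"]
        ]
        assert len(cross) > 0


class TestRunPipeline:
    def _config(self, tmp_path, seed=0):
        return PipelineConfig(layers=[], metadata_path="",
                              outdir=str(tmp_path), seed=seed)

    def test_deterministic_report(self, tmp_path):
        cfg = SimConfig(seed=5, n_taxa=20, n_genes=40, n_metabolites=60,
                        n_diff_taxa=8, n_diff_genes=12, n_diff_metabolites=12)
        ds, _ = generate_dataset(cfg)
        r1 = run_pipeline(self._config(tmp_path / "a", seed=5), dataset=ds)
        r2 = run_pipeline(self._config(tmp_path / "b", seed=5), dataset=ds)
        assert r1.report == r2.report
        assert (tmp_path / "a" / "report.json").read_bytes() == \
            (tmp_path / "b" / "report.json").read_bytes()

    def test_zero_effects_propagate_without_crashing(self, tmp_path):
        cfg = SimConfig(seed=6, taxon_log2fc=0.0, gene_log2fc=0.0,
                        metabolite_shift_sd=0.0, loading=0.05,
                        exposure_loading=0.0, with_hubs=False,
                        n_taxa=20, n_genes=40, n_metabolites=60,
                        n_diff_taxa=8, n_diff_genes=12, n_diff_metabolites=12)
        ds, _ = generate_dataset(cfg)
        result = run_pipeline(self._config(tmp_path, seed=6), dataset=ds)
        stages = result.report["stages"]
        assert stages["integrated_nodes"] <= sum(stages["core_sizes"].values())

    def test_stage_count_consistency_and_provenance(self, tmp_path):
        ds, _ = generate_dataset(SimConfig(seed=7))
        result = run_pipeline(self._config(tmp_path, seed=7), dataset=ds)
        stages = result.report["stages"]
        assert stages["integrated_nodes"] <= sum(stages["core_sizes"].values())
        assert stages["n_key_features"] <= stages["integrated_nodes"]
        # every key feature traces back to a flagged biomarker
        biomarkers = set()
        for df in result.screens.values():
            biomarkers |= set(df.loc[df["is_biomarker"], "feature_id"])
        selected = result.key_features.loc[result.key_features["selected"], "node_id"]
        assert set(selected) <= biomarkers

    def test_artifacts_written(self, tmp_path):
        ds, _ = generate_dataset(SimConfig(seed=8, n_taxa=20, n_genes=40,
                                           n_metabolites=60, n_diff_taxa=8,
                                           n_diff_genes=12, n_diff_metabolites=12))
        run_pipeline(self._config(tmp_path, seed=8), dataset=ds)
        for name in ["core_features.tsv", "integrated_network.tsv",
                     "integrated_network.graphml", "integrated_partition.tsv",
                     "key_features.tsv", "report.json"]:
            assert (tmp_path / name).exists()
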