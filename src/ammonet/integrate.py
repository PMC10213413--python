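"""Two-stage multi-omics integration.

Stage 1 builds a Spearman network per omic layer from that layer's
biomarkers and extracts its *core community*: the largest community of the
best-modularity Girvan-Newman partition (size ties broken by highest mean
|rho| over internal edges, then by lexicographically smallest member set).

Stage 2 pools the core features of all layers, recomputes the correlation
network over every within- and cross-layer pair (cross-layer edges cannot
exist otherwise), partitions the integrated network with Girvan-Newman, and
ranks nodes by maximal clique centrality.  Key features are the nodes at or
above the 90th MCC percentile by default (boundary ties all included); a
top-k rule is available for exact-k emulation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (
    AlignedDataset,
    FeatureTable,
    SampleMetadata,
    align_samples,
    read_feature_table,
    read_metadata,
)
from .graphcore import CommunityPartition, girvan_newman, mcc_scores
from .netbuild import (
    EdgeGate,
    OmicsNetwork,
    build_network,
    write_edges_tsv,
    write_graphml,
)
from .plsvip import screen_metabolites
from .screen import default_gate, screen_table

logger = logging.getLogger(__name__)

__all__ = [
    "extract_core_community",
    "build_integrated_network",
    "rank_key_features",
    "PipelineConfig",
    "IntegrationResult",
    "run_pipeline",
]


def extract_core_community(network: OmicsNetwork) -> List[str]:
    """Core community of a per-omic network.

    Girvan-Newman best-Q partition; core = the largest community.  Ties on
    size go to the community with the highest mean |rho| over its internal
    edges (isolated singletons score 0), remaining ties to the
    lexicographically smallest sorted member tuple.  Returns sorted node ids.
    """
    if network.graph.n_nodes == 0:
        raise ValueError("cannot extract a core from an empty network")
    best, _ = girvan_newman(network.graph)

    def mean_abs_rho(comm: frozenset) -> float:
        rhos = [
            abs(network.edge_attrs[e]["rho"])
            for e in network.edges
            if e[0] in comm and e[1] in comm
        ]
        return float(np.mean(rhos)) if rhos else 0.0

    ranked = sorted(
        best.communities,
        key=lambda c: (-len(c), -mean_abs_rho(c), tuple(sorted(c))),
    )
    return sorted(ranked[0])


def build_integrated_network(
    dataset: AlignedDataset,
    cores: Mapping[Tuple[str, str], Sequence[str]],
    gate: Optional[EdgeGate] = None,
    group_filter: str = "high",
    seed: int = 0,
) -> OmicsNetwork:
    """Pool per-layer core features and test all within- and cross-layer
    pairs in one multiplicity family.  Requires >= 2 contributing layers."""
    contributing = {k: list(v) for k, v in cores.items() if len(v) > 0}
    if len({layer for (layer, _level) in contributing}) < 2:
        raise ValueError("integration needs core features from >= 2 layers")
    net = build_network(
        dataset,
        contributing,
        gate=gate,
        scope="all_pairs",
        group_filter=group_filter,
        seed=seed,
    )
    assert isinstance(net, OmicsNetwork)
    return net


def rank_key_features(
    network: OmicsNetwork,
    rule: Tuple[str, float] = ("mcc_quantile", 0.90),
) -> pd.DataFrame:
    """Rank integrated-network nodes by maximal clique centrality.

    ``rule`` is ``('mcc_quantile', q)`` (select MCC >= the q-quantile,
    boundary ties all included) or ``('top_k', k)`` (select the k best, plus
    any node tied with the k-th).  Rows are ordered by MCC descending then
    node id ascending; ``rank`` is 1-based with equal MCC sharing the
    smallest rank.
    """
    if network.graph.n_nodes == 0:
        raise ValueError("empty network")
    scores = mcc_scores(network.graph)
    df = pd.DataFrame(
        {"node_id": list(scores), "mcc": [scores[n] for n in scores]}
    ).sort_values(["mcc", "node_id"], ascending=[False, True], ignore_index=True)
    df["rank"] = df["mcc"].rank(method="min", ascending=False).astype(int)

    kind, value = rule
    mcc = df["mcc"].to_numpy(dtype=float)
    if kind == "mcc_quantile":
        threshold = float(np.quantile(mcc, value))
        df["selected"] = df["mcc"] >= threshold
    elif kind == "top_k":
        k = int(value)
        if k < 1:
            raise ValueError("top_k requires k >= 1")
        cut = df["mcc"].iloc[min(k, len(df)) - 1]
        df["selected"] = df["mcc"] >= cut
    else:
        raise ValueError(f"unknown selection rule {kind!r}")
    df["layer"] = [network.node_attrs.get(n, {}).get("layer", "") for n in df["node_id"]]
    df["level"] = [network.node_attrs.get(n, {}).get("level", "") for n in df["node_id"]]
    return df


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class LayerSpec:
    """One input table of the pipeline."""

    layer: str
    level: str
    table_path: str


@dataclass
class PipelineConfig:
    """Configuration of one full pipeline run (YAML-serialisable)."""

    layers: List[LayerSpec]
    metadata_path: str
    outdir: str = "ammonet_out"
    seed: int = 0
    group_filter: str = "high"
    edge_gate: EdgeGate = field(default_factory=EdgeGate)
    selection_rule: Tuple[str, float] = ("mcc_quantile", 0.90)
    n_pls_components: int = 2
    base_dir: str = "."  #: input paths resolve against this (YAML location)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        layers = [LayerSpec(**d) for d in raw.pop("layers")]
        gate = EdgeGate(**raw.pop("edge_gate", {}))
        rule = raw.pop("selection_rule", ["mcc_quantile", 0.90])
        raw.pop("base_dir", None)
        return cls(layers=layers, edge_gate=gate,
                   selection_rule=(rule[0], float(rule[1])),
                   base_dir=str(path.parent), **raw)

    def resolve(self, p: str) -> Path:
        p = Path(p)
        return p if p.is_absolute() else Path(self.base_dir) / p

    def to_dict(self) -> dict:
        d = asdict(self)
        d["selection_rule"] = list(self.selection_rule)
        # run-location details are not scientific configuration; dropping
        # them keeps artifacts byte-identical across run locations
        d.pop("outdir", None)
        d.pop("base_dir", None)
        return d


@dataclass
class IntegrationResult:
    """Everything the two-stage integration produced, plus provenance."""

    screens: Dict[Tuple[str, str], pd.DataFrame]
    per_omic_networks: Dict[Tuple[str, str], OmicsNetwork]
    core_features: Dict[Tuple[str, str], List[str]]
    integrated_network: OmicsNetwork
    integrated_partition: CommunityPartition
    key_features: pd.DataFrame
    report: dict


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with a stage label."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def run_pipeline(
    config: PipelineConfig,
    dataset: Optional[AlignedDataset] = None,
    write_outputs: bool = True,
) -> IntegrationResult:
    """Execute screen -> VIP -> per-layer networks -> core communities ->
    integrated network -> Girvan-Newman -> MCC key features.

    ``dataset`` may be supplied directly (e.g. synthetic); otherwise tables
    and metadata are read from the paths in ``config``.  All outputs are
    deterministic given (inputs, config, seed): artifacts carry no
    wall-clock information.
    """
    outdir = Path(config.outdir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)

    if dataset is None:
        with _stage("load"):
            meta = read_metadata(config.resolve(config.metadata_path))
            tables = [
                read_feature_table(config.resolve(ls.table_path), ls.layer, ls.level)
                for ls in config.layers
            ]
            dataset = align_samples(tables, meta)

    screens: Dict[Tuple[str, str], pd.DataFrame] = {}
    biomarkers: Dict[Tuple[str, str], List[str]] = {}
    with _stage("screen"):
        for key, table in sorted(dataset.tables.items()):
            if table.level == "metabolite":
                res = screen_metabolites(
                    table, dataset.metadata,
                    n_components=config.n_pls_components, seed=config.seed,
                )
            else:
                res = screen_table(table, dataset.metadata, seed=config.seed)
            screens[key] = res
            biomarkers[key] = list(res.loc[res["is_biomarker"], "feature_id"])
            logger.info(
                "screen %s:%s -> %d/%d biomarkers",
                key[0], key[1], len(biomarkers[key]), len(res)
            )

    with _stage("per_omic_networks"):
        networks = build_network(
            dataset,
            {k: v for k, v in biomarkers.items() if v},
            gate=config.edge_gate,
            scope="within_layer",
            group_filter=config.group_filter,
            seed=config.seed,
        )
        assert isinstance(networks, dict)

    cores: Dict[Tuple[str, str], List[str]] = {}
    with _stage("core_communities"):
        for key, net in sorted(networks.items()):
            cores[key] = extract_core_community(net) if net.graph.n_nodes else []
            logger.info("core %s:%s -> %d features", key[0], key[1], len(cores[key]))

    with _stage("integrate"):
        contributing_layers = {k[0] for k, v in cores.items() if v}
        if len(contributing_layers) >= 2:
            integrated = build_integrated_network(
                dataset, cores, gate=config.edge_gate,
                group_filter=config.group_filter, seed=config.seed,
            )
        else:
            # degenerate run (near-empty biomarker sets): carry the few core
            # features forward as an edgeless network instead of failing
            from .graphcore import Graph

            nodes = sorted(f for v in cores.values() for f in v)
            attrs = {
                f: {"layer": k[0], "level": k[1]}
                for k, v in cores.items() for f in v
            }
            integrated = OmicsNetwork(Graph(nodes=nodes), attrs, {})
        partition, _trace = girvan_newman(integrated.graph)
        if integrated.graph.n_nodes:
            keys_df = rank_key_features(integrated, rule=config.selection_rule)
        else:
            keys_df = pd.DataFrame(
                columns=["node_id", "mcc", "rank", "selected", "layer", "level"]
            )

    report = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {
            "screened": {f"{k[0]}:{k[1]}": int(len(v)) for k, v in screens.items()},
            "biomarkers": {f"{k[0]}:{k[1]}": int(len(v)) for k, v in biomarkers.items()},
            "network_nodes": {f"{k[0]}:{k[1]}": v.graph.n_nodes for k, v in networks.items()},
            "network_edges": {f"{k[0]}:{k[1]}": v.graph.n_edges for k, v in networks.items()},
            "core_sizes": {f"{k[0]}:{k[1]}": int(len(v)) for k, v in cores.items()},
            "integrated_nodes": integrated.graph.n_nodes,
            "integrated_edges": integrated.graph.n_edges,
            "n_communities": partition.n_communities,
            "modularity_q": partition.modularity_q,
            "n_key_features": int(keys_df["selected"].sum()),
        },
    }

    result = IntegrationResult(
        screens=screens,
        per_omic_networks=networks,
        core_features=cores,
        integrated_network=integrated,
        integrated_partition=partition,
        key_features=keys_df,
        report=report,
    )
    if write_outputs:
        with _stage("write"):
            write_result(result, outdir)
    return result


def write_result(result: IntegrationResult, outdir: str | Path) -> None:
    """Write all stage artifacts (TSV/GraphML/JSON) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (layer, level), df in sorted(result.screens.items()):
        df.to_csv(outdir / f"screen_{layer}_{level}.tsv", sep="\t",
                  index=False, float_format="%.17g")
    for (layer, level), net in sorted(result.per_omic_networks.items()):
        write_edges_tsv(net, outdir / f"network_{layer}_{level}.tsv")
        write_graphml(net, outdir / f"network_{layer}_{level}.graphml")
    core_rows = [
        {"layer": k[0], "level": k[1], "feature_id": f}
        for k, feats in sorted(result.core_features.items())
        for f in feats
    ]
    pd.DataFrame(core_rows, columns=["layer", "level", "feature_id"]).to_csv(
        outdir / "core_features.tsv", sep="\t", index=False
    )
    write_edges_tsv(result.integrated_network, outdir / "integrated_network.tsv")
    write_graphml(result.integrated_network, outdir / "integrated_network.graphml")
    labels = result.integrated_partition.labels()
    pd.DataFrame(
        sorted(labels.items()), columns=["node_id", "community_id"]
    ).to_csv(outdir / "integrated_partition.tsv", sep="\t", index=False)
    result.key_features.to_csv(outdir / "key_features.tsv", sep="\t", index=False)
    (outdir / "report.json").write_text(
        json.dumps(result.report, indent=2, sort_keys=True) + "\n"
    )
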