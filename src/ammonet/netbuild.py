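"""Spearman correlation networks over matched subjects from biomarker features.

Nodes are the biomarker features of the requested layers; every candidate
pair is tested with Spearman's rho (Pearson correlation of mid-ranks) and a
two-sided permutation p-value.  With n <= 7 matched subjects the permutation
null is enumerated exhaustively (<= 5040 orderings) so p is exact; otherwise
a seeded Monte-Carlo null is used.  BH adjustment runs over all pairs tested
in one build (a single multiplicity family per network) and an edge is kept
iff q < max_q and |rho| >= min_abs_rho.  The correlation sign survives as an
edge attribute; graph algorithms downstream treat the network as unweighted.

By default networks are built on the high-exposure group only, following
the study design (biomarker interplay under high ammonia challenge); a
group filter widens this to both groups for 12-subject analyses.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import AlignedDataset
from .graphcore import Graph
from .screen import bh_adjust

__all__ = [
    "spearman_rho",
    "permutation_pvalue",
    "EdgeGate",
    "OmicsNetwork",
    "build_network",
    "write_edges_tsv",
    "write_graphml",
    "read_graphml",
]

EXHAUSTIVE_MAX_N = 7  #: enumerate all n! orderings up to here (5040)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of mid-rank vectors.

    Returns NaN (with no error) when either vector has zero rank variance;
    callers skip such pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def _perm_indices(n: int, n_perm: int, seed: int) -> Tuple[np.ndarray, bool]:
    """Permutation index matrix: exhaustive (n!, n) when n <= 7, else
    (n_perm, n) seeded draws.  Second element flags exhaustiveness."""
    if n <= EXHAUSTIVE_MAX_N:
        return np.array(list(itertools.permutations(range(n)))), True
    rng = np.random.default_rng(seed)
    return np.argsort(rng.random((n_perm, n)), axis=1), False


def permutation_pvalue(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Two-sided permutation p for Spearman's rho.

    Exhaustive: p = #{pi : |rho(x, y_pi)| >= |rho|} / n!.
    Monte-Carlo: p = (1 + #exceedances) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = spearman_rho(x, y)
    if math.isnan(obs):
        return float("nan")
    perms, exhaustive = _perm_indices(x.size, n_perm, seed)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    denom = np.linalg.norm(rx) * np.linalg.norm(ry - ry.mean())
    rho_star = (ry[perms] - ry.mean()) @ rx / denom
    exceed = int(np.sum(np.abs(rho_star) >= abs(obs) - 1e-12))
    if exhaustive:
        return exceed / len(perms)
    return (1.0 + exceed) / (len(perms) + 1.0)


@dataclass(frozen=True)
class EdgeGate:
    """Edge-retention gate: |rho| >= min_abs_rho AND BH q < max_q, over
    at least min_n matched subjects.

    The 0.8 default reflects 6-subject networks where only strong monotone
    relations are meaningful; 12-subject analyses typically relax it to 0.6.
    """

    min_abs_rho: float = 0.8
    max_q: float = 0.05
    min_n: int = 6
    n_perm: int = 999

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_abs_rho):
            raise ValueError("min_abs_rho must be >= 0")
        if not (0.0 < self.max_q <= 1.0):
            raise ValueError("max_q must be in (0, 1]")


@dataclass
class OmicsNetwork:
    """Undirected simple graph of biomarker features with Spearman edges.

    ``graph`` holds topology only; ``edge_attrs`` maps canonical edge tuples
    to rho / p_perm / q_fdr, ``node_attrs`` maps node -> layer and level.
    """

    graph: Graph
    node_attrs: Dict[str, Dict[str, str]]
    edge_attrs: Dict[Tuple[str, str], Dict[str, float]]
    n_subjects: int = 0
    n_pairs_tested: int = 0

    @property
    def nodes(self) -> List[str]:
        return self.graph.nodes

    @property
    def edges(self) -> List[Tuple[str, str]]:
        return self.graph.edges

    def rho(self, u: str, v: str) -> float:
        e = (u, v) if u <= v else (v, u)
        return self.edge_attrs[e]["rho"]


def _collect_node_matrix(
    dataset: AlignedDataset,
    features: Mapping[Tuple[str, str], Sequence[str]],
    subject_idx: np.ndarray,
) -> Tuple[List[str], np.ndarray, Dict[str, Dict[str, str]]]:
    """Stack the requested features (rows) over the selected subjects."""
    node_ids: List[str] = []
    rows: List[np.ndarray] = []
    attrs: Dict[str, Dict[str, str]] = {}
    for (layer, level), feats in sorted(features.items()):
        if not feats:
            continue
        table = dataset.tables[(layer, level)]
        sub = table.data.loc[list(feats)].to_numpy(dtype=float)[:, subject_idx]
        for f in feats:
            if f in attrs:
                raise ValueError(f"feature id {f!r} is not unique across layers")
        node_ids.extend(feats)
        rows.append(sub)
        attrs.update({f: {"layer": layer, "level": level} for f in feats})
    if not node_ids:
        raise ValueError("no biomarker features to build a network from")
    return node_ids, np.vstack(rows), attrs


def build_network(
    dataset: AlignedDataset,
    biomarkers: Mapping[Tuple[str, str], Sequence[str]],
    gate: Optional[EdgeGate] = None,
    scope: str = "within_layer",
    group_filter: str = "high",
    seed: int = 0,
) -> OmicsNetwork | Dict[Tuple[str, str], OmicsNetwork]:
    """Build Spearman network(s) over biomarker features.

    ``scope='within_layer'`` returns one network per (layer, level) with all
    within-layer pairs tested; ``scope='all_pairs'`` pools every feature and
    tests all within- and cross-layer pairs in one multiplicity family.
    ``group_filter`` selects the subjects ('high', 'low' or 'both').  Node
    sets equal the biomarker sets exactly; isolated nodes are retained so
    every biomarker stays rankable downstream.
    """
    gate = gate or EdgeGate()
    if scope not in ("within_layer", "all_pairs"):
        raise ValueError(f"unknown scope {scope!r}")
    if group_filter not in ("high", "low", "both"):
        raise ValueError(f"unknown group_filter {group_filter!r}")
    idx = dataset.group_indices(group_filter)
    if idx.size < gate.min_n:
        raise ValueError(
            f"{idx.size} matched subjects after group filter; gate requires "
            f">= {gate.min_n}"
        )
    if scope == "within_layer":
        return {
            key: _network_from_matrix(
                *_collect_node_matrix(dataset, {key: feats}, idx), gate, seed
            )
            for key, feats in sorted(biomarkers.items())
            if len(feats) > 0
        }
    node_ids, matrix, attrs = _collect_node_matrix(dataset, biomarkers, idx)
    return _network_from_matrix(node_ids, matrix, attrs, gate, seed)


def _network_from_matrix(
    node_ids: List[str],
    matrix: np.ndarray,
    node_attrs: Dict[str, Dict[str, str]],
    gate: EdgeGate,
    seed: int,
) -> OmicsNetwork:
    """Test all row pairs of ``matrix`` and keep gated edges.

    Vectorised: rank-transform rows once, then evaluate the permutation null
    for every pair simultaneously via matrix products.
    """
    n_nodes, n = matrix.shape
    graph = Graph(nodes=node_ids)
    edge_attrs: Dict[Tuple[str, str], Dict[str, float]] = {}
    if n_nodes < 2:
        return OmicsNetwork(graph, node_attrs, edge_attrs, n, 0)

    ranks = np.apply_along_axis(stats.rankdata, 1, matrix)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    degenerate = norms == 0.0  # constant rows: rho undefined, pairs skipped
    safe = np.where(degenerate, 1.0, norms)
    z = centered / safe[:, None]
    rho = z @ z.T

    perms, exhaustive = _perm_indices(n, gate.n_perm, seed)
    n_p = len(perms)
    exceed = np.zeros((n_nodes, n_nodes), dtype=np.int64)
    abs_obs = np.abs(rho) - 1e-12
    for pi in perms:
        rho_star = z @ z[:, pi].T
        exceed += np.abs(rho_star) >= abs_obs
    if exhaustive:
        p_mat = exceed / n_p
    else:
        # observed ordering is included as the +1 of the MC convention,
        # but the identity permutation also sits in `perms` only when
        # exhaustive; count it explicitly here
        p_mat = (1.0 + exceed) / (n_p + 1.0)

    iu = np.triu_indices(n_nodes, k=1)
    valid = ~(degenerate[iu[0]] | degenerate[iu[1]])
    pairs = [(iu[0][k], iu[1][k]) for k in range(len(iu[0])) if valid[k]]
    p_list = np.array([p_mat[i, j] for i, j in pairs])
    if p_list.size:
        q_list = bh_adjust(p_list)
        for (i, j), p_val, q_val in zip(pairs, p_list, q_list):
            r = rho[i, j]
            if q_val < gate.max_q and abs(r) >= gate.min_abs_rho:
                u, v = node_ids[i], node_ids[j]
                graph.add_edge(u, v)
                e = (u, v) if u <= v else (v, u)
                edge_attrs[e] = {"rho": float(r), "p_perm": float(p_val),
                                 "q_fdr": float(q_val)}
    return OmicsNetwork(graph, node_attrs, edge_attrs, n, len(pairs))


# ---------------------------------------------------------------------------
# serialisation


def write_edges_tsv(network: OmicsNetwork, path: str | Path) -> None:
    rows = []
    for (u, v) in network.edges:
        a = network.edge_attrs[(u, v)]
        rows.append(
            {
                "node_a": u,
                "node_b": v,
                "rho": a["rho"],
                "p_perm": a["p_perm"],
                "q_fdr": a["q_fdr"],
                "layer_a": network.node_attrs[u]["layer"],
                "layer_b": network.node_attrs[v]["layer"],
            }
        )
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "rho", "p_perm",
                                     "q_fdr", "layer_a", "layer_b"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


_GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"


def write_graphml(network: OmicsNetwork, path: str | Path) -> None:
    """Minimal deterministic GraphML with layer/level node attributes and
    rho/p_perm/q_fdr edge attributes."""
    ET.register_namespace("", _GRAPHML_NS)
    root = ET.Element(f"{{{_GRAPHML_NS}}}graphml")
    keys = [
        ("layer", "node", "string"), ("level", "node", "string"),
        ("rho", "edge", "double"), ("p_perm", "edge", "double"),
        ("q_fdr", "edge", "double"),
    ]
    for name, target, typ in keys:
        k = ET.SubElement(root, f"{{{_GRAPHML_NS}}}key")
        k.set("id", name)
        k.set("for", target)
        k.set("attr.name", name)
        k.set("attr.type", typ)
    g = ET.SubElement(root, f"{{{_GRAPHML_NS}}}graph")
    g.set("edgedefault", "undirected")
    for n in network.nodes:
        el = ET.SubElement(g, f"{{{_GRAPHML_NS}}}node")
        el.set("id", str(n))
        for attr, val in sorted(network.node_attrs.get(n, {}).items()):
            d = ET.SubElement(el, f"{{{_GRAPHML_NS}}}data")
            d.set("key", attr)
            d.text = str(val)
    for (u, v) in network.edges:
        el = ET.SubElement(g, f"{{{_GRAPHML_NS}}}edge")
        el.set("source", str(u))
        el.set("target", str(v))
        for attr, val in sorted(network.edge_attrs[(u, v)].items()):
            d = ET.SubElement(el, f"{{{_GRAPHML_NS}}}data")
            d.set("key", attr)
            d.text = repr(float(val))
    ET.indent(root)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def read_graphml(path: str | Path) -> OmicsNetwork:
    """Read a GraphML file written by :func:`write_graphml` (round-trip)."""
    tree = ET.parse(path)
    ns = {"g": _GRAPHML_NS}
    graph = Graph()
    node_attrs: Dict[str, Dict[str, str]] = {}
    edge_attrs: Dict[Tuple[str, str], Dict[str, float]] = {}
    for el in tree.findall(".//g:node", ns):
        nid = el.get("id")
        graph.add_node(nid)
        node_attrs[nid] = {d.get("key"): d.text for d in el.findall("g:data", ns)}
    for el in tree.findall(".//g:edge", ns):
        u, v = el.get("source"), el.get("target")
        graph.add_edge(u, v)
        e = (u, v) if u <= v else (v, u)
        edge_attrs[e] = {d.get("key"): float(d.text) for d in el.findall("g:data", ns)}
    return OmicsNetwork(graph, node_attrs, edge_attrs)
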