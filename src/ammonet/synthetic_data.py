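"""Seeded generator of matched multi-omics datasets emulating the study design.

The emulated design: two exposure groups ("high" / "low" house ammonia) of
six rabbits each (three male, three female), profiled on five layers —
nasal and colonic microbiome (genus-level counts whose 8 phylum groups are
dominated by the top five, >= 95% of mass), lung and colon transcriptomes
(negative-binomial gene counts, dispersion 0.1), and a 515-feature muscle
metabolome (log-normal intensities).

Planted structure, recorded feature-by-feature in :class:`SyntheticTruth`:

* **Differential features** per layer: genes shifted by a configured log2
  fold change, metabolites by a pooled-SD shift (log scale), taxa by a log2
  fold change before compositional closure.  A latent exposure factor
  z ~ N(delta * 1{high}, 1) contributes weak correlated noise (loading 0.2
  SD) to all planted features; the configured mean effect itself is applied
  deterministically so effect sizes are exact by construction.
* **Cross-omic correlation blocks**: each of ``n_blocks`` latent factors
  f_b ~ N(0,1) per subject loads on ``block_size`` planted-differential
  features per layer with loading lambda (feature = lambda*f_b +
  sqrt(1-lambda^2)*noise on the standardised log scale), inducing Spearman
  correlation ~ lambda^2 within a block both within and across layers.
* **Hubs**: one designated hub feature per block, an additional block
  member placed in layer b (round-robin), loading lambda on its own factor
  and sqrt(1-lambda^2) on the neighbouring block's factor with no
  idiosyncratic noise.

All randomness flows from one seed through per-layer child streams
(`numpy` SeedSequence spawning), so identical seeds give identical tables
and layer-local edits do not perturb other layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data_model import (
    AlignedDataset,
    FeatureTable,
    SampleMetadata,
    align_samples,
)
from .graphcore import Graph

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "generate_dataset",
    "planted_partition_graph",
    "truth_table",
    "read_truth",
]

MICROBIOME_LAYERS = ("nasal_microbiome", "colonic_microbiome")
TRANSCRIPTOME_LAYERS = ("lung_transcriptome", "colon_transcriptome")
METABOLOME_LAYER = "muscle_metabolome"

#: phylum base weights: top five hold 96% of mass, mirroring the dominance
#: of five phyla in both nasal and colonic communities
PHYLUM_WEIGHTS = (0.40, 0.25, 0.15, 0.10, 0.06, 0.02, 0.012, 0.008)


@dataclass
class SimConfig:
    """Study-design parameters of the generator (defaults = the emulated study).

    Effect sizes: ``taxon_log2fc`` and ``gene_log2fc`` are log2 fold changes
    of the high-group mean; ``metabolite_shift_sd`` is a mean shift in
    pooled-SD units on the log-intensity scale.  ``loading`` is the latent
    block-factor loading on the standardised feature scale.
    """

    n_per_group: int = 6
    n_taxa: int = 60
    n_genes: int = 300
    n_metabolites: int = 515
    n_diff_taxa: int = 12
    n_diff_genes: int = 100
    n_diff_metabolites: int = 70
    taxon_log2fc: float = 3.5
    gene_log2fc: float = 2.0
    metabolite_shift_sd: float = 1.5
    n_blocks: int = 3
    block_size: int = 2
    loading: float = 0.95
    with_hubs: bool = True
    nb_dispersion: float = 0.1
    sequencing_depth: int = 50_000
    exposure_delta: float = 2.0
    exposure_loading: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_per_group", "n_taxa", "n_genes", "n_metabolites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.loading < 1.0):
            raise ValueError("loading must be in (0, 1)")
        n_block_feats = self.n_blocks * self.block_size
        if n_block_feats > min(self.n_diff_taxa, self.n_diff_genes,
                               self.n_diff_metabolites):
            raise ValueError(
                "blocks exceed the planted differential features of a layer"
            )
        if self.n_diff_taxa > self.n_taxa or self.n_diff_genes > self.n_genes \
                or self.n_diff_metabolites > self.n_metabolites:
            raise ValueError("planted features exceed layer size")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset.

    ``features`` columns: feature_id, layer, level, is_planted_diff, effect,
    block_id (0 = none), planted_hub.  ``groups`` maps subject -> group.
    """

    features: pd.DataFrame
    groups: Dict[str, str]

    def planted(self, layer: Optional[str] = None) -> List[str]:
        df = self.features
        mask = df["is_planted_diff"]
        if layer is not None:
            mask = mask & (df["layer"] == layer)
        return list(df.loc[mask, "feature_id"])

    def block_members(self, layer: Optional[str] = None) -> pd.DataFrame:
        df = self.features[self.features["block_id"] > 0]
        return df if layer is None else df[df["layer"] == layer]

    def hubs(self) -> List[str]:
        return list(self.features.loc[self.features["planted_hub"], "feature_id"])


def _subjects(config: SimConfig) -> Tuple[List[str], Dict[str, str], Dict[str, str]]:
    n = config.n_per_group
    subjects = [f"R{i + 1:02d}" for i in range(2 * n)]
    groups = {s: ("high" if i < n else "low") for i, s in enumerate(subjects)}
    sexes = {s: ("M" if i % 2 == 0 else "F") for i, s in enumerate(subjects)}
    return subjects, groups, sexes


def _block_assignment(
    prefix: str, n_features: int, n_diff: int, config: SimConfig
) -> Tuple[np.ndarray, np.ndarray]:
    """(is_diff, block_id) per feature; blocks occupy the first planted slots."""
    is_diff = np.zeros(n_features, dtype=bool)
    is_diff[:n_diff] = True
    block_id = np.zeros(n_features, dtype=int)
    pos = 0
    for b in range(1, config.n_blocks + 1):
        block_id[pos:pos + config.block_size] = b
        pos += config.block_size
    return is_diff, block_id


def generate_dataset(config: SimConfig) -> Tuple[AlignedDataset, SyntheticTruth]:
    """Draw one matched multi-omics dataset plus its ground truth.

    Deterministic for a fixed ``config.seed``.
    """
    subjects, groups, sexes = _subjects(config)
    n_sub = len(subjects)
    high = np.array([groups[s] == "high" for s in subjects], dtype=float)

    root = np.random.SeedSequence(config.seed)
    ss = root.spawn(8)
    rng_common = np.random.default_rng(ss[0])
    layer_rngs = {
        "nasal_microbiome": np.random.default_rng(ss[1]),
        "colonic_microbiome": np.random.default_rng(ss[2]),
        "lung_transcriptome": np.random.default_rng(ss[3]),
        "colon_transcriptome": np.random.default_rng(ss[4]),
        METABOLOME_LAYER: np.random.default_rng(ss[5]),
    }

    # shared latent structure over subjects
    z = rng_common.normal(size=n_sub) + config.exposure_delta * high
    z_noise = z - config.exposure_delta * high  # centred exposure noise
    # block factors are orthonormalised over the subject panel (zero mean,
    # unit in-sample variance, zero in-sample cross-correlation): the
    # factors represent distinct physiological drivers, and orthogonalising
    # their finite-sample draws keeps the planted structures identifiable
    # instead of randomly confounded at n ~ 12
    raw = rng_common.normal(size=(config.n_blocks, n_sub))
    raw = raw - raw.mean(axis=1, keepdims=True)
    q, _ = np.linalg.qr(raw.T)
    factors = (q.T[: config.n_blocks]) * np.sqrt(n_sub)
    # keep each factor's sign aligned with its raw draw for determinism
    signs = np.sign((factors * raw).sum(axis=1))
    factors *= np.where(signs == 0, 1.0, signs)[:, None]

    lam = config.loading
    resid = np.sqrt(1.0 - lam * lam)

    def hub_signal(block: int) -> np.ndarray:
        """Hub subject signal: own factor at full loading, the neighbouring
        block's factor carrying the residual weight, no idiosyncratic noise."""
        nb = (block + 1) % config.n_blocks
        return lam * factors[block] + resid * factors[nb]

    tables: List[FeatureTable] = []
    truth_rows: List[dict] = []
    meta_rows: List[dict] = []

    all_layers = MICROBIOME_LAYERS + TRANSCRIPTOME_LAYERS + (METABOLOME_LAYER,)
    layer_prefix = {
        "nasal_microbiome": "nasal",
        "colonic_microbiome": "colonic",
        "lung_transcriptome": "lung",
        "colon_transcriptome": "colon",
        METABOLOME_LAYER: "muscle",
    }

    for li, layer in enumerate(all_layers):
        rng = layer_rngs[layer]
        prefix = layer_prefix[layer]
        for s in subjects:
            meta_rows.append(
                {
                    "sample_id": f"{prefix}-{s}",
                    "subject_id": s,
                    "group": groups[s],
                    "sex": sexes[s],
                }
            )
        sample_ids = [f"{prefix}-{s}" for s in subjects]

        if layer in MICROBIOME_LAYERS:
            table, rows = _simulate_microbiome(
                layer, prefix, sample_ids, high, z_noise, config, rng,
                factors, hub_signal, li,
            )
        elif layer in TRANSCRIPTOME_LAYERS:
            table, rows = _simulate_transcriptome(
                layer, prefix, sample_ids, high, z_noise, config, rng,
                factors, hub_signal, li,
            )
        else:
            table, rows = _simulate_metabolome(
                layer, prefix, sample_ids, high, z_noise, config, rng,
                factors, hub_signal, li,
            )
        tables.append(table)
        truth_rows.extend(rows)

    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    dataset = align_samples(tables, metadata)
    truth = SyntheticTruth(
        features=pd.DataFrame(truth_rows),
        groups=groups,
    )
    return dataset, truth


def _hub_here(config: SimConfig, layer_index: int, block: int) -> bool:
    """Hub of block b lives in layer b (round-robin over layers)."""
    return config.with_hubs and layer_index == block % 5


def _apply_planted(
    log_vals: np.ndarray,
    is_diff: np.ndarray,
    block_id: np.ndarray,
    effect_log: float,
    scale: float,
    high: np.ndarray,
    z_noise: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    factors: np.ndarray,
) -> None:
    """Overlay group effect, exposure noise and block factors in place.

    ``log_vals`` is (features, subjects) on a log-ish scale where ``scale``
    is the per-feature SD; planted features get a deterministic
    ``effect_log`` mean shift in the high group plus weak correlated
    exposure noise; block members split their unit-variance signal between
    the latent block factor (weight = loading) and idiosyncratic noise.
    """
    lam = config.loading
    resid = np.sqrt(1.0 - lam * lam)
    for f in np.nonzero(is_diff)[0]:
        if block_id[f] > 0:
            log_vals[f] += scale * (
                lam * factors[block_id[f] - 1] + resid * rng.normal(size=high.size)
            )
        else:
            log_vals[f] += scale * rng.normal(size=high.size)
        log_vals[f] += effect_log * high + config.exposure_loading * scale * z_noise
    for f in np.nonzero(~is_diff)[0]:
        log_vals[f] += scale * rng.normal(size=high.size)


def _simulate_microbiome(
    layer, prefix, sample_ids, high, z_noise, config, rng,
    factors, hub_signal, layer_index,
):
    """Genus-level counts: log-normal base composition grouped into 8 phyla
    (top five >= 95% mass), planted taxa multiplied by 2^(log2fc * group),
    multinomial sequencing at fixed depth."""
    n = config.n_taxa
    n_sub = high.size
    ids = [f"{prefix}_g{i + 1:03d}" for i in range(n)]
    is_diff, block_id = _block_assignment(prefix, n, config.n_diff_taxa, config)

    # taxa cycle through the 8 phyla; base mass of a taxon is its phylum's
    # weight split evenly over the phylum's taxa, with log-normal spread
    phyla = np.array([i % len(PHYLUM_WEIGHTS) for i in range(n)])
    # planted taxa are rare members of the five dominant phyla (~0.1% mass
    # each): their fold change then barely moves the compositional closure,
    # so unplanted taxa are not dragged into apparent differences, and the
    # top-five phylum dominance is preserved in both groups
    phyla[is_diff] = np.arange(int(is_diff.sum())) % 5
    weights = np.array(PHYLUM_WEIGHTS)[phyla]
    base = np.log(weights / np.bincount(phyla, minlength=8)[phyla])
    base += rng.normal(scale=0.5, size=n)  # within-phylum spread
    base[is_diff] = np.log(1e-3) + rng.normal(scale=0.5, size=int(is_diff.sum()))

    scale = 0.6  # log-scale biological SD
    log_vals = np.tile(base[:, None], (1, n_sub)).astype(float)
    effect_log = np.log(2.0) * config.taxon_log2fc
    _apply_planted(log_vals, is_diff, block_id, effect_log, scale,
                   high, z_noise, config, rng, factors)

    hub_ids: List[str] = []
    hub_rows = []
    for b in range(config.n_blocks):
        if _hub_here(config, layer_index, b):
            hid = f"{prefix}_hub_b{b + 1}"
            hub_ids.append(hid)
            hub_rows.append(
                np.log(1e-3) + scale * hub_signal(b)
                + effect_log * high + config.exposure_loading * scale * z_noise
            )
    if hub_ids:
        log_vals = np.vstack([log_vals, np.array(hub_rows)])
        ids = ids + hub_ids

    comp = np.exp(log_vals)
    comp /= comp.sum(axis=0)
    counts = np.empty_like(comp, dtype=int)
    for j in range(n_sub):
        counts[:, j] = rng.multinomial(config.sequencing_depth, comp[:, j])
    table = FeatureTable(
        layer=layer, level="genus",
        data=pd.DataFrame(counts, index=ids, columns=sample_ids),
    )
    rows = _truth_rows(ids, layer, "genus", is_diff, block_id,
                       config.taxon_log2fc, hub_ids, config)
    return table, rows


def _simulate_transcriptome(
    layer, prefix, sample_ids, high, z_noise, config, rng,
    factors, hub_signal, layer_index,
):
    """Negative-binomial gene counts (dispersion 0.1) with planted log2FC.

    Block genes carry the latent factor on the log-mean scale with a
    coefficient calibrated so the factor dominates the NB sampling noise and
    the realised inter-gene correlation approaches loading^2.
    """
    n = config.n_genes
    n_sub = high.size
    ids = [f"{prefix}_gene{i + 1:04d}" for i in range(n)]
    is_diff, block_id = _block_assignment(prefix, n, config.n_diff_genes, config)

    base = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=n)
    log_mu = np.tile(np.log(base)[:, None], (1, n_sub))
    # NB noise floor on the log scale ~ CV^2 = 1/mu + dispersion
    cv2 = 1.0 / np.maximum(base, 1.0) + config.nb_dispersion
    lam2 = config.loading**2
    block_coef = np.sqrt(cv2 * lam2 / (1.0 - lam2))  # per-gene factor scale

    effect_log = np.log(2.0) * config.gene_log2fc
    # the NB sampling noise itself plays the idiosyncratic role, so block
    # genes carry the pure factor, scaled per gene to reach corr ~ loading^2
    for f in range(n):
        if is_diff[f]:
            if block_id[f] > 0:
                log_mu[f] += block_coef[f] * factors[block_id[f] - 1]
            log_mu[f] += effect_log * high \
                + config.exposure_loading * np.sqrt(cv2[f]) * z_noise

    hub_ids: List[str] = []
    for b in range(config.n_blocks):
        if _hub_here(config, layer_index, b):
            hid = f"{prefix}_hub_b{b + 1}"
            hub_ids.append(hid)
            hub_mu = np.log(150.0) \
                + np.sqrt(cv2.mean() * lam2 / (1.0 - lam2)) * hub_signal(b) \
                + effect_log * high
            log_mu = np.vstack([log_mu, hub_mu])
    ids = ids + hub_ids

    mu = np.exp(log_mu)
    r = 1.0 / config.nb_dispersion
    lam = rng.gamma(shape=r, scale=mu / r)
    counts = rng.poisson(lam)
    table = FeatureTable(
        layer=layer, level="gene",
        data=pd.DataFrame(counts, index=ids, columns=sample_ids),
    )
    rows = _truth_rows(ids, layer, "gene", is_diff, block_id,
                       config.gene_log2fc, hub_ids, config)
    return table, rows


def _simulate_metabolome(
    layer, prefix, sample_ids, high, z_noise, config, rng,
    factors, hub_signal, layer_index,
):
    """Log-normal intensities; planted shifts in pooled-SD units on the log
    scale (monotone in the raw intensities, so rank tests are unaffected by
    the exponential)."""
    n = config.n_metabolites
    n_sub = high.size
    ids = [f"{prefix}_met{i + 1:04d}" for i in range(n)]
    is_diff, block_id = _block_assignment(prefix, n, config.n_diff_metabolites, config)

    base = rng.normal(loc=10.0, scale=1.5, size=n)  # log-intensity grand means
    scale = 0.5
    log_vals = np.tile(base[:, None], (1, n_sub)).astype(float)
    effect_log = config.metabolite_shift_sd * scale
    _apply_planted(log_vals, is_diff, block_id, effect_log, scale,
                   high, z_noise, config, rng, factors)

    hub_ids: List[str] = []
    for b in range(config.n_blocks):
        if _hub_here(config, layer_index, b):
            hid = f"{prefix}_hub_b{b + 1}"
            hub_ids.append(hid)
            log_vals = np.vstack([
                log_vals,
                10.0 + scale * hub_signal(b) + effect_log * high,
            ])
    ids = ids + hub_ids

    table = FeatureTable(
        layer=layer, level="metabolite",
        data=pd.DataFrame(np.exp(log_vals), index=ids, columns=sample_ids),
    )
    rows = _truth_rows(ids, layer, "metabolite", is_diff, block_id,
                       config.metabolite_shift_sd, hub_ids, config)
    return table, rows


def _truth_rows(ids, layer, level, is_diff, block_id, effect, hub_ids, config):
    rows = []
    n_base = len(ids) - len(hub_ids)
    for i, fid in enumerate(ids[:n_base]):
        rows.append(
            {
                "feature_id": fid,
                "layer": layer,
                "level": level,
                "is_planted_diff": bool(is_diff[i]),
                "effect": float(effect) if is_diff[i] else 0.0,
                "block_id": int(block_id[i]),
                "planted_hub": False,
            }
        )
    for k, fid in enumerate(hub_ids):
        b = int(fid.rsplit("_b", 1)[1])
        rows.append(
            {
                "feature_id": fid,
                "layer": layer,
                "level": level,
                "is_planted_diff": True,
                "effect": float(effect),
                "block_id": b,
                "planted_hub": True,
            }
        )
    return rows


# ---------------------------------------------------------------------------
# graph fixture


def planted_partition_graph(
    n_blocks: int,
    block_size: int,
    p_in: float,
    p_out: float,
    seed: int = 0,
) -> Tuple[Graph, Dict[str, int]]:
    """Stochastic block model draw: within-block edges with probability
    ``p_in``, between-block with ``p_out``.  Returns the graph and the true
    block label per node."""
    if not (0.0 <= p_in <= 1.0 and 0.0 <= p_out <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    nodes = [f"n{b:02d}_{i:03d}" for b in range(n_blocks) for i in range(block_size)]
    labels = {n: int(n[1:3]) for n in nodes}
    g = Graph(nodes=nodes)
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            p = p_in if labels[nodes[a]] == labels[nodes[b]] else p_out
            if rng.random() < p:
                g.add_edge(nodes[a], nodes[b])
    return g, labels


# ---------------------------------------------------------------------------
# truth serialisation

TRUTH_COLUMNS = [
    "feature_id", "layer", "level", "is_planted_diff", "effect",
    "block_id", "planted_hub",
]


def truth_table(truth: SyntheticTruth, path: str | Path) -> None:
    """TSV serialisation of the ground truth (round-trips exactly)."""
    if len(truth.features) == 0:
        raise ValueError("empty truth rejected")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = truth.features[TRUTH_COLUMNS].copy()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    groups = pd.DataFrame(
        sorted(truth.groups.items()), columns=["subject_id", "group"]
    )
    groups.to_csv(path.with_suffix(".groups.tsv"), sep="\t", index=False)


def read_truth(path: str | Path) -> SyntheticTruth:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    df["is_planted_diff"] = df["is_planted_diff"].astype(bool)
    df["planted_hub"] = df["planted_hub"].astype(bool)
    groups_df = pd.read_csv(path.with_suffix(".groups.tsv"), sep="\t")
    groups = dict(zip(groups_df["subject_id"], groups_df["group"]))
    return SyntheticTruth(features=df[TRUTH_COLUMNS], groups=groups)
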