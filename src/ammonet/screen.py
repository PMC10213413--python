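"""Differential-feature screening per omic layer.

The screening procedure is uniform across layers: an exact two-sided
Wilcoxon rank-sum test per feature, Benjamini-Hochberg FDR adjustment over
all features of one table (one taxonomic/feature level at a time), a
log2 fold-change of group means, and a layer-specific biomarker gate:

* microbiome / functional levels: q < 0.05
* genes:                         q < 0.01 and |log2FC| > 1
* metabolites:                   q < 0.05 and VIP > 1 (VIP from `plsvip`)

With 6 + 6 matched subjects the exact test enumerates all C(12,6) = 924
rank assignments, so the smallest attainable two-sided p-value is
2/924 = 0.0021645; every inference downstream inherits this granularity.

Also here: Shannon and ACE alpha-diversity indices and the 2^-ddCt qPCR
fold-change used to validate key features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ABUNDANCE_LEVELS, AlignedDataset, FeatureTable, SampleMetadata

__all__ = [
    "wilcoxon_rank_sum",
    "bh_adjust",
    "log2_fold_change",
    "shannon_index",
    "ace_index",
    "AceResult",
    "ddct_fold_change",
    "DdctResult",
    "GateConfig",
    "default_gate",
    "screen_table",
    "diversity_table",
]

EXACT_MAX_N = 14  #: full enumeration up to this combined sample size
TIE_PERMUTATIONS = 10_000  #: seeded Monte-Carlo draws when ties block enumeration


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


@lru_cache(maxsize=64)
def _rank_sum_null(n1: int, n2: int) -> np.ndarray:
    """Exact null distribution of the group-1 rank sum W over all C(n,n1)
    assignments of ranks 1..n, as an array of counts indexed by W.

    Computed by the classic subset-sum dynamic programme (polynomial
    coefficients of the Gaussian binomial), equivalent to full enumeration.
    """
    n = n1 + n2
    max_w = n1 * n + 10
    # dp[k][w] = number of k-subsets of ranks seen so far with rank sum w
    dp = np.zeros((n1 + 1, max_w + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            dp[k, r:] += dp[k - 1, :-r] if r > 0 else dp[k - 1]
    return dp[n1]


def _exact_two_sided_p(w: float, n1: int, n2: int) -> float:
    """Two-sided p by doubling the smaller exact tail, capped at 1."""
    counts = _rank_sum_null(n1, n2)
    total = counts.sum()
    ws = np.arange(counts.size)
    lo = counts[ws <= w + 1e-9].sum() / total
    hi = counts[ws >= w - 1e-9].sum() / total
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
    n_perm: int = TIE_PERMUTATIONS,
    seed: int = 0,
) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns ``(W, p)`` with W the rank
    sum of ``x`` (mid-ranks under ties).

    * ``exact`` (or ``auto`` with n1+n2 <= 14): tie-free inputs get the full
      enumeration p; tied inputs get a seeded Monte-Carlo permutation p using
      mid-ranks, two-sided via |W - E[W]|.
    * ``approx`` (or large ``auto``): normal approximation with tie
      correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if mode not in ("exact", "approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # mid-ranks
    w = float(ranks[:n1].sum())
    has_ties = np.unique(pooled).size < n

    use_exact = mode == "exact" or (mode == "auto" and n <= EXACT_MAX_N)
    if use_exact:
        if not has_ties:
            return w, _exact_two_sided_p(w, n1, n2)
        # ties: exact distribution is input-specific; seeded permutation
        rng = np.random.default_rng(seed)
        mean_w = n1 * (n + 1) / 2.0
        obs = abs(w - mean_w)
        idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n1]
        w_star = ranks[idx].sum(axis=1)
        count = int(np.sum(np.abs(w_star - mean_w) >= obs - 1e-9))
        return w, (1.0 + count) / (n_perm + 1.0)

    # normal approximation with tie correction
    mean_w = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n * (n - 1)) or 1)
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return w, 1.0
    z = (abs(w - mean_w) - 0.5) / math.sqrt(var_w)
    return w, float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))


def _rank_sum_pvalues(
    high: np.ndarray, low: np.ndarray, seed: int = 0
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised per-row exact Wilcoxon over a (features x samples) split.

    Tie-free rows share one cached enumeration null; tied rows share one
    seeded permutation index matrix.  Returns ``(W, p)`` arrays.
    """
    n1, n2 = high.shape[1], low.shape[1]
    n = n1 + n2
    pooled = np.concatenate([high, low], axis=1)
    ranks = stats.rankdata(pooled, axis=1)
    w = ranks[:, :n1].sum(axis=1)
    tied = np.array([np.unique(row).size < n for row in pooled])
    p = np.empty(pooled.shape[0])

    if n <= EXACT_MAX_N:
        counts = _rank_sum_null(n1, n2)
        total = counts.sum()
        cum = np.cumsum(counts)
        ws = np.round(w[~tied]).astype(int)
        lo = cum[ws] / total
        hi = (total - np.concatenate([[0.0], cum])[ws]) / total
        p[~tied] = np.minimum(1.0, 2.0 * np.minimum(lo, hi))
        if tied.any():
            rng = np.random.default_rng(seed)
            idx = np.argsort(rng.random((TIE_PERMUTATIONS, n)), axis=1)[:, :n1]
            mean_w = n1 * (n + 1) / 2.0
            tr = ranks[tied]
            w_star = tr[:, idx].sum(axis=2)  # (n_tied, n_perm)
            obs = np.abs(w[tied] - mean_w)
            cnt = (np.abs(w_star - mean_w) >= obs[:, None] - 1e-9).sum(axis=1)
            p[tied] = (1.0 + cnt) / (TIE_PERMUTATIONS + 1.0)
    else:
        for i in range(pooled.shape[0]):
            _, p[i] = wilcoxon_rank_sum(high[i], low[i], mode="approx")
    return w, p


# ---------------------------------------------------------------------------
# BH-FDR


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} min(1, m * p_(j) / j) at sorted positions, mapped
    back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# effect size


def log2_fold_change(
    x: Sequence[float], y: Sequence[float], pseudocount: float = 0.0
) -> float:
    """log2((mean(x) + c) / (mean(y) + c)) for nonnegative data, with
    pseudocount c regularising zero means."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("fold change requires nonnegative values")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    num, den = x.mean() + pseudocount, y.mean() + pseudocount
    if num <= 0 or den <= 0:
        raise ValueError("zero mean with zero pseudocount")
    return float(np.log2(num / den))


def _default_pseudocount(values: np.ndarray) -> float:
    """Half the smallest positive value in the table (scale-free)."""
    pos = values[values > 0]
    return float(pos.min()) / 2.0 if pos.size else 1e-9


# ---------------------------------------------------------------------------
# alpha diversity


def shannon_index(abundances: Sequence[float]) -> float:
    """Shannon entropy H = -sum p_i ln p_i (nats) over normalised nonzero
    proportions; 0 iff exactly one taxon is present."""
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = a.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum())


@dataclass(frozen=True)
class AceResult:
    """ACE richness estimate with its intermediate quantities."""

    ace: float
    s_abund: int
    s_rare: int
    f1: int
    n_rare: int
    c_ace: float
    gamma_sq: float
    chao1_fallback: bool = False


def ace_index(counts: Sequence[int], rare_cutoff: int = 10) -> AceResult:
    """Abundance-based coverage estimator of species richness.

    ACE = S_abund + S_rare/C_ace + (F1/C_ace) * gamma^2, with
    C_ace = 1 - F1/N_rare (sample coverage of the rare group, counts <=
    ``rare_cutoff``) and gamma^2 the rare-class coefficient of variation,
    floored at 0.  When every rare individual is a singleton (C_ace = 0)
    the estimator is undefined and the bias-corrected Chao1 is returned
    with ``chao1_fallback=True``; with no rare species ACE equals the
    observed richness.
    """
    c = np.asarray(counts)
    if c.size == 0 or (c < 0).any():
        raise ValueError("counts must be a nonempty nonnegative vector")
    if not np.allclose(c, np.round(c)):
        raise ValueError("ACE requires integer counts")
    c = np.round(c).astype(int)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("at least one positive count required")
    rare = c[c <= rare_cutoff]
    abund = c[c > rare_cutoff]
    s_abund, s_rare = int(abund.size), int(rare.size)
    f1 = int((rare == 1).sum())
    n_rare = int(rare.sum())
    if s_rare == 0:
        return AceResult(float(s_abund), s_abund, 0, 0, 0, 1.0, 0.0)
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        # bias-corrected Chao1 on the full sample
        f2 = int((c == 2).sum())
        s_obs = int(c.size)
        chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
        return AceResult(float(chao1), s_abund, s_rare, f1, n_rare, 0.0, 0.0, True)
    fi = np.bincount(rare, minlength=rare_cutoff + 1)
    i = np.arange(fi.size)
    num = (i * (i - 1) * fi).sum()
    gamma_sq = max((s_rare / c_ace) * num / (n_rare * (n_rare - 1)) - 1.0, 0.0) \
        if n_rare > 1 else 0.0
    ace = s_abund + s_rare / c_ace + (f1 / c_ace) * gamma_sq
    return AceResult(float(ace), s_abund, s_rare, f1, n_rare, float(c_ace), float(gamma_sq))


def diversity_table(table: FeatureTable, rare_cutoff: int = 10) -> pd.DataFrame:
    """Shannon (nats) and ACE per sample from a count-level table."""
    rows = []
    for s in table.sample_ids:
        col = table.data[s].to_numpy()
        ace = ace_index(col, rare_cutoff) if table.is_counts else None
        rows.append(
            {
                "sample_id": s,
                "shannon": shannon_index(col),
                "ace": ace.ace if ace else np.nan,
                "ace_chao1_fallback": bool(ace.chao1_fallback) if ace else False,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR 2^-ddCt


@dataclass(frozen=True)
class DdctResult:
    ddct: float
    fold_change: float


def ddct_fold_change(
    target_treated: float,
    ref_treated: float,
    target_control: float,
    ref_control: float,
) -> DdctResult:
    """Relative expression by the 2^-ddCt method: ddCt = (Ct_target -
    Ct_reference) in the treated condition minus the same difference in the
    control condition; fold change = 2^-ddCt."""
    for v in (target_treated, ref_treated, target_control, ref_control):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (target_treated - ref_treated) - (target_control - ref_control)
    return DdctResult(ddct=ddct, fold_change=2.0 ** (-ddct))


# ---------------------------------------------------------------------------
# per-table screening


@dataclass(frozen=True)
class GateConfig:
    """Biomarker gate for one feature level."""

    max_q: float = 0.05
    min_abs_log2fc: float = 0.0
    min_vip: Optional[float] = None  # metabolites only


def default_gate(level: str) -> GateConfig:
    if level == "gene":
        return GateConfig(max_q=0.01, min_abs_log2fc=1.0)
    if level == "metabolite":
        return GateConfig(max_q=0.05, min_vip=1.0)
    return GateConfig(max_q=0.05)


SCREEN_COLUMNS = [
    "feature_id", "layer", "level", "mean_high", "mean_low", "log2fc",
    "p_raw", "q_fdr", "vip", "direction", "is_biomarker",
]


def screen_table(
    table: FeatureTable,
    metadata: SampleMetadata,
    gate: Optional[GateConfig] = None,
    vip: Optional[pd.Series] = None,
    pseudocount: Optional[float] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Screen every feature of one table for a high-vs-low group difference.

    Exact Wilcoxon rank-sum p per feature, BH adjustment over all features of
    this table (the FDR family is one table at one level), log2 fold change
    of group means with a scale-free pseudocount (half the smallest positive
    value unless given).  ``vip`` supplies per-feature VIP scores when the
    gate requires them.  Returns one row per feature (input order) with the
    columns of ``SCREEN_COLUMNS``.
    """
    gate = gate or default_gate(table.level)
    subj_of = metadata.subject_of()
    grp_of = metadata.group_of_subject()
    cols_high = [s for s in table.sample_ids if grp_of[subj_of[s]] == "high"]
    cols_low = [s for s in table.sample_ids if grp_of[subj_of[s]] == "low"]
    if len(cols_high) < 3 or len(cols_low) < 3:
        raise ValueError(
            f"screening needs >= 3 samples per group, got "
            f"{len(cols_high)} high / {len(cols_low)} low"
        )
    high = table.data[cols_high].to_numpy(dtype=float)
    low = table.data[cols_low].to_numpy(dtype=float)

    _, p_raw = _rank_sum_pvalues(high, low, seed=seed)
    q_fdr = bh_adjust(p_raw)
    pc = _default_pseudocount(table.values) if pseudocount is None else pseudocount
    mean_high, mean_low = high.mean(axis=1), low.mean(axis=1)
    log2fc = np.log2((mean_high + pc) / (mean_low + pc))

    out = pd.DataFrame(
        {
            "feature_id": table.feature_ids,
            "layer": table.layer,
            "level": table.level,
            "mean_high": mean_high,
            "mean_low": mean_low,
            "log2fc": log2fc,
            "p_raw": p_raw,
            "q_fdr": q_fdr,
        }
    )
    if vip is not None:
        out["vip"] = vip.reindex(out["feature_id"]).to_numpy()
    else:
        out["vip"] = np.nan
    out["direction"] = np.where(log2fc >= 0, "up_in_high", "up_in_low")

    ok = out["q_fdr"] < gate.max_q
    if gate.min_abs_log2fc > 0:
        ok &= out["log2fc"].abs() > gate.min_abs_log2fc
    if gate.min_vip is not None:
        ok &= out["vip"].fillna(0.0) > gate.min_vip
    out["is_biomarker"] = ok
    return out[SCREEN_COLUMNS]
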