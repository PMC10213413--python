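"""Two-class PLS discriminant analysis and VIP scores for metabolite screening.

The metabolite biomarker gate combines an exact Wilcoxon/BH q-value with a
Variable Importance in Projection (VIP) threshold from a two-class partial
least squares discriminant model.  The PLS fit is a plain NIPALS PLS1:
variables are autoscaled (zero mean, unit variance; constant columns get
zero weight), the class response is coded -1/+1 and centred, and components
are extracted sequentially with deflation.

VIP_j = sqrt( p * sum_a(SSY_a * w_aj^2) / sum_a SSY_a ), with p variables,
w_a the unit weight vectors and SSY_a the response sum of squares explained
by component a; mean(VIP^2) = 1 identically, so VIP > 1 flags variables of
above-average influence on class separation.

The orthogonal filtering of OPLS-DA is deliberately not reproduced: the
orthogonal rotation redistributes predictive variance between components
but leaves the VIP > 1 screening role intact, so a plain PLS-DA VIP is used
(see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import FeatureTable, SampleMetadata
from .screen import GateConfig, default_gate, screen_table

__all__ = ["PlsModel", "fit_plsda", "vip_scores", "screen_metabolites"]

_EPS = 1e-12


@dataclass(frozen=True)
class PlsModel:
    """Fitted two-class PLS1 model (NIPALS, deflated X)."""

    n_components: int
    weights: np.ndarray        #: (A, p) unit weight vectors w_a
    scores: np.ndarray         #: (A, n) sample score vectors t_a
    explained_y_ss: np.ndarray #: (A,) SSY_a explained per component
    active: np.ndarray         #: (p,) bool, False for zero-variance columns


def fit_plsda(
    matrix: np.ndarray,
    groups: Sequence[str] | np.ndarray,
    n_components: int = 2,
) -> PlsModel:
    """Fit a two-class PLS-DA on a samples x variables matrix.

    ``groups`` holds exactly two distinct labels; the response is coded
    -1/+1 (centred), making explained sums of squares symmetric in the
    group labelling.  ``n_components`` is capped at min(n_samples - 1,
    n_variables).  Deterministic for fixed input.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be samples x variables")
    labels = np.asarray(groups)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two classes, got {uniq}")
    counts = [(labels == u).sum() for u in uniq]
    if min(counts) < 2:
        raise ValueError("need >= 2 samples per class")
    n, p = x.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    n_components = min(n_components, n - 1, p)

    y = np.where(labels == uniq[1], 1.0, -1.0)
    y = y - y.mean()
    sd = x.std(axis=0, ddof=1)
    active = sd > _EPS
    xs = np.zeros_like(x)
    xs[:, active] = (x[:, active] - x[:, active].mean(axis=0)) / sd[active]

    weights = np.zeros((n_components, p))
    scores = np.zeros((n_components, n))
    ssy = np.zeros(n_components)
    xa, ya = xs.copy(), y.copy()
    a_done = 0
    for a in range(n_components):
        w = xa.T @ ya
        norm = np.linalg.norm(w)
        if norm <= _EPS:
            break
        w = w / norm
        t = xa @ w
        tt = float(t @ t)
        if tt <= _EPS:
            break
        p_load = xa.T @ t / tt
        q = float(ya @ t) / tt
        weights[a] = w
        scores[a] = t
        ssy[a] = q * q * tt
        xa = xa - np.outer(t, p_load)
        ya = ya - q * t
        a_done = a + 1
    return PlsModel(
        n_components=a_done,
        weights=weights[:a_done],
        scores=scores[:a_done],
        explained_y_ss=ssy[:a_done],
        active=active,
    )


def vip_scores(model: PlsModel) -> np.ndarray:
    """Per-variable VIP; satisfies sum(VIP^2) = p up to float error."""
    if model.n_components == 0 or model.explained_y_ss.sum() <= _EPS:
        raise ValueError("model explains no class variance; VIP undefined")
    w2 = model.weights**2
    num = (model.explained_y_ss[:, None] * w2).sum(axis=0)
    return np.sqrt(w2.shape[1] * num / model.explained_y_ss.sum())


def screen_metabolites(
    table: FeatureTable,
    metadata: SampleMetadata,
    n_components: int = 2,
    gate: Optional[GateConfig] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Metabolite screening: exact Wilcoxon + BH q combined with PLS-DA VIP.

    Biomarker iff q < 0.05 and VIP > 1 (default gate).  Zero-variance
    metabolites receive VIP 0 and cannot pass the gate.
    """
    gate = gate or default_gate(table.level)
    subj_of = metadata.subject_of()
    grp_of = metadata.group_of_subject()
    labels = np.array([grp_of[subj_of[s]] for s in table.sample_ids])
    model = fit_plsda(table.values.T, labels, n_components=n_components)
    vip = vip_scores(model)  # zero-variance columns have zero weight -> VIP 0
    vip_series = pd.Series(vip, index=table.feature_ids)
    return screen_table(table, metadata, gate=gate, vip=vip_series, seed=seed)
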