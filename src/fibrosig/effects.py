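"""Downstream functional effects via the weighted activation z-score.

A causal network links genes to functional terms with a literature-
derived direction (activating / inhibiting) and finding counts.  Given
a differential-expression result, each called gene contributes a
concordance sign

    x_i = sign(log fold change) × (+1 activating / −1 inhibiting)

and an evidence weight

    w_i = |M_activating − M_inhibiting| / (M_activating + M_inhibiting + 1)

so fully conflicting literature evidence carries zero weight.  The
function's activation score is

    z = Σ_i w_i x_i / sqrt(Σ_i w_i²)

which has unit variance when the x_i are independent ±1 coin flips —
the null model against which significance is assessed, both by exact
normal approximation and by Monte-Carlo draws.  |z| ≥ 2 (configurable)
calls a function increased (z > 0) or decreased (z < 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sam import DEResult


class EffectsError(ValueError):
    pass


VALID_DIRECTIONS = ("activating", "inhibiting")


class CausalNetwork:
    """Gene→function edges with finding counts.

    Duplicate (gene, function) edges are collapsed by summing their
    finding counts before weighting; direction is kept if the duplicates
    agree, otherwise re-derived from the summed counts (activating iff
    m_activating >= m_inhibiting).  Direction may also be omitted
    entirely (empty/NaN), in which case it is derived from counts.
    """

    def __init__(self, edges: pd.DataFrame) -> None:
        required = {"gene_id", "function_id", "m_activating", "m_inhibiting"}
        missing = required - set(edges.columns)
        if missing:
            raise EffectsError(f"network edges missing columns {sorted(missing)}")
        edges = edges.copy()
        if "direction" not in edges.columns:
            edges["direction"] = None
        for col in ("m_activating", "m_inhibiting"):
            edges[col] = pd.to_numeric(edges[col], errors="raise").astype(int)
            if (edges[col] < 0).any():
                raise EffectsError(f"{col} must be >= 0")
        if ((edges["m_activating"] + edges["m_inhibiting"]) < 1).any():
            raise EffectsError("each edge needs at least one finding")

        rows = []
        for (gene, func), grp in edges.groupby(["gene_id", "function_id"],
                                               sort=False):
            m_act = int(grp["m_activating"].sum())
            m_inh = int(grp["m_inhibiting"].sum())
            dirs = {d for d in grp["direction"] if d in VALID_DIRECTIONS}
            if len(dirs) == 1:
                direction = dirs.pop()
            else:  # absent or conflicting → derive from counts
                direction = "activating" if m_act >= m_inh else "inhibiting"
            rows.append({
                "gene_id": gene, "function_id": func, "direction": direction,
                "m_activating": m_act, "m_inhibiting": m_inh,
            })
        if not rows:
            raise EffectsError("network has no edges")
        self.edges = pd.DataFrame(rows)

    @property
    def functions(self) -> list[str]:
        return list(pd.unique(self.edges["function_id"]))

    def edges_for(self, function_id: str) -> pd.DataFrame:
        return self.edges[self.edges["function_id"] == function_id]


def edge_weight(m_activating: int, m_inhibiting: int) -> float:
    """Evidence weight |Ma − Mi| / (Ma + Mi + 1); in [0, 1)."""
    if m_activating < 0 or m_inhibiting < 0:
        raise EffectsError("finding counts must be >= 0")
    if m_activating + m_inhibiting < 1:
        raise EffectsError("edge needs at least one finding")
    return abs(m_activating - m_inhibiting) / (m_activating + m_inhibiting + 1)


@dataclass
class ActivationEntry:
    function_id: str
    z: float | None
    n_genes: int
    n_increased: int
    n_decreased: int
    p_value: float | None
    p_normal: float | None
    call: str  # increased / decreased / none


@dataclass
class ActivationResult:
    table: pd.DataFrame  # one row per function
    z_call: float

    @property
    def calls(self) -> dict[str, str]:
        return dict(zip(self.table["function_id"], self.table["call"]))


def _contributions(de: DEResult, net_edges: pd.DataFrame):
    """Signed contributions of called genes on a function's edges.

    Genes not called, or with exactly zero log fold change, do not
    contribute.  Returns (weights, signs) arrays.
    """
    called = de.table[de.table["called"]]
    weights, signs = [], []
    for row in net_edges.itertuples():
        if row.gene_id not in called.index:
            continue
        fc = called.at[row.gene_id, "fold_change"]
        if fc == 1.0:
            continue
        fc_sign = 1.0 if fc > 1.0 else -1.0
        edge_sign = 1.0 if row.direction == "activating" else -1.0
        weights.append(edge_weight(row.m_activating, row.m_inhibiting))
        signs.append(fc_sign * edge_sign)
    return np.array(weights), np.array(signs)


def activation_z(
    de: DEResult, network: CausalNetwork, function_id: str, z_call: float = 2.0
) -> ActivationEntry:
    """Weighted activation z for one functional term."""
    net_edges = network.edges_for(function_id)
    if net_edges.empty:
        raise EffectsError(f"function {function_id!r} not in network")
    w, x = _contributions(de, net_edges)
    n_inc = int((x > 0).sum())
    n_dec = int((x < 0).sum())
    denom = float(np.sqrt((w ** 2).sum())) if w.size else 0.0
    if w.size == 0 or denom == 0.0:
        return ActivationEntry(function_id, None, len(net_edges), n_inc, n_dec,
                               None, None, "none")
    z = float((w * x).sum() / denom)
    call = "increased" if z >= z_call else "decreased" if z <= -z_call else "none"
    return ActivationEntry(function_id, z, int(w.size), n_inc, n_dec,
                           None, None, call)


def null_significance(
    z: float, weights, n_draws: int = 10000, seed: int = 0
) -> tuple[float, float]:
    """Two-sided significance of z under the random ±1 null.

    Draws ``n_draws`` vectors of i.i.d. equiprobable ±1 signs with the
    same weights and reports the fraction with |z_null| >= |z|, together
    with the normal-approximation p for comparison.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.size == 0:
        raise EffectsError("null_significance needs at least one weight")
    if n_draws < 1000:
        raise EffectsError("n_draws must be >= 1000")
    rng = np.random.default_rng(seed)
    denom = np.sqrt((weights ** 2).sum())
    if denom == 0:
        raise EffectsError("all weights are zero")
    signs = rng.choice([-1.0, 1.0], size=(n_draws, weights.size))
    z_null = signs @ weights / denom
    p_mc = float(np.mean(np.abs(z_null) >= abs(z)))
    p_normal = float(2 * stats.norm.sf(abs(z)))
    return p_mc, p_normal


def score_all_functions(
    de: DEResult,
    network: CausalNetwork,
    z_call: float = 2.0,
    n_draws: int = 10000,
    seed: int = 0,
) -> ActivationResult:
    """Score every function in the network; BH-adjust the null p-values."""
    rows = []
    for k, function_id in enumerate(network.functions):
        entry = activation_z(de, network, function_id, z_call=z_call)
        if entry.z is not None:
            w, _ = _contributions(de, network.edges_for(function_id))
            p_mc, p_norm = null_significance(
                entry.z, w, n_draws=n_draws, seed=(seed + k) % 2**31
            )
            entry.p_value, entry.p_normal = p_mc, p_norm
        rows.append(entry.__dict__)
    table = pd.DataFrame(rows)
    scored = table["p_value"].notna()
    table["p_adjusted"] = np.nan
    if scored.any():
        table.loc[scored, "p_adjusted"] = multipletests(
            table.loc[scored, "p_value"], method="fdr_bh"
        )[1]
    return ActivationResult(table=table, z_call=z_call)
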