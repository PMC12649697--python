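"""Node centrality for weighted symptom networks.

Strength (absolute-weight sum), one-step expected influence (signed
sum), and bridge expected influence (signed sum restricted to edges that
cross the SCL / QOL community boundary), plus a ranked report with
z-standardized columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import COMMUNITIES, NODE_LABELS

__all__ = [
    "strength",
    "expected_influence",
    "bridge_expected_influence",
    "centrality_table",
    "rank_report",
]


def _check_weights(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weights must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("weights must be symmetric")
    return W


def strength(weights: np.ndarray) -> np.ndarray:
    """s_i = sum_j |w_ij| (diagonal ignored; NetworkModel keeps it zero)."""
    W = _check_weights(weights)
    A = np.abs(W).copy()
    np.fill_diagonal(A, 0.0)
    return A.sum(axis=1)


def expected_influence(weights: np.ndarray) -> np.ndarray:
    """One-step expected influence EI_i = sum_j w_ij (signed)."""
    W = _check_weights(weights).copy()
    np.fill_diagonal(W, 0.0)
    return W.sum(axis=1)


def bridge_expected_influence(
    weights: np.ndarray, communities: tuple[str, ...] = COMMUNITIES
) -> np.ndarray:
    """BEI_i: signed sum of w_ij over neighbours in the other community."""
    W = _check_weights(weights)
    comm = np.asarray(communities)
    if len(comm) != W.shape[0]:
        raise ValueError("one community label required per node")
    cross = comm[:, None] != comm[None, :]
    return (np.where(cross, W, 0.0)).sum(axis=1)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def centrality_table(
    weights: np.ndarray,
    communities: tuple[str, ...] = COMMUNITIES,
    node_names: tuple[str, ...] = NODE_LABELS,
    predictability: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-node table: strength, EI, BEI (raw and z-standardized)."""
    s = strength(weights)
    ei = expected_influence(weights)
    bei = bridge_expected_influence(weights, communities)
    table = pd.DataFrame({
        "node": list(node_names),
        "community": list(communities),
        "strength": s,
        "ei": ei,
        "bei": bei,
        "strength_z": _zscore(s),
        "ei_z": _zscore(ei),
        "bei_z": _zscore(bei),
    })
    if predictability is not None:
        table["predictability"] = np.asarray(predictability, dtype=float)
    return table


def rank_report(table: pd.DataFrame, index: str = "ei", top_k: int | None = None) -> pd.DataFrame:
    """Nodes sorted descending by a centrality column, ties by node order.

    ``index`` is one of the columns of :func:`centrality_table`.
    """
    if index not in table.columns:
        raise ValueError(f"unknown centrality index {index!r}")
    order = np.lexsort((np.arange(len(table)), -table[index].to_numpy()))
    out = table.iloc[order].reset_index(drop=True)
    return out if top_k is None else out.head(top_k)
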