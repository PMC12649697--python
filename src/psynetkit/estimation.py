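"""Regularized partial-correlation network estimation.

Pipeline: z-score the subscale columns, take the Pearson correlation
matrix, fit the graphical lasso along a log-spaced penalty path, select
the penalty minimizing the Extended Bayesian Information Criterion
(EBIC, gamma = 0.5), and report the selected precision matrix as a
partial-correlation weight matrix together with per-node predictability
(the variance share of each node explained by all others).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd

from .datasets import COMMUNITIES, NODE_LABELS
from .glasso import glasso

__all__ = [
    "EstimationSettings",
    "NetworkModel",
    "correlation_matrix",
    "glasso_fit",
    "lambda_path",
    "ebic",
    "select_network",
    "predictability",
    "n_possible_edges",
    "EDGE_EPS",
]

#: entries below this magnitude are floating-point dust, not edges
EDGE_EPS = 1e-10


@dataclass(frozen=True)
class EstimationSettings:
    """Tuning constants of the EBIC-glasso estimator."""

    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    convergence_tol: float = 1e-6
    max_iter: int = 500

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if not (0 < self.lambda_min_ratio < 1):
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        if self.n_lambda < 1 or self.max_iter < 1 or self.convergence_tol <= 0:
            raise ValueError("invalid settings")


@dataclass
class NetworkModel:
    """A selected sparse partial-correlation network over 22 nodes."""

    weights: np.ndarray           # symmetric, zero diagonal, entries in (-1, 1)
    lambda_selected: float
    ebic_value: float
    n: int
    node_names: tuple[str, ...] = NODE_LABELS
    communities: tuple[str, ...] = COMMUNITIES
    predictability: np.ndarray | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if not np.allclose(W, W.T, atol=1e-8):
            raise ValueError("weights must be symmetric")
        if np.abs(np.diag(W)).max() > 1e-12:
            raise ValueError("weights must have zero diagonal")
        if np.abs(W).max() >= 1.0:
            raise ValueError("partial correlations must lie in (-1, 1)")
        self.weights = W
        if len(self.node_names) != W.shape[0] or len(self.communities) != W.shape[0]:
            raise ValueError("node_names/communities must match the weight matrix size")
        if self.predictability is not None:
            self.predictability = np.asarray(self.predictability, dtype=float)
            if np.any(self.predictability < 0) or np.any(self.predictability > 1):
                raise ValueError("predictability must lie in [0, 1]")

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices_from(self.weights, k=1)
        return int(np.sum(np.abs(self.weights[iu]) > EDGE_EPS))

    def edge_frame(self) -> pd.DataFrame:
        """Nonzero edges as a (node_a, node_b, weight) table."""
        iu, ju = np.triu_indices_from(self.weights, k=1)
        keep = np.abs(self.weights[iu, ju]) > EDGE_EPS
        return pd.DataFrame({
            "node_a": [self.node_names[i] for i in iu[keep]],
            "node_b": [self.node_names[j] for j in ju[keep]],
            "weight": self.weights[iu[keep], ju[keep]],
        })

    def to_json(self, path, settings: EstimationSettings | None = None) -> None:
        doc = {
            "weights": self.weights.tolist(),
            "lambda_selected": self.lambda_selected,
            "ebic_value": self.ebic_value,
            "n": self.n,
            "node_names": list(self.node_names),
            "communities": list(self.communities),
            "predictability": None if self.predictability is None
            else self.predictability.tolist(),
            "n_edges": self.n_edges,
        }
        if settings is not None:
            doc["settings"] = asdict(settings)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def n_possible_edges(p: int) -> int:
    """Number of distinct node pairs, p(p-1)/2."""
    return p * (p - 1) // 2


def correlation_matrix(scores: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the score columns."""
    X = np.asarray(scores, dtype=float)
    sd = X.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant column(s) at index {bad.tolist()}")
    S = np.corrcoef(X, rowvar=False)
    return 0.5 * (S + S.T)


def glasso_fit(
    S: np.ndarray, lam: float, settings: EstimationSettings = EstimationSettings(),
    warm=None,
):
    """Graphical lasso at one penalty; returns (precision, covariance, state)."""
    return glasso(
        S, lam, tol=settings.convergence_tol, max_iter=settings.max_iter, warm=warm
    )


def lambda_path(
    S: np.ndarray, settings: EstimationSettings = EstimationSettings()
) -> np.ndarray:
    """Log-spaced penalty path from lambda_max down to its min ratio.

    ``lambda_max`` is the largest absolute off-diagonal correlation (the
    smallest penalty yielding an empty graph).  If all off-diagonals are
    zero the path degenerates to {0}.
    """
    S = np.asarray(S, dtype=float)
    off = S[~np.eye(S.shape[0], dtype=bool)]
    lam_max = float(np.abs(off).max()) if off.size else 0.0
    if lam_max == 0.0:
        return np.array([0.0])
    return np.geomspace(lam_max, lam_max * settings.lambda_min_ratio, settings.n_lambda)


def ebic(
    precision: np.ndarray, S: np.ndarray, n: int, gamma: float, p: int | None = None
) -> float:
    """Extended BIC of a Gaussian graphical model.

    EBIC = -2 l + E log n + 4 gamma E log p, with Gaussian log-likelihood
    l = (n/2)[log det K - tr(S K)] and E the number of nonzero
    off-diagonal upper-triangle precision entries.  gamma = 0 recovers
    the ordinary BIC penalty.
    """
    K = np.asarray(precision, dtype=float)
    if p is None:
        p = K.shape[0]
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise ValueError("precision matrix must be positive definite")
    ll = (n / 2.0) * (logdet - float(np.sum(S * K)))
    iu = np.triu_indices(K.shape[0], k=1)
    E = int(np.sum(np.abs(K[iu]) > EDGE_EPS))
    return float(-2.0 * ll + E * np.log(n) + 4.0 * gamma * E * np.log(p))


def _to_partial_correlations(K: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(K))
    W = -K / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    return 0.5 * (W + W.T)


def predictability(precision: np.ndarray) -> np.ndarray:
    """Per-node R-squared for data standardized to unit variance.

    The residual variance of node i given all others is 1/K_ii, so
    R2_i = 1 - 1/K_ii; clipped into [0, 1].
    """
    d = np.diag(precision)
    assert np.all(d > 0), "positive-definite precision has positive diagonal"
    return np.clip(1.0 - 1.0 / d, 0.0, 1.0)


def _default_labels(p: int) -> tuple[tuple[str, ...], tuple[str, ...]]:
    if p == len(NODE_LABELS):
        return NODE_LABELS, COMMUNITIES
    return tuple(f"n{i}" for i in range(p)), ("A",) * p


def select_network(
    scores: np.ndarray,
    communities: tuple[str, ...] | None = None,
    settings: EstimationSettings = EstimationSettings(),
    node_names: tuple[str, ...] | None = None,
) -> NetworkModel:
    """Fit the EBIC-selected graphical lasso network of a score matrix.

    Columns are z-scored, the penalty path is swept with warm starts, and
    the minimum-EBIC precision matrix is returned as partial-correlation
    weights with per-node predictability attached.
    """
    X = np.asarray(scores, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows than nodes (n={n}, p={p})")
    default_names, default_comm = _default_labels(p)
    if node_names is None:
        node_names = default_names
    if communities is None:
        communities = default_comm
    S = correlation_matrix(X)
    path = lambda_path(S, settings)
    best = None
    state = None
    for idx, lam in enumerate(path):
        K, _W, state = glasso_fit(S, float(lam), settings, warm=state)
        crit = ebic(K, S, n, settings.gamma, p)
        if best is None or crit < best[0]:
            best = (crit, lam, K, idx)
    crit, lam, K, _idx = best
    return NetworkModel(
        weights=_to_partial_correlations(K),
        lambda_selected=float(lam),
        ebic_value=float(crit),
        n=n,
        node_names=tuple(node_names),
        communities=tuple(communities),
        predictability=predictability(K),
    )
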