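"""Bootstrap accuracy and stability diagnostics for estimated networks.

Three diagnostics, all of which refit the full EBIC-glasso estimator per
resample:

* nonparametric bootstrap of the edge weights with 95% quantile CIs;
* bootstrapped difference tests between edges (or node centralities),
  significant when the 95% interval of the replicate differences
  excludes zero;
* case-dropping bootstrap of centrality, summarized by the
  correlation-stability (CS) coefficient — the largest case-drop
  fraction at which at least 95% of subsample centrality vectors still
  correlate above 0.7 with the full-sample vector.  CS > 0.25 is read as
  acceptable stability and CS > 0.5 as excellent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centrality import expected_influence, strength
from .estimation import EstimationSettings, select_network

__all__ = [
    "EdgeBootstrap",
    "CaseDropResult",
    "CSCoefficient",
    "DEFAULT_DROP_GRID",
    "bootstrap_edges",
    "bootstrap_difference_test",
    "case_drop_bootstrap",
    "cs_coefficient",
]

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.76, 0.05), 2))


@dataclass
class EdgeBootstrap:
    """Bootstrap distribution of all edge weights.

    ``replicates`` has shape (B_effective, p, p): the full weight matrix
    of every successful refit, so difference tests can be formed for any
    edge or node pair afterwards.
    """

    point: np.ndarray        # full-sample weight matrix
    replicates: np.ndarray
    B: int
    n_failed: int
    seed: int
    node_names: tuple[str, ...]

    def summary(self) -> pd.DataFrame:
        """Per-edge point estimate, bootstrap mean and 95% quantile CI."""
        iu, ju = np.triu_indices_from(self.point, k=1)
        reps = self.replicates[:, iu, ju]
        lo, hi = np.quantile(reps, [0.025, 0.975], axis=0)  # type-7 quantiles
        return pd.DataFrame({
            "node_a": [self.node_names[i] for i in iu],
            "node_b": [self.node_names[j] for j in ju],
            "estimate": self.point[iu, ju],
            "boot_mean": reps.mean(axis=0),
            "ci_lower": lo,
            "ci_upper": hi,
        })


@dataclass
class CaseDropResult:
    """Case-dropping bootstrap correlations, long format."""

    table: pd.DataFrame      # columns: index, proportion, replicate, correlation
    index: str               # which centrality was tracked
    skipped: list[float] = field(default_factory=list)


@dataclass
class CSCoefficient:
    value: float             # largest passing grid proportion, or 0
    interpolated: float      # linear interpolation between adjacent grid points
    r_threshold: float = 0.7
    confidence: float = 0.95


_INDEX_FNS = {"strength": strength, "ei": expected_influence}


def _fit_weights(X, settings):
    return select_network(X, settings=settings).weights


def bootstrap_edges(
    scores: np.ndarray,
    settings: EstimationSettings = EstimationSettings(),
    B: int = 1000,
    seed: int = 0,
    node_names: tuple[str, ...] | None = None,
) -> EdgeBootstrap:
    """Nonparametric row bootstrap of the edge-weight estimates.

    Each of the ``B`` resamples draws n rows with replacement and reruns
    the entire penalty-path selection.  Resamples whose fit fails (e.g.
    a constant column) are skipped and counted.
    """
    if B < 100:
        raise ValueError("B must be at least 100 for quantile CIs")
    X = np.asarray(scores, dtype=float)
    n, p = X.shape
    model = select_network(X, settings=settings)
    names = tuple(node_names) if node_names is not None else model.node_names
    rng = np.random.default_rng(seed)
    reps, n_failed = [], 0
    for _ in range(B):
        rows = rng.integers(0, n, size=n)
        try:
            reps.append(_fit_weights(X[rows], settings))
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
    return EdgeBootstrap(
        point=model.weights,
        replicates=np.array(reps),
        B=B,
        n_failed=n_failed,
        seed=seed,
        node_names=names,
    )


def _edge_values(boot: EdgeBootstrap, edge: tuple[str, str]) -> tuple[float, np.ndarray]:
    try:
        i = boot.node_names.index(edge[0])
        j = boot.node_names.index(edge[1])
    except ValueError as err:
        raise ValueError(f"unknown node in edge {edge}") from err
    return boot.point[i, j], boot.replicates[:, i, j]


def _node_values(boot: EdgeBootstrap, node: str, index: str) -> tuple[float, np.ndarray]:
    fn = _INDEX_FNS[index]
    try:
        i = boot.node_names.index(node)
    except ValueError as err:
        raise ValueError(f"unknown node {node!r}") from err
    return fn(boot.point)[i], np.array([fn(W)[i] for W in boot.replicates])


def bootstrap_difference_test(
    boot: EdgeBootstrap,
    pairs: list[tuple],
    kind: str = "edge",
    index: str = "strength",
) -> pd.DataFrame:
    """Bootstrapped difference tests between edges or node centralities.

    ``pairs`` holds ((a, b), (c, d)) edge pairs when ``kind='edge'`` or
    (node, node) pairs when ``kind='node'`` (comparing the centrality
    named by ``index``).  A difference is flagged significant when the
    95% quantile interval of its replicate distribution excludes zero.
    """
    rows = []
    for pair in pairs:
        if kind == "edge":
            est1, rep1 = _edge_values(boot, pair[0])
            est2, rep2 = _edge_values(boot, pair[1])
            label1, label2 = "-".join(pair[0]), "-".join(pair[1])
        elif kind == "node":
            est1, rep1 = _node_values(boot, pair[0], index)
            est2, rep2 = _node_values(boot, pair[1], index)
            label1, label2 = pair
        else:
            raise ValueError("kind must be 'edge' or 'node'")
        diff = rep1 - rep2
        lo, hi = np.quantile(diff, [0.025, 0.975])
        rows.append({
            "first": label1, "second": label2,
            "observed_difference": est1 - est2,
            "ci_lower": lo, "ci_upper": hi,
            "significant": bool(lo > 0 or hi < 0),
        })
    return pd.DataFrame(rows)


def case_drop_bootstrap(
    scores: np.ndarray,
    index: str = "ei",
    grid: tuple[float, ...] = DEFAULT_DROP_GRID,
    B: int = 100,
    seed: int = 0,
    settings: EstimationSettings = EstimationSettings(),
) -> CaseDropResult:
    """Case-dropping (subset) bootstrap of a centrality index.

    For each drop proportion q, ``B`` subsamples of size ceil((1-q) n)
    are drawn without replacement, the network refit, and the Pearson
    correlation of the subsample centrality vector with the full-sample
    vector recorded.  Proportions whose retained size would not exceed
    the node count are skipped with a warning entry.
    """
    if index not in _INDEX_FNS:
        raise ValueError(f"index must be one of {sorted(_INDEX_FNS)}")
    X = np.asarray(scores, dtype=float)
    n, p = X.shape
    grid = tuple(grid)
    if any(q <= 0 or q > 0.75 for q in grid) or list(grid) != sorted(grid):
        raise ValueError("grid must be strictly increasing in (0, 0.75]")
    fn = _INDEX_FNS[index]
    full = fn(select_network(X, settings=settings).weights)
    rng = np.random.default_rng(seed)
    rows, skipped = [], []
    for q in grid:
        keep = int(np.ceil((1 - q) * n))
        if keep <= p:
            skipped.append(q)
            continue
        for b in range(B):
            rows_idx = rng.choice(n, size=keep, replace=False)
            try:
                sub = fn(select_network(X[rows_idx], settings=settings).weights)
            except (ValueError, np.linalg.LinAlgError):
                continue
            r = np.corrcoef(full, sub)[0, 1]
            rows.append({
                "index": index, "proportion": q, "replicate": b,
                "correlation": float(r),
            })
    return CaseDropResult(table=pd.DataFrame(rows), index=index, skipped=skipped)


def cs_coefficient(
    result: CaseDropResult, r_threshold: float = 0.7, confidence: float = 0.95
) -> CSCoefficient:
    """Correlation-stability coefficient of a case-dropping run.

    Value: the largest drop proportion q at which at least ``confidence``
    of the correlations exceed ``r_threshold`` (0 if none).  Also
    reports a linearly interpolated value between the last passing and
    first failing grid point, since the true breakdown fraction
    generally falls between grid steps.
    """
    df = result.table
    if df.empty:
        raise ValueError("empty case-dropping result")
    props = np.array(sorted(df["proportion"].unique()))
    frac = np.array([
        float(np.mean(df.loc[df["proportion"] == q, "correlation"] > r_threshold))
        for q in props
    ])
    passing = frac >= confidence
    if not passing.any():
        return CSCoefficient(0.0, 0.0, r_threshold, confidence)
    k = int(np.flatnonzero(passing).max())  # largest passing grid proportion
    value = float(props[k])
    if k == len(props) - 1:
        interp = value
    else:
        q0, q1 = props[k], props[k + 1]
        f0, f1 = frac[k], frac[k + 1]
        # where the passing fraction crosses the confidence level
        t = 0.0 if f0 == f1 else (f0 - confidence) / (f0 - f1)
        interp = float(q0 + np.clip(t, 0.0, 1.0) * (q1 - q0))
    return CSCoefficient(value, interp, r_threshold, confidence)
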