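"""Propensity-score matching and balance diagnostics.

Exposure probability is modelled by maximum-likelihood logistic
regression on the matching covariates; exposed participants are paired
1:1 to unexposed controls by greedy nearest-neighbour matching on the
logit of the propensity score, without replacement, inside a caliper of
0.2 standard deviations of that logit.  Balance before/after matching is
summarised by standardized mean differences, Welch t-tests (continuous)
and Pearson chi-square tests (categorical).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datasets import REGISTRATION_LEVELS, SubscaleDataset

__all__ = [
    "PropensityResult",
    "MatchResult",
    "fit_propensity",
    "match_nearest",
    "welch_t_from_summary",
    "chi_square_independence",
    "balance_table",
    "standardized_mean_difference",
    "match_dataset",
]


@dataclass
class PropensityResult:
    """Fitted exposure model: per-participant scores and coefficients."""

    scores: np.ndarray            # P(exposed | covariates), in (0, 1)
    linear_predictor: np.ndarray  # logit scale
    coefficients: pd.Series
    converged: bool
    separation_warning: bool = False

    def __post_init__(self) -> None:
        if np.any(self.scores <= 0) or np.any(self.scores >= 1):
            raise ValueError("propensity scores must lie strictly inside (0, 1)")
        expit = 1.0 / (1.0 + np.exp(-self.linear_predictor))
        if np.max(np.abs(self.scores - expit)) > 1e-10:
            raise ValueError("scores inconsistent with linear predictor")


@dataclass
class MatchResult:
    """1:1 matched pairs and the caliper actually applied (logit units)."""

    pairs: list[tuple]            # (exposed_id, control_id)
    caliper_width: float
    unmatched_exposed: list = field(default_factory=list)

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def _design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """One-hot design with reference levels dropped, plus intercept."""
    X = pd.DataFrame({
        "const": 1.0,
        "age": covariates["age"].astype(float),
        "sex": covariates["sex"].astype(float),
        "only_child": covariates["only_child"].astype(float),
        "father_drunkenness": covariates["father_drunkenness"].astype(float),
    })
    reg = covariates["registration"].astype(str)
    for level in REGISTRATION_LEVELS[1:]:  # reference level: city
        X[f"registration[{level}]"] = (reg == level).astype(float)
    return X


def fit_propensity(covariates: pd.DataFrame, exposure: np.ndarray) -> PropensityResult:
    """Maximum-likelihood logistic regression of exposure on covariates.

    Convergence by Newton iterations with coefficient-update tolerance
    1e-8 (at most 100 iterations).  Quasi-separation — any coefficient
    beyond +-20 on standardized inputs — is flagged, not fatal; rank
    deficiency of the one-hot design raises.
    """
    exposure = np.asarray(exposure, dtype=int)
    if len(np.unique(exposure)) < 2:
        raise ValueError("both exposure classes must be present")
    X = _design_matrix(covariates)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix rank deficient (rank {rank} < {X.shape[1]} columns)"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(exposure, X).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
    eta = np.asarray(fit.fittedvalues, dtype=float)  # linear predictor
    # separation check on standardized-input scale
    scales = X.to_numpy().std(axis=0)
    scales[scales == 0] = 1.0
    separated = bool(np.any(np.abs(fit.params.to_numpy() * scales) > 20))
    if separated:
        warnings.warn("possible separation: a standardized coefficient exceeds 20")
    eta = np.clip(eta, -30, 30)  # keep scores strictly inside (0, 1)
    return PropensityResult(
        scores=1.0 / (1.0 + np.exp(-eta)),
        linear_predictor=eta,
        coefficients=fit.params,
        converged=bool(fit.mle_retvals["converged"]),
        separation_warning=separated,
    )


def match_nearest(
    propensity: PropensityResult,
    exposure: np.ndarray,
    ids: np.ndarray,
    caliper_sd_multiplier: float = 0.2,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbour matching on the propensity logit.

    The caliper is ``caliper_sd_multiplier`` times the SD of the linear
    predictor over the full sample.  Exposed units are processed in
    descending propensity order (hardest to match first); each takes the
    nearest still-unmatched control inside the caliper, ties broken by
    lowest control id.  Exposed units with no eligible control are
    dropped and listed.
    """
    if caliper_sd_multiplier <= 0:
        raise ValueError("caliper_sd_multiplier must be positive")
    exposure = np.asarray(exposure, dtype=int)
    ids = np.asarray(ids)
    eta = propensity.linear_predictor
    caliper = caliper_sd_multiplier * float(np.std(eta))

    exp_idx = np.flatnonzero(exposure == 1)
    ctl_idx = np.flatnonzero(exposure == 0)
    pairs: list[tuple] = []
    unmatched: list = []
    if ctl_idx.size == 0:
        return MatchResult(pairs=[], caliper_width=caliper,
                           unmatched_exposed=list(ids[exp_idx]))

    # stable descending order of exposed by propensity, ties by id
    order = exp_idx[np.lexsort((ids[exp_idx], -eta[exp_idx]))]
    ctl_eta = eta[ctl_idx]
    ctl_ids = ids[ctl_idx]
    available = np.ones(ctl_idx.size, dtype=bool)
    for e in order:
        d = np.abs(ctl_eta - eta[e])
        d[~available] = np.inf
        best = np.min(d)
        if best > caliper:
            unmatched.append(ids[e])
            continue
        cand = np.flatnonzero(d <= best + 1e-15)
        pick = cand[np.argmin(ctl_ids[cand])]  # tie-break: lowest control id
        available[pick] = False
        pairs.append((ids[e], ctl_ids[pick]))
    return MatchResult(pairs=pairs, caliper_width=caliper, unmatched_exposed=unmatched)


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch two-sample t-test from summary statistics.

    Returns (t, Welch-Satterthwaite df, two-sided p).
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be at least 2")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    se2 = v1 + v2
    if se2 == 0:
        raise ValueError("zero pooled variance")
    t = (mean1 - mean2) / np.sqrt(se2)
    df = se2**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def chi_square_independence(contingency: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction."""
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table must be at least 2 x 2")
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has an all-zero margin")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def standardized_mean_difference(x1: np.ndarray, x0: np.ndarray) -> float:
    """SMD with the pooled-variance denominator sqrt((s1^2 + s0^2)/2)."""
    m1, m0 = np.mean(x1), np.mean(x0)
    v1, v0 = np.var(x1, ddof=1), np.var(x0, ddof=1)
    denom = np.sqrt((v1 + v0) / 2)
    if denom == 0:
        return 0.0 if m1 == m0 else np.inf
    return float((m1 - m0) / denom)


def balance_table(dataset: SubscaleDataset) -> pd.DataFrame:
    """Covariate balance between exposure groups.

    One row per covariate (categorical levels expanded to indicators for
    the SMD; the test is a single chi-square over the full table).
    """
    cov = dataset.covariates
    e = dataset.exposure == 1
    rows = []
    for name in ("age", "sex", "only_child", "father_drunkenness"):
        x = cov[name].to_numpy(float)
        if name == "age":
            t, df, p = welch_t_from_summary(
                x[e].mean(), x[e].std(ddof=1), e.sum(),
                x[~e].mean(), x[~e].std(ddof=1), (~e).sum(),
            )
            stat, kind = t, "welch_t"
        else:
            table = pd.crosstab(cov[name], dataset.exposure).to_numpy()
            stat, df, p = chi_square_independence(table)
            kind = "chi_square"
        rows.append({
            "covariate": name, "kind": kind,
            "mean_exposed": x[e].mean(), "mean_control": x[~e].mean(),
            "smd": standardized_mean_difference(x[e], x[~e]),
            "statistic": stat, "df": df, "p_value": p,
        })
    # registration: one chi-square, per-level indicator SMDs aggregated as max
    table = pd.crosstab(cov["registration"], dataset.exposure).to_numpy()
    stat, df, p = chi_square_independence(table)
    smds = [
        standardized_mean_difference(
            (cov["registration"][e] == lvl).to_numpy(float),
            (cov["registration"][~e] == lvl).to_numpy(float),
        )
        for lvl in REGISTRATION_LEVELS
    ]
    rows.append({
        "covariate": "registration", "kind": "chi_square",
        "mean_exposed": np.nan, "mean_control": np.nan,
        "smd": smds[int(np.argmax(np.abs(smds)))],
        "statistic": stat, "df": df, "p_value": p,
    })
    return pd.DataFrame(rows)


def match_dataset(
    dataset: SubscaleDataset, caliper_sd_multiplier: float = 0.2
) -> tuple[SubscaleDataset, MatchResult, PropensityResult]:
    """Fit the propensity model, match 1:1, and return the matched subset."""
    ps = fit_propensity(dataset.covariates, dataset.exposure)
    match = match_nearest(ps, dataset.exposure, dataset.ids, caliper_sd_multiplier)
    keep = [pid for pair in match.pairs for pid in pair]
    return dataset.subset(np.array(keep)), match, ps
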