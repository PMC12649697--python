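"""Synthetic two-group subscale datasets with planted graphical structure.

The generator emulates a matched case-control psychometric study: two
groups of adolescents (exposed / unexposed to cyberbullying), each
described by 9 SCL-90 symptom subscales and 13 QLSCA quality-of-life
subscales, with group-specific marginal profiles (means / SDs), a
group-specific sparse Gaussian-graphical dependence structure, and
exposure assignment confounded with demographic covariates through a
logistic model.  Every downstream stage (matching, network estimation,
stability, comparison) is testable offline against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SCL_LABELS",
    "QOL_LABELS",
    "NODE_LABELS",
    "COMMUNITIES",
    "REGISTRATION_LEVELS",
    "ScenarioParams",
    "SubscaleDataset",
    "make_planted_precision",
    "partial_correlations",
    "sample_dataset",
    "default_scenario",
    "read_dataset_csv",
    "write_dataset_csv",
    "read_scenario_yaml",
    "write_scenario_yaml",
]

SCL_LABELS = tuple(f"SCL{i}" for i in range(1, 10))
QOL_LABELS = tuple(f"QOL{i}" for i in range(1, 14))
NODE_LABELS = SCL_LABELS + QOL_LABELS
#: community label per node: mental-health symptoms vs quality-of-life domains
COMMUNITIES = tuple(["SCL"] * 9 + ["QOL"] * 13)

REGISTRATION_LEVELS = ("city", "township", "other_city", "other_province")

COVARIATE_COLUMNS = ("age", "sex", "registration", "only_child", "father_drunkenness")

# Post-matching group profiles (mean, SD) per subscale: column 0 = unexposed,
# column 1 = exposed.  Exposed adolescents score higher on every symptom
# dimension and lower on every quality-of-life dimension.
_MEANS = np.array([
    # SCL1..SCL9
    [15.98, 21.41], [16.64, 20.09], [13.83, 17.62], [19.06, 25.08],
    [14.36, 18.82], [8.15, 11.16], [9.32, 12.43], [8.40, 11.14], [13.80, 18.18],
    # QOL1..QOL13
    [16.15, 13.52], [15.96, 13.54], [12.32, 10.45], [7.97, 7.30],
    [10.80, 9.63], [14.62, 13.42], [11.00, 10.48], [8.66, 8.16],
    [6.69, 5.69], [7.83, 6.94], [8.39, 7.29], [17.86, 15.14], [5.44, 5.04],
]).T

_SDS = np.array([
    [6.29, 10.18], [6.85, 9.04], [5.94, 8.37], [8.28, 12.26],
    [6.21, 9.27], [3.35, 5.65], [3.94, 6.25], [3.46, 5.42], [5.45, 8.51],
    [2.82, 4.14], [2.85, 4.10], [2.53, 3.28], [1.61, 1.47],
    [2.56, 3.04], [2.94, 3.91], [2.46, 3.04], [1.72, 2.23],
    [1.24, 1.80], [2.10, 2.44], [2.22, 2.49], [3.66, 4.76], [1.02, 1.54],
]).T


def _node_index(label: str) -> int:
    return NODE_LABELS.index(label)


@dataclass
class ScenarioParams:
    """Population model for a two-group subscale study.

    Attributes
    ----------
    n_per_group
        Participants per exposure group.
    node_names
        22 ordered labels, 9 SCL followed by 13 QOL.
    means_by_group, sds_by_group
        2 x 22 marginal profiles (row 0 unexposed, row 1 exposed), in
        subscale score units.
    precision_by_group
        Two 22 x 22 symmetric positive-definite precision matrices on the
        standardized scale; off-diagonal entries encode the planted
        partial-correlation network of each group.
    confounder_coefs
        Coefficients of the exposure logistic model over the design
        (intercept, centered age, sex, 3 registration dummies,
        only-child, paternal drunkenness).
    seed
        Base seed for all sampling.
    """

    n_per_group: int
    node_names: tuple[str, ...] = NODE_LABELS
    means_by_group: np.ndarray = field(default_factory=lambda: _MEANS.copy())
    sds_by_group: np.ndarray = field(default_factory=lambda: _SDS.copy())
    precision_by_group: tuple[np.ndarray, np.ndarray] = None  # type: ignore[assignment]
    confounder_coefs: np.ndarray = None  # type: ignore[assignment]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group <= 0:
            raise ValueError("n_per_group must be positive")
        names = tuple(self.node_names)
        if len(names) != 22 or names[:9] != SCL_LABELS or names[9:] != QOL_LABELS:
            raise ValueError("node_names must be SCL1..SCL9 followed by QOL1..QOL13")
        self.node_names = names
        self.means_by_group = np.asarray(self.means_by_group, dtype=float)
        self.sds_by_group = np.asarray(self.sds_by_group, dtype=float)
        if self.means_by_group.shape != (2, 22) or self.sds_by_group.shape != (2, 22):
            raise ValueError("means/sds must be 2 x 22")
        if np.any(self.sds_by_group <= 0):
            raise ValueError("sds must be strictly positive")
        if self.precision_by_group is None:
            self.precision_by_group = (np.eye(22), np.eye(22))
        self.precision_by_group = tuple(
            np.asarray(K, dtype=float) for K in self.precision_by_group
        )
        for g, K in enumerate(self.precision_by_group):
            if K.shape != (22, 22) or not np.allclose(K, K.T, atol=1e-10):
                raise ValueError(f"precision matrix for group {g} must be 22x22 symmetric")
            if np.linalg.eigvalsh(K).min() <= 0:
                raise ValueError(f"precision matrix for group {g} is not positive definite")
        if self.confounder_coefs is None:
            self.confounder_coefs = np.zeros(8)
        self.confounder_coefs = np.asarray(self.confounder_coefs, dtype=float)
        if self.confounder_coefs.shape != (8,):
            raise ValueError("confounder_coefs must have length 8")


@dataclass
class SubscaleDataset:
    """Per-participant subscale scores, exposure and matching covariates."""

    scores: np.ndarray
    exposure: np.ndarray
    covariates: pd.DataFrame
    ids: np.ndarray
    node_names: tuple[str, ...] = NODE_LABELS

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.exposure = np.asarray(self.exposure, dtype=int)
        self.ids = np.asarray(self.ids)
        n = self.scores.shape[0]
        if self.scores.ndim != 2 or self.scores.shape[1] != len(self.node_names):
            raise ValueError("scores must be n x 22")
        if np.isnan(self.scores).any():
            raise ValueError("scores contain missing values")
        if len(self.exposure) != n or len(self.ids) != n or len(self.covariates) != n:
            raise ValueError("inconsistent row counts")
        if len(np.unique(self.ids)) != n:
            raise ValueError("participant ids must be unique")
        if set(np.unique(self.exposure)) - {0, 1}:
            raise ValueError("exposure must be binary")
        if len(np.unique(self.exposure)) < 2:
            raise ValueError("both exposure classes must be present")

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    def group_scores(self, exposed: bool) -> np.ndarray:
        """Score matrix of one exposure group."""
        return self.scores[self.exposure == int(exposed)]

    def subset(self, mask_or_ids) -> "SubscaleDataset":
        """Row subset by boolean mask or id list (keeps row order)."""
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            pos = {pid: k for k, pid in enumerate(self.ids)}
            idx = np.array([pos[i] for i in arr])
        return SubscaleDataset(
            scores=self.scores[idx],
            exposure=self.exposure[idx],
            covariates=self.covariates.iloc[idx].reset_index(drop=True),
            ids=self.ids[idx],
            node_names=self.node_names,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.ids, "exposure": self.exposure})
        df[list(COVARIATE_COLUMNS)] = self.covariates[list(COVARIATE_COLUMNS)].values
        for j, name in enumerate(self.node_names):
            df[name] = self.scores[:, j]
        return df


def make_planted_precision(
    n_nodes: int,
    edge_list: list[tuple[int, int, float]],
    jitter: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Build a positive-definite precision matrix with planted partial correlations.

    Each entry ``(i, j, rho)`` requests partial correlation
    ``rho = -K_ij / sqrt(K_ii K_jj)`` between nodes ``i`` and ``j``.  With
    ``jitter > 0`` every non-planted off-diagonal receives a small uniform
    perturbation (so "absent" edges are near, not exactly, zero).

    Because partial correlations are invariant to diagonal rescaling, a
    positive-definite precision with exactly the requested partials exists
    if and only if the unit-diagonal construction ``I - rho`` is itself
    positive definite; no repair can rescue an infeasible request.

    Raises
    ------
    ValueError
        On invalid edges, or if the requested partials admit no
        positive-definite completion (names the strongest,
        likeliest-offending edges).
    """
    rng = np.random.default_rng(seed)
    seen: set[tuple[int, int]] = set()
    for i, j, rho in edge_list:
        if i == j:
            raise ValueError(f"self edge ({i},{j}) not allowed")
        if not (0 <= i < n_nodes and 0 <= j < n_nodes):
            raise ValueError(f"edge ({i},{j}) out of range for {n_nodes} nodes")
        if not abs(rho) < 1:
            raise ValueError(f"edge ({i},{j}): |partial correlation| must be < 1, got {rho}")
        key = (min(i, j), max(i, j))
        if key in seen:
            raise ValueError(f"duplicate edge {key}")
        seen.add(key)

    base = np.zeros((n_nodes, n_nodes))
    for i, j, rho in edge_list:
        base[i, j] = base[j, i] = rho
    if jitter > 0:
        noise = rng.uniform(-jitter, jitter, size=(n_nodes, n_nodes))
        noise = np.triu(noise, 1)
        noise += noise.T
        planted = base != 0
        base = base + np.where(planted | np.eye(n_nodes, dtype=bool), 0.0, noise)

    K = np.eye(n_nodes) - base
    if np.linalg.eigvalsh(K).min() > 1e-8:
        return K
    strengths = sorted(edge_list, key=lambda e: -abs(e[2]))[:5]
    raise ValueError(
        "no positive-definite completion for the requested edges; "
        f"strongest (likeliest offending) edges: {strengths}"
    )


def partial_correlations(K: np.ndarray) -> np.ndarray:
    """Partial correlations implied by a precision matrix (zero diagonal)."""
    d = np.sqrt(np.diag(K))
    R = -K / np.outer(d, d)
    np.fill_diagonal(R, 0.0)
    return R


def _correlation_from_precision(K: np.ndarray) -> np.ndarray:
    C = np.linalg.inv(K)
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


def _covariate_design(cov: pd.DataFrame) -> np.ndarray:
    """Design matrix of the exposure model: intercept, centered age, dummies."""
    reg = cov["registration"].astype(str)
    X = np.column_stack([
        np.ones(len(cov)),
        cov["age"].to_numpy(float) - 16.2,
        cov["sex"].to_numpy(float),
        (reg == "township").to_numpy(float),
        (reg == "other_city").to_numpy(float),
        (reg == "other_province").to_numpy(float),
        cov["only_child"].to_numpy(float),
        cov["father_drunkenness"].to_numpy(float),
    ])
    return X


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Covariate marginals of a Chinese high-school survey population."""
    age = rng.normal(16.2, 1.24, size=n)
    while True:  # truncate to the surveyed age range
        out = (age < 14) | (age > 19)
        if not out.any():
            break
        age[out] = rng.normal(16.2, 1.24, size=out.sum())
    return pd.DataFrame({
        "age": np.round(age, 2),
        "sex": rng.binomial(1, 0.49, size=n),  # 1 = girl
        "registration": rng.choice(
            REGISTRATION_LEVELS, size=n, p=[0.487, 0.416, 0.063, 0.034]
        ),
        "only_child": rng.binomial(1, 0.51, size=n),
        "father_drunkenness": rng.binomial(1, 0.10, size=n),
    })


def sample_dataset(params: ScenarioParams) -> SubscaleDataset:
    """Draw a two-group dataset from a scenario.

    Covariates are drawn from population marginals, exposure is assigned
    by the logistic confounding model, and candidates accumulate until
    both groups reach ``n_per_group`` (conditional sampling).  Each
    participant's 22 scores are then drawn from their group's
    multivariate normal: standardized draws with correlation
    ``corr(inv(K_g))``, scaled by the group SD profile and shifted by the
    group mean profile.  Fully reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n_goal = params.n_per_group
    cov_parts, exp_parts = [], []
    n_have = np.zeros(2, dtype=int)
    batch = max(512, 4 * n_goal)
    for _ in range(10_000):
        cand = _draw_covariates(rng, batch)
        eta = _covariate_design(cand) @ params.confounder_coefs
        e = (rng.random(batch) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
        for g in (0, 1):
            take = np.flatnonzero(e == g)[: n_goal - n_have[g]]
            if take.size:
                cov_parts.append(cand.iloc[take])
                exp_parts.append(e[take])
                n_have[g] += take.size
        if (n_have == n_goal).all():
            break
    else:  # pragma: no cover - requires a degenerate exposure model
        raise RuntimeError("could not fill both exposure groups; exposure model degenerate")

    covariates = pd.concat(cov_parts, ignore_index=True)
    exposure = np.concatenate(exp_parts)

    scores = np.empty((2 * n_goal, 22))
    for g in (0, 1):
        C = _correlation_from_precision(params.precision_by_group[g])
        L = np.linalg.cholesky(C)
        z = rng.standard_normal((n_goal, 22)) @ L.T
        scores[exposure == g] = params.means_by_group[g] + z * params.sds_by_group[g]

    return SubscaleDataset(
        scores=scores,
        exposure=exposure,
        covariates=covariates,
        ids=np.arange(2 * n_goal),
        node_names=params.node_names,
    )


# --- default scenario -------------------------------------------------------

# Sparse backbone shared by both groups: first- and second-neighbour chains
# within each instrument (so within-instrument subscales are substantially
# intercorrelated, as on real questionnaires) plus four cross-instrument
# bridges.  Edges are (label_a, label_b, partial corr).
_BASE_EDGES: list[tuple[str, str, float]] = (
    [(f"SCL{i}", f"SCL{i+1}", 0.28) for i in range(1, 9)]
    + [(f"SCL{i}", f"SCL{i+2}", 0.12) for i in range(1, 8)]
    + [(f"QOL{i}", f"QOL{i+1}", 0.26) for i in range(1, 13)]
    + [(f"QOL{i}", f"QOL{i+2}", 0.12) for i in range(1, 12)]
    + [
        ("SCL3", "QOL7", 0.10),   # interpersonal sensitivity - negative emotion
        ("SCL4", "QOL12", -0.15),  # depression - self satisfaction
        ("SCL5", "QOL1", -0.12),   # anxiety - teacher-student relationship
        ("SCL9", "QOL5", -0.12),   # psychoticism - self concept
    ]
)

# Extra structure in the exposed group: a denser, more tightly coupled
# network, with a clearly stronger interpersonal-sensitivity /
# negative-emotion bridge and a strengthened somatic-sensation /
# negative-emotion edge.
_EXPOSED_EXTRA: list[tuple[str, str, float]] = [
    ("SCL1", "SCL5", 0.14),
    ("SCL2", "SCL7", 0.14),
    ("SCL4", "SCL9", 0.14),
    ("QOL1", "QOL5", 0.14),
    ("QOL2", "QOL9", 0.12),
    ("QOL4", "QOL11", 0.12),
    ("QOL7", "QOL12", -0.14),
    ("SCL2", "QOL13", -0.12),
    ("SCL6", "QOL10", -0.12),
]
_EXPOSED_OVERRIDE: dict[tuple[str, str], float] = {
    ("SCL3", "QOL7"): 0.35,   # the planted group contrast
    ("QOL6", "QOL7"): 0.32,
}


def _edges_to_indexed(edges: list[tuple[str, str, float]]) -> list[tuple[int, int, float]]:
    return [(_node_index(a), _node_index(b), w) for a, b, w in edges]


def default_scenario(n_per_group: int = 766, seed: int = 0) -> ScenarioParams:
    """The packaged two-group scenario.

    Marginal mean/SD profiles follow the matched study groups for all 22
    subscales; the exposed group's precision matrix has strictly more
    nonzero off-diagonal entries than the unexposed group's, including a
    much stronger SCL3-QOL7 (interpersonal sensitivity - negative
    emotion) edge; exposure is confounded with age, sex, registration,
    only-child status and paternal drunkenness at roughly 8.5%
    population prevalence.
    """
    base = _BASE_EDGES
    exposed = [
        (a, b, _EXPOSED_OVERRIDE.get((a, b), w)) for a, b, w in base
    ] + _EXPOSED_EXTRA
    K0 = make_planted_precision(22, _edges_to_indexed(base), seed=seed)
    K1 = make_planted_precision(22, _edges_to_indexed(exposed), seed=seed + 1)
    # Effect sizes are set so every matched covariate carries a pre-match
    # standardized mean difference of roughly 0.2-0.3 (the top of the
    # plausible survey range), i.e. clearly above the ~sqrt(2/766) ~ 0.05
    # post-match sampling noise floor at the default group size; the
    # intercept is calibrated to ~8.5% population exposure prevalence.
    coefs = np.array([-2.27, 0.20, 0.45, -0.50, -0.70, -0.90, -0.55, 0.85])
    return ScenarioParams(
        n_per_group=n_per_group,
        precision_by_group=(K0, K1),
        confounder_coefs=coefs,
        seed=seed,
    )


# --- serialization ----------------------------------------------------------

def write_dataset_csv(dataset: SubscaleDataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def read_dataset_csv(path) -> SubscaleDataset:
    df = pd.read_csv(path)
    return SubscaleDataset(
        scores=df[list(NODE_LABELS)].to_numpy(float),
        exposure=df["exposure"].to_numpy(int),
        covariates=df[list(COVARIATE_COLUMNS)].reset_index(drop=True),
        ids=df["id"].to_numpy(),
    )


def write_scenario_yaml(params: ScenarioParams, path) -> None:
    """Serialize a scenario; documented keys mirror ScenarioParams fields."""
    doc = {
        "n_per_group": int(params.n_per_group),
        "node_names": list(params.node_names),
        "means_by_group": params.means_by_group.tolist(),
        "sds_by_group": params.sds_by_group.tolist(),
        "precision_by_group": [K.tolist() for K in params.precision_by_group],
        "confounder_coefs": params.confounder_coefs.tolist(),
        "seed": int(params.seed),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_scenario_yaml(path) -> ScenarioParams:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return ScenarioParams(
        n_per_group=doc["n_per_group"],
        node_names=tuple(doc["node_names"]),
        means_by_group=np.array(doc["means_by_group"]),
        sds_by_group=np.array(doc["sds_by_group"]),
        precision_by_group=tuple(np.array(K) for K in doc["precision_by_group"]),
        confounder_coefs=np.array(doc["confounder_coefs"]),
        seed=doc["seed"],
    )
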