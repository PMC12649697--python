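"""Synthetic-data generator: planted structure, marginals, reproducibility."""

import numpy as np
import pytest

from psynetkit import (
    NODE_LABELS,
    ScenarioParams,
    default_scenario,
    make_planted_precision,
    partial_correlations,
    read_dataset_csv,
    sample_dataset,
    write_dataset_csv,
)
from psynetkit.datasets import (
    QOL_LABELS,
    SCL_LABELS,
    read_scenario_yaml,
    write_scenario_yaml,
)

from conftest import mvn_from_precision


def sample_partial_correlations(X: np.ndarray) -> np.ndarray:
    """Closed-form sample partial correlations via the inverse correlation."""
    K = np.linalg.inv(np.corrcoef(X, rowvar=False))
    return partial_correlations(K)


class TestMakePlantedPrecision:
    def test_empty_edge_list_gives_identity(self):
        K = make_planted_precision(3, [], jitter=0.0)
        assert np.array_equal(K, np.eye(3))

    def test_two_node_edge_matches_formula(self):
        K = make_planted_precision(2, [(0, 1, 0.5)])
        assert K[0, 1] == pytest.approx(-0.5 * np.sqrt(K[0, 0] * K[1, 1]))
        assert partial_correlations(K)[0, 1] == pytest.approx(0.5, abs=1e-8)

    def test_random_edges_recovered_and_positive_definite(self):
        rng = np.random.default_rng(1)
        edges = []
        seen = set()
        while len(edges) < 40:
            i, j = sorted(rng.integers(0, 22, 2))
            if i == j or (i, j) in seen:
                continue
            seen.add((i, j))
            edges.append((i, j, rng.uniform(0.1, 0.3) * rng.choice([-1, 1])))
        K = make_planted_precision(22, edges, seed=1)
        assert np.linalg.eigvalsh(K).min() > 0
        R = partial_correlations(K)
        for i, j, rho in edges:
            assert R[i, j] == pytest.approx(rho, abs=1e-3)

    def test_round_trip_exact_without_repair(self):
        edges = [(0, 1, 0.3), (1, 2, -0.2), (3, 4, 0.25)]
        K = make_planted_precision(5, edges)
        R = partial_correlations(K)
        for i, j, rho in edges:
            assert R[i, j] == pytest.approx(rho, abs=1e-8)

    def test_hub_feasibility_boundary(self):
        # a 5-spoke star with spoke partials rho is feasible iff rho < 1/sqrt(5);
        # partials are scale-invariant, so no diagonal rescue exists beyond it
        feasible = [(0, j, 0.44) for j in range(1, 6)]
        K = make_planted_precision(6, feasible)
        assert np.linalg.eigvalsh(K).min() > 0
        R = partial_correlations(K)
        for i, j, rho in feasible:
            assert R[i, j] == pytest.approx(rho, abs=1e-8)
        infeasible = [(0, j, 0.45) for j in range(1, 6)]
        with pytest.raises(ValueError, match="positive-definite"):
            make_planted_precision(6, infeasible)

    def test_infeasible_edges_raise_naming_offenders(self):
        edges = [(0, j, 0.95) for j in range(1, 8)]
        with pytest.raises(ValueError, match="positive-definite"):
            make_planted_precision(8, edges)

    @pytest.mark.parametrize(
        "edges, message",
        [
            ([(0, 0, 0.5)], "self edge"),
            ([(0, 9, 0.5)], "out of range"),
            ([(0, 1, 1.0)], "partial correlation"),
            ([(0, 1, 0.2), (1, 0, 0.2)], "duplicate"),
        ],
    )
    def test_invalid_edges_rejected(self, edges, message):
        with pytest.raises(ValueError, match=message):
            make_planted_precision(5, edges)


class TestSampleDataset:
    def test_independence_model_has_near_zero_partials(self):
        params = ScenarioParams(n_per_group=500, seed=7)
        data = sample_dataset(params)
        for exposed in (False, True):
            R = sample_partial_correlations(data.group_scores(exposed))
            iu = np.triu_indices(22, 1)
            assert np.abs(R[iu]).max() < 0.15

    def test_group_means_match_profile(self, scenario):
        data = sample_dataset(scenario)
        som = data.group_scores(False)[:, 0]
        target_mean, target_sd = 15.98, 6.29
        se = target_sd / np.sqrt(len(som))
        assert abs(som.mean() - target_mean) < 3 * se

    def test_planted_group_contrast_visible(self):
        # SCL3-QOL7 planted at 0.35 in the exposed group vs 0.10 unexposed
        i, j = NODE_LABELS.index("SCL3"), NODE_LABELS.index("QOL7")
        gaps = []
        for seed in range(10):
            params = default_scenario(n_per_group=2000, seed=seed)
            data = sample_dataset(params)
            r0 = sample_partial_correlations(data.group_scores(False))[i, j]
            r1 = sample_partial_correlations(data.group_scores(True))[i, j]
            gaps.append(r1 - r0)
        assert np.mean(gaps) >= 0.2

    def test_sampling_consistency_in_n(self, scenario):
        # sample covariance of standardized scores approaches inv(K)
        K = scenario.precision_by_group[0]
        C = np.linalg.inv(K)
        d = np.sqrt(np.diag(C))
        C_target = C / np.outer(d, d)
        dists = []
        for n in (200, 2000, 20000):
            X = mvn_from_precision(K, n, np.random.default_rng(3))
            dists.append(np.linalg.norm(np.corrcoef(X, rowvar=False) - C_target))
        assert dists[0] > dists[1] > dists[2]

    def test_determinism(self, scenario):
        a = sample_dataset(scenario)
        b = sample_dataset(scenario)
        assert np.array_equal(a.scores, b.scores)
        assert np.array_equal(a.exposure, b.exposure)
        assert a.covariates.equals(b.covariates)

    def test_covariate_ranges(self, scenario):
        data = sample_dataset(scenario)
        assert data.covariates["age"].between(14, 19).all()
        assert set(data.covariates["registration"]).issubset(
            {"city", "township", "other_city", "other_province"}
        )
        assert data.exposure.sum() == scenario.n_per_group


class TestDefaultScenario:
    def test_table_profile_values(self, scenario):
        som = NODE_LABELS.index("SCL1")
        satisf = NODE_LABELS.index("QOL12")
        assert scenario.means_by_group[0, som] == 15.98
        assert scenario.means_by_group[1, satisf] == 15.14
        assert scenario.sds_by_group[0, som] == 6.29

    def test_precisions_positive_definite(self, scenario):
        for K in scenario.precision_by_group:
            assert np.linalg.eigvalsh(K).min() > 0

    def test_exposed_group_denser_with_stronger_bridge(self, scenario):
        K0, K1 = scenario.precision_by_group
        nz = lambda K: int((np.abs(np.triu(K, 1)) > 1e-9).sum())
        assert nz(K1) > nz(K0)
        i, j = NODE_LABELS.index("SCL3"), NODE_LABELS.index("QOL7")
        R0, R1 = partial_correlations(K0), partial_correlations(K1)
        assert R1[i, j] > R0[i, j] > 0

    def test_node_label_structure(self, scenario):
        assert scenario.node_names[:9] == SCL_LABELS
        assert scenario.node_names[9:] == QOL_LABELS


class TestSerialization:
    def test_dataset_csv_round_trip(self, tmp_path):
        params = default_scenario(n_per_group=50, seed=3)
        data = sample_dataset(params)
        path = tmp_path / "data.csv"
        write_dataset_csv(data, path)
        header = path.read_text().splitlines()[0].split(",")
        assert header[:7] == [
            "id", "exposure", "age", "sex", "registration",
            "only_child", "father_drunkenness",
        ]
        assert header[7:] == list(NODE_LABELS)
        back = read_dataset_csv(path)
        np.testing.assert_allclose(back.scores, data.scores)
        assert np.array_equal(back.exposure, data.exposure)

    def test_scenario_yaml_round_trip(self, tmp_path):
        params = default_scenario(n_per_group=30, seed=5)
        path = tmp_path / "scenario.yaml"
        write_scenario_yaml(params, path)
        back = read_scenario_yaml(path)
        np.testing.assert_allclose(back.means_by_group, params.means_by_group)
        np.testing.assert_allclose(
            back.precision_by_group[1], params.precision_by_group[1]
        )
        assert back.seed == params.seed
        a, b = sample_dataset(params), sample_dataset(back)
        np.testing.assert_array_equal(a.scores, b.scores)


class TestValidation:
    def test_rejects_nonpositive_sds(self):
        sds = np.ones((2, 22))
        sds[0, 3] = 0.0
        with pytest.raises(ValueError, match="positive"):
            ScenarioParams(n_per_group=10, sds_by_group=sds)

    def test_rejects_indefinite_precision(self):
        K = np.eye(22)
        K[0, 1] = K[1, 0] = 1.5
        with pytest.raises(ValueError, match="positive definite"):
            ScenarioParams(n_per_group=10, precision_by_group=(K, np.eye(22)))
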