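"""Quality proxy, exponent schedule, distance, and grid search."""

import math

import numpy as np
import pandas as pd
import pytest

from winepi.quality import (
    QualityModel,
    euclidean_distance,
    exponent_schedule,
    grid_search,
    grid_search_over_forms,
    quality_proxy,
    quality_proxy_two_group,
    quality_report,
    two_group_case_study,
)
from winepi.synthetic import generate_physiochem

# Published 18-wine reference: perceived panel quality next to the proxy
# column computed at alpha=0.8, n=1.0 (regression fixture for the distance).
REFERENCE_PAIRS = [
    (5.02, 5.848), (5.70, 3.688), (6.55, 6.849), (6.09, 6.271), (6.35, 6.428),
    (6.52, 6.576), (5.52, 6.203), (5.98, 5.813), (5.89, 6.768), (6.07, 6.920),
    (6.02, 6.768), (6.23, 5.327), (5.43, 4.863), (6.34, 3.554), (4.72, 5.257),
    (5.72, 6.790), (5.30, 6.730), (4.82, 6.742),
]


class TestExponentSchedule:
    @pytest.mark.parametrize(
        "alpha, n, m, expected",
        [
            (1.0, 1.0, 5, [1, 1, 1, 1, 1]),
            (0.8, 1.0, 5, [1.0, 0.8, 0.64, 0.512, 0.4096]),
            (0.5, 2.0, 3, [2.0, 1.0, 0.5]),
        ],
    )
    def test_geometric_weights(self, alpha, n, m, expected):
        schedule = exponent_schedule(alpha, n, m)
        assert schedule.weights == pytest.approx(expected, rel=1e-12)
        # the defining identity holds exactly in float arithmetic
        assert all(w == alpha**i * n for i, w in enumerate(schedule.weights))

    def test_non_positive_rejected(self):
        for alpha, n in [(0.0, 1.0), (1.0, 0.0), (-0.5, 1.0)]:
            with pytest.raises(ValueError):
                exponent_schedule(alpha, n, 5)


def _model(alpha=0.8, n=1.0, m=5, k=1.0):
    return QualityModel(
        pi_forms=tuple(f"pi{i}" for i in range(m)),
        schedule=exponent_schedule(alpha, n, m),
        k=k,
    )


class TestQualityProxy:
    def test_identity_pis(self):
        assert quality_proxy([1, 1, 1, 1, 1], _model()) == pytest.approx(1.0)

    def test_only_first_factor_active(self):
        assert quality_proxy([2, 1, 1, 1, 1], _model(alpha=0.37)) == pytest.approx(2.0)

    def test_log_domain_oracle(self):
        # independent oracle: explicit log-space sum
        expected = math.exp(math.log(2.0) * (1 + 0.8 + 0.64 + 0.512 + 0.4096))
        assert quality_proxy([2] * 5, _model()) == pytest.approx(expected, rel=1e-12)

    def test_matrix_input_matches_rowwise(self):
        rng = np.random.default_rng(0)
        mat = rng.uniform(0.5, 3.0, size=(6, 5))
        model = _model(alpha=0.7, n=1.1, k=2.0)
        rows = np.array([quality_proxy(row, model) for row in mat])
        np.testing.assert_allclose(quality_proxy(mat, model), rows, rtol=1e-12)

    def test_non_positive_pi_rejected(self):
        with pytest.raises(ValueError):
            quality_proxy([1, 1, 0, 1, 1], _model())

    def test_monotone_in_each_pi(self):
        model = _model(alpha=0.8, n=1.0)
        base = quality_proxy([1.5] * 5, model)
        for i in range(5):
            bumped = [1.5] * 5
            bumped[i] = 1.6
            assert quality_proxy(bumped, model) > base

    def test_log_linearity_by_finite_differences(self):
        model = _model(alpha=0.75, n=0.9)
        weights = model.schedule.weights
        x = np.array([1.2, 0.8, 2.0, 1.5, 0.6])
        h = 1e-6
        for i in range(5):
            up, down = x.copy(), x.copy()
            up[i] *= math.exp(h)
            down[i] *= math.exp(-h)
            slope = (
                math.log(quality_proxy(up, model)) - math.log(quality_proxy(down, model))
            ) / (2 * h)
            assert slope == pytest.approx(weights[i], rel=1e-5)


class TestTwoGroupProxy:
    def test_unity_pis_return_k(self):
        assert quality_proxy_two_group(1.0, 1.0, 0.94, 1.0) == pytest.approx(0.94)

    def test_first_group_only(self):
        assert quality_proxy_two_group(2.0, 1.0, 1.0, 1.0) == pytest.approx(2.0)

    def test_log_domain_oracle(self):
        expected = 2**0.5 * 2**0.25
        assert quality_proxy_two_group(2.0, 2.0, 1.0, 0.5) == pytest.approx(expected, rel=1e-12)


class TestEuclideanDistance:
    def test_identical_vectors(self):
        assert euclidean_distance([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_three_four_five(self):
        assert euclidean_distance([0, 0, 0], [1, 2, 2]) == pytest.approx(3.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            euclidean_distance([1.0], [1.0, 2.0])

    def test_published_reference_regression(self):
        observed = [p for p, _ in REFERENCE_PAIRS]
        predicted = [q for _, q in REFERENCE_PAIRS]
        # independent spreadsheet-style oracle over the printed pairs
        oracle = math.sqrt(math.fsum((p - q) ** 2 for p, q in REFERENCE_PAIRS))
        d = euclidean_distance(predicted, observed)
        assert d == pytest.approx(oracle, abs=1e-12)
        assert d == pytest.approx(4.845959450924038, abs=1e-9)


class TestGridSearch:
    def _pis(self, n_wines=10, seed=0):
        rng = np.random.default_rng(seed)
        return rng.uniform(0.5, 3.0, size=(n_wines, 5))

    def test_single_cell_grid(self):
        pis = self._pis()
        obs = quality_proxy(pis, _model(0.9, 1.1))
        res = grid_search(pis, obs, [0.9], [1.1], top_m=1)
        assert res.best.alpha == 0.9 and res.best.n == 1.1
        assert res.best.distance == pytest.approx(0.0, abs=1e-9)

    def test_top_m_and_ordering(self):
        pis = self._pis()
        obs = quality_proxy(pis, _model(0.8, 1.0))
        alpha = np.linspace(0.5, 1.2, 10)
        n = np.linspace(0.5, 1.5, 10)
        res = grid_search(pis, obs, alpha, n, top_m=5)
        assert len(res.ranked) == 5
        d = [p.distance for p in res.ranked]
        assert d == sorted(d)

    def test_matches_exhaustive_oracle(self):
        pis = self._pis(seed=3)
        rng = np.random.default_rng(4)
        obs = rng.uniform(3, 8, size=10)
        alphas = [0.6, 0.8, 1.0, 1.1, 1.2]
        ns = [0.5, 0.8, 1.0, 1.3, 1.5]
        res = grid_search(pis, obs, alphas, ns, top_m=25)
        oracle = {}
        for a in alphas:
            for n in ns:
                pred = quality_proxy(pis, _model(a, n))
                oracle[(a, n)] = math.sqrt(sum((p - o) ** 2 for p, o in zip(pred, obs)))
        for point in res.ranked:
            assert point.distance == pytest.approx(oracle[(point.alpha, point.n)], rel=1e-12)
        assert res.best.distance == pytest.approx(min(oracle.values()), rel=1e-12)

    def test_ties_break_lexicographically(self):
        # one wine with pi=1 everywhere: every cell predicts k=1, all tie
        pis = np.ones((3, 5))
        obs = np.full(3, 2.0)
        res = grid_search(pis, obs, [0.9, 0.6, 0.8], [1.2, 1.0], top_m=3)
        assert [(p.alpha, p.n) for p in res.ranked] == [(0.6, 1.0), (0.6, 1.2), (0.8, 1.0)]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search(np.ones((2, 5)), [1, 1], [], [1.0])

    def test_calibrated_k_never_worse_than_fixed(self):
        pis = self._pis(seed=6)
        rng = np.random.default_rng(7)
        obs = rng.uniform(3, 8, size=10)
        grid = dict(alpha_grid=[0.7, 0.9], n_grid=[0.8, 1.2], top_m=1)
        fixed = grid_search(pis, obs, k=1.0, k_mode="fixed", **grid)
        cal = grid_search(pis, obs, k=1.0, k_mode="calibrated", **grid)
        assert cal.best.distance <= fixed.best.distance + 1e-12

    def test_quick_recovery_of_generating_parameters(self, noiseless_study, recovery_truth):
        from winepi.modulators import DEFAULT_ASSIGNMENT, ModulatorSet
        from winepi.quality import pis_from_chemistry

        sets = [ModulatorSet(l, m) for l, m in DEFAULT_ASSIGNMENT.items()]
        pis = pis_from_chemistry(noiseless_study.chemistry, sets, recovery_truth.pi_forms)
        res = grid_search(
            pis,
            noiseless_study.quality.to_numpy(),
            np.round(np.arange(0.5, 1.201, 0.01), 2),
            np.round(np.arange(0.5, 1.501, 0.02), 2),
            top_m=1,
        )
        assert (res.best.alpha, res.best.n) == (0.8, 1.0)
        assert res.best.distance <= 1e-9

    def test_search_over_form_assignments_finds_generating_forms(self):
        rng = np.random.default_rng(11)
        pis_true = rng.uniform(0.5, 3.0, size=(12, 5))
        pis_other = rng.uniform(0.5, 3.0, size=(12, 5))
        obs = quality_proxy(pis_true, _model(0.8, 1.0))
        res = grid_search_over_forms(
            {("f_true",) * 5: pis_true, ("f_other",) * 5: pis_other},
            obs,
            [0.7, 0.8, 0.9],
            [0.9, 1.0, 1.1],
            top_m=3,
        )
        assert res.best.pi_forms == ("f_true",) * 5
        assert (res.best.alpha, res.best.n) == (0.8, 1.0)


class TestCaseStudy:
    def test_two_group_tied_search_runs_on_defaults(self):
        physiochem = generate_physiochem(18, seed=1)
        rng = np.random.default_rng(2)
        obs = rng.uniform(4.5, 6.5, size=18)
        res, pis = two_group_case_study(
            physiochem, obs, n_grid=[0.6, 0.8, 1.0, 1.2], k_mode="calibrated"
        )
        assert pis.shape == (18, 2)
        assert (pis.to_numpy() > 0).all()
        assert all(p.alpha == p.n for p in res.ranked)
        d = [p.distance for p in res.ranked]
        assert d == sorted(d)


class TestQualityReport:
    def test_published_shape(self):
        rng = np.random.default_rng(1)
        pis = rng.uniform(0.5, 3.0, size=(18, 5))
        obs = rng.uniform(4.5, 6.5, size=18)
        models = [_model(a, n) for a, n in [(0.8, 1.0), (0.7, 1.0), (0.8, 0.8), (0.75, 1.0), (0.75, 0.9)]]
        report = quality_report(models, pis, obs)
        assert report.shape == (18, 6)
        assert report.columns[0] == "perceived_quality"

    def test_zero_models_keeps_observed_column(self):
        report = quality_report([], np.ones((3, 5)), [5.0, 6.0, 7.0])
        assert list(report.columns) == ["perceived_quality"]

    def test_csv_round_trip_preserves_values(self, tmp_path):
        rng = np.random.default_rng(5)
        pis = rng.uniform(0.5, 3.0, size=(6, 5))
        obs = rng.uniform(4, 7, size=6)
        report = quality_report([_model(0.8, 1.0)], pis, obs)
        path = tmp_path / "report.csv"
        report.to_csv(path)
        back = pd.read_csv(path, index_col="wine_id")
        np.testing.assert_allclose(back.to_numpy(), report.to_numpy(), atol=1e-12)
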