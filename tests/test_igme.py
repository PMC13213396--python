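import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from encompass.igme import (
    igme_ck,
    igme_lsf,
    igme_scan,
    lump_dtrajs,
    macro_tpm_series,
    model_kinetics,
    pcca_lump,
)
from encompass.msm import TPM, DiscreteTrajectorySet, estimate_tpm
from encompass.synthetic import (
    FineChainSpec,
    TPMSeries,
    exact_projected_tpms,
    gen_fine_chain,
)


def tpm_of(matrix):
    n = matrix.shape[0]
    return TPM(lag=1, matrix=matrix, counts=np.ones((n, n)), active_set=np.arange(n))


def markov_series(t0, K):
    return TPMSeries(tau=1, matrices=[np.linalg.matrix_power(t0, k) for k in range(1, K + 1)])


T0 = np.array([[0.9, 0.08, 0.02], [0.05, 0.9, 0.05], [0.02, 0.08, 0.9]])


class TestPccaLump:
    def test_block_diagonal_exact(self):
        t = np.zeros((4, 4))
        t[:2, :2] = [[0.7, 0.3], [0.4, 0.6]]
        t[2:, 2:] = [[0.8, 0.2], [0.5, 0.5]]
        lump = pcca_lump(tpm_of(t), 2)
        assert np.allclose(np.sort(lump.memberships.ravel()), [0, 0, 0, 0, 1, 1, 1, 1])
        assert adjusted_rand_score([0, 0, 1, 1], lump.assignment) == 1.0

    def test_planted_thirty_state_partition(self):
        rng = np.random.default_rng(0)
        n = 30
        rates = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    same = i // 10 == j // 10
                    rates[i, j] = rng.uniform(0.5, 1.0) * (1.0 if same else 0.01)
        t = rates / rates.sum(axis=1, keepdims=True)
        t = 0.5 * np.eye(n) + 0.5 * t
        lump = pcca_lump(tpm_of(t), 3)
        assert adjusted_rand_score(np.repeat(np.arange(3), 10), lump.assignment) == 1.0

    def test_identity_lumping(self):
        lump = pcca_lump(tpm_of(T0), 3)
        assert np.allclose(lump.memberships, np.eye(3))

    def test_membership_rows_sum_to_one(self, memory_spec):
        obs, _ = gen_fine_chain(memory_spec, 5, 3000, seed=1)
        tpm = estimate_tpm(obs, 1, reversible=True)
        lump = pcca_lump(tpm, 2)
        assert np.allclose(lump.memberships.sum(axis=1), 1.0, atol=1e-10)
        assert lump.memberships.min() >= 0

    def test_invalid_n_macro(self):
        with pytest.raises(ValueError):
            pcca_lump(tpm_of(T0), 1)
        with pytest.raises(ValueError):
            pcca_lump(tpm_of(T0), 4)


class TestLumpDtrajs:
    def test_hard_assignment_mapping(self):
        dtrajs = DiscreteTrajectorySet([np.array([0, 1, 2, 3])], n_states=4)
        t = np.zeros((4, 4))
        t[:2, :2] = [[0.7, 0.3], [0.4, 0.6]]
        t[2:, 2:] = [[0.8, 0.2], [0.5, 0.5]]
        lump = pcca_lump(tpm_of(t), 2)
        macro = lump_dtrajs(dtrajs, lump)
        labels = macro.trajectories[0]
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]


class TestMacroSeries:
    def test_markov_consistency(self):
        spec = FineChainSpec(3, T0, np.arange(3))
        obs, _ = gen_fine_chain(spec, 20, 5000, seed=2)
        series = macro_tpm_series(obs, tau=1, K=5)
        t1 = series.matrix(1)
        for k in (2, 5):
            assert np.abs(series.matrix(k) - np.linalg.matrix_power(t1, k)).max() < 0.02

    def test_matches_exact_oracle(self, memory_spec):
        obs, _ = gen_fine_chain(memory_spec, 30, 5000, seed=3)
        series = macro_tpm_series(obs, tau=1, K=4)
        oracle = exact_projected_tpms(memory_spec, 4)
        for k in range(1, 5):
            assert np.abs(series.matrix(k) - oracle.matrix(k)).max() < 0.01

    def test_k_equals_one_matches_estimate_tpm(self, memory_spec):
        obs, _ = gen_fine_chain(memory_spec, 5, 1000, seed=4)
        series = macro_tpm_series(obs, tau=2, K=1)
        tpm = estimate_tpm(obs, lag=2)
        assert series.K == 1
        assert np.allclose(series.matrix(1), tpm.matrix)


class TestIgmeLsf:
    def test_memoryless_limit(self):
        series = markov_series(T0, 12)
        model = igme_lsf(series, n0=2, L=6)
        assert model.rmse <= 1e-10
        assert np.abs(model.A - np.eye(3)).max() <= 1e-6
        assert np.abs(model.T_hat - T0).max() <= 1e-6

    def test_operator_pair_recovery(self):
        rng = np.random.default_rng(5)
        a_star = np.eye(4) + 0.03 * rng.standard_normal((4, 4))
        a_star /= a_star.sum(axis=1, keepdims=True)  # keep A.T_hat^n row-stochastic
        t_star = rng.dirichlet(np.ones(4) * 20, size=4)
        mats = [a_star @ np.linalg.matrix_power(t_star, n) for n in range(1, 19)]
        series = TPMSeries(tau=1, matrices=mats)
        model = igme_lsf(series, n0=3, L=8)
        assert model.rmse <= 1e-8
        # in-window and one window-length of forward extrapolation
        for n in range(3, 19):
            assert np.abs(model.predict(n) - series.matrix(n)).max() <= 1e-6

    def test_lumped_fixture_stationary(self, memory_spec):
        series = exact_projected_tpms(memory_spec, 20)
        model = igme_lsf(series, n0=8, L=6)
        pi = model.stationary
        exact = memory_spec.projected_stationary()
        assert np.abs(pi - exact).max() / exact.min() < 0.01

    def test_window_validation(self):
        series = markov_series(T0, 5)
        with pytest.raises(ValueError):
            igme_lsf(series, n0=0, L=3)
        with pytest.raises(ValueError):
            igme_lsf(series, n0=1, L=1)
        with pytest.raises(ValueError):
            igme_lsf(series, n0=4, L=3)


class TestIgmeScan:
    def test_single_point_grid(self):
        series = markov_series(T0, 10)
        ens = igme_scan(series, [(2, 4)], top_fraction=0.05)
        assert len(ens.models) == 1
        assert len(ens.retained) == 1
        assert np.allclose(ens.summary["population_sd"], 0.0)

    def test_markov_series_all_rmse_tiny(self):
        series = markov_series(T0, 12)
        grid = [(n0, L) for n0 in (1, 2, 3) for L in (3, 4)]
        ens = igme_scan(series, grid, top_fraction=0.5)
        assert all(m.rmse < 1e-9 for m in ens.models)
        from encompass.msm import stationary_distribution

        pi = stationary_distribution(T0)
        assert np.abs(ens.summary["population_mean"] - pi).max() < 1e-8

    def test_forty_point_grid_top_five_percent(self, memory_spec):
        series = exact_projected_tpms(memory_spec, 16)
        grid = [(n0, L) for n0 in range(1, 9) for L in range(3, 8)]
        assert len(grid) == 40
        ens = igme_scan(series, grid, top_fraction=0.05)
        assert len(ens.retained) == 2
        worst_kept = max(m.rmse for m in ens.retained)
        best_dropped = min(m.rmse for m in ens.models[2:])
        assert worst_kept <= best_dropped

    def test_grid_order_invariance(self, memory_spec):
        series = exact_projected_tpms(memory_spec, 16)
        grid = [(n0, L) for n0 in range(1, 7) for L in (3, 4, 5)]
        e1 = igme_scan(series, grid, top_fraction=0.2)
        e2 = igme_scan(series, grid[::-1], top_fraction=0.2)
        assert np.allclose(e1.summary["population_mean"], e2.summary["population_mean"])
        assert [m.fit_window for m in e1.retained] == [m.fit_window for m in e2.retained]

    def test_empty_grid(self):
        with pytest.raises(ValueError):
            igme_scan(markov_series(T0, 5), [])


class TestModelKinetics:
    T_HAT = np.array([[0.9, 0.1], [0.2, 0.8]])

    def _model(self):
        series = markov_series(self.T_HAT, 8)
        return igme_lsf(series, n0=1, L=4)

    def test_stationary_two_thirds(self):
        model = self._model()
        assert np.allclose(model.stationary, [2 / 3, 1 / 3], atol=1e-8)

    def test_mfpt_two_state(self):
        kin = model_kinetics(self._model())
        # 2-state chain: MFPT(0->1) = 1/p01 = 10 steps of tau
        assert kin["mfpt"][0, 1] == pytest.approx(10.0, abs=1e-6)
        assert kin["mfpt"][1, 0] == pytest.approx(5.0, abs=1e-6)
        assert kin["mfpt"][0, 0] == 0.0

    def test_symmetric_uniform(self):
        t = np.array([[0.8, 0.2], [0.2, 0.8]])
        model = igme_lsf(markov_series(t, 8), n0=1, L=4)
        assert np.allclose(model.stationary, 0.5, atol=1e-8)

    def test_timescale_closed_form(self):
        model = self._model()
        # lambda_2 = 0.7 -> t = -1/ln(0.7)
        assert model.timescales[0] == pytest.approx(-1 / np.log(0.7), abs=1e-6)


class TestIgmeCk:
    def test_markov_curves_coincide(self):
        series = markov_series(T0, 14)
        model = igme_lsf(series, n0=1, L=5)
        result = igme_ck(model, series)
        for k in result.factors:
            assert result.rmse_igme[k] < 1e-9
            assert result.rmse_msm[k] < 1e-9

    def test_lumped_fixture_igme_beats_msm(self, memory_spec):
        series = exact_projected_tpms(memory_spec, 16)
        model = igme_lsf(series, n0=4, L=5)
        result = igme_ck(model, series)
        assert result.factors == list(range(9, 17))
        for k in result.factors:
            assert result.rmse_igme[k] < result.rmse_msm[k]

    def test_requires_lags_beyond_window(self):
        series = markov_series(T0, 6)
        model = igme_lsf(series, n0=1, L=6)
        with pytest.raises(ValueError):
            igme_ck(model, series)
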