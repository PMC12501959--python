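"""Multivariate-Bernoulli joint occupancy, its marginalized likelihood and
the odds-ratio summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camtrap_cooccur import occupancy_multi as om
from camtrap_cooccur import occupancy_single as osm
from camtrap_cooccur.data_model import DetectionHistory


def _params(beta_vals, gamma_dict, S):
    gamma = np.zeros((S, S))
    for (i, j), v in gamma_dict.items():
        gamma[i, j] = gamma[j, i] = v
    return om.NaturalParams(beta=[np.atleast_1d(np.asarray(b, float)) for b in beta_vals],
                            gamma=gamma)


def _intercept_x(params):
    return [np.concatenate([[1.0], np.zeros(len(b) - 1)]) for b in params.beta]


class TestJointPsi:
    def test_all_zero_params_uniform_over_16_states(self):
        params = _params([0.0] * 4, {}, 4)
        _, probs = om.joint_psi(params, _intercept_x(params))
        assert np.allclose(probs, 1 / 16)

    def test_two_species_enumeration(self):
        params = _params([0.5, -0.3], {(0, 1): 1.0}, 2)
        states, probs = om.joint_psi(params, _intercept_x(params))
        w = np.exp([0.0, 0.5, -0.3, 1.2])
        assert np.allclose(probs, w / w.sum())
        assert np.array_equal(states[3], [1, 1])

    def test_strong_negative_interaction_kills_cooccurrence(self):
        params = _params([0.0, 0.0], {(0, 1): -30.0}, 2)
        states, probs = om.joint_psi(params, _intercept_x(params))
        assert probs[np.all(states == 1, axis=1)][0] < 1e-10

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10 ** 6))
    def test_normalization_property(self, seed):
        rng = np.random.default_rng(seed)
        S = int(rng.integers(2, 5))
        params = _params(
            rng.normal(scale=2, size=S),
            {(i, j): rng.normal(scale=2) for i, j in itertools.combinations(range(S), 2)},
            S,
        )
        _, probs = om.joint_psi(params, _intercept_x(params))
        assert probs.min() >= 0
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_gamma_factorizes(self):
        rng = np.random.default_rng(3)
        f = rng.normal(size=3)
        params = _params(f, {}, 3)
        states, probs = om.joint_psi(params, _intercept_x(params))
        marg = 1 / (1 + np.exp(-f))
        expected = np.prod(np.where(states == 1, marg, 1 - marg), axis=1)
        assert np.allclose(probs, expected, atol=1e-12)


def _random_instance(rng, S=None, n=None, T=None):
    S = S or int(rng.integers(2, 5))
    n = n or int(rng.integers(1, 5))
    T = T or int(rng.integers(1, 4))
    ys = rng.choice([0.0, 1.0, np.nan], size=(S, n, T), p=[0.45, 0.45, 0.1])
    ys[:, :, :] = np.where(np.isnan(ys[0:1]), np.nan, np.nan_to_num(ys))  # shared NA
    designs = [np.column_stack([np.ones(n), rng.normal(size=n)]) for _ in range(S)]
    p_X = np.column_stack([np.ones(T), rng.normal(size=T)])
    k = 2 * S + S * (S - 1) // 2 + 2 * S
    theta = rng.normal(scale=1.2, size=k)
    return theta, ys, designs, p_X


class TestNllMulti:
    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            theta, ys, designs, p_X = _random_instance(rng)
            assert om.nll_multi(theta, ys, designs, p_X) == pytest.approx(
                om.brute_force_nll_multi(theta, ys, designs, p_X), abs=1e-10
            )

    def test_one_species_reduces_to_single_species_likelihood(self):
        # a lone species with no interactions is the classic occupancy model
        rng = np.random.default_rng(1)
        n, T = 6, 3
        y = rng.choice([0.0, 1.0], size=(n, T))
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        p_X = np.column_stack([np.ones(T)])
        th_psi = rng.normal(size=2)
        th_p = rng.normal(size=1)
        single = osm.nll_single(np.r_[th_psi, th_p], y, X, p_X)
        # embed as S=2 with the companion species fixed to an empty history
        ys = np.stack([y, np.zeros_like(y)])
        theta = np.r_[th_psi, -50.0, 0.0, th_p, -50.0]  # companion psi,p ~ 0
        multi = om.nll_multi(theta, ys, [X, np.ones((n, 1))], p_X)
        assert multi == pytest.approx(single, abs=1e-6)

    def test_perfect_detection_limit_concentrates_on_observed_state(self):
        # with p ~ 1 the site likelihood collapses to psi(observed state | x)
        ys = np.array([[[1.0, 1.0]], [[0.0, 0.0]]])  # S=2, 1 site, 2 occasions
        X = np.ones((1, 1))
        p_X = np.ones((2, 1))
        f1, f2, g = 0.4, -0.2, 0.7
        theta = np.array([f1, f2, g, 50.0, 50.0])  # logit p huge
        params = _params([f1, f2], {(0, 1): g}, 2)
        states, probs = om.joint_psi(params, [np.ones(1), np.ones(1)])
        expected = -np.log(probs[np.all(states == [1, 0], axis=1)][0])
        assert om.nll_multi(theta, ys, [X, X], p_X) == pytest.approx(expected, abs=1e-8)

    def test_misaligned_na_patterns_rejected(self):
        ys = np.zeros((2, 2, 2))
        ys[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="misaligned"):
            om.nll_multi(
                np.zeros(2 + 2 + 1 + 2 + 2)[:7], ys,
                [np.ones((2, 1)), np.ones((2, 1))], np.ones((2, 1)),
            )

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(19)
        theta, ys, designs, p_X = _random_instance(rng, S=3, n=4, T=2)
        S = 3
        beta, gamma, beta_p = om.unpack_params(theta, [2] * S, S, 2)
        perm = [2, 0, 1]
        beta_perm = [beta[p] for p in perm]
        gamma_perm = gamma[np.ix_(perm, perm)]
        bp_perm = [beta_p[p] for p in perm]
        theta_perm = om.pack_params(beta_perm, gamma_perm, bp_perm)
        ys_perm = ys[perm]
        designs_perm = [designs[p] for p in perm]
        assert om.nll_multi(theta, ys, designs, p_X) == pytest.approx(
            om.nll_multi(theta_perm, ys_perm, designs_perm, p_X), abs=1e-10
        )


class TestOddsRatios:
    def test_zero_gamma_gives_zero_orsp_in_both_modes(self):
        rng = np.random.default_rng(2)
        params = _params(rng.normal(size=4), {}, 4)
        for mode in ("pairwise", "all_others"):
            for partner in (1, 2, 3):
                assert om.or_sp(params, 0, partner, mode=mode) == pytest.approx(
                    0.0, abs=1e-10
                )

    def test_two_species_pairwise_orsp_equals_interaction_intercept(self):
        params = _params([0.3, -0.8], {(0, 1): -1.7}, 2)
        assert om.or_sp(params, 0, 1) == pytest.approx(-1.7, abs=1e-12)

    def test_four_species_pairwise_matches_independent_enumeration(self):
        rng = np.random.default_rng(8)
        gam = {(i, j): rng.normal() for i, j in itertools.combinations(range(4), 2)}
        params = _params(rng.normal(size=4), gam, 4)
        # independent oracle: loop over all 16 states with plain python
        f = [float(b[0]) for b in params.beta]
        weights = {}
        for z in itertools.product((0, 1), repeat=4):
            e = sum(f[s] * z[s] for s in range(4))
            e += sum(params.gamma[i, j] * z[i] * z[j]
                     for i, j in itertools.combinations(range(4), 2))
            weights[z] = np.exp(e)
        tot = sum(weights.values())

        def odds(focal, partner, v):
            num = sum(w for z, w in weights.items() if z[focal] == 1 and z[partner] == v)
            den = sum(w for z, w in weights.items() if z[focal] == 0 and z[partner] == v)
            return num / den

        expected = np.log(odds(0, 2, 1)) - np.log(odds(0, 2, 0))
        assert om.or_sp(params, 0, 2) == pytest.approx(expected, abs=1e-10)


class TestConditionalOccupancy:
    def test_independence_makes_conditional_equal_marginal(self):
        params = _params([0.4, -0.6], {}, 2)
        x = _intercept_x(params)
        for v in (0, 1):
            assert om.conditional_occupancy(params, 0, 1, v, x) == pytest.approx(
                1 / (1 + np.exp(-0.4)), abs=1e-12
            )

    def test_two_species_closed_form(self):
        f1, f12 = 0.9, -1.3
        params = _params([f1, 0.2], {(0, 1): f12}, 2)
        got = om.conditional_occupancy(params, 0, 1, 1, _intercept_x(params))
        assert got == pytest.approx(1 / (1 + np.exp(-(f1 + f12))), abs=1e-12)

    def test_strong_negative_interaction_direction(self):
        # an interaction intercept of -10.745 must depress focal occupancy
        # in the partner's presence at every covariate value
        for x_val in np.linspace(-2, 2, 9):
            params = _params([[0.5, 0.6], [0.3, -1.9]], {(0, 1): -10.745}, 2)
            x = [np.array([1.0, x_val]), np.array([1.0, x_val])]
            present = om.conditional_occupancy(params, 0, 1, 1, x)
            absent = om.conditional_occupancy(params, 0, 1, 0, x)
            assert present < absent


def _fit_inputs(rng, n=200, T=8):
    """Simulate a 2-species dataset from known natural parameters."""
    true = _params([[0.4, 0.8], [-0.2, -0.6]], {(0, 1): -1.5}, 2)
    x = rng.normal(size=n)
    designs = [np.column_stack([np.ones(n), x])] * 2
    states = om.state_matrix(2)
    z = np.empty((n, 2))
    for i in range(n):
        xi = [np.array([1.0, x[i]])] * 2
        _, probs = om.joint_psi(true, xi)
        z[i] = states[rng.choice(4, p=probs)]
    p = np.array([0.45, 0.35])
    ys = np.stack([
        ((rng.uniform(size=(n, T)) < p[s]) & (z[:, s:s + 1] == 1)).astype(float)
        for s in range(2)
    ])
    return true, ys, designs, x


class TestFitMulti:
    def test_recovers_truth_within_3_se(self):
        rng = np.random.default_rng(21)
        true, ys, designs, x = _fit_inputs(rng)
        hists = {}
        idx = [f"S{i}" for i in range(ys.shape[1])]
        occ = pd.DataFrame({
            "start": pd.date_range("2022-06-01", periods=ys.shape[2], freq="10D"),
            "end": pd.date_range("2022-06-11", periods=ys.shape[2], freq="10D"),
            "n_days": 10.0,
        })
        for s, name in enumerate(["a", "b"]):
            hists[name] = DetectionHistory(
                matrix=pd.DataFrame(ys[s], index=idx,
                                    columns=[f"occ_{t + 1:03d}" for t in range(ys.shape[2])]),
                occasions=occ,
            )
        design = pd.DataFrame({"Ele": x}, index=idx)
        occ_cov = pd.DataFrame(index=range(ys.shape[2]))
        fit = om.fit_multi({"a": ("Ele",), "b": ("Ele",)}, hists, design, occ_cov,
                           p_covariates=(), n_starts=2, seed=0)
        truth_vec = om.pack_params(true.beta, true.gamma,
                                   [np.array([np.log(0.45 / 0.55)]),
                                    np.array([np.log(0.35 / 0.65)])])
        ok = np.abs(fit.params - truth_vec) < 3 * fit.se
        assert ok.mean() >= 0.8
        gamma_hat = fit.natural_params.gamma[0, 1]
        assert gamma_hat < 0  # strong simulated avoidance keeps its sign
        assert fit.summary().shape[0] == fit.K

    def test_importance_table_layout_and_dominant_cell(self):
        rng = np.random.default_rng(4)
        true, ys, designs, x = _fit_inputs(rng)
        params = _params([[0.2, 0.05], [0.1, 0.02]], {(0, 1): -2.5}, 2)
        fit = om.MultiOccFit(
            species=["a", "b"],
            psi_covariates={"a": ("Ele",), "b": ("Ele",)},
            natural_params=params,
            detection={"a": np.zeros(2), "b": np.zeros(2)},
            p_covariates=("Time",),
            params=np.zeros(9), se=np.ones(9), param_names=["x"] * 9,
            logLik=0.0, K=9, n_sites=10, converged=True,
        )
        table = om.importance_table(fit)
        # pairwise ORsp is symmetric for S=2 and dominates the covariate rows
        assert table.loc["b", "a"] == pytest.approx(table.loc["a", "b"], abs=1e-12)
        assert table.loc["b", "a"] == table["a"].max()
        assert np.isnan(table.loc["a", "a"])

    def test_or_h_reduces_to_beta_times_dx(self):
        params = _params([[0.1, 0.595], [0.3, -1.9]], {(0, 1): -3.0}, 2)
        fit = om.MultiOccFit(
            species=["red_deer", "cattle"],
            psi_covariates={"red_deer": ("Ele",), "cattle": ("Ele",)},
            natural_params=params,
            detection={"red_deer": np.zeros(2), "cattle": np.zeros(2)},
            p_covariates=("Time",),
            params=np.zeros(9), se=np.ones(9), param_names=["x"] * 9,
            logLik=0.0, K=9, n_sites=10, converged=True,
        )
        assert om.or_h(fit, "red_deer", "Ele", dx=1.0) == pytest.approx(0.595, abs=1e-9)
        assert om.or_h(fit, "red_deer", "Ele", dx=0.0) == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError, match="not in the"):
            om.or_h(fit, "red_deer", "Slo")

    def test_zero_beta_gives_unit_odds_ratio(self):
        params = _params([[0.1, 0.0], [0.3, 0.0]], {(0, 1): -1.0}, 2)
        fit = om.MultiOccFit(
            species=["a", "b"], psi_covariates={"a": ("Ele",), "b": ("Ele",)},
            natural_params=params,
            detection={"a": np.zeros(2), "b": np.zeros(2)}, p_covariates=("Time",),
            params=np.zeros(9), se=np.ones(9), param_names=["x"] * 9,
            logLik=0.0, K=9, n_sites=10, converged=True,
        )
        assert om.or_h(fit, "a", "Ele") == pytest.approx(0.0, abs=1e-12)
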