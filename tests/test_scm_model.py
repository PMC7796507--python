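"""Likelihood, priors, posterior decomposition and shared-variance fractions."""

import numpy as np
import pandas as pd
import pytest

from jointmap.areal_graph import DistrictGraph
from jointmap.scm_model import (
    ModelSpec,
    ParameterState,
    ProbabilitySurface,
    bernoulli_log_likelihood,
    fraction_explained_state,
    gamma_from_delta,
    linear_predictors,
    log_posterior,
    log_prior,
    recenter_field,
)


@pytest.fixture(scope="module")
def toy():
    graph = DistrictGraph(("A", "B", "C"), ((0, 1), (1, 2)))
    rng = np.random.default_rng(42)
    n = 30
    table = pd.DataFrame(
        {
            "district_id": rng.choice(["A", "B", "C"], n),
            "x1": rng.standard_normal(n),
            "x2": rng.standard_normal(n),
            "y_htn": rng.integers(0, 2, n),
            "y_dm": rng.integers(0, 2, n),
        }
    )
    spec = ModelSpec(shared=True, covariates1=("x1", "x2"), covariates2=("x1",))
    return graph, table, spec


def random_state(rng, J=3, p1=2, p2=1):
    def centered(J):
        z = rng.standard_normal(J)
        return z - z.mean()

    return ParameterState(
        alpha=rng.standard_normal(2),
        beta1=rng.standard_normal(p1),
        beta2=rng.standard_normal(p2),
        u_shared=centered(J), u_spec1=centered(J), u_spec2=centered(J),
        eps1=rng.standard_normal(J), eps2=rng.standard_normal(J),
        log_delta=rng.normal(0, 0.3),
        tau_shared=rng.gamma(2, 1) + 0.1, tau_spec1=rng.gamma(2, 1) + 0.1,
        tau_spec2=rng.gamma(2, 1) + 0.1, tau_eps1=rng.gamma(2, 1) + 0.1,
        tau_eps2=rng.gamma(2, 1) + 0.1,
    )


class TestGamma:
    @pytest.mark.parametrize(
        "ld, g", [(0.0, (1.0, 1.0)), (np.log(2.0), (2.0, 0.5))]
    )
    def test_values(self, ld, g):
        assert gamma_from_delta(ld) == pytest.approx(g)

    def test_product_is_one(self):
        """gamma_2 is constructed as 1/gamma_1, so the product is the
        identity up to one floating-point rounding."""
        for ld in (-3.7, -0.1, 0.9, 12.0):
            g1, g2 = gamma_from_delta(ld)
            assert abs(g1 * g2 - 1.0) <= 1e-15


class TestModelSpecConfig:
    def test_yaml_round_trip(self, tmp_path):
        from jointmap.scm_model import McmcSettings, PriorSpec

        spec = ModelSpec(
            shared=True, covariates1=("age_c", "female"), covariates2=("age_c",),
            priors=PriorSpec(sd_alpha=5.0),
            mcmc=McmcSettings(chains=3, iterations=100, burn_in=50, thin=2),
        )
        p = tmp_path / "run.yaml"
        spec.to_yaml(p)
        assert ModelSpec.from_yaml(p) == spec

    def test_invalid_settings_rejected(self):
        from jointmap.scm_model import McmcSettings, PriorSpec

        with pytest.raises(ValueError):
            McmcSettings(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            PriorSpec(prec_rate=0.0)


class TestLinearPredictors:
    def test_all_zero_gives_half(self, toy):
        graph, table, spec = toy
        state = ParameterState.zeros(3, 2, 1)
        probs = linear_predictors(state, table, graph, spec)
        assert np.allclose(probs.pi, 0.5)

    def test_intercept_only_inverse_logit(self, toy):
        graph, table, spec = toy
        state = ParameterState.zeros(3, 2, 1)
        state.alpha = np.array([np.log(0.25 / 0.75), 0.0])
        probs = linear_predictors(state, table, graph, spec)
        assert np.allclose(probs.pi[:, 0], 0.25)

    def test_matches_naive_per_person_loop(self, toy):
        graph, table, spec = toy
        rng = np.random.default_rng(1)
        state = random_state(rng)
        probs = linear_predictors(state, table, graph, spec)
        g1, g2 = state.gammas
        for i, row in table.iterrows():
            j = graph.index_of(row["district_id"])
            eta1 = (
                state.alpha[0]
                + state.beta1[0] * row["x1"] + state.beta1[1] * row["x2"]
                + g1 * state.u_shared[j] + state.u_spec1[j] + state.eps1[j]
            )
            eta2 = (
                state.alpha[1] + state.beta2[0] * row["x1"]
                + g2 * state.u_shared[j] + state.u_spec2[j] + state.eps2[j]
            )
            assert probs.eta[i, 0] == pytest.approx(eta1, abs=1e-12)
            assert probs.eta[i, 1] == pytest.approx(eta2, abs=1e-12)

    def test_unknown_district_rejected(self, toy):
        graph, table, spec = toy
        bad = table.copy()
        bad.loc[0, "district_id"] = "ZZ"
        with pytest.raises(KeyError):
            linear_predictors(ParameterState.zeros(3, 2, 1), bad, graph, spec)

    def test_affine_in_parameter_blocks(self, toy):
        """eta is affine in each block: finite differences are direction-exact."""
        graph, table, spec = toy
        rng = np.random.default_rng(2)
        state = random_state(rng)
        base = linear_predictors(state, table, graph, spec).eta
        state2 = random_state(rng)
        state2.__dict__.update(
            {k: v for k, v in state.__dict__.items() if k != "beta1"}
        )
        mid_b = 0.5 * (state.beta1 + state2.beta1)
        import copy

        sm = copy.deepcopy(state)
        sm.beta1 = mid_b
        s2 = copy.deepcopy(state)
        s2.beta1 = state2.beta1
        eta2 = linear_predictors(s2, table, graph, spec).eta
        etam = linear_predictors(sm, table, graph, spec).eta
        assert np.allclose(etam, 0.5 * (base + eta2), atol=1e-12)


class TestLikelihood:
    def test_single_person_closed_form(self):
        table = pd.DataFrame({"y_htn": [1], "y_dm": [1]})
        probs = ProbabilitySurface(eta=np.zeros((1, 2)))
        assert bernoulli_log_likelihood(probs, table) == pytest.approx(
            2 * np.log(0.5)
        )

    def test_extreme_eta_stable(self):
        table = pd.DataFrame({"y_htn": [1], "y_dm": [0]})
        probs = ProbabilitySurface(eta=np.array([[50.0, -50.0]]))
        ll = bernoulli_log_likelihood(probs, table)
        assert np.isfinite(ll)
        assert ll == pytest.approx(0.0, abs=1e-15)

    def test_matches_high_precision_oracle(self):
        from mpmath import mp, mpf, log, exp

        mp.dps = 50
        rng = np.random.default_rng(8)
        eta = rng.normal(0, 3, size=(50, 2))
        y = rng.integers(0, 2, size=(50, 2))
        table = pd.DataFrame({"y_htn": y[:, 0], "y_dm": y[:, 1]})
        expected = mpf(0)
        for i in range(50):
            for k in range(2):
                p = 1 / (1 + exp(-mpf(eta[i, k])))
                expected += y[i, k] * log(p) + (1 - y[i, k]) * log(1 - p)
        got = bernoulli_log_likelihood(ProbabilitySurface(eta=eta), table)
        assert got == pytest.approx(float(expected), abs=1e-10)


class TestPriorAndPosterior:
    def test_eps_shift_changes_only_eps_term(self, toy):
        graph, _, spec = toy
        rng = np.random.default_rng(3)
        state = random_state(rng)
        import copy

        shifted = copy.deepcopy(state)
        c = 0.37
        shifted.eps1 = state.eps1 + c
        diff = log_prior(shifted, graph, spec) - log_prior(state, graph, spec)
        expected = -0.5 * state.tau_eps1 * (
            np.sum((state.eps1 + c) ** 2) - np.sum(state.eps1**2)
        )
        assert diff == pytest.approx(expected, abs=1e-10)

    def test_no_shared_variant_drops_shared_terms(self, toy):
        graph, _, spec = toy
        rng = np.random.default_rng(4)
        state = random_state(rng)
        state.u_shared = np.zeros(3)
        with_shared = log_prior(state, graph, spec)
        reduced = log_prior(state, graph, spec.without_shared())
        # difference = shared ICAR at zero field + gamma prior + log_delta prior
        from jointmap.areal_graph import icar_log_density
        from jointmap.scm_model import _gamma_logpdf, _normal_logpdf_sum

        expected = (
            icar_log_density(np.zeros(3), state.tau_shared, graph)
            + _gamma_logpdf(state.tau_shared, spec.priors.prec_shape, spec.priors.prec_rate)
            + _normal_logpdf_sum(np.array([state.log_delta]), spec.priors.sd_log_delta)
        )
        assert with_shared - reduced == pytest.approx(expected, abs=1e-10)

    def test_posterior_is_likelihood_plus_prior(self, toy):
        graph, table, spec = toy
        rng = np.random.default_rng(5)
        state = random_state(rng)
        lp = log_posterior(state, table, graph, spec)
        probs = linear_predictors(state, table, graph, spec)
        assert lp == pytest.approx(
            bernoulli_log_likelihood(probs, table) + log_prior(state, graph, spec),
            abs=1e-12,
        )

    def test_improving_fit_raises_posterior(self, toy):
        graph, table, spec = toy
        state = ParameterState.zeros(3, 2, 1)
        base = log_posterior(state, table, graph, spec)
        import copy

        better = copy.deepcopy(state)
        # nudge intercepts toward the empirical prevalences
        better.alpha = np.array(
            [
                0.5 * np.log(table.y_htn.mean() / (1 - table.y_htn.mean())),
                0.5 * np.log(table.y_dm.mean() / (1 - table.y_dm.mean())),
            ]
        )
        assert log_posterior(better, table, graph, spec) > base

    def test_recentering_preserves_likelihood_exactly(self, toy):
        graph, table, spec = toy
        rng = np.random.default_rng(6)
        state = random_state(rng)
        state.u_shared = state.u_shared + 0.8  # off-centre on purpose
        probs0 = linear_predictors(state, table, graph, spec)
        recentred = recenter_field(state, "u_shared", graph)
        probs1 = linear_predictors(recentred, table, graph, spec)
        assert np.allclose(probs0.eta, probs1.eta, atol=1e-12)
        assert abs(recentred.u_shared.sum()) < 1e-10


class TestFractionExplained:
    def test_pure_shared_gives_one(self):
        state = ParameterState.zeros(3, 0, 0)
        state.u_shared = np.array([1.0, -1.0, 0.0])
        f1, f2 = fraction_explained_state(state)
        assert f1 == pytest.approx(1.0) and f2 == pytest.approx(1.0)

    def test_no_shared_gives_zero(self):
        state = ParameterState.zeros(3, 0, 0)
        state.u_spec1 = np.array([1.0, -1.0, 0.0])
        state.eps1 = np.array([0.2, -0.1, -0.1])
        f1, _ = fraction_explained_state(state)
        assert f1 == 0.0

    def test_hand_variance_arithmetic(self):
        state = ParameterState.zeros(3, 0, 0)
        state.u_shared = np.array([1.0, -1.0, 0.0])
        state.u_spec1 = np.array([1.0, -1.0, 0.0])
        f1, _ = fraction_explained_state(state)
        assert f1 == pytest.approx(np.var([1, -1, 0]) / np.var([2, -2, 0]))
        assert f1 == pytest.approx(0.25)

    def test_scale_confounding_invariance(self):
        """Multiplying U by c and dividing gamma by c leaves the fraction
        unchanged — the identifiability constraint exists for this reason."""
        rng = np.random.default_rng(7)
        state = ParameterState.zeros(5, 0, 0)
        z = rng.standard_normal(5)
        state.u_shared = z - z.mean()
        state.u_spec1 = rng.standard_normal(5) * 0.3
        state.log_delta = 0.4
        f_base = fraction_explained_state(state)[0]
        c = 2.5
        import copy

        scaled = copy.deepcopy(state)
        scaled.u_shared = state.u_shared * c
        scaled.log_delta = state.log_delta - np.log(c)
        assert fraction_explained_state(scaled)[0] == pytest.approx(f_base, abs=1e-12)
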