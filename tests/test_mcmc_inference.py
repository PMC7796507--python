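"""Sampler correctness, conjugate updates, DIC and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from jointmap.areal_graph import DistrictGraph, build_lattice_graph
from jointmap.mcmc_inference import (
    PosteriorSamples,
    compute_dic,
    deviance,
    diagnostics,
    load_samples,
    run_chain,
    save_samples,
    summarize_fit,
    update_precision_gibbs,
)
from jointmap.scm_model import McmcSettings, ModelSpec, ProbabilitySurface
from jointmap.synthetic_data import simulate_cohort


def _fast_mcmc(**kw):
    defaults = dict(chains=2, iterations=800, burn_in=400, thin=4)
    defaults.update(kw)
    return McmcSettings(**defaults)


@pytest.fixture(scope="module")
def small_fit():
    table, truth, graph, spec = simulate_cohort(
        "sage-like", seed=77, graph=build_lattice_graph(3, 4), n_total=700
    )
    spec = ModelSpec(
        shared=True, covariates1=spec.covariates1, covariates2=spec.covariates2,
        mcmc=_fast_mcmc(),
    )
    samples = run_chain(spec, table, graph, seed=5)
    return table, graph, spec, samples


class TestRunChain:
    def test_same_seed_bitwise_identical(self, small_fit):
        table, graph, spec, samples = small_fit
        again = run_chain(spec, table, graph, seed=5)
        for name, arr in samples.blocks.items():
            assert np.array_equal(arr, again.blocks[name]), name

    def test_draw_count_and_shapes(self, small_fit):
        table, graph, spec, samples = small_fit
        assert samples.n_chains == 2
        assert samples.n_draws == spec.mcmc.n_draws == 100
        assert samples.blocks["u_shared"].shape == (2, 100, graph.n_districts)
        assert samples.blocks["beta1"].shape == (2, 100, 3)

    def test_stored_states_satisfy_invariants(self, small_fit):
        table, graph, spec, samples = small_fit
        st = samples.state_at(0, 50)
        st.validate(graph, tol=1e-8)
        g1, g2 = st.gammas
        assert abs(g1 * g2 - 1.0) <= 1e-15

    def test_intercept_posterior_near_empirical_logit(self):
        """Balanced outcome, no covariates or strong fields: alpha_1
        posterior mean should sit near logit(0.5) = 0."""
        rng = np.random.default_rng(0)
        n = 400
        graph = DistrictGraph(("A", "B"), ((0, 1),))
        table = pd.DataFrame(
            {
                "district_id": rng.choice(["A", "B"], n),
                "y_htn": rng.integers(0, 2, n),
                "y_dm": rng.integers(0, 2, n),
            }
        )
        spec = ModelSpec(
            shared=True, covariates1=(), covariates2=(),
            mcmc=McmcSettings(chains=2, iterations=5000, burn_in=2500, thin=5),
        )
        samples = run_chain(spec, table, graph, seed=1)
        a1 = samples.flat("alpha")[:, 0]
        emp = np.log(table.y_htn.mean() / (1 - table.y_htn.mean()))
        assert abs(a1.mean() - emp) < 0.15

    def test_acceptance_rates_healthy(self, small_fit):
        _, _, _, samples = small_fit
        rates = samples.acceptance.to_numpy()
        assert np.all(rates > 0.1) and np.all(rates < 0.75)

    def test_no_shared_blocks_absent_in_reduced_model(self, small_fit):
        table, graph, spec, _ = small_fit
        reduced = spec.without_shared()
        samples = run_chain(reduced, table, graph, seed=2)
        assert "u_shared" not in samples.blocks
        assert "log_delta" not in samples.blocks
        assert "tau_shared" not in samples.blocks

    def test_disconnected_graph_rejected(self, small_fit):
        table, _, spec, _ = small_fit
        bad = DistrictGraph(("A", "B", "C", "D"), ((0, 1), (2, 3)))
        with pytest.raises(ValueError, match="connected"):
            run_chain(spec, table.head(10), bad, seed=0)


class TestPrecisionGibbs:
    def test_zero_field_draws_from_prior(self, path3):
        rng = np.random.default_rng(0)
        draws = [
            update_precision_gibbs(np.zeros(3), "icar", 0.5, 0.0005, rng, path3)
            for _ in range(20_000)
        ]
        # Gamma(0.5 + (J-C)/2, 0.0005) = Gamma(1.5, 0.0005)
        assert np.mean(draws) == pytest.approx(1.5 / 0.0005, rel=0.03)

    def test_fixed_field_matches_closed_form_moments(self, path3):
        rng = np.random.default_rng(1)
        u = np.array([1.0, -1.0, 0.0])  # penalty 5 -> rate 0.0005 + 2.5
        draws = np.array(
            [
                update_precision_gibbs(u, "icar", 0.5, 0.0005, rng, path3)
                for _ in range(20_000)
            ]
        )
        a, b = 1.5, 2.5005
        assert draws.mean() == pytest.approx(a / b, rel=0.03)
        assert draws.var() == pytest.approx(a / b**2, rel=0.03)

    def test_iid_structure_uses_sum_of_squares(self):
        rng = np.random.default_rng(2)
        e = np.array([2.0, 0.0, -1.0, 1.0])
        draws = np.array(
            [update_precision_gibbs(e, "iid", 1.0, 1.0, rng) for _ in range(20_000)]
        )
        a, b = 1.0 + 2.0, 1.0 + 3.0
        assert draws.mean() == pytest.approx(a / b, rel=0.03)

    def test_larger_penalty_gives_smaller_precision(self, path3):
        rng = np.random.default_rng(3)
        small = np.array([0.1, -0.1, 0.0])
        large = np.array([2.0, -2.0, 0.0])
        d_small = [
            update_precision_gibbs(small, "icar", 0.5, 0.0005, rng, path3)
            for _ in range(500)
        ]
        d_large = [
            update_precision_gibbs(large, "icar", 0.5, 0.0005, rng, path3)
            for _ in range(500)
        ]
        from scipy.stats import mannwhitneyu

        assert mannwhitneyu(d_large, d_small, alternative="less").pvalue < 1e-6


class TestDeviance:
    def test_closed_form_at_half(self):
        table = pd.DataFrame({"y_htn": np.zeros(10), "y_dm": np.ones(10)})
        probs = ProbabilitySurface(eta=np.zeros((10, 2)))
        assert deviance(probs, table) == pytest.approx(-2 * 20 * np.log(0.5))

    def test_perfect_fit_approaches_zero(self):
        table = pd.DataFrame({"y_htn": [1, 0], "y_dm": [0, 1]})
        probs = ProbabilitySurface(
            eta=np.array([[30.0, -30.0], [-30.0, 30.0]])
        )
        d = deviance(probs, table)
        assert 0 < d < 1e-10


class TestDIC:
    def test_identity_and_degenerate_draws(self, small_fit):
        table, graph, spec, samples = small_fit
        dic = compute_dic(samples, table, graph)
        assert dic.dic == pytest.approx(dic.dbar + dic.pd)
        assert np.isfinite(dic.pd) and dic.pd > 0

        # collapse every draw (all chains) to one state: pD must vanish
        frozen = {
            k: np.tile(v[:1, :1, ...], (v.shape[0], v.shape[1]) + (1,) * (v.ndim - 2))
            for k, v in samples.blocks.items()
        }
        degen = PosteriorSamples(
            blocks=frozen, acceptance=samples.acceptance, spec=spec,
            seed=0, district_ids=samples.district_ids,
        )
        dic0 = compute_dic(degen, table, graph)
        assert dic0.pd == pytest.approx(0.0, abs=1e-8)
        assert dic0.dic == pytest.approx(dic0.dbar)

    def test_too_few_draws_rejected(self, small_fit):
        table, graph, spec, samples = small_fit
        few = PosteriorSamples(
            blocks={k: v[:, :10, ...] for k, v in samples.blocks.items()},
            acceptance=samples.acceptance, spec=spec, seed=0,
            district_ids=samples.district_ids,
        )
        with pytest.raises(ValueError):
            compute_dic(few, table, graph)


class TestDiagnostics:
    def _wrap(self, arr_dict, shared=False):
        spec = ModelSpec(shared=shared)
        return PosteriorSamples(
            blocks=arr_dict, acceptance=pd.DataFrame(), spec=spec, seed=0,
            district_ids=("A", "B"),
        )

    def test_identical_iid_chains_rhat_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        samples = self._wrap({"alpha": np.stack([x, x])})
        d = diagnostics(samples)
        assert d.loc["alpha", "rhat"] == pytest.approx(1.0, abs=0.01)

    def test_offset_chains_flagged(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(1000)
        samples = self._wrap({"alpha": np.stack([x, x + 10.0])})
        assert diagnostics(samples).loc["alpha", "rhat"] > 1.1

    def test_ar1_ess_closed_form(self):
        rho = 0.9
        rng = np.random.default_rng(2)
        n = 20_000
        x = np.empty((2, n))
        for c in range(2):
            z = rng.standard_normal(n)
            x[c, 0] = z[0]
            for t in range(1, n):
                x[c, t] = rho * x[c, t - 1] + np.sqrt(1 - rho**2) * z[t]
        samples = self._wrap({"alpha": x})
        ess = diagnostics(samples).loc["alpha", "ess"]
        expected = 2 * n * (1 - rho) / (1 + rho)
        assert ess == pytest.approx(expected, rel=0.30)

    def test_single_chain_rhat_unavailable(self):
        rng = np.random.default_rng(3)
        samples = self._wrap({"alpha": rng.standard_normal((1, 500))})
        assert np.isnan(diagnostics(samples).loc["alpha", "rhat"])


class TestSummaries:
    def test_constant_beta_draws_give_exact_aor(self):
        draws = np.full((2, 60, 1), np.log(2.0))
        spec = ModelSpec(shared=False, covariates1=("x",), covariates2=())
        samples = PosteriorSamples(
            blocks={
                "alpha": np.zeros((2, 60, 2)), "beta1": draws,
                "beta2": np.zeros((2, 60, 0)),
                "u_spec1": np.zeros((2, 60, 2)), "u_spec2": np.zeros((2, 60, 2)),
                "eps1": np.zeros((2, 60, 2)), "eps2": np.zeros((2, 60, 2)),
                "tau_spec1": np.ones((2, 60)), "tau_spec2": np.ones((2, 60)),
                "tau_eps1": np.ones((2, 60)), "tau_eps2": np.ones((2, 60)),
            },
            acceptance=pd.DataFrame(), spec=spec, seed=0, district_ids=("A", "B"),
        )
        fit = summarize_fit(samples, DistrictGraph(("A", "B"), ((0, 1),)))
        row = fit.coefficients.loc[("disease1", "x")]
        assert row["aOR"] == pytest.approx(2.0)
        assert row["lower"] == pytest.approx(2.0)
        assert row["upper"] == pytest.approx(2.0)
        # zero fields -> district odds exactly 1
        assert np.allclose(fit.districts.filter(like="odds").to_numpy(), 1.0)

    def test_interval_ordering(self, small_fit):
        table, graph, spec, samples = small_fit
        fit = summarize_fit(samples, graph)
        c = fit.coefficients
        assert (c["lower"] <= c["aOR"]).all() and (c["aOR"] <= c["upper"]).all()

    def test_save_load_round_trip(self, small_fit, tmp_path):
        _, _, _, samples = small_fit
        save_samples(samples, tmp_path / "s")
        back = load_samples(tmp_path / "s")
        assert back.n_draws == samples.n_draws
        for k in samples.blocks:
            assert np.allclose(back.blocks[k].reshape(samples.blocks[k].shape),
                               samples.blocks[k], atol=1e-12), k
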