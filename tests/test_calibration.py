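"""Posterior assembly, gradients, sampling and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from jab.calibration import (FitConfig, _logp_and_grad, build_model_data,
                             log_posterior, rhat_diagnostics, sample_posterior,
                             summarize_posterior)
from jab.core import PARAM_NAMES
from jab.datasets import posterior_mean_params
from jab.observation import nb_log_likelihood
from jab.priors import default_prior_table
from jab.synth import SynthConfig, generate_synthetic_dataset
from scipy.special import gammaln
from scipy.stats import norm


@pytest.fixture(scope="module")
def small_model():
    params, consts = posterior_mean_params()
    ds = generate_synthetic_dataset(SynthConfig(n_plots=6, seed=1))
    priors = default_prior_table()
    md = build_model_data(ds, priors, consts)
    return ds, priors, md, params, consts


def _theta_near_mode(md, rng, jitter=0.05):
    mode = np.where(md.gamma_alpha > 1, (md.gamma_alpha - 1) / md.gamma_beta,
                    0.5 / md.gamma_beta)
    base = np.concatenate([md.prior_mu.reshape(-1), np.full(len(md.phi_levels), 1.0),
                           np.log(np.maximum(mode, 1e-8)).reshape(-1)])
    return base + jitter * rng.standard_normal(base.size)


class TestLogPosterior:
    def test_gradient_matches_finite_differences(self, small_model):
        _, _, md, _, _ = small_model
        rng = np.random.default_rng(0)
        theta = _theta_near_mode(md, rng)[None, :]
        lp, grad = _logp_and_grad(theta, md)
        assert np.isfinite(lp[0])
        eps = 1e-6
        idx = np.concatenate([np.arange(32), rng.integers(32, md.dim, 20)])
        for i in idx:
            tp, tm = theta.copy(), theta.copy()
            tp[0, i] += eps
            tm[0, i] -= eps
            fd = (_logp_and_grad(tp, md)[0][0] - _logp_and_grad(tm, md)[0][0]) / (2 * eps)
            assert grad[0, i] == pytest.approx(fd, rel=2e-4, abs=1e-5)

    def test_scalar_oracle_on_two_plot_model(self, small_model):
        """Independent recomputation of priors + likelihood for a point."""
        ds, priors, md, params, consts = small_model
        rng = np.random.default_rng(1)
        log_par = {n: params.log(n) + rng.normal(0, 0.05, 2) for n in PARAM_NAMES}
        phis = {k: float(rng.uniform(0.5, 3.0)) for k in md.phi_levels}
        x0 = np.exp(np.log(np.maximum(
            np.where(md.gamma_alpha > 1, (md.gamma_alpha - 1) / md.gamma_beta,
                     0.5 / md.gamma_beta), 1e-8)) + rng.normal(0, 0.05, md.gamma_alpha.shape))

        value = log_posterior(log_par, x0, phis, ds, priors, consts)

        # oracle: scalar loops over every term
        from jab.core import PlotForcing, SpeciesParams, StageState, simulate

        expected = 0.0
        for i, name in enumerate(PARAM_NAMES):
            for j, sp in enumerate(md.species):
                mu, sd = priors.get(name, sp)
                expected += norm.logpdf(log_par[name][j], mu, sd)
        for k in md.phi_levels:
            u = np.log(phis[k])
            expected += 0.5 * np.log(2 / np.pi) - 0.5 * np.exp(-2 * u) - u
        for p in range(md.n_plots):
            for j in range(md.n_species):
                for s in range(3):
                    a, b = md.gamma_alpha[p, j, s], md.gamma_beta[p, j, s]
                    z = np.log(x0[p, j, s])
                    expected += a * z - b * x0[p, j, s] + a * np.log(b) - gammaln(a)
        sp_params = SpeciesParams(md.species, log_par)
        for p in range(md.n_plots):
            forcing = PlotForcing.from_l(sp_params.l, md.B_p[p])
            st0 = StageState.from_stages(x0[p, :, 0], x0[p, :, 1], x0[p, :, 2], consts)
            traj = simulate(st0, sp_params, forcing, consts, max(md.survey_years))
            for r, year in enumerate(md.survey_years):
                st = traj[year]
                for k, stage in enumerate(("J", "A", "B")):
                    state_val = getattr(st, stage)
                    for j in range(md.n_species):
                        expected += nb_log_likelihood(
                            int(md.counts[r, k, p, j]),
                            md.offsets[r, k, p, j] * state_val[j],
                            phis[md.phi_levels[md.phi_index[r, k, j]]])
        assert value == pytest.approx(expected, rel=1e-10)

    def test_species_permutation_symmetry(self, small_model):
        ds, priors, md, params, consts = small_model
        rng = np.random.default_rng(2)
        theta = _theta_near_mode(md, rng)[None, :]
        lp, _ = _logp_and_grad(theta, md)

        # permute species everywhere: data, priors and parameter vector
        ds2 = type(ds)(obs=ds.obs.copy(), species=ds.species[::-1],
                       survey_years=ds.survey_years)
        pri2 = default_prior_table(priors.species[::-1])
        from jab.core import Constants

        consts2 = Constants(beta_uA=consts.beta_uA, beta_mA=consts.beta_mA[::-1],
                            dbh_JA_cm=consts.dbh_JA_cm, dbh_AB_cm=consts.dbh_AB_cm)
        md2 = build_model_data(ds2, pri2, consts2)
        k1 = 9 * 2
        lpdim = theta[0, :k1].reshape(9, 2)
        phi_part = np.array([theta[0, k1 + md.phi_levels.index(lev)]
                             for lev in md2.phi_levels])
        z_part = theta[0, k1 + 14:].reshape(md.n_plots, 2, 3)[:, ::-1, :]
        theta2 = np.concatenate([lpdim[:, ::-1].reshape(-1), phi_part,
                                 z_part.reshape(-1)])[None, :]
        lp2, _ = _logp_and_grad(theta2, md2)
        assert lp2[0] == pytest.approx(lp[0], rel=1e-12)


class TestSampling:
    def test_seeded_determinism(self):
        ds = generate_synthetic_dataset(SynthConfig(n_plots=4, seed=9))
        priors = default_prior_table()
        cfg = FitConfig(chains=2, warmup=40, sampling=30, seed=5)
        d1, _ = sample_posterior(ds, priors, cfg)
        d2, _ = sample_posterior(ds, priors, cfg)
        np.testing.assert_array_equal(d1.log_params, d2.log_params)
        np.testing.assert_array_equal(d1.init_states, d2.init_states)

    def test_small_fit_runs_and_reports(self):
        ds = generate_synthetic_dataset(SynthConfig(n_plots=8, seed=11))
        priors = default_prior_table()
        cfg = FitConfig(chains=2, warmup=150, sampling=100, seed=3)
        draws, report = sample_posterior(ds, priors, cfg)
        assert draws.log_params.shape == (2, 100, 9, 2)
        assert np.all(np.isfinite(draws.log_params))
        assert np.all(draws.init_states > 0)
        assert {"rhat", "ess_bulk"} <= set(report.table.columns)

    def test_information_gain_with_more_plots(self):
        """4x more plots should not widen the posterior of log g and log s."""
        priors = default_prior_table()
        sds = {}
        for n in (10, 40):
            ds = generate_synthetic_dataset(SynthConfig(n_plots=n, seed=21))
            cfg = FitConfig(chains=2, warmup=250, sampling=250, seed=13)
            draws, _ = sample_posterior(ds, priors, cfg)
            flat = draws.flat_log_params()
            i_g = PARAM_NAMES.index("g")
            i_s = PARAM_NAMES.index("s")
            sds[n] = np.array([flat[:, i_g, :].std(0), flat[:, i_s, :].std(0)])
        assert np.all(sds[40] <= sds[10] * 1.25)


class TestDiagnostics:
    def test_well_mixed_chains(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal((4, 1000, 3))
        rep = rhat_diagnostics(draws)
        assert rep.max_rhat < 1.01
        assert rep.converged

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(1)
        draws = rng.standard_normal((4, 500, 1)) + np.arange(4).reshape(4, 1, 1)
        rep = rhat_diagnostics(draws)
        assert rep.max_rhat > 1.05
        assert not rep.converged

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="chains"):
            rhat_diagnostics(np.zeros((1, 100, 2)))

    def test_split_rhat_matches_textbook_formula(self):
        # independent oracle: split chains in half, then
        # R-hat = sqrt(((n-1)/n * W + B/n) / W)
        rng = np.random.default_rng(7)
        x = rng.standard_normal((4, 400)) + 0.3 * np.arange(4)[:, None]
        rep = rhat_diagnostics(x[:, :, None], method="split")
        halves = x.reshape(8, 200)
        n = 200
        means = halves.mean(1)
        W = halves.var(1, ddof=1).mean()
        B = n * means.var(ddof=1)
        expected = np.sqrt(((n - 1) / n * W + B / n) / W)
        assert rep.table["rhat"].iloc[0] == pytest.approx(expected, abs=1e-6)


class TestSummary:
    @pytest.fixture(scope="class")
    def fitted(self):
        ds = generate_synthetic_dataset(SynthConfig(n_plots=5, seed=30))
        cfg = FitConfig(chains=2, warmup=100, sampling=60, seed=17)
        draws, _ = sample_posterior(ds, default_prior_table(), cfg)
        return draws

    def test_mean_sd_match_brute_force(self, fitted):
        summary = summarize_posterior(fitted, max_eq_draws=4, seed=0)
        flat = fitted.flat_log_params()
        for i, name in enumerate(PARAM_NAMES):
            for j, sp in enumerate(fitted.species):
                row = summary[summary["quantity"] == f"log_{name}[{sp}]"].iloc[0]
                assert row["mean"] == pytest.approx(flat[:, i, j].mean(), rel=1e-12)
                assert row["sd"] == pytest.approx(flat[:, i, j].std(ddof=1), rel=1e-12)

    def test_constant_draws_have_zero_sd(self, fitted):
        const = type(fitted)(
            species=fitted.species,
            log_params=fitted.log_params.copy(),
            log_phi=fitted.log_phi.copy(),
            init_states=fitted.init_states.copy(),
            phi_levels=fitted.phi_levels, B_p=fitted.B_p, consts=fitted.consts)
        const.log_params[:] = const.log_params[0, 0]
        const.log_phi[:] = const.log_phi[0, 0]
        const.init_states[:] = const.init_states[0, 0]
        summary = summarize_posterior(const, max_eq_draws=2, seed=0)
        rows = summary[summary["quantity"].str.startswith(("log_", "phi["))
                       & ~summary["quantity"].str.contains("_dd_")]
        assert (rows["sd"].abs() < 1e-12).all()

    def test_predominance_fractions_are_proportions(self, fitted):
        summary = summarize_posterior(fitted, max_eq_draws=4, seed=0)
        fr = summary[summary["quantity"].str.startswith("predominance_")]["mean"]
        assert ((fr >= 0) & (fr <= 1)).all()
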