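"""Bayesian calibration: the joint posterior over demographic rates, latent
initial states and dispersion levels, sampled with Hamiltonian Monte Carlo.

The model: nine demographic rates per species, sampled globally on the log
scale with normal priors; one latent positive initial state per plot ×
species × stage, with gamma priors moded at the first-survey observation;
one negative-binomial dispersion φ per stage/species/survey group, with
half-normal(1) priors on 1/φ.  First-survey count expectations are the latent
states scaled by their offsets; later surveys are obtained by simulating each
plot forward deterministically with the stage map and the plot's seedling
input L_p = l·B_p.  Everything is sampled on an unconstrained scale (logs,
with the gamma/half-normal Jacobians included); the gradient of the log
posterior is propagated through the inter-survey simulation by the exact
adjoint of the yearly map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

from . import _batch
from ._hmc import sample_hmc
from .core import PARAM_NAMES, Constants, SpeciesParams, StageState, dd_rates
from .data_io import Dataset
from .equilibrium import find_equilibrium, predominant_species
from .observation import STAGES, dispersion_levels, initial_state_prior, phi_group
from .priors import NormalPriorTable

__all__ = [
    "FitConfig",
    "ModelData",
    "PosteriorDraws",
    "DiagnosticsReport",
    "build_model_data",
    "log_posterior",
    "sample_posterior",
    "rhat_diagnostics",
    "summarize_posterior",
]

_HALF_LOG_2_OVER_PI = 0.5 * np.log(2.0 / np.pi)
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class FitConfig:
    """Sampler configuration (defaults: 4 chains, 1000 warmup + 1000 draws)."""

    chains: int = 4
    warmup: int = 1000
    sampling: int = 1000
    seed: int = 0
    rhat_threshold: float = 1.05
    target_accept: float = 0.8
    max_leapfrog: int = 32
    survey_years: tuple[int, ...] | None = None  # default: taken from the data

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("at least 2 chains required")
        if self.warmup < 1 or self.sampling < 1:
            raise ValueError("iterations must be >= 1")
        if self.rhat_threshold <= 1:
            raise ValueError("rhat_threshold must exceed 1")


@dataclass
class ModelData:
    """Dense arrays extracted from a :class:`~jab.data_io.Dataset`.

    Shapes: counts/offsets (n_surveys, 3 stages, n_plots, n_species);
    ``phi_index`` maps each (survey, stage, species) cell into ``phi_levels``;
    gamma prior (alpha, beta) per latent initial state (n_plots, n_species, 3).
    """

    species: tuple[str, ...]
    plot_ids: list
    survey_years: tuple[int, ...]
    counts: np.ndarray
    offsets: np.ndarray
    B_p: np.ndarray
    phi_levels: list[tuple]
    phi_index: np.ndarray
    gamma_alpha: np.ndarray
    gamma_beta: np.ndarray
    consts: Constants
    prior_mu: np.ndarray   # (9, n_species) in PARAM_NAMES order
    prior_sd: np.ndarray

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def dim(self) -> int:
        return 9 * self.n_species + len(self.phi_levels) + self.n_plots * self.n_species * 3


def build_model_data(dataset: Dataset, priors: NormalPriorTable,
                     consts: Constants) -> ModelData:
    """Assemble the dense model arrays and the latent-state gamma priors."""
    obs = dataset.obs
    species = tuple(priors.species)
    if set(species) != set(dataset.species):
        raise ValueError("prior table and dataset disagree on species labels")
    plot_ids = dataset.plot_ids
    years = dataset.survey_years
    n_sv, n_p, n_s = len(years), len(plot_ids), len(species)

    pidx = {p: i for i, p in enumerate(plot_ids)}
    sidx = {s: j for j, s in enumerate(species)}
    stidx = {s: k for k, s in enumerate(STAGES)}

    counts = np.full((n_sv, 3, n_p, n_s), np.nan)
    offsets = np.full((n_sv, 3, n_p, n_s), np.nan)
    B_p = np.full((n_p, n_s), np.nan)
    for row in obs.itertuples(index=False):
        r, k = row.survey - 1, stidx[row.stage]
        i, j = pidx[row.plot_id], sidx[row.species]
        counts[r, k, i, j] = row.count
        offsets[r, k, i, j] = row.offset
        B_p[i, j] = row.B_p
    for name, arr in (("count", counts), ("offset", offsets), ("B_p", B_p)):
        if np.any(np.isnan(arr)):
            raise ValueError(
                f"incomplete dataset: missing {name} for some "
                "(plot, survey, species, stage) cell")

    levels = dispersion_levels(species)
    lidx = {k: i for i, k in enumerate(levels)}
    phi_index = np.empty((n_sv, 3, n_s), dtype=int)
    for r in range(n_sv):
        for k, stage in enumerate(STAGES):
            for j, sp in enumerate(species):
                phi_index[r, k, j] = lidx[phi_group(stage, sp, r + 1)]

    # gamma priors on latent initial states, from the first-survey observations
    values = counts[0] / offsets[0]          # per-ha observed value (3, n_p, n_s)
    minima = {}
    for k, stage in enumerate(STAGES):
        pos = values[k][counts[0, k] > 0]
        minima[stage] = float(pos.min()) if pos.size else np.nan
    alpha = np.empty((n_p, n_s, 3))
    beta = np.empty((n_p, n_s, 3))
    for k, stage in enumerate(STAGES):
        for i in range(n_p):
            for j in range(n_s):
                spec = initial_state_prior(counts[0, k, i, j], values[k, i, j],
                                           stage, minima)
                alpha[i, j, k] = spec.alpha
                beta[i, j, k] = spec.beta

    prior_mu = np.array([priors.mu[name] for name in PARAM_NAMES])
    prior_sd = np.array([priors.sigma[name] for name in PARAM_NAMES])
    return ModelData(species=species, plot_ids=plot_ids, survey_years=tuple(years),
                     counts=counts, offsets=offsets, B_p=B_p, phi_levels=levels,
                     phi_index=phi_index, gamma_alpha=alpha, gamma_beta=beta,
                     consts=consts, prior_mu=prior_mu, prior_sd=prior_sd)


def _unpack(theta: np.ndarray, md: ModelData):
    """Split flat (n_chains, dim) positions into the three blocks."""
    n_s, n_p = md.n_species, md.n_plots
    k1 = 9 * n_s
    k2 = k1 + len(md.phi_levels)
    lp = theta[:, :k1].reshape(-1, 9, n_s)
    lphi = theta[:, k1:k2]
    z = theta[:, k2:].reshape(-1, n_p, n_s, 3)
    return lp, lphi, z


def _logp_and_grad(theta: np.ndarray, md: ModelData):
    """Batched log posterior and gradient; rows with invalid states get -inf."""
    C_n = theta.shape[0]
    n_p, n_s = md.n_plots, md.n_species
    log_par, log_phi, z = _unpack(theta, md)
    T = max(md.survey_years)

    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        par = np.exp(log_par)                      # (C, 9, n_s)
        phi = np.exp(log_phi)                      # (C, K)
        x0 = np.exp(z)                             # (C, n_p, n_s, 3)

        nat = {name: par[:, i, None, :] for i, name in enumerate(PARAM_NAMES)}
        Lp = nat["l"] * md.B_p                     # (C, n_p, n_s)
        Js, As, Bs = _batch.forward_sim(
            x0[..., 0], x0[..., 1], x0[..., 2], nat, Lp,
            md.consts.beta_uA, md.consts.beta_mA, T)

        logp = np.zeros(C_n)
        # --- normal priors on log params
        resid = (log_par - md.prior_mu) / md.prior_sd
        logp += -0.5 * (resid**2).sum((1, 2)) - (np.log(md.prior_sd).sum() + 9 * n_s * _LOG_SQRT_2PI)
        g_log_par = -resid / md.prior_sd

        # --- half-normal(1) prior on 1/phi, sampled as log phi (with Jacobian)
        logp += (_HALF_LOG_2_OVER_PI - 0.5 * np.exp(-2 * log_phi) - log_phi).sum(1)
        g_log_phi = np.exp(-2 * log_phi) - 1.0

        # --- gamma priors on latent states, sampled as z = log x (with Jacobian)
        a, b = md.gamma_alpha, md.gamma_beta
        logp += (a * z - b * x0).sum((1, 2, 3)) + float(
            (a * np.log(b) - gammaln(a)).sum())
        g_z = a - b * x0

        # --- negative-binomial likelihood at each survey
        invalid = np.zeros(C_n, dtype=bool)
        adjJ = np.zeros((C_n, n_p, n_s))
        adjA = np.zeros_like(adjJ)
        adjB = np.zeros_like(adjJ)
        obs_grads = {}
        for r, year in enumerate(md.survey_years):
            states = (Js[year], As[year], Bs[year])
            for k in range(3):
                state = states[k]
                invalid |= (state < 0).any((1, 2)) | ~np.isfinite(state).all((1, 2))
                o = md.offsets[r, k]
                cnt = md.counts[r, k]
                ph = phi[:, md.phi_index[r, k]][:, None, :]   # (C, 1, n_s)
                mu = np.maximum(o * state, 1e-300)
                ll = (gammaln(cnt + ph) - gammaln(ph) - gammaln(cnt + 1.0)
                      + ph * np.log(ph) - (cnt + ph) * np.log(ph + mu)
                      + cnt * np.log(mu))
                logp += np.where(np.isfinite(ll), ll, -np.inf).sum((1, 2))
                dmu = cnt / mu - (cnt + ph) / (ph + mu)
                dphi = (digamma(cnt + ph) - digamma(ph) + np.log(ph) + 1.0
                        - np.log(ph + mu) - (cnt + ph) / (ph + mu))
                g_state = dmu * o
                obs_grads[(r, k)] = g_state
                dlogphi = (dphi * ph).sum(1)                  # (C, n_s)
                for j in range(n_s):
                    np.add.at(g_log_phi, (slice(None), md.phi_index[r, k, j]),
                              dlogphi[:, j])

        # --- backward sweep through the simulation
        year_of = {y: r for r, y in enumerate(md.survey_years)}
        par_adj = {k: 0.0 for k in _batch.PARAM_KEYS}
        adj_Lp = np.zeros((C_n, n_p, n_s))
        for t in range(T, 0, -1):
            if t in year_of:
                r = year_of[t]
                adjJ = adjJ + obs_grads[(r, 0)]
                adjA = adjA + obs_grads[(r, 1)]
                adjB = adjB + obs_grads[(r, 2)]
            aJ, aA, aB, aLp, padj = _batch.step_vjp(
                Js[t - 1], As[t - 1], Bs[t - 1], nat, Lp,
                md.consts.beta_uA, md.consts.beta_mA, adjJ, adjA, adjB)
            adjJ, adjA, adjB = aJ, aA, aB
            adj_Lp += aLp
            for k in _batch.PARAM_KEYS:
                par_adj[k] = par_adj[k] + padj[k]
        if 0 in year_of:
            r = year_of[0]
            adjJ = adjJ + obs_grads[(r, 0)]
            adjA = adjA + obs_grads[(r, 1)]
            adjB = adjB + obs_grads[(r, 2)]

        g_z += np.stack([adjJ, adjA, adjB], axis=-1) * x0

        # chain rule natural -> log scale for the demographic rates
        adj_l = (adj_Lp * md.B_p).sum(1)          # (C, n_s)
        for i, name in enumerate(PARAM_NAMES):
            if name == "l":
                g_log_par[:, i, :] += adj_l * par[:, i, :]
            else:
                g_log_par[:, i, :] += par_adj[name][:, 0, :] * par[:, i, :]

        grad = np.concatenate([
            g_log_par.reshape(C_n, -1), g_log_phi, g_z.reshape(C_n, -1)], axis=1)
        bad = ~np.isfinite(logp) | invalid
        if np.any(bad):
            logp = np.where(bad, -np.inf, logp)
            grad = np.where(bad[:, None], 0.0, grad)
    return logp, grad


def log_posterior(params_log: Mapping[str, Sequence[float]],
                  init_states: np.ndarray,
                  phis: Mapping[tuple, float] | Sequence[float],
                  dataset: Dataset, priors: NormalPriorTable,
                  consts: Constants) -> float:
    """Scalar log posterior density at one point (convenience wrapper).

    ``init_states`` has shape (n_plots, n_species, 3) on the natural positive
    scale; ``phis`` maps dispersion-level keys to φ (or lists them in
    :func:`~jab.observation.dispersion_levels` order).  The density is that of
    the unconstrained parameterization (log params, log φ, log states),
    including the transform Jacobians.
    """
    md = build_model_data(dataset, priors, consts)
    log_par = np.array([params_log[name] for name in PARAM_NAMES]).reshape(-1)
    if isinstance(phis, Mapping):
        lphi = np.log([phis[k] for k in md.phi_levels])
    else:
        lphi = np.log(np.asarray(phis, dtype=float))
    z = np.log(np.asarray(init_states, dtype=float)).reshape(-1)
    theta = np.concatenate([log_par, lphi, z])[None, :]
    logp, _ = _logp_and_grad(theta, md)
    return float(logp[0])


@dataclass
class PosteriorDraws:
    """Posterior draws indexed (chain, draw), plus sampler statistics.

    ``log_params`` has shape (chains, draws, 9, n_species) in
    :data:`~jab.core.PARAM_NAMES` order; ``log_phi`` (chains, draws, K);
    ``init_states`` (chains, draws, n_plots, n_species, 3) on the natural
    scale.
    """

    species: tuple[str, ...]
    log_params: np.ndarray
    log_phi: np.ndarray
    init_states: np.ndarray
    phi_levels: list[tuple]
    B_p: np.ndarray
    consts: Constants
    sampler_stats: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.log_params.shape[0] * self.log_params.shape[1]

    def to_inference_data(self, include_latents: bool = True):
        import arviz as az

        data = {}
        for i, name in enumerate(PARAM_NAMES):
            data[f"log_{name}"] = self.log_params[:, :, i, :]
        data["log_phi"] = self.log_phi
        if include_latents:
            data["init_state"] = self.init_states
        return az.convert_to_inference_data(data)

    def params_at(self, chain: int, draw: int) -> SpeciesParams:
        return SpeciesParams(self.species, {
            name: self.log_params[chain, draw, i, :]
            for i, name in enumerate(PARAM_NAMES)})

    def flat_log_params(self) -> np.ndarray:
        """(n_total_draws, 9, n_species)."""
        return self.log_params.reshape(-1, 9, len(self.species))

    def to_frame(self, include_latents: bool = False) -> pd.DataFrame:
        """Long format (chain, draw, quantity, value) for the global quantities."""
        n_c, n_d = self.log_params.shape[:2]
        chains, draws_ix = np.meshgrid(np.arange(n_c), np.arange(n_d), indexing="ij")
        recs = {}
        for i, name in enumerate(PARAM_NAMES):
            for j, sp in enumerate(self.species):
                recs[f"log_{name}[{sp}]"] = self.log_params[:, :, i, j]
        for k, lev in enumerate(self.phi_levels):
            recs["log_phi[" + "|".join(lev) + "]"] = self.log_phi[:, :, k]
        if include_latents:
            n_p = self.init_states.shape[2]
            for i in range(n_p):
                for j, sp in enumerate(self.species):
                    for k, st in enumerate(STAGES):
                        recs[f"init[{i}|{sp}|{st}]"] = self.init_states[:, :, i, j, k]
        frames = [pd.DataFrame({"chain": chains.ravel(), "draw": draws_ix.ravel(),
                                "quantity": q, "value": v.ravel()})
                  for q, v in recs.items()]
        return pd.concat(frames, ignore_index=True)


@dataclass
class DiagnosticsReport:
    """Per-quantity split-R̂ and bulk ESS, and the overall convergence flag."""

    table: pd.DataFrame
    rhat_threshold: float

    @property
    def converged(self) -> bool:
        return bool((self.table["rhat"] < self.rhat_threshold).all())

    @property
    def max_rhat(self) -> float:
        return float(self.table["rhat"].max())


def rhat_diagnostics(draws: PosteriorDraws | np.ndarray,
                     rhat_threshold: float = 1.05,
                     method: str = "rank",
                     include_latents: bool = True) -> DiagnosticsReport:
    """Split-R̂ and bulk effective sample size for every sampled quantity.

    ``method`` selects the R̂ flavour ("rank" = rank-normalized split-R̂,
    "split" = plain split-R̂).  Accepts either :class:`PosteriorDraws` or a raw
    (chains, draws, ...) array.
    """
    import arviz as az

    if isinstance(draws, np.ndarray):
        if draws.ndim < 2 or draws.shape[0] < 2:
            raise ValueError("need at least 2 chains")
        idata = az.convert_to_inference_data({"x": draws})
    else:
        if draws.log_params.shape[0] < 2:
            raise ValueError("need at least 2 chains")
        idata = draws.to_inference_data(include_latents=include_latents)
    rhat = az.rhat(idata, method=method)
    ess = az.ess(idata, method="bulk")
    rows = []
    for name in rhat.data_vars:
        r = np.asarray(rhat[name]).ravel()
        e = np.asarray(ess[name]).ravel()
        for i, (ri, ei) in enumerate(zip(r, e)):
            rows.append({"quantity": f"{name}[{i}]" if r.size > 1 else name,
                         "rhat": float(ri), "ess_bulk": float(ei)})
    return DiagnosticsReport(table=pd.DataFrame(rows), rhat_threshold=rhat_threshold)


def _initial_positions(md: ModelData, config: FitConfig,
                       rng: np.random.Generator) -> np.ndarray:
    n_c = config.chains
    mode = np.where(md.gamma_alpha > 1.0,
                    (md.gamma_alpha - 1.0) / md.gamma_beta,
                    0.5 / md.gamma_beta)
    z0 = np.log(np.maximum(mode, 1e-8))
    lp0 = md.prior_mu.reshape(-1)
    lphi0 = np.full(len(md.phi_levels), 1.0)
    base = np.concatenate([lp0, lphi0, z0.reshape(-1)])
    x0 = base[None, :] + 0.1 * rng.standard_normal((n_c, base.size))
    return x0


def sample_posterior(dataset: Dataset, priors: NormalPriorTable,
                     config: FitConfig, consts: Constants | None = None
                     ) -> tuple[PosteriorDraws, DiagnosticsReport]:
    """Fit the model by HMC and return draws plus convergence diagnostics.

    The sampler runs ``config.chains`` chains of ``warmup + sampling``
    iterations with adapted step size and diagonal metric; a warning is issued
    if any R̂ reaches the threshold.
    """
    if consts is None:
        from .datasets import posterior_mean_params

        _, consts = posterior_mean_params()
    md = build_model_data(dataset, priors, consts)
    if config.survey_years is not None and tuple(config.survey_years) != md.survey_years:
        raise ValueError("config.survey_years disagrees with the dataset; "
                         "per-plot survey schedules are not supported")
    rng = np.random.default_rng(config.seed)
    x0 = _initial_positions(md, config, rng)
    logp0, _ = _logp_and_grad(x0, md)
    if not np.all(np.isfinite(logp0)):
        raise RuntimeError("non-finite log posterior at the initial positions")

    draws_flat, stats = sample_hmc(
        lambda th: _logp_and_grad(th, md), x0, config.warmup, config.sampling,
        rng, target_accept=config.target_accept, max_leapfrog=config.max_leapfrog)

    n_c, n_d = config.chains, config.sampling
    theta = draws_flat.reshape(n_c * n_d, -1)
    lp, lphi, z = _unpack(theta, md)
    n_s, n_p = md.n_species, md.n_plots
    draws = PosteriorDraws(
        species=md.species,
        log_params=lp.reshape(n_c, n_d, 9, n_s),
        log_phi=lphi.reshape(n_c, n_d, -1),
        init_states=np.exp(z).reshape(n_c, n_d, n_p, n_s, 3),
        phi_levels=md.phi_levels,
        B_p=md.B_p,
        consts=md.consts,
        sampler_stats={"accept_rate": stats.accept_rate,
                       "step_size": stats.step_size,
                       "n_divergent": stats.n_divergent},
    )
    report = rhat_diagnostics(draws, rhat_threshold=config.rhat_threshold)
    if not report.converged:
        import warnings

        warnings.warn(f"chains may not have converged: max R-hat = {report.max_rhat:.3f}")
    return draws, report


def summarize_posterior(draws: PosteriorDraws, max_eq_draws: int = 200,
                        tol: float = 1e-3, t_min: int = 250, t_max: int = 5000,
                        seed: int = 0) -> pd.DataFrame:
    """Posterior mean ± sd per global quantity, with derived rates and
    predominance frequencies.

    Density-dependent rates are evaluated per draw at (a) the draw's mean
    initial state across plots and (b) the equilibrium reached from that mean
    state (with the per-draw mean seedling input), then averaged.  Equilibria
    are evaluated on at most ``max_eq_draws`` randomly chosen draws to bound
    the cost; predominance frequencies at the initial state are over all
    (plot × draw) cases and at equilibrium over the evaluated draws.
    """
    rng = np.random.default_rng(seed)
    n_c, n_d = draws.log_params.shape[:2]
    total = n_c * n_d
    species = draws.species
    rows = []
    flat = draws.flat_log_params()
    for i, name in enumerate(PARAM_NAMES):
        for j, sp in enumerate(species):
            v = flat[:, i, j]
            rows.append({"quantity": f"log_{name}[{sp}]",
                         "mean": v.mean(), "sd": v.std(ddof=1) if total > 1 else 0.0})
    lphi = draws.log_phi.reshape(total, -1)
    for k, lev in enumerate(draws.phi_levels):
        v = np.exp(lphi[:, k])
        rows.append({"quantity": "phi[" + "|".join(lev) + "]",
                     "mean": v.mean(), "sd": v.std(ddof=1) if total > 1 else 0.0})

    # mean initial state per draw, (total, n_s, 3)
    mean_init = draws.init_states.reshape(total, *draws.init_states.shape[2:]).mean(1)
    init_counts = {sp: 0 for sp in species}
    init_counts["tie"] = 0
    flat_init = draws.init_states.reshape(total, -1, len(species), 3)
    consts = draws.consts
    for m in range(total):
        for p in range(flat_init.shape[1]):
            st = StageState.from_stages(flat_init[m, p, :, 0], flat_init[m, p, :, 1],
                                        flat_init[m, p, :, 2], consts)
            init_counts[predominant_species(st, species)] += 1
    n_cases = total * flat_init.shape[1]

    sel = rng.permutation(total)[:min(max_eq_draws, total)]
    dd_init = np.zeros((len(sel), 3, len(species)))
    dd_eq = np.zeros_like(dd_init)
    eq_ba = np.zeros((len(sel), len(species)))
    eq_counts = {sp: 0 for sp in species}
    eq_counts["tie"] = 0
    from .core import PlotForcing

    mean_Bp = draws.B_p.mean(0)
    for m_i, m in enumerate(sel):
        params = SpeciesParams(species, {name: flat[m, i, :]
                                         for i, name in enumerate(PARAM_NAMES)})
        st0 = StageState.from_stages(mean_init[m, :, 0], mean_init[m, :, 1],
                                     mean_init[m, :, 2], consts)
        dd = dd_rates(st0, params)
        dd_init[m_i] = [dd["log_g_dd"], dd["log_h_dd"], dd["log_b_dd"]]
        forcing = PlotForcing.from_l(params.l, mean_Bp)
        res = find_equilibrium(st0, params, forcing, consts, tol=tol,
                               t_min=t_min, t_max=t_max)
        dd = dd_rates(res.state_star, params)
        dd_eq[m_i] = [dd["log_g_dd"], dd["log_h_dd"], dd["log_b_dd"]]
        eq_ba[m_i] = res.state_star.BA
        eq_counts[predominant_species(res.state_star, species)] += 1

    for lab, arr in (("init", dd_init), ("eq", dd_eq)):
        for k, nm in enumerate(("g", "h", "b")):
            for j, sp in enumerate(species):
                v = arr[:, k, j]
                rows.append({"quantity": f"log_{nm}_dd_{lab}[{sp}]",
                             "mean": v.mean(), "sd": v.std(ddof=1) if len(sel) > 1 else 0.0})
    for j, sp in enumerate(species):
        rows.append({"quantity": f"BA_eq[{sp}]", "mean": eq_ba[:, j].mean(),
                     "sd": eq_ba[:, j].std(ddof=1) if len(sel) > 1 else 0.0})
        rows.append({"quantity": f"predominance_init[{sp}]",
                     "mean": init_counts[sp] / n_cases, "sd": np.nan})
        rows.append({"quantity": f"predominance_eq[{sp}]",
                     "mean": eq_counts[sp] / len(sel), "sd": np.nan})
    return pd.DataFrame(rows)
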