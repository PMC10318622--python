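"""Chain-vectorized Hamiltonian Monte Carlo on an unconstrained parameter space.

All chains advance in lockstep through the same number of leapfrog steps each
iteration (the number is jittered uniformly up to a maximum), which lets the
target's value-and-gradient callback evaluate every chain in one batched call.
Warmup follows the usual windowed scheme: per-chain step-size adaptation by
dual averaging throughout, and a diagonal metric re-estimated from pooled
cross-chain draws in doubling memory windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HMCStats", "sample_hmc"]

_DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class HMCStats:
    accept_rate: np.ndarray        # per chain
    step_size: np.ndarray          # per chain, final adapted value
    n_divergent: np.ndarray        # per chain, sampling phase only
    inv_metric: np.ndarray         # diagonal inverse metric


def _adaptation_windows(n_warmup: int) -> list[tuple[int, int]]:
    """(start, end) iteration ranges of the metric-estimation windows."""
    if n_warmup < 20:
        return []
    init_buf = max(int(0.15 * n_warmup), 10)
    term_buf = max(int(0.10 * n_warmup), 10)
    windows = []
    start = init_buf
    size = max(int(0.05 * n_warmup), 10)
    while start + size <= n_warmup - term_buf:
        end = start + size
        # last window absorbs the remainder
        if end + 2 * size > n_warmup - term_buf:
            end = n_warmup - term_buf
        windows.append((start, end))
        start = end
        size *= 2
    return windows


def sample_hmc(logp_and_grad, x0: np.ndarray, n_warmup: int, n_samples: int,
               rng: np.random.Generator, target_accept: float = 0.8,
               max_leapfrog: int = 32, init_step_size: float = 0.02):
    """Sample with batched HMC.

    Parameters
    ----------
    logp_and_grad
        Callback mapping positions ``(n_chains, dim)`` to ``(logp (n_chains,),
        grad (n_chains, dim))``.  Non-finite values mark forbidden regions.
    x0
        Initial positions, one row per chain; the log density must be finite
        there.

    Returns
    -------
    draws : ndarray (n_chains, n_samples, dim)
    stats : HMCStats
    """
    x = np.array(x0, dtype=float)
    n_chains, dim = x.shape
    logp, grad = logp_and_grad(x)
    if not np.all(np.isfinite(logp)):
        bad = np.flatnonzero(~np.isfinite(logp))
        raise RuntimeError(f"non-finite initial log density in chains {bad.tolist()}")

    inv_metric = np.ones(dim)
    eps = np.full(n_chains, float(init_step_size))

    # dual averaging state (per chain)
    mu_da = np.log(10.0 * eps)
    log_eps_bar = np.zeros(n_chains)
    h_bar = np.zeros(n_chains)
    gamma, t0, kappa = 0.05, 10.0, 0.75

    windows = _adaptation_windows(n_warmup)
    win_idx = 0
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    draws = np.empty((n_chains, n_samples, dim))
    n_accept = np.zeros(n_chains)
    n_div = np.zeros(n_chains, dtype=int)

    total = n_warmup + n_samples
    for it in range(total):
        warming = it < n_warmup
        L = int(rng.integers(1, max_leapfrog + 1))
        p0 = rng.standard_normal((n_chains, dim)) / np.sqrt(inv_metric)
        h0 = -logp + 0.5 * np.sum(p0**2 * inv_metric, axis=1)

        xq, pq, gq = x.copy(), p0.copy(), grad.copy()
        diverged = np.zeros(n_chains, dtype=bool)
        e = eps[:, None]
        with np.errstate(over="ignore", invalid="ignore"):
            for _ in range(L):
                pq = pq + 0.5 * e * gq
                xq = xq + e * inv_metric * pq
                lq, gq = logp_and_grad(xq)
                bad = ~np.isfinite(lq) | ~np.all(np.isfinite(gq), axis=1)
                if np.any(bad):
                    diverged |= bad
                    lq = np.where(bad, -np.inf, lq)
                    gq = np.where(bad[:, None], 0.0, gq)
                pq = pq + 0.5 * e * gq
            h1 = -lq + 0.5 * np.sum(pq**2 * inv_metric, axis=1)
            delta_h = h1 - h0
        diverged |= ~np.isfinite(delta_h) | (delta_h > _DIVERGENCE_THRESHOLD)
        accept_prob = np.where(diverged, 0.0, np.exp(np.minimum(0.0, -delta_h)))
        u = rng.random(n_chains)
        accept = (u < accept_prob) & ~diverged
        x = np.where(accept[:, None], xq, x)
        logp = np.where(accept, lq, logp)
        grad = np.where(accept[:, None], gq, grad)

        if warming:
            # dual averaging of the step size toward the target acceptance
            m = it + 1
            eta = 1.0 / (m + t0)
            h_bar = (1 - eta) * h_bar + eta * (target_accept - accept_prob)
            log_eps = mu_da - np.sqrt(m) / gamma * h_bar
            w = m ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = np.exp(log_eps)

            if win_idx < len(windows):
                w_start, w_end = windows[win_idx]
                if w_start <= it < w_end:
                    for c in range(n_chains):
                        welford_n += 1
                        delta = x[c] - welford_mean
                        welford_mean += delta / welford_n
                        welford_m2 += delta * (x[c] - welford_mean)
                if it == w_end - 1:
                    var = welford_m2 / max(welford_n - 1, 1)
                    n_eff = welford_n
                    inv_metric = (n_eff / (n_eff + 5.0)) * var + (5.0 / (n_eff + 5.0)) * 1e-3
                    inv_metric = np.clip(inv_metric, 1e-10, None)
                    welford_n = 0
                    welford_mean[:] = 0.0
                    welford_m2[:] = 0.0
                    win_idx += 1
                    # restart step-size adaptation around the current value
                    mu_da = np.log(10.0 * eps)
                    h_bar[:] = 0.0
                    log_eps_bar = np.log(eps)
            if it == n_warmup - 1:
                eps = np.exp(log_eps_bar)
        else:
            k = it - n_warmup
            draws[:, k, :] = x
            n_accept += accept
            n_div += diverged

    stats = HMCStats(accept_rate=n_accept / n_samples, step_size=eps,
                     n_divergent=n_div, inv_metric=inv_metric)
    return draws, stats
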