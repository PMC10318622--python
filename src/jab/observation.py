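"""Measurement layer: offsets, negative-binomial counts, dispersion levels,
and gamma priors on latent initial states.

Latent stage abundances are standardized per hectare; inventory protocols
observe each tree class on a size-dependent effective area.  An offset ``o``
converts the per-hectare state ``x̂`` to the expected count ``μ = o·x̂``; for
the large-tree stage (recorded as basal area) the offset additionally carries
a counts-per-basal-area factor ``c_p / ba_p`` from angle-count sampling.
Counts are negative-binomial with mean ``μ`` and variance ``μ + μ²/φ``, with
dispersion ``φ`` fitted separately per stage, species and survey group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "STAGES",
    "GammaSpec",
    "expected_count",
    "nb_log_likelihood",
    "gamma_from_mode_sd",
    "zeta_rule",
    "initial_state_prior",
    "phi_group",
    "dispersion_levels",
]

STAGES = ("J", "A", "B")

#: sd of the gamma initial-state prior as a function of the raw observed count κ.
_ZETA_RULES = {"J": (100.0, 20.0), "A": (10.0, 2.0), "B": (1.0, 0.2)}

#: For zero observations: prior expected value as a fraction of the smallest
#: positive observed per-ha value within the stage.
ZERO_E_FACTORS = {"J": 0.1, "A": 0.02, "B": 0.01}


def expected_count(state_value, offset):
    """Expected count μ = o · x̂ for per-ha state ``x̂`` and offset ``o`` [ha]."""
    state_value = np.asarray(state_value, dtype=float)
    offset = np.asarray(offset, dtype=float)
    if np.any(offset <= 0):
        raise ValueError("offsets must be strictly positive")
    if np.any(state_value < 0):
        raise ValueError("state values must be non-negative")
    return offset * state_value


def nb_log_likelihood(C, mu, phi):
    """Negative-binomial log-pmf with mean ``mu`` and dispersion ``phi``.

    Variance is ``mu + mu²/phi`` (1/φ is the overdispersion; φ → ∞ recovers
    Poisson).  ``mu = 0`` yields 0 for ``C = 0`` and −inf for ``C > 0``.
    """
    C = np.asarray(C)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(C < 0) or not np.issubdtype(C.dtype, np.integer) and np.any(C != np.floor(C)):
        raise ValueError("counts must be non-negative integers")
    if np.any(phi <= 0):
        raise ValueError("phi must be strictly positive")
    if np.any(mu < 0):
        raise ValueError("mu must be non-negative")
    C = C.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = (
            gammaln(C + phi) - gammaln(phi) - gammaln(C + 1.0)
            + phi * np.log(phi / (phi + mu))
            + C * np.log(mu / (phi + mu))
        )
        # mu == 0: point mass at zero
        logp = np.where(mu == 0, np.where(C == 0, 0.0, -np.inf), logp)
    return logp if logp.shape else float(logp)


@dataclass(frozen=True)
class GammaSpec:
    """A gamma prior, shape ``alpha`` and rate ``beta``, with its provenance.

    Built either from a mode ``nu`` and sd ``zeta`` (positive observations) or
    from shape 1 and expected value ``E`` (zero observations).
    """

    alpha: float
    beta: float
    nu: float | None = None
    zeta: float | None = None
    E: float | None = None
    kappa: float | None = None

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("gamma parameters must be positive")

    @property
    def mode(self) -> float:
        return max(self.alpha - 1.0, 0.0) / self.beta

    @property
    def mean(self) -> float:
        return self.alpha / self.beta

    @property
    def variance(self) -> float:
        return self.alpha / self.beta**2


def gamma_from_mode_sd(nu: float, zeta: float, kappa: float | None = None) -> GammaSpec:
    """Gamma distribution with mode ``nu`` and standard deviation ``zeta``.

    β = (ν + √(ν² + 4ζ²)) / (2ζ²) and α = 1 + νβ, so that (α−1)/β = ν and
    α/β² = ζ² exactly.
    """
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    if nu < 0:
        raise ValueError("nu must be non-negative")
    beta = (nu + math.sqrt(nu**2 + 4.0 * zeta**2)) / (2.0 * zeta**2)
    alpha = 1.0 + nu * beta
    return GammaSpec(alpha=alpha, beta=beta, nu=nu, zeta=zeta, kappa=kappa)


def zeta_rule(stage: str, kappa: float) -> float:
    """Prior sd of the latent initial state given the raw observed count κ."""
    if stage not in _ZETA_RULES:
        raise KeyError(f"unknown stage {stage!r}")
    a, b = _ZETA_RULES[stage]
    return a + b * kappa


def initial_state_prior(kappa: float, value: float, stage: str,
                        stage_minima: Mapping[str, float]) -> GammaSpec:
    """Gamma prior for one latent initial per-ha state.

    For a positive observed count κ the prior mode is the observed per-ha
    value with sd from :func:`zeta_rule`.  For κ = 0 the prior is exponential
    (α = 1) with expected value a small stage-specific fraction of the
    smallest positive observed per-ha value in that stage, so mass concentrates
    near zero but permits latent presence.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if stage not in STAGES:
        raise KeyError(f"unknown stage {stage!r}")
    if kappa > 0:
        return gamma_from_mode_sd(nu=value, zeta=zeta_rule(stage, kappa), kappa=kappa)
    if stage not in stage_minima or not np.isfinite(stage_minima[stage]) or stage_minima[stage] <= 0:
        raise ValueError(f"no positive observed minimum available for stage {stage!r}")
    E = ZERO_E_FACTORS[stage] * stage_minima[stage]
    return GammaSpec(alpha=1.0, beta=1.0 / E, E=E, kappa=kappa)


def phi_group(stage: str, species: str, survey: int) -> tuple:
    """Dispersion-level key for (stage, species, survey).

    Stage J has one level per survey (sampling areas changed between surveys);
    stages A and B distinguish only the initial survey from later ones.  For
    two species this yields 6 + 4 + 4 = 14 distinct levels.
    """
    if stage not in STAGES:
        raise KeyError(f"unknown stage {stage!r}")
    if survey not in (1, 2, 3):
        raise KeyError(f"unknown survey {survey!r}")
    if stage == "J":
        return ("J", species, {1: "initial", 2: "survey2", 3: "survey3"}[survey])
    return (stage, species, "initial" if survey == 1 else "later")


def dispersion_levels(species: Sequence[str], surveys: Sequence[int] = (1, 2, 3)) -> list[tuple]:
    """All distinct dispersion-level keys, in deterministic order."""
    keys: list[tuple] = []
    for stage in STAGES:
        for sp in species:
            for sv in surveys:
                key = phi_group(stage, sp, sv)
                if key not in keys:
                    keys.append(key)
    return keys
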