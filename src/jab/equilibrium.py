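"""Fixed-point extrapolation of competitive equilibria and counterfactual switching.

An equilibrium is detected by iterating the yearly map until the largest
species-specific relative change in basal area over one step drops to 1‰ or
less, after a burn-in of at least 250 years (to avoid mistaking transient
extrema for the fixed point) and within at most 5000 years.  Counterfactual
equilibria exchange selected demographic rates between the two species and
re-solve, asking which species then holds more than half of the total basal
area ("predominance").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import Constants, PlotForcing, SpeciesParams, StageState, step

__all__ = [
    "SWITCH_SETS",
    "EquilibriumResult",
    "PredominanceSummary",
    "find_equilibrium",
    "predominant_species",
    "switch_parameters",
    "counterfactual_suite",
]

#: The named counterfactual scenarios: which parameters are exchanged between
#: the two species.  "none" is the identity (the plain extrapolated equilibrium).
SWITCH_SETS: dict[str, tuple[str, ...]] = {
    "none": (),
    "l_r": ("l", "r"),
    "c_J": ("c_J",),
    "s": ("s",),
    "g": ("g",),
    "g_c_J_s": ("g", "c_J", "s"),
    "g_s": ("g", "s"),
    "c_A": ("c_A",),
    "h": ("h",),
    "h_c_A": ("h", "c_A"),
    "b": ("b",),
    "c_B": ("c_B",),
    "b_c_B": ("b", "c_B"),
}


@dataclass(frozen=True)
class EquilibriumResult:
    """Result of the fixed-point iteration.

    ``criterion_value`` is the max over species of the relative BA change in
    the final step; ``converged`` is true iff it reached the tolerance by
    ``t_max``.
    """

    state_star: StageState
    years: int
    converged: bool
    criterion_value: float


def _ba_criterion(BA_prev: np.ndarray, BA: np.ndarray) -> float:
    """Species-wise relative BA change; absolute change where BA is zero."""
    delta = np.abs(BA - BA_prev)
    rel = np.where(BA > 0, delta / np.where(BA > 0, BA, 1.0), delta)
    return float(rel.max())


def find_equilibrium(state0: StageState, params: SpeciesParams, forcing: PlotForcing,
                     consts: Constants, tol: float = 1e-3, t_min: int = 250,
                     t_max: int = 5000) -> EquilibriumResult:
    """Iterate the yearly map to the competitive equilibrium.

    Terminates at the first year ``t >= t_min`` with
    ``max_j |BA_t − BA_{t−1}| / BA_t <= tol``, or at ``t_max`` with
    ``converged=False``.  The criterion is evaluated every year.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if not (0 < t_min <= t_max):
        raise ValueError("require 0 < t_min <= t_max")
    state = state0
    crit = np.inf
    for _ in range(t_max):
        prev_ba = state.BA
        try:
            state = step(state, params, forcing, consts)
        except FloatingPointError as exc:
            raise FloatingPointError(f"equilibrium iteration diverged at year {state.t + 1}: {exc}") from exc
        crit = _ba_criterion(prev_ba, state.BA)
        if state.t >= t_min and crit <= tol:
            return EquilibriumResult(state_star=state, years=state.t, converged=True,
                                     criterion_value=crit)
    return EquilibriumResult(state_star=state, years=state.t, converged=False,
                             criterion_value=crit)


def predominant_species(state: StageState, species: Sequence[str] | None = None) -> str:
    """Label of the species holding >50% of total basal area, or ``"tie"``."""
    total = state.BA.sum()
    if total <= 0:
        raise ValueError("predominance undefined: total basal area is zero")
    labels = list(species) if species is not None else [str(j) for j in range(state.n_species)]
    share = state.BA / total
    winners = np.flatnonzero(share > 0.5)
    if winners.size == 0:
        return "tie"
    return labels[int(winners[0])]


def switch_parameters(params: SpeciesParams, switch_set: str | Iterable[str]) -> SpeciesParams:
    """Exchange the listed parameters between the two species.

    ``switch_set`` is either a scenario name from :data:`SWITCH_SETS` or an
    iterable of parameter names.  Switching is an involution: applying the
    same set twice restores the original parameters.  Only two-species
    parameter sets are supported.
    """
    if params.n_species != 2:
        raise ValueError("parameter switching requires exactly 2 species")
    if isinstance(switch_set, str):
        if switch_set not in SWITCH_SETS:
            raise ValueError(f"unknown switch set {switch_set!r}; known: {sorted(SWITCH_SETS)}")
        names = SWITCH_SETS[switch_set]
    else:
        names = tuple(switch_set)
    return params.replace(**{name: params.log(name)[::-1] for name in names})


@dataclass
class PredominanceSummary:
    """Per-scenario predominance fractions and equilibrium basal areas.

    ``table`` has one row per (scenario, species) with columns
    ``predominance_fraction``, ``mean_BA_eq``, ``sd_BA_eq``, ``n_nonconverged``;
    ``tie_fraction`` and ``initial_fraction`` are per-scenario /
    per-species side tables.  Fractions are over all converged
    (plot × parameter-draw) cases.
    """

    table: pd.DataFrame
    tie_fraction: dict[str, float]
    initial_fraction: dict[str, float]
    n_cases: int


def counterfactual_suite(
    param_sets: SpeciesParams | Sequence[SpeciesParams],
    initial_states: StageState | Sequence[StageState],
    forcings: PlotForcing | Sequence[PlotForcing],
    consts: Constants,
    scenarios: Sequence[str] = tuple(SWITCH_SETS),
    tol: float = 1e-3,
    t_min: int = 250,
    t_max: int = 5000,
) -> PredominanceSummary:
    """Counterfactual equilibria over (scenario × plot × parameter draw).

    For every scenario the listed parameters are exchanged between species,
    the equilibrium is re-solved from each plot's initial state, and the case
    is classified by predominance.  The seedling input is recomputed per case
    as L_p = l ⊙ B_p from the (switched) draw's ``l`` and the plot's regional
    basal area, so switching ``l`` takes effect.  The identity scenario
    (``"none"``) gives the plain extrapolated equilibrium; the classification
    of the initial states themselves is reported alongside.  Non-converged
    runs are excluded from the fractions and counted in ``n_nonconverged``.
    """
    if isinstance(param_sets, SpeciesParams):
        param_sets = [param_sets]
    if isinstance(initial_states, StageState):
        initial_states = [initial_states]
    if isinstance(forcings, PlotForcing):
        forcings = [forcings] * len(initial_states)
    if len(forcings) != len(initial_states):
        raise ValueError("need one forcing per initial state")
    if len(scenarios) == 0:
        raise ValueError("at least one scenario required")
    species = list(param_sets[0].species)

    init_counts = {lab: 0 for lab in species + ["tie"]}
    for st in initial_states:
        for _ in param_sets:
            init_counts[predominant_species(st, species)] += 1
    n_cases = len(initial_states) * len(param_sets)

    rows = []
    tie_fraction = {}
    for scen in scenarios:
        counts = {lab: 0 for lab in species + ["tie"]}
        ba_eq = []
        n_nonconv = 0
        for draw in param_sets:
            switched = switch_parameters(draw, scen) if scen != "none" else draw
            for st, fc in zip(initial_states, forcings):
                fc_draw = PlotForcing.from_l(switched.l, fc.B_p)
                res = find_equilibrium(st, switched, fc_draw, consts, tol=tol,
                                       t_min=t_min, t_max=t_max)
                if not res.converged:
                    n_nonconv += 1
                    continue
                counts[predominant_species(res.state_star, species)] += 1
                ba_eq.append(res.state_star.BA)
        n_conv = n_cases - n_nonconv
        ba_eq = np.asarray(ba_eq) if ba_eq else np.zeros((0, len(species)))
        for j, lab in enumerate(species):
            rows.append({
                "scenario": scen,
                "species": lab,
                "predominance_fraction": counts[lab] / n_conv if n_conv else np.nan,
                "mean_BA_eq": float(ba_eq[:, j].mean()) if n_conv else np.nan,
                "sd_BA_eq": float(ba_eq[:, j].std(ddof=1)) if n_conv > 1 else 0.0,
                "n_nonconverged": n_nonconv,
            })
        tie_fraction[scen] = counts["tie"] / n_conv if n_conv else np.nan
    return PredominanceSummary(
        table=pd.DataFrame(rows),
        tie_fraction=tie_fraction,
        initial_fraction={lab: c / n_cases for lab, c in init_counts.items()},
        n_cases=n_cases,
    )
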