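"""Deterministic JAB dynamics: stage-structured competition between tree species.

The JAB model iterates three size stages per species in discrete yearly steps:
saplings ``J`` (counts per hectare), intermediary trees ``A`` (counts per
hectare) and large trees ``B`` (basal area, m² ha⁻¹).  The combined overstory
basal area ``BA = A ⊙ β_mA + B`` drives asymmetric competition on the sapling
layer (shading) and symmetric density dependence within the overstory.  All
demographic parameters are strictly positive; density dependence is hyperbolic,
i.e. stages are divided by a denominator slightly greater than one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PARAM_NAMES",
    "Constants",
    "SpeciesParams",
    "PlotForcing",
    "StageState",
    "Trajectory",
    "derive_constants",
    "seedling_input",
    "step",
    "simulate",
    "dd_rates",
]

#: The nine per-species demographic rates, in canonical order.
PARAM_NAMES = ("r", "l", "c_J", "s", "g", "c_A", "h", "b", "c_B")

#: Transition fractions that must not exceed one.
_FRACTION_PARAMS = ("g", "h")

#: Default species-specific mean basal area of one A-stage tree [m²].
DEFAULT_BETA_MA = (0.01586, 0.01611)


def _as_vector(x, n: int | None = None, name: str = "value") -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if n is not None and arr.shape[0] != n:
        raise ValueError(f"{name} must have length {n}, got {arr.shape[0]}")
    return arr


@dataclass(frozen=True)
class Constants:
    """Stage-threshold constants shared by all plots.

    Parameters
    ----------
    beta_uA
        Basal area of one tree at the A→B diameter threshold [m²]; converts
        A-stage counts transitioning to B into basal area.
    beta_mA
        Per-species mean basal area of one A-stage tree [m²]; converts A-stage
        counts into basal area for the combined overstory BA.
    dbh_JA_cm
        Lower diameter bound of stage A [cm].
    dbh_AB_cm
        Diameter threshold between stages A and B [cm].
    """

    beta_uA: float
    beta_mA: np.ndarray
    dbh_JA_cm: float = 10.0
    dbh_AB_cm: float = 18.0

    def __post_init__(self):
        object.__setattr__(self, "beta_mA", _as_vector(self.beta_mA, name="beta_mA"))
        if self.beta_uA <= 0:
            raise ValueError("beta_uA must be positive")
        if np.any(self.beta_mA <= 0):
            raise ValueError("all beta_mA entries must be positive")
        if not (0 < self.dbh_JA_cm < self.dbh_AB_cm):
            raise ValueError("require 0 < dbh_JA_cm < dbh_AB_cm")

    @property
    def n_species(self) -> int:
        return self.beta_mA.shape[0]

    def to_dict(self) -> dict:
        return {
            "beta_uA": float(self.beta_uA),
            "beta_mA": [float(v) for v in self.beta_mA],
            "dbh_JA_cm": float(self.dbh_JA_cm),
            "dbh_AB_cm": float(self.dbh_AB_cm),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Constants":
        return cls(
            beta_uA=float(d["beta_uA"]),
            beta_mA=np.asarray(d["beta_mA"], dtype=float),
            dbh_JA_cm=float(d.get("dbh_JA_cm", 10.0)),
            dbh_AB_cm=float(d.get("dbh_AB_cm", 18.0)),
        )


def derive_constants(
    dbh_AB_cm: float = 18.0,
    beta_mA: Sequence[float] = DEFAULT_BETA_MA,
    dbh_JA_cm: float = 10.0,
) -> Constants:
    """Derive stage constants from the A→B diameter threshold.

    ``beta_uA`` is the basal area of a circular stem of diameter ``dbh_AB_cm``:
    π·(dbh/200)² with dbh in cm yielding m².
    """
    if dbh_AB_cm <= 0:
        raise ValueError("dbh_AB_cm must be positive")
    beta_uA = math.pi * (dbh_AB_cm / 200.0) ** 2
    return Constants(beta_uA=beta_uA, beta_mA=np.asarray(beta_mA, dtype=float),
                     dbh_JA_cm=dbh_JA_cm, dbh_AB_cm=dbh_AB_cm)


class SpeciesParams:
    """The nine per-species demographic rates, stored on the log scale.

    Natural-scale values are exposed as attributes (``params.g`` etc.) and are
    exactly ``exp`` of the stored log values.  Transition fractions ``g`` and
    ``h`` must lie in (0, 1]; all rates must be strictly positive (guaranteed
    by the log-scale storage).
    """

    def __init__(self, species: Sequence[str], log_values: Mapping[str, Iterable[float]]):
        self.species = tuple(str(s) for s in species)
        n = len(self.species)
        if n < 1:
            raise ValueError("at least one species required")
        missing = set(PARAM_NAMES) - set(log_values)
        if missing:
            raise ValueError(f"missing parameters: {sorted(missing)}")
        self._log = {
            name: _as_vector(log_values[name], n, name=f"log {name}")
            for name in PARAM_NAMES
        }
        for name in PARAM_NAMES:
            if not np.all(np.isfinite(self._log[name])):
                raise ValueError(f"non-finite log {name}")
        for name in _FRACTION_PARAMS:
            if np.any(self._log[name] > 0):
                raise ValueError(f"{name} must not exceed 1 (transition fraction)")

    @classmethod
    def from_natural(cls, species: Sequence[str], values: Mapping[str, Iterable[float]]) -> "SpeciesParams":
        log_values = {}
        for name in PARAM_NAMES:
            arr = _as_vector(values[name], len(species), name=name)
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be strictly positive")
            log_values[name] = np.log(arr)
        return cls(species, log_values)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def log(self, name: str) -> np.ndarray:
        return self._log[name].copy()

    def __getattr__(self, name: str):
        if name.startswith("log_") and name[4:] in PARAM_NAMES:
            return self._log[name[4:]].copy()
        if name in PARAM_NAMES:
            return np.exp(self._log[name])
        raise AttributeError(name)

    def natural(self) -> dict[str, np.ndarray]:
        return {name: np.exp(v) for name, v in self._log.items()}

    def replace(self, **log_values) -> "SpeciesParams":
        new = dict(self._log)
        for name, v in log_values.items():
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {name!r}")
            new[name] = _as_vector(v, self.n_species, name=name)
        return SpeciesParams(self.species, new)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpeciesParams):
            return NotImplemented
        return self.species == other.species and all(
            np.array_equal(self._log[k], other._log[k]) for k in PARAM_NAMES
        )

    def __repr__(self) -> str:
        return f"SpeciesParams(species={self.species})"

    def to_dict(self, constants: Constants | None = None) -> dict:
        d = {
            "species": list(self.species),
            "log_params": {k: [float(x) for x in v] for k, v in self._log.items()},
        }
        if constants is not None:
            d["constants"] = constants.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SpeciesParams":
        return cls(d["species"], {k: np.asarray(v, dtype=float) for k, v in d["log_params"].items()})

    def to_json(self, path, constants: Constants | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(constants), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SpeciesParams":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def seedling_input(l: np.ndarray, B_p: np.ndarray) -> np.ndarray:
    """External per-species seedling input L_p = l ⊙ B_p [counts ha⁻¹ yr⁻¹].

    ``B_p`` is the regional long-term basal area of each species [m² ha⁻¹];
    ``l`` converts it into a yearly seedling influx independent of the local
    stand.
    """
    l = _as_vector(l, name="l")
    B_p = _as_vector(B_p, l.shape[0], name="B_p")
    if np.any(l <= 0):
        raise ValueError("l must be strictly positive")
    if np.any(B_p < 0):
        raise ValueError("B_p must be non-negative")
    return l * B_p


@dataclass(frozen=True)
class PlotForcing:
    """Plot-level forcing: regional basal area B_p and seedling input L_p."""

    B_p: np.ndarray
    L_p: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "B_p", _as_vector(self.B_p, name="B_p"))
        object.__setattr__(self, "L_p", _as_vector(self.L_p, self.B_p.shape[0], name="L_p"))
        if np.any(self.B_p < 0) or np.any(self.L_p < 0):
            raise ValueError("forcing must be non-negative")

    @classmethod
    def from_l(cls, l: np.ndarray, B_p: np.ndarray) -> "PlotForcing":
        return cls(B_p=np.asarray(B_p, dtype=float), L_p=seedling_input(l, B_p))

    @property
    def n_species(self) -> int:
        return self.B_p.shape[0]


@dataclass(frozen=True)
class StageState:
    """Per-species stage abundances at one time step.

    ``J`` and ``A`` are counts ha⁻¹, ``B`` and the derived ``BA`` are m² ha⁻¹,
    with ``BA = A ⊙ β_mA + B``.
    """

    J: np.ndarray
    A: np.ndarray
    B: np.ndarray
    BA: np.ndarray
    t: int = 0

    def __post_init__(self):
        J = _as_vector(self.J, name="J")
        n = J.shape[0]
        object.__setattr__(self, "J", J)
        object.__setattr__(self, "A", _as_vector(self.A, n, name="A"))
        object.__setattr__(self, "B", _as_vector(self.B, n, name="B"))
        object.__setattr__(self, "BA", _as_vector(self.BA, n, name="BA"))
        for name in ("J", "A", "B", "BA"):
            v = getattr(self, name)
            if np.any(v < 0):
                raise ValueError(f"invalid state: negative entries in stage {name}")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"invalid state: non-finite entries in stage {name}")

    @classmethod
    def from_stages(cls, J, A, B, consts: Constants, t: int = 0) -> "StageState":
        """Build a state computing BA = A ⊙ β_mA + B from the constants."""
        A = _as_vector(A, name="A")
        B = _as_vector(B, A.shape[0], name="B")
        return cls(J=np.asarray(J, dtype=float), A=A, B=B,
                   BA=A * consts.beta_mA + B, t=t)

    @property
    def n_species(self) -> int:
        return self.J.shape[0]

    def total_ba(self) -> float:
        return float(self.BA.sum())


class Trajectory:
    """Ordered sequence of :class:`StageState` from t=0 to t=T."""

    def __init__(self, states: Sequence[StageState]):
        self.states = list(states)
        ts = [s.t for s in self.states]
        if ts != sorted(ts) or len(set(ts)) != len(ts):
            raise ValueError("trajectory times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, i) -> StageState:
        return self.states[i]

    def __iter__(self):
        return iter(self.states)

    def to_frame(self, species: Sequence[str] | None = None) -> pd.DataFrame:
        """Long-format table with columns (t, species, J, A, B, BA)."""
        n = self.states[0].n_species
        labels = list(species) if species is not None else [str(j) for j in range(n)]
        rows = []
        for s in self.states:
            for j in range(n):
                rows.append({"t": s.t, "species": labels[j], "J": s.J[j],
                             "A": s.A[j], "B": s.B[j], "BA": s.BA[j]})
        return pd.DataFrame(rows)


def _check_shapes(state: StageState, params: SpeciesParams, forcing: PlotForcing, consts: Constants):
    n = state.n_species
    if params.n_species != n or forcing.n_species != n or consts.n_species != n:
        raise ValueError(
            "species dimension mismatch between state "
            f"({n}), params ({params.n_species}), forcing ({forcing.n_species}) "
            f"and constants ({consts.n_species})"
        )


def step(state: StageState, params: SpeciesParams, forcing: PlotForcing,
         consts: Constants) -> StageState:
    """One yearly iteration of the JAB map.

    With per-species vectors and ⊙/⊘ elementwise, ``den_J = 1 + c_J·ΣJ + s·ΣBA``
    and ``den_A/B = 1 + c_{A/B}·ΣBA`` (sums over all species):

    - J' = L_p + r ⊙ BA + (J − g ⊙ J) ⊘ den_J
    - A' = (g ⊙ J) ⊘ den_J + (A − h ⊙ A) ⊘ den_A
    - B' = (h ⊙ A)·β_uA ⊘ den_A + ((1+b) ⊙ B) ⊘ den_B
    - BA' = A' ⊙ β_mA + B'
    """
    _check_shapes(state, params, forcing, consts)
    p = params.natural()
    SJ = state.J.sum()
    SBA = state.BA.sum()
    den_J = 1.0 + p["c_J"] * SJ + p["s"] * SBA
    den_A = 1.0 + p["c_A"] * SBA
    den_B = 1.0 + p["c_B"] * SBA

    J_next = forcing.L_p + p["r"] * state.BA + (state.J - p["g"] * state.J) / den_J
    A_next = (p["g"] * state.J) / den_J + (state.A - p["h"] * state.A) / den_A
    B_next = (p["h"] * state.A) * consts.beta_uA / den_A + (1.0 + p["b"]) * state.B / den_B
    BA_next = A_next * consts.beta_mA + B_next

    for name, v in (("J", J_next), ("A", A_next), ("B", B_next), ("BA", BA_next)):
        if not np.all(np.isfinite(v)):
            raise FloatingPointError(f"non-finite value in stage {name} at t={state.t + 1}")
    return StageState(J=J_next, A=A_next, B=B_next, BA=BA_next, t=state.t + 1)


def simulate(state0: StageState, params: SpeciesParams, forcing: PlotForcing,
             consts: Constants, T: int) -> Trajectory:
    """Iterate :func:`step` for ``T`` years, returning all T+1 states."""
    if T < 0 or int(T) != T:
        raise ValueError("T must be a non-negative integer")
    states = [state0]
    s = state0
    for k in range(int(T)):
        try:
            s = step(s, params, forcing, consts)
        except FloatingPointError as exc:
            raise FloatingPointError(f"simulation failed at year {s.t + 1}: {exc}") from exc
        states.append(s)
    return Trajectory(states)


def dd_rates(state: StageState, params: SpeciesParams) -> dict[str, np.ndarray]:
    """Log density-dependent growth rates at a given state.

    Returns per-species ``log_g_dd = log g − log den_J``, ``log_h_dd = log h −
    log den_A`` and ``log_b_dd = log b − log den_B``, the effective (competition-
    reduced) transition and growth rates.
    """
    if params.n_species != state.n_species:
        raise ValueError("species dimension mismatch between state and params")
    p = params.natural()
    SJ = state.J.sum()
    SBA = state.BA.sum()
    return {
        "log_g_dd": params.log("g") - np.log1p(p["c_J"] * SJ + p["s"] * SBA),
        "log_h_dd": params.log("h") - np.log1p(p["c_A"] * SBA),
        "log_b_dd": params.log("b") - np.log1p(p["c_B"] * SBA),
    }
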