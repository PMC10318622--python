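"""Shipped reference fixtures: fitted posterior-mean parameters and mean states.

These are the published point estimates of the two-species (Fagus / pooled
others) system and serve as defaults for the synthetic-data generator and as
inputs for equilibrium and counterfactual analyses.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .core import Constants, SpeciesParams, StageState

__all__ = ["posterior_mean_params", "reference_states", "reference_stage_state",
           "reference_phi"]


def _load(name: str) -> dict:
    with resources.files("jab.data").joinpath(name).open(encoding="utf-8") as fh:
        return json.load(fh)


def posterior_mean_params() -> tuple[SpeciesParams, Constants]:
    """Posterior-mean demographic rates and the stage-threshold constants."""
    d = _load("posterior_means.json")
    return SpeciesParams.from_dict(d), Constants.from_dict(d["constants"])


def reference_states() -> dict:
    """Raw reference-state table (means, sds, dispersion levels)."""
    return _load("reference_states.json")


def reference_stage_state(which: str = "initial_model") -> StageState:
    """One of the mean reference states as a :class:`StageState`.

    ``which`` is ``"initial_data"``, ``"initial_model"`` or ``"equilibrium"``.
    BA is taken as tabulated (it may differ from A·β_mA + B in the last printed
    digit).
    """
    d = reference_states()
    if which not in ("initial_data", "initial_model", "equilibrium"):
        raise ValueError(f"unknown reference state {which!r}")
    s = d[which]
    return StageState(J=np.array(s["J"]), A=np.array(s["A"]), B=np.array(s["B"]),
                      BA=np.array(s["BA"]), t=0)


def reference_phi() -> dict[tuple, float]:
    """Posterior-mean dispersion φ per (stage, species, survey-group) level."""
    d = reference_states()
    return {tuple(k.split("|")): float(v) for k, v in d["phi"].items()}
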