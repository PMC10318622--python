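"""Dataset container, CSV/JSON serialization and validation.

The observation table is long-format: one row per (plot, survey, species,
stage) with the observed count, the sampling offset that converts per-hectare
states to expected counts, optional angle-count helpers ``c_p``/``ba_p`` for
the basal-area stage, and the per-species regional basal area ``B_p``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Constants, SpeciesParams
from .observation import STAGES

__all__ = ["Dataset", "DatasetValidationError", "read_dataset", "write_dataset",
           "validate_dataset"]

OBS_COLUMNS = ("plot_id", "survey", "year", "species", "stage", "count",
               "offset", "c_p", "ba_p", "B_p")

#: 17 significant digits keep float64 round-trips exact.
_FLOAT_FMT = "%.17g"


class DatasetValidationError(ValueError):
    """Schema violation(s) in an observation table; carries the full list."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid dataset:\n" + "\n".join(errors))


@dataclass
class Dataset:
    """Observations plus per-plot metadata and an optional ground-truth block."""

    obs: pd.DataFrame
    species: tuple[str, ...]
    survey_years: tuple[int, ...]
    truth: dict | None = None

    @property
    def plot_ids(self) -> list:
        return list(dict.fromkeys(self.obs["plot_id"]))

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    def B_p(self) -> pd.DataFrame:
        """Per-plot regional basal area, plots × species."""
        sub = self.obs.drop_duplicates(["plot_id", "species"])
        return sub.pivot(index="plot_id", columns="species", values="B_p")[list(self.species)]


def _collect_errors(df: pd.DataFrame) -> list[str]:
    errors: list[str] = []
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        return [f"missing columns: {missing}"]
    # line numbers refer to the CSV file (header = line 1)
    lines = df.index.to_numpy() + 2

    def flag(mask, msg):
        for ln in lines[np.asarray(mask)][:20]:
            errors.append(f"line {ln}: {msg}")

    counts = pd.to_numeric(df["count"], errors="coerce")
    flag(counts.isna() | (counts < 0) | (counts != np.floor(counts.fillna(0))),
         "count must be a non-negative integer")
    offs = pd.to_numeric(df["offset"], errors="coerce")
    flag(offs.isna() | (offs <= 0), "offset must be positive (column 'offset')")
    bp = pd.to_numeric(df["B_p"], errors="coerce")
    flag(bp.isna() | (bp < 0), "B_p must be non-negative (column 'B_p')")
    flag(~df["stage"].isin(STAGES), "stage must be one of J, A, B")
    flag(~df["survey"].isin((1, 2, 3)), "survey must be 1, 2 or 3")
    dup = df.duplicated(["plot_id", "survey", "species", "stage"], keep=False)
    flag(dup & df.duplicated(["plot_id", "survey", "species", "stage"], keep="first"),
         "duplicate (plot_id, survey, species, stage) combination")
    # survey -> year must be a single consistent mapping
    yr = df.groupby("survey")["year"].nunique()
    for sv, nun in yr.items():
        if nun > 1:
            errors.append(f"survey {sv} maps to multiple years {sorted(df.loc[df['survey'] == sv, 'year'].unique())}")
    # B_p must be constant within (plot, species)
    nun = df.groupby(["plot_id", "species"])["B_p"].nunique()
    for (pid, sp), k in nun.items():
        if k > 1:
            errors.append(f"B_p not constant for plot {pid!r} species {sp!r}")
            break
    return errors


def validate_dataset(path) -> Dataset:
    """Load and validate an observation CSV; raises with all errors found."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    errors = _collect_errors(df)
    if errors:
        raise DatasetValidationError(errors)
    species = tuple(dict.fromkeys(df["species"]))
    years = tuple(int(y) for _, y in sorted(
        df.drop_duplicates("survey")[["survey", "year"]].itertuples(index=False)))
    truth = None
    truth_path = path.with_suffix(".truth.json")
    if truth_path.exists():
        with open(truth_path, encoding="utf-8") as fh:
            truth = json.load(fh)
    return Dataset(obs=df, species=species, survey_years=years, truth=truth)


def read_dataset(path) -> Dataset:
    return validate_dataset(path)


def write_dataset(dataset: Dataset, path) -> None:
    """Write the observation CSV (and a ``.truth.json`` sidecar if present)."""
    path = Path(path)
    dataset.obs.to_csv(path, index=False, float_format=_FLOAT_FMT)
    if dataset.truth is not None:
        with open(path.with_suffix(".truth.json"), "w", encoding="utf-8") as fh:
            json.dump(dataset.truth, fh, indent=1)


def load_params(path) -> tuple[SpeciesParams, Constants | None]:
    """Read a parameter-set JSON: species, log_params, optional constants."""
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    params = SpeciesParams.from_dict(d)
    consts = Constants.from_dict(d["constants"]) if "constants" in d else None
    return params, consts


def save_params(params: SpeciesParams, path, constants: Constants | None = None) -> None:
    params.to_json(path, constants)
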