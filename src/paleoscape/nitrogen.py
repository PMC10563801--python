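"""Decadal watershed nitrogen-loading budget (NLM-style).

Attributes watershed nitrogen inputs to four sources, each attenuated by
a loss/retention fraction, per decade:

* fertilizer: max(0, application rate × cultivated area − crop export)
  × leaching fraction (a net-surplus model: harvest removal is subtracted
  before leaching);
* wastewater: per-capita N excretion × population, partitioned between
  septic and sewered homes with their respective transmission fractions;
* atmospheric deposition: rate × area × (1 − retention) summed over land
  covers;
* livestock: head count × excretion rate × (1 − loss fraction) per type
  (the dairy loss fraction reflects retention-pond capture).

All coefficients live in a YAML parameter file (see ``data/nlm_params.yaml``)
with defaults drawn from the published nitrogen-loading-model literature;
none are hard-coded in the formulas.  This module estimates watershed
*inputs* only — no in-stream or estuarine transformation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

LAND_COVERS = ("cultivated", "natural", "impervious", "wetland")
LIVESTOCK_TYPES = ("dairy_cattle", "other_cattle")
SOURCES = ("fertilizer", "wastewater", "atmospheric", "livestock")

REQUIRED_INPUT_COLUMNS = [
    "population",
    "homes_septic",
    "homes_sewered",
    "atmospheric_deposition",
    "area_cultivated",
    "area_natural",
    "area_impervious",
    "area_wetland",
    "fertilizer_rate",
    "crop_export",
    "dairy_cattle",
    "other_cattle",
]


class NLMValidationError(ValueError):
    pass


@dataclass(frozen=True)
class NLMParams:
    """Loss/retention coefficients of the loading model.

    Fractions are dimensionless in [0, 1]; rates are kg N per unit per
    year.  ``deposition_retention`` maps land cover to the fraction of
    deposited N retained (not exported); ``livestock_loss`` maps livestock
    type to the fraction of excreted N captured before export.
    """

    per_capita_n: float = 4.8  # kg N person^-1 yr^-1
    septic_transmission: float = 0.35  # fraction of septic N reaching the estuary
    sewered_loss: float = 0.9  # fraction removed by treatment + outfall routing
    deposition_retention: Mapping[str, float] = field(
        default_factory=lambda: {
            "cultivated": 0.62,
            "natural": 0.90,
            "impervious": 0.15,
            "wetland": 0.90,
        }
    )
    fertilizer_leaching: float = 0.61
    livestock_excretion: Mapping[str, float] = field(
        default_factory=lambda: {"dairy_cattle": 100.0, "other_cattle": 60.0}
    )
    livestock_loss: Mapping[str, float] = field(
        default_factory=lambda: {"dairy_cattle": 0.8, "other_cattle": 0.5}
    )

    def validate(self) -> None:
        fracs = [self.septic_transmission, self.sewered_loss, self.fertilizer_leaching]
        fracs += list(self.deposition_retention.values())
        fracs += list(self.livestock_loss.values())
        for f in fracs:
            if not 0.0 <= f <= 1.0:
                raise NLMValidationError(f"fraction {f} outside [0, 1]")
        if self.per_capita_n < 0:
            raise NLMValidationError("per_capita_n must be >= 0")
        for r in self.livestock_excretion.values():
            if r < 0:
                raise NLMValidationError("excretion rates must be >= 0")
        for cover in LAND_COVERS:
            if cover not in self.deposition_retention:
                raise NLMValidationError(f"missing deposition retention for {cover!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NLMParams":
        obj = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        p = cls(**obj)
        p.validate()
        return p

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["deposition_retention"] = dict(self.deposition_retention)
        d["livestock_excretion"] = dict(self.livestock_excretion)
        d["livestock_loss"] = dict(self.livestock_loss)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")


def default_nlm_params() -> NLMParams:
    """The packaged default coefficients (data/nlm_params.yaml)."""
    ref = importlib.resources.files("paleoscape").joinpath("data/nlm_params.yaml")
    obj = yaml.safe_load(ref.read_text(encoding="utf-8"))
    p = NLMParams(**obj)
    p.validate()
    return p


def validate_inputs(inputs: pd.DataFrame) -> None:
    for col in REQUIRED_INPUT_COLUMNS:
        if col not in inputs.columns:
            raise NLMValidationError(f"missing input column {col!r}")
    if (inputs[REQUIRED_INPUT_COLUMNS] < 0).any().any():
        raise NLMValidationError("inputs must be non-negative")
    decades = inputs.index.to_numpy()
    if not (np.diff(decades) > 0).all():
        raise NLMValidationError("decades must be strictly increasing")


# ---------------------------------------------------------------------------
# per-source loads (kg N / yr); accept a decade row (Series) or the full frame


def fertilizer_load(inputs, params: NLMParams):
    surplus = inputs["fertilizer_rate"] * inputs["area_cultivated"] - inputs["crop_export"]
    return np.maximum(surplus, 0.0) * params.fertilizer_leaching


def wastewater_load(inputs, params: NLMParams):
    homes = inputs["homes_septic"] + inputs["homes_sewered"]
    with np.errstate(divide="ignore", invalid="ignore"):
        septic_frac = np.where(homes > 0, inputs["homes_septic"] / homes, 1.0)
    total_n = params.per_capita_n * inputs["population"]
    septic = total_n * septic_frac * params.septic_transmission
    sewered = total_n * (1.0 - septic_frac) * (1.0 - params.sewered_loss)
    out = septic + sewered
    if isinstance(inputs, pd.DataFrame):
        return pd.Series(out, index=inputs.index)
    return float(out)


def atmospheric_load(inputs, params: NLMParams):
    total = 0.0
    for cover in LAND_COVERS:
        passed = 1.0 - params.deposition_retention[cover]
        total = total + inputs["atmospheric_deposition"] * inputs[f"area_{cover}"] * passed
    return total


def livestock_load(inputs, params: NLMParams):
    total = 0.0
    for typ in LIVESTOCK_TYPES:
        total = total + (
            inputs[typ]
            * params.livestock_excretion[typ]
            * (1.0 - params.livestock_loss[typ])
        )
    return total


# ---------------------------------------------------------------------------
# budget


@dataclass
class NLMBudget:
    """Per-decade loads by source, totals, and source fractions (kg N/yr)."""

    table: pd.DataFrame  # index decade; columns fertilizer..livestock, total, frac_*

    @property
    def decades(self) -> np.ndarray:
        return self.table.index.to_numpy()

    def dominant_source(self, decade: int) -> str:
        row = self.table.loc[decade, list(SOURCES)]
        return str(row.idxmax())

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, float_format="%.4f")

    def stacked_series(self) -> pd.DataFrame:
        """Long-form (decade, source, load) table for stacked-area plots."""
        rows = []
        for decade, row in self.table.iterrows():
            for src in SOURCES:
                rows.append({"decade": decade, "source": src, "load_kg_yr": row[src]})
        return pd.DataFrame(rows)


def nlm_budget(inputs: pd.DataFrame, params: NLMParams) -> NLMBudget:
    """Compute the four source loads, the exact total and source fractions.

    ``inputs`` is decade-indexed with the columns of
    ``REQUIRED_INPUT_COLUMNS``; ``params`` is validated before any
    computation.  total = Σ sources exactly; fractions sum to 1 whenever
    the total is positive.
    """
    params.validate()
    validate_inputs(inputs)
    out = pd.DataFrame(index=inputs.index.copy())
    out["fertilizer"] = fertilizer_load(inputs, params)
    out["wastewater"] = wastewater_load(inputs, params)
    out["atmospheric"] = atmospheric_load(inputs, params)
    out["livestock"] = livestock_load(inputs, params)
    out["total"] = out[list(SOURCES)].sum(axis=1)
    for src in SOURCES:
        with np.errstate(divide="ignore", invalid="ignore"):
            out[f"frac_{src}"] = np.where(
                out["total"] > 0, out[src] / out["total"], np.nan
            )
    return NLMBudget(out)
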