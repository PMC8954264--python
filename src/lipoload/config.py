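"""Formulation configs and the end-to-end prediction pipeline.

A formulation config declares the whole bench protocol: lipid stock and
injection volumes, the concentration step, the vesicle size distribution,
and the compounds to load with their aliquot volumes.  Key names carry
explicit unit suffixes (``_nm``, ``_mM``, ``_uL``, ``_h``) so a mis-scaled
value is visible at the key, not buried in a docstring.  Configs are
schema-validated (unknown keys rejected) before any computation runs.

:func:`run_pipeline` executes the protocol: injection dilution ->
concentration -> per-compound aliquot mixing -> equilibration, and returns
a JSON-serializable summary bundle recording every parameter actually
used, including defaults.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .equilibrate import Compound, LoadingConditions, equilibrate
from .geometry import DEFAULT_AREA_PER_LIPID_NM2, DEFAULT_BILAYER_THICKNESS_NM
from .population import SizeDistribution, Suspension, concentrate, mix

__all__ = ["FormulationConfig", "CompoundConfig", "run_pipeline", "load_config"]

SCHEMA_VERSION = 1


class CompoundConfig(BaseModel):
    """One compound entry: identity, class, stock and aliquot volume."""

    model_config = ConfigDict(extra="forbid")

    name: str
    loading_class: Literal["hydrophilic", "lipophilic"]
    stock_concentration_mM: float = Field(gt=0)
    aliquot_volume_uL: float = Field(gt=0)
    partition_coefficient: float = Field(default=1.0, gt=0)
    temperature_C: float | None = None
    duration_h: float | None = None


class FormulationConfig(BaseModel):
    """Declarative description of a liposome formulation protocol."""

    model_config = ConfigDict(extra="forbid")

    # synthesis: alcoholic lipid stock injected into water
    lipid_stock_mM: float = Field(default=10.0, gt=0)
    injection_volume_uL: float = Field(default=1000.0, gt=0)
    water_volume_uL: float = Field(default=9000.0, gt=0)

    # concentration step (filter centrifugation)
    concentration_fold: float = Field(default=20.0, ge=1.0)
    lipid_retention: float = Field(default=1.0, gt=0, le=1.0)

    # population geometry
    mean_diameter_nm: float = Field(default=79.56, gt=0)
    pdi: float = Field(default=0.0, ge=0.0, lt=1.0)
    bilayer_thickness_nm: float = Field(default=DEFAULT_BILAYER_THICKNESS_NM, ge=0)
    area_per_lipid_nm2: float = Field(default=DEFAULT_AREA_PER_LIPID_NM2, gt=0)

    # loading step: volume of suspension taken per compound aliquot
    suspension_aliquot_uL: float = Field(default=450.0, gt=0)
    compounds: list[CompoundConfig] = Field(default_factory=list)

    seed: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _geometry_consistent(self) -> "FormulationConfig":
        if self.mean_diameter_nm <= 2.0 * self.bilayer_thickness_nm:
            raise ValueError(
                "mean_diameter_nm must exceed 2 * bilayer_thickness_nm"
            )
        return self


def load_config(path: str | Path) -> FormulationConfig:
    """Load a YAML or JSON formulation config (format auto-detected)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return FormulationConfig.model_validate(data)


def run_pipeline(config: FormulationConfig) -> dict:
    """Run the synthesis -> concentration -> loading pipeline.

    Returns a bundle with the suspension state after each mass-balance
    step, the excluded-volume fractions, and one equilibration result per
    configured compound (empty compound list gives the geometry/alpha
    report only).  Deterministic: all randomness in downstream synthetic
    steps flows from ``config.seed``.
    """
    from .population import excluded_volume_fraction

    synthesis_volume = config.injection_volume_uL + config.water_volume_uL
    initial_lipid_mM = (
        config.lipid_stock_mM * config.injection_volume_uL / synthesis_volume
    )
    dist = SizeDistribution(config.mean_diameter_nm, config.pdi)
    synthesized = Suspension(
        lipid_concentration_mM=initial_lipid_mM,
        volume_uL=synthesis_volume,
        distribution=dist,
        bilayer_thickness_nm=config.bilayer_thickness_nm,
        area_per_lipid_nm2=config.area_per_lipid_nm2,
    )
    concentrated = concentrate(
        synthesized, config.concentration_fold, config.lipid_retention
    )

    results = []
    for cc in config.compounds:
        aliquot = concentrated.aliquot(
            min(config.suspension_aliquot_uL, concentrated.volume_uL)
        )
        mixed, c_t = mix(aliquot, cc.aliquot_volume_uL, cc.stock_concentration_mM)
        compound = Compound(
            name=cc.name,
            loading_class=cc.loading_class,
            partition_coefficient=cc.partition_coefficient,
            stock_concentration_mM=cc.stock_concentration_mM,
        )
        cond = LoadingConditions(
            bulk_drug_concentration_mM=c_t,
            temperature_C=cc.temperature_C,
            duration_h=cc.duration_h,
        )
        res = equilibrate(mixed, compound, cond)
        entry = asdict(res)
        entry["lipid_concentration_mM"] = mixed.lipid_concentration_mM
        results.append(entry)

    bundle = {
        "schema_version": SCHEMA_VERSION,
        "config": config.model_dump(),
        "synthesis": {
            "volume_uL": synthesized.volume_uL,
            "lipid_concentration_mM": synthesized.lipid_concentration_mM,
        },
        "concentrated": {
            "volume_uL": concentrated.volume_uL,
            "lipid_concentration_mM": concentrated.lipid_concentration_mM,
        },
        "alpha": {
            "core": excluded_volume_fraction(concentrated, "core"),
            "membrane": excluded_volume_fraction(concentrated, "membrane"),
        },
        "compounds": results,
    }
    return bundle


def write_summary(bundle: dict, path: str | Path) -> None:
    """Write a pipeline bundle as JSON."""
    Path(path).write_text(json.dumps(bundle, indent=2, sort_keys=True) + "\n")
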