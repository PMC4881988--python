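"""Configuration documents mirroring the analogs' parameter tables.

Field names follow the model's parameter names exactly (*pBind*,
*cytokineExponent*, *sampleRatioFactor*, ...).  Culture parameters that
differ between the dose-response and time-course experiments, and liver
parameters that differ between control and LPS arms, live in separate
sections/arm-variant pairs.  Documents are strict: unknown keys are
rejected, probabilities are range-checked, and cross-references (accepted
solutes, expressing cell types, metabolite products) are validated on load.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .components import EnzymeType, SoluteType, TypeRegistry
from .ishc import ISHCSettings
from .isl import ISLSettings
from .mechanisms import BindingConfig, DownRegConfig, InflammationConfig

__all__ = [
    "ConfigDocument",
    "load_config",
    "save_config",
    "default_config",
    "build_registry",
    "ishc_settings_from",
    "isl_settings_from",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SoluteTypeSection(_Strict):
    bindable: bool = False
    inflammatory: bool = False
    pMetabolize: float | tuple[float, float] | None = None
    metabolicProduct: list[str] = Field(default_factory=list)
    pDegrade: float | None = Field(default=None, ge=0.0, le=1.0)
    sampleRatioFactor: float | None = Field(default=None, gt=0.0)
    Vd_change: float | None = Field(default=None, gt=0.0)
    pExitCell: float | None = Field(default=None, ge=0.0, le=1.0)
    pExitMedia: float | None = Field(default=None, ge=0.0, le=1.0)


class EnzymeTypeSection(_Strict):
    expressingCellTypes: list[str]
    acceptedSolutes: list[str] = Field(default_factory=list)
    metabolic: bool = False
    downRegulated: bool = False
    pRemove: float | None = Field(default=None, ge=0.0, le=1.0)
    bindExponent: float = Field(default=1.0, gt=0.0)


class ISHCSection(_Strict):
    """Whole-model culture parameters for one experiment variant."""

    cycleLimit: int = Field(gt=0)
    doseTime: int = Field(default=1, ge=1)
    dosage: list[int] | int
    dose_solute: str
    gridWidth: int = Field(default=25, gt=0)
    gridHeight: int = Field(default=25, gt=0)
    kcDensity: float = Field(ge=0.0, le=1.0)
    hepDensity: float = Field(ge=0.0, le=1.0)
    enzymesPerCellMin: int = Field(default=4, ge=0)
    enzymesPerCellMax: int = Field(default=8, ge=0)
    inflammatoryThreshold: int | None = Field(default=None, ge=0)
    cytokineThreshold: int | None = Field(default=None, ge=0)
    cytokineExponent: float | None = Field(default=None, gt=0.0)
    pRemove: float | None = Field(default=None, ge=0.0, le=1.0)
    delay: int | None = Field(default=None, ge=0)
    pReplenish: float | None = Field(default=None, ge=0.0, le=1.0)
    measurementCycles: list[int] = Field(default_factory=list)
    solute_types: dict[str, SoluteTypeSection]
    enzyme_types: dict[str, EnzymeTypeSection] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "ISHCSection":
        if self.kcDensity + self.hepDensity > 1.0 + 1e-12:
            raise ValueError("kcDensity + hepDensity must not exceed 1")
        if self.enzymesPerCellMin > self.enzymesPerCellMax:
            raise ValueError("enzymesPerCellMin exceeds enzymesPerCellMax")
        return self


class LobuleSection(_Strict):
    layers: int = Field(ge=2)
    segmentsPerLayer: int = Field(ge=1)
    coreLength: int = Field(default=10, ge=1)
    spaceCircumference: int = Field(default=2, ge=1)


class ISLSection(_Strict):
    """Whole-model liver parameters, shared by every arm and drug."""

    pBind: float = Field(ge=0.0, le=1.0)
    bindCycles: int = Field(gt=0)
    bindingMode: Literal["stepwise", "variable"] = "variable"
    inflammatoryThreshold: int = Field(ge=0)
    cytokineThreshold: int = Field(ge=0)
    cytokineExponent: float = Field(gt=0.0)
    delay: int = Field(ge=0)
    pReplenish: float = Field(ge=0.0, le=1.0)
    enzymesPerCellMin: int = Field(default=4, ge=0)
    enzymesPerCellMax: int = Field(default=8, ge=0)
    ecDensity: float = Field(ge=0.0, le=1.0)
    kcDensity: float = Field(ge=0.0, le=1.0)
    hepDensity: float = Field(ge=0.0, le=1.0)
    sampleRatio: float = Field(ge=0.0, le=1.0)
    forwardBias: float = Field(ge=0.0, le=1.0)
    lateralBias: float = Field(ge=0.0, le=1.0)
    flowRate: int = Field(gt=0)
    kupffer_expresses_nonspecific: bool = False
    lobule: dict[str, LobuleSection]
    solute_types: dict[str, SoluteTypeSection]
    enzyme_types: dict[str, EnzymeTypeSection]

    @model_validator(mode="after")
    def _check(self) -> "ISLSection":
        if self.ecDensity + self.kcDensity > 1.0 + 1e-12:
            raise ValueError("ecDensity + kcDensity must not exceed 1")
        if self.forwardBias + self.lateralBias > 1.0 + 1e-12:
            raise ValueError("forwardBias + lateralBias must not exceed 1")
        for name, et in self.enzyme_types.items():
            for sn in et.acceptedSolutes:
                if sn not in self.solute_types:
                    raise ValueError(f"enzyme {name}: unknown solute {sn}")
                if not self.solute_types[sn].bindable:
                    raise ValueError(f"enzyme {name}: {sn} is not bindable")
        return self


class ISLProtocolSection(_Strict):
    """Per-drug, per-arm experiment-design parameters (doses, durations)."""

    cycleLimit_control: int = Field(gt=0)
    cycleLimit_lps: int = Field(gt=0)
    lps_dosage: int = Field(ge=0)
    drug_dosage: int = Field(ge=0)
    drug_doseTime_lps: int = Field(ge=1)
    measurementPoints: int = Field(default=12, ge=2)


class MultiDrugSection(_Strict):
    drug_dosage_control: int = Field(ge=0)
    drug_dosage_lps: int = Field(ge=0)


class SimulationControl(_Strict):
    monteCarloTrials: int = Field(default=16, ge=1)


class ConfigDocument(_Strict):
    simulation: SimulationControl = Field(default_factory=SimulationControl)
    ishc_dose_response: ISHCSection
    ishc_timecourse: ISHCSection
    isl: ISLSection
    isl_protocols: dict[str, ISLProtocolSection]
    multidrug: MultiDrugSection


def _to_solute_type(name: str, sec: SoluteTypeSection) -> SoluteType:
    pm = sec.pMetabolize
    if isinstance(pm, (list, tuple)):
        pm = (float(pm[0]), float(pm[1]))
    return SoluteType(
        name=name,
        bindable=sec.bindable,
        inflammatory=sec.inflammatory,
        pMetabolize=pm,
        metabolicProduct=tuple(sec.metabolicProduct),
        pDegrade=sec.pDegrade,
        sampleRatioFactor=sec.sampleRatioFactor,
        Vd_change=sec.Vd_change,
        pExitCell=sec.pExitCell,
        pExitMedia=sec.pExitMedia,
    )


def _to_enzyme_type(name: str, sec: EnzymeTypeSection) -> EnzymeType:
    return EnzymeType(
        name=name,
        expressingCellTypes=tuple(sec.expressingCellTypes),
        acceptedSolutes=tuple(sec.acceptedSolutes),
        metabolic=sec.metabolic,
        downRegulated=sec.downRegulated,
        pRemove=sec.pRemove,
        bindExponent=sec.bindExponent,
    )


def build_registry(
    solute_types: dict[str, SoluteTypeSection],
    enzyme_types: dict[str, EnzymeTypeSection],
    kupffer_expresses_nonspecific: bool = False,
) -> TypeRegistry:
    return TypeRegistry(
        [_to_solute_type(n, s) for n, s in solute_types.items()],
        [_to_enzyme_type(n, e) for n, e in enzyme_types.items()],
        kupffer_expresses_nonspecific=kupffer_expresses_nonspecific,
    )


def ishc_settings_from(sec: ISHCSection, mode: str = "pooled") -> ISHCSettings:
    infl = InflammationConfig(
        inflammatoryThreshold=sec.inflammatoryThreshold or 0,
        cytokineThreshold=sec.cytokineThreshold or 0,
        cytokineExponent=sec.cytokineExponent or 1.0,
    )
    downreg = DownRegConfig(
        delay=sec.delay or 0,
        pReplenish=sec.pReplenish or 0.0,
        pRemove=sec.pRemove,
    )
    return ISHCSettings(
        registry=build_registry(sec.solute_types, sec.enzyme_types),
        width=sec.gridWidth,
        height=sec.gridHeight,
        kcDensity=sec.kcDensity,
        hepDensity=sec.hepDensity,
        enzymesPerCellMin=sec.enzymesPerCellMin,
        enzymesPerCellMax=sec.enzymesPerCellMax,
        inflammation=infl,
        downreg=downreg,
        mode=mode,
    )


def isl_settings_from(sec: ISLSection, lobule: str = "full") -> ISLSettings:
    if lobule not in sec.lobule:
        raise KeyError(f"no lobule preset named {lobule!r}")
    lob = sec.lobule[lobule]
    return ISLSettings(
        registry=build_registry(
            sec.solute_types,
            sec.enzyme_types,
            kupffer_expresses_nonspecific=sec.kupffer_expresses_nonspecific,
        ),
        layers=lob.layers,
        segments_per_layer=lob.segmentsPerLayer,
        core_length=lob.coreLength,
        space_circumference=lob.spaceCircumference,
        ecDensity=sec.ecDensity,
        kcDensity=sec.kcDensity,
        hepDensity=sec.hepDensity,
        enzymesPerCellMin=sec.enzymesPerCellMin,
        enzymesPerCellMax=sec.enzymesPerCellMax,
        sampleRatio=sec.sampleRatio,
        forwardBias=sec.forwardBias,
        lateralBias=sec.lateralBias,
        flowRate=sec.flowRate,
        binding=BindingConfig(
            mode=sec.bindingMode, pBind=sec.pBind, bindCycles=sec.bindCycles
        ),
        inflammation=InflammationConfig(
            inflammatoryThreshold=sec.inflammatoryThreshold,
            cytokineThreshold=sec.cytokineThreshold,
            cytokineExponent=sec.cytokineExponent,
        ),
        downreg=DownRegConfig(delay=sec.delay, pReplenish=sec.pReplenish),
    )


def load_config(path: str | Path) -> ConfigDocument:
    """Load and validate a configuration document from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return ConfigDocument.model_validate(raw)


def save_config(doc: ConfigDocument, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(doc.model_dump(exclude_none=True), fh, sort_keys=True)


def default_config() -> ConfigDocument:
    """The shipped validating-experiment parameterization."""
    ref = resources.files("hepsim").joinpath("configs/validating.yaml")
    raw = yaml.safe_load(ref.read_text())
    return ConfigDocument.model_validate(raw)


def config_hash(doc: ConfigDocument) -> str:
    blob = yaml.safe_dump(doc.model_dump(exclude_none=True), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
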