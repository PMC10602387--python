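"""Scenario configuration: validated YAML/JSON files and bundled presets."""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .grid import DEFAULT_N, DEFAULT_TF, TimeGrid
from .params import (
    EpidemicParams,
    GovernmentParams,
    InfectionCostParams,
    ModelParams,
    UtilityParams,
)
from .sweep import SweepOptions

__all__ = ["ScenarioConfig", "load_scenario", "preset_path", "list_presets"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EpidemicSection(_Strict):
    kappa_star: float = Field(4.0, gt=1.0)
    i0: float = Field(3e-8, gt=0.0, lt=1.0)


class CostSection(_Strict):
    alpha0: float = Field(ge=0.0)
    alpha1: float | None = None
    i_hc: float = Field(0.1, gt=0.0)
    sigma: float = Field(300.0, gt=0.0)
    constant: bool = False

    @model_validator(mode="after")
    def _check_alpha1(self):
        if not self.constant and self.alpha1 is None:
            raise ValueError("alpha1 is required unless constant=true")
        if self.alpha1 is not None and self.alpha1 < self.alpha0:
            raise ValueError("alpha1 must be >= alpha0")
        return self

    def build(self) -> InfectionCostParams:
        return InfectionCostParams(
            alpha0=self.alpha0,
            alpha1=self.alpha1,
            i_hc=self.i_hc,
            sigma=self.sigma,
            constant=self.constant,
        )


class UtilitySection(_Strict):
    f: float = Field(1.0, ge=1.0)
    beta: float = Field(1.0, gt=0.0)
    cost: CostSection

    def build(self) -> UtilityParams:
        return UtilityParams(f=self.f, beta=self.beta, cost=self.cost.build())


class GovernmentSection(_Strict):
    f_g: float = Field(1.0, ge=1.0)
    beta_g: float = Field(1.0, gt=0.0)
    gamma_g: float = Field(0.0, ge=0.0)
    cost: CostSection

    def build(self) -> GovernmentParams:
        return GovernmentParams(
            f_g=self.f_g,
            beta_g=self.beta_g,
            gamma_g=self.gamma_g,
            cost_g=self.cost.build(),
        )


class GridSection(_Strict):
    tf: float = Field(DEFAULT_TF, gt=0.0)
    n: int = Field(DEFAULT_N, ge=2)

    def build(self) -> TimeGrid:
        return TimeGrid(tf=self.tf, n=self.n)


class SweepSection(_Strict):
    relaxation: float = Field(0.1, gt=0.0, le=1.0)
    tol: float | None = Field(None, gt=0.0)
    max_iter: int = Field(10000, ge=1)
    verbose: bool = False

    def build(self) -> SweepOptions:
        return SweepOptions(
            relaxation=self.relaxation,
            tol=self.tol,
            max_iter=self.max_iter,
            verbose=self.verbose,
        )


class ScanSection(_Strict):
    parameter: Literal["alpha1", "alpha_g1"] = "alpha_g1"
    values: list[float] = Field(min_length=1)

    @model_validator(mode="after")
    def _ascending(self):
        if sorted(self.values) != self.values:
            raise ValueError("scan values must be ascending")
        return self


class ScenarioConfig(_Strict):
    """Validated scenario description.

    ``mode`` selects the solver; the government section is required for the
    government and (alpha_g1) scan modes, the scan section for scan mode.
    """

    name: str = "scenario"
    mode: Literal["baseline", "nash", "utilitarian", "government", "scan"] = "nash"
    epidemic: EpidemicSection = EpidemicSection()
    utility: UtilitySection
    government: GovernmentSection | None = None
    grid: GridSection = GridSection()
    sweep: SweepSection = SweepSection()
    sweep_outer: SweepSection = SweepSection(relaxation=0.05)
    scan: ScanSection | None = None
    seed: int = 0
    duration_threshold: float = Field(1e-4, gt=0.0)

    @model_validator(mode="after")
    def _mode_sections(self):
        if self.mode == "government" and self.government is None:
            raise ValueError("mode 'government' requires a government section")
        if self.mode == "scan":
            if self.scan is None:
                raise ValueError("mode 'scan' requires a scan section")
            if self.scan.parameter == "alpha_g1" and self.government is None:
                raise ValueError("alpha_g1 scan requires a government section")
        return self

    def model_params(self) -> ModelParams:
        return ModelParams(
            epidemic=EpidemicParams(
                kappa_star=self.epidemic.kappa_star, i0=self.epidemic.i0
            ),
            utility=self.utility.build(),
            government=self.government.build() if self.government else None,
        )


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Load and validate a YAML (or JSON) scenario file.

    Validation failures are re-raised with the offending keys spelled out.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    try:
        return ScenarioConfig.model_validate(raw)
    except ValidationError as err:
        locs = ", ".join(
            "/".join(str(p) for p in e["loc"]) or "<root>" for e in err.errors()
        )
        raise ValueError(f"{path}: invalid scenario config (keys: {locs})\n{err}") from err


def list_presets() -> list[str]:
    """Names of the scenario presets bundled with the package."""
    pkg = resources.files("epictrl") / "presets"
    return sorted(p.name for p in pkg.iterdir() if p.name.endswith(".yaml"))


def preset_path(name: str) -> Path:
    """Filesystem path of a bundled preset (with or without .yaml suffix)."""
    if not name.endswith(".yaml"):
        name += ".yaml"
    p = resources.files("epictrl") / "presets" / name
    if not p.is_file():
        raise FileNotFoundError(
            f"no preset {name!r}; available: {', '.join(list_presets())}"
        )
    return Path(str(p))
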