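"""Model configuration schema and (de)serialization.

A :class:`ModelConfig` holds everything a run needs: the three-state
structure, cycle length and horizon rule, the transition-probability
table with its time profiles, treatment-effect hazard ratios, utilities,
unit costs, discount rates, the willingness-to-pay threshold and the PSA
settings. Configs are YAML files validated up front; validation failures
report every offending field, and unknown keys are rejected.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .markov import LifeTable

__all__ = [
    "ModelConfig",
    "TransitionTable",
    "UtilitySet",
    "CostSchedule",
    "IndirectCosts",
    "DiscountSpec",
    "Population",
    "PsaSettings",
    "HazardRatios",
    "LifeTableSpec",
    "ConfigError",
    "load_config",
    "save_config",
]

SCENARIOS = (
    "base_case",
    "equal_discount_4",
    "no_discount",
    "no_extrapolation",
    "no_indirect_costs",
    "general_population_survival",
)


class ConfigError(ValueError):
    """Configuration failed validation; message lists every problem."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class HazardRatios(_Strict):
    """Intervention-vs-control hazard ratios with optional 95% CIs."""

    hr_pfs: float = Field(0.21, gt=0)
    hr_os: float = Field(0.54, gt=0)
    hr_sd_vs_pd: float = Field(0.44, gt=0)
    ci_pfs: Optional[tuple[float, float]] = (0.14, 0.33)
    ci_os: Optional[tuple[float, float]] = None
    ci_sd_vs_pd: Optional[tuple[float, float]] = (0.24, 0.79)

    @model_validator(mode="after")
    def _ci_brackets_mean(self):
        for name in ("pfs", "os", "sd_vs_pd"):
            ci = getattr(self, f"ci_{name}")
            if ci is not None:
                lo, hi = ci
                mean = getattr(self, f"hr_{name}")
                if not lo < mean < hi:
                    raise ValueError(f"ci_{name}={ci} must bracket hr_{name}={mean}")
        return self


class TransitionTable(_Strict):
    """Printed per-cycle transition probabilities and their time profiles.

    The SD -> PD probability is annotated as exponential over time
    (constant per cycle); the death probabilities follow a gamma time
    profile whose shape/rate are calibration constants of the fixture
    (the published analysis reports only the family, not the parameters).
    Intervention-arm CIs are the printed 95% intervals; control-arm
    probabilities carry no interval and default to an 80-120% band in
    sensitivity analyses.
    """

    sd_pd_control: float = Field(0.0854, ge=0, lt=1)
    sd_pd_intervention: float = Field(0.0183, ge=0, lt=1)
    sd_d_control: float = Field(0.0095, ge=0, lt=1)
    sd_d_intervention: float = Field(0.0073, ge=0, lt=1)
    pd_d_control: float = Field(0.0216, ge=0, lt=1)
    pd_d_intervention: float = Field(0.0116, ge=0, lt=1)
    ci_sd_pd_intervention: Optional[tuple[float, float]] = (0.0119, 0.0283)
    ci_sd_d_intervention: Optional[tuple[float, float]] = (0.0059, 0.0088)
    ci_pd_d_intervention: Optional[tuple[float, float]] = (0.0093, 0.0139)
    profile_sd_pd: Literal["exponential"] = "exponential"
    profile_death: Literal["gamma"] = "gamma"
    #: gamma time-profile parameters (month time unit), calibrated so the
    #: deterministic run reproduces the published discounted QALY totals
    gamma_shape: float = Field(1.833, gt=0)
    gamma_rate: float = Field(5.5, gt=0)


class UtilitySet(_Strict):
    """Health-state utilities (time-trade-off tariff, beta-distributed in PSA)."""

    u_sd: float = Field(0.771, ge=0, le=1)
    u_sd_range: tuple[float, float] = (0.509, 0.818)
    u_sd_ae_control: float = Field(0.666, ge=0, le=1)
    u_sd_ae_control_range: tuple[float, float] = (0.619, 0.709)
    u_sd_ae_intervention: float = Field(0.687, ge=0, le=1)
    u_sd_ae_intervention_range: tuple[float, float] = (0.642, 0.730)
    u_pd: float = Field(0.612, ge=0, le=1)
    u_pd_range: tuple[float, float] = (0.564, 0.659)
    u_dead: float = Field(0.0, ge=0, le=0)
    #: fraction of each arm experiencing a grade III/IV adverse event, all
    #: assumed to occur at the start of treatment
    ae_affected_fraction_control: float = Field(0.10, ge=0, le=1)
    ae_affected_fraction_intervention: float = Field(0.20, ge=0, le=1)
    #: cycles over which the AE-blended SD utility applies; adverse events
    #: are assumed to occur at the start of treatment and are valued for a
    #: single cycle
    ae_window_cycles: int = Field(1, ge=0)

    @model_validator(mode="after")
    def _ranges_bracket_means(self):
        for name in ("u_sd", "u_sd_ae_control", "u_sd_ae_intervention", "u_pd"):
            lo, hi = getattr(self, f"{name}_range")
            mean = getattr(self, name)
            if not lo <= mean <= hi:
                raise ValueError(f"{name}_range=({lo}, {hi}) must bracket {name}={mean}")
        return self


class IndirectCosts(_Strict):
    """Indirect (disease-unrelated) medical costs in life-years gained.

    Split into an age-dependent annual cost in "other" life stages and a
    one-time end-of-life cost charged to the newly dead, following the
    PAID framework. The annual cost grows geometrically with age from the
    value at the cohort's starting age.
    """

    annual_at_start_age: float = Field(3600.0, ge=0)
    annual_growth_per_year: float = Field(0.05, ge=0)
    end_of_life: float = Field(24000.0, ge=0)

    def annual_cost(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        return self.annual_at_start_age * (1.0 + self.annual_growth_per_year) ** (age - 63.0)


class CostSchedule(_Strict):
    """Unit costs (2019 euros, healthcare perspective).

    Treatment costs apply only in stable disease and drop to zero on
    progression; the radionuclide course is four injections billed at the
    scheduled cycles conditional on SD occupancy.
    """

    lo_price_initial: float = Field(16000.0, ge=0)
    lo_price_increased: float = Field(90000.0, ge=0)
    lo_n_injections: int = Field(4, ge=1)
    #: 8-weekly schedule: the lower bound of the licensed 8-10 week interval
    lo_injection_cycles: tuple[int, ...] = (0, 2, 4, 6)
    lo_admin_per_injection: float = Field(1000.0, ge=0)
    #: high-dose (60 mg) comparator cost per 28-day cycle, drug + administration;
    #: calibrated jointly with the maintenance cost to the published totals
    olar_cycle_control: float = Field(4025.0, ge=0)
    #: standard-dose (30 mg) maintenance cost per cycle in the intervention arm
    olar_cycle_intervention: float = Field(1375.0, ge=0)
    ae_management_control: float = Field(500.0, ge=0)
    ae_management_intervention: float = Field(1500.0, ge=0)
    #: outpatient follow-up visit with blood testing, every 6 months in PD
    pd_followup_visit: float = Field(150.0, ge=0)
    pd_followup_interval_months: float = Field(6.0, gt=0)
    indirect: IndirectCosts = IndirectCosts()
    currency_year: int = 2019

    @model_validator(mode="after")
    def _injections_consistent(self):
        if len(self.lo_injection_cycles) != self.lo_n_injections:
            raise ValueError(
                f"lo_injection_cycles has {len(self.lo_injection_cycles)} entries "
                f"but lo_n_injections={self.lo_n_injections}"
            )
        return self


class DiscountSpec(_Strict):
    """Annual discount rates (Dutch guideline: 4% costs, 1.5% effects)."""

    annual_rate_costs: float = Field(0.04, ge=0)
    annual_rate_effects: float = Field(0.015, ge=0)


class Population(_Strict):
    cohort_size: int = Field(1000, ge=1)
    start_age: float = Field(63.0, ge=0)
    #: printed sex mix of the two arms (54% / 47% male), cohort-averaged
    male_fraction: float = Field(0.505, ge=0, le=1)


class LifeTableSpec(_Strict):
    """General-population mortality: a CSV path or a Gompertz emulation.

    The bundled default emulates national-statistics life tables with a
    Gompertz hazard per sex, reaching probability 1 at ``max_age``.
    """

    csv_path: Optional[str] = None
    max_age: int = Field(105, gt=63)
    #: annual death probability at age 63, per sex
    q63_male: float = Field(0.0115, gt=0, le=1)
    q63_female: float = Field(0.0077, gt=0, le=1)
    #: mortality doubling time in years
    doubling_years: float = Field(8.0, gt=0)


class PsaSettings(_Strict):
    n_draws: int = Field(10000, ge=1)
    seed: int = Field(20190101, ge=0)
    #: relative half-width of the assumed interval for parameters published
    #: without a confidence interval
    default_interval: float = Field(0.20, gt=0, lt=1)
    cost_cv: float = Field(0.20, gt=0)


class ModelConfig(_Strict):
    """Complete configuration of the cost-effectiveness model."""

    states: tuple[str, str, str] = ("SD", "PD", "Dead")
    cycle_days: float = Field(28.0, gt=0)
    #: trace stops once this fraction of the cohort is dead
    absorption_threshold: float = Field(0.99, gt=0, lt=1)
    transition_source: Literal["table", "curves"] = "table"
    population: Population = Population()
    transitions: TransitionTable = TransitionTable()
    hazard_ratios: HazardRatios = HazardRatios()
    utilities: UtilitySet = UtilitySet()
    costs: CostSchedule = CostSchedule()
    discounting: DiscountSpec = DiscountSpec()
    life_table: LifeTableSpec = LifeTableSpec()
    wtp_threshold: float = Field(80000.0, ge=0)
    price_scenario: Literal["initial", "increased"] = "increased"
    psa: PsaSettings = PsaSettings()
    scenario: Literal[
        "base_case", "equal_discount_4", "no_discount", "no_extrapolation",
        "no_indirect_costs", "general_population_survival",
    ] = "base_case"
    #: months of trial follow-up; progression is not extrapolated past this
    #: point in the no_extrapolation scenario
    followup_months: float = Field(25.0, gt=0)
    life_table_override: Literal["switch", "max"] = "switch"

    @model_validator(mode="after")
    def _states_fixed(self):
        if tuple(self.states) != ("SD", "PD", "Dead"):
            raise ValueError("states must be ('SD', 'PD', 'Dead')")
        return self

    # -- derived objects ----------------------------------------------------

    def life_table_object(self) -> LifeTable:
        from .synthetic import make_life_table

        if self.life_table.csv_path:
            import pandas as pd

            df = pd.read_csv(self.life_table.csv_path)
            return LifeTable.from_dataframe(df)
        return make_life_table(
            max_age=self.life_table.max_age,
            q63_male=self.life_table.q63_male,
            q63_female=self.life_table.q63_female,
            doubling_years=self.life_table.doubling_years,
        )

    def with_scenario(self, scenario: str) -> "ModelConfig":
        """Return a copy with exactly one documented scenario mutation applied."""
        if scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario '{scenario}'; valid names: {', '.join(SCENARIOS)}"
            )
        cfg = self.model_copy(deep=True)
        cfg.scenario = scenario
        if scenario == "equal_discount_4":
            cfg.discounting = DiscountSpec(annual_rate_costs=0.04, annual_rate_effects=0.04)
        elif scenario == "no_discount":
            cfg.discounting = DiscountSpec(annual_rate_costs=0.0, annual_rate_effects=0.0)
        elif scenario == "no_indirect_costs":
            costs = cfg.costs.model_copy(deep=True)
            costs.indirect = IndirectCosts(annual_at_start_age=0.0,
                                           annual_growth_per_year=0.0, end_of_life=0.0)
            cfg.costs = costs
        elif scenario == "general_population_survival":
            cfg.life_table_override = "max"
        # no_extrapolation is handled inside the engine via followup_months
        return cfg

    def to_dict(self) -> dict:
        return self.model_dump(mode="json")


def _format_validation_error(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(x) for x in err["loc"]) or "<root>"
        lines.append(f"  {loc}: {err['msg']} (got {err.get('input')!r})")
    return "configuration invalid:\n" + "\n".join(lines)


def load_config(path: str | Path | None = None) -> ModelConfig:
    """Load and validate a YAML model configuration.

    With no path, returns the bundled case-study configuration. All
    validation problems are reported together, not just the first.
    """
    if path is None:
        from .synthetic import make_case_config

        return make_case_config()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return ModelConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from exc


def save_config(config: ModelConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
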