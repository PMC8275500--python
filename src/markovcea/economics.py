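"""Valuation of a cohort trace: utilities, costs, discounting, ICERs.

Per-cycle state occupancies are weighted by health-state utilities and
unit costs, discounted at the guideline rates, and summed into totals;
strategy pairs are compared through the incremental cost-effectiveness
ratio (ICER), net monetary benefit, and the proportional-shortfall
willingness-to-pay class.

All core accumulators are written against arrays of shape
``(n_cycles, n_draws)`` so a deterministic run and a 10,000-draw
probabilistic run share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import CostSchedule, DiscountSpec, UtilitySet
from .markov import DAYS_PER_YEAR, CohortTrace

__all__ = [
    "OutcomeTotals",
    "ICERResult",
    "discount_factor",
    "discount_factors",
    "accumulate_qalys",
    "accumulate_costs",
    "icer",
    "net_monetary_benefit",
    "proportional_shortfall",
    "round_to_hundreds",
]


def round_to_hundreds(x: float) -> float:
    return float(np.round(x / 100.0) * 100.0)


def _sum_cycles(per_cycle: np.ndarray) -> np.ndarray:
    """Sum per-cycle increments sequentially over the cycle axis.

    Plain ``np.sum(..., axis=0)`` picks its pairwise-summation blocking
    from the array shape, so a batch of identical columns would not sum
    bit-identically to a single column; strict cycle order makes a
    degenerate PSA reproduce the deterministic totals exactly.
    """
    total = np.zeros(per_cycle.shape[1], dtype=float)
    for c in range(per_cycle.shape[0]):
        total += per_cycle[c]
    return total


# ---------------------------------------------------------------------------
# discounting
# ---------------------------------------------------------------------------


def discount_factors(annual_rate: float, n_cycles: int,
                     cycle_days: float) -> np.ndarray:
    """Per-cycle discount factors ``(1 + r)^(-c * cycle_days / 365.25)``.

    Cycle 0 is undiscounted. The 4%/1.5% annual guideline rates
    correspond to roughly 0.3%/0.11% per 28-day cycle.
    """
    cycles = np.arange(n_cycles)
    return (1.0 + annual_rate) ** (-cycles * cycle_days / DAYS_PER_YEAR)


def discount_factor(spec: DiscountSpec, which: str, cycle_index: int,
                    cycle_days: float = 28.0) -> float:
    """Discount factor for a single cycle; ``which`` is 'costs' or 'effects'."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    if which == "costs":
        rate = spec.annual_rate_costs
    elif which == "effects":
        rate = spec.annual_rate_effects
    else:
        raise ValueError("which must be 'costs' or 'effects'")
    return float((1.0 + rate) ** (-cycle_index * cycle_days / DAYS_PER_YEAR))


# ---------------------------------------------------------------------------
# vectorized accumulator cores
# ---------------------------------------------------------------------------


def qaly_core(occ_sd, occ_pd, active, *, cycle_days, rate_effects,
              u_sd, u_sd_ae, ae_fraction, ae_window, u_pd):
    """Discounted QALYs and life-years from occupancy paths.

    Arrays are ``(n_cycles, ...)``; utility parameters may be scalars or
    per-draw arrays. During the adverse-event window (treatment start)
    the SD utility is the blend of the plain and AE-affected values
    weighted by the affected fraction; life-years value every alive
    state at utility 1.
    """
    occ_sd = np.atleast_2d(occ_sd)
    occ_pd = np.atleast_2d(occ_pd)
    active = np.atleast_2d(active)
    n_cycles = occ_sd.shape[0]
    dt = cycle_days / DAYS_PER_YEAR
    disc = discount_factors(rate_effects, n_cycles, cycle_days)[:, None]

    u_sd = np.asarray(u_sd, dtype=float)
    u_sd_ae = np.asarray(u_sd_ae, dtype=float)
    u_blend = (1.0 - ae_fraction) * u_sd + ae_fraction * u_sd_ae
    in_window = (np.arange(n_cycles) < ae_window)[:, None]
    u_sd_eff = np.where(in_window, u_blend, u_sd)

    qaly = _sum_cycles(active * (occ_sd * u_sd_eff + occ_pd * u_pd) * dt * disc)
    ly = _sum_cycles(active * (occ_sd + occ_pd) * dt * disc)
    return qaly, ly


def cost_core(occ_sd, occ_pd, new_dead, active, *, cycle_days, rate_costs,
              arm, price_scenario, start_age,
              lo_price_initial, lo_price_increased, lo_injection_cycles,
              lo_n_injections, lo_admin, olar_cycle, ae_management,
              pd_followup_visit, pd_followup_interval_months,
              indirect_annual_at_start, indirect_growth, indirect_eol):
    """Discounted total cost from occupancy paths for one arm.

    Components per cycle (all occupancy-weighted and cost-discounted):
    radionuclide injections at the scheduled cycles in SD (intervention
    only, price per treatment split over the injections), somatostatin-
    analogue drug+administration in SD, the 6-monthly follow-up visit
    pro-rated per cycle in PD, age-indexed indirect unrelated medical
    costs for every alive patient, end-of-life indirect costs for the
    newly dead, and a one-time adverse-event management cost at cycle 0.
    """
    occ_sd = np.atleast_2d(occ_sd)
    occ_pd = np.atleast_2d(occ_pd)
    new_dead = np.atleast_2d(new_dead)
    active = np.atleast_2d(active)
    n_cycles = occ_sd.shape[0]
    dt = cycle_days / DAYS_PER_YEAR
    disc = discount_factors(rate_costs, n_cycles, cycle_days)[:, None]

    per_cycle = np.zeros_like(occ_sd)

    # somatostatin analogue while in stable disease
    per_cycle = per_cycle + np.asarray(olar_cycle) * occ_sd

    if arm == "intervention":
        if price_scenario == "initial":
            price = lo_price_initial
        elif price_scenario == "increased":
            price = lo_price_increased
        else:
            raise ValueError(
                f"price_scenario must be 'initial' or 'increased'; got {price_scenario!r}"
            )
        inj = np.zeros((n_cycles, 1))
        for c in lo_injection_cycles:
            if c < n_cycles:
                inj[c, 0] = 1.0
        per_injection = np.asarray(price) / lo_n_injections + np.asarray(lo_admin)
        per_cycle = per_cycle + inj * per_injection * occ_sd

    # follow-up visits in progressive disease, pro-rated per cycle
    interval_cycles = pd_followup_interval_months * (DAYS_PER_YEAR / 12.0) / cycle_days
    per_cycle = per_cycle + np.asarray(pd_followup_visit) / interval_cycles * occ_pd

    # indirect unrelated medical costs: age-indexed annual cost for the
    # alive, end-of-life component for the newly dead
    ages = start_age + np.arange(n_cycles) * cycle_days / DAYS_PER_YEAR
    growth = (1.0 + indirect_growth) ** (ages - start_age)
    annual = np.asarray(indirect_annual_at_start) * growth[:, None]
    per_cycle = per_cycle + annual * dt * (occ_sd + occ_pd)
    per_cycle = per_cycle + np.asarray(indirect_eol) * new_dead

    total = _sum_cycles(active * per_cycle * disc)
    # adverse-event management, all charged at treatment start
    total = total + np.asarray(ae_management) * np.ones(total.shape)
    return total


# ---------------------------------------------------------------------------
# trace-facing operations
# ---------------------------------------------------------------------------


def _trace_arrays(trace: CohortTrace, threshold: float = 0.99):
    occ_sd = trace.occ_sd[:-1][:, None]
    occ_pd = trace.occ_pd[:-1][:, None]
    new_dead = trace.new_deaths[:, None]
    active = (trace.occ_dead[:-1] <= threshold)[:, None]
    return occ_sd, occ_pd, new_dead, active


def accumulate_qalys(trace: CohortTrace, utilities: UtilitySet,
                     spec: DiscountSpec, arm: str) -> tuple[float, float]:
    """Discounted (QALYs, life-years) for one cohort trace."""
    if arm == "control":
        u_ae = utilities.u_sd_ae_control
        frac = utilities.ae_affected_fraction_control
    elif arm == "intervention":
        u_ae = utilities.u_sd_ae_intervention
        frac = utilities.ae_affected_fraction_intervention
    else:
        raise ValueError(f"arm must be 'control' or 'intervention'; got {arm!r}")
    occ_sd, occ_pd, _, active = _trace_arrays(trace)
    qaly, ly = qaly_core(
        occ_sd, occ_pd, active,
        cycle_days=trace.cycle_days, rate_effects=spec.annual_rate_effects,
        u_sd=utilities.u_sd, u_sd_ae=u_ae, ae_fraction=frac,
        ae_window=utilities.ae_window_cycles, u_pd=utilities.u_pd,
    )
    return float(qaly[0]), float(ly[0])


def accumulate_costs(trace: CohortTrace, costs: CostSchedule,
                     spec: DiscountSpec, arm: str,
                     price_scenario: str | None = None) -> float:
    """Discounted total cost for one cohort trace."""
    if arm == "intervention" and price_scenario is None:
        raise ValueError("price_scenario is required for the intervention arm")
    if arm == "control":
        olar = costs.olar_cycle_control
        ae = costs.ae_management_control
    elif arm == "intervention":
        olar = costs.olar_cycle_intervention
        ae = costs.ae_management_intervention
    else:
        raise ValueError(f"arm must be 'control' or 'intervention'; got {arm!r}")
    occ_sd, occ_pd, new_dead, active = _trace_arrays(trace)
    total = cost_core(
        occ_sd, occ_pd, new_dead, active,
        cycle_days=trace.cycle_days, rate_costs=spec.annual_rate_costs,
        arm=arm, price_scenario=price_scenario or "initial",
        start_age=trace.start_age,
        lo_price_initial=costs.lo_price_initial,
        lo_price_increased=costs.lo_price_increased,
        lo_injection_cycles=costs.lo_injection_cycles,
        lo_n_injections=costs.lo_n_injections,
        lo_admin=costs.lo_admin_per_injection,
        olar_cycle=olar, ae_management=ae,
        pd_followup_visit=costs.pd_followup_visit,
        pd_followup_interval_months=costs.pd_followup_interval_months,
        indirect_annual_at_start=costs.indirect.annual_at_start_age,
        indirect_growth=costs.indirect.annual_growth_per_year,
        indirect_eol=costs.indirect.end_of_life,
    )
    return float(total[0])


# ---------------------------------------------------------------------------
# comparison statistics
# ---------------------------------------------------------------------------


@dataclass
class OutcomeTotals:
    """Discounted totals for one strategy under one price scenario."""

    strategy: str
    cost: float
    qaly: float
    life_years: float
    price_scenario: str | None = None
    wtp_threshold: float = 80000.0

    def __post_init__(self) -> None:
        if self.cost < 0 or self.qaly < 0 or self.life_years < 0:
            raise ValueError("totals must be non-negative")
        if self.qaly > self.life_years + 1e-9:
            raise ValueError("QALYs cannot exceed life-years")


@dataclass
class ICERResult:
    """Incremental cost-effectiveness ratio with dominance handling.

    ``value`` is rounded to the nearest hundred euros for reporting;
    ``raw`` keeps the unrounded ratio. When the incremental effect is
    non-positive the ratio is not meaningful and ``flag`` says which
    quadrant the pair falls in instead.
    """

    delta_cost: float
    delta_effect: float
    effect_unit: str = "qaly"
    flag: str | None = None

    @property
    def raw(self) -> float:
        if self.flag in ("dominant", "dominated", "undefined"):
            return float("nan")
        return self.delta_cost / self.delta_effect

    @property
    def value(self) -> float:
        r = self.raw
        return float("nan") if np.isnan(r) else round_to_hundreds(r)

    def __float__(self) -> float:
        return self.value


def icer(a: OutcomeTotals, b: OutcomeTotals, effect: str = "qaly") -> ICERResult:
    """ICER of strategy ``a`` versus ``b``: (cost_a - cost_b)/(E_a - E_b).

    Rounding to hundreds applies only at reporting (the ``value``
    property); internal comparisons should use ``raw``. Quadrant cases:
    ``dominant`` (cheaper and at least as effective), ``dominated``
    (costlier and no more effective), ``undefined`` (equal effects with
    equal costs handled as 0 only when costs are also equal).
    """
    if effect == "qaly":
        d_e = a.qaly - b.qaly
    elif effect in ("ly", "lyg"):
        d_e = a.life_years - b.life_years
    else:
        raise ValueError("effect must be 'qaly' or 'ly'")
    d_c = a.cost - b.cost
    flag = None
    if d_e <= 0:
        if d_e == 0 and d_c == 0:
            flag = None  # identical strategies: ICER 0 by convention
            d_e = 1.0
            d_c = 0.0
        elif d_c < 0:
            flag = "dominant" if d_e == 0 else "undefined"
        elif d_e < 0 <= d_c:
            flag = "dominated"
        else:
            flag = "undefined"
    return ICERResult(delta_cost=d_c, delta_effect=d_e, effect_unit=effect, flag=flag)


def net_monetary_benefit(a: OutcomeTotals, b: OutcomeTotals, wtp: float) -> float:
    """NMB of ``a`` vs ``b``: ``wtp * dQALY - dCost``; positive iff ICER < wtp."""
    if wtp < 0:
        raise ValueError("willingness to pay must be non-negative")
    return wtp * (a.qaly - b.qaly) - (a.cost - b.cost)


def proportional_shortfall(disease_qalys: float, remaining_qale_healthy: float,
                           class_boundaries: tuple[float, float, float] = (0.10, 0.41, 0.71),
                           class_thresholds: tuple[float, float, float] = (20000.0, 50000.0, 80000.0),
                           ) -> tuple[float, float]:
    """Burden-of-disease proportional shortfall and the applicable WTP class.

    The shortfall is the fraction of remaining quality-adjusted life
    expectancy lost to the disease, clamped to [0, 1], and is mapped to
    the Dutch three-class reference values for willingness to pay (the
    highest class, 80,000 euro/QALY, applies from a shortfall of 0.71).
    """
    if disease_qalys < 0 or remaining_qale_healthy <= 0:
        raise ValueError("QALY inputs must be non-negative with positive healthy QALE")
    shortfall = (remaining_qale_healthy - disease_qalys) / remaining_qale_healthy
    shortfall = float(np.clip(shortfall, 0.0, 1.0))
    wtp = class_thresholds[0]
    for bound, thr in zip(class_boundaries[1:], class_thresholds[1:]):
        if shortfall >= bound:
            wtp = thr
    return shortfall, float(wtp)
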