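"""Sensitivity analysis: probabilistic (PSA), one-way tornado, scenarios.

The PSA propagates parameter uncertainty through the model by plain
Monte-Carlo sampling of independent parameter draws: beta distributions
for utilities and probabilities (moment-matched to the mean and 95%
interval, interval width treated as 3.92 standard deviations), gamma for
costs (sd = 20% of the mean when no interval is published), lognormal
for hazard ratios. Parameters published without intervals get the
assumed 80-120% band. Draw order follows the declared parameter order,
which together with the seed is the reproducibility contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ModelConfig
from .economics import ICERResult, OutcomeTotals, icer, round_to_hundreds
from .engine import evaluate_strategy

__all__ = [
    "ParameterSpec",
    "PsaResult",
    "TornadoEntry",
    "parameter_specs",
    "sample_parameters",
    "run_psa",
    "ceac",
    "tornado",
    "run_scenario",
    "run_deterministic",
]

PRICE_SCENARIOS = ("initial", "increased")


# ---------------------------------------------------------------------------
# parameter specifications
# ---------------------------------------------------------------------------


@dataclass
class ParameterSpec:
    """One uncertain model input.

    ``low``/``high`` are the 95% interval used both for distribution
    fitting (PSA) and as the tornado bounds. ``dist`` is ``beta``
    (utilities, probabilities), ``gamma`` (costs), ``lognormal`` (hazard
    ratios) or ``fixed``.
    """

    name: str
    mean: float
    dist: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low <= self.mean <= self.high:
            raise ValueError(
                f"{self.name}: mean {self.mean} outside bounds "
                f"({self.low}, {self.high})"
            )
        if self.dist == "beta" and not (0 <= self.low and self.high <= 1):
            raise ValueError(f"{self.name}: beta support violated by bounds")
        if self.dist in ("gamma", "lognormal") and self.low < 0:
            raise ValueError(f"{self.name}: negative bound for {self.dist}")

    @property
    def sd(self) -> float:
        return (self.high - self.low) / 3.92

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` values; degenerate specs return constants."""
        m, s = self.mean, self.sd
        if self.dist == "fixed" or s == 0 or m == 0 and self.dist != "beta":
            return np.full(n, m)
        if self.dist == "beta":
            v = s * s
            if v >= m * (1 - m):
                raise ValueError(f"{self.name}: variance too large for a beta")
            k = m * (1 - m) / v - 1.0
            return rng.beta(m * k, (1 - m) * k, size=n)
        if self.dist == "gamma":
            shape = (m / s) ** 2
            return rng.gamma(shape, m / shape, size=n)
        if self.dist == "lognormal":
            sigma = (np.log(self.high) - np.log(self.low)) / 3.92
            mu = np.log(m) - 0.5 * sigma * sigma
            return rng.lognormal(mu, sigma, size=n)
        raise ValueError(f"{self.name}: unknown distribution '{self.dist}'")


def _band(mean: float, rel: float) -> tuple[float, float]:
    return mean * (1 - rel), mean * (1 + rel)


def parameter_specs(config: ModelConfig) -> list[ParameterSpec]:
    """The declared, ordered list of uncertain parameters.

    Transition probabilities and utilities use their published 95%
    intervals where available; everything else gets the assumed 80-120%
    band. Unit costs are sampled with a 20% coefficient of variation.
    The radionuclide list price is the policy variable under study and
    is never sampled.
    """
    tp, ut, co = config.transitions, config.utilities, config.costs
    rel = config.psa.default_interval
    cv = config.psa.cost_cv

    def prob(name, mean, ci):
        lo, hi = ci if ci is not None else _band(mean, rel)
        return ParameterSpec(name, mean, "beta", lo, hi)

    def cost(name, mean):
        # 95% interval implied by the cost cv, for tornado bounds
        return ParameterSpec(name, mean, "gamma", *_band(mean, 1.96 * cv))

    specs = [
        prob("p_sd_pd_control", tp.sd_pd_control, None),
        prob("p_sd_pd_intervention", tp.sd_pd_intervention, tp.ci_sd_pd_intervention),
        prob("p_sd_d_control", tp.sd_d_control, None),
        prob("p_sd_d_intervention", tp.sd_d_intervention, tp.ci_sd_d_intervention),
        prob("p_pd_d_control", tp.pd_d_control, None),
        prob("p_pd_d_intervention", tp.pd_d_intervention, tp.ci_pd_d_intervention),
        ParameterSpec("u_sd", ut.u_sd, "beta", *ut.u_sd_range),
        ParameterSpec("u_sd_ae_control", ut.u_sd_ae_control, "beta",
                      *ut.u_sd_ae_control_range),
        ParameterSpec("u_sd_ae_intervention", ut.u_sd_ae_intervention, "beta",
                      *ut.u_sd_ae_intervention_range),
        ParameterSpec("u_pd", ut.u_pd, "beta", *ut.u_pd_range),
        cost("olar_cycle_control", co.olar_cycle_control),
        cost("olar_cycle_intervention", co.olar_cycle_intervention),
        cost("lo_admin_per_injection", co.lo_admin_per_injection),
        cost("ae_management_control", co.ae_management_control),
        cost("ae_management_intervention", co.ae_management_intervention),
        cost("pd_followup_visit", co.pd_followup_visit),
        cost("indirect_annual", co.indirect.annual_at_start_age),
        cost("indirect_end_of_life", co.indirect.end_of_life),
    ]
    return specs


def sample_parameters(specs: list[ParameterSpec], seed: int,
                      n: int = 1) -> dict[str, np.ndarray]:
    """One joint draw (or ``n`` joint draws) from all parameter distributions.

    Draws are independent across parameters and taken in declared order
    from a single seeded generator, so the same seed always reproduces
    the same joint draw.
    """
    rng = np.random.default_rng(seed)
    return {spec.name: spec.sample(rng, n) for spec in specs}


# ---------------------------------------------------------------------------
# deterministic evaluation helpers
# ---------------------------------------------------------------------------


def run_deterministic(config: ModelConfig,
                      overrides: dict | None = None) -> dict:
    """Evaluate both arms at both price levels with parameters at their means.

    Returns ``{(strategy, price_scenario): OutcomeTotals}``; the control
    arm carries no price scenario but is keyed per scenario for symmetry.
    """
    out: dict[tuple[str, str], OutcomeTotals] = {}
    for arm in ("control", "intervention"):
        for price in PRICE_SCENARIOS:
            if arm == "control" and price == "increased":
                out[(arm, price)] = out[(arm, "initial")]
                continue
            c, q, ly = evaluate_strategy(config, arm, price, overrides)
            out[(arm, price)] = OutcomeTotals(
                strategy=arm, cost=float(c[0]), qaly=float(q[0]),
                life_years=float(ly[0]),
                price_scenario=price if arm == "intervention" else None,
                wtp_threshold=config.wtp_threshold,
            )
    return out


def _pair_icer(totals: dict, price: str, effect: str = "qaly") -> ICERResult:
    return icer(totals[("intervention", price)], totals[("control", price)], effect)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class PsaResult:
    """Paired incremental draws from the probabilistic sensitivity analysis.

    ``delta_cost[scenario]`` and ``delta_qaly[scenario]`` hold one entry
    per draw for each price scenario (effects are price-invariant, so
    ``delta_qaly`` is shared). Feeds the CE plane, CEAC and
    probability-of-cost-effectiveness summaries.
    """

    n_draws: int
    seed: int
    delta_cost: dict[str, np.ndarray]
    delta_qaly: np.ndarray
    delta_ly: np.ndarray
    wtp_threshold: float = 80000.0
    n_redraws: int = 0
    draws: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def probability_cost_effective(self, wtp: float, scenario: str = "increased") -> float:
        """Fraction of draws with positive net monetary benefit at ``wtp``."""
        nmb = wtp * self.delta_qaly - self.delta_cost[scenario]
        return float(np.mean(nmb > 0))

    def ce_plane_frame(self) -> pd.DataFrame:
        frames = []
        for scen in PRICE_SCENARIOS:
            frames.append(pd.DataFrame({
                "draw": np.arange(self.n_draws),
                "scenario": scen,
                "d_cost": self.delta_cost[scen],
                "d_qaly": self.delta_qaly,
            }))
        return pd.concat(frames, ignore_index=True)

    def plot_ce_plane(self, ax=None, wtp: float | None = None):
        from .plotting import plot_ce_plane

        return plot_ce_plane(self, ax=ax, wtp=wtp)

    def plot_ceac(self, wtp_grid=None, ax=None):
        from .plotting import plot_ceac

        grid = np.arange(0, 120001, 1000) if wtp_grid is None else wtp_grid
        return plot_ceac(ceac(self, grid), ax=ax)


def run_psa(config: ModelConfig, n: int | None = None,
            seed: int | None = None,
            specs: list[ParameterSpec] | None = None) -> PsaResult:
    """Monte-Carlo parameter uncertainty propagation.

    For every draw the transition schedules are rebuilt, both arms run,
    and the incremental cost and effect recorded under both price
    levels. Draws whose sampled parameters produce an invalid schedule
    (SD row exceeding probability 1) are rejected and redrawn from the
    stream's continuation; the count is reported on the result.
    """
    n = config.psa.n_draws if n is None else int(n)
    seed = config.psa.seed if seed is None else int(seed)
    specs = parameter_specs(config) if specs is None else specs
    rng = np.random.default_rng(seed)

    draws = {s.name: s.sample(rng, n) for s in specs}
    n_redraws = 0
    for _ in range(100):
        bad = np.zeros(n, dtype=bool)
        for armname in ("control", "intervention"):
            if f"p_sd_pd_{armname}" in draws and f"p_sd_d_{armname}" in draws:
                bad |= (draws[f"p_sd_pd_{armname}"]
                        + draws[f"p_sd_d_{armname}"] >= 1.0)
        if not bad.any():
            break
        n_bad = int(bad.sum())
        n_redraws += n_bad
        redraw = {s.name: s.sample(rng, n_bad) for s in specs}
        for k in draws:
            draws[k][bad] = redraw[k]
    else:
        raise RuntimeError("could not find valid parameter draws")

    cost = {}
    qaly = {}
    ly = {}
    for arm in ("control", "intervention"):
        prices = PRICE_SCENARIOS if arm == "intervention" else ("initial",)
        for price in prices:
            c, q, l = evaluate_strategy(config, arm, price, dict(draws))
            cost[(arm, price)] = c
            qaly[arm] = q
            ly[arm] = l
    d_qaly = qaly["intervention"] - qaly["control"]
    d_ly = ly["intervention"] - ly["control"]
    d_cost = {
        scen: cost[("intervention", scen)] - cost[("control", "initial")]
        for scen in PRICE_SCENARIOS
    }
    return PsaResult(n_draws=n, seed=seed, delta_cost=d_cost, delta_qaly=d_qaly,
                     delta_ly=d_ly, wtp_threshold=config.wtp_threshold,
                     n_redraws=n_redraws, draws=draws)


def ceac(psa: PsaResult, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve table.

    One row per willingness-to-pay grid point per price scenario with
    the fraction of draws whose net monetary benefit is positive.
    """
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    rows = []
    for scen in PRICE_SCENARIOS:
        nmb = wtp_grid[:, None] * psa.delta_qaly[None, :] - psa.delta_cost[scen][None, :]
        prob = np.mean(nmb > 0, axis=1)
        rows.append(pd.DataFrame({"wtp": wtp_grid, "scenario": scen,
                                  "probability": prob}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# one-way (tornado) analysis
# ---------------------------------------------------------------------------


@dataclass
class TornadoEntry:
    """ICER range produced by one parameter swept to its bounds.

    ``icer_low_bound``/``icer_high_bound`` are rounded to hundreds for
    reporting (the published presentation); ``raw_low``/``raw_high``
    keep the unrounded ratios, and ``width`` — the sort key — is the
    unrounded bar width. A bar whose unrounded width is below the
    hundred-euro reporting resolution is a zero-width bar once rounded.
    """

    parameter: str
    icer_low_bound: float
    icer_high_bound: float
    icer_base: float
    raw_low: float = float("nan")
    raw_high: float = float("nan")
    flagged: str | None = None

    @property
    def width(self) -> float:
        return abs(self.raw_high - self.raw_low)

    @property
    def rounded_width(self) -> float:
        return round_to_hundreds(self.width)


def tornado(config: ModelConfig, specs: list[ParameterSpec] | None = None,
            price_scenario: str = "increased") -> list[TornadoEntry]:
    """One-way deterministic sensitivity analysis.

    Each parameter is set to its lower and upper bound in turn (all
    others at their means) and the deterministic ICER recomputed; bars
    are sorted by width, widest first. ICERs are reported rounded to
    hundreds, as in the published tornado. A bound producing a dominance
    quadrant flags the entry instead of dropping it.
    """
    specs = parameter_specs(config) if specs is None else specs
    base_totals = run_deterministic(config)
    base = _pair_icer(base_totals, price_scenario)

    entries = []
    for spec in specs:
        vals = []
        flag = None
        for bound in (spec.low, spec.high):
            totals = run_deterministic(config, {spec.name: bound})
            res = _pair_icer(totals, price_scenario)
            if res.flag is not None:
                flag = f"{spec.name} at {bound:g}: {res.flag}"
            vals.append(res)
        entries.append(TornadoEntry(
            parameter=spec.name,
            icer_low_bound=vals[0].value,
            icer_high_bound=vals[1].value,
            icer_base=base.value,
            raw_low=vals[0].raw,
            raw_high=vals[1].raw,
            flagged=flag,
        ))
    # flagged (dominance) entries sort first: their influence is unbounded
    entries.sort(key=lambda e: np.inf if np.isnan(e.width) else e.width,
                 reverse=True)
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": e.parameter,
        "icer_low": e.icer_low_bound,
        "icer_high": e.icer_high_bound,
        "icer_base": e.icer_base,
        "width": e.width,
        "flagged": e.flagged,
    } for e in entries])


# ---------------------------------------------------------------------------
# named scenarios
# ---------------------------------------------------------------------------


def run_scenario(config: ModelConfig, scenario: str) -> dict:
    """Run one named scenario: a single documented config mutation.

    Returns the outcome totals for both arms and price levels plus the
    resulting ICERs, in the same layout as the deterministic base case.
    """
    cfg = config.with_scenario(scenario)
    totals = run_deterministic(cfg)
    return {
        "scenario": scenario,
        "totals": totals,
        "icer_qaly": {p: _pair_icer(totals, p, "qaly") for p in PRICE_SCENARIOS},
        "icer_ly": {p: _pair_icer(totals, p, "ly") for p in PRICE_SCENARIOS},
    }
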