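"""Vectorized model evaluation.

One code path evaluates the table-driven Markov model for a whole batch
of parameter draws at once: probabilities, utilities and unit costs may
each be a scalar (deterministic run) or an array of draws (PSA,
tornado). The cycle loop runs over at most the 60-year guard horizon and
stops early once every draw's cohort is absorbed.
"""

from __future__ import annotations

import numpy as np

from .config import ModelConfig
from .economics import cost_core, qaly_core
from .markov import DAYS_PER_YEAR, gamma_hazard_weights, max_cycles
from .survival import DAYS_PER_MONTH

__all__ = ["evaluate_strategy", "simulate_paths", "override_paths"]


def override_paths(q_model: np.ndarray, q_lt: np.ndarray, mode: str) -> np.ndarray:
    """Background-mortality override along whole probability paths.

    ``q_model`` is ``(n_cycles, n_draws)``; ``q_lt`` the life-table
    per-cycle probability path ``(n_cycles,)``. In ``switch`` mode the
    life-table value replaces the model value permanently from each
    draw's first crossing cycle; ``max`` mode takes the per-cycle
    maximum.
    """
    q_lt_col = q_lt[:, None]
    if mode == "max":
        return np.maximum(q_model, q_lt_col)
    crossed = q_lt_col > q_model
    any_cross = crossed.any(axis=0)
    first = np.where(any_cross, crossed.argmax(axis=0), q_model.shape[0])
    idx = np.arange(q_model.shape[0])[:, None]
    return np.where(idx >= first[None, :], q_lt_col, q_model)


def simulate_paths(p_prog: np.ndarray, q_sd: np.ndarray, q_pd: np.ndarray,
                   *, absorption_threshold: float = 0.99,
                   prog_cutoff_cycle: int | None = None):
    """Run the cohort forward for every draw simultaneously.

    Parameters
    ----------
    p_prog
        SD -> PD probability per draw, shape ``(n_draws,)`` (constant
        over time, exponential profile).
    q_sd, q_pd
        Death probability paths, shape ``(n_cycles, n_draws)``.
    prog_cutoff_cycle
        If set, progression stops from this cycle on (trial follow-up
        not extrapolated).

    Returns occupancy paths at cycle starts, the newly-dead fraction per
    cycle and the active mask (cohort not yet >99% absorbed at cycle
    start), each ``(n_cycles, n_draws)``, truncated at the cycle where
    every draw is absorbed.
    """
    n_cycles, n = q_sd.shape
    p_prog = np.broadcast_to(np.asarray(p_prog, dtype=float), (n,))

    occ_sd = np.zeros((n_cycles, n))
    occ_pd = np.zeros((n_cycles, n))
    new_dead = np.zeros((n_cycles, n))
    active = np.zeros((n_cycles, n), dtype=bool)

    sd = np.ones(n)
    pd_ = np.zeros(n)
    dead = np.zeros(n)
    end = n_cycles
    for c in range(n_cycles):
        act = dead <= absorption_threshold
        if not act.any():
            end = c
            break
        occ_sd[c] = sd
        occ_pd[c] = pd_
        active[c] = act
        prog = p_prog if (prog_cutoff_cycle is None or c < prog_cutoff_cycle) else 0.0
        prog = np.minimum(prog, 1.0 - q_sd[c])
        nd = sd * q_sd[c] + pd_ * q_pd[c]
        sd, pd_, dead = (sd * (1.0 - prog - q_sd[c]),
                         sd * prog + pd_ * (1.0 - q_pd[c]),
                         dead + nd)
        new_dead[c] = nd
    return occ_sd[:end], occ_pd[:end], new_dead[:end], active[:end]


def _death_paths(q0, weights: np.ndarray, n: int) -> np.ndarray:
    """Anchor a cycle-0 death probability on the gamma hazard profile."""
    q0 = np.broadcast_to(np.asarray(q0, dtype=float), (n,))
    return 1.0 - (1.0 - q0[None, :]) ** weights[:, None]


def evaluate_strategy(config: ModelConfig, arm: str, price_scenario: str,
                      overrides: dict[str, np.ndarray] | None = None):
    """Evaluate one strategy: discounted (cost, qaly, life-years) per draw.

    ``overrides`` maps sensitivity-parameter names (see
    :func:`markovcea.sensitivity.parameter_specs`) to scalars or
    ``(n_draws,)`` arrays; anything not overridden sits at its
    configured deterministic mean. Scenario flags on the config
    (discounting, follow-up cutoff, override mode, indirect costs) are
    honoured here so scenario runs remain single config mutations.
    """
    if arm not in ("control", "intervention"):
        raise ValueError(f"arm must be 'control' or 'intervention'; got {arm!r}")
    ov = dict(overrides or {})
    tp = config.transitions
    ut = config.utilities
    co = config.costs

    def P(name, default):
        return np.asarray(ov.pop(name, default), dtype=float)

    p_prog = P(f"p_sd_pd_{arm}", getattr(tp, f"sd_pd_{arm}"))
    q_sd0 = P(f"p_sd_d_{arm}", getattr(tp, f"sd_d_{arm}"))
    q_pd0 = P(f"p_pd_d_{arm}", getattr(tp, f"pd_d_{arm}"))
    u_sd = P("u_sd", ut.u_sd)
    u_sd_ae = P(f"u_sd_ae_{arm}", getattr(ut, f"u_sd_ae_{arm}"))
    u_pd = P("u_pd", ut.u_pd)
    olar = P(f"olar_cycle_{arm}", getattr(co, f"olar_cycle_{arm}"))
    lo_admin = P("lo_admin_per_injection", co.lo_admin_per_injection)
    ae_cost = P(f"ae_management_{arm}", getattr(co, f"ae_management_{arm}"))
    pd_visit = P("pd_followup_visit", co.pd_followup_visit)
    ind_annual = P("indirect_annual", co.indirect.annual_at_start_age)
    ind_eol = P("indirect_end_of_life", co.indirect.end_of_life)
    # overrides for the other arm's parameters are legitimately unused here
    known_other = {k for k in ov if k.endswith(("_control", "_intervention"))}
    unknown = set(ov) - known_other
    if unknown:
        raise KeyError(f"unknown parameter overrides: {sorted(unknown)}")

    n = max(np.size(v) for v in
            (p_prog, q_sd0, q_pd0, u_sd, u_sd_ae, u_pd, olar, lo_admin,
             ae_cost, pd_visit, ind_annual, ind_eol))

    n_cycles = max_cycles(config.cycle_days)
    weights = gamma_hazard_weights(tp.gamma_shape, tp.gamma_rate, n_cycles,
                                   config.cycle_days)
    lt = config.life_table_object()
    ages = (config.population.start_age
            + np.arange(n_cycles) * config.cycle_days / DAYS_PER_YEAR)
    q_lt = np.array([
        lt.cycle_probability(a, config.cycle_days, config.population.male_fraction)
        for a in ages
    ])

    q_sd = override_paths(_death_paths(q_sd0, weights, n), q_lt,
                          config.life_table_override)
    q_pd = override_paths(_death_paths(q_pd0, weights, n), q_lt,
                          config.life_table_override)

    cutoff = None
    if config.scenario == "no_extrapolation":
        cutoff = int(np.ceil(config.followup_months * DAYS_PER_MONTH
                             / config.cycle_days))

    occ_sd, occ_pd, new_dead, active = simulate_paths(
        p_prog, q_sd, q_pd,
        absorption_threshold=config.absorption_threshold,
        prog_cutoff_cycle=cutoff,
    )

    if arm == "control":
        ae_frac = ut.ae_affected_fraction_control
    else:
        ae_frac = ut.ae_affected_fraction_intervention

    qaly, ly = qaly_core(
        occ_sd, occ_pd, active,
        cycle_days=config.cycle_days,
        rate_effects=config.discounting.annual_rate_effects,
        u_sd=u_sd, u_sd_ae=u_sd_ae, ae_fraction=ae_frac,
        ae_window=ut.ae_window_cycles, u_pd=u_pd,
    )
    cost = cost_core(
        occ_sd, occ_pd, new_dead, active,
        cycle_days=config.cycle_days,
        rate_costs=config.discounting.annual_rate_costs,
        arm=arm, price_scenario=price_scenario,
        start_age=config.population.start_age,
        lo_price_initial=co.lo_price_initial,
        lo_price_increased=co.lo_price_increased,
        lo_injection_cycles=co.lo_injection_cycles,
        lo_n_injections=co.lo_n_injections,
        lo_admin=lo_admin, olar_cycle=olar, ae_management=ae_cost,
        pd_followup_visit=pd_visit,
        pd_followup_interval_months=co.pd_followup_interval_months,
        indirect_annual_at_start=ind_annual,
        indirect_growth=co.indirect.annual_growth_per_year,
        indirect_eol=ind_eol,
    )
    return cost, qaly, ly
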