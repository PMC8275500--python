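"""Model/Results interface to the cost-effectiveness analysis.

:class:`CostEffectivenessModel` wraps a validated configuration;
``fit()`` evaluates the deterministic model for both strategies and
price levels and returns a :class:`CEResults` carrying the discounted
totals, the ICERs and a summary table. Probabilistic, one-way and
scenario analyses hang off the model object.

Example
-------
>>> from markovcea import CostEffectivenessModel
>>> model = CostEffectivenessModel.from_config()   # bundled case study
>>> res = model.fit()
>>> print(res.summary())                           # doctest: +SKIP
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ModelConfig, load_config
from .economics import (
    ICERResult,
    OutcomeTotals,
    net_monetary_benefit,
    proportional_shortfall,
)
from .sensitivity import (
    PRICE_SCENARIOS,
    PsaResult,
    ceac,
    run_deterministic,
    run_psa,
    run_scenario,
    tornado,
    tornado_frame,
)

__all__ = ["CostEffectivenessModel", "CEResults", "run_pipeline"]


class CostEffectivenessModel:
    """Three-state Markov cohort cost-effectiveness model.

    Parameters
    ----------
    config
        A validated :class:`~markovcea.config.ModelConfig`. Use
        :meth:`from_config` to build from a YAML file or to get the
        bundled case-study configuration.
    """

    def __init__(self, config: ModelConfig):
        self.config = config

    @classmethod
    def from_config(cls, path: str | Path | ModelConfig | None = None
                    ) -> "CostEffectivenessModel":
        if isinstance(path, ModelConfig):
            return cls(path)
        return cls(load_config(path))

    # -- estimation ---------------------------------------------------------

    def fit(self) -> "CEResults":
        """Deterministic evaluation at the parameter means."""
        totals = run_deterministic(self.config)
        return CEResults(model=self, totals=totals)

    # -- analyses -----------------------------------------------------------

    def run_psa(self, n: int | None = None, seed: int | None = None) -> PsaResult:
        return run_psa(self.config, n=n, seed=seed)

    def tornado(self, price_scenario: str = "increased"):
        return tornado(self.config, price_scenario=price_scenario)

    def scenario(self, name: str) -> "CEResults":
        cfg = self.config.with_scenario(name)
        sub = CostEffectivenessModel(cfg)
        res = sub.fit()
        res.scenario_name = name
        return res

    def config_hash(self) -> str:
        blob = json.dumps(self.config.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class CEResults:
    """Deterministic results: totals per strategy/price, ICERs, summary."""

    model: CostEffectivenessModel
    totals: dict[tuple[str, str], OutcomeTotals]
    scenario_name: str | None = None

    def outcome(self, strategy: str, price_scenario: str = "increased") -> OutcomeTotals:
        return self.totals[(strategy, price_scenario)]

    def icer(self, price_scenario: str = "increased", effect: str = "qaly") -> ICERResult:
        from .economics import icer as _icer

        return _icer(self.totals[("intervention", price_scenario)],
                     self.totals[("control", price_scenario)], effect)

    def nmb(self, price_scenario: str = "increased",
            wtp: float | None = None) -> float:
        wtp = self.model.config.wtp_threshold if wtp is None else wtp
        return net_monetary_benefit(self.totals[("intervention", price_scenario)],
                                    self.totals[("control", price_scenario)], wtp)

    def proportional_shortfall(self, remaining_qale_healthy: float = 18.9
                               ) -> tuple[float, float]:
        """Burden-of-disease shortfall of the untreated course vs healthy QALE.

        Uses the comparator arm's modelled QALY total as the disease
        outlook; the healthy quality-adjusted life expectancy at the
        cohort age is a config-level judgement, defaulting to 18.9 QALYs.
        """
        return proportional_shortfall(self.totals[("control", "initial")].qaly,
                                      remaining_qale_healthy)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for price in PRICE_SCENARIOS:
            for strategy in ("control", "intervention"):
                t = self.totals[(strategy, price)]
                rows.append({
                    "strategy": strategy, "price_scenario": price,
                    "cost": t.cost, "qaly": t.qaly, "life_years": t.life_years,
                })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text results table in the published layout."""
        cfg = self.model.config
        lines = []
        title = "Cost-effectiveness results (discounted)"
        if self.scenario_name:
            title += f" — scenario: {self.scenario_name}"
        lines.append(title)
        lines.append("=" * 78)
        lines.append(f"{'Strategy':<28}{'Costs (EUR)':>14}{'QALY':>8}{'LYG':>8}"
                     f"{'ICER/QALY':>14}{'ICER/LYG':>10}")
        lines.append("-" * 78)
        ctrl = self.totals[("control", "initial")]
        lines.append(f"{'High-dose O-LAR':<28}{ctrl.cost:>14,.0f}{ctrl.qaly:>8.2f}"
                     f"{ctrl.life_years:>8.2f}{'--':>14}{'--':>10}")
        for price in PRICE_SCENARIOS:
            t = self.totals[("intervention", price)]
            iq = self.icer(price, "qaly")
            il = self.icer(price, "ly")
            label = f"LO + O-LAR ({price} price)"
            iq_s = f"{iq.value:,.0f}" if not np.isnan(iq.value) else iq.flag
            il_s = f"{il.value:,.0f}" if not np.isnan(il.value) else il.flag
            lines.append(f"{label:<28}{t.cost:>14,.0f}{t.qaly:>8.2f}"
                         f"{t.life_years:>8.2f}{iq_s:>14}{il_s:>10}")
        lines.append("-" * 78)
        lines.append(f"WTP threshold: EUR {cfg.wtp_threshold:,.0f}/QALY; "
                     f"cycle {cfg.cycle_days:.0f} days; cohort "
                     f"{cfg.population.cohort_size} aged {cfg.population.start_age:.0f}; "
                     f"discounting {cfg.discounting.annual_rate_costs:.1%} costs / "
                     f"{cfg.discounting.annual_rate_effects:.1%} effects")
        lines.append("Costs and ICERs rounded at reporting; ICERs to the nearest hundred.")
        return "\n".join(lines)


def run_pipeline(config: ModelConfig, out_dir: str | Path | None = None,
                 psa_n: int | None = None, seed: int | None = None) -> dict:
    """Run the full deterministic + probabilistic pipeline.

    Evaluates both strategies under both price levels, runs the PSA and
    the named scenarios, and (optionally) writes the report files and a
    run manifest (config hash, seed, version) to ``out_dir``. Returns
    everything as a dict of in-memory objects.
    """
    model = CostEffectivenessModel(config)
    results = model.fit()
    psa = model.run_psa(n=psa_n, seed=seed)
    wtp_grid = np.arange(0.0, 120001.0, 1000.0)
    ceac_df = ceac(psa, wtp_grid)
    torn = model.tornado()
    scenarios = {name: run_scenario(config, name)
                 for name in ("equal_discount_4", "no_discount", "no_extrapolation",
                              "no_indirect_costs", "general_population_survival")}
    manifest = {
        "config_hash": model.config_hash(),
        "seed": psa.seed,
        "n_draws": psa.n_draws,
        "version": __version__,
    }
    report = {
        "results": results,
        "psa": psa,
        "ceac": ceac_df,
        "tornado": torn,
        "scenarios": scenarios,
        "manifest": manifest,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_frame().to_csv(out / "outcome_totals.csv", index=False)
        psa.ce_plane_frame().to_csv(out / "ce_plane.csv", index=False)
        ceac_df.to_csv(out / "ceac.csv", index=False)
        tornado_frame(torn).to_csv(out / "tornado.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        with open(out / "summary.txt", "w") as fh:
            fh.write(results.summary() + "\n")
    return report
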