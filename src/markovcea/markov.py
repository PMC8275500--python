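"""Three-state Markov cohort engine: SD -> PD -> Dead.

Builds per-cycle transition schedules for each treatment strategy and runs
the discrete-time cohort simulation. Transitions can come either from
fitted survival curves (splitting the overall-survival hazard between the
stable-disease and progressive-disease states) or directly from a table of
printed per-cycle probabilities with a parametric time profile.

State order is fixed: 0 = stable disease (SD), 1 = progressive disease
(PD), 2 = Dead. Dead is absorbing and PD -> SD re-entry is not modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .survival import (
    DAYS_PER_MONTH,
    HazardRatioSet,
    ParametricSurvival,
    apply_hazard_ratio,
    cycle_probability,
)

STATES = ("SD", "PD", "Dead")
DAYS_PER_YEAR = 365.25

#: hard numerical guard on the simulation length (years); the >99%-absorbed
#: termination rule ends traces far earlier in practice
MAX_HORIZON_YEARS = 60.0

#: cohort is considered fully absorbed once the dead fraction exceeds this
ABSORPTION_THRESHOLD = 0.99

__all__ = [
    "STATES",
    "LifeTable",
    "TransitionSchedule",
    "CohortTrace",
    "split_death_probability",
    "derive_transitions",
    "schedule_from_table",
    "run_cohort",
    "gamma_hazard_weights",
    "max_cycles",
]


def max_cycles(cycle_days: float) -> int:
    return int(np.ceil(MAX_HORIZON_YEARS * DAYS_PER_YEAR / cycle_days))


# ---------------------------------------------------------------------------
# life table
# ---------------------------------------------------------------------------


class LifeTable:
    """Age- and sex-specific annual mortality of the general population.

    Stores one annual death probability per (age, sex) and serves
    cohort-blended per-cycle probabilities. Ages must be contiguous per
    sex; the final age is treated as absorbing (probability 1 is allowed
    but not required -- queries beyond the last age return the last value).
    """

    def __init__(self, ages: np.ndarray, q_male: np.ndarray, q_female: np.ndarray):
        ages = np.asarray(ages, dtype=int)
        q_male = np.asarray(q_male, dtype=float)
        q_female = np.asarray(q_female, dtype=float)
        if not (len(ages) == len(q_male) == len(q_female)):
            raise ValueError("ages and probability columns must align")
        if np.any(np.diff(ages) != 1):
            raise ValueError("life-table ages must be contiguous")
        for q in (q_male, q_female):
            if np.any((q < 0) | (q > 1)):
                raise ValueError("annual mortality probabilities must lie in [0, 1]")
        self.ages = ages
        self.q_male = q_male
        self.q_female = q_female

    @classmethod
    def from_rows(cls, rows) -> "LifeTable":
        """Build from (age, sex, annual_mortality) triples ('male'/'female')."""
        male = {int(a): float(q) for a, s, q in rows if str(s).lower().startswith("m")}
        female = {int(a): float(q) for a, s, q in rows if str(s).lower().startswith("f")}
        if set(male) != set(female):
            raise ValueError("male and female rows must cover the same ages")
        ages = np.array(sorted(male))
        return cls(ages, np.array([male[a] for a in ages]),
                   np.array([female[a] for a in ages]))

    @classmethod
    def from_dataframe(cls, df) -> "LifeTable":
        return cls.from_rows(df[["age", "sex", "annual_mortality"]].itertuples(index=False))

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def annual_probability(self, age: float, male_fraction: float = 0.5) -> float:
        """Cohort-blended annual death probability at (possibly fractional) age."""
        idx = int(np.clip(np.floor(age), self.ages[0], self.ages[-1]) - self.ages[0])
        return float(male_fraction * self.q_male[idx]
                     + (1.0 - male_fraction) * self.q_female[idx])

    def cycle_probability(self, age: float, cycle_days: float,
                          male_fraction: float = 0.5) -> float:
        """Per-cycle death probability at constant hazard within the year."""
        q = self.annual_probability(age, male_fraction)
        if q >= 1.0:
            return 1.0
        return 1.0 - (1.0 - q) ** (cycle_days / DAYS_PER_YEAR)

    def covers(self, age_lo: float, age_hi: float) -> bool:
        """Whether the table can serve every age in the span.

        A table whose final age carries probability 1 is absorbing, so
        any age beyond it is vacuously covered.
        """
        if age_lo < self.ages[0]:
            return False
        if age_hi <= self.ages[-1]:
            return True
        return bool(self.q_male[-1] >= 1.0 and self.q_female[-1] >= 1.0)


# ---------------------------------------------------------------------------
# transition schedule
# ---------------------------------------------------------------------------


@dataclass
class TransitionSchedule:
    """Per-cycle transition probabilities for one strategy.

    Stored compactly as the three free probabilities per cycle; the full
    3x3 row-stochastic matrix is materialized on demand. Dead is absorbing
    and PD -> SD does not occur.
    """

    p_sd_pd: np.ndarray
    p_sd_d: np.ndarray
    p_pd_d: np.ndarray
    strategy: str = ""
    cycle_days: float = 28.0

    def __post_init__(self) -> None:
        self.p_sd_pd = np.asarray(self.p_sd_pd, dtype=float)
        self.p_sd_d = np.asarray(self.p_sd_d, dtype=float)
        self.p_pd_d = np.asarray(self.p_pd_d, dtype=float)
        n = len(self.p_sd_pd)
        if not (len(self.p_sd_d) == len(self.p_pd_d) == n):
            raise ValueError("probability arrays must share a length")
        for name, arr in (("p_sd_pd", self.p_sd_pd), ("p_sd_d", self.p_sd_d),
                          ("p_pd_d", self.p_pd_d)):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} outside [0, 1]")
        if np.any(self.p_sd_pd + self.p_sd_d > 1.0 + 1e-12):
            k = int(np.argmax(self.p_sd_pd + self.p_sd_d > 1.0 + 1e-12))
            raise ValueError(f"SD row exceeds probability 1 at cycle {k}")

    @property
    def n_cycles(self) -> int:
        return len(self.p_sd_pd)

    def matrix(self, cycle: int) -> np.ndarray:
        """Full 3x3 row-stochastic matrix for one cycle."""
        p_pd = self.p_sd_pd[cycle]
        q_sd = self.p_sd_d[cycle]
        q_pd = self.p_pd_d[cycle]
        return np.array([
            [1.0 - p_pd - q_sd, p_pd, q_sd],
            [0.0, 1.0 - q_pd, q_pd],
            [0.0, 0.0, 1.0],
        ])

    def matrices(self) -> np.ndarray:
        return np.stack([self.matrix(c) for c in range(self.n_cycles)])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "cycle": np.arange(self.n_cycles),
            "p_sd_pd": self.p_sd_pd,
            "p_sd_d": self.p_sd_d,
            "p_pd_d": self.p_pd_d,
        })


@dataclass
class CohortTrace:
    """State occupancy over time for one simulated cohort.

    ``occupancy`` has one row per cycle start (row 0 is the initial
    distribution); ``new_deaths[c]`` is the fraction dying during cycle c.
    The trace ends at the first cycle start with more than 99% of the
    cohort absorbed, or at the hard 60-year cap.
    """

    occupancy: np.ndarray
    new_deaths: np.ndarray
    cycle_days: float = 28.0
    start_age: float = 63.0
    cohort_size: int = 1000
    strategy: str = ""
    terminated_by_absorption: bool = field(default=True)

    def __post_init__(self) -> None:
        self.occupancy = np.atleast_2d(np.asarray(self.occupancy, dtype=float))
        self.new_deaths = np.asarray(self.new_deaths, dtype=float)
        sums = self.occupancy.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("occupancy rows must sum to 1")

    @property
    def n_cycles(self) -> int:
        """Number of completed cycles (occupancy rows minus one)."""
        return self.occupancy.shape[0] - 1

    @property
    def occ_sd(self) -> np.ndarray:
        return self.occupancy[:, 0]

    @property
    def occ_pd(self) -> np.ndarray:
        return self.occupancy[:, 1]

    @property
    def occ_dead(self) -> np.ndarray:
        return self.occupancy[:, 2]

    def ages(self) -> np.ndarray:
        return self.start_age + np.arange(self.occupancy.shape[0]) * self.cycle_days / DAYS_PER_YEAR

    def to_dataframe(self):
        import pandas as pd

        rows = self.occupancy.shape[0]
        nd = np.concatenate([self.new_deaths, [np.nan] * (rows - len(self.new_deaths))])
        return pd.DataFrame({
            "cycle": np.arange(rows),
            "age": self.ages(),
            "occ_sd": self.occ_sd,
            "occ_pd": self.occ_pd,
            "occ_dead": self.occ_dead,
            "new_deaths": nd,
        })


# ---------------------------------------------------------------------------
# hazard split
# ---------------------------------------------------------------------------


def split_death_probability(p_os: float, share_sd: float, hr_sd_vs_pd: float,
                            tol: float = 1e-14) -> tuple[float, float]:
    """Split an overall per-cycle death probability between SD and PD.

    Finds per-cycle death probabilities ``(p_sd, p_pd)`` whose underlying
    hazards are in the ratio ``hr_sd_vs_pd`` (SD relative to PD) and whose
    occupancy-weighted mean over the alive states equals ``p_os``:

        share_sd * p_sd + (1 - share_sd) * p_pd = p_os,
        p_sd = 1 - exp(-r h),  p_pd = 1 - exp(-h).

    Solved by bisection on the PD cycle hazard h (monotone in h).
    """
    if not 0.0 <= p_os < 1.0:
        raise ValueError(f"p_os must lie in [0, 1); got {p_os}")
    if not 0.0 <= share_sd <= 1.0:
        raise ValueError("share_sd must lie in [0, 1]")
    if hr_sd_vs_pd <= 0:
        raise ValueError("hr_sd_vs_pd must be positive")
    if p_os == 0.0:
        return 0.0, 0.0
    r = hr_sd_vs_pd

    def weighted(h: float) -> float:
        return (share_sd * (1.0 - np.exp(-r * h))
                + (1.0 - share_sd) * (1.0 - np.exp(-h)))

    hi = 1.0
    while weighted(hi) < p_os:
        hi *= 2.0
        if hi > 1e8:  # p_os effectively 1 for this mix
            warnings.warn("death split clamped: target probability unattainable",
                          stacklevel=2)
            break
    lo = 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if weighted(mid) < p_os:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, hi):
            break
    h = 0.5 * (lo + hi)
    return float(1.0 - np.exp(-r * h)), float(1.0 - np.exp(-h))


# ---------------------------------------------------------------------------
# schedule construction
# ---------------------------------------------------------------------------


def _override_life_table(q_model: float, q_lt: float, engaged: bool,
                         mode: str) -> tuple[float, bool]:
    """Background-mortality floor: general-population mortality replaces the
    disease-model probability once it exceeds it.

    ``switch`` mode (default) replaces permanently from the first crossing;
    ``max`` mode takes the per-cycle maximum.
    """
    if mode == "max":
        return max(q_model, q_lt), False
    if engaged or q_lt > q_model:
        return q_lt, True
    return q_model, False


def derive_transitions(pfs: ParametricSurvival, os: ParametricSurvival,
                       hrs: HazardRatioSet, lt: LifeTable, strategy: str,
                       n_cycles: int, *, cycle_days: float = 28.0,
                       start_age: float = 63.0, male_fraction: float = 0.5,
                       start: tuple[float, float, float] = (1.0, 0.0, 0.0),
                       override_mode: str = "switch") -> TransitionSchedule:
    """Build a transition schedule from fitted comparator-arm survival curves.

    Per cycle, the overall-survival curve gives the death probability among
    the alive cohort (multiplied by ``hr_os`` on the hazard scale for the
    intervention strategy); it is split between SD and PD with hazards in
    ratio ``hr_sd_vs_pd`` using the evolving occupancy as weights. The
    SD -> PD probability is the PFS event probability (times ``hr_pfs`` for
    intervention) in excess of SD death. From the first cycle where the
    age-specific life-table probability exceeds a state's model death
    probability, the life-table value is used instead.
    """
    if strategy not in ("control", "intervention"):
        raise ValueError("strategy must be 'control' or 'intervention'")
    end_age = start_age + n_cycles * cycle_days / DAYS_PER_YEAR
    if not lt.covers(start_age, min(end_age, start_age + MAX_HORIZON_YEARS)):
        raise ValueError(
            f"life table covers ages {lt.ages[0]}..{lt.ages[-1]} but the "
            f"simulation needs {start_age:.0f}..{end_age:.0f}"
        )
    intervention = strategy == "intervention"

    occ = np.array(start, dtype=float)
    p_sd_pd = np.zeros(n_cycles)
    p_sd_d = np.zeros(n_cycles)
    p_pd_d = np.zeros(n_cycles)
    engaged_sd = engaged_pd = False

    for c in range(n_cycles):
        p_os = cycle_probability(os, c, cycle_days)
        p_pfs = cycle_probability(pfs, c, cycle_days)
        if intervention:
            p_os = apply_hazard_ratio(p_os, hrs.hr_os)
            p_pfs = apply_hazard_ratio(p_pfs, hrs.hr_pfs)

        alive = occ[0] + occ[1]
        share_sd = occ[0] / alive if alive > 0 else 1.0
        q_sd, q_pd = split_death_probability(p_os, share_sd, hrs.hr_sd_vs_pd)

        age = start_age + c * cycle_days / DAYS_PER_YEAR
        q_lt = lt.cycle_probability(age, cycle_days, male_fraction)
        q_sd, engaged_sd = _override_life_table(q_sd, q_lt, engaged_sd, override_mode)
        q_pd, engaged_pd = _override_life_table(q_pd, q_lt, engaged_pd, override_mode)

        prog = max(0.0, p_pfs - q_sd)
        if prog + q_sd > 1.0:
            warnings.warn(f"SD row clamped at cycle {c}", stacklevel=2)
            prog = 1.0 - q_sd

        p_sd_pd[c], p_sd_d[c], p_pd_d[c] = prog, q_sd, q_pd

        occ = np.array([
            occ[0] * (1.0 - prog - q_sd),
            occ[0] * prog + occ[1] * (1.0 - q_pd),
            occ[2] + occ[0] * q_sd + occ[1] * q_pd,
        ])

    return TransitionSchedule(p_sd_pd, p_sd_d, p_pd_d, strategy=strategy,
                              cycle_days=cycle_days)


def gamma_hazard_weights(shape: float, rate: float, n_cycles: int,
                         cycle_days: float = 28.0) -> np.ndarray:
    """Cycle-wise cumulative-hazard increments of a gamma survival curve,
    normalized so the first cycle has weight 1.

    Used to give table-sourced death probabilities the time profile of the
    fitted gamma overall-survival curve: the cycle-0 probability is
    anchored at the printed value and later cycles scale with these
    weights on the hazard scale.
    """
    surv = ParametricSurvival(family="gamma", params={"shape": shape, "rate": rate})
    edges = np.arange(n_cycles + 1) * cycle_days / DAYS_PER_MONTH
    with np.errstate(invalid="ignore"):
        ch = surv.cumulative_hazard(edges)
        inc = np.diff(ch)
    good = np.isfinite(inc) & (inc > 0)
    if not good[0]:
        raise ValueError("degenerate gamma profile: no hazard in first cycle")
    if not good.all():
        # survival underflows to 0 in double precision at extreme ages; hold
        # the last finite increment from there on
        first_bad = int(np.argmin(good))
        inc[first_bad:] = inc[first_bad - 1]
    return inc / inc[0]


def schedule_from_table(params, strategy: str, n_cycles: int, *,
                        override_mode: str = "switch") -> TransitionSchedule:
    """Build a transition schedule from printed per-cycle probabilities.

    ``params`` is a case-study fixture (see :mod:`markovcea.config`)
    carrying the six per-cycle probabilities with their time-profile
    annotations: SD -> PD is constant over time (exponential profile) and
    the two death probabilities follow the gamma hazard profile anchored at
    the printed cycle-0 values. The general-population mortality override
    applies exactly as in :func:`derive_transitions`.
    """
    if strategy not in ("control", "intervention"):
        raise ValueError("strategy must be 'control' or 'intervention'")
    tp = params.transitions
    lt = params.life_table_object()
    cycle_days = params.cycle_days
    start_age = params.population.start_age
    male_fraction = params.population.male_fraction

    if strategy == "control":
        p_prog, q_sd0, q_pd0 = tp.sd_pd_control, tp.sd_d_control, tp.pd_d_control
    else:
        p_prog, q_sd0, q_pd0 = tp.sd_pd_intervention, tp.sd_d_intervention, tp.pd_d_intervention
    for name, v in (("sd_pd", p_prog), ("sd_d", q_sd0), ("pd_d", q_pd0)):
        if v is None:
            raise ValueError(f"missing transition probability {name} for {strategy}")

    w = gamma_hazard_weights(tp.gamma_shape, tp.gamma_rate, n_cycles, cycle_days)
    # anchor the printed probability at cycle 0 and let the hazard evolve
    # with the gamma profile: q_c = 1 - (1 - q_0)^{w_c}
    q_sd = 1.0 - (1.0 - q_sd0) ** w
    q_pd = 1.0 - (1.0 - q_pd0) ** w

    ages = start_age + np.arange(n_cycles) * cycle_days / DAYS_PER_YEAR
    q_lt = np.array([lt.cycle_probability(a, cycle_days, male_fraction) for a in ages])
    q_sd = _apply_override_path(q_sd, q_lt, override_mode)
    q_pd = _apply_override_path(q_pd, q_lt, override_mode)

    p_sd_pd = np.minimum(np.full(n_cycles, p_prog), 1.0 - q_sd)
    return TransitionSchedule(p_sd_pd, q_sd, q_pd, strategy=strategy,
                              cycle_days=cycle_days)


def _apply_override_path(q_model: np.ndarray, q_lt: np.ndarray,
                         mode: str) -> np.ndarray:
    """Vectorized background-mortality override along a whole schedule."""
    if mode == "max":
        return np.maximum(q_model, q_lt)
    crossed = q_lt > q_model
    if not crossed.any():
        return q_model
    first = int(np.argmax(crossed))
    out = q_model.copy()
    out[first:] = q_lt[first:]
    return out


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def run_cohort(schedule: TransitionSchedule, start=(1.0, 0.0, 0.0), *,
               start_age: float = 63.0, cohort_size: int = 1000,
               strategy: str | None = None) -> CohortTrace:
    """Run the discrete-time cohort simulation.

    Occupancy evolves as ``occ(t+1) = occ(t) @ M(t)``. The trace stops at
    the first cycle start with more than 99% of the cohort dead, at the
    end of the schedule, or at the hard 60-year cap, whichever comes
    first. State membership is counted at cycle start (no half-cycle
    correction).
    """
    start = np.asarray(start, dtype=float)
    if start.shape != (3,) or abs(start.sum() - 1.0) > 1e-9 or np.any(start < 0):
        raise ValueError("start must be a 3-vector of non-negative fractions summing to 1")
    mats = schedule.matrices()
    for c, m in enumerate(mats):
        if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9) or np.any(m < -1e-15):
            raise ValueError(f"non-stochastic transition matrix at cycle {c}")

    cap = min(schedule.n_cycles, max_cycles(schedule.cycle_days))
    occ = [start]
    deaths = []
    absorbed = start[2] > ABSORPTION_THRESHOLD
    for c in range(cap):
        if absorbed:
            break
        cur = occ[-1]
        nxt = cur @ mats[c]
        deaths.append(nxt[2] - cur[2])
        occ.append(nxt)
        absorbed = nxt[2] > ABSORPTION_THRESHOLD
    return CohortTrace(
        occupancy=np.array(occ),
        new_deaths=np.array(deaths),
        cycle_days=schedule.cycle_days,
        start_age=start_age,
        cohort_size=cohort_size,
        strategy=strategy if strategy is not None else schedule.strategy,
        terminated_by_absorption=absorbed,
    )
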