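"""Survival-curve reconstruction and parametric fitting.

Digitized Kaplan-Meier curves (coordinates read off a published figure plus
the numbers-at-risk table printed underneath it) are converted back to
pseudo individual-patient data with the Guyot reconstruction algorithm.
Parametric families are then fitted to the pseudo-IPD by right-censored
maximum likelihood, and the fitted survival functions are converted into
per-cycle transition probabilities for the cohort model.

Times are handled in months throughout (30.4375 days per month); cycle
lengths given in days are converted on entry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

DAYS_PER_MONTH = 30.4375

__all__ = [
    "DAYS_PER_MONTH",
    "DigitizedKM",
    "PseudoIPD",
    "ParametricSurvival",
    "HazardRatioSet",
    "reconstruct_ipd",
    "fit_parametric",
    "select_best",
    "cycle_probability",
    "apply_hazard_ratio",
    "km_estimate",
    "SUPPORTED_FAMILIES",
]


class ReconstructionError(ValueError):
    """Raised when a digitized curve or risk table is internally inconsistent."""


class FitError(RuntimeError):
    """Raised when maximum-likelihood fitting is impossible or fails to converge."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class DigitizedKM:
    """Digitized survival curve: (time, survival) coordinates plus a risk table.

    Parameters
    ----------
    curve_points
        Sequence of ``(time_months, survival_fraction)`` pairs. The curve
        must start at ``(0, 1.0)`` and survival must be non-increasing.
    risk_table
        Sequence of ``(time_months, n_at_risk)`` pairs with non-increasing
        counts; at least two rows are required for reconstruction.
    label
        Free-text label (arm / endpoint) carried through to outputs.
    """

    curve_points: list[tuple[float, float]]
    risk_table: list[tuple[float, int]]
    label: str = ""

    def __post_init__(self) -> None:
        pts = [(float(t), float(s)) for t, s in self.curve_points]
        if not pts:
            raise ReconstructionError("curve_points is empty")
        if pts[0][0] != 0.0 or abs(pts[0][1] - 1.0) > 1e-9:
            raise ReconstructionError(
                f"curve must start at (0, 1.0); got {pts[0]}"
            )
        times = np.array([t for t, _ in pts])
        surv = np.array([s for _, s in pts])
        if np.any(times < 0):
            raise ReconstructionError("negative curve time")
        if np.any(np.diff(times) <= 0):
            raise ReconstructionError("curve times must be strictly increasing")
        if np.any(np.diff(surv) > 1e-9):
            k = int(np.argmax(np.diff(surv) > 1e-9))
            raise ReconstructionError(
                "survival increases between "
                f"t={times[k]:g} and t={times[k + 1]:g}"
            )
        if np.any(surv < 0) or np.any(surv > 1):
            raise ReconstructionError("survival fractions must lie in [0, 1]")
        rt = [(float(t), int(n)) for t, n in self.risk_table]
        if rt:
            rtimes = np.array([t for t, _ in rt])
            counts = np.array([n for _, n in rt])
            if np.any(rtimes < 0):
                raise ReconstructionError("negative risk-table time")
            if np.any(np.diff(rtimes) <= 0):
                raise ReconstructionError("risk-table times must be strictly increasing")
            if np.any(np.diff(counts) > 0):
                k = int(np.argmax(np.diff(counts) > 0))
                raise ReconstructionError(
                    f"risk-table counts increase between t={rtimes[k]:g} "
                    f"and t={rtimes[k + 1]:g}"
                )
            if np.any(counts < 0):
                raise ReconstructionError("negative at-risk count")
        self.curve_points = pts
        self.risk_table = rt

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.curve_points])

    @property
    def survival(self) -> np.ndarray:
        return np.array([s for _, s in self.curve_points])


@dataclass
class PseudoIPD:
    """Reconstructed pseudo individual-patient data.

    ``records`` holds ``(time_months, event_flag)`` pairs where the flag is
    1 for an observed event and 0 for right censoring.
    """

    records: list[tuple[float, int]]
    label: str = ""

    def __post_init__(self) -> None:
        recs = [(float(t), int(e)) for t, e in self.records]
        for t, e in recs:
            if t < 0:
                raise ValueError(f"negative record time {t}")
            if e not in (0, 1):
                raise ValueError(f"event flag must be 0 or 1, got {e}")
        self.records = recs

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.records])

    @property
    def events(self) -> np.ndarray:
        return np.array([e for _, e in self.records])

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def n_events(self) -> int:
        return int(self.events.sum()) if self.records else 0


@dataclass
class HazardRatioSet:
    """Treatment-effect hazard ratios applied to the comparator-arm curves.

    ``hr_pfs`` and ``hr_os`` act on the progression-free and overall
    survival hazards of the intervention arm; ``hr_sd_vs_pd`` is the
    mortality hazard in stable disease relative to progressive disease and
    drives the split of overall mortality between the two alive states.
    """

    hr_pfs: float = 0.21
    hr_os: float = 0.54
    hr_sd_vs_pd: float = 0.44
    ci_pfs: tuple[float, float] | None = (0.14, 0.33)
    ci_os: tuple[float, float] | None = None
    ci_sd_vs_pd: tuple[float, float] | None = (0.24, 0.79)

    def __post_init__(self) -> None:
        for name in ("hr_pfs", "hr_os", "hr_sd_vs_pd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("ci_pfs", "ci_os", "ci_sd_vs_pd"):
            ci = getattr(self, name)
            if ci is not None:
                lo, hi = ci
                mean = getattr(self, name.replace("ci_", "hr_"))
                if not (lo < mean < hi):
                    raise ValueError(f"{name} bounds must bracket the mean")


# ---------------------------------------------------------------------------
# Kaplan-Meier helper
# ---------------------------------------------------------------------------


def km_estimate(ipd: PseudoIPD) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit estimate from pseudo-IPD.

    Returns step times (event times only) and the survival value just after
    each step. Censored observations reduce the risk set between steps.
    """
    times = ipd.times
    events = ipd.events
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    s = 1.0
    out_t, out_s = [], []
    n_risk = len(times)
    i = 0
    while i < len(times):
        t = times[i]
        d = 0
        c = 0
        while i < len(times) and times[i] == t:
            if events[i]:
                d += 1
            else:
                c += 1
            i += 1
        if d > 0:
            s *= 1.0 - d / n_risk
            out_t.append(t)
            out_s.append(s)
        n_risk -= d + c
    return np.array(out_t), np.array(out_s)


def km_survival_at(ipd: PseudoIPD, times: np.ndarray) -> np.ndarray:
    """Evaluate the step KM estimate of ``ipd`` at arbitrary times."""
    st, ss = km_estimate(ipd)
    times = np.asarray(times, dtype=float)
    if len(st) == 0:
        return np.ones_like(times)
    idx = np.searchsorted(st, times, side="right")
    vals = np.concatenate([[1.0], ss])
    return vals[idx]


def n_at_risk(ipd: PseudoIPD, t: float) -> int:
    """Number of subjects still under observation just before time ``t``."""
    return int(np.sum(ipd.times >= t))


# ---------------------------------------------------------------------------
# Guyot reconstruction
# ---------------------------------------------------------------------------


def reconstruct_ipd(km: DigitizedKM, total_events: int | None = None) -> PseudoIPD:
    """Reconstruct pseudo individual-patient data from a digitized KM curve.

    Implements the interval-wise allocation algorithm: within each interval
    between consecutive numbers-at-risk rows, the number censored is
    adjusted iteratively until the implied at-risk count at the next row
    matches the published count exactly, while event counts at each
    digitized step are chosen so the product-limit recursion tracks the
    digitized survival values. Censoring is spread uniformly within each
    interval. When ``total_events`` is supplied, censoring in the final
    interval is rescaled so the reconstructed total matches it.

    Raises
    ------
    ReconstructionError
        If the risk table has fewer than two rows or is inconsistent with
        the digitized curve (implied events exceeding the at-risk count).
    """
    if len(km.risk_table) < 2:
        raise ReconstructionError("risk table needs at least 2 rows")

    t = km.times
    s = km.survival
    K = len(t)
    rt_times = np.array([x for x, _ in km.risk_table])
    rt_n = np.array([n for _, n in km.risk_table])
    n_int = len(rt_times)

    # interval i covers digitized points with time in (rt_times[i], rt_times[i+1]]:
    # a drop printed exactly at a risk-table time reflects events occurring
    # before that count was taken, so it belongs to the preceding interval
    lower = np.searchsorted(t, rt_times, side="right")
    # horizon for terminal censoring: last observed time on either axis
    t_end = max(t[-1], rt_times[-1])

    d = np.zeros(K, dtype=int)          # events at each digitized time
    cens_times_all: list[float] = []

    n_hat = rt_n[0]
    km_prev = 1.0  # reconstructed KM value entering the interval

    for i in range(n_int):
        lo = lower[i]
        hi = lower[i + 1] if i + 1 < n_int else K
        last = i + 1 >= n_int

        if not last:
            # initial censoring guess assumes the published drop in n at risk
            # beyond what pure events would explain
            s_lo = s[min(lo, K - 1)]
            s_hi = s[min(hi, K - 1)]
            guess = int(round(n_hat * (s_hi / s_lo if s_lo > 0 else 0.0))) - rt_n[i + 1]
            c_i = max(0, guess)
        else:
            c_i = 0

        t_lo = rt_times[i]
        t_hi = rt_times[i + 1] if not last else t_end

        best = None
        for _ in range(n_hat + 2):  # censoring count can only range 0..n_hat
            c_i = int(min(max(c_i, 0), n_hat))
            if c_i > 0 and t_hi > t_lo:
                ct = t_lo + (np.arange(1, c_i + 1) / (c_i + 1)) * (t_hi - t_lo)
            else:
                ct = np.array([])
            d_int = np.zeros(hi - lo, dtype=int)
            n_k = n_hat
            km_k = km_prev
            # censorings falling before the interval's first digitized point
            # leave the risk set ahead of any event in the interval
            if ct.size and lo < K:
                n_k -= int(np.sum(ct < t[lo]))
            for j, k in enumerate(range(lo, hi)):
                if n_k <= 0:
                    break
                if km_k > 0 and s[k] < km_k:
                    d_k = int(round(n_k * (1.0 - s[k] / km_k)))
                    d_k = min(max(d_k, 0), n_k)
                else:
                    d_k = 0
                if d_k > 0:
                    km_k *= 1.0 - d_k / n_k
                d_int[j] = d_k
                # censorings falling before the next digitized time leave the risk set
                t_next = t[k + 1] if k + 1 < K else np.inf
                c_k = int(np.sum((ct >= t[k]) & (ct < t_next))) if ct.size else 0
                n_k -= d_k + c_k
            if ct.size and lo >= K:
                n_k -= int(ct.size)
            if last:
                best = (c_i, d_int, ct, n_k, km_k)
                break
            mismatch = n_k - rt_n[i + 1]
            if best is None or abs(mismatch) < abs(best[0]):
                best = (mismatch, c_i, d_int, ct, n_k, km_k)
            if mismatch == 0:
                break
            c_i += mismatch

        if last:
            c_i, d_int, ct, n_k, km_k = best
        else:
            mismatch, c_i, d_int, ct, n_k, km_k = best
            if n_k < 0:
                raise ReconstructionError(
                    f"implied events exceed the at-risk count in interval "
                    f"[{t_lo:g}, {t_hi:g}) (published n drops {n_hat}->{rt_n[i + 1]})"
                )
            if mismatch != 0:
                # digitization rounding can leave an irreducible off-by-one;
                # keep the best allocation and carry the reconstructed count
                warnings.warn(
                    f"risk table matched to within {mismatch} in interval "
                    f"[{t_lo:g}, {t_hi:g})",
                    stacklevel=2,
                )

        d[lo:hi] = d_int
        cens_times_all.extend(ct.tolist())
        n_hat = n_k
        km_prev = km_k

    # subjects still at risk beyond the last interval are censored at the horizon
    terminal_censored = n_hat

    extra_events = 0
    if total_events is not None:
        got = int(d.sum())
        if got > total_events:
            # trim events at the latest steps, converting them to censorings
            excess = got - total_events
            for k in range(K - 1, -1, -1):
                take = min(excess, d[k])
                d[k] -= take
                cens_times_all.extend([t[k]] * take)
                excess -= take
                if excess == 0:
                    break
        elif got < total_events:
            # convert terminal censorings into late events at the horizon
            extra_events = min(total_events - got, terminal_censored)
            terminal_censored -= extra_events
            if got + extra_events < total_events:
                warnings.warn(
                    f"cannot reach total_events={total_events}; reconstructed "
                    f"{got + extra_events}",
                    stacklevel=2,
                )

    records: list[tuple[float, int]] = []
    eps = 1e-9 * max(t_end, 1.0)
    boundary = set(float(x) for x in rt_times if x > 0)
    for k in range(K):
        # events printed exactly at a risk-table time happened just before
        # the count was taken; nudge them below it so recomputed at-risk
        # numbers match the published table
        tk = float(t[k])
        if tk in boundary:
            tk -= eps
        records.extend([(tk, 1)] * int(d[k]))
    records.extend([(float(ct), 0) for ct in cens_times_all])
    records.extend([(float(t_end), 1)] * int(extra_events))
    records.extend([(float(t_end), 0)] * int(terminal_censored))
    records.sort()
    return PseudoIPD(records=records, label=km.label)


# ---------------------------------------------------------------------------
# parametric families
# ---------------------------------------------------------------------------

# Each family maps a parameter dict to a frozen scipy distribution on time
# in months. Parameter order matters: it is the optimization order and the
# order in serialized fit summaries.

_FAMILY_PARAMS: dict[str, tuple[str, ...]] = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "gamma": ("shape", "rate"),
    "gompertz": ("shape", "rate"),
    "lognormal": ("median", "sigma"),
    "loglogistic": ("shape", "scale"),
}

SUPPORTED_FAMILIES = tuple(_FAMILY_PARAMS)


def _frozen(family: str, params: dict[str, float]):
    if family == "exponential":
        return stats.expon(scale=1.0 / params["rate"])
    if family == "weibull":
        return stats.weibull_min(c=params["shape"], scale=params["scale"])
    if family == "gamma":
        return stats.gamma(a=params["shape"], scale=1.0 / params["rate"])
    if family == "gompertz":
        # sf(t) = exp(-(rate/shape) (e^{shape t} - 1))
        return stats.gompertz(c=params["rate"] / params["shape"], scale=1.0 / params["shape"])
    if family == "lognormal":
        return stats.lognorm(s=params["sigma"], scale=params["median"])
    if family == "loglogistic":
        return stats.fisk(c=params["shape"], scale=params["scale"])
    raise ValueError(f"unknown family '{family}'; choose from {SUPPORTED_FAMILIES}")


@dataclass
class ParametricSurvival:
    """A fitted parametric survival function.

    Attributes
    ----------
    family
        One of ``exponential, weibull, gamma, gompertz, lognormal,
        loglogistic``.
    params
        Family-specific parameters (all positive; time unit is months).
    log_likelihood, aic
        Right-censored log-likelihood at the optimum and ``2k - 2 logL``.
    """

    family: str
    params: dict[str, float]
    log_likelihood: float = float("nan")
    aic: float = float("nan")
    n: int = 0
    n_events: int = 0
    converged: bool = True
    _dist: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        want = _FAMILY_PARAMS.get(self.family)
        if want is None:
            raise ValueError(
                f"unknown family '{self.family}'; choose from {SUPPORTED_FAMILIES}"
            )
        missing = set(want) - set(self.params)
        if missing:
            raise ValueError(f"{self.family} needs parameters {want}; missing {missing}")
        for k in want:
            if not np.isfinite(self.params[k]) or self.params[k] <= 0:
                raise ValueError(f"parameter {k}={self.params[k]} must be positive")
        self._dist = _frozen(self.family, self.params)

    @property
    def n_params(self) -> int:
        return len(_FAMILY_PARAMS[self.family])

    def survival(self, t):
        """S(t); vectorized, S(0) = 1."""
        t = np.asarray(t, dtype=float)
        return self._dist.sf(np.maximum(t, 0.0))

    def hazard(self, t):
        """Instantaneous hazard f(t)/S(t)."""
        t = np.asarray(t, dtype=float)
        with np.errstate(divide="ignore", over="ignore"):
            return np.exp(self._dist.logpdf(t) - self._dist.logsf(t))

    def cumulative_hazard(self, t):
        t = np.asarray(t, dtype=float)
        return -self._dist.logsf(np.maximum(t, 0.0))

    def median(self) -> float:
        return float(self._dist.median())

    def param_tuple(self) -> tuple[float, ...]:
        return tuple(self.params[k] for k in _FAMILY_PARAMS[self.family])


def _neg_loglik(family: str, log_params: np.ndarray, times: np.ndarray,
                events: np.ndarray) -> float:
    names = _FAMILY_PARAMS[family]
    params = {k: float(np.exp(v)) for k, v in zip(names, log_params)}
    try:
        dist = _frozen(family, params)
    except Exception:
        return 1e12
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        ll_ev = dist.logpdf(times[events == 1])
        ll_cn = dist.logsf(times[events == 0])
    total = np.sum(ll_ev) + np.sum(ll_cn)
    if not np.isfinite(total):
        return 1e12
    return -float(total)


def _start_values(family: str, times: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Deterministic moment-matched starting values on the log scale."""
    exposure = times.sum()
    d = events.sum()
    rate0 = d / exposure if exposure > 0 else 1.0
    mean_ev = times[events == 1].mean()
    if family == "exponential":
        return np.log([rate0])
    if family in ("weibull", "loglogistic"):
        return np.log([1.0, mean_ev])
    if family == "gamma":
        return np.log([1.0, rate0])
    if family == "gompertz":
        return np.log([0.05, rate0])
    if family == "lognormal":
        return np.log([mean_ev, 1.0])
    raise ValueError(family)


def fit_parametric(ipd: PseudoIPD, family: str) -> ParametricSurvival:
    """Fit one parametric family to pseudo-IPD by right-censored ML.

    The exponential rate has the closed form events/exposure and is used
    directly; other families are optimized by L-BFGS-B on log-parameters
    from deterministic moment-matched starts (relative log-likelihood
    tolerance 1e-8), so repeated fits are bit-identical.
    """
    if family not in _FAMILY_PARAMS:
        raise ValueError(f"unknown family '{family}'; choose from {SUPPORTED_FAMILIES}")
    times = ipd.times
    events = ipd.events
    if events.sum() < 1:
        raise FitError("cannot fit a survival model to data with no events")
    if family != "exponential" and events.sum() < 2:
        raise FitError(f"{family} fitting needs at least 2 events")
    if np.any(times <= 0):
        # zero times break log-time families; nudge to a small positive value
        times = np.where(times <= 0, 1e-8, times)

    names = _FAMILY_PARAMS[family]
    if family == "exponential":
        rate = float(events.sum() / times.sum())
        params = {"rate": rate}
        ll = -_neg_loglik(family, np.log([rate]), times, events)
        return ParametricSurvival(
            family=family, params=params, log_likelihood=ll,
            aic=2 * 1 - 2 * ll, n=ipd.n, n_events=int(events.sum()),
        )

    x0 = _start_values(family, times, events)
    res = optimize.minimize(
        lambda lp: _neg_loglik(family, lp, times, events),
        x0,
        method="L-BFGS-B",
        bounds=[(-20.0, 20.0)] * len(x0),
        options={"ftol": 1e-8, "gtol": 1e-10, "maxiter": 500},
    )
    if not res.success and not np.isfinite(res.fun):
        raise FitError(
            f"{family} fit did not converge (final gradient norm "
            f"{np.linalg.norm(res.jac):.3g}): {res.message}"
        )
    params = {k: float(np.exp(v)) for k, v in zip(names, res.x)}
    ll = -float(res.fun)
    return ParametricSurvival(
        family=family, params=params, log_likelihood=ll,
        aic=2 * len(names) - 2 * ll, n=ipd.n, n_events=int(events.sum()),
        converged=bool(res.success),
    )


def select_best(ipd: PseudoIPD, families: list[str]) -> ParametricSurvival:
    """Fit each candidate family and return the minimum-AIC fit.

    Ties (within 1e-9 of AIC) are broken by fewer parameters, then by the
    order of ``families``. Individual fit failures are logged as warnings;
    the call fails only if every family fails.
    """
    if not families:
        raise ValueError("need at least one candidate family")
    fits: list[tuple[float, int, int, ParametricSurvival]] = []
    errors: list[str] = []
    for order, fam in enumerate(families):
        try:
            fit = fit_parametric(ipd, fam)
        except (FitError, ValueError) as exc:
            errors.append(f"{fam}: {exc}")
            warnings.warn(f"fit failed for {fam}: {exc}", stacklevel=2)
            continue
        fits.append((fit.aic, fit.n_params, order, fit))
    if not fits:
        raise FitError("all candidate families failed to fit: " + "; ".join(errors))
    fits.sort(key=lambda rec: (round(rec[0], 9), rec[1], rec[2]))
    return fits[0][3]


# ---------------------------------------------------------------------------
# cycle conversion
# ---------------------------------------------------------------------------


def cycle_probability(model: ParametricSurvival, cycle_index: int,
                      cycle_days: float) -> float:
    """Per-cycle event probability 1 - S(t1)/S(t0) for one model cycle.

    ``t0 = cycle_index * cycle_days`` and ``t1 = t0 + cycle_days``, with
    days converted to the model's month time unit. Returns 1 (with a
    warning) if survival has already reached zero at the cycle start.
    """
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    if cycle_days <= 0:
        raise ValueError("cycle_days must be positive")
    cycle_months = cycle_days / DAYS_PER_MONTH
    t0 = cycle_index * cycle_months
    s0 = float(model.survival(t0))
    if s0 <= 0.0:
        warnings.warn(
            f"survival already 0 at cycle {cycle_index}; returning probability 1",
            stacklevel=2,
        )
        return 1.0
    s1 = float(model.survival(t0 + cycle_months))
    return min(max(1.0 - s1 / s0, 0.0), 1.0 - 1e-15)


def apply_hazard_ratio(p: float, hr: float) -> float:
    """Apply a hazard ratio to a per-cycle probability.

    Assumes a constant hazard within the cycle, giving
    ``1 - (1 - p)**hr``. Identity at ``hr = 1``; undefined at ``p = 1``.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must lie in [0, 1); got {p}")
    if hr <= 0:
        raise ValueError(f"hazard ratio must be positive; got {hr}")
    # clamp below 1: extreme (p, hr) pairs saturate in double precision
    return min(1.0 - (1.0 - p) ** hr, np.nextafter(1.0, 0.0))
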