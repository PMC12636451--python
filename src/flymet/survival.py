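"""Gompertz decomposition of lifespan data.

The mortality model is the Gompertz hazard

    h(t) = alpha * exp(beta * t)

where ``alpha`` (per day) is baseline mortality at the start of adult life
(t = 0 at eclosion) and ``beta`` (per day) is the aging rate -- the
exponential increase in mortality risk with age.  Vial-census lifespan
records (deaths counted only at twice-weekly transfers) are first expanded
to per-fly event times, then analysed with:

* the Kaplan-Meier product-limit estimator (via lifelines),
* a kernel-smoothed empirical hazard (Epanechnikov smoothing of
  Nelson-Aalen increments with boundary reflection) used to check
  log-linearity of the hazard before trusting the parametric fit,
* right-censored Gompertz maximum likelihood with standard errors from the
  observed information, and
* pairwise Wald z-tests on fitted parameters with Holm correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .multitest import holm_adjust

__all__ = [
    "SurvivalTable",
    "EventTimes",
    "KaplanMeierResult",
    "HazardEstimate",
    "GompertzFit",
    "ParamComparison",
    "GompertzFitter",
    "KernelHazardEstimator",
    "impute_event_times",
    "kaplan_meier",
    "empirical_hazard",
    "loghazard_linearity",
    "fit_gompertz",
    "gompertz_loglik",
    "compare_parameters",
    "holm_adjust",
]

SURVIVAL_COLUMNS = ["genotype", "vial", "census_day", "deaths", "censored"]


# ---------------------------------------------------------------------------
# containers


@dataclass
class SurvivalTable:
    """Vial-census death counts: one row per (genotype, vial, census day).

    ``deaths`` are flies found dead at that census; ``censored`` flies were
    removed alive at that census.  Initial occupancy of a vial is the total
    of deaths and censorings ever recorded for it (every fly is followed
    until death or removal).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SURVIVAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"survival table missing columns: {missing}")
        df = self.data[SURVIVAL_COLUMNS].copy()
        if len(df) == 0:
            raise ValueError("empty survival table")
        if (df["census_day"] < 0).any():
            raise ValueError("census days must be >= 0")
        if (df["deaths"] < 0).any() or (df["censored"] < 0).any():
            raise ValueError("death/censor counts must be >= 0")
        for (_, _), grp in df.groupby(["genotype", "vial"]):
            days = grp["census_day"].to_numpy(dtype=float)
            if np.any(np.diff(days) <= 0):
                raise ValueError("census days must be strictly increasing within a vial")
        self.data = df

    @property
    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self.data["genotype"]))

    def initial_n(self) -> pd.Series:
        """Initial occupancy per (genotype, vial)."""
        g = self.data.groupby(["genotype", "vial"])
        return g["deaths"].sum() + g["censored"].sum()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SurvivalTable":
        return cls(pd.read_csv(path))


@dataclass
class EventTimes:
    """Per-fly event times for one genotype: death (event=1) or censoring (0)."""

    label: str
    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.times.shape != self.events.shape:
            raise ValueError("times and event indicators must have equal length")
        if np.any(self.times <= 0):
            raise ValueError("event times must be > 0")

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @property
    def death_times(self) -> np.ndarray:
        return self.times[self.events == 1]


@dataclass
class KaplanMeierResult:
    label: str
    times: np.ndarray          # step-change times (0 included)
    survival: np.ndarray       # S(t) immediately after each time
    median: float              # first t with S(t) <= 0.5; nan if never reached
    median_defined: bool


@dataclass
class HazardEstimate:
    grid_times: np.ndarray
    hazard: np.ndarray
    bandwidth: float
    n_events: int


@dataclass
class GompertzFit:
    label: str
    alpha: float
    beta: float
    se_alpha: float
    se_beta: float
    cov: np.ndarray
    loglik: float
    converged: bool
    n_events: int


@dataclass
class ParamComparison:
    pair: tuple[str, str]
    parameter: str
    z: float
    p_raw: float
    p_adj: float
    method: str = field(default="holm")


# ---------------------------------------------------------------------------
# census -> event times


def impute_event_times(table: SurvivalTable, rule: str = "interval_midpoint") -> dict[str, EventTimes]:
    """Expand census counts to per-fly event times.

    Deaths in the interval (previous census, census] are placed at the
    interval midpoint (default) or at the census day itself
    (``right_endpoint``).  Censored flies always carry their census day.
    The first interval opens at t = 0 (eclosion).
    """
    aliases = {"interval_midpoint": "interval_midpoint", "midpoint": "interval_midpoint",
               "right_endpoint": "right_endpoint", "right": "right_endpoint"}
    if rule not in aliases:
        raise ValueError(f"unknown imputation rule {rule!r}")
    rule = aliases[rule]

    out: dict[str, EventTimes] = {}
    for genotype, gdf in table.data.groupby("genotype", sort=False):
        times: list[float] = []
        events: list[int] = []
        for _, vdf in gdf.groupby("vial", sort=False):
            prev = 0.0
            for _, row in vdf.sort_values("census_day").iterrows():
                day = float(row["census_day"])
                rep = 0.5 * (prev + day) if rule == "interval_midpoint" else day
                times.extend([rep] * int(row["deaths"]))
                events.extend([1] * int(row["deaths"]))
                times.extend([day] * int(row["censored"]))
                events.extend([0] * int(row["censored"]))
                prev = day
        out[str(genotype)] = EventTimes(str(genotype), np.array(times), np.array(events))
    return out


# ---------------------------------------------------------------------------
# Kaplan-Meier


def kaplan_meier(events: EventTimes) -> KaplanMeierResult:
    """Product-limit survival curve and median lifespan.

    The median is the first time at which S(t) drops to 0.5 or below; with
    too few deaths it is undefined and flagged.
    """
    if len(events.times) == 0:
        raise ValueError("no events")
    kmf = KaplanMeierFitter()
    kmf.fit(events.times, event_observed=events.events)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    below = np.nonzero(surv <= 0.5)[0]
    if below.size:
        median = float(times[below[0]])
        defined = True
    else:
        median = float("nan")
        defined = False
    return KaplanMeierResult(events.label, times, surv, median, defined)


# ---------------------------------------------------------------------------
# kernel-smoothed empirical hazard


def _epanechnikov(u: np.ndarray) -> np.ndarray:
    out = 0.75 * (1.0 - u * u)
    out[np.abs(u) > 1] = 0.0
    return out


class KernelHazardEstimator(BaseEstimator):
    """Kernel-smoothed hazard from Nelson-Aalen increments.

    The Nelson-Aalen increment at a distinct death time is d_j / n_j (deaths
    over number at risk); the hazard estimate convolves those increments with
    an Epanechnikov kernel, with mass reflected at both ends of the event
    range so the boundary does not bias the estimate downwards.

    Parameters
    ----------
    bandwidth : float or "auto"
        Kernel bandwidth in days.  "auto" uses the normal-reference rule
        1.06 * sd(death times) * n_deaths**(-1/5).
    n_grid : int
        Number of evaluation points across [min event, max event].
    """

    def __init__(self, bandwidth="auto", n_grid: int = 101):
        self.bandwidth = bandwidth
        self.n_grid = n_grid

    def fit(self, times, events) -> "KernelHazardEstimator":
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=int)
        deaths = times[events == 1]
        if deaths.size < 10:
            raise ValueError("need at least 10 deaths for hazard smoothing")
        if self.bandwidth == "auto":
            bw = 1.06 * float(np.std(deaths, ddof=1)) * deaths.size ** (-1 / 5)
        else:
            bw = float(self.bandwidth)
        if bw <= 0:
            raise ValueError("bandwidth must be > 0")

        # Nelson-Aalen increments at distinct death times
        uniq = np.unique(deaths)
        d_j = np.array([(deaths == t).sum() for t in uniq], dtype=float)
        n_j = np.array([(times >= t).sum() for t in uniq], dtype=float)
        dH = d_j / n_j

        lo, hi = float(times.min()), float(times.max())
        grid = np.linspace(lo, hi, self.n_grid)
        # direct + reflections about both boundaries
        centers = [uniq, 2 * lo - uniq, 2 * hi - uniq]
        h = np.zeros_like(grid)
        for c in centers:
            h += _epanechnikov((grid[:, None] - c[None, :]) / bw) @ dH
        h /= bw
        self.grid_times_ = grid
        self.hazard_ = np.maximum(h, 0.0)
        self.bandwidth_ = bw
        self.n_events_ = int(events.sum())
        return self

    def result(self) -> HazardEstimate:
        return HazardEstimate(self.grid_times_, self.hazard_, self.bandwidth_, self.n_events_)


def empirical_hazard(events: EventTimes, bandwidth="auto", n_grid: int = 101) -> HazardEstimate:
    return KernelHazardEstimator(bandwidth=bandwidth, n_grid=n_grid).fit(events.times, events.events).result()


def loghazard_linearity(h: HazardEstimate, trim: float = 0.10) -> tuple[float, float, float]:
    """OLS of ln h(t) on t over the trimmed interior grid.

    Under a Gompertz hazard ln h(t) = ln(alpha) + beta * t, so the slope
    estimates the aging rate and R^2 quantifies how Gompertz-like the cohort
    is.  The outer ``trim`` fraction of grid points at each end (kernel
    boundary region) and any nonpositive hazard values are dropped.

    Returns (slope per day, intercept, R^2).
    """
    n = len(h.grid_times)
    k = int(np.floor(trim * n))
    sl = slice(k, n - k if k else n)
    t = h.grid_times[sl]
    hz = h.hazard[sl]
    keep = hz > 0
    t, hz = t[keep], hz[keep]
    if t.size < 5:
        raise ValueError("fewer than 5 positive hazard points after trimming")
    res = stats.linregress(t, np.log(hz))
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


# ---------------------------------------------------------------------------
# Gompertz maximum likelihood


def _cum_haz_scaled(beta: float, t: np.ndarray) -> np.ndarray:
    """(exp(beta*t) - 1)/beta, continuous through beta -> 0."""
    if abs(beta) < 1e-12:
        return t * (1.0 + 0.5 * beta * t)
    return np.expm1(beta * t) / beta


def gompertz_loglik(alpha: float, beta: float, times, events) -> float:
    """Right-censored Gompertz log-likelihood.

    Deaths contribute ln(alpha) + beta*t plus the log-survival term; every
    subject (dead or censored) contributes -alpha*(exp(beta*t)-1)/beta.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    td = times[events == 1]
    with np.errstate(over="ignore"):
        cum = _cum_haz_scaled(beta, times).sum()
    return float(td.size * math.log(alpha) + beta * td.sum() - alpha * cum)


def _grad_natural(alpha: float, beta: float, times: np.ndarray, events: np.ndarray) -> np.ndarray:
    td = times[events == 1]
    D = td.size
    with np.errstate(over="ignore", invalid="ignore"):
        G = _cum_haz_scaled(beta, times)
        if abs(beta) < 1e-12:
            dG = 0.5 * times**2 * (1.0 + beta * times * 2.0 / 3.0)
        else:
            dG = (times * np.exp(beta * times)) / beta - G / beta
        return np.array([D / alpha - G.sum(), td.sum() - alpha * dG.sum()])


class GompertzFitter(BaseEstimator):
    """Maximum-likelihood Gompertz fit to right-censored event times.

    Optimization runs over (ln alpha, ln beta) (quasi-Newton with analytic
    gradient, Nelder-Mead fallback), initialized from OLS on the smoothed
    log-hazard when enough deaths are available.  The exponential limit
    beta -> 0 is handled continuously; data with no age dependence drive
    ln(beta) to its lower bound and recover the exponential MLE
    alpha = deaths / total exposure.  Standard errors come from the inverse
    observed information at the optimum, on the natural (alpha, beta) scale.

    Attributes (after :meth:`fit`): ``alpha_``, ``beta_``, ``se_alpha_``,
    ``se_beta_``, ``cov_``, ``loglik_``, ``converged_``, ``n_events_``.
    """

    _LOG_BETA_MIN = math.log(1e-9)

    def __init__(self, grad_tol: float = 1e-8, max_iter: int = 500):
        self.grad_tol = grad_tol
        self.max_iter = max_iter

    # -- internals ---------------------------------------------------------

    def _initial(self, times: np.ndarray, events: np.ndarray) -> np.ndarray:
        td = times[events == 1]
        alpha0 = max(td.size / times.sum(), 1e-8)
        beta0 = 0.01
        if td.size >= 10:
            try:
                hz = KernelHazardEstimator().fit(times, events).result()
                slope, intercept, _ = loghazard_linearity(hz)
                if slope > 1e-6:
                    beta0 = slope
                    alpha0 = max(math.exp(intercept), 1e-10)
            except ValueError:
                pass
        return np.array([math.log(alpha0), math.log(max(beta0, 1e-6))])

    def fit(self, durations, event_observed=None) -> "GompertzFitter":
        times = np.asarray(durations, dtype=float)
        if event_observed is None:
            events = np.ones_like(times, dtype=int)
        else:
            events = np.asarray(event_observed, dtype=int)
        if np.any(times <= 0):
            raise ValueError("event times must be > 0")
        td = times[events == 1]
        if np.unique(td).size < 2:
            raise ValueError("need at least 2 distinct death times")

        def negll(theta):
            a, b = math.exp(theta[0]), math.exp(theta[1])
            return -gompertz_loglik(a, b, times, events)

        def neggrad(theta):
            a, b = math.exp(theta[0]), math.exp(theta[1])
            g = _grad_natural(a, b, times, events)
            return -np.array([g[0] * a, g[1] * b])

        theta0 = self._initial(times, events)
        bounds = [(math.log(1e-12), math.log(10.0)), (self._LOG_BETA_MIN, math.log(10.0))]
        res = optimize.minimize(negll, theta0, jac=neggrad, method="L-BFGS-B",
                                bounds=bounds, options={"maxiter": self.max_iter, "gtol": self.grad_tol})
        if not res.success:
            nm = optimize.minimize(negll, res.x, method="Nelder-Mead",
                                   options={"maxiter": 4 * self.max_iter, "xatol": 1e-10, "fatol": 1e-12})
            if nm.fun <= res.fun:
                res = nm

        alpha, beta = math.exp(res.x[0]), math.exp(res.x[1])
        at_boundary = res.x[1] <= self._LOG_BETA_MIN + 1e-6
        cov, ses = self._covariance(alpha, beta, times, events)
        self.alpha_, self.beta_ = alpha, beta
        self.se_alpha_, self.se_beta_ = ses
        self.cov_ = cov
        self.loglik_ = -float(res.fun)
        self.converged_ = bool(res.success or at_boundary) and np.all(np.isfinite(ses))
        self.n_events_ = int(td.size)
        return self

    @staticmethod
    def _covariance(alpha, beta, times, events):
        # observed information: central differences of the analytic gradient
        h = np.array([max(1e-8, 1e-6 * alpha), max(1e-8, 1e-6 * max(beta, 1e-4))])
        H = np.zeros((2, 2))
        for j, (da, db) in enumerate(((h[0], 0.0), (0.0, h[1]))):
            gp = _grad_natural(alpha + da, beta + db, times, events)
            gm = _grad_natural(alpha - da, beta - db, times, events)
            H[:, j] = (gp - gm) / (2 * h[j])
        H = 0.5 * (H + H.T)
        try:
            cov = np.linalg.inv(-H)
            if np.any(np.diag(cov) <= 0):
                raise np.linalg.LinAlgError
            ses = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            cov = np.full((2, 2), np.nan)
            ses = np.array([np.nan, np.nan])
        return cov, ses

    # -- fitted-model conveniences ----------------------------------------

    def hazard(self, t):
        return self.alpha_ * np.exp(self.beta_ * np.asarray(t, dtype=float))

    def survival(self, t):
        return np.exp(-self.alpha_ * _cum_haz_scaled(self.beta_, np.asarray(t, dtype=float)))

    def result(self, label: str = "") -> GompertzFit:
        return GompertzFit(label, self.alpha_, self.beta_, self.se_alpha_, self.se_beta_,
                           self.cov_, self.loglik_, self.converged_, self.n_events_)


def fit_gompertz(events: EventTimes) -> GompertzFit:
    return GompertzFitter().fit(events.times, events.events).result(events.label)


# ---------------------------------------------------------------------------
# parameter comparisons


def compare_parameters(fits: list[GompertzFit], parameter: str) -> list[ParamComparison]:
    """All pairwise Wald z-tests on one Gompertz parameter.

    z = (p1 - p2) / sqrt(SE1^2 + SE2^2), two-sided normal p, Holm-adjusted
    across the family of pairwise comparisons for that parameter.
    """
    if parameter not in ("alpha", "beta"):
        raise ValueError("parameter must be 'alpha' or 'beta'")
    for f in fits:
        if not f.converged:
            raise ValueError(f"fit for {f.label!r} did not converge")
        se = f.se_alpha if parameter == "alpha" else f.se_beta
        if not np.isfinite(se) or se <= 0:
            raise ValueError(f"non-positive SE for {f.label!r}")

    pairs, zs, ps = [], [], []
    for i in range(len(fits)):
        for j in range(i + 1, len(fits)):
            a, b = fits[i], fits[j]
            if parameter == "alpha":
                diff, se = a.alpha - b.alpha, math.hypot(a.se_alpha, b.se_alpha)
            else:
                diff, se = a.beta - b.beta, math.hypot(a.se_beta, b.se_beta)
            z = diff / se
            pairs.append((a.label, b.label))
            zs.append(z)
            ps.append(2 * stats.norm.sf(abs(z)))
    padj = holm_adjust(ps) if ps else []
    return [ParamComparison(pair, parameter, z, p, pa)
            for pair, z, p, pa in zip(pairs, zs, ps, padj)]


def fits_to_frame(fits: list[GompertzFit]) -> pd.DataFrame:
    return pd.DataFrame([
        {"genotype": f.label, "alpha": f.alpha, "se_alpha": f.se_alpha,
         "beta": f.beta, "se_beta": f.se_beta, "loglik": f.loglik,
         "converged": f.converged, "n": f.n_events}
        for f in fits
    ])


def comparisons_to_frame(comps: list[ParamComparison]) -> pd.DataFrame:
    return pd.DataFrame([
        {"group1": c.pair[0], "group2": c.pair[1], "parameter": c.parameter,
         "z": c.z, "p_raw": c.p_raw, "p_adj": c.p_adj, "method": c.method}
        for c in comps
    ])
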