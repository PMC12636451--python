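"""pH-corrected ratiometric ATP/ADP trace analysis.

PercevalHR is a ratiometric ATP/ADP sensor read out as the 488/405 nm
excitation ratio; the ratio is pH-sensitive, so every experiment ends with
an NH4Cl pulse that transiently alkalinizes the cytosol and provides a pure
pH perturbation.  The pHrodo channel tracks intracellular pH throughout.

The processing chain per ROI:

1. background-subtract both excitation channels and form the raw ratio;
2. normalize the whole trace to an exponential fit of the pre-treatment
   (premix) baseline, which removes bleach and pins the premix mean to 1;
3. regress the NH4Cl-window ratio deviation on the fractional pHrodo
   deviation and subtract the fitted pH component from the trace;
4. extrapolate the pre-treatment baseline over the treatment window
   (local-linear-trend state space, or an OLS linear trend in fallback
   mode) to obtain the counterfactual "no treatment" trace with a 95% band;
5. report the integrated change: trapezoidal AUC of (trace - counterfactual)
   over [treatment, washout] divided by the window length.

Group comparisons use medians with binomial order-statistic 95% CIs and
two-sided Mann-Whitney tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .multitest import holm_adjust

__all__ = [
    "TraceEvents",
    "RatioTraceSet",
    "CorrectedTrace",
    "PhCalibration",
    "CounterfactualBaseline",
    "IntegratedChange",
    "TraceCorrector",
    "compute_ratio",
    "normalize_to_baseline",
    "calibrate_ph",
    "ph_correct",
    "counterfactual_baseline",
    "integrated_change",
    "compare_groups",
]

TRACE_COLUMNS = ["roi", "time_s", "f405", "f488", "phrodo", "is_background"]


@dataclass
class TraceEvents:
    """Protocol event times in seconds: treatment onset, washout, NH4Cl window."""

    treatment: float
    washout: float
    nh4cl_start: float
    nh4cl_end: float

    def __post_init__(self) -> None:
        if not (self.treatment < self.washout < self.nh4cl_start < self.nh4cl_end):
            raise ValueError("event times must satisfy treatment < washout < NH4Cl start < NH4Cl end")


@dataclass
class RatioTraceSet:
    """Long-format dual-excitation ROI series plus one background ROI."""

    data: pd.DataFrame
    events: TraceEvents

    def __post_init__(self) -> None:
        missing = [c for c in TRACE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trace table missing columns: {missing}")
        bg = self.data.loc[self.data["is_background"].astype(bool), "roi"].unique()
        if len(bg) != 1:
            raise ValueError("exactly one background ROI is required")
        t0 = None
        for _, grp in self.data.groupby("roi"):
            t = grp["time_s"].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ValueError("time base must be strictly increasing per ROI")
            if t0 is None:
                t0 = t
            elif t.shape != t0.shape or not np.allclose(t, t0):
                raise ValueError("all ROIs must share a common time base")

    @property
    def background_roi(self):
        return self.data.loc[self.data["is_background"].astype(bool), "roi"].iloc[0]

    @property
    def roi_ids(self) -> list:
        bg = self.background_roi
        return [r for r in self.data["roi"].unique() if r != bg]

    def roi_frame(self, roi) -> pd.DataFrame:
        return self.data[self.data["roi"] == roi].sort_values("time_s")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class CorrectedTrace:
    roi: object
    time: np.ndarray
    ratio: np.ndarray              # normalized (and possibly pH-corrected) ratio
    phrodo: np.ndarray             # raw pHrodo intensity on the same grid
    baseline_mean: float           # premix mean after normalization (== 1)
    bleach_amplitude: float
    bleach_rate: float             # per second, >= 0
    bleach_fit_converged: bool
    ph_corrected: bool = False


@dataclass
class PhCalibration:
    slope: float                   # ratio deviation per unit fractional pHrodo deviation
    intercept: float
    r2: float
    scope: str                     # "per_roi" or "pooled"


@dataclass
class CounterfactualBaseline:
    time: np.ndarray               # post-treatment grid
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    method: str                    # "statespace" or "ols"


@dataclass
class IntegratedChange:
    roi: object
    value: float                   # (AUC trace - AUC baseline) / window length
    value_lower: float             # same, against the band edges
    value_upper: float


# ---------------------------------------------------------------------------
# ratio computation


def compute_ratio(traces: RatioTraceSet) -> pd.DataFrame:
    """Background-subtracted 488/405 ratio per ROI and timepoint.

    Timepoints where the background-subtracted 405 denominator is <= 0 are
    masked (NaN) with a warning; an all-masked ROI is an error.
    """
    bg = traces.roi_frame(traces.background_roi)
    b405 = bg["f405"].to_numpy(dtype=float)
    b488 = bg["f488"].to_numpy(dtype=float)
    rows = []
    for roi in traces.roi_ids:
        g = traces.roi_frame(roi)
        num = g["f488"].to_numpy(dtype=float) - b488
        den = g["f405"].to_numpy(dtype=float) - b405
        bad = den <= 0
        if bad.all():
            raise ValueError(f"ROI {roi!r}: denominator nonpositive at every timepoint")
        if bad.any():
            warnings.warn(f"ROI {roi!r}: {bad.sum()} timepoint(s) masked (nonpositive denominator)")
        ratio = np.where(bad, np.nan, num / np.where(bad, 1.0, den))
        rows.append(pd.DataFrame({"roi": roi, "time_s": g["time_s"].to_numpy(dtype=float),
                                  "ratio": ratio, "phrodo": g["phrodo"].to_numpy(dtype=float)}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# baseline normalization (bleach removal)


def _fit_premix_exponential(t: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Fit y = A*exp(-k*t), k >= 0, to the premix baseline.

    The fit is ordinary least squares on the log scale, which keeps the
    normalization idempotent: once a trace has been divided by its fitted
    envelope, a second fit finds zero slope and changes nothing.  Traces
    with nonpositive premix values fall back to a constant baseline.
    """
    a0 = float(np.nanmean(y))
    if not np.all(y > 0):
        warnings.warn("nonpositive premix ratios; falling back to constant baseline")
        return a0, 0.0, False
    slope, intercept = np.polyfit(t, np.log(y), 1)
    if slope >= 0:                  # no bleach detectable; constant baseline
        return a0, 0.0, True
    return float(np.exp(intercept)), float(-slope), True


def normalize_to_baseline(time: np.ndarray, ratio: np.ndarray, premix_end: float
                          ) -> tuple[np.ndarray, float, float, bool]:
    """Divide a ratio trace by the exponential fit of its premix baseline.

    Returns (normalized trace, amplitude A, bleach rate k, fit converged).
    After normalization the premix mean is exactly 1 (a final rescale pins
    it, so the step is idempotent).
    """
    time = np.asarray(time, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    pre = (time < premix_end) & np.isfinite(ratio)
    if pre.sum() < 5:
        raise ValueError("need at least 5 premix points")
    a, k, ok = _fit_premix_exponential(time[pre], ratio[pre])
    envelope = a * np.exp(-k * time)
    out = ratio / envelope
    out = out / np.nanmean(out[pre])
    return out, a, k, ok


# ---------------------------------------------------------------------------
# pH calibration and correction


def _phrodo_deviation(time: np.ndarray, phrodo: np.ndarray, ref_start: float, ref_end: float) -> np.ndarray:
    """Fractional pHrodo deviation from its local reference-window mean.

    Fractional (not absolute) deviation makes the calibration invariant to
    the arbitrary intensity scale of the dye.
    """
    ref = (time >= ref_start) & (time < ref_end)
    if ref.sum() < 2:
        raise ValueError("pHrodo reference window contains fewer than 2 points")
    mu = float(np.nanmean(phrodo[ref]))
    if mu == 0:
        raise ValueError("zero pHrodo reference intensity")
    return phrodo / mu - 1.0


def calibrate_ph(corrected: list[CorrectedTrace], events: TraceEvents,
                 scope: str = "per_roi", ref_window_s: float = 30.0
                 ) -> dict[object, PhCalibration]:
    """Linear map from fractional pHrodo deviation to ratio deviation.

    Deviations are measured from the ``ref_window_s`` seconds preceding
    NH4Cl onset; the regression uses points inside the NH4Cl window.  With
    ``scope="pooled"`` one line is fitted to all ROIs' points and assigned
    to each; per-ROI scope falls back to the pooled line for ROIs whose
    NH4Cl response is degenerate (zero pHrodo variance).
    """
    if scope not in ("per_roi", "pooled"):
        raise ValueError("scope must be 'per_roi' or 'pooled'")
    ref_start, ref_end = events.nh4cl_start - ref_window_s, events.nh4cl_start

    def window_pairs(tr: CorrectedTrace):
        t = tr.time
        dev_p = _phrodo_deviation(t, tr.phrodo, ref_start, ref_end)
        ref = (t >= ref_start) & (t < ref_end)
        dev_r = tr.ratio - float(np.nanmean(tr.ratio[ref]))
        win = (t >= events.nh4cl_start) & (t <= events.nh4cl_end) & np.isfinite(dev_r)
        if win.sum() < 5:
            raise ValueError("NH4Cl window contains fewer than 5 points")
        return dev_p[win], dev_r[win]

    def fit_line(x, y, scope_label):
        if np.std(x) == 0:
            raise ValueError("zero variance in pHrodo deviations (no pH response)")
        res = stats.linregress(x, y)
        return PhCalibration(float(res.slope), float(res.intercept), float(res.rvalue**2), scope_label)

    all_x, all_y = [], []
    pairs = {}
    for tr in corrected:
        x, y = window_pairs(tr)
        pairs[tr.roi] = (x, y)
        all_x.append(x)
        all_y.append(y)
    pooled = fit_line(np.concatenate(all_x), np.concatenate(all_y), "pooled")
    if scope == "pooled":
        return {tr.roi: pooled for tr in corrected}
    out = {}
    for tr in corrected:
        x, y = pairs[tr.roi]
        try:
            out[tr.roi] = fit_line(x, y, "per_roi")
        except ValueError:
            warnings.warn(f"ROI {tr.roi!r}: degenerate NH4Cl response, using pooled pH calibration")
            out[tr.roi] = pooled
    return out


def ph_correct(trace: CorrectedTrace, cal: PhCalibration, events: TraceEvents,
               ref_window_s: float = 30.0) -> CorrectedTrace:
    """Subtract the pH component (slope x pHrodo deviation) from the trace."""
    dev_p = _phrodo_deviation(trace.time, trace.phrodo,
                              events.nh4cl_start - ref_window_s, events.nh4cl_start)
    return CorrectedTrace(trace.roi, trace.time, trace.ratio - cal.slope * dev_p,
                          trace.phrodo, trace.baseline_mean, trace.bleach_amplitude,
                          trace.bleach_rate, trace.bleach_fit_converged, ph_corrected=True)


# ---------------------------------------------------------------------------
# counterfactual baseline


def counterfactual_baseline(time: np.ndarray, ratio: np.ndarray, treatment_time: float,
                            method: str = "statespace", level: float = 0.95
                            ) -> CounterfactualBaseline:
    """Extrapolate the pre-treatment baseline over the treatment window.

    ``statespace`` fits a Gaussian local-linear-trend model (level + slope
    random walks plus observation noise) to the pre-treatment points by
    maximum likelihood and forecasts with pointwise prediction intervals;
    ``ols`` fits a deterministic linear trend and uses its prediction
    intervals.  The state-space route falls back to OLS when the likelihood
    optimization fails.  Band width is nondecreasing with horizon.
    """
    time = np.asarray(time, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    pre = time < treatment_time
    post = ~pre
    if pre.sum() < 10:
        raise ValueError("need at least 10 pre-treatment points")
    if post.sum() == 0:
        raise ValueError("no post-treatment points to extrapolate over")
    alpha = 1.0 - level

    if method == "statespace":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mod = sm.tsa.UnobservedComponents(ratio[pre], level="local linear trend")
                fit = mod.fit(disp=False)
                fc = fit.get_forecast(steps=int(post.sum()))
                mean = np.asarray(fc.predicted_mean)
                ci = np.asarray(fc.conf_int(alpha=alpha))
            if not (np.all(np.isfinite(mean)) and np.all(np.isfinite(ci))):
                raise ValueError("non-finite state-space forecast")
            return CounterfactualBaseline(time[post], mean, ci[:, 0], ci[:, 1], "statespace")
        except Exception:
            warnings.warn("state-space baseline fit failed; falling back to OLS trend")
            method = "ols"
    if method != "ols":
        raise ValueError("method must be 'statespace' or 'ols'")

    X = sm.add_constant(time[pre])
    fit = sm.OLS(ratio[pre], X).fit()
    pred = fit.get_prediction(sm.add_constant(time[post]))
    mean = np.asarray(pred.predicted_mean)
    if fit.df_resid > 0 and fit.mse_resid > 0:
        ci = np.asarray(pred.conf_int(obs=True, alpha=alpha))
        lower, upper = ci[:, 0], ci[:, 1]
    else:  # degenerate exact fit: zero-width band
        lower = upper = mean
    return CounterfactualBaseline(time[post], mean, lower, upper, "ols")


# ---------------------------------------------------------------------------
# integrated change


def integrated_change(trace: CorrectedTrace, baseline: CounterfactualBaseline,
                      treatment_time: float, washout_time: float) -> IntegratedChange:
    """Duration-adjusted AUC of (trace - counterfactual) over the treatment window."""
    if washout_time <= treatment_time:
        raise ValueError("washout must come after treatment")
    if treatment_time < trace.time[0] or washout_time > trace.time[-1]:
        raise ValueError("integration window outside the recorded time range")
    win = (baseline.time >= treatment_time) & (baseline.time <= washout_time)
    if win.sum() < 2:
        raise ValueError("fewer than 2 points in the integration window")
    t = baseline.time[win]
    y = np.interp(t, trace.time, trace.ratio)
    dur = washout_time - treatment_time

    def auc_vs(ref):
        return float(np.trapezoid(y - ref, t) / dur)

    val = auc_vs(baseline.mean[win])
    v_lo = auc_vs(baseline.upper[win])   # against the upper band edge -> smallest change
    v_hi = auc_vs(baseline.lower[win])
    return IntegratedChange(trace.roi, val, min(v_lo, v_hi), max(v_lo, v_hi))


# ---------------------------------------------------------------------------
# group comparison


def _median_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """Median with a distribution-free binomial order-statistic CI."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    med = float(np.median(x))
    if n < 3:
        return med, float("nan"), float("nan")
    alpha = 1 - level
    lo_idx = int(stats.binom.ppf(alpha / 2, n, 0.5))
    hi_idx = int(stats.binom.isf(alpha / 2, n, 0.5))
    lo_idx = max(lo_idx, 0)
    hi_idx = min(hi_idx, n - 1)
    return med, float(x[lo_idx]), float(x[hi_idx])


def compare_groups(values: dict[str, np.ndarray], level: float = 0.95
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Medians with 95% CIs per group plus pairwise two-sided Mann-Whitney tests.

    Returns (summary frame, tests frame).  With more than two groups the
    Mann-Whitney p-values are Holm-adjusted across the pairwise family.
    """
    for k, v in values.items():
        if len(v) < 3:
            raise ValueError(f"group {k!r} has fewer than 3 observations")
    summary = pd.DataFrame([
        {"group": k, "n": len(v), **dict(zip(("median", "ci_lower", "ci_upper"), _median_ci(np.asarray(v), level)))}
        for k, v in values.items()
    ])
    rows = []
    for a, b in combinations(values, 2):
        u, p = stats.mannwhitneyu(values[a], values[b], alternative="two-sided")
        rows.append({"group1": a, "group2": b, "U": float(u), "p_raw": float(p)})
    tests = pd.DataFrame(rows)
    if len(tests):
        tests["p_adj"] = holm_adjust(tests["p_raw"].to_numpy()) if len(tests) > 1 else tests["p_raw"]
    return summary, tests


# ---------------------------------------------------------------------------
# end-to-end corrector


class TraceCorrector(BaseEstimator):
    """Full ratio-correction chain as a fit/transform estimator.

    ``fit`` learns the per-ROI bleach envelopes and pH calibrations from a
    :class:`RatioTraceSet`; ``transform`` returns the corrected traces; and
    :meth:`integrated_changes` runs the counterfactual-baseline AUC step.

    Parameters
    ----------
    ph_scope : "per_roi" or "pooled" calibration scope.
    ph_ref_window_s : reference window (s) before NH4Cl onset.
    baseline_method : "statespace" or "ols" counterfactual model.
    """

    def __init__(self, ph_scope: str = "per_roi", ph_ref_window_s: float = 30.0,
                 baseline_method: str = "statespace"):
        self.ph_scope = ph_scope
        self.ph_ref_window_s = ph_ref_window_s
        self.baseline_method = baseline_method

    def fit(self, traces: RatioTraceSet, y=None) -> "TraceCorrector":
        self.events_ = traces.events
        ratios = compute_ratio(traces)
        normalized = []
        for roi, g in ratios.groupby("roi", sort=False):
            t = g["time_s"].to_numpy()
            r = g["ratio"].to_numpy()
            norm, a, k, ok = normalize_to_baseline(t, r, traces.events.treatment)
            normalized.append(CorrectedTrace(roi, t, norm, g["phrodo"].to_numpy(), 1.0, a, k, ok))
        self.calibrations_ = calibrate_ph(normalized, traces.events,
                                          scope=self.ph_scope, ref_window_s=self.ph_ref_window_s)
        self.corrected_ = [ph_correct(tr, self.calibrations_[tr.roi], traces.events,
                                      self.ph_ref_window_s) for tr in normalized]
        return self

    def transform(self, traces: RatioTraceSet = None) -> list[CorrectedTrace]:
        return self.corrected_

    def fit_transform(self, traces: RatioTraceSet, y=None) -> list[CorrectedTrace]:
        return self.fit(traces).transform()

    def integrated_changes(self) -> pd.DataFrame:
        ev = self.events_
        rows = []
        for tr in self.corrected_:
            base = counterfactual_baseline(tr.time, tr.ratio, ev.treatment,
                                           method=self.baseline_method)
            ic = integrated_change(tr, base, ev.treatment, ev.washout)
            rows.append({"roi": ic.roi, "integrated_change": ic.value,
                         "band_lower": ic.value_lower, "band_upper": ic.value_upper})
        return pd.DataFrame(rows)

    def corrected_frame(self) -> pd.DataFrame:
        return pd.concat([pd.DataFrame({"roi": tr.roi, "time_s": tr.time, "ratio": tr.ratio})
                          for tr in self.corrected_], ignore_index=True)
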