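"""Mixed-model analysis of extracellular flux (Seahorse-style) assays.

OCR (oxygen consumption rate, pmol O2/min) indexes mitochondrial
respiration; ECAR (extracellular acidification rate, mpH/min) indexes
glycolytic flux.  A mitochondrial/glycolytic stress test injects drugs in
sequence (oligomycin A -> FCCP -> rotenone + antimycin A -> 2-deoxyglucose),
and each derived metric is a difference of estimated marginal means (EMMs)
between two injection phases, taken from a random-intercept linear
mixed model of the form

    response ~ phase x genotype + (1|well) + (1|batch)

fitted by REML (statsmodels MixedLM, crossed random intercepts as variance
components).  Metrics:

* glycolytic reserve  = ECAR after rotenone/antimycin - basal ECAR
* maximal ECAR        = ECAR EMM during the rotenone/antimycin phase
* 2DG decline slope   = genotype-specific ECAR slope on centered time post-2DG
* ATP-linked respiration   = basal OCR - post-oligomycin OCR
* respiratory reserve      = FCCP-uncoupled OCR - basal OCR
* peak respiratory capacity = FCCP-uncoupled OCR - post-rotenone/antimycin OCR

Genotype differences are interaction contrasts with normal-reference
(z) p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "FluxAssay",
    "LMMFit",
    "RandomInterceptLMM",
    "PHASES",
    "label_phases",
    "fit_random_intercept_lmm",
    "glycolytic_reserve",
    "maximal_ecar",
    "dg2_slope",
    "ocr_metrics",
]

PHASES = ["baseline", "post_oligo", "post_fccp", "post_rotAA", "post_2dg"]
FLUX_COLUMNS = ["well", "batch", "genotype", "medium", "phase", "time_min", "ocr", "ecar"]


@dataclass
class FluxAssay:
    """Well x timepoint OCR/ECAR measurements with phase labels."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FLUX_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"flux table missing columns: {missing}")
        if len(self.data) == 0:
            raise ValueError("empty flux table")
        bad = set(self.data["phase"]) - set(PHASES)
        if bad:
            raise ValueError(f"unknown phases: {sorted(bad)}")
        per_well = self.data.groupby("well")[["genotype", "batch", "medium"]].nunique()
        if (per_well > 1).any().any():
            raise ValueError("each well must have exactly one genotype, batch and medium")
        if not np.isfinite(self.data[["ocr", "ecar"]].to_numpy(dtype=float)).all():
            raise ValueError("OCR/ECAR values must be finite")

    @property
    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self.data["genotype"]))

    def subset_phases(self, phases: list[str]) -> pd.DataFrame:
        df = self.data[self.data["phase"].isin(phases)].copy()
        for ph in phases:
            if ph not in set(df["phase"]):
                raise ValueError(f"phase {ph!r} missing from assay")
        return df

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FluxAssay":
        return cls(pd.read_csv(path))


def label_phases(raw: pd.DataFrame, injections: list[tuple[float, str]],
                 drop_first_after_injection: bool = False) -> FluxAssay:
    """Assign each measurement the phase of the most recent injection.

    ``injections`` is a list of (time_min, phase) pairs in chronological
    order; measurements before the first injection are ``baseline``.  The
    first measurement cycle after each injection can optionally be dropped
    as a mixing artifact.
    """
    times = [t for t, _ in injections]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("injection times must be strictly increasing")
    df = raw.copy()
    if (df["time_min"] < 0).any():
        raise ValueError("measurement before the start of recording")
    labels = np.full(len(df), "baseline", dtype=object)
    t = df["time_min"].to_numpy(dtype=float)
    for inj_time, phase in injections:
        labels[t >= inj_time] = phase
    df["phase"] = labels
    if drop_first_after_injection:
        keep = np.ones(len(df), dtype=bool)
        for inj_time, _ in injections:
            for well, wdf in df.groupby("well"):
                post = wdf.index[wdf["time_min"] >= inj_time]
                if len(post):
                    keep[df.index.get_indexer([post[0]])] = False
        df = df[keep]
    return FluxAssay(df)


# ---------------------------------------------------------------------------
# random-intercept LMM


@dataclass
class LMMFit:
    fe_params: pd.Series
    fe_cov: pd.DataFrame
    vc: dict[str, float]           # variance components incl. "residual"
    method: str                    # "reml" or "ml"
    converged: bool
    design_info: object            # patsy design info for EMM rows
    loglik: float

    def _row(self, cell: dict) -> np.ndarray:
        frame = pd.DataFrame([cell])
        return np.asarray(patsy.dmatrix(self.design_info, frame, return_type="matrix"))[0]

    def emm(self, cells: list[dict]) -> pd.DataFrame:
        """Equally-weighted cell-mean predictions (estimated marginal means)."""
        rows = []
        beta = self.fe_params.to_numpy()
        cov = self.fe_cov.to_numpy()
        for cell in cells:
            x = self._row(cell)
            rows.append({**cell, "emm": float(x @ beta), "se": float(np.sqrt(x @ cov @ x))})
        return pd.DataFrame(rows)

    def contrast(self, cells_plus: list[dict], cells_minus: list[dict]) -> dict:
        """z-test of (mean of cells_plus) - (mean of cells_minus)."""
        xp = np.mean([self._row(c) for c in cells_plus], axis=0)
        xm = np.mean([self._row(c) for c in cells_minus], axis=0)
        x = xp - xm
        est = float(x @ self.fe_params.to_numpy())
        se = float(np.sqrt(x @ self.fe_cov.to_numpy() @ x))
        z = est / se if se > 0 else np.nan
        p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        return {"estimate": est, "se": se, "z": z, "p": p}


class RandomInterceptLMM(BaseEstimator):
    """Linear mixed model with crossed Gaussian random intercepts.

    Fits ``formula`` (fixed effects, patsy syntax) with independent random
    intercepts for each factor in ``random`` by REML (default) or ML.
    Single-level random factors have their variance fixed at 0 with a
    warning; with no usable random factor the model reduces to OLS.
    Negative variance estimates are truncated at 0 and flagged.

    Attributes after :meth:`fit`: ``fit_`` (:class:`LMMFit`),
    ``boundary_`` (True when a variance component hit 0).
    """

    def __init__(self, formula: str, random: tuple = ("well", "batch"), reml: bool = True):
        self.formula = formula
        self.random = random
        self.reml = reml

    def fit(self, df: pd.DataFrame, y=None) -> "RandomInterceptLMM":
        usable = []
        for factor in self.random:
            if df[factor].nunique() >= 2:
                usable.append(factor)
            else:
                warnings.warn(f"random factor {factor!r} has a single level; variance fixed at 0")
        y_dm, X_dm = patsy.dmatrices(self.formula, df, return_type="dataframe")
        design_info = X_dm.design_info
        if np.linalg.matrix_rank(X_dm.to_numpy()) < X_dm.shape[1]:
            raise ValueError("singular fixed-effect design")

        if not usable:
            ols = sm.OLS(y_dm.iloc[:, 0], X_dm).fit()
            self.fit_ = LMMFit(ols.params, pd.DataFrame(ols.cov_params()),
                               {"residual": float(ols.mse_resid)},
                               "reml" if self.reml else "ml", True, design_info, float(ols.llf))
            self.boundary_ = False
            return self

        vcf = {f: f"0 + C({f})" for f in usable}
        groups = np.ones(len(df))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM.from_formula(self.formula, data=df, groups=groups,
                                            vc_formula=vcf, re_formula="0")
            # run two optimizers at tight tolerance and keep the better REML
            # optimum: L-BFGS-B occasionally stalls on a spurious stationary
            # point while claiming convergence, and BFGS covers that case
            res = model.fit(reml=self.reml, method="lbfgs", pgtol=1e-10, factr=10.0)
            res_b = model.fit(reml=self.reml, method="bfgs", gtol=1e-10)
            if np.isfinite(res_b.llf) and (not np.isfinite(res.llf) or res_b.llf > res.llf):
                res = res_b
        vc = {f: max(float(res.vcomp[i]), 0.0) for i, f in enumerate(model.exog_vc.names)}
        vc["residual"] = float(res.scale)
        self.boundary_ = bool(np.any(np.asarray(res.vcomp) <= 1e-10))
        fe = res.fe_params
        fe_cov = pd.DataFrame(np.asarray(res.cov_params())[:len(fe), :len(fe)],
                              index=fe.index, columns=fe.index)
        self.fit_ = LMMFit(fe, fe_cov, vc, "reml" if self.reml else "ml",
                           bool(res.converged), design_info, float(res.llf))
        return self

    def result(self) -> LMMFit:
        return self.fit_


def fit_random_intercept_lmm(df: pd.DataFrame, formula: str,
                             random: tuple = ("well", "batch"), reml: bool = True) -> LMMFit:
    return RandomInterceptLMM(formula, random=random, reml=reml).fit(df).result()


# ---------------------------------------------------------------------------
# metric helpers


def _pairwise(genotypes: list[str]):
    for i in range(len(genotypes)):
        for j in range(i + 1, len(genotypes)):
            yield genotypes[i], genotypes[j]


def _phase_difference_metric(assay: FluxAssay, response: str, phase0: str, phase1: str,
                             reml: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """EMM(phase1) - EMM(phase0) per genotype, plus interaction contrasts.

    The model is ``response ~ phase01 * genotype + (1|well) + (1|batch)``
    with the phase coded 0/1.
    """
    df = assay.subset_phases([phase0, phase1])
    df["phase01"] = (df["phase"] == phase1).astype(int)
    fit = fit_random_intercept_lmm(df, f"{response} ~ phase01 * C(genotype)", reml=reml)
    genotypes = list(dict.fromkeys(df["genotype"]))
    per = []
    for g in genotypes:
        c = fit.contrast([{"phase01": 1, "genotype": g}], [{"phase01": 0, "genotype": g}])
        per.append({"genotype": g, **c})
    contrasts = []
    for g1, g2 in _pairwise(genotypes):
        x = fit.contrast([{"phase01": 1, "genotype": g1}, {"phase01": 0, "genotype": g2}],
                         [{"phase01": 0, "genotype": g1}, {"phase01": 1, "genotype": g2}])
        # the two-vs-two averaging halves the interaction; rescale to the full difference
        contrasts.append({"group1": g1, "group2": g2,
                          "estimate": 2 * x["estimate"], "se": 2 * x["se"],
                          "z": x["z"], "p": x["p"]})
    return pd.DataFrame(per), pd.DataFrame(contrasts)


def glycolytic_reserve(assay: FluxAssay, reml: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Glycolytic reserve: maximal (post rotenone/antimycin) minus basal ECAR."""
    return _phase_difference_metric(assay, "ecar", "baseline", "post_rotAA", reml=reml)


def maximal_ecar(assay: FluxAssay, reml: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ECAR EMM per genotype during the rotenone/antimycin phase, plus contrasts."""
    df = assay.subset_phases(["post_rotAA"])
    fit = fit_random_intercept_lmm(df, "ecar ~ C(genotype)", reml=reml)
    genotypes = list(dict.fromkeys(df["genotype"]))
    emms = fit.emm([{"genotype": g} for g in genotypes]).rename(columns={"emm": "estimate"})
    contrasts = []
    for g1, g2 in _pairwise(genotypes):
        c = fit.contrast([{"genotype": g1}], [{"genotype": g2}])
        contrasts.append({"group1": g1, "group2": g2, **c})
    return emms, pd.DataFrame(contrasts)


def dg2_slope(assay: FluxAssay, reml: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Post-2DG ECAR decline rate per genotype (mpH/min per min) and contrasts.

    Genotype-specific marginal slopes from ``ecar ~ time_c * genotype`` on
    centered time within the post-2DG phase.
    """
    df = assay.subset_phases(["post_2dg"])
    if df["time_min"].nunique() < 3:
        raise ValueError("need at least 3 post-2DG timepoints")
    df["time_c"] = df["time_min"] - df["time_min"].mean()
    fit = fit_random_intercept_lmm(df, "ecar ~ time_c * C(genotype)", reml=reml)
    genotypes = list(dict.fromkeys(df["genotype"]))
    per, contrasts = [], []
    # slope = EMM at time_c=+0.5 minus EMM at time_c=-0.5
    for g in genotypes:
        c = fit.contrast([{"time_c": 0.5, "genotype": g}], [{"time_c": -0.5, "genotype": g}])
        per.append({"genotype": g, "slope": c["estimate"], "se": c["se"], "z": c["z"], "p": c["p"]})
    for g1, g2 in _pairwise(genotypes):
        x = fit.contrast([{"time_c": 0.5, "genotype": g1}, {"time_c": -0.5, "genotype": g2}],
                         [{"time_c": -0.5, "genotype": g1}, {"time_c": 0.5, "genotype": g2}])
        contrasts.append({"group1": g1, "group2": g2,
                          "estimate": 2 * x["estimate"], "se": 2 * x["se"],
                          "z": x["z"], "p": x["p"]})
    return pd.DataFrame(per), pd.DataFrame(contrasts)


def ocr_metrics(assay: FluxAssay, reml: bool = True) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """ATP-linked respiration, respiratory reserve and peak respiratory capacity.

    Each metric comes from its own phase-coded OCR mixed model:
    ATP-linked = baseline - post-oligomycin; respiratory reserve =
    post-FCCP - baseline; peak capacity = post-FCCP - post-rotenone/antimycin.
    """
    atp_per, atp_con = _phase_difference_metric(assay, "ocr", "post_oligo", "baseline", reml=reml)
    res_per, res_con = _phase_difference_metric(assay, "ocr", "baseline", "post_fccp", reml=reml)
    peak_per, peak_con = _phase_difference_metric(assay, "ocr", "post_rotAA", "post_fccp", reml=reml)
    return {"atp_linked": (atp_per, atp_con),
            "respiratory_reserve": (res_per, res_con),
            "peak_capacity": (peak_per, peak_con)}
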