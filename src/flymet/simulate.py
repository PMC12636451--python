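"""Synthetic-data generators with the statistical structure the analysis
modules assume.

Each generator draws from an explicitly seeded :class:`numpy.random.Generator`
(no global RNG state) and emits the same containers / CSV schemas the
analysis modules read, so the whole chain runs end-to-end with no external
data:

* Gompertz-distributed death times censused twice weekly in vials of <= 15
  flies (deaths recorded at the census day closing their interval);
* dual-excitation PercevalHR + pHrodo ROI traces with bleach decay, a
  treatment deflection, an NH4Cl pH artifact coupled into the ratio, and
  Gaussian noise;
* flux plates whose measurements are phase means plus independent Gaussian
  well, batch and residual components;
* negative-binomial count matrices with genotype-specific differential
  expression and ground-truth direction labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flux import PHASES, FluxAssay
from .survival import SurvivalTable
from .traces import RatioTraceSet, TraceEvents
from .transcriptome import CountMatrix

__all__ = [
    "GenotypeLifespan",
    "LifespanSimSpec",
    "TraceSimSpec",
    "FluxSimSpec",
    "CountSimSpec",
    "simulate_lifespans",
    "simulate_traces",
    "simulate_flux_plate",
    "simulate_counts",
    "gompertz_survival",
    "sample_gompertz",
]


# ---------------------------------------------------------------------------
# lifespans


@dataclass
class GenotypeLifespan:
    label: str
    alpha: float                   # baseline hazard per day, > 0
    beta: float                    # aging rate per day, >= 0
    n_flies: int = 100

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.n_flies < 1:
            raise ValueError("n_flies must be >= 1")


@dataclass
class LifespanSimSpec:
    genotypes: list[GenotypeLifespan]
    census_interval_days: float = 3.5      # twice-weekly transfers
    max_flies_per_vial: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        self.genotypes = [g if isinstance(g, GenotypeLifespan) else GenotypeLifespan(*g)
                          for g in self.genotypes]
        if self.census_interval_days <= 0:
            raise ValueError("census interval must be > 0")
        if self.max_flies_per_vial < 1:
            raise ValueError("max_flies_per_vial must be >= 1")


def gompertz_survival(t, alpha: float, beta: float):
    """Closed-form Gompertz survival S(t) = exp(-(alpha/beta)(e^{beta t}-1))."""
    t = np.asarray(t, dtype=float)
    if beta == 0:
        return np.exp(-alpha * t)
    return np.exp(-(alpha / beta) * np.expm1(beta * t))


def sample_gompertz(rng: np.random.Generator, alpha: float, beta: float, n: int) -> np.ndarray:
    """Inverse-CDF draws of Gompertz death times (exponential when beta = 0)."""
    u = rng.uniform(size=n)
    if beta == 0:
        return -np.log(u) / alpha
    return np.log1p(-(beta / alpha) * np.log(u)) / beta


def simulate_lifespans(spec: LifespanSimSpec) -> SurvivalTable:
    """Draw death times, assign flies round-robin to vials, census-bin deaths.

    Deaths in the interval ((k-1)*I, k*I] are recorded at census day k*I,
    mirroring counting only at twice-weekly transfers.  All flies are
    followed to death (no censoring in the default protocol).
    """
    rng = np.random.default_rng(spec.seed)
    interval = spec.census_interval_days
    rows = []
    for g in spec.genotypes:
        times = sample_gompertz(rng, g.alpha, g.beta, g.n_flies)
        vials = np.arange(g.n_flies) // spec.max_flies_per_vial
        census_idx = np.maximum(np.ceil(times / interval).astype(int), 1)
        df = pd.DataFrame({"vial": vials, "census": census_idx})
        counts = df.groupby(["vial", "census"]).size()
        for (vial, k), deaths in counts.items():
            rows.append({"genotype": g.label, "vial": f"{g.label}_v{vial}",
                         "census_day": k * interval, "deaths": int(deaths), "censored": 0})
    out = pd.DataFrame(rows).sort_values(["genotype", "vial", "census_day"]).reset_index(drop=True)
    return SurvivalTable(out)


# ---------------------------------------------------------------------------
# imaging traces


@dataclass
class TraceSimSpec:
    """Protocol timing mirrors the imaging assay: 2 min baseline, 6 min
    treatment, 2 min washout, then an NH4Cl pulse for pH calibration."""

    n_rois: int = 15
    dt: float = 2.0                        # seconds
    baseline_duration: float = 120.0
    treatment_time: float = 120.0
    washout_time: float = 480.0
    nh4cl_window: tuple[float, float] = (600.0, 720.0)
    bleach_rate: float = 5e-4              # per second, on the ratio
    treatment_effect: float = -0.2         # fractional ratio deflection
    ph_coupling: float = 0.5               # ratio deviation per fractional pHrodo deviation
    ph_amplitude: float = 0.4              # fractional pHrodo deviation during NH4Cl
    noise_sd: float = 0.01                 # sd of multiplicative channel noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not (self.treatment_time < self.washout_time < self.nh4cl_window[0] < self.nh4cl_window[1]):
            raise ValueError("event times must be ordered: treatment < washout < NH4Cl window")
        if self.bleach_rate < 0 or self.noise_sd < 0:
            raise ValueError("bleach_rate and noise_sd must be >= 0")

    @property
    def events(self) -> TraceEvents:
        return TraceEvents(self.treatment_time, self.washout_time, *self.nh4cl_window)


def _ph_deviation_profile(t: np.ndarray, spec: TraceSimSpec) -> np.ndarray:
    """Fractional pHrodo deviation: smooth rise/plateau inside the NH4Cl window."""
    t0, t1 = spec.nh4cl_window
    dev = np.zeros_like(t)
    inside = (t >= t0) & (t <= t1)
    tau = 10.0                              # seconds, onset time constant
    dev[inside] = spec.ph_amplitude * (1.0 - np.exp(-(t[inside] - t0) / tau))
    return dev


def simulate_traces(spec: TraceSimSpec) -> RatioTraceSet:
    """Emit F405/F488/pHrodo channels whose background-subtracted ratio is

        r(t) = [1 + treatment_effect*1(treat<=t<washout)
                  + ph_coupling*phdev(t)] * exp(-bleach_rate*t)

    with multiplicative Gaussian noise on the signal channels.  The pHrodo
    channel always responds to NH4Cl (it is the pH proxy); ``ph_coupling``
    controls how much of that pH swing leaks into the ratio.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.nh4cl_window[1] + spec.dt / 2, spec.dt)
    a405, a488, phrodo0 = 1000.0, 1000.0, 500.0
    b405, b488 = 100.0, 80.0
    phdev = _ph_deviation_profile(t, spec)
    true_ratio = 1.0 + spec.treatment_effect * ((t >= spec.treatment_time) & (t < spec.washout_time))
    true_ratio = true_ratio + spec.ph_coupling * phdev
    envelope = np.exp(-spec.bleach_rate * t)

    frames = []
    for i in range(spec.n_rois):
        noise = rng.normal(0.0, spec.noise_sd, size=t.size) if spec.noise_sd else 0.0
        f405 = b405 + a405 * np.ones_like(t)
        f488 = b488 + a488 * true_ratio * envelope * (1.0 + noise)
        ph = phrodo0 * (1.0 + phdev)
        frames.append(pd.DataFrame({"roi": f"roi{i:02d}", "time_s": t, "f405": f405,
                                    "f488": f488, "phrodo": ph, "is_background": False}))
    frames.append(pd.DataFrame({"roi": "background", "time_s": t,
                                "f405": np.full(t.size, b405), "f488": np.full(t.size, b488),
                                "phrodo": np.zeros(t.size), "is_background": True}))
    return RatioTraceSet(pd.concat(frames, ignore_index=True), spec.events)


# ---------------------------------------------------------------------------
# flux plates


def _default_phase_means() -> dict:
    # OCR follows a canonical mito stress test; ECAR gives the tau genotype a
    # higher basal and a smaller glycolytic reserve than control.
    return {
        "control": {"baseline": (100.0, 10.0), "post_oligo": (40.0, 14.0),
                    "post_fccp": (150.0, 16.0), "post_rotAA": (10.0, 30.0),
                    "post_2dg": (10.0, 12.0)},
        "tau": {"baseline": (90.0, 15.0), "post_oligo": (45.0, 18.0),
                "post_fccp": (140.0, 19.0), "post_rotAA": (12.0, 25.0),
                "post_2dg": (12.0, 14.0)},
    }


@dataclass
class FluxSimSpec:
    """Phase means per genotype (OCR, ECAR) plus Gaussian well/batch/residual
    components: measurement = phase mean + well + batch + residual."""

    phase_means: dict = field(default_factory=_default_phase_means)
    sigma_well: float = 2.0
    sigma_batch: float = 1.0
    sigma_resid: float = 1.0
    n_wells: int = 6                        # per genotype
    n_batches: int = 2
    measurements_per_phase: int = 3
    cycle_min: float = 6.5
    medium: str = "full"
    dg2_slopes: dict | None = None          # optional ECAR decline per min post-2DG
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_well, self.sigma_batch, self.sigma_resid) < 0:
            raise ValueError("all sigma must be >= 0")
        if self.n_wells < 1 or self.n_batches < 1 or self.measurements_per_phase < 1:
            raise ValueError("counts must be >= 1")
        for g, phases in self.phase_means.items():
            missing = [p for p in phases if p not in PHASES]
            if missing:
                raise ValueError(f"unknown phases for {g!r}: {missing}")


def simulate_flux_plate(spec: FluxSimSpec) -> FluxAssay:
    """Balanced plate: every genotype contributes ``n_wells`` wells spread
    round-robin over batches; each well yields ``measurements_per_phase``
    cycles per phase.  Well and batch intercepts are shared between the OCR
    and ECAR channels of a measurement (one probe, two readouts)."""
    rng = np.random.default_rng(spec.seed)
    batch_eff = {b: rng.normal(0.0, spec.sigma_batch) for b in range(spec.n_batches)}
    rows = []
    for genotype, phases in spec.phase_means.items():
        for w in range(spec.n_wells):
            batch = w % spec.n_batches
            well_id = f"{genotype}_w{w}"
            well_eff = rng.normal(0.0, spec.sigma_well)
            cycle = 0
            for phase in PHASES:
                if phase not in phases:
                    continue
                ocr_mu, ecar_mu = phases[phase]
                for m in range(spec.measurements_per_phase):
                    t = cycle * spec.cycle_min
                    ecar_mean = ecar_mu
                    if spec.dg2_slopes and phase == "post_2dg":
                        ecar_mean = ecar_mu + spec.dg2_slopes.get(genotype, 0.0) * m * spec.cycle_min
                    rows.append({
                        "well": well_id, "batch": f"b{batch}", "genotype": genotype,
                        "medium": spec.medium, "phase": phase, "time_min": t,
                        "ocr": ocr_mu + well_eff + batch_eff[batch] + rng.normal(0.0, spec.sigma_resid),
                        "ecar": ecar_mean + well_eff + batch_eff[batch] + rng.normal(0.0, spec.sigma_resid),
                    })
                    cycle += 1
    return FluxAssay(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# count matrices


@dataclass
class CountSimSpec:
    n_genes: int = 2000
    n_samples_per_group: int = 3
    base_mean: float = 100.0
    dispersion: float = 10.0               # NB size; variance = mu + mu^2/size
    frac_deg: float = 0.2
    lfc_sd: float = 1.0                    # log2 units
    min_abs_lfc: float = 0.0               # push DEG effects away from 0 (strong-effect runs)
    length_range: tuple[int, int] = (500, 5000)
    groups: tuple[str, str] = ("control", "treatment")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0 <= self.frac_deg <= 1:
            raise ValueError("frac_deg must be in [0, 1]")
        if self.length_range[0] < 1:
            raise ValueError("gene lengths must be >= 1 bp")


def simulate_counts(spec: CountSimSpec) -> tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial counts with a DEG fraction and truth labels.

    Per-gene base means are log-normal around ``base_mean``; the first
    ``frac_deg`` fraction of genes get a second-group mean scaled by
    2**lfc with lfc ~ N(0, lfc_sd).  Returns the count matrix and a truth
    frame (is_deg, true_lfc, direction).
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    lengths = pd.Series(rng.integers(spec.length_range[0], spec.length_range[1] + 1,
                                     size=spec.n_genes), index=genes, name="length")
    mu = spec.base_mean * rng.lognormal(0.0, 1.0, size=spec.n_genes)
    n_deg = int(round(spec.frac_deg * spec.n_genes))
    lfc = np.zeros(spec.n_genes)
    if n_deg:
        draws = rng.normal(0.0, spec.lfc_sd, size=n_deg)
        draws[draws == 0] = spec.lfc_sd
        if spec.min_abs_lfc > 0:
            draws = np.sign(draws) * (spec.min_abs_lfc + np.abs(draws))
        lfc[:n_deg] = draws
    mu2 = mu * 2.0**lfc

    def draw(means, n_samples):
        size = spec.dispersion
        p = size / (size + means[:, None])
        return rng.negative_binomial(size, p, size=(spec.n_genes, n_samples))

    g1, g2 = spec.groups
    c1 = draw(mu, spec.n_samples_per_group)
    c2 = draw(mu2, spec.n_samples_per_group)
    samples = [f"{g1}_{i+1}" for i in range(spec.n_samples_per_group)] + \
              [f"{g2}_{i+1}" for i in range(spec.n_samples_per_group)]
    counts = pd.DataFrame(np.hstack([c1, c2]), index=genes, columns=samples)
    group_map = pd.Series({s: (g1 if s.startswith(g1) else g2) for s in samples})
    truth = pd.DataFrame({"is_deg": lfc != 0, "true_lfc": lfc,
                          "direction": np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none"))},
                         index=genes)
    return CountMatrix(counts, lengths, group_map), truth


# ---------------------------------------------------------------------------
# config plumbing


_SPEC_TYPES = {"lifespan": LifespanSimSpec, "traces": TraceSimSpec,
               "flux": FluxSimSpec, "counts": CountSimSpec}


def spec_from_config(kind: str, params: dict):
    """Build a generator spec from a YAML/JSON parameter block."""
    if kind not in _SPEC_TYPES:
        raise ValueError(f"unknown generator kind {kind!r}; choose from {sorted(_SPEC_TYPES)}")
    params = dict(params)
    if kind == "lifespan" and "genotypes" in params:
        params["genotypes"] = [GenotypeLifespan(**g) if isinstance(g, dict) else GenotypeLifespan(*g)
                               for g in params["genotypes"]]
    for key in ("nh4cl_window", "length_range", "groups"):
        if key in params and isinstance(params[key], list):
            params[key] = tuple(params[key])
    return _SPEC_TYPES[kind](**params)


def write_counts(cm: CountMatrix, counts_path, lengths_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    cm.lengths.to_frame().to_csv(lengths_path, sep="\t")
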