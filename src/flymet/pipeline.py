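"""Configuration-driven orchestration across the analysis stages.

A run is described by a YAML config with per-stage parameter blocks; all
randomness flows from one root seed.  Each stage reads/writes CSV/TSV files
in the run directory and the pipeline records a manifest (config hash,
seeds, per-file SHA-256 checksums, warnings, timings).  The pipeline adds
no computation of its own: every stage is a thin call into the library and
can be run standalone on its own inputs.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import flux as flux_mod
from . import simulate as sim
from . import survival as surv
from . import traces as traces_mod
from . import transcriptome as tx

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "make_fixtures", "STAGES"]

STAGES = ["simulate", "surv", "traces", "flux", "tx"]


@dataclass
class RunConfig:
    out_dir: Path
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    params: dict = field(default_factory=dict)      # per-stage blocks

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(out_dir=raw.get("out_dir", "run"), stages=raw.get("stages", list(STAGES)),
                   seed=int(raw.get("seed", 0)), params=raw.get("params", {}))

    def digest(self) -> str:
        blob = json.dumps({"stages": self.stages, "seed": self.seed, "params": self.params},
                          sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)      # stage -> {outputs, elapsed_s}
    warnings: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config_hash": self.config_hash, "seed": self.seed,
                       "stages": self.stages, "warnings": self.warnings}, fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _require(path: Path, stage: str) -> Path:
    if not Path(path).exists():
        raise FileNotFoundError(f"stage {stage!r}: required input {path} is missing "
                                f"(run the upstream stage first)")
    return Path(path)


def _stage_simulate(cfg: RunConfig, d: Path) -> list[Path]:
    p = cfg.params.get("simulate", {})
    rng_seed = cfg.seed

    life = sim.spec_from_config("lifespan", {
        "genotypes": p.get("genotypes", [{"label": "control", "alpha": 0.002, "beta": 0.08},
                                         {"label": "tau", "alpha": 0.002, "beta": 0.16}]),
        "seed": rng_seed, **p.get("lifespan", {})})
    sim.simulate_lifespans(life).to_csv(d / "census.csv")

    tr_spec = sim.spec_from_config("traces", {"seed": rng_seed + 1, **p.get("traces", {})})
    sim.simulate_traces(tr_spec).to_csv(d / "traces.csv")
    ev = tr_spec.events
    with open(d / "events.yaml", "w") as fh:
        yaml.safe_dump({"treatment": ev.treatment, "washout": ev.washout,
                        "nh4cl_start": ev.nh4cl_start, "nh4cl_end": ev.nh4cl_end}, fh)

    fx_spec = sim.spec_from_config("flux", {"seed": rng_seed + 2, **p.get("flux", {})})
    sim.simulate_flux_plate(fx_spec).to_csv(d / "flux.csv")

    ct_spec = sim.spec_from_config("counts", {"seed": rng_seed + 3, **p.get("counts", {})})
    cm, truth = sim.simulate_counts(ct_spec)
    sim.write_counts(cm, d / "counts.tsv", d / "lengths.tsv")
    truth.to_csv(d / "deg_truth.tsv", sep="\t")
    cm.groups.to_frame("group").to_csv(d / "sample_groups.tsv", sep="\t")
    return [d / f for f in ("census.csv", "traces.csv", "events.yaml", "flux.csv",
                            "counts.tsv", "lengths.tsv", "deg_truth.tsv", "sample_groups.tsv")]


def _stage_surv(cfg: RunConfig, d: Path) -> list[Path]:
    p = cfg.params.get("surv", {})
    table = surv.SurvivalTable.from_csv(_require(d / "census.csv", "surv"))
    events = surv.impute_event_times(table, rule=p.get("rule", "interval_midpoint"))
    fits = [surv.fit_gompertz(ev) for ev in events.values()]
    surv.fits_to_frame(fits).to_csv(d / "gompertz_fits.csv", index=False)
    out = [d / "gompertz_fits.csv"]
    for param in ("alpha", "beta"):
        comps = surv.compare_parameters(fits, param)
        path = d / f"comparisons_{param}.csv"
        surv.comparisons_to_frame(comps).to_csv(path, index=False)
        out.append(path)
    return out


def _load_events(path) -> traces_mod.TraceEvents:
    with open(path) as fh:
        ev = yaml.safe_load(fh)
    return traces_mod.TraceEvents(ev["treatment"], ev["washout"], ev["nh4cl_start"], ev["nh4cl_end"])


def _stage_traces(cfg: RunConfig, d: Path) -> list[Path]:
    p = cfg.params.get("traces", {})
    data = pd.read_csv(_require(d / "traces.csv", "traces"))
    events = _load_events(_require(d / "events.yaml", "traces"))
    ts = traces_mod.RatioTraceSet(data, events)
    corr = traces_mod.TraceCorrector(baseline_method=p.get("baseline_method", "ols"),
                                     ph_scope=p.get("ph_scope", "per_roi"))
    corr.fit(ts)
    corr.corrected_frame().to_csv(d / "corrected_traces.csv", index=False)
    corr.integrated_changes().to_csv(d / "integrated_changes.csv", index=False)
    return [d / "corrected_traces.csv", d / "integrated_changes.csv"]


def _stage_flux(cfg: RunConfig, d: Path) -> list[Path]:
    assay = flux_mod.FluxAssay.from_csv(_require(d / "flux.csv", "flux"))
    out = []
    per, con = flux_mod.glycolytic_reserve(assay)
    per.to_csv(d / "glycolytic_reserve.csv", index=False)
    con.to_csv(d / "glycolytic_reserve_contrasts.csv", index=False)
    out += [d / "glycolytic_reserve.csv", d / "glycolytic_reserve_contrasts.csv"]
    emms, con = flux_mod.maximal_ecar(assay)
    emms.to_csv(d / "maximal_ecar.csv", index=False)
    out.append(d / "maximal_ecar.csv")
    for name, (per, con) in flux_mod.ocr_metrics(assay).items():
        path = d / f"ocr_{name}.csv"
        per.to_csv(path, index=False)
        out.append(path)
    return out


def _stage_tx(cfg: RunConfig, d: Path) -> list[Path]:
    counts = pd.read_csv(_require(d / "counts.tsv", "tx"), sep="\t", index_col=0)
    lengths = pd.read_csv(_require(d / "lengths.tsv", "tx"), sep="\t", index_col=0).iloc[:, 0]
    groups = pd.read_csv(_require(d / "sample_groups.tsv", "tx"), sep="\t", index_col=0)["group"]
    cm = tx.CountMatrix(counts, lengths, groups)
    tpm_mat = tx.tpm(cm)
    tpm_mat.to_csv(d / "tpm.tsv", sep="\t")
    coords, varfrac, _ = tx.pca_kmeans(tpm_mat, k=2, seed=cfg.seed)
    coords.to_csv(d / "pca_clusters.csv")
    return [d / "tpm.tsv", d / "pca_clusters.csv"]


_STAGE_FUNCS = {"simulate": _stage_simulate, "surv": _stage_surv,
                "traces": _stage_traces, "flux": _stage_flux, "tx": _stage_tx}


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the requested stages in dependency order and write a manifest."""
    d = config.out_dir
    d.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.digest(), config.seed)
    ordered = [s for s in STAGES if s in config.stages]
    for stage in ordered:
        t0 = time.perf_counter()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            outputs = _STAGE_FUNCS[stage](config, d)
        manifest.warnings.extend(f"{stage}: {w.message}" for w in caught)
        manifest.stages[stage] = {
            "elapsed_s": round(time.perf_counter() - t0, 3),
            "outputs": {str(p.name): _sha256(p) for p in outputs},
        }
    manifest.to_json(d / "manifest.json")
    return manifest


def make_fixtures(seed: int, out_dir) -> dict[str, str]:
    """Write the small toy datasets used in docs and tests; returns checksums."""
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    life = sim.LifespanSimSpec(genotypes=[sim.GenotypeLifespan("control", 0.002, 0.08, 30),
                                          sim.GenotypeLifespan("tau", 0.002, 0.16, 30)], seed=seed)
    sim.simulate_lifespans(life).to_csv(d / "toy_census.csv")
    tr = sim.TraceSimSpec(n_rois=5, seed=seed + 1)
    sim.simulate_traces(tr).to_csv(d / "toy_traces.csv")
    fx = sim.FluxSimSpec(n_wells=4, n_batches=2, seed=seed + 2)
    sim.simulate_flux_plate(fx).to_csv(d / "toy_flux.csv")
    cm, _ = sim.simulate_counts(sim.CountSimSpec(n_genes=50, seed=seed + 3))
    sim.write_counts(cm, d / "toy_counts.tsv", d / "toy_lengths.tsv")
    return {p.name: _sha256(p) for p in sorted(d.iterdir()) if p.is_file()}
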