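"""End-to-end orchestration: config validation and the full pipeline run.

A run goes: generate (or load) data → thin occurrences → pool into clades →
sample pseudo-absences → screen predictors → fit the four-model battery →
replicate evaluation → AUC-weighted ensemble → project current and scenario
climates → MPA binarisation → footprint mask → dispersal scenarios → range
change → threat levels + landscape metrics.  Every artefact lands in a run
directory with a checksummed manifest, and every stage draws its seed
deterministically from the master seed and stage name, so a run is fully
reproducible from (config, seed).

Defaults mirror standard practice for this analysis: 10 km thinning radius,
10,000 pseudo-absences, VIF threshold 6 with |r| ≤ 0.75, 10 evaluation
replicates at a 75/25 split, footprint cutoff 50, four GCMs × two RCPs × two
periods.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthgrid
from .errors import ConfigurationError
from .evaluation import build_ensemble, evaluate_replicates, predict_ensemble
from .niche_models import make_model, serialize_model
from .occurrences import OccurrenceSet, pool_by_clade, thin_occurrences
from .predictors import build_training_table, sample_pseudo_absences, select_predictors
from .projection import (
    BinaryRangeMap,
    RangeChangeSummary,
    ScenarioPlan,
    apply_dispersal,
    average_over_gcms,
    apply_footprint_mask,
    binarize,
    enumerate_projections,
    mean_range_altitude,
    mpa_threshold,
    range_change,
    summarize_over_gcms,
)
from .raster import PredictorStack, RasterGrid
from .risk import LandscapeMetrics, assess

logger = logging.getLogger(__name__)

DEFAULT_GCMS = ["CCSM4", "CNRM-CM5", "HadGEM2-ES", "MIROC5"]
DEFAULT_RCPS = ["RCP4.5", "RCP8.5"]
DEFAULT_PERIODS = ["2050", "2070"]

#: Relative severity of each (rcp, period) scenario applied to the synthetic
#: climate shift; ordered so contraction grows over time and with emissions.
SCENARIO_SEVERITY = {
    ("RCP4.5", "2050"): 1.0,
    ("RCP8.5", "2050"): 1.6,
    ("RCP4.5", "2070"): 1.8,
    ("RCP8.5", "2070"): 2.6,
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study system."""

    n_rows: int = 100
    n_cols: int = 100
    n_layers: int = 6
    autocorr_range_cells: float = 10.0
    collinear_pairs: int = 2
    relief_m: float = 3000.0
    developed_fraction: float = 0.1
    prevalence_target: float = 0.15
    n_occurrences: int = 300
    shift_layer: str = "bio1"
    base_shift: float = 0.12
    noise_sd: float = 0.05
    linear_coef: float = 8.0
    quadratic_coef: float = -16.0


@dataclass
class FilesConfig:
    """Paths to user-supplied data (all plain-text rasters/CSV)."""

    stack_dir: str = ""
    dem: str = ""
    footprint: str = ""
    occurrences: str = ""
    future_stack_dirs: dict = field(default_factory=dict)  # "gcm/rcp/period" -> dir


@dataclass
class PipelineConfig:
    """Validated, fully-defaulted pipeline settings."""

    mode: str = "synthetic"
    seed: int = 1
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    files: FilesConfig = field(default_factory=FilesConfig)
    thinning_radius_km: float = 10.0
    pseudo_absences: int = 10_000
    vif_threshold: float = 6.0
    cor_threshold: float = 0.75
    algorithms: list = field(default_factory=lambda: ["GLM", "GBM", "SRE", "MAXENT"])
    replicates: int = 10
    train_fraction: float = 0.75
    gcms: list = field(default_factory=lambda: list(DEFAULT_GCMS))
    rcps: list = field(default_factory=lambda: list(DEFAULT_RCPS))
    periods: list = field(default_factory=lambda: list(DEFAULT_PERIODS))
    footprint_cutoff: float = 50.0
    dispersal: list = field(default_factory=lambda: ["none", "unlimited"])
    connectivity: str = "rook"
    si_denominator: str = "landscape"

    def plan(self) -> ScenarioPlan:
        return ScenarioPlan(list(self.algorithms), self.replicates,
                            list(self.gcms), list(self.rcps), list(self.periods))


def _apply_section(obj, section: dict, path: str) -> None:
    for key, value in section.items():
        if not hasattr(obj, key):
            raise ConfigurationError(f"unknown config key '{path}{key}'")
        current = getattr(obj, key)
        if isinstance(current, (SyntheticConfig, FilesConfig)):
            if not isinstance(value, dict):
                raise ConfigurationError(f"{path}{key} must be a mapping")
            _apply_section(current, value, f"{path}{key}.")
        else:
            setattr(obj, key, value)


def validate_config(raw: dict | None) -> PipelineConfig:
    """Fill defaults, reject unknown keys, sanity-check counts and modes."""
    cfg = PipelineConfig()
    _apply_section(cfg, raw or {}, "")
    if cfg.mode not in ("synthetic", "files"):
        raise ConfigurationError("mode must be 'synthetic' or 'files'")
    positive = {
        "thinning_radius_km": cfg.thinning_radius_km,
        "pseudo_absences": cfg.pseudo_absences,
        "vif_threshold": cfg.vif_threshold,
        "cor_threshold": cfg.cor_threshold,
        "replicates": cfg.replicates,
        "synthetic.n_occurrences": cfg.synthetic.n_occurrences,
        "synthetic.n_rows": cfg.synthetic.n_rows,
        "synthetic.n_cols": cfg.synthetic.n_cols,
    }
    for name, value in positive.items():
        if value <= 0:
            raise ConfigurationError(f"{name} must be positive, got {value}")
    if not 0 < cfg.train_fraction < 1:
        raise ConfigurationError("train_fraction must be in (0, 1)")
    unknown_disp = set(cfg.dispersal) - {"none", "unlimited"}
    if unknown_disp:
        raise ConfigurationError(f"unknown dispersal scenario(s) {sorted(unknown_disp)}")
    if cfg.mode == "files":
        for attr in ("stack_dir", "dem", "footprint", "occurrences"):
            p = getattr(cfg.files, attr)
            if not p or not Path(p).exists():
                raise ConfigurationError(f"files.{attr} missing or does not exist: {p!r}")
    logger.info("resolved config: %s", json.dumps(asdict(cfg), default=str))
    return cfg


def stage_seed(master: int, stage: str, clade: str = "") -> int:
    """Deterministic per-stage seed below 2^31; stable across clade additions."""
    token = f"{master}:{stage}:{clade}".encode()
    return int.from_bytes(hashlib.sha256(token).digest()[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _synthetic_inputs(cfg: PipelineConfig):
    s = cfg.synthetic
    seed = stage_seed(cfg.seed, "generate")
    stack = synthgrid.make_climate_stack(
        seed, n_layers=s.n_layers, n_rows=s.n_rows, n_cols=s.n_cols,
        autocorr_range_cells=s.autocorr_range_cells,
        collinear_pairs=s.collinear_pairs)
    dem = synthgrid.make_dem(seed, s.n_rows, s.n_cols, s.relief_m)
    footprint = synthgrid.make_footprint(seed, stack.reference,
                                         s.developed_fraction)
    spec = synthgrid.VirtualSpeciesSpec(
        coefficients={s.shift_layer: (s.linear_coef, s.quadratic_coef)},
        prevalence_target=s.prevalence_target)
    suit = synthgrid.true_suitability(stack, spec)
    occs = synthgrid.sample_occurrences(
        suit, s.n_occurrences, stage_seed(cfg.seed, "occurrences"))
    # a base layer and its collinear copies shift coherently, as physically
    # correlated climate variables do
    partners = synthgrid.collinear_partners(s.n_layers, s.collinear_pairs)
    shifted_layers = [s.shift_layer, *partners.get(s.shift_layer, [])]
    futures = {}
    for gcm in cfg.gcms:
        for rcp in cfg.rcps:
            for period in cfg.periods:
                severity = SCENARIO_SEVERITY.get((rcp, period), 1.0)
                pert = synthgrid.ScenarioPerturbation(
                    gcm_name=gcm, rcp_name=rcp, period=period,
                    additive_shift={l: severity * s.base_shift
                                    for l in shifted_layers},
                    noise_sd=s.noise_sd)
                futures[(gcm, rcp, period)] = synthgrid.make_future_stack(
                    stack, pert, stage_seed(cfg.seed, "future"))
    return stack, dem, footprint, occs, futures


def _file_inputs(cfg: PipelineConfig):
    f = cfg.files
    stack = PredictorStack.read_dir(f.stack_dir)
    dem = RasterGrid.read_ascii(f.dem)
    footprint = RasterGrid.read_ascii(f.footprint)
    occs = OccurrenceSet.read_csv(f.occurrences)
    futures = {}
    for key, d in f.future_stack_dirs.items():
        gcm, rcp, period = key.split("/")
        futures[(gcm, rcp, period)] = PredictorStack.read_dir(d)
    return stack, dem, footprint, occs, futures


def run_clade(clade: str, occs: OccurrenceSet, stack: PredictorStack,
              dem: RasterGrid, footprint: RasterGrid, futures: dict,
              cfg: PipelineConfig, out_dir: Path | None = None) -> dict:
    """Model one clade end to end; returns its tables and maps."""
    seed = lambda stage: stage_seed(cfg.seed, stage, clade)  # noqa: E731

    absences = sample_pseudo_absences(stack, cfg.pseudo_absences,
                                      seed("pseudo_absences"))
    table = build_training_table(stack, occs.lonlat, absences)
    retained, selection_log = select_predictors(
        table, cfg.vif_threshold, cfg.cor_threshold)
    table = table.subset(retained)

    algorithms = {a: make_model(a, seed=seed(f"fit:{a}")) for a in cfg.algorithms}
    eval_records = evaluate_replicates(
        table, algorithms, n_replicates=cfg.replicates,
        train_fraction=cfg.train_fraction, seed=seed("evaluate"))
    ensemble = build_ensemble(table, algorithms, eval_records)

    current_suit = predict_ensemble(ensemble, stack.subset(retained))
    threshold = mpa_threshold(current_suit, occs)
    current_bin = apply_footprint_mask(binarize(current_suit, threshold),
                                       footprint, cfg.footprint_cutoff)

    summaries: list[RangeChangeSummary] = []
    metrics: dict[tuple, LandscapeMetrics] = {}
    metrics[(clade, "current", "", "", "")] = LandscapeMetrics.of(
        current_bin, cfg.connectivity, cfg.si_denominator)
    scenario_maps: dict[tuple, list] = {}
    for (gcm, rcp, period), future_stack in futures.items():
        fut_suit = predict_ensemble(ensemble, future_stack.subset(retained))
        scenario_maps.setdefault((rcp, period), []).append(fut_suit)
        fut_bin = apply_footprint_mask(binarize(fut_suit, threshold),
                                       footprint, cfg.footprint_cutoff)
        for disp in cfg.dispersal:
            realized = apply_dispersal(current_bin, fut_bin, disp)
            meta = dict(clade=clade, gcm=gcm, rcp=rcp, period=period,
                        dispersal=disp)
            summary = range_change(current_bin, realized, **meta)
            if realized.n_suitable:
                summary.mean_altitude_m = mean_range_altitude(realized, dem)
                metrics[(clade, gcm, rcp, period, disp)] = LandscapeMetrics.of(
                    realized, cfg.connectivity, cfg.si_denominator)
            summaries.append(summary)

    consensus_maps = {key: average_over_gcms(maps)
                      for key, maps in scenario_maps.items()}
    result = {
        "clade": clade,
        "threshold": threshold,
        "selection": {"retained": retained, "log": selection_log},
        "eval_records": eval_records,
        "summaries": summaries,
        "metrics": metrics,
        "current_map": current_bin,
        "consensus_maps": consensus_maps,
        "ensemble": ensemble,
        "table": table,
    }
    if out_dir is not None:
        _write_clade(result, out_dir)
    return result


def _write_clade(result: dict, out_dir: Path) -> None:
    d = out_dir / f"clade_{result['clade']}"
    d.mkdir(parents=True, exist_ok=True)
    result["table"].write_csv(d / "training.csv")
    (d / "selection.json").write_text(json.dumps(result["selection"], indent=1))
    result["eval_records"].to_csv(d / "eval_records.csv", index=False)
    result["current_map"].write_ascii(d / "current_range.asc")
    for (rcp, period), smap in result["consensus_maps"].items():
        smap.write_ascii(d / f"consensus_{rcp}_{period}.asc")
    weights = {m.algorithm: float(w) for m, w in
               zip(result["ensemble"].members, result["ensemble"].weights)}
    members = [serialize_model(m, blob_dir=d)
               for m in result["ensemble"].members]
    (d / "ensemble.json").write_text(json.dumps(
        {"threshold": result["threshold"], "weights": weights,
         "members": members}, indent=1))


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline; returns the run directory.

    Writes occurrence/evaluation/summary/risk tables, per-clade artefacts and
    a ``manifest.json`` with a sha256 checksum of every output plus the
    enumerated projection-task count.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "load" if cfg.mode == "files" else "generate"
    try:
        if cfg.mode == "synthetic":
            stack, dem, footprint, occs, futures = _synthetic_inputs(cfg)
        else:
            stack, dem, footprint, occs, futures = _file_inputs(cfg)
        stage = "thin"
        occs = thin_occurrences(occs, cfg.thinning_radius_km,
                                stage_seed(cfg.seed, "thin"))
        occs.write_csv(out_dir / "occurrences_thinned.csv")
        stage = "pool"
        labels = occs.data["clade"].unique()
        clades = pool_by_clade(occs, {l: l for l in labels})

        all_summaries: list[RangeChangeSummary] = []
        all_metrics: dict[tuple, LandscapeMetrics] = {}
        for clade, clade_occs in clades.items():
            stage = f"clade:{clade}"
            result = run_clade(clade, clade_occs, stack, dem, footprint,
                               futures, cfg, out_dir)
            all_summaries.extend(result["summaries"])
            all_metrics.update(result["metrics"])

        stage = "report"
        report = assess(all_summaries, all_metrics)
        report.to_csv(out_dir / "risk_report.csv", index=False)
        summarize_over_gcms(all_summaries).to_csv(
            out_dir / "summary_over_gcms.csv", index=False)

        plan = cfg.plan()
        tasks = enumerate_projections(plan)
        manifest = {
            "seed": cfg.seed,
            "n_projection_tasks_per_clade": len(tasks),
            "clades": sorted(clades),
            "outputs": {},
        }
        for p in sorted(out_dir.rglob("*")):
            if p.is_file() and p.name != "manifest.json":
                manifest["outputs"][str(p.relative_to(out_dir))] = _sha256(p)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except Exception as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out_dir
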