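"""End-to-end pipeline: clean -> thin -> split -> M -> jackknife -> grid
calibration -> selection -> bootstrap -> transfer -> MOP -> agreement.

`run_pipeline` drives the whole workflow from a single
:class:`PipelineConfig`, either on user-supplied occurrence/layer files or
on a freshly simulated virtual species, and writes every artifact (CSV
tables, model JSON, ASCII rasters, a machine-readable run log with the
seeds and a config hash) into a run directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .maxent import ALLOWED_COMBOS, FeatureConfig
from .occurrences import (
    OccurrenceSet,
    build_M,
    filter_by_range,
    filter_by_uncertainty,
    spatial_thin,
    split_calibration_evaluation,
)
from .projection import (
    binarize,
    extrapolation_agreement,
    gcm_agreement,
    mop,
    suitability_threshold,
    transfer,
)
from .rasters import RasterStack, write_ascii_grid
from .selection import (
    CalibrationGrid,
    best_candidate,
    bootstrap_ensemble,
    enumerate_rm_values,
    jackknife_sets_for_grid,
    jackknife_variable_sets,
    occurrence_values,
    results_to_frame,
    run_calibration,
)

log = logging.getLogger(__name__)

#: mixed temperature/precipitation layers excluded before variable selection
DEFAULT_EXCLUSION = ("BIO_8", "BIO_9", "BIO_18", "BIO_19")

#: the protocol's published bioclimatic variable sets (jackknife steps 2-4):
#: nested subsets ending in annual mean temperature, annual precipitation,
#: precipitation seasonality and precipitation of the driest quarter
PROTOCOL_VARIABLE_SETS = {
    "set_1": [
        "BIO_1", "BIO_2", "BIO_5", "BIO_6", "BIO_11", "BIO_12",
        "BIO_13", "BIO_14", "BIO_15", "BIO_16", "BIO_17",
    ],
    "set_2": ["BIO_1", "BIO_5", "BIO_11", "BIO_12", "BIO_14", "BIO_15", "BIO_17"],
    "set_3": ["BIO_1", "BIO_12", "BIO_15", "BIO_17"],
}


@dataclass
class PipelineConfig:
    """Every tunable constant of the workflow, with the protocol defaults."""

    seed: int = 0
    # input paths (None -> simulate a virtual species)
    occurrences_csv: str | None = None
    layers_dir: str | None = None
    range_geojson: str | None = None
    # synthetic-data settings
    sim_grid_rows: int = 60
    sim_grid_cols: int = 60
    sim_n_presences: int = 250
    exclusion_list: tuple[str, ...] = DEFAULT_EXCLUSION
    # cleaning / splitting
    max_uncertainty_m: float = 10_000.0
    min_distance_km: float = 50.0
    split_fraction: float = 0.5
    buffer_degrees: float = 7.0
    # variable selection
    jackknife_steps: int = 4
    drop_fraction: float = 0.25
    # candidate grid
    rm_values: tuple[float, ...] = tuple(enumerate_rm_values())
    feature_combos: tuple[tuple[str, ...], ...] = ALLOWED_COMBOS
    n_threshold_knots: int = 10
    n_hinge_knots: int = 20
    max_background: int = 10_000
    # selection thresholds
    p_threshold: float = 0.1
    omission_threshold: float = 0.1
    delta_aicc_threshold: float = 2.0
    e_threshold: float = 0.05
    proc_iterations: int = 500
    proc_resample: float = 0.5
    n_replicates: int = 10
    # projection
    mop_fraction: float = 0.1
    n_gcms: int = 4
    scenarios: tuple[tuple[str, float], ...] = (("rcp45", 1.0), ("rcp85", 2.0))
    future_delta: float = 2.0
    future_delta_sd: float = 0.5
    write_rasters: bool = True

    def config_hash(self) -> str:
        doc = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    """In-memory handles to everything the pipeline produced."""

    config: PipelineConfig
    stack: RasterStack
    occ_thinned: OccurrenceSet
    occ_cal: OccurrenceSet
    occ_eval: OccurrenceSet
    variable_sets: dict[str, list[str]]
    candidates: list
    best: object
    ensemble: object
    present_median: np.ndarray
    present_range: np.ndarray
    threshold: float
    projections: dict
    agreement: dict
    extrapolation: dict
    out_dir: Path | None = None


def _load_inputs(cfg: PipelineConfig):
    if cfg.occurrences_csv and cfg.layers_dir:
        stack = RasterStack.read_dir(cfg.layers_dir)
        occ = OccurrenceSet.from_csv(cfg.occurrences_csv)
        futures = None
    else:
        stack, vs, _suit, occ = synthetic.default_virtual_species(
            seed=cfg.seed,
            grid_rows=cfg.sim_grid_rows,
            grid_cols=cfg.sim_grid_cols,
            n_presences=cfg.sim_n_presences,
        )
        futures = None
    return stack, occ, futures


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> RunResult:
    """Execute the full workflow; see the module docstring for the stages."""
    t0 = time.time()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stack, occ_raw, _ = _load_inputs(cfg)

    # --- cleaning -----------------------------------------------------
    occ = filter_by_uncertainty(occ_raw, cfg.max_uncertainty_m)
    if cfg.range_geojson:
        from shapely.geometry import shape

        with open(cfg.range_geojson) as fh:
            geo = json.load(fh)
        geom = geo["features"][0]["geometry"] if "features" in geo else geo
        occ = filter_by_range(occ, shape(geom))
    occ_thin = spatial_thin(occ, cfg.min_distance_km, seed=cfg.seed)
    occ_cal, occ_eval = split_calibration_evaluation(
        occ_thin, cfg.split_fraction, seed=cfg.seed + 1
    )

    # --- accessible area and variable selection -----------------------
    area = build_M(occ_thin, stack, cfg.buffer_degrees)
    exclude = [n for n in cfg.exclusion_list if n in stack.layer_names]
    report = jackknife_variable_sets(
        occ_cal,
        stack,
        area,
        max_steps=cfg.jackknife_steps,
        drop_fraction=cfg.drop_fraction,
        exclude=exclude,
        max_background=cfg.max_background,
        seed=cfg.seed,
    )
    variable_sets = jackknife_sets_for_grid(report)

    # --- candidate grid ------------------------------------------------
    grid = CalibrationGrid(
        variable_sets=variable_sets,
        rm_values=list(cfg.rm_values),
        feature_combos=cfg.feature_combos,
        n_threshold_knots=cfg.n_threshold_knots,
        n_hinge_knots=cfg.n_hinge_knots,
    )
    results = run_calibration(
        grid,
        occ_cal,
        occ_eval,
        stack,
        seed=cfg.seed,
        area=area,
        max_background=cfg.max_background,
        e_threshold=cfg.e_threshold,
        p_threshold=cfg.p_threshold,
        omission_threshold=cfg.omission_threshold,
        delta_aicc_threshold=cfg.delta_aicc_threshold,
        proc_iterations=cfg.proc_iterations,
        proc_resample=cfg.proc_resample,
    )
    best = best_candidate(results)

    ensemble = None
    present_median = present_range = None
    threshold = float("nan")
    projections: dict = {}
    agreement: dict = {}
    extrap: dict = {}
    if best is not None:
        var_set = grid.variable_sets[best.variable_set]
        fc = FeatureConfig(
            classes=tuple(c.upper() for c in best.features),
            n_threshold_knots=cfg.n_threshold_knots,
            n_hinge_knots=cfg.n_hinge_knots,
        )
        ensemble = bootstrap_ensemble(
            var_set,
            fc,
            best.rm,
            occ_cal,
            stack,
            area,
            n_replicates=cfg.n_replicates,
            max_background=cfg.max_background,
            seed=cfg.seed + 2,
        )
        present_median, present_range = ensemble.median, ensemble.range_
        cal_vals = occurrence_values(occ_cal, stack, var_set)
        cal_suit = np.median(
            np.stack([m.logistic_values(cal_vals) for m in ensemble.models]), axis=0
        )
        threshold = suitability_threshold(cal_suit, cfg.e_threshold)

        # --- futures ---------------------------------------------------
        fut_cfg = synthetic.FutureSimConfig(
            n_gcms=cfg.n_gcms,
            scenarios=cfg.scenarios,
            delta_mean={n: cfg.future_delta for n in var_set[:1]},
            delta_sd=cfg.future_delta_sd,
            seed=cfg.seed + 3,
        )
        futures = synthetic.generate_future_stacks(stack, fut_cfg)
        present_bin = binarize(present_median, threshold)
        valid = stack.valid_mask()
        for (gcm, scen), fstack in futures.items():
            med, rng_ = transfer(ensemble, fstack)
            sim, strict = mop(stack, area.mask, fstack, var_set, cfg.mop_fraction)
            projections[(gcm, scen)] = {
                "median": med,
                "range": rng_,
                "mop_similarity": sim,
                "strict": strict,
            }
        for scen, _intensity in cfg.scenarios:
            gcms = sorted({g for (g, s) in futures if s == scen})
            future_bins = [
                binarize(projections[(g, scen)]["median"], threshold) for g in gcms
            ]
            agreement[scen] = gcm_agreement(present_bin, future_bins, valid_mask=valid)
            extrap[scen] = extrapolation_agreement(
                [projections[(g, scen)]["strict"] for g in gcms]
            )

    result = RunResult(
        config=cfg,
        stack=stack,
        occ_thinned=occ_thin,
        occ_cal=occ_cal,
        occ_eval=occ_eval,
        variable_sets=variable_sets,
        candidates=results,
        best=best,
        ensemble=ensemble,
        present_median=present_median,
        present_range=present_range,
        threshold=threshold,
        projections=projections,
        agreement=agreement,
        extrapolation=extrap,
        out_dir=out,
    )
    if out is not None:
        _write_artifacts(result, report)
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return result


def _write_artifacts(res: RunResult, report) -> None:
    out = res.out_dir
    cfg = res.config
    chash = cfg.config_hash()
    assert out is not None
    res.occ_thinned.to_csv(out / "occurrences_thinned.csv")
    res.occ_cal.to_csv(out / "occurrences_calibration.csv")
    res.occ_eval.to_csv(out / "occurrences_evaluation.csv")
    frame = results_to_frame(res.candidates)
    with open(out / "candidates.csv", "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        frame.to_csv(fh, index=False)
    if res.ensemble is not None:
        models_dir = out / "models"
        models_dir.mkdir(exist_ok=True)
        for i, m in enumerate(res.ensemble.models):
            (models_dir / f"replicate_{i:02d}.json").write_text(m.to_json())
    if cfg.write_rasters and res.present_median is not None:
        grid = res.stack.grid
        write_ascii_grid(out / "suitability_median.asc", grid, res.present_median)
        write_ascii_grid(out / "suitability_range.asc", grid, res.present_range)
        for (gcm, scen), proj in res.projections.items():
            write_ascii_grid(out / f"suitability_{gcm}_{scen}.asc", grid, proj["median"])
            write_ascii_grid(out / f"mop_{gcm}_{scen}.asc", grid, proj["mop_similarity"])
            write_ascii_grid(
                out / f"strict_{gcm}_{scen}.asc", grid, proj["strict"].astype(float)
            )
        for scen, codes in res.agreement.items():
            write_ascii_grid(out / f"agreement_{scen}.asc", grid, codes.astype(float))
        for scen, counts in res.extrapolation.items():
            write_ascii_grid(
                out / f"extrapolation_agreement_{scen}.asc", grid, counts.astype(float)
            )
    run_log = {
        "config_hash": chash,
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "n_occurrences_thinned": len(res.occ_thinned),
        "n_calibration": len(res.occ_cal),
        "n_evaluation": len(res.occ_eval),
        "variable_sets": res.variable_sets,
        "jackknife": [
            {
                "variables": s.variables,
                "gain_alone": s.gain_alone,
                "gain_drop": s.gain_drop,
                "surviving": s.surviving,
            }
            for s in report.steps
        ],
        "n_candidates": len(res.candidates),
        "selected": [r.candidate_id for r in res.candidates if r.selected],
        "best": res.best.candidate_id if res.best else None,
        "threshold": res.threshold,
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=1, default=str))
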