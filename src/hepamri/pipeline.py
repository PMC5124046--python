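"""End-to-end orchestration of the two imaging arms plus statistics.

``run_pipeline`` either simulates a cohort (control + ConA groups) or
consumes user data from a manifest directory, then runs the DCE arm
(normalize, EMM fit, derived parameters), the ASL arm (T1 maps,
perfusion map, threshold, ROI summary) and the cohort statistics
(group comparisons and the Spearman matrix), writing per-animal JSON,
group CSVs and a run log that records every setting and seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import asl, dce, stats, synthetic
from .config import ConfigError, PipelineConfig

logger = logging.getLogger(__name__)

#: per-animal parameters compared between groups
_COMPARED = ["A", "alpha", "beta", "gamma", "q",
             "t_peak", "es", "t_half", "auc", "perfusion", "t1_ns"]


def _analyze_animal_dce(curve: dce.DCECurve, cfg: PipelineConfig) -> dict:
    norm = dce.normalize_curve(curve)
    fit = dce.fit_emm(norm, r2_gate=cfg.r2_gate)
    derived = dce.derive_parameters(norm, fit.params)
    out = {"emm": fit.params.as_dict(), "derived": derived.as_dict(),
           "gate_passed": fit.gate_passed}
    return out


def _analyze_animal_asl(ir_sel: asl.IRSeries, ir_ns: asl.IRSeries,
                        rois: list[np.ndarray], cfg: PipelineConfig) -> dict:
    t1_sel = asl.compute_t1_map(ir_sel)
    t1_ns = asl.compute_t1_map(ir_ns)
    pmap = asl.compute_perfusion_map(t1_sel, t1_ns, cfg.lambda_partition)
    pmap = asl.threshold_map(pmap, cfg.threshold_lo, cfg.threshold_hi)
    perf = asl.roi_summary(pmap, rois)
    t1_summary = asl.roi_summary(t1_ns, rois)
    return {"perfusion": perf.pooled_mean, "perfusion_roi_means": perf.means,
            "t1_ns": t1_summary.pooled_mean,
            "n_valid_pixels": int(pmap.valid_mask.sum())}


def _default_rois(shape: tuple[int, int]) -> list[np.ndarray]:
    return synthetic.corner_rois(shape, n_rois=3)


def _load_cohort(input_dir: Path, cfg: PipelineConfig) -> synthetic.Cohort:
    """Reconstruct a cohort from a manifest directory written by
    :func:`hepamri.synthetic.write_cohort`."""
    manifest_path = input_dir / "manifest.json"
    if not manifest_path.exists():
        raise ConfigError(f"manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    animals = []
    from .emm import EMMParams
    for entry in manifest["animals"]:
        curve = ir_sel = ir_ns = None
        if "curve_csv" in entry:
            p = input_dir / entry["curve_csv"]
            if not p.exists():
                raise ConfigError(f"curve file missing: {p}")
            curve = dce.read_curve_csv(p, cfg.schedule.injection_time)
        for key, attr in (("ir_sel", "sel"), ("ir_ns", "ns")):
            if key in entry:
                p = input_dir / entry[key]
                sidecar = p.with_suffix(p.suffix + ".json")
                if not sidecar.exists():
                    raise ConfigError(f"missing IR sidecar: {sidecar}")
                series = asl.load_ir_series(p)
                if attr == "sel":
                    ir_sel = series
                else:
                    ir_ns = series
        animals.append(synthetic.SyntheticAnimal(
            group=entry["group"], index=entry["index"], seed=entry["seed"],
            true_emm=EMMParams.from_dict(entry["true_emm"]),
            true_f=entry["true_f"], true_t1_ns=entry["true_t1_ns"],
            covariates=entry["covariates"], curve=curve,
            ir_selective=ir_sel, ir_nonselective=ir_ns))
    return synthetic.Cohort(seed=manifest["cohort_seed"], animals=animals)


def run_pipeline(config: PipelineConfig, mode: str = "simulate") -> dict:
    """Run the full analysis; returns the cohort report as a dict.

    ``mode="simulate"`` generates a control + ConA cohort at the
    configured sizes and analyzes it; ``mode="analyze"`` consumes data
    under ``config.input_dir``.  Per-animal and per-parameter failures
    are recorded in the report, not fatal.
    """
    if mode not in ("simulate", "analyze"):
        raise ConfigError(f"mode must be simulate|analyze, got {mode!r}")
    sched = dce.AcquisitionSchedule(**config.schedule.model_dump())
    if mode == "simulate":
        specs = [synthetic.GroupSpec.control(config.n_per_group),
                 synthetic.GroupSpec.cona(config.n_per_group)]
        cohort = synthetic.simulate_cohort(
            specs, seed=config.seed, schedule=sched,
            dce_noise_sd=config.dce_noise_sd, ir_shape=config.ir_shape,
            ir_noise_frac=config.ir_noise_frac,
            lambda_partition=config.lambda_partition)
    else:
        if config.input_dir is None:
            raise ConfigError("analyze mode requires input_dir")
        cohort = _load_cohort(Path(config.input_dir), config)

    rows, per_animal, errors = [], {}, {}
    for a in cohort.animals:
        aid = f"{a.group}_{a.index}"
        record: dict = {"animal": aid, "group": a.group}
        result: dict = {}
        if a.curve is not None:
            try:
                d = _analyze_animal_dce(a.curve, config)
                result.update(d)
                record.update(d["emm"])
                record.update({k: d["derived"][k]
                               for k in ("t_peak", "es", "t_half", "auc", "r_squared")})
            except Exception as exc:
                errors[aid] = f"dce: {exc}"
        if a.ir_selective is not None and a.ir_nonselective is not None:
            try:
                shape = a.ir_nonselective.frames.shape[1:]
                d = _analyze_animal_asl(a.ir_selective, a.ir_nonselective,
                                        _default_rois(shape), config)
                result.update(d)
                record["perfusion"] = d["perfusion"]
                record["t1_ns"] = d["t1_ns"]
            except Exception as exc:
                errors[aid] = errors.get(aid, "") + f" asl: {exc}"
        record.update(a.covariates)
        rows.append(record)
        per_animal[aid] = result

    table = pd.DataFrame(rows)
    group_names = [g for g in table["group"].unique()]

    comparisons = None
    comparison_errors = {}
    if len(group_names) == 2:
        value_cols = [c for c in _COMPARED if c in table.columns]
        comparisons = stats.compare_table(table, "group", value_cols,
                                          config.normality_alpha)
    else:
        comparison_errors["groups"] = f"need 2 groups, got {group_names}"

    correlations = None
    try:
        row_vars = [c for c in ("ALT", "AST", "coagulative_necrosis",
                                "vessel_wall_infiltration", "tissue_changes")
                    if c in table.columns]
        col_vars = [c for c in ("t_peak", "A", "alpha", "beta", "gamma", "q",
                                "t_half", "es", "auc") if c in table.columns]
        if row_vars and col_vars:
            cm = stats.spearman_matrix(table, row_vars, col_vars,
                                       alpha=config.normality_alpha)
            correlations = {"r": cm.r, "p": cm.p}
    except ValueError as exc:
        comparison_errors["spearman"] = str(exc)

    report = {"mode": mode, "settings": config.settings_record(),
              "cohort_seed": cohort.seed, "n_animals": len(cohort.animals),
              "per_animal": per_animal, "table": table,
              "comparisons": comparisons, "correlations": correlations,
              "animal_errors": errors, "stage_errors": comparison_errors}

    if config.output_dir is not None:
        _write_report(report, cohort, Path(config.output_dir))
    return report


def _write_report(report: dict, cohort: synthetic.Cohort, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for aid, result in report["per_animal"].items():
        (outdir / f"{aid}.json").write_text(json.dumps(result, indent=1))
    report["table"].to_csv(outdir / "cohort_table.csv", index=False)
    if report["comparisons"] is not None:
        report["comparisons"].to_csv(outdir / "group_comparisons.csv", index=False)
        (outdir / "group_comparisons.json").write_text(
            report["comparisons"].to_json(orient="records", indent=1))
    if report["correlations"] is not None:
        report["correlations"]["r"].to_csv(outdir / "spearman_r.csv")
        report["correlations"]["p"].to_csv(outdir / "spearman_p.csv")
    log = {"settings": report["settings"], "cohort_seed": report["cohort_seed"],
           "animal_seeds": {f"{a.group}_{a.index}": a.seed for a in cohort.animals},
           "animal_errors": report["animal_errors"],
           "stage_errors": report["stage_errors"]}
    (outdir / "run_log.json").write_text(json.dumps(log, indent=1))
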