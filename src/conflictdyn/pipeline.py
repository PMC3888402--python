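"""End-to-end orchestration: simulate/load -> validate -> behavior dwell-time
analysis -> emotion fluctuation analysis -> group comparison -> report.

Stage functions are plain (DataFrame in, DataFrame out) so they can be run
individually; ``run_pipeline`` sequences them, writes the report tables and a
manifest sufficient to reproduce the run bit-for-bit, and removes partial
outputs if any stage fails.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .durations import (
    compare_fits,
    estimate_pdf_multibin,
    extract_durations,
    pool_durations,
    BEHAVIOR_STATES,
)
from .errors import (
    FitFailureError,
    InsufficientDataError,
    ParameterError,
    PipelineError,
)
from .fluctuation import (
    DEFAULT_TAIL_RANGE,
    dichotomize_and_intervals,
    power_spectrum,
    rescaled_range_hurst,
    slope_to_hurst,
)
from .groups import mann_whitney_u, summarize_groups
from .io import StudyTable, read_study, validate_session, write_study
from .synthetic import StudyGenConfig, generate_study

logger = logging.getLogger("conflictdyn")

COMPARED_METRICS = ("hurst_H", "hurst_r_squared")


@dataclass
class PipelineConfig:
    """Configuration for a full run. Exactly one of (data_path, metadata_path)
    or gen_config must be set."""

    data_path: str | None = None
    metadata_path: str | None = None
    gen_config: StudyGenConfig | None = None
    bin_widths: list[int] | None = None
    min_count: int = 5
    segment_sizes: list[int] | None = None
    tail_range: tuple[float, float] = DEFAULT_TAIL_RANGE
    psd_method: str = "periodogram"
    test_alternative: str = "less"  # intractable metric shifted low vs tractable
    out_dir: str = "results"
    master_seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        has_paths = self.data_path is not None or self.metadata_path is not None
        if has_paths == (self.gen_config is not None):
            raise ParameterError(
                "exactly one of input paths or a generator config must be set"
            )
        if has_paths and (self.data_path is None or self.metadata_path is None):
            raise ParameterError("both data_path and metadata_path are required")


@dataclass
class ReportBundle:
    fits: pd.DataFrame
    metrics: pd.DataFrame
    tests: pd.DataFrame
    manifest: dict
    study: StudyTable = field(repr=False, default=None)


def behavior_fits_table(study: StudyTable, bin_widths=None, min_count: int = 5) -> pd.DataFrame:
    """Pool dwell durations per group (each state and all states combined) and
    fit the three candidate densities; rows mirror the study's R^2 tables."""
    rows = []
    for group, records in sorted(study.groups().items()):
        per_state = {s: [] for s in BEHAVIOR_STATES}
        for rec in records:
            if rec.behavior is None:
                logger.info("behavior: %s p%s has no behavior stream; skipped",
                            rec.dyad_id, rec.person)
                continue
            for s, ds in extract_durations(rec.behavior).items():
                per_state[s].append(ds)
        if not any(per_state.values()):
            continue
        pools = {s: pool_durations(per_state[s], {s}) for s in BEHAVIOR_STATES}
        pools["123"] = pool_durations(
            [d for sets in per_state.values() for d in sets], set(BEHAVIOR_STATES)
        )
        for label, pooled in pools.items():
            try:
                pdf = estimate_pdf_multibin(pooled, bin_widths, min_count)
                fits = compare_fits(pdf)
            except (InsufficientDataError, FitFailureError) as exc:
                # too little pooled data for this state; report what can be fit
                logger.warning("behavior: group %s state %s skipped (%s)",
                               group, label, exc)
                continue
            for fit in fits:
                rows.append({
                    "group": group,
                    "state": label,
                    "n_durations": pooled.n_total,
                    "form": fit.form,
                    "r_squared": fit.r_squared,
                    "amplitude_A": fit.amplitude_A,
                    "rate_a": fit.rate_a,
                    "exponent_b": fit.exponent_b,
                    "exponent_alpha": fit.exponent_alpha,
                })
    return pd.DataFrame(rows)


def emotion_metrics_table(study: StudyTable, segment_sizes=None,
                          tail_range=DEFAULT_TAIL_RANGE,
                          psd_method: str = "periodogram") -> pd.DataFrame:
    """Per-person fluctuation metrics: R/S Hurst on the increments, PSD tail
    slope on the raw trace, the PSD-implied Hurst exponent, and the number of
    mean-crossing intervals."""
    rows = []
    for rec in sorted(study.records, key=lambda r: (r.dyad_id, r.person)):
        row = {"dyad": rec.dyad_id, "person": rec.person, "group": rec.group}
        if rec.emotion is None:
            logger.info("emotion: %s p%s has no emotion stream; metrics NA",
                        rec.dyad_id, rec.person)
            row.update({"tail_slope": np.nan, "hurst_H": np.nan,
                        "hurst_r_squared": np.nan, "psd_hurst": np.nan,
                        "n_crossing_intervals": np.nan})
        else:
            increments = np.diff(np.asarray(rec.emotion, dtype=float))
            hurst = rescaled_range_hurst(increments, segment_sizes)
            psd = power_spectrum(rec.emotion, psd_method, tail_range)
            row.update({
                "tail_slope": psd.tail_slope,
                "hurst_H": hurst.hurst_H,
                "hurst_r_squared": hurst.r_squared,
                "psd_hurst": slope_to_hurst(psd.tail_slope, "data_slope"),
                "n_crossing_intervals": dichotomize_and_intervals(rec.emotion).n_total,
            })
        rows.append(row)
    return pd.DataFrame(rows)


def comparison_table(metrics: pd.DataFrame, alternative: str = "less") -> pd.DataFrame:
    """Mann-Whitney tests (intractable vs tractable) on the per-person Hurst
    exponent and on the R/S line-fit R^2."""
    rows = []
    for metric in COMPARED_METRICS:
        x = metrics.loc[metrics["group"] == "intractable", metric].dropna()
        y = metrics.loc[metrics["group"] == "tractable", metric].dropna()
        res = mann_whitney_u(x, y, alternative)
        rows.append({
            "metric": metric,
            "n_intractable": len(x),
            "n_tractable": len(y),
            "u_statistic": res.u_statistic,
            "p_one_sided": res.p_one_sided,
            "p_two_sided": res.p_two_sided,
            "method": res.method,
            "alternative": res.alternative,
        })
    return pd.DataFrame(rows)


def _config_manifest(config: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, tuple):
            return list(obj)
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        return obj

    out = enc(config)
    # paths and verbosity do not affect the computation; keeping them out of
    # the manifest makes reruns into different directories byte-identical
    out.pop("out_dir", None)
    out.pop("log_level", None)
    return out


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every stage and write fits/metrics/tests CSVs plus a manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    warnings: list[str] = []

    def _abort(stage, exc):
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, str(exc)) from exc

    # --- acquire ---
    try:
        if config.gen_config is not None:
            study = generate_study(config.gen_config, seed=config.master_seed)
            data_p, meta_p = out_dir / "study_data.csv", out_dir / "study_metadata.csv"
            write_study(study, data_p, meta_p)
            written += [data_p, meta_p]
        else:
            study = read_study(config.data_path, config.metadata_path)
        warnings.extend(study.warnings)
    except PipelineError:
        raise
    except Exception as exc:
        _abort("acquire", exc)

    # --- validate ---
    try:
        for rec in study.records:
            for v in validate_session(rec):
                raise ParameterError(
                    f"dyad {rec.dyad_id}, person {rec.person}: {v.message} "
                    f"(field {v.field}, index {v.index}, value {v.value})"
                )
    except Exception as exc:
        _abort("validate", exc)

    # --- behavior ---
    try:
        fits = behavior_fits_table(study, config.bin_widths, config.min_count)
    except Exception as exc:
        _abort("behavior", exc)

    # --- emotion ---
    try:
        metrics = emotion_metrics_table(study, config.segment_sizes,
                                        config.tail_range, config.psd_method)
    except Exception as exc:
        _abort("emotion", exc)

    # --- compare ---
    try:
        summary = summarize_groups(metrics)
        tests = comparison_table(metrics, config.test_alternative)
        warnings.extend(summary.footnotes)
    except Exception as exc:
        _abort("compare", exc)

    # --- report ---
    try:
        manifest = {
            "package": "conflictdyn",
            "version": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "config": _config_manifest(config),
            "master_seed": config.master_seed,
            "n_records": len(study.records),
            "warnings": warnings,
        }
        fits_p = out_dir / "fits.csv"
        metrics_p = out_dir / "metrics.csv"
        tests_p = out_dir / "tests.csv"
        manifest_p = out_dir / "manifest.json"
        fits.to_csv(fits_p, index=False, lineterminator="\n")
        summary.table.to_csv(metrics_p, index=False, lineterminator="\n")
        tests.to_csv(tests_p, index=False, lineterminator="\n")
        manifest_p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written += [fits_p, metrics_p, tests_p, manifest_p]
    except Exception as exc:
        _abort("report", exc)

    return ReportBundle(fits=fits, metrics=summary.table, tests=tests,
                        manifest=manifest, study=study)
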