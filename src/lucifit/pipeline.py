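"""Config-driven end-to-end analysis: read → trim → detrend → fit →
filter → summarize → Q10 → estimation statistics → report.

All randomness (bootstrap resampling) flows from one top-level seed, and
re-running with an identical config produces byte-identical reports.
Per-stage sample counts, convergence failures and the cutoffs applied
are logged, so every report row is traceable to input sample ids.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .cohort import (
    FilterResult,
    GroupSummary,
    default_error_cutoff,
    filter_fits,
    q10_from_summary,
    summarize_groups,
)
from .core import SampleMetadata, TimeSeries
from .estimation import EffectSize, shared_control
from .exceptions import PipelineError, ValidationError
from .fitting import FitConfig, FitResult, fit_damped_cosine, mean_level
from .preprocess import detrend_moving_average, discard_initial, extract_dd

__all__ = ["RunConfig", "analyze_series", "analyze_cohort", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs, loadable from a YAML file."""

    long_csv: str | None = None
    metadata_csv: str | None = None
    out_dir: str = "lucifit-out"
    discard_initial_h: float = 24.0
    detrend_window_h: float = 24.0
    detrend_mode: str = "subtract"
    fit: FitConfig = field(default_factory=FitConfig)
    error_cutoffs: dict[str, float] | None = None
    q10_temperatures: tuple[float, float] | None = None  # None = extremes
    control_temperature_c: float | None = None  # None = coldest group
    n_boot: int = 5000
    ci_method: str = "bca"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        fit_raw = raw.pop("fit", {})
        if fit_raw:
            fit_raw = {
                k: tuple(v) if isinstance(v, list) else v for k, v in fit_raw.items()
            }
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        if "q10_temperatures" in raw and raw["q10_temperatures"] is not None:
            raw["q10_temperatures"] = tuple(raw["q10_temperatures"])
        return cls(fit=FitConfig(**fit_raw), **raw)


def analyze_series(
    ts: TimeSeries,
    discard_initial_h: float = 24.0,
    detrend_window_h: float = 24.0,
    detrend_mode: str = "subtract",
    fit_config: FitConfig | None = None,
) -> FitResult:
    """Run the single-sample chain: discard → extract DD → detrend → fit.

    The result carries the sample's mean CPS over the analyzed window
    (post-discard raw counts) and its group annotations.
    """
    trimmed = discard_initial(ts, discard_initial_h)
    cps = mean_level(trimmed)
    dd = extract_dd(trimmed)
    det = detrend_moving_average(dd, window_h=detrend_window_h, mode=detrend_mode)
    fit = fit_damped_cosine(det, fit_config)
    fit.mean_cps = cps
    fit.temperature_c = ts.temperature_c
    fit.annotations = dict(ts.annotations)
    return fit


def analyze_cohort(
    series: Sequence[TimeSeries],
    discard_initial_h: float = 24.0,
    detrend_window_h: float = 24.0,
    detrend_mode: str = "subtract",
    fit_config: FitConfig | None = None,
) -> list[FitResult]:
    """Fit every sample; failures are logged and returned unconverged."""
    out = []
    for ts in series:
        try:
            out.append(
                analyze_series(
                    ts,
                    discard_initial_h=discard_initial_h,
                    detrend_window_h=detrend_window_h,
                    detrend_mode=detrend_mode,
                    fit_config=fit_config,
                )
            )
        except ValidationError:
            raise
        except Exception as exc:
            logger.warning("sample %s failed to fit: %s", ts.sample_id, exc)
            out.append(
                FitResult(
                    sample_id=ts.sample_id,
                    tau_h=np.nan,
                    amplitude_cps=np.nan,
                    damping_per_h=np.nan,
                    phase_h=np.nan,
                    offset_cps=np.nan,
                    error=1.0,
                    converged=False,
                    temperature_c=ts.temperature_c,
                    annotations=dict(ts.annotations),
                )
            )
    return out


def _filter_by_tissue(
    fits: Sequence[FitResult], cutoffs: dict[str, float] | None
) -> tuple[list[FitResult], dict[str, int]]:
    kept: list[FitResult] = []
    excluded: dict[str, int] = {}
    by_tissue: dict[str, list[FitResult]] = {}
    for f in fits:
        by_tissue.setdefault(f.annotations.get("tissue", ""), []).append(f)
    for tissue, group in by_tissue.items():
        cutoff = (cutoffs or {}).get(tissue, default_error_cutoff(tissue))
        res: FilterResult = filter_fits(group, cutoff)
        logger.info(
            "tissue %r: %d/%d fits retained at error < %.2f",
            tissue, len(res.kept), len(group), cutoff,
        )
        kept.extend(res.kept)
        excluded[tissue] = res.n_excluded
    return kept, excluded


def _report_frame(
    summaries: Sequence[GroupSummary], q10_by_group: dict[tuple[str, str], float]
) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "genotype": s.genotype,
                "tissue": s.tissue,
                "temperature_c": s.temperature_c,
                "n": s.n,
                "tau_mean_h": round(s.tau_mean_h, 1),
                "tau_sem_h": round(s.tau_sem_h, 1) if np.isfinite(s.tau_sem_h) else "",
                "error_mean": round(s.error_mean, 2),
                "error_sem": round(s.error_sem, 2) if np.isfinite(s.error_sem) else "",
                "cps_mean": round(s.cps_mean, 1),
                "cps_sem": round(s.cps_sem, 1) if np.isfinite(s.cps_sem) else "",
                "q10": q10_by_group.get((s.genotype, s.tissue), ""),
            }
        )
    return pd.DataFrame(rows, columns=lio.REPORT_COLUMNS)


def _effects_frame(effects: Sequence[EffectSize], seed: int) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "control": e.control_label,
                "test": e.test_label,
                "mean_difference_h": e.mean_difference,
                "ci_low_h": e.ci_low,
                "ci_high_h": e.ci_high,
                "crosses_zero": e.crosses_zero,
                "n_control": e.n_control,
                "n_test": e.n_test,
                "n_boot": e.n_boot,
                "ci_level": e.ci_level,
                "method": e.method,
                "seed": seed,
            }
            for e in effects
        ]
    )


def run_pipeline(
    config: RunConfig,
    series: Sequence[TimeSeries] | None = None,
    metadata: Sequence[SampleMetadata] | None = None,
) -> dict[str, Path]:
    """Execute every stage and write the report files.

    Inputs come from ``config.long_csv``/``config.metadata_csv`` unless
    in-memory series are passed. Writes ``fits.csv`` (one row per
    sample), ``report.csv`` (one row per group, publication-table
    layout), ``effects.csv`` (shared-control mean differences on τ) and
    ``run.log`` into ``config.out_dir``; returns their paths.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("lucifit")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(logging.INFO)
    try:
        # --- read -----------------------------------------------------
        try:
            if series is None:
                if config.long_csv is None:
                    raise ValidationError("no input: set long_csv or pass series")
                series = lio.read_long_csv(config.long_csv)
                if config.metadata_csv:
                    metadata = lio.read_metadata_csv(config.metadata_csv)
            if metadata is not None:
                series = lio.join_metadata(series, metadata)
        except Exception as exc:
            raise PipelineError(f"[read] {exc}") from exc
        logger.info("read %d samples", len(series))

        # --- fit ------------------------------------------------------
        try:
            fits = analyze_cohort(
                series,
                discard_initial_h=config.discard_initial_h,
                detrend_window_h=config.detrend_window_h,
                detrend_mode=config.detrend_mode,
                fit_config=config.fit,
            )
        except Exception as exc:
            raise PipelineError(f"[fit] {exc}") from exc
        n_failed = sum(not f.converged for f in fits)
        logger.info("fitted %d samples (%d unconverged)", len(fits), n_failed)
        fits_path = out_dir / "fits.csv"
        lio.write_fits_csv(fits, fits_path)

        # --- filter + summarize --------------------------------------
        try:
            kept, excluded = _filter_by_tissue(fits, config.error_cutoffs)
            logger.info("excluded per tissue: %s", excluded)
            summaries = summarize_groups(kept)
        except Exception as exc:
            raise PipelineError(f"[summarize] {exc}") from exc

        # --- Q10 ------------------------------------------------------
        q10_by_group: dict[tuple[str, str], float] = {}
        try:
            by_gt: dict[tuple[str, str], list[GroupSummary]] = {}
            for s in summaries:
                by_gt.setdefault((s.genotype, s.tissue), []).append(s)
            for key, group in by_gt.items():
                temps = {s.temperature_c for s in group}
                pair = config.q10_temperatures
                if pair is not None and not set(pair) <= temps:
                    logger.warning(
                        "group %s lacks temperatures %s; skipping Q10", key, pair
                    )
                    continue
                if len(temps) < 2:
                    continue
                res = q10_from_summary(
                    group,
                    t_cold_c=None if pair is None else pair[0],
                    t_warm_c=None if pair is None else pair[1],
                    round_tau_to=1,
                )
                q10_by_group[key] = round(res.q10, 2)
                logger.info(
                    "Q10 %s: %.2f (tau %.1f h @ %g°C vs %.1f h @ %g°C)",
                    key, res.q10, res.tau_cold_h, res.t_cold_c,
                    res.tau_warm_h, res.t_warm_c,
                )
        except Exception as exc:
            raise PipelineError(f"[q10] {exc}") from exc
        report_path = out_dir / "report.csv"
        _report_frame(summaries, q10_by_group).to_csv(report_path, index=False)

        # --- estimation statistics ------------------------------------
        try:
            effects: list[EffectSize] = []
            for (gen, tis), group in by_gt.items():
                temps = sorted(s.temperature_c for s in group)
                control_t = (
                    config.control_temperature_c
                    if config.control_temperature_c is not None
                    else temps[0]
                )
                groups = {}
                for t in temps:
                    taus = [
                        f.tau_h
                        for f in kept
                        if f.annotations.get("genotype", "") == gen
                        and f.annotations.get("tissue", "") == tis
                        and f.temperature_c == t
                    ]
                    if len(taus) >= 2:
                        groups[f"{gen}/{tis}/{t:g}C"] = taus
                control_label = f"{gen}/{tis}/{control_t:g}C"
                if control_label not in groups or len(groups) < 2:
                    logger.warning(
                        "group %s/%s: too few samples for shared-control "
                        "comparison", gen, tis,
                    )
                    continue
                effects.extend(
                    shared_control(
                        groups,
                        control_label,
                        n_boot=config.n_boot,
                        method=config.ci_method,
                        seed=config.seed,
                    )
                )
        except Exception as exc:
            raise PipelineError(f"[effects] {exc}") from exc
        effects_path = out_dir / "effects.csv"
        _effects_frame(effects, config.seed).to_csv(effects_path, index=False)
        logger.info("wrote %s, %s, %s", fits_path, report_path, effects_path)
    finally:
        root.removeHandler(handler)
        root.setLevel(old_level)
        handler.close()
    return {
        "fits": fits_path,
        "report": report_path,
        "effects": effects_path,
        "log": log_path,
    }
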