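"""End-to-end analysis pipeline and machine-readable report.

``run_pipeline`` chains the stages — read/validate, Delta-scale pairing,
asymmetry tests, repeated-measures ANOVA, mixed time-matching regressions,
windowed aggregation with log-log fits, and the bootstrap null test per
(window size, condition) — into one versioned JSON-serializable report.
The report schema is published in ``schema/report.schema.json``.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from pydantic import BaseModel, Field

from . import io_model, metrics, pairing, windows

log = logging.getLogger("deltagroom")

SCHEMA_VERSION = "1.0"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class RunConfig(BaseModel):
    events_path: str
    sessions_path: str
    reuse_x: bool = False
    merge_gap_s: Optional[int] = None
    window_sizes_min: List[float] = Field(default=[20, 40, 60, 240])
    bootstrap_reps: int = 100_000
    seed: int = 0
    output_dir: Optional[str] = None

    def model_post_init(self, __context) -> None:
        if any(w <= 0 for w in self.window_sizes_min):
            raise ValueError("window sizes must be positive")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")


class SummaryReport(BaseModel):
    n_events: int
    total_observation_hours: float
    total_groomed_hours: float
    n_active_dyads: int
    n_possible_dyads: int
    n_mutual_dyads: int


class PairingReport(BaseModel):
    n_pairs: int
    n_within_bout: int
    n_delayed: int
    min_delta_min: float
    max_delta_min: float
    delta_bin_edges_min: List[float]
    delta_counts: List[int]


class AsymmetryReport(BaseModel):
    by: str
    condition: str
    n_units: int
    n_reject: int
    median_of_medians: float


class AnovaReport(BaseModel):
    F: float
    df_num: int
    df_den: int
    p: float
    eta_sq: float
    mean_diff: float
    cohens_d: float
    n_dyads_both: int


class MixedReport(BaseModel):
    condition: str
    alpha: float
    beta: float
    se_alpha: float
    se_beta: float
    p: float
    n_pairs: int
    n_dyads: int
    singular: bool


class WindowReport(BaseModel):
    window_size_min: float
    condition: str
    n_dyad_windows: int
    n_excluded: int
    slope: float
    intercept: float
    adj_r_squared: float


class BootstrapReport(BaseModel):
    window_size_min: float
    condition: str
    P_med_empirical: float
    lower_crit: float
    upper_crit: float
    n_reps: int
    reject: bool
    n_dyad_windows: int


class AnalysisReport(BaseModel):
    """Full pipeline output (Table-2/3/4-shaped results plus the summary)."""

    schema_version: str = SCHEMA_VERSION
    seed: int
    summary: SummaryReport
    pairing: PairingReport
    asymmetry: List[AsymmetryReport]
    anova: Optional[AnovaReport]
    mixed: List[MixedReport]
    windowed: List[WindowReport]
    bootstrap: List[BootstrapReport]
    stage_seconds: Dict[str, float]


def _stage(name: str, timings: Dict[str, float]):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            timings[name] = round(time.perf_counter() - self.t0, 4)
            if exc is not None:
                log.error("stage %s: failed (%s)", name, exc)
                raise PipelineError(name, exc) from exc
            log.info("stage %s: done in %.2fs", name, timings[name])

    return _Ctx()


def analyze_log(
    event_log: io_model.EventLog,
    policy: pairing.PairingPolicy = pairing.PairingPolicy(),
    window_sizes_min: Tuple[float, ...] = windows.DEFAULT_WINDOW_SIZES,
    bootstrap_reps: int = 100_000,
    seed: int = 0,
) -> AnalysisReport:
    """Run every analysis stage on an in-memory event log."""
    timings: Dict[str, float] = {}
    with _stage("summary", timings):
        summary = io_model.summarize_log(event_log)
        if summary["n_events"] == 0:
            raise ValueError("event log contains no events")

    with _stage("pairing", timings):
        pairs = pairing.pair_events(event_log, policy)
        if not pairs:
            raise ValueError("no reciprocation pairs found")
        dsum = pairing.delta_summary(pairs)
        n_within = sum(1 for p in pairs if p.condition == pairing.WITHIN_BOUT)
        pairing_report = PairingReport(
            n_pairs=len(pairs),
            n_within_bout=n_within,
            n_delayed=len(pairs) - n_within,
            min_delta_min=dsum["min_delta_min"],
            max_delta_min=dsum["max_delta_min"],
            delta_bin_edges_min=dsum["bin_edges_min"],
            delta_counts=dsum["counts"],
        )

    conditions = sorted({p.condition for p in pairs})
    with _stage("asymmetry", timings):
        asym = []
        for by in ("dyad", "individual"):
            for cond in conditions:
                table = metrics.asymmetry_test(pairs, by=by, condition=cond)
                if table.empty:
                    continue
                asym.append(
                    AsymmetryReport(
                        by=by,
                        condition=cond,
                        n_units=len(table),
                        n_reject=int(table["reject"].sum()),
                        median_of_medians=float(table["median"].median()),
                    )
                )

    with _stage("anova", timings):
        anova_report = None
        if len(conditions) == 2:
            try:
                a = metrics.rm_anova(pairs)
                anova_report = AnovaReport(**a.__dict__)
            except ValueError as exc:
                log.warning("anova skipped: %s", exc)

    with _stage("mixed_regression", timings):
        mixed = []
        for cond in conditions:
            fit = metrics.mixed_regression(pairs, condition=cond)
            mixed.append(
                MixedReport(
                    condition=cond,
                    alpha=fit.alpha,
                    beta=fit.beta,
                    se_alpha=fit.se_alpha,
                    se_beta=fit.se_beta,
                    p=fit.p,
                    n_pairs=fit.n_pairs,
                    n_dyads=fit.n_dyads,
                    singular=fit.singular,
                )
            )

    with _stage("windowed", timings):
        windowed = []
        for w in window_sizes_min:
            for cond in conditions:
                agg = windows.aggregate_windows(pairs, w, condition=cond)
                if len(agg) < 3:
                    continue
                fit = windows.loglog_fit(agg)
                windowed.append(
                    WindowReport(
                        window_size_min=w,
                        condition=cond,
                        n_dyad_windows=fit.n,
                        n_excluded=fit.n_excluded,
                        slope=fit.slope,
                        intercept=fit.intercept,
                        adj_r_squared=fit.r_squared,
                    )
                )

    with _stage("bootstrap", timings):
        boot = []
        for w in window_sizes_min:
            for cond in conditions:
                res = windows.bootstrap_test(
                    pairs, w, cond, n_reps=bootstrap_reps, seed=seed
                )
                boot.append(
                    BootstrapReport(
                        window_size_min=res.window_size_min,
                        condition=cond,
                        P_med_empirical=res.P_med_empirical,
                        lower_crit=res.lower_crit,
                        upper_crit=res.upper_crit,
                        n_reps=res.n_reps,
                        reject=res.reject,
                        n_dyad_windows=res.n_dyad_windows,
                    )
                )

    return AnalysisReport(
        seed=seed,
        summary=SummaryReport(**summary),
        pairing=pairing_report,
        asymmetry=asym,
        anova=anova_report,
        mixed=mixed,
        windowed=windowed,
        bootstrap=boot,
        stage_seconds=timings,
    )


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Read the input tables and run the full analysis per the config."""
    timings: Dict[str, float] = {}
    with _stage("io_model", timings):
        event_log = io_model.read_events(config.events_path, config.sessions_path)
    report = analyze_log(
        event_log,
        policy=pairing.PairingPolicy(reuse_x=config.reuse_x, merge_gap_s=config.merge_gap_s),
        window_sizes_min=tuple(config.window_sizes_min),
        bootstrap_reps=config.bootstrap_reps,
        seed=config.seed,
    )
    report.stage_seconds.update(timings)
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(report.model_dump_json(indent=2) + "\n")
    return report


def report_json_schema() -> dict:
    """JSON schema of :class:`AnalysisReport` (published in schema/)."""
    return AnalysisReport.model_json_schema()
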