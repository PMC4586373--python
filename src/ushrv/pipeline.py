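"""End-to-end orchestration: generate → QC → segment → metrics → agreement →
null simulation, with reproducible manifests and plot-ready TSV reports.

All randomness is controlled by three explicit seeds (generator,
segmentation, bootstrap) persisted in the run manifest; re-running a
manifest reproduces every output bit-identically.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import io as ushrv_io
from .agreement import AgreementResult, ICCResult, agreement_table
from .metrics import (SubjectExcluded, SubjectHRVTable, build_subject_table,
                      tables_to_frame)
from .nullsim import DEFAULT_N_REPS, NullSimResult, null_simulation_table
from .preprocess import interpolate_artifacts, UnrecoverableSeriesError
from .segments import ALL_LABELS
from .series import NNSeries
from .synth import PopulationSpec, default_population_spec, generate_population

logger = logging.getLogger("ushrv")

#: Assumptions recorded with every run (interpretive choices of the pipeline).
ANALYSIS_METADATA = {
    "validity_rule": "recording invalid if > 5% of intervals are interpolated (counted on intervals, not time)",
    "avg10s_aggregation": "arithmetic mean of raw ms values; ln field is log of the mean",
    "avg10s_null_n": "Avg10s enters the variance decomposition with the mean 10 s interval count",
    "interpolated_in_metrics": "interpolated intervals are included in SDNN/RMSSD",
    "percentile_definition": "inclusive linear interpolation",
    "loa_multiplier": 1.96,
}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: Path
    population: Optional[PopulationSpec] = None   # generator mode
    input_path: Optional[Path] = None             # or pre-existing dataset
    segmentation_seed: int = 1
    bootstrap_seed: int = 2
    n_reps: int = DEFAULT_N_REPS

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.population is None and self.input_path is None:
            raise ValueError("RunConfig needs a population spec or an input path")


@dataclass
class Exclusion:
    subject_id: str
    stage: str     # "recording" or "segment"
    code: str      # machine-readable reason code
    detail: str


def qc_population(series_list: Sequence[NNSeries]
                  ) -> Tuple[List[NNSeries], List[Exclusion]]:
    """Interpolate artifacts and drop invalid recordings (> 5% interpolated)."""
    kept: List[NNSeries] = []
    excl: List[Exclusion] = []
    for s in series_list:
        try:
            cleaned, report = interpolate_artifacts(s)
        except UnrecoverableSeriesError as e:
            excl.append(Exclusion(s.subject_id, "recording", "unrecoverable", str(e)))
            continue
        if not report.valid:
            excl.append(Exclusion(s.subject_id, "recording",
                                  "interpolated_gt_5pct", report.reason))
            continue
        kept.append(cleaned)
    return kept, excl


def build_population_tables(series_list: Sequence[NNSeries], seed: int
                            ) -> Tuple[List[SubjectHRVTable], List[Exclusion]]:
    """Segment each validated recording and compute its HRV table.

    Each subject gets an independent segmentation sub-seed derived from
    ``seed`` so that 10 s window placement differs between subjects but the
    whole pass is reproducible.
    """
    rng = np.random.default_rng(seed)
    tables: List[SubjectHRVTable] = []
    excl: List[Exclusion] = []
    for s in series_list:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            tables.append(build_subject_table(s, sub_seed))
        except SubjectExcluded as e:
            excl.append(Exclusion(e.subject_id, "segment", "segment_rule", e.reason))
        except ValueError as e:
            excl.append(Exclusion(s.subject_id, "segment", "invalid_recording", str(e)))
    return tables, excl


# ---------------------------------------------------------------------------
# Report frames (plot-ready tables)
# ---------------------------------------------------------------------------

def descriptives_frame(tables: Sequence[SubjectHRVTable]) -> pd.DataFrame:
    """Per-label mean (SD) of raw and ln SDNN/RMSSD across subjects."""
    df = tables_to_frame(tables)
    rows = []
    for lab in ALL_LABELS:
        g = df[df["label"] == lab]
        rows.append({
            "label": lab, "n": len(g),
            "sdnn_mean": g["sdnn"].mean(), "sdnn_sd": g["sdnn"].std(ddof=1),
            "ln_sdnn_mean": g["ln_sdnn"].mean(), "ln_sdnn_sd": g["ln_sdnn"].std(ddof=1),
            "rmssd_mean": g["rmssd"].mean(), "rmssd_sd": g["rmssd"].std(ddof=1),
            "ln_rmssd_mean": g["ln_rmssd"].mean(), "ln_rmssd_sd": g["ln_rmssd"].std(ddof=1),
            "sdnn_median": g["sdnn"].median(), "rmssd_median": g["rmssd"].median(),
        })
    return pd.DataFrame(rows)


def agreement_frame(results: Sequence[AgreementResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "metric": r.metric, "label": r.label, "n": r.n,
        "r": r.r, "r_ci_low": r.r_ci[0], "r_ci_high": r.r_ci[1],
        "bias": r.bias, "bias_ci_low": r.bias_ci[0], "bias_ci_high": r.bias_ci[1],
        "loa_low": r.loa_low, "loa_high": r.loa_high,
        "cohens_d": r.cohens_d, "d_ci_low": r.d_ci[0], "d_ci_high": r.d_ci[1],
        "d_band": r.d_band,
    } for r in results])


def icc_frame(iccs: Sequence[ICCResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "metric": r.metric, "pair": f"{r.pair[0]} vs {r.pair[1]}", "n": r.n,
        "icc": r.icc, "ci_low": r.ci[0], "ci_high": r.ci[1],
    } for r in iccs])


def bland_altman_frame(tables: Sequence[SubjectHRVTable]) -> pd.DataFrame:
    """Per-subject (gold value, difference) pairs for every metric x label."""
    from .agreement import METRICS
    from .segments import LABEL_TOTAL, SHORT_LABELS
    rows = []
    for metric, attr in METRICS.items():
        for lab in SHORT_LABELS:
            for t in tables:
                g = getattr(t[LABEL_TOTAL], attr)
                s = getattr(t[lab], attr)
                if np.isfinite(g) and np.isfinite(s):
                    rows.append({"metric": metric, "label": lab,
                                 "subject_id": t.subject_id,
                                 "gold": g, "difference": g - s})
    return pd.DataFrame(rows)


def nullsim_frame(results: Sequence[NullSimResult],
                  observed: Sequence[AgreementResult]) -> pd.DataFrame:
    obs = {(o.metric, o.label): o for o in observed}
    rows = []
    for r in results:
        o = obs.get((r.metric, r.label))
        for stat, rng_ in (("r", r.ref_range_r), ("bias", r.ref_range_bias),
                           ("loa_low", r.ref_range_loa_low),
                           ("loa_high", r.ref_range_loa_high),
                           ("d", r.ref_range_d)):
            observed_value = None
            if o is not None:
                observed_value = {"r": o.r, "bias": o.bias, "loa_low": o.loa_low,
                                  "loa_high": o.loa_high, "d": o.cohens_d}[stat]
            rows.append({"metric": r.metric, "label": r.label, "statistic": stat,
                         "observed": observed_value,
                         "ref_low": rng_[0], "ref_high": rng_[1],
                         "verdict": r.verdicts.get(stat, ""),
                         "n_reps": r.n_reps, "n_dropped": r.n_dropped,
                         "n_redrawn": r.n_redrawn})
    return pd.DataFrame(rows)


def exclusions_frame(exclusions: Sequence[Exclusion]) -> pd.DataFrame:
    return pd.DataFrame([{"subject_id": e.subject_id, "stage": e.stage,
                          "code": e.code, "detail": e.detail} for e in exclusions],
                        columns=["subject_id", "stage", "code", "detail"])


# ---------------------------------------------------------------------------
# Run verbs
# ---------------------------------------------------------------------------

def _write_manifest(config: RunConfig, outdir: Path, extra: Dict) -> None:
    manifest = {
        "segmentation_seed": config.segmentation_seed,
        "bootstrap_seed": config.bootstrap_seed,
        "n_reps": config.n_reps,
        "analysis_metadata": ANALYSIS_METADATA,
        **extra,
    }
    if config.population is not None:
        manifest["population"] = ushrv_io.population_spec_to_dict(config.population)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_simulate(config: RunConfig) -> Path:
    """Generate the synthetic population and write the NN dataset + manifest."""
    if config.population is None:
        raise ValueError("simulate requires a population spec")
    config.outdir.mkdir(parents=True, exist_ok=True)
    series = generate_population(config.population)
    data_path = config.outdir / "nn_intervals.tsv"
    ushrv_io.write_nn_table(series, data_path)
    _write_manifest(config, config.outdir,
                    {"verb": "simulate", "dataset": data_path.name,
                     "dataset_sha256": _sha256(data_path)})
    logger.info("wrote %d subjects to %s", len(series), data_path)
    return data_path


def _load_series(config: RunConfig) -> List[NNSeries]:
    if config.input_path is not None:
        return ushrv_io.read_nn_table(config.input_path)
    assert config.population is not None
    return generate_population(config.population)


@dataclass
class AnalysisRun:
    """In-memory results of a full analysis (also written as TSVs)."""

    tables: List[SubjectHRVTable]
    exclusions: List[Exclusion]
    agreement: List[AgreementResult]
    iccs: List[ICCResult]
    nullsim: Optional[List[NullSimResult]] = None


def analyze_population(series_list: Sequence[NNSeries], segmentation_seed: int,
                       bootstrap_seed: int = 0) -> AnalysisRun:
    """QC, segment, measure and compute agreement for a population in memory."""
    kept, excl_rec = qc_population(series_list)
    tables, excl_seg = build_population_tables(kept, segmentation_seed)
    if len(tables) < 3:
        raise ValueError(f"only {len(tables)} complete subjects; need >= 3")
    results, iccs = agreement_table(tables, seed=bootstrap_seed)
    return AnalysisRun(tables=tables, exclusions=excl_rec + excl_seg,
                       agreement=results, iccs=iccs)


def run_analyze(config: RunConfig) -> AnalysisRun:
    """Full analysis: writes descriptives, agreement, ICC, Bland-Altman and
    exclusion tables to the output directory."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    series = _load_series(config)
    run = analyze_population(series, config.segmentation_seed, config.bootstrap_seed)
    descriptives_frame(run.tables).to_csv(config.outdir / "descriptives.tsv",
                                          sep="\t", index=False)
    tables_to_frame(run.tables).to_csv(config.outdir / "subject_hrv.tsv",
                                       sep="\t", index=False)
    agreement_frame(run.agreement).to_csv(config.outdir / "agreement.tsv",
                                          sep="\t", index=False)
    icc_frame(run.iccs).to_csv(config.outdir / "icc.tsv", sep="\t", index=False)
    bland_altman_frame(run.tables).to_csv(config.outdir / "bland_altman.tsv",
                                          sep="\t", index=False)
    exclusions_frame(run.exclusions).to_csv(config.outdir / "exclusions.tsv",
                                            sep="\t", index=False)
    _write_manifest(config, config.outdir,
                    {"verb": "analyze", "n_subjects": len(run.tables),
                     "n_excluded": len(run.exclusions)})
    for e in run.exclusions:
        logger.info("excluded %s at %s: %s", e.subject_id, e.stage, e.code)
    return run


def run_nullsim(config: RunConfig, run: Optional[AnalysisRun] = None) -> AnalysisRun:
    """Null simulation on top of an analysis; writes the reference-range table."""
    if run is None:
        run = run_analyze(config)
    run.nullsim = null_simulation_table(run.tables, run.agreement,
                                        n_reps=config.n_reps,
                                        seed=config.bootstrap_seed)
    nullsim_frame(run.nullsim, run.agreement).to_csv(
        config.outdir / "null_simulation.tsv", sep="\t", index=False)
    return run
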