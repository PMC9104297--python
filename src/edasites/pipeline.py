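"""End-to-end orchestration: simulate or load, then analyse and report.

``analyze_cohort`` is the core routine: given recordings plus stage
annotations it resamples, filters and segments each channel, decomposes
every (stage, site) segment, computes per-segment indices and spectral
quality, and assembles the cohort-level statistics (within-subject
correlations against the reference site, baseline-vs-stress tests per
index and site, ROC/AUC, and per-stage quality).  ``run_pipeline`` wraps
it with file I/O, tidy-CSV outputs and a run manifest.

The site-comparison summary ranks sites along the three axes such studies
use: agreement with the reference site, sensitivity to cognitive stress,
and robustness to motion artifacts.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .decompose import DecompositionConfig, DecompositionResult, decompose
from .indices import IndexSet, compute_indices, index_table, INDEX_NAMES
from .io import (
    PipelineConfig,
    Recording,
    StageAnnotation,
    ValidationError,
    read_annotations,
    read_recording,
    write_recording,
    write_annotations,
)
from .preprocess import SegmentedRecording, segment_by_stages
from .quality import QualityReport, noise_power_fraction
from .simulate import SimulationConfig, simulate_cohort
from .stats import (
    CorrelationEntry,
    RocResult,
    TestResult,
    compare_stages,
    correlation_summary,
    correlation_table,
    roc_curve,
    significance_stars,
)

logger = logging.getLogger("edasites")

__all__ = [
    "SubjectAnalysis",
    "CohortReport",
    "RunManifest",
    "analyze_subject",
    "analyze_cohort",
    "run_pipeline",
]


@dataclass
class SubjectAnalysis:
    """All per-subject intermediate products."""

    subject_id: str
    segmented: SegmentedRecording
    decompositions: dict[tuple[str, str], DecompositionResult]
    indices: list[IndexSet]
    quality: list[QualityReport]


@dataclass
class CohortReport:
    """Cohort-level outputs of the site-comparison analysis."""

    correlations: list[CorrelationEntry]
    correlation_summary: pd.DataFrame
    tests: list[TestResult]
    rocs: list[RocResult]
    quality: pd.DataFrame
    subjects: list[SubjectAnalysis]
    site_ranking: pd.DataFrame


@dataclass
class RunManifest:
    """What a pipeline run produced, for reproducibility."""

    config: dict
    mode: str
    seed: int | None
    outputs: dict[str, str]
    version: str = __version__
    started: str = ""
    finished: str = ""
    failure_stage: str | None = None

    def write(self, path: Path) -> Path:
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))
        return path


def analyze_subject(
    rec: Recording,
    annotations: Sequence[StageAnnotation],
    cfg: PipelineConfig,
    dcfg: DecompositionConfig | None = None,
    stress_stages: Sequence[str] = ("baseline", "scwt"),
    decompose_stages: Sequence[str] | None = None,
) -> SubjectAnalysis:
    """Preprocess, decompose and score one subject.

    ``decompose_stages`` restricts the expensive decomposition to the
    stages that feed indices and correlations (default: all annotated
    stages).  Spectral quality is computed for every stage on both the
    unfiltered and filtered series.  Unless a custom decomposition config
    is supplied, the response kernel is shaped by the same zero-phase
    low-pass applied to the data, keeping the convolution model consistent
    with the preprocessing.
    """
    dcfg = dcfg or DecompositionConfig(
        match_lowpass_order=cfg.lowpass_order,
        match_lowpass_cutoff_hz=cfg.lowpass_cutoff_hz,
    )
    seg = segment_by_stages(rec, list(annotations), cfg)
    stages = list(decompose_stages) if decompose_stages is not None else seg.stage_order
    decs: dict[tuple[str, str], DecompositionResult] = {}
    idx: list[IndexSet] = []
    qual: list[QualityReport] = []
    for stage in seg.stage_order:
        for site in seg.sites:
            if stage in stages:
                d = decompose(seg.series(stage, site), seg.fs, dcfg)
                decs[(stage, site)] = d
                if not d.converged:
                    logger.warning(
                        "subject %s %s/%s: decomposition not converged (%s)",
                        rec.subject_id, stage, site, d.solver_message,
                    )
                else:
                    idx.append(
                        compute_indices(d, seg.fs, cfg, stage, site, rec.subject_id)
                    )
            for filtered in (False, True):
                q = noise_power_fraction(
                    seg.series(stage, site, filtered=filtered),
                    seg.fs,
                    cfg,
                    stage=stage + ("_filtered" if filtered else ""),
                    site=site,
                    subject_id=rec.subject_id,
                )
                qual.append(q)
    return SubjectAnalysis(rec.subject_id, seg, decs, idx, qual)


def _component_series(subj: SubjectAnalysis, stages: Sequence[str]) -> dict:
    """Raw/phasic/tonic per-site series over the given stages, concatenated."""
    sites = subj.segmented.sites
    out = {"subject_id": subj.subject_id, "raw": {}, "phasic": {}, "tonic": {}}
    for site in sites:
        if not all((st, site) in subj.decompositions for st in stages):
            continue
        out["raw"][site] = np.concatenate(
            [subj.segmented.series(st, site) for st in stages]
        )
        out["phasic"][site] = np.concatenate(
            [subj.decompositions[(st, site)].phasic for st in stages]
        )
        out["tonic"][site] = np.concatenate(
            [subj.decompositions[(st, site)].tonic for st in stages]
        )
    return out


def analyze_cohort(
    recordings: Sequence[Recording],
    annotations: Sequence[StageAnnotation],
    cfg: PipelineConfig | None = None,
    dcfg: DecompositionConfig | None = None,
    baseline_stage: str = "baseline",
    stress_stage: str = "scwt",
    decompose_stages: Sequence[str] | None = None,
) -> CohortReport:
    """Full site-comparison analysis of a cohort.

    By default only the baseline and stress stages are decomposed (those
    feed the indices, tests, ROC and component correlations); quality is
    assessed for every stage.
    """
    cfg = cfg or PipelineConfig()
    if decompose_stages is None:
        decompose_stages = (baseline_stage, stress_stage)
    subjects = [
        analyze_subject(rec, annotations, cfg, dcfg, decompose_stages=decompose_stages)
        for rec in recordings
    ]

    corr_stages = [s for s in (baseline_stage, stress_stage) if s in
                   subjects[0].segmented.stage_order]
    comp_series = [_component_series(s, corr_stages) for s in subjects]
    correlations = correlation_table(comp_series, cfg, stages=corr_stages)
    corr_sum = correlation_summary(correlations)

    # per-site, per-index paired comparisons and ROC
    idx_rows = index_table([i for s in subjects for i in s.indices])
    tests: list[TestResult] = []
    rocs: list[RocResult] = []
    sites = subjects[0].segmented.sites
    for site in sites:
        for name in INDEX_NAMES:
            sub = idx_rows[(idx_rows.site == site) & (idx_rows["index"] == name)]
            piv = sub.pivot(index="subject_id", columns="stage", values="value")
            if baseline_stage not in piv or stress_stage not in piv:
                continue
            piv = piv.dropna(subset=[baseline_stage, stress_stage])
            base = piv[baseline_stage].to_numpy()
            stress = piv[stress_stage].to_numpy()
            try:
                tests.append(compare_stages(base, stress, cfg, site, name))
                rocs.append(roc_curve(base, stress, site, name))
            except ValidationError as exc:
                logger.warning("site %s index %s: %s", site, name, exc)

    qual_rows = pd.DataFrame(
        [
            {
                "subject_id": q.subject_id,
                "site": q.site,
                "stage": q.stage,
                "pn": q.pn,
                "total_power": q.total_power,
                "noise_band_power": q.noise_band_power,
                "degenerate": q.degenerate,
            }
            for s in subjects
            for q in s.quality
        ]
    )

    ranking = _site_ranking(cfg, corr_sum, tests, qual_rows)
    return CohortReport(
        correlations=correlations,
        correlation_summary=corr_sum,
        tests=tests,
        rocs=rocs,
        quality=qual_rows,
        subjects=subjects,
        site_ranking=ranking,
    )


def _site_ranking(
    cfg: PipelineConfig,
    corr_sum: pd.DataFrame,
    tests: Sequence[TestResult],
    quality: pd.DataFrame,
) -> pd.DataFrame:
    """Rank sites on the three comparison axes.

    (a) mean raw correlation with the reference, (b) number of indices
    significantly different between baseline and stress, (c) median Pn per
    motion stage (lower is more robust).
    """
    sites = sorted(
        set(quality.site).union(t.site for t in tests) - {cfg.reference_site}
    )
    rows = []
    for site in sorted(set(quality.site)):
        row: dict = {"site": site}
        if site != cfg.reference_site and not corr_sum.empty:
            sel = corr_sum[(corr_sum.site == site) & (corr_sum.component == "raw")]
            row["mean_r_vs_reference"] = (
                float(sel.mean_r.iloc[0]) if len(sel) else np.nan
            )
        else:
            row["mean_r_vs_reference"] = np.nan
        row["n_significant_indices"] = sum(
            1 for t in tests if t.site == site and t.significant
        )
        for stage in ("walking", "weightlifting"):
            sel = quality[(quality.site == site) & (quality.stage == stage)]
            row[f"median_pn_{stage}"] = (
                float(sel.pn.median()) if len(sel) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _write_report(report: CohortReport, out: Path, cfg: PipelineConfig) -> dict[str, str]:
    out.mkdir(parents=True, exist_ok=True)
    outputs = {}

    corr_df = pd.DataFrame(
        [
            {
                "subject_id": e.subject_id,
                "site": e.site,
                "component": e.component,
                "stage_window": e.stage_window,
                "r": e.r,
            }
            for e in report.correlations
        ]
    )
    paths = {
        "correlations": (corr_df, "correlations.csv"),
        "correlation_summary": (report.correlation_summary, "correlation_summary.csv"),
        "indices": (index_table([i for s in report.subjects for i in s.indices]),
                    "indices.csv"),
        "quality": (report.quality, "quality.csv"),
        "site_ranking": (report.site_ranking, "site_ranking.csv"),
    }
    tests_df = pd.DataFrame(
        [
            {
                "site": t.site,
                "index": t.index_name,
                "test": t.stat_name,
                "statistic": t.statistic,
                "p_value": t.p_value,
                "normal_gate_passed": t.normal_gate_passed,
                "significant": t.significant,
                "stars": significance_stars(t.p_value),
                "n": t.n,
            }
            for t in report.tests
        ]
    )
    if tests_df.empty:
        tests_df = pd.DataFrame(
            columns=["site", "index", "test", "statistic", "p_value",
                     "normal_gate_passed", "significant", "stars", "n"]
        )
    paths["index_tests"] = (tests_df, "index_tests.csv")
    roc_df = pd.DataFrame(
        [
            {"site": r.site, "index": r.index_name, "threshold": th,
             "tpr": tp, "fpr": fp, "auc": r.auc}
            for r in report.rocs
            for th, tp, fp in zip(r.thresholds, r.tpr, r.fpr)
        ]
    )
    if roc_df.empty:
        roc_df = pd.DataFrame(
            columns=["site", "index", "threshold", "tpr", "fpr", "auc"]
        )
    paths["roc"] = (roc_df, "roc.csv")
    for key, (df, name) in paths.items():
        p = out / name
        df.to_csv(p, index=False)
        outputs[key] = str(p)
    return outputs


def run_pipeline(
    output_dir: str | Path,
    mode: str = "simulate",
    config: PipelineConfig | None = None,
    sim_config: SimulationConfig | None = None,
    recording_paths: Sequence[str | Path] | None = None,
    annotation_path: str | Path | None = None,
    site_columns: Sequence[str] | None = None,
    fs_raw: float = 100.0,
    seed: int | None = None,
    write_simulated: bool = False,
) -> RunManifest:
    """Run the full pipeline and write tidy CSV outputs plus a manifest.

    ``mode="simulate"`` generates a synthetic cohort (optionally writing
    the recordings); ``mode="analyze"`` loads recordings and annotations
    from files.  Deterministic for a fixed seed and configuration.
    """
    cfg = config or PipelineConfig()
    out = Path(output_dir)
    manifest = RunManifest(
        config=cfg.to_dict(),
        mode=mode,
        seed=seed,
        outputs={},
        started=datetime.datetime.now().isoformat(timespec="seconds"),
    )
    try:
        if mode == "simulate":
            scfg = sim_config or SimulationConfig()
            if seed is not None:
                scfg = scfg.replace(seed=seed)
            cohort = simulate_cohort(scfg)
            recordings = [rec for rec, _ in cohort]
            annotations = scfg.annotations()
            if write_simulated:
                sim_dir = out / "simulated"
                sim_dir.mkdir(parents=True, exist_ok=True)
                for rec, _ in cohort:
                    write_recording(rec, sim_dir / f"{rec.subject_id}.csv")
                write_annotations(annotations, sim_dir / "annotations.csv")
                manifest.outputs["simulated_dir"] = str(sim_dir)
        elif mode == "analyze":
            if not recording_paths or annotation_path is None:
                raise ValidationError(
                    "analyze mode needs recording_paths and annotation_path"
                )
            annotations = read_annotations(annotation_path)
            if site_columns is None:
                head = pd.read_csv(recording_paths[0], sep=None, engine="python",
                                   nrows=1)
                site_columns = [c for c in head.columns if c != "time_s"]
            recordings = [
                read_recording(p, fs=fs_raw, site_columns=site_columns,
                               artifact_distorted=True)
                for p in recording_paths
            ]
        else:
            raise ValidationError(f"unknown mode {mode!r}")

        report = analyze_cohort(recordings, annotations, cfg)
        manifest.outputs.update(_write_report(report, out, cfg))
        manifest.finished = datetime.datetime.now().isoformat(timespec="seconds")
        out.mkdir(parents=True, exist_ok=True)
        manifest.write(out / "manifest.json")
        manifest.outputs["manifest"] = str(out / "manifest.json")
        return manifest
    except Exception:
        manifest.failure_stage = _current_stage_hint(manifest)
        raise


def _current_stage_hint(manifest: RunManifest) -> str:
    return "input" if not manifest.outputs else "analysis"
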