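"""Statistical comparison machinery for multi-site EDA.

Four pieces, mirroring how wearable-EDA site-comparison studies are
analysed:

* within-subject Pearson correlations between each site and a reference
  site (default: finger), separately for the raw signal and the phasic and
  tonic components;
* a normality-gated paired comparison of per-subject EDA indices between
  the baseline and cognitive-stress stages: one-sample Kolmogorov-Smirnov
  gate on each group, paired t-test when both pass, two-sided Wilcoxon
  rank-sum otherwise;
* ROC curves (higher index value predicts stress) with trapezoidal AUC;
* a per-stage count of subjects whose site correlation exceeds a cut
  (default 0.5), used to track slow responsiveness changes such as
  electrode-site hydration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .io import PipelineConfig, ValidationError

logger = logging.getLogger("edasites")

__all__ = [
    "CorrelationEntry",
    "TestResult",
    "RocResult",
    "NormalityGate",
    "pearson_r",
    "correlation_table",
    "correlation_summary",
    "normality_gate",
    "compare_stages",
    "roc_curve",
    "hydration_progression",
    "significance_stars",
]


@dataclass(frozen=True)
class CorrelationEntry:
    """One within-subject correlation against the reference site."""

    subject_id: str
    site: str
    component: str  # raw | phasic | tonic
    stage_window: str
    r: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValidationError(f"correlation {self.r} outside [-1, 1]")


@dataclass(frozen=True)
class TestResult:
    """Baseline-vs-stress comparison of one index at one site."""

    site: str
    index_name: str
    stat_name: str  # paired_t | rank_sum | signed_rank
    statistic: float
    p_value: float
    normal_gate_passed: bool
    significant: bool
    n: int = 0


@dataclass
class RocResult:
    """ROC sweep for one index at one site (positive class = stress)."""

    site: str
    index_name: str
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class NormalityGate:
    passed: bool
    p_value: float
    degenerate: bool = False


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("need equal-length series with >= 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant series")
    return float(sstats.pearsonr(x, y).statistic)


def correlation_table(
    subjects: Iterable[Mapping],
    cfg: PipelineConfig | None = None,
    stages: Sequence[str] = ("baseline", "scwt"),
    stage_window: str | None = None,
    components: Sequence[str] = ("raw", "phasic", "tonic"),
) -> list[CorrelationEntry]:
    """Within-subject correlations of every non-reference site vs reference.

    Each element of ``subjects`` maps component name -> {site -> series}
    plus a ``subject_id``; the series for the given stages are
    concatenated per site before correlating (the stress stages are
    contiguous with baseline in the protocol, so concatenation matches a
    continuous window).  Subjects missing the reference site are skipped
    with a logged warning.
    """
    cfg = cfg or PipelineConfig()
    window = stage_window or "+".join(stages)
    ref = cfg.reference_site
    out: list[CorrelationEntry] = []
    for subj in subjects:
        sid = subj.get("subject_id", "?")
        for comp in components:
            series = subj.get(comp)
            if series is None:
                continue
            if ref not in series:
                logger.warning(
                    "subject %s: reference site %r missing, skipped", sid, ref
                )
                continue
            x = np.asarray(series[ref], dtype=float)
            for site, y in series.items():
                if site == ref:
                    continue
                try:
                    r = pearson_r(x, np.asarray(y, dtype=float))
                except ValidationError as exc:
                    logger.warning(
                        "subject %s site %s (%s): %s", sid, site, comp, exc
                    )
                    continue
                out.append(CorrelationEntry(sid, site, comp, window, r))
    return out


def correlation_summary(entries: Sequence[CorrelationEntry]) -> pd.DataFrame:
    """Mean and SD of r across subjects per (site, component)."""
    df = pd.DataFrame(
        [
            {
                "site": e.site,
                "component": e.component,
                "stage_window": e.stage_window,
                "r": e.r,
            }
            for e in entries
        ]
    )
    if df.empty:
        return df
    return (
        df.groupby(["site", "component", "stage_window"])["r"]
        .agg(mean_r="mean", sd_r="std", n="count")
        .reset_index()
    )


def normality_gate(sample: Sequence[float], alpha: float = 0.05) -> NormalityGate:
    """One-sample Kolmogorov-Smirnov normality gate.

    The sample is standardized to zero mean and unit SD and compared with
    the standard normal CDF; the gate passes when p >= alpha.  A
    zero-variance sample fails with the ``degenerate`` flag set.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValidationError("need at least 4 observations for the gate")
    sd = x.std(ddof=1)
    if sd == 0:
        return NormalityGate(passed=False, p_value=0.0, degenerate=True)
    z = (x - x.mean()) / sd
    res = sstats.kstest(z, "norm")
    return NormalityGate(passed=bool(res.pvalue >= alpha), p_value=float(res.pvalue))


def compare_stages(
    values_baseline: Sequence[float],
    values_stress: Sequence[float],
    cfg: PipelineConfig | None = None,
    site: str = "",
    index_name: str = "",
) -> TestResult:
    """Baseline-vs-stress test for one index, paired by subject.

    Both groups are KS-gated for normality; if both pass, a two-sided
    paired t-test is used, otherwise the two-sided Wilcoxon rank-sum test
    (or the signed-rank test when ``cfg.paired_fallback`` is set).
    """
    cfg = cfg or PipelineConfig()
    a = np.asarray(values_baseline, dtype=float)
    b = np.asarray(values_stress, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(
            f"groups must be paired by subject: {a.size} vs {b.size} values"
        )
    if a.size < 5:
        raise ValidationError("need at least 5 subjects")
    gate_a = normality_gate(a, cfg.significance_level)
    gate_b = normality_gate(b, cfg.significance_level)
    gate = gate_a.passed and gate_b.passed
    if gate:
        if np.all(a == b):
            stat, p = 0.0, 1.0  # zero paired difference everywhere
        else:
            res = sstats.ttest_rel(b, a)
            stat, p = float(res.statistic), float(res.pvalue)
        name = "paired_t"
    elif cfg.paired_fallback:
        if np.all(a == b):
            stat, p = 0.0, 1.0
        else:
            res = sstats.wilcoxon(b, a)
            stat, p = float(res.statistic), float(res.pvalue)
        name = "signed_rank"
    else:
        res = sstats.ranksums(b, a)
        stat, p = float(res.statistic), float(res.pvalue)
        name = "rank_sum"
    return TestResult(
        site=site,
        index_name=index_name,
        stat_name=name,
        statistic=stat,
        p_value=p,
        normal_gate_passed=gate,
        significant=bool(p < cfg.significance_level),
        n=int(a.size),
    )


def roc_curve(
    values_baseline: Sequence[float],
    values_stress: Sequence[float],
    site: str = "",
    index_name: str = "",
) -> RocResult:
    """ROC sweep: a sample is predicted stressed when value >= threshold.

    Thresholds run over +inf and every distinct observed value in
    decreasing order, so the (FPR, TPR) path goes from (0, 0) to (1, 1);
    tied values share one threshold point.  AUC is the trapezoid area
    under that path.  Indices that *decrease* under stress yield
    AUC < 0.5 and are reported as-is.
    """
    a = np.asarray(values_baseline, dtype=float)
    b = np.asarray(values_stress, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need at least 2 observations per class")
    thresholds = np.concatenate([[np.inf], np.unique(np.concatenate([a, b]))[::-1]])
    tpr = np.array([(b >= t).mean() for t in thresholds])
    fpr = np.array([(a >= t).mean() for t in thresholds])
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(
        site=site,
        index_name=index_name,
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
    )


def hydration_progression(
    entries_by_stage: Mapping[str, Sequence[CorrelationEntry]],
    cut: float = 0.5,
) -> dict[str, int]:
    """Per-stage count of subjects with correlation strictly above ``cut``.

    Emulates tracking whether a dry electrode site becomes responsive over
    the session.  Subjects missing from any stage are excluded from every
    stage (with a warning) so the counts stay comparable.
    """
    stage_subjects = {
        stage: {e.subject_id for e in entries} for stage, entries in entries_by_stage.items()
    }
    common = set.intersection(*stage_subjects.values()) if stage_subjects else set()
    dropped = set.union(*stage_subjects.values(), set()) - common
    if dropped:
        logger.warning(
            "hydration progression: subjects %s missing in some stage, excluded",
            sorted(dropped),
        )
    return {
        stage: sum(1 for e in entries if e.subject_id in common and e.r > cut)
        for stage, entries in entries_by_stage.items()
    }


def significance_stars(p: float) -> str:
    """Conventional significance marks: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
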