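"""Per-segment EDA indices: SCR count, phasic and tonic moments.

The SCR counter uses a relative threshold: a local maximum of the phasic
series counts as a skin conductance response when its amplitude is at
least ``threshold_fraction`` (default 0.05) of the largest peak amplitude
of that same phasic segment.  The relative rule makes the count invariant
to channel gain, which differs across body sites.  A minimum inter-peak
separation of 1 s suppresses numerical jitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .decompose import DecompositionResult
from .io import PipelineConfig, ValidationError

__all__ = ["IndexSet", "detect_scrs", "compute_indices", "index_table"]

INDEX_NAMES = ("n_scr", "phasic_mean", "phasic_variance", "tonic_mean", "tonic_variance")

MIN_PEAK_SEPARATION_S = 1.0


@dataclass(frozen=True)
class IndexSet:
    """The five per-segment EDA indices for one (subject, site, stage)."""

    n_scr: int
    phasic_mean: float
    phasic_variance: float
    tonic_mean: float
    tonic_variance: float
    stage: str = ""
    site: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.n_scr < 0:
            raise ValidationError("n_scr must be >= 0")
        if self.phasic_variance < 0 or self.tonic_variance < 0:
            raise ValidationError("variances must be >= 0")

    def value(self, name: str) -> float:
        if name not in INDEX_NAMES:
            raise KeyError(f"unknown index {name!r}; use one of {INDEX_NAMES}")
        return getattr(self, name)

    def as_dict(self) -> dict:
        return {name: self.value(name) for name in INDEX_NAMES}


def detect_scrs(
    phasic: np.ndarray, fs: float, threshold_fraction: float = 0.05
) -> list[tuple[float, float]]:
    """Detect SCR peaks in a phasic series.

    Returns ``(peak_time_s, peak_amplitude_us)`` pairs for every local
    maximum with amplitude >= threshold_fraction * (largest peak amplitude
    of this series), at least 1 s apart.  All-zero or all-nonpositive
    input yields an empty list.
    """
    phasic = np.asarray(phasic, dtype=float)
    if not np.all(np.isfinite(phasic)):
        raise ValidationError("non-finite phasic samples")
    if not 0 < threshold_fraction < 1:
        raise ValidationError("threshold_fraction must be in (0, 1)")
    if phasic.size < 3 or np.max(phasic) <= 0:
        return []
    distance = max(1, int(round(MIN_PEAK_SEPARATION_S * fs)))
    all_peaks, _ = sps.find_peaks(phasic)
    if all_peaks.size == 0:
        return []
    max_peak = phasic[all_peaks].max()
    if max_peak <= 0:
        return []
    threshold = threshold_fraction * max_peak
    peaks, props = sps.find_peaks(phasic, height=threshold, distance=distance)
    return [(i / fs, float(phasic[i])) for i in peaks]


def compute_indices(
    dec: DecompositionResult,
    fs: float,
    cfg: PipelineConfig | None = None,
    stage: str = "",
    site: str = "",
    subject_id: str = "",
) -> IndexSet:
    """Five indices from one decomposed segment.

    Variances use the unbiased (n-1) estimator.  Refuses a non-converged
    decomposition: its component split is not trustworthy.
    """
    cfg = cfg or PipelineConfig()
    if not dec.converged:
        raise ValidationError(
            f"decomposition did not converge ({dec.solver_message}); "
            "indices would be unreliable"
        )
    scrs = detect_scrs(dec.phasic, fs, cfg.scr_threshold_fraction)
    return IndexSet(
        n_scr=len(scrs),
        phasic_mean=float(np.mean(dec.phasic)),
        phasic_variance=float(np.var(dec.phasic, ddof=1)),
        tonic_mean=float(np.mean(dec.tonic)),
        tonic_variance=float(np.var(dec.tonic, ddof=1)),
        stage=stage,
        site=site,
        subject_id=subject_id,
    )


def index_table(index_sets: list[IndexSet]) -> pd.DataFrame:
    """Tidy long-format table: subject_id, site, stage, index, value."""
    rows = [
        {
            "subject_id": s.subject_id,
            "site": s.site,
            "stage": s.stage,
            "index": name,
            "value": s.value(name),
        }
        for s in index_sets
        for name in INDEX_NAMES
    ]
    return pd.DataFrame(rows)
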