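"""Data model and tabular I/O for multi-site skin-conductance recordings.

A :class:`Recording` holds simultaneously sampled conductance channels
(microsiemens) from several body sites; a :class:`StageAnnotation` marks one
protocol stage; :class:`PipelineConfig` collects every analysis constant in
one place.  Files are plain CSV: recordings as ``time_s,<site>,...``,
annotations as ``stage,start_s,end_s``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("edasites")

__all__ = [
    "Recording",
    "StageAnnotation",
    "PipelineConfig",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "FormatError",
    "ValidationError",
]


class FormatError(ValueError):
    """A file does not have the expected tabular shape."""


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


@dataclass
class Recording:
    """Multi-channel conductance series, one column per body site.

    Parameters
    ----------
    subject_id : str
        Identifier of the recorded subject.
    fs : float
        Sampling rate in Hz. Authoritative for the time axis.
    sites : list of str
        Ordered, unique site labels (e.g. forehead, neck, finger, foot).
    samples : (n, n_sites) ndarray
        Conductance in microsiemens, one row per time point.
    t0 : float
        Start time in seconds.
    artifact_distorted : bool
        When True, transient electrode-motion distortion may drive samples
        negative; negativity checks are relaxed.
    """

    subject_id: str
    fs: float
    sites: list[str]
    samples: np.ndarray
    t0: float = 0.0
    artifact_distorted: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D (n, n_sites) array")
        self.validate()

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if len(self.sites) == 0:
            raise ValidationError("at least one site label required")
        if len(set(self.sites)) != len(self.sites):
            raise ValidationError(f"site labels must be unique: {self.sites}")
        if self.samples.shape[1] != len(self.sites):
            raise ValidationError(
                f"{len(self.sites)} sites but {self.samples.shape[1]} sample columns"
            )
        if self.samples.shape[0] < 2:
            raise ValidationError("need at least 2 samples per channel")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("conductance values must be finite")
        if not self.artifact_distorted and np.any(self.samples < 0):
            raise ValidationError(
                "negative conductance in a recording not flagged artifact_distorted"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        """Time axis in seconds, derived from ``t0`` and ``fs``."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, site: str) -> np.ndarray:
        try:
            j = self.sites.index(site)
        except ValueError:
            raise KeyError(f"site {site!r} not in recording (has {self.sites})")
        return self.samples[:, j]


@dataclass(frozen=True)
class StageAnnotation:
    """One protocol stage: label plus a [start_s, end_s) interval."""

    stage: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValidationError(
                f"stage {self.stage!r}: end_s ({self.end_s}) must exceed "
                f"start_s ({self.start_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def validate_annotations(annotations: Sequence[StageAnnotation]) -> list[StageAnnotation]:
    """Sort annotations by start time and reject any overlapping pair."""
    ordered = sorted(annotations, key=lambda a: a.start_s)
    bad = [
        (i, i + 1)
        for i in range(len(ordered) - 1)
        if ordered[i + 1].start_s < ordered[i].end_s
    ]
    if bad:
        rows = "; ".join(
            f"{ordered[i].stage!r} [{ordered[i].start_s}, {ordered[i].end_s}) overlaps "
            f"{ordered[j].stage!r} [{ordered[j].start_s}, {ordered[j].end_s})"
            for i, j in bad
        )
        raise ValidationError(f"overlapping stage annotations: {rows}")
    return ordered


@dataclass
class PipelineConfig:
    """Analysis constants, each with the conventional default.

    ``target_fs``/``lowpass_*`` govern the preprocessing path feeding the
    decomposition; ``noise_band_low_hz`` and the Welch settings govern the
    spectral quality metric, which runs on the resampled but *unfiltered*
    signal; ``scr_threshold_fraction`` is the relative SCR amplitude
    threshold; ``reference_site`` anchors within-subject correlations.
    """

    target_fs: float = 8.0
    lowpass_order: int = 6
    lowpass_cutoff_hz: float = 0.6
    noise_band_low_hz: float = 0.4
    scr_threshold_fraction: float = 0.05
    significance_level: float = 0.05
    correlation_cut: float = 0.5
    welch_overlap_fraction: float = 0.5
    welch_segment_s: float = 32.0
    reference_site: str = "finger"
    paired_fallback: bool = False  # rank-sum fallback by default; signed-rank if True

    def __post_init__(self) -> None:
        if not 0 < self.lowpass_cutoff_hz < self.target_fs / 2:
            raise ValidationError(
                f"lowpass cutoff {self.lowpass_cutoff_hz} Hz must lie in "
                f"(0, {self.target_fs / 2}) Hz"
            )
        if self.noise_band_low_hz <= 0:
            raise ValidationError("noise_band_low_hz must be positive")
        if not 0 < self.scr_threshold_fraction < 1:
            raise ValidationError("scr_threshold_fraction must be in (0, 1)")
        if not 0 < self.welch_overlap_fraction < 1:
            raise ValidationError("welch_overlap_fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from YAML or JSON; unknown keys are rejected."""
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        raw = raw or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# readers / writers


def read_recording(
    path: str | Path,
    fs: float,
    site_columns: Sequence[str],
    subject_id: str = "",
    artifact_distorted: bool = False,
) -> Recording:
    """Read a delimited recording file into a :class:`Recording`.

    The file must carry one named column per requested site; a ``time_s``
    column, if present, is ignored (``fs`` is authoritative). Semicolon- or
    comma-delimited text is accepted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in site_columns if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing column(s) {missing}; file has {list(df.columns)}"
        )
    cols = df[list(site_columns)]
    bad = cols.apply(pd.to_numeric, errors="coerce")
    nonnum = bad.isna() & cols.notna()
    if nonnum.any().any():
        row = int(np.argwhere(nonnum.to_numpy())[0][0])
        raise FormatError(f"{path.name}: non-numeric value at data row {row}")
    if bad.isna().any().any():
        row = int(np.argwhere(bad.isna().to_numpy())[0][0])
        raise FormatError(f"{path.name}: missing value at data row {row}")
    return Recording(
        subject_id=subject_id or path.stem,
        fs=fs,
        sites=list(site_columns),
        samples=bad.to_numpy(dtype=float),
        artifact_distorted=artifact_distorted,
    )


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording as CSV with a leading ``time_s`` column."""
    rec.validate()
    path = Path(path)
    df = pd.DataFrame({"time_s": rec.time})
    for j, site in enumerate(rec.sites):
        df[site] = rec.samples[:, j]
    df.to_csv(path, index=False, float_format="%.8g")
    return path


def read_annotations(path: str | Path) -> list[StageAnnotation]:
    """Read a ``stage,start_s,end_s`` table; returns time-ordered annotations."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"stage", "start_s", "end_s"}
    if not required <= set(df.columns):
        raise FormatError(
            f"{path.name}: annotation file needs columns {sorted(required)}, "
            f"has {list(df.columns)}"
        )
    anns = [
        StageAnnotation(str(r.stage), float(r.start_s), float(r.end_s))
        for r in df.itertuples()
    ]
    return validate_annotations(anns)


def write_annotations(annotations: Sequence[StageAnnotation], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [{"stage": a.stage, "start_s": a.start_s, "end_s": a.end_s} for a in annotations]
    ).to_csv(path, index=False)
    return path
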