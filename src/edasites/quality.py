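"""Spectral signal-quality assessment via the noise-band power fraction.

Autonomic sudomotor dynamics live below ~0.4 Hz, so spectral power above
0.4 Hz in a skin-conductance channel is attributed to motion artifacts or
other non-EDA processes.  The quality score is

    Pn = (power at f > 0.4 Hz) / (total power, f > 0),

estimated from a Welch periodogram (Hann window, 50% overlap, per-window
linear detrend).  Pn is computed on the resampled but *unfiltered* signal:
after the 0.6 Hz analysis low-pass the noise band would be empty by
construction.  Higher Pn means more motion artifact.  The mean is removed
(per-window detrend) because the DC bin otherwise dominates total power
and pushes Pn of every channel towards zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import PipelineConfig, ValidationError

__all__ = ["QualityReport", "welch_psd", "noise_power_fraction"]


@dataclass
class QualityReport:
    """Noise-band power fraction and its underlying spectrum."""

    pn: float
    total_power: float
    noise_band_power: float
    freqs: np.ndarray
    psd: np.ndarray
    stage: str = ""
    site: str = ""
    subject_id: str = ""
    degenerate: bool = False


def welch_psd(
    x: np.ndarray,
    fs: float,
    segment_s: float = 32.0,
    overlap_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density with Hann window and linear detrend.

    ``segment_s`` is the window length in seconds; windows overlap by
    ``overlap_fraction``.  Returns (frequencies in Hz up to fs/2, PSD in
    µS²/Hz).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite samples")
    if not 0 < overlap_fraction < 1:
        raise ValidationError("overlap_fraction must be in (0, 1)")
    nperseg = int(round(segment_s * fs))
    if nperseg < 8:
        raise ValidationError("segment_s too short for this sampling rate")
    if x.size < nperseg:
        raise ValidationError(
            f"input ({x.size} samples) shorter than one Welch window ({nperseg})"
        )
    freqs, psd = sps.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap_fraction * nperseg)),
        detrend="linear",
    )
    return freqs, psd


def _band_power(freqs: np.ndarray, psd: np.ndarray, f_lo: float) -> float:
    """Trapezoid integral of the PSD over f >= f_lo, interpolating the edge."""
    if f_lo <= freqs[0]:
        return float(np.trapezoid(psd, freqs))
    if f_lo >= freqs[-1]:
        return 0.0
    edge = float(np.interp(f_lo, freqs, psd))
    mask = freqs > f_lo
    f_band = np.concatenate([[f_lo], freqs[mask]])
    p_band = np.concatenate([[edge], psd[mask]])
    return float(np.trapezoid(p_band, f_band))


def noise_power_fraction(
    x: np.ndarray,
    fs: float,
    cfg: PipelineConfig | None = None,
    stage: str = "",
    site: str = "",
    subject_id: str = "",
) -> QualityReport:
    """Fraction of spectral power above the noise-band edge (default 0.4 Hz).

    Amplitude-scale invariant (a ratio of powers).  A constant input has no
    power after detrending; the report is then flagged ``degenerate`` with
    ``pn = nan``.
    """
    cfg = cfg or PipelineConfig()
    if fs <= 2 * cfg.noise_band_low_hz:
        raise ValidationError(
            f"fs = {fs} Hz leaves no spectrum above the {cfg.noise_band_low_hz} Hz "
            "band edge"
        )
    freqs, psd = welch_psd(x, fs, cfg.welch_segment_s, cfg.welch_overlap_fraction)
    total = _band_power(freqs, psd, freqs[0])
    noise = _band_power(freqs, psd, cfg.noise_band_low_hz)
    if total <= 1e-300 or total < 1e-12 * float(np.mean(np.square(x))):
        return QualityReport(
            pn=float("nan"),
            total_power=total,
            noise_band_power=noise,
            freqs=freqs,
            psd=psd,
            stage=stage,
            site=site,
            subject_id=subject_id,
            degenerate=True,
        )
    return QualityReport(
        pn=noise / total,
        total_power=total,
        noise_band_power=noise,
        freqs=freqs,
        psd=psd,
        stage=stage,
        site=site,
        subject_id=subject_id,
    )
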