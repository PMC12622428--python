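"""Retraction-trace preprocessing ahead of rupture-event scoring.

Baseline correction, robust noise estimation, contact-point location and
optional Savitzky-Golay smoothing.  The far-separation end of the retract
trace, where no specific interaction persists, serves as the baseline
reference for all of these.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .fd_model_io import ForceDistanceCurve

__all__ = [
    "PreprocessConfig",
    "correct_baseline",
    "estimate_noise",
    "find_contact_point",
    "smooth_curve",
]

#: MAD -> SD consistency factor for a normal distribution
_MAD_SCALE = 1.4826


@dataclass
class PreprocessConfig:
    """Knobs for baseline, noise and smoothing.

    baseline_fraction : fraction of the far-separation end of the retract
        trace used for the linear baseline fit (0 < f <= 0.5).  The default
        (0.45) keeps the fitted line's extrapolation error at zero
        separation small relative to the noise band; short baseline windows
        amplify that error roughly as (window fraction)^-3/2.
    smooth_window : odd sample count of the local-polynomial smoother.
    smooth_order : polynomial order of the smoother (< smooth_window).
    noise_k : multiplier on the noise SD defining the noise band used for
        contact finding and for bounding the adhesion-energy region; event
        calling does not use it (events use a fixed force threshold).
    """

    baseline_fraction: float = 0.45
    smooth_window: int = 11
    smooth_order: int = 2
    noise_k: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.baseline_fraction <= 0.5):
            raise ValueError("baseline_fraction must be in (0, 0.5]")
        if self.smooth_window < 3 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 3")
        if self.smooth_order >= self.smooth_window:
            raise ValueError("smooth_order must be < smooth_window")
        if self.noise_k <= 0:
            raise ValueError("noise_k must be positive")


def _baseline_window(n: int, cfg: PreprocessConfig) -> int:
    """Number of far-field samples in the baseline window."""
    w = int(round(n * cfg.baseline_fraction))
    return max(w, 0)


def correct_baseline(
    curve: ForceDistanceCurve, cfg: PreprocessConfig | None = None
) -> ForceDistanceCurve:
    """Subtract a straight-line baseline fitted on the far-field tail.

    The line is fitted (ordinary least squares) on the farthest
    ``baseline_fraction`` of the retract samples and subtracted from the
    whole retract trace, so the far-field mean of the result is ~0 within
    noise.  Idempotent to numerical precision.
    """
    cfg = cfg or PreprocessConfig()
    if not curve.has_retract():
        raise ValueError("curve has no retract segment")
    z, f = curve.retract()
    w = _baseline_window(z.size, cfg)
    if w < 4:
        raise ValueError(
            f"baseline window has {w} samples; at least 4 required"
        )
    zb, fb = z[-w:], f[-w:]
    slope, intercept = np.polyfit(zb, fb, deg=1)
    corrected = f - (slope * z + intercept)
    return curve.with_retract_force(corrected)


def estimate_noise(
    curve: ForceDistanceCurve, cfg: PreprocessConfig | None = None
) -> float:
    """Robust noise SD (MAD x 1.4826) of the far-field baseline window."""
    cfg = cfg or PreprocessConfig()
    z, f = curve.retract()
    w = _baseline_window(z.size, cfg)
    if w < 4:
        raise ValueError("baseline window too small for noise estimation")
    tail = f[-w:]
    return float(_MAD_SCALE * np.median(np.abs(tail - np.median(tail))))


def find_contact_point(
    curve: ForceDistanceCurve,
    cfg: PreprocessConfig | None = None,
    noise_sd: float | None = None,
) -> float | None:
    """Separation where the retract trace first leaves the noise band.

    Scanning outward from zero separation, returns the separation of the
    last in-band sample before the trace first exceeds ``noise_k * sd`` in
    magnitude (or the first sample's separation if the trace starts outside
    the band).  Returns ``None`` ("no contact") when the whole trace stays
    inside the band; callers treat the adhesion energy as zero in that case.
    """
    cfg = cfg or PreprocessConfig()
    z, f = curve.retract()
    if noise_sd is None:
        noise_sd = estimate_noise(curve, cfg)
    band = cfg.noise_k * noise_sd
    outside = np.abs(f) > band
    if not outside.any():
        return None
    first = int(np.argmax(outside))
    return float(z[max(first - 1, 0)])


def smooth_curve(
    curve: ForceDistanceCurve, cfg: PreprocessConfig | None = None
) -> ForceDistanceCurve:
    """Savitzky-Golay smoothing of the retract force trace.

    Local polynomial of order ``smooth_order`` in a ``smooth_window``-sample
    window; the separation grid is untouched and endpoints are handled by
    polynomial fits on truncated windows (scipy ``mode='interp'``).  Assumes
    approximately uniform sample spacing.
    """
    cfg = cfg or PreprocessConfig()
    z, f = curve.retract()
    if cfg.smooth_window > f.size:
        raise ValueError(
            f"smooth_window {cfg.smooth_window} exceeds trace length {f.size}"
        )
    smoothed = savgol_filter(
        f, window_length=cfg.smooth_window, polyorder=cfg.smooth_order,
        mode="interp",
    )
    return curve.with_retract_force(smoothed)
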