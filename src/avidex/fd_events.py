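"""Rupture-event scoring of retraction traces.

This is the core nanomechanical analysis: on each baseline-corrected
retraction trace it detects abrupt force recoveries (bond ruptures) above a
fixed force threshold (300 pN by default), classifies the curve as
no-binding / single / multiple binding (two or more ruptures = multivalent
contact), and computes the maximum adhesion force F_max and the adhesion
energy E_adh (integral of adhesive force over separation).  Grid-level
summaries and heatmaps aggregate the per-curve metrics per surface.

Conventions
-----------
* The threshold applies to the rupture *jump* (recovery toward baseline),
  not to the absolute force at rupture, so a second rupture riding on a deep
  first adhesion well is still counted.
* F_max is the magnitude of the most attractive excursion over the whole
  retract trace, so sub-threshold nonspecific adhesion still yields a
  nonzero F_max.
* E_adh integrates |F| dz over adhesive runs (contiguous stretches below the
  noise band) that are deep enough to be distinguishable from noise; run
  boundaries are extended to the interpolated band crossings, which makes
  the trapezoid rule exact on piecewise-linear traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fd_model_io import FDGrid, ForceDistanceCurve
from .fd_preprocess import (
    PreprocessConfig,
    correct_baseline,
    estimate_noise,
    find_contact_point,
    smooth_curve,
)

__all__ = [
    "EventConfig",
    "RuptureEvent",
    "CurveMetrics",
    "SurfaceSummary",
    "detect_rupture_events",
    "classify_binding",
    "max_adhesion_force",
    "adhesion_energy",
    "score_curve",
    "score_grid",
    "summarize_surface",
    "build_heatmaps",
]

#: multiplier on the noise SD a run's peak depth must exceed to count as
#: adhesive signal in the energy integral (4 sigma keeps the expected
#: noise-only contribution far below 1 pN nm per curve at sigma = 30 pN)
DEEP_RUN_K = 4.0


@dataclass
class EventConfig:
    """Rupture-detection parameters.

    threshold : minimum abrupt force recovery (pN) for a rupture event.
    min_event_gap : events closer than this (nm) are merged, keeping the
        larger magnitude.
    within_window : the recovery must be completed within this much
        separation (nm) after the local force minimum.
    """

    threshold: float = 300.0
    min_event_gap: float = 1.0
    within_window: float = 2.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.min_event_gap <= 0 or self.within_window <= 0:
            raise ValueError("gaps must be positive")


@dataclass
class RuptureEvent:
    """One detected bond rupture on a retraction trace."""

    separation: float      # nm, location of the rupture (force minimum)
    magnitude: float       # pN, abrupt recovery toward baseline
    pre_level: float       # pN, force just before the rupture
    post_level: float      # pN, force just after the rupture


@dataclass
class CurveMetrics:
    """Per-curve scoring result."""

    n_events: int
    binding_class: str     # "no_binding" | "single" | "multiple"
    f_max: float           # pN, maximum adhesion force (>= 0)
    e_adh: float           # pN nm, adhesion energy (>= 0)
    contact_point: float | None  # nm, or None for "no contact"
    events: list[RuptureEvent] = field(default_factory=list)


@dataclass
class SurfaceSummary:
    """Grid-level statistics for one capture surface.

    Prevalences are fractions of curves per binding class; force and energy
    statistics are sample mean +/- sample SD (n - 1); ``f_single_*`` /
    ``f_multiple_*`` are the maximum adhesion force stratified by binding
    class at curve level.
    """

    surface_label: str
    n_curves: int
    prevalence_multiple: float
    prevalence_single: float
    f_max_mean: float
    f_max_sd: float
    e_adh_mean: float
    e_adh_sd: float
    f_single_mean: float
    f_single_sd: float
    f_multiple_mean: float
    f_multiple_sd: float


# ---------------------------------------------------------------------------
# detection


def detect_rupture_events(
    curve: ForceDistanceCurve, cfg: EventConfig | None = None
) -> list[RuptureEvent]:
    """Detect abrupt force recoveries >= threshold on the retract trace.

    A candidate event is a local force minimum followed, within
    ``within_window`` nm of separation, by a recovery toward baseline of at
    least ``threshold`` pN.  Events closer than ``min_event_gap`` are merged
    keeping the larger magnitude.  The trace is expected to be
    baseline-corrected; smoothing is optional and up to the caller.
    """
    cfg = cfg or EventConfig()
    z, f = curve.retract()
    if z.size == 0:
        raise ValueError("empty retract segment")
    if np.any(np.diff(z) <= 0):
        raise ValueError("retract separations must be strictly increasing")

    # local minima (plateau-tolerant at the left edge)
    n = z.size
    candidates = []
    for i in range(n):
        left_ok = i == 0 or f[i] <= f[i - 1]
        right_ok = i == n - 1 or f[i] <= f[i + 1]
        if left_ok and right_ok and f[i] < 0:
            candidates.append(i)

    events: list[RuptureEvent] = []
    for i in candidates:
        j = i + 1
        peak = f[i]
        best_j = None
        while j < n and z[j] - z[i] <= cfg.within_window:
            if f[j] > peak:
                peak = f[j]
                best_j = j
            j += 1
        if best_j is None:
            continue
        magnitude = peak - f[i]
        if magnitude >= cfg.threshold:
            events.append(
                RuptureEvent(
                    separation=float(z[i]),
                    magnitude=float(magnitude),
                    pre_level=float(f[i]),
                    post_level=float(peak),
                )
            )

    # merge events closer than min_event_gap, keeping larger magnitude
    events.sort(key=lambda e: e.separation)
    merged: list[RuptureEvent] = []
    for ev in events:
        if merged and ev.separation - merged[-1].separation < cfg.min_event_gap:
            if ev.magnitude > merged[-1].magnitude:
                merged[-1] = ev
        else:
            merged.append(ev)
    return merged


def classify_binding(events: list[RuptureEvent]) -> str:
    """0 events -> no_binding, 1 -> single, >= 2 -> multiple."""
    if len(events) >= 2:
        return "multiple"
    if len(events) == 1:
        return "single"
    return "no_binding"


def max_adhesion_force(curve: ForceDistanceCurve) -> float:
    """Magnitude of the most attractive force excursion, >= 0 (pN)."""
    _, f = curve.retract()
    return float(max(0.0, -np.min(f)))


# ---------------------------------------------------------------------------
# adhesion energy


def adhesion_energy(
    curve: ForceDistanceCurve,
    cfg: PreprocessConfig | None = None,
    noise_sd: float | None = None,
) -> float:
    """Adhesion energy: trapezoidal integral of |F| dz over adhesive runs.

    An adhesive run is a maximal stretch of samples with
    ``F < -noise_k * sd`` whose peak depth also exceeds
    ``DEEP_RUN_K * sd`` (so isolated noise excursions past the band do not
    accumulate spurious energy).  Each run is extended to the linearly
    interpolated band crossings on either side, which makes the integral
    exact on noise-free piecewise-linear traces.  Returns 0.0 when no run
    qualifies (the "no contact" case).
    """
    cfg = cfg or PreprocessConfig()
    z, f = curve.retract()
    if noise_sd is None:
        noise_sd = estimate_noise(curve, cfg)
    band = cfg.noise_k * noise_sd
    deep = max(DEEP_RUN_K * noise_sd, band)

    below = f < -band
    if not below.any():
        return 0.0

    total = 0.0
    n = z.size
    i = 0
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and below[j + 1]:
            j += 1
        run_min = float(np.min(f[i : j + 1]))
        if -run_min >= deep:
            zs = list(z[i : j + 1])
            fs = list(f[i : j + 1])
            # extend to the interpolated band crossing on each side
            if i > 0:
                z0 = _crossing(z[i - 1], f[i - 1], z[i], f[i], -band)
                zs.insert(0, z0)
                fs.insert(0, -band)
            if j < n - 1:
                z1 = _crossing(z[j], f[j], z[j + 1], f[j + 1], -band)
                zs.append(z1)
                fs.append(-band)
            total += float(np.trapezoid(-np.asarray(fs), np.asarray(zs)))
        i = j + 1
    return max(total, 0.0)


def _crossing(z0: float, f0: float, z1: float, f1: float, level: float) -> float:
    """Separation where the segment (z0,f0)-(z1,f1) crosses a force level."""
    if f1 == f0:
        return z0
    t = (level - f0) / (f1 - f0)
    t = min(max(t, 0.0), 1.0)
    return z0 + t * (z1 - z0)


# ---------------------------------------------------------------------------
# per-curve / per-grid scoring


def score_curve(
    curve: ForceDistanceCurve,
    pre_cfg: PreprocessConfig | None = None,
    ev_cfg: EventConfig | None = None,
    smooth: bool = False,
) -> CurveMetrics:
    """Full per-curve pipeline: baseline -> (smooth) -> detect -> metrics."""
    pre_cfg = pre_cfg or PreprocessConfig()
    ev_cfg = ev_cfg or EventConfig()
    corrected = correct_baseline(curve, pre_cfg)
    if smooth:
        corrected = smooth_curve(corrected, pre_cfg)
    noise_sd = estimate_noise(corrected, pre_cfg)
    contact = find_contact_point(corrected, pre_cfg, noise_sd=noise_sd)
    events = detect_rupture_events(corrected, ev_cfg)
    e_adh = (
        0.0
        if contact is None
        else adhesion_energy(corrected, pre_cfg, noise_sd=noise_sd)
    )
    return CurveMetrics(
        n_events=len(events),
        binding_class=classify_binding(events),
        f_max=max_adhesion_force(corrected),
        e_adh=e_adh,
        contact_point=contact,
        events=events,
    )


def score_grid(
    grid: FDGrid,
    pre_cfg: PreprocessConfig | None = None,
    ev_cfg: EventConfig | None = None,
    smooth: bool = False,
) -> list[CurveMetrics]:
    """Score every curve of a grid."""
    return [score_curve(c, pre_cfg, ev_cfg, smooth=smooth) for c in grid]


# ---------------------------------------------------------------------------
# aggregation


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    if values.size == 0:
        return 0.0, 0.0
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return mean, sd


def summarize_surface(grid: FDGrid, metrics: list[CurveMetrics]) -> SurfaceSummary:
    """Prevalences and force/energy statistics over a scored grid."""
    if not metrics:
        raise ValueError("no metrics to summarize")
    if len(metrics) != len(grid.curves):
        raise ValueError("one CurveMetrics per curve required")
    classes = np.array([m.binding_class for m in metrics])
    f_max = np.array([m.f_max for m in metrics])
    e_adh = np.array([m.e_adh for m in metrics])
    n = len(metrics)
    f_mean, f_sd = _mean_sd(f_max)
    e_mean, e_sd = _mean_sd(e_adh)
    fs_mean, fs_sd = _mean_sd(f_max[classes == "single"])
    fm_mean, fm_sd = _mean_sd(f_max[classes == "multiple"])
    return SurfaceSummary(
        surface_label=grid.surface_label,
        n_curves=n,
        prevalence_multiple=float(np.mean(classes == "multiple")),
        prevalence_single=float(np.mean(classes == "single")),
        f_max_mean=f_mean,
        f_max_sd=f_sd,
        e_adh_mean=e_mean,
        e_adh_sd=e_sd,
        f_single_mean=fs_mean,
        f_single_sd=fs_sd,
        f_multiple_mean=fm_mean,
        f_multiple_sd=fm_sd,
    )


def build_heatmaps(
    grid: FDGrid, metrics: list[CurveMetrics]
) -> tuple[np.ndarray, np.ndarray]:
    """(F_max map, E_adh map) as n_rows x n_cols matrices, NaN where absent."""
    if len(metrics) != len(grid.curves):
        raise ValueError("one CurveMetrics per curve required")
    f_map = np.full((grid.n_rows, grid.n_cols), np.nan)
    e_map = np.full((grid.n_rows, grid.n_cols), np.nan)
    seen: set[tuple[int, int]] = set()
    for curve, m in zip(grid.curves, metrics):
        idx = curve.grid_index
        if idx in seen:
            raise ValueError(f"duplicate grid_index {idx}")
        seen.add(idx)
        row, col = idx
        if row >= grid.n_rows or col >= grid.n_cols:
            raise ValueError(f"grid_index {idx} outside {grid.n_rows}x{grid.n_cols}")
        f_map[row, col] = m.f_max
        e_map[row, col] = m.e_adh
    return f_map, e_map
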