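"""Ellipsometric biosensor calibration: dose-response fit and detection limit.

A solution-immersed-silicon (SIS) ellipsometry sensor reports binding as a
differential change dPsi of the ellipsometric angle Psi.  Vesicle standards
are introduced serially at increasing concentrations; each step settles to a
plateau, and the plateau levels follow a log-linear dose-response

    dPsi = intercept + slope * log10(concentration)

over the sensor's working range.  The limit of detection is the
concentration whose calibrated signal equals the baseline mean plus three
baseline standard deviations (the 3-sigma rule), obtained by inverting the
fitted line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Sensorgram",
    "CalibrationFit",
    "extract_plateaus",
    "fit_dose_response",
    "compute_lod",
    "simulate_sensorgram",
]


@dataclass
class Sensorgram:
    """A dPsi-versus-time trace with its concentration schedule.

    ``concentration_schedule`` lists (start_time_s, concentration) steps in
    chronological order with non-decreasing concentrations (serial
    introduction); a leading zero-concentration step is the running-buffer
    baseline.
    """

    time: np.ndarray
    d_psi: np.ndarray
    concentration_schedule: list[tuple[float, float]]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.d_psi = np.asarray(self.d_psi, dtype=float)
        if self.time.size != self.d_psi.size:
            raise ValueError("time and d_psi lengths differ")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        concs = [c for _, c in self.concentration_schedule]
        if any(c < 0 for c in concs):
            raise ValueError("concentrations must be non-negative")
        if any(b < a for a, b in zip(concs, concs[1:])):
            raise ValueError("concentrations must be non-decreasing")
        starts = [t for t, _ in self.concentration_schedule]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("schedule start times must be increasing")

    def baseline_stats(self) -> tuple[float, float]:
        """Mean and SD of dPsi over the pre-injection (zero-conc) segment."""
        zero_steps = [
            (t, c) for t, c in self.concentration_schedule if c == 0
        ]
        if not zero_steps:
            raise ValueError("no zero-concentration baseline segment")
        start = zero_steps[0][0]
        idx = [
            i
            for i, (t, _) in enumerate(self.concentration_schedule)
            if t == start
        ][0]
        end = (
            self.concentration_schedule[idx + 1][0]
            if idx + 1 < len(self.concentration_schedule)
            else self.time[-1] + 1
        )
        mask = (self.time >= start) & (self.time < end)
        seg = self.d_psi[mask]
        if seg.size < 2:
            raise ValueError("baseline segment too short")
        return float(np.mean(seg)), float(np.std(seg, ddof=1))


@dataclass
class CalibrationFit:
    """Log-linear dose-response calibration.

    slope : dPsi per decade of concentration.
    intercept : dPsi at log10(concentration) = 0.
    r_squared : coefficient of determination of the fit.
    baseline_mean, baseline_sd : blank-signal statistics (dPsi units).
    lod : limit of detection (concentration units); NaN until computed.
    """

    slope: float
    intercept: float
    r_squared: float
    baseline_mean: float = 0.0
    baseline_sd: float = 0.0
    lod: float = float("nan")


def extract_plateaus(
    gram: Sensorgram, window: float
) -> list[tuple[float, float]]:
    """Mean dPsi over the trailing ``window`` seconds of each nonzero step.

    Raises if the window is longer than any step.
    """
    sched = gram.concentration_schedule
    if len([1 for _, c in sched if c > 0]) < 2:
        raise ValueError("schedule needs at least 2 nonzero concentration steps")
    points = []
    for i, (start, conc) in enumerate(sched):
        end = sched[i + 1][0] if i + 1 < len(sched) else float(gram.time[-1])
        if end - start < window:
            raise ValueError(
                f"window {window}s longer than step at t={start}s ({end - start}s)"
            )
        if conc <= 0:
            continue
        mask = (gram.time >= end - window) & (gram.time < end)
        points.append((float(conc), float(np.mean(gram.d_psi[mask]))))
    return points


def fit_dose_response(
    points: Sequence[tuple[float, float]],
    baseline: tuple[float, float] | None = None,
    conc_range: tuple[float, float] | None = None,
) -> CalibrationFit:
    """OLS fit of dPsi on log10(concentration).

    Parameters
    ----------
    points : (concentration, dPsi) pairs; concentrations must be positive
        and at least 3 distinct values are required.
    baseline : optional (mean, sd) of the blank signal, stored on the fit
        for the LOD computation.
    conc_range : optional (lo, hi); points outside are excluded before
        fitting (the sensor's stated working range).
    """
    pts = [(float(c), float(y)) for c, y in points]
    if any(c <= 0 for c, _ in pts):
        raise ValueError("concentrations must be positive")
    if conc_range is not None:
        lo, hi = conc_range
        pts = [(c, y) for c, y in pts if lo <= c <= hi]
    if len({c for c, _ in pts}) < 3:
        raise ValueError("at least 3 distinct positive concentrations required")
    logc = np.array([np.log10(c) for c, _ in pts])
    y = np.array([v for _, v in pts])
    res = stats.linregress(logc, y)
    fit = CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
    if baseline is not None:
        fit.baseline_mean, fit.baseline_sd = float(baseline[0]), float(baseline[1])
    return fit


def compute_lod(fit: CalibrationFit) -> float:
    """Limit of detection by the 3-sigma rule.

    Inverts the calibration line at signal = baseline_mean + 3 * baseline_sd:

        LOD = 10 ** ((baseline_mean + 3 * baseline_sd - intercept) / slope)

    and stores the result on ``fit.lod``.
    """
    if fit.slope <= 0:
        raise ValueError("LOD requires a positive dose-response slope")
    signal = fit.baseline_mean + 3.0 * fit.baseline_sd
    lod = float(10.0 ** ((signal - fit.intercept) / fit.slope))
    fit.lod = lod
    return lod


def simulate_sensorgram(
    slope: float,
    intercept: float,
    concentrations: Sequence[float],
    noise_sd: float,
    seed: int,
    step_duration: float = 120.0,
    baseline_duration: float = 120.0,
    dt: float = 1.0,
) -> Sensorgram:
    """Staircase sensorgram whose plateaus follow the log-linear law.

    A zero-concentration baseline segment (level 0) is followed by one step
    per concentration at level ``intercept + slope * log10(c)``, plus
    i.i.d. Gaussian noise.  Deterministic for a given seed.
    """
    concs = [float(c) for c in concentrations]
    if any(c <= 0 for c in concs) or any(
        b <= a for a, b in zip(concs, concs[1:])
    ):
        raise ValueError("concentrations must be positive and increasing")
    rng = np.random.default_rng(seed)
    schedule = [(0.0, 0.0)] + [
        (baseline_duration + i * step_duration, c) for i, c in enumerate(concs)
    ]
    total = baseline_duration + step_duration * len(concs)
    time = np.arange(0.0, total, dt)
    d_psi = np.zeros_like(time)
    for start, conc in schedule:
        if conc > 0:
            d_psi[time >= start] = intercept + slope * np.log10(conc)
    if noise_sd > 0:
        d_psi = d_psi + rng.normal(0.0, noise_sd, size=time.size)
    return Sensorgram(time=time, d_psi=d_psi, concentration_schedule=schedule)
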