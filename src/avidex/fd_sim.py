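"""Synthetic force-distance data: multivalent sawtooth retraction curves.

The generator emulates retraction traces from functionalized capture
surfaces probed with a ligand-coated AFM tip: a curve carries m = 0, 1, 2,
... sequential bond ruptures (sawtooth profile), a shallow nonspecific
adhesion dip near the surface, and additive Gaussian force noise.

Model
-----
* The number of bonds per contact m is drawn from a per-surface probability
  mass function; curves with m >= 2 are the multivalent ("multiple
  binding") population.
* Per-bond rupture magnitudes are lognormal, truncated from below at
  ``force_floor`` so that every generated bond produces a detectable jump
  (the scored population then mirrors the generated one; sub-floor contacts
  are part of the nonspecific background by construction).  Curves with a
  single bond and the bonds of multivalent curves may follow different
  lognormal laws, which lets the class-stratified force statistics be
  calibrated independently.
* Between ruptures the force loads along a steep linear ramp
  (``loading_stiffness``); at each rupture it recovers instantaneously.
  Breakpoint samples are inserted at the ramp nodes in addition to the
  uniform separation grid, so the piecewise-linear geometry (and hence the
  trapezoidal adhesion energy) is represented exactly at any grid spacing.
* The nonspecific dip recovers gradually (bounded slope), so it contributes
  to the maximum adhesion force but is never mistaken for an abrupt
  rupture.

Profiles for the four study surfaces are shipped pre-calibrated (see
``presets.yaml``); :func:`calibrate_profile` is the moment-matching routine
that produced them and can retarget a profile to any summary table.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.special import ndtr, ndtri

from .fd_events import EventConfig, SurfaceSummary, score_grid, summarize_surface
from .fd_model_io import FDGrid, ForceDistanceCurve
from .fd_preprocess import PreprocessConfig

__all__ = [
    "SurfaceProfile",
    "CalibrationError",
    "simulate_curve",
    "simulate_curve_with_truth",
    "simulate_grid",
    "calibrate_profile",
    "builtin_presets",
    "canonical_s0",
    "canonical_s1",
    "canonical_s2",
    "make_piecewise_curve",
    "profile_to_dict",
    "profile_from_dict",
]

#: tiny separation offset representing an instantaneous rupture
_JUMP_EPS = 1e-6

#: maximum recovery slope of the nonspecific dip (pN/nm); over the event
#: detector's 2 nm window this yields at most 160 pN, safely sub-threshold
_DIP_RECOVERY_SLOPE = 80.0


@dataclass
class SurfaceProfile:
    """Simulator parameterization of one capture surface.

    bond_count_pmf : mapping m -> probability of m specific bonds per
        contact (must sum to 1).
    rupture_force_logmean/logsd : lognormal parameters (log-pN) of the
        rupture magnitude for single-bond curves.
    multibond_logmean/logsd : lognormal parameters for the per-bond
        magnitudes of multivalent curves; default to the single-bond law.
    force_floor : lower truncation (pN) of the rupture-magnitude law.
    rupture_sep_range : (nm, nm) interval the ordered rupture separations
        are drawn from.
    min_bond_gap : minimum spacing (nm) between consecutive ruptures.
    loading_stiffness : slope (pN/nm) of the loading ramp before each
        rupture; larger values make ruptures spatially sharper and lower
        the adhesion energy per bond (E = F^2 / 2k).
    noise_sd : Gaussian force noise SD (pN).
    nonspecific_depth : mean depth (pN) of the shallow adhesion dip applied
        to all curves (0 disables it).
    nonspecific_logsd : log-SD of the lognormal dip depth.
    sample_spacing / z_max : uniform separation grid (nm).
    """

    name: str = "custom"
    bond_count_pmf: dict[int, float] = field(
        default_factory=lambda: {0: 0.2, 1: 0.3, 2: 0.3, 3: 0.15, 4: 0.05}
    )
    rupture_force_logmean: float = 6.5
    rupture_force_logsd: float = 0.7
    multibond_logmean: float | None = None
    multibond_logsd: float | None = None
    force_floor: float = 450.0
    rupture_sep_range: tuple[float, float] = (5.0, 60.0)
    min_bond_gap: float = 3.0
    loading_stiffness: float = 20000.0
    noise_sd: float = 30.0
    nonspecific_depth: float = 50.0
    nonspecific_logsd: float = 0.4
    sample_spacing: float = 0.5
    z_max: float = 160.0
    achieved: SurfaceSummary | None = None

    def __post_init__(self) -> None:
        total = sum(self.bond_count_pmf.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"bond_count_pmf sums to {total}, expected 1")
        if any(p < 0 for p in self.bond_count_pmf.values()):
            raise ValueError("bond_count_pmf has negative mass")
        if self.rupture_force_logsd < 0:
            raise ValueError("rupture_force_logsd must be >= 0")
        lo, hi = self.rupture_sep_range
        if not (0 < lo < hi):
            raise ValueError("rupture_sep_range must be positive and ordered")
        if self.loading_stiffness <= 0:
            raise ValueError("loading_stiffness must be positive")

    @property
    def multi_logmean(self) -> float:
        return (
            self.multibond_logmean
            if self.multibond_logmean is not None
            else self.rupture_force_logmean
        )

    @property
    def multi_logsd(self) -> float:
        return (
            self.multibond_logsd
            if self.multibond_logsd is not None
            else self.rupture_force_logsd
        )


class CalibrationError(RuntimeError):
    """Raised when profile calibration does not converge; carries residuals."""

    def __init__(self, message: str, residuals: dict[str, float]):
        super().__init__(f"{message}: residuals {residuals}")
        self.residuals = residuals


# ---------------------------------------------------------------------------
# curve construction


def make_piecewise_curve(
    breakpoints: Sequence[tuple[float, float]],
    spacing: float = 0.5,
    z_max: float = 100.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    grid_index: tuple[int, int] = (0, 0),
    surface_label: str = "",
) -> ForceDistanceCurve:
    """Sample a piecewise-linear retract trace on a uniform grid plus nodes.

    The breakpoint separations themselves are included as samples, so the
    returned polyline reproduces the geometry exactly (instantaneous
    ruptures are represented by a node pair a negligible separation apart).
    """
    bp = np.asarray(breakpoints, dtype=float)
    if np.any(np.diff(bp[:, 0]) <= 0):
        raise ValueError("breakpoint separations must be strictly increasing")
    coarse = np.arange(0.0, z_max + spacing / 2, spacing)
    z = np.unique(np.concatenate([coarse, bp[:, 0]]))
    z = z[(z >= 0) & (z <= z_max)]
    f = np.interp(z, bp[:, 0], bp[:, 1], left=0.0, right=0.0)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        f = f + rng.normal(0.0, noise_sd, size=f.size)
    return ForceDistanceCurve(
        separation=z,
        force=f,
        segment=np.full(z.size, "retract", dtype=object),
        grid_index=grid_index,
        surface_label=surface_label,
        sample_spacing=spacing,
    )


def _truncated_lognormal(
    rng: np.random.Generator, logmean: float, logsd: float, floor: float, size: int
) -> np.ndarray:
    """Lognormal(logmean, logsd) conditioned on being >= floor (inverse CDF)."""
    if size == 0:
        return np.zeros(0)
    if logsd == 0:
        value = np.exp(logmean)
        if value < floor:
            value = floor
        return np.full(size, value)
    a = ndtr((np.log(floor) - logmean) / logsd)
    u = rng.uniform(a, 1.0, size=size)
    u = np.clip(u, a, 1.0 - 1e-15)
    return np.exp(logmean + logsd * ndtri(u))


def _draw_separations(
    rng: np.random.Generator, m: int, lo: float, hi: float, gap: float
) -> np.ndarray:
    """m ordered separations in (lo, hi) with pairwise gaps >= gap."""
    for _ in range(1000):
        z = np.sort(rng.uniform(lo, hi, size=m))
        if m < 2 or np.all(np.diff(z) >= gap):
            return z
    # fall back to an evenly spaced layout (pathological gap/range combos)
    return np.linspace(lo, min(hi, lo + gap * (m - 1) + 1e-6), m)


def simulate_curve(
    profile: SurfaceProfile,
    seed: int | Sequence[int],
    grid_index: tuple[int, int] = (0, 0),
) -> ForceDistanceCurve:
    """Draw one synthetic retraction curve from a surface profile.

    Identical ``(profile, seed)`` pairs produce identical curves.
    """
    curve, _ = simulate_curve_with_truth(profile, seed, grid_index)
    return curve


def simulate_curve_with_truth(
    profile: SurfaceProfile,
    seed: int | Sequence[int],
    grid_index: tuple[int, int] = (0, 0),
) -> tuple[ForceDistanceCurve, list[tuple[float, float]]]:
    """As :func:`simulate_curve`, also returning the generated bond list.

    The second element lists the ground-truth ruptures as
    ``(separation_nm, magnitude_pN)`` pairs — the oracle for detector
    recall/precision tests.
    """
    rng = np.random.default_rng(seed)
    ms = sorted(profile.bond_count_pmf)
    probs = np.array([profile.bond_count_pmf[m] for m in ms])
    m = int(rng.choice(ms, p=probs / probs.sum()))

    nodes: list[tuple[float, float]] = [(0.0, 0.0)]
    truth: list[tuple[float, float]] = []
    cursor = 0.0

    # nonspecific dip: shallow, gradual recovery -> never an abrupt event
    if profile.nonspecific_depth > 0:
        mu_d = np.log(profile.nonspecific_depth) - profile.nonspecific_logsd**2 / 2
        depth = float(
            np.exp(mu_d + profile.nonspecific_logsd * rng.standard_normal())
        )
        apex = 0.75
        rec_end = apex + max(1.5, depth / _DIP_RECOVERY_SLOPE)
        nodes += [(apex, -depth), (rec_end, 0.0)]
        cursor = rec_end

    if m > 0:
        lo, hi = profile.rupture_sep_range
        seps = _draw_separations(rng, m, lo, hi, profile.min_bond_gap)
        if m == 1:
            forces = _truncated_lognormal(
                rng,
                profile.rupture_force_logmean,
                profile.rupture_force_logsd,
                profile.force_floor,
                1,
            )
        else:
            forces = _truncated_lognormal(
                rng,
                profile.multi_logmean,
                profile.multi_logsd,
                profile.force_floor,
                m,
            )
        for z_r, f_r in zip(seps, forces):
            ramp_start = max(z_r - f_r / profile.loading_stiffness, cursor + 1e-4)
            if ramp_start >= z_r:
                ramp_start = (cursor + z_r) / 2
            nodes += [(ramp_start, 0.0), (z_r, -f_r), (z_r + _JUMP_EPS, 0.0)]
            cursor = z_r + _JUMP_EPS
            truth.append((float(z_r), float(f_r)))

    nodes.append((profile.z_max, 0.0))
    curve = make_piecewise_curve(
        nodes,
        spacing=profile.sample_spacing,
        z_max=profile.z_max,
        noise_sd=profile.noise_sd,
        rng=rng,
        grid_index=grid_index,
        surface_label=profile.name,
    )
    return curve, truth


def simulate_grid(
    profile: SurfaceProfile, n_rows: int, n_cols: int, seed: int
) -> FDGrid:
    """Simulate an n_rows x n_cols force-volume grid.

    Each curve gets an independent stream derived from ``(seed, row, col)``,
    so the result is reproducible and independent of acquisition order.
    """
    curves = [
        simulate_curve(profile, (seed, row, col), grid_index=(row, col))
        for row in range(n_rows)
        for col in range(n_cols)
    ]
    return FDGrid(
        curves=curves,
        n_rows=n_rows,
        n_cols=n_cols,
        surface_label=profile.name,
    )


# ---------------------------------------------------------------------------
# canonical analytic fixtures


def canonical_s0() -> ForceDistanceCurve:
    """S0: flat zero-force trace (no contact)."""
    return make_piecewise_curve([(0.0, 0.0), (100.0, 0.0)], spacing=0.5)


def canonical_s1() -> ForceDistanceCurve:
    """S1: two-event sawtooth with analytically known metrics.

    Ramp to -500 pN over 0-20 nm, instantaneous rupture to baseline; ramp
    to -800 pN over 20-50 nm, rupture; flat to 100 nm; 0.5 nm grid spacing
    with rupture nodes inserted.  Events: 500 pN at 20 nm, 800 pN at 50 nm;
    F_max = 800 pN; E_adh = 0.5*20*500 + 0.5*30*800 = 17000 pN nm.
    """
    nodes = [
        (0.0, 0.0),
        (20.0, -500.0),
        (20.0 + _JUMP_EPS, 0.0),
        (50.0, -800.0),
        (50.0 + _JUMP_EPS, 0.0),
        (100.0, 0.0),
    ]
    return make_piecewise_curve(nodes, spacing=0.5)


def canonical_s2() -> ForceDistanceCurve:
    """S2: single sub-threshold triangular dip (250 pN deep, 10 nm base)."""
    nodes = [(0.0, 0.0), (5.0, -250.0), (10.0, 0.0), (100.0, 0.0)]
    return make_piecewise_curve(nodes, spacing=0.5)


# ---------------------------------------------------------------------------
# calibration


_CAL_KEYS = (
    "prevalence_multiple",
    "prevalence_single",
    "f_max_mean",
    "e_adh_mean",
    "f_single_mean",
    "f_multiple_mean",
)


def _summary_targets(targets: Mapping[str, float] | SurfaceSummary) -> dict:
    if isinstance(targets, SurfaceSummary):
        targets = {k: getattr(targets, k) for k in _CAL_KEYS}
    out = {k: float(v) for k, v in targets.items() if v is not None}
    if "prevalence_multiple" not in out:
        raise ValueError("targets must include prevalence_multiple")
    return out


def _simulate_and_summarize(
    profile: SurfaceProfile, n_curves: int, seed: int
) -> SurfaceSummary:
    grid = simulate_grid(profile, n_curves, 1, seed)
    metrics = score_grid(grid, PreprocessConfig(), EventConfig())
    return summarize_surface(grid, metrics)


def calibrate_profile(
    targets: Mapping[str, float] | SurfaceSummary,
    base: SurfaceProfile,
    n_curves: int = 2000,
    seed: int = 7,
    tol: float = 0.05,
    max_iter: int = 20,
) -> SurfaceProfile:
    """Moment-match a surface profile to target pipeline summaries.

    The bond-count PMF is set so the simulated multivalent prevalence equals
    ``prevalence_multiple`` by construction (and the single-bond prevalence
    when provided).  Force and energy moments are then matched by fixed-point
    iteration: the lognormal log-means are shifted by the log-ratio of target
    to achieved force mean (stratified by class when stratified targets are
    given) and the loading stiffness is rescaled by the achieved/target
    energy ratio, re-simulating and re-scoring with common random numbers
    until every targeted quantity is within ``tol`` (relative).

    Raises
    ------
    CalibrationError
        If residuals still exceed ``tol`` after ``max_iter`` iterations.
    """
    tgt = _summary_targets(targets)
    profile = copy.deepcopy(base)
    profile.achieved = None

    # --- PMF by construction -------------------------------------------------
    p_multi = tgt["prevalence_multiple"]
    base_multi = {m: p for m, p in base.bond_count_pmf.items() if m >= 2}
    w = sum(base_multi.values()) or 1.0
    pmf = {m: p_multi * p / w for m, p in base_multi.items()}
    if "prevalence_single" in tgt:
        p_single = tgt["prevalence_single"]
    else:
        p1 = base.bond_count_pmf.get(1, 0.0)
        p0 = base.bond_count_pmf.get(0, 0.0)
        rest = p0 + p1
        p_single = (1.0 - p_multi) * (p1 / rest if rest > 0 else 0.0)
    p_zero = 1.0 - p_multi - p_single
    if p_zero < -1e-9:
        raise ValueError("prevalence targets exceed total probability")
    pmf[1] = p_single
    pmf[0] = max(p_zero, 0.0)
    total = sum(pmf.values())
    profile.bond_count_pmf = {m: p / total for m, p in sorted(pmf.items())}

    stratified = "f_single_mean" in tgt and "f_multiple_mean" in tgt
    if stratified and profile.multibond_logmean is None:
        profile.multibond_logmean = profile.rupture_force_logmean
        profile.multibond_logsd = profile.rupture_force_logsd

    residuals: dict[str, float] = {}
    for _ in range(max_iter):
        achieved = _simulate_and_summarize(profile, n_curves, seed)
        residuals = {}

        def _rel(name: str, ach: float) -> float | None:
            if name not in tgt:
                return None
            r = ach / tgt[name] - 1.0 if tgt[name] != 0 else ach
            residuals[name] = r
            return r

        r_single = _rel("f_single_mean", achieved.f_single_mean)
        r_multi = _rel("f_multiple_mean", achieved.f_multiple_mean)
        r_overall = _rel("f_max_mean", achieved.f_max_mean)
        r_energy = _rel("e_adh_mean", achieved.e_adh_mean)

        if all(abs(r) <= tol for r in residuals.values()):
            profile.achieved = achieved
            return profile

        if stratified:
            if r_single is not None and achieved.f_single_mean > 0:
                profile.rupture_force_logmean += np.log(
                    tgt["f_single_mean"] / achieved.f_single_mean
                )
            if r_multi is not None and achieved.f_multiple_mean > 0:
                profile.multibond_logmean += np.log(
                    tgt["f_multiple_mean"] / achieved.f_multiple_mean
                )
        elif r_overall is not None and achieved.f_max_mean > 0:
            # shift both laws together toward the overall force target;
            # damped because the nonspecific floor does not scale with them
            shift = np.log(tgt["f_max_mean"] / achieved.f_max_mean)
            profile.rupture_force_logmean += shift
            if profile.multibond_logmean is not None:
                profile.multibond_logmean += shift

        if r_energy is not None and achieved.e_adh_mean > 0:
            profile.loading_stiffness *= achieved.e_adh_mean / tgt["e_adh_mean"]

    raise CalibrationError("calibration did not converge", residuals)


# ---------------------------------------------------------------------------
# presets


def profile_to_dict(profile: SurfaceProfile) -> dict:
    """Plain-dict form of a profile for YAML serialization."""
    return {
        "name": profile.name,
        "bond_count_pmf": {int(m): float(p) for m, p in profile.bond_count_pmf.items()},
        "rupture_force_logmean": float(profile.rupture_force_logmean),
        "rupture_force_logsd": float(profile.rupture_force_logsd),
        "multibond_logmean": (
            None if profile.multibond_logmean is None else float(profile.multibond_logmean)
        ),
        "multibond_logsd": (
            None if profile.multibond_logsd is None else float(profile.multibond_logsd)
        ),
        "force_floor": float(profile.force_floor),
        "rupture_sep_range": [float(x) for x in profile.rupture_sep_range],
        "min_bond_gap": float(profile.min_bond_gap),
        "loading_stiffness": float(profile.loading_stiffness),
        "noise_sd": float(profile.noise_sd),
        "nonspecific_depth": float(profile.nonspecific_depth),
        "nonspecific_logsd": float(profile.nonspecific_logsd),
        "sample_spacing": float(profile.sample_spacing),
        "z_max": float(profile.z_max),
    }


def profile_from_dict(data: Mapping) -> SurfaceProfile:
    data = dict(data)
    data["bond_count_pmf"] = {int(m): float(p) for m, p in data["bond_count_pmf"].items()}
    data["rupture_sep_range"] = tuple(data["rupture_sep_range"])
    return SurfaceProfile(**data)


def builtin_presets() -> dict[str, SurfaceProfile]:
    """The four pre-calibrated study-surface profiles.

    Keys: ``G7-pPDL1`` (dendrimer-peptide conjugate), ``aPD-L1``
    (antibody), ``pPDL1`` (free peptide), ``G7-pPDL1-scr`` (scrambled
    peptide negative control).  Parameters were fixed once by running
    :func:`calibrate_profile` against each surface's published summary
    (prevalences, force and energy means) at n = 4000 curves, seed 7.
    """
    text = resources.files("avidex").joinpath("presets.yaml").read_text()
    raw = yaml.safe_load(text)
    return {name: profile_from_dict(d) for name, d in raw.items()}
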