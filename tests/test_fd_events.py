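import dataclasses

import numpy as np
import pytest

from avidex.fd_events import (
    CurveMetrics,
    EventConfig,
    RuptureEvent,
    adhesion_energy,
    build_heatmaps,
    classify_binding,
    detect_rupture_events,
    max_adhesion_force,
    score_curve,
    score_grid,
    summarize_surface,
)
from avidex.fd_model_io import FDGrid, ForceDistanceCurve
from avidex.fd_preprocess import correct_baseline
from avidex.fd_sim import SurfaceProfile, make_piecewise_curve, simulate_grid

from conftest import flat_curve


# --- detection -------------------------------------------------------------


def test_flat_curve_has_no_events(s0):
    assert detect_rupture_events(s0) == []


def test_s1_sawtooth_detected_exactly(s1):
    events = detect_rupture_events(s1)
    assert len(events) == 2
    assert events[0].separation == pytest.approx(20.0, abs=1e-9)
    assert events[0].magnitude == pytest.approx(500.0, abs=1e-3)
    assert events[1].separation == pytest.approx(50.0, abs=1e-9)
    assert events[1].magnitude == pytest.approx(800.0, abs=1e-3)


def test_sub_threshold_dip_not_detected(s2):
    assert detect_rupture_events(s2) == []


def test_gradual_recovery_not_detected():
    # 500 pN deep but recovering over 10 nm: not an abrupt rupture
    curve = make_piecewise_curve(
        [(0.0, 0.0), (20.0, -500.0), (30.0, 0.0), (100.0, 0.0)], spacing=0.5
    )
    assert detect_rupture_events(curve) == []


def test_close_events_are_merged():
    nodes = [
        (0.0, 0.0),
        (20.0, -400.0),
        (20.0 + 1e-6, 0.0),
        (20.5, -600.0),
        (20.5 + 1e-6, 0.0),
        (100.0, 0.0),
    ]
    curve = make_piecewise_curve(nodes, spacing=0.5)
    events = detect_rupture_events(curve, EventConfig(min_event_gap=1.0))
    assert len(events) == 1
    assert events[0].magnitude == pytest.approx(600.0, abs=1e-3)


def test_unsorted_retract_rejected():
    curve = flat_curve(n=20)
    object.__setattr__(curve, "separation", curve.separation[::-1].copy())
    with pytest.raises(ValueError):
        detect_rupture_events(curve)


def test_detection_invariant_under_stored_direction(s1):
    reversed_curve = ForceDistanceCurve(
        separation=s1.separation[::-1].copy(),
        force=s1.force[::-1].copy(),
        segment=s1.segment.copy(),
    )
    ev_a = detect_rupture_events(s1)
    ev_b = detect_rupture_events(reversed_curve)
    assert [e.magnitude for e in ev_a] == pytest.approx(
        [e.magnitude for e in ev_b]
    )
    assert max_adhesion_force(s1) == max_adhesion_force(reversed_curve)


@pytest.mark.parametrize(
    "n_events,expected",
    [(0, "no_binding"), (1, "single"), (2, "multiple"), (5, "multiple")],
)
def test_classification_by_event_count(n_events, expected):
    events = [RuptureEvent(10.0 * (i + 1), 500.0, -500.0, 0.0) for i in range(n_events)]
    assert classify_binding(events) == expected


# --- F_max and E_adh -------------------------------------------------------


def test_max_adhesion_force(s0, s1):
    assert max_adhesion_force(s0) == 0.0
    assert max_adhesion_force(s1) == pytest.approx(800.0)
    shifted = correct_baseline(s1.with_force(s1.force + 100.0))
    assert max_adhesion_force(shifted) == pytest.approx(800.0, abs=1e-6)


def test_adhesion_energy_flat_zero(s0):
    assert adhesion_energy(s0) == 0.0


def test_adhesion_energy_s1_exact_triangles(s1):
    # 0.5*20*500 + 0.5*30*800 = 17000; trapezoid exact on piecewise-linear
    assert adhesion_energy(s1, noise_sd=0.0) == pytest.approx(17000.0, rel=1e-6)


def test_adhesion_energy_single_triangle():
    curve = make_piecewise_curve(
        [(0.0, 0.0), (5.0, -400.0), (10.0, 0.0), (100.0, 0.0)], spacing=0.5
    )
    assert adhesion_energy(curve, noise_sd=0.0) == pytest.approx(2000.0, rel=1e-6)


def test_adhesion_energy_nonnegative_on_noise():
    rng = np.random.default_rng(4)
    for _ in range(20):
        curve = flat_curve(n=200).with_force(rng.normal(0, 30.0, 200))
        assert adhesion_energy(curve) >= 0.0


def test_no_contact_implies_zero_energy(s0):
    metrics = score_curve(s0)
    assert metrics.contact_point is None
    assert metrics.e_adh == 0.0


# --- false events on pure noise -------------------------------------------


def test_false_event_rate_below_one_percent_on_pure_noise():
    """At sigma = 30 pN the 300 pN jump threshold sits at 10 sigma."""
    profile = SurfaceProfile(
        name="noise",
        bond_count_pmf={0: 1.0},
        nonspecific_depth=0.0,
        noise_sd=30.0,
    )
    grid = simulate_grid(profile, 1000, 1, seed=99)
    metrics = score_grid(grid)
    false_rate = np.mean([m.n_events > 0 for m in metrics])
    assert false_rate < 0.01


# --- aggregation -----------------------------------------------------------


def _metric(n_events, f_max, e_adh):
    cls = classify_binding(
        [RuptureEvent(10.0 * (i + 1), 500.0, -500.0, 0.0) for i in range(n_events)]
    )
    return CurveMetrics(n_events, cls, f_max, e_adh, 0.0 if f_max > 0 else None)


def _grid_of(n):
    curves = [flat_curve(grid_index=(i, 0)) for i in range(n)]
    return FDGrid(curves=curves, n_rows=n, n_cols=1, surface_label="x")


def test_summary_all_no_binding():
    metrics = [_metric(0, 0.0, 0.0) for _ in range(4)]
    s = summarize_surface(_grid_of(4), metrics)
    assert s.prevalence_multiple == 0.0
    assert s.prevalence_single == 0.0
    assert s.f_max_mean == 0.0


def test_summary_prevalence_counting():
    metrics = [_metric(2, 100.0, 1.0) for _ in range(9)] + [_metric(0, 0.0, 0.0)]
    s = summarize_surface(_grid_of(10), metrics)
    assert s.prevalence_multiple == pytest.approx(0.9)


def test_summary_matches_brute_force_recomputation():
    rng = np.random.default_rng(5)
    n = 60
    metrics = [
        _metric(int(rng.integers(0, 4)), float(rng.gamma(2, 300)), float(rng.gamma(2, 30)))
        for _ in range(n)
    ]
    s = summarize_surface(_grid_of(n), metrics)
    f = np.array([m.f_max for m in metrics])
    e = np.array([m.e_adh for m in metrics])
    cls = np.array([m.binding_class for m in metrics])
    assert s.f_max_mean == pytest.approx(f.mean())
    assert s.f_max_sd == pytest.approx(f.std(ddof=1))
    assert s.e_adh_mean == pytest.approx(e.mean())
    assert s.e_adh_sd == pytest.approx(e.std(ddof=1))
    assert s.prevalence_multiple == pytest.approx(np.mean(cls == "multiple"))
    assert s.prevalence_single == pytest.approx(np.mean(cls == "single"))
    assert s.f_single_mean == pytest.approx(f[cls == "single"].mean())
    assert s.f_multiple_mean == pytest.approx(f[cls == "multiple"].mean())
    assert s.prevalence_single + s.prevalence_multiple <= 1.0


def test_summary_empty_errors():
    with pytest.raises(ValueError):
        summarize_surface(_grid_of(1), [])


def test_heatmaps_uniform_and_missing():
    grid = FDGrid(
        curves=[flat_curve(grid_index=(0, 0))], n_rows=2, n_cols=2
    )
    f_map, e_map = build_heatmaps(grid, [_metric(1, 500.0, 10.0)])
    assert f_map[0, 0] == 500.0
    assert np.isnan(f_map).sum() == 3
    assert np.isnan(e_map).sum() == 3


def test_heatmaps_checkerboard():
    curves, metrics = [], []
    for r in range(2):
        for c in range(2):
            curves.append(flat_curve(grid_index=(r, c)))
            high = (r + c) % 2 == 0
            metrics.append(_metric(1, 900.0 if high else 100.0, 1.0))
    grid = FDGrid(curves=curves, n_rows=2, n_cols=2)
    f_map, _ = build_heatmaps(grid, metrics)
    np.testing.assert_array_equal(f_map, [[900.0, 100.0], [100.0, 900.0]])


def test_event_config_invariants():
    with pytest.raises(ValueError):
        EventConfig(threshold=0.0)
    with pytest.raises(ValueError):
        EventConfig(min_event_gap=-1.0)
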