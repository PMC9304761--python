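"""Atom-pair traces, plateau/switching detection, path tracing, RMSD."""

import math

import numpy as np
import pytest

from cpus.analysis import (
    DistanceTrace,
    detect_plateaus,
    detect_switching,
    distance_histogram,
    exit_direction_label,
    pair_distance_series,
    rmsd_series,
    superpose_rmsd,
    trace_path,
)
from cpus.driver import WalkerRun, WindowSchedule, run_walker
from cpus.dynamics import IntegratorParams, RestraintSpec, WindowTimeSeries
from cpus.landscape import Landscape, LigandState, isotropic_well


def _trace(values, dt=1.0):
    v = np.asarray(values, dtype=float)
    return DistanceTrace(
        times=dt * np.arange(len(v)), distances=v,
        pair_label="test", window_index=np.zeros(len(v), dtype=int),
    )


def _synthetic_run(frames_per_window, d_ref=3.0, delta=0.1, spring_k=10.0):
    """WalkerRun whose windows carry hand-chosen ligand frames."""
    n = len(frames_per_window)
    sched = WindowSchedule(d_ref=d_ref, n_forward=n, delta=delta, n_backward=0)
    windows = []
    for i, frames in enumerate(frames_per_window):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim == 2:
            frames = frames[:, None, :]
        m = len(frames)
        windows.append(WindowTimeSeries(
            times=np.arange(m, dtype=float), distances=np.ones(m),
            vdw=np.zeros(m), elec=np.zeros(m),
            restraint=RestraintSpec(spring_k, d_ref + delta * i),
            frames=frames, frame_times=np.arange(m, dtype=float),
            window_index=i,
        ))
    return WalkerRun(schedule=sched, windows=windows, walker_id=0,
                     master_seed=0, spring_k=spring_k)


# -- pair distances -------------------------------------------------------


def test_pair_distance_trivial_geometries():
    ls = Landscape(host_anchors=[[1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
    run = _synthetic_run([[[1.0, 0.0, 0.0]], [[1.0, 0.0, 0.0]]])
    coincident = pair_distance_series(run, 0, 0, landscape=ls)
    assert np.all(coincident.distances == 0.0)
    static = pair_distance_series(run, 1, 0, landscape=ls)
    assert np.allclose(static.distances, 1.0)
    with pytest.raises(ValueError):
        pair_distance_series(run, 5, 0, landscape=ls)


def test_pulled_ligand_distance_is_monotone_after_smoothing():
    """Outward pulling at high bias stiffness: the distance to the
    host-center anchor (the purely radial signal) is non-decreasing for
    >= 90% of consecutive 100-sample means.  Off-center anchors add slow
    angular wander on top, which is the subject of the plateau analysis,
    not of this monotonicity property."""
    ls = isotropic_well(host_anchors=[[0.0, 0.0, 0.0]])
    sched = WindowSchedule(d_ref=2.7, n_forward=60, delta=0.1, n_backward=0)
    run = run_walker(ls, sched, IntegratorParams(seed=31), 0,
                     n_steps=800, stride=4, path_stride=1, spring_k=40.0)
    trace = pair_distance_series(run, 0, 0, landscape=ls)
    w = 100
    kernel = np.ones(w) / w
    smooth = np.convolve(trace.distances, kernel, mode="valid")
    diffs = np.diff(smooth[::w])
    assert np.mean(diffs >= 0) >= 0.9


# -- histograms -----------------------------------------------------------


def test_histogram_constant_trace_single_bin():
    h = distance_histogram(_trace([3.0] * 50), bin_width=0.2)
    assert np.count_nonzero(h.counts) == 1
    assert h.counts.sum() == 50


def test_histogram_counts_conserved_and_bimodal_peaks(rng):
    a = rng.normal(3.0, 0.15, 4000)
    b = rng.normal(7.0, 0.15, 4000)
    t = _trace(np.concatenate([a, b]))
    h = distance_histogram(t, bin_width=0.2)
    assert h.counts.sum() == 8000
    assert len(h.peak_positions) == 2
    assert min(abs(h.peak_positions - 3.0)) <= 0.2
    assert min(abs(h.peak_positions - 7.0)) <= 0.2
    with pytest.raises(ValueError):
        distance_histogram(_trace([]), 0.1)


# -- plateau segmentation --------------------------------------------------


def test_constant_trace_is_one_ground_segment():
    segs = detect_plateaus(_trace([3.0] * 100), min_duration=5.0, level_tol=0.5)
    assert len(segs) == 1
    assert segs[0].label == "ground"
    assert segs[0].mean_level == pytest.approx(3.0)


def test_staircase_segmentation(rng):
    levels = [3.0, 7.0, 12.0]
    x = np.concatenate([rng.normal(v, 0.2, 400) for v in levels])
    segs = detect_plateaus(_trace(x), min_duration=20.0, level_tol=1.0)
    assert len(segs) == 3
    assert segs[0].label == "ground" and segs[1].label == "plateau"
    for seg, lvl in zip(segs, levels):
        assert seg.mean_level == pytest.approx(lvl, abs=0.3)
    # segments partition the trace in time order
    for a, b in zip(segs, segs[1:]):
        assert b.start_time > a.end_time


def test_back_motion_staircase_revisits_ground(rng):
    x = np.concatenate([
        rng.normal(3.0, 0.2, 400), rng.normal(7.0, 0.2, 400), rng.normal(3.0, 0.2, 400)
    ])
    segs = detect_plateaus(_trace(x), min_duration=20.0, level_tol=1.0)
    assert len(segs) == 3
    assert abs(segs[-1].mean_level - segs[0].mean_level) < 1.0


# -- switching -------------------------------------------------------------


def test_switching_counting_rules():
    a = _trace([1.0] * 10)
    b = _trace([2.0] * 10)
    n, occ = detect_switching(a, b, engage_cut=3.0)
    assert n == 0 and occ == (1.0, 0.0)

    alt_a = _trace([1.0 if i % 2 == 0 else 2.0 for i in range(10)])
    alt_b = _trace([2.0 if i % 2 == 0 else 1.0 for i in range(10)])
    n, occ = detect_switching(alt_a, alt_b, engage_cut=3.0)
    assert n == 9
    assert occ == (0.5, 0.5)

    far_a, far_b = _trace([9.0] * 10), _trace([8.0] * 10)
    n, occ = detect_switching(far_a, far_b, engage_cut=3.0)
    assert n == 0 and occ == (0.0, 0.0)

    with pytest.raises(ValueError, match="aligned"):
        detect_switching(_trace([1.0]), _trace([1.0, 2.0]), 3.0)


# -- path tracing ----------------------------------------------------------


def test_path_representative_selection_and_tie_break():
    single = _synthetic_run([[[0.0, 0.0, 3.0]]])
    pt = trace_path(single, max_r=10.0)
    assert len(pt) == 1
    assert np.allclose(pt.points[0], [0.0, 0.0, 3.0])

    tie = _synthetic_run([[[0.0, 0.0, 1.0], [0.0, 0.0, 3.0]]])
    pt = trace_path(tie, max_r=10.0)
    # window-center (0,0,2); both frames equidistant -> earliest wins
    assert pt.frame_indices[0] == 0
    assert np.allclose(pt.points[0], [0.0, 0.0, 1.0])


def test_path_window_retention_rule():
    """delta = 0.1 with max_r = 10 retains at most 101 windows (r = 0..10)."""
    frames = [[[0.0, 0.0, 3.0 + 0.1 * i]] for i in range(120)]
    run = _synthetic_run(frames, d_ref=3.0, delta=0.1)
    pt = trace_path(run, max_r=10.0)
    assert len(pt) == 101
    assert pt.targets_r[-1] == pytest.approx(10.0)
    assert np.all(np.diff(pt.targets_r) > 0)


# -- RMSD ------------------------------------------------------------------


def _random_rotation_matrix(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def test_rmsd_superposition_invariances(rng):
    ref = LigandState.rigid_triad([0.0, 0.0, 3.0]).positions
    assert superpose_rmsd(ref, ref) < 1e-12
    moved = (ref + np.array([3.0, -2.0, 1.0])) @ _random_rotation_matrix(rng).T
    assert superpose_rmsd(moved, ref) < 1e-9


def test_rmsd_against_brute_force_rotation_grid(rng):
    """Kabsch must not exceed the best RMSD over a dense random rotation
    sample, and stays within the sqrt(1/n) single-bead displacement bound."""
    ref = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.5, 0], [0, -1.5, 0]])
    d = 0.8
    coords = ref.copy()
    coords[0] += [0.0, 0.0, d]
    impl = superpose_rmsd(coords, ref)
    brute = min(
        superpose_rmsd(coords @ _random_rotation_matrix(rng).T, ref)
        for _ in range(200)
    )  # rotating the input must never beat the optimal superposition
    assert impl <= brute + 1e-9
    assert impl <= d * math.sqrt(1.0 / len(ref)) + 1e-9


def test_rmsd_series_runs_and_checks_bead_count():
    ls = isotropic_well()
    sched = WindowSchedule(d_ref=2.7, n_forward=3, delta=0.1, n_backward=0)
    run = run_walker(ls, sched, IntegratorParams(seed=13), 0,
                     n_steps=400, stride=10, path_stride=2, n_beads=3)
    ref = run.windows[0].start_state
    times, vals = rmsd_series(run, ref)
    assert len(times) == len(vals) > 0
    assert np.all(vals < 0.5)  # rigid ligand: only roundoff + superposition
    with pytest.raises(ValueError, match="bead count"):
        rmsd_series(run, LigandState.single_bead([0, 0, 0]))
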