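"""Mechanistic analyses of CPUS trajectories.

Mirrors the descriptive toolbox used to interpret ligand dissociation runs:
atom-pair distance time series between host pseudo-atom sites and ligand
beads, their histograms with peak lists, step/plateau segmentation of the
traces (ground level vs transient plateaus), H-bond-style acceptor switching
between two competing sites, ligand RMSD after optimal superposition, and
tracing of the curvilinear dissociation path through per-window
representative conformations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .driver import WalkerRun
from .landscape import LigandState


@dataclass
class DistanceTrace:
    """Atom-pair distance time series across the windows of a walker."""

    times: np.ndarray
    distances: np.ndarray
    pair_label: str
    window_index: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        self.window_index = np.asarray(self.window_index)
        if not (len(self.times) == len(self.distances) == len(self.window_index)):
            raise ValueError("trace arrays must have equal length")
        if np.any(self.distances < 0):
            raise ValueError("distances must be >= 0")

    def __len__(self) -> int:
        return len(self.distances)


@dataclass(frozen=True)
class PlateauSegment:
    start_time: float
    end_time: float
    mean_level: float
    label: str  # "ground" or "plateau"


@dataclass
class Histogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    peak_positions: np.ndarray
    peak_indices: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class PathTrace:
    """Representative ligand CoG per retained window, in the host frame."""

    targets_r: np.ndarray          # window target - d_ref, A
    points: np.ndarray             # (n, 3) representative CoG positions
    window_indices: np.ndarray
    frame_indices: np.ndarray      # which recorded frame was representative
    max_r: float

    def __len__(self) -> int:
        return len(self.window_indices)


class MissingFramesError(ValueError):
    pass


def pair_distance_series(
    run: WalkerRun,
    site_a: int,
    site_b: int,
    stride: int = 1,
    landscape=None,
) -> DistanceTrace:
    """Distance between host anchor ``site_a`` and ligand bead ``site_b``
    for every ``stride``-th recorded frame, in window execution order.

    The host anchors are taken from ``landscape`` if given, else from the
    run's metadata-free default: the anchors must be supplied via
    ``landscape``.
    """
    if landscape is None:
        raise ValueError("pass the landscape so host anchor positions are known")
    anchors = landscape.host_anchors
    if not (0 <= site_a < len(anchors)):
        raise ValueError(f"host anchor id {site_a} out of range")
    anchor = anchors[site_a]
    times, dists, widx = [], [], []
    for w in run.windows:
        if w.frames is None or len(w.frames) == 0:
            raise MissingFramesError(
                f"window {w.window_index} has no recorded ligand frames"
            )
        if not (0 <= site_b < w.frames.shape[1]):
            raise ValueError(f"ligand bead id {site_b} out of range")
        sel = w.frames[::stride, site_b, :]
        d = np.linalg.norm(sel - anchor, axis=1)
        times.append(w.frame_times[::stride])
        dists.append(d)
        widx.append(np.full(len(d), w.window_index))
    return DistanceTrace(
        times=np.concatenate(times),
        distances=np.concatenate(dists),
        pair_label=f"anchor{site_a}-bead{site_b}",
        window_index=np.concatenate(widx),
    )


def distance_histogram(
    trace: DistanceTrace,
    bin_width: float,
    prominence_fraction: float = 0.05,
) -> Histogram:
    """Histogram of a distance trace with a peak list.

    Peaks are local maxima of the counts with prominence above
    ``prominence_fraction`` of the tallest bin; counts are conserved.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(trace) == 0:
        raise ValueError("empty trace")
    lo = np.floor(trace.distances.min() / bin_width) * bin_width
    hi = np.ceil(trace.distances.max() / bin_width) * bin_width
    n = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n + 1)
    counts, _ = np.histogram(trace.distances, bins=edges)
    padded = np.concatenate([[0], counts, [0]])  # allow edge-bin peaks
    idx, _ = find_peaks(padded, prominence=max(1.0, prominence_fraction * counts.max()))
    idx = idx - 1
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Histogram(
        bin_edges=edges,
        counts=counts,
        peak_positions=centers[idx],
        peak_indices=idx,
    )


def detect_plateaus(
    trace: DistanceTrace,
    min_duration: float,
    level_tol: float,
) -> List[PlateauSegment]:
    """Greedy running-mean change-point segmentation of a distance trace.

    A new segment opens when a sample departs from the running mean of the
    current one by more than ``level_tol`` (A); segments shorter than
    ``min_duration`` (ps) are merged into the neighbour whose level is
    closer.  The first segment is labelled ``ground``, later ones
    ``plateau``.  Segments partition the trace in time order.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    dt_sample = float(np.min(np.diff(trace.times))) if len(trace) > 1 else 0.0
    if len(trace) > 1 and min_duration < dt_sample:
        raise ValueError("min_duration must be >= the sampling interval")
    x = trace.distances
    t = trace.times
    bounds = [0]
    mean = x[0]
    count = 1
    for i in range(1, len(x)):
        if abs(x[i] - mean) > level_tol:
            bounds.append(i)
            mean = x[i]
            count = 1
        else:
            count += 1
            mean += (x[i] - mean) / count
    bounds.append(len(x))
    segs = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]

    def duration(seg):
        i, j = seg
        return t[j - 1] - t[i] + dt_sample

    # merge short segments into the nearer-level neighbour
    changed = True
    while changed and len(segs) > 1:
        changed = False
        for si, seg in enumerate(segs):
            if duration(seg) < min_duration:
                level = float(np.mean(x[seg[0]:seg[1]]))
                neighbours = []
                if si > 0:
                    prev = segs[si - 1]
                    neighbours.append((abs(level - np.mean(x[prev[0]:prev[1]])), si - 1))
                if si < len(segs) - 1:
                    nxt = segs[si + 1]
                    neighbours.append((abs(level - np.mean(x[nxt[0]:nxt[1]])), si + 1))
                _, target = min(neighbours)
                lo = min(segs[target][0], seg[0])
                hi = max(segs[target][1], seg[1])
                segs[min(si, target)] = (lo, hi)
                del segs[max(si, target)]
                changed = True
                break
    return [
        PlateauSegment(
            start_time=float(t[i]),
            end_time=float(t[j - 1]),
            mean_level=float(np.mean(x[i:j])),
            label="ground" if si == 0 else "plateau",
        )
        for si, (i, j) in enumerate(segs)
    ]


def detect_switching(
    trace_a: DistanceTrace,
    trace_b: DistanceTrace,
    engage_cut: float,
) -> Tuple[int, Tuple[float, float]]:
    """Count alternations of engagement between two competing sites.

    Per frame, the ligand is *engaged* with the nearer of the two sites if
    that distance is below ``engage_cut``, else disengaged.  The switch
    count is the number of changes of the engaged identity (disengaged
    frames do not reset it); occupancies are the fractions of frames engaged
    with each site.
    """
    if len(trace_a) != len(trace_b):
        raise ValueError("traces must be aligned (equal length)")
    a = trace_a.distances
    b = trace_b.distances
    nearer_is_a = a <= b
    engaged = np.minimum(a, b) < engage_cut
    switches = 0
    last = None
    occ_a = occ_b = 0
    for i in range(len(a)):
        if not engaged[i]:
            continue
        cur = bool(nearer_is_a[i])
        if cur:
            occ_a += 1
        else:
            occ_b += 1
        if last is not None and cur != last:
            switches += 1
        last = cur
    n = len(a) if len(a) else 1
    return switches, (occ_a / n, occ_b / n)


def trace_path(run: WalkerRun, max_r: float = 10.0) -> PathTrace:
    """Curvilinear dissociation path from per-window representatives.

    For every window whose target satisfies ``target - d_ref <= max_r``, the
    window-center is the mean of the recorded frame CoGs and the
    representative conformation is the frame whose CoG is nearest to it
    (ties -> earliest frame).  The host is static, so the alignment step of
    the all-atom protocol is the identity here.  Output is ordered by window
    target.
    """
    entries = []
    for w in run.windows:
        if w.restraint is None:
            continue
        r = w.restraint.target - run.d_ref
        if r > max_r + 1e-12:
            continue
        if w.frames is None or len(w.frames) == 0:
            raise MissingFramesError(
                f"window {w.window_index} has no recorded ligand frames"
            )
        cogs = w.frames.mean(axis=1)  # (n_frames, 3)
        center = cogs.mean(axis=0)
        dist2 = np.sum((cogs - center) ** 2, axis=1)
        best = int(np.argmin(dist2))  # argmin returns the earliest minimum
        entries.append((r, w.window_index, best, cogs[best]))
    entries.sort(key=lambda e: e[0])
    return PathTrace(
        targets_r=np.array([e[0] for e in entries]),
        points=np.array([e[3] for e in entries]).reshape(-1, 3),
        window_indices=np.array([e[1] for e in entries]),
        frame_indices=np.array([e[2] for e in entries]),
        max_r=max_r,
    )


def exit_direction_label(path: PathTrace, r_probe: float = None) -> str:
    """Coarse exit label ("+x" / "-x") from the path point at the largest
    retained separation (or the first point with r >= r_probe)."""
    if len(path) == 0:
        raise ValueError("empty path")
    if r_probe is None:
        point = path.points[-1]
    else:
        sel = np.nonzero(path.targets_r >= r_probe)[0]
        point = path.points[sel[0]] if sel.size else path.points[-1]
    return "+x" if point[0] >= 0 else "-x"


def superpose_rmsd(coords: np.ndarray, reference: np.ndarray) -> float:
    """RMSD after optimal rigid superposition (Kabsch, via SVD)."""
    p = coords - coords.mean(axis=0)
    q = reference - reference.mean(axis=0)
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    diff = p @ rot - q
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))


def rmsd_series(
    run: WalkerRun,
    reference: LigandState,
    stride: int = 1,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-frame ligand RMSD to a reference after optimal superposition.

    Returns (times, rmsd).  Raises if bead counts differ.
    """
    ref = reference.positions
    times, vals = [], []
    for w in run.windows:
        if w.frames is None or len(w.frames) == 0:
            raise MissingFramesError(
                f"window {w.window_index} has no recorded ligand frames"
            )
        if w.frames.shape[1] != ref.shape[0]:
            raise ValueError(
                f"bead count mismatch: frames have {w.frames.shape[1]}, "
                f"reference has {ref.shape[0]}"
            )
        for ft, frame in zip(w.frame_times[::stride], w.frames[::stride]):
            times.append(ft)
            vals.append(superpose_rmsd(frame, ref))
    return np.asarray(times), np.asarray(vals)
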