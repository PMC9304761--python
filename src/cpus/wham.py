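"""Weighted histogram analysis method (WHAM) for the umbrella windows.

Standard self-consistent WHAM on the scalar CoG-CoG distance: with per-window
histograms ``n_wj`` over shared bins ``j`` and bias energies
``b_w(D_j) = k_w/2 (D_j - target_w)^2``,

    p_j  =  sum_w n_wj  /  sum_w N_w exp(-beta (b_wj - f_w)),
    exp(-beta f_w)  =  sum_j p_j exp(-beta b_wj),

iterated until the window free-energy shifts ``f_w`` are stationary.  The
unbiased profile is ``A_j = -kBT ln p_j`` anchored per the requested
convention.  Because the histogrammed coordinate is the scalar distance, the
profile intrinsically contains the ``-2 kBT ln D`` distance-distribution
term; it is deliberately not subtracted (the downstream standard-state
correction is formulated on exactly this profile).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple, Union

import numpy as np

from .constants import kbt
from .driver import WalkerRun
from .dynamics import WindowTimeSeries
from .pmf import ANCHOR_MIN_ZERO, PMFProfile, delta_g_pmf  # re-export  # noqa: F401

DEFAULT_BIN_WIDTH_A = 0.05


class EmptyWindowError(ValueError):
    pass


class GapWarning(UserWarning):
    """Adjacent windows have disjoint support; the profile has a hole."""


@dataclass
class BinnedWindows:
    """Per-window histograms on a shared uniform grid.

    ``counts[w, j]`` is the number of samples of window ``w`` in bin ``j``;
    ``bias`` holds one ``(spring_k, target)`` pair per window (absolute
    distance coordinate).
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    bias: List[Tuple[float, float]]
    d_ref: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != len(self.bias):
            raise ValueError("counts must be (n_windows, n_bins) aligned with bias")
        if self.counts.shape[1] != len(self.bin_edges) - 1:
            raise ValueError("counts columns must match bin_edges")
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, widths[0], rtol=1e-9):
            raise ValueError("bin width must be uniform")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def total_counts(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def _iter_windows(run) -> List[WindowTimeSeries]:
    if isinstance(run, WalkerRun):
        return list(run.windows)
    if isinstance(run, WindowTimeSeries):
        return [run]
    out: List[WindowTimeSeries] = []
    for item in run:
        out.extend(_iter_windows(item))
    return out


def bin_windows(
    run: Union[WalkerRun, WindowTimeSeries, Sequence],
    bin_width: float = DEFAULT_BIN_WIDTH_A,
    d_ref: float = None,
) -> BinnedWindows:
    """Histogram the window samples on one shared grid.

    ``run`` may be a single :class:`WalkerRun`, a bare window, or any nested
    sequence of them (e.g. a whole ensemble, pooled).  The grid spans all
    samples with one empty guard bin on each side; total counts are
    conserved.  Windows without a restraint (unbiased pre-runs) get a zero
    spring constant.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    windows = _iter_windows(run)
    if not windows:
        raise EmptyWindowError("no windows to bin")
    for w in windows:
        if len(w) == 0:
            raise EmptyWindowError(f"window {w.window_index} holds no samples")
    if d_ref is None:
        d_ref = run.d_ref if isinstance(run, WalkerRun) else 0.0
    lo = min(float(np.min(w.distances)) for w in windows)
    hi = max(float(np.max(w.distances)) for w in windows)
    first = np.floor(lo / bin_width) - 1  # guard bin below
    n_bins = int(np.ceil(hi / bin_width) - first) + 1  # and above
    edges = (first + np.arange(n_bins + 1)) * bin_width
    counts = np.zeros((len(windows), n_bins), dtype=np.int64)
    bias = []
    for i, w in enumerate(windows):
        c, _ = np.histogram(w.distances, bins=edges)
        counts[i] = c
        if w.restraint is None:
            bias.append((0.0, 0.0))
        else:
            bias.append((w.restraint.spring_k, w.restraint.target))
    return BinnedWindows(bin_edges=edges, counts=counts, bias=bias, d_ref=d_ref)


def wham_solve(
    binned: BinnedWindows,
    temperature: float = 295.0,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    anchor: str = ANCHOR_MIN_ZERO,
) -> PMFProfile:
    """Self-consistent WHAM solution.

    Iterates until the largest change of any window shift ``f_w`` is below
    ``tol`` (kcal/mol).  If ``max_iter`` is reached first the profile is
    still returned with ``converged=False``.  Interior bins with zero counts
    between occupied regions trigger a :class:`GapWarning` naming the gap
    interval; their free energy is ``+inf``.
    """
    kt = kbt(temperature)
    beta = 1.0 / kt
    centers = binned.bin_centers
    counts = binned.counts.astype(float)
    n_w = counts.shape[0]
    N_w = counts.sum(axis=1)
    if np.any(N_w == 0):
        raise EmptyWindowError("window with zero samples")
    m_j = counts.sum(axis=0)
    ks = np.array([b[0] for b in binned.bias])
    tg = np.array([b[1] for b in binned.bias])
    b_wj = 0.5 * ks[:, None] * (centers[None, :] - tg[:, None]) ** 2
    exp_nb = np.exp(-beta * b_wj)  # (W, B)

    f = np.zeros(n_w)
    converged = False
    it = 0
    occupied = m_j > 0
    for it in range(1, max_iter + 1):
        denom = (N_w * np.exp(beta * f)) @ exp_nb  # (B,)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(occupied, m_j / denom, 0.0)
        z = exp_nb @ p  # (W,)
        f_new = -kt * np.log(z)
        f_new -= f_new[0]
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tol:
            converged = True
            break

    denom = (N_w * np.exp(beta * f)) @ exp_nb
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(occupied, m_j / denom, 0.0)
        a = -kt * np.log(p)
    a[~occupied] = np.inf
    finite = np.isfinite(a)
    a = a - np.min(a[finite])

    occ_idx = np.nonzero(occupied)[0]
    biased = ks > 0
    if np.any(biased):
        interior_gaps = occ_idx[np.nonzero(np.diff(occ_idx) > 1)[0]]
        t_lo = float(np.min(tg[biased]))
        t_hi = float(np.max(tg[biased]))
    else:
        # unbiased input: holes are sampling sparsity, not missing windows
        interior_gaps = np.empty(0, dtype=int)
        t_lo = t_hi = 0.0
    for gi in interior_gaps:
        gap_lo = binned.bin_edges[gi + 1]
        nxt = occ_idx[occ_idx > gi][0]
        gap_hi = binned.bin_edges[nxt]
        # holes beyond the biased-target range are sparse-tail artifacts,
        # not missing windows
        if gap_hi < t_lo or gap_lo > t_hi:
            continue
        warnings.warn(
            f"disjoint window support: no samples in [{gap_lo:.3f}, {gap_hi:.3f}] A",
            GapWarning,
        )

    profile = PMFProfile(
        r_centers=centers - binned.d_ref,
        a_values=a,
        counts=binned.total_counts,
        anchor_convention=ANCHOR_MIN_ZERO,
        temperature=temperature,
        d_ref=binned.d_ref,
        converged=converged,
        iterations=it,
        meta={"tol": tol, "window_shifts": f},
    )
    if anchor != ANCHOR_MIN_ZERO:
        profile = profile.reanchored(anchor)
        profile.counts = binned.total_counts
    return profile
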