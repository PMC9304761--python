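"""Orchestration of the curvilinear-path umbrella sampling (CPUS) protocol.

One *walker* is an independent umbrella-sampling sweep: starting from the
equilibrated bound state, windows are sampled sequentially with the last
conformation of each window handed off as the start of the next, so the
dissociation path evolves spontaneously rather than along a predefined
vector.  A backward sweep (restarting from the same equilibrated bound state)
completes the profile below the reference bound distance.  Multiple walkers
differ only in their noise streams and therefore explore different
curvilinear exit paths; their PMF plateaus generally differ, which is why a
lower-bound selection across the ensemble is performed downstream.

Reproducibility: each walker draws from a counter-based Philox stream keyed
by ``(master_seed, walker_id)``, so ensembles are independent of execution
order and bit-reproducible.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .dynamics import (
    InstabilityError,
    IntegratorParams,
    RestraintSpec,
    WindowTimeSeries,
    run_window,
)
from .landscape import Landscape, LigandState

#: Paper-protocol defaults: window spacing and bias spring constant.
DEFAULT_DELTA_A = 0.1
DEFAULT_SPRING_K = 10.0
DEFAULT_N_WALKERS = 15

#: Fraction of each window's steps discarded as within-window equilibration.
#: The handed-off start is centered on the previous target, so the first part
#: of every window relaxes toward the new bias; recording it would skew every
#: forward histogram the same way and the bias accumulates over the sweep.
DEFAULT_EQUIL_FRACTION = 0.1

_EQUILIBRATION_STREAM = 1 << 16  # reserved spawn key for the unbiased pre-run


class InsufficientEquilibrationError(ValueError):
    """Too few unbiased samples to estimate the reference bound distance."""


def walker_rng(master_seed: int, walker_id: int) -> np.random.Generator:
    """Counter-based stream for one walker, independent across walkers."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(walker_id,))
    return np.random.Generator(np.random.Philox(ss))


@dataclass(frozen=True)
class WindowSchedule:
    """Umbrella window schedule.

    Forward targets are ``D_xi = d_ref + delta * (xi - 1)`` for
    ``xi = 1 .. n_forward``; backward targets ``d_ref - delta * j`` for
    ``j = 1 .. n_backward``.
    """

    d_ref: float
    n_forward: int
    delta: float = DEFAULT_DELTA_A
    n_backward: int = 10

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.n_forward < 1:
            raise ValueError("n_forward must be >= 1")
        if self.n_backward < 0:
            raise ValueError("n_backward must be >= 0")
        if self.d_ref - self.delta * self.n_backward <= 0:
            raise ValueError("backward sweep would cross zero separation")

    @property
    def forward_targets(self) -> np.ndarray:
        return self.d_ref + self.delta * np.arange(self.n_forward)

    @property
    def backward_targets(self) -> np.ndarray:
        return self.d_ref - self.delta * np.arange(1, self.n_backward + 1)

    @property
    def targets(self) -> np.ndarray:
        """All targets in execution order (forward sweep, then backward)."""
        return np.concatenate([self.forward_targets, self.backward_targets])

    @property
    def n_windows(self) -> int:
        return self.n_forward + self.n_backward


@dataclass
class WalkerRun:
    """All windows of one walker, in execution order, plus provenance."""

    schedule: WindowSchedule
    windows: List[WindowTimeSeries]
    walker_id: int
    master_seed: int
    spring_k: float
    start_state: Optional[LigandState] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.windows) != self.schedule.n_windows:
            raise ValueError(
                f"expected {self.schedule.n_windows} windows, got {len(self.windows)}"
            )

    @property
    def forward_windows(self) -> List[WindowTimeSeries]:
        return self.windows[: self.schedule.n_forward]

    @property
    def backward_windows(self) -> List[WindowTimeSeries]:
        return self.windows[self.schedule.n_forward:]

    @property
    def d_ref(self) -> float:
        return self.schedule.d_ref

    def mean_vdw_by_window(self):
        """(targets, mean vdW) over the forward sweep, for cutoff detection."""
        targets = self.schedule.forward_targets
        means = np.array([w.mean_vdw for w in self.forward_windows])
        return targets, means

    def digest(self) -> str:
        """SHA-256 over all recorded samples; equal digests imply equal runs."""
        h = hashlib.sha256()
        for w in self.windows:
            h.update(w.distances.tobytes())
            h.update(w.vdw.tobytes())
            h.update(w.elec.tobytes())
            if w.frames is not None:
                h.update(np.ascontiguousarray(w.frames).tobytes())
        return h.hexdigest()


def estimate_dref(unbiased: WindowTimeSeries, min_samples: int = 100) -> float:
    """Reference bound distance: mean CoG-CoG distance of an unbiased run.

    ``min_samples`` guards against under-equilibrated input; pass 0 to
    disable the check (test mode).
    """
    if len(unbiased) < min_samples:
        raise InsufficientEquilibrationError(
            f"only {len(unbiased)} unbiased samples; need >= {min_samples} "
            "to estimate the reference bound distance"
        )
    return unbiased.mean_distance


def make_bound_state(landscape: Landscape, n_beads: int = 1) -> LigandState:
    """Ligand placed at the bound well along +z."""
    cog = np.array([0.0, 0.0, landscape.well_radius])
    if n_beads == 1:
        return LigandState.single_bead(cog)
    if n_beads == 3:
        return LigandState.rigid_triad(cog)
    raise ValueError("supported ligand sizes: 1 or 3 beads")


@dataclass
class PreparedRun:
    schedule: WindowSchedule
    start_state: LigandState
    unbiased: WindowTimeSeries


def prepare_run(
    landscape: Landscape,
    params: IntegratorParams,
    n_forward: int,
    *,
    n_backward: int = 10,
    delta: float = DEFAULT_DELTA_A,
    n_beads: int = 1,
    pre_samples: int = 1000,
    stride: int = 10,
    d_ref: Optional[float] = None,
    equil_fraction: float = DEFAULT_EQUIL_FRACTION,
) -> PreparedRun:
    """Unbiased pre-run: equilibrate the bound complex, estimate ``d_ref``
    and provide the common starting conformation for all walkers.

    ``d_ref`` may be forced (skipping the estimate) for externally chosen
    schedules.
    """
    rng = np.random.Generator(
        np.random.Philox(
            np.random.SeedSequence(entropy=params.seed, spawn_key=(_EQUILIBRATION_STREAM,))
        )
    )
    start = make_bound_state(landscape, n_beads=n_beads)
    n_pre = pre_samples * stride
    unbiased = run_window(
        start, None, landscape, params, n_steps=int(n_pre * (1 + equil_fraction)),
        stride=stride, rng=rng, window_index=-1,
        n_equil=int(n_pre * equil_fraction),
    )
    if d_ref is None:
        d_ref = estimate_dref(unbiased, min_samples=min(100, pre_samples))
    schedule = WindowSchedule(
        d_ref=d_ref, n_forward=n_forward, delta=delta, n_backward=n_backward
    )
    return PreparedRun(schedule=schedule, start_state=unbiased.final_state, unbiased=unbiased)


def run_walker(
    landscape: Landscape,
    schedule: WindowSchedule,
    params: IntegratorParams,
    walker_id: int,
    *,
    spring_k: float = DEFAULT_SPRING_K,
    n_steps: int = 10_000,
    stride: int = 10,
    path_stride: int = 10,
    start_state: Optional[LigandState] = None,
    n_beads: int = 1,
    equil_fraction: float = DEFAULT_EQUIL_FRACTION,
) -> WalkerRun:
    """One sequential CPUS sweep: forward windows with last-frame handoff,
    then the backward sweep restarting from the equilibrated bound state.

    The first ``equil_fraction`` of each window's steps relaxes the
    handed-off conformation to the new target and is excluded from the
    histograms.  Fully reproducible from ``(params.seed, walker_id)``.  An
    instability in any window aborts the walker with the window index in
    the message.
    """
    rng = walker_rng(params.seed, walker_id)
    if start_state is None:
        start_state = make_bound_state(landscape, n_beads=n_beads)
    windows: List[WindowTimeSeries] = []
    window_time = n_steps * params.dt
    n_equil = int(round(equil_fraction * n_steps))

    def _sweep(targets: np.ndarray, first_state: LigandState, idx0: int):
        state = first_state
        for j, tgt in enumerate(targets):
            idx = idx0 + j
            try:
                w = run_window(
                    state,
                    RestraintSpec(spring_k=spring_k, target=float(tgt)),
                    landscape,
                    params,
                    n_steps=n_steps,
                    stride=stride,
                    rng=rng,
                    path_stride=path_stride,
                    t0=idx * window_time,
                    window_index=idx,
                    n_equil=n_equil,
                )
            except InstabilityError as exc:
                raise InstabilityError(
                    f"walker {walker_id}, window {idx} "
                    f"(target {tgt:.3f} A): {exc}"
                ) from exc
            windows.append(w)
            state = w.final_state

    _sweep(schedule.forward_targets, start_state, 0)
    _sweep(schedule.backward_targets, start_state, schedule.n_forward)
    return WalkerRun(
        schedule=schedule,
        windows=windows,
        walker_id=walker_id,
        master_seed=params.seed,
        spring_k=spring_k,
        start_state=start_state.copy(),
        meta={"n_steps": n_steps, "stride": stride, "path_stride": path_stride},
    )


def run_ensemble(
    landscape: Landscape,
    schedule: WindowSchedule,
    params: IntegratorParams,
    n_walkers: int = DEFAULT_N_WALKERS,
    **walker_kwargs,
) -> List[WalkerRun]:
    """Independent walkers 0 .. n_walkers-1 on distinct Philox streams.

    Walkers that fail (integration instability) are skipped with a warning
    summary; the surviving runs are returned ordered by walker_id.
    """
    if n_walkers < 1:
        raise ValueError("n_walkers must be >= 1")
    runs: List[WalkerRun] = []
    failures = []
    for wid in range(n_walkers):
        try:
            runs.append(run_walker(landscape, schedule, params, wid, **walker_kwargs))
        except InstabilityError as exc:
            failures.append((wid, str(exc)))
    if failures:
        summary = "; ".join(f"walker {wid}: {msg}" for wid, msg in failures)
        warnings.warn(f"{len(failures)} walker(s) failed: {summary}")
    return runs


def audit_handoff(run: WalkerRun) -> bool:
    """True iff every window within each sweep starts bitwise-identically at
    the previous window's final state (the sequential-enhancement contract)."""
    nf = run.schedule.n_forward
    for seq in (run.windows[:nf], run.windows[nf:]):
        for prev, cur in zip(seq, seq[1:]):
            if not np.array_equal(prev.final_state.positions, cur.start_state.positions):
                return False
    return True
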