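"""Overdamped Brownian dynamics of the ligand under a harmonic distance bias.

The single-step primitive :func:`step` is the Euler-Maruyama discretization
of the overdamped Langevin equation for the ligand CoG,

    x(t+dt) = x(t) + F/gamma * dt + sqrt(2 kBT dt / gamma) * xi,

with ``F = -grad(U_landscape + U_bias)`` and ``xi`` standard normal per
coordinate.  Free-energy estimates depend only on the stationary
distribution, so inertial dynamics would add nothing here.

The production window loop (:func:`run_window`) uses the Leimkuhler-Matthews
variant of the same update, which replaces ``xi_n`` by the average of two
consecutive noises, ``(xi_n + xi_{n+1}) / 2``.  The scheme costs nothing,
has the same drift and long-time diffusion, and samples the configurational
Boltzmann distribution with O(dt^2) accuracy (exactly, for a harmonic
potential) where Euler-Maruyama inflates the stationary variance by a
relative ``k_eff dt / (2 gamma)``.  That accuracy is what allows the default
``dt = 0.01 ps`` to be used for quantitative free-energy work (see
docs/methods.md for the error budget).

Multi-bead ligands translate via the CoG force and undergo free rotational
Brownian diffusion (variance ``2 kBT dt / rot_friction`` per axis); inside
:func:`run_window` orientational updates are applied at the recording stride,
which leaves the distance statistics untouched and keeps the inner loop cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constants import kbt
from .landscape import Landscape, LigandState, scalar_energy_force

#: A displacement beyond this, in one step, aborts the integration.
MAX_STEP_DISPLACEMENT_A = 5.0


class InstabilityError(RuntimeError):
    """Single-step displacement exceeded the stability limit."""


@dataclass(frozen=True)
class RestraintSpec:
    """Harmonic umbrella bias  U = 1/2 * spring_k * (D - target)^2  on the
    CoG-CoG distance D."""

    spring_k: float
    target: float

    def __post_init__(self):
        if self.spring_k <= 0:
            raise ValueError("spring_k must be positive")

    def energy(self, distance: float) -> float:
        return 0.5 * self.spring_k * (distance - self.target) ** 2


@dataclass(frozen=True)
class IntegratorParams:
    """Euler-Maruyama parameters.

    dt : ps;  friction : drag coefficient (kcal/mol * ps / A^2, numerically
    the collision frequency in 1/ps under the unit-mass convention);
    temperature : K;  seed : master seed (same seed => bit-identical
    trajectory);  rot_friction : rotational drag for multi-bead ligands.
    """

    dt: float = 0.01
    friction: float = 1.0
    temperature: float = 295.0
    seed: int = 0
    rot_friction: float = 5.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.friction <= 0 or self.rot_friction <= 0:
            raise ValueError("friction must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")


@dataclass
class WindowTimeSeries:
    """Samples recorded in one umbrella window (or one unbiased run).

    ``times``/``distances`` are the biased coordinate samples; ``vdw`` and
    ``elec`` the landscape components at the recorded CoG; ``frames`` holds
    ligand bead positions every ``path_stride`` recorded samples.
    """

    times: np.ndarray
    distances: np.ndarray
    vdw: np.ndarray
    elec: np.ndarray
    restraint: Optional[RestraintSpec] = None
    start_state: Optional[LigandState] = None
    final_state: Optional[LigandState] = None
    frames: Optional[np.ndarray] = None
    frame_times: Optional[np.ndarray] = None
    window_index: int = -1
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        self.vdw = np.asarray(self.vdw, dtype=float)
        self.elec = np.asarray(self.elec, dtype=float)
        if not (len(self.times) == len(self.distances)):
            raise ValueError("times and distances must have equal length")

    def __len__(self) -> int:
        return len(self.distances)

    @property
    def mean_distance(self) -> float:
        return float(np.mean(self.distances))

    @property
    def mean_vdw(self) -> float:
        return float(np.mean(self.vdw))

    @property
    def mean_elec(self) -> float:
        return float(np.mean(self.elec))


def _random_rotation(rng: np.random.Generator, sigma: float) -> np.ndarray:
    """Small random rotation matrix with per-axis angle std ``sigma``."""
    w = rng.standard_normal(3) * sigma
    angle = float(np.linalg.norm(w))
    if angle < 1e-15:
        return np.eye(3)
    ax, ay, az = w / angle
    c, s = math.cos(angle), math.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + ax * ax * C, ax * ay * C - az * s, ax * az * C + ay * s],
            [ay * ax * C + az * s, c + ay * ay * C, ay * az * C - ax * s],
            [az * ax * C - ay * s, az * ay * C + ax * s, c + az * az * C],
        ]
    )


def step(
    state: LigandState,
    landscape: Landscape,
    restraint: Optional[RestraintSpec],
    params: IntegratorParams,
    rng: np.random.Generator,
) -> LigandState:
    """One Euler-Maruyama step; returns a new state.

    Deterministic given the generator state.  Raises
    :class:`InstabilityError` if the displacement exceeds
    ``MAX_STEP_DISPLACEMENT_A``.
    """
    x, y, z = (float(v) for v in state.cog)
    _, _, fx, fy, fz = scalar_energy_force(landscape, x, y, z)
    if restraint is not None:
        d = math.sqrt(x * x + y * y + z * z)
        if d > 1e-12:
            fb = -restraint.spring_k * (d - restraint.target) / d
            fx += fb * x
            fy += fb * y
            fz += fb * z
    mob = params.dt / params.friction
    sig = math.sqrt(2.0 * kbt(params.temperature) * params.dt / params.friction) \
        if params.temperature > 0 else 0.0
    nx, ny, nz = (rng.standard_normal(3) * sig) if sig > 0 else (0.0, 0.0, 0.0)
    dx = fx * mob + nx
    dy = fy * mob + ny
    dz = fz * mob + nz
    disp = math.sqrt(dx * dx + dy * dy + dz * dz)
    if disp > MAX_STEP_DISPLACEMENT_A:
        raise InstabilityError(
            f"displacement {disp:.2f} A in one step exceeds "
            f"{MAX_STEP_DISPLACEMENT_A} A; reduce dt (currently dt={params.dt} ps)"
        )
    shift = np.array([dx, dy, dz])
    new_pos = state.positions + shift
    if state.n_beads > 1 and params.temperature > 0:
        sig_rot = math.sqrt(
            2.0 * kbt(params.temperature) * params.dt / params.rot_friction
        )
        R = _random_rotation(rng, sig_rot)
        cog = new_pos.mean(axis=0)
        new_pos = cog + (new_pos - cog) @ R.T
    return LigandState(new_pos)


def _propagate(
    ls: Landscape,
    x: float,
    y: float,
    z: float,
    spring_k: float,
    target: float,
    params: IntegratorParams,
    n_steps: int,
    stride: int,
    rng: np.random.Generator,
    n_equil: int = 0,
):
    """Inner translation loop (Leimkuhler-Matthews).  Returns recorded
    arrays and the final CoG.

    The first ``n_equil`` steps are propagated but not recorded (relaxation
    from the handed-off start).  Plain-float arithmetic; the per-step noise
    is drawn in one block so the stream consumption is reproducible
    regardless of recording options.
    """
    mob = params.dt / params.friction
    kt = kbt(params.temperature)
    sig = math.sqrt(2.0 * kt * params.dt / params.friction) if params.temperature > 0 else 0.0
    # Leimkuhler-Matthews: step i adds sig * (xi_i + xi_{i+1}) / 2
    noise = (
        (rng.standard_normal(3 * (n_steps + 1)) * (0.5 * sig)).tolist()
        if sig > 0
        else [0.0] * (3 * (n_steps + 1))
    )
    n_rec = (n_steps - n_equil) // stride
    dist = np.empty(n_rec)
    vdw_r = np.empty(n_rec)
    elec_r = np.empty(n_rec)
    cogs = np.empty((n_rec, 3))
    rec = 0
    max_disp2 = MAX_STEP_DISPLACEMENT_A * MAX_STEP_DISPLACEMENT_A
    sef = scalar_energy_force
    for i in range(n_steps):
        vdw, elec, fx, fy, fz = sef(ls, x, y, z)
        d2 = x * x + y * y + z * z
        d = math.sqrt(d2) if d2 > 1e-24 else 1e-12
        if spring_k != 0.0:
            fb = -spring_k * (d - target) / d
            fx += fb * x
            fy += fb * y
            fz += fb * z
        j = 3 * i
        dx = fx * mob + noise[j] + noise[j + 3]
        dy = fy * mob + noise[j + 1] + noise[j + 4]
        dz = fz * mob + noise[j + 2] + noise[j + 5]
        if dx * dx + dy * dy + dz * dz > max_disp2:
            raise InstabilityError(
                f"displacement exceeds {MAX_STEP_DISPLACEMENT_A} A at step {i}; "
                f"reduce dt (currently dt={params.dt} ps)"
            )
        x += dx
        y += dy
        z += dz
        if i + 1 > n_equil and (i + 1 - n_equil) % stride == 0:
            vdw, elec, _, _, _ = sef(ls, x, y, z)
            dist[rec] = math.sqrt(x * x + y * y + z * z)
            vdw_r[rec] = vdw
            elec_r[rec] = elec
            cogs[rec, 0] = x
            cogs[rec, 1] = y
            cogs[rec, 2] = z
            rec += 1
    return dist, vdw_r, elec_r, cogs, (x, y, z)


def run_window(
    start: LigandState,
    restraint: Optional[RestraintSpec],
    landscape: Landscape,
    params: IntegratorParams,
    n_steps: int,
    stride: int = 10,
    *,
    rng: Optional[np.random.Generator] = None,
    path_stride: int = 10,
    t0: float = 0.0,
    window_index: int = -1,
    n_equil: int = 0,
) -> WindowTimeSeries:
    """Sample one umbrella window, recording (time, D) every ``stride`` steps.

    The first ``n_equil`` steps relax the handed-off start toward the new
    bias target and are not recorded.  Energy components (vdw, elec) are
    recorded with every sample and ligand bead positions every
    ``path_stride`` recorded samples.  ``restraint=None`` runs unbiased
    dynamics.  The final state is stored for the sequential last-frame
    handoff to the next window.
    """
    if stride <= 0 or n_steps - n_equil < stride:
        raise ValueError("need n_steps - n_equil >= stride >= 1")
    if n_equil < 0:
        raise ValueError("n_equil must be >= 0")
    if rng is None:
        rng = np.random.Generator(np.random.Philox(params.seed))
    x0, y0, z0 = (float(v) for v in start.cog)
    k = restraint.spring_k if restraint is not None else 0.0
    tgt = restraint.target if restraint is not None else 0.0
    dist, vdw, elec, cogs, (x, y, z) = _propagate(
        landscape, x0, y0, z0, k, tgt, params, n_steps, stride, rng, n_equil
    )
    times = t0 + params.dt * (n_equil + stride * (1.0 + np.arange(len(dist))))
    body = start.positions - start.cog
    n_rec = len(dist)
    frame_idx = np.arange(path_stride - 1, n_rec, path_stride)
    if start.n_beads > 1:
        # orientational diffusion applied at the recording stride
        sig_rot = (
            math.sqrt(2.0 * kbt(params.temperature) * params.dt * stride / params.rot_friction)
            if params.temperature > 0
            else 0.0
        )
        frames = np.empty((len(frame_idx), start.n_beads, 3))
        fi = 0
        R = np.eye(3)
        for r in range(n_rec):
            if sig_rot > 0:
                R = _random_rotation(rng, sig_rot) @ R
            if fi < len(frame_idx) and r == frame_idx[fi]:
                frames[fi] = cogs[r] + body @ R.T
                fi += 1
        final_state = LigandState(np.array([x, y, z]) + body @ R.T)
    else:
        frames = cogs[frame_idx][:, None, :]
        final_state = LigandState.single_bead([x, y, z])
    return WindowTimeSeries(
        times=times,
        distances=dist,
        vdw=vdw,
        elec=elec,
        restraint=restraint,
        start_state=start.copy(),
        final_state=final_state,
        frames=frames,
        frame_times=times[frame_idx],
        window_index=window_index,
        meta={"n_steps": n_steps, "stride": stride, "path_stride": path_stride,
              "t0": t0, "n_equil": n_equil},
    )
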