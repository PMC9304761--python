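"""Standard binding free energy from a PMF profile.

The profile plateau gives the uncorrected estimate ``dG_PMF`` (minus the
plateau height).  It is referred to the 1 M standard state through

    dG0_bind = dG_PMF - kBT ln[ (4 pi r_cut^2 / V0) * Int_bound e^{-beta A(r)} dr ]

with ``V0 = 1663 A^3`` the volume per molecule at 1 M and ``r_cut`` the
separation (r = D - d_ref coordinate) at which the vdW-like host-guest
interaction component first vanishes and stays vanished -- the operational
definition of "the molecules no longer feel each other".  The bound integral
runs over the basin of the profile anchored to zero at its bound minimum.

Every intermediate (integral, prefactor, correction) is retained on the
result so the identity above is re-computable from the stored pieces.

Also here: the variational lower-bound selection across walkers (the smallest
plateau work is the least-dissipation, best estimate), dG <-> Kd conversion
at the 1 M reference state, and van't Hoff temperature transfer of measured
binding free energies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .constants import KB_KCAL_MOL_K, V0_A3, kbt
from .pmf import ANCHOR_BOUND_REF_ZERO, PMFProfile, UnvisitedBinError, delta_g_pmf

DEFAULT_CUTOFF_THRESHOLD = 0.05  # kcal/mol
DEFAULT_CUTOFF_PERSISTENCE = 5   # windows


class NoCutoffError(ValueError):
    """The vdW component never cancelled within the sampled schedule."""


@dataclass(frozen=True)
class CutoffResult:
    """First persistent cancellation of the vdW interaction component."""

    r_cut: float
    window_index: int
    mean_vdw_at_cut: float
    persistence_used: int


@dataclass
class BindingFreeEnergyResult:
    """dG0_bind with every intermediate of the standard-state correction."""

    dg_pmf: float
    bound_integral: float
    correction: float
    dg_bind0: float
    standard_volume: float
    temperature: float
    r_cut: float
    d_final: float
    bound_region: Tuple[float, float]
    walker_id: int = -1
    meta: dict = field(default_factory=dict)

    def audit_identity(self) -> float:
        """Residual of dg_bind0 = dg_pmf - kBT ln[(4 pi r_cut^2 / V0) I];
        zero (to roundoff) for any result produced by this module."""
        kt = KB_KCAL_MOL_K * self.temperature
        rhs = self.dg_pmf - kt * math.log(
            4.0 * math.pi * self.r_cut ** 2 * self.bound_integral / self.standard_volume
        )
        return self.dg_bind0 - rhs


def detect_cutoff(
    energies: Sequence[float],
    targets: Sequence[float],
    threshold: float = DEFAULT_CUTOFF_THRESHOLD,
    persistence: int = DEFAULT_CUTOFF_PERSISTENCE,
    d_ref: float = 0.0,
) -> CutoffResult:
    """First window where |mean vdW| <= threshold and stays there.

    ``energies`` are per-window mean vdW components aligned with the window
    ``targets`` (absolute distances; pass ``d_ref`` so that
    ``r_cut = target - d_ref``, or targets already in the r coordinate with
    ``d_ref = 0``).  The cancellation must persist for ``persistence``
    consecutive windows (or to the end of the series if fewer remain): a
    single noisy zero crossing does not count.
    """
    e = np.asarray(energies, dtype=float)
    t = np.asarray(targets, dtype=float)
    if e.shape != t.shape or e.ndim != 1 or e.size == 0:
        raise ValueError("energies and targets must be equal-length 1-D series")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    ok = np.abs(e) <= threshold
    n = len(ok)
    for i in range(n):
        span = min(persistence, n - i)
        if np.all(ok[i:i + span]):
            return CutoffResult(
                r_cut=float(t[i] - d_ref),
                window_index=i,
                mean_vdw_at_cut=float(e[i]),
                persistence_used=span,
            )
    raise NoCutoffError(
        f"|mean vdW| never stayed <= {threshold} kcal/mol for {persistence} "
        "windows; extend the schedule until the vdW component converges to zero"
    )


def default_bound_region(profile: PMFProfile) -> Tuple[float, float]:
    """Basin of the profile: from the first visited bin to the first bin
    (outward of the minimum) where A rises to within kBT of the plateau.

    The plateau is the profile value at ``profile.d_final`` (or the last
    visited bin).  The integrand e^{-beta A} is negligible beyond this edge,
    so the integral is insensitive to the precise choice.
    """
    visited = profile.visited
    vis = np.nonzero(visited)[0]
    if vis.size == 0:
        raise ValueError("profile has no visited bins")
    a = profile.a_values
    r = profile.r_centers
    i_min = vis[np.argmin(a[vis])]
    d_final = profile.d_final if profile.d_final is not None else float(r[vis[-1]])
    plateau = profile.value_at(d_final)
    kt = kbt(profile.temperature)
    # inner edge: walk down from the minimum through the contiguous visited
    # block (sparse holes against the repulsive wall stay outside the region)
    lo = i_min
    while lo > 0 and visited[lo - 1]:
        lo -= 1
    edge = vis[-1]
    for i in vis[vis >= i_min]:
        if a[i] >= plateau - kt:
            edge = i
            break
    return float(r[lo]), float(r[edge])


def bound_integral(
    profile: PMFProfile,
    bound_region: Tuple[float, float],
    temperature: Optional[float] = None,
) -> float:
    """Trapezoidal quadrature of e^{-beta A(r)} over the bound region, in A.

    The profile is re-anchored so the basin minimum is zero before
    integrating.  Bins inside the region that were never visited make the
    integral undefined and raise :class:`UnvisitedBinError`.
    """
    r_lo, r_hi = bound_region
    if r_hi <= r_lo:
        raise ValueError("bound region must have r_hi > r_lo")
    if temperature is None:
        temperature = profile.temperature
    prof = profile.reanchored(ANCHOR_BOUND_REF_ZERO)
    r = prof.r_centers
    sel = (r >= r_lo - 1e-12) & (r <= r_hi + 1e-12)
    if np.count_nonzero(sel) < 2:
        raise ValueError("bound region must cover at least two bins")
    bad = sel & ~prof.visited
    if np.any(bad):
        raise UnvisitedBinError(
            f"bound region contains unvisited bins at r = {r[bad].round(4).tolist()} A"
        )
    beta = 1.0 / kbt(temperature)
    return float(np.trapezoid(np.exp(-beta * prof.a_values[sel]), r[sel]))


def standard_correction(
    profile: PMFProfile,
    cutoff: CutoffResult,
    temperature: Optional[float] = None,
    standard_volume: float = V0_A3,
    bound_region: Optional[Tuple[float, float]] = None,
    d_final: Optional[float] = None,
    walker_id: int = -1,
) -> BindingFreeEnergyResult:
    """Apply the standard-state correction to a PMF profile.

    ``d_final`` defaults to ``profile.d_final`` or the last visited bin;
    ``bound_region`` defaults to :func:`default_bound_region`.
    """
    if temperature is None:
        temperature = profile.temperature
    if cutoff.r_cut <= 0:
        raise ValueError("r_cut must be positive for the standard-state prefactor")
    if d_final is None:
        d_final = profile.d_final
    if d_final is None:
        vis = np.nonzero(profile.visited)[0]
        d_final = float(profile.r_centers[vis[-1]])
    prof = profile.reanchored(ANCHOR_BOUND_REF_ZERO)
    prof.d_final = d_final
    if bound_region is None:
        bound_region = default_bound_region(prof)
    dg_pmf = delta_g_pmf(prof, d_final)
    integral = bound_integral(prof, bound_region, temperature)
    if integral <= 0:
        raise ValueError("bound integral must be positive")
    kt = kbt(temperature)
    log_arg = 4.0 * math.pi * cutoff.r_cut ** 2 * integral / standard_volume
    correction = -kt * math.log(log_arg)
    return BindingFreeEnergyResult(
        dg_pmf=dg_pmf,
        bound_integral=integral,
        correction=correction,
        dg_bind0=dg_pmf + correction,
        standard_volume=standard_volume,
        temperature=temperature,
        r_cut=cutoff.r_cut,
        d_final=d_final,
        bound_region=bound_region,
        walker_id=walker_id,
        meta={
            "prefactor": 4.0 * math.pi * cutoff.r_cut ** 2 / standard_volume,
            "log_argument": log_arg,
            "cutoff_window_index": cutoff.window_index,
        },
    )


def select_lower_bound(
    results: Sequence[BindingFreeEnergyResult],
) -> Tuple[int, BindingFreeEnergyResult]:
    """Variational selection: the walker whose plateau work is smallest.

    Every umbrella profile overestimates the reversible work by its excess
    dissipation, so the smallest plateau magnitude |dG_PMF| is the best
    (lower-bound) estimate.  Ties break to the lowest list index.
    """
    if len(results) == 0:
        raise ValueError("no results to select from")
    idx = 0
    best = abs(results[0].dg_pmf)
    for i, res in enumerate(results[1:], start=1):
        work = abs(res.dg_pmf)
        if work < best - 1e-15:
            idx, best = i, work
    return idx, results[idx]


def dg_to_k(dg: float, temperature: float) -> float:
    """Dissociation constant (M, 1 M standard state) from a binding dG."""
    return math.exp(dg / kbt(temperature))


def k_to_dg(k: float, temperature: float) -> float:
    """Binding dG (kcal/mol) from a dissociation constant in M."""
    if k <= 0:
        raise ValueError("dissociation constant must be positive")
    return kbt(temperature) * math.log(k)


def vant_hoff_extrapolate(dg_t1: float, dh: float, t1: float, t2: float) -> float:
    """Transfer dG(T1) to T2 assuming temperature-independent dH and dS:
    dG(T2) = dH - T2 (dH - dG(T1)) / T1."""
    if t1 <= 0 or t2 <= 0:
        raise ValueError("temperatures must be positive")
    return dh - t2 * (dh - dg_t1) / t1


@dataclass(frozen=True)
class ExperimentRecord:
    """A measured binding affinity, transferable between temperatures.

    ``dg_exp`` (kcal/mol) and ``k_exp`` (M) refer to ``t_measured``;
    ``dh`` is the user-supplied van't Hoff binding enthalpy.
    """

    dg_exp: Optional[float] = None
    k_exp: Optional[float] = None
    dh: Optional[float] = None
    t_measured: float = 288.15
    t_target: float = 295.0

    def __post_init__(self):
        if self.dg_exp is None and self.k_exp is None:
            raise ValueError("need at least one of dg_exp, k_exp")
        if self.dg_exp is not None and self.k_exp is not None:
            implied = k_to_dg(self.k_exp, self.t_measured)
            if abs(implied - self.dg_exp) > 0.05:
                raise ValueError(
                    f"dg_exp={self.dg_exp} and k_exp={self.k_exp} disagree "
                    f"({implied:.3f} implied) beyond rounding"
                )

    def dg_at_target(self) -> float:
        dg = self.dg_exp if self.dg_exp is not None else k_to_dg(self.k_exp, self.t_measured)
        if self.t_target == self.t_measured:
            return dg
        if self.dh is None:
            raise ValueError("temperature transfer requires the binding enthalpy dh")
        return vant_hoff_extrapolate(dg, self.dh, self.t_measured, self.t_target)
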