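"""Potential-of-mean-force profiles along the host-guest separation coordinate.

A :class:`PMFProfile` holds the free-energy curve ``A(r)`` on a uniform grid of
the separation coordinate ``r = D - d_ref`` (``D`` is the CoG-CoG distance and
``d_ref`` the reference bound distance).  Profiles are produced either by WHAM
de-biasing of umbrella windows (:mod:`cpus.wham`) or by angular quadrature on a
synthetic landscape (:mod:`cpus.landscape`).

Sign convention
---------------
Profiles are stored *rising* out of the bound basin: the anchored values obey
``min A = 0`` (``min_zero``) or ``A = 0`` at the basin minimum inside a stated
bound region (``bound_ref_zero``; identical for single-basin profiles).  The
binding free-energy estimate ``dG_PMF`` is reported *negated* -- minus the
profile value at the final separation -- so that a deep well yields a negative
number, the direction of the association reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .constants import kbt

ANCHOR_MIN_ZERO = "min_zero"
ANCHOR_BOUND_REF_ZERO = "bound_ref_zero"
_ANCHORS = (ANCHOR_MIN_ZERO, ANCHOR_BOUND_REF_ZERO)


class UnvisitedBinError(ValueError):
    """A requested separation falls in a bin with no recorded samples."""


@dataclass
class PMFProfile:
    """Free-energy profile A(r) on a uniform separation grid.

    Attributes
    ----------
    r_centers : ndarray
        Bin centers of the separation coordinate r = D - d_ref, in A,
        strictly increasing and uniformly spaced.
    a_values : ndarray
        Free energy per bin, kcal/mol, anchored per ``anchor_convention``.
        Bins never visited by any window hold ``+inf``.
    counts : ndarray or None
        Total samples per bin pooled over windows (None for analytic
        profiles, which are treated as fully visited).
    anchor_convention : str
        ``"min_zero"`` or ``"bound_ref_zero"``.
    temperature : float
        Temperature the profile refers to, K.
    d_ref : float
        Reference bound distance used for the r = D - d_ref shift, A.
    d_final : float or None
        Separation at which dG_PMF was evaluated (r coordinate), A.
    dg_pmf : float or None
        Binding-direction PMF value, kcal/mol (negative for a bound well).
    converged : bool
        WHAM self-consistency reached the requested tolerance.
    iterations : int
        WHAM iterations performed (0 for analytic profiles).
    """

    r_centers: np.ndarray
    a_values: np.ndarray
    counts: Optional[np.ndarray] = None
    anchor_convention: str = ANCHOR_MIN_ZERO
    temperature: float = 295.0
    d_ref: float = 0.0
    d_final: Optional[float] = None
    dg_pmf: Optional[float] = None
    converged: bool = True
    iterations: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r_centers = np.asarray(self.r_centers, dtype=float)
        self.a_values = np.asarray(self.a_values, dtype=float)
        if self.r_centers.ndim != 1 or self.r_centers.size < 2:
            raise ValueError("r_centers must be a 1-D grid with >= 2 points")
        if self.r_centers.shape != self.a_values.shape:
            raise ValueError("r_centers and a_values must have equal length")
        dr = np.diff(self.r_centers)
        if np.any(dr <= 0):
            raise ValueError("r_centers must be strictly increasing")
        if self.anchor_convention not in _ANCHORS:
            raise ValueError(f"unknown anchor convention {self.anchor_convention!r}")
        if self.counts is not None:
            self.counts = np.asarray(self.counts)

    @property
    def bin_width(self) -> float:
        return float(self.r_centers[1] - self.r_centers[0])

    @property
    def visited(self) -> np.ndarray:
        """Boolean mask of bins supported by data."""
        if self.counts is None:
            return np.isfinite(self.a_values)
        return self.counts > 0

    def index_of(self, r: float) -> int:
        """Index of the bin whose center is nearest to ``r``.

        Raises
        ------
        UnvisitedBinError
            If ``r`` lies outside the grid or in an unvisited bin.
        """
        lo = self.r_centers[0] - 0.5 * self.bin_width
        hi = self.r_centers[-1] + 0.5 * self.bin_width
        if not (lo <= r <= hi):
            raise UnvisitedBinError(
                f"r = {r:g} A outside profile range [{lo:g}, {hi:g}] A; "
                "refusing to extrapolate"
            )
        i = int(np.argmin(np.abs(self.r_centers - r)))
        if not self.visited[i]:
            raise UnvisitedBinError(f"bin at r = {self.r_centers[i]:g} A was never sampled")
        return i

    def value_at(self, r: float) -> float:
        return float(self.a_values[self.index_of(r)])

    def reanchored(self, convention: str) -> "PMFProfile":
        """Copy of the profile shifted to the requested anchor convention.

        Both conventions zero the minimum over visited bins (profiles here
        have a single bound basin), so re-anchoring changes ``a_values`` by
        a constant only.
        """
        if convention not in _ANCHORS:
            raise ValueError(f"unknown anchor convention {convention!r}")
        vis = self.visited
        if not np.any(vis):
            raise ValueError("profile has no visited bins")
        shift = float(np.min(self.a_values[vis]))
        return replace(
            self,
            a_values=self.a_values - shift,
            anchor_convention=convention,
            counts=None if self.counts is None else self.counts.copy(),
        )


def delta_g_pmf(profile: PMFProfile, d_final: float) -> float:
    """Binding-direction PMF value at the final separation.

    Returns minus the height of the profile at ``d_final`` (r coordinate)
    above the bound anchor, i.e. ``-(A(d_final) - min A)``.  A profile rising
    to a plateau of height 11.09 kcal/mol therefore reports -11.09.

    Raises :class:`UnvisitedBinError` if ``d_final`` falls outside the
    sampled support.
    """
    vis = profile.visited
    a_min = float(np.min(profile.a_values[vis]))
    return -(profile.value_at(d_final) - a_min)


def write_pmf_tsv(profile: PMFProfile, path) -> None:
    """Write the profile as a two-column TSV with a '#' header."""
    with open(path, "w") as fh:
        fh.write(f"# anchor_convention={profile.anchor_convention}\n")
        fh.write(f"# temperature_K={float(profile.temperature)!r}\n")
        fh.write(f"# d_ref_A={float(profile.d_ref)!r}\n")
        fh.write(f"# converged={profile.converged} iterations={profile.iterations}\n")
        fh.write("# r_A\tpmf_kcal_mol\tcounts\n")
        counts = profile.counts
        for i, (r, a) in enumerate(zip(profile.r_centers, profile.a_values)):
            c = int(counts[i]) if counts is not None else -1
            fh.write(f"{float(r)!r}\t{float(a)!r}\t{c}\n")


def read_pmf_tsv(path) -> PMFProfile:
    """Read a profile written by :func:`write_pmf_tsv`."""
    header: dict = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        header[k] = v
                continue
            parts = line.split("\t")
            rows.append((float(parts[0]), float(parts[1]), int(parts[2])))
    if not rows:
        raise ValueError(f"no data rows in {path}")
    r = np.array([row[0] for row in rows])
    a = np.array([row[1] for row in rows])
    c = np.array([row[2] for row in rows])
    counts = None if np.all(c < 0) else np.where(c < 0, 0, c)
    return PMFProfile(
        r_centers=r,
        a_values=a,
        counts=counts,
        anchor_convention=header.get("anchor_convention", ANCHOR_MIN_ZERO),
        temperature=float(header.get("temperature_K", 295.0)),
        d_ref=float(header.get("d_ref_A", 0.0)),
        converged=header.get("converged", "True") == "True",
        iterations=int(header.get("iterations", 0)),
    )


def boltzmann_inversion(r_centers, probabilities, temperature: float) -> np.ndarray:
    """-kBT ln p with the minimum anchored to zero; p = 0 maps to +inf."""
    p = np.asarray(probabilities, dtype=float)
    kt = kbt(temperature)
    with np.errstate(divide="ignore"):
        a = -kt * np.log(p)
    finite = np.isfinite(a)
    if not np.any(finite):
        raise ValueError("all probabilities are zero")
    return a - np.min(a[finite])
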