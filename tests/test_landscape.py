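"""Synthetic host-guest landscapes and their quadrature oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpus.constants import KB_KCAL_MOL_K
from cpus.landscape import (
    Channel,
    Landscape,
    LigandState,
    analytic_binding_dG,
    analytic_pmf,
    isotropic_well,
    landscape_energy,
    scalar_energy_force,
    two_channel_landscape,
)

KT295 = KB_KCAL_MOL_K * 295.0


class _SquareWell:
    """Isotropic piecewise reference potential: -depth inside radius, 0 outside."""

    is_isotropic = True

    def __init__(self, depth, radius):
        self.depth = depth
        self.radius = radius

    def components(self, points):
        X = np.asarray(points, dtype=float)
        D = np.linalg.norm(X, axis=-1)
        u = np.where(D <= self.radius, -self.depth, 0.0)
        return u, np.zeros_like(u), u


coords = st.floats(min_value=-30.0, max_value=30.0, allow_nan=False)


@settings(max_examples=100, derandomize=True)
@given(x=coords, y=coords, z=st.floats(min_value=0.5, max_value=30.0))
def test_energy_decomposition_is_exact(x, y, z):
    """total = vdw + elec to machine precision, at arbitrary CoG positions."""
    ls = Landscape(channels=(Channel((0, 0, 1), 0.4, 1.0),))
    total, vdw, elec = ls.components(np.array([x, y, z]))
    assert abs(total - (vdw + elec)) < 1e-10
    sv, se, *_ = scalar_energy_force(ls, x, y, z)
    assert abs(sv - vdw) < 1e-10 and abs(se - elec) < 1e-10


def test_potential_vanishes_at_large_separation(default_landscape):
    far = 100.0 * default_landscape.lj_sigma
    total, vdw, elec = landscape_energy(
        default_landscape, LigandState.single_bead([0.0, 0.0, far])
    )
    assert abs(total) < 1e-6 and abs(vdw) < 1e-6 and abs(elec) < 1e-6


def test_energy_terms_match_hand_evaluation():
    """At the center of the association well each closed-form term is
    re-evaluated independently and summed."""
    ls = Landscape(well_depth=5.0)
    d = ls.well_radius
    total, vdw, elec = landscape_energy(ls, LigandState.single_bead([0, 0, d]))
    rep = ls.rep_amplitude * math.exp(-d / ls.rep_decay)
    tail = -ls.vdw_tail_amplitude * math.exp(-d / ls.vdw_tail_decay)
    screened = ls.elec_amplitude * math.exp(-d / ls.elec_decay)
    well = -5.0  # Gaussian well at its own center
    assert vdw == pytest.approx(rep + tail, abs=1e-12)
    assert elec == pytest.approx(screened + well, abs=1e-12)
    assert total == pytest.approx(rep + tail + screened + well, abs=1e-12)


def test_zero_amplitude_kills_elec_component(rng):
    ls = Landscape(elec_amplitude=0.0, well_depth=0.0)
    pts = rng.normal(scale=6.0, size=(100, 3))
    _, _, elec = ls.components(pts)
    assert np.all(elec == 0.0)


def test_force_matches_numerical_gradient(rng):
    for ls in (isotropic_well(), two_channel_landscape()):
        for _ in range(10):
            p = rng.normal(scale=3.0, size=3) + [0, 0, 3.0]
            _, _, fx, fy, fz = scalar_energy_force(ls, *p)
            h = 1e-6
            num = []
            for ax in range(3):
                dp = np.zeros(3)
                dp[ax] = h
                up, _, _ = ls.components(p + dp)
                um, _, _ = ls.components(p - dp)
                num.append(-(float(up) - float(um)) / (2 * h))
            assert np.allclose([fx, fy, fz], num, atol=1e-4)


def test_nonfinite_coordinates_rejected(default_landscape):
    with pytest.raises(ValueError):
        default_landscape.components(np.array([np.nan, 0.0, 1.0]))
    with pytest.raises(ValueError):
        LigandState.single_bead([np.inf, 0, 0])


def test_landscape_json_round_trip(tmp_path):
    ls = two_channel_landscape()
    path = tmp_path / "landscape.json"
    ls.to_json(path)
    back = Landscape.from_json(path)
    assert back.to_json_dict() == ls.to_json_dict()
    with pytest.raises(ValueError, match="unknown"):
        Landscape.from_json_dict({"well_depth_kcal_mol": 5.0, "bogus_key": 1})


# -- analytic PMF oracle --------------------------------------------------


def test_isotropic_pmf_collapses_to_radial_potential():
    ls = isotropic_well()
    grid = np.linspace(1.8, 16.0, 300)
    prof = analytic_pmf(ls, grid, temperature=295.0, include_jacobian=False)
    u = ls.components(np.stack([np.zeros_like(grid)] * 2 + [grid], axis=-1))[0]
    expected = u - u.min()
    assert np.max(np.abs(prof.a_values - expected)) < 1e-6


def test_square_well_pmf_is_a_step():
    sw = _SquareWell(depth=5.0, radius=4.0)
    grid = np.linspace(0.5, 8.0, 151)
    prof = analytic_pmf(sw, grid, temperature=295.0, include_jacobian=False)
    inside = grid < 4.0 - 1e-9
    outside = grid > 4.0 + 1e-9
    assert np.allclose(prof.a_values[inside], 0.0, atol=1e-9)
    assert np.allclose(prof.a_values[outside], 5.0, atol=1e-9)


def test_angular_quadrature_agrees_with_monte_carlo(rng):
    """Orientation average vs brute-force Monte Carlo on three anisotropic
    landscapes, within 3 standard errors."""
    beta = 1.0 / KT295
    cases = [
        two_channel_landscape(),
        Landscape(channels=(Channel((0, 0, 1), 0.3, 0.5),), background_barrier=3.0),
        Landscape(
            channels=(Channel((1, 1, 1), 0.6, 1.0), Channel((0, 1, 0), 0.25, 0.0)),
            background_barrier=5.0,
        ),
    ]
    for ls in cases:
        d = 5.0  # inside the barrier shell where anisotropy is strongest
        n = 300_000
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        w = np.exp(-beta * ls.components(v * d)[0])
        mc_mean = w.mean()
        mc_se = w.std(ddof=1) / math.sqrt(n)
        prof = analytic_pmf(ls, np.array([d, d + 0.1]), temperature=295.0,
                            include_jacobian=False)
        # compare free energies; propagate the MC error through the log
        a_quad = prof.meta.get("quadrature_tol_achieved", 0.0)
        from cpus.landscape import orientation_averaged_weight
        quad = orientation_averaged_weight(ls, np.array([d]), 295.0)[0]
        assert abs(quad - mc_mean) < 3.0 * mc_se + 1e-12


# -- analytic standard binding free energy --------------------------------


def test_zero_potential_closed_form(zero_landscape):
    """U = 0: dG0 = -kBT ln(4 pi b^3 / (3 V0)); b = 7.36 A makes the bound
    volume equal V0, hence dG0 = 0 to the rounding of b."""
    dg = analytic_binding_dG(zero_landscape, 295.0, 1663.0, bound_boundary=7.36)
    assert abs(dg) < 0.01
    b = 5.0
    expected = -KT295 * math.log(4.0 * math.pi * b ** 3 / (3.0 * 1663.0))
    assert analytic_binding_dG(zero_landscape, 295.0, 1663.0, b) == pytest.approx(
        expected, abs=1e-6
    )


def test_square_well_binding_closed_form():
    """depth 5 kcal/mol on [0, 8 A]: hand closed form
    -kBT ln[(4 pi 8^3 / 3 / 1663) e^{beta eps}]."""
    sw = _SquareWell(depth=5.0, radius=8.0)
    dg = analytic_binding_dG(sw, 295.0, 1663.0, bound_boundary=8.0)
    expected = -KT295 * math.log(
        (4.0 * math.pi * 8.0 ** 3 / 3.0 / 1663.0) * math.exp(5.0 / KT295)
    )
    assert dg == pytest.approx(expected, rel=1e-6)


def test_binding_dg_monotone_in_well_depth():
    shallow = analytic_binding_dG(isotropic_well(well_depth=5.0), 295.0, 1663.0, 20.0)
    deep = analytic_binding_dG(isotropic_well(well_depth=10.0), 295.0, 1663.0, 20.0)
    assert deep < shallow


def test_binding_dg_insensitive_to_boundary_beyond_interaction_range():
    """Once the boundary exceeds the interaction range, only the slowly
    growing free-volume term remains; for a bound system it is a small
    perturbation of the configurational integral."""
    ls = isotropic_well()
    a = analytic_binding_dG(ls, 295.0, 1663.0, bound_boundary=18.0)
    b = analytic_binding_dG(ls, 295.0, 1663.0, bound_boundary=22.0)
    assert abs(a - b) < 0.05
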