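"""Standard-state correction, cutoff detection, and unit conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpus.binding import (
    ExperimentRecord,
    NoCutoffError,
    bound_integral,
    default_bound_region,
    detect_cutoff,
    dg_to_k,
    k_to_dg,
    select_lower_bound,
    standard_correction,
    vant_hoff_extrapolate,
)
from cpus.constants import KB_KCAL_MOL_K
from cpus.landscape import Landscape
from cpus.pmf import PMFProfile, UnvisitedBinError
from cpus.reference import FKBP12_RAPAMYCIN, ddg_bind0, ddg_exp

KT295 = KB_KCAL_MOL_K * 295.0


def _profile(a_values, r0=0.0, width=0.05, counts=None, d_final=None):
    n = len(a_values)
    prof = PMFProfile(
        r_centers=r0 + width * np.arange(n),
        a_values=np.asarray(a_values, dtype=float),
        counts=counts, temperature=295.0,
    )
    prof.d_final = d_final if d_final is not None else float(prof.r_centers[-1])
    return prof


# -- cutoff ---------------------------------------------------------------


def test_cutoff_immediate_cancellation():
    res = detect_cutoff([0.0, 0.0, 0.0], [4.0, 4.1, 4.2], d_ref=4.0)
    assert res.window_index == 0
    assert res.r_cut == 0.0


def test_cutoff_definition_walkthrough():
    res = detect_cutoff(
        [-3.0, -1.0, -0.05, -0.01, 0.0], [5.0, 5.1, 5.2, 5.3, 5.4],
        threshold=0.1, persistence=2,
    )
    assert res.window_index == 2
    assert res.r_cut == pytest.approx(5.2)


def test_cutoff_requires_persistence():
    # a single noisy zero crossing does not count
    e = [-3.0, -0.01, -3.0, -3.0, -0.02, -0.01, -0.03, -0.01, -0.02, -0.01]
    t = list(np.arange(10, dtype=float))
    res = detect_cutoff(e, t, threshold=0.1, persistence=5)
    assert res.window_index == 4
    with pytest.raises(NoCutoffError, match="converges to zero"):
        detect_cutoff([-3.0, -2.0, -1.0], [1.0, 2.0, 3.0], threshold=0.1)


def test_cutoff_on_lj_landscape_matches_closed_form():
    """Mean vdW per window evaluated from the closed-form 12-6 term: the
    detected cutoff must sit within one window spacing of the exact
    threshold crossing found by brute-force root scanning."""
    ls = Landscape(
        well_depth=0.0, rep_amplitude=0.0, vdw_tail_amplitude=0.0,
        elec_amplitude=0.0, lj_epsilon=2.0, lj_sigma=3.0,
    )
    targets = np.arange(3.5, 12.0, 0.1)
    means = ls._vdw_radial(targets)
    fine = np.arange(3.5, 12.0, 1e-4)
    exact = fine[np.abs(ls._vdw_radial(fine)) <= 0.05][0]
    res = detect_cutoff(means, targets, threshold=0.05, persistence=5)
    assert abs(targets[res.window_index] - exact) <= 0.1


# -- bound integral -------------------------------------------------------


def test_bound_integral_unit_integrand():
    prof = _profile(np.zeros(41))  # r = 0 .. 2.0
    assert bound_integral(prof, (0.0, 2.0)) == pytest.approx(2.0)


def test_bound_integral_exponential_closed_form():
    a_slope, L = 2.0, 2.0
    r = 0.05 * np.arange(41)  # [0, 2]
    prof = _profile(a_slope * r)
    beta = 1.0 / KT295
    expected = (1.0 - math.exp(-beta * a_slope * L)) / (beta * a_slope)
    assert bound_integral(prof, (0.0, L)) == pytest.approx(expected, abs=1e-3)


def test_bound_integral_quadrature_converges_with_bin_width():
    beta = 1.0 / KT295
    coarse = _profile(2.0 * 0.05 * np.arange(41), width=0.05)
    fine = PMFProfile(
        r_centers=0.025 * np.arange(81),
        a_values=2.0 * 0.025 * np.arange(81), temperature=295.0,
    )
    i1 = bound_integral(coarse, (0.0, 2.0))
    i2 = bound_integral(fine, (0.0, 2.0))
    assert abs(i1 - i2) / i2 < 0.005


def test_bound_integral_refuses_unvisited_bins():
    counts = np.ones(41, dtype=int)
    counts[20] = 0
    prof = _profile(np.zeros(41), counts=counts)
    with pytest.raises(UnvisitedBinError, match="unvisited"):
        bound_integral(prof, (0.0, 2.0))


# -- the standard-state correction ----------------------------------------


def test_flat_profile_correction_closed_form():
    """A at 0 on [0, 1 A], r_cut = 16: the whole correction collapses to
    -kBT ln(4 pi 16^2 * 1 / 1663), evaluated independently here."""
    prof = _profile(np.zeros(21), d_final=1.0)
    cut = detect_cutoff([0.0], [16.0], persistence=1)
    res = standard_correction(prof, cut, bound_region=(0.0, 1.0))
    expected = -KT295 * math.log(4.0 * math.pi * 16.0 ** 2 * 1.0 / 1663.0)
    assert res.dg_pmf == 0.0
    assert res.bound_integral == pytest.approx(1.0)
    assert res.correction == pytest.approx(expected, abs=1e-9)
    assert res.dg_bind0 == pytest.approx(expected, abs=1e-9)
    assert abs(res.audit_identity()) < 1e-12


def test_correction_vanishes_when_prefactor_times_integral_is_v0():
    prof = _profile(np.zeros(21), d_final=1.0)
    r_star = math.sqrt(1663.0 / (4.0 * math.pi * 1.0))
    cut = detect_cutoff([0.0], [r_star], persistence=1)
    res = standard_correction(prof, cut, bound_region=(0.0, 1.0))
    assert res.correction == pytest.approx(0.0, abs=1e-9)
    assert res.dg_bind0 == pytest.approx(res.dg_pmf, abs=1e-9)


def test_doubling_v0_shifts_dg_by_kbt_ln2():
    a = np.concatenate([np.linspace(0, 6, 100), np.full(40, 6.0)])
    prof = _profile(a)
    cut = detect_cutoff([0.0], [5.0], persistence=1)
    r1 = standard_correction(prof, cut, standard_volume=1663.0)
    r2 = standard_correction(prof, cut, standard_volume=3326.0)
    assert r2.dg_bind0 - r1.dg_bind0 == pytest.approx(KT295 * math.log(2.0), abs=1e-12)


def test_default_bound_region_tracks_the_basin():
    a = np.concatenate([np.linspace(3, 0, 20), np.linspace(0, 6, 100), np.full(20, 6.0)])
    prof = _profile(a)
    r_lo, r_hi = default_bound_region(prof)
    assert r_lo == prof.r_centers[0]
    # edge where A first reaches plateau - kBT
    assert prof.value_at(r_hi) >= 6.0 - KT295 - 1e-9


# -- lower-bound selection -------------------------------------------------


def _result(dg_pmf, walker_id=0):
    prof = _profile(np.linspace(0, abs(dg_pmf), 50))
    cut = detect_cutoff([0.0], [10.0], persistence=1)
    return standard_correction(prof, cut, walker_id=walker_id)


def test_lower_bound_selection():
    single = [_result(-7.0)]
    assert select_lower_bound(single)[0] == 0
    results = [_result(v, i) for i, v in enumerate([12.4, 11.09, 13.0])]
    idx, best = select_lower_bound(results)
    assert idx == 1
    assert best.dg_pmf == pytest.approx(-11.09)
    perm = [results[2], results[0], results[1]]
    _, best2 = select_lower_bound(perm)
    assert best2.dg_pmf == best.dg_pmf
    with pytest.raises(ValueError):
        select_lower_bound([])


def test_selected_plateau_is_variational_minimum():
    results = [_result(v, i) for i, v in enumerate([9.4, 8.2, 8.9, 10.0])]
    _, best = select_lower_bound(results)
    assert all(abs(best.dg_pmf) <= abs(r.dg_pmf) + 1e-12 for r in results)


# -- conversions ----------------------------------------------------------


def test_dg_to_k_reference_state():
    assert dg_to_k(0.0, 295.0) == 1.0


def test_table_kd_row_consistency():
    """Kd = 0.54 nM at 295 K corresponds to -12.51 kcal/mol, matching the
    tabulated -12.53 within the rounding of the printed pair."""
    dg = k_to_dg(0.54e-9, 295.0)
    assert dg == pytest.approx(-12.51, abs=0.005)
    assert abs(dg - FKBP12_RAPAMYCIN["WT"].dg_exp) < 0.03


@settings(max_examples=60, derandomize=True)
@given(st.floats(min_value=-20.0, max_value=5.0))
def test_dg_k_round_trip(dg):
    assert k_to_dg(dg_to_k(dg, 295.0), 295.0) == pytest.approx(dg, abs=1e-12)


def test_vant_hoff_identities():
    assert vant_hoff_extrapolate(-10.0, -3.0, 288.15, 288.15) == -10.0
    assert vant_hoff_extrapolate(-10.0, -10.0, 288.15, 310.0) == pytest.approx(-10.0)
    assert vant_hoff_extrapolate(-10.0, 0.0, 288.15, 295.0) == pytest.approx(
        -10.0 * 295.0 / 288.15, abs=1e-9
    )
    assert vant_hoff_extrapolate(-10.0, 0.0, 288.15, 295.0) == pytest.approx(
        -10.2377, abs=1e-4
    )


def test_experiment_record_consistency_check():
    rec = ExperimentRecord(k_exp=0.54e-9, dh=-8.0, t_measured=288.15, t_target=288.15)
    assert rec.dg_at_target() == pytest.approx(k_to_dg(0.54e-9, 288.15))
    with pytest.raises(ValueError, match="disagree"):
        ExperimentRecord(dg_exp=-5.0, k_exp=0.54e-9)
    with pytest.raises(ValueError, match="enthalpy"):
        ExperimentRecord(dg_exp=-12.0, t_measured=288.15, t_target=295.0).dg_at_target()


def test_mutant_shifts_from_reference_table():
    assert ddg_bind0("Y82F") == pytest.approx(0.76, abs=1e-9)
    assert ddg_bind0("D37V") == pytest.approx(3.20, abs=1e-9)
    assert ddg_exp("Y82F") == pytest.approx(0.55, abs=1e-9)
    assert ddg_exp("D37V") == pytest.approx(2.92, abs=1e-9)
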