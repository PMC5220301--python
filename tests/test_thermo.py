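"""PMF construction, minima, standard-state Kd and free-energy identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dimerscope import (
    FixturePlan,
    MeanForceProfile,
    depth_for_kd,
    dg_from_kd,
    find_minima,
    fold_ratio,
    integrate_mean_force,
    kd_from_dg,
    kd_from_pmf,
    synth_mean_force,
)
from dimerscope.thermo import (
    PMFProfile,
    ProfileError,
    R_KCAL,
    STANDARD_VOLUME_NM3,
)


def test_zero_force_gives_flat_pmf_with_quadrature_error():
    r = np.arange(2.6, 5.4, 0.02)
    prof = MeanForceProfile(r, np.zeros_like(r), np.full_like(r, 0.5))
    pmf = integrate_mean_force(prof)
    np.testing.assert_allclose(pmf.w, 0.0, atol=1e-12)
    # the error is smallest inside the reference window and grows moving
    # away from it toward short distances
    ref_err = pmf.error[pmf.r >= 4.6].max()
    below = pmf.r < 4.6
    assert pmf.error[0] == pmf.error[below].max() > ref_err
    assert (np.diff(pmf.error[below]) <= 1e-15).all()


def test_harmonic_force_integrates_to_quadratic():
    r = np.arange(2.6, 5.4, 0.01)
    k, r0 = 4.0, 4.9
    prof = MeanForceProfile(r, -k * (r - r0), np.zeros_like(r))
    pmf = integrate_mean_force(prof, reference=(4.85, 4.95))
    expected = 0.5 * k * (r - r0) ** 2
    expected -= expected[(r >= 4.85) & (r <= 4.95)].mean()
    np.testing.assert_allclose(pmf.w, expected, atol=1e-3)


def test_non_monotonic_grid_rejected():
    with pytest.raises(ProfileError):
        MeanForceProfile(np.array([1.0, 0.9, 1.1]), np.zeros(3), np.zeros(3))


def test_noisy_force_recovered_within_propagated_errors():
    """Seeded noisy samples of a known force: the integrated PMF stays
    within 2 propagated standard errors of the true curve at >= 95% of
    grid points over 25 seeds."""
    ok = 0
    trials = 0
    for seed in range(25):
        plan = FixturePlan(seed=seed, pmf_noise_kcal_nm=1.0)
        prof, _ = synth_mean_force(plan)
        pmf = integrate_mean_force(prof)
        from dimerscope.synth import gaussian_pmf
        truth = gaussian_pmf(pmf.r, plan.pmf_depth_kcal, plan.pmf_center_nm,
                             plan.pmf_width_nm)
        in_ref = pmf.r >= 4.6
        truth = truth - truth[in_ref].mean()
        inside = np.abs(pmf.w - truth) <= 2 * np.maximum(pmf.error, 1e-12)
        ok += inside[:-1].sum()
        trials += inside[:-1].size
    assert ok / trials >= 0.95


def test_find_minima_single_double_flat():
    r = np.arange(2.6, 5.4, 0.02)
    from dimerscope.synth import gaussian_pmf
    single = PMFProfile(r, gaussian_pmf(r, 3.0, 3.6, 0.2), np.zeros_like(r),
                        (4.6, 5.4))
    m = find_minima(single)
    assert len(m) == 1 and m[0][0] == pytest.approx(3.6, abs=0.02)
    double_w = gaussian_pmf(r, 2.0, 3.2, 0.12) + gaussian_pmf(r, 2.5, 3.6, 0.12)
    double = PMFProfile(r, double_w, np.zeros_like(r), (4.6, 5.4))
    locs = [x for x, _ in find_minima(double, depth_min=0.5)]
    assert locs == pytest.approx([3.2, 3.6], abs=0.02)
    flat = PMFProfile(r, np.zeros_like(r), np.zeros_like(r), (4.6, 5.4))
    assert find_minima(flat) == []


def test_square_well_kd_matches_closed_form():
    r = np.linspace(2.0, 6.0, 4001)
    depth, lo, hi = 4.0, 3.0, 3.5
    w = np.where((r >= lo) & (r <= hi), -depth, 0.0)
    pmf = PMFProfile(r, w, np.zeros_like(r), (4.6, 6.0))
    est = kd_from_pmf(pmf, bound_window=(lo, hi), temperature=300.0)
    rt = R_KCAL * 300.0
    ka = (4 * np.pi / 3) * (hi ** 3 - lo ** 3) * np.exp(depth / rt) \
        / STANDARD_VOLUME_NM3
    assert est.kd == pytest.approx(1.0 / ka, rel=1e-3)


def test_flat_pmf_kd_is_pure_volume_entropy():
    r = np.linspace(2.0, 6.0, 2001)
    pmf = PMFProfile(r, np.zeros_like(r), np.zeros_like(r), (4.6, 6.0))
    est = kd_from_pmf(pmf, bound_window=(3.0, 3.5))
    ka = (4 * np.pi / 3) * (3.5 ** 3 - 3.0 ** 3) / STANDARD_VOLUME_NM3
    assert est.kd == pytest.approx(1.0 / ka, rel=1e-6)


def test_unflat_reference_rejected():
    r = np.linspace(2.6, 5.4, 200)
    w = -np.exp(-((r - 4.8) ** 2) / 0.08)        # feature inside reference
    pmf = PMFProfile(r, w, np.zeros_like(r), (4.6, 5.4))
    with pytest.raises(ProfileError, match="reference"):
        kd_from_pmf(pmf)


def test_inverse_constructed_5mM_profile_recovered_within_1_percent():
    depth = depth_for_kd(5e-3, 3.6, 0.25)
    plan = FixturePlan(pmf_depth_kcal=depth)
    prof, true_kd = synth_mean_force(plan)
    assert true_kd == pytest.approx(5e-3, rel=1e-3)
    est = kd_from_pmf(integrate_mean_force(prof))
    assert est.kd == pytest.approx(5e-3, rel=0.01)


def test_dg_kd_paper_scale_values():
    assert dg_from_kd(1.0) == 0.0
    assert dg_from_kd(5e-3, 300.0) == pytest.approx(-3.16, abs=0.005)
    assert dg_from_kd(0.107, 300.0) == pytest.approx(-1.33, abs=0.005)
    with pytest.raises(ProfileError):
        dg_from_kd(-1.0)


@settings(deadline=None, max_examples=40)
@given(log_kd=st.floats(-12, 2), temp=st.floats(250, 350))
def test_dg_kd_round_trip_identity(log_kd, temp):
    kd = 10.0 ** log_kd
    back = kd_from_dg(dg_from_kd(kd, temp), temp)
    assert back == pytest.approx(kd, rel=1e-12)


def test_fold_ratio_and_invariance():
    from dimerscope.thermo import BindingEstimate
    a = BindingEstimate(5e-3, dg_from_kd(5e-3), 300.0, (2.6, 4.0), [])
    b = BindingEstimate(0.107, dg_from_kd(0.107), 300.0, (2.6, 4.0), [])
    assert fold_ratio(a, a) == 1.0
    assert fold_ratio(a, b) == pytest.approx(21.4, abs=0.01)
    # unchanged under a Kd <-> dG round trip
    a2 = BindingEstimate(kd_from_dg(a.dg_bind), a.dg_bind, 300.0, (2.6, 4.0), [])
    assert fold_ratio(a2, b) == pytest.approx(fold_ratio(a, b), rel=1e-12)
    with pytest.raises(ProfileError):
        fold_ratio(a, BindingEstimate(1.0, 0.0, 310.0, (2.6, 4.0), []))


def test_kd_invariant_to_constant_shift_before_rereferencing():
    prof, _ = synth_mean_force(FixturePlan())
    pmf = integrate_mean_force(prof)
    shifted = PMFProfile(pmf.r, pmf.w + 7.0, pmf.error, pmf.reference_window)
    # re-reference the shifted curve
    in_ref = (shifted.r >= 4.6)
    rereferenced = PMFProfile(shifted.r, shifted.w - shifted.w[in_ref].mean(),
                              shifted.error, shifted.reference_window)
    k1 = kd_from_pmf(pmf).kd
    k2 = kd_from_pmf(rereferenced).kd
    assert k2 == pytest.approx(k1, rel=1e-12)


def test_deeper_well_strictly_decreases_kd():
    kds = []
    for depth in (1.0, 2.0, 3.0, 4.0, 5.0):
        prof, _ = synth_mean_force(FixturePlan(pmf_depth_kcal=depth))
        kds.append(kd_from_pmf(integrate_mean_force(prof)).kd)
    assert all(a > b for a, b in zip(kds, kds[1:]))


def test_grid_refinement_converges():
    # fixed bound window so the comparison isolates quadrature convergence
    # from bound-window snapping to the grid
    window = (2.6, 4.0)
    coarse, _ = synth_mean_force(FixturePlan(pmf_grid=(2.6, 5.4, 0.02)))
    fine, _ = synth_mean_force(FixturePlan(pmf_grid=(2.6, 5.4, 0.01)))
    k_c = kd_from_pmf(integrate_mean_force(coarse), bound_window=window).kd
    k_f = kd_from_pmf(integrate_mean_force(fine), bound_window=window).kd
    assert abs(k_c - k_f) / k_f < 0.005
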