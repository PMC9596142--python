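import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

from vibroraman import (
    BasisSpec,
    Invariants,
    absorption_spectrum,
    build_hamiltonian,
    compose_tensor_correlation,
    compute_vrr,
    eigen_correlations,
    enumerate_basis,
    excitation_profile,
    half_fourier_alpha,
    match_excitation,
    peak_position,
    rotational_invariants,
    scale_raman_axis,
    spectrum_section,
    sum_over_states_alpha,
    time_grid,
    vrr_intensity,
)
from vibroraman import fixtures
from vibroraman.spectra import (
    CorrelationTensorSeries,
    SpectrumSettings,
    VRRSpectrum2D,
    _invariants_arrays,
)

from conftest import random_rotation


class TestComposeTensor:
    def test_single_state_rank_one(self, one_mode_model):
        tg = time_grid(0.2, 20.0)
        basis = enumerate_basis(1, BasisSpec(n_max=8, n_tot=8), 1)
        corrs = eigen_correlations(one_mode_model, basis, [0], tg)
        chi = compose_tensor_correlation(corrs, one_mode_model)
        mu = one_mode_model.states[0].dipole
        c = corrs["S1"].get("S1", 1)
        expected = np.einsum("r,s,t->rst", mu, mu, c)
        np.testing.assert_allclose(chi.chi[1], expected, atol=1e-14)

    def test_zero_dipoles(self, one_mode_model):
        m = dataclasses.replace(
            one_mode_model,
            states=(dataclasses.replace(one_mode_model.states[0], dipole=np.zeros(3)),),
        )
        tg = time_grid(0.2, 10.0)
        basis = enumerate_basis(1, BasisSpec(n_max=6, n_tot=6), 1)
        chi = compose_tensor_correlation(eigen_correlations(m, basis, [0], tg), m)
        assert np.all(chi.chi == 0.0)

    def test_two_uncoupled_states_sum(self, interference_model):
        m = interference_model
        tg = time_grid(0.2, 30.0)
        basis = enumerate_basis(1, BasisSpec(n_max=8, n_tot=8), 2)
        corrs = eigen_correlations(m, basis, [0, 1], tg)
        full = compose_tensor_correlation(corrs, m)
        diag = compose_tensor_correlation(corrs, m, diagonal_only=True)
        # k != m terms vanish for uncoupled surfaces
        np.testing.assert_allclose(full.chi, diag.chi, atol=1e-12)

    def test_missing_state_raises(self, interference_model):
        tg = time_grid(0.2, 10.0)
        basis = enumerate_basis(1, BasisSpec(n_max=6, n_tot=6), 2)
        corrs = eigen_correlations(interference_model, basis, [0], tg)
        with pytest.raises(KeyError, match="missing"):
            compose_tensor_correlation(corrs, interference_model, subset=["S1", "S2"])


class TestHalfFourier:
    def _single_phase_series(self, e, tg, e_g0=0.0):
        chi = np.zeros((1, 3, 3, len(tg)), dtype=complex)
        chi[0, 0, 0] = np.exp(-1j * e * tg)
        return CorrelationTensorSeries(tgrid=tg, chi=chi, e_g0=e_g0)

    def test_closed_form_pole(self):
        gamma, e = 0.12, 5.0
        tg = time_grid(0.01, 150.0)
        series = self._single_phase_series(e, tg)
        w = np.arange(4.5, 5.5, 0.01)
        alpha = half_fourier_alpha(series, w, gamma)
        expected = 1j / (gamma - 1j * (w - e))
        np.testing.assert_allclose(alpha.alpha[0, :, 0, 0], expected, rtol=1e-3)
        at_res = alpha.alpha[0, np.argmin(np.abs(w - e)), 0, 0]
        assert at_res == pytest.approx(1j / gamma, rel=1e-4)

    def test_linearity(self):
        tg = time_grid(0.05, 120.0)
        s1 = self._single_phase_series(5.0, tg)
        s2 = self._single_phase_series(5.3, tg)
        both = CorrelationTensorSeries(tgrid=tg, chi=s1.chi + s2.chi, e_g0=0.0)
        w = np.arange(4.5, 5.8, 0.05)
        a1 = half_fourier_alpha(s1, w, 0.12).alpha
        a2 = half_fourier_alpha(s2, w, 0.12).alpha
        ab = half_fourier_alpha(both, w, 0.12).alpha
        np.testing.assert_allclose(ab, a1 + a2, atol=1e-12)

    def test_quadrature_convergence_halving_dt(self, one_mode_model):
        # narrow near-resonant window so the trapezoid error is quadrature-dominated
        basis = enumerate_basis(1, BasisSpec(n_max=14, n_tot=14), 1)
        w = np.arange(4.95, 5.15, 0.005)
        results = []
        for dt in (0.02, 0.01):
            tg = time_grid(dt, 150.0)
            corrs = eigen_correlations(one_mode_model, basis, [0], tg)
            chi = compose_tensor_correlation(corrs, one_mode_model)
            results.append(half_fourier_alpha(chi, w, 0.12).alpha[1])
        dev = np.max(np.abs(results[0] - results[1])) / np.max(np.abs(results[1]))
        assert dev < 1e-6

    def test_gamma_validation(self):
        tg = time_grid(0.1, 100.0)
        series = self._single_phase_series(5.0, tg)
        with pytest.raises(ValueError, match="gamma"):
            half_fourier_alpha(series, np.array([5.0]), -0.1)

    def test_short_grid_warns(self):
        tg = time_grid(0.1, 10.0)
        series = self._single_phase_series(5.0, tg)
        with pytest.warns(UserWarning, match="too short"):
            half_fourier_alpha(series, np.array([5.0]), 0.04)


class TestRotationalInvariants:
    def test_isotropic(self):
        inv = rotational_invariants((2.0 - 1.0j) * np.eye(3))
        assert inv.a == pytest.approx(2.0 - 1.0j)
        assert inv.g2 == pytest.approx(0.0, abs=1e-14)
        assert inv.d2 == pytest.approx(0.0, abs=1e-14)

    def test_antisymmetric(self):
        alpha = np.zeros((3, 3), dtype=complex)
        alpha[0, 1], alpha[1, 0] = 1.0, -1.0
        inv = rotational_invariants(alpha)
        assert inv.a == pytest.approx(0.0)
        assert inv.g2 == pytest.approx(0.0, abs=1e-14)
        assert inv.d2 == pytest.approx(3.0)

    @hyp_settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        alpha = rng.normal(size=(3, 3)) + 1j * rng.normal(size=(3, 3))
        rot = random_rotation(seed + 1)
        a, b = rotational_invariants(alpha), rotational_invariants(rot.T @ alpha @ rot)
        assert b.a == pytest.approx(a.a, abs=1e-10)
        assert b.g2 == pytest.approx(a.g2, rel=1e-10, abs=1e-10)
        assert b.d2 == pytest.approx(a.d2, rel=1e-10, abs=1e-10)

    def test_nonnegative(self):
        rng = np.random.default_rng(0)
        alpha = rng.normal(size=(3, 3)) + 1j * rng.normal(size=(3, 3))
        inv = rotational_invariants(alpha)
        assert inv.g2 >= 0.0 and inv.d2 >= 0.0


class TestVRRIntensity:
    def test_zero_tensor(self):
        assert vrr_intensity(Invariants(a=0.0, g2=0.0, d2=0.0), 2.0, 0.1) == 0.0

    def test_arithmetic(self):
        assert vrr_intensity(Invariants(a=1.0, g2=0.0, d2=0.0), 2.0, 0.0) == pytest.approx(16.0)

    def test_quadratic_scaling(self):
        alpha = np.array([[1.0, 0.5j, 0], [0, 2.0, 0], [0.1, 0, 0.3]], dtype=complex)
        i1 = vrr_intensity(rotational_invariants(alpha), 2.0, 0.1)
        i2 = vrr_intensity(rotational_invariants(3.0 * alpha), 2.0, 0.1)
        assert i2 == pytest.approx(9.0 * i1)

    def test_sign_violation(self):
        with pytest.raises(ValueError, match="exceed"):
            vrr_intensity(Invariants(a=1.0, g2=0.0, d2=0.0), 0.1, 0.2)


class TestProtocols:
    def test_single_uncoupled_state_all_protocols_equal(self, one_mode_model, fast_settings):
        specs = [
            compute_vrr(one_mode_model, p, settings=fast_settings)
            for p in ("lvc", "vg_int", "vg_sum")
        ]
        np.testing.assert_allclose(specs[0].intensities, specs[1].intensities, rtol=1e-12)
        np.testing.assert_array_equal(specs[1].intensities, specs[2].intensities)

    def test_lvc_collapses_to_vg_int(self, conical_model, fast_settings):
        m = conical_model.with_couplings_zeroed()
        lvc = compute_vrr(m, "lvc", settings=fast_settings)
        vgi = compute_vrr(m, "vg_int", settings=fast_settings)
        scale = np.max(np.abs(vgi.intensities))
        assert np.max(np.abs(lvc.intensities - vgi.intensities)) / scale < 1e-10

    def test_interference_dip(self, interference_model):
        settings = SpectrumSettings(gamma=0.04, tmax=350.0, n_tot=10, omega_step=0.01)
        vgi = compute_vrr(interference_model, "vg_int", settings=settings)
        vgs = compute_vrr(interference_model, "vg_sum", settings=settings)
        w = vgi.omega_grid
        valley = (w > 4.98) & (w < 5.15)
        assert np.all(vgi.intensities[0, valley] < vgs.intensities[0, valley])

    def test_vrr_oracle_against_sum_over_states(self, conical_model):
        settings = SpectrumSettings(gamma=0.12, tmax=150.0, n_tot=8, omega_step=0.02)
        spec = compute_vrr(conical_model, "lvc", settings=settings)
        basis = enumerate_basis(2, BasisSpec(n_max=8, n_tot=8), 2)
        w = spec.omega_grid
        for f in (1, 2):
            sos = sum_over_states_alpha(conical_model, basis, w, 0.12, f)
            a, g2, d2 = _invariants_arrays(sos)
            wf = conical_model.omegas[f - 1]
            expected = w * (w - wf) ** 3 * (45 * np.abs(a) ** 2 + 7 * g2 + 5 * d2) / 45.0
            dev = np.max(np.abs(spec.intensities[f - 1] - expected)) / np.max(expected)
            assert dev < 1e-3

    def test_unknown_protocol(self, one_mode_model):
        with pytest.raises(ValueError, match="unknown protocol"):
            compute_vrr(one_mode_model, "vg")

    def test_empty_bright_subset(self, one_mode_model):
        with pytest.raises(ValueError, match="non-empty"):
            compute_vrr(one_mode_model, "lvc", bright=[])

    def test_intensities_nonnegative(self, conical_model, fast_settings):
        spec = compute_vrr(conical_model, "lvc", settings=fast_settings)
        assert np.all(spec.intensities >= 0.0)

    def test_frame_invariance(self, conical_model, fast_settings):
        rot = random_rotation(99)
        states = tuple(
            dataclasses.replace(s, dipole=rot @ s.dipole) for s in conical_model.states
        )
        rotated = dataclasses.replace(conical_model, states=states)
        a = compute_vrr(conical_model, "lvc", settings=fast_settings)
        b = compute_vrr(rotated, "lvc", settings=fast_settings)
        scale = np.max(a.intensities)
        assert np.max(np.abs(a.intensities - b.intensities)) / scale < 1e-10


class TestSymmetryActivation:
    def test_dark_mode_needs_coupling(self, fast_settings):
        on = compute_vrr(fixtures.cs_bright_dark(), "lvc", settings=fast_settings)
        off = compute_vrr(fixtures.cs_bright_dark(coupling=0.0), "lvc", settings=fast_settings)
        strongest = np.max(on.intensities)
        assert np.max(off.intensities[2]) < 1e-14 * np.max(off.intensities)
        assert np.max(on.intensities[2]) > 1e-6 * strongest

    def test_intensity_flows_through_dark_dipole(self, fast_settings):
        with_mu = compute_vrr(fixtures.cs_bright_dark(), "lvc", settings=fast_settings)
        no_mu = compute_vrr(
            fixtures.cs_bright_dark(dark_dipole=0.0), "lvc",
            bright=["ppi", "npi"], settings=fast_settings,
        )
        assert np.max(no_mu.intensities[2]) < 1e-14 * np.max(no_mu.intensities)
        assert np.max(with_mu.intensities[2]) > 0.0


class TestAbsorption:
    def test_single_stick_gaussian(self):
        from vibroraman import LVCModel, ModeSpec, StateSpec

        m = LVCModel(
            modes=(ModeSpec(index=1, omega=0.1),),
            states=(StateSpec(label="S", energy=5.0, gradient=[0.0], dipole=[1, 0, 0]),),
        )
        hwhm = 0.04
        settings = SpectrumSettings(gamma=0.04, tmax=300.0, n_tot=4, omega_step=0.0005)
        spec = absorption_spectrum(m, "lvc", hwhm, settings=settings, omega_prefactor=False)
        peak = peak_position(spec)
        assert peak == pytest.approx(5.0, abs=0.002)
        half = np.max(spec.intensity) / 2.0
        above = spec.omega_grid[spec.intensity >= half]
        measured_hwhm = (above[-1] - above[0]) / 2.0
        assert measured_hwhm == pytest.approx(hwhm, rel=0.02)

    def test_sum_rule(self, conical_model):
        settings = SpectrumSettings(
            gamma=0.04, tmax=200.0, n_tot=6, omega_step=0.005,
            omega_min=3.0, omega_max=8.0,
        )
        spec = absorption_spectrum(
            conical_model, "lvc", hwhm=0.1, settings=settings, omega_prefactor=False
        )
        integral = np.trapezoid(spec.intensity, spec.omega_grid)
        expected = np.pi * sum(np.dot(s.dipole, s.dipole) for s in conical_model.states)
        assert integral == pytest.approx(expected, rel=1e-3)

    def test_peaks_match_eigenvalue_sticks(self, conical_model):
        settings = SpectrumSettings(gamma=0.04, tmax=300.0, n_tot=8, omega_step=0.002)
        spec = absorption_spectrum(conical_model, "lvc", hwhm=0.01, settings=settings)
        basis = enumerate_basis(2, BasisSpec(n_max=8, n_tot=8), 2)
        H = build_hamiltonian(conical_model, basis)
        evals, vecs = np.linalg.eigh(H.dense())
        mu = conical_model.dipole_matrix()
        weights = np.zeros(len(evals))
        for k in range(2):
            weights += np.abs(vecs[basis.vacuum_index(k)]) ** 2 * np.dot(mu[k], mu[k])
        top_stick = evals[np.argmax(weights)] - conical_model.zpe
        peak = spec.omega_grid[np.argmax(spec.intensity)]
        assert abs(peak - top_stick) < 0.01 + 2 * settings.omega_step

    def test_broadening_positivity(self, conical_model, fast_settings):
        spec = absorption_spectrum(conical_model, "lvc", hwhm=0.12, settings=fast_settings)
        assert np.min(spec.intensity) > -1e-10 * np.max(spec.intensity)

    def test_frame_invariance(self, conical_model, fast_settings):
        rot = random_rotation(7)
        states = tuple(
            dataclasses.replace(s, dipole=rot @ s.dipole) for s in conical_model.states
        )
        rotated = dataclasses.replace(conical_model, states=states)
        a = absorption_spectrum(conical_model, "lvc", 0.04, settings=fast_settings)
        b = absorption_spectrum(rotated, "lvc", 0.04, settings=fast_settings)
        assert np.max(np.abs(a.intensity - b.intensity)) / np.max(a.intensity) < 1e-10

    def test_invalid_hwhm(self, one_mode_model):
        with pytest.raises(ValueError, match="HWHM"):
            absorption_spectrum(one_mode_model, "lvc", hwhm=0.0)


def _toy_spectrum(shifts=(1000.0, 1600.0)):
    w = np.arange(4.0, 6.0, 0.01)
    intensities = np.zeros((len(shifts), len(w)))
    for i in range(len(shifts)):
        intensities[i] = (i + 1.0) * np.exp(-((w - 5.0) ** 2) / 0.1)
    return VRRSpectrum2D(
        omega_grid=w,
        mode_indices=np.arange(1, len(shifts) + 1),
        shifts_cm1=np.array(shifts),
        intensities=intensities,
    )


class TestDerivedViews:
    def test_profile_matches_map(self):
        spec = _toy_spectrum()
        w, prof = excitation_profile(spec, 2)
        np.testing.assert_array_equal(prof, spec.intensities[1])

    def test_profile_unknown_mode(self):
        with pytest.raises(KeyError):
            excitation_profile(_toy_spectrum(), 9)

    def test_profile_of_silent_mode_zero(self, cs_model, fast_settings):
        spec = compute_vrr(cs_model.with_couplings_zeroed(), "lvc", settings=fast_settings)
        _, prof = excitation_profile(spec, 3)
        assert np.max(np.abs(prof)) < 1e-20 * np.max(spec.intensities)

    def test_profile_peak_near_vibronic_pole(self):
        model = fixtures.displaced_one_mode(s_hr=0.5, e_v=5.0)
        settings = SpectrumSettings(gamma=0.04, tmax=350.0, n_tot=12, omega_step=0.005)
        spec = compute_vrr(model, "lvc", settings=settings)
        _, prof = excitation_profile(spec, 1)
        peak = spec.omega_grid[np.argmax(prof)]
        w = model.omegas[0]
        vibronic = 5.0 - 0.5 * w + np.arange(4) * w  # 0-n lines of the displaced surface
        assert np.min(np.abs(vibronic - peak)) < 0.04

    def test_section_single_gaussian(self):
        spec = _toy_spectrum(shifts=(1000.0,))
        shift, section = spectrum_section(spec, 5.0, conv_hwhm_cm1=15.0)
        half = np.max(section) / 2.0
        above = shift[section >= half]
        assert (above[-1] - above[0]) / 2.0 == pytest.approx(15.0, rel=0.05)

    def test_section_conserves_integral(self):
        spec = _toy_spectrum()
        shift, section = spectrum_section(spec, 5.0)
        iw = np.argmin(np.abs(spec.omega_grid - 5.0))
        total = np.trapezoid(section, shift)
        assert total == pytest.approx(np.sum(spec.intensities[:, iw]), rel=1e-10)

    def test_close_modes_merge(self):
        spec = _toy_spectrum(shifts=(1000.0, 1005.0))
        shift, section = spectrum_section(spec, 5.0, conv_hwhm_cm1=15.0)
        interior = section[1:-1]
        maxima = np.sum(
            (interior > section[:-2]) & (interior > section[2:])
        )
        assert maxima == 1

    def test_off_grid_snaps_with_warning(self):
        spec = _toy_spectrum()
        with pytest.warns(UserWarning, match="snapping"):
            spectrum_section(spec, 5.0033)

    def test_scale_raman_axis(self):
        spec = _toy_spectrum(shifts=(1000.0,))
        scaled = scale_raman_axis(spec, 0.96)
        assert scaled.shifts_cm1[0] == pytest.approx(960.0)
        np.testing.assert_array_equal(scaled.intensities, spec.intensities)
        unscaled = scale_raman_axis(spec, 1.0)
        np.testing.assert_array_equal(unscaled.shifts_cm1, spec.shifts_cm1)

    def test_scale_factor_range(self):
        with pytest.raises(ValueError, match="scale factor"):
            scale_raman_axis(_toy_spectrum(), 1.5)


class TestMatchExcitation:
    def test_zero_shift(self):
        assert match_excitation(5.32, 5.0, 5.0) == pytest.approx(5.32)

    def test_blue_shift(self):
        assert match_excitation(5.32, 5.5, 5.0) == pytest.approx(5.82)

    def test_peak_refinement_within_grid_resolution(self):
        from vibroraman import LVCModel, ModeSpec, StateSpec

        m = LVCModel(
            modes=(ModeSpec(index=1, omega=0.1),),
            states=(StateSpec(label="S", energy=5.123, gradient=[0.0], dipole=[1, 0, 0]),),
        )
        settings = SpectrumSettings(gamma=0.04, tmax=200.0, n_tot=4, omega_step=0.01)
        spec = absorption_spectrum(m, "lvc", hwhm=0.05, settings=settings)
        assert abs(peak_position(spec) - 5.123) <= settings.omega_step
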