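"""Binning, Luzzati-D refinement, beta scaling and MLHL phase combination."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special

import betadm as bd
from betadm.phase_combination import N_PHASE_POINTS


def make_rice_set(d_star, n, seed, sigma_f2=50.0, cell=None, n_bins_d=1):
    """Reflections with |Fo| drawn from the acentric Rice model at known D."""
    rng = np.random.default_rng(seed)
    cell = cell or bd.UnitCell(18.0, 18.0, 18.0)
    sigma2 = 2 * sigma_f2 * (1.0 - d_star**2)
    fc = np.abs(
        rng.normal(0, np.sqrt(sigma_f2), n) + 1j * rng.normal(0, np.sqrt(sigma_f2), n)
    )
    noise = rng.normal(0, np.sqrt(sigma2 / 2), n) + 1j * rng.normal(
        0, np.sqrt(sigma2 / 2), n
    )
    fo = np.abs(d_star * fc + noise)
    d = np.linspace(2.5, 4.0, n) if n_bins_d > 1 else np.full(n, 2.5)
    return bd.ReflectionSet(
        hkl=np.column_stack([np.arange(n) + 1, np.zeros(n, int), np.zeros(n, int)]),
        d=d,
        fo=fo,
        sigfo=np.ones(n),
        cell=cell,
        f_c=fc.astype(complex),
    ), sigma2


class TestAssignBins:
    def test_single_bin(self, toy_dataset):
        refl, _ = toy_dataset
        binning = bd.assign_bins(refl, 1)
        assert binning.n_bins == 1
        assert np.all(binning.bin_id == 0)

    def test_equal_counts(self, toy_dataset):
        refl, _ = toy_dataset
        binning = bd.assign_bins(refl, 7)
        assert binning.counts.max() - binning.counts.min() <= 1

    def test_boundaries_monotone_in_resolution(self, toy_dataset):
        refl, _ = toy_dataset
        binning = bd.assign_bins(refl, 5)
        assert np.all(np.diff(binning.edges) >= 0)
        # higher bin id -> higher 1/d^2 (worse resolution)
        inv_d2 = 1.0 / refl.d**2
        means = [inv_d2[binning.bin_id == b].mean() for b in range(5)]
        assert np.all(np.diff(means) > 0)

    def test_too_many_bins_merged(self, toy_dataset):
        refl, _ = toy_dataset
        with pytest.warns(UserWarning, match="reducing n_bins"):
            binning = bd.assign_bins(refl, 1000)
        assert binning.counts.min() >= 50


class TestRefineLuzzati:
    def test_perfect_model_limit(self):
        """|Fo| = |Fc| exactly: D -> 1 and the variance term vanishes."""
        refl, _ = make_rice_set(0.9, 2000, seed=1)
        refl.fo = np.abs(refl.f_c)
        binning = bd.assign_bins(refl, 1)
        model = bd.refine_luzzati(refl, binning, use_set="all")
        assert model.d[0] == pytest.approx(1.0, abs=1e-6)
        assert model.sigma_d2[0] < 1e-4 * (refl.fo**2).mean()

    @pytest.mark.parametrize("d_star", [0.3, 0.5, 0.7, 0.9])
    def test_parameter_recovery(self, d_star):
        """Rice-simulated data: recovered D unbiased to within 0.03."""
        recovered = []
        for rep in range(10):
            refl, sigma2 = make_rice_set(d_star, 5000, seed=100 * rep + 7)
            binning = bd.assign_bins(refl, 1)
            model = bd.refine_luzzati(refl, binning, use_set="all")
            recovered.append(model.d[0])
        assert abs(np.mean(recovered) - d_star) < 0.03

    def test_independent_model_gives_zero_d(self):
        """F_c unrelated to Fo: D not significantly positive.  The null
        sampling scale of the amplitude-only D estimate is ~ n^(-1/4), so
        single draws at n = 5000 scatter up to ~0.15; the replicate mean
        must sit well below that."""
        estimates = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            refl, _ = make_rice_set(0.7, 5000, seed=1000 + seed)
            refl.f_c = np.abs(
                rng.normal(0, 7, 5000) + 1j * rng.normal(0, 7, 5000)
            ).astype(complex)
            binning = bd.assign_bins(refl, 1)
            estimates.append(bd.refine_luzzati(refl, binning, use_set="all").d[0])
        assert np.mean(estimates) < 0.1
        assert max(estimates) < 0.25

    def test_working_set_excludes_free(self):
        """Free-flagged reflections do not influence the working-set fit."""
        refl, _ = make_rice_set(0.7, 4000, seed=3)
        refl.free[:2000] = True
        refl.fo[:2000] = np.abs(refl.f_c[:2000])  # corrupt the free half
        binning = bd.assign_bins(refl, 1)
        fit_work = bd.refine_luzzati(refl, binning, use_set="working")
        fit_all = bd.refine_luzzati(refl, binning, use_set="all")
        assert fit_work.d[0] < fit_all.d[0]
        assert abs(fit_work.d[0] - 0.7) < 0.05

    def test_requires_fc(self, toy_dataset):
        refl, _ = toy_dataset
        binning = bd.assign_bins(refl, 1)
        with pytest.raises(ValueError):
            bd.refine_luzzati(refl, binning)


class TestApplyBeta:
    def test_identity_at_one(self):
        model = bd.LuzzatiModel(
            d=np.array([0.8]), sigma_d2=np.array([5.0]), fc2_mean=np.array([100.0])
        )
        cov = bd.apply_beta(model, 1.0)
        np.testing.assert_array_equal(cov.d_eff, model.d)
        np.testing.assert_array_equal(cov.sigma_eff, model.sigma_d2)

    def test_scaling_arithmetic(self):
        model = bd.LuzzatiModel(
            d=np.array([0.8]), sigma_d2=np.array([5.0]), fc2_mean=np.array([100.0])
        )
        cov = bd.apply_beta(model, 0.5)
        assert cov.d_eff[0] == pytest.approx(0.4)
        # second moment D^2 <Fc^2> + sigma preserved
        assert cov.d_eff[0] ** 2 * 100.0 + cov.sigma_eff[0] == pytest.approx(
            0.8**2 * 100.0 + 5.0
        )

    def test_rejects_nonpositive_beta(self):
        model = bd.LuzzatiModel(
            d=np.array([0.8]), sigma_d2=np.array([5.0]), fc2_mean=np.array([100.0])
        )
        with pytest.raises(ValueError):
            bd.apply_beta(model, 0.0)

    def test_smaller_beta_weaker_combined_fom(self, toy_dataset):
        refl, phases = toy_dataset
        binning = bd.assign_bins(refl, 4)
        refl.f_c = refl.f_true.copy()
        model = bd.refine_luzzati(refl, binning, use_set="all")
        fom_half = bd.combine_phases(phases, refl, bd.apply_beta(model, 0.5)).fom
        fom_full = bd.combine_phases(phases, refl, bd.apply_beta(model, 1.0)).fom
        assert fom_half.mean() < fom_full.mean()


class TestCombinePhases:
    def _cov(self, refl, d_eff_scale=1.0):
        binning = bd.assign_bins(refl, 1)
        model = bd.LuzzatiModel(
            d=np.array([0.7 * d_eff_scale]),
            sigma_d2=np.array([float((refl.fo**2).mean())]),
            fc2_mean=np.array([float((np.abs(refl.f_c) ** 2).mean())]),
        )
        return bd.apply_beta(model, 1.0)

    def test_zero_model_weight_is_identity(self, toy_dataset):
        refl, phases = toy_dataset
        refl.f_c = refl.f_true.copy()
        binning = bd.assign_bins(refl, 1)
        model = bd.LuzzatiModel(
            d=np.array([0.0]),
            sigma_d2=np.array([1.0]),
            fc2_mean=np.array([1.0]),
        )
        comb = bd.combine_phases(phases, refl, bd.apply_beta(model, 1.0))
        np.testing.assert_allclose(comb.hl, phases.hl)
        np.testing.assert_allclose(comb.fom, phases.fom, atol=1e-9)

    def test_model_only_limit_closed_form(self, toy_dataset):
        """Flat experimental distribution: combined m = I1(X)/I0(X) at phi_c."""
        refl, phases = toy_dataset
        refl.f_c = refl.f_true.copy()
        flat = bd.PhaseDistribution(
            hl=np.zeros((refl.n, 4)),
            phase=np.zeros(refl.n),
            fom=np.zeros(refl.n),
        )
        cov = self._cov(refl)
        comb = bd.combine_phases(flat, refl, cov)
        x = 2.0 * cov.d_eff[0] * refl.fo * np.abs(refl.f_c) / cov.sigma_eff[0]
        x = np.minimum(x, 200.0)
        expected_m = special.i1e(x) / special.i0e(x)
        np.testing.assert_allclose(comb.fom, expected_m, atol=1e-6)
        dphi = bd.wrap_phase(comb.phase - np.angle(refl.f_c))
        np.testing.assert_allclose(dphi[x > 1e-3], 0.0, atol=1e-6)

    def test_quadrature_convergence(self, toy_dataset):
        """360-point quadrature agrees with a 10x finer grid to 1e-6."""
        refl, phases = toy_dataset
        refl.f_c = refl.f_true.copy()
        comb = bd.combine_phases(phases, refl, self._cov(refl))
        phase_f, fom_f = bd.hl_centroid_fom(comb.hl, 10 * N_PHASE_POINTS)
        assert np.abs(comb.fom - fom_f).max() < 1e-6
        assert np.abs(bd.wrap_phase(comb.phase - phase_f)).max() < 1e-5

    def test_fom_in_unit_interval(self, toy_dataset):
        refl, phases = toy_dataset
        refl.f_c = refl.f_true.copy()
        comb = bd.combine_phases(phases, refl, self._cov(refl))
        assert np.all((comb.fom >= 0) & (comb.fom <= 1))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=40.0))
    def test_combined_fom_monotone_in_model_weight(self, x):
        """Adding model concentration along the centroid raises the FOM."""
        hl = np.array([[1.5, 0.8, 0.0, 0.0]])
        phase0, fom0 = bd.hl_centroid_fom(hl)
        hl_x = hl + np.array([[x * np.cos(phase0[0]), x * np.sin(phase0[0]), 0, 0]])
        _, fom_x = bd.hl_centroid_fom(hl_x)
        assert fom_x[0] >= fom0[0] - 1e-12


class TestMapCoefficients:
    def test_perfect_agreement_modes_coincide(self, toy_dataset):
        refl, _ = toy_dataset
        refl.f_c = refl.fo * np.exp(1j * refl.phi_true)
        bd.assign_bins(refl, 1)
        comb = bd.PhaseDistribution(
            hl=np.zeros((refl.n, 4)),
            phase=refl.phi_true.copy(),
            fom=np.ones(refl.n),
        )
        model = bd.LuzzatiModel(
            d=np.array([1.0]), sigma_d2=np.array([1.0]), fc2_mean=np.array([1.0])
        )
        cov = bd.apply_beta(model, 1.0)
        cen = bd.map_coefficients(comb, refl, cov, "centroid")
        two = bd.map_coefficients(comb, refl, cov, "2mfodfc")
        expected = refl.fo * np.exp(1j * refl.phi_true)
        np.testing.assert_allclose(cen, expected, rtol=1e-12)
        np.testing.assert_allclose(two, expected, rtol=1e-12)

    def test_zero_fom_zero_centroid_coefficient(self, toy_dataset):
        refl, _ = toy_dataset
        comb = bd.PhaseDistribution(
            hl=np.zeros((refl.n, 4)),
            phase=np.zeros(refl.n),
            fom=np.zeros(refl.n),
        )
        cen = bd.map_coefficients(comb, refl, None, "centroid")
        np.testing.assert_array_equal(cen, 0.0)

    def test_unknown_mode_rejected(self, toy_dataset):
        refl, phases = toy_dataset
        with pytest.raises(ValueError, match="mode"):
            bd.map_coefficients(phases, refl, None, "sharpened")

    def test_2mfodfc_less_correlated_with_experimental_map(self, toy_dataset):
        """The 2mFo-DFc synthesis decorrelates from the input map more than
        the centroid synthesis does."""
        refl, phases = toy_dataset
        shape = bd.default_grid_shape(refl.cell, 2.5)
        exp_coeffs = phases.fom * refl.fo * np.exp(1j * phases.phase)
        exp_map = bd.synthesize_map(refl.hkl, exp_coeffs, refl.cell, shape)
        trace = bd.run_dm(refl, phases, bd.DMOptions(n_cycles=1))
        refl.f_c = trace.final_fc
        binning = bd.assign_bins(refl, 8)
        model = bd.refine_luzzati(refl, binning, use_set="all")
        cov = bd.apply_beta(model, 1.0)
        comb = bd.combine_phases(phases, refl, cov)
        cc = {}
        for mode in ("centroid", "2mfodfc"):
            coeffs = bd.map_coefficients(comb, refl, cov, mode)
            m = bd.synthesize_map(refl.hkl, coeffs, refl.cell, shape)
            cc[mode] = bd.map_correlation(m, exp_map)
        assert cc["2mfodfc"] < cc["centroid"]
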