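"""Interface heights, capillary spectra, stiffness and width scaling."""
import math

import numpy as np
import pytest

import activeblend as ab
from activeblend.capillary import InterfaceExtractionError


@pytest.fixture(scope="module")
def q2_ensemble():
    """400 snapshots of a gamma*beta = 1 capillary ensemble at nB = 16."""
    spec = ab.SpectrumSpec(L=40.0, gamma_beta=1.0, nB=16, n_snapshots=400,
                           seed=7)
    return ab.make_height_ensemble(spec)


class TestFourierAmplitudes:
    def test_flat_field_has_no_modes(self):
        hf = ab.HeightField(np.full((8, 8), 3.2), 20.0, "lower")
        amps = ab.fourier_amplitudes(hf)
        assert np.abs(amps.C2).max() < 1e-20

    def test_single_cosine_mode(self):
        nB, L, a = 16, 40.0, 0.8
        x = (np.arange(nB) + 0.5) / nB * L
        h = a * np.cos(2 * np.pi * x / L)[:, None] * np.ones((1, nB))
        amps = ab.fourier_amplitudes(ab.HeightField(h, L, "lower"))
        sel = (amps.n_idx == 1) & (amps.m_idx == 0)
        assert float(amps.A[sel][0]) == pytest.approx(a, rel=1e-10)
        assert float(amps.B[sel][0]) == pytest.approx(0.0, abs=1e-12)
        assert float(amps.C2[sel][0]) == pytest.approx(a ** 2 / 2.0, rel=1e-10)
        others = ~sel
        assert np.abs(amps.C2[others]).max() < 1e-20

    def test_sine_mode_lands_in_B(self):
        nB, L, a = 8, 16.0, 0.5
        x = (np.arange(nB) + 0.5) / nB * L
        h = a * np.sin(2 * np.pi * x / L)[:, None] * np.ones((1, nB))
        amps = ab.fourier_amplitudes(ab.HeightField(h, L, "lower"))
        sel = (amps.n_idx == 1) & (amps.m_idx == 0)
        assert float(amps.B[sel][0]) == pytest.approx(a, rel=1e-10)
        assert float(amps.A[sel][0]) == pytest.approx(0.0, abs=1e-12)

    def test_parseval_identity(self):
        rng = np.random.default_rng(3)
        h = rng.standard_normal((12, 12))
        amps = ab.fourier_amplitudes(ab.HeightField(h, 24.0, "lower"))
        assert amps.C2.sum() == pytest.approx(h.var(), rel=1e-12)


class TestSpectrum:
    def test_generator_matches_q2_law(self, q2_ensemble):
        spec = ab.spectrum_from_heights(q2_ensemble)
        expected = 2.0 / (40.0 ** 2 * spec.q ** 2)
        dev = np.abs(spec.c2 - expected)
        assert np.all(dev < 4.0 * spec.stderr + 1e-12)

    def test_flat_ensemble_is_silent(self):
        fields = [ab.HeightField(np.zeros((8, 8)), 20.0, "lower")
                  for _ in range(20)]
        spec = ab.spectrum_from_heights(fields)
        assert np.abs(spec.c2).max() < 1e-20

    def test_spectrum_independent_of_block_count(self):
        # same physical spectrum sampled at nB = 16 and 32
        s16 = ab.spectrum_from_heights(ab.make_height_ensemble(
            ab.SpectrumSpec(L=40.0, gamma_beta=1.0, nB=16, n_snapshots=300,
                            seed=1)))
        s32 = ab.spectrum_from_heights(ab.make_height_ensemble(
            ab.SpectrumSpec(L=40.0, gamma_beta=1.0, nB=32, n_snapshots=300,
                            seed=2)))
        shared = np.intersect1d(np.round(s16.q, 9), np.round(s32.q, 9))[:6]
        for q in shared:
            i16 = np.argmin(np.abs(s16.q - q))
            i32 = np.argmin(np.abs(s32.q - q))
            tol = 3.0 * math.hypot(s16.stderr[i16], s32.stderr[i32])
            assert abs(s16.c2[i16] - s32.c2[i32]) < tol


class TestStiffness:
    def test_unit_stiffness_recovery(self, q2_ensemble):
        spec = ab.spectrum_from_heights(q2_ensemble)
        est = ab.stiffness_from_spectrum(spec)
        assert est.physical
        assert est.gamma_beta == pytest.approx(1.0, rel=0.02)

    def test_prefactor_linearity(self):
        spec2 = ab.spectrum_from_heights(ab.make_height_ensemble(
            ab.SpectrumSpec(L=40.0, gamma_beta=2.0, nB=16, n_snapshots=400,
                            seed=9)))
        est = ab.stiffness_from_spectrum(spec2)
        assert est.gamma_beta == pytest.approx(2.0, rel=0.02)

    def test_excluding_slowest_mode_is_benign(self, q2_ensemble):
        spec = ab.spectrum_from_heights(q2_ensemble)
        full = ab.stiffness_from_spectrum(spec)
        trimmed = ab.stiffness_from_spectrum(spec, exclude_slowest=True)
        tol = 3.0 * math.hypot(full.uncertainty, trimmed.uncertainty)
        assert abs(full.gamma_beta - trimmed.gamma_beta) < max(tol, 0.05)

    def test_multiple_nb_averaged(self):
        specs = [ab.spectrum_from_heights(ab.make_height_ensemble(
            ab.SpectrumSpec(L=40.0, gamma_beta=1.0, nB=nb, n_snapshots=200,
                            seed=nb))) for nb in (8, 16)]
        est = ab.stiffness_from_spectrum(specs)
        assert est.nB == (8, 16)
        assert est.gamma_beta == pytest.approx(1.0, rel=0.05)


class TestAutocorrelation:
    def test_ar1_recovery(self):
        series = ab.make_ar1_series(tau_c=5000.0, spacing=1000.0,
                                    length=6000, seed=4)
        ac = ab.autocorrelation_time(series, spacing=1000.0)
        assert ac.c[0] == 1.0
        assert ac.tau_c == pytest.approx(5000.0, rel=0.10)

    def test_white_noise_decorrelates_immediately(self):
        rng = np.random.default_rng(0)
        ac = ab.autocorrelation_time(rng.standard_normal(4000), spacing=100.0)
        assert ac.tau_c <= 100.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ab.autocorrelation_time(np.ones(100), spacing=1.0)


class TestWidthScaling:
    def test_single_mode_width(self):
        nB, L, a = 8, 16.0, 0.6
        x = (np.arange(nB) + 0.5) / nB * L
        h = a * np.cos(2 * np.pi * x / L)[:, None] * np.ones((1, nB))
        hf = ab.HeightField(h, L, "lower")
        w2, _ = ab.width_from_heights([hf, hf])
        assert w2 == pytest.approx(a ** 2 / 2.0, rel=1e-10)

    def test_flat_ensemble_zero_width(self):
        per_nb = {nb: [ab.HeightField(np.zeros((nb, nb)), 20.0, "lower")]
                  for nb in (5, 6, 7, 8, 9)}
        for fields in per_nb.values():
            assert ab.width_from_heights(fields)[0] == 0.0

    def test_q2_ensemble_slope_recovery(self):
        per_nb = {}
        for nb in (5, 6, 7, 8, 9, 12, 16):
            spec = ab.SpectrumSpec(L=40.0, gamma_beta=1.0, nB=nb,
                                   n_snapshots=400, seed=20 + nb)
            per_nb[nb] = ab.make_height_ensemble(spec)
        ws = ab.width_scaling_from_heights(per_nb)
        assert ws.gamma_beta == pytest.approx(1.0, rel=0.10)
        # cross-method consistency on the same synthetic physics
        spec16 = ab.spectrum_from_heights(per_nb[16])
        est = ab.stiffness_from_spectrum(spec16)
        assert ws.gamma_beta == pytest.approx(est.gamma_beta, rel=0.10)

    def test_too_few_blocks_in_range(self):
        per_nb = {nb: [ab.HeightField(np.zeros((nb, nb)), 20.0, "lower")]
                  for nb in (5, 6)}
        with pytest.raises(ValueError):
            ab.width_scaling_from_heights(per_nb)


class TestInterfaceHeights:
    @staticmethod
    def _slab_state(corrugation=(), seed=0):
        spec = ab.TwoPhaseSpec(box=(16.0, 16.0, 40.0), interfaces=(10.0, 30.0),
                               rho_hot_phase=3.0, rho_cold_phase=3.0,
                               corrugation=corrugation)
        return ab.make_two_phase(spec, seed=seed)

    def test_planar_interfaces_recovered(self):
        state = self._slab_state(seed=1)
        lower, upper = ab.interface_heights(state, nB=4, n_slabs=80)
        assert np.abs(lower.heights - 10.0).max() < 1.0
        assert np.abs(upper.heights - 30.0).max() < 1.0

    def test_imposed_corrugation_recovered(self):
        amp = 0.8
        a10 = []
        for seed in range(6):
            state = self._slab_state(corrugation=((1, 0, amp),), seed=10 + seed)
            lower, _ = ab.interface_heights(state, nB=8)
            m = ab.fourier_amplitudes(lower)
            a10.append(float(m.A[(m.n_idx == 1) & (m.m_idx == 0)][0]))
        assert np.mean(a10) == pytest.approx(amp, abs=0.25)

    def test_mixed_state_rejected(self):
        rng = np.random.default_rng(2)
        n = 4000
        state = ab.SystemState(
            positions=rng.random((n, 3)) * [16.0, 16.0, 40.0],
            velocities=np.zeros((n, 3)),
            species=rng.integers(0, 2, n).astype(np.int8),
            chain_id=np.arange(n, dtype=np.int32),
            box=ab.SimulationBox((16.0, 16.0, 40.0)))
        with pytest.raises(InterfaceExtractionError):
            ab.interface_heights(state, nB=4)


class TestChiStarFromStiffness:
    def test_exact_root(self):
        chi = np.array([0.7, 1.0, 1.5, 2.0])
        gb = 1.2 * (np.sqrt(chi) - math.sqrt(0.54))
        chi_star, unc = ab.chi_star_from_stiffness(chi, gb)
        assert chi_star == pytest.approx(0.54, abs=1e-10)

    def test_two_points_exact_line(self):
        chi = np.array([1.0, 2.0])
        gb = 0.8 * (np.sqrt(chi) - math.sqrt(0.5))
        chi_star, _ = ab.chi_star_from_stiffness(chi, gb)
        assert chi_star == pytest.approx(0.5, abs=1e-10)

    def test_noisy_coverage(self):
        rng = np.random.default_rng(6)
        chi = np.array([0.7, 0.9, 1.2, 1.6, 2.0])
        estimates = []
        for _ in range(50):
            gb = 1.2 * (np.sqrt(chi) - math.sqrt(0.54))
            gb = gb + rng.normal(0, 0.02, chi.size)
            estimates.append(ab.chi_star_from_stiffness(
                chi, gb, errors=np.full(chi.size, 0.02))[0])
        assert np.mean(estimates) == pytest.approx(0.54, abs=0.05)

    def test_negative_trend_rejected(self):
        chi = np.array([0.7, 1.0, 1.5])
        with pytest.raises(ValueError):
            ab.chi_star_from_stiffness(chi, np.array([1.0, 0.8, 0.5]))


class TestWidthChiScaling:
    def test_constant_product_for_scaling_widths(self):
        entries = []
        k = 1.3
        for chi in (0.8, 1.2, 1.8):
            w2 = np.full(3, (k / math.sqrt(chi)) ** 2)
            ws = ab.WidthScaling(nB=np.array([5, 7, 9]), w2=w2,
                                 w2_err=np.zeros(3), gamma_beta=1.0,
                                 gamma_beta_err=0.0, c=1.0, fit_range=(5, 9))
            entries.append((chi, ws))
        table = ab.width_chi_scaling(entries)
        np.testing.assert_allclose(table["w_sqrt_chi"], k, rtol=1e-12)

    def test_noisy_product_is_trendless(self):
        rng = np.random.default_rng(9)
        chis = np.linspace(0.6, 2.0, 8)
        entries = []
        for chi in chis:
            w = 1.3 / math.sqrt(chi) * (1 + rng.normal(0, 0.10))
            ws = ab.WidthScaling(nB=np.array([5]), w2=np.array([w ** 2]),
                                 w2_err=np.zeros(1), gamma_beta=1.0,
                                 gamma_beta_err=0.0, c=1.0, fit_range=(5, 9))
            entries.append((chi, ws))
        table = ab.width_chi_scaling(entries)
        slope = np.polyfit(table["chi"], table["w_sqrt_chi"], 1)[0]
        se = (np.std(table["w_sqrt_chi"], ddof=1)
              / np.std(table["chi"]) / math.sqrt(len(table)))
        assert abs(slope) < 3 * se

    def test_single_chi_passthrough(self):
        ws = ab.WidthScaling(nB=np.array([5]), w2=np.array([1.0]),
                             w2_err=np.zeros(1), gamma_beta=1.0,
                             gamma_beta_err=0.0, c=1.0, fit_range=(5, 9))
        table = ab.width_chi_scaling([(1.0, ws)])
        assert len(table) == 1 and table.loc[0, "w"] == 1.0
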