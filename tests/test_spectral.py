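import numpy as np
import pytest

from pausim import beamform, core, scene, spectral
from pausim.beamform import PAImage, SpectroStack

from helpers import background_scene, model_stack


@pytest.fixture(scope="module")
def geometry():
    return core.build_probe_geometry()


@pytest.fixture(scope="module")
def grid():
    return core.ImageGrid.centered(12.8e-3, 12e-3, 0.2e-3, z0=2e-3)


@pytest.fixture(scope="module")
def tube_mask(grid):
    X, Z = grid.mesh()
    return (X - 0.0) ** 2 + (Z - 10e-3) ** 2 <= (0.7e-3) ** 2


def make_model_stack(geometry, grid, tube_mask, wavelengths=(715.0, 755.0, 795.0, 835.0, 875.0),
                     chromophore="ink", mu_a_scale=0.3, rng=None, amp_noise=0.0):
    mu_a_bg, mu_s, mu_eff = background_scene(mu_a_scale)
    spec = scene.chromophore_spectrum(chromophore, np.arange(650.0, 951.0, 5.0))

    def mu_a_fn(w):
        return mu_a_bg(w) + tube_mask * (2.0 * float(spec(w)) / spec.values.max())

    stack = model_stack(geometry, grid, wavelengths, mu_a_fn, mu_eff, mu_s,
                        rng=rng, amp_noise=amp_noise)
    truth = {w: mu_eff(w) for w in wavelengths}
    return stack, truth


class TestNoiseFloor:
    def test_zero_noise_zero_floor(self):
        grid = core.ImageGrid.unit((32, 32))
        img = PAImage(np.zeros(grid.shape, complex), grid, 700.0, laser_energy=0.0)
        assert np.all(spectral.estimate_noise_floor(img) == 0)

    def test_nonzero_energy_frame_rejected(self):
        grid = core.ImageGrid.unit((8, 8))
        img = PAImage(np.zeros(grid.shape, complex), grid, 700.0, laser_energy=1.0)
        with pytest.raises(ValueError, match="laser-off"):
            spectral.estimate_noise_floor(img)

    def test_uniform_noise_gives_uniform_positive_floor(self):
        rng = np.random.default_rng(0)
        grid = core.ImageGrid.unit((128, 128))
        field = rng.standard_normal(grid.shape) + 1j * rng.standard_normal(grid.shape)
        img = PAImage(field, grid, 700.0, laser_energy=0.0)
        floor = spectral.estimate_noise_floor(img)
        assert np.all(floor > 0)
        assert floor.std() / floor.mean() < 0.3

    def test_subtracting_floor_centers_noise_region(self):
        rng = np.random.default_rng(1)
        grid = core.ImageGrid.unit((128, 128))
        field = rng.standard_normal(grid.shape) + 1j * rng.standard_normal(grid.shape)
        img = PAImage(field, grid, 700.0, laser_energy=0.0)
        floor = spectral.estimate_noise_floor(img)
        residual = np.abs(field) - floor
        assert abs(residual.mean()) < 0.05 * np.abs(field).mean()


class TestEstimateMuEff:
    def test_noiseless_recovery_within_grid_step(self, geometry, grid, tube_mask):
        stack, truth = make_model_stack(geometry, grid, tube_mask)
        search = spectral.SearchGrid.default(mu_eff_step=0.05)
        for w in stack.wavelengths:
            fit = spectral.estimate_mu_eff(stack, geometry, w, mask=tube_mask, search=search)
            assert fit.mu_eff_hat == pytest.approx(truth[w], abs=0.05)

    def test_zero_attenuation_hits_lower_bound(self, geometry, grid, tube_mask):
        mu_a_bg, mu_s, _ = background_scene(0.0)
        stack = model_stack(geometry, grid, [800.0],
                            lambda w: np.full(grid.shape, 0.1) + tube_mask * 2.0,
                            lambda w: 0.0, mu_s)
        fit = spectral.estimate_mu_eff(stack, geometry, 800.0, mask=tube_mask,
                                       use_beer_bracket=False)
        assert fit.mu_eff_hat == 0.0

    def test_monte_carlo_recovery_under_10pct_noise(self, geometry, grid, tube_mask):
        # 10% multiplicative amplitude noise: >= 90% of seeds within 10%
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            stack, truth = make_model_stack(geometry, grid, tube_mask,
                                            wavelengths=(795.0,), rng=rng, amp_noise=0.10)
            fit = spectral.estimate_mu_eff(stack, geometry, 795.0, mask=tube_mask)
            if abs(fit.mu_eff_hat - truth[795.0]) <= 0.10 * truth[795.0]:
                hits += 1
        assert hits >= int(0.9 * n_seeds)

    def test_empty_mask_rejected(self, geometry, grid):
        stack, _ = make_model_stack(geometry, grid, np.zeros(grid.shape, bool) | False)
        with pytest.raises(ValueError, match="no pixels"):
            spectral.estimate_mu_eff(stack, geometry, stack.wavelengths[0],
                                     mask=np.zeros(grid.shape, bool))

    def test_mask_from_noise_floor(self, geometry, grid, tube_mask):
        stack, truth = make_model_stack(geometry, grid, tube_mask)
        w = stack.wavelengths[2]
        floor = np.full(grid.shape, 0.25 * stack.compound_envelope(w).max())
        fit = spectral.estimate_mu_eff(stack, geometry, w, noise_floor=floor)
        assert fit.mu_eff_hat == pytest.approx(truth[w], abs=0.1)

    def test_beer_initial_close_to_truth(self, geometry, grid, tube_mask):
        stack, truth = make_model_stack(geometry, grid, tube_mask)
        w = stack.wavelengths[0]
        fit = spectral.estimate_mu_eff(stack, geometry, w, mask=tube_mask)
        assert fit.mu_eff_initial == pytest.approx(truth[w], rel=0.1)

    def test_mu_eff_within_search_bounds(self, geometry, grid, tube_mask):
        stack, _ = make_model_stack(geometry, grid, tube_mask)
        search = spectral.SearchGrid.default(mu_eff_max=5.0)
        fit = spectral.estimate_mu_eff(stack, geometry, stack.wavelengths[0],
                                       mask=tube_mask, search=search)
        assert 0.0 <= fit.mu_eff_hat <= 5.0
        assert fit.residual >= 0.0


class TestCompensation:
    def test_uniform_fluence_changes_nothing_but_scale(self, geometry, grid, tube_mask):
        # near-zero attenuation: compensation must be a near-global constant
        mu_a_bg, mu_s, _ = background_scene(0.0)
        stack = model_stack(geometry, grid, [750.0, 800.0, 850.0],
                            lambda w: np.full(grid.shape, 0.1) + tube_mask * 2.0,
                            lambda w: 1e-6, mu_s)
        fits = {w: spectral.estimate_mu_eff(stack, geometry, w, mask=tube_mask)
                for w in stack.wavelengths}
        out = spectral.compensate_fluence(stack, fits, geometry)
        for w in stack.wavelengths:
            ratio = out.compound_envelope(w)[tube_mask] / stack.compound_envelope(w)[tube_mask]
            assert ratio.std() / ratio.mean() < 0.25

    def test_ink_slope_sign_inversion_corrected(self, geometry, grid, tube_mask):
        # deep sloped-spectrum target under wavelength-dependent attenuation:
        # raw spectrum slope flips sign, compensation restores it
        stack, _ = make_model_stack(geometry, grid, tube_mask, chromophore="ink",
                                    mu_a_scale=0.3)
        fits = {w: spectral.estimate_mu_eff(stack, geometry, w, mask=tube_mask)
                for w in stack.wavelengths}
        out = spectral.compensate_fluence(stack, fits, geometry)
        wl = np.array(stack.wavelengths)

        def tube_slope(s):
            sp = spectral.pixel_spectra(s)
            return np.polyfit(wl, sp.area_normalized()[:, tube_mask].mean(axis=1), 1)[0]

        assert tube_slope(stack) > 0  # inverted by fluence
        assert tube_slope(out) < 0  # true decreasing shape restored

    def test_compensated_gnr_spectrum_better_than_raw(self, geometry, grid, tube_mask):
        stack, _ = make_model_stack(geometry, grid, tube_mask, chromophore="gnr",
                                    mu_a_scale=0.3)
        fits = {w: spectral.estimate_mu_eff(stack, geometry, w, mask=tube_mask)
                for w in stack.wavelengths}
        out = spectral.compensate_fluence(stack, fits, geometry)
        wl = np.array(stack.wavelengths)
        spec = scene.chromophore_spectrum("gnr", wl)
        mu_a_bg, _, _ = background_scene(0.3)
        truth = np.array([2.0 * v / scene.chromophore_spectrum("gnr", np.arange(650., 951., 5.)).values.max()
                          + mu_a_bg(w) for w, v in zip(wl, spec.values)])

        def ncc(s):
            sp = spectral.pixel_spectra(s)
            return spectral.spectral_ncc(sp.area_normalized()[:, tube_mask].mean(axis=1), truth)

        assert ncc(out) > ncc(stack)
        assert ncc(out) > 0.95

    def test_invalid_rescale_rejected(self, geometry, grid, tube_mask):
        stack, _ = make_model_stack(geometry, grid, tube_mask, wavelengths=(800.0,))
        fits = {800.0: spectral.estimate_mu_eff(stack, geometry, 800.0, mask=tube_mask)}
        with pytest.raises(ValueError, match="rescale"):
            spectral.compensate_fluence(stack, fits, geometry, rescale="nope")


class TestPixelSpectra:
    def test_area_normalized_sums_to_one(self, geometry, grid, tube_mask):
        stack, _ = make_model_stack(geometry, grid, tube_mask)
        sp = spectral.pixel_spectra(stack)
        w = sp.trapezoid_weights()
        total = np.tensordot(w, sp.area_normalized(), axes=(0, 0))
        np.testing.assert_allclose(total[tube_mask], 1.0, rtol=1e-9)

    def test_noise_subtraction_floors_at_zero(self):
        grid = core.ImageGrid.unit((8, 8))
        stack = SpectroStack(grid=grid, wavelengths=(700.0, 750.0), motion_corrected=True)
        for w in stack.wavelengths:
            stack.subimages[w] = np.ones((1, 8, 8), complex)
            stack.compound[w] = np.full((8, 8), 0.5 + 0j)
            stack.laser_energy[w] = 1.0
        sp = spectral.pixel_spectra(stack, noise_floor=np.ones(grid.shape))
        assert np.all(sp.amplitudes == 0)
        assert "noise_subtracted" in sp.variant


class TestSigmaLambda:
    grid = core.ImageGrid.unit((16, 16))

    def stack_with(self, fields, laser_off=()):
        wavelengths = tuple(700.0 + 20 * k for k in range(len(fields)))
        s = SpectroStack(grid=self.grid, wavelengths=wavelengths,
                         laser_off_wavelengths=laser_off, motion_corrected=True)
        for w, f in zip(wavelengths, fields):
            s.subimages[w] = f[None]
            s.compound[w] = f
            s.laser_energy[w] = 0.0 if w in laser_off else 1.0
        return s

    def test_identical_frames_scale_by_count(self):
        rng = np.random.default_rng(0)
        f = rng.standard_normal(self.grid.shape) + 1j * rng.standard_normal(self.grid.shape)
        out = spectral.sigma_lambda_compound(self.stack_with([f] * 9))
        np.testing.assert_allclose(out.envelope, 9.0 * np.abs(f))

    def test_single_wavelength_identity(self):
        rng = np.random.default_rng(1)
        f = rng.standard_normal(self.grid.shape) + 0j
        out = spectral.sigma_lambda_compound(self.stack_with([f]))
        np.testing.assert_allclose(out.envelope, np.abs(f))

    def test_laser_off_excluded(self):
        f = np.ones(self.grid.shape, complex)
        stack = self.stack_with([100 * f, f, f], laser_off=(700.0,))
        out = spectral.sigma_lambda_compound(stack)
        np.testing.assert_allclose(out.envelope, 2.0)

    def test_uncorrected_stack_warns(self):
        f = np.ones(self.grid.shape, complex)
        stack = self.stack_with([f])
        stack.motion_corrected = False
        with pytest.warns(UserWarning, match="motion"):
            spectral.sigma_lambda_compound(stack)

    def test_snr_gain_at_least_9db_for_9_wavelengths(self):
        # identical signal + independent noise in each of 9 frames
        rng = np.random.default_rng(2)
        grid = core.ImageGrid.unit((100, 100))
        signal = 40.0
        fields = [signal + rng.standard_normal(grid.shape) + 0j for _ in range(9)]
        s = SpectroStack(grid=grid, wavelengths=tuple(700.0 + 20 * k for k in range(9)),
                         motion_corrected=True)
        for w, f in zip(s.wavelengths, fields):
            s.subimages[w] = f[None]
            s.compound[w] = f
            s.laser_energy[w] = 1.0
        out = spectral.sigma_lambda_compound(s)
        snr1 = signal / np.abs(fields[0]).std()
        snr9 = 9 * signal / out.envelope.std()
        assert 20 * np.log10(snr9 / snr1) >= 9.0


class TestComponentWeighted:
    wavelengths = tuple(715.0 + 20 * k for k in range(9))

    def spectra_from(self, cube):
        return spectral.PixelSpectrum(np.asarray(self.wavelengths), cube, "compensated")

    def test_matching_spectrum_full_weight(self):
        ref = scene.chromophore_spectrum("gnr", np.arange(650.0, 951.0, 5.0))
        vals = ref(np.asarray(self.wavelengths))
        cube = np.tile(vals[:, None, None], (1, 4, 4))
        sig = PAImage(np.ones((4, 4), complex), core.ImageGrid.unit((4, 4)))
        out = spectral.component_weighted(self.spectra_from(cube), sig, ref)
        np.testing.assert_allclose(out.ncc_map, 1.0, atol=1e-9)
        np.testing.assert_allclose(out.image, 1.0, atol=1e-9)

    def test_anticorrelated_spectrum_zero_weight(self):
        ref = scene.chromophore_spectrum("gnr", np.arange(650.0, 951.0, 5.0))
        vals = ref(np.asarray(self.wavelengths))
        flipped = vals.mean() - (vals - vals.mean())
        cube = np.tile(flipped[:, None, None], (1, 4, 4))
        sig = PAImage(np.ones((4, 4), complex), core.ImageGrid.unit((4, 4)))
        out = spectral.component_weighted(self.spectra_from(cube), sig, ref)
        np.testing.assert_allclose(out.ncc_map, -1.0, atol=1e-9)
        np.testing.assert_allclose(out.image, 0.0, atol=1e-12)

    def test_ncc_and_weight_bounds(self):
        rng = np.random.default_rng(0)
        ref = scene.chromophore_spectrum("ink", np.arange(650.0, 951.0, 5.0))
        cube = np.abs(rng.standard_normal((9, 8, 8)))
        sig = PAImage(np.ones((8, 8), complex), core.ImageGrid.unit((8, 8)))
        out = spectral.component_weighted(self.spectra_from(cube), sig, ref)
        assert np.all((out.ncc_map >= -1) & (out.ncc_map <= 1))
        assert np.all((out.weight >= 0) & (out.weight <= 1))

    def test_reference_must_cover_band(self):
        ref = scene.Spectrum(np.array([700.0, 800.0]), np.array([1.0, 1.0]))
        cube = np.ones((9, 2, 2))
        sig = PAImage(np.ones((2, 2), complex), core.ImageGrid.unit((2, 2)))
        with pytest.raises(ValueError, match="cover"):
            spectral.component_weighted(self.spectra_from(cube), sig, ref)

    def test_display_mask_threshold(self):
        ref = scene.chromophore_spectrum("flat", np.arange(650.0, 951.0, 5.0))
        cube = np.ones((9, 2, 2))
        field = np.array([[1.0, 0.1], [0.05, 1.0]]).astype(complex)
        sig = PAImage(field, core.ImageGrid.unit((2, 2)))
        out = spectral.component_weighted(self.spectra_from(cube), sig, ref,
                                          display_threshold_db=-15.0)
        np.testing.assert_array_equal(out.display_mask,
                                      np.abs(field) > 10 ** (-15 / 20))

    def test_two_target_gnr_weighting_suppresses_flat_target(self, geometry):
        # resonant target passes, spectrally flat ("needle-like") target is
        # suppressed by >= 20 dB relative to its wavelength-compounded level.
        # The background attenuates identically at all wavelengths so the
        # needle's spectrum stays exactly flat after compensation.
        grid = core.ImageGrid.centered(12.8e-3, 10e-3, 0.2e-3, z0=2e-3)
        X, Z = grid.mesh()
        gnr_mask = (X + 3e-3) ** 2 + (Z - 6e-3) ** 2 <= (0.7e-3) ** 2
        flat_mask = (X - 3e-3) ** 2 + (Z - 6e-3) ** 2 <= (0.7e-3) ** 2
        mu_s = lambda w: 10.0
        mu_eff = lambda w: 2.0  # sqrt(3 * (4/30) * 10), independent of wavelength
        gnr = scene.chromophore_spectrum("gnr", np.arange(650.0, 951.0, 5.0))

        def mu_a_fn(w):
            return (4.0 / 30.0 + gnr_mask * 2.0 * float(gnr(w)) / gnr.values.max()
                    + flat_mask * 1.5)

        stack = model_stack(geometry, grid, self.wavelengths, mu_a_fn, mu_eff, mu_s)
        fits = {w: spectral.estimate_mu_eff(stack, geometry, w, mask=gnr_mask | flat_mask)
                for w in stack.wavelengths}
        comp = spectral.compensate_fluence(stack, fits, geometry)
        sig = spectral.sigma_lambda_compound(comp)
        out = spectral.component_weighted(spectral.pixel_spectra(comp), sig, gnr)
        flat_db = 20 * np.log10(out.image[flat_mask].max() / sig.envelope[flat_mask].max())
        assert flat_db <= -20.0
        gnr_db = 20 * np.log10(out.image[gnr_mask].max() / sig.envelope[gnr_mask].max())
        assert gnr_db > -3.0


def test_spectral_ncc_basics():
    assert spectral.spectral_ncc([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
    assert spectral.spectral_ncc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
    assert spectral.spectral_ncc([1, 1, 1], [1, 2, 3]) == 0.0
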