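"""Orientation histograms, von Mises fitting, depth profiles, nuclei morphometry."""

import numpy as np
import pytest
from scipy import stats as sps
from skimage import draw as skdraw
from skimage.transform import rotate

from valvescale import microstructure as ms
from valvescale import synthetic


def _const_truth(mu, kappa, seed=0):
    t = synthetic.default_truth(seed=seed)
    t.vm_mu_deg = lambda z: np.full_like(np.asarray(z, float), float(mu))
    t.vm_kappa = lambda z: np.full_like(np.asarray(z, float), float(kappa))
    return t


class TestOrientationHistogram:
    def test_parallel_lines_mode(self):
        img = np.zeros((256, 256))
        img[:, ::8] = 1.0  # vertical stripes = 90 deg fibers
        d, c, _ = ms.orientation_histogram(img, normalize_input=False)
        assert abs(c[np.argmax(d)] - 90.0) <= 1.0

    def test_constant_image_uniform(self):
        d, c, flags = ms.orientation_histogram(np.ones((64, 64)))
        assert "zero_coherency_uniform" in flags
        assert np.allclose(d, 1 / 180.0)
        assert np.trapezoid(d, c) == pytest.approx(1.0, rel=1e-2)

    def test_synthetic_fiber_image_recovers_mean_angle(self):
        t = _const_truth(60.0, 5.0, seed=3)
        imgs = synthetic.gen_fiber_stack(t, n_slices=1, as_images=True,
                                         fibers_drawn=120, image_size=384)
        d, c, _ = ms.orientation_histogram(imgs[0])
        mu, _, _ = ms.fit_von_mises(d, c)
        assert abs(mu - 60.0) <= 3.0

    def test_rotation_equivariance(self):
        t = _const_truth(40.0, 8.0, seed=5)
        img = synthetic.gen_fiber_stack(t, n_slices=1, as_images=True,
                                        fibers_drawn=100, image_size=384)[0]
        d0, c, _ = ms.orientation_histogram(img)
        mu0, _, _ = ms.fit_von_mises(d0, c)
        # skimage.rotate(+25) is CCW in the y-up convention used for angles
        d1, _, _ = ms.orientation_histogram(rotate(img, 25.0))
        mu1, _, _ = ms.fit_von_mises(d1, c)
        circ_diff = ((mu1 - mu0) - 25.0 + 90.0) % 180.0 - 90.0
        assert abs(circ_diff) <= 2.0


class TestFitVonMises:
    def test_uniform_histogram_zero_kappa(self):
        c = np.arange(0.5, 180, 1.0)
        mu, kappa, flags = ms.fit_von_mises(np.full(c.size, 1 / 180), c)
        assert kappa == pytest.approx(0.0, abs=1e-6)
        assert "mu_undefined" in flags

    def test_symmetric_histogram_gives_exact_mu(self):
        c = np.arange(0.5, 180, 1.0)
        d = np.exp(-0.5 * ((c - 90) / 15) ** 2)
        d /= np.trapezoid(d, c)
        mu, _, _ = ms.fit_von_mises(d, c)
        assert mu == pytest.approx(90.0, abs=1e-9)

    def test_single_bin_caps_kappa(self):
        c = np.arange(0.5, 180, 1.0)
        d = np.zeros(c.size)
        d[90] = 1.0
        mu, kappa, flags = ms.fit_von_mises(d, c)
        assert kappa == ms.KAPPA_CAP
        assert "kappa_capped_single_bin" in flags

    def test_sample_mle_matches_scipy_oracle(self, rng):
        # independent oracle: scipy's von Mises MLE on the doubled angles
        angles = np.mod(np.degrees(
            sps.vonmises.rvs(3.0, loc=np.radians(100), size=10_000, random_state=rng)
        ) / 2.0, 180.0)
        mu, kappa = ms.fit_von_mises_samples(angles)
        k_sp, loc_sp, _ = sps.vonmises.fit(np.radians(2 * angles), fscale=1)
        assert kappa == pytest.approx(k_sp, rel=0.02)
        assert abs(mu - np.mod(np.degrees(loc_sp) / 2, 180.0)) < 1.0

    def test_histogram_fit_recovers_sampled_parameters(self):
        t = _const_truth(90.0, 3.0, seed=2)
        prof = synthetic.gen_fiber_stack(t, n_slices=2, n_fibers_per_slice=10_000)
        prof.fit_all()
        assert np.all(np.abs(prof.vm_mu - 90.0) < 3.0)
        assert np.all(np.abs(prof.vm_kappa - 3.0) / 3.0 < 0.10)

    def test_kappa_monotone_in_dispersion(self):
        kappas = [0.5, 1, 2, 4, 8]
        fitted = []
        for i, k in enumerate(kappas):
            t = _const_truth(90.0, k, seed=20 + i)
            prof = synthetic.gen_fiber_stack(t, n_slices=1, n_fibers_per_slice=10_000)
            prof.fit_all()
            fitted.append(prof.vm_kappa[0])
        assert np.all(np.diff(fitted) > 0)


class TestAssembleDepthProfile:
    def test_identical_stacks_average_to_one(self, truth):
        prof = synthetic.gen_fiber_stack(truth, n_slices=10, n_fibers_per_slice=3000)
        out = ms.assemble_depth_profile([prof.histograms] * 3, prof.bin_centers_deg,
                                        n_depth=10)
        direct = ms.assemble_depth_profile([prof.histograms], prof.bin_centers_deg,
                                           n_depth=10)
        assert np.allclose(out.histograms, direct.histograms)

    def test_unit_integral_preserved(self, truth):
        prof = synthetic.gen_fiber_stack(truth, n_slices=8, n_fibers_per_slice=2000)
        out = ms.assemble_depth_profile([prof.histograms], prof.bin_centers_deg)
        integrals = (out.histograms * np.gradient(out.bin_centers_deg)).sum(axis=1)
        assert np.allclose(integrals, 1.0, atol=1e-6)

    def test_different_slice_counts_interpolate_same_field(self):
        # two stacks sampling the same smooth kappa(z) field at different depths
        c = np.arange(0.5, 180, 1.0)

        def field(z):
            d = sps.vonmises.pdf(np.radians(2 * c), 2 + 3 * z, loc=np.radians(180))
            d = d * 2 * np.pi / 180  # doubled-angle pdf mapped to degrees on [0,180)
            return d / np.trapezoid(d, c)

        st1 = np.stack([field(z) for z in np.linspace(0, 1, 11)])
        st2 = np.stack([field(z) for z in np.linspace(0, 1, 21)])
        out = ms.assemble_depth_profile([st1, st2], c, n_depth=11)
        expect = np.stack([field(z) for z in np.linspace(0, 1, 11)])
        assert np.max(np.abs(out.histograms - expect)) < 0.01

    def test_single_slice_stack_rejected(self):
        c = np.arange(0.5, 180, 1.0)
        with pytest.raises(ValueError):
            ms.assemble_depth_profile([np.ones((1, c.size)) / 180], c)


class TestDepthRegionSummary:
    def _profile_with_kappa(self, kappa_values):
        n = len(kappa_values)
        c = np.arange(0.5, 180, 1.0)
        prof = ms.OrientationDepthProfile(
            depth_fraction=np.linspace(0, 1, n),
            bin_centers_deg=c,
            histograms=np.ones((n, c.size)) / 180.0,
        )
        prof.vm_kappa = np.asarray(kappa_values, float)
        prof.vm_mu = np.full(n, 90.0)
        return prof

    def test_constant_kappa(self):
        out = ms.depth_region_summary(self._profile_with_kappa([4.0] * 30))
        assert all(v == pytest.approx(4.0) for v in out.values())

    def test_linear_kappa_region_means(self):
        n = 300
        out = ms.depth_region_summary(self._profile_with_kappa(np.linspace(0, 1, n)))
        grid_err = 1.0 / n
        assert out["D1"] == pytest.approx(1 / 6, abs=3 * grid_err)
        assert out["D2"] == pytest.approx(1 / 2, abs=3 * grid_err)
        assert out["D3"] == pytest.approx(5 / 6, abs=3 * grid_err)

    def test_planted_step_recovered(self):
        z = np.linspace(0, 1, 30)
        k = np.where(z < 1 / 3, 8.0, 2.0)
        out = ms.depth_region_summary(self._profile_with_kappa(k))
        assert out["D1"] == pytest.approx(8.0)
        assert out["D2"] == pytest.approx(2.0)
        assert out["D3"] == pytest.approx(2.0)


class TestNucleiMorphometry:
    def test_circle_is_round(self):
        img = np.zeros((100, 100))
        rr, cc = skdraw.disk((50, 50), 20)
        img[rr, cc] = 1
        st = ms.nuclei_morphometry(img, threshold=0.5)
        assert st.nar[0] == pytest.approx(1.0, abs=0.01)
        assert st.circularity[0] == pytest.approx(1.0, abs=0.05)

    def test_ellipse_axes_and_orientation(self):
        img = np.zeros((200, 200))
        rr, cc = skdraw.ellipse(100, 100, 10, 20, rotation=np.radians(30))
        img[rr, cc] = 1
        st = ms.nuclei_morphometry(img, threshold=0.5)
        assert st.nar[0] == pytest.approx(2.0, abs=0.05)
        assert st.orientation_deg[0] == pytest.approx(30.0, abs=2.0)

    def test_generated_field_normal_fit_recovery(self, truth):
        img, table = synthetic.gen_nuclei_field(truth, n_nuclei=500, image_size=2048)
        st = ms.nuclei_morphometry(img, threshold=0.5)
        assert st.nar.size == 500
        assert abs(st.nar_fit[0] - truth.nar_mean) < 0.05
        assert abs(st.nar_fit[1] - truth.nar_sd) / truth.nar_sd < 0.20

    def test_circularity_bounded(self, truth):
        img, _ = synthetic.gen_nuclei_field(truth, n_nuclei=100, image_size=1024)
        st = ms.nuclei_morphometry(img, threshold=0.5)
        assert np.all(st.circularity <= 1.05)
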