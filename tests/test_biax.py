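"""Biaxial kinematics, membrane tension, downstroke extraction, J-curve metrics."""

import numpy as np
import pytest

from valvescale import biax, synthetic
from valvescale.biax import TensionStretchCurve
from valvescale.synthetic import CurveLaw


def _lstsq_affine_oracle(ref, defm):
    """Independent full-design least-squares affine fit: y = F x + t."""
    n = ref.shape[0]
    A = np.zeros((2 * n, 6))
    b = np.zeros(2 * n)
    for i in range(n):
        A[2 * i, 0:2] = ref[i]
        A[2 * i, 4] = 1.0
        A[2 * i + 1, 2:4] = ref[i]
        A[2 * i + 1, 5] = 1.0
        b[2 * i] = defm[i, 0]
        b[2 * i + 1] = defm[i, 1]
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:4].reshape(2, 2)


class TestEstimateDeformation:
    def test_identity_when_undeformed(self):
        ref = synthetic._reference_markers()
        st = biax.estimate_deformation(ref, ref)
        assert np.allclose(st.F, np.eye(2), atol=1e-14)
        assert st.lambda_circ == pytest.approx(1.0)
        assert st.residual_rms_mm == pytest.approx(0.0, abs=1e-14)

    def test_uniform_scaling_about_centroid(self):
        ref = synthetic._reference_markers()
        cen = ref.mean(axis=0)
        st = biax.estimate_deformation(ref, (ref - cen) * 1.2 + cen)
        assert np.allclose(st.F, 1.2 * np.eye(2), atol=1e-12)
        assert st.residual_rms_mm < 1e-12

    def test_matches_independent_lstsq_oracle(self, rng):
        for _ in range(200):
            ref = rng.uniform(-3, 3, (4, 2))
            G = (ref - ref.mean(0)).T @ (ref - ref.mean(0))
            if np.linalg.det(G) < 1e-2:
                continue
            defm = rng.uniform(-4, 4, (4, 2))
            st = biax.estimate_deformation(ref, defm)
            F_oracle = _lstsq_affine_oracle(ref, defm)
            assert np.allclose(st.F, F_oracle, atol=1e-10)

    def test_noisy_marker_recovery_within_one_percent(self, truth):
        F_true = np.array([[1.25, 0.03], [0.01, 1.10]])
        t = synthetic.default_truth(seed=11, prescribed_F=F_true)
        rec = synthetic.gen_biax_record(t, noise_sd_mm=0.01, path="ramp")
        st = biax.estimate_deformation(rec.reference_markers, rec.markers[-1])
        assert np.all(np.abs(st.F - F_true) <= 0.01 * np.max(np.abs(F_true)))
        oracle = _lstsq_affine_oracle(rec.reference_markers, rec.markers[-1])
        assert np.allclose(st.F, oracle, atol=1e-10)

    def test_affine_consistency(self, rng):
        # applying A to all deformed markers maps the estimate F -> A F
        ref = synthetic._reference_markers()
        F = np.array([[1.2, 0.05], [0.02, 1.3]])
        defm = (ref - ref.mean(0)) @ F.T + ref.mean(0)
        A = np.array([[0.9, 0.2], [-0.1, 1.1]])
        st = biax.estimate_deformation(ref, defm @ A.T)
        assert np.allclose(st.F, A @ F, atol=1e-12)

    def test_rigid_motion_leaves_stretches_unchanged(self, rng):
        # translating both configurations changes nothing; rotating both
        # (device axes included) preserves the principal stretches
        ref = synthetic._reference_markers()
        F = np.diag([1.15, 1.3])
        defm = (ref - ref.mean(0)) @ F.T + ref.mean(0)
        st0 = biax.estimate_deformation(ref, defm)
        st_t = biax.estimate_deformation(ref + [3, -2], defm + [3, -2])
        assert st_t.lambda_circ == pytest.approx(st0.lambda_circ, abs=1e-12)
        assert st_t.lambda_rad == pytest.approx(st0.lambda_rad, abs=1e-12)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        st_r = biax.estimate_deformation(ref @ R.T + [3, -2], defm @ R.T + [3, -2])
        assert np.allclose(
            np.sort(np.linalg.eigvalsh(st_r.C)), np.sort(np.linalg.eigvalsh(st0.C)),
            atol=1e-12,
        )

    def test_collinear_reference_rejected(self):
        ref = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]])
        with pytest.raises(ValueError, match="collinear"):
            biax.estimate_deformation(ref, ref)


class TestMembraneTension:
    def test_unit_arithmetic(self):
        assert biax.membrane_tension(300.0, 10.0) == pytest.approx(30.0)
        assert biax.membrane_tension(0.0, 5.0) == 0.0

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            biax.membrane_tension(10.0, 0.0)


class TestExtractDownstroke:
    def test_final_downstroke_matches_generator_path(self, truth):
        rec = synthetic.gen_biax_record(truth, n_samples=400)
        curves = biax.extract_downstroke(rec)
        for d in ("circ", "rad"):
            lam_true = rec.truth[f"lambda_{d}"]
            t_true = rec.truth[f"tension_{d}"]
            for lam, ten in zip(curves[d].stretch, curves[d].tension_N_per_m):
                # every extracted point sits on the generator's law
                law = rec.truth[f"law_{d}"]
                assert ten == pytest.approx(float(law.tension(lam)), abs=1e-9)
            assert curves[d].max_tension == pytest.approx(t_true.max(), rel=1e-9)

    def test_identical_cycles_agree(self, truth):
        rec = synthetic.gen_biax_record(truth, n_samples=400, n_cycles=2)
        last = biax.extract_downstroke(rec, cycle="last")
        first = biax.extract_downstroke(rec, cycle=0)
        assert np.allclose(last["circ"].stretch, first["circ"].stretch, atol=1e-12)

    def test_monotone_ramp_has_no_cycle(self, truth):
        rec = synthetic.gen_biax_record(truth, path="ramp")
        with pytest.raises(ValueError, match="cycle"):
            biax.extract_downstroke(rec)

    def test_rake_stretch_source_available(self, truth):
        rec = synthetic.gen_biax_record(truth)
        curves = biax.extract_downstroke(rec, stretch_source="rake")
        assert curves["circ"].stretch.max() > 1.05


def _bilinear_curve(toe, calf, lam_t, t_max=25.0, n=200, direction="circ"):
    law = CurveLaw(toe, calf, lam_t)
    lam_end = float(law.stretch_at(t_max))
    lam = np.linspace(1.0, lam_end, n)
    return TensionStretchCurve(direction=direction, stretch=lam,
                               tension_N_per_m=law.tension(lam))


class TestJCurveMetrics:
    def test_exact_bilinear_recovery_auto_windows(self):
        c = _bilinear_curve(5.0, 120.0, 1.15)
        r = _bilinear_curve(5.0, 120.0, 1.15, direction="rad")
        m = biax.jcurve_metrics(c, r, toe_window="auto")
        assert m["circ"].toe_stiffness == pytest.approx(5.0, abs=1e-9)
        assert m["circ"].calf_stiffness == pytest.approx(120.0, abs=1e-9)
        grid = np.max(np.diff(c.stretch))
        assert abs(m["circ"].transition_stretch - 1.15) <= grid + 1e-12

    def test_linear_curve_flags_undefined_transition(self):
        lam = np.linspace(1.0, 1.5, 100)
        c = TensionStretchCurve("circ", lam, 50 * (lam - 1))
        m = biax.jcurve_metrics(c, c, toe_window=(0.5, 4.0), calf_window=(16.0, 20.0))
        circ = m["circ"]
        assert circ.toe_stiffness == pytest.approx(circ.calf_stiffness, rel=1e-6)
        assert "transition_undefined_parallel_lines" in circ.flags

    def test_isotropic_curves_give_unit_anisotropy(self):
        c = _bilinear_curve(10.0, 200.0, 1.12)
        m = biax.jcurve_metrics(c, _bilinear_curve(10.0, 200.0, 1.12, direction="rad"))
        assert m["anisotropy_index"] == pytest.approx(1.0, abs=1e-9)

    def test_circ_stiffer_gives_index_below_one(self, truth):
        # circumferentially stiffer tissue stretches less at 20 N/m
        rec = synthetic.gen_biax_record(truth)
        curves = biax.extract_downstroke(rec)
        m = biax.jcurve_metrics(curves["circ"], curves["rad"], toe_window="auto")
        assert m["anisotropy_index"] < 1.0

    def test_curve_short_of_eval_tension_flagged(self):
        c = _bilinear_curve(5.0, 120.0, 1.1, t_max=12.0)
        m = biax.jcurve_metrics(c, c, toe_window="auto")
        assert "eval_tension_reduced" in m["circ"].flags
        assert m["circ"].eval_tension == pytest.approx(12.0)
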