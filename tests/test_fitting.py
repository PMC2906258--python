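"""Scaling, bulk solvent, twinning, TLS reconstruction and R factors."""

import numpy as np
import pytest
from dataclasses import replace

from xtalaudit.core import CrystalFrame
from xtalaudit.pdbio import HeaderInfo, TLSGroup
from xtalaudit.fitting import (
    CrystalFit,
    ScaleModel,
    apply_header_cutoffs,
    apply_tls,
    candidate_twin_laws,
    f_model_amplitudes,
    fit_scale_model,
    r_factor,
    twin_fit,
    u_from_tls,
)
from xtalaudit.reflections import ReflectionSet
from xtalaudit.synthetic import GroundTruth, make_toy_crystal, simulate_fobs
from xtalaudit.sfcalc import f_mask, fcalc_direct, solvent_mask

DEG2RAD = np.pi / 180.0


class TestFModel:
    def test_identity_when_no_solvent_or_scaling(self):
        frame = CrystalFrame((10, 11, 12, 90, 90, 90), "P1")
        miller = np.array([[1, 0, 0], [0, 2, 1], [3, 1, 2]])
        fc = np.array([10 + 2j, 5 - 1j, 3 + 3j])
        fm = np.array([1 + 0j, 2 + 0j, 0.5 + 0j])
        out = f_model_amplitudes(ScaleModel(), fc, fm, frame, miller)
        assert np.allclose(out, np.abs(fc))

    def test_large_b_sol_kills_solvent_at_high_resolution(self):
        frame = CrystalFrame((10, 11, 12, 90, 90, 90), "P1")
        miller = np.array([[5, 0, 0], [0, 5, 2]])  # d < 2.1 A
        fc = np.array([10 + 2j, 5 - 1j])
        fmv = np.array([50 + 0j, 30 + 0j])
        big_b = f_model_amplitudes(
            ScaleModel(k_sol=0.4, b_sol=4000.0), fc, fmv, frame, miller
        )
        no_sol = f_model_amplitudes(ScaleModel(), fc, fmv, frame, miller)
        assert np.allclose(big_b, no_sol, atol=1e-6)

    def test_three_reflection_hand_oracle(self):
        # scalar arithmetic computed independently below, term by term
        frame = CrystalFrame((10.0, 10.0, 10.0, 90, 90, 90), "P1")
        miller = np.array([[1, 0, 0], [2, 0, 0], [2, 2, 0]])
        fc = np.array([8 + 6j, -3 + 4j, 2 - 2j])
        fmv = np.array([20 + 0j, -10 + 5j, 1 + 1j])
        scale = ScaleModel(k_overall=1.7, k_sol=0.35, b_sol=46.0)
        out = f_model_amplitudes(scale, fc, fmv, frame, miller)
        expected = []
        for (h, k, l), a, b in zip(miller, fc, fmv):
            s_sq = (h**2 + k**2 + l**2) / 100.0
            w = 0.35 * np.exp(-46.0 * s_sq / 4.0)
            expected.append(1.7 * abs(a + w * b))
        assert np.allclose(out, expected, rtol=1e-12)


class TestRFactor:
    def test_closed_forms(self):
        fo = np.array([1.0, 2.0, 3.0])
        assert r_factor(fo, fo) == 0.0
        assert r_factor(fo, 2 * fo) == pytest.approx(1.0)

    def test_five_reflection_hand_example(self):
        fo = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        fm = np.array([11.0, 18.0, 33.0, 40.0, 45.0])
        # |diffs| = 1+2+3+0+5 = 11 ; sum fo = 150
        assert r_factor(fo, fm) == pytest.approx(11.0 / 150.0)

    def test_empty_selection_absent(self):
        assert r_factor(np.array([1.0]), np.array([1.0]),
                        np.array([False])) is None

    def test_union_r_between_work_and_free(self):
        rng = np.random.default_rng(25)
        fo = rng.uniform(10, 100, 500)
        fm = fo * (1 + rng.normal(0, 0.05, 500))
        free = rng.random(500) < 0.3
        r_w = r_factor(fo, fm, ~free)
        r_f = r_factor(fo, fm, free)
        r_all = r_factor(fo, fm)
        assert min(r_w, r_f) <= r_all <= max(r_w, r_f)


@pytest.fixture(scope="module")
def solvent_crystal():
    ens = make_toy_crystal(50, "P21", (16.0, 17.0, 15.0, 90, 102, 90), seed=31)
    frame = ens.frame
    miller = frame.unique_reflections(1.8)
    fc = fcalc_direct(ens, miller)
    fmv = f_mask(solvent_mask(ens, 1.8), frame, miller)
    return ens, frame, miller, fc, fmv


class TestScaleFit:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_recovers_table_scale_solvent_parameters(self, solvent_crystal,
                                                     seed):
        ens, frame, miller, fc, fmv = solvent_crystal
        truth = ScaleModel(k_overall=1.0, k_sol=0.35, b_sol=46.0)
        f_true = f_model_amplitudes(truth, fc, fmv, frame, miller)
        rng = np.random.default_rng(seed)
        fo = f_true * (1 + rng.normal(0, 0.03, len(f_true)))
        fitted = fit_scale_model(fo, fc, fmv, frame, miller)
        assert fitted.k_sol == pytest.approx(0.35, abs=0.05)
        assert fitted.b_sol == pytest.approx(46.0, abs=10.0)

    def test_null_solvent_recovery(self, solvent_crystal):
        ens, frame, miller, fc, fmv = solvent_crystal
        rng = np.random.default_rng(4)
        fo = np.abs(fc) * (1 + rng.normal(0, 0.02, len(fc)))
        fitted = fit_scale_model(fo, fc, fmv, frame, miller)
        assert fitted.k_sol <= 0.05
        fm = f_model_amplitudes(fitted, fc, fmv, frame, miller)
        assert r_factor(fo, fm) <= 0.02  # at the noise floor

    def test_anisotropic_scale_recovery(self, solvent_crystal):
        ens, frame, miller, fc, fmv = solvent_crystal
        u_true = np.diag([0.01, -0.01, 0.0])  # zero-trace, monoclinic b-axis ok?
        # keep it point-group compatible for P21 (b unique): diag tensor is
        u_true = np.diag([0.015, -0.005, -0.01])
        truth = ScaleModel(k_overall=1.0, u_cryst=u_true, k_sol=0.0, b_sol=0.0)
        fo = f_model_amplitudes(truth, fc, fmv, frame, miller)
        fitted = fit_scale_model(fo, fc, fmv, frame, miller)
        assert np.abs(fitted.u_cryst - u_true).max() < 0.1 * np.abs(u_true).max()

    def test_never_worse_than_isotropic_best_k(self, solvent_crystal):
        ens, frame, miller, fc, fmv = solvent_crystal
        rng = np.random.default_rng(5)
        fo = np.abs(fc) * (1 + rng.normal(0, 0.10, len(fc)))
        fitted = fit_scale_model(fo, fc, fmv, frame, miller)
        fm_fit = f_model_amplitudes(fitted, fc, fmv, frame, miller)
        base = np.abs(fc)
        k0 = np.sum(fo * base) / np.sum(base * base)
        assert r_factor(fo, fm_fit) <= r_factor(fo, k0 * base) + 1e-12

    def test_few_reflections_disables_bulk_solvent(self, solvent_crystal):
        ens, frame, miller, fc, fmv = solvent_crystal
        with pytest.warns(UserWarning, match="bulk solvent"):
            fitted = fit_scale_model(np.abs(fc[:30]), fc[:30], fmv[:30],
                                     frame, miller[:30])
        assert fitted.k_sol == 0.0


class TestTwinLaws:
    def test_generic_orthorhombic_has_none(self):
        frame = CrystalFrame((17.0, 19.0, 23.0, 90, 90, 90), "P212121")
        assert candidate_twin_laws(frame) == []

    def test_p41_has_the_tetragonal_merohedry(self):
        frame = CrystalFrame((16.0, 16.0, 22.0, 90, 90, 90), "P41")
        laws = candidate_twin_laws(frame)
        assert len(laws) >= 1
        # some law must be coset-equivalent to (h,k,l)->(k,h,-l)
        target = np.array([[0, 1, 0], [1, 0, 0], [0, 0, -1]])
        laue = {tuple(r.ravel()) for r in frame.rotations}
        laue |= {tuple((-r).ravel()) for r in frame.rotations}

        def same_coset(m1, m2):
            q = m1 @ np.linalg.inv(m2).round().astype(np.int64)
            return tuple(q.ravel()) in laue

        assert any(same_coset(law, target) for law in laws)

    def test_trigonal_merohedry_has_twofold_law(self):
        frame = CrystalFrame((16.0, 16.0, 20.0, 90, 90, 120), "P31")
        laws = candidate_twin_laws(frame)
        assert len(laws) >= 1
        for law in laws:
            assert np.array_equal(np.abs(np.linalg.det(law)), 1)


@pytest.fixture(scope="module")
def twinned_setup():
    ens = make_toy_crystal(50, "P4", (16.0, 16.0, 20.0, 90, 90, 90), seed=32)
    frame = ens.frame
    law = candidate_twin_laws(frame)[0]
    miller = frame.unique_reflections(2.0)
    fc = fcalc_direct(ens, miller)
    fmv = f_mask(solvent_mask(ens, 2.0), frame, miller)
    fm = f_model_amplitudes(ScaleModel(), fc, fmv, frame, miller)
    return frame, law, miller, fm


class TestTwinFit:
    def mix(self, frame, law, miller, fm, alpha, seed):
        lookup = {tuple(h): i for i, h in enumerate(miller)}
        canon, _, _ = frame.map_to_asu(miller @ law)
        mate = np.array([lookup[tuple(h)] for h in canon])
        i_twin = (1 - alpha) * fm**2 + alpha * fm[mate] ** 2
        rng = np.random.default_rng(seed)
        return np.sqrt(i_twin) * (1 + rng.normal(0, 0.03, len(fm)))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_untwinned_null(self, twinned_setup, seed):
        frame, law, miller, fm = twinned_setup
        fo = self.mix(frame, law, miller, fm, 0.0, seed)
        alpha, r_twin, _ = twin_fit(fo, fm, miller, law, frame)
        assert alpha <= 0.02
        assert r_twin >= r_factor(fo, fm * np.sum(fo * fm) / np.sum(fm**2)) \
            - 0.001

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_alpha_045_recovery_and_r_drop(self, twinned_setup, seed):
        frame, law, miller, fm = twinned_setup
        fo = self.mix(frame, law, miller, fm, 0.45, seed)
        alpha, r_twin, _ = twin_fit(fo, fm, miller, law, frame)
        assert alpha == pytest.approx(0.45, abs=0.03)
        k = np.sum(fo * fm) / np.sum(fm**2)
        r_blind = r_factor(fo, k * fm)
        assert r_blind - r_twin >= 0.05

    def test_alpha_05_invariant_under_law_inverse(self, twinned_setup):
        frame, law, miller, fm = twinned_setup
        fo = self.mix(frame, law, miller, fm, 0.5, 7)
        inv = np.linalg.inv(law).round().astype(np.int64)
        _, r1, _ = twin_fit(fo, fm, miller, law, frame)
        _, r2, _ = twin_fit(fo, fm, miller, inv, frame)
        assert r1 == pytest.approx(r2, abs=1e-6)


class TestUTfromTls:
    def group(self, T, L, S, origin=(0, 0, 0)):
        return TLSGroup(group_id=1, selection_text="", ranges=[("A", 1, 999)],
                        origin=np.asarray(origin, dtype=float),
                        T=np.asarray(T, dtype=float),
                        L=np.asarray(L, dtype=float),
                        S=np.asarray(S, dtype=float), dialect="refmac")

    def test_pure_translation_gives_t_everywhere(self):
        g = self.group(0.03 * np.eye(3), np.zeros((3, 3)), np.zeros((3, 3)),
                       origin=(5, 5, 5))
        for xyz in [(0, 0, 0), (9, 1, 4), (5, 5, 5)]:
            assert np.allclose(u_from_tls(g, xyz), 0.03 * np.eye(3))

    def test_libration_axis_through_atom_adds_nothing(self):
        g = self.group(0.02 * np.eye(3), np.diag([25.0, 0, 0]),
                       np.zeros((3, 3)))
        u = u_from_tls(g, (7.0, 0.0, 0.0))  # on the x axis through origin
        assert np.allclose(u, 0.02 * np.eye(3), atol=1e-12)
        # off-axis position does feel the libration
        u_off = u_from_tls(g, (0.0, 5.0, 0.0))
        assert not np.allclose(u_off, 0.02 * np.eye(3), atol=1e-6)

    def test_matches_monte_carlo_rigid_body_oracle(self):
        rng = np.random.default_rng(33)
        T = 0.02 * np.eye(3)
        L = np.diag([16.0, 9.0, 4.0])        # deg^2
        S = 0.02 * rng.normal(size=(3, 3))   # A deg
        # joint covariance of (lambda [rad], t [A]) must be PSD
        C = np.zeros((6, 6))
        C[:3, :3] = L * DEG2RAD**2
        C[3:, 3:] = T
        C[:3, 3:] = S * DEG2RAD
        C[3:, :3] = (S * DEG2RAD).T
        w, v = np.linalg.eigh(C)
        assert w.min() > 0, "fixture must be a valid rigid-body covariance"
        chol = np.linalg.cholesky(C)
        n = 200_000
        z = rng.normal(size=(n, 6)) @ chol.T
        lam, t = z[:, :3], z[:, 3:]
        g = self.group(T, L, S, origin=(2.0, 1.0, 3.0))
        xyz = np.array([[5.0, 4.0, -1.0], [2.0, 8.0, 3.0], [-3.0, 1.0, 0.5]])
        for pos in xyz:
            d = pos - g.origin
            disp = t + np.cross(lam, np.broadcast_to(d, (n, 3)))
            u_mc = np.cov(disp.T)
            u_an = u_from_tls(g, pos)
            assert np.abs(u_mc - u_an).max() < 0.02 * np.abs(u_an).max()


@pytest.fixture(scope="module")
def tls_crystal():
    ens = make_toy_crystal(60, "P21", (17.0, 18.0, 16.0, 90, 103, 90),
                           b_range=(8, 14), seed=34)
    grp = TLSGroup(
        group_id=1, selection_text="chain A", ranges=[("A", 1, 999)],
        origin=np.mean([a.xyz for a in ens.models[0]], axis=0),
        T=0.02 * np.eye(3), L=np.diag([30.0, 20.0, 10.0]),
        S=np.zeros((3, 3)), dialect="refmac",
    )
    return replace(ens, tls_groups=[grp]), grp


class TestAdpConventionAndCutoffs:
    def test_residual_deposit_resolved_with_gap(self, tls_crystal):
        ens, grp = tls_crystal
        truth = GroundTruth(k_sol=0.3, b_sol=50.0, noise=0.03, seed=35)
        rs = simulate_fobs(ens, truth, 2.0, apply_truth_tls=True)
        res = CrystalFit(ens, rs, twin="none").fit()
        assert res.adp_convention == "residual->total"
        gap = res.variants["total"].r_work \
            - res.variants["residual->total"].r_work
        assert gap >= 0.02

    def test_total_deposit_resolved(self, tls_crystal):
        ens, grp = tls_crystal
        truth = GroundTruth(k_sol=0.3, b_sol=50.0, noise=0.03, seed=36)
        rs = simulate_fobs(ens, truth, 2.0, apply_truth_tls=True)
        ens_total = replace(apply_tls(ens), tls_groups=[grp])
        res = CrystalFit(ens_total, rs, twin="none").fit()
        assert res.adp_convention == "total"

    def test_defective_tls_forces_total_with_r_penalty(self, tls_crystal):
        ens, grp = tls_crystal
        truth = GroundTruth(k_sol=0.3, b_sol=50.0, noise=0.03, seed=37)
        rs = simulate_fobs(ens, truth, 2.0, apply_truth_tls=True)
        res_good = CrystalFit(ens, rs, twin="none").fit()
        from xtalaudit.pdbio import TlsDefect
        broken = replace(ens, tls_groups=[],
                         tls_defects=[TlsDefect(1, "b", "missing origin")])
        res_bad = CrystalFit(broken, rs, twin="none").fit()
        assert res_bad.adp_convention == "total"
        assert res_bad.tls_defects
        assert res_bad.r_work > res_good.r_work

    def test_header_cutoffs(self):
        frame = CrystalFrame((12, 13, 14, 90, 90, 90), "P1")
        hs = frame.unique_reflections(2.0)
        rng = np.random.default_rng(38)
        values = rng.uniform(5, 50, len(hs))
        sigmas = rng.uniform(1, 10, len(hs))
        rs = ReflectionSet(miller=hs, value=values, sigma=sigmas,
                           kind="amplitude", frame=frame)
        out, label = apply_header_cutoffs(rs, HeaderInfo())
        assert label == "all data" and len(out) == len(rs)
        cut, label = apply_header_cutoffs(rs, HeaderInfo(sigma_cutoff=2.0))
        assert "F/sig>=2.0" in label
        assert len(cut) == int(np.sum(values / sigmas >= 2.0))
        d = rs.d
        win, _ = apply_header_cutoffs(rs, HeaderInfo(d_max=4.0))
        assert win.d.max() <= 4.0 + 1e-6


class TestSelfConsistency:
    def test_noise_free_pipeline_r_below_1e4(self):
        ens = make_toy_crystal(40, "P21", (15.0, 16.0, 14.0, 90, 100, 90),
                               seed=39)
        truth = GroundTruth(k_sol=0.35, b_sol=46.0, noise=0.0, seed=39)
        rs = simulate_fobs(ens, truth, 1.8)
        res = CrystalFit(ens, rs, twin="none").fit()
        assert res.r_work < 1e-4
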