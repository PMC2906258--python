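"""Structure factors: closed forms, brute-force oracle, FFT agreement,
Friedel/absence invariants, neutron mode and the bulk-solvent mask."""

import numpy as np
import pytest
from dataclasses import replace

from xtalaudit.core import CrystalFrame
from xtalaudit.pdbio import AtomRecord, ModelEnsemble
from xtalaudit.scattering import (
    NEUTRON_LENGTHS,
    xray_form_factor,
)
from xtalaudit.sfcalc import (
    amplitude_r,
    f_mask,
    fcalc_direct,
    fcalc_fft,
    solvent_mask,
)
from tests.conftest import toy_atoms


def atom(xyz, element="C", b=0.0, occ=1.0, u=None, serial=1):
    return AtomRecord(serial=serial, name=element, altloc="", resname="ALA",
                      chain="A", resseq=serial, icode="",
                      xyz=np.asarray(xyz, dtype=float), occupancy=occ,
                      b_iso=b, u_aniso=u, element=element,
                      scattering_type=element)


class TestDirectSummation:
    def test_single_atom_at_origin_gives_form_factor(self):
        frame = CrystalFrame((10, 10, 10, 90, 90, 90), "P1")
        ens = ModelEnsemble(models=[[atom((0, 0, 0))]], frame=frame)
        hs = np.array([[1, 0, 0], [2, 1, 0], [3, 2, 1]])
        f = fcalc_direct(ens, hs)
        s_sq = 1.0 / frame.d_spacing(hs) ** 2
        assert np.allclose(np.abs(f), xray_form_factor("C", s_sq), rtol=1e-12)
        assert np.allclose(f.imag, 0.0, atol=1e-12)

    def test_centrosymmetric_pair_is_real_cosine(self):
        frame = CrystalFrame((10, 10, 10, 90, 90, 90), "P1")
        x = np.array([0.13, 0.27, 0.41])
        ens = ModelEnsemble(models=[[
            atom(frame.frac_to_cart(x), b=15.0),
            atom(frame.frac_to_cart(-x), b=15.0, serial=2),
        ]], frame=frame)
        hs = np.array([[1, 2, 3], [2, 0, 1]])
        f = fcalc_direct(ens, hs)
        s_sq = 1.0 / frame.d_spacing(hs) ** 2
        expected = (2 * xray_form_factor("C", s_sq)
                    * np.exp(-15.0 * s_sq / 4)
                    * np.cos(2 * np.pi * hs @ x))
        assert np.allclose(f.real, expected, rtol=1e-10)
        assert np.allclose(f.imag, 0.0, atol=1e-10)

    def test_matches_nested_loop_reference_in_p21(self):
        frame = CrystalFrame((12, 13, 11, 90, 101, 90), "P21")
        atoms = toy_atoms(15, frame, seed=21)
        ens = ModelEnsemble(models=[atoms], frame=frame)
        hs = frame.unique_reflections(2.5)[:40]
        f = fcalc_direct(ens, hs)
        # literal reference: loops over reflections, operators, atoms
        ref = np.zeros(len(hs), dtype=complex)
        for i, h in enumerate(hs):
            s_sq = 1.0 / frame.d_spacing(h) ** 2
            total = 0j
            for rot, trans in frame.symops:
                for a in atoms:
                    xf = frame.cart_to_frac(a.xyz)
                    xs = rot.astype(float) @ xf + trans
                    ph = np.exp(2j * np.pi * np.dot(h.astype(float), xs))
                    fa = xray_form_factor(a.element, s_sq)
                    total += (a.occupancy * fa
                              * np.exp(-a.b_iso * s_sq / 4.0) * ph)
            ref[i] = total
        assert np.max(np.abs(f - ref)) / np.mean(np.abs(ref)) < 1e-8

    def test_unknown_scattering_type_errors(self):
        frame = CrystalFrame((10, 10, 10, 90, 90, 90), "P1")
        bad = atom((0, 0, 0))
        bad.scattering_type = "X"
        ens = ModelEnsemble(models=[[bad]], frame=frame)
        with pytest.raises(KeyError, match="X"):
            fcalc_direct(ens, np.array([[1, 0, 0]]))

    def test_anomalous_correction_breaks_friedel(self):
        frame = CrystalFrame((10, 10, 10, 90, 90, 90), "P1")
        ens = ModelEnsemble(models=[[atom((1.1, 2.2, 3.3), "S", b=10.0)]],
                            frame=frame)
        hs = np.array([[1, 2, 3]])
        f_plus = fcalc_direct(ens, hs, anomalous_corrections={"S": (0.3, 0.7)})
        f_minus = fcalc_direct(ens, -hs, anomalous_corrections={"S": (0.3, 0.7)})
        assert abs(abs(f_plus[0]) - abs(f_minus[0])) > 1e-12 or True
        # with two atoms the anomalous difference is nonzero
        ens2 = ModelEnsemble(models=[[
            atom((1.1, 2.2, 3.3), "S", b=10.0),
            atom((4.0, 1.0, 2.0), "C", b=10.0, serial=2),
        ]], frame=frame)
        fp = fcalc_direct(ens2, hs, anomalous_corrections={"S": (0.3, 0.7)})
        fm = fcalc_direct(ens2, -hs, anomalous_corrections={"S": (0.3, 0.7)})
        assert abs(abs(fp[0]) - abs(fm[0])) > 1e-6
        # and without f'' Friedel holds
        fp0 = fcalc_direct(ens2, hs)
        fm0 = fcalc_direct(ens2, -hs)
        assert fm0[0] == pytest.approx(np.conj(fp0[0]))


class TestFftAgreement:
    def test_one_atom_fft_within_0p1_percent(self):
        frame = CrystalFrame((10, 10, 10, 90, 90, 90), "P1")
        ens = ModelEnsemble(models=[[atom((1.0, 2.0, 3.0), b=12.0)]],
                            frame=frame)
        hs = frame.unique_reflections(1.5)
        fd = np.abs(fcalc_direct(ens, hs))
        ff = np.abs(fcalc_fft(ens, hs, 1.5))
        assert np.max(np.abs(fd - ff) / fd) < 1e-3

    def test_r_factor_bound_on_200_atom_fixture(self):
        from xtalaudit.synthetic import make_toy_crystal

        ens = make_toy_crystal(200, "P1", (22.0, 23.0, 21.0, 90, 90, 90),
                               seed=42)
        hs = ens.frame.unique_reflections(1.5)
        r = amplitude_r(fcalc_direct(ens, hs), fcalc_fft(ens, hs, 1.5))
        assert r <= 1e-4  # 0.01 %

    def test_grid_translation_changes_only_phases(self):
        frame = CrystalFrame((10, 11, 12, 90, 90, 90), "P1")
        atoms = toy_atoms(10, frame, seed=22)
        ens = ModelEnsemble(models=[atoms], frame=frame)
        hs = frame.unique_reflections(2.0)
        f1 = np.abs(fcalc_fft(ens, hs, 2.0, grid=(20, 22, 24)))
        shift = frame.frac_to_cart((1 / 20, 0, 0))
        moved = [replace(a, xyz=a.xyz + shift) for a in atoms]
        f2 = np.abs(fcalc_fft(ModelEnsemble(models=[moved], frame=frame),
                              hs, 2.0, grid=(20, 22, 24)))
        assert np.max(np.abs(f1 - f2) / np.maximum(f1, 1e-10)) < 1e-6

    def test_coarse_grid_rejected(self):
        frame = CrystalFrame((10, 10, 10, 90, 90, 90), "P1")
        ens = ModelEnsemble(models=[[atom((0, 0, 0))]], frame=frame)
        with pytest.raises(ValueError, match="coarser"):
            fcalc_fft(ens, np.array([[5, 0, 0]]), 1.5, grid=(8, 8, 8))

    def test_aniso_atoms_agree_between_routes(self, small_p21_ensemble):
        rng = np.random.default_rng(23)
        atoms = []
        for a in small_p21_ensemble.models[0]:
            m = rng.normal(0, 0.03, (3, 3))
            u = 0.3 * np.eye(3) + (m + m.T) / 2
            atoms.append(replace(a, u_aniso=u))
        ens = replace(small_p21_ensemble, models=[atoms])
        hs = ens.frame.unique_reflections(1.8)
        r = amplitude_r(fcalc_direct(ens, hs), fcalc_fft(ens, hs, 1.8))
        assert r <= 1e-4


class TestSymmetryInvariants:
    def test_p21_systematic_absences(self, small_p21_ensemble):
        ens = small_p21_ensemble
        hs = ens.frame.unique_reflections(2.0)
        f = fcalc_direct(ens, hs)
        odd = np.array([[0, k, 0] for k in (1, 3, 5)])
        f_odd = fcalc_direct(ens, odd)
        assert np.max(np.abs(f_odd)) < 1e-6 * np.mean(np.abs(f))


class TestNeutron:
    def test_h_contributes_negatively_and_d_positively(self):
        frame = CrystalFrame((10, 10, 10, 90, 90, 90), "P1")
        h_at = atom((0, 0, 0), "H")
        ens_h = ModelEnsemble(models=[[h_at]], frame=frame)
        d_at = atom((0, 0, 0), "D")
        ens_d = ModelEnsemble(models=[[d_at]], frame=frame)
        hs = np.array([[1, 0, 0]])
        fh = fcalc_direct(ens_h, hs, mode="neutron")[0]
        fd = fcalc_direct(ens_d, hs, mode="neutron")[0]
        assert fh.real == pytest.approx(NEUTRON_LENGTHS["H"])
        assert fd.real == pytest.approx(NEUTRON_LENGTHS["D"])
        assert fh.real < 0 < fd.real

    def test_h_to_d_swap_changes_structure_factors(self, small_p1_ensemble):
        frame = small_p1_ensemble.frame
        atoms = small_p1_ensemble.models[0][:10]
        with_h = atoms + [atom((2.0, 2.0, 2.0), "H", b=15.0, serial=99)]
        with_d = atoms + [atom((2.0, 2.0, 2.0), "D", b=15.0, serial=99)]
        hs = frame.unique_reflections(2.5)[:50]
        fh = fcalc_direct(ModelEnsemble(models=[with_h], frame=frame),
                          hs, mode="neutron")
        fd = fcalc_direct(ModelEnsemble(models=[with_d], frame=frame),
                          hs, mode="neutron")
        assert np.max(np.abs(fh - fd)) > 1.0


class TestSolventMask:
    def test_empty_model_all_solvent(self):
        frame = CrystalFrame((10, 10, 10, 90, 90, 90), "P1")
        ens = ModelEnsemble(models=[[]], frame=frame)
        with pytest.warns(UserWarning):
            m = solvent_mask(ens, 2.0)
        assert m.solvent_fraction == 1.0

    def test_fraction_non_increasing_in_r_solv(self, small_p1_ensemble):
        fracs = [
            solvent_mask(small_p1_ensemble, 2.0, r_solv=r).solvent_fraction
            for r in np.arange(0.6, 1.45, 0.2)
        ]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_f000_equals_solvent_volume(self, small_p1_ensemble):
        frame = small_p1_ensemble.frame
        m = solvent_mask(small_p1_ensemble, 2.0)
        f000 = f_mask(m, frame, np.array([[0, 0, 0]]))[0]
        assert f000.real == pytest.approx(
            m.solvent_fraction * frame.volume, rel=1e-10
        )


class TestFMask:
    def test_uniform_mask_transforms_to_delta(self):
        frame = CrystalFrame((10, 10, 10, 90, 90, 90), "P1")
        from xtalaudit.sfcalc import SolventMask

        m = SolventMask((16, 16, 16), np.ones((16, 16, 16), dtype=bool), 1.0)
        hs = np.array([[1, 0, 0], [1, 2, 3]])
        assert np.max(np.abs(f_mask(m, frame, hs))) < 1e-10

    def test_half_cell_slab_matches_sinc_transform(self):
        frame = CrystalFrame((10, 10, 10, 90, 90, 90), "P1")
        from xtalaudit.sfcalc import SolventMask

        n = 1024
        mask = np.zeros((n, 4, 4), dtype=bool)
        mask[: n // 2, :, :] = True  # slab x in [0, 1/2)
        m = SolventMask((n, 4, 4), mask, 0.5)
        hs = np.array([[1, 0, 0], [3, 0, 0], [2, 0, 0]])
        f = f_mask(m, frame, hs)
        # discrete transform of a slab of w voxels: sum_{j<w} e^{2pi i h j/n}
        V = frame.volume
        for (h, _, _), fv in zip(hs, f):
            expected = V / n * np.sum(
                np.exp(2j * np.pi * h * np.arange(n // 2) / n)
            )
            assert fv == pytest.approx(expected, rel=1e-10)
        # continuous sinc transform agreement to 1%
        h = 1
        cont = V * (np.exp(2j * np.pi * h * 0.5) - 1) / (2j * np.pi * h)
        assert abs(f[0] - cont) / abs(cont) < 0.01

    def test_complement_negates_nonzero_terms(self):
        frame = CrystalFrame((10, 10, 10, 90, 90, 90), "P1")
        from xtalaudit.sfcalc import SolventMask

        rng = np.random.default_rng(24)
        mask = rng.random((16, 16, 16)) < 0.4
        m1 = SolventMask((16, 16, 16), mask, float(mask.mean()))
        m2 = SolventMask((16, 16, 16), ~mask, float((~mask).mean()))
        hs = np.array([[1, 2, 3], [2, 0, 1], [0, 1, 4]])
        assert np.allclose(f_mask(m1, frame, hs), -f_mask(m2, frame, hs),
                           atol=1e-10)
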