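"""Tensor model: effective ratios, rotations, and the brute-force oracle."""

import numpy as np
import pytest

from dsppol.tensor import (
    FiberGeometry,
    MolecularSusceptibility,
    effective_ratios,
    lab_tensor_2d,
    lab_tensor_2d_from_ratios,
    molecular_tensor_3d,
    rotate_tensor_2d,
)

MOL = MolecularSusceptibility(chi_zzz=1.6, chi_xyz_mag=0.28284271247461906,
                              delta_phase=np.pi / 4)


@pytest.mark.parametrize(
    "alpha_deg, exp_R, exp_C, exp_sigma",
    [
        (0.0, 1.6, 0.0, 0.0),
        (90.0, 3.0, 0.28284271247461906, None),
        (30.0, 1.95, 0.14142135623730948, 0.06779661016949151),
    ],
)
def test_effective_ratios(alpha_deg, exp_R, exp_C, exp_sigma):
    eff = effective_ratios(MOL, np.radians(alpha_deg))
    assert eff.R == pytest.approx(exp_R, abs=1e-12)
    assert eff.C == pytest.approx(exp_C, abs=1e-12)
    if exp_sigma is not None:
        assert eff.sigma == pytest.approx(exp_sigma, abs=1e-6)
    # sigma definition holds exactly
    assert eff.sigma == pytest.approx(
        2 * eff.C * np.cos(eff.delta_phase) / (eff.R + 1), abs=1e-15
    )


def test_achiral_in_plane_tensor():
    t = lab_tensor_2d(MolecularSusceptibility(chi_zzz=1.6), FiberGeometry())
    assert t.zzz == pytest.approx(1.6)
    assert t.zxx == pytest.approx(1.0)
    assert t.xxz == pytest.approx(1.0)
    assert t.xzz == pytest.approx(0.0, abs=1e-15)
    assert t.zxz == pytest.approx(0.0, abs=1e-15)


def test_chiral_tilted_tensor_entries():
    """At delta = 0 the normalized entries are (R, 1, 1, -2 C e^{iD}, +C e^{iD})."""
    g = FiberGeometry(delta=0.0, alpha=np.radians(30.0))
    t = lab_tensor_2d(MOL, g)
    eff = effective_ratios(MOL, g.alpha)
    k = eff.C * np.exp(1j * eff.delta_phase)
    assert t.zzz == pytest.approx(1.95, abs=1e-12)
    assert t.xzz == pytest.approx(-2 * k, abs=1e-12)
    assert t.zxz == pytest.approx(k, abs=1e-12)
    # jk-index symmetry
    assert np.allclose(t.array, np.swapaxes(t.array, -1, -2))


def test_full_rotation_matches_ratio_construction():
    for delta_deg, alpha_deg in [(0, 0), (23, 30), (-60, -45), (85, 10)]:
        g = FiberGeometry(delta=np.radians(delta_deg), alpha=np.radians(alpha_deg))
        eff = effective_ratios(MOL, g.alpha)
        a = lab_tensor_2d(MOL, g).array
        b = lab_tensor_2d_from_ratios(eff.R, eff.C, eff.delta_phase, g.delta)
        assert np.allclose(a, b, atol=1e-13)


def test_rotation_composition():
    """Rotating by delta equals evaluating at delta = 0 then rotating in 2D."""
    d = np.radians(37.0)
    g0 = FiberGeometry(delta=0.0, alpha=np.radians(20.0))
    t0 = lab_tensor_2d(MOL, g0).array
    t1 = lab_tensor_2d(MOL, FiberGeometry(delta=d, alpha=g0.alpha)).array
    assert np.allclose(rotate_tensor_2d(t0, d), t1, atol=1e-13)


def _brute_force_lab_tensor(mol, delta, alpha):
    """Independent oracle: explicit 27-term rotation sums, no einsum."""
    chi = np.zeros((3, 3, 3), dtype=complex)
    x, y, z = 0, 1, 2
    chi[z][z][z] = mol.chi_zzz
    chi[z][x][x] = chi[z][y][y] = mol.chi_zxx
    chi[x][x][z] = chi[x][z][x] = chi[y][y][z] = chi[y][z][y] = mol.chi_xxz
    k = mol.chi_xyz_mag * np.exp(1j * mol.delta_phase)
    chi[x][y][z] = chi[x][z][y] = k
    chi[y][x][z] = chi[y][z][x] = -k
    ca, sa = np.cos(alpha), np.sin(alpha)
    cd, sd = np.cos(delta), np.sin(delta)
    tilt = [[1, 0, 0], [0, ca, sa], [0, -sa, ca]]   # lab (X,Y,Z) x mol (x,y,z)
    spin = [[cd, 0, sd], [0, 1, 0], [-sd, 0, cd]]
    rot = [[sum(spin[i][m] * tilt[m][j] for m in range(3)) for j in range(3)]
           for i in range(3)]
    lab = np.zeros((3, 3, 3), dtype=complex)
    for I in range(3):
        for J in range(3):
            for K in range(3):
                acc = 0.0
                for i in range(3):
                    for j in range(3):
                        for kk in range(3):
                            acc += rot[I][i] * rot[J][j] * rot[K][kk] * chi[i][j][kk]
                lab[I][J][K] = acc
    sub = lab[np.ix_([0, 2], [0, 2], [0, 2])]
    return sub / (mol.chi_zxx * ca)


def test_brute_force_rotation_oracle():
    rng = np.random.default_rng(42)
    for _ in range(100):
        mol = MolecularSusceptibility(
            chi_zzz=rng.uniform(0.3, 3.0),
            chi_zxx=rng.uniform(0.5, 2.0),
            chi_xxz=rng.uniform(0.5, 2.0),
            chi_xyz_mag=rng.uniform(0.0, 0.5),
            delta_phase=rng.uniform(-np.pi, np.pi),
        )
        delta = rng.uniform(-np.pi / 2, np.pi / 2)
        alpha = rng.uniform(-1.4, 1.4)
        got = lab_tensor_2d(mol, FiberGeometry(delta=delta, alpha=alpha)).array
        want = _brute_force_lab_tensor(mol, delta, alpha)
        assert np.allclose(got, want, atol=1e-12)


def test_monotone_R_in_tilt():
    """R increases with sin^2(alpha) when chi_zzz < 1 + 2 chi_xxz/chi_zxx."""
    mol = MolecularSusceptibility(chi_zzz=1.6)
    alphas = np.linspace(0, np.pi / 2, 50)
    rs = [effective_ratios(mol, a).R for a in alphas]
    assert np.all(np.diff(rs) > 0)


def test_degenerate_tilt_flagged():
    t = lab_tensor_2d(MOL, FiberGeometry(alpha=np.pi / 2))
    assert t.degenerate
    # effective ratios remain defined at the degenerate tilt
    eff = effective_ratios(MOL, np.pi / 2)
    assert np.isfinite(eff.R) and np.isfinite(eff.C)


def test_real_tensor_when_phase_zero():
    mol = MolecularSusceptibility(chi_zzz=1.6, chi_xyz_mag=0.3, delta_phase=0.0)
    t = lab_tensor_2d(mol, FiberGeometry(delta=0.4, alpha=0.5))
    assert np.allclose(t.array.imag, 0.0, atol=1e-14)


def test_validation_and_json_round_trip():
    with pytest.raises(ValueError):
        MolecularSusceptibility(chi_zxx=0.0)
    with pytest.raises(ValueError):
        MolecularSusceptibility(chi_xyz_mag=-0.1)
    with pytest.raises(ValueError):
        FiberGeometry(delta=2.0)
    mol = MolecularSusceptibility.from_json(MOL.to_json())
    assert mol == MOL
    g = FiberGeometry(delta=0.3, alpha=-0.2)
    assert FiberGeometry.from_json(g.to_json()) == g
    # Kleinman-like default: chi_xxz follows chi_zxx unless set
    assert MolecularSusceptibility(chi_zxx=1.5).chi_xxz == 1.5
    assert MolecularSusceptibility(chi_xxz=0.8).chi_xxz == 0.8
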