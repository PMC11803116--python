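"""DSP parameters: measured-side vs closed-form oracle equivalence."""

import numpy as np
import pytest

from conftest import stokes_images_from_ratios
from dsppol.parameters import closed_form_params, compute_parameters

EXACT = ("L", "CA_CD", "T", "W", "SHG_CD", "D", "A", "B", "H", "SHG_LD", "SHG_45")


def _hybrid_close(a, b, tol=1e-9):
    """|a - b| <= tol * max(|b|, 1): relative where the oracle is O(1) or
    larger, absolute near zero."""
    ok = np.isfinite(a) & np.isfinite(b)
    return np.all(np.abs(a[ok] - b[ok]) <= tol * np.maximum(np.abs(b[ok]), 1.0))


def test_measured_equals_closed_form_on_grid(ratio_grid):
    """Field-model Stokes data reproduce every exact closed form to 1e-9."""
    Rg, Cg, Dg, dg = ratio_grid
    imgs = stokes_images_from_ratios(Rg, Cg, Dg, dg)
    meas = compute_parameters(imgs)
    cf, coef = closed_form_params(Rg, Cg, Dg, dg)
    for name in EXACT:
        assert _hybrid_close(meas[name], cf[name]), name
    # derived coefficients at C = 0 collapse to a = R^2 - 1, b = 0
    zero_c = Cg == 0
    assert np.allclose(coef.a[zero_c], Rg[zero_c] ** 2 - 1)
    assert np.allclose(coef.b[zero_c], 0.0)


@pytest.mark.parametrize(
    "name, R, C, Delta, delta, expected",
    [
        ("SHG_LD", 1.6, 0.0, 0.0, 0.0, -0.87640),
        ("A", 1.6, 0.0, 0.0, 0.0, 1.0),
        ("B", 1.6, 0.0, 0.0, 0.0, 0.0),
        ("SHG_45", 1.6, 0.0, 0.0, 0.0, 0.0),
        ("CA_CD", 1.6, 0.0, 0.0, 0.0, 1.10092),
        ("L", 1.6, 0.0, 0.0, 0.0, 0.75615),
        ("T", 1.6, 0.2, np.pi / 4, 0.0, 0.23825),
        ("W", 1.6, 0.2, np.pi / 4, 0.0, -0.23825),
        ("D", 1.6, 0.2, np.pi / 4, 0.0, 1.0),
        ("H", 1.6, 0.2, np.pi / 4, 0.0, 0.34258),
    ],
)
def test_parameter_point_values(name, R, C, Delta, delta, expected):
    imgs = stokes_images_from_ratios(np.array(R), np.array(C), np.array(Delta),
                                     np.array(delta))
    meas = compute_parameters(imgs)
    assert float(meas[name]) == pytest.approx(expected, abs=2e-5)


def test_zero_chirality_nulls_chiral_parameters():
    imgs = stokes_images_from_ratios(np.array(1.6), np.array(0.0), np.array(0.0),
                                     np.radians(33.0))
    meas = compute_parameters(imgs)
    for name in ("T", "H", "SHG_CD", "W"):
        assert float(meas[name]) == pytest.approx(0.0, abs=1e-12)


def test_kappa_and_sigma_values():
    cf, coef = closed_form_params(1.6, 0.0, 0.0, 0.0)
    assert float(coef.kappa) == pytest.approx(-4.9121, abs=1e-4)
    cf2, _ = closed_form_params(1.6, 0.2, np.pi / 4, 0.0)
    assert float(cf2.meta["sigma"]) == pytest.approx(0.10879, abs=1e-5)
    # approximate H = 3 sigma vs exact H (both branches are first-class)
    assert float(cf2.approx["H"]) == pytest.approx(3 * 0.108786, abs=1e-5)
    assert float(cf2.maps["H"]) == pytest.approx(0.34258, abs=1e-5)


def test_delta_invariance_of_orientation_independent_params():
    deltas = np.radians(np.linspace(-89, 89, 31))
    imgs = stokes_images_from_ratios(
        np.full_like(deltas, 1.6), np.full_like(deltas, 0.2),
        np.full_like(deltas, np.pi / 4), deltas,
    )
    meas = compute_parameters(imgs)
    for name in ("T", "H", "SHG_CD", "W", "D", "CA_CD", "L"):
        v = meas[name]
        assert np.nanmax(np.abs(v - v[0])) < 1e-9, name


def test_D_times_T_is_minus_W(ratio_grid):
    Rg, Cg, Dg, dg = ratio_grid
    meas = compute_parameters(stokes_images_from_ratios(Rg, Cg, Dg, dg))
    ok = np.isfinite(meas["D"])
    assert np.allclose((meas["D"] * meas["T"])[ok], -meas["W"][ok], atol=1e-12)


def test_gain_invariance():
    imgs = stokes_images_from_ratios(np.array(1.95), np.array(0.14),
                                     np.array(0.5), np.array(0.3))
    scaled = stokes_images_from_ratios(np.array(1.95), np.array(0.14),
                                       np.array(0.5), np.array(0.3))
    for k in scaled.stokes:
        scaled.stokes[k] = scaled.stokes[k] * 137.0
    a, b = compute_parameters(imgs), compute_parameters(scaled)
    for name in a.maps:
        fa, fb = a[name], b[name]
        ok = np.isfinite(fa) & np.isfinite(fb)
        assert np.allclose(fa[ok], fb[ok], atol=1e-12), name


def test_sigma_approximation_error_small_C_and_grows():
    """The sigma-approximate forms match to 1e-3 when 4C^2 <= 0.01 |R^2-1|
    and their error grows with C."""
    R, Delta, delta = 1.6, np.pi / 4, np.radians(10.0)
    lim = np.sqrt(0.01 * abs(R**2 - 1) / 4)  # 4C^2 = 0.01 |R^2 - 1|
    cf_small, _ = closed_form_params(R, 0.9 * lim, Delta, delta)
    # A and H approximations are second order in C: below 1e-3 at the bound;
    # the dichroism forms keep an O(C^2/(R-3)) remainder, still below 1e-2
    for name, tol in (("A", 2e-3), ("H", 1e-3), ("SHG_LD", 1e-2), ("SHG_45", 1e-2)):
        exact, app = float(cf_small.maps[name]), float(cf_small.approx[name])
        assert abs(exact - app) <= tol * max(abs(exact), 1.0), name
    for name in ("A", "H", "SHG_LD", "SHG_45"):
        errs = []
        for c in (0.02, 0.1, 0.3):
            cf, _ = closed_form_params(R, c, Delta, delta)
            errs.append(abs(float(cf.maps[name]) - float(cf.approx[name])))
        assert errs[0] < errs[1] < errs[2], name


def test_denominator_floor_masks_and_counts():
    # delta = 22.5 deg, C = 0: the A denominator vanishes (its pole)
    imgs = stokes_images_from_ratios(np.array([1.6]), np.array([0.0]),
                                     np.array([0.0]), np.array([np.pi / 8]))
    meas = compute_parameters(imgs)
    assert not meas.masks["A"][0]
    assert np.isnan(meas["A"][0])
    assert meas.masked_counts["A"] == 1
    # T = 0 at C = 0 masks the D ratio
    assert not meas.masks["D"][0]
    # delta = 45 deg: the B denominator (s1 sums) vanishes
    imgs45 = stokes_images_from_ratios(np.array([1.6]), np.array([0.0]),
                                       np.array([0.0]), np.array([np.pi / 4]))
    meas45 = compute_parameters(imgs45)
    assert not meas45.masks["B"][0]


def test_pole_flagged_in_closed_forms():
    cf, _ = closed_form_params(3.0, 0.0, 0.0, 0.1)
    assert bool(cf.meta["pole"])
    assert not bool(cf.masks["SHG_LD"])
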