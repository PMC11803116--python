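"""Inversion: orientation, achiral ratio, chiral components, full recovery."""

import numpy as np
import pytest

from conftest import stokes_images_from_ratios
from dsppol.inversion import (
    chiral_components,
    chiral_validity_mask,
    delta_from_A,
    delta_from_B,
    extend_delta_range,
    invert_maps,
    r_from_cacd,
    r_from_cacd_and_L,
    tan_delta_from_cd_h,
)
from dsppol.parameters import closed_form_params, compute_parameters


def test_delta_from_A_trivial_and_exact_achiral():
    assert delta_from_A(np.array(1.0), 0.0) == pytest.approx(0.0)
    cf, _ = closed_form_params(1.6, 0.0, 0.0, np.radians(20.0))
    rec = np.degrees(delta_from_A(cf.maps["A"], 0.0))
    assert float(rec) == pytest.approx(20.0, abs=0.01)


def test_delta_from_A_error_bounded_in_C():
    """With the exact sigma the A-equation error stays below 1 deg for
    C <= 0.2 at R = 1.6 and shrinks as C -> 0."""
    errs = []
    for c in (0.0, 0.05, 0.1, 0.2):
        cf, _ = closed_form_params(1.6, c, np.pi / 4, np.radians(20.0))
        sigma = float(cf.meta["sigma"])
        rec = np.degrees(delta_from_A(cf.maps["A"], sigma))
        errs.append(abs(float(rec) - 20.0))
    assert errs[-1] <= 1.0
    assert errs[0] <= 1e-6


def test_delta_from_B_is_exact_inverse():
    assert delta_from_B(np.array(0.0), 0.0) == pytest.approx(0.0)
    # forward B then invert, with the exact sigma: identity for any delta
    rng = np.random.default_rng(8)
    for _ in range(50):
        R = rng.uniform(0.4, 2.9)
        C = rng.uniform(-0.3, 0.3)
        D = rng.uniform(-1.5, 1.5)
        d = rng.uniform(-np.pi / 4 + 1e-3, np.pi / 4 - 1e-3)
        cf, _ = closed_form_params(R, C, D, d)
        rec = delta_from_B(cf.maps["B"], float(cf.meta["sigma"]))
        assert float(rec) == pytest.approx(d, abs=1e-10)


def test_delta_from_B_spec_point():
    """B at (delta = 20 deg, R = 1.6, C = 0.2, Delta = pi/4) inverts back."""
    cf, _ = closed_form_params(1.6, 0.2, np.pi / 4, np.radians(20.0))
    sigma = float(cf.meta["sigma"])
    assert sigma == pytest.approx(0.10879, abs=1e-5)
    B = float(cf.maps["B"])
    assert B == pytest.approx(-0.5256, abs=1e-4)
    tan2d = (-B + 2 * sigma) / (1 + 2 * sigma * B)
    assert tan2d == pytest.approx(np.tan(np.radians(40.0)), abs=1e-9)
    assert np.degrees(float(delta_from_B(np.array(B), sigma))) == pytest.approx(20.0, abs=1e-6)


def test_quadrant_extension_sweep():
    """Noise-free sweep over the full range recovers every quadrant."""
    deltas = np.radians(np.linspace(-89.5, 89.5, 181))
    R = np.full_like(deltas, 1.6)
    imgs = stokes_images_from_ratios(R, np.zeros_like(deltas),
                                     np.zeros_like(deltas), deltas)
    meas = compute_parameters(imgs)
    dq = delta_from_B(meas["B"], 0.0)
    full, unambiguous = extend_delta_range(dq, meas["SHG_LD"], meas["SHG_45"], R)
    assert unambiguous.all()
    assert np.allclose(np.degrees(full), np.degrees(deltas), atol=1e-6)


def test_quadrant_example_60deg():
    imgs = stokes_images_from_ratios(np.array(1.6), np.array(0.0),
                                     np.array(0.0), np.radians(60.0))
    meas = compute_parameters(imgs)
    dq = delta_from_B(meas["B"], 0.0)
    full, _ = extend_delta_range(dq, meas["SHG_LD"], meas["SHG_45"], np.array(1.6))
    assert np.degrees(float(full)) == pytest.approx(60.0, abs=1e-6)


def test_quadrant_boundary_and_ambiguity():
    """At the +-45 deg boundary the diagonal dichroism still separates the
    candidates; a modulation-free fiber (R = 1, C = 0) is genuinely
    ambiguous and keeps the in-range candidate, flagged."""
    imgs = stokes_images_from_ratios(np.array(1.6), np.array(0.0),
                                     np.array(0.0), np.array(np.pi / 4))
    meas = compute_parameters(imgs)
    full, unamb = extend_delta_range(np.array(np.pi / 4), meas["SHG_LD"],
                                     meas["SHG_45"], np.array(1.6))
    assert np.degrees(float(full)) == pytest.approx(45.0, abs=1e-9)
    assert unamb[()]
    # R = 1: no orientation modulation at all -> ambiguous, tie-break in range
    flat = stokes_images_from_ratios(np.array(1.0), np.array(0.0),
                                     np.array(0.0), np.array(0.2))
    m2 = compute_parameters(flat)
    full2, unamb2 = extend_delta_range(np.array(0.2), m2["SHG_LD"],
                                       m2["SHG_45"], np.array(1.0))
    assert float(full2) == pytest.approx(0.2)
    assert not unamb2[()]


def test_r_from_cacd_branches():
    R, ok = r_from_cacd(np.array(1.10092))
    assert ok[()] and float(R) == pytest.approx(1.600, abs=1e-3)
    R, ok = r_from_cacd(np.array(2.0))
    assert float(R) == pytest.approx(3.0, abs=1e-9)  # double root
    Rp, _ = r_from_cacd(np.array(1.10092), branch="plus")
    assert float(Rp) == pytest.approx(7.667, abs=1e-3)
    # both branches substitute back into the CA_CD closed form
    for r in (float(R),):
        cf, _ = closed_form_params(r, 0.0, 0.0, 0.0)
        assert float(cf.maps["CA_CD"]) == pytest.approx(2.0, abs=1e-6)
    _, ok = r_from_cacd(np.array(0.0))
    assert not ok[()]


def test_r_from_cacd_and_L_exact_and_consistent():
    cf, _ = closed_form_params(1.95, 0.14142135623730948, np.pi / 4, 0.0)
    R, ok = r_from_cacd_and_L(cf.maps["CA_CD"], cf.maps["L"])
    assert ok[()] and float(R) == pytest.approx(1.95, abs=1e-6)
    # at C = 0 both paths agree to 1e-9
    cf0, _ = closed_form_params(1.6, 0.0, 0.0, 0.0)
    R21, _ = r_from_cacd_and_L(cf0.maps["CA_CD"], cf0.maps["L"])
    R20, _ = r_from_cacd(cf0.maps["CA_CD"])
    assert float(R21) == pytest.approx(float(R20), abs=1e-9)
    # degenerate point R = 1 (CA_CD = 0, L = 2/3)
    Rd, okd = r_from_cacd_and_L(np.array(0.0), np.array(2.0 / 3.0))
    assert okd[()] and float(Rd) == pytest.approx(1.0, abs=1e-9)


def test_chiral_components_fixed_point():
    res = chiral_components(np.array(0.23824714), np.array(-0.23824714),
                            np.array(1.6))
    assert float(res["c_cos"]) == pytest.approx(0.14142135, abs=1e-6)
    assert float(res["c_sin"]) == pytest.approx(0.14142135, abs=1e-6)
    assert float(res["C"]) == pytest.approx(0.2, abs=1e-6)
    assert np.degrees(float(res["Delta"])) == pytest.approx(45.0, abs=1e-4)
    assert res["valid"][()]


def test_chiral_components_sources_agree():
    cf, _ = closed_form_params(1.95, -0.14142135623730948, np.pi / 3, 0.0)
    tw = chiral_components(cf.maps["T"], cf.maps["W"], np.array(1.95))
    hcd = chiral_components(cf.maps["T"], cf.maps["W"], np.array(1.95),
                            H=cf.maps["H"], shg_cd=cf.maps["SHG_CD"], source="HCD")
    assert float(tw["c_cos"]) == pytest.approx(float(hcd["c_cos"]), abs=1e-9)
    assert float(tw["c_sin"]) == pytest.approx(float(hcd["c_sin"]), abs=1e-9)
    # sign of C follows C cos(Delta)
    assert float(tw["C"]) < 0
    # the tan(Delta) closed form agrees with the atan2 phase
    td = tan_delta_from_cd_h(cf.maps["SHG_CD"], cf.maps["H"], 1.95,
                             C=float(tw["C"]))
    assert float(td) == pytest.approx(np.tan(np.pi / 3), abs=1e-9)


def test_chiral_validity_threshold():
    assert not chiral_validity_mask(np.array(0.01), np.array(0.01))[()]
    assert chiral_validity_mask(np.array(0.05), np.array(0.0))[()]
    assert chiral_validity_mask(np.array(0.0), np.array(0.0), threshold=0.0)[()]


def test_full_recovery_grid():
    """Noise-free full-pipeline recovery across the physical regime:
    R, delta, C, Delta all to numerical precision (exact-sigma mode)."""
    Rg, Cg, Dg, dg = np.meshgrid(
        np.linspace(0.5, 2.9, 6), np.linspace(-0.3, 0.3, 5),
        np.linspace(-1.4, 1.4, 5), np.radians(np.linspace(-85, 85, 7)),
        indexing="ij",
    )
    imgs = stokes_images_from_ratios(Rg, Cg, Dg, dg)
    meas = compute_parameters(imgs)
    um = invert_maps(meas, sigma_mode="exact")
    assert np.nanmax(np.abs(um.R - Rg)) < 1e-6
    m = um.masks["delta"]
    assert np.degrees(np.nanmax(np.abs(um.delta - dg)[m])) < 1e-3
    chiral = np.abs(Cg) > 1e-9
    assert np.nanmax(np.abs(um.C - Cg)[chiral]) < 1e-6
    expect_phase = np.arctan2(Cg * np.sin(Dg), Cg * np.cos(Dg))
    assert np.nanmax(np.abs(um.Delta - expect_phase)[chiral]) < 1e-6
    # the two Delta conventions agree on their shared principal domain
    principal = chiral & (np.abs(Dg) < np.pi / 2 - 1e-6) & (Cg > 0)
    assert np.nanmax(np.abs(um.Delta_principal - Dg)[principal]) < 1e-6


def test_sigma_h3_biases_delta_slightly():
    """The default sigma = H/3 carries an O(C^2) error that perturbs delta
    for strongly chiral fibers; the exact mode does not."""
    imgs = stokes_images_from_ratios(np.array(1.6), np.array(0.25),
                                     np.array(np.pi / 6), np.radians(20.0))
    meas = compute_parameters(imgs)
    d_h3 = invert_maps(meas, sigma_mode="h3").delta
    d_exact = invert_maps(meas, sigma_mode="exact").delta
    assert abs(np.degrees(float(d_exact)) - 20.0) < 1e-6
    assert abs(np.degrees(float(d_h3)) - 20.0) > abs(np.degrees(float(d_exact)) - 20.0)
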