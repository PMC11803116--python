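"""Inversion of DSP parameter maps to ultrastructural parameters.

The pipeline recovers, per pixel:

* the achiral ratio R — either from CA_CD alone (circular-only, small-C
  approximation) or from CA_CD and L jointly (exact in C);
* the chiral components C cos(Delta) and C sin(Delta) from (T, W) or
  (H, SHG_CD); because C^2 appears on both sides of the closed forms the
  solution is a fixed-point iteration started at C = 0;
* the signed magnitude C = sign(C cos Delta) sqrt((C cos D)^2 + (C sin D)^2)
  and the phase Delta (atan2 and tan-based conventions both emitted);
* the chirality correction sigma, then the in-plane orientation delta from
  the B (or A) parameter, extended from the quarter range (-pi/4, pi/4) to
  (-pi/2, pi/2] using the measured signs of SHG_LD and SHG_45 against their
  model predictions at the two candidate angles.

Validity masks propagate through every stage; the 0.02 chirality threshold
removes Delta estimates where both chiral components are too small for the
phase to be meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import DSPParameterSet, _s0_linear_exact

__all__ = [
    "UltrastructureMaps",
    "delta_from_A",
    "delta_from_B",
    "extend_delta_range",
    "r_from_cacd",
    "r_from_cacd_and_L",
    "chiral_components",
    "chiral_validity_mask",
    "invert_maps",
    "CHIRAL_THRESHOLD",
]

#: default chirality threshold below which Delta is considered undefined
CHIRAL_THRESHOLD = 0.02


@dataclass
class UltrastructureMaps:
    """Recovered ultrastructural parameter maps with validity masks.

    ``Delta`` is the atan2(C sin D, C cos D) phase in (-pi, pi];
    ``Delta_principal`` is the tan-based phase from D = -W/T in
    (-pi/2, pi/2).  ``masks`` maps quantity name -> boolean validity.
    """

    delta: np.ndarray
    R: np.ndarray
    c_cos: np.ndarray
    c_sin: np.ndarray
    C: np.ndarray
    Delta: np.ndarray
    Delta_principal: np.ndarray
    sigma: np.ndarray
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def valid(self, name: str) -> np.ndarray:
        v = getattr(self, name)
        m = self.masks.get(name)
        return v[m] if m is not None else np.ravel(v)


def _quarter_angle(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """delta = arctan(num/den)/2 in (-pi/4, pi/4], poles mapping to pi/4."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den != 0, num / np.where(den != 0, den, 1.0), np.inf * np.sign(num + (num == 0)))
    return 0.5 * np.arctan(ratio)


def delta_from_A(A: np.ndarray, sigma: np.ndarray | float = 0.0) -> np.ndarray:
    """Quarter-range orientation from the A parameter,
    tan(2 delta) = ((A-1) - (A+1) sigma) / ((A+1) + (A-1) sigma)."""
    A = np.asarray(A, dtype=float)
    num = (A - 1.0) - (A + 1.0) * sigma
    den = (A + 1.0) + (A - 1.0) * sigma
    return _quarter_angle(num, den)


def delta_from_B(B: np.ndarray, sigma: np.ndarray | float = 0.0) -> np.ndarray:
    """Quarter-range orientation from the B parameter,
    tan(2 delta) = (-B + 2 sigma) / (1 + 2 sigma B) — the exact algebraic
    inverse of the B closed form."""
    B = np.asarray(B, dtype=float)
    num = -B + 2.0 * np.asarray(sigma)
    den = 1.0 + 2.0 * np.asarray(sigma) * B
    return _quarter_angle(num, den)


def _predict_ld_45(delta, R, p, q):
    """Exact model predictions of (SHG_LD, SHG_45) at orientation delta."""
    s0_h = _s0_linear_exact(np.pi / 2 - delta, R, p, q)
    s0_v = _s0_linear_exact(-delta, R, p, q)
    s0_p = _s0_linear_exact(np.pi / 4 - delta, R, p, q)
    s0_m = _s0_linear_exact(-np.pi / 4 - delta, R, p, q)
    return 2 * (s0_h - s0_v) / (s0_h + s0_v), 2 * (s0_p - s0_m) / (s0_p + s0_m)


def extend_delta_range(
    delta_quarter: np.ndarray,
    shg_ld: np.ndarray,
    shg_45: np.ndarray,
    R: np.ndarray | float = 1.6,
    c_cos: np.ndarray | float = 0.0,
    c_sin: np.ndarray | float = 0.0,
    ambiguity_tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Extend quarter-range delta to (-pi/2, pi/2] with measured dichroisms.

    The two candidates delta and delta +- pi/2 produce opposite modulation
    patterns of SHG_LD and SHG_45; the candidate whose model prediction
    (at the recovered R and chiral components) is closer to the measured
    pair wins.  Returns (delta_full, unambiguous_mask); pixels where both
    candidates explain the measurement equally well (within
    ``ambiguity_tol`` relatively) are flagged ambiguous, with the in-range
    candidate kept as the deterministic tie-break.
    """
    dq = np.asarray(delta_quarter, dtype=float)
    alt = np.where(dq > 0, dq - np.pi / 2, dq + np.pi / 2)
    R, p, q = (np.asarray(x, dtype=float) for x in (R, c_cos, c_sin))
    ld1, d45_1 = _predict_ld_45(dq, R, p, q)
    ld2, d45_2 = _predict_ld_45(alt, R, p, q)
    score1 = np.abs(shg_ld - ld1) + np.abs(shg_45 - d45_1)
    score2 = np.abs(shg_ld - ld2) + np.abs(shg_45 - d45_2)
    take_alt = score2 < score1  # ties stay on the in-range candidate
    out = np.where(take_alt, alt, dq)
    total = score1 + score2
    # ambiguous when the candidates are indistinguishable relatively or the
    # modulation is absent altogether (e.g. R = 1, C = 0: no dichroism)
    unambiguous = (np.abs(score1 - score2) > ambiguity_tol * (total + 1e-300)) & (
        total > 1e-12
    )
    return out, unambiguous


def r_from_cacd(
    ca_cd: np.ndarray, branch: str = "minus", C: np.ndarray | float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """R from CA_CD alone:  R = 1 + 4/CA_CD +- 2 sqrt(4/CA_CD^2 - 1 - 2C^2
    + 4C^2/CA_CD).  With the default C = 0 this is the small-C form.

    The minus branch is the collagen regime (R < 1 + 4/CA_CD); the plus
    branch is the conjugate root.  Returns (R, valid) where ``valid`` is
    False at CA_CD = 0 or negative discriminant.
    """
    if branch not in ("minus", "plus"):
        raise ValueError("branch must be 'minus' or 'plus'")
    x = np.asarray(ca_cd, dtype=float)
    C = np.asarray(C, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 4.0 / x
        disc = 4.0 / x**2 - 1.0 - 2.0 * C**2 + 4.0 * C**2 / x
        root = np.sqrt(np.clip(disc, 0.0, None))
        sign = -1.0 if branch == "minus" else 1.0
        R = 1.0 + inv + sign * 2.0 * root
    valid = (x != 0) & (disc >= -1e-12) & np.isfinite(R)
    return np.where(valid, R, np.nan), valid


def _cacd_from_RC2(R, c2):
    return 8.0 * ((R - 1.0) + 2.0 * c2) / ((R - 1.0) ** 2 + 8.0 * c2 + 4.0)


def _r_from_L_small_c(L):
    """Invert the L closed form at C = 0:
    (3L - 2) R^2 + (2L - 4) R + (7L - 2) = 0, lower root (collagen regime);
    linear where the leading coefficient vanishes (L = 2/3)."""
    L = np.asarray(L, dtype=float)
    a2 = 3.0 * L - 2.0
    a1 = 2.0 * L - 4.0
    a0 = 7.0 * L - 2.0
    lin = np.abs(a2) < 1e-12
    disc = np.clip(a1**2 - 4.0 * a2 * a0, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        quad = (-a1 - np.sqrt(disc)) / (2.0 * np.where(lin, 1.0, a2))
        linear = -a0 / np.where(np.abs(a1) > 1e-300, a1, 1.0)
    return np.where(lin, linear, quad)


def _implied_c2_from_L(R, L):
    """C^2 consistent with the L closed form at a given R."""
    return (2.0 * (R + 1.0) ** 2 - L * (3.0 * R**2 + 2.0 * R + 7.0)) / (16.0 * (1.0 + L))


def r_from_cacd_and_L(
    ca_cd: np.ndarray, L: np.ndarray, branch: str = "auto"
) -> tuple[np.ndarray, np.ndarray]:
    """C-independent R from CA_CD and L jointly.

    R = (+-2 sqrt(3 (CA_CD - 2)(L - 2)(2 CA_CD + 6 L + CA_CD L + 4))
         + 6 L + 3 CA_CD L + 12) / (4 CA_CD + 6 L - CA_CD L - 4).

    ``branch`` 'auto' picks per pixel the root whose back-substitution into
    the CA_CD and L closed forms has the smaller residual (minus as the
    tie-break, the collagen regime); 'minus'/'plus' force a root.
    Returns (R, valid): invalid where the radicand is negative or the
    denominator vanishes.
    """
    x = np.asarray(ca_cd, dtype=float)
    L = np.asarray(L, dtype=float)
    x, L = np.broadcast_arrays(x, L)
    radicand = 3.0 * (x - 2.0) * (L - 2.0) * (2.0 * x + 6.0 * L + x * L + 4.0)
    den = 4.0 * x + 6.0 * L - x * L - 4.0
    degenerate = np.abs(den) <= 1e-9 * (1.0 + np.abs(x) + np.abs(L))
    valid = (radicand >= -1e-12) & np.isfinite(den)
    root = np.sqrt(np.clip(radicand, 0.0, None))
    num0 = 6.0 * L + 3.0 * x * L + 12.0
    safe_den = np.where(degenerate, 1.0, den)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_minus = (num0 - 2.0 * root) / safe_den
        r_plus = (num0 + 2.0 * root) / safe_den
    if np.any(degenerate):
        # the quadratic's leading coefficient vanishes (the R = 1 manifold):
        # fall back to the L-only relation at C = 0, which is linear there
        r_deg = _r_from_L_small_c(L)
        r_minus = np.where(degenerate, r_deg, r_minus)
        r_plus = np.where(degenerate, r_deg, r_plus)
    if branch == "minus":
        R = r_minus
    elif branch == "plus":
        R = r_plus
    elif branch == "auto":
        # Both roots can satisfy the (CA_CD, L) pair exactly, each with its
        # own implied C^2, so the comparison must be decisive: the plus root
        # is taken only where its back-substitution residual is clearly
        # smaller, otherwise the collagen-regime minus root wins.
        res = []
        for cand in (r_minus, r_plus):
            c2 = _implied_c2_from_L(cand, L)
            bad = c2 < -1e-12
            resid = np.abs(_cacd_from_RC2(cand, np.clip(c2, 0.0, None)) - x)
            res.append(np.where(bad | ~np.isfinite(resid), np.inf, resid))
        atol = 1e-9 * (1.0 + np.abs(x))
        with np.errstate(invalid="ignore"):
            take_plus = res[1] < res[0] - atol
        R = np.where(take_plus, r_plus, r_minus)
    else:
        raise ValueError("branch must be 'minus', 'plus' or 'auto'")
    valid = valid & np.isfinite(R)
    return np.where(valid, R, np.nan), valid


def chiral_components(
    T: np.ndarray,
    W: np.ndarray,
    R: np.ndarray,
    H: np.ndarray | None = None,
    shg_cd: np.ndarray | None = None,
    source: str = "TW",
    tol: float = 1e-10,
    max_iter: int = 100,
) -> dict[str, np.ndarray]:
    """Chiral components (C cos Delta, C sin Delta, C, Delta) at known R.

    The closed forms contain C^2 on their right-hand sides, so the pair is
    solved by fixed-point iteration from C = 0; in the physical regime
    (|C| well below 1) the C^2 corrections are small against the leading
    denominators and the iteration contracts.  ``source`` selects which
    measured pair drives the solution: "TW" (default) or "HCD"
    (H and SHG_CD).  Non-convergent pixels are flagged invalid.
    """
    R = np.asarray(R, dtype=float)
    if source == "TW":
        u, v = np.asarray(T, float), np.asarray(W, float)
    elif source == "HCD":
        if H is None or shg_cd is None:
            raise ValueError("source 'HCD' requires H and shg_cd")
        u, v = np.asarray(H, float), np.asarray(shg_cd, float)
    else:
        raise ValueError("source must be 'TW' or 'HCD'")

    c2 = np.zeros(np.broadcast_shapes(u.shape, R.shape), dtype=float)
    c_cos = np.zeros_like(c2)
    c_sin = np.zeros_like(c2)
    converged = np.zeros(c2.shape, dtype=bool)
    rp1 = R + 1.0
    for _ in range(max_iter):
        if source == "TW":
            big = 3.0 * R**2 + 2.0 * R + 7.0 + 16.0 * c2
            c_cos_new = u * big / (12.0 * rp1)
            c_sin_new = -v * big / (12.0 * rp1)
        else:
            c_cos_new = u * (rp1**2 - 8.0 * c2) / (6.0 * rp1)
            c_sin_new = -v * ((R - 1.0) ** 2 + 8.0 * c2 + 4.0) / (8.0 * rp1)
        c2_new = c_cos_new**2 + c_sin_new**2
        step = np.abs(np.sqrt(c2_new) - np.sqrt(c2))
        c_cos, c_sin, c2 = c_cos_new, c_sin_new, c2_new
        converged = step < tol
        if np.all(converged | ~np.isfinite(step)):
            break
    mag = np.sqrt(c2)
    C = np.where(c_cos < 0, -mag, mag)  # sign carried by C cos(Delta)
    Delta = np.arctan2(c_sin, c_cos)
    valid = converged & np.isfinite(c_cos) & np.isfinite(c_sin)
    return {
        "c_cos": c_cos,
        "c_sin": c_sin,
        "C": C,
        "Delta": Delta,
        "valid": valid,
    }


def chiral_validity_mask(
    c_cos: np.ndarray, c_sin: np.ndarray, threshold: float = CHIRAL_THRESHOLD
) -> np.ndarray:
    """Delta is defined only where at least one chiral component exceeds the
    threshold (default 0.02)."""
    return (np.abs(c_cos) >= threshold) | (np.abs(c_sin) >= threshold)


def tan_delta_from_cd_h(shg_cd, H, R, C=0.0):
    """tan(Delta) from SHG_CD and H at known R (and optionally C),
    tan D = -(3/4) SHG_CD ((R-1)^2 + 8C^2 + 4) / (H ((R+1)^2 - 8C^2))."""
    shg_cd, H, R, C = (np.asarray(x, float) for x in (shg_cd, H, R, C))
    c2 = C**2
    with np.errstate(divide="ignore", invalid="ignore"):
        return -0.75 * shg_cd * ((R - 1.0) ** 2 + 8.0 * c2 + 4.0) / (
            H * ((R + 1.0) ** 2 - 8.0 * c2)
        )


def invert_maps(
    params: DSPParameterSet,
    r_path: str = "cacd_l",
    r_branch: str = "auto",
    delta_path: str = "B",
    sigma_mode: str = "h3",
    chiral_source: str = "TW",
    c_threshold: float = CHIRAL_THRESHOLD,
) -> UltrastructureMaps:
    """Full inversion of a DSP parameter set to ultrastructure maps.

    ``r_path`` is "cacd_l" (C-independent, default) or "cacd" (circular-only
    small-C form).  ``sigma_mode`` "h3" takes sigma = H/3 (the direct
    measurement); "exact" computes sigma = 2 C cos(Delta)/(R+1) from the
    recovered chiral components, removing the (R+1)^2 >> 8C^2 approximation.
    ``delta_path`` is "B" (circular incident, exact inverse) or "A"
    (linear-only, small-C form).
    """
    if r_path == "cacd_l":
        R, r_valid = r_from_cacd_and_L(params["CA_CD"], params["L"], branch=r_branch)
    elif r_path == "cacd":
        branch = "minus" if r_branch == "auto" else r_branch
        R, r_valid = r_from_cacd(params["CA_CD"], branch=branch)
    else:
        raise ValueError("r_path must be 'cacd_l' or 'cacd'")

    chir = chiral_components(
        params["T"], params["W"], R,
        H=params["H"], shg_cd=params["SHG_CD"], source=chiral_source,
    )
    if sigma_mode == "exact":
        sigma = 2.0 * chir["c_cos"] / (R + 1.0)
    elif sigma_mode == "h3":
        sigma = np.asarray(params["H"], float) / 3.0
    else:
        raise ValueError("sigma_mode must be 'h3' or 'exact'")

    if delta_path == "B":
        dq = delta_from_B(params["B"], sigma)
    elif delta_path == "A":
        dq = delta_from_A(params["A"], sigma)
    else:
        raise ValueError("delta_path must be 'A' or 'B'")
    delta, unambiguous = extend_delta_range(
        dq, params["SHG_LD"], params["SHG_45"], R, chir["c_cos"], chir["c_sin"]
    )

    with np.errstate(invalid="ignore"):
        delta_principal = np.arctan(np.asarray(params["D"], float))

    base = np.ones(np.shape(R), dtype=bool)
    for name in ("CA_CD", "L", "T", "W", "H", "SHG_CD"):
        m = params.masks.get(name)
        if m is not None:
            base = base & m
    chiral_ok = chiral_validity_mask(chir["c_cos"], chir["c_sin"], c_threshold)
    masks = {
        "R": base & r_valid,
        "c_cos": base & r_valid & chir["valid"],
        "c_sin": base & r_valid & chir["valid"],
        "C": base & r_valid & chir["valid"],
        "Delta": base & r_valid & chir["valid"] & chiral_ok,
        "Delta_principal": base & chiral_ok & params.masks.get("D", base),
        "delta": base & r_valid & unambiguous,
        "sigma": base & r_valid & chir["valid"],
    }
    return UltrastructureMaps(
        delta=delta,
        R=R,
        c_cos=chir["c_cos"],
        c_sin=chir["c_sin"],
        C=chir["C"],
        Delta=chir["Delta"],
        Delta_principal=delta_principal,
        sigma=sigma,
        masks=masks,
        meta={
            "r_path": r_path,
            "r_branch": r_branch,
            "delta_path": delta_path,
            "sigma_mode": sigma_mode,
            "chiral_source": chiral_source,
            "c_threshold": c_threshold,
            "ambiguous_count": int(np.size(unambiguous) - np.count_nonzero(unambiguous)),
        },
    )
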