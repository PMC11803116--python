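"""DSP polarimetric parameters: measured-side ratios and closed forms.

Eleven dimensionless parameters are formed from sums and differences of the
SHG Stokes components over the six incident states.  Four depend on the
in-plane fiber orientation delta (A, B, SHG_LD, SHG_45) and seven are
delta-independent (CA_CD, L, T, H, SHG_CD, W, D).

Each parameter exists twice: as a per-pixel ratio of measured Stokes
components (``orientation_dependent_params`` / ``orientation_independent_params``)
and as an analytic prediction from the model parameters (R, C, Delta, delta)
(``closed_form_params``).  On noise-free simulations the two sides agree to
numerical precision for the exact forms, which is the core consistency
check of the whole package.  Where the printed theory uses the small-
chirality approximation (|R^2 - 1| >> 4 C^2 for A, SHG_LD, SHG_45;
(R+1)^2 >> 8 C^2 for H ~ 3 sigma), both the exact and the approximate
variants are first-class outputs so the approximation error can be
quantified instead of silently mixed in.

Notation used throughout:  p = C cos(Delta),  q = C sin(Delta),
sigma = 2 p / (R + 1),  a = R^2 - 1 + 4 C^2,  b = 2 (R - 1) p,
kappa = ((3 R^2 + 2 R + 7) + 16 C^2) / ((R + 1)(R - 3)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filtering import StokesImageSet

__all__ = [
    "DSPParameterSet",
    "DerivedCoefficients",
    "orientation_dependent_params",
    "orientation_independent_params",
    "compute_parameters",
    "closed_form_params",
    "DENOMINATOR_FLOOR",
]

#: relative denominator floor: |den| below this times the pixel s0 scale is masked
DENOMINATOR_FLOOR = 1e-6

PARAM_NAMES = ("A", "B", "SHG_LD", "SHG_45", "CA_CD", "L", "T", "H", "SHG_CD", "W", "D")


@dataclass
class DSPParameterSet:
    """Maps of the eleven DSP parameters with per-parameter validity masks.

    ``approx`` holds the sigma-approximate variants (closed-form side only).
    ``masked_counts`` records, per parameter, how many pixels were dropped by
    the denominator floor — needed to reproduce histogram statistics.
    """

    maps: dict[str, np.ndarray]
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    approx: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]

    def valid(self, name: str) -> np.ndarray:
        """Values of ``name`` where its mask is True (1D)."""
        m = self.masks.get(name)
        v = self.maps[name]
        return v[m] if m is not None else np.ravel(v)

    @property
    def masked_counts(self) -> dict[str, int]:
        return {k: int(np.size(m) - np.count_nonzero(m)) for k, m in self.masks.items()}

    def update(self, other: "DSPParameterSet") -> "DSPParameterSet":
        self.maps.update(other.maps)
        self.masks.update(other.masks)
        self.approx.update(other.approx)
        self.meta.update(other.meta)
        return self


@dataclass(frozen=True)
class DerivedCoefficients:
    """a = R^2 - 1 + 4C^2, b = 2(R-1) C cos(Delta), and the kappa of the
    linear-dichroism closed forms."""

    a: np.ndarray | float
    b: np.ndarray | float
    kappa: np.ndarray | float


def _safe_ratio(
    num: np.ndarray, den: np.ndarray, scale: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray]:
    """num/den with pixels masked where |den| is below the relative floor."""
    den = np.asarray(den, dtype=float)
    ok = np.abs(den) >= DENOMINATOR_FLOOR * np.asarray(scale, dtype=float)
    out = np.full(np.broadcast_shapes(np.shape(num), np.shape(den)), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        np.divide(num, den, out=out, where=ok)
    return out, ok


def orientation_dependent_params(images: StokesImageSet) -> DSPParameterSet:
    """A, B, SHG_LD and SHG_45 maps from measured Stokes images."""
    s = images.stokes
    scale = images.mean_s0()
    d_hv = s["HLP"][..., 0] - s["VLP"][..., 0]
    sum_hv = s["HLP"][..., 0] + s["VLP"][..., 0]
    d_45 = s["P45"][..., 0] - s["M45"][..., 0]
    sum_45 = s["P45"][..., 0] + s["M45"][..., 0]

    A, mA = _safe_ratio(d_hv - d_45, d_hv + d_45, scale)
    B, mB = _safe_ratio(
        s["RCP"][..., 2] + s["LCP"][..., 2], s["RCP"][..., 1] + s["LCP"][..., 1], scale
    )
    shg_ld, mLD = _safe_ratio(2.0 * d_hv, sum_hv, scale)
    shg_45, m45 = _safe_ratio(2.0 * d_45, sum_45, scale)
    base = images.mask
    return DSPParameterSet(
        maps={"A": A, "B": B, "SHG_LD": shg_ld, "SHG_45": shg_45},
        masks={"A": mA & base, "B": mB & base, "SHG_LD": mLD & base, "SHG_45": m45 & base},
    )


def orientation_independent_params(images: StokesImageSet) -> DSPParameterSet:
    """CA_CD, L, T, H, SHG_CD, W and D maps from measured Stokes images."""
    s = images.stokes
    scale = images.mean_s0()
    sum4 = sum(s[m][..., 0] for m in ("HLP", "VLP", "P45", "M45"))
    lin_num = s["HLP"][..., 1] - s["VLP"][..., 1] + s["P45"][..., 2] - s["M45"][..., 2]
    t_num = s["HLP"][..., 2] - s["VLP"][..., 2] - (s["P45"][..., 1] - s["M45"][..., 1])
    w_num = sum(s[m][..., 3] for m in ("HLP", "VLP", "P45", "M45"))
    sum_circ = s["RCP"][..., 0] + s["LCP"][..., 0]

    L, mL = _safe_ratio(lin_num, sum4, scale)
    T, mT = _safe_ratio(t_num, sum4, scale)
    W, mW = _safe_ratio(w_num, sum4, scale)
    H, mH = _safe_ratio(t_num, lin_num, scale)
    ca_cd, mCA = _safe_ratio(2.0 * (s["RCP"][..., 3] - s["LCP"][..., 3]), sum_circ, scale)
    shg_cd, mCD = _safe_ratio(2.0 * (s["RCP"][..., 0] - s["LCP"][..., 0]), sum_circ, scale)
    D, mD = _safe_ratio(-w_num, t_num, scale)
    base = images.mask
    masks = {
        "CA_CD": mCA, "L": mL, "T": mT, "H": mH,
        "SHG_CD": mCD, "W": mW, "D": mD,
    }
    return DSPParameterSet(
        maps={"CA_CD": ca_cd, "L": L, "T": T, "H": H, "SHG_CD": shg_cd, "W": W, "D": D},
        masks={k: v & base for k, v in masks.items()},
    )


def compute_parameters(images: StokesImageSet) -> DSPParameterSet:
    """All eleven DSP parameter maps from measured Stokes images."""
    out = orientation_dependent_params(images)
    return out.update(orientation_independent_params(images))


def _s0_linear_exact(m: np.ndarray, R, p, q) -> np.ndarray:
    """Exact s0 for an incident linear state at fiber-frame angle ``m``
    (angle between the state and the fiber axis), from the CCS field model
    written out component-wise."""
    c2, s2 = np.cos(2 * m), np.sin(2 * m)
    ex_re = s2 - p * (1.0 + c2)
    ex_im = -q * (1.0 + c2)
    ez_re = 0.5 * (1.0 + R) + 0.5 * (R - 1.0) * c2 + p * s2
    ez_im = q * s2
    return ex_re**2 + ex_im**2 + ez_re**2 + ez_im**2


def closed_form_params(
    R, C, delta_phase, delta=0.0
) -> tuple[DSPParameterSet, DerivedCoefficients]:
    """Analytic DSP parameters predicted from (R, C, Delta, delta).

    Returns exact values in ``maps`` and the sigma-approximate variants of
    A, SHG_LD, SHG_45 and H in ``approx``.  ``masks`` flags the poles
    (R = 3 enters kappa; R = -1 the sigma normalization; delta at the
    45-degree singularities of A and B).  All inputs broadcast.
    """
    R, C, delta_phase, delta = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (R, C, delta_phase, delta))
    )
    p = C * np.cos(delta_phase)
    q = C * np.sin(delta_phase)
    c2 = C**2
    sigma = 2.0 * p / (R + 1.0)
    a = R**2 - 1.0 + 4.0 * c2
    b = 2.0 * (R - 1.0) * p
    den_k = (R + 1.0) * (R - 3.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(
            den_k != 0, ((3.0 * R**2 + 2.0 * R + 7.0) + 16.0 * c2) / np.where(den_k != 0, den_k, 1.0), np.nan
        )

    cos2d, sin2d = np.cos(2.0 * delta), np.sin(2.0 * delta)

    big = 3.0 * R**2 + 2.0 * R + 7.0 + 16.0 * c2
    circ = (R - 1.0) ** 2 + 8.0 * c2 + 4.0

    L = (2.0 * (R + 1.0) ** 2 - 16.0 * c2) / big
    ca_cd = 8.0 * ((R - 1.0) + 2.0 * c2) / circ
    T = 12.0 * p * (R + 1.0) / big
    shg_cd = -8.0 * q * (R + 1.0) / circ
    W = -12.0 * q * (R + 1.0) / big
    H_exact = 6.0 * p * (R + 1.0) / ((R + 1.0) ** 2 - 8.0 * c2)
    with np.errstate(divide="ignore", invalid="ignore"):
        D = np.where(p != 0, q / p, np.nan)

    A_num = -(a + b) * cos2d - (a - b) * sin2d
    A_den = -(a - b) * cos2d + (a + b) * sin2d
    with np.errstate(divide="ignore", invalid="ignore"):
        A = A_num / A_den
        B = (-sin2d + 2.0 * sigma * cos2d) / (cos2d + 2.0 * sigma * sin2d)

    # exact SHG_LD / SHG_45 via the component-wise pure-state s0 formulas
    s0_h = _s0_linear_exact(np.pi / 2 - delta, R, p, q)
    s0_v = _s0_linear_exact(-delta, R, p, q)
    s0_p = _s0_linear_exact(np.pi / 4 - delta, R, p, q)
    s0_m = _s0_linear_exact(-np.pi / 4 - delta, R, p, q)
    shg_ld = 2.0 * (s0_h - s0_v) / (s0_h + s0_v)
    shg_45 = 2.0 * (s0_p - s0_m) / (s0_p + s0_m)

    # sigma-approximate printed forms
    root1 = np.sqrt(1.0 + sigma**2)
    root2 = np.sqrt(1.0 + 4.0 * sigma**2)
    phase2 = 2.0 * np.arctan(sigma / (1.0 + root1))
    phase4 = 2.0 * np.arctan(2.0 * sigma / (1.0 + root2))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (R - 1.0) / (R - 3.0)
        ld_app = -8.0 * ratio * root1 * np.cos(2.0 * delta + phase2) / (
            root2 * np.cos(4.0 * delta + phase4) + kappa
        )
        p45_phase = 2.0 * np.arctan(1.0 / (sigma + root1))
        s45_app = 8.0 * ratio * root1 * np.cos(2.0 * delta - p45_phase) / (
            -root2 * np.cos(4.0 * delta + phase4) + kappa
        )
        A_app = (-(1.0 + sigma) * cos2d - (1.0 - sigma) * sin2d) / (
            -(1.0 - sigma) * cos2d + (1.0 + sigma) * sin2d
        )

    pole = np.isclose(R, 3.0) | np.isclose(R, -1.0)
    ok = ~pole & np.isfinite(A) & np.isfinite(B)
    params = DSPParameterSet(
        maps={
            "A": A, "B": B, "SHG_LD": shg_ld, "SHG_45": shg_45,
            "CA_CD": ca_cd, "L": L, "T": T, "H": H_exact,
            "SHG_CD": shg_cd, "W": W, "D": D,
        },
        masks={"A": np.isfinite(A), "B": np.isfinite(B),
               "SHG_LD": ~pole, "SHG_45": ~pole, "D": np.isfinite(D)},
        approx={"A": A_app, "SHG_LD": ld_app, "SHG_45": s45_app, "H": 3.0 * sigma},
        meta={"sigma": sigma, "pole": pole, "valid": ok},
    )
    return params, DerivedCoefficients(a=a, b=b, kappa=kappa)
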