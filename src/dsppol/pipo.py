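"""Linear polarization-in polarization-out (PIPO) simulation and fitting.

PIPO probes the same SHG response with an 8x8 grid of linear polarizer /
analyzer angles (0 to 157.5 deg in 22.5 deg steps) and recovers the
ultrastructure by per-pixel nonlinear least squares instead of closed
forms.  It is the established baseline the closed-form pipeline is
compared against.

The simulator reuses the exact same forward model as the 36-state stacks
(no separate trigonometric formula), which guarantees internal consistency
between the two measurement geometries.  The fitter parameterizes the
response with (delta, R, c) where c = C cos(Delta): the imaginary chiral
part C sin(Delta) enters linear-only intensities only at second order and
is not resolvable by a PIPO measurement, matching what PIPO fitting
extracts in practice.

Fitting is a batched Levenberg-Marquardt over all pixels simultaneously
(3 structural parameters plus a profiled-out amplitude), with multi-start
over the initial orientation to escape the 90-degree ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import BirefringenceSpec, PolarimetricStack, simulate_stack
from .polarization import PIPO_ANGLES_DEG
from .tensor import MolecularSusceptibility

__all__ = ["PipoFitResult", "simulate_pipo", "fit_pipo", "fit_pipo_image", "pipo_model"]


@dataclass
class PipoFitResult:
    """Per-pixel PIPO fit output (arrays share the pixel grid shape)."""

    delta: np.ndarray
    R: np.ndarray
    c_cos: np.ndarray
    amplitude: np.ndarray
    residual: np.ndarray
    converged: np.ndarray
    meta: dict = field(default_factory=dict)


def simulate_pipo(
    mol: MolecularSusceptibility,
    delta: np.ndarray | float,
    alpha: np.ndarray | float,
    biref: BirefringenceSpec | None = None,
    gain: float = 100.0,
    noise_seed: int | None = None,
) -> PolarimetricStack:
    """Simulate the 64-image PIPO stack with the shared forward model."""
    return simulate_stack(
        mol, delta, alpha, states="pipo", gain=gain, biref=biref, noise_seed=noise_seed
    )


def pipo_model(
    delta: np.ndarray, R: np.ndarray, c: np.ndarray, angles_deg=PIPO_ANGLES_DEG
) -> np.ndarray:
    """Noise-free PIPO intensity pattern (..., n_psg, n_psa), unit amplitude.

    Written in the fiber frame: for an incident linear state at angle
    m = theta - delta from the fiber axis the SHG field is

        E_x = sin 2m - c (1 + cos 2m)
        E_z = (1 - cos 2m)/2 + c sin 2m + R (1 + cos 2m)/2

    and the analyzer at lab angle phi projects with (sin(phi - delta),
    cos(phi - delta)).  Real arithmetic throughout (c = C cos Delta).
    """
    delta, R, c = (np.asarray(x, dtype=float) for x in (delta, R, c))
    ang = np.radians(np.asarray(angles_deg, dtype=float))
    m = ang - delta[..., None]  # (..., n_psg)
    c2m, s2m = np.cos(2 * m), np.sin(2 * m)
    ex = s2m - c[..., None] * (1.0 + c2m)
    ez = (
        0.5 * (1.0 - c2m)
        + c[..., None] * s2m
        + 0.5 * R[..., None] * (1.0 + c2m)
    )
    ma = ang - delta[..., None]  # analyzer angles in fiber frame
    sa, ca = np.sin(ma), np.cos(ma)
    amp = ex[..., :, None] * sa[..., None, :] + ez[..., :, None] * ca[..., None, :]
    return amp**2


def _profiled_amplitude(f: np.ndarray, I: np.ndarray) -> np.ndarray:
    """Least-squares optimal per-pixel amplitude for pattern f against data I."""
    num = np.sum(f * I, axis=(-2, -1))
    den = np.sum(f * f, axis=(-2, -1))
    return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)


def _ssr(x: np.ndarray, I: np.ndarray, w: np.ndarray | None):
    f = pipo_model(x[..., 0], x[..., 1], x[..., 2])
    a = _profiled_amplitude(f if w is None else f * w, I if w is None else I * w)
    r = a[..., None, None] * f - I
    if w is not None:
        r = r * w
    return np.sum(r * r, axis=(-2, -1)), a, r


def fit_pipo_image(
    stack: PolarimetricStack,
    n_starts: int = 5,
    n_refine: int = 2,
    max_iter: int = 60,
    xtol: float = 1e-12,
    poisson_weights: bool = False,
    init: tuple[float, float, float] | None = None,
) -> PipoFitResult:
    """Batched per-pixel least-squares PIPO fit of a 64-image stack.

    ``n_starts`` initial orientations spaced 180/n_starts degrees are
    screened; Levenberg-Marquardt refinement runs from the ``n_refine``
    best.  ``poisson_weights`` weights residuals by 1/sqrt(max(I, 1)),
    the shot-noise model for counting detection.  ``init`` forces a single
    explicit (delta, R, c) start instead.
    """
    if stack.data.shape[0] * stack.data.shape[1] < 3:
        raise ValueError("PIPO fit needs at least 3 grid points")
    grid = stack.grid_shape
    I = np.moveaxis(stack.data.reshape(stack.data.shape[:2] + (-1,)), -1, 0)  # (N,8,8)
    N = I.shape[0]
    w = 1.0 / np.sqrt(np.clip(I, 1.0, None)) if poisson_weights else None

    if init is not None:
        starts = [np.array(init, dtype=float)]
    else:
        step = 180.0 / n_starts
        starts = [
            np.array([np.radians(-90.0 + step * (k + 0.5)), 1.6, 0.0]) for k in range(n_starts)
        ]

    # screen starts by SSR, keep the best n_refine per pixel
    ssr0 = np.empty((len(starts), N))
    for k, s in enumerate(starts):
        x = np.broadcast_to(s, (N, 3)).copy()
        ssr0[k], _, _ = _ssr(x, I, w)
    order = np.argsort(ssr0, axis=0)
    n_refine = min(n_refine, len(starts)) if init is None else 1

    best = None
    for rank in range(n_refine):
        x = np.stack([starts[k] for k in order[rank]], axis=0).astype(float)
        x, ssr, amp, conv = _lm_refine(x, I, w, max_iter=max_iter, xtol=xtol)
        if best is None or np.any(ssr < best[1]):
            if best is None:
                best = [x, ssr, amp, conv]
            else:
                better = ssr < best[1]
                for arr, new in zip(best, (x, ssr, amp, conv)):
                    arr[better] = new[better]

    x, ssr, amp, conv = best
    delta = _wrap_half_pi(x[:, 0])
    return PipoFitResult(
        delta=delta.reshape(grid),
        R=x[:, 1].reshape(grid),
        c_cos=x[:, 2].reshape(grid),
        amplitude=amp.reshape(grid),
        residual=ssr.reshape(grid),
        converged=conv.reshape(grid),
        meta={"n_starts": len(starts), "n_refine": n_refine,
              "poisson_weights": poisson_weights},
    )


def _wrap_half_pi(delta: np.ndarray) -> np.ndarray:
    """Wrap orientation to [-pi/2, pi/2) (the fiber axis is headless)."""
    return (delta + np.pi / 2) % np.pi - np.pi / 2


def _model_and_jacobian(delta, R, c, angles_deg=PIPO_ANGLES_DEG):
    """Unit-amplitude PIPO pattern and its analytic derivatives w.r.t.
    (delta, R, c), each shaped (..., n_psg, n_psa)."""
    ang = np.radians(np.asarray(angles_deg, dtype=float))
    m = ang - delta[..., None]
    c2m, s2m = np.cos(2 * m), np.sin(2 * m)
    cc = c[..., None]
    ex = s2m - cc * (1.0 + c2m)
    ez = 0.5 * (1.0 - c2m) + cc * s2m + 0.5 * R[..., None] * (1.0 + c2m)
    dex_dd = -(2.0 * c2m + 2.0 * cc * s2m)
    dez_dd = -(s2m + 2.0 * cc * c2m - R[..., None] * s2m)
    dex_dc = -(1.0 + c2m)
    dez_dc = s2m
    dez_dR = 0.5 * (1.0 + c2m)
    sa, ca = np.sin(m), np.cos(m)  # analyzer in fiber frame (same angles)
    ex_, ez_ = ex[..., :, None], ez[..., :, None]
    sa_, ca_ = sa[..., None, :], ca[..., None, :]
    proj = ex_ * sa_ + ez_ * ca_
    dproj_dd = (
        dex_dd[..., :, None] * sa_
        - ex_ * ca_
        + dez_dd[..., :, None] * ca_
        + ez_ * sa_
    )
    dproj_dR = dez_dR[..., :, None] * ca_
    dproj_dc = dex_dc[..., :, None] * sa_ + dez_dc[..., :, None] * ca_
    f = proj**2
    return f, 2.0 * proj * dproj_dd, 2.0 * proj * dproj_dR, 2.0 * proj * dproj_dc


def _lm_refine(x, I, w, max_iter=60, xtol=1e-12, lam0=1e-3):
    """Vectorized Levenberg-Marquardt over (amplitude, delta, R, c) with an
    analytic Jacobian; each pixel carries its own damping factor.

    ``x`` enters and leaves as the (N, 3) structural block (delta, R, c);
    the amplitude is seeded by its profiled least-squares value.
    """
    N = x.shape[0]
    lam = np.full(N, lam0)
    ssr, amp, _ = _ssr(x, I, w)
    xa = np.concatenate([amp[:, None], x], axis=1)  # (N, 4): amp, delta, R, c
    converged = np.zeros(N, dtype=bool)
    eye = np.eye(4)

    def full_ssr(xa):
        f = pipo_model(xa[:, 1], xa[:, 2], xa[:, 3])
        r = xa[:, 0, None, None] * f - I
        if w is not None:
            r = r * w
        return np.sum(r * r, axis=(-2, -1)), r

    ssr, _ = full_ssr(xa)
    for _ in range(max_iter):
        if np.all(converged):
            break
        f, fd, fR, fc = _model_and_jacobian(xa[:, 1], xa[:, 2], xa[:, 3])
        a = xa[:, 0, None, None]
        res = a * f - I
        cols = [f, a * fd, a * fR, a * fc]
        if w is not None:
            res = res * w
            cols = [col * w for col in cols]
        res = res.reshape(N, -1)
        J = np.stack([col.reshape(N, -1) for col in cols], axis=-1)
        jtj = np.einsum("nij,nik->njk", J, J)
        g = np.einsum("nij,ni->nj", J, res)
        damp = lam[:, None, None] * (eye * np.maximum(
            np.einsum("njj->n", jtj)[:, None, None] / 4.0, 1e-30))
        dx = -np.linalg.solve(jtj + damp + 1e-30 * eye, g[..., None])[..., 0]
        xa_new = xa + dx
        ssr_new, _ = full_ssr(xa_new)
        improved = ssr_new <= ssr
        xa[improved] = xa_new[improved]
        ssr = np.where(improved, ssr_new, ssr)
        lam = np.clip(np.where(improved, lam * 0.3, lam * 5.0), 1e-14, 1e10)
        small = np.max(np.abs(dx), axis=1) < xtol * (1.0 + np.max(np.abs(xa), axis=1))
        converged = converged | (improved & small) | (ssr <= 1e-24 * np.maximum(np.sum(I * I, axis=(-2, -1)), 1e-30))
    return xa[:, 1:], ssr, xa[:, 0], converged


def fit_pipo(stack: PolarimetricStack, init=None, **kwargs) -> PipoFitResult:
    """Fit a PIPO stack (any pixel grid); single-pixel stacks give scalars
    in 0-d arrays.  See :func:`fit_pipo_image`."""
    return fit_pipo_image(stack, init=init, **kwargs)
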