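"""Polarization states, Stokes algebra and retarder optics.

Conventions (pinned once, used everywhere):

* Jones vectors are ordered (X, Z): X is the horizontal lab axis, Z the
  vertical one; light propagates along Y.
* HLP = (1, 0), VLP = (0, 1), P45 = (1, 1)/sqrt2, M45 = (1, -1)/sqrt2,
  RCP = (1, -i)/sqrt2, LCP = (1, +i)/sqrt2.
* Stokes components from a Jones field E = (E_X, E_Z):
  s0 = |E_X|^2 + |E_Z|^2, s1 = |E_X|^2 - |E_Z|^2,
  s2 = 2 Re(E_X E_Z*), s3 = 2 Im(E_X E_Z*),
  so that an ideal analyzer for state a transmits (s0 + a.(s1,s2,s3))/2.

The circular handedness (RCP = (1, -i)/sqrt2 together with
s3 = 2 Im(E_X E_Z*)) is the one for which the chiral closed forms of the
DSP parameter set come out with their published signs; flipping the time
convention flips both definitions at once and leaves every observable
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PolarizationState",
    "DSP_STATES",
    "PIPO_ANGLES_DEG",
    "state_jones",
    "linear_jones",
    "stokes_from_field",
    "analyzer_intensity",
    "apply_retarder",
    "degree_of_polarization",
]

_SQ2 = 1.0 / np.sqrt(2.0)

#: Jones vectors of the six canonical states, ordered (X, Z).
_CANONICAL = {
    "HLP": np.array([1.0, 0.0], dtype=complex),
    "VLP": np.array([0.0, 1.0], dtype=complex),
    "P45": np.array([_SQ2, _SQ2], dtype=complex),
    "M45": np.array([_SQ2, -_SQ2], dtype=complex),
    "RCP": np.array([_SQ2, -1j * _SQ2], dtype=complex),
    "LCP": np.array([_SQ2, 1j * _SQ2], dtype=complex),
}

#: Canonical incident/analyzer state labels in stack order.
DSP_STATES = ("HLP", "VLP", "P45", "M45", "RCP", "LCP")

#: PIPO polarizer/analyzer angles (degrees, measured like delta from lab Z).
PIPO_ANGLES_DEG = tuple(22.5 * i for i in range(8))


@dataclass(frozen=True)
class PolarizationState:
    """A labeled pure polarization state with its unit-norm Jones vector."""

    label: str
    jones: np.ndarray

    def __post_init__(self):
        j = np.asarray(self.jones, dtype=complex)
        n = np.linalg.norm(j)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError(f"Jones vector of {self.label!r} must be unit norm")
        object.__setattr__(self, "jones", j)

    @classmethod
    def canonical(cls, label: str) -> "PolarizationState":
        try:
            return cls(label, _CANONICAL[label].copy())
        except KeyError:
            raise ValueError(f"unknown state label {label!r}") from None

    @classmethod
    def linear(cls, angle_rad: float, label: str | None = None) -> "PolarizationState":
        return cls(label or f"LIN{np.degrees(angle_rad):.1f}", linear_jones(angle_rad))


def state_jones(label: str) -> np.ndarray:
    """Jones vector for a canonical state label."""
    return _CANONICAL[label].copy()


def linear_jones(angle_rad: float | np.ndarray) -> np.ndarray:
    """Jones vector(s) of a linear state at ``angle_rad`` from lab Z
    (same angular convention as the fiber orientation delta)."""
    a = np.asarray(angle_rad, dtype=float)
    out = np.empty(a.shape + (2,), dtype=complex)
    out[..., 0] = np.sin(a)
    out[..., 1] = np.cos(a)
    return out


def stokes_from_field(E: np.ndarray) -> np.ndarray:
    """Stokes vector(s) (s0, s1, s2, s3) of Jones field(s) with trailing
    axis (E_X, E_Z).  Works on any leading shape."""
    E = np.asarray(E, dtype=complex)
    ex, ez = E[..., 0], E[..., 1]
    ix = (ex * ex.conj()).real
    iz = (ez * ez.conj()).real
    cross = ex * ez.conj()
    return np.stack([ix + iz, ix - iz, 2.0 * cross.real, 2.0 * cross.imag], axis=-1)


def analyzer_intensity(stokes: np.ndarray, analyzer: str | np.ndarray) -> np.ndarray:
    """Intensity behind an ideal analyzer, from the Stokes vector.

    ``analyzer`` is a canonical label or a Jones vector.  This is the
    Mueller-side projection I = (s0 + a_hat . (s1, s2, s3)) / 2 and holds
    for partially polarized light as well.
    """
    if isinstance(analyzer, str):
        a = _CANONICAL[analyzer]
    else:
        a = np.asarray(analyzer, dtype=complex)
    a_st = stokes_from_field(a)  # unit s0
    s = np.asarray(stokes, dtype=float)
    return 0.5 * np.einsum("...c,c->...", s, a_st)


def apply_retarder(
    E: np.ndarray, phase: float, axis: float | np.ndarray
) -> np.ndarray:
    """Apply a linear retarder to Jones field(s).

    ``axis`` is the orientation of the retarded (slow) axis, measured like
    delta from lab Z; the component along it acquires the phase
    ``e^{i phase}`` while the orthogonal (fast) component is unchanged.
    The transformation is unitary.  ``axis`` broadcasts against the leading
    shape of ``E``.
    """
    E = np.asarray(E, dtype=complex)
    u = linear_jones(axis).real  # slow-axis direction, real unit vector
    along = np.einsum("...j,...j->...", E, u)
    par = along[..., None] * u
    perp = E - par
    return perp + np.exp(1j * phase) * par


def degree_of_polarization(stokes: np.ndarray) -> np.ndarray:
    """DOP = sqrt(s1^2 + s2^2 + s3^2) / s0 for Stokes vector(s) with the
    component axis last.  Raises on s0 == 0."""
    s = np.asarray(stokes, dtype=float)
    s0 = s[..., 0]
    if np.any(s0 == 0):
        raise ValueError("DOP undefined where s0 == 0")
    return np.sqrt(np.sum(s[..., 1:] ** 2, axis=-1)) / s0
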