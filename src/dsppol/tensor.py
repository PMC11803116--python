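"""Chiral C6 susceptibility model and laboratory-frame tensor construction.

A fiber with C6 symmetry (collagen, myosin) has four independent
second-order susceptibility components in the molecular frame (fiber axis
along molecular z):

* ``chi_zzz`` — axial achiral component,
* ``chi_zxx = chi_zyy`` — transverse achiral component (normalization),
* ``chi_xxz = chi_xzx = chi_yyz = chi_yzy`` — shear achiral component,
* ``chi_xyz = chi_xzy = -chi_yxz = -chi_yzx`` — chiral component.

Under the complex chiral susceptibility (CCS) model the achiral components
are real while the chiral one is complex, ``chi_xyz = |chi_xyz| e^{i Delta}``.
The phase ``Delta`` is the retardance between chiral and achiral responses.

The laboratory frame is chosen with the image plane spanned by X (horizontal)
and Z (vertical) and light propagating along Y.  The fiber is tilted out of
the image plane by ``alpha`` and its in-plane projection makes an angle
``delta`` with the lab Z axis, so the in-plane fiber direction is
``(sin delta, cos delta)`` in (X, Z).

Because only field components transverse to the propagation direction
matter, the effective description collapses to a 2D third-rank tensor over
indices {X, Z} together with the effective ratios

    R = (chi_zzz/chi_zxx) cos^2(alpha) + (1 + 2 chi_xxz/chi_zxx) sin^2(alpha)
    C = (|chi_xyz|/chi_zxx) sin(alpha)

C is signed: it carries the sign of sin(alpha) and therefore the fiber
polarity (which way the fiber tilts out of the image plane).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field

import numpy as np

__all__ = [
    "MolecularSusceptibility",
    "FiberGeometry",
    "EffectiveRatios",
    "LabTensor2D",
    "effective_ratios",
    "molecular_tensor_3d",
    "lab_tensor_3d",
    "lab_tensor_2d",
    "lab_tensor_2d_from_ratios",
    "rotate_tensor_2d",
]

_X, _Z = 0, 1  # 2D lab indices


@dataclass(frozen=True)
class MolecularSusceptibility:
    """Independent C6 molecular susceptibility components, in units of chi_zxx.

    ``chi_xxz`` defaults to ``chi_zxx`` (the Kleinman-like assumption the
    closed-form theory uses); it is kept as a separate field so that the
    assumption is a configuration rather than a hard-coding.
    """

    chi_zzz: float = 1.6
    chi_zxx: float = 1.0
    chi_xxz: float | None = None
    chi_xyz_mag: float = 0.0
    delta_phase: float = 0.0  # radians, in (-pi, pi]

    def __post_init__(self):
        if self.chi_zxx <= 0:
            raise ValueError("chi_zxx must be positive (it is the normalization)")
        if self.chi_xyz_mag < 0:
            raise ValueError("chi_xyz_mag must be non-negative")
        if self.chi_xxz is None:
            object.__setattr__(self, "chi_xxz", self.chi_zxx)

    @property
    def chi_xyz(self) -> complex:
        return self.chi_xyz_mag * np.exp(1j * self.delta_phase)

    @classmethod
    def from_complex_xyz(
        cls, chi_zzz: float, chi_xyz: complex, chi_zxx: float = 1.0,
        chi_xxz: float | None = None,
    ) -> "MolecularSusceptibility":
        """Build from a complex chi_xyz, e.g. the 0.2 + 0.2i of a typical
        collagen simulation."""
        return cls(
            chi_zzz=chi_zzz,
            chi_zxx=chi_zxx,
            chi_xxz=chi_xxz,
            chi_xyz_mag=abs(chi_xyz),
            delta_phase=math.atan2(chi_xyz.imag, chi_xyz.real),
        )

    def to_json(self) -> str:
        d = asdict(self)
        d["delta_phase_rad"] = d.pop("delta_phase")
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "MolecularSusceptibility":
        d = json.loads(s)
        d["delta_phase"] = d.pop("delta_phase_rad")
        return cls(**d)


@dataclass(frozen=True)
class FiberGeometry:
    """Fiber orientation: in-plane angle ``delta`` (from lab Z) and
    out-of-plane tilt ``alpha``, both in [-pi/2, pi/2] radians."""

    delta: float = 0.0
    alpha: float = 0.0

    def __post_init__(self):
        half = math.pi / 2 + 1e-12
        if not (-half <= self.delta <= half):
            raise ValueError("delta must lie in [-pi/2, pi/2]")
        if not (-half <= self.alpha <= half):
            raise ValueError("alpha must lie in [-pi/2, pi/2]")

    def to_json(self) -> str:
        return json.dumps({"delta_rad": self.delta, "alpha_rad": self.alpha})

    @classmethod
    def from_json(cls, s: str) -> "FiberGeometry":
        d = json.loads(s)
        return cls(delta=d["delta_rad"], alpha=d["alpha_rad"])


@dataclass(frozen=True)
class EffectiveRatios:
    """Effective achiral ratio R, signed chiral ratio C, phase Delta and the
    chirality correction sigma = 2 C cos(Delta) / (R + 1)."""

    R: float
    C: float
    delta_phase: float
    sigma: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self, "sigma", 2.0 * self.C * math.cos(self.delta_phase) / (self.R + 1.0)
        )


def effective_ratios(mol: MolecularSusceptibility, alpha: float) -> EffectiveRatios:
    """Effective (R, C, Delta, sigma) for a fiber tilted by ``alpha``.

    R mixes the axial and shear achiral components with the tilt; C is the
    chiral magnitude scaled by sin(alpha), so it vanishes for in-plane fibers
    and changes sign with the tilt direction (fiber polarity).
    """
    ca, sa = math.cos(alpha), math.sin(alpha)
    R = (mol.chi_zzz / mol.chi_zxx) * ca**2 + (1.0 + 2.0 * mol.chi_xxz / mol.chi_zxx) * sa**2
    C = (mol.chi_xyz_mag / mol.chi_zxx) * sa
    return EffectiveRatios(R=R, C=C, delta_phase=mol.delta_phase)


def molecular_tensor_3d(mol: MolecularSusceptibility) -> np.ndarray:
    """Full 3x3x3 molecular-frame tensor (axis order x, y, z), complex.

    Intrinsic permutation symmetry in the last two indices is built in.
    """
    t = np.zeros((3, 3, 3), dtype=complex)
    x, y, z = 0, 1, 2
    t[z, z, z] = mol.chi_zzz
    t[z, x, x] = t[z, y, y] = mol.chi_zxx
    t[x, x, z] = t[x, z, x] = mol.chi_xxz
    t[y, y, z] = t[y, z, y] = mol.chi_xxz
    k = mol.chi_xyz
    t[x, y, z] = t[x, z, y] = k
    t[y, x, z] = t[y, z, x] = -k
    return t


def _rotation_matrix(delta: float, alpha: float) -> np.ndarray:
    """Molecular->lab rotation. Lab axis order (X, Y, Z).

    Tilt alpha about lab X moves the molecular z axis toward +Y
    (z_mol = (0, sin a, cos a), y_mol = (0, cos a, -sin a)); the subsequent
    in-plane rotation delta about the propagation axis Y moves the fiber
    projection from lab Z toward lab X.
    """
    ca, sa = math.cos(alpha), math.sin(alpha)
    tilt = np.array([[1.0, 0.0, 0.0], [0.0, ca, sa], [0.0, -sa, ca]])
    cd, sd = math.cos(delta), math.sin(delta)
    # rotation about Y taking (X, Z) fiber-frame axes to x'=(cd,-sd), z'=(sd,cd)
    spin = np.array([[cd, 0.0, sd], [0.0, 1.0, 0.0], [-sd, 0.0, cd]])
    return spin @ tilt


def lab_tensor_3d(mol: MolecularSusceptibility, geom: FiberGeometry) -> np.ndarray:
    """Unnormalized 3x3x3 laboratory-frame tensor (axis order X, Y, Z)."""
    t = molecular_tensor_3d(mol)
    rot = _rotation_matrix(geom.delta, geom.alpha)
    return np.einsum("Ii,Jj,Kk,ijk->IJK", rot, rot, rot, t)


@dataclass(frozen=True)
class LabTensor2D:
    """Effective 2D lab tensor over transverse indices {X, Z}.

    ``array`` has shape (..., 2, 2, 2) with index order (i, j, k), 0 = X,
    1 = Z, and is symmetric in (j, k).  Entries are normalized by
    chi_zxx * cos(alpha) so that at delta = 0 the ZZZ entry equals the
    effective ratio R and ZXX equals 1.  ``degenerate`` flags fibers at
    alpha = +-pi/2 where cos(alpha) = 0 and the normalization is undefined.
    """

    array: np.ndarray
    delta: float = 0.0
    degenerate: bool = False

    def entry(self, name: str) -> np.ndarray | complex:
        idx = tuple(0 if c in "xX" else 1 for c in name)
        if len(idx) != 3:
            raise ValueError("entry name must have three index letters")
        return self.array[(..., *idx)]

    @property
    def zzz(self):
        return self.entry("zzz")

    @property
    def zxx(self):
        return self.entry("zxx")

    @property
    def xxz(self):
        return self.entry("xxz")

    @property
    def xzz(self):
        return self.entry("xzz")

    @property
    def zxz(self):
        return self.entry("zxz")


def rotate_tensor_2d(array: np.ndarray, delta: float | np.ndarray) -> np.ndarray:
    """In-plane rotation of a 2D third-rank tensor by ``delta``.

    ``delta`` may be a scalar or an array broadcastable against the leading
    dimensions of ``array``.
    """
    cd, sd = np.cos(delta), np.sin(delta)
    q = np.empty(np.shape(cd) + (2, 2), dtype=float)
    # columns are the fiber-frame axes expressed in the lab: x'=(cd,-sd), z'=(sd,cd)
    q[..., 0, 0] = cd
    q[..., 0, 1] = sd
    q[..., 1, 0] = -sd
    q[..., 1, 1] = cd
    return np.einsum("...Ii,...Jj,...Kk,...ijk->...IJK", q, q, q, array)


def lab_tensor_2d_from_ratios(
    R: float | np.ndarray,
    C: float | np.ndarray = 0.0,
    delta_phase: float | np.ndarray = 0.0,
    delta: float | np.ndarray = 0.0,
) -> np.ndarray:
    """2D lab tensor (shape (..., 2, 2, 2)) directly from effective ratios.

    At delta = 0 the normalized entries are  ZZZ = R, ZXX = 1, XXZ = XZX = 1,
    XZZ = -2 C e^{i Delta}, ZXZ = ZZX = +C e^{i Delta}; a nonzero ``delta``
    applies the in-plane rotation.  All inputs broadcast.
    """
    R, C, delta_phase, delta = np.broadcast_arrays(
        np.asarray(R, dtype=float),
        np.asarray(C, dtype=float),
        np.asarray(delta_phase, dtype=float),
        np.asarray(delta, dtype=float),
    )
    k = C * np.exp(1j * delta_phase)
    t = np.zeros(R.shape + (2, 2, 2), dtype=complex)
    t[..., _Z, _Z, _Z] = R
    t[..., _Z, _X, _X] = 1.0
    t[..., _X, _X, _Z] = t[..., _X, _Z, _X] = 1.0
    t[..., _X, _Z, _Z] = -2.0 * k
    t[..., _Z, _X, _Z] = t[..., _Z, _Z, _X] = k
    return rotate_tensor_2d(t, delta)


def lab_tensor_2d(mol: MolecularSusceptibility, geom: FiberGeometry) -> LabTensor2D:
    """Effective 2D lab tensor for a molecular model and fiber geometry.

    Built by the full third-rank rotation of the molecular tensor, restricted
    to transverse indices and normalized by chi_zxx cos(alpha).  This path is
    deliberately independent of :func:`lab_tensor_2d_from_ratios` (which uses
    the closed-form entries) so each can validate the other.
    """
    full = lab_tensor_3d(mol, geom)
    ca = math.cos(geom.alpha)
    degenerate = abs(ca) < 1e-12
    sub = full[np.ix_([0, 2], [0, 2], [0, 2])]
    if degenerate:
        arr = np.full((2, 2, 2), np.nan, dtype=complex)
    else:
        arr = sub / (mol.chi_zxx * ca)
    return LabTensor2D(array=arr, delta=geom.delta, degenerate=degenerate)
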