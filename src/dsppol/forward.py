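"""Forward simulation of polarimetric SHG data.

The second-harmonic field radiated by a fiber with effective 2D lab tensor
``t`` under an incident Jones field ``e`` is

    E_i(2w)  proportional to  sum_jk  t_ijk e_j e_k,    i, j, k in {X, Z}.

Generation is treated as occurring at a single plane in the middle of the
section: sample birefringence acts as one linear retarder on the fundamental
before generation (phase at the fundamental wavelength) and one on the SHG
after generation (phase at the SHG wavelength), both sharing the same axis
(by default the in-plane projection of the fiber, the slow axis of a
positively birefringent fiber).

Detection emulates a photon-counting PMT behind a polarization state
analyzer: intensities are analyzer projections of the SHG Stokes vector
scaled by a gain, optionally Poisson sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .polarization import (
    DSP_STATES,
    PIPO_ANGLES_DEG,
    analyzer_intensity,
    apply_retarder,
    linear_jones,
    state_jones,
    stokes_from_field,
)
from .tensor import (
    FiberGeometry,
    MolecularSusceptibility,
    effective_ratios,
    lab_tensor_2d_from_ratios,
)

__all__ = [
    "BirefringenceSpec",
    "StokesSet",
    "PolarimetricStack",
    "shg_field",
    "birefringence_phase",
    "simulate_stokes_set",
    "simulate_stokes_maps",
    "simulate_stack",
]


@dataclass(frozen=True)
class BirefringenceSpec:
    """Linear birefringence of the sample section.

    The retarder phase is phi = 2 pi dn l / lambda at each wavelength.
    ``axis`` is the slow-axis orientation (delta convention, from lab Z);
    ``None`` means fiber-aligned (the in-plane fiber projection), the default
    for a positively birefringent fiber such as collagen.
    ``path_length_um`` defaults to half a 10 um section, the effective path
    for mid-slice generation.
    """

    delta_n: float = 0.002
    path_length_um: float = 5.0
    lambda_fund_nm: float = 1030.0
    lambda_shg_nm: float | None = None
    axis: float | None = None

    def __post_init__(self):
        if self.path_length_um < 0:
            raise ValueError("path_length_um must be >= 0")
        if self.lambda_shg_nm is None:
            object.__setattr__(self, "lambda_shg_nm", self.lambda_fund_nm / 2.0)

    @property
    def phase_fund(self) -> float:
        return birefringence_phase(self, self.lambda_fund_nm)

    @property
    def phase_shg(self) -> float:
        return birefringence_phase(self, self.lambda_shg_nm)


def birefringence_phase(b: BirefringenceSpec, wavelength_nm: float) -> float:
    """Retarder phase phi = 2 pi dn l / lambda (radians) at ``wavelength_nm``."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return 2.0 * math.pi * b.delta_n * (b.path_length_um * 1e3) / wavelength_nm


def shg_field(tensor: np.ndarray, e: np.ndarray) -> np.ndarray:
    """SHG Jones field E_i = sum_jk t_ijk e_j e_k (unnormalized).

    ``tensor`` has trailing shape (2, 2, 2); ``e`` trailing shape (2);
    leading shapes broadcast.
    """
    t = np.asarray(tensor, dtype=complex)
    e = np.asarray(e, dtype=complex)
    return np.einsum("...ijk,...j,...k->...i", t, e, e)


@dataclass
class StokesSet:
    """SHG Stokes vectors per incident state.

    ``stokes[label]`` is an array with trailing axis (s0, s1, s2, s3); the
    leading shape is the pixel grid (empty for a single fiber).
    """

    stokes: dict[str, np.ndarray]
    degenerate: bool = False
    meta: dict = field(default_factory=dict)

    def __getitem__(self, label: str) -> np.ndarray:
        return self.stokes[label]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.stokes)


def _tensor_from_geometry(
    mol: MolecularSusceptibility,
    delta: np.ndarray | float,
    alpha: np.ndarray | float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel effective 2D tensor plus (R, C) maps from orientation maps."""
    alpha = np.asarray(alpha, dtype=float)
    delta = np.asarray(delta, dtype=float)
    ca, sa = np.cos(alpha), np.sin(alpha)
    R = (mol.chi_zzz / mol.chi_zxx) * ca**2 + (1.0 + 2.0 * mol.chi_xxz / mol.chi_zxx) * sa**2
    C = (mol.chi_xyz_mag / mol.chi_zxx) * sa
    t = lab_tensor_2d_from_ratios(R, C, mol.delta_phase, delta)
    return t, R, C


def _incident_fields(
    labels_or_angles, shape: tuple[int, ...]
) -> dict[str, np.ndarray]:
    out = {}
    for st in labels_or_angles:
        if isinstance(st, str):
            j = state_jones(st)
            key = st
        else:
            j = linear_jones(math.radians(st))
            key = f"{st:g}"
        out[key] = np.broadcast_to(j, shape + (2,)).copy()
    return out


def simulate_stokes_maps(
    mol: MolecularSusceptibility,
    delta: np.ndarray | float,
    alpha: np.ndarray | float,
    biref: BirefringenceSpec | None = None,
    incident=DSP_STATES,
) -> StokesSet:
    """Noise-free SHG Stokes vectors per incident state for orientation maps.

    ``delta`` and ``alpha`` may be scalars or equal-shape arrays; the output
    Stokes arrays have that shape plus a trailing component axis.
    """
    tensor, R, C = _tensor_from_geometry(mol, delta, alpha)
    degenerate = bool(np.any(np.isclose(np.cos(np.asarray(alpha, float)), 0.0, atol=1e-12)))
    shape = np.broadcast_shapes(np.shape(delta), np.shape(alpha))
    fields = _incident_fields(incident, shape)
    if biref is not None:
        axis = biref.axis if biref.axis is not None else np.asarray(delta, dtype=float)
    stokes = {}
    for label, e in fields.items():
        if biref is not None:
            e = apply_retarder(e, biref.phase_fund, axis)
        E = shg_field(tensor, e)
        if biref is not None:
            E = apply_retarder(E, biref.phase_shg, axis)
        stokes[label] = stokes_from_field(E)
    return StokesSet(
        stokes=stokes,
        degenerate=degenerate,
        meta={"R": R, "C": C, "delta_phase": mol.delta_phase},
    )


def simulate_stokes_set(
    mol: MolecularSusceptibility,
    geom: FiberGeometry,
    biref: BirefringenceSpec | None = None,
) -> StokesSet:
    """Noise-free SHG Stokes vectors for a single fiber.

    Without birefringence every returned vector is an exact pure state
    (s0^2 = s1^2 + s2^2 + s3^2).
    """
    eff = effective_ratios(mol, geom.alpha)
    out = simulate_stokes_maps(mol, geom.delta, geom.alpha, biref)
    out.meta.update({"effective": eff})
    return out


@dataclass
class PolarimetricStack:
    """Measured or simulated intensity images indexed by (PSG, PSA) state.

    ``data`` has shape (n_psg, n_psa, *grid); DSP stacks are 6x6 over the
    canonical states, PIPO stacks 8x8 over linear angles in 22.5 deg steps.
    """

    data: np.ndarray
    psg_labels: tuple[str, ...]
    psa_labels: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.psg_labels = tuple(self.psg_labels)
        self.psa_labels = tuple(self.psa_labels)
        if self.data.shape[:2] != (len(self.psg_labels), len(self.psa_labels)):
            raise ValueError("data shape does not match state labels")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.data.shape[2:]

    def intensity(self, psg: str, psa: str) -> np.ndarray:
        return self.data[self.psg_labels.index(psg), self.psa_labels.index(psa)]

    @property
    def kind(self) -> str:
        return "dsp" if set(self.psg_labels) == set(DSP_STATES) else "pipo"


def simulate_stack(
    mol: MolecularSusceptibility,
    delta: np.ndarray | float,
    alpha: np.ndarray | float,
    states: str = "dsp",
    gain: float | np.ndarray = 100.0,
    biref: BirefringenceSpec | None = None,
    noise_seed: int | None = None,
    dop: float = 1.0,
) -> PolarimetricStack:
    """Simulate a full (PSG, PSA) intensity stack.

    ``states`` is "dsp" (6x6 canonical grid) or "pipo" (8x8 linear grid).
    ``gain`` scales |field|^2 to detector counts and may be a per-pixel
    array (e.g. zero on background); ``dop`` < 1 models uniform
    depolarization by shrinking (s1, s2, s3) before the analyzer, leaving s0.
    With ``noise_seed`` set, each analyzer image is Poisson sampled
    independently (photon-counting detection).
    """
    gain = np.asarray(gain, dtype=float)
    if np.any(gain < 0):
        raise ValueError("gain must be non-negative")
    if not (0.0 <= dop <= 1.0):
        raise ValueError("dop must lie in [0, 1]")
    if states == "dsp":
        psg: tuple = DSP_STATES
        psa: tuple = DSP_STATES
    elif states == "pipo":
        psg = PIPO_ANGLES_DEG
        psa = PIPO_ANGLES_DEG
    else:
        raise ValueError("states must be 'dsp' or 'pipo'")

    sset = simulate_stokes_maps(mol, delta, alpha, biref, incident=psg)
    psg_labels = tuple(sset.labels)
    psa_jones = [
        state_jones(p) if isinstance(p, str) else linear_jones(math.radians(p))
        for p in psa
    ]
    psa_labels = tuple(p if isinstance(p, str) else f"{p:g}" for p in psa)

    grid = np.broadcast_shapes(np.shape(delta), np.shape(alpha))
    data = np.empty((len(psg_labels), len(psa_labels)) + grid, dtype=float)
    for i, lbl in enumerate(psg_labels):
        s = sset[lbl].copy()
        if dop < 1.0:
            s[..., 1:] *= dop
        for j, a in enumerate(psa_jones):
            data[i, j] = gain * analyzer_intensity(s, a)
    data = np.clip(data, 0.0, None)
    if noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
        data = rng.poisson(data).astype(float)
    return PolarimetricStack(
        data=data,
        psg_labels=psg_labels,
        psa_labels=psa_labels,
        meta={
            "gain": float(gain) if gain.ndim == 0 else "per-pixel",
            "dop": dop,
            "noise_seed": noise_seed,
            "kind": states,
            "birefringence": None if biref is None else vars(biref).copy(),
            "degenerate": sset.degenerate,
        },
    )
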