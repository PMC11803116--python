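"""Synthetic phantom generation with known ground truth.

Phantoms emulate the two canonical tendon-section geometries used to
validate polarimetric SHG pipelines:

* ``longitudinal`` — fibers lying in the image plane (alpha = 0), tightly
  aligned around a single in-plane orientation (default -39 deg with a
  5 deg spread).  Chirality is invisible here (C = sin(alpha) * |ratio| = 0),
  so the chiral parameter maps should be null.
* ``oblique`` — fibers tilted out of the image plane in sign-alternating
  bands (polarity domains, alpha = +-30 deg by default) with broadly
  distributed in-plane orientations.  The default 30 deg tilt puts the
  effective achiral ratio at R = 1.95 for the default tensor
  (chi_zzz = 1.6), i.e. in the regime reported for obliquely cut tendon;
  this is a modeling choice calibrated to the effective R, not a claim
  about the true tilt distribution of any real section.

Counts are Poisson-distributed per analyzer image (photon-counting
detection); a left-edge background strip of configurable fraction carries
zero signal so intensity thresholding is exercised.  All randomness is
fixed by a single seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np

from .forward import BirefringenceSpec, PolarimetricStack, simulate_stack
from .tensor import MolecularSusceptibility, effective_ratios

__all__ = ["PhantomSpec", "generate_phantom", "sweep_dataset", "PRESETS"]

#: available phantom presets
PRESETS = ("longitudinal", "oblique", "uniform")

#: default molecular tensor: chi_zzz = 1.6, chi_xyz = 0.2 + 0.2i, chi_zxx = chi_xxz = 1
DEFAULT_MOL = MolecularSusceptibility.from_complex_xyz(1.6, 0.2 + 0.2j)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic sample and its acquisition.

    ``gain`` is counts per unit squared field; with the default tensor the
    brightest (fiber-parallel) pixels reach roughly ``gain * R^2`` counts,
    so the default 100 gives a few hundred counts — typical photon-counting
    levels.  ``noise_seed = None`` turns Poisson noise off.
    """

    preset: str = "longitudinal"
    shape: tuple[int, int] = (200, 200)
    mol: MolecularSusceptibility = DEFAULT_MOL
    delta_center_deg: float = -39.0
    delta_spread_deg: float = 5.0
    alpha_deg: float = 30.0
    band_px: int = 25
    gain: float = 100.0
    background_fraction: float = 0.0
    dop: float = 1.0
    biref: BirefringenceSpec | None = None
    noise_seed: int | None = None
    states: str = "dsp"

    def with_(self, **kw) -> "PhantomSpec":
        return replace(self, **kw)

    def to_yaml(self) -> str:
        import yaml

        d = asdict(self)
        d["mol"] = {"chi_zzz": self.mol.chi_zzz, "chi_zxx": self.mol.chi_zxx,
                    "chi_xxz": self.mol.chi_xxz, "chi_xyz_mag": self.mol.chi_xyz_mag,
                    "delta_phase": self.mol.delta_phase}
        d["shape"] = list(self.shape)
        if self.biref is not None:
            d["biref"] = {k: getattr(self.biref, k) for k in
                          ("delta_n", "path_length_um", "lambda_fund_nm",
                           "lambda_shg_nm", "axis")}
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PhantomSpec":
        import yaml

        d = yaml.safe_load(text)
        d["shape"] = tuple(d["shape"])
        d["mol"] = MolecularSusceptibility(**d["mol"])
        if d.get("biref") is not None:
            d["biref"] = BirefringenceSpec(**d["biref"])
        return cls(**d)


def _orientation_maps(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    h, w = spec.shape
    rng = np.random.default_rng(
        spec.noise_seed if spec.noise_seed is not None else 0
    )
    if spec.preset == "longitudinal":
        delta = np.radians(
            spec.delta_center_deg + spec.delta_spread_deg * rng.standard_normal((h, w))
        )
        delta = np.clip(delta, -np.pi / 2 + 1e-6, np.pi / 2 - 1e-6)
        alpha = np.zeros((h, w))
    elif spec.preset == "oblique":
        # broad, smooth in-plane orientation ramp plus jitter
        ramp = np.linspace(-80.0, 80.0, w)[None, :] * np.ones((h, 1))
        delta = np.radians(
            np.clip(ramp + spec.delta_spread_deg * rng.standard_normal((h, w)), -89.0, 89.0)
        )
        # sign-alternating tilt bands: polarity domains
        bands = (np.arange(h)[:, None] // max(spec.band_px, 1)) % 2
        sign = np.where(bands == 0, 1.0, -1.0) * np.ones((1, w))
        alpha = np.radians(spec.alpha_deg) * sign
    elif spec.preset == "uniform":
        delta = np.full((h, w), np.radians(spec.delta_center_deg))
        alpha = np.full((h, w), np.radians(spec.alpha_deg))
    else:
        raise ValueError(f"unknown preset {spec.preset!r}")
    return delta, alpha


def generate_phantom(spec: PhantomSpec) -> tuple[PolarimetricStack, dict[str, np.ndarray]]:
    """Simulate a phantom stack and return it with its ground-truth maps.

    Truth maps: ``delta``, ``alpha``, ``R``, ``C``, ``Delta`` (all per
    pixel) plus the boolean ``background`` mask.  Identical seeds give
    bit-identical stacks.
    """
    delta, alpha = _orientation_maps(spec)
    h, w = spec.shape
    background = np.zeros((h, w), dtype=bool)
    n_bg = int(round(spec.background_fraction * w))
    background[:, :n_bg] = True
    gain_map = np.where(background, 0.0, spec.gain)

    # decorrelate the Poisson stream from the orientation-jitter stream
    noise_seed = None if spec.noise_seed is None else (spec.noise_seed + 1000003) % 2**31
    stack = simulate_stack(
        spec.mol, delta, alpha,
        states=spec.states, gain=gain_map, biref=spec.biref,
        noise_seed=noise_seed, dop=spec.dop,
    )
    ca, sa = np.cos(alpha), np.sin(alpha)
    m = spec.mol
    truth = {
        "delta": delta,
        "alpha": alpha,
        "R": (m.chi_zzz / m.chi_zxx) * ca**2 + (1 + 2 * m.chi_xxz / m.chi_zxx) * sa**2,
        "C": (m.chi_xyz_mag / m.chi_zxx) * sa,
        "Delta": np.full((h, w), m.delta_phase),
        "background": background,
    }
    stack.meta.update({"preset": spec.preset, "background_fraction": spec.background_fraction})
    return stack, truth


def sweep_dataset(
    grid: dict[str, list],
    mol: MolecularSusceptibility = DEFAULT_MOL,
    gain: float = 100.0,
    states: str = "dsp",
) -> list[tuple[PolarimetricStack, dict]]:
    """Deterministic enumeration of single-fiber (stack, truth) pairs.

    ``grid`` maps axis names to value lists; recognized axes are
    ``alpha_deg``, ``delta_deg``, ``noise_seed`` and ``biref``.  The
    Cartesian product is enumerated in a fixed order; each pair carries a
    scalar-geometry stack and a truth record with the effective
    (R, C, Delta) of its tilt.  An empty grid yields an empty list.
    """
    if not grid:
        return []
    axes = list(grid)
    allowed = {"alpha_deg", "delta_deg", "noise_seed", "biref"}
    unknown = set(axes) - allowed
    if unknown:
        raise ValueError(f"unknown sweep axes: {sorted(unknown)}")
    from itertools import product

    out = []
    for combo in product(*(grid[a] for a in axes)):
        kv = dict(zip(axes, combo))
        alpha = np.radians(kv.get("alpha_deg", 0.0))
        delta = np.radians(kv.get("delta_deg", 0.0))
        eff = effective_ratios(mol, alpha)
        stack = simulate_stack(
            mol, delta, alpha, states=states, gain=gain,
            biref=kv.get("biref"), noise_seed=kv.get("noise_seed"),
        )
        truth = {
            "delta": delta, "alpha": alpha,
            "R": eff.R, "C": eff.C, "Delta": mol.delta_phase,
            "sigma": eff.sigma, **kv,
        }
        out.append((stack, truth))
    return out
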