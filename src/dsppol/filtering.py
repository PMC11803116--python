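"""Stokes image reconstruction and the data-consistency filters.

From a 6x6 intensity stack the SHG Stokes vector for each incident state m
is assembled from the analyzer intensities:

    s0 = I_HLP + I_VLP,  s1 = I_HLP - I_VLP,
    s2 = I_P45 - I_M45,  s3 = I_RCP - I_LCP.

Three per-pixel filters follow the measurement model:

* an intensity threshold on the mean s0 over the six incident states
  (dim pixels carry no usable polarimetric information);
* the pure-state substitution s0 <- sqrt(s1^2 + s2^2 + s3^2), valid because
  the closed-form theory assumes fully polarized SHG;
* the circular consistency identity s0^RCP - s0^LCP = s3^RCP + s3^LCP,
  which holds exactly for any pure-state SHG response and flags pixels
  dominated by noise or depolarization.

All filters are purely per-pixel, so they commute with cropping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import PolarimetricStack, StokesSet
from .polarization import DSP_STATES, degree_of_polarization

__all__ = [
    "StokesImageSet",
    "stokes_from_intensities",
    "degree_of_polarization",
    "pure_state_s0",
    "apply_pure_state_filter",
    "circular_consistency_mask",
    "intensity_mask",
]

#: analyzer labels entering each Stokes component as (positive, negative)
_COMPONENT_PAIRS = (("HLP", "VLP"), ("HLP", "VLP"), ("P45", "M45"), ("RCP", "LCP"))


@dataclass
class StokesImageSet:
    """Per-incident-state Stokes images with a shared validity mask.

    ``stokes[label]`` has trailing axis (s0..s3); ``mask`` is True where a
    pixel is valid.  ``masks`` records each named filter separately so that
    masked-pixel counts stay reportable.
    """

    stokes: dict[str, np.ndarray]
    mask: np.ndarray | None = None
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mask is None:
            grid = next(iter(self.stokes.values())).shape[:-1]
            self.mask = np.ones(grid, dtype=bool)

    def __getitem__(self, label: str) -> np.ndarray:
        return self.stokes[label]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.stokes)

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.mask.shape

    def add_mask(self, name: str, mask: np.ndarray) -> None:
        """AND a named filter into the combined validity mask."""
        self.masks[name] = np.asarray(mask, dtype=bool)
        self.mask = self.mask & self.masks[name]

    def mean_s0(self) -> np.ndarray:
        return np.mean([s[..., 0] for s in self.stokes.values()], axis=0)

    @classmethod
    def from_stokes_set(cls, sset: StokesSet) -> "StokesImageSet":
        return cls(stokes={k: np.array(v, dtype=float) for k, v in sset.stokes.items()},
                   meta=dict(sset.meta))


def stokes_from_intensities(stack: PolarimetricStack) -> StokesImageSet:
    """Assemble per-incident-state Stokes images from a 6x6 DSP stack."""
    missing = [s for s in DSP_STATES if s not in stack.psa_labels]
    if missing:
        raise ValueError(f"stack is missing PSA state(s): {', '.join(missing)}")
    stokes = {}
    for m in stack.psg_labels:
        comps = []
        for ci, (pos, neg) in enumerate(_COMPONENT_PAIRS):
            a, b = stack.intensity(m, pos), stack.intensity(m, neg)
            comps.append(a + b if ci == 0 else a - b)
        stokes[m] = np.stack(comps, axis=-1)
    return StokesImageSet(stokes=stokes, meta=dict(stack.meta))


def pure_state_s0(s: np.ndarray) -> np.ndarray:
    """Replace measured s0 by sqrt(s1^2 + s2^2 + s3^2) (pure-state filter).

    Accepts Stokes array(s) with trailing component axis; returns a copy.
    The original s0 is what the caller holds, so unfiltered processing stays
    available for comparison.
    """
    s = np.array(s, dtype=float)
    s[..., 0] = np.sqrt(np.sum(s[..., 1:] ** 2, axis=-1))
    return s


def apply_pure_state_filter(images: StokesImageSet) -> StokesImageSet:
    """Return a new set with the pure-state s0 substitution in every state."""
    out = StokesImageSet(
        stokes={k: pure_state_s0(v) for k, v in images.stokes.items()},
        mask=images.mask.copy(),
        masks=dict(images.masks),
        meta={**images.meta, "pure_state_filtered": True},
    )
    return out


def circular_consistency_mask(
    images: StokesImageSet, tol: float | None = None
) -> np.ndarray:
    """Mask from the identity s0^RCP - s0^LCP = s3^RCP + s3^LCP.

    Pixels whose residual exceeds ``tol`` times the local s0 scale are
    invalid.  With ``tol=None`` the tolerance is three Poisson standard
    errors of the left-hand side (sqrt(s0^RCP + s0^LCP) in count units),
    normalized by the same scale — a documented default; the choice of
    distance criterion is not prescribed by the identity itself.
    """
    r, l = images["RCP"], images["LCP"]
    lhs = r[..., 0] - l[..., 0]
    rhs = r[..., 3] + l[..., 3]
    scale = np.maximum(r[..., 0] + l[..., 0], 1e-300)
    residual = np.abs(lhs - rhs)
    if tol is None:
        bound = 3.0 * np.sqrt(scale)
    else:
        bound = tol * scale
    return residual <= bound


def intensity_mask(images: StokesImageSet, threshold_counts: float = 10.0) -> np.ndarray:
    """Mask pixels whose s0 averaged over the incident states is below the
    count threshold (default 10 counts)."""
    return images.mean_s0() >= threshold_counts
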