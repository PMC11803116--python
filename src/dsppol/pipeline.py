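"""End-to-end processing: intensity stack -> Stokes -> parameters -> maps.

``RunConfig`` gathers every threshold, branch and convention choice so two
runs are comparable; ``process_stack`` is the single entry point the CLI
and the scripts use.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np

from .filtering import (
    StokesImageSet,
    apply_pure_state_filter,
    circular_consistency_mask,
    intensity_mask,
    stokes_from_intensities,
)
from .forward import PolarimetricStack
from .inversion import UltrastructureMaps, invert_maps
from .parameters import DSPParameterSet, compute_parameters

log = logging.getLogger("dsppol")

__all__ = ["RunConfig", "process_stack"]


@dataclass
class RunConfig:
    """All tunables of the standard processing pipeline.

    ``intensity_threshold`` is in detector counts (mean s0 over the six
    incident states); ``c_threshold`` is the chirality level below which
    the phase Delta is considered undefined; ``consistency_tol`` of None
    uses the shot-noise-scaled default of the circular consistency filter.
    """

    intensity_threshold: float = 10.0
    c_threshold: float = 0.02
    consistency_tol: float | None = None
    pure_state_filter: bool = True
    circular_filter: bool = True
    r_path: str = "cacd_l"
    r_branch: str = "auto"
    delta_path: str = "B"
    sigma_mode: str = "h3"
    chiral_source: str = "TW"
    seed: int | None = None

    def __post_init__(self):
        if self.intensity_threshold < 0 or self.c_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        if self.consistency_tol is not None and self.consistency_tol < 0:
            raise ValueError("consistency_tol must be non-negative")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "RunConfig":
        return cls(**json.loads(s))

    def to_yaml(self) -> str:
        import yaml

        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        import yaml

        return cls(**yaml.safe_load(text))


def process_stack(
    stack: PolarimetricStack, config: RunConfig | None = None
) -> tuple[StokesImageSet, DSPParameterSet, UltrastructureMaps]:
    """Run the full closed-form pipeline on a 36-image stack."""
    cfg = config or RunConfig()
    images = stokes_from_intensities(stack)
    images.add_mask("intensity", intensity_mask(images, cfg.intensity_threshold))
    if cfg.circular_filter:
        images.add_mask("circular", circular_consistency_mask(images, cfg.consistency_tol))
    for name, m in images.masks.items():
        log.info("filter %s: %d pixels masked", name, int(m.size - np.count_nonzero(m)))
    if cfg.pure_state_filter:
        images = apply_pure_state_filter(images)
    params = compute_parameters(images)
    log.info("parameter denominator masking: %s", params.masked_counts)
    um = invert_maps(
        params,
        r_path=cfg.r_path,
        r_branch=cfg.r_branch,
        delta_path=cfg.delta_path,
        sigma_mode=cfg.sigma_mode,
        chiral_source=cfg.chiral_source,
        c_threshold=cfg.c_threshold,
    )
    log.info(
        "inversion: r_path=%s delta_path=%s sigma=%s ambiguous=%d",
        cfg.r_path, cfg.delta_path, cfg.sigma_mode, um.meta["ambiguous_count"],
    )
    return images, params, um
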