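"""File formats and summary statistics.

Stacks travel as multi-page TIFF in PSG-major page order (page index =
i_psg * n_psa + i_psa) with a JSON sidecar holding the state labels and
acquisition metadata.  Stokes image sets are 24-page TIFFs (6 incident
states x 4 components) plus masks as 8-bit TIFF.  Parameter and
ultrastructure maps are written one page per map with CSV summaries
(median, interquartile range, valid-pixel count and fixed-rule histograms).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .filtering import StokesImageSet
from .forward import PolarimetricStack
from .polarization import DSP_STATES

__all__ = [
    "write_stack",
    "read_stack",
    "write_stokes_images",
    "write_maps",
    "summarize_maps",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(path: str | Path, stack: PolarimetricStack, dtype=np.float32) -> None:
    """Write a stack as multi-page TIFF (PSG-major) with a JSON sidecar."""
    path = Path(path)
    n_psg, n_psa = len(stack.psg_labels), len(stack.psa_labels)
    pages = stack.data.reshape((n_psg * n_psa,) + stack.grid_shape).astype(dtype)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "psg_labels": list(stack.psg_labels),
        "psa_labels": list(stack.psa_labels),
        "page_order": "psg_major",
        **{k: v for k, v in stack.meta.items() if _jsonable(v)},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def read_stack(path: str | Path, metadata: dict | None = None) -> PolarimetricStack:
    """Read a stack written by :func:`write_stack`.

    ``metadata`` overrides the sidecar (useful for foreign files); the
    declared state grid must match the page count, and for a DSP stack the
    six canonical PSA states must all be present — the error names the
    first missing (PSG, PSA) pair.
    """
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if metadata is None:
        side = _sidecar(path)
        if not side.exists():
            raise FileNotFoundError(f"missing JSON sidecar {side}")
        metadata = json.loads(side.read_text())
    psg = tuple(metadata["psg_labels"])
    psa = tuple(metadata["psa_labels"])
    expected = len(psg) * len(psa)
    if pages.shape[0] != expected:
        i = pages.shape[0]  # first absent page in psg-major order
        missing = (psg[i // len(psa)], psa[i % len(psa)]) if i < expected else None
        raise ValueError(
            f"page count {pages.shape[0]} does not match declared "
            f"{len(psg)}x{len(psa)} grid"
            + (f"; first missing pair is (PSG={missing[0]}, PSA={missing[1]})" if missing else "")
        )
    if len(psg) == len(psa) == 6:
        for s in DSP_STATES:
            if s not in psa:
                raise ValueError(f"DSP stack is missing PSA state {s}")
    data = pages.reshape((len(psg), len(psa)) + pages.shape[1:]).astype(float)
    meta = {k: v for k, v in metadata.items() if k not in ("psg_labels", "psa_labels")}
    return PolarimetricStack(data=data, psg_labels=psg, psa_labels=psa, meta=meta)


def write_stokes_images(path: str | Path, images: StokesImageSet) -> None:
    """24-page TIFF (state-major, 4 components each) plus mask TIFF and
    JSON sidecar."""
    path = Path(path)
    order = [s for s in DSP_STATES if s in images.stokes] or list(images.labels)
    pages = np.concatenate(
        [np.moveaxis(images[s], -1, 0) for s in order], axis=0
    ).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")
    tifffile.imwrite(
        path.with_name(path.stem + "_mask" + path.suffix),
        images.mask.astype(np.uint8) * 255,
        photometric="minisblack",
    )
    _sidecar(path).write_text(
        json.dumps({"states": order, "components": ["s0", "s1", "s2", "s3"],
                    **{k: v for k, v in images.meta.items() if _jsonable(v)}}, indent=2)
    )


def write_maps(path: str | Path, maps: dict[str, np.ndarray]) -> None:
    """One float32 page per named map, names in the sidecar."""
    path = Path(path)
    names = list(maps)
    tifffile.imwrite(path, np.stack([np.asarray(maps[n], dtype=np.float32) for n in names]), photometric="minisblack")
    _sidecar(path).write_text(json.dumps({"maps": names}, indent=2))


def summarize_maps(
    maps: dict[str, np.ndarray],
    masks: dict[str, np.ndarray] | None = None,
    n_bins: int = 50,
) -> pd.DataFrame:
    """Median / IQR / count summary per map, masked pixels excluded.

    Histogram bin edges follow a fixed rule (``n_bins`` equal-width bins
    between the 0.5 and 99.5 percentiles) so two runs are comparable.
    Returns a DataFrame with one row per map; all-masked maps yield a row
    with count 0 and NaN statistics.
    """
    rows = []
    for name, arr in maps.items():
        arr = np.asarray(arr, dtype=float)
        m = np.isfinite(arr)
        if masks and name in masks and masks[name] is not None:
            m &= np.asarray(masks[name], dtype=bool)
        vals = arr[m]
        if vals.size == 0:
            rows.append({"map": name, "count": 0, "median": np.nan,
                         "iqr": np.nan, "q25": np.nan, "q75": np.nan,
                         "bin_edges": "", "bin_counts": ""})
            continue
        q25, med, q75 = np.percentile(vals, [25, 50, 75])
        lo, hi = np.percentile(vals, [0.5, 99.5])
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
        rows.append({
            "map": name, "count": int(vals.size), "median": med,
            "iqr": q75 - q25, "q25": q25, "q75": q75,
            "bin_edges": ";".join(f"{e:.6g}" for e in edges),
            "bin_counts": ";".join(str(c) for c in counts),
        })
    return pd.DataFrame(rows)
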