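"""Image-stack readers/writers and flat config files.

Stacks are multi-page TIFF files or directories of per-slice PNGs (slice
order = page order, or lexicographic filename order for directories).  Three
kinds are supported:

* ``binary``  — values must be exactly {0, dtype-max} (or {0, 1} for float /
  bool data) and are mapped to {0, 1}; anything else is rejected.
* ``prob``    — integer data is scaled linearly to [0, 1] by its dtype range;
  float data is validated to lie within [0, 1].
* ``label``   — integers passed through unchanged.

Boundary maps follow the convention 1 = cell interior.  Datasets encoded with
1 = membrane can be flipped at read time with ``invert=True``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Sequence, Union

import imageio.v3 as iio
import numpy as np
import tifffile

from .core import BoundaryMap, LabelImage, ProbBoundaryMap, ScoringError

logger = logging.getLogger("emscore")

__all__ = ["read_stack", "write_stack", "read_config"]

_KINDS = ("binary", "prob", "label")


def _load_pages(path: Path) -> List[np.ndarray]:
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".png")
        if not files:
            raise ScoringError(f"no .png files found in directory {path}")
        pages = [np.asarray(iio.imread(f)) for f in files]
    elif path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
        pages = [p for p in data] if data.ndim == 3 else [data]
    else:
        raise ScoringError(f"unreadable stack path {path}: expected a .tif file or a PNG directory")
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise ScoringError(f"mixed slice dimensions in {path}: {sorted(shapes)}")
    if pages[0].ndim != 2:
        raise ScoringError(f"slices in {path} must be single-channel 2D images")
    return pages


def _dtype_max(arr: np.ndarray) -> float:
    if arr.dtype == bool:
        return 1
    if np.issubdtype(arr.dtype, np.integer):
        return np.iinfo(arr.dtype).max
    return 1.0


def read_stack(
    path: Union[str, Path], kind: str, invert: bool = False
) -> List[Union[BoundaryMap, ProbBoundaryMap, LabelImage]]:
    """Read an image stack as a list of maps of the requested ``kind``."""
    if kind not in _KINDS:
        raise ScoringError(f"kind must be one of {_KINDS}, got {kind!r}")
    path = Path(path)
    pages = _load_pages(path)
    out: List[Union[BoundaryMap, ProbBoundaryMap, LabelImage]] = []
    for i, page in enumerate(pages):
        if kind == "binary":
            top = _dtype_max(page)
            vals = np.unique(page)
            if not np.isin(vals, (0, top)).all():
                bad = vals[~np.isin(vals, (0, top))]
                raise ScoringError(
                    f"non-binary input in slice {i} of {path}: values {bad.tolist()[:5]} "
                    f"(expected only 0 and {top})"
                )
            bmap = BoundaryMap((page == top).astype(np.uint8))
            out.append(bmap.inverted() if invert else bmap)
        elif kind == "prob":
            arr = page.astype(np.float64) / _dtype_max(page)
            pm = ProbBoundaryMap(arr)
            out.append(ProbBoundaryMap(1.0 - pm.pixels) if invert else pm)
        else:
            if not np.issubdtype(page.dtype, np.integer):
                raise ScoringError(f"label stack {path} must contain integers, got {page.dtype}")
            out.append(LabelImage(page.astype(np.int64)))
    if invert:
        logger.info("read %s with inverted polarity (input used 1 = membrane)", path)
    return out


def write_stack(path: Union[str, Path], maps: Sequence, kind: str) -> None:
    """Write a stack of maps as multi-page TIFF (``.tif``/``.tiff`` path) or
    a directory of per-slice PNGs (any other path).  Round-trips with
    :func:`read_stack`."""
    if kind not in _KINDS:
        raise ScoringError(f"kind must be one of {_KINDS}, got {kind!r}")
    if not maps:
        raise ScoringError("cannot write an empty stack")
    path = Path(path)
    if kind == "binary":
        pages = [(m.pixels * np.uint8(255)) for m in maps]
    elif kind == "prob":
        pages = [m.pixels.astype(np.float32) for m in maps]
    else:
        pages = [m.labels.astype(np.int32) for m in maps]
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.stack(pages), photometric="minisblack")
    else:
        if kind == "prob":
            raise ScoringError("probabilistic stacks must be written as TIFF (float PNG unsupported)")
        path.mkdir(parents=True, exist_ok=True)
        for i, page in enumerate(pages):
            if kind == "label":
                page = page.astype(np.uint16)
            iio.imwrite(path / f"slice_{i:04d}.png", page)


def read_config(path: Union[str, Path]) -> Dict[str, str]:
    """Read a flat ``key = value`` config file mirroring the CLI flags.

    Blank lines and lines starting with ``#`` are ignored; values are returned
    as strings and interpreted by the CLI layer.
    """
    out: Dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ScoringError(f"bad config line {lineno} in {path}: {line!r} (expected key = value)")
        key, _, value = line.partition("=")
        out[key.strip().replace("-", "_")] = value.strip()
    return out
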