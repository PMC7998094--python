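"""File formats: channel images, boundary annotation files, manifests.

Images are single-plane grayscale TIFF or PNG files, one per channel;
the physical pixel size always comes from the run configuration, never
from embedded metadata.

Boundary files are plain text, one per image, holding the ROI polygon
and the three boundary polylines as ordered ``x,y`` coordinate lists
(0-based pixel indices, (x, y) = (column, row), origin top-left):

    # cervimage boundaries v1
    [roi_polygon]
    12.0,3.5
    ...
    [basal_line]
    ...
    [ecad_boundary_line]
    ...
    [apical_line]
    ...
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import tifffile
from imageio.v3 import imread as _png_imread, imwrite as _png_imwrite

from .geometry import BoundaryError, BoundarySet

__all__ = [
    "read_image",
    "write_image",
    "read_boundaries",
    "write_boundaries",
]

logger = logging.getLogger(__name__)

_SECTIONS = ("roi_polygon", "basal_line", "ecad_boundary_line", "apical_line")


def read_image(path) -> np.ndarray:
    """Read a single-plane grayscale TIFF or PNG as a float array."""
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(p)
    else:
        arr = _png_imread(p)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):  # collapse accidental RGB
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ValueError(f"{p}: expected a single 2D plane, got shape {arr.shape}")
    return arr.astype(float)


def write_image(path, pixels: np.ndarray) -> None:
    """Write a 2D array as grayscale TIFF (float32) or PNG (uint8-scaled)."""
    p = Path(path)
    arr = np.asarray(pixels)
    if p.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(p, arr.astype(np.float32))
    else:
        hi = arr.max() if arr.size and arr.max() > 0 else 1.0
        _png_imwrite(p, np.clip(255.0 * arr / hi, 0, 255).astype(np.uint8))


def write_boundaries(path, boundaries: BoundarySet) -> None:
    """Write a BoundarySet to the plain-text boundary file format."""
    lines = ["# cervimage boundaries v1",
             "# x,y per line; 0-based pixel indices, origin top-left"]
    for name in _SECTIONS:
        lines.append(f"[{name}]")
        for x, y in getattr(boundaries, name):
            lines.append(f"{x:.3f},{y:.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_boundaries(path) -> BoundarySet:
    """Parse a plain-text boundary file into a BoundarySet."""
    sections: dict[str, list[tuple[float, float]]] = {}
    current: str | None = None
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            if current not in _SECTIONS:
                raise BoundaryError(f"{path}:{ln}: unknown section {current!r}")
            sections[current] = []
            continue
        if current is None:
            raise BoundaryError(f"{path}:{ln}: coordinates before any section header")
        try:
            xs, ys = line.split(",")
            sections[current].append((float(xs), float(ys)))
        except ValueError as exc:
            raise BoundaryError(f"{path}:{ln}: malformed coordinate {line!r}") from exc
    missing = [s for s in _SECTIONS if s not in sections]
    if missing:
        raise BoundaryError(f"{path}: missing sections {missing}")
    return BoundarySet(
        roi_polygon=np.array(sections["roi_polygon"]),
        basal_line=np.array(sections["basal_line"]),
        ecad_boundary_line=np.array(sections["ecad_boundary_line"]),
        apical_line=np.array(sections["apical_line"]),
    )
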