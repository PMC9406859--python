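"""Fundus image loading, resizing, and the fixed 8-patch division scheme.

A fundus photograph is resized to a square 256 x 256 canvas, split into four
equal 128 x 128 quadrants, and each quadrant is cut in two along a direction
that depends on its position: the upper-left and lower-right quadrants are cut
horizontally (yielding wide, short 64 x 128 strips), the upper-right and
lower-left quadrants vertically (tall, narrow 128 x 64 strips).  The eight
patches P1..P8 plus the resized main image are the nine inputs later fed to
the embedding backend.

Patch numbering is fixed so downstream feature columns have a reproducible
provenance:

    P1, P2 : upper-left quadrant, top then bottom half        (horizontal)
    P3, P4 : upper-right quadrant, left then right half       (vertical)
    P5, P6 : lower-left quadrant, left then right half        (vertical)
    P7, P8 : lower-right quadrant, top then bottom half       (horizontal)

All coordinates are 0-based, half-open row/col ranges on the resized canvas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage.transform import resize as _sk_resize

from .errors import ContractError, InputError, ParameterError

logger = logging.getLogger(__name__)

#: side of the square working canvas, in pixels
CANVAS_SIDE = 256

#: quadrant -> cut direction, fixed by the division scheme
QUADRANT_ORIENTATION = {
    "UL": "horizontal",
    "UR": "vertical",
    "LL": "vertical",
    "LR": "horizontal",
}


@dataclass
class FundusImage:
    """A 3-channel 8-bit fundus photograph with optional class label."""

    pixels: np.ndarray
    source_id: str = ""
    label: Optional[object] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ContractError(
                f"FundusImage requires a rows x cols x 3 array, got shape {px.shape}"
            )
        if px.dtype != np.uint8:
            raise ContractError(
                f"FundusImage requires uint8 pixels, got dtype {px.dtype}"
            )
        self.pixels = px

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass
class Patch:
    """One rectangular patch cut from the resized canvas."""

    pixels: np.ndarray
    index: int  # 1..8
    quadrant: str  # UL | UR | LL | LR
    orientation: str  # horizontal | vertical
    origin: tuple  # (row, col) offset in the resized main image


@dataclass
class PatchSet:
    """The resized main image together with its eight oriented patches."""

    main: FundusImage
    patches: list = field(default_factory=list)

    def inputs(self):
        """Yield the nine embedding inputs in canonical order: main, P1..P8."""
        yield "main", self.main.pixels
        for p in self.patches:
            yield f"P{p.index}", p.pixels


def load_image(path, source_id: Optional[str] = None) -> FundusImage:
    """Load a PNG or JPEG file as a 3-channel uint8 :class:`FundusImage`.

    Grayscale images are promoted to 3 channels by replication; an alpha
    channel is dropped with a logged warning.  Unreadable files raise
    :class:`InputError` naming the path.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("RGBA", "LA", "PA"):
                logger.warning("dropping alpha channel of %s (mode %s)", path, im.mode)
                im = im.convert("RGB")
            elif im.mode != "RGB":
                im = im.convert("RGB")
            pixels = np.asarray(im, dtype=np.uint8)
    except (OSError, UnidentifiedImageError, SyntaxError) as exc:
        raise InputError(f"cannot read image file {path}: {exc}") from exc
    return FundusImage(pixels=pixels, source_id=source_id or path.name)


def resize_to_canvas(
    img: FundusImage, side: int = CANVAS_SIDE, interpolation: str = "bilinear"
) -> FundusImage:
    """Resize anisotropically to ``side x side`` (no letterboxing).

    A ``side x side`` input is returned unchanged, bitwise.  ``side`` must be
    even so that quadrants are equal.  Interpolation is bilinear by default;
    ``"nearest"`` selects nearest-neighbour resampling.
    """
    if side < 2 or side % 2 != 0:
        raise ParameterError(f"canvas side must be even and >= 2, got {side}")
    if interpolation not in ("bilinear", "nearest"):
        raise ParameterError(f"unknown interpolation {interpolation!r}")
    if img.pixels.shape[:2] == (side, side):
        return img
    order = 1 if interpolation == "bilinear" else 0
    out = _sk_resize(
        img.pixels,
        (side, side),
        order=order,
        preserve_range=True,
        anti_aliasing=False,
    )
    return FundusImage(
        pixels=np.clip(np.rint(out), 0, 255).astype(np.uint8),
        source_id=img.source_id,
        label=img.label,
    )


def _patch_slices():
    """The fixed (index, quadrant, row-slice, col-slice) layout on the canvas."""
    q = CANVAS_SIDE // 2  # quadrant side, 128
    h = CANVAS_SIDE // 4  # half-quadrant, 64
    return [
        # UL quadrant, horizontal cuts: top half then bottom half
        (1, "UL", slice(0, h), slice(0, q)),
        (2, "UL", slice(h, q), slice(0, q)),
        # UR quadrant, vertical cuts: left half then right half
        (3, "UR", slice(0, q), slice(q, q + h)),
        (4, "UR", slice(0, q), slice(q + h, 2 * q)),
        # LL quadrant, vertical cuts: left half then right half
        (5, "LL", slice(q, 2 * q), slice(0, h)),
        (6, "LL", slice(q, 2 * q), slice(h, q)),
        # LR quadrant, horizontal cuts: top half then bottom half
        (7, "LR", slice(q, q + h), slice(q, 2 * q)),
        (8, "LR", slice(q + h, 2 * q), slice(q, 2 * q)),
    ]


def divide_into_patches(img: FundusImage) -> PatchSet:
    """Cut a 256 x 256 image into the eight fixed patches P1..P8.

    The patches partition the canvas exactly: every pixel is copied into
    exactly one patch.  Inputs of any other size raise :class:`ContractError`
    (resize first with :func:`resize_to_canvas`).
    """
    if img.pixels.shape[:2] != (CANVAS_SIDE, CANVAS_SIDE):
        raise ContractError(
            f"patch division requires a {CANVAS_SIDE}x{CANVAS_SIDE} canvas, "
            f"got {img.pixels.shape[0]}x{img.pixels.shape[1]}; resize first"
        )
    patches = []
    for index, quadrant, rs, cs in _patch_slices():
        patches.append(
            Patch(
                pixels=img.pixels[rs, cs].copy(),
                index=index,
                quadrant=quadrant,
                orientation=QUADRANT_ORIENTATION[quadrant],
                origin=(rs.start, cs.start),
            )
        )
    return PatchSet(main=img, patches=patches)


def prepare_patchset(img: FundusImage, interpolation: str = "bilinear") -> PatchSet:
    """Convenience: resize to the canvas then divide into patches."""
    return divide_into_patches(resize_to_canvas(img, interpolation=interpolation))
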