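"""Pixel masks: FIT2D ``.msk`` bitmaps and image-file masks.

A mask marks detector pixels to EXCLUDE from integration (dead pixels, module
gaps, the beamstop shadow).  The boolean grid uses ``True`` = masked, matching
the FIT2D convention that a set bit excludes the pixel.

The binary ``.msk`` dialect implemented here: a 1024-byte header whose first
four bytes are ``b"MASK"`` with the image width (horizontal, pixels) and
height (vertical, pixels) stored as little-endian int32 at byte offsets 16 and
20, followed by one bit-packed row per image row, least-significant bit first
within each byte, every row padded to a multiple of 4 bytes.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

__all__ = [
    "PixelMask",
    "read_fit2d_mask",
    "write_fit2d_mask",
    "read_image_mask",
    "combine_masks",
]

_MSK_MAGIC = b"MASK"
_MSK_HEADER_SIZE = 1024


class MaskFormatError(ValueError):
    """Raised for unreadable mask files or shape mismatches."""


def _as_mask(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=bool)
    if grid.ndim != 2:
        raise MaskFormatError("a pixel mask must be a 2D boolean grid")
    return grid


#: Alias used in type hints: boolean 2D array, True = pixel excluded.
PixelMask = np.ndarray


def _row_bytes(width: int) -> int:
    # bit-packed row, padded to a multiple of 4 bytes
    return ((width + 7) // 8 + 3) // 4 * 4


def read_fit2d_mask(path, expected_shape: tuple[int, int]) -> PixelMask:
    """Read a FIT2D-style binary ``.msk`` bitmap.

    Parameters
    ----------
    path : path-like
        Mask file.
    expected_shape : (int, int)
        ``(vertical, horizontal)`` image size from the calibration; the file's
        own dimensions must match.

    Returns
    -------
    PixelMask
        Boolean grid, ``True`` where the pixel is excluded.
    """
    with open(path, "rb") as fh:
        header = fh.read(_MSK_HEADER_SIZE)
        if len(header) < _MSK_HEADER_SIZE or header[:4] != _MSK_MAGIC:
            raise MaskFormatError(f"{path}: not a recognizable .msk file (bad header)")
        width = int.from_bytes(header[16:20], "little")
        height = int.from_bytes(header[20:24], "little")
        if (height, width) != tuple(expected_shape):
            raise MaskFormatError(
                f"{path}: mask is {height}x{width} but calibration expects "
                f"{expected_shape[0]}x{expected_shape[1]}"
            )
        stride = _row_bytes(width)
        body = fh.read(stride * height)
        if len(body) < stride * height:
            raise MaskFormatError(f"{path}: truncated .msk body")
    rows = np.frombuffer(body, dtype=np.uint8).reshape(height, stride)
    bits = np.unpackbits(rows, axis=1, bitorder="little")[:, :width]
    return bits.astype(bool)


def write_fit2d_mask(mask: PixelMask, path) -> None:
    """Write a boolean mask grid as a ``.msk`` bitmap (dialect above)."""
    mask = _as_mask(mask)
    height, width = mask.shape
    header = bytearray(_MSK_HEADER_SIZE)
    header[:4] = _MSK_MAGIC
    header[16:20] = int(width).to_bytes(4, "little")
    header[20:24] = int(height).to_bytes(4, "little")
    stride = _row_bytes(width)
    packed = np.packbits(mask.astype(np.uint8), axis=1, bitorder="little")
    rows = np.zeros((height, stride), dtype=np.uint8)
    rows[:, : packed.shape[1]] = packed
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(rows.tobytes())


def read_image_mask(path, expected_shape: tuple[int, int]) -> PixelMask:
    """Read a single-channel image file as a mask; nonzero pixels are excluded."""
    with Image.open(path) as img:
        arr = np.asarray(img)
    if arr.ndim != 2:
        raise MaskFormatError(f"{path}: mask images must have a single channel")
    if arr.shape != tuple(expected_shape):
        raise MaskFormatError(
            f"{path}: mask image is {arr.shape} but calibration expects {tuple(expected_shape)}"
        )
    return arr != 0


def load_mask(path, expected_shape: tuple[int, int]) -> PixelMask:
    """Dispatch on file extension: ``.msk`` binary bitmap, otherwise image file."""
    if str(path).lower().endswith(".msk"):
        return read_fit2d_mask(path, expected_shape)
    return read_image_mask(path, expected_shape)


def combine_masks(masks: list[PixelMask]) -> PixelMask:
    """Logical OR of exclusions; all masks must share one shape."""
    if not masks:
        raise MaskFormatError("combine_masks needs at least one mask")
    grids = [_as_mask(m) for m in masks]
    shape = grids[0].shape
    for g in grids[1:]:
        if g.shape != shape:
            raise MaskFormatError(f"mask shapes differ: {g.shape} vs {shape}")
    out = grids[0].copy()
    for g in grids[1:]:
        out |= g
    return out
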