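"""Non-overlapping patch extraction at two magnifications.

A whole-mount image is divided into a grid of square patches that cover the
top-left ``floor(H/ps) x floor(W/ps)`` region exactly; residual right/bottom
margins are discarded, never padded.  Low-magnification patches (128 px)
correspond to high-magnification regions (1024 px) through an 8x linear
scale factor, and each high-magnification region is further divided into
28-px sub-patches (36 x 36 = 1296 per region, with a 16-px discarded margin
per axis).

Coordinates are 0-based, half-open and row-major throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

#: linear scale between the low- and high-magnification planes (25x vs 200x)
DEFAULT_SCALE_FACTOR = 8
#: low-magnification patch edge, pixels
LOW_PATCH_SIZE = 128
#: high-magnification region edge, pixels (= 128 * 8)
HIGH_REGION_SIZE = 1024
#: high-magnification sub-patch edge, pixels
SUB_PATCH_SIZE = 28


@dataclass
class SlideImage:
    """An RGB slide with identity and magnification bookkeeping."""

    slide_id: str
    patient_id: str
    pixels: np.ndarray  # (H, W, 3) uint8
    magnification: Literal["low", "high"]

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("slide pixels must be an (H, W, 3) RGB array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass(frozen=True)
class PatchRef:
    """Reference to one patch: slide index i, patch j, optional sub-patch j'."""

    slide: int
    patch: int
    sub_patch: Optional[int] = None


@dataclass
class PatchGrid:
    """A raster-ordered grid of non-overlapping square patches."""

    slide_id: str
    patch_size: int
    n_rows: int
    n_cols: int
    patches: np.ndarray  # (n_rows*n_cols, ps, ps, 3)
    origin: tuple[int, int] = (0, 0)  # (y, x) pixel offset of cell (0, 0)

    def __len__(self) -> int:
        return self.n_rows * self.n_cols

    def rowcol(self, j: int) -> tuple[int, int]:
        """Row/column of patch index ``j`` (row-major raster order)."""
        if not 0 <= j < len(self):
            raise IndexError(f"patch index {j} outside grid of {len(self)}")
        return divmod(j, self.n_cols)[0], j % self.n_cols

    def offset(self, j: int) -> tuple[int, int]:
        """Top-left pixel (y0, x0) of patch ``j`` on the source image."""
        r, c = self.rowcol(j)
        return (self.origin[0] + r * self.patch_size,
                self.origin[1] + c * self.patch_size)

    def manifest(self) -> pd.DataFrame:
        """TSV-ready manifest: one row per patch with grid and pixel coords."""
        rows = []
        for j in range(len(self)):
            r, c = self.rowcol(j)
            y0, x0 = self.offset(j)
            rows.append((self.slide_id, j, r, c, y0, x0, self.patch_size))
        return pd.DataFrame(
            rows, columns=["slide_id", "j", "row", "col", "y0", "x0", "size"]
        )

    def reassemble(self) -> np.ndarray:
        """Stitch the patches back into the covered (cropped) image region."""
        ps = self.patch_size
        out = self.patches.reshape(self.n_rows, self.n_cols, ps, ps, 3)
        return out.transpose(0, 2, 1, 3, 4).reshape(
            self.n_rows * ps, self.n_cols * ps, 3
        )


def tile(image: np.ndarray | SlideImage, patch_size: int,
         slide_id: str = "", origin: tuple[int, int] = (0, 0)) -> PatchGrid:
    """Divide ``image`` into non-overlapping ``patch_size`` squares.

    The grid covers ``floor(H/ps) x floor(W/ps)`` patches anchored at the
    top-left corner; any residual margin is discarded.
    """
    if isinstance(image, SlideImage):
        slide_id = slide_id or image.slide_id
        image = image.pixels
    if patch_size < 1:
        raise ValueError("patch_size must be >= 1")
    h, w = image.shape[:2]
    if h < patch_size or w < patch_size:
        raise ValueError(
            f"image of {h}x{w} px is smaller than one {patch_size}-px patch"
        )
    n_rows, n_cols = h // patch_size, w // patch_size
    ps = patch_size
    cropped = image[: n_rows * ps, : n_cols * ps]
    patches = (
        cropped.reshape(n_rows, ps, n_cols, ps, -1)
        .transpose(0, 2, 1, 3, 4)
        .reshape(n_rows * n_cols, ps, ps, -1)
    )
    return PatchGrid(slide_id, ps, n_rows, n_cols, patches, origin)


def map_low_to_high(row: int, col: int,
                    low_patch_size: int = LOW_PATCH_SIZE,
                    factor: int = DEFAULT_SCALE_FACTOR,
                    high_shape: tuple[int, int] | None = None,
                    ) -> tuple[int, int, int, int]:
    """Map a low-magnification grid cell to its high-magnification rectangle.

    Returns the half-open pixel rectangle ``(y0, y1, x0, x1)`` on the
    high-magnification slide that corresponds to the low-magnification patch
    at grid position ``(row, col)``.
    """
    if row < 0 or col < 0:
        raise ValueError("grid position must be non-negative")
    size = low_patch_size * factor
    y0, x0 = row * size, col * size
    y1, x1 = y0 + size, x0 + size
    if high_shape is not None and (y1 > high_shape[0] or x1 > high_shape[1]):
        raise ValueError(
            f"mapped rectangle [{y0},{y1})x[{x0},{x1}) exceeds the "
            f"high-magnification slide of {high_shape[0]}x{high_shape[1]} px "
            "(slides of mismatched extent)"
        )
    return y0, y1, x0, x1


def tile_highmag_region(high_image: np.ndarray | SlideImage, row: int, col: int,
                        sub_patch_size: int = SUB_PATCH_SIZE,
                        low_patch_size: int = LOW_PATCH_SIZE,
                        factor: int = DEFAULT_SCALE_FACTOR) -> PatchGrid:
    """Tile the high-magnification region behind one low-magnification patch.

    For the default geometry (1024-px region, 28-px sub-patches) this yields
    exactly 36 x 36 = 1296 sub-patches; the 16-px remainder per axis is
    discarded at the right/bottom edge.
    """
    if isinstance(high_image, SlideImage):
        slide_id = high_image.slide_id
        high_image = high_image.pixels
    else:
        slide_id = ""
    y0, y1, x0, x1 = map_low_to_high(
        row, col, low_patch_size, factor, high_shape=high_image.shape[:2]
    )
    region = high_image[y0:y1, x0:x1]
    return tile(region, sub_patch_size, slide_id=slide_id, origin=(y0, x0))


def block_mean_downsample(image: np.ndarray, factor: int = DEFAULT_SCALE_FACTOR
                          ) -> np.ndarray:
    """Exact block-mean downsampling by an integer factor.

    This is the link between the two magnifications: the low-magnification
    slide is defined as the ``factor`` x ``factor`` block mean of the
    high-magnification slide, so 128-px low patches correspond
    bit-consistently to 1024-px high regions.
    """
    h, w = image.shape[:2]
    if h % factor or w % factor:
        raise ValueError(f"image dims {h}x{w} not multiples of factor {factor}")
    out = image.reshape(h // factor, factor, w // factor, factor, -1).mean(
        axis=(1, 3), dtype=np.float32
    )
    if np.issubdtype(image.dtype, np.integer):
        out = np.rint(out).astype(image.dtype)
    return out
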