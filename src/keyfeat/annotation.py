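"""Automatically annotated whole-slide maps.

Every low-magnification patch is shaded by its Step-1 impact score — red
above 0.5, blue below, unfilled for unscored/background/tie — and labelled
with the triple [feature index] [Step-1 impact] [Step-2 impact].  The
rendering is a blended PNG at a configurable downscale together with a TSV
sidecar that round-trips the overlay losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image

from .step1_features import Assignment
from .tiling import PatchGrid

RED, BLUE, NONE = "red", "blue", "none"
_FILL = {RED: np.array([255.0, 0.0, 0.0]), BLUE: np.array([0.0, 0.0, 255.0])}

SIDECAR_COLUMNS = ["row", "col", "y0", "x0", "size", "feature_k",
                   "impact1", "impact2", "color", "retained"]


@dataclass
class OverlayMap:
    """Per-patch fill colors and label triples for one slide."""

    slide_id: str
    patch_size: int
    n_rows: int
    n_cols: int
    cells: pd.DataFrame  # SIDECAR_COLUMNS, one row per grid cell

    def color_grid(self) -> np.ndarray:
        return (self.cells["color"].to_numpy()
                .reshape(self.n_rows, self.n_cols))


def _color_of(score: float) -> str:
    if np.isnan(score):
        return NONE
    if score > 0.5:
        return RED
    if score < 0.5:
        return BLUE
    return NONE  # exactly 0.5: tie, unfilled


def build_overlay(grid: PatchGrid, scores1: np.ndarray, scores2: np.ndarray,
                  assignment: Assignment,
                  retained: Optional[np.ndarray] = None) -> OverlayMap:
    """Overlay cells from the grid geometry, scores and feature assignment."""
    n = len(grid)
    s1 = np.asarray(scores1, dtype=np.float64)
    s2 = np.asarray(scores2, dtype=np.float64)
    if len(s1) != n or len(s2) != n or len(assignment) != n:
        raise ValueError(
            f"grid has {n} patches but scores/assignment cover "
            f"{len(s1)}/{len(s2)}/{len(assignment)}"
        )
    retained = (np.ones(n, dtype=bool) if retained is None
                else np.asarray(retained, dtype=bool))
    rows = []
    for j in range(n):
        r, c = grid.rowcol(j)
        y0, x0 = grid.offset(j)
        unscored = np.isnan(s1[j])
        rows.append((
            r, c, y0, x0, grid.patch_size,
            -1 if unscored else int(assignment.labels[j]),
            s1[j], s2[j], _color_of(s1[j]), bool(retained[j]),
        ))
    cells = pd.DataFrame(rows, columns=SIDECAR_COLUMNS)
    return OverlayMap(grid.slide_id, grid.patch_size, grid.n_rows,
                      grid.n_cols, cells)


def render(overlay: OverlayMap, slide_pixels: np.ndarray,
           opacity: float = 0.35, scale: float = 0.25
           ) -> tuple[np.ndarray, pd.DataFrame]:
    """Blend the overlay onto the (rescaled) slide image.

    Returns the annotated RGB array and the sidecar table (one row per
    scored patch).  ``opacity`` 0 reproduces the rescaled input exactly.
    """
    h_grid = overlay.n_rows * overlay.patch_size
    w_grid = overlay.n_cols * overlay.patch_size
    if slide_pixels.shape[0] < h_grid or slide_pixels.shape[1] < w_grid:
        raise ValueError("slide image smaller than the overlay grid")
    img = slide_pixels[:h_grid, :w_grid].astype(np.float64)
    if scale != 1.0:
        out_size = (max(1, int(round(w_grid * scale))),
                    max(1, int(round(h_grid * scale))))
        pil = Image.fromarray(slide_pixels[:h_grid, :w_grid])
        img = np.asarray(pil.resize(out_size, Image.BILINEAR)).astype(np.float64)
    cell_h = img.shape[0] / overlay.n_rows
    cell_w = img.shape[1] / overlay.n_cols
    for _, cell in overlay.cells.iterrows():
        if cell["color"] == NONE or opacity == 0.0:
            continue
        fill = _FILL[cell["color"]]
        y0 = int(round(cell["row"] * cell_h))
        y1 = int(round((cell["row"] + 1) * cell_h))
        x0 = int(round(cell["col"] * cell_w))
        x1 = int(round((cell["col"] + 1) * cell_w))
        img[y0:y1, x0:x1] = ((1 - opacity) * img[y0:y1, x0:x1]
                             + opacity * fill)
    sidecar = overlay.cells[overlay.cells["feature_k"] >= 0].reset_index(drop=True)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), sidecar


def write_sidecar(overlay: OverlayMap, path) -> None:
    overlay.cells.to_csv(path, sep="\t", index=False)


def read_sidecar(path, slide_id: str = "") -> OverlayMap:
    cells = pd.read_csv(path, sep="\t")
    n_rows = int(cells["row"].max()) + 1
    n_cols = int(cells["col"].max()) + 1
    size = int(cells["size"].iloc[0])
    return OverlayMap(slide_id, size, n_rows, n_cols, cells)
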