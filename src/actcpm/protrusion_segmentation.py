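"""Protrusion extraction from the activity field.

A protrusion is an 8-connected patch of at least 10 active lattice sites
within one cell.  Its orientation relative to a chemoattractant gradient
is the angle between the gradient direction and the vector from the cell
centroid to the protrusion centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .lattice import LatticeState
from .track_metrics import centroid_and_axes, minimal_image

MIN_PROTRUSION_SITES = 10

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class Protrusion:
    cell_id: int
    sites: np.ndarray          # (k, 2) of (x, y), original lattice frame
    size: int
    centroid: tuple[float, float]  # (x, y), wrapped into the lattice


def _roll_offsets(state: LatticeState, cell_id: int) -> tuple[int, int]:
    """Shifts that move the cell away from the periodic boundary."""
    ys, xs = np.nonzero(state.spin == cell_id)
    H, W = state.spin.shape

    def center(c, period):
        theta = c * (2.0 * np.pi / period)
        return np.arctan2(np.sin(theta).mean(),
                          np.cos(theta).mean()) * period / (2.0 * np.pi)

    sx = W // 2 - int(round(center(xs, W)))
    sy = H // 2 - int(round(center(ys, H)))
    return sx, sy


def segment_protrusions(state: LatticeState, cell_id: int,
                        activity_threshold: int = 0,
                        min_sites: int = MIN_PROTRUSION_SITES) -> list[Protrusion]:
    """8-connected patches of the cell's sites with activity above threshold.

    Components smaller than ``min_sites`` are discarded.  The lattice is
    recentered on the cell first, so patches straddling the wrapped
    boundary are kept whole.
    """
    if not (state.spin == cell_id).any():
        raise ValueError(f"cell {cell_id} has no sites")
    sx, sy = _roll_offsets(state, cell_id)
    spin = np.roll(state.spin, (sy, sx), axis=(0, 1))
    act = np.roll(state.activity, (sy, sx), axis=(0, 1))
    mask = (spin == cell_id) & (act > activity_threshold)
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    H, W = spin.shape
    out = []
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labels == lab)
        if len(xs) < min_sites:
            continue
        cx = (xs.mean() - sx) % W
        cy = (ys.mean() - sy) % H
        sites = np.column_stack([(xs - sx) % W, (ys - sy) % H])
        out.append(Protrusion(cell_id, sites, len(xs), (float(cx), float(cy))))
    return out


def protrusion_gradient_angle(protrusion_centroid, cell_centroid,
                              gradient_axis: str = "y",
                              lattice_shape: tuple[int, int] | None = None
                              ) -> float:
    """Angle (deg, 0..180) between the gradient and the centroid offset.

    0 degrees: the protrusion points straight up the gradient; 180:
    straight down.  With ``lattice_shape`` = (width, height) the offset
    is taken with minimal-image wrapping.  NaN for coincident centroids.
    """
    dx = protrusion_centroid[0] - cell_centroid[0]
    dy = protrusion_centroid[1] - cell_centroid[1]
    if lattice_shape is not None:
        dx = minimal_image(dx, lattice_shape[0])
        dy = minimal_image(dy, lattice_shape[1])
    norm = np.hypot(dx, dy)
    if norm == 0.0:
        return np.nan
    up = dy if gradient_axis == "y" else dx
    return float(np.degrees(np.arccos(np.clip(up / norm, -1.0, 1.0))))


def protrusion_table(state: LatticeState, cell_ids,
                     gradient_axis: str = "y", activity_threshold: int = 0):
    """Per-snapshot protrusion listing: cell_id, protrusion_id, size, angle."""
    import pandas as pd

    W, H = state.width, state.height
    rows = []
    for cid in cell_ids:
        geom = centroid_and_axes(state, cid)
        for k, pr in enumerate(segment_protrusions(
                state, cid, activity_threshold)):
            ang = protrusion_gradient_angle(pr.centroid, geom.centroid,
                                            gradient_axis, (W, H))
            rows.append((cid, k, pr.size, ang))
    return pd.DataFrame(rows, columns=["cell_id", "protrusion_id",
                                       "size", "angle"])
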