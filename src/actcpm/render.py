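"""PNG snapshots: cells colored by type, activity as a green-to-red ramp."""

from __future__ import annotations

import numpy as np

from .lattice import CPM

# muted per-type base colors (medium is white)
_TYPE_COLORS = [
    (0.55, 0.70, 0.95),
    (0.70, 0.70, 0.70),
    (0.85, 0.75, 0.55),
    (0.75, 0.60, 0.85),
]


def snapshot_rgb(sim: CPM) -> np.ndarray:
    """(H, W, 3) float image of the current lattice.

    Sites are tinted by cell type; active sites blend toward a
    green (fresh low activity) to red (activity at the type maximum)
    ramp, matching the usual activity colorbar.
    """
    spin = sim.state.spin
    act = sim.state.activity
    H, W = spin.shape
    img = np.ones((H, W, 3))
    type_of_site = sim._ctype[spin]
    for tid in range(1, len(sim.types) + 1):
        color = _TYPE_COLORS[(tid - 1) % len(_TYPE_COLORS)]
        img[type_of_site == tid] = color
        ma = sim._max_act[tid]
        if ma > 0:
            sel = (type_of_site == tid) & (act > 0)
            frac = act[sel] / ma
            ramp = np.column_stack([frac, 1.0 - frac, np.zeros(len(frac))])
            img[sel] = ramp
    # black cell outlines
    edge = np.zeros((H, W), dtype=bool)
    for dy, dx in ((0, 1), (1, 0)):
        edge |= spin != np.roll(spin, (-dy, -dx), axis=(0, 1))
    img[edge & (spin > 0)] *= 0.55
    return img


def save_snapshot(sim: CPM, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.imsave(path, np.clip(snapshot_rgb(sim), 0, 1), origin="lower")
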