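"""Static linear chemoattractant fields and the chemotaxis energy bias.

The standard Potts chemotaxis term

    dH_chem(u -> v) = lambda_chem * (C_v - C_u)

is subtracted from the energy change, so copies toward higher
concentration are favored.  Increasing ``lambda_chem`` is equivalent to
steepening the gradient.
"""

from __future__ import annotations

import numpy as np

from .lattice import Site


def linear_gradient(width: int, height: int, slope: float,
                    axis: str = "y") -> np.ndarray:
    """Concentration plane C = slope * coordinate along the given axis.

    With slope 0.33 and height 300 the field spans roughly 0..100 from
    bottom to top.
    """
    if axis == "y":
        c = slope * np.arange(height, dtype=np.float64)[:, None]
        return np.broadcast_to(c, (height, width)).copy()
    if axis == "x":
        c = slope * np.arange(width, dtype=np.float64)[None, :]
        return np.broadcast_to(c, (height, width)).copy()
    raise ValueError("axis must be 'x' or 'y'")


def delta_h_chemotaxis(field: np.ndarray, u: Site, v: Site,
                       lambda_chem: float) -> float:
    """lambda_chem * (C_v - C_u); the caller subtracts this from dH."""
    return float(lambda_chem * (field[v[1], v[0]] - field[u[1], u[0]]))
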