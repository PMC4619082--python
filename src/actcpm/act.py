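"""The activity (protrusion-feedback) extension of the Potts engine.

Every lattice site carries a non-negative integer activity.  A site
freshly incorporated by a cell receives the cell type's maximum value
``max_act``; the value then decays by one per MCS, so a site remembers
for ``max_act`` steps that it was recently active.  Copy attempts from
high- to low-activity neighborhoods are favored by subtracting

    dH_act(u -> v) = lambda_act / max_act * (GM_act(u) - GM_act(v))

from the energy change, where GM_act(u) is the geometric mean of
activity over u and its same-cell Moore neighbors.  The geometric mean
(rather than the arithmetic one) makes a single inactive site nullify
the neighborhood, so only compact active patches push effectively —
the positive feedback that lets random membrane ruffles grow into
protrusions.  ``max_act`` switches the emergent phenotype (small values:
erratic amoeboid cells; large values: persistent, half-moon
keratocyte-like cells) while ``lambda_act`` scales the maximal
protrusive force.

The compiled Monte Carlo sweep applies these rules internally; the
wrappers here expose them one site at a time.
"""

from __future__ import annotations

import numpy as np

from . import _kernels as K
from .lattice import LatticeState, Site


def gm_act(state: LatticeState, u: Site) -> float:
    """Geometric mean activity over {u} and u's same-cell Moore neighbors.

    Zero for medium sites and whenever any neighborhood member is
    inactive.
    """
    return float(K.gm_act(state.spin, state.activity, u[1], u[0]))


def delta_h_act(state: LatticeState, u: Site, v: Site,
                lambda_act: float, max_act: int) -> float:
    """lambda_act / max_act * (GM_act(u) - GM_act(v)); 0 for a basic type.

    The caller subtracts the returned value from dH, so a positive value
    makes acceptance more likely.
    """
    if lambda_act == 0.0 or max_act == 0:
        return 0.0
    return (lambda_act / max_act
            * (gm_act(state, u) - gm_act(state, v)))


def on_copy_success(state: LatticeState, u: Site, v: Site,
                    max_act_source: int) -> None:
    """Set v's activity after u's identity won the site.

    A cell source stamps its type's maximum activity; a medium source
    (retraction) leaves the site inactive.
    """
    if state.spin[u[1], u[0]] > 0:
        state.activity[v[1], v[0]] = max_act_source
    else:
        state.activity[v[1], v[0]] = 0


def decay_activity(state: LatticeState) -> None:
    """One per-MCS decay tick: every positive activity value drops by 1."""
    K.decay_activity(state.activity)
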