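"""Headline measurement protocols: repeated single-cell runs and the
protrusion-direction experiment in a gradient.

These wrap :mod:`actcpm.scenarios` into the standard study designs —
several independent runs per condition, sampling every 20 MCS after a
relaxation burn-in — and return per-run measurements so callers can
report means and spreads.
"""

from __future__ import annotations

import numpy as np

from .protrusion_segmentation import segment_protrusions
from .scenarios import build_scenario, run_scenario
from .track_metrics import (Track, fit_furth, orientation_direction_angles,
                            turning_angles)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


def single_cell_tracks(max_act: int, lambda_act: float, n_runs: int,
                       run_mcs: int, seed: int,
                       burn_in: int = 500) -> list[Track]:
    """Independent single-cell runs on the 200x200 lattice, one track each."""
    tracks = []
    for s in _child_seeds(seed, n_runs):
        cfg = build_scenario("single_cell", max_act=max_act,
                             lambda_act=lambda_act)
        res = run_scenario(cfg, seed=s, run_mcs=run_mcs, burn_in=burn_in)
        tracks.append(res.tracks[1])
    return tracks


def pooled_orientation_angle(tracks: list[Track]) -> float:
    """Mean orientation-direction angle (deg) over all samples of all runs."""
    return float(np.nanmean(np.concatenate(
        [orientation_direction_angles(t) for t in tracks])))


def pooled_turning_angle(tracks: list[Track]) -> float:
    return float(np.nanmean(np.concatenate(
        [turning_angles(t) for t in tracks])))


def mean_motility(tracks: list[Track]) -> float:
    return float(np.mean([fit_furth(t).motility for t in tracks]))


def protrusion_counts_in_gradient(
        lambda_chem_values=(0.0, 50.0, 100.0, 150.0, 200.0),
        runs_per_value: int = 5, max_act: int = 20,
        lambda_act: float = 200.0, run_mcs: int = 500, burn_in: int = 500,
        seed: int = 0) -> list[int]:
    """Simultaneous-protrusion counts of amoeboid cells in a linear gradient.

    For each chemotaxis strength, independent runs each yield one final
    snapshot; protrusions are 8-connected patches of >= 10 active sites.
    Returns the per-snapshot counts pooled over all strengths.
    """
    seeds = iter(_child_seeds(seed, len(lambda_chem_values) * runs_per_value))
    counts = []
    for lam in lambda_chem_values:
        for _ in range(runs_per_value):
            cfg = build_scenario("chemotaxis", max_act=max_act,
                                 lambda_act=lambda_act,
                                 lambda_chemotaxis=float(lam))
            res = run_scenario(cfg, seed=next(seeds), run_mcs=run_mcs,
                               burn_in=burn_in)
            counts.append(len(segment_protrusions(res.sim.state, 1)))
    return counts
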