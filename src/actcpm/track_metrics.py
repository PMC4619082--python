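"""Measurements on simulated cells and their centroid tracks.

Geometry (centroid, principal axes, length) comes from the moments of
inertia of a cell's sites, computed on a common periodic image so cells
straddling the wrapped boundary are handled correctly.  Track-level
statistics follow the conventions usual for cell-migration analysis:

* instantaneous speed — centroid displacement per MCS between samples;
* turning angle — angle between consecutive displacement directions
  (90 degrees on average for unbiased jiggling);
* orientation-direction angle — acute angle between the cell's major
  axis and its direction of motion (small for cells moving along their
  long axis, large for transversally gliding cells);
* persistence time and motility coefficient — from a least-squares fit
  of Fuerth's persistent-random-walk equation
  ``msd(t) = 2 n M (t - P (1 - exp(-t/P)))`` with n = 2 to the
  mean-squared-displacement curve;
* directed speed and chemotactic index for runs in a gradient;
* order index — magnitude of the mean unit direction vector over cells,
  0 for random and 1 for fully collective migration;
* scanned fraction and stop durations for migration through tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from ._kernels import RING_DY, RING_DX
from .lattice import LatticeState

# --------------------------------------------------------------- geometry


@dataclass
class CellGeometry:
    centroid: tuple[float, float]      # (x, y), wrapped into the lattice
    axis: tuple[float, float]          # unit major-axis vector (axial: +/- equivalent)
    length: float                      # extent along the major axis
    degenerate: bool                   # no unique major axis


def _unwrap_coords(c: np.ndarray, period: int) -> np.ndarray:
    """Map site coordinates on a circle to one contiguous periodic image."""
    theta = c * (2.0 * np.pi / period)
    mean = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean())
    center = mean * period / (2.0 * np.pi)
    return (c - center + period / 2.0) % period + center - period / 2.0


def centroid_and_axes(state: LatticeState, cell_id: int) -> CellGeometry:
    """Centroid, major axis and length of a cell from its second moments.

    The major axis is the principal eigenvector of the covariance of the
    site coordinates; the length is the extent of the site projections
    onto it (max - min + 1).  A cell whose two principal moments are
    equal (for example a perfect square) has no unique axis and is
    flagged degenerate; a single-site cell has length 1.
    """
    ys, xs = np.nonzero(state.spin == cell_id)
    if xs.size == 0:
        raise ValueError(f"cell {cell_id} has no sites")
    xs = _unwrap_coords(xs.astype(np.float64), state.width)
    ys = _unwrap_coords(ys.astype(np.float64), state.height)
    cx, cy = xs.mean(), ys.mean()
    dx, dy = xs - cx, ys - cy
    centroid = (float(cx % state.width), float(cy % state.height))
    if xs.size == 1:
        return CellGeometry(centroid, (1.0, 0.0), 1.0, True)
    sxx, syy, sxy = (dx * dx).mean(), (dy * dy).mean(), (dx * dy).mean()
    # eigen-decomposition of [[sxx, sxy], [sxy, syy]] in closed form
    tr, det = sxx + syy, sxx * syy - sxy * sxy
    disc = max(tr * tr / 4.0 - det, 0.0)
    gap = 2.0 * np.sqrt(disc)  # lambda_major - lambda_minor
    degenerate = gap <= 1e-9 * max(tr, 1.0)
    theta = 0.5 * np.arctan2(2.0 * sxy, sxx - syy)
    ax, ay = float(np.cos(theta)), float(np.sin(theta))
    proj = dx * ax + dy * ay
    length = float(proj.max() - proj.min() + 1.0)
    return CellGeometry(centroid, (ax, ay), length, degenerate)


# ------------------------------------------------------------------ tracks


@dataclass
class Track:
    """Sampled trajectory of one cell: unwrapped centroid, axis, length.

    ``x``/``y`` are continuous (minimal-image unwrapped) coordinates, so
    displacements are meaningful across the periodic boundary as long as
    a cell moves less than half the lattice per sampling interval.
    """

    mcs: np.ndarray         # (n,) sample times, constant spacing dt
    x: np.ndarray           # (n,) unwrapped centroid x
    y: np.ndarray           # (n,)
    axis: np.ndarray        # (n, 2) unit major-axis vectors
    length: np.ndarray      # (n,)
    degenerate: np.ndarray  # (n,) bool

    def __post_init__(self):
        d = np.diff(self.mcs)
        if len(d) and (d <= 0).any():
            raise ValueError("sample times must be strictly increasing")
        if len(d) and not np.all(d == d[0]):
            raise ValueError("sampling interval must be constant")

    @property
    def dt(self) -> float:
        return float(self.mcs[1] - self.mcs[0]) if len(self.mcs) > 1 else np.nan

    @property
    def n(self) -> int:
        return len(self.mcs)

    def displacements(self) -> np.ndarray:
        """(n-1, 2) per-step displacement vectors."""
        return np.column_stack([np.diff(self.x), np.diff(self.y)])


def minimal_image(delta: float, period: int) -> float:
    """Smallest-magnitude representative of a displacement on a circle."""
    return (delta + period / 2.0) % period - period / 2.0


class TrackRecorder:
    """Accumulates unwrapped tracks from periodic lattice snapshots."""

    def __init__(self, width: int, height: int):
        self.width = width
        self.height = height
        self._data: dict[int, list] = {}
        self._last: dict[int, tuple[float, float]] = {}

    def record(self, state: LatticeState, mcs: int, cell_ids) -> None:
        for cid in cell_ids:
            g = centroid_and_axes(state, cid)
            cx, cy = g.centroid
            if cid in self._last:
                # continue the unwrapped trajectory by the minimal-image step
                px, py = self._last[cid]
                cx = px + minimal_image(cx - (px % self.width), self.width)
                cy = py + minimal_image(cy - (py % self.height), self.height)
            self._last[cid] = (cx, cy)
            self._data.setdefault(cid, []).append(
                (mcs, cx, cy, g.axis[0], g.axis[1], g.length, g.degenerate))

    def tracks(self) -> dict[int, Track]:
        out = {}
        for cid, rows in self._data.items():
            a = np.array([r[:6] for r in rows], dtype=np.float64)
            out[cid] = Track(mcs=a[:, 0], x=a[:, 1], y=a[:, 2],
                             axis=a[:, 3:5], length=a[:, 5],
                             degenerate=np.array([r[6] for r in rows]))
        return out


# ------------------------------------------------------------- point stats


def instantaneous_speed(track: Track, i: int) -> float:
    """Centroid speed over the step ending at sample i, in sites per MCS."""
    if i < 1:
        raise IndexError("speed needs a preceding sample")
    d = np.hypot(track.x[i] - track.x[i - 1], track.y[i] - track.y[i - 1])
    return float(d / track.dt)


def speeds(track: Track) -> np.ndarray:
    d = track.displacements()
    return np.hypot(d[:, 0], d[:, 1]) / track.dt


def turning_angle(track: Track, i: int) -> float:
    """Angle (deg) between displacement steps i-1 and i; NaN if either is zero."""
    if i < 2:
        raise IndexError("turning angle needs two preceding samples")
    d = track.displacements()
    return _vector_angle(d[i - 2], d[i - 1])


def turning_angles(track: Track) -> np.ndarray:
    d = track.displacements()
    return np.array([_vector_angle(d[i], d[i + 1]) for i in range(len(d) - 1)])


def _vector_angle(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.hypot(*a), np.hypot(*b)
    if na == 0.0 or nb == 0.0:
        return np.nan
    c = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def orientation_direction_angle(track: Track, i: int) -> float:
    """Acute angle (deg, 0..90) between the major axis and the motion direction.

    The displacement over (i-1, i] is paired with the axis measured at
    the start of the step.  Axial symmetry: an axis flipped by 180
    degrees gives the same angle.  NaN when the step is zero or the axis
    is degenerate.
    """
    if i < 1:
        raise IndexError("needs a preceding sample")
    if track.degenerate[i - 1]:
        return np.nan
    d = (track.x[i] - track.x[i - 1], track.y[i] - track.y[i - 1])
    nd = np.hypot(*d)
    if nd == 0.0:
        return np.nan
    c = abs(d[0] * track.axis[i - 1, 0] + d[1] * track.axis[i - 1, 1]) / nd
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def orientation_direction_angles(track: Track) -> np.ndarray:
    return np.array([orientation_direction_angle(track, i)
                     for i in range(1, track.n)])


# ----------------------------------------------------------- MSD and Fuerth


def mean_squared_displacement(track: Track, max_lag: int | None = None):
    """MSD over time lags using all overlapping start points.

    Returns (lag_times, msd) with lag_times in MCS.
    """
    n = track.n
    if max_lag is None:
        max_lag = n - 1
    lags = np.arange(1, min(max_lag, n - 1) + 1)
    msd = np.empty(len(lags))
    for j, k in enumerate(lags):
        dx = track.x[k:] - track.x[:-k]
        dy = track.y[k:] - track.y[:-k]
        msd[j] = np.mean(dx * dx + dy * dy)
    return lags * track.dt, msd


def furth_msd(t: np.ndarray, M: float, P: float, n_dim: int = 2) -> np.ndarray:
    """Fuerth's persistent-random-walk MSD: 2 n M (t - P (1 - exp(-t/P)))."""
    P = max(P, 1e-12)
    return 2.0 * n_dim * M * (t - P * (1.0 - np.exp(-t / P)))


@dataclass
class FurthFit:
    motility: float          # M, sites^2 / MCS
    persistence: float       # P, MCS
    converged: bool
    residual: float = np.nan


def fit_furth(track: Track, max_lag_fraction: float = 0.1) -> FurthFit:
    """Fit (M, P) of Fuerth's equation to the track's MSD curve.

    Lags up to ``max_lag_fraction`` of the track length are used (longer
    lags have too few independent windows), with relative weighting so
    the short-lag curvature that carries the persistence signal is not
    swamped by the large long-lag values.  Both parameters are
    constrained positive.
    """
    n_lag = max(int(track.n * max_lag_fraction), 10)
    t, msd = mean_squared_displacement(track, max_lag=n_lag)
    if len(t) < 10:
        raise ValueError("track too short for a motility fit")
    # initial guess from the asymptote msd ~ 4M t - 4M P
    slope, intercept = np.polyfit(t[len(t) // 2:], msd[len(t) // 2:], 1)
    m0 = max(slope / 4.0, 1e-6)
    p0 = min(max(-intercept / max(slope, 1e-12), track.dt / 10.0), t[-1])
    try:
        popt, _ = curve_fit(furth_msd, t, msd, p0=(m0, p0),
                            sigma=np.maximum(msd, 1e-12),
                            bounds=([0.0, 0.0], [np.inf, np.inf]),
                            maxfev=20000)
        resid = float(np.sqrt(np.mean((furth_msd(t, *popt) - msd) ** 2)))
        return FurthFit(float(popt[0]), float(popt[1]), True, resid)
    except RuntimeError:
        return FurthFit(np.nan, np.nan, False)


def persistence_from_autocorrelation(track: Track) -> float:
    """Persistence time from an exponential fit to the direction autocorrelation.

    Secondary estimator: fits <cos(theta(lag))> ~ exp(-lag/P) over the
    first decade of lags; cross-checks the Fuerth-fit persistence.
    """
    d = track.displacements()
    norm = np.hypot(d[:, 0], d[:, 1])
    ok = norm > 0
    u = d[ok] / norm[ok, None]
    n = len(u)
    if n < 10:
        return np.nan
    max_lag = max(n // 4, 2)
    lags = np.arange(1, max_lag + 1)
    ac = np.array([np.mean(np.sum(u[k:] * u[:-k], axis=1)) for k in lags])
    pos = ac > 0.05
    if pos.sum() < 2:
        return float(track.dt)  # decorrelated within one sampling interval
    t = lags[pos] * track.dt
    return float(-1.0 / np.polyfit(t, np.log(ac[pos]), 1)[0])


# ------------------------------------------------------------- chemotaxis


@dataclass
class ChemoStats:
    directed_speed: float      # mean velocity component up the gradient
    chemotactic_index: float   # net up-gradient displacement / path length


def chemo_stats(track: Track, gradient_axis: str = "y") -> ChemoStats:
    d = track.displacements()
    if len(d) == 0:
        raise ValueError("need at least two samples")
    up = d[:, 1] if gradient_axis == "y" else d[:, 0]
    path = np.hypot(d[:, 0], d[:, 1]).sum()
    directed = float(up.mean() / track.dt)
    index = float(up.sum() / path) if path > 0 else np.nan
    return ChemoStats(directed, index)


# ------------------------------------------------------------- order index


def order_index(directions: np.ndarray) -> float:
    """Magnitude of the mean unit direction vector over cells (0..1).

    ``directions`` is (n, 2); zero vectors are excluded.  NaN if every
    cell stood still.
    """
    directions = np.asarray(directions, dtype=np.float64)
    norm = np.hypot(directions[:, 0], directions[:, 1])
    ok = norm > 0
    if not ok.any():
        return np.nan
    u = directions[ok] / norm[ok, None]
    mean = u.mean(axis=0)
    return float(np.hypot(mean[0], mean[1]))


def order_index_series(tracks: dict[int, Track]) -> np.ndarray:
    """Order index at each sampling step across all cells."""
    ids = list(tracks)
    n_steps = min(tracks[c].n for c in ids) - 1
    out = np.empty(n_steps)
    for i in range(n_steps):
        d = np.array([[tracks[c].x[i + 1] - tracks[c].x[i],
                       tracks[c].y[i + 1] - tracks[c].y[i]] for c in ids])
        out[i] = order_index(d)
    return out


# ---------------------------------------------------- tissue scanning, stops


def contacted_ids(spin: np.ndarray, cell_id: int) -> set[int]:
    """Identities Moore-adjacent to the given cell (medium excluded)."""
    mask = spin == cell_id
    out: set[int] = set()
    for dy, dx in zip(RING_DY, RING_DX):
        out |= set(np.unique(np.roll(spin, (-int(dy), -int(dx)),
                                     axis=(0, 1))[mask]).tolist())
    out.discard(cell_id)
    out.discard(0)
    return out


class ScanTracker:
    """Cumulative record of which tissue cells an active cell has touched."""

    def __init__(self, act_cell_id: int, tissue_cell_ids):
        self.act_cell_id = act_cell_id
        self.tissue = set(tissue_cell_ids)
        self.seen: set[int] = set()

    def update(self, spin: np.ndarray) -> None:
        self.seen |= contacted_ids(spin, self.act_cell_id) & self.tissue

    @property
    def scanned_fraction(self) -> float:
        if not self.tissue:
            return np.nan
        return len(self.seen) / len(self.tissue)


def scan_stats(state_history, act_cell_id: int, tissue_cell_ids) -> float:
    """Fraction of tissue cells contacted at least once during the run."""
    tracker = ScanTracker(act_cell_id, tissue_cell_ids)
    for state in state_history:
        spin = state.spin if isinstance(state, LatticeState) else state
        tracker.update(spin)
    return tracker.scanned_fraction


def stop_durations(speed_trace: np.ndarray, threshold: float,
                   dt: float) -> list[float]:
    """Lengths (in MCS) of maximal runs of samples slower than the threshold."""
    below = np.asarray(speed_trace) < threshold
    out = []
    run = 0
    for b in below:
        if b:
            run += 1
        elif run:
            out.append(run * dt)
            run = 0
    if run:
        out.append(run * dt)
    return out


def default_stop_threshold(speed_trace: np.ndarray,
                           fraction: float = 0.25) -> float:
    """Stationarity threshold as a fraction of the median speed."""
    return float(fraction * np.median(speed_trace))


# ---------------------------------------------------------------- summaries


@dataclass
class MigrationSummary:
    mean_speed: float
    mean_turning_angle: float
    mean_orientation_angle: float
    persistence_time: float
    motility_coefficient: float
    directed_speed: float = np.nan
    chemotactic_index: float = np.nan


def summarize(track: Track, gradient_axis: str | None = None) -> MigrationSummary:
    """All single-cell migration statistics of one track."""
    fit = fit_furth(track) if track.n >= 40 else FurthFit(np.nan, np.nan, False)
    ds, ci = np.nan, np.nan
    if gradient_axis is not None:
        cs = chemo_stats(track, gradient_axis)
        ds, ci = cs.directed_speed, cs.chemotactic_index
    return MigrationSummary(
        mean_speed=float(np.mean(speeds(track))),
        mean_turning_angle=float(np.nanmean(turning_angles(track))),
        mean_orientation_angle=float(np.nanmean(orientation_direction_angles(track))),
        persistence_time=fit.persistence,
        motility_coefficient=fit.motility,
        directed_speed=ds,
        chemotactic_index=ci,
    )
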