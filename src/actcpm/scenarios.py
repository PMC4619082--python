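"""Reproducible experiment setups: single cells, chemotaxis, collective
migration, skin patrol, and tissue density/rigidity sweeps.

Every scenario fixes the lattice, the cell-type parameter table and the
seeding layout; :func:`run_scenario` then produces sampled centroid
tracks.  Shared constants: temperature T = 20, area constraint
lambda_Area = 50, medium self-energy J = 0, perimeter constraint
lambda_Perimeter = 2 (varied only for tissue rigidity).  Motile cells in
the single-cell and collective setups have target area 500 (collective:
200), target perimeter 340 (collective: 180), J_cell,cell = 100
(collective: varied to set the surface tension) and J_cell,medium = 20.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .chemotaxis import linear_gradient
from .lattice import CPM, CellType
from .track_metrics import Track, TrackRecorder

TEMPERATURE = 20.0
LAMBDA_AREA = 50.0
LAMBDA_PERIMETER = 2.0

#: parameter grid spanning the amoeboid-to-keratocyte morphospace
MORPHOSPACE_MAX_ACT = (0, 10, 20, 30, 40, 50, 60, 70, 80, 100)
MORPHOSPACE_LAMBDA_ACT = (0, 10, 50, 100, 200, 300, 500, 1000, 2000)


@dataclass
class Population:
    """One group of identically parameterized cells to seed.

    Either ``count`` or ``coverage`` (fraction of the lattice the
    population's target areas should add up to) must be given.
    ``placement`` is ``"random"`` or ``"center"`` (a single cell at the
    lattice center).
    """

    type_name: str
    count: int | None = None
    coverage: float | None = None
    placement: str = "random"


@dataclass
class ScenarioConfig:
    name: str
    width: int
    height: int
    types: list[CellType]
    J: np.ndarray
    populations: list[Population]
    temperature: float = TEMPERATURE
    gradient_slope: float = 0.0
    gradient_axis: str = "y"
    run_mcs: int = 10_000
    burn_in: int = 500
    sample_every: int = 20

    def type_named(self, name: str) -> CellType:
        for t in self.types:
            if t.name == name:
                return t
        raise KeyError(name)


# ------------------------------------------------------------------ builders


def _motile_type(name: str = "cell", max_act: int = 20,
                 lambda_act: float = 200.0, lambda_chemotaxis: float = 0.0,
                 target_area: float = 500.0, target_perimeter: float = 340.0,
                 connectivity: bool = False) -> CellType:
    return CellType(name=name, lambda_area=LAMBDA_AREA,
                    target_area=target_area,
                    lambda_perimeter=LAMBDA_PERIMETER,
                    target_perimeter=target_perimeter,
                    max_act=max_act, lambda_act=lambda_act,
                    lambda_chemotaxis=lambda_chemotaxis,
                    connectivity_enforced=connectivity)


def build_scenario(name: str, **kw) -> ScenarioConfig:
    """Return the named scenario's configuration.

    Known names: ``single_cell``, ``morphospace``, ``chemotaxis``,
    ``collective``, ``skin``, ``tissue_density``, ``tissue_rigidity``.
    Keyword arguments override scenario-specific knobs (for example
    ``max_act``, ``lambda_act``, ``lambda_chemotaxis``, ``coverage``,
    ``j_cell_cell``, ``lambda_perimeter_tissue``).
    """
    builders = {
        "single_cell": _single_cell,
        "morphospace": _single_cell,   # same setup, swept over the grid
        "chemotaxis": _chemotaxis,
        "collective": _collective,
        "skin": _skin,
        "tissue_density": _tissue,
        "tissue_rigidity": _tissue_rigidity,
    }
    if name not in builders:
        raise KeyError(f"unknown scenario {name!r}")
    cfg = builders[name](**kw)
    return replace(cfg, name=name)


def _single_cell(max_act: int = 20, lambda_act: float = 200.0,
                 run_mcs: int = 10_000, burn_in: int = 500) -> ScenarioConfig:
    ct = _motile_type(max_act=max_act, lambda_act=lambda_act)
    J = np.array([[0.0, 20.0], [20.0, 100.0]])
    return ScenarioConfig("single_cell", 200, 200, [ct], J,
                          [Population("cell", count=1, placement="center")],
                          run_mcs=run_mcs, burn_in=burn_in)


def _chemotaxis(max_act: int = 20, lambda_act: float = 200.0,
                lambda_chemotaxis: float = 150.0, slope: float = 0.33,
                run_mcs: int = 5_000, burn_in: int = 500) -> ScenarioConfig:
    ct = _motile_type(max_act=max_act, lambda_act=lambda_act,
                      lambda_chemotaxis=lambda_chemotaxis)
    J = np.array([[0.0, 20.0], [20.0, 100.0]])
    return ScenarioConfig("chemotaxis", 100, 300, [ct], J,
                          [Population("cell", count=1, placement="center")],
                          gradient_slope=slope, gradient_axis="y",
                          run_mcs=run_mcs, burn_in=burn_in)


#: J_cell,cell values realizing surface tensions gamma = 0, 50, 100
#: (gamma = J_cell,medium - (J_cell,cell + J_medium,medium) / 2)
COLLECTIVE_ADHESION = {"neutral": 40.0, "medium": -60.0, "high": -160.0}


def _collective(max_act: int = 80, lambda_act: float = 200.0,
                coverage: float = 0.5, j_cell_cell: float = 40.0,
                run_mcs: int = 20_000, burn_in: int = 1_000) -> ScenarioConfig:
    ct = _motile_type(max_act=max_act, lambda_act=lambda_act,
                      target_area=200.0, target_perimeter=180.0,
                      connectivity=True)
    J = np.array([[0.0, 20.0], [20.0, j_cell_cell]])
    return ScenarioConfig("collective", 500, 500, [ct], J,
                          [Population("cell", coverage=coverage)],
                          run_mcs=run_mcs, burn_in=burn_in)


def _skin(n_tcells: int = 10, lambda_act: float = 2000.0,
          run_mcs: int = 20_000, burn_in: int = 500) -> ScenarioConfig:
    tcell = _motile_type("tcell", max_act=20, lambda_act=lambda_act,
                         target_area=100.0, target_perimeter=140.0,
                         connectivity=True)
    skin = CellType("skin", lambda_area=LAMBDA_AREA, target_area=152.0,
                    lambda_perimeter=LAMBDA_PERIMETER, target_perimeter=145.0)
    #           medium  tcell   skin
    J = np.array([[0.0, 20.0, 20.0],
                  [20.0, 100.0, 20.0],
                  [20.0, 20.0, 20.0]])
    return ScenarioConfig("skin", 200, 200, [tcell, skin], J,
                          [Population("tcell", count=n_tcells),
                           Population("skin", coverage=1.0)],
                          run_mcs=run_mcs, burn_in=burn_in)


def _tissue(max_act: int = 20, lambda_act: float = 2000.0,
            coverage: float = 1.0, lambda_perimeter_tissue: float = 2.0,
            run_mcs: int = 20_000, burn_in: int = 500) -> ScenarioConfig:
    act = _motile_type("act", max_act=max_act, lambda_act=lambda_act,
                       target_area=100.0, target_perimeter=140.0,
                       connectivity=True)
    tissue = CellType("tissue", lambda_area=LAMBDA_AREA, target_area=152.0,
                      lambda_perimeter=lambda_perimeter_tissue,
                      target_perimeter=145.0)
    #           medium   act   tissue
    J = np.array([[0.0, 20.0, 20.0],
                  [20.0, 100.0, 20.0],
                  [20.0, 20.0, 20.0]])
    return ScenarioConfig("tissue_density", 200, 200, [act, tissue], J,
                          [Population("act", count=1, placement="center"),
                           Population("tissue", coverage=coverage)],
                          run_mcs=run_mcs, burn_in=burn_in)


def _tissue_rigidity(lambda_perimeter_tissue: float = 10.0, **kw):
    return _tissue(coverage=1.0,
                   lambda_perimeter_tissue=lambda_perimeter_tissue, **kw)


# ------------------------------------------------------------------ seeding


def seed_cells(config: ScenarioConfig, rng: np.random.Generator) -> CPM:
    """Build an engine with the scenario's cells placed on the lattice.

    Low total coverage seeds compact squares on a jittered grid; (near)
    full coverage tessellates the lattice into nearest-seed domains so
    the packing is gapless.  Activity starts at zero everywhere; the
    relaxation burn-in lets shapes and areas settle before measurement.
    """
    W, H = config.width, config.height
    chem = None
    if config.gradient_slope:
        chem = linear_gradient(W, H, config.gradient_slope,
                               config.gradient_axis)
    sim = CPM(W, H, config.types, config.J,
              temperature=config.temperature, chemokine=chem, seed=rng)
    counts = []
    for pop in config.populations:
        if pop.count is not None:
            n = pop.count
        elif pop.coverage is not None:
            area = config.type_named(pop.type_name).target_area
            used = sum(config.type_named(p.type_name).target_area * c
                       for p, c in zip(config.populations, counts))
            n = max(int(round((pop.coverage * W * H - used) / area)), 0)
        else:
            raise ValueError("population needs count or coverage")
        counts.append(n)
    total_cov = sum(config.type_named(p.type_name).target_area * c
                    for p, c in zip(config.populations, counts)) / (W * H)
    if total_cov > 1.02:
        raise ValueError(
            f"requested cells cover {total_cov:.2f} of the lattice")
    if total_cov >= 0.95:
        spin, type_ids = _seed_voronoi(config, counts, rng)
    else:
        spin, type_ids = _seed_squares(config, counts, rng)
    sim.load_cells(spin, type_ids)
    return sim


def _seed_points(config, counts, rng):
    pts, type_ids = [], []
    for pop, n in zip(config.populations, counts):
        tid = [t.name for t in config.types].index(pop.type_name) + 1
        for i in range(n):
            if pop.placement == "center" and i == 0:
                pts.append((config.width / 2.0, config.height / 2.0))
            else:
                pts.append((rng.uniform(0, config.width),
                            rng.uniform(0, config.height)))
            type_ids.append(tid)
    return np.array(pts), np.array(type_ids, dtype=np.int64)


def _seed_voronoi(config, counts, rng):
    """Nearest-seed tessellation on the torus: gapless full coverage."""
    pts, type_ids = _seed_points(config, counts, rng)
    W, H = config.width, config.height
    tiles = []
    for dy in (-H, 0, H):
        for dx in (-W, 0, W):
            tiles.append(pts + [dx, dy])
    tree = cKDTree(np.vstack(tiles))
    xs, ys = np.meshgrid(np.arange(W) + 0.5, np.arange(H) + 0.5)
    _, idx = tree.query(np.column_stack([xs.ravel(), ys.ravel()]))
    spin = (idx % len(pts) + 1).astype(np.int32).reshape(H, W)
    return spin, type_ids


def _seed_squares(config, counts, rng):
    """Compact squares of roughly the target area on a jittered grid."""
    W, H = config.width, config.height
    n_total = sum(counts)
    if n_total == 0:
        return np.zeros((H, W), dtype=np.int32), np.array([], dtype=np.int64)
    sides = {p.type_name: max(int(round(np.sqrt(
        config.type_named(p.type_name).target_area))), 1)
        for p in config.populations}
    max_side = max(sides.values())
    k = int(np.ceil(np.sqrt(n_total)))
    pitch_x, pitch_y = W // k, H // k
    if min(pitch_x, pitch_y) < max_side:
        raise ValueError(
            f"cannot place {n_total} cells of side {max_side} on "
            f"{W}x{H} without overlap")
    slots = [(i, j) for i in range(k) for j in range(k)]
    rng.shuffle(slots)
    # a "center" population claims the slot nearest the lattice middle
    order = []
    for pop, n in zip(config.populations, counts):
        for i in range(n):
            order.append((pop, i))
    center_slot = min(slots, key=lambda s: (s[0] * pitch_x + pitch_x / 2 - W / 2) ** 2
                      + (s[1] * pitch_y + pitch_y / 2 - H / 2) ** 2)
    spin = np.zeros((H, W), dtype=np.int32)
    type_ids = []
    slot_iter = iter([s for s in slots if s != center_slot])
    for sigma, (pop, i) in enumerate(order, start=1):
        side = sides[pop.type_name]
        if pop.placement == "center" and i == 0:
            sx, sy = center_slot
        else:
            sx, sy = next(slot_iter)
        jx = rng.integers(0, pitch_x - side + 1)
        jy = rng.integers(0, pitch_y - side + 1)
        x0, y0 = sx * pitch_x + jx, sy * pitch_y + jy
        spin[y0:y0 + side, x0:x0 + side] = sigma
        tid = [t.name for t in config.types].index(pop.type_name) + 1
        type_ids.append(tid)
    return spin, np.array(type_ids, dtype=np.int64)


# ------------------------------------------------------------------ running


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    sim: CPM
    tracks: dict[int, Track]


def run_scenario(config: ScenarioConfig, seed: int,
                 run_mcs: int | None = None, burn_in: int | None = None,
                 sample_every: int | None = None,
                 observers: list | None = None) -> ScenarioResult:
    """Seed, relax, and run a scenario, sampling tracks at fixed intervals.

    ``observers`` are callables ``f(sim, mcs)`` invoked at every sample
    (after burn-in), e.g. for snapshotting or contact tracking.  Identical
    seeds give identical trajectories.
    """
    run_mcs = config.run_mcs if run_mcs is None else run_mcs
    burn_in = config.burn_in if burn_in is None else burn_in
    dt = config.sample_every if sample_every is None else sample_every
    rng = np.random.default_rng(seed)
    sim = seed_cells(config, rng)
    sim.run(burn_in)
    recorder = TrackRecorder(config.width, config.height)
    cells = sim.cell_ids
    recorder.record(sim.state, sim.mcs, cells)
    if observers:
        for obs in observers:
            obs(sim, sim.mcs)
    n_samples = run_mcs // dt
    for _ in range(n_samples):
        sim.run(dt)
        recorder.record(sim.state, sim.mcs, cells)
        if observers:
            for obs in observers:
                obs(sim, sim.mcs)
    return ScenarioResult(config, sim, recorder.tracks())


def tracks_to_frame(result: ScenarioResult):
    """Long-format DataFrame of all tracks (one row per cell per sample)."""
    import pandas as pd

    rows = []
    for cid, tr in result.tracks.items():
        ang = np.degrees(np.arctan2(tr.axis[:, 1], tr.axis[:, 0])) % 180.0
        for i in range(tr.n):
            rows.append((int(tr.mcs[i]), cid, tr.x[i], tr.y[i],
                         ang[i], tr.length[i]))
    return pd.DataFrame(rows, columns=["mcs", "cell_id", "x_unwrapped",
                                       "y_unwrapped", "major_axis_angle",
                                       "length"])
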