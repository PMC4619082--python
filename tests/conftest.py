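import numpy as np
import pytest

from actcpm.lattice import CPM, CellType

MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def make_sim(width=12, height=12, types=None, J=None, temperature=20.0,
             chemokine=None, seed=0):
    if types is None:
        types = [CellType("cell", lambda_area=0.0, lambda_perimeter=0.0)]
    if J is None:
        n = len(types) + 1
        J = np.zeros((n, n))
    return CPM(width, height, types, J, temperature=temperature,
               chemokine=chemokine, seed=seed)


def square_sites(x0, y0, side):
    return [(x0 + i, y0 + j) for j in range(side) for i in range(side)]


def brute_hamiltonian(sim):
    """Whole-lattice energy by explicit site loops (independent oracle)."""
    spin = sim.state.spin
    H, W = spin.shape
    ctype = sim._ctype
    e = 0.0
    for y in range(H):
        for x in range(W):
            s1 = spin[y, x]
            for dy, dx in MOORE:
                s2 = spin[(y + dy) % H, (x + dx) % W]
                if s1 != s2:
                    e += sim.J[ctype[s1], ctype[s2]]
    e /= 2.0  # each unordered pair was visited twice
    for sigma in range(1, len(ctype)):
        t = sim.types[ctype[sigma] - 1]
        a = 0
        p = 0
        for y in range(H):
            for x in range(W):
                if spin[y, x] != sigma:
                    continue
                a += 1
                for dy, dx in MOORE:
                    if spin[(y + dy) % H, (x + dx) % W] != sigma:
                        p += 1
        e += t.lambda_area * (a - t.target_area) ** 2
        e += t.lambda_perimeter * (p - t.target_perimeter) ** 2
    return e


def random_cell_sim(rng, width=10, height=10, n_cells=3,
                    lambda_area=0.0, lambda_perimeter=0.0, adhesion=True):
    """Engine loaded with a random identity plane (scattered cells allowed)."""
    types = [
        CellType("a", lambda_area=lambda_area, target_area=20,
                 lambda_perimeter=lambda_perimeter, target_perimeter=40),
        CellType("b", lambda_area=lambda_area, target_area=35,
                 lambda_perimeter=lambda_perimeter, target_perimeter=60),
    ]
    if adhesion:
        J = np.array([[0.0, 20.0, 16.0],
                      [20.0, 14.0, 11.0],
                      [16.0, 11.0, 8.0]])
    else:
        J = np.zeros((3, 3))
    sim = CPM(width, height, types, J, seed=rng)
    spin = rng.integers(0, n_cells + 1, size=(height, width)).astype(np.int32)
    type_ids = rng.integers(1, 3, size=n_cells)
    sim.load_cells(spin, type_ids)
    return sim


def random_nontrivial_pair(sim, rng):
    spin = sim.state.spin
    H, W = spin.shape
    while True:
        y = int(rng.integers(H))
        x = int(rng.integers(W))
        dy, dx = MOORE[int(rng.integers(8))]
        vy, vx = (y + dy) % H, (x + dx) % W
        if spin[y, x] != spin[vy, vx]:
            return (x, y), (vx, vy)


def synthetic_ou_track(n_steps, dt, persistence, speed_var, rng,
                       oversample=10):
    """Persistent random walk: Ornstein-Uhlenbeck velocity, known (M, P).

    Exact AR(1) discretization at dt/oversample; the theoretical motility
    coefficient is M = speed_var * persistence (per spatial dimension
    velocity variance = speed_var).
    """
    h = dt / oversample
    a = np.exp(-h / persistence)
    s = np.sqrt(speed_var * (1 - a * a))
    n = n_steps * oversample
    v = np.empty((n + 1, 2))
    v[0] = rng.normal(0, np.sqrt(speed_var), 2)
    noise = rng.normal(0, s, (n, 2))
    for i in range(n):
        v[i + 1] = a * v[i] + noise[i]
    pos = np.cumsum(v[:-1] * h, axis=0)
    pos = np.vstack([[0.0, 0.0], pos])[::oversample]
    t = np.arange(n_steps + 1) * dt
    return t, pos[:, 0], pos[:, 1]


def make_track(x, y, dt=20.0):
    from actcpm.track_metrics import Track

    n = len(x)
    return Track(mcs=np.arange(n) * dt, x=np.asarray(x, float),
                 y=np.asarray(y, float),
                 axis=np.tile([1.0, 0.0], (n, 1)),
                 length=np.ones(n), degenerate=np.zeros(n, bool))
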