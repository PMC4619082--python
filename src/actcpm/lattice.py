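"""Cellular Potts engine: lattice state, energy terms, Metropolis dynamics.

Cells are sets of lattice sites sharing an identity sigma > 0; identity 0
is the medium.  The global energy

    H = sum_(u,v) J_tau(u),tau(v) (1 - delta_sigma_u,sigma_v)
        + sum_cells lambda_Area (a - A)^2
        + sum_cells lambda_Perimeter (p - P)^2

sums adhesion energies over unordered Moore-neighbor pairs plus quadratic
penalties on deviations from the target area A and target perimeter P.
The lattice evolves by random identity-copy attempts accepted with the
Metropolis rule at temperature T; one Monte Carlo step (MCS) is as many
attempts as there are lattice sites.  The activity field and its energy
bias (the protrusion feedback) are documented in :mod:`actcpm.act`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K

Site = tuple[int, int]  # (x, y)


@dataclass
class CellType:
    """Parameter bundle shared by all cells of one type.

    ``max_act`` is both the activity ceiling and the activity memory in
    MCS; ``max_act = 0`` together with ``lambda_act = 0`` defines a basic
    (non-protrusive) CPM type.
    """

    name: str
    lambda_area: float = 50.0
    target_area: float = 0.0
    lambda_perimeter: float = 2.0
    target_perimeter: float = 0.0
    max_act: int = 0
    lambda_act: float = 0.0
    lambda_chemotaxis: float = 0.0
    connectivity_enforced: bool = False


@dataclass
class Cell:
    """Per-cell bookkeeping view: identity, type, running area and perimeter."""

    id: int
    type: CellType
    area: int
    perimeter: int


@dataclass
class LatticeState:
    """Spin (identity) and activity planes on a toroidal lattice."""

    spin: np.ndarray      # (H, W) int32, [y, x]
    activity: np.ndarray  # (H, W) int32
    boundary: str = "torus"

    @property
    def width(self) -> int:
        return self.spin.shape[1]

    @property
    def height(self) -> int:
        return self.spin.shape[0]


class CPM:
    """A Cellular Potts simulation on a wrapped rectangular lattice.

    Parameters
    ----------
    width, height:
        Lattice dimensions in sites.
    types:
        Cell types; type ids are assigned in order starting at 1
        (id 0 is the medium).
    J:
        Symmetric contact-energy table of shape ``(n_types+1, n_types+1)``
        including the medium row/column at index 0.
    temperature:
        Metropolis temperature T (default 20).
    chemokine:
        Optional ``(H, W)`` concentration array; see
        :mod:`actcpm.chemotaxis`.
    seed:
        Seed for the simulation's random stream.
    """

    def __init__(self, width: int, height: int, types: list[CellType],
                 J: np.ndarray, temperature: float = 20.0,
                 chemokine: np.ndarray | None = None,
                 seed: int | np.random.Generator = 0):
        self.types = list(types)
        nt = len(self.types) + 1
        J = np.asarray(J, dtype=np.float64)
        if J.shape != (nt, nt):
            raise ValueError(f"J must be ({nt}, {nt}) including the medium")
        if not np.allclose(J, J.T):
            raise ValueError("J must be symmetric")
        self.J = J
        self.temperature = float(temperature)
        self.state = LatticeState(
            spin=np.zeros((height, width), dtype=np.int32),
            activity=np.zeros((height, width), dtype=np.int32),
        )
        if chemokine is None:
            self.chemokine = np.zeros((height, width), dtype=np.float64)
        else:
            self.chemokine = np.asarray(chemokine, dtype=np.float64)
            if self.chemokine.shape != (height, width):
                raise ValueError("chemokine field must match the lattice shape")
        self.rng = (seed if isinstance(seed, np.random.Generator)
                    else np.random.default_rng(seed))
        # per-type parameter vectors, index 0 = medium
        self._lam_area = np.array([0.0] + [t.lambda_area for t in types])
        self._tgt_area = np.array([0.0] + [t.target_area for t in types])
        self._lam_perim = np.array([0.0] + [t.lambda_perimeter for t in types])
        self._tgt_perim = np.array([0.0] + [t.target_perimeter for t in types])
        self._max_act = np.array([0] + [t.max_act for t in types], dtype=np.int64)
        self._lam_act = np.array([0.0] + [t.lambda_act for t in types])
        self._lam_chem = np.array([0.0] + [t.lambda_chemotaxis for t in types])
        self._conn = np.array([False] + [t.connectivity_enforced for t in types])
        # per-cell vectors, index 0 = medium
        self._ctype = np.zeros(1, dtype=np.int64)
        self._areas = np.zeros(1, dtype=np.int64)
        self._perims = np.zeros(1, dtype=np.int64)
        self.mcs = 0

    # ------------------------------------------------------------------ cells

    def seed_cell(self, type_name: str, sites: list[Site]) -> int:
        """Create a new cell of the named type occupying ``sites``.

        Sites must currently be medium.  Returns the new cell identity.
        """
        tid = self._type_id(type_name)
        sigma = len(self._ctype)
        spin = self.state.spin
        for (x, y) in sites:
            if spin[y, x] != 0:
                raise ValueError(f"site ({x}, {y}) is already occupied")
        for (x, y) in sites:
            spin[y, x] = sigma
        self._ctype = np.append(self._ctype, tid)
        self._areas = np.append(self._areas, len(sites))
        self._perims = np.append(self._perims, 0)
        self._perims[sigma] = self._recount_perimeter(sigma)
        # neighbors' perimeters change too; recount them
        for s in self._touching(sigma):
            self._perims[s] = self._recount_perimeter(s)
        return sigma

    def load_cells(self, spin: np.ndarray, cell_type_ids) -> None:
        """Bulk-register cells from a pre-built identity plane.

        ``spin`` holds identities 1..n for the n cells (0 = medium);
        ``cell_type_ids`` gives each cell's type id (1-based, in identity
        order).  Running areas and perimeters are computed from scratch;
        activity is reset to zero.
        """
        spin = np.asarray(spin, dtype=np.int32)
        if spin.shape != self.state.spin.shape:
            raise ValueError("spin plane must match the lattice shape")
        n = len(cell_type_ids)
        if spin.max() > n:
            raise ValueError("spin contains identities without a type")
        self.state.spin[:] = spin
        self.state.activity[:] = 0
        self._ctype = np.concatenate([[0], cell_type_ids]).astype(np.int64)
        self._areas = np.bincount(spin.ravel(), minlength=n + 1).astype(np.int64)
        perims = np.zeros(n + 1, dtype=np.int64)
        for dy, dx in zip(K.RING_DY, K.RING_DX):
            rolled = np.roll(spin, (-dy, -dx), axis=(0, 1))
            diff = spin != rolled
            perims += np.bincount(spin[diff], minlength=n + 1)
        perims[0] = 0
        self._perims = perims

    def _type_id(self, name: str) -> int:
        for i, t in enumerate(self.types):
            if t.name == name:
                return i + 1
        raise KeyError(name)

    def cell(self, sigma: int) -> Cell:
        return Cell(sigma, self.types[self._ctype[sigma] - 1],
                    int(self._areas[sigma]), int(self._perims[sigma]))

    @property
    def cell_ids(self) -> list[int]:
        """Identities of live (area > 0) cells."""
        return [s for s in range(1, len(self._ctype)) if self._areas[s] > 0]

    def cell_type_of(self, sigma: int) -> CellType:
        return self.types[self._ctype[sigma] - 1]

    # -------------------------------------------------------------- dynamics

    def run(self, n_mcs: int) -> None:
        """Advance the simulation by ``n_mcs`` Monte Carlo steps."""
        if n_mcs <= 0:
            return
        kernel_seed = int(self.rng.integers(2**31 - 1))
        K.run_mcs_kernel(self.state.spin, self.state.activity,
                         self._ctype, self._areas, self._perims, self.J,
                         self._lam_area, self._tgt_area,
                         self._lam_perim, self._tgt_perim,
                         self._max_act, self._lam_act, self._lam_chem,
                         self._conn, self.chemokine,
                         self.temperature, n_mcs, kernel_seed)
        self.mcs += n_mcs

    def attempt_copy(self, u: Site, v: Site) -> bool:
        """Evaluate and (possibly) commit a single copy attempt u -> v.

        Exposed for testing and instrumentation; :meth:`run` performs the
        same computation in compiled code.
        """
        ux, uy = u
        vx, vy = v
        spin = self.state.spin
        s_u, s_v = spin[uy, ux], spin[vy, vx]
        if s_u == s_v:
            raise ValueError("trivial attempt: same identity on both sides")
        if s_v > 0 and self._conn[self._ctype[s_v]]:
            if not K.connectivity_allows(spin, self._areas, vy, vx):
                return False
        dh = self.delta_h_total(u, v)
        if metropolis_accept(dh, self.temperature, self.rng):
            K.apply_copy(spin, self.state.activity, self._ctype,
                         self._areas, self._perims, self._max_act,
                         uy, ux, vy, vx)
            return True
        return False

    # --------------------------------------------------------- energy terms

    def delta_h_adhesion(self, u: Site, v: Site) -> float:
        return float(K.adhesion_delta(self.state.spin, self._ctype, self.J,
                                      u[1], u[0], v[1], v[0]))

    def delta_h_area(self, u: Site, v: Site) -> float:
        s_u = int(self.state.spin[u[1], u[0]])
        s_v = int(self.state.spin[v[1], v[0]])
        return float(K.area_delta(self._areas, self._ctype, self._lam_area,
                                  self._tgt_area, s_u, s_v))

    def delta_h_perimeter(self, u: Site, v: Site) -> float:
        s_u = int(self.state.spin[u[1], u[0]])
        s_v = int(self.state.spin[v[1], v[0]])
        return float(K.perimeter_energy_delta(
            self.state.spin, self._ctype, self._perims,
            self._lam_perim, self._tgt_perim, v[1], v[0], s_u, s_v))

    def delta_h_total(self, u: Site, v: Site) -> float:
        """dH_adhesion + dH_area + dH_perimeter - dH_act - dH_chemotaxis."""
        return float(K.total_delta_h(
            self.state.spin, self.state.activity, self._ctype,
            self._areas, self._perims, self.J,
            self._lam_area, self._tgt_area, self._lam_perim, self._tgt_perim,
            self._max_act, self._lam_act, self._lam_chem, self.chemokine,
            u[1], u[0], v[1], v[0]))

    def connectivity_allows(self, v: Site) -> bool:
        """Whether the cell currently holding v may lose it (local arc test)."""
        return bool(K.connectivity_allows(self.state.spin, self._areas,
                                          v[1], v[0]))

    # -------------------------------------------------------------- auditing

    def global_hamiltonian(self) -> float:
        """Whole-lattice energy, recomputed from scratch (audit path)."""
        spin = self.state.spin
        H_, W_ = spin.shape
        types = self._ctype[spin]
        e = 0.0
        # each unordered Moore pair once: E/SE/S/SW shifts
        for dy, dx in ((0, 1), (1, 1), (1, 0), (1, -1)):
            ns = np.roll(spin, (-dy, -dx), axis=(0, 1))
            nt = np.roll(types, (-dy, -dx), axis=(0, 1))
            diff = spin != ns
            e += self.J[types[diff], nt[diff]].sum()
        for s in range(1, len(self._ctype)):
            t = self._ctype[s]
            a = np.count_nonzero(spin == s)
            if a == 0:
                continue
            e += self._lam_area[t] * (a - self._tgt_area[t]) ** 2
            p = self._recount_perimeter(s)
            e += self._lam_perim[t] * (p - self._tgt_perim[t]) ** 2
        return float(e)

    def _recount_perimeter(self, sigma: int) -> int:
        spin = self.state.spin
        mask = spin == sigma
        p = 0
        for dy, dx in zip(K.RING_DY, K.RING_DX):
            p += np.count_nonzero(mask & (np.roll(spin, (-dy, -dx),
                                                  axis=(0, 1)) != sigma))
        return int(p)

    def _recount_area(self, sigma: int) -> int:
        return int(np.count_nonzero(self.state.spin == sigma))

    def audit(self) -> None:
        """Raise if running area/perimeter totals drift from recounts."""
        for s in range(1, len(self._ctype)):
            if self._recount_area(s) != self._areas[s]:
                raise AssertionError(f"area drift for cell {s}")
            if self._recount_perimeter(s) != self._perims[s]:
                raise AssertionError(f"perimeter drift for cell {s}")
        if (self.state.activity[self.state.spin == 0] != 0).any():
            raise AssertionError("active medium site")

    def _touching(self, sigma: int) -> set[int]:
        spin = self.state.spin
        mask = spin == sigma
        out: set[int] = set()
        for dy, dx in zip(K.RING_DY, K.RING_DX):
            out |= set(np.unique(np.roll(spin, (-dy, -dx), axis=(0, 1))[mask]))
        out.discard(sigma)
        out.discard(0)
        return out


def metropolis_accept(delta_h: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Metropolis rule: always accept dH < 0, else with probability e^(-dH/T)."""
    if delta_h < 0:
        return True
    return bool(rng.random() < math.exp(-delta_h / temperature))


# ------------------------------------------------------------------ state IO

def save_state(state: LatticeState, path) -> None:
    """Write a lattice state as plain text.

    Format: a header line ``actcpm-state <width> <height> <boundary>``,
    then H rows of W identities, a blank line, and H rows of W activity
    values.
    """
    with open(path, "w") as fh:
        fh.write(f"actcpm-state {state.width} {state.height} {state.boundary}\n")
        for row in state.spin:
            fh.write(" ".join(str(int(s)) for s in row) + "\n")
        fh.write("\n")
        for row in state.activity:
            fh.write(" ".join(str(int(a)) for a in row) + "\n")


def load_state(path) -> LatticeState:
    with open(path) as fh:
        header = fh.readline().split()
        if header[0] != "actcpm-state":
            raise ValueError("not an actcpm state file")
        w, h = int(header[1]), int(header[2])
        boundary = header[3]
        rows = [line.split() for line in fh if line.strip()]
    grid = np.array(rows, dtype=np.int32)
    if grid.shape != (2 * h, w):
        raise ValueError("state file does not match its header")
    return LatticeState(spin=grid[:h].copy(), activity=grid[h:].copy(),
                        boundary=boundary)
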