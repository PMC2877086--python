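"""Cellular Potts (Glazier-Graner-Hogeweg) engine.

The tumor and the tissue matrix (TM) live on a single 3D integer lattice
``sigma``: ``sigma[x] = id`` of the Generalized Cell occupying voxel x.  The
TM is one unconstrained Generalized Cell with the reserved id
:data:`TM_ID` (index 0 is never used, so every voxel belongs to a registered
cell).  The effective energy is

    H = sum_pairs J(tau, tau') + sum_cells lam_V (V - V_t)^2
        + sum_cells lam_S (S - S_t)^2

where the contact sum runs over unordered fourth-order neighbor voxel pairs
spanning a cell boundary, and the constraint sums skip the TM cell.  The
surface S of a cell is counted as the number of face-adjacent voxel pairs
spanning its boundary.  Dynamics are Metropolis copy attempts: a random site
adopts the index of a random fourth-order neighbor with probability 1 if the
energy change is non-positive and exp(-dH/T_m) otherwise; one Monte Carlo
Step (MCS) is L^3 attempts.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, Optional

import numpy as np

from . import _kernels
from .config import SimulationConfig

TM_ID = 1
TM_TYPE = _kernels.TM_TYPE
TUMOR_TYPE = _kernels.TUMOR_TYPE

# phenotype codes
PROLIFERATING = 0
QUIESCENT = 1
NECROTIC = 2

_STATE_NAMES = {PROLIFERATING: "proliferating", QUIESCENT: "quiescent",
                NECROTIC: "necrotic"}


class AuditError(RuntimeError):
    """The incremental cell ledger disagrees with the lattice."""


class CellType(Enum):
    TM = "TM"
    TUMOR = "tumor"


# ----------------------------------------------------------------------
# Neighborhood
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class NeighborTable:
    """Interaction offsets up to the requested neighbor order.

    Orders are ranked by squared distance on the cubic lattice: 1 -> d^2=1
    (6 offsets), 2 -> d^2=2 (12), 3 -> d^2=3 (8), 4 -> d^2=4 (6); the
    fourth-order table therefore holds 32 offsets.
    """

    offsets: np.ndarray
    order: int

    @property
    def count(self) -> int:
        return len(self.offsets)


def build_neighbor_table(order: int = 4) -> NeighborTable:
    max_d2 = {1: 1, 2: 2, 3: 3, 4: 4}[order]
    offs = []
    for dx in range(-2, 3):
        for dy in range(-2, 3):
            for dz in range(-2, 3):
                d2 = dx * dx + dy * dy + dz * dz
                if 1 <= d2 <= max_d2:
                    offs.append((dx, dy, dz))
    offs.sort(key=lambda o: (o[0] ** 2 + o[1] ** 2 + o[2] ** 2, o))
    return NeighborTable(np.array(offs, dtype=np.int64), order)


# ----------------------------------------------------------------------
# Cells and lattice
# ----------------------------------------------------------------------
class GeneralizedCell:
    """Read-only view of one cell's state inside a :class:`CellLattice`."""

    __slots__ = ("_lat", "id")

    def __init__(self, lattice: "CellLattice", cid: int):
        self._lat = lattice
        self.id = cid

    @property
    def type(self) -> CellType:
        return CellType.TUMOR if self._lat.ctype[self.id] == TUMOR_TYPE \
            else CellType.TM

    @property
    def V(self) -> int:
        return int(self._lat.V[self.id])

    @property
    def V_t(self) -> float:
        return float(self._lat.Vt[self.id])

    @property
    def S(self) -> int:
        return int(self._lat.S[self.id])

    @property
    def S_t(self) -> float:
        return float(self._lat.St[self.id])

    @property
    def com(self) -> np.ndarray:
        v = self.V
        if v == 0:
            return np.full(3, np.nan)
        return np.array([self._lat.comx[self.id], self._lat.comy[self.id],
                         self._lat.comz[self.id]]) / v

    @property
    def state(self) -> str:
        return _STATE_NAMES[int(self._lat.state[self.id])]

    def __repr__(self) -> str:
        return (f"GeneralizedCell(id={self.id}, type={self.type.value}, "
                f"V={self.V}, V_t={self.V_t:.2f}, state={self.state})")


class CellLattice:
    """3D cell-index lattice plus the per-cell state ledger.

    Per-cell quantities are stored in flat arrays indexed by cell id; the
    Metropolis kernel keeps them consistent with ``sigma`` incrementally and
    :meth:`audit` verifies them from scratch.
    """

    def __init__(self, L: int, seed: int = 0, capacity: int = 4096):
        self.L = L
        self.sigma = np.full((L, L, L), TM_ID, dtype=np.int32)
        self._cap = capacity
        self.ctype = np.zeros(capacity, dtype=np.uint8)
        self.state = np.zeros(capacity, dtype=np.uint8)
        self.alive = np.zeros(capacity, dtype=np.uint8)
        self.V = np.zeros(capacity, dtype=np.int64)
        self.Vt = np.zeros(capacity, dtype=np.float64)
        self.S = np.zeros(capacity, dtype=np.int64)
        self.St = np.zeros(capacity, dtype=np.float64)
        self.comx = np.zeros(capacity, dtype=np.float64)
        self.comy = np.zeros(capacity, dtype=np.float64)
        self.comz = np.zeros(capacity, dtype=np.float64)
        self.bbmin = np.zeros((capacity, 3), dtype=np.int32)
        self.bbmax = np.zeros((capacity, 3), dtype=np.int32)
        self.next_id = TM_ID + 1
        self.mcs = 0
        self.seed = seed
        # kernel RNG drives copy attempts; this generator drives biology
        # (division axes) so the two streams stay independent.
        self.bio_rng = np.random.default_rng(np.uint32(seed) + 1_000_003)
        _kernels.seed_rng(seed)
        # register TM as one unconstrained Generalized Cell covering the domain
        self.ctype[TM_ID] = TM_TYPE
        self.alive[TM_ID] = 1
        self.V[TM_ID] = L ** 3
        csum = (L - 1) / 2.0 * L ** 3
        self.comx[TM_ID] = csum
        self.comy[TM_ID] = csum
        self.comz[TM_ID] = csum
        self.bbmin[TM_ID] = 0
        self.bbmax[TM_ID] = L - 1

    # ------------------------------------------------------------------
    def _ensure_capacity(self, n: int) -> None:
        if n < self._cap:
            return
        new = max(2 * self._cap, n + 1)
        for name in ("ctype", "state", "alive", "V", "Vt", "S", "St",
                     "comx", "comy", "comz"):
            arr = getattr(self, name)
            grown = np.zeros(new, dtype=arr.dtype)
            grown[: self._cap] = arr
            setattr(self, name, grown)
        for name in ("bbmin", "bbmax"):
            arr = getattr(self, name)
            grown = np.zeros((new, 3), dtype=arr.dtype)
            grown[: self._cap] = arr
            setattr(self, name, grown)
        self._cap = new

    def new_cell_id(self) -> int:
        cid = self.next_id
        self.next_id += 1
        self._ensure_capacity(self.next_id)
        return cid

    # ------------------------------------------------------------------
    @property
    def registry(self) -> Dict[int, GeneralizedCell]:
        return {cid: GeneralizedCell(self, cid)
                for cid in range(TM_ID, self.next_id)
                if self.alive[cid]}

    def tumor_ids(self, states=None) -> np.ndarray:
        """Ids of live tumor cells, optionally restricted to given states."""
        ids = np.arange(self.next_id)
        mask = (self.alive[: self.next_id] == 1) & \
               (self.ctype[: self.next_id] == TUMOR_TYPE)
        if states is not None:
            mask &= np.isin(self.state[: self.next_id], states)
        return ids[mask]

    @property
    def n_tumor_cells(self) -> int:
        return len(self.tumor_ids())

    def tumor_mask(self) -> np.ndarray:
        return self.ctype[self.sigma] == TUMOR_TYPE

    def tumor_touches_boundary(self) -> bool:
        s = self.sigma
        for face in (s[0], s[-1], s[:, 0], s[:, -1], s[:, :, 0], s[:, :, -1]):
            if np.any(self.ctype[face] == TUMOR_TYPE):
                return True
        return False

    def state_counts(self) -> Dict[str, int]:
        ids = self.tumor_ids()
        st = self.state[ids]
        return {name: int(np.sum(st == code))
                for code, name in _STATE_NAMES.items()}

    # ------------------------------------------------------------------
    def audit(self) -> None:
        """Recompute V, S, com from sigma; raise AuditError on any mismatch
        and verify the volume ledger sums exactly to L^3."""
        V, S, sx, sy, sz = _kernels.audit_stats(self.sigma, self.next_id)
        n = self.next_id
        if int(V.sum()) != self.L ** 3:
            raise AuditError("voxel count does not sum to L^3")
        if not np.array_equal(V, self.V[:n]):
            raise AuditError("cell volumes disagree with lattice")
        if not np.array_equal(S, self.S[:n]):
            raise AuditError("cell surfaces disagree with lattice")
        if not (np.allclose(sx, self.comx[:n]) and np.allclose(sy, self.comy[:n])
                and np.allclose(sz, self.comz[:n])):
            raise AuditError("center-of-mass sums disagree with lattice")
        dead_with_voxels = [cid for cid in range(TM_ID, n)
                            if not self.alive[cid] and V[cid] > 0]
        if dead_with_voxels:
            raise AuditError(f"dead cells still own voxels: {dead_with_voxels}")

    def reap_empty_cells(self) -> int:
        """Unregister tumor cells whose last voxel was overwritten."""
        ids = self.tumor_ids()
        empty = ids[self.V[ids] == 0]
        self.alive[empty] = 0
        return len(empty)


# ----------------------------------------------------------------------
# Construction
# ----------------------------------------------------------------------
def _register_cube(lattice: CellLattice, origin, size: int, Vt: float,
                   St: float) -> int:
    cid = lattice.new_cell_id()
    o = np.asarray(origin)
    sl = tuple(slice(o[d], o[d] + size) for d in range(3))
    lattice.sigma[sl] = cid
    lattice.ctype[cid] = TUMOR_TYPE
    lattice.alive[cid] = 1
    lattice.state[cid] = PROLIFERATING
    lattice.Vt[cid] = Vt
    lattice.St[cid] = St
    return cid


def build_initial_state(config: SimulationConfig):
    """Initial condition: 8 tumor cells, each a 3x3x3 voxel cube, arranged as
    a 2x2x2 block (6^3 voxels) centered in the domain; everything else is the
    single TM cell.  Returns ``(lattice, fields)``."""
    from .fields import init_fields

    L = config.lattice_size
    if L < 8:
        raise ValueError("lattice too small for the 6x6x6 tumor seed block")
    lattice = CellLattice(L, seed=config.seed)
    start = (L - 6) // 2
    Vt0 = 27.0
    St0 = config.shape_constant * Vt0 ** (2.0 / 3.0)
    for ox in (0, 3):
        for oy in (0, 3):
            for oz in (0, 3):
                _register_cube(lattice, (start + ox, start + oy, start + oz),
                               3, Vt0, St0)
    # rebuild the ledger from the lattice
    V, S, sx, sy, sz = _kernels.audit_stats(lattice.sigma, lattice.next_id)
    n = lattice.next_id
    lattice.V[:n] = V
    lattice.S[:n] = S
    lattice.comx[:n] = sx
    lattice.comy[:n] = sy
    lattice.comz[:n] = sz
    for cid in range(TM_ID + 1, n):
        res = _kernels.cell_stats_in_box(lattice.sigma, cid, 0, 0, 0,
                                         L - 1, L - 1, L - 1)
        lattice.bbmin[cid] = res[5:8]
        lattice.bbmax[cid] = res[8:11]
    lattice.audit()
    fields = init_fields(config)
    return lattice, fields


def lattice_from_sigma(sigma: np.ndarray, tm_id: int = TM_ID, seed: int = 0,
                       Vt=None, St=None) -> CellLattice:
    """Build a consistent CellLattice from an arbitrary index lattice.

    Every id present in ``sigma`` other than ``tm_id`` is registered as a
    tumor cell.  Target volumes/surfaces default to the realized values
    (energy-neutral constraints) unless given as ``{id: value}`` maps.
    """
    sigma = np.ascontiguousarray(sigma, dtype=np.int32)
    if sigma.shape[0] != sigma.shape[1] or sigma.shape[0] != sigma.shape[2]:
        raise ValueError("sigma must be cubic")
    if np.any(sigma == 0):
        raise ValueError("index 0 is reserved; use the TM id for medium")
    L = sigma.shape[0]
    lattice = CellLattice(L, seed=seed)
    lattice.sigma = sigma
    ids = np.unique(sigma)
    lattice.next_id = int(ids.max()) + 1
    lattice._ensure_capacity(lattice.next_id)
    V, S, sx, sy, sz = _kernels.audit_stats(sigma, lattice.next_id)
    n = lattice.next_id
    lattice.V[:n] = V
    lattice.S[:n] = S
    lattice.comx[:n] = sx
    lattice.comy[:n] = sy
    lattice.comz[:n] = sz
    lattice.alive[:n] = 0
    for cid in ids:
        cid = int(cid)
        lattice.alive[cid] = 1
        lattice.ctype[cid] = TM_TYPE if cid == tm_id else TUMOR_TYPE
        lattice.state[cid] = PROLIFERATING
        if cid != tm_id:
            lattice.Vt[cid] = (Vt or {}).get(cid, float(V[cid]))
            lattice.St[cid] = (St or {}).get(cid, float(S[cid]))
        res = _kernels.cell_stats_in_box(sigma, cid, 0, 0, 0,
                                         L - 1, L - 1, L - 1)
        lattice.bbmin[cid] = res[5:8]
        lattice.bbmax[cid] = res[8:11]
    lattice.audit()
    return lattice


# ----------------------------------------------------------------------
# Energies
# ----------------------------------------------------------------------
def contact_matrix(config: SimulationConfig) -> np.ndarray:
    """2x2 contact-energy matrix indexed by (type, type).  The TM-TM entry is
    irrelevant (a single TM cell has no heterocell TM-TM boundary)."""
    J = np.zeros((2, 2), dtype=np.float64)
    J[TUMOR_TYPE, TUMOR_TYPE] = config.J_tumor_tumor
    J[TUMOR_TYPE, TM_TYPE] = config.J_tumor_tm
    J[TM_TYPE, TUMOR_TYPE] = config.J_tumor_tm
    return J


def surface_tension(J_tumor_tm: float, J_tumor_tumor: float) -> float:
    """gamma = J(t,TM) - J(t,t)/2: the tumor-TM surface tension controlling
    whether tumor cells cluster (gamma > 0) or disperse."""
    return J_tumor_tm - J_tumor_tumor / 2.0


def contact_energy_total(lattice: CellLattice, J: np.ndarray,
                         neighbors: Optional[NeighborTable] = None) -> float:
    if neighbors is None:
        neighbors = build_neighbor_table(4)
    return float(_kernels.contact_energy(lattice.sigma,
                                         lattice.ctype, neighbors.offsets, J))


def effective_energy(lattice: CellLattice, config: SimulationConfig,
                     neighbors: Optional[NeighborTable] = None) -> float:
    """Full effective energy: contact + volume + surface constraints (the TM
    cell is unconstrained and excluded from the penalty sums)."""
    E = contact_energy_total(lattice, contact_matrix(config), neighbors)
    ids = lattice.tumor_ids()
    dv = lattice.V[ids] - lattice.Vt[ids]
    ds = lattice.S[ids] - lattice.St[ids]
    E += config.lambda_V * float(np.sum(dv * dv))
    E += config.lambda_S * float(np.sum(ds * ds))
    return E


def delta_H(lattice: CellLattice, site, candidate: int,
            config: SimulationConfig,
            neighbors: Optional[NeighborTable] = None) -> float:
    """Energy change for copying ``candidate`` into ``site``, evaluated
    locally; equals the difference of two global energies."""
    x0, x1, x2 = site
    if lattice.sigma[x0, x1, x2] == candidate:
        raise ValueError("candidate equals the current index (no-op attempt)")
    if neighbors is None:
        neighbors = build_neighbor_table(config.neighbor_order)
    return float(_kernels.delta_h(
        lattice.sigma, lattice.ctype, lattice.V, lattice.Vt, lattice.S,
        lattice.St, neighbors.offsets, contact_matrix(config),
        config.lambda_V, config.lambda_S, x0, x1, x2, candidate))


# ----------------------------------------------------------------------
# Dynamics
# ----------------------------------------------------------------------
def _sweep(lattice: CellLattice, config: SimulationConfig,
           neighbors: NeighborTable, n_attempts: int) -> int:
    return int(_kernels.sweep(
        lattice.sigma, lattice.ctype, lattice.V, lattice.Vt, lattice.S,
        lattice.St, lattice.comx, lattice.comy, lattice.comz,
        lattice.bbmin, lattice.bbmax, neighbors.offsets,
        contact_matrix(config), config.T_m, config.lambda_V, config.lambda_S,
        n_attempts))


def metropolis_attempt(lattice: CellLattice, config: SimulationConfig,
                       neighbors: Optional[NeighborTable] = None) -> bool:
    """One copy attempt at a random site; returns whether a copy happened."""
    if neighbors is None:
        neighbors = build_neighbor_table(config.neighbor_order)
    return _sweep(lattice, config, neighbors, 1) == 1


def run_mcs(lattice: CellLattice, fields, config: SimulationConfig,
            n_mcs: int, *, stop_cells: Optional[int] = None,
            stop_on_boundary: bool = False, record: bool = True,
            on_snapshot=None):
    """Advance the simulation n_mcs Monte Carlo Steps.

    Each MCS is L^3 copy attempts, then one field update (all substeps plus
    the per-cell point secretion/uptake), then the biology rules (growth,
    mitosis, phenotype transitions).  A morphometrics record is emitted every
    ``config.snapshot_interval`` MCS and at the final step.  Returns a
    ``RunResult`` with the records and stop information.
    """
    from . import tumor_biology as bio
    from .fields import step_fields_mcs
    from .morphometrics import compute_record

    neighbors = build_neighbor_table(config.neighbor_order)
    records = []
    stopped = None
    mcs_at_stop_cells = None

    def snapshot():
        lattice.audit()
        rec = compute_record(lattice, config)
        records.append(rec)
        if on_snapshot is not None:
            on_snapshot(lattice, fields, rec)
        return rec

    if record and lattice.mcs == 0 and n_mcs > 0:
        snapshot()

    for _ in range(n_mcs):
        _sweep(lattice, config, neighbors, config.n_sites)
        step_fields_mcs(fields, lattice, config)
        bio.grow_cells(lattice, fields.c, config)
        bio.divide_ready_cells(lattice, config)
        if config.quiescence_enabled or config.necrosis_enabled:
            bio.apply_phenotype_rules(lattice, fields.c, config)
        lattice.reap_empty_cells()
        lattice.mcs += 1

        if stop_cells is not None and mcs_at_stop_cells is None \
                and lattice.n_tumor_cells >= stop_cells:
            mcs_at_stop_cells = lattice.mcs
            stopped = "cells"
        if stop_on_boundary and stopped is None and lattice.mcs % 10 == 0 \
                and lattice.tumor_touches_boundary():
            stopped = "boundary"
        if stopped is not None:
            break
        if record and lattice.mcs % config.snapshot_interval == 0:
            snapshot()

    if record and n_mcs > 0 and (not records or records[-1].mcs != lattice.mcs):
        snapshot()

    return RunResult(records=records, stopped=stopped,
                     final_mcs=lattice.mcs,
                     mcs_at_stop_cells=mcs_at_stop_cells)


@dataclass
class RunResult:
    records: list
    stopped: Optional[str]
    final_mcs: int
    mcs_at_stop_cells: Optional[int]
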