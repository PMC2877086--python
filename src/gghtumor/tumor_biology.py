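"""Tumor-cell biology: growth, mitosis, and phenotype rules.

Growth law
    A proliferating tumor cell's target volume grows at a rate proportional
    to the local limiting-substrate concentration sampled at the cell's
    center-of-mass voxel:  V_t <- V_t + g c(com).  There is no concentration
    threshold for growth; cells deep inside the tumor, where c is nearly
    zero, simply barely grow (implicit quiescence).

Shape constraint
    The target surface tracks the target volume so the nondimensional ratio
    S_t / V_t^(2/3) stays constant at 6, anchored by the initial 3x3x3 cube
    (V_t = 27, S_t = 54); this keeps growing cells roughly spherical.

Mitosis
    When a cell reaches the doubling volume V_d = 54 voxels (trigger on the
    realized volume by default), it splits along a plane through its center
    of mass with a uniformly random orientation; both daughters inherit the
    phenotype and receive half the parent's target volume.

Phenotypes (optional rules, studied separately)
    Quiescence: a cell whose center-of-mass substrate concentration drops
    below ``c_threshold`` stops growing, consuming substrate and producing
    MDE; the arrest is reversible.  Necrosis: the same trigger makes the
    cell irreversibly stop consuming/producing and shrink at ``g_necrotic``
    until its volume reaches zero, at which point it is removed.

The G <-> k correspondence
    The dimensionless diffusion-limitation parameter G (maximum tumor-growth
    rate over maximum substrate-transport rate) is varied through the
    consumption rate k via G = k L^2 / D_c; with L = 100, D_c = 10 the rates
    k = 0.05..0.2 map onto G = 50..200.
"""

from __future__ import annotations

import math

import numpy as np

from .config import SimulationConfig


# ----------------------------------------------------------------------
# Diffusion-limitation parameterization
# ----------------------------------------------------------------------
def G_from_k(k: float, L: float, D_c: float, constant: float = 1.0) -> float:
    return constant * k * L * L / D_c


def k_from_G(G: float, L: float, D_c: float, constant: float = 1.0) -> float:
    return G * D_c / (constant * L * L)


# ----------------------------------------------------------------------
# Growth
# ----------------------------------------------------------------------
def update_target_surface(V_t: float, shape_constant: float = 6.0) -> float:
    """S_t = shape_constant * V_t^(2/3); zero for V_t <= 0 (necrotic
    shrink-out)."""
    if V_t <= 0.0:
        return 0.0
    return shape_constant * V_t ** (2.0 / 3.0)


def com_voxel(com, L: int):
    """Nearest-voxel rounding of a real-valued center of mass, ties toward
    negative infinity, clipped into the domain."""
    return tuple(int(min(L - 1, max(0, math.ceil(x - 0.5)))) for x in com)


def grow_cells(lattice, c_field: np.ndarray, config: SimulationConfig) -> None:
    """Per-MCS growth: V_t += g c(com) for proliferating cells, necrotic
    cells shrink at g_necrotic (floored at 0), quiescent cells unchanged;
    S_t follows V_t for all of them."""
    from .cpm_core import NECROTIC, PROLIFERATING

    ids = lattice.tumor_ids(states=[PROLIFERATING])
    ids = ids[lattice.V[ids] > 0]
    if len(ids):
        i = np.empty(len(ids), dtype=np.int64)
        j = np.empty(len(ids), dtype=np.int64)
        k = np.empty(len(ids), dtype=np.int64)
        for row, cid in enumerate(ids):
            v = lattice.V[cid]
            i[row], j[row], k[row] = com_voxel(
                (lattice.comx[cid] / v, lattice.comy[cid] / v,
                 lattice.comz[cid] / v), lattice.L)
        lattice.Vt[ids] += config.g * c_field[i, j, k]
        lattice.St[ids] = config.shape_constant * lattice.Vt[ids] ** (2.0 / 3.0)

    nec = lattice.tumor_ids(states=[NECROTIC])
    if len(nec):
        lattice.Vt[nec] = np.maximum(0.0, lattice.Vt[nec] + config.g_necrotic)
        pos = lattice.Vt[nec] > 0
        lattice.St[nec] = 0.0
        lattice.St[nec[pos]] = (config.shape_constant
                                * lattice.Vt[nec[pos]] ** (2.0 / 3.0))


# ----------------------------------------------------------------------
# Mitosis
# ----------------------------------------------------------------------
def _random_unit_vector(rng) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def mitose(lattice, cell_id: int, rng, config: SimulationConfig) -> int:
    """Split one cell along a random plane through its center of mass.

    Voxels with (x - com) . n >= 0 move to a fresh id.  If a draw leaves one
    side empty the axis is redrawn (up to 10 times), then the coordinate axis
    of largest extent is used.  Returns the new daughter's id.
    """
    from . import _kernels
    from .cpm_core import TUMOR_TYPE

    V_parent = int(lattice.V[cell_id])
    if V_parent < 2:
        raise ValueError("cannot divide a cell with fewer than 2 voxels")
    cx = lattice.comx[cell_id] / V_parent
    cy = lattice.comy[cell_id] / V_parent
    cz = lattice.comz[cell_id] / V_parent
    b = lattice.bbmin[cell_id].copy()
    e = lattice.bbmax[cell_id].copy()

    new_id = lattice.new_cell_id()
    moved = 0
    for attempt in range(11):
        if attempt < 10:
            n = _random_unit_vector(rng)
        else:
            extents = (e - b).astype(float)
            n = np.zeros(3)
            n[int(np.argmax(extents))] = 1.0
        moved = _kernels.relabel_halfspace(
            lattice.sigma, cell_id, new_id,
            int(b[0]), int(b[1]), int(b[2]), int(e[0]), int(e[1]), int(e[2]),
            cx, cy, cz, n[0], n[1], n[2])
        if 0 < moved < V_parent:
            break
        if moved:  # degenerate: everything moved; undo and redraw
            _kernels.relabel_all(lattice.sigma, new_id, cell_id,
                                 int(b[0]), int(b[1]), int(b[2]),
                                 int(e[0]), int(e[1]), int(e[2]))
            moved = 0
    if not 0 < moved < V_parent:
        raise RuntimeError(f"degenerate division of cell {cell_id}")

    half_Vt = lattice.Vt[cell_id] / 2.0
    for cid in (cell_id, new_id):
        res = _kernels.cell_stats_in_box(
            lattice.sigma, cid,
            int(b[0]), int(b[1]), int(b[2]), int(e[0]), int(e[1]), int(e[2]))
        V, S, sx, sy, sz = res[:5]
        lattice.V[cid] = V
        lattice.S[cid] = S
        lattice.comx[cid] = sx
        lattice.comy[cid] = sy
        lattice.comz[cid] = sz
        lattice.bbmin[cid] = res[5:8]
        lattice.bbmax[cid] = res[8:11]
        lattice.Vt[cid] = half_Vt
        lattice.St[cid] = update_target_surface(half_Vt, config.shape_constant)
    lattice.ctype[new_id] = TUMOR_TYPE
    lattice.alive[new_id] = 1
    lattice.state[new_id] = lattice.state[cell_id]
    return new_id


def divide_ready_cells(lattice, config: SimulationConfig) -> int:
    """Divide every tumor cell that reached the doubling volume; returns the
    number of divisions."""
    ids = lattice.tumor_ids()
    if config.division_trigger == "actual":
        ready = ids[lattice.V[ids] >= config.V_doubling]
    else:
        ready = ids[lattice.Vt[ids] >= config.V_doubling]
    for cid in ready:
        mitose(lattice, int(cid), lattice.bio_rng, config)
    return len(ready)


# ----------------------------------------------------------------------
# Phenotype rules
# ----------------------------------------------------------------------
def apply_phenotype_rules(lattice, c_field: np.ndarray,
                          config: SimulationConfig) -> None:
    """Threshold rules on c(com): reversible quiescence or irreversible
    necrosis (the two variants are studied separately and cannot be enabled
    together)."""
    from .cpm_core import NECROTIC, PROLIFERATING, QUIESCENT

    ids = lattice.tumor_ids()
    ids = ids[lattice.V[ids] > 0]
    if len(ids) == 0:
        return
    c_at = np.empty(len(ids))
    for row, cid in enumerate(ids):
        v = lattice.V[cid]
        c_at[row] = c_field[com_voxel(
            (lattice.comx[cid] / v, lattice.comy[cid] / v,
             lattice.comz[cid] / v), lattice.L)]
    starved = c_at < config.c_threshold

    if config.quiescence_enabled:
        st = lattice.state[ids]
        lattice.state[ids[starved & (st == PROLIFERATING)]] = QUIESCENT
        lattice.state[ids[~starved & (st == QUIESCENT)]] = PROLIFERATING
    elif config.necrosis_enabled:
        st = lattice.state[ids]
        lattice.state[ids[starved & (st != NECROTIC)]] = NECROTIC
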