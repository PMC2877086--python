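"""The three scalar fields and their forward-Euler evolution.

Three co-registered lattices share the cell lattice's shape and co-occupy
space with the cells:

* ``f`` — tissue-matrix (TM) density, degraded by MDE:  df/dt = -delta m f.
  Degradation consumes no MDE and f never increases (no TM regeneration).
* ``m`` — matrix-degrading enzyme (MDE), produced by living tumor cells at
  their centers of mass at rate mu per MCS and diffusing with constant D_m;
  capped at 1.
* ``c`` — the limiting substrate as a fraction of its maximum soluble
  concentration, produced by TM at rate S_prod f (1-c) Theta(1-c) (the
  Heaviside factor saturates production at c=1), diffusing with constant D_c,
  and consumed at rate k at each living tumor cell's center-of-mass voxel
  (clamped so consumption cannot drive c negative).

All values stay in [0, 1].  Diffusion uses the 7-point Laplacian with
no-flux (mirror) boundaries and explicit Euler substeps sized by
:func:`stability_substeps`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .config import SimulationConfig


@dataclass
class FieldSet:
    f: np.ndarray
    m: np.ndarray
    c: np.ndarray
    substeps_per_mcs: int       # substrate (the stiffest field)
    substeps_mde: int = 1       # MDE diffusion + TM degradation

    def __post_init__(self):
        self._cbuf = np.empty_like(self.c)
        self._mbuf = np.empty_like(self.m)


def stability_substeps(D: float, dt_mcs: float = 1.0,
                       safety: float = 0.8) -> int:
    """Smallest substep count n with D dt/n <= safety/6 (3D explicit-Euler
    stability bound at unit voxel spacing)."""
    if D <= 0:
        return 1
    return max(1, math.ceil(6.0 * D * dt_mcs / safety))


def init_fields(config: SimulationConfig) -> FieldSet:
    """Uniform initial condition: f = 1, m = 0, c = 1 everywhere (including
    under the tumor seed; degradation and uptake begin at the first MCS)."""
    L = config.lattice_size
    shape = (L, L, L)
    return FieldSet(f=np.ones(shape), m=np.zeros(shape), c=np.ones(shape),
                    substeps_per_mcs=stability_substeps(config.D_c),
                    substeps_mde=stability_substeps(config.D_m))


def laplacian_noflux(field: np.ndarray) -> np.ndarray:
    """7-point (2D: 5-point) Laplacian with mirror (zero-normal-gradient)
    boundaries, i.e. ghost voxels copy the edge value."""
    padded = np.pad(field, 1, mode="edge")
    lap = -2.0 * field.ndim * field
    for ax in range(field.ndim):
        sl_lo = tuple(slice(1, -1) if a != ax else slice(0, -2)
                      for a in range(field.ndim))
        sl_hi = tuple(slice(1, -1) if a != ax else slice(2, None)
                      for a in range(field.ndim))
        lap = lap + padded[sl_lo] + padded[sl_hi]
    return lap


def degrade_tm(f: np.ndarray, m: np.ndarray, delta_dt: float) -> np.ndarray:
    """One forward-Euler degradation step f <- f (1 - delta m dt), clamped
    at 0.  ``delta_dt`` is the product delta * dt of one substep."""
    out = f * (1.0 - delta_dt * m)
    np.maximum(out, 0.0, out=out)
    return out


def _com_voxels(lattice, ids) -> tuple:
    from .tumor_biology import com_voxel
    L = lattice.L
    vox = np.empty((len(ids), 3), dtype=np.int64)
    for row, cid in enumerate(ids):
        vox[row] = com_voxel(
            (lattice.comx[cid] / lattice.V[cid],
             lattice.comy[cid] / lattice.V[cid],
             lattice.comz[cid] / lattice.V[cid]), L)
    return vox[:, 0], vox[:, 1], vox[:, 2]


def update_mde(m: np.ndarray, lattice, config: SimulationConfig) -> np.ndarray:
    """Full-MCS MDE update: diffusion substeps, then production mu at each
    living (proliferating) tumor cell's center-of-mass voxel, then clamp."""
    from .cpm_core import PROLIFERATING

    n_sub = stability_substeps(config.D_m)
    dt = 1.0 / n_sub
    for _ in range(n_sub):
        m = m + config.D_m * dt * laplacian_noflux(m)
    ids = lattice.tumor_ids(states=[PROLIFERATING])
    ids = ids[lattice.V[ids] > 0]
    if len(ids):
        i, j, k = _com_voxels(lattice, ids)
        np.add.at(m, (i, j, k), config.mu)
    np.clip(m, 0.0, 1.0, out=m)
    return m


def update_substrate(c: np.ndarray, f: np.ndarray, lattice,
                     config: SimulationConfig) -> np.ndarray:
    """Full-MCS substrate update: per substep diffusion + saturating
    production, then per-MCS point consumption k at each living tumor cell's
    center of mass, clamped at 0."""
    from .cpm_core import PROLIFERATING

    n_sub = stability_substeps(config.D_c)
    dt = 1.0 / n_sub
    for _ in range(n_sub):
        prod = config.S_prod * f * np.maximum(1.0 - c, 0.0)
        c = c + dt * (config.D_c * laplacian_noflux(c) + prod)
        np.clip(c, 0.0, 1.0, out=c)
    ids = lattice.tumor_ids(states=[PROLIFERATING])
    ids = ids[lattice.V[ids] > 0]
    if len(ids):
        i, j, k = _com_voxels(lattice, ids)
        np.subtract.at(c, (i, j, k), config.k_value)
    np.clip(c, 0.0, 1.0, out=c)
    return c


def step_fields_mcs(fields: FieldSet, lattice, config: SimulationConfig) -> None:
    """One full MCS of field evolution on the fused fast path.

    The substrate advances through its stability-bound substep count (with
    the TM density frozen for the MCS), MDE diffusion and TM degradation
    advance through theirs, and then the per-cell point terms are applied
    once: MDE secretion +mu and substrate uptake -k at the center-of-mass
    voxel of every living, non-quiescent, non-necrotic tumor cell.
    """
    from .cpm_core import PROLIFERATING

    c = _kernels.substrate_substeps(fields.c, fields.f, fields._cbuf,
                                    fields.substeps_per_mcs, config.D_c,
                                    config.S_prod)
    m = _kernels.mde_tm_substeps(fields.m, fields.f, fields._mbuf,
                                 fields.substeps_mde, config.D_m,
                                 config.delta)
    # the kernels ping-pong buffers; adopt whichever holds the new state
    if c is not fields.c:
        fields._cbuf = fields.c
        fields.c = c
    if m is not fields.m:
        fields._mbuf = fields.m
        fields.m = m

    ids = lattice.tumor_ids(states=[PROLIFERATING])
    ids = ids[lattice.V[ids] > 0]
    if len(ids):
        i, j, k = _com_voxels(lattice, ids)
        np.add.at(fields.m, (i, j, k), config.mu)
        np.subtract.at(fields.c, (i, j, k), config.k_value)
        fields.m[i, j, k] = np.clip(fields.m[i, j, k], 0.0, 1.0)
        fields.c[i, j, k] = np.clip(fields.c[i, j, k], 0.0, 1.0)
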