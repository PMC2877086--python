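"""Shared fixtures and independent oracles for the test suite.

The energy oracles here are deliberately written as plain brute-force python
over all voxel pairs, independent of the package's incremental kernels, so
they can serve as ground truth for the engine tests.
"""

import numpy as np
import pytest

from gghtumor import SimulationConfig, lattice_from_sigma
from gghtumor.cpm_core import TM_ID, TUMOR_TYPE, build_neighbor_table

# fourth-order offsets, regenerated independently of the package
OFFSETS4 = np.array([(dx, dy, dz)
                     for dx in range(-2, 3)
                     for dy in range(-2, 3)
                     for dz in range(-2, 3)
                     if 1 <= dx * dx + dy * dy + dz * dz <= 4])


def brute_force_contact(sigma, type_of, J):
    """Contact energy summed over unordered voxel pairs within fourth range."""
    L = sigma.shape[0]
    E = 0.0
    for x in np.ndindex(sigma.shape):
        a = sigma[x]
        for off in OFFSETS4:
            y = (x[0] + off[0], x[1] + off[1], x[2] + off[2])
            if any(c < 0 or c >= L for c in y):
                continue
            b = sigma[y]
            if a != b:
                E += J[type_of(a), type_of(b)]
    return E / 2.0  # each unordered pair visited twice


def brute_force_surfaces(sigma):
    """Face-count surface of every id, from scratch."""
    L = sigma.shape[0]
    S = {}
    for x in np.ndindex(sigma.shape):
        a = sigma[x]
        for off in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                    (0, 0, 1), (0, 0, -1)):
            y = (x[0] + off[0], x[1] + off[1], x[2] + off[2])
            if any(c < 0 or c >= L for c in y):
                continue
            if sigma[y] != a:
                S[a] = S.get(a, 0) + 1
    return S


def brute_force_effective_energy(sigma, config, Vt, St, tm_id=TM_ID):
    """Global effective energy recomputed entirely from the index lattice."""
    J = {(TUMOR_TYPE, TUMOR_TYPE): config.J_tumor_tumor,
         (TUMOR_TYPE, 0): config.J_tumor_tm,
         (0, TUMOR_TYPE): config.J_tumor_tm,
         (0, 0): 0.0}

    def type_of(cid):
        return 0 if cid == tm_id else TUMOR_TYPE

    E = brute_force_contact(sigma, type_of, J)
    S = brute_force_surfaces(sigma)
    ids, counts = np.unique(sigma, return_counts=True)
    for cid, V in zip(ids, counts):
        if cid == tm_id:
            continue
        E += config.lambda_V * (V - Vt[cid]) ** 2
        E += config.lambda_S * (S.get(cid, 0) - St[cid]) ** 2
    return E


def random_lattice(rng, L=6, n_cells=3, seed=0):
    """Random consistent small lattice: n_cells tumor cells as random blobs
    in TM, with slightly off-target V_t/S_t so all energy terms are active."""
    sigma = np.full((L, L, L), TM_ID, dtype=np.int32)
    for cid in range(2, 2 + n_cells):
        ctr = rng.integers(1, L - 1, size=3)
        n_vox = int(rng.integers(4, 12))
        pts = np.clip(ctr + rng.integers(-2, 3, size=(n_vox, 3)), 0, L - 1)
        sigma[pts[:, 0], pts[:, 1], pts[:, 2]] = cid
    present = [c for c in range(2, 2 + n_cells) if np.any(sigma == c)]
    Vt = {c: float(np.sum(sigma == c)) + rng.uniform(-2, 2) for c in present}
    St = {c: rng.uniform(10, 40) for c in present}
    lat = lattice_from_sigma(sigma, seed=seed, Vt=Vt, St=St)
    return lat, Vt, St


@pytest.fixture(scope="session")
def neighbor_table():
    return build_neighbor_table(4)


@pytest.fixture
def small_config():
    return SimulationConfig(lattice_size=8, k=0.05, seed=0)
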