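"""Numba kernels for the Cellular Potts sweep and the field integrator.

All state lives in plain numpy arrays owned by :class:`gghtumor.cpm_core.CellLattice`;
the kernels mutate them in place.  Cell-lattice copy attempts use numba's global
random stream, seeded once per simulation through :func:`seed_rng`, so a run is
bit-reproducible for a fixed seed.  Per-cell bookkeeping (volume, surface,
center-of-mass sums, bounding boxes) is updated incrementally on every accepted
copy; :func:`audit_stats` recomputes everything from scratch for integrity checks.
"""

import numpy as np
from numba import njit

# Generalized-Cell type codes (index into the 2x2 contact-energy matrix).
TM_TYPE = 0
TUMOR_TYPE = 1

# Face-adjacent neighbor offsets used for the surface estimator.
_FACES = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _delta_h_site(sigma, ctype, V, Vt, S, St, offsets, J, lam_V, lam_S,
                  x0, x1, x2, b):
    """Energy change for copying index b into site x, plus the face-count
    surface increments of the two affected cells.

    Only terms local to x change: contact pairs between x and its interaction
    neighborhood, and the volume/surface penalties of the losing cell a and the
    gaining cell b (skipped for the unconstrained TM cell).
    """
    L0, L1, L2 = sigma.shape
    a = sigma[x0, x1, x2]
    ta = ctype[a]
    tb = ctype[b]

    dE = 0.0
    for o in range(offsets.shape[0]):
        y0 = x0 + offsets[o, 0]
        y1 = x1 + offsets[o, 1]
        y2 = x2 + offsets[o, 2]
        if y0 < 0 or y0 >= L0 or y1 < 0 or y1 >= L1 or y2 < 0 or y2 >= L2:
            continue
        s = sigma[y0, y1, y2]
        ts = ctype[s]
        if s != b:
            dE += J[tb, ts]
        if s != a:
            dE -= J[ta, ts]

    if ta == TUMOR_TYPE:
        dv = V[a] - Vt[a]
        dE += lam_V * ((dv - 1.0) ** 2 - dv ** 2)
    if tb == TUMOR_TYPE:
        dv = V[b] - Vt[b]
        dE += lam_V * ((dv + 1.0) ** 2 - dv ** 2)

    # Surface increments from face-adjacent pairs.
    n_a = 0
    n_b = 0
    n_nb = 0
    for o in range(6):
        y0 = x0 + _FACES[o, 0]
        y1 = x1 + _FACES[o, 1]
        y2 = x2 + _FACES[o, 2]
        if y0 < 0 or y0 >= L0 or y1 < 0 or y1 >= L1 or y2 < 0 or y2 >= L2:
            continue
        n_nb += 1
        s = sigma[y0, y1, y2]
        if s == a:
            n_a += 1
        if s == b:
            n_b += 1
    dS_a = 2 * n_a - n_nb
    dS_b = n_nb - 2 * n_b

    if ta == TUMOR_TYPE:
        ds = S[a] - St[a]
        dE += lam_S * ((ds + dS_a) ** 2 - ds ** 2)
    if tb == TUMOR_TYPE:
        ds = S[b] - St[b]
        dE += lam_S * ((ds + dS_b) ** 2 - ds ** 2)

    return dE, dS_a, dS_b


@njit(cache=True)
def delta_h(sigma, ctype, V, Vt, S, St, offsets, J, lam_V, lam_S, x0, x1, x2, b):
    dE, _, _ = _delta_h_site(sigma, ctype, V, Vt, S, St, offsets, J, lam_V,
                             lam_S, x0, x1, x2, b)
    return dE


@njit(cache=True)
def _apply_copy(sigma, V, S, comx, comy, comz, bbmin, bbmax,
                x0, x1, x2, a, b, dS_a, dS_b):
    sigma[x0, x1, x2] = b
    V[a] -= 1
    V[b] += 1
    S[a] += dS_a
    S[b] += dS_b
    comx[a] -= x0
    comy[a] -= x1
    comz[a] -= x2
    comx[b] += x0
    comy[b] += x1
    comz[b] += x2
    if x0 < bbmin[b, 0]:
        bbmin[b, 0] = x0
    if x1 < bbmin[b, 1]:
        bbmin[b, 1] = x1
    if x2 < bbmin[b, 2]:
        bbmin[b, 2] = x2
    if x0 > bbmax[b, 0]:
        bbmax[b, 0] = x0
    if x1 > bbmax[b, 1]:
        bbmax[b, 1] = x1
    if x2 > bbmax[b, 2]:
        bbmax[b, 2] = x2


@njit(cache=True)
def sweep(sigma, ctype, V, Vt, S, St, comx, comy, comz, bbmin, bbmax,
          offsets, J, T_m, lam_V, lam_S, n_attempts):
    """n_attempts Metropolis copy attempts; returns the number accepted.

    The randomly chosen site x is the *target*: a random fourth-order neighbor
    attempts to extend its index into x.  Neighbors outside the domain and
    same-cell picks are no-ops that still consume an attempt.
    """
    L0, L1, L2 = sigma.shape
    n_off = offsets.shape[0]
    n_sites = L0 * L1 * L2
    accepted = 0
    for _ in range(n_attempts):
        # one uniform deviate selects the site (uniform over L^3 <= 2^53)
        idx = int(np.random.random() * n_sites)
        if idx >= n_sites:
            idx = n_sites - 1
        x0 = idx // (L1 * L2)
        r = idx - x0 * (L1 * L2)
        x1 = r // L2
        x2 = r - x1 * L2
        o = int(np.random.random() * n_off)
        if o >= n_off:
            o = n_off - 1
        y0 = x0 + offsets[o, 0]
        y1 = x1 + offsets[o, 1]
        y2 = x2 + offsets[o, 2]
        if y0 < 0 or y0 >= L0 or y1 < 0 or y1 >= L1 or y2 < 0 or y2 >= L2:
            continue
        a = sigma[x0, x1, x2]
        b = sigma[y0, y1, y2]
        if a == b:
            continue
        dE, dS_a, dS_b = _delta_h_site(sigma, ctype, V, Vt, S, St, offsets, J,
                                       lam_V, lam_S, x0, x1, x2, b)
        if dE <= 0.0 or np.random.random() < np.exp(-dE / T_m):
            _apply_copy(sigma, V, S, comx, comy, comz, bbmin, bbmax,
                        x0, x1, x2, a, b, dS_a, dS_b)
            accepted += 1
    return accepted


@njit(cache=True)
def forced_acceptance(dH, T_m, n):
    """Apply the Metropolis acceptance rule n times at a fixed energy change."""
    acc = 0
    for _ in range(n):
        if dH <= 0.0 or np.random.random() < np.exp(-dH / T_m):
            acc += 1
    return acc


@njit(cache=True)
def audit_stats(sigma, n_ids):
    """Recompute per-cell volume, face-count surface and center-of-mass sums."""
    L0, L1, L2 = sigma.shape
    V = np.zeros(n_ids, dtype=np.int64)
    S = np.zeros(n_ids, dtype=np.int64)
    sx = np.zeros(n_ids, dtype=np.float64)
    sy = np.zeros(n_ids, dtype=np.float64)
    sz = np.zeros(n_ids, dtype=np.float64)
    for i in range(L0):
        for j in range(L1):
            for k in range(L2):
                a = sigma[i, j, k]
                V[a] += 1
                sx[a] += i
                sy[a] += j
                sz[a] += k
                for o in range(6):
                    y0 = i + _FACES[o, 0]
                    y1 = j + _FACES[o, 1]
                    y2 = k + _FACES[o, 2]
                    if (y0 < 0 or y0 >= L0 or y1 < 0 or y1 >= L1
                            or y2 < 0 or y2 >= L2):
                        continue
                    if sigma[y0, y1, y2] != a:
                        S[a] += 1
    return V, S, sx, sy, sz


@njit(cache=True)
def contact_energy(sigma, ctype, offsets, J):
    """Total contact energy; each unordered heterocell pair counted once."""
    L0, L1, L2 = sigma.shape
    E = 0.0
    for i in range(L0):
        for j in range(L1):
            for k in range(L2):
                a = sigma[i, j, k]
                ta = ctype[a]
                for o in range(offsets.shape[0]):
                    y0 = i + offsets[o, 0]
                    y1 = j + offsets[o, 1]
                    y2 = k + offsets[o, 2]
                    if (y0 < 0 or y0 >= L0 or y1 < 0 or y1 >= L1
                            or y2 < 0 or y2 >= L2):
                        continue
                    b = sigma[y0, y1, y2]
                    if b != a:
                        E += J[ta, ctype[b]]
    return 0.5 * E


@njit(cache=True, fastmath=True)
def substrate_substeps(c, f, cbuf, n_sub, D_c, S_prod):
    """n_sub forward-Euler substeps of the substrate field:

      c <- c + D_c dt lap(c) + S_prod dt f (1-c) Theta(1-c),  dt = 1/n_sub,

    clamped to [0, 1] each substep.  TM density f is frozen for the MCS.
    The Laplacian uses edge-clamped (mirror-ghost) indexing, which realizes
    zero-normal-gradient (no-flux) boundaries and conserves mass exactly.
    Returns the buffer holding the final state.
    """
    L0, L1, L2 = c.shape
    dt = 1.0 / n_sub
    ac = D_c * dt
    ap = S_prod * dt
    for _ in range(n_sub):
        for i in range(L0):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < L0 - 1 else L0 - 1
            for j in range(L1):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < L1 - 1 else L1 - 1
                for k in range(L2):
                    km = k - 1 if k > 0 else 0
                    kp = k + 1 if k < L2 - 1 else L2 - 1
                    cc = c[i, j, k]
                    lap = (c[im, j, k] + c[ip, j, k] + c[i, jm, k]
                           + c[i, jp, k] + c[i, j, km] + c[i, j, kp]
                           - 6.0 * cc)
                    w = 1.0 - cc
                    if w < 0.0:
                        w = 0.0
                    cn = cc + ac * lap + ap * f[i, j, k] * w
                    if cn < 0.0:
                        cn = 0.0
                    elif cn > 1.0:
                        cn = 1.0
                    cbuf[i, j, k] = cn
        c, cbuf = cbuf, c
    return c


@njit(cache=True, fastmath=True)
def mde_tm_substeps(m, f, mbuf, n_sub, D_m, delta):
    """n_sub forward-Euler substeps of MDE diffusion and TM degradation:

      m <- m + D_m dt lap(m)          (no-flux boundaries)
      f <- f (1 - delta m dt)         (clamped at 0)

    with dt = 1/n_sub, both terms from start-of-substep values.  Returns the
    buffer holding the final m.
    """
    L0, L1, L2 = m.shape
    dt = 1.0 / n_sub
    am = D_m * dt
    ad = delta * dt
    for _ in range(n_sub):
        for i in range(L0):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < L0 - 1 else L0 - 1
            for j in range(L1):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < L1 - 1 else L1 - 1
                for k in range(L2):
                    km = k - 1 if k > 0 else 0
                    kp = k + 1 if k < L2 - 1 else L2 - 1
                    mm = m[i, j, k]
                    lapm = (m[im, j, k] + m[ip, j, k] + m[i, jm, k]
                            + m[i, jp, k] + m[i, j, km] + m[i, j, kp]
                            - 6.0 * mm)
                    mbuf[i, j, k] = mm + am * lapm
                    fn = f[i, j, k] * (1.0 - ad * mm)
                    if fn < 0.0:
                        fn = 0.0
                    f[i, j, k] = fn
        m, mbuf = mbuf, m
    return m


@njit(cache=True)
def relabel_halfspace(sigma, cell_id, new_id, b0, b1, b2, e0, e1, e2,
                      cx, cy, cz, n0, n1, n2):
    """Relabel the cell's voxels on the (x - com) . n >= 0 side of the
    division plane to new_id; returns the number moved."""
    moved = 0
    for i in range(b0, e0 + 1):
        for j in range(b1, e1 + 1):
            for k in range(b2, e2 + 1):
                if sigma[i, j, k] != cell_id:
                    continue
                if (i - cx) * n0 + (j - cy) * n1 + (k - cz) * n2 >= 0.0:
                    sigma[i, j, k] = new_id
                    moved += 1
    return moved


@njit(cache=True)
def relabel_all(sigma, cell_id, new_id, b0, b1, b2, e0, e1, e2):
    for i in range(b0, e0 + 1):
        for j in range(b1, e1 + 1):
            for k in range(b2, e2 + 1):
                if sigma[i, j, k] == cell_id:
                    sigma[i, j, k] = new_id


@njit(cache=True)
def cell_stats_in_box(sigma, cell_id, b0, b1, b2, e0, e1, e2):
    """Exact V, S, com sums and bounding box of one cell inside a known box."""
    L0, L1, L2 = sigma.shape
    V = 0
    S = 0
    sx = 0.0
    sy = 0.0
    sz = 0.0
    mn0 = L0
    mn1 = L1
    mn2 = L2
    mx0 = -1
    mx1 = -1
    mx2 = -1
    for i in range(b0, e0 + 1):
        for j in range(b1, e1 + 1):
            for k in range(b2, e2 + 1):
                if sigma[i, j, k] != cell_id:
                    continue
                V += 1
                sx += i
                sy += j
                sz += k
                if i < mn0:
                    mn0 = i
                if j < mn1:
                    mn1 = j
                if k < mn2:
                    mn2 = k
                if i > mx0:
                    mx0 = i
                if j > mx1:
                    mx1 = j
                if k > mx2:
                    mx2 = k
                for o in range(6):
                    y0 = i + _FACES[o, 0]
                    y1 = j + _FACES[o, 1]
                    y2 = k + _FACES[o, 2]
                    if (y0 < 0 or y0 >= L0 or y1 < 0 or y1 >= L1
                            or y2 < 0 or y2 >= L2):
                        continue
                    if sigma[y0, y1, y2] != cell_id:
                        S += 1
    return V, S, sx, sy, sz, mn0, mn1, mn2, mx0, mx1, mx2
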