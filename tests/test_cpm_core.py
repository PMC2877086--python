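"""Engine correctness: neighborhood, energies, local-vs-global dH, Metropolis
acceptance law, volume ledger, initial condition, determinism."""

import numpy as np
import pytest

import gghtumor as gt
from gghtumor import _kernels
from gghtumor.cpm_core import (TM_ID, TUMOR_TYPE, _sweep, build_neighbor_table,
                               contact_matrix, lattice_from_sigma)
from conftest import (OFFSETS4, brute_force_contact,
                      brute_force_effective_energy, random_lattice)


# ----------------------------------------------------------------------
# Neighborhood
# ----------------------------------------------------------------------
class TestNeighborTable:
    def test_fourth_order_has_32_offsets_in_shells(self):
        nb = build_neighbor_table(4)
        assert nb.count == 32
        d2 = np.sum(nb.offsets ** 2, axis=1)
        shells = {1: 6, 2: 12, 3: 8, 4: 6}
        for dist2, n in shells.items():
            assert np.sum(d2 == dist2) == n

    def test_table_symmetric_under_negation(self):
        nb = build_neighbor_table(4)
        offs = {tuple(o) for o in nb.offsets}
        assert offs == {tuple(-o) for o in nb.offsets}

    @pytest.mark.parametrize("order,count", [(1, 6), (2, 18), (3, 26)])
    def test_lower_orders(self, order, count):
        assert build_neighbor_table(order).count == count


# ----------------------------------------------------------------------
# Initial condition
# ----------------------------------------------------------------------
class TestInitialState:
    def test_seed_block_voxel_counts(self):
        cfg = gt.SimulationConfig(lattice_size=20, k=0.05)
        lat, _ = gt.build_initial_state(cfg)
        assert lat.n_tumor_cells == 8
        assert int(np.sum(lat.tumor_mask())) == 8 * 27
        assert lat.V[TM_ID] == 20 ** 3 - 216
        for cid in lat.tumor_ids():
            assert lat.V[cid] == 27
            assert lat.Vt[cid] == 27.0
            assert lat.St[cid] == pytest.approx(54.0)

    def test_smallest_legal_domain_centered(self):
        cfg = gt.SimulationConfig(lattice_size=8, k=0.05)
        lat, _ = gt.build_initial_state(cfg)
        occ = np.nonzero(lat.tumor_mask())
        for ax in range(3):
            assert occ[ax].min() == 1 and occ[ax].max() == 6

    def test_volume_ledger_sums_to_L_cubed(self):
        cfg = gt.SimulationConfig(lattice_size=11, k=0.05)
        lat, _ = gt.build_initial_state(cfg)
        n = lat.next_id
        assert int(lat.V[:n].sum()) == 11 ** 3
        lat.audit()

    def test_too_small_domain_rejected(self):
        with pytest.raises(gt.ConfigError):
            gt.SimulationConfig(lattice_size=5, k=0.05)


# ----------------------------------------------------------------------
# Energies
# ----------------------------------------------------------------------
class TestContactEnergy:
    def test_single_cell_filling_lattice_is_zero(self, neighbor_table):
        sigma = np.full((6, 6, 6), 2, dtype=np.int32)
        lat = lattice_from_sigma(sigma)
        cfg = gt.SimulationConfig(lattice_size=8, k=0.05)
        assert gt.contact_energy_total(lat, contact_matrix(cfg),
                                       neighbor_table) == 0.0

    def test_two_adjacent_single_voxel_cells_match_brute_force(
            self, neighbor_table):
        sigma = np.full((6, 6, 6), TM_ID, dtype=np.int32)
        sigma[2, 2, 2] = 2
        sigma[2, 2, 3] = 3
        lat = lattice_from_sigma(sigma)
        cfg = gt.SimulationConfig(lattice_size=8, k=0.05,
                                  J_tumor_tumor=16.0, J_tumor_tm=8.0)
        J = {(1, 1): 16.0, (1, 0): 8.0, (0, 1): 8.0, (0, 0): 0.0}
        expected = brute_force_contact(
            sigma, lambda cid: 0 if cid == TM_ID else 1, J)
        got = gt.contact_energy_total(lat, contact_matrix(cfg), neighbor_table)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_doubling_J_doubles_total(self, neighbor_table):
        rng = np.random.default_rng(7)
        lat, _, _ = random_lattice(rng)
        cfg = gt.SimulationConfig(lattice_size=8, k=0.05)
        e1 = gt.contact_energy_total(lat, contact_matrix(cfg), neighbor_table)
        e2 = gt.contact_energy_total(lat, 2.0 * contact_matrix(cfg),
                                     neighbor_table)
        assert e2 == pytest.approx(2.0 * e1, rel=1e-12)

    def test_invariant_under_cell_relabeling(self, neighbor_table):
        rng = np.random.default_rng(11)
        lat, Vt, St = random_lattice(rng)
        cfg = gt.SimulationConfig(lattice_size=8, k=0.05)
        sigma2 = lat.sigma.copy()
        # swap two tumor ids; only types matter for J
        sigma2[lat.sigma == 2], sigma2[lat.sigma == 3] = 3, 2
        lat2 = lattice_from_sigma(sigma2)
        e1 = gt.contact_energy_total(lat, contact_matrix(cfg), neighbor_table)
        e2 = gt.contact_energy_total(lat2, contact_matrix(cfg), neighbor_table)
        assert e1 == pytest.approx(e2, rel=1e-12)


class TestEffectiveEnergy:
    def test_on_target_cells_leave_only_contact_term(self, neighbor_table):
        sigma = np.full((6, 6, 6), TM_ID, dtype=np.int32)
        sigma[2:4, 2:4, 2:4] = 2
        lat = lattice_from_sigma(sigma)  # Vt=V, St=S by default
        cfg = gt.SimulationConfig(lattice_size=8, k=0.05)
        contact = gt.contact_energy_total(lat, contact_matrix(cfg),
                                          neighbor_table)
        assert gt.effective_energy(lat, cfg) == pytest.approx(contact)

    def test_volume_and_surface_penalty_arithmetic(self):
        # lambda_V (V - V_t)^2 = 20 * 1^2 and lambda_S (S - S_t)^2 = 0.4 * 4
        sigma = np.full((8, 8, 8), TM_ID, dtype=np.int32)
        sigma[2:5, 2:5, 2:5] = 2
        sigma[5, 2, 2] = 2  # V = 28 (one over target), S = 58 (two over)
        lat = lattice_from_sigma(sigma, Vt={2: 27.0}, St={2: 56.0})
        assert lat.V[2] == 28 and lat.S[2] == 58
        cfg = gt.SimulationConfig(lattice_size=8, k=0.05, J_tumor_tumor=4.0)
        contact = gt.contact_energy_total(lat, contact_matrix(cfg),
                                          build_neighbor_table(4))
        expected = contact + 20.0 * 1.0 + 0.4 * 4.0
        assert gt.effective_energy(lat, cfg) == pytest.approx(expected)

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(3)
        lat, Vt, St = random_lattice(rng)
        cfg = gt.SimulationConfig(lattice_size=8, k=0.05)
        expected = brute_force_effective_energy(lat.sigma, cfg, Vt, St)
        assert gt.effective_energy(lat, cfg) == pytest.approx(expected,
                                                              rel=1e-12)


# ----------------------------------------------------------------------
# Local dH vs global recomputation
# ----------------------------------------------------------------------
class TestDeltaH:
    def test_local_equals_global_on_random_attempts(self):
        rng = np.random.default_rng(42)
        cfg = gt.SimulationConfig(lattice_size=8, k=0.05)
        checked = 0
        for rep in range(10):
            lat, Vt, St = random_lattice(rng, L=6, n_cells=3, seed=rep)
            nb = build_neighbor_table(4)
            while checked < (rep + 1) * 10:
                x = tuple(rng.integers(0, 6, size=3))
                off = OFFSETS4[rng.integers(0, len(OFFSETS4))]
                y = tuple(np.array(x) + off)
                if any(c < 0 or c >= 6 for c in y):
                    continue
                cand = int(lat.sigma[y])
                if cand == lat.sigma[x]:
                    continue
                dH = gt.delta_H(lat, x, cand, cfg, nb)
                e_before = gt.effective_energy(lat, cfg, nb)
                sigma_after = lat.sigma.copy()
                sigma_after[x] = cand
                vt_all = dict(Vt)
                st_all = dict(St)
                e_after = brute_force_effective_energy(sigma_after, cfg,
                                                       vt_all, st_all)
                assert dH == pytest.approx(e_after - e_before, abs=1e-9)
                checked += 1
        assert checked == 100

    def test_reversing_a_copy_negates_dH(self):
        rng = np.random.default_rng(5)
        lat, _, _ = random_lattice(rng, L=6)
        cfg = gt.SimulationConfig(lattice_size=8, k=0.05)
        nb = build_neighbor_table(4)
        x = (2, 2, 2)
        old = int(lat.sigma[x])
        cand = 2 if old != 2 else TM_ID
        dH1 = gt.delta_H(lat, x, cand, cfg, nb)
        # rebuild the post-copy lattice (same targets) and reverse the copy
        sigma2 = lat.sigma.copy()
        sigma2[x] = cand
        Vt = {c: float(lat.Vt[c]) for c in np.unique(sigma2) if c != TM_ID}
        St = {c: float(lat.St[c]) for c in np.unique(sigma2) if c != TM_ID}
        lat2 = lattice_from_sigma(sigma2, Vt=Vt, St=St)
        dH2 = gt.delta_H(lat2, x, old, cfg, nb)
        assert dH2 == pytest.approx(-dH1, abs=1e-9)

    def test_noop_candidate_rejected(self):
        cfg = gt.SimulationConfig(lattice_size=8, k=0.05)
        lat, _ = gt.build_initial_state(cfg)
        with pytest.raises(ValueError):
            gt.delta_H(lat, (0, 0, 0), TM_ID, cfg)


# ----------------------------------------------------------------------
# Metropolis dynamics
# ----------------------------------------------------------------------
class TestMetropolis:
    def test_acceptance_law_at_forced_dH(self):
        # P(accept) = exp(-dH/T_m): at dH = T_m = 60 the rate is 1/e
        _kernels.seed_rng(123)
        n = 100_000
        p = np.exp(-1.0)
        acc = _kernels.forced_acceptance(60.0, 60.0, n)
        se = np.sqrt(p * (1 - p) * n)
        assert abs(acc - p * n) < 3 * se

    def test_always_accept_nonpositive_dH(self):
        _kernels.seed_rng(1)
        assert _kernels.forced_acceptance(0.0, 60.0, 1000) == 1000
        assert _kernels.forced_acceptance(-5.0, 60.0, 1000) == 1000

    def test_forbidden_move_sentinel_rejected(self):
        _kernels.seed_rng(1)
        assert _kernels.forced_acceptance(np.inf, 60.0, 1000) == 0

    def test_volume_conservation_and_ledger_after_sweeps(self):
        cfg = gt.SimulationConfig(lattice_size=12, k=0.05, seed=9)
        lat, _ = gt.build_initial_state(cfg)
        nb = build_neighbor_table(4)
        for _ in range(5):
            _sweep(lat, cfg, nb, cfg.n_sites)
        lat.audit()  # V, S, com ledger still exact; sum V == L^3

    def test_one_mcs_is_L_cubed_attempts(self):
        cfg = gt.SimulationConfig(lattice_size=20, k=0.05, seed=2,
                                  snapshot_interval=1)
        lat, flds = gt.build_initial_state(cfg)
        # attempts are not directly observable; the MCS definition is in the
        # sweep call: verify the engine draws exactly L^3 attempts by
        # checking the kernel honors the requested budget
        nb = build_neighbor_table(4)
        accepted = _sweep(lat, cfg, nb, 20 ** 3)
        assert 0 <= accepted <= 20 ** 3

    def test_same_seed_bit_identical_trajectories(self):
        cfg = gt.SimulationConfig(lattice_size=14, k=0.1, seed=31,
                                  snapshot_interval=10)
        runs = []
        for _ in range(2):
            lat, flds = gt.build_initial_state(cfg)
            gt.run_mcs(lat, flds, cfg, 30, record=False)
            runs.append((lat.sigma.copy(), flds.c.copy()))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert np.array_equal(runs[0][1], runs[1][1])

    def test_zero_mcs_leaves_state_unchanged(self):
        cfg = gt.SimulationConfig(lattice_size=10, k=0.05, seed=4)
        lat, flds = gt.build_initial_state(cfg)
        before = lat.sigma.copy()
        gt.run_mcs(lat, flds, cfg, 0)
        assert np.array_equal(before, lat.sigma)


# ----------------------------------------------------------------------
# Surface tension
# ----------------------------------------------------------------------
class TestSurfaceTension:
    @pytest.mark.parametrize("J_ttm,J_tt,gamma", [
        (8.0, 4.0, 6.0),
        (8.0, 16.0, 0.0),
        (5.0, 10.0, 0.0),   # J(t,t) = 2 J(t,TM) is the symmetry point
    ])
    def test_gamma_formula(self, J_ttm, J_tt, gamma):
        assert gt.surface_tension(J_ttm, J_tt) == pytest.approx(gamma)

    def test_config_gamma_roundtrip(self):
        cfg = gt.SimulationConfig(k=0.05).with_gamma(2.0)
        assert cfg.gamma == pytest.approx(2.0)
        assert cfg.J_tumor_tumor == pytest.approx(12.0)


# ----------------------------------------------------------------------
# Cell sorting sanity
# ----------------------------------------------------------------------
def heterotypic_boundary_area(lat):
    tumor = lat.tumor_mask().astype(np.int8)
    area = 0
    for ax in range(3):
        area += int(np.sum(np.abs(np.diff(tumor, axis=ax))))
    return area


def test_positive_surface_tension_rounds_up_fragmented_cells():
    """With gamma > 0 and no growth, scattered tumor material compacts:
    tumor-TM boundary area decreases in trend over 10^3 MCS (5 seeds)."""
    cfg = gt.SimulationConfig(lattice_size=16, k=0.05, J_tumor_tumor=4.0,
                              J_tumor_tm=8.0)
    nb = build_neighbor_table(4)
    drops = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        sigma = np.full((16, 16, 16), TM_ID, dtype=np.int32)
        for cid in (2, 3):
            pts = rng.integers(3, 13, size=(60, 3))
            sigma[pts[:, 0], pts[:, 1], pts[:, 2]] = cid
        Vt = {c: float(np.sum(sigma == c)) for c in (2, 3)}
        St = {c: 6.0 * Vt[c] ** (2 / 3) for c in (2, 3)}
        lat = lattice_from_sigma(sigma, seed=seed, Vt=Vt, St=St)
        a0 = heterotypic_boundary_area(lat)
        for _ in range(1000):
            _sweep(lat, cfg, nb, cfg.n_sites)
        drops.append(heterotypic_boundary_area(lat) / a0)
    drops = np.array(drops)
    assert np.mean(drops) < 0.85
    assert np.sum(drops < 1.0) >= 4
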