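import numpy as np
import pytest

import prewet.hamiltonian as ham
from prewet.bulk import (BulkMolecule, Reservoir, bulk_kink_move,
                         reptation_move, reservoir_exchange,
                         sample_ideal_walk, spin_flip_minimal)
from prewet.hamiltonian import ModelParams
from prewet.lattice import LatticeGeometry
from prewet.system import SystemState
from conftest import batch_se


def make_state(geometry, molecules=(), gas=None, chain=None):
    state = SystemState(geometry=geometry, chain=chain,
                        molecules=list(molecules), gas=gas)
    state.sync_fields()
    return state


class TestKink:
    def test_corner_molecule_kinks_preserve_validity(self, cube8, rng):
        # an L-shaped molecule has a corner whose flip is the kink move;
        # a straight molecule has none (its bond translations are all
        # additions, which fixed-length molecules reject)
        p = ModelParams(L=8, N_max=20, N_b=3)
        mol = BulkMolecule(1, [(0, 0, 0), (0, 0, 1), (0, 1, 1)])
        state = make_state(cube8, molecules=[mol])
        accepted = 0
        for _ in range(2000):
            accepted += bulk_kink_move(mol, state, p, rng)
            mol.validate(cube8, 3)
        assert accepted > 0
        state.check_consistent()

    def test_same_species_overlap_rejected(self, cube8, rng):
        p = ModelParams(L=8, N_max=20, N_b=3)
        # two parallel molecules one lattice spacing apart: kinks toward the
        # neighbour collide and must be rejected
        m1 = BulkMolecule(1, [(0, 0, 0), (0, 0, 1), (0, 0, 2)])
        m2 = BulkMolecule(1, [(1, 0, 0), (1, 0, 1), (1, 0, 2)])
        state = make_state(cube8, molecules=[m1, m2])
        for _ in range(3000):
            bulk_kink_move(m1, state, p, rng)
            bulk_kink_move(m2, state, p, rng)
        state.check_consistent()  # would fail on any overlap

    def test_cross_species_overlap_geometrically_allowed(self, cube8, rng):
        p = ModelParams(L=8, N_max=20, N_b=3, j_bulk=2.0)
        m1 = BulkMolecule(1, [(0, 0, 0), (0, 0, 1), (0, 1, 1)])
        m2 = BulkMolecule(2, [(1, 0, 0), (1, 0, 1), (1, 1, 1)])
        state = make_state(cube8, molecules=[m1, m2])
        overlapped = False
        for _ in range(5000):
            for m in (m1, m2):
                if rng.random() < 0.5:
                    bulk_kink_move(m, state, p, rng)
                else:
                    reptation_move(m, state, p, rng)
            if state.fields.s1 & state.fields.s2:
                overlapped = True
        assert overlapped  # on-site attraction makes overlap common
        state.check_consistent()


class TestReptation:
    def test_moves_preserve_length_and_connectivity(self, cube8, rng):
        p = ModelParams(L=8, N_max=20, N_b=4)
        mol = BulkMolecule(1, [(0, 0, 0), (0, 0, 1), (0, 0, 2), (0, 0, 3)])
        state = make_state(cube8, molecules=[mol])
        accepted = 0
        for _ in range(2000):
            accepted += reptation_move(mol, state, p, rng)
            mol.validate(cube8, 4)
        assert accepted > 1000  # free molecule: most slithers succeed
        state.check_consistent()

    def test_walled_in_molecule_cannot_move(self, rng):
        g = LatticeGeometry.cubic(4)
        # every other site blocked by same-species monomers: both ends of
        # the L-shaped molecule have nowhere to grow (the vacated tail is
        # never adjacent to the opposite end)
        p = ModelParams(L=4, N_max=10, N_b=3)
        mol = BulkMolecule(1, [(0, 0, 0), (0, 0, 1), (0, 1, 1)])
        state = SystemState(geometry=g, molecules=[mol])
        state.sync_fields()
        blockers = [s for s in g.sites() if s not in set(mol.sites)]
        state.fields.s1.update(blockers)
        before = list(mol.sites)
        for _ in range(200):
            assert not reptation_move(mol, state, p, rng)
        assert mol.sites == before

    def test_forward_then_reverse_can_restore(self, cube8):
        p = ModelParams(L=8, N_max=20, N_b=3)
        mol = BulkMolecule(1, [(0, 0, 0), (0, 0, 1), (0, 0, 2)])
        state = make_state(cube8, molecules=[mol])
        start = list(mol.sites)
        rng = np.random.default_rng(1)
        moved = False
        for _ in range(500):
            reptation_move(mol, state, p, rng)
            if mol.sites == start:
                moved = True
                break
        assert moved  # the original configuration is revisited
        state.check_consistent()


class TestReservoir:
    def test_printed_rates(self):
        assert Reservoir(10).rates(0) == pytest.approx((10 / 11, 1 / 11))

    def test_empty_reservoir_blocks_insertion(self):
        lam_plus, lam_minus = Reservoir(0).rates(5)
        assert lam_plus == 0.0

    @pytest.mark.parametrize("nr,ns", [(0, 0), (3, 7), (100, 1)])
    def test_rates_sum_to_one(self, nr, ns):
        assert sum(Reservoir(nr).rates(ns)) == pytest.approx(1.0)

    def test_exchange_conserves_total_and_stays_valid(self, rng):
        g = LatticeGeometry.cubic(6)
        p = ModelParams(L=6, N_max=20, N_b=3, mu_b=0.5, j_bulk=0.5)
        state = make_state(g)
        reservoirs = {1: Reservoir(30), 2: Reservoir(30)}
        for _ in range(3000):
            reservoir_exchange(state, p, reservoirs, rng)
        for sp in (1, 2):
            n_sys = sum(1 for m in state.molecules if m.species == sp)
            assert reservoirs[sp].n_reservoir + n_sys == 30
            assert reservoirs[sp].n_reservoir >= 0
        for m in state.molecules:
            m.validate(g, 3)
        state.check_consistent()

    def test_ideal_walk_has_unit_steps(self, cube8, rng):
        for _ in range(50):
            walk = sample_ideal_walk(cube8, 6, rng)
            assert len(walk) == 6
            for a, b in zip(walk, walk[1:]):
                d = cube8.displacement(a, b)
                assert sorted(map(abs, d)) == [0, 0, 1]


class TestSpinFlip:
    def test_zero_couplings_always_accept(self, rng):
        g = LatticeGeometry.cubic(3)
        state = make_state(g, gas=set())
        p = ModelParams(L=3, N_max=10, mu_b=0.0, j_bulk=0.0)
        for _ in range(200):
            assert spin_flip_minimal(state, p, rng)

    def test_isolated_site_on_with_positive_mu_always_accepted(self):
        g = LatticeGeometry.cubic(5)
        state = make_state(g, gas=set())
        p = ModelParams(L=5, N_max=10, mu_b=1.0, j_bulk=0.5)
        # delta H = -mu_b = -1 < 0: deterministic acceptance
        assert spin_flip_minimal(state, p, np.random.default_rng(0),
                                 site=(2, 2, 2))
        assert (2, 2, 2) in state.gas

    def test_independent_site_occupancy_closed_form(self, rng):
        # J_bulk = 0: occupancy is exactly e^mu / (1 + e^mu)
        g = LatticeGeometry.cubic(3)
        state = make_state(g, gas=set())
        mu = 0.8
        p = ModelParams(L=3, N_max=10, mu_b=mu, j_bulk=0.0)
        occ = []
        for sweep in range(30000):
            for _ in range(27):
                spin_flip_minimal(state, p, rng)
            if sweep >= 500:
                occ.append(len(state.gas) / 27)
        expected = np.exp(mu) / (1 + np.exp(mu))
        se = batch_se(occ)
        assert abs(np.mean(occ) - expected) < 3 * se
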