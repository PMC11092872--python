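import numpy as np
import pytest

import prewet.hamiltonian as ham
from prewet.bulk import BulkMolecule, spin_flip_minimal
from prewet.hamiltonian import ModelParams
from prewet.lattice import LatticeGeometry
from prewet.polymer import (PolymerChain, attempt_polymer_move,
                            propose_polymer_move, spanning_chain)
from prewet.system import SystemState


def make_state(geometry, chain=None, molecules=(), gas=None):
    state = SystemState(geometry=geometry, chain=chain,
                        molecules=list(molecules), gas=gas)
    state.sync_fields()
    return state


class TestParams:
    @pytest.mark.parametrize("kwargs", [
        {"N_b": 1}, {"N_max": 10, "L": 16}, {"delta": -1}, {"p_kink": 1.0},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_per_type_couplings(self):
        p = ModelParams(j_int={1: 2.0, 2: 0.0})
        assert p.j_int_for(1) == 2.0
        assert p.j_int_for(2) == 0.0
        assert p.j_int_for(99) == 0.0  # unknown types do not couple


class TestEnergyPolymer:
    def test_straight_trimer(self, cube8):
        chain = PolymerChain(sites=[(0, 0, 0), (0, 0, 1), (0, 0, 2)])
        state = make_state(cube8, chain)
        p = ModelParams(L=8, N_max=20, mu_p=0.0, v_p=1.0)
        # -(0+1)*3 + 1*2 sequential contacts
        assert ham.energy_polymer(state, p) == pytest.approx(-1.0)

    def test_square_four_mer(self, cube8):
        chain = PolymerChain(
            sites=[(0, 0, 0), (0, 0, 1), (0, 1, 1), (0, 1, 0)])
        state = make_state(cube8, chain)
        p = ModelParams(L=8, N_max=20, mu_p=0.0, v_p=1.0)
        # 3 sequential + 1 non-sequential contact
        assert ham.energy_polymer(state, p) == pytest.approx(0.0)

    def test_vanishing_couplings_give_zero(self, cube8):
        chain = PolymerChain(sites=[(0, 0, 0), (1, 0, 0), (1, 1, 0)])
        state = make_state(cube8, chain)
        p = ModelParams(L=8, N_max=20, mu_p=0.0, v_p=0.0)
        assert ham.energy_polymer(state, p) == 0.0


class TestEnergyBulk:
    def test_perfect_cross_species_overlap(self, cube8):
        sites = [(0, 0, z) for z in range(4)]
        m1 = BulkMolecule(1, list(sites))
        m2 = BulkMolecule(2, list(sites))
        state = make_state(cube8, molecules=[m1, m2])
        p = ModelParams(L=8, N_max=20, N_b=4, j_bulk=1.5, mu_b=0.0, j_nn=0.0)
        assert ham.energy_bulk(state, p) == pytest.approx(-1.5 * 4)

    def test_empty_bulk_zero(self, cube8):
        state = make_state(cube8)
        p = ModelParams(L=8, N_max=20, mu_b=3.0, j_bulk=1.0)
        assert ham.energy_bulk(state, p) == 0.0

    def test_chemical_potential_counts_molecules(self, cube8):
        m1 = BulkMolecule(1, [(0, 0, 0), (0, 0, 1)])
        m2 = BulkMolecule(1, [(4, 4, 4), (4, 4, 5)])
        state = make_state(cube8, molecules=[m1, m2])
        p = ModelParams(L=8, N_max=20, N_b=2, mu_b=0.7, j_nn=0.0)
        assert ham.energy_bulk(state, p) == pytest.approx(-1.4)

    def test_symmetrized_nn_term(self, cube8):
        # one species-1 and one species-2 monomer pair on adjacent sites
        m1 = BulkMolecule(1, [(0, 0, 0), (0, 0, 1)])
        m2 = BulkMolecule(2, [(1, 0, 0), (1, 0, 1)])
        state = make_state(cube8, molecules=[m1, m2])
        p = ModelParams(L=8, N_max=20, N_b=2, mu_b=0.0, j_nn=0.5)
        # adjacent unordered pairs: (000,001)s1s1, (100,101)s2s2,
        # (000,100) cross, (001,101) cross -> 4 pairs total
        assert ham.energy_bulk(state, p) == pytest.approx(-0.5 * 4)


class TestEnergyInteraction:
    def test_counts_shared_sites(self, cube8):
        chain = PolymerChain(sites=[(0, 0, z) for z in range(5)])
        m1 = BulkMolecule(1, [(0, 0, z) for z in range(5)])
        state = make_state(cube8, chain=chain, molecules=[m1])
        p = ModelParams(L=8, N_max=20, N_b=5, j_int=1.0)
        assert ham.energy_interaction(state, p) == pytest.approx(-5.0)

    def test_species_two_does_not_couple(self, cube8):
        chain = PolymerChain(sites=[(0, 0, z) for z in range(5)])
        m2 = BulkMolecule(2, [(0, 0, z) for z in range(5)])
        state = make_state(cube8, chain=chain, molecules=[m2])
        p = ModelParams(L=8, N_max=20, N_b=5, j_int=3.0)
        assert ham.energy_interaction(state, p) == 0.0

    def test_inert_segment_type_contributes_zero(self, cube8):
        chain = PolymerChain(sites=[(0, 0, z) for z in range(4)],
                             types=[1, 1, 2, 2])
        m1 = BulkMolecule(1, [(0, 0, z) for z in range(4)])
        state = make_state(cube8, chain=chain, molecules=[m1])
        p = ModelParams(L=8, N_max=20, N_b=4, j_int={1: 2.0, 2: 0.0})
        assert ham.energy_interaction(state, p) == pytest.approx(-4.0)


class TestEnergyDelta:
    def test_null_proposal_zero(self, cube8):
        state = make_state(cube8)
        assert ham.energy_delta(state, None, ModelParams()) == 0.0

    def test_minimal_flip_on_matches_local_formula(self):
        g = LatticeGeometry.cubic(4)
        gas = {(0, 0, 1), (0, 1, 0)}  # two neighbours of the target
        state = make_state(g, gas=gas)
        p = ModelParams(L=4, N_max=10, mu_b=0.8, j_bulk=0.3)
        assert ham.gas_flip_delta(state, p, (0, 0, 0)) == pytest.approx(
            -0.8 - 0.3 * 2)

    def test_polymer_deltas_match_full_recompute(self, rng):
        g = LatticeGeometry.cubic(5)
        chain = spanning_chain(g)
        gas = {(int(x), int(y), int(z))
               for x, y, z in rng.integers(0, 5, size=(40, 3))}
        state = make_state(g, chain=chain, gas=gas)
        p = ModelParams(L=5, N_max=30, mu_p=0.3, v_p=-0.7, mu_b=0.1,
                        j_bulk=0.4, j_int=0.9)
        checked = 0
        for _ in range(12_000):
            prop = propose_polymer_move(chain, state, p, rng)
            if prop is None:
                continue
            before = (ham.energy_polymer(state, p)
                      + ham.energy_interaction(state, p))
            local = ham.energy_delta(state, prop, p)
            from prewet.polymer import apply_proposal
            apply_proposal(chain, state, prop)
            after = (ham.energy_polymer(state, p)
                     + ham.energy_interaction(state, p))
            assert local == pytest.approx(after - before, abs=1e-12)
            checked += 1
        assert checked > 300

    def test_gas_flip_delta_matches_full_recompute(self, rng):
        g = LatticeGeometry.cubic(3)
        state = make_state(g, gas=set())
        p = ModelParams(L=3, N_max=10, mu_b=0.5, j_bulk=0.7)
        for _ in range(500):
            site = tuple(int(v) for v in rng.integers(0, 3, size=3))
            before = ham.energy_lattice_gas(state, p)
            local = ham.gas_flip_delta(state, p, site)
            if site in state.gas:
                state.gas.discard(site)
            else:
                state.gas.add(site)
            after = ham.energy_lattice_gas(state, p)
            assert local == pytest.approx(after - before, abs=1e-12)

    def test_bulk_insertion_deltas_match_full_recompute(self, cube8, rng):
        p = ModelParams(L=8, N_max=20, N_b=3, mu_b=0.4, j_bulk=0.8, j_nn=0.2,
                        j_int=1.1)
        chain = PolymerChain(sites=[(0, 0, z) for z in range(4)])
        m0 = BulkMolecule(2, [(0, 0, 0), (0, 0, 1), (0, 1, 1)])
        state = make_state(cube8, chain=chain, molecules=[m0])
        walk = [(0, 0, 0), (0, 0, 1), (0, 0, 2)]
        before = ham.energy_bulk(state, p) + ham.energy_interaction(state, p)
        delta = -p.mu_b
        for s in walk:
            delta += ham.bulk_add_delta(state, p, 1, s)
            state.fields.s1.add(s)
        state.molecules.append(BulkMolecule(1, walk))
        after = ham.energy_bulk(state, p) + ham.energy_interaction(state, p)
        assert delta == pytest.approx(after - before, abs=1e-12)


class TestInvariances:
    def test_translation_invariance(self, cube8):
        p = ModelParams(L=8, N_max=20, N_b=3, mu_p=0.2, v_p=-0.4, mu_b=0.3,
                        j_bulk=0.6, j_nn=0.1, j_int=0.8)

        def build(shift):
            w = lambda s: cube8.wrap(tuple(c + d for c, d in zip(s, shift)))
            chain = PolymerChain(sites=[w((0, 0, z)) for z in range(4)])
            m1 = BulkMolecule(1, [w((0, 0, 1)), w((0, 0, 2)), w((0, 1, 2))])
            m2 = BulkMolecule(2, [w((0, 0, 2)), w((1, 0, 2)), w((1, 0, 3))])
            return make_state(cube8, chain=chain, molecules=[m1, m2])

        e0 = ham.total_energy(build((0, 0, 0)), p)
        for shift in [(1, 0, 0), (3, 5, 7), (7, 7, 7)]:
            assert ham.total_energy(build(shift), p) == pytest.approx(e0)

    def test_chain_direction_relabeling_invariance(self, cube8):
        p = ModelParams(L=8, N_max=20, mu_p=0.1, v_p=-0.9)
        sites = [(0, 0, 0), (0, 0, 1), (0, 1, 1), (1, 1, 1)]
        e_fwd = ham.energy_polymer(make_state(cube8, PolymerChain(sites=list(sites))), p)
        e_rev = ham.energy_polymer(make_state(cube8, PolymerChain(sites=sites[::-1])), p)
        assert e_fwd == pytest.approx(e_rev)
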