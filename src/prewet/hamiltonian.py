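"""Dimensionless lattice Hamiltonians and exact local energy differences.

All energies are in units of k_BT.  The model has three pieces:

* ``H_poly = -(mu_p + v_p) * N_p + v_p * (nearest-neighbour monomer pairs)``
  where ``N_p`` is the number of polymer-occupied sites.  The ``-v_p``
  per-monomer shift cancels the bonded (sequential) contacts counted in the
  pair sum, up to an O(1) end effect, so ``v_p`` acts only on non-bonded
  contacts; positive ``v_p`` is repulsive.

* the bulk energy: ``-mu_b`` per bulk molecule, an on-site cross-species
  attraction ``-J_bulk`` per doubly occupied site, and a weak
  nearest-neighbour term ``-J_nn`` acting on total bulk occupancy.  The
  minimal (lattice-gas) bulk instead reads
  ``-mu_b * sum_i s_i - J_bulk * sum_<ij> s_i s_j``.

* the polymer-bulk coupling ``-J_int,t`` per site where bulk species 1
  co-occupies a type-``t`` monomer.  Species 2 never couples to the polymer
  directly.

Nearest-neighbour sums are computed as half the directional sum over the
six lattice directions, which equals the unordered-pair count on any
lattice with all dimensions >= 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, Iterable, Mapping, Set, Union

from .lattice import DIRECTIONS, LatticeGeometry, Site


def _as_jint_map(j_int: Union[float, Mapping[int, float]]) -> Dict[int, float]:
    if isinstance(j_int, Mapping):
        return dict(j_int)
    return {0: float(j_int)}


@dataclass
class ModelParams:
    """All lattice-model couplings and the Monte-Carlo schedule.

    Defaults follow the standard study conditions: box size ``L = 64``,
    monomer chemical potential ``mu_p = 0``, bulk molecules of ``N_b = 20``
    units, polymer length cap ``N_max = 1500`` and segment slack
    ``delta = 12``.  ``j_int`` may be a scalar (single-type polymer, type 0)
    or a mapping from monomer type to coupling.
    """

    L: int = 64
    mu_p: float = 0.0
    v_p: float = 0.0
    mu_b: float = 0.0
    N_b: int = 20
    j_bulk: float = 0.0
    j_nn: float = 0.0
    j_int: Union[float, Mapping[int, float]] = 0.0
    N_max: int = 1500
    delta: int = 12
    p_kink: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N_b < 2:
            raise ValueError("N_b must be >= 2")
        if self.N_max <= self.L:
            raise ValueError("N_max must exceed L")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not 0.0 <= self.p_kink < 1.0:
            raise ValueError("p_kink must lie in [0, 1)")
        self._jmap = _as_jint_map(self.j_int)

    def j_int_for(self, monomer_type: int) -> float:
        return self._jmap.get(monomer_type, 0.0)


def nn_occupied(site: Site, occupied, geometry: LatticeGeometry) -> int:
    """Directional count of occupied nearest neighbours of ``site``."""
    count = 0
    dims = geometry.dims
    periodic = geometry.periodic
    x, y, z = site
    for dx, dy, dz in DIRECTIONS:
        nx, ny, nz = x + dx, y + dy, z + dz
        if periodic:
            cand = (nx % dims[0], ny % dims[1], nz % dims[2])
        else:
            if not (0 <= nx < dims[0] and 0 <= ny < dims[1] and 0 <= nz < dims[2]):
                continue
            cand = (nx, ny, nz)
        if cand in occupied:
            count += 1
    return count


def pair_count(occupied, geometry: LatticeGeometry) -> float:
    """Nearest-neighbour pair count within a site collection (half-sum)."""
    total = 0
    for site in occupied:
        total += nn_occupied(site, occupied, geometry)
    return total / 2.0


def energy_polymer(state, params: ModelParams) -> float:
    """Polymer self-energy evaluated on the occupancy field."""
    poly = state.fields.poly
    n = len(poly)
    contacts = pair_count(poly, state.geometry)
    return -(params.mu_p + params.v_p) * n + params.v_p * contacts


def energy_bulk(state, params: ModelParams) -> float:
    """Two-species molecular bulk energy (chemical potential per molecule)."""
    s1, s2 = state.fields.s1, state.fields.s2
    e = -params.mu_b * len(state.molecules)
    e -= params.j_bulk * len(s1 & s2)
    if params.j_nn != 0.0:
        # symmetrized: (s1_i + s2_i)(s1_j + s2_j) per unordered pair
        weights = {}
        for site in s1:
            weights[site] = weights.get(site, 0) + 1
        for site in s2:
            weights[site] = weights.get(site, 0) + 1
        tot = 0.0
        geometry = state.geometry
        for site, w in weights.items():
            for nb in _wrapped_neighbors(site, geometry):
                tot += w * weights.get(nb, 0)
        e -= params.j_nn * tot / 2.0
    return e


def energy_lattice_gas(state, params: ModelParams) -> float:
    """Minimal single-species bulk: -mu_b * N - J_bulk * (NN pairs)."""
    gas = state.gas
    return -params.mu_b * len(gas) - params.j_bulk * pair_count(gas, state.geometry)


def energy_interaction(state, params: ModelParams) -> float:
    """Polymer coupling to bulk species 1: -J_int,t per co-occupied site."""
    s1 = state.species1_sites()
    e = 0.0
    for site, t in state.fields.poly.items():
        if site in s1:
            e -= params.j_int_for(t)
    return e


def total_energy(state, params: ModelParams) -> float:
    e = energy_polymer(state, params) + energy_interaction(state, params)
    if state.gas is not None:
        e += energy_lattice_gas(state, params)
    else:
        e += energy_bulk(state, params)
    return e


def energy_delta(state, proposal, params: ModelParams) -> float:
    """Exact local energy difference for a move proposal.

    Each proposal type knows its own local terms; a ``None`` proposal is the
    null move with zero difference.  The locals agree with the difference of
    full energies to floating-point round-off (a tested invariant).
    """
    if proposal is None:
        return 0.0
    return proposal.local_delta(state, params)


# ---------------------------------------------------------------------------
# Incremental helpers shared by the engines.  Each assumes the stated
# occupancy of the affected site and must be called in apply order.
# ---------------------------------------------------------------------------

def _wrapped_neighbors(site: Site, geometry: LatticeGeometry):
    dims = geometry.dims
    periodic = geometry.periodic
    x, y, z = site
    for dx, dy, dz in DIRECTIONS:
        nx, ny, nz = x + dx, y + dy, z + dz
        if periodic:
            yield (nx % dims[0], ny % dims[1], nz % dims[2])
        elif 0 <= nx < dims[0] and 0 <= ny < dims[1] and 0 <= nz < dims[2]:
            yield (nx, ny, nz)


def poly_add_delta(state, params: ModelParams, site: Site, mono_type: int) -> float:
    """Energy change of occupying ``site`` with a type-``mono_type`` monomer.

    ``site`` must not yet be in the polymer field.
    """
    d = -(params.mu_p + params.v_p)
    d += params.v_p * nn_occupied(site, state.fields.poly, state.geometry)
    if site in state.species1_sites():
        d -= params.j_int_for(mono_type)
    return d


def poly_remove_delta(state, params: ModelParams, site: Site, mono_type: int) -> float:
    """Energy change of vacating ``site`` (still present in the field)."""
    poly = state.fields.poly
    nn = nn_occupied(site, poly, state.geometry)
    d = (params.mu_p + params.v_p) - params.v_p * nn
    if site in state.species1_sites():
        d += params.j_int_for(mono_type)
    return d


def bulk_add_delta(state, params: ModelParams, species: int, site: Site) -> float:
    """Energy change of adding one species-``species`` bulk monomer at ``site``.

    Excludes the per-molecule ``-mu_b`` term, which the caller adds once per
    inserted molecule.  ``site`` must not yet be in its species field.
    """
    s1, s2 = state.fields.s1, state.fields.s2
    other = s2 if species == 1 else s1
    d = 0.0
    if site in other:
        d -= params.j_bulk
    if params.j_nn != 0.0:
        geometry = state.geometry
        tot = 0
        for nb in _wrapped_neighbors(site, geometry):
            tot += (nb in s1) + (nb in s2)
        d -= params.j_nn * tot
    if species == 1:
        t = state.fields.poly.get(site)
        if t is not None:
            d -= params.j_int_for(t)
    return d


def bulk_remove_delta(state, params: ModelParams, species: int, site: Site) -> float:
    """Energy change of removing one bulk monomer (site still in its field)."""
    s1, s2 = state.fields.s1, state.fields.s2
    other = s2 if species == 1 else s1
    d = 0.0
    if site in other:
        d += params.j_bulk
    if params.j_nn != 0.0:
        tot = 0
        for nb in _wrapped_neighbors(site, state.geometry):
            tot += (nb in s1) + (nb in s2)
        d += params.j_nn * tot
    if species == 1:
        t = state.fields.poly.get(site)
        if t is not None:
            d += params.j_int_for(t)
    return d


def gas_flip_delta(state, params: ModelParams, site: Site) -> float:
    """Energy change of flipping the minimal-bulk spin at ``site``."""
    gas = state.gas
    occ = site in gas
    nn = nn_occupied(site, gas, state.geometry)
    t = state.fields.poly.get(site)
    d = -params.mu_b - params.j_bulk * nn
    if t is not None:
        d -= params.j_int_for(t)
    return -d if occ else d
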