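"""Monte-Carlo engine for the bulk fluid.

Two variants are provided:

* the full two-species fluid of short chains of fixed length ``N_b``
  (default 20): kink moves analogous to the long polymer's, reptation
  (slithering-snake) moves, and grand-canonical exchange with an ideal
  reservoir at rates ``lambda+ = N_r / (N_r + N_s + 1)`` and
  ``lambda- = (N_s + 1) / (N_r + N_s + 1)``;

* the minimal single-species lattice gas: single-site spin flips with
  Metropolis acceptance.

Molecules of the same species are mutually self-avoiding; different
species may share a site (that is where the on-site ``J_bulk`` attraction
acts) and both may share a site with the polymer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from . import hamiltonian as ham
from .hamiltonian import ModelParams
from .lattice import DIRECTIONS, LatticeGeometry, Site
from .polymer import classify_move, orthogonal_directions


@dataclass
class BulkMolecule:
    """A short chain of exactly ``N_b`` nearest-neighbour sites."""

    species: int
    sites: List[Site]

    def validate(self, geometry: LatticeGeometry, N_b: int) -> None:
        if len(self.sites) != N_b:
            raise ValueError(f"molecule length {len(self.sites)} != N_b {N_b}")
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("molecule self-overlap")
        for a, b in zip(self.sites, self.sites[1:]):
            if sorted(map(abs, geometry.displacement(a, b))) != [0, 0, 1]:
                raise ValueError(f"non-unit bond {a} -> {b}")


@dataclass
class Reservoir:
    """Ideal (non-interacting) particle reservoir for one species."""

    n_reservoir: int

    def rates(self, n_system: int) -> Tuple[float, float]:
        """(lambda+, lambda-) for the current system molecule count."""
        tot = self.n_reservoir + n_system + 1
        return self.n_reservoir / tot, (n_system + 1) / tot


def _species_set(state, species: int) -> set:
    return state.fields.s1 if species == 1 else state.fields.s2


# ---------------------------------------------------------------------------
# Kink
# ---------------------------------------------------------------------------

def bulk_kink_move(molecule: BulkMolecule, state, params: ModelParams,
                   rng: np.random.Generator) -> bool:
    """One kink attempt on a bulk molecule; True if accepted.

    Uses the same bond-translation classification as the long polymer;
    addition/removal classes are rejected outright because molecule length
    is fixed.  Kink proposals are symmetric (Hastings factor 1).
    """
    geometry = state.geometry
    nb = len(molecule.sites) - 1
    j = int(rng.integers(nb))
    b, c = molecule.sites[j], molecule.sites[j + 1]
    bond = geometry.displacement(b, c)
    direction = orthogonal_directions(bond)[int(rng.integers(4))]
    # reuse the polymer classification on a throwaway unpinned view
    from .polymer import PolymerChain
    view = PolymerChain(sites=molecule.sites)
    kind = classify_move(view, j, direction, geometry)
    if kind != "kink":
        return False
    tb = geometry.wrap((b[0] + direction[0], b[1] + direction[1], b[2] + direction[2]))
    tc = geometry.wrap((c[0] + direction[0], c[1] + direction[1], c[2] + direction[2]))
    prev_flank = molecule.sites[j - 1] if j >= 1 else None
    if prev_flank is not None and prev_flank in (tb, tc):
        moved, target = j, tc
    else:
        moved, target = j + 1, tb
    occ = _species_set(state, molecule.species)
    if target in occ:
        return False
    old = molecule.sites[moved]
    delta = ham.bulk_remove_delta(state, params, molecule.species, old)
    occ.discard(old)
    delta += ham.bulk_add_delta(state, params, molecule.species, target)
    if delta <= 0.0 or rng.random() < np.exp(-delta):
        occ.add(target)
        molecule.sites[moved] = target
        return True
    occ.add(old)
    return False


# ---------------------------------------------------------------------------
# Reptation
# ---------------------------------------------------------------------------

def reptation_move(molecule: BulkMolecule, state, params: ModelParams,
                   rng: np.random.Generator) -> bool:
    """One slithering-snake attempt; True if accepted.

    A monomer is removed from one end (chosen uniformly) and re-attached at
    a uniformly chosen free site adjacent to the other end.  The Hastings
    factor is the ratio of free-site counts at the two ends, evaluated on
    the occupancy with the sliding tail removed.
    """
    geometry = state.geometry
    occ = _species_set(state, molecule.species)
    remove_head = bool(rng.integers(2))
    if remove_head:
        tail, pivot = molecule.sites[-1], molecule.sites[0]
        rev_pivot = molecule.sites[-2]
    else:
        tail, pivot = molecule.sites[0], molecule.sites[-1]
        rev_pivot = molecule.sites[1]
    base = occ - {tail}
    candidates = [s for s in _wrapped_nbrs(pivot, geometry) if s not in base]
    if not candidates:
        return False
    target = candidates[int(rng.integers(len(candidates)))]
    k_fwd = len(candidates)
    k_rev = sum(1 for s in _wrapped_nbrs(rev_pivot, geometry) if s not in base)
    delta = ham.bulk_remove_delta(state, params, molecule.species, tail)
    occ.discard(tail)
    delta += ham.bulk_add_delta(state, params, molecule.species, target)
    acc = (k_fwd / k_rev) * np.exp(-delta)
    if acc >= 1.0 or rng.random() < acc:
        occ.add(target)
        if remove_head:
            molecule.sites.pop()
            molecule.sites.insert(0, target)
        else:
            molecule.sites.pop(0)
            molecule.sites.append(target)
        return True
    occ.add(tail)
    return False


def _wrapped_nbrs(site: Site, geometry: LatticeGeometry):
    dims = geometry.dims
    x, y, z = site
    for dx, dy, dz in DIRECTIONS:
        yield ((x + dx) % dims[0], (y + dy) % dims[1], (z + dz) % dims[2])


# ---------------------------------------------------------------------------
# Reservoir exchange
# ---------------------------------------------------------------------------

def sample_ideal_walk(geometry: LatticeGeometry, n: int,
                      rng: np.random.Generator) -> List[Site]:
    """A uniformly sampled ideal (non-self-avoiding) walk of ``n`` sites."""
    lx, ly, lz = geometry.dims
    cur = (int(rng.integers(lx)), int(rng.integers(ly)), int(rng.integers(lz)))
    sites = [cur]
    for _ in range(n - 1):
        d = DIRECTIONS[int(rng.integers(6))]
        cur = geometry.wrap((cur[0] + d[0], cur[1] + d[1], cur[2] + d[2]))
        sites.append(cur)
    return sites


def reservoir_exchange(state, params: ModelParams, reservoirs,
                       rng: np.random.Generator,
                       species: Optional[int] = None) -> bool:
    """One insertion-or-removal exchange attempt; True if accepted.

    The species is chosen uniformly unless given.  Inserted molecules take
    fresh configurations drawn from the reservoir's ideal-chain ensemble;
    any resulting same-species overlap (including self-overlap) is a
    rejection.  ``N_r + N_s`` per species is conserved by construction.
    """
    if species is None:
        species = 1 + int(rng.integers(len(reservoirs)))
    res = reservoirs[species]
    mols = [m for m in state.molecules if m.species == species]
    n_s = len(mols)
    lam_plus, _ = res.rates(n_s)
    occ = _species_set(state, species)
    if rng.random() < lam_plus:
        walk = sample_ideal_walk(state.geometry, params.N_b, rng)
        if len(set(walk)) != len(walk) or any(s in occ for s in walk):
            return False
        delta = -params.mu_b
        added = []
        for s in walk:
            delta += ham.bulk_add_delta(state, params, species, s)
            occ.add(s)
            added.append(s)
        if delta <= 0.0 or rng.random() < np.exp(-delta):
            state.molecules.append(BulkMolecule(species, walk))
            res.n_reservoir -= 1
            return True
        for s in added:
            occ.discard(s)
        return False
    if n_s == 0:
        return False
    mol = mols[int(rng.integers(n_s))]
    delta = params.mu_b
    removed = []
    for s in mol.sites:
        delta += ham.bulk_remove_delta(state, params, species, s)
        occ.discard(s)
        removed.append(s)
    if delta <= 0.0 or rng.random() < np.exp(-delta):
        state.molecules.remove(mol)
        res.n_reservoir += 1
        return True
    for s in removed:
        occ.add(s)
    return False


# ---------------------------------------------------------------------------
# Minimal lattice gas
# ---------------------------------------------------------------------------

def spin_flip_minimal(state, params: ModelParams,
                      rng: np.random.Generator,
                      site: Optional[Site] = None) -> bool:
    """One Metropolis spin flip of the minimal bulk; True if accepted."""
    if site is None:
        lx, ly, lz = state.geometry.dims
        site = (int(rng.integers(lx)), int(rng.integers(ly)), int(rng.integers(lz)))
    delta = ham.gas_flip_delta(state, params, site)
    if delta <= 0.0 or rng.random() < np.exp(-delta):
        if site in state.gas:
            state.gas.discard(site)
        else:
            state.gas.add(site)
        return True
    return False
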