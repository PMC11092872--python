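"""Exact small-system references for validating the samplers.

Exhaustive enumeration of (i) self-avoiding pinned lattice walks under the
polymer Hamiltonian and (ii) lattice-gas states under the minimal bulk
Hamiltonian.  Both use the same energy functions as the Monte-Carlo
engines, so a discrepancy between enumeration and sampling isolates a
sampler bug rather than an energy bug.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import hamiltonian as ham
from .hamiltonian import ModelParams
from .lattice import LatticeGeometry, Site, neighbors
from .system import SystemState


class EnumerationTooLarge(RuntimeError):
    """The requested state space exceeds the declared cap."""


@dataclass
class EnumerationResult:
    """Partition function and exact Boltzmann averages."""

    Z: float
    means: Dict[str, float]
    n_states: int
    states: Optional[list] = None  # (sites/occupancy, energy) when requested


def enumerate_pinned_walks(geometry: LatticeGeometry, start: Site, end: Site,
                           N_max: int, params: ModelParams, n_min: int = 2,
                           cap: int = 10_000_000, keep_states: bool = False,
                           displacement: Optional[Site] = None
                           ) -> EnumerationResult:
    """All self-avoiding walks from ``start`` to ``end`` with n_min <= N < N_max.

    ``N`` is the number of monomers.  Returns exact averages of monomer
    count, nearest-neighbour contact count (non-bonded pairs excluded by
    the Hamiltonian's per-monomer shift, but the raw pair count is
    reported) and energy under the polymer Hamiltonian.

    On a periodic lattice the local bond-translation moves conserve the
    chain's net unwrapped displacement (its winding class), so a sampler
    pinned at two sites explores exactly one class.  Pass ``displacement``
    (the net unwrapped end-minus-start vector, e.g. the minimal-image
    displacement for a non-winding chain) to restrict the enumeration to
    that class; ``None`` enumerates every class.
    """
    walks: List[List[Site]] = []
    path = [start]
    occupied = {start}
    offset = [0, 0, 0]  # unwrapped displacement accumulated along the path

    def dfs() -> None:
        if len(walks) > cap:
            raise EnumerationTooLarge(f"more than {cap} states")
        cur = path[-1]
        if cur == end and n_min <= len(path) < N_max and (
                displacement is None or tuple(offset) == tuple(displacement)):
            walks.append(list(path))
        if len(path) + 1 >= N_max:
            return
        for nb in neighbors(cur, geometry):
            if nb in occupied:
                continue
            d = geometry.displacement(cur, nb)
            path.append(nb)
            occupied.add(nb)
            for ax in range(3):
                offset[ax] += d[ax]
            dfs()
            path.pop()
            occupied.discard(nb)
            for ax in range(3):
                offset[ax] -= d[ax]

    dfs()
    if not walks:
        raise ValueError("no admissible walks between the pinned endpoints")

    Z = 0.0
    acc = {"N_p": 0.0, "contacts": 0.0, "energy": 0.0}
    states = [] if keep_states else None
    for sites in walks:
        n = len(sites)
        contacts = ham.pair_count(set(sites), geometry)
        e = -(params.mu_p + params.v_p) * n + params.v_p * contacts
        w = np.exp(-e)
        Z += w
        acc["N_p"] += w * n
        acc["contacts"] += w * contacts
        acc["energy"] += w * e
        if keep_states:
            states.append((tuple(sites), e))
    means = {k: v / Z for k, v in acc.items()}
    return EnumerationResult(Z=Z, means=means, n_states=len(walks), states=states)


def enumerate_lattice_gas(geometry: LatticeGeometry, params: ModelParams,
                          poly_sites: Tuple[Site, ...] = (),
                          keep_states: bool = False) -> EnumerationResult:
    """Sum over all 2^n lattice-gas states (n <= 24 sites).

    ``poly_sites`` optionally marks polymer-occupied sites so the
    polymer-bulk coupling ``-J_int`` enters the enumerated energies.
    """
    sites = list(geometry.sites())
    n = len(sites)
    if n > 24:
        raise EnumerationTooLarge(f"{n} sites exceeds the 24-site cap")
    index = {s: i for i, s in enumerate(sites)}
    # directional adjacency with multiplicity (degenerate dims of 2 allowed)
    adj: List[List[int]] = [[] for _ in range(n)]
    for s in sites:
        for nb in neighbors(s, geometry):
            adj[index[s]].append(index[nb])
    coupled = np.zeros(n)
    for s in poly_sites:
        coupled[index[geometry.wrap(s)]] = params.j_int_for(0)

    Z = 0.0
    acc = {"occupancy": 0.0, "n_occupied": 0.0, "energy": 0.0}
    states = [] if keep_states else None
    for code in range(1 << n):
        occ = [(code >> i) & 1 for i in range(n)]
        k = sum(occ)
        pairs = 0
        for i in range(n):
            if occ[i]:
                for j in adj[i]:
                    pairs += occ[j]
        pairs /= 2.0
        e = -params.mu_b * k - params.j_bulk * pairs - float(
            sum(c for c, o in zip(coupled, occ) if o))
        w = np.exp(-e)
        Z += w
        acc["n_occupied"] += w * k
        acc["occupancy"] += w * k / n
        acc["energy"] += w * e
        if keep_states:
            states.append((code, e))
    means = {k: v / Z for k, v in acc.items()}
    return EnumerationResult(Z=Z, means=means, n_states=1 << n, states=states)
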