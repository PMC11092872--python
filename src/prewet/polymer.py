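"""Monte-Carlo engine for the single long self-avoiding polymer.

The chain lives on the periodic lattice with both endpoints pinned.  The
standard setup is a box-spanning chain anchored at ``(L/2, L/2, 0)`` whose
far end sits at ``(L/2, L/2, L)`` — the same lattice site reached after
winding once around the box in z.  The chain is stored as an open monomer
list whose first and last entries share that wrapped anchor site; exactly
this terminal pair is exempt from self-avoidance, and the winding number is
conserved because all moves are local bond translations and the terminal
monomers never move.

Moves follow the bond-translation picture: a bond (monomers ``s``,
``s + 1``) is translated one step orthogonally.  Whether this adds two
monomers, removes two, or kinks the chain is fully determined by whether
the translated bond intersects the two monomers flanking the bond.  Move
classes are proposed with probabilities

    P_add = (N_p + 2) / (2 (1 + N_p)) * (1 - P_kink)
    P_rem =  N_p      / (2 (1 + N_p)) * (1 - P_kink)

and detailed balance is guaranteed by an explicit Hastings factor computed
from the actual forward and reverse proposal probabilities (class
probability times the uniform bond and direction choice), so any
configurable ``P_kink`` and any proposal schedule samples the Boltzmann
distribution exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import hamiltonian as ham
from .hamiltonian import ModelParams
from .lattice import DIRECTIONS, LatticeGeometry, Site


class InfeasibleSegmentSpec(ValueError):
    """Segment windows cannot be satisfied by the current chain length."""


@dataclass(frozen=True)
class SegmentSpec:
    """Ordered block layout of a multi-component polymer.

    ``blocks`` is a list of ``(type label, nominal monomer count)``; moves
    may shift each realized block count by at most ``delta`` from nominal.
    """

    blocks: Tuple[Tuple[int, int], ...]
    delta: int = 12

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if any(n < 1 for _, n in self.blocks):
            raise ValueError("nominal block counts must be positive")

    def bounds(self, block_index: int) -> Tuple[int, int]:
        nominal = self.blocks[block_index][1]
        return max(1, nominal - self.delta), nominal + self.delta


@dataclass
class PolymerChain:
    """Ordered monomer positions with pinned endpoints.

    ``sites`` are wrapped lattice sites.  ``N_p`` counts distinct occupied
    sites; for an anchored box-spanning chain (first and last monomer on
    the same wrapped site) this is ``len(sites) - 1`` so that the minimal
    spanning chain has ``N_p = L``.
    """

    sites: List[Site]
    types: Optional[List[int]] = None
    n_min: int = 2
    segment_spec: Optional[SegmentSpec] = None
    block_of: Optional[List[int]] = None      # per-monomer block index
    block_counts: Optional[List[int]] = None  # realized monomers per block

    @property
    def anchored(self) -> bool:
        return len(self.sites) > 1 and self.sites[0] == self.sites[-1]

    @property
    def N_p(self) -> int:
        return len(self.sites) - (1 if self.anchored else 0)

    @property
    def n_bonds(self) -> int:
        return len(self.sites) - 1

    def type_of(self, i: int) -> int:
        return 0 if self.types is None else self.types[i]

    def validate(self, geometry: LatticeGeometry) -> None:
        seen = set()
        n = len(self.sites)
        for i, s in enumerate(self.sites):
            if s in seen and not (self.anchored and i == n - 1):
                raise ValueError(f"self-avoidance violated at {s}")
            seen.add(s)
        for a, b in zip(self.sites, self.sites[1:]):
            d = geometry.displacement(a, b)
            if sorted(map(abs, d)) != [0, 0, 1]:
                raise ValueError(f"non-unit bond {a} -> {b}")


def spanning_chain(geometry: LatticeGeometry, types: Optional[List[int]] = None
                   ) -> PolymerChain:
    """The minimal box-spanning chain: a straight line winding once in z."""
    lx, ly, lz = geometry.dims
    c = (lx // 2, ly // 2)
    sites = [(c[0], c[1], z) for z in range(lz)] + [(c[0], c[1], 0)]
    return PolymerChain(sites=sites, types=types, n_min=lz)


def pinned_path(geometry: LatticeGeometry, start: Site, end: Site) -> PolymerChain:
    """A minimal staircase path between two distinct pinned sites.

    Steps follow the minimal-image displacement, so the resulting chain is
    in the non-winding homotopy class (local moves conserve that class on
    a periodic lattice).
    """
    disp = geometry.displacement(start, end)
    path = [start]
    cur = list(start)
    for axis in range(3):
        step = 1 if disp[axis] >= 0 else -1
        for _ in range(abs(disp[axis])):
            cur[axis] += step
            path.append(geometry.wrap((cur[0], cur[1], cur[2])))
    return PolymerChain(sites=path, n_min=2)


# ---------------------------------------------------------------------------
# Move classification and proposal
# ---------------------------------------------------------------------------

@dataclass
class MoveProposal:
    """A classified bond-translation with everything needed to apply it."""

    kind: str                      # addition | removal | kink | blocked
    bond_index: int
    direction: Site
    new_sites: Tuple[Site, ...] = ()   # sites to occupy (wrapped)
    moved_index: int = -1              # kink: monomer that moves
    old_site: Optional[Site] = None    # kink: vacated site
    hastings: float = 1.0
    mono_type: int = 0                 # addition: type of inserted monomers
    removed_types: Tuple[int, ...] = ()

    def local_delta(self, state, params: ModelParams) -> float:
        """Exact local energy difference; see :func:`hamiltonian.energy_delta`.

        Computes by transiently updating the occupancy field and reverting.
        """
        fields = state.fields.poly
        d = 0.0
        if self.kind == "addition":
            u, v = self.new_sites
            d += ham.poly_add_delta(state, params, u, self.mono_type)
            fields[u] = self.mono_type
            d += ham.poly_add_delta(state, params, v, self.mono_type)
            del fields[u]
        elif self.kind == "removal":
            u, v = self.new_sites  # here: the two vacated sites
            tu, tv = self.removed_types
            d += ham.poly_remove_delta(state, params, u, tu)
            saved = fields.pop(u)
            d += ham.poly_remove_delta(state, params, v, tv)
            fields[u] = saved
        elif self.kind == "kink":
            t = self.mono_type
            d += ham.poly_remove_delta(state, params, self.old_site, t)
            saved = fields.pop(self.old_site)
            d += ham.poly_add_delta(state, params, self.new_sites[0], t)
            fields[self.old_site] = saved
        return d


def orthogonal_directions(bond: Site) -> List[Site]:
    """The four unit directions orthogonal to a unit bond vector."""
    return [d for d in DIRECTIONS
            if d[0] * bond[0] + d[1] * bond[1] + d[2] * bond[2] == 0]


def classify_move(chain: PolymerChain, bond_index: int, direction: Site,
                  geometry: LatticeGeometry) -> str:
    """Classify the translation of a bond as addition, removal or kink.

    The translated bond's intersection with the two flanking monomers fully
    determines the class: neither -> addition (two monomers inserted),
    both -> removal (the bond's monomers deleted), exactly one -> kink (the
    monomer on the intersected side hops to the diagonal site).  A terminal
    bond is missing one flank and can therefore never be classified as a
    removal; proposals that would displace a pinned terminal monomer are
    ``blocked``.
    """
    n = len(chain.sites)
    if not 0 <= bond_index < n - 1:
        raise ValueError(f"bond index {bond_index} out of range")
    b, c = chain.sites[bond_index], chain.sites[bond_index + 1]
    bond = geometry.displacement(b, c)
    if direction[0] * bond[0] + direction[1] * bond[1] + direction[2] * bond[2] != 0 \
            or sorted(map(abs, direction)) != [0, 0, 1]:
        raise ValueError(f"direction {direction} not orthogonal unit vector")
    tb = geometry.wrap((b[0] + direction[0], b[1] + direction[1], b[2] + direction[2]))
    tc = geometry.wrap((c[0] + direction[0], c[1] + direction[1], c[2] + direction[2]))
    prev_flank = chain.sites[bond_index - 1] if bond_index >= 1 else None
    next_flank = chain.sites[bond_index + 2] if bond_index + 2 < n else None
    hits_prev = prev_flank is not None and prev_flank in (tb, tc)
    hits_next = next_flank is not None and next_flank in (tb, tc)
    if hits_prev and hits_next:
        return "removal"
    if hits_prev or hits_next:
        # the monomer on the intersected side hops; terminals are pinned
        moved = bond_index if hits_prev else bond_index + 1
        if moved == 0 or moved == n - 1:
            return "blocked"
        return "kink"
    return "addition"


def proposal_probabilities(N_p: int, p_kink: float) -> Tuple[float, float, float]:
    """Move-class probabilities (P_add, P_rem, P_kink); they sum to one."""
    if N_p < 2:
        raise ValueError("N_p must be >= 2")
    if not 0.0 <= p_kink < 1.0:
        raise ValueError("p_kink must lie in [0, 1)")
    p_add = (N_p + 2) / (2.0 * (1 + N_p)) * (1.0 - p_kink)
    p_rem = N_p / (2.0 * (1 + N_p)) * (1.0 - p_kink)
    return p_add, p_rem, p_kink


def _class_probability(kind: str, N_p: int, p_kink: float) -> float:
    p_add, p_rem, pk = proposal_probabilities(N_p, p_kink)
    return {"addition": p_add, "removal": p_rem, "kink": pk}[kind]


def propose_polymer_move(chain: PolymerChain, state, params: ModelParams,
                         rng: np.random.Generator) -> Optional[MoveProposal]:
    """Draw one bond-translation proposal; ``None`` means immediate rejection.

    Rejections here are class mismatches (the drawn bond/direction does not
    realize the drawn move class), length-window, segment-window or
    self-avoidance violations — all counted as attempted moves.
    """
    geometry = state.geometry
    n_bonds = chain.n_bonds
    N = chain.N_p
    p_add, p_rem, pk = proposal_probabilities(N, params.p_kink)
    u = rng.random()
    if u < p_add:
        want = "addition"
    elif u < p_add + p_rem:
        want = "removal"
    elif u < p_add + p_rem + pk:
        want = "kink"
    else:  # p_kink < 1 leaves no residual mass; defensive
        return None
    j = int(rng.integers(n_bonds))
    b, c = chain.sites[j], chain.sites[j + 1]
    bond = geometry.displacement(b, c)
    direction = orthogonal_directions(bond)[int(rng.integers(4))]
    kind = classify_move(chain, j, direction, geometry)
    if kind != want or kind == "blocked":
        return None

    poly = state.fields.poly
    tb = geometry.wrap((b[0] + direction[0], b[1] + direction[1], b[2] + direction[2]))
    tc = geometry.wrap((c[0] + direction[0], c[1] + direction[1], c[2] + direction[2]))
    fwd = _class_probability(kind, N, params.p_kink) / (4.0 * n_bonds)

    if kind == "addition":
        if N + 2 >= params.N_max:
            return None
        if tb in poly or tc in poly or tb == tc:
            return None
        mono_type = chain.type_of(j)
        if chain.segment_spec is not None:
            blk = chain.block_of[j]
            lo, hi = chain.segment_spec.bounds(blk)
            if chain.block_counts[blk] + 2 > hi:
                return None
        rev = _class_probability("removal", N + 2, params.p_kink) / (4.0 * (n_bonds + 2))
        return MoveProposal("addition", j, direction, (tb, tc),
                            hastings=rev / fwd, mono_type=mono_type)

    if kind == "removal":
        if N - 2 < chain.n_min:
            return None
        if chain.segment_spec is not None:
            blk1, blk2 = chain.block_of[j], chain.block_of[j + 1]
            counts = list(chain.block_counts)
            counts[blk1] -= 1
            counts[blk2] -= 1
            for blk in {blk1, blk2}:
                lo, hi = chain.segment_spec.bounds(blk)
                if counts[blk] < lo:
                    return None
        rev = _class_probability("addition", N - 2, params.p_kink) / (4.0 * (n_bonds - 2))
        return MoveProposal("removal", j, direction, (b, c),
                            hastings=rev / fwd,
                            removed_types=(chain.type_of(j), chain.type_of(j + 1)))

    # kink: the monomer on the intersected side hops to the diagonal site
    prev_flank = chain.sites[j - 1] if j >= 1 else None
    if prev_flank is not None and prev_flank in (tb, tc):
        moved, target = j, tc
    else:
        moved, target = j + 1, tb
    if target in poly:
        return None
    # reverse kink has identical class probability and bond/direction count
    return MoveProposal("kink", j, direction, (target,), moved_index=moved,
                        old_site=chain.sites[moved], hastings=1.0,
                        mono_type=chain.type_of(moved))


def apply_proposal(chain: PolymerChain, state, proposal: MoveProposal) -> None:
    """Apply an accepted proposal to the chain and the occupancy field."""
    poly = state.fields.poly
    j = proposal.bond_index
    if proposal.kind == "addition":
        u, v = proposal.new_sites
        t = proposal.mono_type
        chain.sites[j + 1:j + 1] = [u, v]
        if chain.types is not None:
            chain.types[j + 1:j + 1] = [t, t]
        if chain.block_counts is not None:
            blk = chain.block_of[j]
            chain.block_of[j + 1:j + 1] = [blk, blk]
            chain.block_counts[blk] += 2
        poly[u] = t
        poly[v] = t
    elif proposal.kind == "removal":
        u, v = proposal.new_sites
        del poly[u]
        del poly[v]
        if chain.block_counts is not None:
            chain.block_counts[chain.block_of[j]] -= 1
            chain.block_counts[chain.block_of[j + 1]] -= 1
            del chain.block_of[j:j + 2]
        del chain.sites[j:j + 2]
        if chain.types is not None:
            del chain.types[j:j + 2]
    else:  # kink
        i = proposal.moved_index
        t = proposal.mono_type
        del poly[proposal.old_site]
        poly[proposal.new_sites[0]] = t
        chain.sites[i] = proposal.new_sites[0]


def attempt_polymer_move(state, params: ModelParams,
                         rng: np.random.Generator) -> bool:
    """One Metropolis-Hastings polymer move attempt; True if accepted."""
    chain = state.chain
    proposal = propose_polymer_move(chain, state, params, rng)
    if proposal is None:
        return False
    delta = ham.energy_delta(state, proposal, params)
    acc = proposal.hastings * np.exp(-delta)
    if acc >= 1.0 or rng.random() < acc:
        apply_proposal(chain, state, proposal)
        return True
    return False


# ---------------------------------------------------------------------------
# Multi-component segment assignment
# ---------------------------------------------------------------------------

def assign_segments(chain: PolymerChain, spec: SegmentSpec) -> List[int]:
    """Impose a contiguous block layout on the chain; returns realized counts.

    Blocks are labeled in order along the contour.  Realized counts start
    from the nominal layout and absorb any surplus or deficit of monomers
    round-robin across blocks, each staying within nominal +/- delta.
    """
    n = len(chain.sites)
    nominals = [cnt for _, cnt in spec.blocks]
    lo_total = sum(max(1, c - spec.delta) for c in nominals)
    hi_total = sum(c + spec.delta for c in nominals)
    if not lo_total <= n <= hi_total:
        raise InfeasibleSegmentSpec(
            f"chain of {n} monomers cannot satisfy segment windows "
            f"[{lo_total}, {hi_total}]")
    counts = list(nominals)
    excess = n - sum(counts)
    step = 1 if excess > 0 else -1
    k = 0
    while excess != 0:
        blk = k % len(counts)
        lo, hi = spec.bounds(blk)
        if lo <= counts[blk] + step <= hi:
            counts[blk] += step
            excess -= step
        k += 1
        if k > 10 * len(counts) * (spec.delta + 1):
            raise InfeasibleSegmentSpec("segment windows infeasible")
    types, block_of = [], []
    for blk, ((label, _), cnt) in enumerate(zip(spec.blocks, counts)):
        types.extend([label] * cnt)
        block_of.extend([blk] * cnt)
    chain.types = types
    chain.block_of = block_of
    chain.block_counts = counts
    chain.segment_spec = spec
    return counts
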