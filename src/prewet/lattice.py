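"""Periodic cubic-lattice geometry and occupancy bookkeeping.

All engines share these conventions: sites are 0-based integer triples
``(x, y, z)`` with ``0 <= coordinate < dim``; the six nearest neighbours of a
site are enumerated in the fixed axis order ``+x, -x, +y, -y, +z, -z`` (the
order matters for reproducible move proposals under a fixed seed).

Occupancy fields are the single source of truth for energy evaluation; the
chain and molecule site lists are the source of truth for connectivity.  The
two representations can be cross-checked at any time with
:func:`rebuild_fields`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

Site = Tuple[int, int, int]

#: Fixed enumeration order for the six lattice directions.
DIRECTIONS: Tuple[Site, ...] = (
    (1, 0, 0),
    (-1, 0, 0),
    (0, 1, 0),
    (0, -1, 0),
    (0, 0, 1),
    (0, 0, -1),
)


@dataclass(frozen=True)
class LatticeGeometry:
    """A 3-D cubic lattice, periodic by default.

    Parameters
    ----------
    dims
        Linear dimensions ``(L_x, L_y, L_z)``, each at least 2.
    periodic
        If True (default) coordinates wrap in every axis.  Open boundaries
        are provided for small enumeration blocks, where a site may then
        have fewer than six neighbours.
    """

    dims: Tuple[int, int, int]
    periodic: bool = True

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(d < 2 for d in self.dims):
            raise ValueError(f"dims must be three integers >= 2, got {self.dims}")

    @classmethod
    def cubic(cls, L: int, periodic: bool = True) -> "LatticeGeometry":
        return cls((L, L, L), periodic)

    @property
    def n_sites(self) -> int:
        return self.dims[0] * self.dims[1] * self.dims[2]

    def wrap(self, site: Iterable[int]) -> Site:
        """Map an arbitrary integer triple onto the lattice (periodic only)."""
        x, y, z = site
        if not self.periodic:
            return (x, y, z)
        return (x % self.dims[0], y % self.dims[1], z % self.dims[2])

    def contains(self, site: Site) -> bool:
        return all(0 <= c < d for c, d in zip(site, self.dims))

    def sites(self) -> Iterable[Site]:
        lx, ly, lz = self.dims
        for x in range(lx):
            for y in range(ly):
                for z in range(lz):
                    yield (x, y, z)

    def displacement(self, a: Site, b: Site) -> Site:
        """Minimal-image displacement ``b - a`` (componentwise nearest)."""
        out = []
        for ca, cb, d in zip(a, b, self.dims):
            delta = cb - ca
            if self.periodic:
                if delta > d // 2:
                    delta -= d
                elif delta < -(d // 2):
                    delta += d
            out.append(delta)
        return (out[0], out[1], out[2])


def neighbors(site: Site, geometry: LatticeGeometry) -> List[Site]:
    """The nearest neighbours of ``site`` in the fixed direction order.

    Periodic lattices always return six sites (not necessarily distinct for
    a dimension of 2); open lattices drop out-of-range candidates.
    """
    if not geometry.contains(site):
        raise ValueError(f"site {site} outside lattice {geometry.dims}")
    out = []
    for d in DIRECTIONS:
        cand = (site[0] + d[0], site[1] + d[1], site[2] + d[2])
        if geometry.periodic:
            out.append(geometry.wrap(cand))
        elif geometry.contains(cand):
            out.append(cand)
    return out


class InvalidStateError(RuntimeError):
    """Raised when site lists violate an exclusion constraint."""


@dataclass
class OccupancyFields:
    """Sparse per-site indicator fields.

    ``poly`` maps an occupied site to the monomer type at that site (0 for
    untyped chains); ``s1`` and ``s2`` are the site sets of bulk species 1
    and 2.  Polymer monomers exclude only each other; bulk species exclude
    same-species overlap but species 1 and 2 (and the polymer) may share a
    site — the on-site couplings of the model act exactly there.
    """

    poly: Dict[Site, int] = field(default_factory=dict)
    s1: set = field(default_factory=set)
    s2: set = field(default_factory=set)

    def copy(self) -> "OccupancyFields":
        return OccupancyFields(dict(self.poly), set(self.s1), set(self.s2))


def rebuild_fields(chains, molecules, geometry: LatticeGeometry) -> OccupancyFields:
    """Construct occupancy fields from chain/molecule site lists.

    Raises :class:`InvalidStateError` on a polymer-polymer or same-species
    bulk collision, naming the offending site.  A chain whose first and last
    monomers share a site (the box-spanning anchored chain) is accepted:
    exactly that terminal pair is exempt from self-avoidance.
    """
    fields = OccupancyFields()
    for chain in chains:
        sites = list(chain.sites) if hasattr(chain, "sites") else list(chain)
        types = getattr(chain, "types", None) or [0] * len(sites)
        n = len(sites)
        anchored = n > 1 and sites[0] == sites[-1]
        for i, (site, t) in enumerate(zip(sites, types)):
            site = geometry.wrap(site)
            if site in fields.poly and not (anchored and i == n - 1):
                raise InvalidStateError(f"polymer self-collision at site {site}")
            fields.poly[site] = t
    for mol in molecules:
        species = getattr(mol, "species", 1)
        target = fields.s1 if species == 1 else fields.s2
        for site in mol.sites:
            site = geometry.wrap(site)
            if site in target:
                raise InvalidStateError(
                    f"species-{species} bulk collision at site {site}"
                )
            target.add(site)
    return fields
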