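"""Order parameters and structural summaries.

Includes the radius of gyration (computed on contour-unwrapped
coordinates, since the spanning chain crosses the periodic boundary), the
dimensionless polymer density ``rho = N_p a^3 / R_g^3``, the on-polymer
vs far-field bulk density difference used as the prewetting order
parameter, per-segment bulk occupancy profiles and monomer contact maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .lattice import LatticeGeometry, Site


class UndefinedObservable(RuntimeError):
    """Raised when an observable's defining region is empty."""


def unwrap_chain(sites: Sequence[Site], geometry: LatticeGeometry) -> np.ndarray:
    """Unwrap monomer coordinates bond-by-bond along the contour.

    Each bond contributes its minimal-image displacement, so a chain that
    winds around the box keeps its physical extent.  Returns an (n, 3)
    float array anchored at the first monomer.
    """
    n = len(sites)
    out = np.zeros((n, 3))
    cur = np.array(sites[0], dtype=float)
    out[0] = cur
    for i in range(1, n):
        d = geometry.displacement(sites[i - 1], sites[i])
        cur = cur + np.array(d, dtype=float)
        out[i] = cur
    return out


def radius_of_gyration(chain, geometry: LatticeGeometry) -> float:
    """R_g on unwrapped coordinates: sqrt(mean |r_i - r_cm|^2)."""
    coords = unwrap_chain(chain.sites, geometry)
    cm = coords.mean(axis=0)
    return float(np.sqrt(((coords - cm) ** 2).sum(axis=1).mean()))


def polymer_density(chain, geometry: LatticeGeometry, a: float = 1.0) -> float:
    """rho = N_p a^3 / R_g^3 (dimensionless)."""
    rg = radius_of_gyration(chain, geometry)
    if rg == 0.0:
        return float("inf")
    return chain.N_p * a ** 3 / rg ** 3


def _chebyshev_shell(poly_sites: Iterable[Site], geometry: LatticeGeometry,
                     radius: int) -> set:
    if radius == 0:
        return set(poly_sites)
    shell = set()
    offs = range(-radius, radius + 1)
    for s in poly_sites:
        for dx in offs:
            for dy in offs:
                for dz in offs:
                    shell.add(geometry.wrap((s[0] + dx, s[1] + dy, s[2] + dz)))
    return shell


def bulk_density_difference(state, shell_radius: int = 0) -> float:
    """On-polymer minus far-field bulk site-fraction density.

    The on-polymer region is all sites within Chebyshev distance
    ``shell_radius`` of any polymer monomer (default 0: the polymer's own
    sites); the far field is every remaining site.  Densities count
    ``s_1 + s_2`` (or the minimal-bulk occupancy) as site fractions.
    """
    poly_sites = set(state.fields.poly)
    shell = _chebyshev_shell(poly_sites, state.geometry, shell_radius)
    n_total = state.geometry.n_sites
    n_far = n_total - len(shell)
    if n_far == 0:
        raise UndefinedObservable("far-field region is empty")
    if state.gas is not None:
        occ = lambda s: 1 if s in state.gas else 0
        on = sum(occ(s) for s in shell)
        total = len(state.gas)
    else:
        s1, s2 = state.fields.s1, state.fields.s2
        occ = lambda s: (s in s1) + (s in s2)
        on = sum(occ(s) for s in shell)
        total = len(s1) + len(s2)
    far = total - on
    if not shell:
        raise UndefinedObservable("on-polymer region is empty")
    return on / len(shell) - far / n_far


# ---------------------------------------------------------------------------
# Frame records
# ---------------------------------------------------------------------------

@dataclass
class FrameObservables:
    sweep: int
    N_p: int
    Rg: float
    rho: float
    delta_rho_b: float
    extras: Dict[str, float] = field(default_factory=dict)

    def as_row(self) -> Dict[str, float]:
        row = {"sweep": self.sweep, "N_p": self.N_p, "Rg": self.Rg,
               "rho": self.rho, "delta_rho_b": self.delta_rho_b}
        row.update(self.extras)
        return row


def frames_to_table(frames: Sequence[FrameObservables]) -> pd.DataFrame:
    return pd.DataFrame([f.as_row() for f in frames])


# ---------------------------------------------------------------------------
# Trajectory summaries
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryFrame:
    """Snapshot of the system sufficient for structural analysis."""

    sites: List[Site]
    types: Optional[List[int]] = None
    s1: set = field(default_factory=set)
    s2: set = field(default_factory=set)


def occupancy_profile(trajectory: Sequence[TrajectoryFrame]
                      ) -> pd.DataFrame:
    """Fraction of frames each monomer type is co-occupied by each species.

    Returns one row per monomer type present, with columns ``occ_1`` and
    ``occ_2``: the fraction of (frame, monomer) observations of that type
    whose site carries bulk species 1 (respectively 2).
    """
    if not trajectory:
        raise ValueError("empty trajectory")
    counts: Dict[int, np.ndarray] = {}
    for frame in trajectory:
        types = frame.types or [0] * len(frame.sites)
        for site, t in zip(frame.sites, types):
            c = counts.setdefault(t, np.zeros(3))
            c[0] += 1
            c[1] += site in frame.s1
            c[2] += site in frame.s2
    rows = [{"type": t, "occ_1": c[1] / c[0], "occ_2": c[2] / c[0]}
            for t, c in sorted(counts.items())]
    return pd.DataFrame(rows)


def contour_occupancy(trajectory: Sequence[TrajectoryFrame], n_bins: int = 50
                      ) -> pd.DataFrame:
    """Species occupancy along fractional contour position (binned)."""
    tot = np.zeros(n_bins)
    o1 = np.zeros(n_bins)
    o2 = np.zeros(n_bins)
    for frame in trajectory:
        n = len(frame.sites)
        for i, site in enumerate(frame.sites):
            b = min(n_bins - 1, i * n_bins // n)
            tot[b] += 1
            o1[b] += site in frame.s1
            o2[b] += site in frame.s2
    with np.errstate(invalid="ignore"):
        return pd.DataFrame({"bin": np.arange(n_bins),
                             "occ_1": np.where(tot > 0, o1 / np.maximum(tot, 1), 0.0),
                             "occ_2": np.where(tot > 0, o2 / np.maximum(tot, 1), 0.0)})


def contact_map(trajectory: Sequence[TrajectoryFrame],
                geometry: LatticeGeometry, bin_size: int = 1,
                n_bins: Optional[int] = None) -> np.ndarray:
    """Binned nearest-neighbour contact probability matrix.

    Monomers are indexed by contour position and linearly rebinned when the
    chain length fluctuates.  Entry (i, j) is the number of lattice
    nearest-neighbour monomer pairs between bins i and j divided by the
    number of monomer pairs between those bins, averaged over frames; it is
    symmetric with entries in [0, 1].
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    n_ref = max(len(f.sites) for f in trajectory)
    if n_bins is None:
        n_bins = max(1, (n_ref + bin_size - 1) // bin_size)
    acc = np.zeros((n_bins, n_bins))
    nframes = 0
    for frame in trajectory:
        n = len(frame.sites)
        bins = np.minimum(np.arange(n) * n_bins // n, n_bins - 1)
        occ: Dict[Site, int] = {}
        for i, s in enumerate(frame.sites):
            occ[s] = i
        counts = np.bincount(bins, minlength=n_bins).astype(float)
        contacts = np.zeros((n_bins, n_bins))
        for i, s in enumerate(frame.sites):
            for nb in _site_neighbors(s, geometry):
                j = occ.get(nb)
                if j is not None and j > i:
                    contacts[bins[i], bins[j]] += 1
                    if bins[i] != bins[j]:
                        contacts[bins[j], bins[i]] += 1
        pairs = np.outer(counts, counts)
        np.fill_diagonal(pairs, counts * (counts - 1) / 2.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            prob = np.where(pairs > 0, contacts / pairs, 0.0)
        acc += prob
        nframes += 1
    return acc / nframes


def _site_neighbors(site: Site, geometry: LatticeGeometry):
    from .lattice import DIRECTIONS
    dims = geometry.dims
    for d in DIRECTIONS:
        yield ((site[0] + d[0]) % dims[0], (site[1] + d[1]) % dims[1],
               (site[2] + d[2]) % dims[2])
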