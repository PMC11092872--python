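"""Container tying together the lattice, the long polymer and the bulk.

Two bulk representations exist, mirroring the two simulation variants:

* the *full* bulk: a two-species fluid of short self-avoiding chains of
  fixed length ``N_b`` exchanged with an ideal reservoir;
* the *minimal* bulk: a single-species lattice gas with one 0/1 spin per
  site, updated by single-site flips.

Either may be combined with the long polymer.  ``fields`` holds the sparse
occupancy indicators used for all energy evaluation; for the minimal bulk
the lattice-gas occupancy set doubles as the species-1 field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

from .lattice import LatticeGeometry, OccupancyFields, rebuild_fields


@dataclass
class SystemState:
    geometry: LatticeGeometry
    chain: Optional[object] = None          # PolymerChain
    molecules: List[object] = field(default_factory=list)  # BulkMolecule
    gas: Optional[set] = None               # minimal-bulk occupancy set
    fields: OccupancyFields = field(default_factory=OccupancyFields)

    def species1_sites(self) -> set:
        """Sites carrying the polymer-coupled bulk species."""
        return self.gas if self.gas is not None else self.fields.s1

    def rebuild(self) -> OccupancyFields:
        chains = [self.chain] if self.chain is not None else []
        # the minimal-bulk gas set is authoritative on its own; fields.s1/s2
        # only track the molecular bulk
        return rebuild_fields(chains, self.molecules, self.geometry)

    def sync_fields(self) -> None:
        self.fields = self.rebuild()

    def check_consistent(self) -> None:
        """Debug cross-check: incremental fields equal a fresh rebuild."""
        ref = self.rebuild()
        if self.fields.poly != ref.poly or self.fields.s1 != ref.s1 \
                or self.fields.s2 != ref.s2:
            raise AssertionError("incrementally maintained fields out of sync")
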