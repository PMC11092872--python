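"""Multi-component polymer: selective occupancy of binding segments.

The chain carries alternating 'yellow' (type 1, bulk-binding) and
'green' (type 2, inert) segments.  Species 1 binds yellow monomers
directly (J_int,1 > 0, J_int,2 = 0); species 2 never touches the polymer
directly but co-localizes through the cross-species attraction J_bulk.
The printed occupancies show strong selection of yellow over green and
indirect (species-2) enrichment only because J_bulk > 0.
"""

import numpy as np

from prewet.hamiltonian import ModelParams
from prewet.observables import occupancy_profile
from prewet.polymer import SegmentSpec
from prewet.simulate import run_full

params = ModelParams(L=8, N_max=60, v_p=0.0, mu_b=-1.0, N_b=4, j_bulk=1.0,
                     j_int={1: 2.0, 2: 0.0}, p_kink=0.2, delta=8)
spec = SegmentSpec(blocks=((1, 16), (2, 16), (1, 16)), delta=8)
res = run_full(params, n_sweeps=2000, n_equil=600, cadence=20, seed=5,
               n_reservoir=150, segments=spec, pre_equil_sweeps=3000)

prof = occupancy_profile(res.frames).set_index("type")
vol = params.L ** 3
far1 = np.mean([len(f.s1 - set(f.sites)) / (vol - len(set(f.sites)))
                for f in res.frames])
print("segment occupancy (fraction of monomer-frames co-occupied):")
print(f"  yellow (binding): species-1 {prof.loc[1, 'occ_1']:.2f}   "
      f"species-2 {prof.loc[1, 'occ_2']:.2f}")
print(f"  green  (inert):   species-1 {prof.loc[2, 'occ_1']:.2f}   "
      f"species-2 {prof.loc[2, 'occ_2']:.2f}")
print(f"  far-field species-1 density: {far1:.3f}")
print("\nYellow segments capture direct binders (and, via J_bulk, indirect")
print("ones); green segments stay near the far-field level.")
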