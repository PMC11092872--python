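# Methods

## Lattice model

All energies are dimensionless (k_BT = 1). The system lives on a
periodic cubic lattice; occupancy indicator fields (one per polymer
monomer type, one per bulk species) are the single source of truth for
energy evaluation, while ordered site lists carry connectivity. The two
representations are cross-checked against each other in a debug path
(`SystemState.check_consistent`), which every long-running test calls.

### Polymer

The chain is pinned at (L/2, L/2, 0) and (L/2, L/2, L). On a periodic
lattice the second point is the first one reached after winding once in
z, so the chain is stored as an open monomer list whose first and last
entries share the anchor site; exactly that pair is exempt from
self-avoidance, and both terminal monomers are immobile. Local bond
translations conserve the net unwrapped displacement, so the winding
number is a constant of the dynamics — the enumeration oracle therefore
restricts itself to the sampler's homotopy class when the two are
compared. `N_p` counts distinct occupied sites (monomers − 1 for the
spanning chain), which makes the minimal spanning chain satisfy
N_p = L exactly.

Moves are translations of a randomly chosen bond in one of the four
orthogonal directions. The translated bond's intersection with the two
flanking monomers fully determines the class: none → addition of two
monomers, both → removal of two, exactly one → kink (the monomer on the
intersected side hops to the diagonal site). The default class
probabilities P_add = (N_p+2)/(2(1+N_p))(1−P_kink) and
P_rem = N_p/(2(1+N_p))(1−P_kink) are the proposal schedule, but
they do not by themselves satisfy P_add(N_p) = P_rem(N_p+2); the engine
therefore multiplies the Metropolis ratio by the exact
reverse-to-forward proposal-probability ratio (class probability ×
uniform bond and direction choice). This Hastings factor guarantees
detailed balance for any P_kink ∈ [0, 1) and any proposal schedule, and
the choice is validated by exact-enumeration tests. P_kink defaults
to 0.2; the sampled distribution is independent of it.

Length obeys L ≤ N_p < N_max with rejections at the boundaries.
Proposals violating self-avoidance, the window, pinning, or (for typed
chains) a segment window are rejections, not errors. One Monte-Carlo
sweep is N_p attempted polymer moves.

Multi-component chains carry contiguous blocks of typed monomers.
`assign_segments` imposes the layout on an equilibrated chain, starting
from the nominal counts and absorbing surplus or deficit round-robin;
moves may shift each realized block count by at most ±Δ (default 12)
from nominal. Monomers inserted at a block boundary inherit the type of
the bond's left monomer.

### Bulk

Full model: two species of self-avoiding chains of fixed length N_b
(default 20), cross-species overlap allowed and rewarded by −J_bulk per
shared site. The nearest-neighbour term is symmetrized — for an
unordered site pair the cross contribution is s¹_i s²_j + s²_i s¹_j —
restoring the physical exchange symmetry between species. The chemical
potential is per molecule (−mu_b per chain), equivalent to a per-site
−mu_b/N_b at fixed length. Updates are kink moves (same geometry rule as
the polymer; addition/removal classes rejected since length is fixed),
reptation (end chosen uniformly; the Hastings factor is the ratio of
free-site counts at the two ends, evaluated with the sliding tail
removed), and reservoir exchange at the rates λ± above with Metropolis
acceptance on the full energy change. Inserted molecules draw fresh
configurations from the reservoir's ideal-chain ensemble (uniform
nearest-neighbour random walks); self-overlapping draws are rejections.
Resampling rather than storing reservoir configurations leaves the
equilibrium unchanged because reservoir chains are non-interacting. One
bulk sweep is one kink-or-reptation attempt per bulk monomer plus one
exchange attempt, interleaved 1:1 with polymer sweeps.

Minimal model: a single-species lattice gas, H = −mu_b Σ s_i −
J_bulk Σ_<ij> s_i s_j, updated by uniformly proposed single-site flips.
The polymer coupling −J_int Σ s_i s_i^p applies on-site in both models
(species 1 only).

Nearest-neighbour sums are implemented as half the directional sum over
the six lattice directions. This equals the unordered-pair count
whenever every dimension is ≥ 3 and remains well defined (with edge
multiplicity 2) on the degenerate 2×2×2 lattice used by the lattice-gas
oracle; the convention is shared by the samplers and the enumerations,
so it cancels in every cross-check.

### Kernels

The production minimal-model loop (polymer moves + spin flips) is
compiled with numba; the pure-Python engines implement the identical
move set and are the reference. Kernel-vs-engine agreement of long-run
averages on a small box is part of the test suite. The kernel seeds
numpy's legacy generator once per call; all pure-Python drivers use a
single `numpy.random.Generator` per run. Identical seed + configuration
reproduce outputs byte-for-byte.

## Observables

R_g is computed on contour-unwrapped coordinates (each bond contributes
its minimal-image displacement): the spanning chain crosses the periodic
boundary, so wrapped coordinates would corrupt the centre of mass. The
anchor appears at both of its images in the average, an O(1/N_p) end
effect. The dimensionless density is ρ = N_p a³/R_g³ with a = 1.

The prewetting order parameter δρ_b is the bulk site-fraction density
(counting s¹+s² or the gas occupancy) on sites within Chebyshev distance
`shell_radius` (default 0, i.e. the polymer's own sites) of any monomer,
minus the density over all remaining sites. The shell radius and
normalization are deliberate, declared choices — the observable is only
defined up to such conventions — and are configurable.

Occupancy profiles report, per monomer type (and per binned contour
position), the fraction of monomer-frames whose site carries each
species. Contact maps index monomers by contour position with linear
rebinning when N_p fluctuates; entry (i, j) is the number of
nearest-neighbour monomer pairs between bins divided by the number of
monomer pairs between bins, averaged over frames.

## Mean-field numerics

`minimize_fpoly0` minimizes the single-chain free energy over ρ with a
400-point log-spaced grid scan on [1e-10, 10] followed by bounded scalar
refinement; this is robust to the minimizer sliding to either boundary
of the physical range. `minimize_fsys` minimizes F_sys/N_p over
(log ρ, φ) by Nelder-Mead multi-start on a 12×12 default grid (ρ
log-spaced in [1e-4, 3], φ spanning one unit beyond the bulk wells),
deduplicating converged points; working in log ρ keeps R_g > 0 implicit,
and the per-monomer scaling keeps function values O(1) at any N_p.
Exact ties of the bulk minimizer (the symmetric well at mu_b = 0) break
toward lower φ for determinism.

A note on the quadratic-bulk limit: substituting the minimizing
φ = φ_∞ + hρ/t_b into F_sys leaves the effective per-monomer coupling
−(h²/2t_b)ρ, which combines with the (v_p/2)ρ term of the chain free
energy to give v_eff = v_p − h²/t_b. At v_p = 0 the surviving terms of
the chain free energy in x = R_g²/(N_p a²) are (3/2)x − ln x + x⁻³/6 —
the three-body term is N-independent in this variable — and the exact
minimizer is x* = 1; the collapse transition at v_p = 0 is unaffected.

`scan_transition` records the global minimum along a parameter grid and
classifies the crossing: first-order if the global-minimum density jumps
by more than 0.05 between adjacent grid points with two coexisting
minima, continuous if ρ* crosses the collapse threshold 0.01 without a
branch exchange; the reported location is the bracket midpoint and both
thresholds are configurable. `quadratic_branches` expands the bulk free
energy to second order around each well, minimizes φ analytically, and
solves the resulting one-dimensional effective chain problem per branch;
the branch-crossing estimate of the first-order point agrees with the
full two-dimensional scan on the tested benchmarks. Confinement-entropy
and higher-order corrections to the chain free energy are omitted.

## Synthetic study conditions and their scope

No external data exists for this model; every simulation input is
generated by the engines themselves. The standard conditions are
L = 64, mu_p = 0, N_max = 1500, N_b = 20, Δ = 12. The test suite runs
scaled-down versions chosen to fit a desk-scale budget while preserving
the qualitative physics:

* sampler validation uses a 3×3×4 box with N_max = 10 (exhaustively
  enumerable) and a 2×2×2 lattice gas;
* the abrupt-vs-continuous prewetting contrast runs the minimal model at
  L = 16, N_max = 120, J_int = 2, v_p = 0, with J_bulk = 1.5
  (subcritical; the lattice-gas critical coupling is ≈ 0.89) against
  J_bulk = 0.5 (supercritical), scanning mu_b in steps of 0.1 with
  30 000-sweep runs and an 80 000-sweep run at the transition bracket;
* the multi-component study runs the full two-species bulk at L = 10,
  N_b = 4, yellow/green/yellow blocks of 22 with Δ = 8, J_int,yellow = 2,
  J_int,green = 0, mu_b = −1, and 250 reservoir molecules per species.

What passing these tests shows: correct equilibrium sampling of the
stated Hamiltonians, the mean-field transition structure, and the
qualitative coupled-transition phenomenology (discontinuous prewetting
with a bimodal order parameter near the jump; continuous rise in the
supercritical bulk; segment-selective direct occupancy and
J_bulk-dependent indirect occupancy). What they do not show: behaviour
at the full default scale (L = 64, N_max = 1500), finite-size scaling
toward the thermodynamic limit, tricritical properties, or any
quantitative mapping of lattice parameters onto real chromatin and
nuclear proteins; small boxes also blunt first-order discontinuities and
shift effective transition locations.

## Known limitations

* The kink/addition/removal move set is local; at strongly attractive
  v_p relaxation slows, and ergodicity on the torus holds within a
  winding class (which is the physically intended ensemble for the
  pinned, spanning chain).
* The grand-canonical exchange uses the explicit-reservoir rate
  construction λ± described above;
  with a finite reservoir, N_r + N_s is conserved per species, so very
  small reservoirs couple the system to reservoir depletion.
* `minimize_fsys` is a multi-start local method: pathological parameter
  sets with basins narrower than the start grid could hide a minimum;
  the default grid spans both basins for all regimes studied here.
* The first-order/continuous classifier relies on grid resolution near a
  weakly first-order point; halving the scan step is the remedy.
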