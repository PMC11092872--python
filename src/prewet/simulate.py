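"""Run loops for the two simulation variants.

``run_minimal`` drives the single-species lattice-gas bulk coupled to the
polymer through the compiled kernels; ``run_full`` drives the two-species
molecular bulk (kink + reptation + reservoir exchange) in pure Python.
Both interleave one polymer sweep (N_p attempted moves) with one bulk
sweep per Monte-Carlo step and return tidy observable tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import bulk as bulk_mod
from . import polymer as poly_mod
from ._kernels import run_minimal as _run_minimal_kernel
from .hamiltonian import ModelParams
from .lattice import LatticeGeometry
from .observables import (FrameObservables, TrajectoryFrame,
                          bulk_density_difference, frames_to_table,
                          polymer_density, radius_of_gyration)
from .system import SystemState


@dataclass
class MinimalRunResult:
    table: pd.DataFrame
    final_chain: poly_mod.PolymerChain
    final_gas: set
    acceptance: Dict[str, float]


def _kernel_seed(seed: int) -> int:
    return int(seed) % (2 ** 31 - 1)


def run_minimal(params: ModelParams, n_sweeps: int, n_equil: int = 0,
                cadence: int = 1, seed: int = 0,
                init_chain: Optional[poly_mod.PolymerChain] = None,
                init_gas: Optional[set] = None) -> MinimalRunResult:
    """Minimal-model run (polymer + lattice gas) via the compiled kernel.

    The observable table has one row per measurement with columns
    ``sweep, N_p, Rg, rho, contacts, n_gas, gas_on_poly, delta_rho_b``.
    """
    L = params.L
    geometry = LatticeGeometry.cubic(L)
    chain = init_chain or poly_mod.spanning_chain(geometry)
    cap = params.N_max + 3
    x = np.zeros(cap, dtype=np.int64)
    y = np.zeros(cap, dtype=np.int64)
    z = np.zeros(cap, dtype=np.int64)
    for i, s in enumerate(chain.sites):
        x[i], y[i], z[i] = s
    n = len(chain.sites)
    gas = np.zeros((L, L, L), dtype=np.uint8)
    if init_gas:
        for s in init_gas:
            gas[s] = 1
    out, n_final, acc, att = _run_minimal_kernel(
        L, x, y, z, n, gas, params.mu_p, params.v_p, params.mu_b,
        params.j_bulk, params.j_int_for(0), params.p_kink, params.N_max,
        chain.n_min, n_sweeps, n_equil, cadence, _kernel_seed(seed))
    cols = ["sweep", "N_p", "Rg2", "contacts", "n_gas", "gas_on_poly",
            "delta_rho_b"]
    table = pd.DataFrame(out, columns=cols)
    table["Rg"] = np.sqrt(table.pop("Rg2"))
    table["rho"] = table["N_p"] / table["Rg"] ** 3
    final_sites = [(int(x[i]), int(y[i]), int(z[i])) for i in range(n_final)]
    final_chain = poly_mod.PolymerChain(sites=final_sites, n_min=chain.n_min)
    final_gas = {(int(i), int(j), int(k))
                 for i, j, k in zip(*np.nonzero(gas))}
    poly_att = max(1, int(att[0]))
    acceptance = {
        "addition": acc[0] / poly_att, "removal": acc[1] / poly_att,
        "kink": acc[2] / poly_att, "flip": acc[3] / max(1, int(att[3])),
    }
    return MinimalRunResult(table, final_chain, final_gas, acceptance)


@dataclass
class FullRunResult:
    table: pd.DataFrame
    frames: List[TrajectoryFrame]
    state: SystemState
    reservoirs: Dict[int, bulk_mod.Reservoir]
    acceptance: Dict[str, float]


def run_full(params: ModelParams, n_sweeps: int, n_equil: int = 0,
             cadence: int = 1, seed: int = 0, n_reservoir: int = 1000,
             segments: Optional[poly_mod.SegmentSpec] = None,
             pre_equil_sweeps: int = 0, shell_radius: int = 0,
             keep_frames: bool = True) -> FullRunResult:
    """Full-model run: polymer + two-species molecular bulk with exchange.

    If ``segments`` is given the chain is first evolved untyped for up to
    ``pre_equil_sweeps`` (or until its length fits the segment windows),
    the block layout is imposed, and the production run proceeds with the
    per-type couplings.  One bulk sweep = one kink-or-reptation attempt
    per bulk monomer plus one reservoir-exchange attempt.
    """
    rng = np.random.default_rng(seed)
    geometry = LatticeGeometry.cubic(params.L)
    chain = poly_mod.spanning_chain(geometry)
    state = SystemState(geometry=geometry, chain=chain, molecules=[])
    state.sync_fields()
    reservoirs = {1: bulk_mod.Reservoir(n_reservoir),
                  2: bulk_mod.Reservoir(n_reservoir)}

    accepted = {"polymer": 0, "bulk_move": 0, "exchange": 0}
    attempted = {"polymer": 0, "bulk_move": 0, "exchange": 0}

    if segments is not None:
        lo = sum(max(1, c - segments.delta) for _, c in segments.blocks)
        hi = sum(c + segments.delta for _, c in segments.blocks)
        grow_params = ModelParams(L=params.L, mu_p=params.mu_p, v_p=params.v_p,
                                  N_max=params.N_max, p_kink=params.p_kink)
        for _ in range(max(pre_equil_sweeps, 1)):
            for _ in range(chain.N_p):
                poly_mod.attempt_polymer_move(state, grow_params, rng)
            if lo <= len(chain.sites) <= hi:
                break
        if not lo <= len(chain.sites) <= hi:
            raise RuntimeError(
                f"chain length {len(chain.sites)} did not reach the segment "
                f"window [{lo}, {hi}] in {pre_equil_sweeps} sweeps")
        poly_mod.assign_segments(chain, segments)
        state.sync_fields()
    elif pre_equil_sweeps:
        for _ in range(pre_equil_sweeps):
            for _ in range(chain.N_p):
                poly_mod.attempt_polymer_move(state, params, rng)

    frames: List[TrajectoryFrame] = []
    rows: List[FrameObservables] = []
    for sweep in range(n_sweeps):
        for _ in range(chain.N_p):
            attempted["polymer"] += 1
            accepted["polymer"] += poly_mod.attempt_polymer_move(
                state, params, rng)
        n_bulk_monomers = sum(len(m.sites) for m in state.molecules)
        for _ in range(n_bulk_monomers):
            mol = state.molecules[int(rng.integers(len(state.molecules)))]
            attempted["bulk_move"] += 1
            if rng.random() < 0.5:
                accepted["bulk_move"] += bulk_mod.bulk_kink_move(
                    mol, state, params, rng)
            else:
                accepted["bulk_move"] += bulk_mod.reptation_move(
                    mol, state, params, rng)
        attempted["exchange"] += 1
        accepted["exchange"] += bulk_mod.reservoir_exchange(
            state, params, reservoirs, rng)
        if sweep >= n_equil and (sweep - n_equil) % cadence == 0:
            rg = radius_of_gyration(chain, geometry)
            rho = polymer_density(chain, geometry)
            try:
                drho = bulk_density_difference(state, shell_radius)
            except Exception:
                drho = float("nan")
            n1 = sum(1 for m in state.molecules if m.species == 1)
            n2 = len(state.molecules) - n1
            rows.append(FrameObservables(
                sweep=sweep, N_p=chain.N_p, Rg=rg, rho=rho,
                delta_rho_b=drho,
                extras={"n_mol_1": n1, "n_mol_2": n2}))
            if keep_frames:
                frames.append(TrajectoryFrame(
                    sites=list(chain.sites),
                    types=list(chain.types) if chain.types else None,
                    s1=set(state.fields.s1), s2=set(state.fields.s2)))
    acceptance = {k: accepted[k] / max(1, attempted[k]) for k in accepted}
    return FullRunResult(frames_to_table(rows), frames, state, reservoirs,
                         acceptance)
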