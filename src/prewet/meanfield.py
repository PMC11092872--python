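"""Coupled mean-field theory of polymer collapse and bulk condensation.

The variational free energy couples two order parameters: the polymer's
radius of gyration ``R_g`` (equivalently the monomer density
``rho = N_p a^3 / R_g^3``) and the local bulk order parameter ``phi``
inside the polymer-occupied sphere of volume ``R_g^3``:

    F_poly^0(R_g) = (3/2) x - ln x + (v_p/2) N_p rho + (N_p/6) rho^2,
        x = R_g^2 / (N_p a^2)
    f_bulk(phi)   = (t_b/2) phi^2 + (u/24) phi^4 - mu_b phi
    F_sys(R_g, phi) = F_poly^0(R_g) - h phi N_p + R_g^3 [f_bulk(phi)
                                                         - f_bulk(phi_inf)]

with ``phi_inf`` the global minimizer of ``f_bulk`` far from the polymer.
For a supercritical bulk (``t_b > 0``) integrating out ``phi`` shifts the
collapse point exactly like a contact attraction: the effective excluded
volume is ``v_eff = v_p - h^2 / t_b``, so the Extended-Collapsed
transition sits at ``v_p = h^2 / t_b`` instead of ``v_p = 0``.  For a
subcritical bulk (``t_b < 0``) the two wells of ``f_bulk`` generate two
branches of ``F_sys`` whose exchange of global stability is a first-order
(generalized prewetting) transition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize


@dataclass(frozen=True)
class MeanFieldParams:
    """Parameters of the coupled variational free energy (k_BT units)."""

    N_p: float = 1.0e6      # monomer count
    a: float = 1.0          # monomer length
    v_p: float = 0.0        # excluded-volume parameter (positive = repulsive)
    t_b: float = 1.0        # reduced temperature of the bulk
    u: float = 6.0          # quartic stability coefficient (> 0)
    mu_b: float = 0.0       # bulk chemical potential
    h: float = 0.0          # per-monomer polymer-bulk coupling

    def __post_init__(self) -> None:
        if self.u <= 0:
            raise ValueError("u must be positive")
        if self.N_p < 1 or self.a <= 0:
            raise ValueError("require N_p >= 1 and a > 0")


@dataclass
class MeanFieldState:
    """A candidate minimum of the coupled free energy."""

    rho: float
    phi: float
    F_sys: float

    @property
    def R_g(self) -> float:
        # rho = N a^3 / R_g^3 with a = 1 units handled by the caller
        return (1.0 / self.rho) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# Free-energy pieces
# ---------------------------------------------------------------------------

def f_poly0(R_g: float, params: MeanFieldParams) -> float:
    """Isolated-polymer free energy as a function of R_g."""
    if R_g <= 0:
        raise ValueError("R_g must be positive")
    N, a = params.N_p, params.a
    x = R_g ** 2 / (N * a ** 2)
    rho = N * a ** 3 / R_g ** 3
    return 1.5 * x - np.log(x) + 0.5 * params.v_p * N * rho + N * rho ** 2 / 6.0


def f_poly0_density(rho, params: MeanFieldParams, v_p: Optional[float] = None):
    """Same free energy in the density variable (vectorized over rho)."""
    rho = np.asarray(rho, dtype=float)
    N = params.N_p
    v = params.v_p if v_p is None else v_p
    x = N ** (-1.0 / 3.0) * rho ** (-2.0 / 3.0)
    return 1.5 * x - np.log(x) + 0.5 * v * N * rho + N * rho ** 2 / 6.0


def f_bulk(phi, params: MeanFieldParams):
    """Landau bulk free-energy density (vectorized over phi)."""
    phi = np.asarray(phi, dtype=float)
    return (0.5 * params.t_b * phi ** 2 + params.u * phi ** 4 / 24.0
            - params.mu_b * phi)


def bulk_minima(params: MeanFieldParams) -> List[float]:
    """Local minima of f_bulk, ascending in phi."""
    # f'(phi) = (u/6) phi^3 + t_b phi - mu_b
    roots = np.roots([params.u / 6.0, 0.0, params.t_b, -params.mu_b])
    real = sorted(float(r.real) for r in roots if abs(r.imag) < 1e-9)
    curv = lambda p: params.t_b + 0.5 * params.u * p ** 2
    return [p for p in real if curv(p) > 0]


def phi_inf(params: MeanFieldParams) -> float:
    """Global minimizer of f_bulk; exact ties break toward lower phi."""
    minima = bulk_minima(params)
    if not minima:
        raise RuntimeError("f_bulk has no local minimum (u must be > 0)")
    vals = [float(f_bulk(p, params)) for p in minima]
    best = min(vals)
    for p, v in zip(minima, vals):   # ascending phi: first tie wins
        if v <= best + 1e-12:
            return p
    return minima[int(np.argmin(vals))]


def delta_f_bulk(phi, params: MeanFieldParams):
    return f_bulk(phi, params) - f_bulk(phi_inf(params), params)


def f_sys(R_g: float, phi: float, params: MeanFieldParams) -> float:
    """Total coupled free energy, Eqs combined (polymer-free bulk subtracted)."""
    return float(f_poly0(R_g, params) - params.h * phi * params.N_p
                 + R_g ** 3 * delta_f_bulk(phi, params))


def _f_sys_density(rho: float, phi: float, params: MeanFieldParams,
                   phi0: float) -> float:
    """Per-monomer F_sys in (rho, phi) with phi_inf precomputed."""
    N = params.N_p
    x = N ** (-1.0 / 3.0) * rho ** (-2.0 / 3.0)
    dfb = float(f_bulk(phi, params) - f_bulk(phi0, params))
    full = (1.5 * x - np.log(x) + 0.5 * params.v_p * N * rho
            + N * rho ** 2 / 6.0 - params.h * phi * N
            + (N * params.a ** 3 / rho) * dfb)
    return full / N


def v_eff(v_p: float, h: float, t_b: float) -> float:
    """Effective excluded volume v_p - h^2/t_b (supercritical bulk only)."""
    if t_b <= 0:
        raise ValueError("v_eff requires t_b > 0 (single-well bulk)")
    return v_p - h ** 2 / t_b


# ---------------------------------------------------------------------------
# Minimization
# ---------------------------------------------------------------------------

def minimize_fpoly0(params: MeanFieldParams,
                    rho_bounds: Tuple[float, float] = (1e-10, 10.0),
                    n_grid: int = 400) -> Tuple[float, float]:
    """Global minimizer of the isolated-polymer free energy over rho.

    Coarse log-spaced grid scan followed by bounded local refinement.
    Returns (rho*, F*).
    """
    grid = np.geomspace(rho_bounds[0], rho_bounds[1], n_grid)
    vals = f_poly0_density(grid, params)
    k = int(np.argmin(vals))
    lo = grid[max(0, k - 1)]
    hi = grid[min(n_grid - 1, k + 1)]
    res = optimize.minimize_scalar(
        lambda lr: float(f_poly0_density(np.exp(lr), params)),
        bounds=(np.log(lo), np.log(hi)), method="bounded",
        options={"xatol": 1e-12})
    rho_star = float(np.exp(res.x))
    return rho_star, float(f_poly0_density(rho_star, params))


def minimize_fsys(params: MeanFieldParams, n_rho: int = 12, n_phi: int = 12,
                  rho_bounds: Tuple[float, float] = (1e-4, 3.0),
                  dedup_tol: float = 1e-2) -> List[MeanFieldState]:
    """All local minima of F_sys(rho, phi) by multi-start local descent.

    Starts on a log-spaced rho grid crossed with a phi grid spanning one
    unit beyond the bulk wells; converged points are deduplicated within
    ``dedup_tol`` and sorted by free energy, global minimum first.
    """
    phi0 = phi_inf(params)
    wells = bulk_minima(params)
    phi_lo, phi_hi = min(wells) - 1.0, max(wells) + 1.0
    rho_starts = np.geomspace(rho_bounds[0], rho_bounds[1], n_rho)
    phi_starts = np.linspace(phi_lo, phi_hi, n_phi)

    def objective(x):
        rho = np.exp(x[0])
        return _f_sys_density(rho, x[1], params, phi0)

    found: List[MeanFieldState] = []
    for r0 in rho_starts:
        for p0 in phi_starts:
            res = optimize.minimize(
                objective, x0=np.array([np.log(r0), p0]),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
            if not np.isfinite(res.fun):
                continue
            rho = float(np.exp(res.x[0]))
            phi = float(res.x[1])
            F = float(res.fun) * params.N_p
            dup = False
            for m in found:
                if (abs(np.log(rho) - np.log(m.rho)) < dedup_tol * 10
                        and abs(phi - m.phi) < dedup_tol):
                    dup = True
                    if F < m.F_sys:
                        m.rho, m.phi, m.F_sys = rho, phi, F
                    break
            if not dup:
                found.append(MeanFieldState(rho, phi, F))
    if not found:
        raise RuntimeError(
            f"no minimum found in rho bounds {rho_bounds}, "
            f"phi range ({phi_lo}, {phi_hi})")
    found.sort(key=lambda m: m.F_sys)
    return found


# ---------------------------------------------------------------------------
# Quadratic branch analysis (subcritical bulk)
# ---------------------------------------------------------------------------

@dataclass
class BranchPrediction:
    """Quadratic-well approximation around one bulk minimum."""

    phi_well: float
    t_eff: float            # curvature of f_bulk at the well
    v_eff: float            # v_p - h^2 / t_eff
    offset_per_monomer: float  # -h * phi_well
    rho: float
    phi: float
    F_sys: float


def quadratic_branches(params: MeanFieldParams) -> List[BranchPrediction]:
    """Expand f_bulk quadratically around each of its two wells.

    Within one well ``Delta f ~ Delta f_m + (t_eff/2)(phi - phi_m)^2``;
    minimizing over phi analytically maps the branch onto an isolated
    polymer with ``v_eff = v_p - h^2/t_eff``, a constant ``-h phi_m N_p``
    and a volume term ``(N_p/rho) Delta f_m``.  The returned minimizers
    locate the branch minima; a first-order transition is where the two
    branch free energies cross.
    """
    wells = bulk_minima(params)
    if len(wells) < 2:
        raise ValueError("quadratic branch analysis needs a double-well bulk")
    phi0 = phi_inf(params)
    out = []
    N = params.N_p
    for phi_m in wells:
        t_eff = params.t_b + 0.5 * params.u * phi_m ** 2
        vb = params.v_p - params.h ** 2 / t_eff
        dfm = float(f_bulk(phi_m, params) - f_bulk(phi0, params))

        def branch_f(rho):
            rho = np.asarray(rho, dtype=float)
            return (f_poly0_density(rho, params, v_p=vb)
                    - params.h * phi_m * N + (N * params.a ** 3 / rho) * dfm)

        grid = np.geomspace(1e-8, 10.0, 400)
        vals = branch_f(grid)
        k = int(np.argmin(vals))
        res = optimize.minimize_scalar(
            lambda lr: float(branch_f(np.exp(lr))),
            bounds=(np.log(grid[max(0, k - 1)]), np.log(grid[min(399, k + 1)])),
            method="bounded", options={"xatol": 1e-12})
        rho_star = float(np.exp(res.x))
        phi_star = phi_m + params.h * rho_star / t_eff
        out.append(BranchPrediction(
            phi_well=phi_m, t_eff=t_eff, v_eff=vb,
            offset_per_monomer=-params.h * phi_m,
            rho=rho_star, phi=phi_star, F_sys=float(branch_f(rho_star))))
    return out


# ---------------------------------------------------------------------------
# Parameter scans and transition location
# ---------------------------------------------------------------------------

@dataclass
class TransitionResult:
    found: bool
    location: Optional[float]
    order: Optional[str]          # "continuous" | "first_order"
    table: pd.DataFrame


def scan_transition(params: MeanFieldParams, axis: str,
                    values: Sequence[float],
                    rho_threshold: float = 0.01,
                    jump_threshold: float = 0.05,
                    n_rho: int = 12, n_phi: int = 12) -> TransitionResult:
    """Scan one parameter and locate the collapse transition.

    For each value the global minimum of F_sys is computed.  A first-order
    transition is a jump of the global-minimum density larger than
    ``jump_threshold`` between adjacent grid points with two coexisting
    minima; a continuous transition is a threshold crossing of rho* with no
    branch exchange.  The reported location is the bracket midpoint.
    """
    if axis not in ("v_p", "mu_b", "t_b"):
        raise ValueError(f"unsupported scan axis {axis!r}")
    rows = []
    for val in values:
        p = replace(params, **{axis: float(val)})
        if p.h == 0.0:
            rho_star, F = minimize_fpoly0(p)
            phi_star = phi_inf(p)
            n_min = 1
        else:
            minima = minimize_fsys(p, n_rho=n_rho, n_phi=n_phi)
            best = minima[0]
            rho_star, phi_star, F = best.rho, best.phi, best.F_sys
            n_min = len(minima)
        rows.append({axis: float(val), "rho": rho_star, "phi": phi_star,
                     "F_sys": F, "n_minima": n_min})
    table = pd.DataFrame(rows)
    rho = table["rho"].to_numpy()
    vals = table[axis].to_numpy()
    location, order = None, None
    for i in range(len(vals) - 1):
        crosses = (rho[i] - rho_threshold) * (rho[i + 1] - rho_threshold) < 0
        if not crosses:
            continue
        location = 0.5 * (vals[i] + vals[i + 1])
        jump = abs(rho[i + 1] - rho[i]) > jump_threshold
        coexist = min(table["n_minima"][i], table["n_minima"][i + 1]) >= 2
        order = "first_order" if (jump and coexist) else "continuous"
        break
    return TransitionResult(found=location is not None, location=location,
                            order=order, table=table)


def branch_crossing(params: MeanFieldParams, axis: str,
                    values: Sequence[float]) -> Optional[float]:
    """Axis value where the two quadratic-branch free energies are equal.

    Returns the midpoint of the bracketing grid interval, or None if the
    branch free-energy difference does not change sign on the grid.
    """
    pts = []
    for val in values:
        p = replace(params, **{axis: float(val)})
        if len(bulk_minima(p)) < 2:
            continue  # outside the spinodal: no second branch to compare
        lo, hi = quadratic_branches(p)[:2]
        pts.append((float(val), lo.F_sys - hi.F_sys))
    for (v0, d0), (v1, d1) in zip(pts, pts[1:]):
        if d0 == 0.0 or d0 * d1 < 0:
            return 0.5 * (v0 + v1)
    return None
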