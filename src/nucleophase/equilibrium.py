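"""Two-phase coexistence for the bulk RNA-protein free energy.

Coexisting dense and light phases satisfy equal protein chemical potential,
equal RNA chemical potential and equal osmotic pressure, and the overall
composition closes the system through the lever rule:

    mu_P(dense) = mu_P(light)
    mu_R(dense) = mu_R(light)
    Pi(dense)   = Pi(light),   Pi = f - mu_P phi_P - mu_R phi_R
    nu phi_P^dense + (1 - nu) phi_P^light = phi_P^total
    nu phi_R^dense + (1 - nu) phi_R^light = phi_R^total

five equations for (phi_P^light, phi_R^light, phi_P^dense, phi_R^dense, nu),
with nu the dense-phase volume fraction.  ``partition_scan`` maps the
re-entrant behaviour of protein partitioning as the total RNA is raised.

The polynomial free energy has no entropic barrier at zero concentration, so
at small total RNA the unconstrained five-equation root places negative RNA
in the light phase.  The physical equilibrium there sits on the boundary of
the composition simplex: RNA is absent from the light phase and the
mu_R-equality is replaced by the complementary-slackness inequality
mu_R(light, 0) >= mu_R(dense).  ``solve_coexistence`` falls back to that
constrained branch whenever the interior root is unphysical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .free_energy import (FreeEnergyParams, bulk_energy, mu_P, mu_R,
                          stability_det)

__all__ = [
    "CoexistenceResult",
    "osmotic_pressure",
    "solve_coexistence",
    "partition_scan",
    "calibrate_defaults",
]

#: solver acceptance tolerances
_RESIDUAL_TOL = 1e-8
_MIN_GAP = 1e-3


@dataclass(frozen=True)
class CoexistenceResult:
    phi_P_light: float
    phi_R_light: float
    phi_P_dense: float
    phi_R_dense: float
    nu: float
    converged: bool
    residual_norm: float

    @property
    def enrichment(self) -> float:
        """Dense/light protein partition ratio (1 when single-phase)."""
        if not self.converged or self.phi_P_light <= 0:
            return 1.0
        return self.phi_P_dense / self.phi_P_light


def osmotic_pressure(phi_P, phi_R, p: FreeEnergyParams):
    """Pi = f - mu_P phi_P - mu_R phi_R (bulk terms only)."""
    return (bulk_energy(phi_P, phi_R, p)
            - mu_P(phi_P, phi_R, p) * np.asarray(phi_P, dtype=float)
            - mu_R(phi_P, phi_R, p) * np.asarray(phi_R, dtype=float))


def _residuals(z, phi_P_total, phi_R_total, p):
    pl, rl, pd_, rd, nu = z
    return np.array([
        mu_P(pd_, rd, p) - mu_P(pl, rl, p),
        mu_R(pd_, rd, p) - mu_R(pl, rl, p),
        osmotic_pressure(pd_, rd, p) - osmotic_pressure(pl, rl, p),
        nu * pd_ + (1.0 - nu) * pl - phi_P_total,
        nu * rd + (1.0 - nu) * rl - phi_R_total,
    ])


def _single_phase(phi_P_total, phi_R_total, p, residual=np.inf):
    # nu in {0, 1}: classify the homogeneous state as light- or dense-like
    nu = 1.0 if phi_P_total > p.threshold else 0.0
    return CoexistenceResult(phi_P_total, phi_R_total, phi_P_total,
                             phi_R_total, nu, False, float(residual))


def _accept(z, p, require_nonneg=False) -> bool:
    pl, rl, pd_, rd, nu = z
    if not np.all(np.isfinite(z)):
        return False
    if pd_ - pl <= _MIN_GAP:
        return False
    if not (-1e-9 <= nu <= 1.0 + 1e-9):
        return False
    if require_nonneg and min(pl, rl, pd_, rd) < -1e-9:
        return False
    # both phases must be locally stable compositions
    if stability_det(pl, rl, p) <= 0 or stability_det(pd_, rd, p) <= 0:
        return False
    return True


def _boundary_residuals(z, phi_P_total, phi_R_total, p):
    # light phase pinned at phi_R = 0; mu_R equality dropped (KKT boundary)
    pl, pd_, rd, nu = z
    return np.array([
        mu_P(pd_, rd, p) - mu_P(pl, 0.0, p),
        osmotic_pressure(pd_, rd, p) - osmotic_pressure(pl, 0.0, p),
        nu * pd_ + (1.0 - nu) * pl - phi_P_total,
        nu * rd - phi_R_total,
    ])


def _solve_boundary(phi_P_total, phi_R_total, p, init=None):
    """Constrained branch: all RNA in the dense phase (phi_R_light = 0)."""
    guesses = []
    if init is not None:
        init = np.asarray(init, dtype=float)
        if init.shape == (5,):
            init = init[[0, 2, 3, 4]]
        guesses.append(init)
    nu0 = np.clip((phi_P_total - p.alpha) / (p.beta - p.alpha), 0.05, 0.95)
    guesses.append(np.array([p.alpha, p.beta, phi_R_total / max(nu0, 0.05),
                             nu0]))
    for g in guesses:
        try:
            sol = optimize.root(_boundary_residuals, g,
                                args=(phi_P_total, phi_R_total, p),
                                method="hybr", options={"xtol": 1e-13})
        except FloatingPointError:
            continue
        pl, pd_, rd, nu = sol.x
        res = float(np.linalg.norm(
            _boundary_residuals(sol.x, phi_P_total, phi_R_total, p)))
        # complementary slackness: adding RNA to the light phase must not
        # lower the free energy
        kkt_ok = mu_R(pl, 0.0, p) >= mu_R(pd_, rd, p) - 1e-9
        z5 = np.array([pl, 0.0, pd_, rd, nu])
        if res < _RESIDUAL_TOL and kkt_ok and _accept(z5, p,
                                                      require_nonneg=True):
            return CoexistenceResult(float(pl), 0.0, float(pd_), float(rd),
                                     float(np.clip(nu, 0.0, 1.0)), True, res)
    return None


def solve_coexistence(phi_P_total: float, phi_R_total: float,
                      p: FreeEnergyParams,
                      init=None) -> CoexistenceResult:
    """Solve the five coexistence relations for one overall composition.

    Returns a single-phase fallback (``converged=False``, nu in {0, 1})
    when no acceptable two-phase root exists; non-convergence is a reported
    state, not an exception.
    """
    if phi_P_total < 0 or phi_R_total < 0:
        raise ValueError("total concentrations must be >= 0")
    if not np.all(np.isfinite([phi_P_total, phi_R_total])):
        raise ValueError("total concentrations must be finite")

    guesses = []
    if init is not None:
        guesses.append(np.asarray(init, dtype=float))
    nu0 = np.clip((phi_P_total - p.alpha) / (p.beta - p.alpha), 0.05, 0.95)
    guesses.append(np.array([p.alpha, phi_R_total, p.beta, phi_R_total, nu0]))
    # RNA preferentially in the dense phase (attraction-dominated regime)
    if phi_R_total > 0:
        guesses.append(np.array([p.alpha, 0.5 * phi_R_total, p.beta,
                                 2.0 * phi_R_total, nu0]))
        guesses.append(np.array([p.alpha, 0.1 * phi_R_total, p.beta,
                                 phi_R_total / max(nu0, 0.05), nu0]))

    best = None
    for g in guesses:
        try:
            sol = optimize.root(_residuals, g,
                                args=(phi_P_total, phi_R_total, p),
                                method="hybr", options={"xtol": 1e-13})
        except FloatingPointError:
            continue
        res = float(np.linalg.norm(
            _residuals(sol.x, phi_P_total, phi_R_total, p)))
        if res < _RESIDUAL_TOL and _accept(sol.x, p, require_nonneg=True):
            pl, rl, pd_, rd, nu = sol.x
            return CoexistenceResult(float(pl), float(rl), float(pd_),
                                     float(rd), float(np.clip(nu, 0.0, 1.0)),
                                     True, res)
        if best is None or res < best:
            best = res
    boundary = _solve_boundary(phi_P_total, phi_R_total, p, init=init)
    if boundary is not None:
        return boundary
    return _single_phase(phi_P_total, phi_R_total, p,
                         np.inf if best is None else best)


def partition_scan(p: FreeEnergyParams, phi_P_total: float,
                   phi_R_grid) -> pd.DataFrame:
    """Coexistence along a grid of total RNA, warm-starting each solve
    from the previous root (continuation along the re-entrant branch)."""
    phi_R_grid = np.asarray(phi_R_grid, dtype=float)
    if phi_R_grid.ndim != 1 or np.any(np.diff(phi_R_grid) <= 0):
        raise ValueError("phi_R_grid must be 1-D strictly increasing")
    rows = []
    warm = None
    for phi_R_total in phi_R_grid:
        r = solve_coexistence(phi_P_total, float(phi_R_total), p, init=warm)
        if r.converged:
            warm = np.array([r.phi_P_light, r.phi_R_light, r.phi_P_dense,
                             r.phi_R_dense, r.nu])
        rows.append({
            "phi_R_total": float(phi_R_total),
            "phi_P_light": r.phi_P_light,
            "phi_P_dense": r.phi_P_dense,
            "phi_R_light": r.phi_R_light,
            "phi_R_dense": r.phi_R_dense,
            "nu": r.nu,
            "enrichment": r.enrichment,
            "converged": r.converged,
        })
    return pd.DataFrame(rows)


def calibrate_defaults() -> FreeEnergyParams:
    """Default free-energy parameters of the package.

    rho_P=1, alpha=0.1, beta=0.7 fix the protein double well.  The coupling
    constants (chi, c_rep, rho_R) were chosen so that protein partitioning
    is re-entrant in total RNA (enrichment rises, peaks, then falls back to
    a mixed phase; see docs/calibration_log.csv, regenerated by
    scripts/calibrate_free_energy.py), and kappa so that a relaxed 1-D
    interface spans a few grid cells at the reference spacing dx=0.2.
    """
    return FreeEnergyParams(rho_P=1.0, alpha=0.1, beta=0.7,
                            chi=0.6, c_rep=1.6, rho_R=0.4, kappa=0.08)
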