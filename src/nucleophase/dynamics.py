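"""Coupled conserved protein / reaction-diffusion RNA dynamics.

Protein undergoes conserved (Model B) relaxation of the free energy,

    dphi_P/dt = M_p lap( mu_P ),   mu_P = df/dphi_P - kappa lap(phi_P)

and RNA is produced by local gene activity, diffuses and decays:

    dphi_R/dt = M_r lap(phi_R) + k_p(x) phi_P - k_d phi_R

on the masked-disk domain with no-flux boundaries everywhere.

Time stepping is a semi-implicit finite-volume scheme with inner sweeps.
The backward-Euler update of the protein field is solved by chord-Newton
iteration: the chemical potential is linearised about the current sweep
iterate, mu_b(phi) ~ mu_b(phi^s) + D (phi - phi^s) with
D = diag(d2f/dphi_P^2), and each sweep solves

    (I - dt M_p L D_ref + dt M_p kappa L^2) phi^{s+1}
        = phi^n + dt M_p L (mu_b(phi^s, phi_R^n) - D_ref phi^s)

with L the no-flux Laplacian.  The sparse LU factor of the left-hand side
is reused across sweeps and across steps while it still contracts (near
steady state the same factor serves for hundreds of steps); when sweeps
stall the matrix is rebuilt at the current fields, and only if that also
fails is the step rejected and dt halved.  Because every update enters
through L (whose columns sum to zero), total protein is conserved to
solver precision, and the implicit RNA update satisfies the discrete
production/degradation balance exactly at the endpoint values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

from .free_energy import FreeEnergyParams, hessian, mu_P
from .geometry import Domain

__all__ = ["KineticParams", "FieldState", "Trajectory", "seed_droplet",
           "uniform_state", "step", "evolve", "EvolveControls",
           "SemiImplicitStepper", "rna_steady_state", "config_hash"]


@dataclass(frozen=True)
class KineticParams:
    """Mobilities and RNA turnover.

    M_p, M_r are the protein and RNA mobility constants (simulation
    units); k_d the first-order RNA degradation rate.  The biologically
    relevant regime for activity-driven nucleation has M_r/M_p of order
    one or below (RNA no more mobile than protein).
    """

    M_p: float = 1.0
    M_r: float = 1.0
    k_d: float = 0.5

    def __post_init__(self):
        if min(self.M_p, self.M_r, self.k_d) < 0:
            raise ValueError("M_p, M_r, k_d must be >= 0")


@dataclass
class FieldState:
    """Protein and RNA concentration fields at one time."""

    t: float
    phi_P: np.ndarray
    phi_R: np.ndarray

    def copy(self) -> "FieldState":
        return FieldState(self.t, self.phi_P.copy(), self.phi_R.copy())


@dataclass
class Trajectory:
    """Decimated snapshots plus per-step scalar series of one run."""

    snapshots: list
    scalars: pd.DataFrame
    run_meta: dict = field(default_factory=dict)

    @property
    def final(self) -> FieldState:
        return self.snapshots[-1]

    def to_hdf5(self, path, domain: Domain | None = None) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            cfg = f.create_group("config")
            cfg.attrs["meta_json"] = json.dumps(self.run_meta, default=str)
            sc = f.create_group("scalars")
            for col in self.scalars.columns:
                sc.create_dataset(col, data=self.scalars[col].to_numpy())
            snaps = f.create_group("snapshots")
            for s in self.snapshots:
                g = snaps.create_group(f"{s.t:.6f}")
                g.attrs["t"] = s.t
                g.create_dataset("phi_P", data=s.phi_P)
                g.create_dataset("phi_R", data=s.phi_R)
            if domain is not None:
                d = f.create_group("domain")
                d.attrs["radius"] = domain.radius
                d.attrs["dx"] = domain.dx

    @classmethod
    def from_hdf5(cls, path) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as f:
            meta = json.loads(f["config"].attrs["meta_json"])
            scalars = pd.DataFrame(
                {k: f["scalars"][k][...] for k in f["scalars"]})
            snaps = sorted(
                (f["snapshots"][k] for k in f["snapshots"]),
                key=lambda g: g.attrs["t"])
            snapshots = [FieldState(float(g.attrs["t"]), g["phi_P"][...],
                                    g["phi_R"][...]) for g in snaps]
        if "t" in scalars.columns:
            scalars = scalars.sort_values("t", ignore_index=True)
        return cls(snapshots=snapshots, scalars=scalars, run_meta=meta)


# ---------------------------------------------------------------------------
# initial conditions

def seed_droplet(domain: Domain, center, R0: float, phi_in: float = 0.63,
                 phi_out: float = 0.13) -> FieldState:
    """Dense protein seed in a dilute background; RNA starts at zero.

    The seed edge is smoothed over about two cells with a tanh ramp so the
    conserved dynamics do not start from a discontinuity.
    """
    cx, cy = center
    if not (0 <= phi_out < phi_in):
        raise ValueError("require 0 <= phi_out < phi_in")
    if np.hypot(cx, cy) + R0 > domain.radius:
        raise ValueError("seed extends outside the domain")
    r = np.hypot(domain.x - cx, domain.y - cy)
    if R0 <= 0:
        phi = np.full(domain.n_cells, phi_out)
    else:
        w = 2.0 * domain.dx
        phi = phi_out + 0.5 * (phi_in - phi_out) * (1.0 - np.tanh(
            (r - R0) / w))
    return FieldState(0.0, phi, np.zeros(domain.n_cells))


def uniform_state(domain: Domain, phi_P0: float) -> FieldState:
    """Spatially uniform dilute protein, zero RNA (the nucleation-from-
    scratch initial condition)."""
    if phi_P0 < 0:
        raise ValueError("phi_P0 must be >= 0")
    return FieldState(0.0, np.full(domain.n_cells, phi_P0),
                      np.zeros(domain.n_cells))


# ---------------------------------------------------------------------------
# stepper

class SemiImplicitStepper:
    """Stabilised IMEX integrator for the coupled fields on one domain.

    Reusable across steps; caches sparse LU factorisations keyed on
    (dt, stabilisation level, mobilities).
    """

    def __init__(self, domain: Domain, fe: FreeEnergyParams,
                 kin: KineticParams, rate: np.ndarray,
                 max_sweeps: int = 5, sweep_tol: float = 1e-6,
                 frozen_protein: bool = False):
        self.domain = domain
        self.fe = fe
        self.kin = kin
        self.rate = np.asarray(rate, dtype=float)
        self.max_sweeps = max_sweeps
        self.sweep_tol = sweep_tol
        self.frozen_protein = frozen_protein
        self.L = domain.laplacian().tocsc()
        self.L2 = (self.L @ self.L).tocsc()
        self.I = sparse.identity(domain.n_cells, format="csc")
        self._lu_P = None
        self._lu_P_dt = None
        self._D_ref = None
        self._lu_R_cache: dict = {}
        self.n_factorisations = 0
        self.min_phi_P_seen = np.inf

    def _build_P(self, dt, phi_P, phi_R) -> None:
        f_pp, _, _ = hessian(phi_P, phi_R, self.fe)
        D = sparse.diags(f_pp).tocsc()
        M = (self.I - dt * self.kin.M_p * (self.L @ D)
             + dt * self.kin.M_p * self.fe.kappa * self.L2)
        self._lu_P = splu(M.tocsc())
        self._lu_P_dt = round(float(dt), 12)
        self._D_ref = f_pp
        self.n_factorisations += 1

    def _lu_R(self, dt):
        key = round(float(dt), 12)
        if key not in self._lu_R_cache:
            M = ((1.0 + dt * self.kin.k_d) * self.I
                 - dt * self.kin.M_r * self.L)
            if len(self._lu_R_cache) > 40:
                self._lu_R_cache.clear()
            self._lu_R_cache[key] = splu(M.tocsc())
        return self._lu_R_cache[key]

    def _sweep(self, phi_Pn, phi_Rn, dt, diag):
        """Chord-Newton sweeps with the current factorisation; returns the
        converged field or None."""
        phi_s = phi_Pn
        for s in range(self.max_sweeps):
            mu_b = mu_P(phi_s, phi_Rn, self.fe)
            rhs = phi_Pn + dt * self.kin.M_p * (
                self.L @ (mu_b - self._D_ref * phi_s))
            phi_next = self._lu_P.solve(rhs)
            resid = float(np.max(np.abs(phi_next - phi_s)))
            phi_s = phi_next
            diag["sweeps"] += 1
            diag["sweep_residual"] = resid
            if not np.all(np.isfinite(phi_s)):
                return None
            if resid < self.sweep_tol:
                return phi_s
        return None

    def attempt(self, state: FieldState, dt: float):
        """Try one step of size dt.

        Returns (new_state, diagnostics) on success or (None, diagnostics)
        on rejection (sweeps failed to converge or fields left the
        trusted range).
        """
        phi_Pn, phi_Rn = state.phi_P, state.phi_R
        diag = {"sweeps": 0, "sweep_residual": np.nan}
        if self.frozen_protein:
            phi_P1 = phi_Pn
        else:
            if self._lu_P is None or self._lu_P_dt != round(float(dt), 12):
                self._build_P(dt, phi_Pn, phi_Rn)
            phi_P1 = self._sweep(phi_Pn, phi_Rn, dt, diag)
            if phi_P1 is None:
                # stale linearisation: rebuild at current fields, retry
                self._build_P(dt, phi_Pn, phi_Rn)
                phi_P1 = self._sweep(phi_Pn, phi_Rn, dt, diag)
            if phi_P1 is None:
                return None, diag
            mn = float(phi_P1.min())
            self.min_phi_P_seen = min(self.min_phi_P_seen, mn)
            if mn < -0.05:
                return None, diag

        lu_r = self._lu_R(dt)
        rhs_r = phi_Rn + dt * self.rate * phi_P1
        phi_R1 = lu_r.solve(rhs_r)
        if not np.all(np.isfinite(phi_R1)):
            return None, diag

        area = self.domain.cell_area
        diag["production"] = float(np.sum(self.rate * phi_P1)) * area
        diag["degradation"] = self.kin.k_d * float(np.sum(phi_R1)) * area
        return FieldState(state.t + dt, phi_P1, phi_R1), diag


def step(state: FieldState, fe: FreeEnergyParams, kin: KineticParams,
         rate: np.ndarray, dt: float, domain: Domain,
         stepper: SemiImplicitStepper | None = None) -> FieldState:
    """Advance one fixed step of size dt (raises on rejection).

    For repeated stepping pass a reusable ``SemiImplicitStepper``; this
    wrapper exists for one-off use and testing.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if stepper is None:
        stepper = SemiImplicitStepper(domain, fe, kin, rate)
    new, diag = stepper.attempt(state, dt)
    if new is None:
        raise RuntimeError(f"step of dt={dt} rejected: {diag}")
    return new


@dataclass
class EvolveControls:
    """Adaptive time-stepping and termination policy."""

    dt0: float = 0.05
    dt_max: float = 0.5
    dt_min: float = 1e-4
    growth: float = 1.1
    max_steps: int = 15000
    t_end: float | None = None
    steady_tol: float = 1e-6
    steady_window: int = 50
    snapshot_every: int = 200
    max_sweeps: int = 5
    sweep_tol: float = 1e-6


def evolve(state: FieldState, fe: FreeEnergyParams, kin: KineticParams,
           rate: np.ndarray, domain: Domain,
           controls: EvolveControls | None = None,
           frozen_protein: bool = False) -> Trajectory:
    """Integrate to steady state or budget exhaustion.

    dt grows by ``growth`` per accepted step (capped at dt_max) and halves
    on rejection; the run stops when max |dphi|/dt stays below
    ``steady_tol`` for ``steady_window`` consecutive accepted steps, when
    ``t_end`` is reached, or when ``max_steps`` accepted steps have run.
    Repeated rejection below dt_min aborts with a diagnostic trajectory.
    """
    c = controls or EvolveControls()
    stepper = SemiImplicitStepper(domain, fe, kin, rate,
                                  max_sweeps=c.max_sweeps,
                                  sweep_tol=c.sweep_tol,
                                  frozen_protein=frozen_protein)
    area = domain.cell_area
    cur = state.copy()
    snapshots = [cur.copy()]
    rows = []
    dt = c.dt0
    steady_run = 0
    stop_reason = "max_steps"
    n_accepted = 0
    while n_accepted < c.max_steps:
        if c.t_end is not None and cur.t >= c.t_end:
            stop_reason = "t_end"
            break
        if c.t_end is not None:
            dt = min(dt, c.t_end - cur.t)
        new, diag = stepper.attempt(cur, dt)
        if new is None:
            dt *= 0.5
            if dt < c.dt_min:
                stop_reason = "aborted_dt_min"
                break
            continue
        dphi = max(float(np.max(np.abs(new.phi_P - cur.phi_P))),
                   float(np.max(np.abs(new.phi_R - cur.phi_R))))
        rate_of_change = dphi / dt
        cur = new
        n_accepted += 1
        rows.append({
            "t": cur.t, "dt": dt, "sweeps": diag["sweeps"],
            "total_P": float(np.sum(cur.phi_P)) * area,
            "total_R": float(np.sum(cur.phi_R)) * area,
            "max_phi_R": float(np.max(cur.phi_R)),
            "min_phi_P": float(np.min(cur.phi_P)),
            "production": diag.get("production", 0.0),
            "degradation": diag.get("degradation", 0.0),
            "rate_of_change": rate_of_change,
        })
        if n_accepted % c.snapshot_every == 0:
            snapshots.append(cur.copy())
        steady_run = steady_run + 1 if rate_of_change < c.steady_tol else 0
        if steady_run >= c.steady_window:
            stop_reason = "steady_state"
            break
        dt = min(dt * c.growth, c.dt_max)
    if not snapshots or snapshots[-1].t < cur.t:
        snapshots.append(cur.copy())
    scalars = pd.DataFrame(rows)
    meta = {
        "stop_reason": stop_reason,
        "n_accepted": n_accepted,
        "min_phi_P_seen": stepper.min_phi_P_seen,
        "n_factorisations": stepper.n_factorisations,
        "frozen_protein": frozen_protein,
    }
    return Trajectory(snapshots=snapshots, scalars=scalars, run_meta=meta)


def rna_steady_state(domain: Domain, rate: np.ndarray, phi_P: np.ndarray,
                     kin: KineticParams) -> np.ndarray:
    """Direct solve of the steady RNA balance
    M_r lap(phi_R) + rate * phi_P - k_d phi_R = 0 for a frozen protein
    field (no time stepping)."""
    L = domain.laplacian().tocsc()
    n = domain.n_cells
    M = kin.k_d * sparse.identity(n, format="csc") - kin.M_r * L
    return splu(M).solve(np.asarray(rate) * np.asarray(phi_P))


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
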