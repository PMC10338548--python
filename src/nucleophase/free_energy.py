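"""Bulk free energy of the RNA-protein mixture.

The local (bulk) free-energy density is

    f(phi_P, phi_R) = rho_P (phi_P - alpha)^2 (phi_P - beta)^2
                      - chi phi_P phi_R
                      + c phi_P^2 phi_R^2
                      + rho_R phi_R^2

a protein double well with binodal roots ``alpha`` and ``beta``, a linear
heterotypic RNA-protein attraction (``chi``), a quartic repulsion at high
joint concentration (``c``, the source of re-entrant phase behaviour) and an
RNA self-repulsion (``rho_R``).  The square-gradient surface energy
(kappa/2)|grad phi_P|^2 is handled by the dynamics and equilibrium-interface
code; only its coefficient ``kappa`` lives here.

Concentrations may transiently go slightly negative during conserved
dynamics; the polynomial energy is defined there and no clipping is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FreeEnergyParams",
    "bulk_energy",
    "mu_P",
    "mu_R",
    "hessian",
    "stability_det",
    "dilute_diffusivity",
]


@dataclass(frozen=True)
class FreeEnergyParams:
    """Coefficients of the bulk free energy plus the gradient penalty.

    Parameters
    ----------
    rho_P : float
        Double-well strength (energy * conc^-4).  Must be > 0.
    alpha, beta : float
        Dilute and dense protein binodal concentrations of the pure double
        well, with 0 <= alpha < beta.
    chi : float
        RNA-protein attraction strength (energy * conc^-2), >= 0.
    c_rep : float
        Quartic RNA-protein repulsion (energy * conc^-4), >= 0.
    rho_R : float
        RNA self-repulsion (energy * conc^-2), >= 0.
    kappa : float
        Square-gradient (surface energy) coefficient
        (energy * length^2 * conc^-2), >= 0.
    """

    rho_P: float = 1.0
    alpha: float = 0.1
    beta: float = 0.7
    chi: float = 0.0
    c_rep: float = 0.0
    rho_R: float = 1.0
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.rho_P, self.alpha, self.beta,
                                   self.chi, self.c_rep, self.rho_R,
                                   self.kappa])):
            raise ValueError("free-energy parameters must be finite")
        if self.rho_P <= 0:
            raise ValueError("rho_P must be > 0")
        if self.rho_R < 0 or self.c_rep < 0 or self.kappa < 0 or self.chi < 0:
            raise ValueError("chi, c_rep, rho_R, kappa must be >= 0")
        if not (0 <= self.alpha < self.beta):
            raise ValueError("require 0 <= alpha < beta")

    @property
    def threshold(self) -> float:
        """Dense-phase segmentation threshold (alpha + beta) / 2."""
        return 0.5 * (self.alpha + self.beta)


def _check_finite(*fields) -> None:
    for f in fields:
        if not np.all(np.isfinite(f)):
            raise FloatingPointError(
                "non-finite concentration passed to free-energy evaluation "
                "(corrupted state)")


def bulk_energy(phi_P, phi_R, p: FreeEnergyParams):
    """Bulk free-energy density f(phi_P, phi_R).  Vectorised."""
    phi_P = np.asarray(phi_P, dtype=float)
    phi_R = np.asarray(phi_R, dtype=float)
    _check_finite(phi_P, phi_R)
    dwell = p.rho_P * (phi_P - p.alpha) ** 2 * (phi_P - p.beta) ** 2
    return (dwell - p.chi * phi_P * phi_R
            + p.c_rep * phi_P ** 2 * phi_R ** 2
            + p.rho_R * phi_R ** 2)


def mu_P(phi_P, phi_R, p: FreeEnergyParams, lap_phi_P=None):
    """Protein chemical potential df/dphi_P.

    With ``lap_phi_P`` given, returns the full functional derivative
    including the interfacial term -kappa * lap(phi_P) used by the conserved
    dynamics; without it, the bulk partial derivative used by the
    equilibrium solver.
    """
    phi_P = np.asarray(phi_P, dtype=float)
    phi_R = np.asarray(phi_R, dtype=float)
    _check_finite(phi_P, phi_R)
    a, b = p.alpha, p.beta
    mu = (2.0 * p.rho_P * (phi_P - a) * (phi_P - b) * (2.0 * phi_P - a - b)
          - p.chi * phi_R + 2.0 * p.c_rep * phi_P * phi_R ** 2)
    if lap_phi_P is not None:
        mu = mu - p.kappa * np.asarray(lap_phi_P, dtype=float)
    return mu


def mu_R(phi_P, phi_R, p: FreeEnergyParams):
    """RNA chemical potential df/dphi_R (bulk)."""
    phi_P = np.asarray(phi_P, dtype=float)
    phi_R = np.asarray(phi_R, dtype=float)
    _check_finite(phi_P, phi_R)
    return (-p.chi * phi_P + 2.0 * p.c_rep * phi_P ** 2 * phi_R
            + 2.0 * p.rho_R * phi_R)


def hessian(phi_P, phi_R, p: FreeEnergyParams):
    """Second partials (f_pp, f_pr, f_rr) of the bulk energy."""
    phi_P = np.asarray(phi_P, dtype=float)
    phi_R = np.asarray(phi_R, dtype=float)
    _check_finite(phi_P, phi_R)
    a, b = p.alpha, p.beta
    f_pp = 2.0 * p.rho_P * ((phi_P - a) ** 2 + 4.0 * (phi_P - a) * (phi_P - b)
                            + (phi_P - b) ** 2) + 2.0 * p.c_rep * phi_R ** 2
    f_pr = -p.chi + 4.0 * p.c_rep * phi_P * phi_R
    f_rr = 2.0 * p.c_rep * phi_P ** 2 + 2.0 * p.rho_R
    return f_pp, f_pr, f_rr


def stability_det(phi_P, phi_R, p: FreeEnergyParams):
    """det of the bulk-energy Hessian; negative marks locally unstable
    (spinodal / interfacial) compositions, the condensate-interface
    criterion used by the morphometrics."""
    f_pp, f_pr, f_rr = hessian(phi_P, phi_R, p)
    return f_pp * f_rr - f_pr ** 2


def dilute_diffusivity(p: FreeEnergyParams, M_p: float = 1.0) -> float:
    """Effective protein diffusivity D_p in the dilute limit.

    Linearising the conserved (Model B) flux about (phi_P, phi_R) = (0, 0)
    gives an effective diffusion coefficient
    D_p = M_p * d2f/dphi_P^2|_(0,0) = 2 M_p rho_P (alpha^2 + 4 alpha beta
    + beta^2); 1.56 * M_p for the default well (rho_P=1, alpha=0.1,
    beta=0.7).  Used to scale condensate drift speeds.
    """
    f_pp, _, _ = hessian(0.0, 0.0, p)
    return float(M_p * f_pp)
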