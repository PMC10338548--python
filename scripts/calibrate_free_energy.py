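"""Regenerate the calibration log for the default free-energy couplings.

Records the re-entrance scan (enrichment vs total RNA) for the shipped
defaults and the 1-D relaxed interface width that motivates the default
kappa.  Output: docs/calibration_log.csv.

Run from the repository root:  python scripts/calibrate_free_energy.py
"""

import numpy as np
import pandas as pd

from nucleophase.equilibrium import calibrate_defaults, partition_scan


def interface_width_1d(p, dx=0.2, n=200, n_steps=40000, dt=2e-4):
    """10-90% rise width of a relaxed 1-D double-well interface (explicit
    conserved dynamics, no RNA; dt below the explicit biharmonic limit)."""
    from nucleophase.free_energy import mu_P

    x = (np.arange(n) + 0.5) * dx
    mid = 0.5 * (p.alpha + p.beta)
    amp = 0.5 * (p.beta - p.alpha)
    phi = mid - amp * np.tanh((x - x.mean()) / (4 * dx))

    def lap(v):
        out = np.empty_like(v)
        out[1:-1] = (v[2:] - 2 * v[1:-1] + v[:-2]) / dx ** 2
        out[0] = (v[1] - v[0]) / dx ** 2
        out[-1] = (v[-2] - v[-1]) / dx ** 2
        return out

    for _ in range(n_steps):
        mu = mu_P(phi, np.zeros_like(phi), p) - p.kappa * lap(phi)
        phi = phi + dt * lap(mu)
    lo = p.alpha + 0.1 * (p.beta - p.alpha)
    hi = p.alpha + 0.9 * (p.beta - p.alpha)
    inside = (phi > lo) & (phi < hi)
    return inside.sum() * dx


def main():
    p = calibrate_defaults()
    grid = np.concatenate([[0.0], np.linspace(0.01, 1.0, 50)])
    df = partition_scan(p, 0.4, grid)
    df["rho_P"], df["alpha"], df["beta"] = p.rho_P, p.alpha, p.beta
    df["chi"], df["c_rep"], df["rho_R"], df["kappa"] = (
        p.chi, p.c_rep, p.rho_R, p.kappa)
    width = interface_width_1d(p)
    df["interface_width_dx02"] = width
    df.to_csv("docs/calibration_log.csv", index=False)
    e = df["enrichment"].to_numpy()
    print(f"defaults: chi={p.chi} c_rep={p.c_rep} rho_R={p.rho_R} "
          f"kappa={p.kappa}")
    print(f"enrichment: start {e[0]:.2f}, max {e.max():.2f} at "
          f"phi_R={df['phi_R_total'][e.argmax()]:.3f}, end {e[-1]:.2f}")
    print(f"re-entrant: {bool(e.max() > e[0] and e[-1] < e.max())}")
    print(f"1-D interface width at dx=0.2: {width:.2f} length units "
          f"({width / 0.2:.1f} cells)")


if __name__ == "__main__":
    main()
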