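"""Condensate morphology and dynamics metrics from field snapshots.

Dense regions are the connected components of phi_P above the midpoint
threshold (alpha + beta)/2; their effective radius is sqrt(area/pi).
Vacuoles are dilute regions fully enclosed by a dense component.
Interfaces are bands where the bulk free-energy Hessian determinant is
negative (locally unstable compositions); a plain droplet crosses one such
band along a radial ray, a vacuole (core-shell) morphology two.  Centroid
and eccentricity come from the first and second moments of the
concentration profile.  Flow metrics convert condensate drift into the
dimensionless velocity v * R_c / D_p with D_p the dilute-limit protein
diffusivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .free_energy import FreeEnergyParams, dilute_diffusivity, stability_det
from .geometry import Domain

__all__ = ["MorphologyReport", "segment_dense", "vacuole_radius",
           "interface_bands", "centroid_eccentricity", "flow_metrics",
           "classify", "morphology_report"]


@dataclass
class MorphologyReport:
    """Per-snapshot morphology summary."""

    R_eff: float
    vacuole_radius: float | None
    n_interfaces: int
    centroid: tuple[float, float] | None
    eccentricity: float | None
    n_components: int
    classification: str | None = None
    dynamics_class: str | None = None


def _dense_mask(phi_P, domain: Domain, fe: FreeEnergyParams):
    grid = domain.to_grid(np.asarray(phi_P), fill=-np.inf)
    return grid > fe.threshold


def segment_dense(phi_P, domain: Domain, fe: FreeEnergyParams):
    """Label connected dense regions (phi_P above (alpha+beta)/2).

    Returns (labels 2-D array, list of region dicts with area, R_eff and
    centroid in physical coordinates).
    """
    dense = _dense_mask(phi_P, domain, fe)
    labels = measure.label(dense, connectivity=1)
    regions = []
    # grid coordinate axes (cell centres) for physical centroids
    n = domain.mask.shape[0]
    coords = (np.arange(n) - n / 2 + 0.5) * domain.dx
    for rp in measure.regionprops(labels):
        area = rp.area * domain.cell_area
        ci, cj = rp.centroid
        regions.append({
            "label": rp.label,
            "area": area,
            "R_eff": float(np.sqrt(area / np.pi)),
            "centroid": (float(np.interp(ci, np.arange(n), coords)),
                         float(np.interp(cj, np.arange(n), coords))),
        })
    regions.sort(key=lambda r: -r["area"])
    return labels, regions


def total_R_eff(phi_P, domain: Domain, fe: FreeEnergyParams) -> float:
    """Effective radius of all dense material, sqrt(total area / pi).

    Threshold-crossing cells contribute their estimated sub-cell covered
    fraction (from the local gradient), so the area does not jump by
    whole cells as the interface moves across the grid.
    """
    phi = np.asarray(phi_P, dtype=float)
    grid = domain.to_grid(phi, fill=np.nan)
    gx, gy = np.gradient(np.nan_to_num(grid, nan=0.0), domain.dx)
    mag = np.hypot(gx, gy)[domain.mask]
    step = mag * domain.dx
    frac = np.where(step > 1e-6,
                    np.clip(0.5 + (phi - fe.threshold)
                            / np.maximum(step, 1e-300), 0.0, 1.0),
                    (phi > fe.threshold).astype(float))
    return float(np.sqrt(frac.sum() * domain.cell_area / np.pi))


def vacuole_radius(phi_P, domain: Domain, fe: FreeEnergyParams,
                   cluster_center=None) -> float | None:
    """Equivalent radius of the largest dilute region enclosed by dense
    material, or None if no vacuole exists."""
    dense = _dense_mask(phi_P, domain, fe)
    filled = ndimage.binary_fill_holes(dense)
    vac = filled & ~dense & domain.mask
    if not vac.any():
        return None
    labels = measure.label(vac, connectivity=1)
    areas = np.bincount(labels.ravel())[1:]
    return float(np.sqrt(areas.max() * domain.cell_area / np.pi))


def interface_bands(phi_P, phi_R, fe: FreeEnergyParams, domain: Domain,
                    center=(0.0, 0.0), direction=(1.0, 0.0)) -> int:
    """Count locally unstable (det(J) < 0) bands along a radial ray.

    The ray starts at ``center`` and runs outward along ``direction`` to
    the domain edge.  Both concentration fields are bilinearly
    interpolated along the ray (quarter-cell sampling) and det(J) is
    evaluated on the interpolated compositions, so that narrow unstable
    bands crossed between adjacent cells are not hopped over; contiguous
    negative runs are counted.  One band marks a plain droplet interface,
    two a vacuole's dual interfaces.
    """
    from scipy.interpolate import RegularGridInterpolator

    cx, cy = center
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    n = domain.mask.shape[0]
    coords = (np.arange(n) - n / 2 + 0.5) * domain.dx
    smax = domain.radius - np.hypot(cx, cy) - domain.dx
    s = np.arange(0.0, max(smax, 0.0), domain.dx / 4.0)
    pts = np.column_stack([cx + s * d[0], cy + s * d[1]])
    interp_P = RegularGridInterpolator(
        (coords, coords), domain.to_grid(np.asarray(phi_P), fill=np.nan),
        bounds_error=False, fill_value=np.nan)
    interp_R = RegularGridInterpolator(
        (coords, coords), domain.to_grid(np.asarray(phi_R), fill=np.nan),
        bounds_error=False, fill_value=np.nan)
    pP, pR = interp_P(pts), interp_R(pts)
    ok = np.isfinite(pP) & np.isfinite(pR)
    vals = np.full(s.shape, np.nan)
    vals[ok] = stability_det(pP[ok], pR[ok], fe)
    neg = (vals < 0) & np.isfinite(vals)
    # count rising edges of the negative indicator
    return int(np.sum(neg[1:] & ~neg[:-1]) + (1 if neg.size and neg[0]
                                              else 0))


def centroid_eccentricity(phi_P, domain: Domain,
                          fe: FreeEnergyParams | None = None,
                          mass: str = "thresholded",
                          formula: str = "invariant"):
    """Mass-weighted centroid and eccentricity of the protein profile.

    mass="thresholded" (default) restricts the weights to the dense region
    phi_P > (alpha+beta)/2 (requires ``fe``); mass="raw" uses the full
    field.  The default eccentricity is the rotation-invariant
    ((I_xx - I_yy)^2 + 4 I_xy^2) / (I_xx + I_yy)^2 of the central second
    moments; formula="literal" evaluates (I_xx - I_yy)^2 - 4 I_xy over the
    same denominator (not rotation-invariant, agrees whenever I_xy = 0).
    """
    w = np.asarray(phi_P, dtype=float).copy()
    if mass == "thresholded":
        if fe is None:
            raise ValueError("thresholded mass weighting requires fe")
        w[w <= fe.threshold] = 0.0
    elif mass != "raw":
        raise ValueError("mass must be 'thresholded' or 'raw'")
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total mass; no centroid defined")
    cx = float(np.dot(w, domain.x) / total)
    cy = float(np.dot(w, domain.y) / total)
    dxs, dys = domain.x - cx, domain.y - cy
    I_xx = float(np.dot(w, dxs ** 2) / total)
    I_yy = float(np.dot(w, dys ** 2) / total)
    I_xy = float(np.dot(w, dxs * dys) / total)
    denom = (I_xx + I_yy) ** 2
    if denom == 0:
        e = 0.0
    elif formula == "invariant":
        e = ((I_xx - I_yy) ** 2 + 4.0 * I_xy ** 2) / denom
    elif formula == "literal":
        e = ((I_xx - I_yy) ** 2 - 4.0 * I_xy) / denom
    else:
        raise ValueError("formula must be 'invariant' or 'literal'")
    return (cx, cy), float(e)


def flow_metrics(traj, fe: FreeEnergyParams, kin, domain: Domain,
                 R_c: float = 4.0):
    """Condensate drift velocity from snapshot centroids.

    Tracks the condensate nearest to the previous position (max jump
    2 R_c per interval); the series is truncated with ``lost=True`` if the
    condensate dissolves or jumps away.  Returns a dict with times,
    positions, speeds, the dimensionless series v R_c / D_p and its peak.
    """
    D_p = dilute_diffusivity(fe, kin.M_p)
    times, pos = [], []
    lost = False
    prev = None
    for s in traj.snapshots:
        _, regions = segment_dense(s.phi_P, domain, fe)
        if not regions:
            lost = prev is not None
            break
        if prev is None:
            r = regions[0]
        else:
            r = min(regions,
                    key=lambda q: np.hypot(q["centroid"][0] - prev[0],
                                           q["centroid"][1] - prev[1]))
            if np.hypot(r["centroid"][0] - prev[0],
                        r["centroid"][1] - prev[1]) > 2.0 * R_c:
                lost = True
                break
        prev = r["centroid"]
        times.append(s.t)
        pos.append(prev)
    times = np.asarray(times)
    pos = np.asarray(pos).reshape(-1, 2)
    if len(times) >= 2:
        dt = np.diff(times)
        steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        speed = steps / dt
    else:
        speed = np.array([])
    vdim = speed * R_c / D_p
    return {
        "t": times,
        "position": pos,
        "speed": speed,
        "dimensionless_velocity": vdim,
        "peak_dimensionless_velocity": float(vdim.max()) if vdim.size
        else 0.0,
        "lost": lost,
        "D_p": D_p,
    }


def morphology_report(state, domain: Domain, fe: FreeEnergyParams,
                      cluster_center=(0.0, 0.0)) -> MorphologyReport:
    """Morphology metrics of a single snapshot."""
    _, regions = segment_dense(state.phi_P, domain, fe)
    if not regions:
        return MorphologyReport(R_eff=0.0, vacuole_radius=None,
                                n_interfaces=0, centroid=None,
                                eccentricity=None, n_components=0)
    centroid, ecc = centroid_eccentricity(state.phi_P, domain, fe)
    return MorphologyReport(
        R_eff=total_R_eff(state.phi_P, domain, fe),
        vacuole_radius=vacuole_radius(state.phi_P, domain, fe),
        n_interfaces=interface_bands(state.phi_P, state.phi_R, fe, domain,
                                     center=cluster_center),
        centroid=centroid,
        eccentricity=ecc,
        n_components=len(regions),
    )


def classify(traj, clusters, fe: FreeEnergyParams, kin, domain: Domain,
             R_c: float = 4.0, ecc_threshold: float = 0.05):
    """Qualitative (morphology, dynamics) outcome of a trajectory.

    Morphology of the final state: ``dissolved`` (no dense region),
    ``vacuole`` (enclosed dilute region), ``aspherical`` (eccentricity
    above threshold), else ``spherical``.  Dynamics relative to the first
    cluster: ``dissolution_renucleation`` (the original condensate
    vanished and a new one appeared at the cluster), ``flow`` (net centroid
    displacement toward the cluster exceeding R_c/2 with the condensate
    persisting), ``at_site`` (started overlapping the cluster and moved
    less than R_c/4), ``no_effect`` otherwise.
    """
    final = traj.final
    _, regions_end = segment_dense(final.phi_P, domain, fe)
    if not regions_end:
        morph = "dissolved"
    elif vacuole_radius(final.phi_P, domain, fe) is not None:
        morph = "vacuole"
    else:
        _, ecc = centroid_eccentricity(final.phi_P, domain, fe)
        morph = "aspherical" if ecc > ecc_threshold else "spherical"

    target = np.asarray(clusters[0].center if clusters else (0.0, 0.0),
                        dtype=float)
    fm = flow_metrics(traj, fe, kin, domain, R_c=R_c)
    if fm["position"].size == 0:
        return morph, "no_effect"
    p0, p_last = fm["position"][0], fm["position"][-1]
    d0 = float(np.linalg.norm(p0 - target))
    d_last = float(np.linalg.norm(p_last - target))
    displacement = float(np.linalg.norm(p_last - p0))
    if fm["lost"]:
        if regions_end and np.linalg.norm(
                np.asarray(regions_end[0]["centroid"]) - target) < 2 * R_c:
            return morph, "dissolution_renucleation"
        return morph, "no_effect"
    if (d0 - d_last) > R_c / 2.0:
        return morph, "flow"
    if d0 <= R_c and displacement < R_c / 4.0:
        return morph, "at_site"
    return morph, "no_effect"
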