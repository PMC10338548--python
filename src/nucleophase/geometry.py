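"""Circular simulation domain and spatially clustered gene activity.

The nucleus is modelled as a 2-D disk discretised on a regular Cartesian
grid masked to the disk; the mask edge carries the no-flux boundary.  Gene
activity enters as a per-cell RNA-production rate constant: one or more
Gaussian clusters k_p(x) = c * exp(-|x - x0|^2 / 2 sigma^2) with total
activity k_T = integral of k_p over the domain, or a spatially uniform
control with the same total activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = ["Domain", "GeneCluster", "build_domain", "rate_field",
           "uniform_rate_field", "disc_rate_field"]


@dataclass(frozen=True)
class GeneCluster:
    """One localised site of transcriptional activity.

    ``k_T`` is the total activity (the rate constant summed over space) and
    ``sigma`` its spatial extent; the infinite-domain peak amplitude is
    k_T / (2 pi sigma^2).
    """

    center: tuple[float, float]
    sigma: float
    k_T: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.k_T < 0:
            raise ValueError("k_T must be >= 0")

    @property
    def amplitude(self) -> float:
        return self.k_T / (2.0 * np.pi * self.sigma ** 2)


@dataclass(frozen=True)
class Domain:
    """Disk of given radius on a cell-centred Cartesian grid.

    Fields live on the 1-D vector of in-disk cells; ``mask`` maps them back
    to the 2-D grid.  The in-domain graph Laplacian (5-point stencil with
    missing-neighbour rows shortened) encodes the no-flux boundary: its
    rows and columns sum to zero, so conserved dynamics conserve mass
    exactly.
    """

    radius: float
    dx: float
    x: np.ndarray = field(repr=False)      # 1-D cell-centre coords, in-disk
    y: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)   # 2-D bool
    index: np.ndarray = field(repr=False)  # 2-D int, -1 outside

    @property
    def n_cells(self) -> int:
        return self.x.size

    @property
    def cell_area(self) -> float:
        return self.dx ** 2

    @property
    def area(self) -> float:
        return self.n_cells * self.cell_area

    def to_grid(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        out = np.full(self.mask.shape, fill, dtype=float)
        out[self.mask] = values
        return out

    def laplacian(self) -> sparse.csr_matrix:
        """No-flux 5-point Laplacian over in-domain cells (cached)."""
        if not hasattr(self, "_lap"):
            n = self.n_cells
            idx = self.index
            rows, cols, vals = [], [], []
            ii, jj = np.nonzero(self.mask)
            me = idx[ii, jj]
            inv = 1.0 / self.dx ** 2
            deg = np.zeros(n)
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = ii + di, jj + dj
                ok = ((ni >= 0) & (ni < idx.shape[0])
                      & (nj >= 0) & (nj < idx.shape[1]))
                nb = np.full(me.shape, -1)
                nb[ok] = idx[ni[ok], nj[ok]]
                has = nb >= 0
                rows.append(me[has])
                cols.append(nb[has])
                vals.append(np.full(has.sum(), inv))
                np.add.at(deg, me[has], inv)
            rows.append(np.arange(n))
            cols.append(np.arange(n))
            vals.append(-deg)
            L = sparse.csr_matrix(
                (np.concatenate(vals),
                 (np.concatenate(rows), np.concatenate(cols))),
                shape=(n, n))
            object.__setattr__(self, "_lap", L)
        return self._lap


def build_domain(radius: float, dx: float) -> Domain:
    """Construct the masked-disk domain.

    Raises if the grid is too coarse to resolve interfaces
    (dx > radius / 10).
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if not (0 < dx <= radius / 10.0):
        raise ValueError(
            f"dx={dx} too coarse for radius={radius}; require "
            "dx <= radius/10 (interfaces would be under-resolved)")
    n_half = int(np.ceil(radius / dx))
    coords = (np.arange(-n_half, n_half) + 0.5) * dx
    X, Y = np.meshgrid(coords, coords, indexing="ij")
    mask = X ** 2 + Y ** 2 <= radius ** 2
    index = np.full(mask.shape, -1, dtype=np.int64)
    index[mask] = np.arange(mask.sum())
    return Domain(radius=radius, dx=dx, x=X[mask], y=Y[mask],
                  mask=mask, index=index)


def rate_field(clusters, domain: Domain) -> np.ndarray:
    """Summed Gaussian rate-constant field of one or more gene clusters.

    Each cluster's amplitude is normalised by the *discrete in-domain*
    integral so that sum(k_p) * cell_area == k_T exactly; for
    sigma << radius this coincides with the analytic k_T / (2 pi sigma^2)
    peak amplitude.
    """
    out = np.zeros(domain.n_cells)
    for cl in clusters:
        cx, cy = cl.center
        if cx ** 2 + cy ** 2 > domain.radius ** 2:
            raise ValueError(f"cluster centre {cl.center} outside domain")
        g = np.exp(-((domain.x - cx) ** 2 + (domain.y - cy) ** 2)
                   / (2.0 * cl.sigma ** 2))
        total = g.sum() * domain.cell_area
        if total > 0 and cl.k_T > 0:
            out += (cl.k_T / total) * g
    return out


def uniform_rate_field(k_T: float, domain: Domain) -> np.ndarray:
    """Spatially constant activity with the same total k_T (the
    declustered control)."""
    if k_T < 0:
        raise ValueError("k_T must be >= 0")
    return np.full(domain.n_cells, k_T / domain.area)


def disc_rate_field(center, radius: float, k_p: float,
                    domain: Domain) -> np.ndarray:
    """Top-hat rate constant: k_p inside a disk, zero outside.

    The piecewise-constant activity profile assumed by the closed-form
    steady-state RNA gradient theory; also usable as a user-supplied
    cluster shape.  Edge cells carry the (linearised) covered fraction so
    the discrete source is not aliased to the grid.
    """
    cx, cy = center
    r = np.hypot(domain.x - cx, domain.y - cy)
    frac = np.clip((radius - r) / domain.dx + 0.5, 0.0, 1.0)
    return float(k_p) * frac
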