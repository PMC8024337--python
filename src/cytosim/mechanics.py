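"""Cell-centre off-lattice mechanics.

Delaunay neighbours carry linear springs with rest length ``r_i + r_j``; a
radial outward force keeps cells above the yolk surface and an inward force
beyond a free band promotes intercalation.  Positions follow overdamped
explicit Euler steps.
"""
from __future__ import annotations

import logging
import math

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .errors import IntegrityError
from .params import Params
from .tissue_init import TissueState, Yolk

__all__ = [
    "delaunay_neighbors", "spring_forces", "yolk_surface_force",
    "intercalation_force", "integrate_step", "mechanics_step", "tissue_forces",
]

log = logging.getLogger(__name__)

_UP = np.array([0.0, 1.0])  # normal fallback for a cell exactly at the centre


def delaunay_neighbors(positions, neighbor_cutoff: float = math.inf) -> set:
    """Edge set ``{(i, j), i < j}`` of the Delaunay triangulation.

    For fewer than 3 points, or degenerate (collinear/duplicate) input where
    qhull fails, falls back to all pairs closer than ``neighbor_cutoff``.
    """
    return set(map(tuple, _delaunay_edges(positions, neighbor_cutoff)))


def _delaunay_edges(positions, neighbor_cutoff: float = math.inf) -> np.ndarray:
    """Vectorised core of :func:`delaunay_neighbors`: unique ``(m, 2)`` int
    array of edges with ``i < j`` per row."""
    pts = np.asarray(positions, dtype=float)
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 points")
    if n >= 3:
        try:
            s = Delaunay(pts).simplices
            e = np.vstack([s[:, [0, 1]], s[:, [0, 2]], s[:, [1, 2]]])
            e.sort(axis=1)
            return np.unique(e, axis=0)
        except QhullError:
            pass
    ii, jj = np.triu_indices(n, k=1)
    d = np.hypot(*(pts[jj] - pts[ii]).T)
    keep = d < neighbor_cutoff
    return np.column_stack([ii[keep], jj[keep]]).astype(np.int64)


def spring_forces(cells, edges, k_spring: float,
                  detach_factor: float = 1.5) -> np.ndarray:
    """Linear pairwise springs: ``F_i = k (d - s_ij) û_ij`` with rest length
    ``s_ij = r_i + r_j``; edges stretched beyond ``detach_factor * s_ij``
    contribute nothing.  Returns an ``(n, 2)`` force array aligned with
    ``cells``."""
    n = len(cells)
    forces = np.zeros((n, 2))
    e = (np.asarray(sorted(edges), dtype=int) if isinstance(edges, (set, frozenset))
         else np.asarray(edges, dtype=int))
    if e.size == 0:
        return forces
    pos = np.array([c.position for c in cells], dtype=float)
    rad = np.array([c.radius for c in cells], dtype=float)
    dvec = pos[e[:, 1]] - pos[e[:, 0]]
    d = np.hypot(dvec[:, 0], dvec[:, 1])
    rest = rad[e[:, 0]] + rad[e[:, 1]]
    coincident = d < 1e-12
    if coincident.any():
        log.warning("coincident cell pair(s) in spring_forces; zero force applied")
    active = (~coincident) & (d <= detach_factor * rest)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(d[:, None] > 0, dvec / np.where(d == 0, 1, d)[:, None], 0.0)
    mag = np.where(active, k_spring * (d - rest), 0.0)
    f = mag[:, None] * unit
    np.add.at(forces, e[:, 0], f)
    np.add.at(forces, e[:, 1], -f)
    return forces


def yolk_surface_force(cell, yolk: Yolk, k_out: float) -> np.ndarray:
    """Outward radial restoring force on a cell inside the yolk surface."""
    rel = cell.position - yolk.centre
    d = math.hypot(rel[0], rel[1])
    if d >= yolk.radius:
        return np.zeros(2)
    n_hat = _UP if d == 0 else rel / d
    return k_out * (yolk.radius - d) * n_hat


def intercalation_force(cell, yolk: Yolk, k_in: float, band: float) -> np.ndarray:
    """Inward radial force on a cell beyond the free band above the surface."""
    rel = cell.position - yolk.centre
    d = math.hypot(rel[0], rel[1])
    limit = yolk.radius + band
    if d <= limit:
        return np.zeros(2)
    return -k_in * (d - limit) * (rel / d)


def _boundary_forces(pos: np.ndarray, yolk: Yolk, k_out: float, k_in: float,
                     band: float) -> np.ndarray:
    """Vectorised sum of the two radial boundary forces."""
    rel = pos - yolk.centre
    d = np.hypot(rel[:, 0], rel[:, 1])
    safe_d = np.where(d == 0, 1.0, d)
    n_hat = rel / safe_d[:, None]
    n_hat[d == 0] = _UP
    mag = np.where(
        d < yolk.radius, k_out * (yolk.radius - d),
        np.where(d > yolk.radius + band, -k_in * (d - yolk.radius - band), 0.0),
    )
    return mag[:, None] * n_hat


def tissue_forces(cells, yolk: Yolk, params: Params) -> np.ndarray:
    """Total force field (springs + boundary terms) on the given cells."""
    pos = np.array([c.position for c in cells], dtype=float)
    edges = (_delaunay_edges(pos, params.neighbor_cutoff) if len(cells) >= 2
             else np.empty((0, 2), dtype=int))
    forces = spring_forces(cells, edges, params.k_spring, params.detach_factor)
    forces += _boundary_forces(pos, yolk, params.k_out, params.k_in, params.band)
    return forces


def integrate_step(cells, forces: np.ndarray, eta: float, dt: float,
                   max_disp: float = math.inf):
    """Overdamped explicit Euler: ``x += (F / eta) dt``, displacement capped at
    ``max_disp`` per step.  Mutates cell positions in place."""
    if dt <= 0 or eta <= 0:
        raise ValueError("dt and eta must be positive")
    if not np.all(np.isfinite(forces)):
        bad = [cells[i].id for i in np.nonzero(~np.isfinite(forces).all(axis=1))[0]]
        raise IntegrityError(f"non-finite force on cell id(s) {bad}")
    disp = forces * (dt / eta)
    norms = np.hypot(disp[:, 0], disp[:, 1])
    over = norms > max_disp
    if over.any():
        disp[over] *= (max_disp / norms[over])[:, None]
    for i, cell in enumerate(cells):
        cell.position = cell.position + disp[i]
    return cells


def mechanics_step(state: TissueState, params: Params,
                   rng: np.random.Generator) -> TissueState:
    """One mechanics update of all alive cells (retriangulated every call)."""
    cells = state.alive_cells()
    if len(cells) < 2:
        return state
    pos = np.array([c.position for c in cells], dtype=float)
    # deterministic de-duplication: coincident centres break qhull
    _, inverse, counts = np.unique(
        pos.round(9), axis=0, return_inverse=True, return_counts=True
    )
    if (counts > 1).any():
        dup = counts[inverse] > 1
        pos[dup] += rng.uniform(-1e-6, 1e-6, size=(int(dup.sum()), 2))
        for i in np.nonzero(dup)[0]:
            cells[i].position = pos[i]
    forces = tissue_forces(cells, state.yolk, params)
    integrate_step(cells, forces, params.eta, params.dt, params.max_disp)
    return state
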