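"""Liquid-structure statistics: RMSD, RDF, coordination, density.

All periodic-boundary handling assumes an orthorhombic cell and the
minimum-image convention, valid for pair distances up to half the shortest
cell length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import AMU_TO_GRAM
from .traj_io import Frame, Trajectory

__all__ = [
    "RDFResult",
    "rmsd",
    "rdf",
    "coordination_number",
    "mass_density",
]


def rmsd(
    frame: Frame,
    reference: Frame,
    wrap: bool = False,
    cell: np.ndarray | float | None = None,
    molecules: list[np.ndarray] | None = None,
    superpose: bool = False,
) -> float:
    """Root-mean-square displacement from a reference structure (Å).

    √(mean‖xᵢ − xᵢʳᵉᶠ‖²) with no rotational fit by default — the quantity
    tracks displacement from a reference (e.g. the starting crystal), not
    shape similarity.  With ``wrap`` each molecule's centroid is imaged
    into the primary cell (autoimage behaviour) in both structures before
    comparing; without a ``molecules`` grouping every atom is its own
    molecule.  ``superpose=True`` applies an optional Kabsch best-fit
    rotation after centroid alignment.
    """
    a = np.array(frame.positions, dtype=float)
    b = np.array(reference.positions, dtype=float)
    if a.shape != b.shape:
        raise ValueError("atom count mismatch between frame and reference")
    if wrap:
        if cell is None:
            raise ValueError("wrap requires a cell")
        cell = np.broadcast_to(np.asarray(cell, dtype=float), (3,))
        groups = (
            molecules
            if molecules is not None
            else [np.array([i]) for i in range(len(a))]
        )
        for x in (a, b):
            for g in groups:
                centroid = x[g].mean(axis=0)
                x[g] -= cell * np.floor(centroid / cell)
    if superpose:
        a = a - a.mean(axis=0)
        b = b - b.mean(axis=0)
        u, _, vt = np.linalg.svd(a.T @ b)
        d = np.sign(np.linalg.det(u @ vt))
        rot = u @ np.diag([1.0, 1.0, d]) @ vt
        a = a @ rot
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


@dataclass
class RDFResult:
    """g(r) on bin centers with the number density of the selected species."""

    r: np.ndarray
    g: np.ndarray
    rho: float

    def __post_init__(self) -> None:
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")


def _resolve_selection(traj_like, selector) -> np.ndarray:
    if isinstance(selector, str):
        return np.flatnonzero(np.array(traj_like.elements) == selector)
    return np.atleast_1d(np.asarray(selector, dtype=int))


def rdf(
    traj: Trajectory,
    pair_selector="O",
    r_max: float | None = None,
    dr: float = 0.05,
    cell: np.ndarray | float | None = None,
) -> RDFResult:
    """Radial distribution function of a same-species pair selection.

    g(r) is the histogram of minimum-image pair distances normalized by
    the ideal-gas expectation (exact spherical-shell volumes), averaged
    over frames.

    Parameters
    ----------
    pair_selector : element symbol (e.g. "O") or an index array.
    r_max : Å, defaults to cell/2 − dr; must satisfy r_max ≤ cell/2.
    """
    if cell is None:
        cell = traj.cell
    if cell is None:
        raise ValueError("RDF requires a periodic cell")
    cell = np.broadcast_to(np.asarray(cell, dtype=float), (3,))
    half = float(cell.min()) / 2.0
    if r_max is None:
        r_max = half - dr
    if r_max > half:
        raise ValueError(f"r_max {r_max} exceeds cell/2 = {half} (minimum image)")
    if dr <= 0:
        raise ValueError("dr must be positive")
    sel = _resolve_selection(traj, pair_selector)
    n = len(sel)
    if n < 2:
        raise ValueError("need at least two selected atoms")
    volume = float(np.prod(cell))
    rho = n / volume
    edges = np.arange(0.0, r_max + dr, dr)
    counts = np.zeros(len(edges) - 1)
    iu, ju = np.triu_indices(n, k=1)
    for f in range(traj.n_frames):
        p = traj.positions[f, sel]
        d = p[iu] - p[ju]
        d -= cell * np.round(d / cell)
        dist = np.linalg.norm(d, axis=1)
        counts += np.histogram(dist, bins=edges)[0]
    counts /= traj.n_frames
    shell = 4.0 * np.pi / 3.0 * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = 0.5 * n * rho * shell  # expected i<j pair count per shell
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFResult(r=centers, g=counts / ideal, rho=rho)


def coordination_number(result: RDFResult, r1: float, r2: float) -> float:
    """Neighbour count n = 4πρ ∫_{r1}^{r2} g(r) r² dr (trapezoidal on bins)."""
    if r1 > r2:
        raise ValueError("require r1 <= r2")
    if r1 == r2:
        return 0.0
    if r1 < 0 or r2 > result.r[-1] + 1e-9:
        raise ValueError("integration range outside RDF support")
    integrand = result.g * result.r**2
    inside = (result.r >= r1) & (result.r <= r2)
    # clip the integration window onto the binned grid exactly
    xs = np.concatenate(([r1], result.r[inside], [r2]))
    ys = np.concatenate(
        (
            [np.interp(r1, result.r, integrand)],
            integrand[inside],
            [np.interp(r2, result.r, integrand)],
        )
    )
    return float(4.0 * np.pi * result.rho * np.trapezoid(ys, xs))


def mass_density(n_molecules: int, molar_mass: float, cell: float) -> float:
    """Mass density in g·cm⁻³ of n molecules of ``molar_mass`` (u) in a cubic cell (Å)."""
    if n_molecules <= 0 or molar_mass <= 0 or cell <= 0:
        raise ValueError("all inputs must be positive")
    volume_cm3 = (cell * 1e-8) ** 3
    return n_molecules * molar_mass * AMU_TO_GRAM / volume_cm3
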