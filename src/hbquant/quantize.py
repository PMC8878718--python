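"""A posteriori nuclear quantization of the bridged proton.

The snapshot-envelope procedure: for each trajectory snapshot a rigid scan
displaces the bridging hydrogen along the instantaneous donor→acceptor
axis with every other atom frozen, producing a 1D proton potential; the
vibrational Schrödinger equation is solved on that curve for ¹H and ²H
masses; the per-snapshot 0→1 fundamentals are summed into Gaussian band
envelopes whose peak positions give the O-H/O-D isotope ratio.

Solvers
-------
The primary eigensolver is a Fourier-grid (sinc-DVR) Hamiltonian: the
curve is cubic-spline interpolated onto a uniform grid and the kinetic
operator is represented exactly in the grid basis, so the method is
variational on the grid and robust for asymmetric double wells.  A Numerov
shooting solver is provided as an independent cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.linalg import eigh

from .constants import (
    AMU_TO_ME,
    BOHR_TO_ANGSTROM,
    HARTREE_TO_INVCM,
    MASS_D,
    MASS_H,
)
from .spectra import Spectrum

__all__ = [
    "PotentialCurve",
    "VibLevels",
    "EnvelopeResult",
    "rigid_scan",
    "solve_levels",
    "numerov_levels",
    "fundamental",
    "envelope",
    "isotope_pipeline",
    "morse_fundamental",
    "harmonic_curve",
    "morse_curve",
]


class NonConfiningError(ValueError):
    """The scanned potential does not confine the proton on the grid."""


@dataclass
class PotentialCurve:
    """1D rigid-scan proton potential along the donor→acceptor axis.

    ``x`` is the O(donor)–H distance grid (Å), ``V`` the energy (hartree)
    re-zeroed to the curve minimum, ``R`` the donor–acceptor distance of
    the snapshot the scan came from.
    """

    x: np.ndarray
    V: np.ndarray
    snapshot_id: int = 0
    R: float = float("nan")

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.x.shape != self.V.shape or self.x.ndim != 1:
            raise ValueError("x and V must be 1D arrays of equal length")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")
        self.V = self.V - self.V.min()

    @property
    def confining(self) -> bool:
        """True if the minimum is interior and both ends rise above it."""
        i = int(np.argmin(self.V))
        if i == 0 or i == len(self.V) - 1:
            return False
        return self.V[0] > self.V[i] and self.V[-1] > self.V[i]


@dataclass
class VibLevels:
    """Lowest bound-state energies (hartree, ascending) for a given mass (u)."""

    energies: np.ndarray
    mass: float

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if np.any(np.diff(self.energies) < 0):
            raise ValueError("energies must be ascending")

    @property
    def n_levels(self) -> int:
        return len(self.energies)


@dataclass
class EnvelopeResult:
    """Per-snapshot fundamentals (cm⁻¹) with their Gaussian band envelope."""

    fundamentals: np.ndarray
    envelope: Spectrum
    peak: float
    mass: float = field(default=MASS_H)


def rigid_scan(
    frame,
    donor_O: int,
    H: int,
    acceptor_O: int,
    evaluator,
    x_lo: float = 0.75,
    x_hi: float = 2.25,
    dx: float = 0.02,
    snapshot_id: int = 0,
) -> PotentialCurve:
    """Scan the bridging H along the donor→acceptor axis, all else frozen.

    Parameters
    ----------
    frame : Frame
        Snapshot geometry.
    evaluator : callable
        Maps a full (n_atoms, 3) position array to an energy in hartree.
    x_lo, x_hi, dx : float
        O(donor)–H distance grid in Å.  ``x_hi`` must not reach closer to
        the acceptor than ``x_lo`` is to the donor.

    Returns
    -------
    PotentialCurve re-zeroed to its minimum.  A curve whose minimum sits
    on the grid edge is returned as-is but flagged non-confining; callers
    building envelopes skip such curves with a warning.
    """
    pos = np.array(frame.positions, dtype=float)
    d = pos[acceptor_O] - pos[donor_O]
    R = float(np.linalg.norm(d))
    if x_hi > R - x_lo:
        raise ValueError(
            f"scan grid [{x_lo}, {x_hi}] Å reaches within {x_lo} Å of the "
            f"acceptor (R = {R:.3f} Å)"
        )
    u = d / R
    x = np.arange(x_lo, x_hi + 0.5 * dx, dx)
    V = np.empty_like(x)
    for i, xi in enumerate(x):
        pos[H] = pos[donor_O] + xi * u
        V[i] = evaluator(pos)
    return PotentialCurve(x=x, V=V, snapshot_id=snapshot_id, R=R)


def _dvr_hamiltonian(x_bohr: np.ndarray, v: np.ndarray, mass_me: float) -> np.ndarray:
    """Sinc-DVR Hamiltonian with Dirichlet-like boundaries (atomic units)."""
    n = len(x_bohr)
    dx = x_bohr[1] - x_bohr[0]
    i = np.arange(n)
    diff = i[:, None] - i[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(
            diff == 0,
            np.pi**2 / 3.0,
            2.0 * (-1.0) ** diff / diff.astype(float) ** 2,
        )
    T *= 1.0 / (2.0 * mass_me * dx**2)
    return T + np.diag(v)


def solve_levels(
    curve: PotentialCurve,
    mass: float = MASS_H,
    n_levels: int = 2,
    n_grid: int = 256,
    check_convergence: bool = False,
) -> VibLevels:
    """Solve −(ħ²/2m)ψ'' + V(x)ψ = Eψ on the scan interval.

    The tabulated curve is cubic-spline interpolated onto a uniform
    ``n_grid``-point grid and the grid Hamiltonian is diagonalized.
    Energies are measured from the curve minimum (V_min = 0).

    Parameters
    ----------
    mass : float, u — mass of the moving particle (bare H or D; all other
        atoms are frozen in the rigid scan).
    check_convergence : bool
        If set, re-solve on a doubled grid and require every reported
        level to move by < 0.1 cm⁻¹.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if not curve.confining:
        raise NonConfiningError(
            f"snapshot {curve.snapshot_id}: potential minimum on grid edge"
        )
    spline = CubicSpline(curve.x, curve.V)

    def _solve(n: int) -> np.ndarray:
        xg = np.linspace(curve.x[0], curve.x[-1], n)
        vg = spline(xg)
        h = _dvr_hamiltonian(xg / BOHR_TO_ANGSTROM, vg, mass * AMU_TO_ME)
        vals = eigh(h, eigvals_only=True, subset_by_index=(0, n_levels - 1))
        return vals

    vals = _solve(n_grid)
    if check_convergence:
        vals2 = _solve(2 * n_grid)
        drift = np.abs(vals - vals2) * HARTREE_TO_INVCM
        if np.any(drift > 0.1):
            raise RuntimeError(
                f"eigenvalues not converged under grid doubling; "
                f"max drift {drift.max():.3f} cm⁻¹"
            )
    return VibLevels(energies=vals, mass=mass)


def numerov_levels(
    curve: PotentialCurve,
    mass: float = MASS_H,
    n_levels: int = 2,
    n_grid: int = 4001,
) -> VibLevels:
    """Numerov shooting eigensolver — independent cross-check for the DVR.

    For a trial energy the Numerov recursion is integrated from the left
    boundary; the node count of the solution brackets each eigenvalue and
    bisection refines it until the bracket is tight.
    """
    if not curve.confining:
        raise NonConfiningError("potential minimum on grid edge")
    spline = CubicSpline(curve.x, curve.V)
    xg = np.linspace(curve.x[0], curve.x[-1], n_grid) / BOHR_TO_ANGSTROM
    vg = spline(np.linspace(curve.x[0], curve.x[-1], n_grid))
    h = xg[1] - xg[0]
    m = mass * AMU_TO_ME

    def node_count(E: float) -> int:
        g = 2.0 * m * (E - vg)
        f = 1.0 + h * h * g / 12.0
        psi_prev, psi = 0.0, 1e-10
        nodes = 0
        for i in range(1, n_grid - 1):
            psi_next = ((12.0 - 10.0 * f[i]) * psi - f[i - 1] * psi_prev) / f[i + 1]
            if psi_next * psi < 0:
                nodes += 1
            # rescale to avoid overflow in classically forbidden regions
            s = abs(psi_next)
            if s > 1e100:
                psi, psi_next = psi / s, psi_next / s
            psi_prev, psi = psi, psi_next
        return nodes

    e_lo, e_hi = 0.0, float(vg.max())
    levels = []
    for n in range(n_levels):
        lo, hi = e_lo, e_hi
        # bisect on node count: E_n is where count passes from n to n+1
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if node_count(mid) > n:
                hi = mid
            else:
                lo = mid
        levels.append(0.5 * (lo + hi))
    return VibLevels(energies=np.array(levels), mass=mass)


def fundamental(levels: VibLevels) -> float:
    """0→1 transition wavenumber in cm⁻¹."""
    if levels.n_levels < 2:
        raise ValueError("need at least two levels")
    return float((levels.energies[1] - levels.energies[0]) * HARTREE_TO_INVCM)


def envelope(
    fundamentals: np.ndarray,
    width: float = 20.0,
    grid: np.ndarray | None = None,
) -> Spectrum:
    """Equal-weight Gaussian sum over per-snapshot fundamentals.

    ``width`` is the Gaussian standard deviation in cm⁻¹.  The result is
    normalized to unit maximum; band support is conventionally read off as
    the interval where intensity exceeds 1% of the maximum.
    """
    f = np.atleast_1d(np.asarray(fundamentals, dtype=float))
    if f.size == 0:
        raise ValueError("no fundamentals to envelope")
    if grid is None:
        lo = max(0.0, f.min() - 6 * width)
        grid = np.arange(lo, f.max() + 6 * width + 1.0, 1.0)
    intensity = np.exp(
        -((grid[:, None] - f[None, :]) ** 2) / (2.0 * width**2)
    ).sum(axis=1)
    return Spectrum(wavenumber=grid, intensity=intensity / intensity.max())


def band_support(spec: Spectrum, threshold: float = 0.01) -> tuple[float, float]:
    """Interval where intensity exceeds ``threshold`` × max."""
    idx = np.flatnonzero(spec.intensity > threshold * spec.intensity.max())
    return float(spec.wavenumber[idx[0]]), float(spec.wavenumber[idx[-1]])


def isotope_pipeline(
    curves: list[PotentialCurve],
    width: float = 20.0,
    n_grid: int = 256,
) -> tuple[EnvelopeResult, EnvelopeResult, float]:
    """O-H and O-D snapshot envelopes plus their peak-position ratio.

    Each confining curve is solved twice — with the proton mass and with
    the deuteron mass — and the two sets of fundamentals are enveloped.
    Non-confining curves are skipped with a warning.  The isotope ratio is
    peak(O-H) / peak(O-D); harmonic curves give √(m_D/m_H) ≈ 1.414 and any
    anharmonicity pulls the ratio below that bound.
    """
    usable = [c for c in curves if c.confining]
    skipped = len(curves) - len(usable)
    if skipped:
        warnings.warn(
            f"{skipped} non-confining curve(s) excluded from envelopes",
            stacklevel=2,
        )
    if not usable:
        raise NonConfiningError("all curves non-confining")
    results = []
    for mass in (MASS_H, MASS_D):
        f = np.array(
            [
                fundamental(solve_levels(c, mass=mass, n_grid=n_grid))
                for c in usable
            ]
        )
        env = envelope(f, width=width)
        peak = float(env.wavenumber[np.argmax(env.intensity)])
        results.append(
            EnvelopeResult(fundamentals=f, envelope=env, peak=peak, mass=mass)
        )
    res_h, res_d = results
    return res_h, res_d, res_h.peak / res_d.peak


# ---------------------------------------------------------------------------
# Closed-form reference curves (solver oracles and calibration aids)


def harmonic_curve(
    wavenumber: float,
    mass: float = MASS_H,
    half_width: float = 0.5,
    n: int = 101,
    x0: float = 1.0,
) -> PotentialCurve:
    """Quadratic potential whose harmonic wavenumber is ``wavenumber`` cm⁻¹."""
    # ω in a.u. (ħ=1): ħω = hcν̃, so ω[hartree] = ν̃ / HARTREE_TO_INVCM
    omega = wavenumber / HARTREE_TO_INVCM
    m = mass * AMU_TO_ME
    x = np.linspace(x0 - half_width, x0 + half_width, n)
    xb = (x - x0) / BOHR_TO_ANGSTROM
    return PotentialCurve(x=x, V=0.5 * m * omega**2 * xb**2)


def morse_curve(
    D: float,
    a: float,
    r0: float = 0.97,
    x_lo: float = 0.5,
    x_hi: float = 2.5,
    n: int = 201,
) -> PotentialCurve:
    """Morse potential D[1−e^(−a(x−r0))]² (D hartree, a Å⁻¹, r0 Å)."""
    x = np.linspace(x_lo, x_hi, n)
    return PotentialCurve(x=x, V=D * (1.0 - np.exp(-a * (x - r0))) ** 2)


def morse_fundamental(D: float, a: float, mass: float) -> float:
    """Analytic Morse 0→1 wavenumber (cm⁻¹): ω̃ₑ − 2ω̃ₑχₑ.

    In atomic units ωₑ = a√(2D/m) and ωₑχₑ = a²/(2m) with a in bohr⁻¹ and
    m in electron masses; the fundamental is ωₑ − a²/m.
    """
    ab = a * BOHR_TO_ANGSTROM  # Å⁻¹ -> bohr⁻¹
    m = mass * AMU_TO_ME
    omega_e = ab * np.sqrt(2.0 * D / m)
    return float((omega_e - ab**2 / m) * HARTREE_TO_INVCM)
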