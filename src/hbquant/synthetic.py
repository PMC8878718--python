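"""Synthetic trajectories with the statistical structure of ab initio MD.

Quantum-chemistry engines are expensive; the analyses downstream are not.
This module generates model data whose *statistics* match what first-
principles simulations of a hydrogen-bonded alcohol produce, so the whole
pipeline is testable at desk scale:

* a double-Morse proton potential V(r, R) whose donor well dominates (the
  bridged proton stays localized on the donor side) and whose acceptor
  well red-shifts the O-H stretch as the donor–acceptor distance R closes;
* a gas-phase dimer trajectory: R(t) follows an Ornstein–Uhlenbeck process
  oscillating around ~3 Å, the bridging proton moves by Langevin dynamics
  in V(r, R(t)), and donor/acceptor roles swap at scheduled times the way
  hydroxyl rotation swaps them in the real dynamics;
* a liquid configuration of coarse 4-site molecules arranged in hydrogen-
  bonded rings under periodic boundary conditions, with first-shell O…O
  distances in a prescribed window and coordination two for every
  hydroxyl oxygen.

All generators are pure functions of (parameters, seed); the RNG is the
counter-based Philox generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .constants import FORCE_TO_ACC, KB_HARTREE_PER_K, MASS_H
from .traj_io import Frame, Trajectory

__all__ = [
    "ModelPotentialParams",
    "OUParams",
    "SwitchSchedule",
    "evaluate_model_potential",
    "model_potential_force",
    "axis_evaluator",
    "generate_dimer_trajectory",
    "generate_liquid_config",
    "sample_snapshots",
    "GenerationError",
]


class GenerationError(RuntimeError):
    """Packing or sampling could not be completed."""


@dataclass(frozen=True)
class ModelPotentialParams:
    """Double-Morse hydrogen-bond potential constants.

    V(r, R) = D1[1−e^(−a1(r−r0))]² + D2[1−e^(−a2(R−r−r0))]² − D2

    with r the donor-O–H distance along the O…O axis and R the O…O
    distance.  D1 > D2 keeps the proton localized on the donor side; the
    acceptor term softens the donor well as R shrinks, producing the
    red shift of the bridged O-H stretch.

    Defaults are calibrated once against the Morse closed form and the
    grid eigensolver so that the quantized H fundamental falls at
    ~3150 cm⁻¹ for R = 3.0 Å (bridged band) and ~3540 cm⁻¹ for large R
    (free band), with the classical well frequency also inside the free
    3500–3700 cm⁻¹ band; see analysis/00_calibrate_potential.py.
    """

    D1: float = 0.23  # hartree
    a1: float = 2.0  # Å⁻¹
    D2: float = 0.10  # hartree
    a2: float = 2.2  # Å⁻¹
    r0: float = 0.97  # Å

    def __post_init__(self) -> None:
        if not (self.D1 > self.D2 > 0):
            raise ValueError("require D1 > D2 > 0 (proton localized on donor)")
        if self.a1 <= 0 or self.a2 <= 0 or self.r0 <= 0:
            raise ValueError("a1, a2, r0 must be positive")


@dataclass(frozen=True)
class OUParams:
    """Ornstein–Uhlenbeck parameters for the donor–acceptor distance R(t).

    Stationary distribution: mean ``mu``, sd ``sigma/√(2·theta)``.  The
    defaults give R oscillating around 3 Å with a 0.15 Å spread and a
    ~200 fs relaxation time, the scale of the intermolecular O…O stretch.
    """

    mu: float = 3.0  # Å
    theta: float = 0.005  # fs⁻¹
    sigma: float = 0.015  # Å·fs⁻½

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def stationary_sd(self) -> float:
        return self.sigma / np.sqrt(2.0 * self.theta)

    @classmethod
    def from_sd(cls, mu: float, sd: float, theta: float = 0.005) -> "OUParams":
        """Construct from a target stationary standard deviation."""
        return cls(mu=mu, theta=theta, sigma=sd * np.sqrt(2.0 * theta))


@dataclass(frozen=True)
class SwitchSchedule:
    """Times (ps, strictly increasing) at which donor/acceptor roles swap."""

    times: tuple = ()

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.times)
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("switch times must be strictly increasing")
        object.__setattr__(self, "times", t)


def evaluate_model_potential(r, R, params: ModelPotentialParams) -> np.ndarray | float:
    """Model proton potential V(r, R) in hartree.

    ``r`` is the donor-O–H distance and ``R`` the O…O distance, both in Å.
    Accepts scalars or broadcastable arrays; requires 0 < r < R.
    """
    r = np.asarray(r, dtype=float)
    R = np.asarray(R, dtype=float)
    if np.any(r <= 0) or np.any(r >= R):
        raise ValueError("require 0 < r < R")
    v = (
        params.D1 * (1.0 - np.exp(-params.a1 * (r - params.r0))) ** 2
        + params.D2 * (1.0 - np.exp(-params.a2 * (R - r - params.r0))) ** 2
        - params.D2
    )
    return float(v) if v.ndim == 0 else v


def model_potential_force(r: float, R: float, params: ModelPotentialParams) -> float:
    """−∂V/∂r in hartree/Å at fixed R."""
    e1 = np.exp(-params.a1 * (r - params.r0))
    e2 = np.exp(-params.a2 * (R - r - params.r0))
    dv = (
        2.0 * params.D1 * params.a1 * (1.0 - e1) * e1
        - 2.0 * params.D2 * params.a2 * (1.0 - e2) * e2
    )
    return -dv


def axis_evaluator(params: ModelPotentialParams, donor_O: int, H: int, acceptor_O: int):
    """Geometry→energy callable for rigid scans, backed by the model potential.

    The proton coordinate is the projection of the O-H vector onto the
    donor→acceptor axis.
    """

    def _energy(positions: np.ndarray) -> float:
        d = positions[acceptor_O] - positions[donor_O]
        R = float(np.linalg.norm(d))
        r = float(np.dot(positions[H] - positions[donor_O], d / R))
        return float(evaluate_model_potential(r, R, params))

    return _energy


def _minimum_r(params: ModelPotentialParams, R: float) -> float:
    """Dense-grid minimum of V(·, R) — cheap and robust for well-shaped V."""
    r = np.linspace(0.7, min(1.6, R - 0.7), 2001)
    return float(r[np.argmin(evaluate_model_potential(r, R, params))])


# geometry constants of the coarse dimer (Å)
_FREE_OH = 0.97
_FREE_OH_DIR_A = np.array([-0.342, 0.940, 0.0])
_FREE_OH_DIR_B = np.array([0.342, 0.940, 0.0])
_CO_BOND = 1.43
_C_DIR_A = np.array([-0.5, -0.866, 0.0])
_C_DIR_B = np.array([0.5, -0.866, 0.0])


def generate_dimer_trajectory(
    pot: ModelPotentialParams = ModelPotentialParams(),
    ou: OUParams = OUParams(),
    switches: SwitchSchedule = SwitchSchedule(),
    n_steps: int = 200_000,
    dt: float = 0.5,
    temperature: float = 300.0,
    seed: int = 0,
    friction: float = 0.002,
    relax_window: float = 50.0,
) -> Trajectory:
    """Gas-phase hydrogen-bonded dimer trajectory with role switches.

    Atoms (6): O, H, C of molecule a; O, H, C of molecule b.  Molecule a
    donates initially.  R(t) = |O_a…O_b| follows the Euler–Maruyama OU
    discretization; the bridging proton coordinate r(t) follows BAOAB
    Langevin dynamics in V(r, R(t)) at ``temperature``; at each scheduled
    switch the donor/acceptor labels swap and the two hydroxyl hydrogens
    are repositioned linearly over ``relax_window`` fs, which avoids
    velocity discontinuities.

    Parameters
    ----------
    dt : time step, fs (0.5 fs is stable for the stiff O-H well).
    friction : Langevin friction, fs⁻¹.
    relax_window : duration of the post-switch repositioning, fs.
    """
    if n_steps <= 0 or dt <= 0:
        raise ValueError("n_steps and dt must be positive")
    duration_ps = n_steps * dt / 1000.0
    for t in switches.times:
        if t >= duration_ps:
            raise ValueError(
                f"switch at {t} ps beyond trajectory duration {duration_ps} ps"
            )
    rng = np.random.Generator(np.random.Philox(seed))

    # --- O...O distance: OU process, vectorized as a linear recursion
    xi = rng.standard_normal(n_steps)
    drive = ou.theta * ou.mu * dt + ou.sigma * np.sqrt(dt) * xi
    decay = 1.0 - ou.theta * dt
    R0 = ou.mu + ou.stationary_sd * rng.standard_normal()
    R = lfilter([1.0], [1.0, -decay], drive, zi=np.array([decay * R0]))[0]
    R = np.concatenate(([R0], R[:-1]))
    np.clip(R, 2.4, None, out=R)  # guard against unphysical close approach

    # --- bridging proton: BAOAB Langevin in V(r, R(t))
    m = MASS_H
    kT = KB_HARTREE_PER_K * temperature
    v_sd = np.sqrt(kT / m * FORCE_TO_ACC)  # thermal velocity, Å/fs
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt(1.0 - c1 * c1) * v_sd
    noise = rng.standard_normal(n_steps)

    switch_steps = [int(round(t * 1000.0 / dt)) for t in switches.times]
    relax_steps = max(1, int(round(relax_window / dt)))

    r = np.empty(n_steps)
    vr = np.empty(n_steps)
    donor = np.empty(n_steps, dtype=np.int8)  # 0 = a donates, 1 = b donates
    blend = np.zeros(n_steps)  # 1 -> fully switched geometry within window

    cur_d = 0
    ri = _minimum_r(pot, R[0]) + 0.01 * rng.standard_normal()
    vi = v_sd * rng.standard_normal()
    next_switch = 0
    for i in range(n_steps):
        if next_switch < len(switch_steps) and i == switch_steps[next_switch]:
            cur_d = 1 - cur_d
            ri = _minimum_r(pot, R[i]) + 0.01 * rng.standard_normal()
            vi = v_sd * rng.standard_normal()
            j0, j1 = i, min(i + relax_steps, n_steps)
            blend[j0:j1] = np.linspace(0.0, 1.0, j1 - j0)
            next_switch += 1
        f = model_potential_force(ri, R[i], pot)
        vi += 0.5 * dt * f / m * FORCE_TO_ACC
        ri += 0.5 * dt * vi
        vi = c1 * vi + c2 * noise[i]
        ri += 0.5 * dt * vi
        f = model_potential_force(ri, R[i], pot)
        vi += 0.5 * dt * f / m * FORCE_TO_ACC
        r[i] = ri
        vr[i] = vi
        donor[i] = cur_d
    # donor after the loop refers to the state *during* each step

    # --- assemble cartesian frames
    pos = np.zeros((n_steps, 6, 3))
    vel = np.zeros((n_steps, 6, 3))
    pos[:, 3, 0] = R  # O_b on the x axis
    vel[1:, 3, 0] = np.diff(R) / dt
    pos[:, 2] = _CO_BOND * _C_DIR_A  # C_a
    pos[:, 5] = pos[:, 3] + _CO_BOND * _C_DIR_B  # C_b
    vel[:, 5] = vel[:, 3]

    a_donates = donor == 0
    # bridging H of the current donor sits r from its O along the axis
    h_a_bridge = np.zeros((n_steps, 3))
    h_a_bridge[:, 0] = r
    h_b_bridge = np.zeros((n_steps, 3))
    h_b_bridge[:, 0] = R - r
    h_a_free = _FREE_OH * _FREE_OH_DIR_A[None, :] * np.ones((n_steps, 1))
    h_b_free = pos[:, 3] + _FREE_OH * _FREE_OH_DIR_B[None, :]

    w = np.where(a_donates, 1.0, 0.0)
    # inside a relax window, blend from the pre-switch to post-switch layout
    in_window = blend > 0
    w_eff = np.where(in_window, np.where(a_donates, blend, 1.0 - blend), w)
    pos[:, 1] = w_eff[:, None] * h_a_bridge + (1.0 - w_eff)[:, None] * h_a_free
    pos[:, 4] = w_eff[:, None] * h_b_free + (1.0 - w_eff)[:, None] * h_b_bridge
    vel[a_donates, 1, 0] = vr[a_donates]
    vel[~a_donates, 4, 0] = -vr[~a_donates]
    vel[~a_donates, 4] += vel[~a_donates, 3]

    return Trajectory(
        positions=pos,
        velocities=vel,
        elements=["O", "H", "C", "O", "H", "C"],
        dt=dt,
        comment={
            "generator": "dimer",
            "seed": seed,
            "temperature_K": temperature,
        },
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, rr = np.linalg.qr(rng.standard_normal((3, 3)))
    return q * np.sign(np.diag(rr))


def _min_image_dists(a: np.ndarray, b: np.ndarray, cell: float) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    d -= cell * np.round(d / cell)
    return np.linalg.norm(d, axis=-1)


def generate_liquid_config(
    n_molecules: int = 200,
    cell: float = 39.182,
    first_shell: tuple[float, float] = (2.7, 2.9),
    seed: int = 0,
    ring_size: int = 10,
    max_attempts: int = 5000,
) -> Trajectory:
    """Single-frame liquid of coarse 4-site molecules in H-bonded rings.

    Each molecule contributes a hydroxyl O, its H, the first chain carbon
    and the terminal carbon.  Molecules are grouped into rings whose
    consecutive O…O edges are drawn from ``first_shell``, so every
    hydroxyl oxygen donates one hydrogen bond and accepts one — the
    prevailing coordination-two motif of a chain-associated alcohol.
    Rings are dropped into the periodic cell with rejection sampling:
    non-bonded O…O pairs are kept beyond 3.6 Å (so the first coordination
    shell contains exactly the two ring neighbours) and all other heavy-
    atom pairs beyond 2.0 Å.
    """
    if n_molecules < 3:
        raise ValueError("need at least 3 molecules")
    lo, hi = first_shell
    if not (0 < lo < hi):
        raise ValueError("invalid first_shell window")
    rng = np.random.Generator(np.random.Philox(seed))

    # partition into rings of ring_size (last ring absorbs the remainder)
    sizes = [ring_size] * (n_molecules // ring_size)
    rem = n_molecules % ring_size
    if rem:
        if sizes and rem < 3:
            sizes[-1] += rem
        else:
            sizes.append(rem)

    placed_O: list[np.ndarray] = []
    placed_heavy: list[np.ndarray] = []
    all_pos: list[np.ndarray] = []
    elements: list[str] = []

    for size in sizes:
        edge = rng.uniform(lo, hi)
        rad = edge / (2.0 * np.sin(np.pi / size))
        ang = 2.0 * np.pi * np.arange(size) / size
        ring_O = np.column_stack([rad * np.cos(ang), rad * np.sin(ang), np.zeros(size)])
        nxt = np.roll(ring_O, -1, axis=0)
        u_edge = (nxt - ring_O) / edge
        ring_H = ring_O + _FREE_OH * u_edge
        out = ring_O / rad  # radial outward unit vectors
        zsign = np.where(np.arange(size) % 2 == 0, 1.0, -1.0)
        ring_C1 = ring_O + _CO_BOND * out
        ring_C8 = ring_O + 4.3 * out + np.column_stack(
            [np.zeros(size), np.zeros(size), 1.5 * zsign]
        )

        local = np.concatenate([ring_O, ring_H, ring_C1, ring_C8])
        ok = False
        for _ in range(max_attempts):
            rot = _random_rotation(rng)
            center = rng.uniform(0.0, cell, size=3)
            cand = local @ rot.T + center
            cO = cand[:size]
            cheavy = np.concatenate([cand[:size], cand[2 * size :]])
            if placed_O:
                if _min_image_dists(cO, np.vstack(placed_O), cell).min() < 3.6:
                    continue
                if _min_image_dists(cheavy, np.vstack(placed_heavy), cell).min() < 2.0:
                    continue
            placed_O.append(cO)
            placed_heavy.append(cheavy)
            # interleave per molecule: O, H, C1, C8
            for i in range(size):
                all_pos.extend(
                    [cand[i], cand[size + i], cand[2 * size + i], cand[3 * size + i]]
                )
                elements.extend(["O", "H", "C", "C"])
            ok = True
            break
        if not ok:
            raise GenerationError(
                f"could not place a {size}-molecule ring after {max_attempts} "
                f"attempts; cell {cell} Å is too crowded for {n_molecules} molecules"
            )

    pos = np.asarray(all_pos)[None, :, :] % cell
    return Trajectory(
        positions=pos,
        elements=elements,
        dt=1.0,
        cell=np.array([cell, cell, cell]),
        comment={"generator": "liquid-rings", "seed": seed},
    )


def sample_snapshots(traj: Trajectory, interval: float) -> list[Frame]:
    """Frames at times k·interval (k ≥ 1), nearest-frame rounding.

    ``interval`` is in ps.  Returns floor(duration/interval) frames; an
    interval longer than the trajectory yields an empty list with a
    warning.
    """
    interval_fs = interval * 1000.0
    if interval_fs < traj.dt:
        raise ValueError("interval shorter than the frame spacing")
    count = int(np.floor(traj.duration / interval_fs + 1e-9))
    if count == 0:
        warnings.warn("interval longer than trajectory; no snapshots", stacklevel=2)
        return []
    return [
        traj.frame(int(round(k * interval_fs / traj.dt)))
        for k in range(1, count + 1)
    ]
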