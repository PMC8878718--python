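"""Hydrogen-bond metric time series, lifetimes, role switches, histograms.

The geometric picture: a donor hydroxyl O-H points at an acceptor oxygen;
the three distances d(O-H), d(H…O_acc) and d(O…O) characterize the bridge.
A bond is declared when the H…acceptor distance falls inside a geometric
criterion window; runs of bonded frames give lifetimes, and alternation of
which hydroxyl satisfies the criterion marks donor/acceptor role-switch
events (hydroxyl-rotation dynamics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traj_io import Trajectory

__all__ = [
    "HBondSeries",
    "HBCriterion",
    "STRICT_HB",
    "LOOSE_HB",
    "Histogram2D",
    "hb_distance_series",
    "classify_hbond",
    "detect_role_switches",
    "hb_lifetimes",
    "proton_histogram2d",
    "isodensity_contours",
]


@dataclass(frozen=True)
class HBCriterion:
    """Geometric hydrogen-bond criterion on the H…acceptor distance.

    Closed interval [d_HA_min, d_HA_max]; optionally also d_OO ≤ d_OO_max.
    """

    d_HA_min: float = 1.60
    d_HA_max: float = 2.00
    d_OO_max: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.d_HA_min < self.d_HA_max):
            raise ValueError("require 0 <= d_HA_min < d_HA_max")


#: Literature geometric criterion: H…Y between 1.60 and 2 Å.
STRICT_HB = HBCriterion(1.60, 2.00)

#: Looser preset for liquid-phase work, where the strict window undercounts.
LOOSE_HB = HBCriterion(0.0, 2.5, d_OO_max=3.5)


@dataclass
class HBondSeries:
    """Per-frame bridge metrics: times (ps) and the three distances (Å)."""

    times: np.ndarray
    d_OH: np.ndarray
    d_HA: np.ndarray
    d_OO: np.ndarray
    bonded: np.ndarray
    partner: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("d_OH", "d_HA", "d_OO", "bonded", "partner"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from times")
        if np.any(self.d_OH <= 0) or np.any(self.d_HA <= 0) or np.any(self.d_OO <= 0):
            raise ValueError("distances must be positive")
        if np.any(self.d_OO > self.d_OH + self.d_HA + 1e-9):
            raise ValueError("triangle inequality violated: d_OO > d_OH + d_HA")


def _min_image(vec: np.ndarray, cell: np.ndarray | None) -> np.ndarray:
    if cell is not None:
        vec = vec - cell * np.round(vec / cell)
    return vec


def hb_distance_series(
    traj: Trajectory,
    donor_O: int,
    H: int,
    acceptor_O: int,
    criterion: HBCriterion = STRICT_HB,
) -> HBondSeries:
    """Bridge-distance time series for one donor-O-H…acceptor-O triple.

    Minimum-image distances when the trajectory has a cell; the bonded
    flag is evaluated with ``criterion``.
    """
    if donor_O == acceptor_O:
        raise ValueError("donor and acceptor must differ")
    p = traj.positions
    d_oh = np.linalg.norm(_min_image(p[:, H] - p[:, donor_O], traj.cell), axis=1)
    d_ha = np.linalg.norm(_min_image(p[:, H] - p[:, acceptor_O], traj.cell), axis=1)
    d_oo = np.linalg.norm(
        _min_image(p[:, acceptor_O] - p[:, donor_O], traj.cell), axis=1
    )
    series = HBondSeries(
        times=traj.times / 1000.0,
        d_OH=d_oh,
        d_HA=d_ha,
        d_OO=d_oo,
        bonded=np.zeros(traj.n_frames, dtype=bool),
        partner=np.full(traj.n_frames, acceptor_O, dtype=int),
    )
    series.bonded = classify_hbond(series, criterion)
    return series


def classify_hbond(series: HBondSeries, criterion: HBCriterion = STRICT_HB) -> np.ndarray:
    """Bonded flags: d_HA inside the closed criterion interval (and d_OO cut)."""
    ok = (series.d_HA >= criterion.d_HA_min) & (series.d_HA <= criterion.d_HA_max)
    if criterion.d_OO_max is not None:
        ok &= series.d_OO <= criterion.d_OO_max
    return ok


def _runs(flags: np.ndarray):
    """(value, start, length) run-length encoding."""
    out = []
    i = 0
    n = len(flags)
    while i < n:
        j = i
        while j < n and flags[j] == flags[i]:
            j += 1
        out.append((flags[i], i, j - i))
        i = j
    return out


def detect_role_switches(
    traj: Trajectory,
    O_a: int,
    H_a: int,
    O_b: int,
    H_b: int,
    criterion: HBCriterion = LOOSE_HB,
    hold: float = 1.0,
) -> list[float]:
    """Times (ps) at which the donor/acceptor roles of two hydroxyls swap.

    Per frame the donor is the hydroxyl whose own H satisfies the bond
    criterion toward the other oxygen; frames where neither or both
    qualify inherit the previous assignment.  A change of donor counts as
    an event only if the new assignment persists for at least ``hold`` ps
    (debouncing librational flicker).

    The default criterion is the loose liquid preset: the strict
    literature window sits right at the thermal mean of the H…O distance
    and would make every assignment flicker.
    """
    sa = hb_distance_series(traj, O_a, H_a, O_b, criterion)
    sb = hb_distance_series(traj, O_b, H_b, O_a, criterion)
    state = np.where(sa.bonded & ~sb.bonded, 0, np.where(sb.bonded & ~sa.bonded, 1, -1))
    # carry the previous assignment through undetermined frames
    filled = state.copy()
    for i in range(1, len(filled)):
        if filled[i] < 0:
            filled[i] = filled[i - 1]
    first = np.flatnonzero(filled >= 0)
    if first.size == 0:
        return []
    filled[: first[0]] = filled[first[0]]
    hold_frames = max(1, int(round(hold * 1000.0 / traj.dt)))
    events = []
    accepted = filled[0]
    for value, start, length in _runs(filled):
        if value != accepted and length >= hold_frames:
            events.append(start * traj.dt / 1000.0)
            accepted = value
    return events


def hb_lifetimes(
    series: HBondSeries, gap_tolerance: float = 20.0
) -> tuple[float, list[float]]:
    """Longest uninterrupted HB lifetime and gap-merged episode durations.

    Frames are counted as one frame-spacing wide, so a run of k bonded
    frames lasts k·Δt.  An *episode* merges bonded runs to the same
    partner whose separating gaps are shorter than ``gap_tolerance`` (ps)
    — the formalization of "periods consisting of several bridge
    formation–breakup events"; its duration is the span from the first to
    the last bonded frame of the merged run.

    Returns
    -------
    (longest_uninterrupted_ps, sorted episode durations ps, descending)
    """
    if gap_tolerance < 0:
        raise ValueError("gap_tolerance must be non-negative")
    t = series.times
    dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
    runs = [
        (start, length)
        for value, start, length in _runs(series.bonded)
        if value
    ]
    if not runs:
        return 0.0, []
    longest = max(length for _, length in runs) * dt
    episodes: list[float] = []
    cur_start, cur_end = runs[0][0], runs[0][0] + runs[0][1] - 1
    cur_partner = series.partner[runs[0][0]]
    for start, length in runs[1:]:
        gap = (start - cur_end - 1) * dt
        # partner identity read at the start of each bonded run
        same = series.partner[start] == cur_partner
        if gap < gap_tolerance and same:
            cur_end = start + length - 1
        else:
            episodes.append((cur_end - cur_start + 1) * dt)
            cur_start, cur_end = start, start + length - 1
            cur_partner = series.partner[start]
    episodes.append((cur_end - cur_start + 1) * dt)
    return float(longest), sorted(episodes, reverse=True)


@dataclass
class Histogram2D:
    """Normalized 2D probability density over (d_OH, d_OO), units Å⁻²."""

    edges_x: np.ndarray
    edges_y: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        dx = np.diff(self.edges_x)[:, None]
        dy = np.diff(self.edges_y)[None, :]
        total = float((self.density * dx * dy).sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"density integrates to {total}, not 1")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    @property
    def centers_x(self) -> np.ndarray:
        return 0.5 * (self.edges_x[:-1] + self.edges_x[1:])

    @property
    def centers_y(self) -> np.ndarray:
        return 0.5 * (self.edges_y[:-1] + self.edges_y[1:])


def proton_histogram2d(
    series_list: list[HBondSeries],
    bins_x: int | np.ndarray = 60,
    bins_y: int | np.ndarray = 60,
) -> Histogram2D:
    """Pooled 2D histogram of proton position vs donor–acceptor distance.

    Series (e.g. the beads of a path-integral run) are pooled with equal
    weight — the standard estimator for bead statistics — and binned in
    (d_OH, d_OO) as a normalized probability density.
    """
    if not series_list:
        raise ValueError("no series to histogram")
    x = np.concatenate([s.d_OH for s in series_list])
    y = np.concatenate([s.d_OO for s in series_list])
    if x.size == 0:
        raise ValueError("empty pooled sample")
    density, ex, ey = np.histogram2d(x, y, bins=(bins_x, bins_y), density=True)
    return Histogram2D(edges_x=ex, edges_y=ey, density=density)


def isodensity_contours(hist: Histogram2D, level: float = 1.0) -> list[np.ndarray]:
    """Boundary of {density ≥ level} by marching squares, in data coordinates.

    Returns a list of (n, 2) arrays of (d_OH, d_OO) vertices — the usual
    probability isocontour drawn through proton-position histograms.
    """
    from skimage import measure

    contours = measure.find_contours(hist.density, level)
    cx, cy = hist.centers_x, hist.centers_y
    out = []
    for c in contours:
        xs = np.interp(c[:, 0], np.arange(len(cx)), cx)
        ys = np.interp(c[:, 1], np.arange(len(cy)), cy)
        out.append(np.column_stack([xs, ys]))
    return out
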