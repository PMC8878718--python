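"""Vibrational spectra from trajectories and from harmonic line lists.

Two routes to a spectrum live here:

* the dynamical route — velocity autocorrelation of selected atoms,
  Fourier transformed into a power spectrum (the classical vibrational
  density of states, no quantum prefactor applied);
* the static route — a list of harmonic line positions/intensities
  broadened with Gaussian envelopes after a global wavenumber scaling, the
  usual post-processing of quantum-chemical harmonic frequencies.

All spectra are normalized to unit maximum intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import C_CM_PER_FS

__all__ = [
    "Spectrum",
    "LineList",
    "vacf",
    "power_spectrum",
    "synthesize_spectrum",
    "band_maxima",
]

#: Default evaluation grid: 1 cm⁻¹ steps over the mid-infrared.
DEFAULT_GRID = np.arange(0.0, 4500.0 + 1.0, 1.0)


@dataclass
class Spectrum:
    """Wavenumber grid (cm⁻¹, strictly increasing) with intensity in [0, 1]."""

    wavenumber: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumber.shape != self.intensity.shape:
            raise ValueError("wavenumber and intensity must match in shape")
        if np.any(np.diff(self.wavenumber) <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")


@dataclass
class LineList:
    """Harmonic lines: positions (cm⁻¹), intensities, per-line band class.

    ``is_OH`` marks O-H(-D) stretching lines, which get the wide envelope;
    everything else gets the narrow one.
    """

    positions: np.ndarray
    intensities: np.ndarray
    is_OH: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.atleast_1d(np.asarray(self.positions, dtype=float))
        self.intensities = np.atleast_1d(np.asarray(self.intensities, dtype=float))
        self.is_OH = np.atleast_1d(np.asarray(self.is_OH, dtype=bool))
        if not (len(self.positions) == len(self.intensities) == len(self.is_OH)):
            raise ValueError("line-list columns must have equal length")
        if np.any(self.positions <= 0):
            raise ValueError("line positions must be positive")
        if np.any(self.intensities < 0):
            raise ValueError("line intensities must be non-negative")


def vacf(traj, atom_selection, max_lag: int | None = None) -> np.ndarray:
    """Velocity autocorrelation C(τ) of the selected atoms, C(0) = 1.

    C(τ) = ⟨Σᵢ vᵢ(t)·vᵢ(t+τ)⟩ₜ computed with an FFT over all available
    time origins.

    Parameters
    ----------
    traj : Trajectory with velocities.
    atom_selection : index array of the atoms to include.
    max_lag : number of lags to return (default n_frames // 2).
    """
    if traj.velocities is None:
        raise ValueError("trajectory has no velocities")
    sel = np.atleast_1d(np.asarray(atom_selection, dtype=int))
    v = traj.velocities[:, sel, :]  # (T, n_sel, 3)
    n = v.shape[0]
    if max_lag is None:
        max_lag = n // 2
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the frame count")
    # FFT autocorrelation, summed over atoms and Cartesian components
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    flat = v.reshape(n, -1)
    F = np.fft.rfft(flat, n=nfft, axis=0)
    acorr = np.fft.irfft((F * F.conj()).real, n=nfft, axis=0)[: max_lag + 1]
    c = acorr.sum(axis=1) / (n - np.arange(max_lag + 1))
    return c / c[0]


def power_spectrum(acf: np.ndarray, dt: float, window: str = "hann") -> Spectrum:
    """Power spectrum of an autocorrelation series, abscissa in cm⁻¹.

    The ACF is windowed (Hann by default, suppressing leakage on short
    trajectories), zero-padded 4× and Fourier transformed; ν̃ = f/c.  The
    native resolution is Δν̃ = 1/(c·T) for an ACF spanning T = N·dt.

    Parameters
    ----------
    acf : autocorrelation values at lags 0..N-1.
    dt : lag spacing in fs.
    window : 'hann' or 'none'.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    acf = np.asarray(acf, dtype=float)
    n = len(acf)
    if window == "hann":
        w = np.hanning(2 * n)[n:]
    elif window in ("none", None):
        w = np.ones(n)
    else:
        raise ValueError(f"unknown window {window!r}")
    # even extension -> real cosine transform via rfft; 4x zero padding
    nfft = 4 * int(2 ** np.ceil(np.log2(2 * n)))
    power = np.abs(np.fft.rfft(acf * w, n=nfft)) ** 2
    freq = np.fft.rfftfreq(nfft, d=dt)  # fs⁻¹
    wavenumber = freq / C_CM_PER_FS
    keep = wavenumber <= 4500.0
    power = power[keep]
    return Spectrum(wavenumber=wavenumber[keep], intensity=power / power.max())


def synthesize_spectrum(
    lines: LineList,
    scale: float = 0.985,
    width_OH: float = 70.0,
    width_other: float = 8.0,
    grid: np.ndarray | None = None,
) -> Spectrum:
    """Broaden a harmonic line list into a normalized band spectrum.

    Each line j contributes Iⱼ·exp(−(ν̃ − s·ν̃ⱼ)²/(2σⱼ²)) where s is the
    global wavenumber scaling and σⱼ is ``width_OH`` for O-H stretching
    lines and ``width_other`` otherwise ("width" is the Gaussian standard
    deviation).  The sum is normalized to unit maximum.
    """
    if len(lines.positions) == 0:
        raise ValueError("empty line list")
    if grid is None:
        grid = DEFAULT_GRID
    sigma = np.where(lines.is_OH, width_OH, width_other)
    centers = scale * lines.positions
    intensity = (
        lines.intensities[None, :]
        * np.exp(-((grid[:, None] - centers[None, :]) ** 2) / (2 * sigma[None, :] ** 2))
    ).sum(axis=1)
    peak = intensity.max()
    if peak == 0:
        raise ValueError("all lines have zero intensity")
    return Spectrum(wavenumber=grid, intensity=intensity / peak)


def band_maxima(
    spec: Spectrum,
    lo: float | None = None,
    hi: float | None = None,
    shoulders: bool = False,
):
    """Local maxima of a spectrum within [lo, hi], sorted by intensity.

    A maximum is a point strictly above both neighbours (plateaus take the
    leftmost point).  With ``shoulders=True`` a second list is returned:
    flank features detected as local minima of the discrete second
    derivative that do not coincide with a detected maximum — the usual
    signature of an unresolved band on the side of a stronger one.

    Returns
    -------
    peaks : list of (wavenumber, intensity), descending intensity
    shoulders (optional) : list of (wavenumber, intensity)
    """
    x, y = spec.wavenumber, spec.intensity
    mask = np.ones_like(x, dtype=bool)
    if lo is not None:
        mask &= x >= lo
    if hi is not None:
        mask &= x <= hi
    x, y = x[mask], y[mask]
    if len(x) < 3:
        return ([], []) if shoulders else []
    interior = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])) + 1
    peaks = sorted(
        [(float(x[i]), float(y[i])) for i in interior],
        key=lambda p: -p[1],
    )
    if not shoulders:
        return peaks
    d2 = np.gradient(np.gradient(y, x), x)
    cand = list(np.flatnonzero((d2[1:-1] < d2[:-2]) & (d2[1:-1] <= d2[2:])) + 1)
    # every resolved maximum owns its nearest curvature minimum; what is
    # left over marks an unresolved band riding on a flank
    for p, _ in peaks:
        if cand:
            cand.remove(min(cand, key=lambda i: abs(x[i] - p)))
    sh = [
        (float(x[i]), float(y[i]))
        for i in cand
        if y[i] > 0.05 * y.max()
    ]
    return peaks, sh
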