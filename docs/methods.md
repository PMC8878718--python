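# Methods

`hbquant` analyzes hydrogen-bond dynamics and vibrational signatures of
hydrogen-bonded alcohols (the reference system is liquid and gas-phase
*n*-octanol) from molecular-dynamics trajectories, and quantizes the
bridging-proton motion a posteriori. Because first-principles trajectories
are expensive to produce, the package ships a synthetic generator whose
outputs have the statistical structure such simulations exhibit; every
analysis stage is exercised and tested against those model data, against
closed forms, and against independent numerical oracles.

## The model proton potential

The hydrogen bridge O–H…O is described by a double-Morse potential

V(r, R) = D₁[1 − e^(−a₁(r−r₀))]² + D₂[1 − e^(−a₂(R−r−r₀))]² − D₂

where r is the donor-O–H distance along the O…O axis and R the
donor–acceptor distance. The first term is the covalent O–H bond; the
second is the attraction of the proton toward the acceptor oxygen, which
softens the donor well as R closes and produces the familiar red shift of
the bonded O-H stretch. D₁ > D₂ keeps the proton localized on the donor
side; no proton transfer occurs in the parameter regime used.

Defaults (frozen after a single calibration pass, reproducible with
`analysis/00_calibrate_potential.py`):

| constant | value | meaning |
|---|---|---|
| D₁ | 0.23 hartree | donor well depth |
| a₁ | 2.0 Å⁻¹ | donor Morse range |
| D₂ | 0.10 hartree | acceptor well depth |
| a₂ | 2.2 Å⁻¹ | acceptor Morse range |
| r₀ | 0.97 Å | equilibrium O-H length |

The calibration targets three windows simultaneously: the *quantized* O-H
fundamental at R = 3.0 Å in the hydrogen-bonded band (computed: 3154 cm⁻¹,
window 3100–3250), the quantized fundamental at large R in the free-OH
band (3543 cm⁻¹, window 3500–3700), and the *classical* well frequency at
large R also inside the free band (≈3676 cm⁻¹), so that both the quantum
solver and the classical velocity-autocorrelation route place the free
stretch in the same band. A donor Morse with a larger range parameter
(a₁ = 2.2 Å⁻¹) satisfies the two quantum windows but pushes the classical
well frequency to ≈3770 cm⁻¹, outside the free band — hence the flatter
well chosen here. The solver was verified against the analytic Morse
spectrum (ω̃ₑ = (a/2πc)√(2D/m), ω̃ₑχₑ = ħa²/4πcm) to < 0.05 cm⁻¹ before
freezing.

## Synthetic trajectory generators

**Dimer.** R(t) follows an Ornstein–Uhlenbeck process (Euler–Maruyama
discretization): mean 3.0 Å, stationary sd 0.15 Å, relaxation rate
θ = 0.005 fs⁻¹ (≈200 fs correlation time, the scale of the intermolecular
O…O stretch). The bridging proton moves in V(r, R(t)) under BAOAB-split
Langevin dynamics at 300 K with dt = 0.5 fs, which is stable for the
stiff O-H well. Friction is 0.002 fs⁻¹: a weak thermostat whose Lorentzian
line contribution (γ/2πc ≈ 11 cm⁻¹) does not smear the O-H band; stronger
coupling visibly broadens and shifts the classical peak. Donor/acceptor
role switches are scheduled events (default 15 ps and 64 ps in a 100 ps
run): labels swap and the two hydroxyl hydrogens are repositioned along a
50 fs linear blend, avoiding velocity discontinuities. The geometry is a
coarse 6-atom representation (hydroxyl O and H plus one placeholder chain
carbon per molecule) — sufficient because every analysis uses only
hydroxyl O/H and chain-end positions. The RNG is the counter-based Philox
generator; all outputs are pure functions of (parameters, seed).

**Liquid.** Coarse 4-site molecules (hydroxyl O, H, first carbon,
terminal carbon) are grouped into hydrogen-bonded rings — default ring
size 10 — whose consecutive O…O edges are drawn from the first-shell
window (default 2.7–2.9 Å). Rings make every hydroxyl oxygen exactly one
donor and one acceptor, the prevailing coordination-two motif of a
chain-associated alcohol; open chains would depress the mean coordination
below two through their termini. Rings are placed by rejection sampling
under periodic boundary conditions with non-bonded O…O pairs kept beyond
3.6 Å (so the first shell contains exactly the two ring neighbours) and
all other heavy-atom pairs beyond 2.0 Å. Edge lengths are sampled once
per ring (regular polygon), so the distribution across rings is uniform
on the window while edges within one ring are equal.

**What the generators do not emulate.** Real liquid data have diffusing
molecules, a continuous distribution of H-bond geometries and breakup
kinetics, chain conformational disorder, and coupling between the proton
and all other modes. Passing tests therefore demonstrate that the
*analysis machinery* recovers known statistical structure planted in the
data — not that the generator reproduces any particular liquid.

## Analyses

**H-bond metrics and classification.** Per-frame minimum-image distances
d(O-H), d(H…O), d(O…O). The default geometric criterion is the
literature window 1.60 Å ≤ d(H…O) ≤ 2.00 Å (closed at both ends); a
looser preset (d(H…O) ≤ 2.5 Å with d(O…O) ≤ 3.5 Å) is provided for
liquid-phase work, where the strict window sits right at the thermal mean
of the H…O distance and undercounts.

**Lifetimes.** The longest uninterrupted lifetime is the longest run of
consecutive bonded frames (each counted one frame-spacing wide). An
*episode* merges bonded runs to the same partner separated by gaps below
a tolerance (default 20 ps) — the formalization of extended
formation–breakup periods; its duration spans first to last bonded frame.
The implementation is property-tested against an independent brute-force
run-length scan on 1000 random boolean series.

**Role switches.** The donor at each frame is the hydroxyl whose own H
satisfies the bond criterion toward the other oxygen (loose preset by
default, see above); undetermined frames inherit the previous assignment,
and a change counts only if it persists ≥ 1 ps, debouncing librational
flicker (water librations are shorter than 200 fs).

**RDF and coordination.** g(r) from minimum-image pair histograms
normalized by exact ideal-gas shell volumes (orthorhombic cells only,
r ≤ L/2); coordination n = 4πρ∫g(r)r²dr by trapezoidal rule on the binned
g(r), with the integration endpoints interpolated onto the grid. Bin
width defaults to 0.05 Å. Cross-checked against MDAnalysis `InterRDF`
(identical up to its N/(N−1) pair normalization) and against exact
lattice shell counts.

**RMSD.** Plain displacement from the reference (no rotational fit by
default — the quantity of interest is drift, not shape); optional
molecule-wise centroid imaging into the primary cell (autoimage) and an
optional Kabsch superposition mode.

**Power spectra.** The velocity autocorrelation of selected atoms is
computed over all time origins (FFT), Hann-windowed (suppressing leakage
on few-ps series), zero-padded 4×, and Fourier transformed; intensity is
the squared transform magnitude normalized to unit maximum, abscissa
ν̃ = f/c with native resolution 1/(cT). No quantum prefactor is applied:
the spectra are raw classical power spectra.

**Line-list synthesis.** Harmonic lines are scaled by a global factor
(default 0.985) and broadened with Gaussians of standard deviation
70 cm⁻¹ for O-H(-D) stretching lines and 8 cm⁻¹ otherwise, then
normalized to unit maximum. "Width" is interpreted as the Gaussian σ; the
only consequence asserted anywhere (separated band maxima staying at the
line positions) is insensitive to that reading. Band maxima are located
by discrete neighbourhood comparison; shoulders are reported as local
minima of the second derivative not owned by a resolved maximum.

## Nuclear quantization

**Rigid scan.** The bridging H is displaced along the instantaneous
donor→acceptor axis (the simplest path containing both wells; the scan
coordinate is the O(donor)–H distance, grid 0.75–2.25 Å, step 0.02 Å)
with all other atoms frozen; an evaluator maps each geometry to an energy
(the model potential by default; tabulated scans from external
electronic-structure codes can be read from TSV and used bit-for-bit
instead). Curves are re-zeroed to their minimum — only differences enter
the eigenproblem.

**Eigensolver.** The curve is cubic-spline interpolated onto a uniform
256-point grid and the 1D Schrödinger equation −(ħ²/2m)ψ″ + Vψ = Eψ is
solved by diagonalizing a Fourier-grid (sinc-DVR) Hamiltonian, which is
variational on the grid and robust for asymmetric double wells. Doubling
the grid moves the reported levels by < 0.1 cm⁻¹ (asserted in tests, and
available at run time via `check_convergence`). An independent Numerov
shooting solver (node-counting bisection) agrees within 0.5 cm⁻¹ on all
test curves. The moving mass is the bare ¹H (1.00783 u) or ²H (2.01410 u)
mass, since every other atom is frozen in the scan.

**Envelopes and the isotope ratio.** Snapshots are taken every 1.45 ps;
each confining curve contributes its 0→1 fundamental with equal weight
(transition-dipole weighting is deliberately out of scope) to a Gaussian
envelope of σ = 20 cm⁻¹. Non-confining curves (minimum on the grid edge)
are excluded with a warning rather than failing the whole envelope. The
isotope ratio is peak(O-H)/peak(O-D). Identical harmonic curves give
√(m_D/m_H) = 1.414 exactly; any Morse-like anharmonicity pulls the ratio
below that bound, and the deeper the well the closer the approach — both
directions are property-tested. For the default model at R = 3.0 Å the
quantized fundamental also lies below the curvature (harmonic) wavenumber
at the minimum: the quantization red shift.

## Numerical and scope choices

- Units at module boundaries: Å, Å/fs, fs (ps for metadata), hartree, u,
  cm⁻¹; one constants table holds all conversions.
- Extended-XYZ text I/O (atom-count line, `Time`/`Lattice` key=value
  comment, optional velocity columns); TSV for scans and spectra; JSON
  sidecars for metadata. Fixed column order and `.` decimals for
  reproducible regression files.
- Problem sizes are desk-scale by design: 100 ps dimer (200 000 steps),
  200-molecule liquid, ≤ 68 snapshot curves; the bundled demo pipeline
  completes in a few seconds on one core.
- Known limitations: 1D quantization only (no mode coupling, no
  tunneling-splitting analysis, no intensities); orthorhombic cells only;
  the liquid generator produces a static, idealized H-bond topology; the
  role-switch mechanism is scheduled rather than emergent.
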