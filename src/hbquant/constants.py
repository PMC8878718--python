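"""Physical constants and unit conversions.

Module-boundary unit contract: positions in Å, velocities in Å/fs, time in
fs (trajectory metadata in ps where noted), energies in hartree, masses in
unified atomic mass units (u), wavenumbers in cm⁻¹.  Everything that leaves
those units goes through this table.
"""

#: 1 hartree in cm⁻¹ (E/hc).
HARTREE_TO_INVCM = 219474.6313632

#: 1 u in electron masses.
AMU_TO_ME = 1822.888486

#: 1 bohr in Å.
BOHR_TO_ANGSTROM = 0.529177210903

#: 1 atomic unit of time in fs (CPMD-style "time step = 3 a.u." inputs).
AU_TIME_TO_FS = 0.02418884

#: Speed of light in cm/fs (wavenumber <-> frequency conversion).
C_CM_PER_FS = 2.99792458e-5

#: Boltzmann constant in hartree/K.
KB_HARTREE_PER_K = 3.166811563e-6

#: 1 u·Å²/fs² in hartree (kinetic-energy unit of the MD unit system).
AMU_ANG2_PER_FS2_TO_HARTREE = 1.66053906660e-17 / 4.3597447222071e-18

#: Acceleration conversion: a[Å/fs²] = F[hartree/Å] / m[u] * this factor.
FORCE_TO_ACC = 1.0 / AMU_ANG2_PER_FS2_TO_HARTREE

#: 1 u in grams (mass-density bookkeeping).
AMU_TO_GRAM = 1.66053906660e-24

#: Masses of the two hydrogen isotopes moved in the 1D quantization (u).
MASS_H = 1.00783
MASS_D = 2.01410
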