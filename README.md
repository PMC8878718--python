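# hbquant

Hydrogen-bond dynamics analysis and a posteriori nuclear quantization for
hydrogen-bonded alcohol MD trajectories.

Liquid alcohols such as *n*-octanol owe their structure to chains and
rings of O-H…O hydrogen bonds. Their vibrational fingerprint — the broad,
red-shifted O-H stretching band — is shaped both by the distribution of
hydrogen-bond geometries and by the quantum nature of the proton, which a
classical trajectory misses. `hbquant` provides the analysis chain for
this problem:

- **hydrogen-bond dynamics**: metric time series d(O-H), d(H…O), d(O…O),
  geometric bond classification, donor/acceptor role-switch detection,
  lifetime and formation–breakup episode statistics, and 2D histograms of
  proton position vs donor–acceptor distance with probability isocontours
  (path-integral bead series are pooled with equal weight);
- **liquid structure**: RMSD with optional molecule-wise wrapping,
  radial distribution functions under periodic boundary conditions,
  coordination numbers n = 4πρ∫g(r)r²dr, and mass-density bookkeeping;
- **spectra**: velocity-autocorrelation power spectra (Hann-windowed FFT,
  ν̃ = f/c) and synthesis of band spectra from harmonic line lists
  (global 0.985 scaling, Gaussian widths 70 cm⁻¹ for νOH / 8 cm⁻¹
  otherwise, unit-maximum normalization);
- **quantization**: the snapshot-envelope method — rigid-scan 1D proton
  potentials along the donor→acceptor axis, a Fourier-grid (sinc-DVR)
  solution of −(ħ²/2m)ψ″+Vψ=Eψ per snapshot (Numerov shooting as
  cross-check), Gaussian band envelopes over the 0→1 fundamentals for
  ¹H and ²H, and the H/D isotope ratio, which is √(m_D/m_H) = 1.414 for a
  harmonic well and below it for any anharmonic one;
- **synthetic data**: a double-Morse proton potential
  V(r,R) = D₁[1−e^(−a₁(r−r₀))]² + D₂[1−e^(−a₂(R−r−r₀))]² − D₂, a
  Langevin/Ornstein–Uhlenbeck dimer trajectory generator with scheduled
  donor/acceptor role switches, and a ring-associated liquid packing
  generator — so the whole chain runs and is tested without any
  electronic-structure engine. Externally computed potential scans (TSV)
  drop in wherever the model potential is used.

See `docs/methods.md` for the model, parameter defaults and numerical
choices.

## Worked example

```python
import numpy as np
from hbquant import synthetic as syn, hbond, quantize

traj = syn.generate_dimer_trajectory(
    ou=syn.OUParams.from_sd(3.0, 0.15),
    switches=syn.SwitchSchedule((15.0, 64.0)),
    n_steps=200_000, dt=0.5, seed=11,
)
s = hbond.hb_distance_series(traj, 0, 1, 3)
print(f"<d_OO> = {s.d_OO.mean():.3f} A")
print("switches:", hbond.detect_role_switches(traj, 0, 1, 3, 4))

frames = syn.sample_snapshots(traj, 1.45)
params = syn.ModelPotentialParams()
curves = [
    quantize.rigid_scan(
        f, 0, 1, 3, syn.axis_evaluator(params, 0, 1, 3),
        x_lo=0.75,
        x_hi=min(2.25, float(np.linalg.norm(f.positions[3] - f.positions[0])) - 0.77),
    )
    for f in frames
]
res_h, res_d, ratio = quantize.isotope_pipeline(curves, width=20.0)
print(f"OH peak {res_h.peak:.0f} cm-1, OD peak {res_d.peak:.0f} cm-1, "
      f"ratio {ratio:.3f}")
```

prints

```
<d_OO> = 3.003 A
switches: [15.026, 64.031]
OH peak 3180 cm-1, OD peak 2283 cm-1, ratio 1.393
```

— the donor–acceptor distance fluctuates around 3 Å as configured, both
scheduled hydroxyl-rotation events are recovered to within a frame of
their schedule, the quantized O-H stretch envelope peaks inside the
hydrogen-bonded band (3100–3250 cm⁻¹), and the anharmonic H/D ratio falls
below the harmonic reference 1.414.

The same workflow is scripted, stage by stage, in `analysis/` (numbered
drivers writing tables under `results/`), and is available as a CLI:

```sh
hbquant all --config configs/demo.toml
```

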