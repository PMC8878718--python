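"""End-to-end orchestration: generate → analyze → quantize → report.

A :class:`RunConfig` (TOML file or keyword overrides) drives the whole
synthetic-data workflow; every stage writes plain-text tables under the
output directory, each stamped with the configuration hash, and a JSON
summary collects the headline numbers (lifetimes, coordination, band
peaks, isotope ratio).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import hbond, quantize, spectra, structure, synthetic, traj_io

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("hbquant")


@dataclass(frozen=True)
class DimerConfig:
    n_steps: int = 200_000
    dt: float = 0.5  # fs
    temperature: float = 300.0  # K
    switch_times: tuple = (15.0, 64.0)  # ps
    ou_mu: float = 3.0  # Å
    ou_sd: float = 0.15  # Å
    ou_theta: float = 0.005  # fs⁻¹


@dataclass(frozen=True)
class LiquidConfig:
    n_molecules: int = 200
    cell: float = 39.182  # Å
    first_shell: tuple = (2.7, 2.9)  # Å
    ring_size: int = 10


@dataclass(frozen=True)
class AnalysisConfig:
    d_HA_min: float = 1.60  # Å, strict geometric HB criterion
    d_HA_max: float = 2.00
    gap_tolerance: float = 20.0  # ps, episode merging
    hold: float = 1.0  # ps, role-switch debounce
    rdf_dr: float = 0.05  # Å
    coord_range: tuple = (2.5, 3.5)  # Å
    snapshot_interval: float = 1.45  # ps
    scan_lo: float = 0.75  # Å
    scan_hi: float = 2.25  # Å
    scan_dx: float = 0.02  # Å
    envelope_width: float = 20.0  # cm⁻¹
    vacf_max_lag: int = 8192  # frames


@dataclass(frozen=True)
class RunConfig:
    seed: int = 11
    outdir: str = "results/pipeline"
    dimer: DimerConfig = field(default_factory=DimerConfig)
    liquid: LiquidConfig = field(default_factory=LiquidConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def hash(self) -> str:
        d = asdict(self)
        d.pop("outdir")  # where results land is not part of the science
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


_SECTIONS = {"dimer": DimerConfig, "liquid": LiquidConfig, "analysis": AnalysisConfig}


def _build_section(cls, data: dict):
    known = set(cls.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s) in [{cls.__name__}]: {sorted(unknown)}")
    data = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**data)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a TOML run configuration; unknown keys are rejected.

    Flat overrides (seed=…, outdir=…) win over the file, which wins over
    defaults.
    """
    data: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    top_known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - top_known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    kwargs: dict = {}
    for key, value in data.items():
        if key in _SECTIONS:
            kwargs[key] = _build_section(_SECTIONS[key], value)
        else:
            kwargs[key] = value
    cfg = RunConfig(**kwargs)
    if overrides:
        bad = set(overrides) - top_known
        if bad:
            raise ValueError(f"unknown config key(s): {sorted(bad)}")
        cfg = replace(cfg, **overrides)
    return cfg


def _timer(stage: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: %.2f s", stage, time.perf_counter() - self.t0)

    return _T()


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = ("all",)) -> dict:
    """Run the requested stages and write their report files.

    Stages: ``generate``, ``hbonds``, ``structure``, ``spectra``,
    ``quantize`` or ``all``.  Returns the summary dictionary (also written
    to ``summary.json``).
    """
    want = set(stages)
    if "all" in want:
        want = {"generate", "hbonds", "structure", "spectra", "quantize"}
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.hash(), "seed": config.seed}
    # sidecar echoing every (defaulted or not) parameter of the run
    traj_io.write_metadata(
        out / "run_config.json", {"config_hash": config.hash(), **asdict(config)}
    )
    summary: dict = dict(meta)

    dc, lc, ac = config.dimer, config.liquid, config.analysis
    need_dimer = want & {"generate", "hbonds", "spectra", "quantize"}
    dimer = liquid = None
    if need_dimer:
        with _timer("generate-dimer"):
            dimer = synthetic.generate_dimer_trajectory(
                ou=synthetic.OUParams.from_sd(dc.ou_mu, dc.ou_sd, dc.ou_theta),
                switches=synthetic.SwitchSchedule(dc.switch_times),
                n_steps=dc.n_steps,
                dt=dc.dt,
                temperature=dc.temperature,
                seed=config.seed,
            )
            dimer.comment["config_hash"] = config.hash()
    if want & {"generate", "structure"}:
        with _timer("generate-liquid"):
            liquid = synthetic.generate_liquid_config(
                n_molecules=lc.n_molecules,
                cell=lc.cell,
                first_shell=lc.first_shell,
                ring_size=lc.ring_size,
                seed=config.seed,
            )
            liquid.comment["config_hash"] = config.hash()

    if "generate" in want:
        stride = max(1, dimer.n_frames // 2000)
        small = traj_io.Trajectory(
            positions=dimer.positions[::stride],
            velocities=dimer.velocities[::stride] if dimer.velocities is not None else None,
            elements=dimer.elements,
            dt=dimer.dt * stride,
            comment=dimer.comment,
        )
        traj_io.write_xyz(small, out / "dimer_trajectory.xyz")
        traj_io.write_xyz(liquid, out / "liquid_config.xyz")
        summary["generate"] = {
            "dimer_frames_written": small.n_frames,
            "liquid_atoms": liquid.n_atoms,
        }

    criterion = hbond.HBCriterion(ac.d_HA_min, ac.d_HA_max)
    if "hbonds" in want:
        with _timer("hbonds"):
            series = hbond.hb_distance_series(dimer, 0, 1, 3, criterion=criterion)
            stride = max(1, len(series.times) // 5000)
            traj_io.write_table(
                out / "hb_series.tsv",
                {
                    "time_ps": series.times[::stride],
                    "d_OH_A": series.d_OH[::stride],
                    "d_HA_A": series.d_HA[::stride],
                    "d_OO_A": series.d_OO[::stride],
                },
                meta=meta,
            )
            switches = hbond.detect_role_switches(dimer, 0, 1, 3, 4, hold=ac.hold)
            loose = hbond.LOOSE_HB
            s_loose = hbond.hb_distance_series(dimer, 0, 1, 3, criterion=loose)
            longest, episodes = hbond.hb_lifetimes(s_loose, ac.gap_tolerance)
            hist = hbond.proton_histogram2d([series])
            np.savetxt(
                out / "proton_histogram2d.tsv",
                hist.density,
                header=f"config_hash={config.hash()}\n"
                f"rows d_OH {hist.edges_x[0]:.3f}..{hist.edges_x[-1]:.3f} A; "
                f"cols d_OO {hist.edges_y[0]:.3f}..{hist.edges_y[-1]:.3f} A; density A^-2",
            )
            summary["hbonds"] = {
                "mean_d_OO_A": float(series.d_OO.mean()),
                "role_switches_ps": switches,
                "longest_lifetime_ps": longest,
                "n_episodes": len(episodes),
            }

    if "structure" in want:
        with _timer("structure"):
            res = structure.rdf(liquid, "O", dr=ac.rdf_dr)
            coord = structure.coordination_number(res, *ac.coord_range)
            traj_io.write_table(
                out / "rdf_OO.tsv", {"r_A": res.r, "g": res.g}, meta=meta
            )
            summary["structure"] = {
                "first_peak_A": float(res.r[np.argmax(res.g)]),
                "coordination_2.5_3.5": coord,
                "number_density_A3": res.rho,
                "mass_density_g_cm3": structure.mass_density(
                    lc.n_molecules, 130.23, lc.cell
                ),
            }

    if "spectra" in want:
        with _timer("spectra"):
            # bridging hydroxyl H of the initial donor
            acf = spectra.vacf(dimer, [1], max_lag=min(ac.vacf_max_lag, dimer.n_frames // 2))
            spec = spectra.power_spectrum(acf, dimer.dt)
            traj_io.write_table(
                out / "power_spectrum_H.tsv",
                {"wavenumber_cm1": spec.wavenumber, "intensity": spec.intensity},
                meta=meta,
            )
            peaks = spectra.band_maxima(spec, lo=2000.0, hi=4200.0)
            summary["spectra"] = {
                "H_peak_cm1": peaks[0][0] if peaks else None,
            }

    if "quantize" in want:
        with _timer("quantize"):
            frames = synthetic.sample_snapshots(dimer, ac.snapshot_interval)
            curves = []
            for k, fr in enumerate(frames):
                # donor is the hydroxyl whose H bridges toward the other O
                d_ab = np.linalg.norm(fr.positions[1] - fr.positions[3])
                d_ba = np.linalg.norm(fr.positions[4] - fr.positions[0])
                donor, H, acc = (0, 1, 3) if d_ab < d_ba else (3, 4, 0)
                R = float(np.linalg.norm(fr.positions[acc] - fr.positions[donor]))
                x_hi = min(ac.scan_hi, R - ac.scan_lo - ac.scan_dx)
                ev = synthetic.axis_evaluator(
                    synthetic.ModelPotentialParams(), donor, H, acc
                )
                curves.append(
                    quantize.rigid_scan(
                        fr, donor, H, acc, ev,
                        x_lo=ac.scan_lo, x_hi=x_hi, dx=ac.scan_dx, snapshot_id=k,
                    )
                )
            res_h, res_d, ratio = quantize.isotope_pipeline(
                curves, width=ac.envelope_width
            )
            traj_io.write_table(
                out / "snapshot_fundamentals.tsv",
                {"fundamental_H_cm1": res_h.fundamentals,
                 "fundamental_D_cm1": res_d.fundamentals},
                meta=meta,
            )
            for tag, res in (("H", res_h), ("D", res_d)):
                traj_io.write_table(
                    out / f"envelope_O{tag}.tsv",
                    {"wavenumber_cm1": res.envelope.wavenumber,
                     "intensity": res.envelope.intensity},
                    meta=meta,
                )
            summary["quantize"] = {
                "n_snapshots": len(frames),
                "OH_peak_cm1": res_h.peak,
                "OD_peak_cm1": res_d.peak,
                "isotope_ratio": ratio,
            }

    traj_io.write_metadata(out / "summary.json", summary)
    return summary
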