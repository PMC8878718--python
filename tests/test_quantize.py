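import numpy as np
import pytest

from hbquant.constants import MASS_D, MASS_H
from hbquant.quantize import (
    EnvelopeResult,
    NonConfiningError,
    PotentialCurve,
    band_support,
    envelope,
    fundamental,
    harmonic_curve,
    isotope_pipeline,
    morse_curve,
    morse_fundamental,
    numerov_levels,
    rigid_scan,
    solve_levels,
)
from hbquant.synthetic import ModelPotentialParams, axis_evaluator
from hbquant.traj_io import Frame

HARMONIC_RATIO = np.sqrt(MASS_D / MASS_H)  # ideal harmonic isotope ratio


class TestSolver:
    def test_harmonic_fundamental(self):
        lv = solve_levels(harmonic_curve(3000.0), mass=MASS_H)
        assert fundamental(lv) == pytest.approx(3000.0, abs=0.1)

    def test_harmonic_levels_equally_spaced(self):
        lv = solve_levels(harmonic_curve(3000.0), mass=MASS_H, n_levels=4)
        gaps = np.diff(lv.energies)
        np.testing.assert_allclose(gaps, gaps[0], rtol=1e-4)

    @pytest.mark.parametrize(
        "D,a", [(0.20, 2.2), (0.23, 2.0), (0.10, 2.5), (0.30, 1.8)]
    )
    def test_morse_closed_form(self, D, a):
        """Grid eigenvalues against the analytic Morse spectrum."""
        lv = solve_levels(morse_curve(D, a), mass=MASS_H)
        assert fundamental(lv) == pytest.approx(morse_fundamental(D, a, MASS_H), abs=0.5)

    def test_mass_scaling_harmonic(self):
        c = harmonic_curve(3000.0)
        f1 = fundamental(solve_levels(c, mass=MASS_H))
        f2 = fundamental(solve_levels(c, mass=2 * MASS_H))
        assert f2 == pytest.approx(f1 / np.sqrt(2.0), abs=0.1)

    def test_grid_doubling_convergence(self):
        """Doubling the grid moves no reported level by 0.1 cm⁻¹."""
        for curve in (harmonic_curve(3200.0), morse_curve(0.23, 2.0)):
            solve_levels(curve, mass=MASS_H, n_levels=4, check_convergence=True)

    @pytest.mark.parametrize("mass", [MASS_H, MASS_D])
    def test_numerov_cross_agreement(self, mass):
        """Independent shooting solver agrees with the grid diagonalization."""
        for curve in (harmonic_curve(3000.0), morse_curve(0.23, 2.0), morse_curve(0.20, 2.2)):
            f_dvr = fundamental(solve_levels(curve, mass=mass))
            f_num = fundamental(numerov_levels(curve, mass=mass))
            assert abs(f_dvr - f_num) < 0.5

    def test_non_confining_rejected(self):
        x = np.linspace(0.5, 2.0, 50)
        curve = PotentialCurve(x=x, V=-0.1 * x)  # monotone downhill
        assert not curve.confining
        with pytest.raises(NonConfiningError):
            solve_levels(curve, mass=MASS_H)

    def test_fundamental_arithmetic(self):
        lv = solve_levels(harmonic_curve(3000.0), mass=MASS_H)
        lv.energies = np.array([0.005, 0.020])
        assert fundamental(lv) == pytest.approx(3292.1, abs=0.1)
        lv.energies = np.array([0.005, 0.005])
        assert fundamental(lv) == 0.0
        with pytest.raises(ValueError):
            fundamental(type(lv)(energies=np.array([0.005]), mass=MASS_H))


def test_tabulated_scan_file_feeds_solver(tmp_path):
    """A TSV scan from an external code replaces the model evaluator."""
    from hbquant.traj_io import read_potential_scan

    ref = morse_curve(0.23, 2.0, n=76)
    p = tmp_path / "scan.tsv"
    np.savetxt(p, np.column_stack([ref.x, ref.V + 0.37]))  # arbitrary offset
    x, v = read_potential_scan(p)
    curve = PotentialCurve(x=x, V=v)
    f = fundamental(solve_levels(curve, mass=MASS_H))
    assert f == pytest.approx(morse_fundamental(0.23, 2.0, MASS_H), abs=0.5)


class TestRigidScan:
    @staticmethod
    def _dimer_frame(R=3.0):
        return Frame(
            positions=np.array(
                [[0, 0, 0], [0.97, 0, 0], [-1, -1, 0], [R, 0, 0], [R + 0.3, 0.9, 0], [R + 1, -1, 0]]
            )
        )

    def test_minimum_beyond_equilibrium_length(self):
        """Acceptor attraction pulls the scan minimum past the free O-H length."""
        p = ModelPotentialParams()
        curve = rigid_scan(
            self._dimer_frame(3.0), 0, 1, 3, axis_evaluator(p, 0, 1, 3),
            x_lo=0.75, x_hi=2.25, dx=0.02,
        )
        # dense-grid oracle on the same evaluator
        from hbquant.synthetic import evaluate_model_potential

        dense = np.linspace(0.75, 2.25, 20001)
        r_oracle = dense[np.argmin(evaluate_model_potential(dense, 3.0, p))]
        r_grid = curve.x[np.argmin(curve.V)]
        assert r_grid > p.r0
        assert r_grid == pytest.approx(r_oracle, abs=0.02)
        assert curve.confining
        assert curve.R == pytest.approx(3.0)

    def test_pure_morse_evaluator_exact(self):
        D, a, r0 = 0.2, 2.2, 0.97

        def morse_eval(pos):
            r = np.linalg.norm(pos[1] - pos[0])
            return D * (1 - np.exp(-a * (r - r0))) ** 2

        curve = rigid_scan(self._dimer_frame(6.0), 0, 1, 3, morse_eval,
                           x_lo=0.75, x_hi=2.25, dx=0.05)
        expected = D * (1 - np.exp(-a * (curve.x - r0))) ** 2
        np.testing.assert_allclose(curve.V, expected - expected.min(), atol=1e-12)

    def test_grid_reaching_acceptor_rejected(self):
        p = ModelPotentialParams()
        with pytest.raises(ValueError):
            rigid_scan(self._dimer_frame(2.8), 0, 1, 3, axis_evaluator(p, 0, 1, 3),
                       x_lo=0.75, x_hi=2.25)


class TestCalibrationWindows:
    """The default model potential reproduces the printed band extents."""

    @staticmethod
    def _curve(R):
        from hbquant.synthetic import evaluate_model_potential

        p = ModelPotentialParams()
        x = np.arange(0.70, min(2.3, R - 0.7), 0.02)
        return PotentialCurve(x=x, V=evaluate_model_potential(x, R, p), R=R)

    def test_bridged_fundamental_window(self):
        f = fundamental(solve_levels(self._curve(3.0), mass=MASS_H))
        assert 3100.0 <= f <= 3250.0

    def test_free_fundamental_window(self):
        f = fundamental(solve_levels(self._curve(6.0), mass=MASS_H))
        assert 3500.0 <= f <= 3700.0

    def test_quantized_below_harmonic_curvature(self):
        """Quantization red shift: fundamental below the curvature wavenumber."""
        from hbquant.constants import (
            AMU_TO_ME,
            BOHR_TO_ANGSTROM,
            HARTREE_TO_INVCM,
        )

        curve = self._curve(3.0)
        i = np.argmin(curve.V)
        d2 = np.gradient(np.gradient(curve.V, curve.x / BOHR_TO_ANGSTROM),
                         curve.x / BOHR_TO_ANGSTROM)
        omega_harm = np.sqrt(d2[i] / (MASS_H * AMU_TO_ME)) * HARTREE_TO_INVCM
        f = fundamental(solve_levels(curve, mass=MASS_H))
        assert f < omega_harm


class TestEnvelope:
    def test_identical_fundamentals_peak(self):
        spec = envelope(np.full(7, 3160.0), width=20.0)
        assert spec.wavenumber[np.argmax(spec.intensity)] == pytest.approx(3160.0, abs=1.0)

    def test_uniform_band_support(self, rng):
        f = rng.uniform(3100.0, 3250.0, 200)
        spec = envelope(f, width=20.0)
        lo, hi = band_support(spec)
        assert lo == pytest.approx(3100.0 - 40.0, abs=25.0)
        assert hi == pytest.approx(3250.0 + 40.0, abs=25.0)

    def test_two_clusters_peak_and_secondary(self):
        f = np.concatenate([np.full(30, 3160.0), np.full(10, 3220.0)])
        spec = envelope(f, width=20.0)
        from hbquant.spectra import band_maxima

        peaks = band_maxima(spec)
        assert peaks[0][0] == pytest.approx(3160.0, abs=2.0)
        # dense-grid oracle on the analytic two-Gaussian sum
        dense = np.arange(3050.0, 3330.0, 0.01)
        yd = 30 * np.exp(-((dense - 3160.0) ** 2) / 800.0) + 10 * np.exp(
            -((dense - 3220.0) ** 2) / 800.0
        )
        assert peaks[0][0] == pytest.approx(dense[np.argmax(yd)], abs=1.0)
        secondary = [p for p in peaks[1:] if abs(p[0] - 3220.0) < 10.0]
        assert secondary, "expected a secondary feature near the minor cluster"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            envelope(np.array([]))


class TestIsotopePipeline:
    def test_harmonic_ratio(self):
        curves = [harmonic_curve(3300.0) for _ in range(3)]
        _, _, ratio = isotope_pipeline(curves)
        assert round(ratio, 3) == round(HARMONIC_RATIO, 3) == 1.414

    def test_single_curve_peak_is_fundamental(self):
        curve = morse_curve(0.23, 2.0)
        res_h, res_d, _ = isotope_pipeline([curve])
        assert res_h.peak == pytest.approx(res_h.fundamentals[0], abs=1.0)
        assert res_d.peak == pytest.approx(res_d.fundamentals[0], abs=1.0)

    @pytest.mark.parametrize("D,a", [(0.15, 2.0), (0.20, 2.2), (0.30, 2.0)])
    def test_anharmonic_ratio_below_harmonic_bound(self, D, a):
        """Every Morse curve pulls H/D below √(m_D/m_H)."""
        f_h = morse_fundamental(D, a, MASS_H)
        f_d = morse_fundamental(D, a, MASS_D)
        assert f_h / f_d < HARMONIC_RATIO
        _, _, ratio = isotope_pipeline([morse_curve(D, a)])
        assert ratio < HARMONIC_RATIO

    def test_monotone_approach_to_harmonic_limit(self):
        """Deeper Morse wells (weaker anharmonicity) push the ratio upward."""
        ratios = []
        for D in (0.15, 0.30, 0.60, 1.20):
            f_h = fundamental(solve_levels(morse_curve(D, 2.0), mass=MASS_H))
            f_d = fundamental(solve_levels(morse_curve(D, 2.0), mass=MASS_D))
            ratios.append(f_h / f_d)
        assert np.all(np.diff(ratios) > 0)
        assert ratios[-1] < HARMONIC_RATIO

    def test_non_confining_curves_skipped_with_warning(self):
        x = np.linspace(0.5, 2.0, 50)
        bad = PotentialCurve(x=x, V=-0.05 * x)
        good = morse_curve(0.23, 2.0)
        with pytest.warns(UserWarning, match="non-confining"):
            res_h, _, _ = isotope_pipeline([good, bad])
        assert len(res_h.fundamentals) == 1
        with pytest.raises(NonConfiningError), pytest.warns(UserWarning):
            isotope_pipeline([bad])

    def test_envelope_result_peak_inside_span(self):
        curves = [morse_curve(D, 2.0) for D in (0.20, 0.23, 0.26)]
        res_h, res_d, ratio = isotope_pipeline(curves)
        for res in (res_h, res_d):
            assert res.fundamentals.min() - 1 <= res.peak <= res.fundamentals.max() + 1
        assert 1.30 < ratio < HARMONIC_RATIO
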