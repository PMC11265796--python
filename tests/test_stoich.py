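"""qPCR standard curves, copy-number inversion, X0 ratios, densitometry."""

import math

import numpy as np
import pytest

from circmotif.simulate import generate_densitometry_panel, generate_qpcr_panel
from circmotif.stoich import (
    AVOGADRO,
    CopyEstimate,
    ProteinCalibration,
    copies_per_cell,
    fit_protein_calibration,
    fit_standard_curve,
    molar_ratio_report,
    protein_copies_per_cell,
    x0_relative,
)


class TestStandardCurve:
    def test_perfect_doubling_analytic_case(self):
        copies = [1e7, 1e6, 1e5, 1e4]
        ct = [10.000, 13.322, 16.644, 19.966]
        curve = fit_standard_curve(copies, ct)
        assert curve.slope == pytest.approx(-3.3219, abs=2e-4)
        assert curve.efficiency == pytest.approx(2.00, abs=1e-3)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_efficiency_recovered_from_noisy_dilutions(self, rng):
        E = 1.9
        slope = -1 / math.log10(E)
        copies = np.array([2.5e7 / 10**i for i in range(6)])
        ct = 38 + slope * np.log10(copies) + rng.normal(0, 0.1, size=6)
        curve = fit_standard_curve(copies, ct)
        assert curve.efficiency == pytest.approx(E, abs=0.05)

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            fit_standard_curve([1e6, 1e5], [13.0, 16.3])

    def test_zero_copy_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_standard_curve([1e5, 1e5, 1e5], [16.0, 16.1, 15.9])


class TestCopiesPerCell:
    def curve(self):
        return fit_standard_curve([1e7, 1e6, 1e5, 1e4],
                                  [10.0, 13.3219, 16.6439, 19.9658])

    def test_cell_equivalent_division(self):
        # 13,200 copies in the reaction over 0.8e6 cells x 3.3e-4 = 264 cell-equivalents
        curve = self.curve()
        ct = curve.copies_to_ct(13_200)
        est = copies_per_cell(ct, curve, n_cells=0.8e6, assay_fraction=3.3e-4)
        assert est.molecules_per_cell == pytest.approx(50.0, rel=1e-6)

    def test_fraction_one_single_cell_identity(self):
        curve = self.curve()
        ct = curve.copies_to_ct(1234.0)
        est = copies_per_cell(ct, curve, n_cells=1, assay_fraction=1.0)
        assert est.molecules_per_cell == pytest.approx(1234.0, rel=1e-9)

    def test_replicates_averaged_on_copy_scale_with_ci(self):
        curve = self.curve()
        cts = [curve.copies_to_ct(c) for c in (900.0, 1000.0, 1100.0)]
        est = copies_per_cell(cts, curve, n_cells=1, assay_fraction=1.0)
        assert est.molecules_per_cell == pytest.approx(1000.0, rel=1e-9)
        assert est.ci_low < 1000.0 < est.ci_high and est.n_replicates == 3

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            copies_per_cell(20.0, self.curve(), n_cells=100, assay_fraction=0.0)


class TestRoundTrip:
    def test_noiseless_panel_inverts_exactly(self):
        panel = generate_qpcr_panel(45.0, efficiency=2.0, n_cells=0.8e6,
                                    assay_fraction=3.3e-4, ct_noise_sd=0.0, seed=3)
        std = panel[panel["role"] == "standard"]
        curve = fit_standard_curve(std["copies"].astype(float), std["ct"])
        est = copies_per_cell(panel.loc[panel["role"] == "sample", "ct"].to_numpy(),
                              curve, n_cells=0.8e6, assay_fraction=3.3e-4)
        assert est.molecules_per_cell == pytest.approx(45.0, rel=1e-6)

    def test_noiseless_sample_ct_is_intercept_minus_log2_copies(self):
        panel = generate_qpcr_panel(45.0, efficiency=2.0, n_cells=0.8e6,
                                    assay_fraction=3.3e-4, ct_noise_sd=0.0,
                                    intercept=38.0, seed=0)
        copies_rxn = 45.0 * 0.8e6 * 3.3e-4
        sample_ct = panel.loc[panel["role"] == "sample", "ct"].iloc[0]
        assert sample_ct == pytest.approx(38.0 - math.log2(copies_rxn), abs=1e-3)

    def test_tenfold_dilution_gives_constant_ct_spacing_at_zero_noise(self):
        panel = generate_qpcr_panel(45.0, efficiency=1.95, n_cells=0.8e6,
                                    assay_fraction=3.3e-4, ct_noise_sd=0.0,
                                    n_replicates=1, seed=0)
        std_ct = panel.loc[panel["role"] == "standard", "ct"].to_numpy()
        spacing = np.diff(std_ct)
        assert np.allclose(spacing, spacing[0], atol=1e-3)

    def test_noisy_triplicate_recovery_within_15_percent(self):
        panel = generate_qpcr_panel(45.0, efficiency=1.95, n_cells=0.8e6,
                                    assay_fraction=3.3e-4, ct_noise_sd=0.15,
                                    n_replicates=3, seed=11)
        std = panel[panel["role"] == "standard"]
        curve = fit_standard_curve(std["copies"].astype(float), std["ct"])
        est = copies_per_cell(panel.loc[panel["role"] == "sample", "ct"].to_numpy(),
                              curve, n_cells=0.8e6, assay_fraction=3.3e-4)
        assert abs(est.molecules_per_cell - 45.0) / 45.0 < 0.15

    def test_invalid_efficiency_rejected(self):
        with pytest.raises(ValueError):
            generate_qpcr_panel(45.0, efficiency=1.0, n_cells=1e6,
                                assay_fraction=1e-4, seed=0)


class TestX0:
    def test_equal_cts_give_unity(self):
        assert x0_relative(22.0, 22.0, 1.9) == pytest.approx(1.0)

    def test_one_cycle_later_halves_at_perfect_doubling(self):
        assert x0_relative(23.0, 22.0, 2.0) == pytest.approx(0.5)

    def test_direct_evaluation(self):
        assert x0_relative(24.0, 22.0, 1.95) == pytest.approx(1.95**-2, rel=1e-9)

    def test_efficiency_at_or_below_one_rejected(self):
        with pytest.raises(ValueError):
            x0_relative(20.0, 20.0, 1.0)


class TestProtein:
    def test_avogadro_arithmetic(self):
        cal = ProteinCalibration(slope=1.0, intercept=0.0, molecular_weight=60_000.0)
        est = protein_copies_per_cell(1.0, cal, n_cells=1e4)  # 1 ng over 1e4 cells
        assert est.molecules_per_cell == pytest.approx(1.004e6, rel=1e-3)

    def test_blank_intensity_gives_zero_copies(self):
        cal = ProteinCalibration(slope=2.0, intercept=5.0, molecular_weight=60_000.0)
        est = protein_copies_per_cell(5.0, cal, n_cells=100)
        assert est.molecules_per_cell == 0.0

    def test_calibration_from_three_exact_points_inverts_exactly(self):
        cal = fit_protein_calibration([10, 20, 40], [105, 205, 405], 66_000.0)
        assert cal.r_squared == pytest.approx(1.0, abs=1e-12)
        assert cal.intensity_to_ng(205) == pytest.approx(20.0, rel=1e-9)

    def test_noisy_panel_round_trip(self):
        panel = generate_densitometry_panel(216_000.0, molecular_weight=66_000.0,
                                            n_cells=1e6, seed=5)
        std = panel[panel["role"] == "standard"]
        cal = fit_protein_calibration(std["mass_ng"].astype(float), std["intensity"],
                                      molecular_weight=66_000.0)
        est = protein_copies_per_cell(
            panel.loc[panel["role"] == "sample", "intensity"].to_numpy(), cal, n_cells=1e6
        )
        assert abs(est.molecules_per_cell - 216_000.0) / 216_000.0 < 0.15

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            ProteinCalibration(slope=-1.0, intercept=0.0, molecular_weight=60_000.0)


class TestMolarRatio:
    def est(self, v):
        return CopyEstimate(v, v, v, 1)

    def test_parity_raises_no_flag(self):
        rep = molar_ratio_report(self.est(50.0), self.est(50.0))
        assert rep["protein_per_rna"] == pytest.approx(1.0)
        assert not rep["one_to_one_cerna_implausible"]

    def test_large_excess_flags_implausibility(self):
        rep = molar_ratio_report(self.est(50.0), self.est(250_000.0))
        assert rep["protein_per_rna"] == pytest.approx(5000.0)
        assert rep["log10_ratio"] == pytest.approx(3.7, abs=0.01)
        assert rep["one_to_one_cerna_implausible"]

    def test_zero_rna_reports_infinite_ratio(self):
        rep = molar_ratio_report(self.est(0.0), self.est(100.0))
        assert math.isinf(rep["protein_per_rna"]) and rep["zero_rna_estimate"]
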