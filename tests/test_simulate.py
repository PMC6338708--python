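"""Synthetic-run generator: determinism, planted truths, validation studies."""

import numpy as np
import pytest

from edcscreen.chem import ElementalFormula, adduct_mz, isotope_pattern, pattern_deviation
from edcscreen.quantify import (
    CalibrationLevel,
    RecoveryExperiment,
    corrected_recovery,
    fit_calibration,
    precision_accuracy,
)
from edcscreen.simulate import (
    NoiseModel,
    PlantedCompound,
    ScanGrid,
    StudyDesign,
    generate_run,
    generate_validation_study,
    make_metabolite_case,
)
from edcscreen.spectra import HIGH, LOW, detect_peaks, extract_xic


def best_area(run, mz):
    peaks = detect_peaks(extract_xic(run, mz))
    return max(peaks, key=lambda p: p.height).area if peaks else 0.0


class TestGenerateRun:
    def test_noiseless_apex_intensity(self, narrow_grid):
        c = PlantedCompound("x", "C9H10O3", rt=1.0, sigma=0.05, apex_intensity=12345.0)
        run = generate_run([c], NoiseModel.noiseless(), narrow_grid, seed=0)
        xic = extract_xic(run, c.mz)
        # scan grid hits rt=1.0 exactly (0.3 + 84 * 0.5/60)
        assert xic.intensity.max() == pytest.approx(12345.0, rel=1e-3)

    def test_scan_count_matches_grid(self, narrow_grid):
        run = generate_run([], NoiseModel.noiseless(), narrow_grid, seed=0,
                           polarity="negative")
        n_cycles = narrow_grid.cycle_times().size
        assert len(run.spectra) == 2 * n_cycles
        assert len(run.channel_spectra(LOW)) == n_cycles

    def test_same_seed_identical(self, narrow_grid):
        c = [PlantedCompound("x", "C12H7Cl3O2", rt=1.0, apex_intensity=1e4)]
        r1 = generate_run(c, NoiseModel(), narrow_grid, seed=7)
        r2 = generate_run(c, NoiseModel(), narrow_grid, seed=7)
        for a, b in zip(r1.spectra, r2.spectra):
            np.testing.assert_array_equal(a.mz, b.mz)
            np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_grid_must_cover_peak(self, narrow_grid):
        c = PlantedCompound("x", "C9H10O3", rt=10.0, apex_intensity=1e4)
        with pytest.raises(ValueError):
            generate_run([c], NoiseModel(), narrow_grid, seed=0)

    def test_cl3_envelope_at_apex(self, narrow_grid):
        """Measured M+2/M ratio at the apex matches the predicted envelope."""
        c = PlantedCompound("tcs", "C12H7Cl3O2", rt=1.2, sigma=0.05, apex_intensity=1e5)
        run = generate_run([c], NoiseModel(), narrow_grid, seed=4)
        predicted = isotope_pattern(c.formula).shifted(c.mz - c.formula.mass)
        apex_scan = min(
            run.channel_spectra(LOW), key=lambda s: abs(s.rt - 1.2)
        )
        observed = []
        for mz in predicted.mz:
            sel = np.abs(apex_scan.mz - mz) <= 0.0025
            observed.append((mz, apex_scan.intensity[sel].sum()))
        assert pattern_deviation(predicted, observed) < 5.0

    def test_fragments_only_in_high_channel(self, bpa_metabolite_run):
        frag = extract_xic(bpa_metabolite_run, 227.1078, channel=HIGH)
        assert frag.intensity.max() > 0
        # the low channel also has planted BPA parent at 227.1078 (its own
        # quantifier), so check the decoy fragment-free region instead:
        run = generate_run(
            [PlantedCompound("m", "C15H16O5S", rt=0.8, apex_intensity=1e4,
                             fragments=((150.0, 0.5),))],
            NoiseModel.noiseless(), ScanGrid(0.3, 1.4, 0.5, (100, 400)), seed=0,
        )
        assert extract_xic(run, 150.0, channel=HIGH).intensity.max() > 0
        assert extract_xic(run, 150.0, channel=LOW).intensity.max() == 0


class TestMakeMetaboliteCase:
    def test_bpa_sulfate_pair(self):
        parent = PlantedCompound("BPA", "C15H16O2", rt=7.7, apex_intensity=1e5)
        parent, metab = make_metabolite_case(parent, rt_offset=-0.9)
        assert metab.formula.hill() == "C15H16O5S"
        assert metab.rt == pytest.approx(6.8)
        assert round(metab.mz, 4) == 307.0646

    def test_chloromethylphenol_sulfate_pair(self):
        parent = PlantedCompound("4-Cl-3-methylphenol", "C7H7ClO", rt=7.5,
                                 apex_intensity=1e5)
        parent, metab = make_metabolite_case(parent, rt_offset=-1.6)
        assert metab.rt == pytest.approx(5.9)
        assert round(metab.mz, 4) == 220.9681

    def test_non_negative_offset_rejected(self):
        parent = PlantedCompound("p", "C7H7ClO", rt=7.5, apex_intensity=1e5)
        with pytest.raises(ValueError):
            make_metabolite_case(parent, rt_offset=0.0)

    def test_empty_delta_rejected(self):
        parent = PlantedCompound("p", "C7H7ClO", rt=7.5, apex_intensity=1e5)
        with pytest.raises(ValueError):
            make_metabolite_case(parent, formula_delta=ElementalFormula({}), rt_offset=-1)


@pytest.fixture(scope="module")
def small_study():
    """One analyte + internal standard, planted recovery 0.8, CV 5%."""
    design = StudyDesign(
        calibration_levels=(0.05, 0.25, 1.0, 5.0, 25.0, 100.0),
        calibration_replicates=3,
        recovery_truth={"tcs": 0.8},
        intra_day_cv=0.05,
        inter_day_cv=0.03,
    )
    analyte = PlantedCompound("tcs", "C12H7Cl3O2", rt=1.0, sigma=0.04, apex_intensity=1.0)
    istd = PlantedCompound("istd", "C13H9Cl3O2", rt=1.1, sigma=0.04, apex_intensity=5e4)
    study = generate_validation_study(
        design, [analyte], istd,
        grid=ScanGrid(0.4, 1.6, 1.0, (250, 350)),
        seed=17,
    )
    return design, study


class TestValidationStudy:
    mz = adduct_mz("C12H7Cl3O2", "[M-H]-")
    mz_is = adduct_mz("C13H9Cl3O2", "[M-H]-")

    def curve(self, study):
        levels = []
        for (conc, rep), run in study.calibration.items():
            a, b = best_area(run, self.mz), best_area(run, self.mz_is)
            if a > 0 and b > 0:
                levels.append(CalibrationLevel(conc, a, b, rep))
        # 1/x weighting: with multiplicative noise over four decades an
        # unweighted fit is dominated by the single top-level draw
        return fit_calibration(levels, weighting="1/x")

    def test_manifest_records_truths(self, small_study):
        design, study = small_study
        m = study.manifest
        assert m["compounds"]["tcs"]["recovery_truth"] == 0.8
        assert m["intra_day_cv"] == design.intra_day_cv
        assert m["calibration_levels_ugl"] == list(design.calibration_levels)

    def test_calibration_linear(self, small_study):
        _, study = small_study
        curve = self.curve(study)
        assert curve.r_squared > 0.995
        # planted response: 2000 counts/ug/L over a 5e4 internal standard
        assert curve.slope == pytest.approx(2000 / 5e4, rel=0.05)

    def test_recovery_recovered(self, small_study):
        """Corrected recoveries over replicates land near the planted truth."""
        design, study = small_study
        curve = self.curve(study)
        recs = []
        for (spike, rep), run in study.spiked.items():
            c_sp = curve.concentration(
                best_area(run, self.mz) / best_area(run, self.mz_is)
            )
            mp = study.mobile_phase[spike]
            c_mp = curve.concentration(
                best_area(mp, self.mz) / best_area(mp, self.mz_is)
            )
            recs.append(corrected_recovery(RecoveryExperiment(c_sp, 0.0, c_mp, spike)))
        assert np.mean(recs) == pytest.approx(80.0, abs=5.0)

    def test_planted_cv_recovered(self, small_study):
        design, study = small_study
        curve = self.curve(study)
        data: dict[float, dict[int, list[float]]] = {}
        for (level, day, rep), run in study.precision.items():
            conc = curve.concentration(
                best_area(run, self.mz) / best_area(run, self.mz_is)
            )
            data.setdefault(level, {}).setdefault(day, []).append(conc)
        reports = precision_accuracy(data)
        for r in reports:
            assert r.intra_day_rsd == pytest.approx(100 * design.intra_day_cv, abs=3.0)

    def test_zero_noise_design_exact_accuracy(self):
        design = StudyDesign(
            calibration_levels=(0.1, 0.5, 1.0, 5.0, 25.0),
            precision_levels=(1.0,),
            precision_replicates=3,
            days=1,
            intra_day_cv=0.0,
            inter_day_cv=0.0,
        )
        analyte = PlantedCompound("a", "C9H10O3", rt=1.0, sigma=0.04, apex_intensity=1.0)
        istd = PlantedCompound("b", "C12H7Cl3O2", rt=1.1, sigma=0.04, apex_intensity=5e4)
        study = generate_validation_study(
            design, [analyte], istd,
            noise=NoiseModel.noiseless(),
            grid=ScanGrid(0.4, 1.6, 1.0, (150, 350)), seed=1,
        )
        mz, mz_is = analyte.mz, istd.mz
        levels = [
            CalibrationLevel(conc, best_area(run, mz), best_area(run, mz_is), rep)
            for (conc, rep), run in study.calibration.items()
        ]
        curve = fit_calibration(levels)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-9)
        for (level, day, rep), run in study.precision.items():
            conc = curve.concentration(best_area(run, mz) / best_area(run, mz_is))
            assert conc == pytest.approx(level, rel=1e-6)
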