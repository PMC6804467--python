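import numpy as np
import pandas as pd
import pytest

from synlink import (
    ArtifactSpec,
    AssayDesign,
    DrugParams,
    QCConfig,
    DoseResponseSeries,
    run_qc,
    simulate_plates,
)
from synlink.qc import (
    control_flag_replace,
    dose_response_flag_replace,
    normalize_plate,
    plate_viability_filter,
    qc_quadruplicates,
    studentized_residuals,
)


class TestQuadruplicates:
    def test_single_deviant_replaced_by_mean_of_rest(self):
        cleaned, flags = qc_quadruplicates([100, 102, 98, 500], 0.3)
        assert flags.tolist() == [False, False, False, True]
        assert cleaned[3] == pytest.approx(100.0)
        assert cleaned[:3].tolist() == [100, 102, 98]

    def test_clean_quadruplicate_untouched(self):
        cleaned, flags = qc_quadruplicates([100, 100, 100, 100], 0.3)
        assert not flags.any()
        assert cleaned.tolist() == [100, 100, 100, 100]

    def test_two_deviants_all_replaced_with_mean(self):
        cleaned, flags = qc_quadruplicates([10, 10, 500, 500], 0.3)
        assert flags.all()
        assert (cleaned == 255.0).all()

    def test_nonpositive_mean_all_replaced(self):
        cleaned, flags = qc_quadruplicates([0.0, 0.0, 0.0, 0.0], 0.3)
        assert flags.all()

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            qc_quadruplicates([1.0, 2.0, 3.0], 0.3)

    def test_idempotent(self):
        cleaned, _ = qc_quadruplicates([100, 102, 98, 500], 0.3)
        again, flags = qc_quadruplicates(cleaned, 0.3)
        assert not flags.any()
        assert np.array_equal(again, cleaned)


class TestPlateViabilityFilter:
    def test_boundary(self):
        retained_low, _ = plate_viability_filter(np.full(384, 1999.0))
        retained_high, _ = plate_viability_filter(np.full(384, 2001.0))
        assert not retained_low and retained_high

    def test_all_zero_removed(self):
        retained, p90 = plate_viability_filter(np.zeros(384))
        assert not retained and p90 == 0.0

    def test_bisection_locates_2000(self):
        # the retain/remove transition of a constant plate sits at 2000 +- 1
        lo, hi = 0.0, 10000.0
        while hi - lo > 0.5:
            mid = 0.5 * (lo + hi)
            retained, _ = plate_viability_filter(np.full(384, mid))
            if retained:
                hi = mid
            else:
                lo = mid
        assert abs(hi - 2000.0) <= 1.0

    def test_percentile_convention_matches_numpy_linear(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 5000, size=97)
        _, p90 = plate_viability_filter(vals)
        assert p90 == np.percentile(vals, 90, method="linear")


class TestStudentizedResiduals:
    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        x = np.arange(12.0)
        y = 3.0 + 0.5 * x + rng.normal(0, 1, 12)
        y[4] += 6
        r = studentized_residuals(x, y)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        expected = ols.get_influence().resid_studentized_external
        np.testing.assert_allclose(r, expected, rtol=1e-8)

    def test_exact_fit_returns_zero(self):
        x = np.arange(6.0)
        assert (studentized_residuals(x, 2 * x + 1) == 0).all()


class TestControlFlagReplace:
    def test_deviant_control_replaced_near_fit(self):
        vals = [5000.0, 5010.0, 4990.0, 5005.0, 900.0]
        cleaned, flags = control_flag_replace(vals, resid_threshold=3.0)
        assert flags.tolist() == [False, False, False, False, True]
        # replacement predicted from the other points' regression
        assert 4950 < cleaned[4] < 5060
        assert cleaned[:4].tolist() == vals[:4]

    def test_collinear_controls_untouched(self):
        vals = np.linspace(4000, 5000, 8)
        cleaned, flags = control_flag_replace(vals)
        assert not flags.any()
        assert np.array_equal(cleaned, vals)

    def test_max_iter_zero_no_change(self):
        vals = [5000.0, 5010.0, 4990.0, 5005.0, 900.0]
        cleaned, flags = control_flag_replace(vals, max_iter=0)
        assert not flags.any()
        assert cleaned.tolist() == vals

    def test_too_few_controls_skipped(self):
        cleaned, flags = control_flag_replace([1.0, 2.0])
        assert not flags.any()


class TestNormalizePlate:
    def test_endpoints_clipped(self):
        v = normalize_plate(np.array([10000.0, 500.0, 5250.0]), 10000.0, 500.0)
        assert v[0] == 0.995 and v[1] == 0.005 and v[2] == pytest.approx(0.5)

    def test_inverted_controls_rejected(self):
        with pytest.raises(ValueError, match="unusable"):
            normalize_plate(np.array([1.0]), 500.0, 10000.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        rfu = rng.uniform(600, 9000, 50)
        v1 = normalize_plate(rfu, 10000.0, 500.0)
        c = 3.7
        v2 = normalize_plate(c * rfu, c * 10000.0, c * 500.0)
        np.testing.assert_allclose(v1, v2, rtol=1e-12)


def _series(doses, viability):
    return DoseResponseSeries(
        cell_line="L", drug="d", doses=np.asarray(doses),
        viability=np.asarray(viability), n_wells=np.full(len(doses), 4),
    )


class TestDoseResponseFlagReplace:
    def test_clean_series_untouched(self):
        doses = np.array([1.0, 2, 4, 8, 16, 32])
        viability = 1.0 / (1.0 + (doses / 4.0) ** 1.5)
        s = _series(doses, viability)
        out, flags = dose_response_flag_replace(s)
        assert not flags.any()
        assert np.array_equal(out.viability, viability)

    def test_displaced_point_restored(self):
        doses = np.array([1.0, 2, 4, 8, 16, 32])
        viability = 1.0 / (1.0 + (doses / 4.0) ** 1.5)
        bad = viability.copy()
        bad[2] = min(bad[2] + 0.5, 0.995)
        out, flags = dose_response_flag_replace(_series(doses, bad))
        assert flags[2] and flags.sum() == 1
        assert out.viability[2] == pytest.approx(viability[2], abs=1e-6)

    def test_short_series_skipped(self):
        s = _series([1.0, 2.0], [0.8, 0.4])
        out, flags = dose_response_flag_replace(s)
        assert not flags.any()


def _make_plates(n_lines=6, artifacts=None, seed=3, cv=0.2):
    design = AssayDesign.default()
    dp = {"drugA": DrugParams(4.0, 1.5, cv), "drugB": DrugParams(1.0, 2.0, cv)}
    lines = [f"L{i}" for i in range(n_lines)]
    rng = np.random.default_rng(seed)
    latent = pd.Series(rng.normal(0, 0.3, n_lines), index=lines)
    plates, truth = simulate_plates(
        lines, latent, design, dp, artifacts or ArtifactSpec(), seed=seed
    )
    return plates, truth, design


class TestRunQC:
    def test_artifact_free_recovers_generating_viability(self):
        plates, truth, design = _make_plates()
        series, report = run_qc(plates)
        assert len(report.wells) == 0
        line = "L0"
        dm = truth.line_params.query("cell_line==@line and drug=='drugA'").dm.iloc[0]
        s = series[(line, "drugA")]
        expected = 1.0 / (1.0 + (s.doses / dm) ** 1.5)
        np.testing.assert_allclose(
            s.viability, np.clip(expected, 0.005, 0.995), atol=1e-9
        )

    def test_dead_plates_counted(self):
        plates, truth, _ = _make_plates(
            n_lines=10, artifacts=ArtifactSpec(dead_plate_rate=0.3), seed=5
        )
        series, report = run_qc(plates)
        assert report.n_plates_removed == len(truth.dead_plates)
        assert set(report.plates.query("~retained").plate_id) == set(truth.dead_plates)

    def test_deviant_wells_flagged(self):
        plates, truth, _ = _make_plates(
            n_lines=12, artifacts=ArtifactSpec(deviant_rate=0.02, noise_sd=150.0),
            seed=6,
        )
        series, report = run_qc(plates)
        flagged = report.flagged_well_keys()
        injected = set(
            zip(truth.deviant_wells.plate_id, truth.deviant_wells.row,
                truth.deviant_wells.col)
        )
        # exclude deviants on dead plates (removed wholesale)
        removed = set(report.plates.query("~retained").plate_id)
        injected = {k for k in injected if k[0] not in removed}
        assert len(injected) > 20
        caught = len(injected & flagged) / len(injected)
        assert caught >= 0.9

    def test_conservation_of_wells(self):
        plates, truth, _ = _make_plates(
            n_lines=8,
            artifacts=ArtifactSpec(deviant_rate=0.02, dead_plate_rate=0.1,
                                   noise_sd=150.0),
            seed=7,
        )
        series, report = run_qc(plates)
        all_wells = set(zip(plates.plate_id, plates.row, plates.col))
        removed_plates = set(report.plates.query("~retained").plate_id)
        removed = {k for k in all_wells if k[0] in removed_plates}
        flagged = report.flagged_well_keys()
        untouched = all_wells - removed - flagged
        assert len(untouched) + len(flagged | removed) == len(all_wells)
        assert not (flagged & removed)

    def test_idempotent_on_clean_data(self):
        plates, _, _ = _make_plates(seed=8)
        series1, report1 = run_qc(plates)
        assert len(report1.wells) == 0 and report1.n_plates_removed == 0
        # feeding cleaned per-stage operators their own output changes nothing
        for (line, drug), s in series1.items():
            out, flags = dose_response_flag_replace(s)
            assert not flags.any()

    def test_line_with_all_plates_dead_excluded(self):
        plates, truth, _ = _make_plates(n_lines=3, seed=9)
        # kill every plate of L1
        mask = plates.cell_line == "L1"
        plates.loc[mask, "rfu"] = 100.0
        series, report = run_qc(plates)
        assert not any(k[0] == "L1" for k in series)
        assert any("L1" in w for w in report.warnings)

    def test_replicate_runs_averaged(self):
        plates, _, design = _make_plates(seed=10)
        series, _ = run_qc(plates)
        s = series[("L0", "drugA")]
        assert int(s.n_wells[0]) == design.n_quadruplicate * design.n_runs
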