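"""Tests of switching-rate estimation from trajectories and datasets."""

import math

import numpy as np
import pytest

from ifnfate import (
    TrajectoryPoint,
    estimate_f,
    fit_closed_form,
    fit_koff_loglinear,
    fit_transient_heritability,
    mean_fraction,
    rates_from_f,
)
from ifnfate.fitting import InsufficientDataError
from ifnfate.lineage import SimulationConfig, simulate_fluctuation_assay


def _model_trajectory(rates, days, x0=1.0):
    return [TrajectoryPoint(float(t), float(mean_fraction(t, rates, x0))) for t in days]


class TestLogLinearFit:
    def test_pure_exponential_recovered_exactly(self):
        traj = [(t, math.exp(-0.3 * t)) for t in range(6)]
        fit = fit_koff_loglinear(traj)
        assert fit.koff == pytest.approx(0.3, abs=1e-12)
        lo, hi = fit.koff_ci95
        assert hi - lo == pytest.approx(0.0, abs=1e-9)

    def test_model_trajectory_small_f_bias(self, fitted_rates):
        """On the full relaxation the log-linear slope underestimates koff
        slightly (the f offset); the residence time still reads ~3.5 days."""
        fit = fit_koff_loglinear(_model_trajectory(fitted_rates, range(6)), f=0.02)
        assert fit.koff == pytest.approx(0.283, abs=0.001)
        assert fit.residence_days == pytest.approx(3.5, abs=0.05)
        assert fit.kon == pytest.approx(fit.koff * 0.02 / 0.98, abs=1e-12)

    def test_zero_fraction_in_range_rejected(self):
        with pytest.raises(ValueError):
            fit_koff_loglinear([(0, 1.0), (1, 0.5), (2, 0.0), (3, 0.1)])

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_koff_loglinear([(0, 1.0), (1, 0.7)])

    def test_day_range_selection(self, fitted_rates):
        traj = _model_trajectory(fitted_rates, range(17))
        fit = fit_koff_loglinear(traj, day_range=(0, 5))
        assert fit.day_range_used == (0.0, 5.0)


class TestClosedFormFit:
    def test_noise_free_self_consistency(self, fitted_rates):
        traj = _model_trajectory(fitted_rates, range(17))
        fit = fit_closed_form(traj, f=0.02, x0=1.0)
        assert fit.koff == pytest.approx(0.29, abs=1e-6)
        assert fit.flags == ()

    def test_constant_trajectory_flagged_unidentifiable(self):
        fit = fit_closed_form([(0, 0.02), (5, 0.02)], f=0.02, x0=1.0)
        assert "unidentifiable" in fit.flags
        assert math.isnan(fit.koff)

    def test_x0_equal_f_flagged(self):
        fit = fit_closed_form([(0, 0.5), (3, 0.4)], f=0.5, x0=0.5)
        assert "unidentifiable" in fit.flags

    def test_agreement_with_loglinear_on_early_days(self, fitted_rates):
        traj = _model_trajectory(fitted_rates, range(6))
        cf = fit_closed_form(traj, f=0.02, x0=1.0)
        ll = fit_koff_loglinear(traj)
        assert abs(cf.koff - ll.koff) / cf.koff < 0.05


class TestEstimateF:
    def _make_dataset(self, rows):
        import pandas as pd

        from ifnfate.lineage import DATASET_COLUMNS, FluctuationDataset

        records = pd.DataFrame(rows, columns=DATASET_COLUMNS)
        return FluctuationDataset(records=records)

    def test_single_record(self):
        ds = self._make_dataset([("c0", 6, 6.0, 64, 1, 1 / 64)])
        assert estimate_f(ds, {6}) == pytest.approx(1 / 64)

    def test_cell_weighted_mean(self):
        ds = self._make_dataset(
            [
                ("c0", 13, 13.0, 8192, 175, 175 / 8192),
                ("c1", 13, 13.0, 8192, 175, 175 / 8192),
            ]
        )
        assert estimate_f(ds, {13}) == pytest.approx(175 / 8192)
        assert estimate_f(ds, {13}) == pytest.approx(0.02134, abs=2e-4)

    def test_all_zero_warns_unidentifiable(self):
        ds = self._make_dataset([("c0", 13, 13.0, 64, 0, 0.0)])
        with pytest.warns(UserWarning, match="unidentifiable"):
            assert estimate_f(ds, {13}) == 0.0

    def test_empty_selection_rejected(self):
        ds = self._make_dataset([("c0", 6, 6.0, 64, 1, 1 / 64)])
        with pytest.raises(ValueError):
            estimate_f(ds, {13})


class TestTransientHeritabilityReport:
    def test_parameter_recovery_within_15_percent(self, fitted_rates):
        """Simulated fluctuation data (30 clones/generation, generations
        0-9) recover koff within 15% of the generating value."""
        for seed in (11, 23, 101):
            config = SimulationConfig(
                generations=list(range(10)), n_clones_per_generation=30, seed=seed
            )
            ds = simulate_fluctuation_assay(config, fitted_rates)
            report = fit_transient_heritability(ds)
            assert report.loglinear is not None
            assert abs(report.koff - 0.29) / 0.29 < 0.15
            assert report.closed_form is not None
            assert abs(report.closed_form.koff - 0.29) / 0.29 < 0.15

    def test_report_contents(self, fitted_rates):
        config = SimulationConfig(
            generations=list(range(10)), n_clones_per_generation=30, seed=11
        )
        report = fit_transient_heritability(
            simulate_fluctuation_assay(config, fitted_rates), cv_tech=0.32
        )
        assert set(report.per_generation["generation"]) == set(range(10))
        assert report.cv_curve is not None
        assert report.cv_peak_day is not None
        assert report.residence_days == pytest.approx(1 / report.koff)
        d = report.to_dict()
        assert {"f", "koff", "residence_days", "per_generation"} <= d.keys()

    def test_single_generation_refuses_koff_but_reports_stats(self, fitted_rates):
        config = SimulationConfig(generations=[6], n_clones_per_generation=20, seed=4)
        report = fit_transient_heritability(simulate_fluctuation_assay(config, fitted_rates))
        assert report.loglinear is None and report.closed_form is None
        assert any("single_generation" in f for f in report.flags)
        assert len(report.per_generation) == 1

    def test_empty_dataset_rejected(self):
        import pandas as pd

        from ifnfate.lineage import DATASET_COLUMNS, FluctuationDataset

        empty = FluctuationDataset(records=pd.DataFrame(columns=DATASET_COLUMNS))
        with pytest.raises(ValueError):
            fit_transient_heritability(empty)

    def test_ci_calibration_over_replicates(self, fitted_rates):
        """Across 500 simulated replicates at 30 clones/generation the
        t-based 95% CI for koff covers the truth in 90-99% of them."""
        covered = 0
        n_rep = 500
        for rep in range(n_rep):
            config = SimulationConfig(
                generations=list(range(6)), n_clones_per_generation=30, seed=20_000 + rep
            )
            ds = simulate_fluctuation_assay(config, fitted_rates)
            per_gen = ds.records.groupby("day").apply(
                lambda g: (g["fraction"] * g["n_cells"]).sum() / g["n_cells"].sum(),
                include_groups=False,
            )
            fit = fit_koff_loglinear(list(zip(per_gen.index, per_gen.values)))
            lo, hi = fit.koff_ci95
            covered += lo <= 0.29 <= hi
        assert 0.90 <= covered / n_rep <= 0.99
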