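"""Requirement regression: oracle equivalence, recovery, conversions."""

import numpy as np
import pytest

from proreq.requirement import (
    ProteinRequirementModel,
    RequirementPoint,
    points_from_trial,
)
from proreq.simulate import generate_requirement_points


def closed_form_ols(x, y):
    """Independent two-parameter OLS oracle: slope = Sxy/Sxx, a = ybar - b xbar."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    b = ((x - x.mean()) @ (y - y.mean())) / ((x - x.mean()) @ (x - x.mean()))
    return y.mean() - b * x.mean(), b


class TestFit:
    def test_noiseless_line_recovered_exactly(self):
        x = np.linspace(-1, 8, 16)
        y = 0.8663 + 0.0725 * x
        res = ProteinRequirementModel(x, y).fit()
        assert res.intercept == pytest.approx(0.8663, abs=1e-10)
        assert res.slope == pytest.approx(0.0725, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0)

    def test_two_point_line_with_duplicates(self):
        x = [0, 10, 0, 10]
        y = [1, 2, 1, 2]
        res = ProteinRequirementModel(x, y).fit()
        assert res.slope == pytest.approx(0.1)
        assert res.intercept == pytest.approx(1.0)

    def test_group_mean_fit_differs_from_individual_fit(self):
        # fitting the 4 treatment-mean points cannot reproduce an
        # individual-animal fit: the group-mean line is much steeper
        x = [-0.84, 2.62, 4.65, 7.97]
        y = [0.57, 0.87, 1.17, 1.51]
        res = ProteinRequirementModel(x, y).fit()
        a, b = closed_form_ols(x, y)
        assert res.slope == pytest.approx(b, abs=1e-10)
        assert res.intercept == pytest.approx(a, abs=1e-10)
        assert round(res.slope, 3) == 0.109
        assert round(res.intercept, 3) == 0.639

    def test_matches_closed_form_on_random_inputs(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            x = rng.normal(3, 3, size=16)
            y = np.abs(rng.normal(1, 0.5, size=16))
            res = ProteinRequirementModel(x, y).fit()
            a, b = closed_form_ols(x, y)
            assert res.intercept == pytest.approx(a, abs=1e-10)
            assert res.slope == pytest.approx(b, abs=1e-10)

    def test_intercept_shifts_with_constant_offset(self):
        pts = generate_requirement_points(seed=3)
        x = [p.adg_g_per_kg_w075 for p in pts]
        y = np.array([p.n_intake_g_per_kg_w075 for p in pts])
        base = ProteinRequirementModel(x, y).fit()
        shifted = ProteinRequirementModel(x, y + 0.5).fit()
        assert shifted.intercept == pytest.approx(base.intercept + 0.5, abs=1e-9)
        assert shifted.slope == pytest.approx(base.slope, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ProteinRequirementModel([1, 2], [1, 2])
        with pytest.raises(ValueError):
            ProteinRequirementModel([1, 1, 1, 1], [1, 2, 3, 4])


class TestRequirementInterpretation:
    def test_cp_equivalents(self):
        x = np.linspace(-1, 8, 16)
        res = ProteinRequirementModel(x, 0.8663 + 0.0725 * x).fit()
        assert res.maintenance_cp == pytest.approx(0.8663 * 6.25)
        disp = res.display_requirements()
        assert disp["maintenance_cp"] == 5.41
        # rounding convention: N rounded first, 0.0725 -> 0.073 -> 0.46
        assert disp["growth_cp"] == 0.46

    def test_zero_intercept_zero_maintenance(self):
        x = np.linspace(0.1, 8, 16)
        res = ProteinRequirementModel(x, 0.1 * x).fit()
        assert res.maintenance_n == pytest.approx(0.0, abs=1e-12)
        assert res.maintenance_cp == pytest.approx(0.0, abs=1e-12)

    def test_summary_mentions_requirements(self):
        pts = generate_requirement_points(seed=5)
        s = ProteinRequirementModel.from_points(pts).fit().summary()
        assert "maintenance" in s and "growth" in s and "R^2" in s


class TestBootstrap:
    def test_noiseless_points_give_zero_width(self):
        x = np.linspace(-1, 8, 16)
        res = ProteinRequirementModel(x, 0.9 + 0.07 * x).fit()
        ci = res.bootstrap(n_boot=50, seed=1)
        assert ci["slope"][0] == pytest.approx(ci["slope"][1], abs=1e-12)

    def test_same_seed_identical(self):
        pts = generate_requirement_points(seed=11)
        res = ProteinRequirementModel.from_points(pts).fit()
        assert res.bootstrap(n_boot=200, seed=4) == res.bootstrap(n_boot=200, seed=4)

    def test_interval_covers_estimate(self):
        pts = generate_requirement_points(seed=13)
        res = ProteinRequirementModel.from_points(pts).fit()
        ci = res.bootstrap(n_boot=500, seed=2)
        assert ci["intercept"][0] < res.intercept < ci["intercept"][1]

    def test_rejects_bad_n_boot(self):
        pts = generate_requirement_points(seed=1)
        res = ProteinRequirementModel.from_points(pts).fit()
        with pytest.raises(ValueError):
            res.bootstrap(n_boot=0)


class TestFromTrial:
    def test_one_point_per_animal(self, trial):
        pts = points_from_trial(trial)
        assert len(pts) == 16
        assert len({p.animal_id for p in pts}) == 16

    def test_per_period_doubles_points(self, trial):
        assert len(points_from_trial(trial, period_handling="per_period")) == 32

    def test_points_match_manual_computation(self, trial):
        rec = trial.records[0]
        diet = trial.diet_for(rec.treatment_label)
        pts = {p.animal_id: p for p in points_from_trial(trial, period_handling="per_period")}
        # per-period point for the first record's animal, period 1
        w075 = rec.average_bw_kg**0.75
        expected_y = rec.dm_intake_kg_d * diet.cp_gkg_dm / 6.25 / w075
        candidates = [
            p for p in points_from_trial(trial, period_handling="per_period")
            if p.animal_id == rec.animal_id
        ]
        assert any(p.n_intake_g_per_kg_w075 == pytest.approx(expected_y) for p in candidates)

    def test_negative_n_intake_rejected(self):
        with pytest.raises(ValueError):
            RequirementPoint(1.0, -0.1)
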