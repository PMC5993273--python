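"""Generative cohort model: determinism, boundary behaviour and statistical
calibration of the per-horse classifier."""

import numpy as np
import pytest
from pydantic import ValidationError

from equilat import (
    Classification,
    Lead,
    SimulationConfig,
    assess_horse,
    recovery_study,
    simulate_focal_horses,
    simulate_race_cohort,
)


class TestSimulationConfig:
    def test_defaults_are_valid(self):
        config = SimulationConfig()
        assert config.n_horses == 44
        assert config.pi_left + config.pi_right + config.pi_ambi == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(pi_left=0.9, pi_right=0.9, pi_ambi=0.0),
            dict(starts_min=10, starts_max=5),
            dict(sex_probs={"mare": 0.5, "gelding": 0.5, "unicorn": 0.0}),
            dict(horses_per_race=20, max_stalls=15),
            dict(seed=-1),
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValidationError):
            SimulationConfig(**bad)

    def test_yaml_roundtrip(self, tmp_path):
        config = SimulationConfig(seed=7, n_horses=12, direction_effect=0.3)
        path = tmp_path / "config.yaml"
        config.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == config


class TestFocalSimulation:
    def test_deterministic_given_seed(self):
        a = simulate_focal_horses(SimulationConfig(seed=5))
        b = simulate_focal_horses(SimulationConfig(seed=5))
        assert [h.record.sequence for h in a] == [h.record.sequence for h in b]
        c = simulate_focal_horses(SimulationConfig(seed=6))
        assert [h.record.sequence for h in a] != [h.record.sequence for h in c]

    def test_enlarging_cohort_keeps_existing_horses(self):
        small = simulate_focal_horses(SimulationConfig(seed=3, n_horses=10))
        big = simulate_focal_horses(SimulationConfig(seed=3, n_horses=30))
        assert [h.record.sequence for h in big[:10]] == [
            h.record.sequence for h in small
        ]

    def test_start_counts_respect_bounds(self):
        horses = simulate_focal_horses(
            SimulationConfig(seed=1, n_horses=200, starts_min=7, starts_max=12)
        )
        lengths = {len(h.record.sequence) for h in horses}
        assert lengths <= set(range(7, 13))

    def test_degenerate_bias_limit_is_fully_lateralized(self):
        """bias_shape_b = 0 pins the bias magnitude at B = 1, so every
        non-ambilateral horse shows one lead only."""
        config = SimulationConfig(
            seed=2, n_horses=100, pi_ambi=0.0, pi_left=0.5, pi_right=0.5,
            bias_shape_b=0.0,
        )
        for horse in simulate_focal_horses(config):
            leads = set(horse.record.sequence)
            assert len(leads) == 1
            expected = Lead.RIGHT if horse.true_class == "R" else Lead.LEFT
            assert leads == {expected}

    def test_ambilateral_theta_is_exactly_half(self):
        config = SimulationConfig(
            seed=4, n_horses=60, pi_ambi=1.0, pi_left=0.0, pi_right=0.0
        )
        assert all(h.theta == 0.5 for h in simulate_focal_horses(config))

    def test_law_of_large_numbers_for_li(self):
        """With many starts the empirical LI converges to 100(2 theta - 1)."""
        config = SimulationConfig(
            seed=9, n_horses=8, starts_min=10_000, starts_max=10_000
        )
        for horse in simulate_focal_horses(config):
            li = 100.0 * (2.0 * horse.record.n_right / 10_000 - 1.0)
            assert li == pytest.approx(100.0 * (2.0 * horse.theta - 1.0), abs=3.0)


class TestClassifierCalibration:
    def test_type_i_error_near_alpha_for_ambilateral_horses(self):
        """All-ambilateral cohorts: the significant-call rate must sit near
        the nominal 5% (exact tests are conservative, so allow 2%-7%)."""
        config = SimulationConfig(
            seed=0, n_horses=200, pi_ambi=1.0, pi_left=0.0, pi_right=0.0,
            starts_min=40, starts_max=40,
        )
        horses = simulate_focal_horses(config)
        hits = sum(
            assess_horse(h.record).classification
            in (Classification.SIG_L, Classification.SIG_R)
            for h in horses
        )
        assert 0.02 <= hits / len(horses) <= 0.07

    def test_few_starts_can_never_reach_significance(self):
        """Five starts cannot produce a doubled-tail exact p below 0.05
        (2 * 0.5^5 = 0.0625), so every call is non-significant."""
        config = SimulationConfig(
            seed=8, n_horses=80, starts_min=5, starts_max=5, bias_shape_b=0.0,
            pi_ambi=0.0, pi_left=0.5, pi_right=0.5,
        )
        for horse in simulate_focal_horses(config):
            result = assess_horse(horse.record)
            assert result.classification not in (
                Classification.SIG_L, Classification.SIG_R
            )

    def test_recovery_sensitivity_for_strong_bias(self):
        """Horses with theta near 0.95 and 40 starts are almost always
        detected; five-start horses essentially never are."""
        strong = SimulationConfig(
            seed=12, n_horses=60, pi_ambi=0.0, pi_left=0.5, pi_right=0.5,
            bias_shape_a=900.0, bias_shape_b=100.0,
            starts_min=40, starts_max=40,
        )
        summary = recovery_study(strong, replicates=3)
        assert summary.sensitivity >= 0.99
        assert summary.sign_accuracy >= 0.99

        weak = strong.model_copy(update={"starts_min": 5, "starts_max": 5})
        assert recovery_study(weak, replicates=3).sensitivity == 0.0

    def test_recovery_specificity_for_ambilateral_cohort(self):
        config = SimulationConfig(
            seed=13, n_horses=100, pi_ambi=1.0, pi_left=0.0, pi_right=0.0,
            starts_min=30, starts_max=30,
        )
        summary = recovery_study(config, replicates=3)
        assert summary.specificity >= 0.9
        assert summary.false_positive_rate == pytest.approx(
            1.0 - summary.specificity
        )
        assert np.isnan(summary.sensitivity)

    def test_recovery_is_deterministic(self):
        config = SimulationConfig(seed=20, n_horses=30)
        a = recovery_study(config, replicates=2)
        b = recovery_study(config, replicates=2)
        assert a == b


class TestRaceCohort:
    def test_shape_and_one_winner_per_race(self):
        config = SimulationConfig(seed=1, n_races=20, horses_per_race=10)
        cohort = simulate_race_cohort(config)
        assert len(cohort) == 200
        by_race = {}
        for obs in cohort:
            by_race.setdefault(obs.race_id, []).append(obs)
        for observations in by_race.values():
            assert sum(o.is_winner for o in observations) == 1
            stalls = [o.stall_position for o in observations]
            assert sorted(stalls) == list(range(1, 11))

    def test_directions_alternate(self):
        cohort = simulate_race_cohort(SimulationConfig(seed=1, n_races=6))
        directions = []
        for obs in cohort:
            if not directions or obs.race_id != directions[-1][0]:
                directions.append((obs.race_id, obs.direction))
        assert [d for _, d in directions] == ["AC", "C", "AC", "C", "AC", "C"]

    def test_balanced_mixture_lead_split_within_three_sigma(self):
        cohort = simulate_race_cohort(SimulationConfig(seed=17))
        n = len(cohort)
        n_right = sum(o.lead is Lead.RIGHT for o in cohort)
        assert abs(n_right - n / 2) <= 3.0 * np.sqrt(n * 0.25)

    def test_direction_effect_shifts_clockwise_leads(self):
        config = SimulationConfig(
            seed=2, n_races=200, direction_effect=2.0,
            pi_ambi=1.0, pi_left=0.0, pi_right=0.0,
        )
        cohort = simulate_race_cohort(config)
        def right_rate(direction):
            leads = [o.lead for o in cohort if o.direction == direction]
            return sum(l is Lead.RIGHT for l in leads) / len(leads)
        assert right_rate("C") > 0.8
        assert 0.4 < right_rate("AC") < 0.6
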