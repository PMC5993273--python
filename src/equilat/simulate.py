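"""Generative model of lateralized cohorts.

Each simulated horse carries a latent probability theta of choosing the
right lead, drawn from a three-component mixture: ambilateral horses have
theta = 0.5 exactly, right-biased horses theta = 0.5 + 0.5 B and
left-biased horses theta = 0.5 - 0.5 B, where the bias magnitude B follows
a Beta(a, b) law on (0, 1).  Lead observations are conditionally
independent Bernoulli(theta) draws — the exchangeable-starts assumption the
analysis itself makes.  Race cohorts add the covariate structure of the
population table: alternating course directions, stall layout, ages, sexes
and one winner per race, with an optional log-odds shift of the right-lead
probability on clockwise starts.

Randomness is driven by a single global seed through per-horse spawned
streams, so enlarging a cohort never perturbs the horses already drawn.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from .cohort import Cohort, FocalHorseRecord, Lead, RaceStartObservation, Sex
from .individual import (
    DEFAULT_ALPHA,
    DEFAULT_EXACT_THRESHOLD,
    Classification,
    assess_horse,
)

__all__ = [
    "SimulationConfig",
    "SimulatedHorse",
    "RecoverySummary",
    "simulate_focal_horses",
    "simulate_race_cohort",
    "recovery_study",
]


class SimulationConfig(BaseModel):
    """Parameters of the cohort generator.

    The defaults mirror the observed study scales: 44 focal horses with 5-46
    starts each, a near-even left/right mixture with a small ambilateral
    component, and a ~2100-start race table (140 races of up to 15 stalls).
    ``bias_shape_a``/``bias_shape_b`` parameterise the Beta law of the bias
    magnitude B; ``bias_shape_b = 0`` denotes the degenerate limit B = 1.
    """

    n_horses: int = Field(default=44, ge=1)
    pi_left: float = Field(default=0.48, ge=0)
    pi_right: float = Field(default=0.48, ge=0)
    pi_ambi: float = Field(default=0.04, ge=0)
    bias_shape_a: float = Field(default=1.3, gt=0)
    bias_shape_b: float = Field(default=2.4, ge=0)
    starts_min: int = Field(default=5, ge=1)
    starts_max: int = Field(default=46, ge=1)
    direction_effect: float = 0.0
    sex_probs: dict[str, float] = Field(
        default_factory=lambda: {"mare": 0.5, "gelding": 0.25, "stallion": 0.25}
    )
    age_range: tuple[int, int] = (2, 10)
    n_races: int = Field(default=140, ge=1)
    horses_per_race: int = Field(default=15, ge=2)
    max_stalls: int = Field(default=15, ge=1)
    seed: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        total = self.pi_left + self.pi_right + self.pi_ambi
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {total}")
        if self.starts_min > self.starts_max:
            raise ValueError("starts_min must not exceed starts_max")
        if abs(sum(self.sex_probs.values()) - 1.0) > 1e-9:
            raise ValueError("sex probabilities must sum to 1")
        if set(self.sex_probs) - {s.value for s in Sex}:
            raise ValueError("sex_probs keys must be mare/gelding/stallion")
        if self.age_range[0] > self.age_range[1] or self.age_range[0] < 2:
            raise ValueError("invalid age range")
        if self.horses_per_race > self.max_stalls:
            raise ValueError("horses_per_race exceeds the stall range")
        return self

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)


@dataclass(frozen=True)
class SimulatedHorse:
    horse_id: str
    true_class: str  # "L", "R" or "AMBI"
    theta: float
    record: FocalHorseRecord


@dataclass(frozen=True)
class RecoverySummary:
    """Mean operating characteristics of per-horse classification."""

    replicates: int
    sensitivity: float  # significant call for truly biased horses
    specificity: float  # non-significant call for ambilateral horses
    sign_accuracy: float  # sign of LI agrees with the latent class
    false_positive_rate: float
    seeds: tuple[int, ...]


def _horse_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, index)))


def _draw_theta(config: SimulationConfig, rng: np.random.Generator) -> tuple[str, float]:
    u = rng.random()
    if u < config.pi_ambi:
        return "AMBI", 0.5
    side = "R" if u < config.pi_ambi + config.pi_right else "L"
    if config.bias_shape_b == 0:
        bias = 1.0
    else:
        bias = rng.beta(config.bias_shape_a, config.bias_shape_b)
    # keep theta strictly inside (0, 1) so the class/sign invariant holds
    bias = min(max(bias, 1e-12), 1.0)
    theta = 0.5 + 0.5 * bias if side == "R" else 0.5 - 0.5 * bias
    return side, theta


def _draw_sex(config: SimulationConfig, rng: np.random.Generator) -> Sex:
    names = sorted(config.sex_probs)
    probs = np.array([config.sex_probs[n] for n in names])
    return Sex(names[rng.choice(len(names), p=probs)])


def simulate_focal_horses(config: SimulationConfig) -> list[SimulatedHorse]:
    """Draw a repeated-measures cohort; deterministic given the config."""
    horses = []
    for i in range(config.n_horses):
        rng = _horse_rng(config.seed, i)
        true_class, theta = _draw_theta(config, rng)
        n_starts = int(rng.integers(config.starts_min, config.starts_max + 1))
        leads = tuple(
            Lead.RIGHT if rng.random() < theta else Lead.LEFT
            for _ in range(n_starts)
        )
        sex = _draw_sex(config, rng)
        horses.append(
            SimulatedHorse(
                horse_id=f"sim{i:04d}",
                true_class=true_class,
                theta=theta,
                record=FocalHorseRecord(f"sim{i:04d}", sex, leads),
            )
        )
    return horses


def _shift_logit(theta: float, effect: float) -> float:
    if effect == 0.0:
        return theta
    theta = min(max(theta, 1e-12), 1 - 1e-12)
    logit = np.log(theta / (1 - theta)) + effect
    return float(1.0 / (1.0 + np.exp(-logit)))


def simulate_race_cohort(config: SimulationConfig) -> Cohort:
    """Simulate the one-start-per-horse population table.

    Races alternate AC/C; each race fills stalls 1..horses_per_race, draws
    one winner uniformly and assigns the remaining finish positions at
    random.  ``direction_effect`` shifts each horse's right-lead log-odds
    on clockwise starts.
    """
    observations = []
    horse_index = 0
    for race in range(config.n_races):
        # race-level stream lives in a disjoint index block from horse streams
        race_rng = _horse_rng(config.seed, 2**33 + race)
        direction = "AC" if race % 2 == 0 else "C"
        n_field = config.horses_per_race
        finish = race_rng.permutation(n_field) + 1
        for stall in range(1, n_field + 1):
            rng = _horse_rng(config.seed, horse_index)
            _, theta = _draw_theta(config, rng)
            if direction == "C":
                theta = _shift_logit(theta, config.direction_effect)
            lead = Lead.RIGHT if rng.random() < theta else Lead.LEFT
            observations.append(
                RaceStartObservation(
                    race_id=f"race{race:04d}",
                    course_name=f"course-{direction}",
                    direction=direction,
                    horse_id=f"pop{horse_index:05d}",
                    lead=lead,
                    stall_position=stall,
                    age=int(rng.integers(config.age_range[0], config.age_range[1] + 1)),
                    sex=_draw_sex(config, rng),
                    finish_position=int(finish[stall - 1]),
                )
            )
            horse_index += 1
    return Cohort(tuple(observations), provenance=f"simulated(seed={config.seed})")


def recovery_study(
    config: SimulationConfig,
    alpha: float = DEFAULT_ALPHA,
    replicates: int = 10,
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
) -> RecoverySummary:
    """Operating characteristics of the per-horse classifier by simulation.

    Each replicate redraws the cohort under a shifted seed, runs the
    per-horse assessment and tabulates sensitivity (significant call given
    a truly biased horse), specificity (non-significant call given an
    ambilateral horse) and sign accuracy among biased horses.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    seeds = tuple(config.seed + 100_000 * (rep + 1) for rep in range(replicates))
    sens, spec, sign_acc, fpr = [], [], [], []
    for rep_seed in seeds:
        rep_config = config.model_copy(update={"seed": rep_seed})
        horses = simulate_focal_horses(rep_config)
        n_biased = n_hit = n_ambi = n_clear = n_sign = 0
        for horse in horses:
            result = assess_horse(horse.record, alpha, exact_threshold)
            significant = result.classification in (
                Classification.SIG_L,
                Classification.SIG_R,
            )
            if horse.true_class == "AMBI":
                n_ambi += 1
                n_clear += not significant
            else:
                n_biased += 1
                n_hit += significant
                correct_sign = (horse.true_class == "R") == (result.li > 0)
                n_sign += correct_sign and result.li != 0
        sens.append(n_hit / n_biased if n_biased else np.nan)
        spec.append(n_clear / n_ambi if n_ambi else np.nan)
        sign_acc.append(n_sign / n_biased if n_biased else np.nan)
        fpr.append(1.0 - n_clear / n_ambi if n_ambi else np.nan)
    def mean_defined(values: list[float]) -> float:
        defined = [v for v in values if not np.isnan(v)]
        return float(np.mean(defined)) if defined else float("nan")

    return RecoverySummary(
        replicates=replicates,
        sensitivity=mean_defined(sens),
        specificity=mean_defined(spec),
        sign_accuracy=mean_defined(sign_acc),
        false_positive_rate=mean_defined(fpr),
        seeds=seeds,
    )
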