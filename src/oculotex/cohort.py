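"""Synthetic cohort generation: sex-balanced groups of healthy adults."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import CohortConfig
from .constants import SEXES


@dataclass(frozen=True)
class ParticipantRecord:
    participant_id: str
    sex: str
    age: float


def generate_cohort(config: CohortConfig) -> list[ParticipantRecord]:
    """Draw a sex-balanced cohort with truncated-normal ages.

    Ages are drawn from a normal(age_mean, age_sd) truncated to
    [age_min, age_max].  Each sex group uses its own RNG substream keyed by
    (seed, group index), so the same seed always yields the same cohort.
    """
    a = (config.age_min - config.age_mean) / config.age_sd
    b = (config.age_max - config.age_mean) / config.age_sd
    records: list[ParticipantRecord] = []
    for gi, sex in enumerate(SEXES):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, gi]))
        ages = stats.truncnorm.rvs(
            a, b, loc=config.age_mean, scale=config.age_sd,
            size=config.n_per_group, random_state=rng,
        )
        prefix = sex[0].upper()
        for i, age in enumerate(ages):
            records.append(
                ParticipantRecord(f"{prefix}{i + 1:03d}", sex, float(age))
            )
    return records
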