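"""Pre-assembled desk-scale validation studies.

Two seeded simulation studies ship with the package:

* **Null study** (type-I calibration): cohorts with no injected effect, 20
  participants per sex group, a three-layer analysis and a 32-voxel depth.
  Reports the fraction of corrected-significant features per correction
  method; under the null this should average at or below the nominal level.

* **Recovery study** (power / locality): the same reduced volumes at the
  full cohort size of 49 participants per sex group, with one strong
  injected effect -- the IPL texture standard deviation doubled in the
  nasal-inferior quadrant (Q4) of female left eyes.  Reports whether
  Entropy/Energy at IPL/Q4 come out corrected-significant in the female
  group, whether *any* feature at IPL/Q4 does (the effect may be reported
  through another member of the mutually correlated disorder-feature
  cluster after decorrelation), and whether anything is detected in the
  male group.

Both studies quantize against the fixed 0-255 reflectivity range rather
than each image's own min-max: synthetic volumes have no between-eye
brightness offsets to normalise away, and a per-image range is a global
statistic that couples all quadrants of an image (an injected single-
quadrant effect would then shift every quadrant's features through the
shared quantization range, defeating locality checks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import generate_cohort
from .config import (CohortConfig, EffectSpec, GLCMConfig, StatsConfig,
                     VolumeConfig)
from .constants import SEXES, feature_id
from .stats import CORRECTION_METHODS, run_group_analysis
from .synth import generate_cohort_volumes
from .texture import extract_features

#: Layers analysed in the reduced studies (the effect target IPL included).
REDUCED_LAYERS = ("RNFL", "IPL", "ONL")

NULL_N_PER_GROUP = 20
RECOVERY_N_PER_GROUP = 49

#: Injected effect for the recovery study: double the IPL texture standard
#: deviation (base 10 -> 20 reflectivity units) in the nasal-inferior
#: quadrant of female left eyes.
RECOVERY_EFFECT = EffectSpec(
    target_sex="female", target_eye="OS", target_layer="IPL",
    target_quadrant="Q4", delta_sd=10.0,
)

STUDY_GLCM = GLCMConfig(quantization="fixed")


def reduced_volume_config() -> VolumeConfig:
    """Half-depth macular cube used by the validation studies."""
    return VolumeConfig(
        n_depth=32,
        layer_mean_thickness=(3.0, 4.0, 3.0, 3.0, 3.0, 6.0),
        foveal_dip_depth=11.0,
        foveal_dip_radius=8.0,
    )


def _run(seed: int, n_per_group: int, effects) -> dict:
    cohort = generate_cohort(CohortConfig(n_per_group=n_per_group, seed=seed))
    scans = generate_cohort_volumes(cohort, reduced_volume_config(), effects,
                                    seed=seed)
    features = extract_features(scans, layers=REDUCED_LAYERS, config=STUDY_GLCM)
    stats_cfg = StatsConfig()
    return {group: run_group_analysis(features, group, stats_cfg)
            for group in SEXES}


def null_trial(seed: int) -> dict[str, dict[str, float]]:
    """One no-effect pipeline run; returns, per group, the fraction of kept
    features declared significant by each correction method."""
    analyses = _run(seed, NULL_N_PER_GROUP, effects=())
    out: dict[str, dict[str, float]] = {}
    for group, ga in analyses.items():
        m = max(ga.counts["n_uncorrelated"], 1)
        out[group] = {method: ga.counts[method] / m
                      for method in CORRECTION_METHODS}
    return out


@dataclass
class RecoveryOutcome:
    """Result of one effect-injection run."""

    #: Entropy and/or Energy at IPL/Q4 corrected-significant in the female group.
    female_target_detected: bool
    #: Some feature at IPL/Q4 corrected-significant in the female group.
    female_cell_detected: bool
    #: Any corrected-significant feature in the male group.
    male_any_detected: bool
    female_counts: dict
    male_counts: dict


def recovery_trial(seed: int) -> RecoveryOutcome:
    """One pipeline run with the injected IPL/Q4 left-eye effect."""
    analyses = _run(seed, RECOVERY_N_PER_GROUP, effects=(RECOVERY_EFFECT,))
    targets = {feature_id("IPL", "Q4", "Entropy"),
               feature_id("IPL", "Q4", "Energy")}

    ga_f = analyses["female"]
    detected: set[str] = set()
    for res in ga_f.corrections.values():
        detected |= {fid for fid, sig in zip(ga_f.selection.kept, res.significant)
                     if sig}
    ga_m = analyses["male"]
    male_any = any(res.significant.any() for res in ga_m.corrections.values())
    return RecoveryOutcome(
        female_target_detected=bool(detected & targets),
        female_cell_detected=any(fid.startswith("IPL/Q4/") for fid in detected),
        male_any_detected=bool(male_any),
        female_counts=ga_f.counts,
        male_counts=ga_m.counts,
    )


def trial_seeds(n_runs: int, seed: int) -> list[int]:
    """Derive per-run seeds below 2**31 from one master seed."""
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n_runs) % (2 ** 31)]


def null_study(n_runs: int, seed: int) -> pd.DataFrame:
    """Corrected-significant fractions per method over seeded null runs."""
    rows = []
    for s in trial_seeds(n_runs, seed):
        fractions = null_trial(s)
        for group, per_method in fractions.items():
            rows.append({"seed": s, "group": group, **per_method})
    return pd.DataFrame(rows)


def recovery_study(n_runs: int, seed: int) -> pd.DataFrame:
    """Per-run detection outcomes over seeded effect-injection runs."""
    rows = []
    for s in trial_seeds(n_runs, seed):
        outcome = recovery_trial(s)
        rows.append({
            "seed": s,
            "female_target_detected": outcome.female_target_detected,
            "female_cell_detected": outcome.female_cell_detected,
            "male_any_detected": outcome.male_any_detected,
            "success": outcome.female_target_detected
                       and not outcome.male_any_detected,
        })
    return pd.DataFrame(rows)
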