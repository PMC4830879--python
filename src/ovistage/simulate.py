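"""Seeded synthetic landmark observations with the calibration's structure.

The generator emulates the calibration study's sampling design: cohorts of
eggs scored at a known true 10 % interval under a constant calibrated
temperature, with each landmark drawn PRESENT independently at its cell's
visibility frequency. Two frequency-sampling policies exist:
REPRESENTATIVE uses the fixed representative probability per category
(the same values the estimator assumes — a well-specified test);
UNIFORM_IN_RANGE draws, once per run, a frequency uniformly inside each
cell's ordinal range (a mis-specification stress test, since the estimator
still assumes the representative values).

Preservation post-processing mirrors what each method leaves observable:
HWK fixation masks the four non-HWK-visible landmarks; direct ethanol
destroys all landmark information, leaving only first-instar larval
morphology on eggs at or past the 90 % interval.

Randomness is deterministic by contract: each egg's stream derives from
(seed, egg index), so cohorts are order-independent and reproducible
bit-for-bit.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .estimator import (
    CategoryProbabilities,
    DEFAULT_CATEGORY_PROBABILITIES,
    ObservationSet,
    PreservationMode,
    Status,
)
from .staging import (
    DevelopmentalInterval,
    StagingTable,
    VisibilityCategory,
    interval_for_proportion,
)
from .thermal import TemperatureProfile, advance_development

__all__ = [
    "FrequencySampling",
    "SimulationConfig",
    "simulate_observation",
    "simulate_cohort_timeline",
]


class FrequencySampling(enum.Enum):
    REPRESENTATIVE = "REPRESENTATIVE"
    UNIFORM_IN_RANGE = "UNIFORM_IN_RANGE"


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one synthetic cohort at a known true interval."""

    true_interval: DevelopmentalInterval
    temp_c: float
    preservation: PreservationMode = PreservationMode.LIVING
    n_eggs: int = 10
    seed: int = 0
    frequency_sampling: FrequencySampling = FrequencySampling.REPRESENTATIVE
    #: optional Gaussian jitter (sd, in proportion units) on each egg's true
    #: development proportion before interval binning; default 0 because the
    #: calibration quantifies no inter-egg developmental asynchrony. Non-zero
    #: values are a robustness-study device only.
    proportion_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_eggs < 1:
            raise ValueError("n_eggs must be >= 1")
        if self.proportion_jitter_sd < 0:
            raise ValueError("proportion_jitter_sd must be >= 0")


def _uniform_in_range(
    category: VisibilityCategory, rng: np.random.Generator
) -> float:
    lo, hi = category.frequency_range
    return float(rng.uniform(lo, hi))


def _cell_frequencies(
    config: SimulationConfig,
    interval: DevelopmentalInterval,
    table: StagingTable,
    probs: CategoryProbabilities,
) -> dict[str, float]:
    """Per-landmark presence frequency for one interval; UNIFORM_IN_RANGE
    draws come from a dedicated stream keyed off (seed,) so egg streams
    stay index-addressable."""
    if config.frequency_sampling is FrequencySampling.UNIFORM_IN_RANGE:
        rng = np.random.default_rng((config.seed, 1, interval.index))
        return {
            lm.id: _uniform_in_range(
                table.category(lm.id, interval, config.temp_c), rng
            )
            for lm in table.landmarks
        }
    return {
        lm.id: probs.prob(table.category(lm.id, interval, config.temp_c))
        for lm in table.landmarks
    }


def _apply_preservation(
    statuses: dict[str, Status],
    preservation: PreservationMode,
    interval: DevelopmentalInterval,
    table: StagingTable,
) -> tuple[dict[str, Status], Status]:
    """Returns (statuses, larval_morphology) after preservation effects."""
    if preservation is PreservationMode.LIVING:
        return statuses, Status.NOT_ASSESSED
    if preservation is PreservationMode.HWK_ETHANOL:
        visible = set(table.hwk_visible_ids)
        return (
            {
                lm: (s if lm in visible else Status.NOT_ASSESSED)
                for lm, s in statuses.items()
            },
            Status.NOT_ASSESSED,
        )
    # ETHANOL_DIRECT: decomposition removes every landmark; only the gross
    # first-instar larval morphology survives, and only near hatching
    masked = {lm: Status.NOT_ASSESSED for lm in statuses}
    larval = Status.PRESENT if interval.index >= 9 else Status.NOT_ASSESSED
    return masked, larval


def simulate_observation(
    config: SimulationConfig,
    table: StagingTable,
    probs: CategoryProbabilities = DEFAULT_CATEGORY_PROBABILITIES,
) -> list[ObservationSet]:
    """Draw a cohort of seeded synthetic observation sets at a known true
    interval under a constant calibrated temperature."""
    if config.temp_c not in table.calibrated_temps:
        raise ValueError(
            f"{config.temp_c} °C is not a calibrated temperature "
            f"{table.calibrated_temps}; cohort simulation requires "
            f"calibration cells"
        )
    out: list[ObservationSet] = []
    for i in range(config.n_eggs):
        rng = np.random.default_rng((config.seed, 0, i))
        interval = config.true_interval
        if config.proportion_jitter_sd > 0:
            p_mid = 0.5 * (interval.proportion_lo + interval.proportion_hi)
            p = float(
                np.clip(rng.normal(p_mid, config.proportion_jitter_sd), 0.0, 1.0)
            )
            interval = interval_for_proportion(p)
        freqs = _cell_frequencies(config, interval, table, probs)
        statuses = {
            lm_id: (Status.PRESENT if rng.random() < q else Status.ABSENT)
            for lm_id, q in freqs.items()
        }
        statuses, larval = _apply_preservation(
            statuses, config.preservation, interval, table
        )
        out.append(
            ObservationSet(
                statuses=statuses,
                preservation=config.preservation,
                nominal_temp_c=config.temp_c,
                larval_morphology=larval,
                egg_id=f"sim-{config.seed}-{i:04d}",
            )
        )
    return out


@dataclass(frozen=True)
class CohortTruth:
    """Sidecar ground truth for a simulated timeline cohort."""

    proportion: float
    interval: DevelopmentalInterval
    hatched: bool
    seed: int


def simulate_cohort_timeline(
    oviposition_time: float,
    profile: TemperatureProfile,
    collection_time: float,
    n_eggs: int,
    seed: int,
    table: StagingTable,
    preservation: PreservationMode = PreservationMode.LIVING,
    probs: CategoryProbabilities = DEFAULT_CATEGORY_PROBABILITIES,
) -> tuple[list[ObservationSet], CohortTruth]:
    """End-to-end driver: run the thermal model forward from oviposition to
    collection, bin the reached proportion into its 10 % interval, and
    simulate a cohort scored there.

    Eggs that reach proportion 1.0 strictly before collection are flagged
    ``hatched`` (their observation record is that of a hatched egg, scored
    at the 100 % interval).
    """
    if collection_time < oviposition_time:
        raise ValueError("collection must not precede oviposition")
    p_raw = advance_development(
        profile, oviposition_time, collection_time, table, cap=False
    )
    p = min(p_raw, 1.0)
    hatched = p_raw > 1.0
    interval = interval_for_proportion(p)

    # cell lookup needs a calibrated temperature; use the one nearest the
    # window's time-weighted mean temperature (ties -> cooler regime)
    mean_temp = _mean_temperature(profile, oviposition_time, collection_time)
    lookup_temp = table.nearest_calibrated_temp(mean_temp)

    config = SimulationConfig(
        true_interval=interval,
        temp_c=lookup_temp,
        preservation=preservation,
        n_eggs=n_eggs,
        seed=seed,
    )
    cohort = simulate_observation(config, table, probs)
    for obs in cohort:
        obs.nominal_temp_c = mean_temp
        obs.collection_time = collection_time
        obs.hatched = hatched
    return cohort, CohortTruth(p, interval, hatched, seed)


def _mean_temperature(
    profile: TemperatureProfile, t_start: float, t_end: float
) -> float:
    if t_end == t_start:
        return profile.temperature_at(t_start)
    total = 0.0
    for dt, temp in profile.segments(t_start, t_end):
        total += dt * temp
    return total / (t_end - t_start)
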