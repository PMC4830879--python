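"""Interval and age inference from landmark observations.

The staging calibration gives, for each 10 % developmental interval, the
ordinal frequency with which each morphological landmark is seen. Reading
each ordinal category as a representative presence probability q turns a
scored egg into a likelihood over the eleven intervals:

    log L(i) = sum over assessed, observable landmarks of
               log q(landmark, i)       if scored PRESENT
               log (1 - q(landmark, i)) if scored ABSENT

Landmark observations are assumed independent given the interval (the
calibration provides no joint frequencies). A prior (uniform by default)
yields a posterior; the report carries the MAP interval, the smallest
contiguous 95 % credible set, and — when a thermal history is available —
chronological age and ADH bounds via the thermal model.

Preservation matters: hot-water-killed, ethanol-stored samples (HWK) lose 4
of the 15 landmarks, which are masked to NOT_ASSESSED; samples dropped
straight into ethanol decompose and are uninformative below the 90 %
interval, yielding censored estimates.
"""

from __future__ import annotations

import csv
import enum
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, TextIO

import numpy as np

from .staging import (
    INTERVALS,
    DevelopmentalInterval,
    StagingTable,
    VisibilityCategory,
)
from .thermal import (
    AgeBounds,
    ExtrapolationWarning,
    TemperatureProfile,
    adh_required,
    invert_age,
)

__all__ = [
    "Status",
    "PreservationMode",
    "CategoryProbabilities",
    "DEFAULT_CATEGORY_PROBABILITIES",
    "ObservationSet",
    "IntervalPosterior",
    "AgeEstimate",
    "category_probability",
    "interval_likelihood",
    "estimate_age",
    "read_observations",
    "write_observation_csv",
    "render_report",
    "report_dict",
    "CREDIBLE_MASS",
    "LARVAL_MORPHOLOGY_ID",
]

#: Target cumulative posterior mass for the credible set.
CREDIBLE_MASS = 0.95

#: Pseudo-landmark id accepted in observation files for the first-instar
#: larval morphology indicator used with direct-ethanol samples.
LARVAL_MORPHOLOGY_ID = "first_instar_larva"


class Status(enum.Enum):
    """Scored state of one landmark on one egg."""

    PRESENT = "PRESENT"
    ABSENT = "ABSENT"
    NOT_ASSESSED = "NOT_ASSESSED"


class PreservationMode(enum.Enum):
    LIVING = "LIVING"  # live dechorionated embryo, all 15 landmarks scorable
    HWK_ETHANOL = "HWK_ETHANOL"  # hot water killed then 80 % ethanol: 11 of 15
    ETHANOL_DIRECT = "ETHANOL_DIRECT"  # straight into ethanol: decomposed


@dataclass(frozen=True)
class CategoryProbabilities:
    """Representative presence probability per visibility category.

    The calibration records only ordinal frequency ranges, so the point
    values are configuration. Each value must lie inside its category's
    range; the ABSENT floor models occasional mis-scoring.
    """

    absent: float = 0.01
    rare: float = 0.125
    common: float = 0.5
    prevalent: float = 0.875

    def __post_init__(self) -> None:
        for cat, value in (
            (VisibilityCategory.ABSENT, self.absent),
            (VisibilityCategory.RARE, self.rare),
            (VisibilityCategory.COMMON, self.common),
            (VisibilityCategory.PREVALENT, self.prevalent),
        ):
            if not cat.contains(value):
                lo, hi = cat.frequency_range
                raise ValueError(
                    f"probability {value} for {cat.name} lies outside its "
                    f"frequency range ({lo}, {hi})"
                )

    def prob(self, category: VisibilityCategory) -> float:
        return {
            VisibilityCategory.ABSENT: self.absent,
            VisibilityCategory.RARE: self.rare,
            VisibilityCategory.COMMON: self.common,
            VisibilityCategory.PREVALENT: self.prevalent,
        }[category]


DEFAULT_CATEGORY_PROBABILITIES = CategoryProbabilities()


def category_probability(
    category: VisibilityCategory,
    probs: CategoryProbabilities = DEFAULT_CATEGORY_PROBABILITIES,
) -> float:
    """Presence probability assigned to a visibility category."""
    return probs.prob(category)


@dataclass
class ObservationSet:
    """One egg's scored landmarks plus collection metadata.

    ``nominal_temp_c`` is the effective temperature used for calibration
    lookup (the likelihood uses the nearest calibrated temperature; the
    thermal model interpolates). ``collection_time`` is the time-axis hour
    of collection, needed only for chronological age. The larval-morphology
    indicator is the one feature still scorable on decomposed
    direct-ethanol samples.
    """

    statuses: dict[str, Status]
    preservation: PreservationMode = PreservationMode.LIVING
    nominal_temp_c: float | None = None
    collection_time: float | None = None
    larval_morphology: Status = Status.NOT_ASSESSED
    hatched: bool = False
    egg_id: str | None = None

    def validate_against(self, table: StagingTable) -> None:
        unknown = set(self.statuses) - set(table.landmark_ids)
        if unknown:
            raise KeyError(
                f"unknown landmark ids {sorted(unknown)}; valid ids: "
                f"{', '.join(table.landmark_ids)} (plus "
                f"{LARVAL_MORPHOLOGY_ID!r})"
            )


@dataclass(frozen=True)
class IntervalPosterior:
    """Normalized posterior over the eleven 10 % intervals."""

    probabilities: np.ndarray
    prior: np.ndarray
    log_likelihoods: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.shape != (11,):
            raise ValueError("posterior must have 11 entries")
        if not np.all(np.isfinite(p)) or np.any(p < 0):
            raise ValueError("posterior entries must be finite and non-negative")
        if abs(float(p.sum()) - 1.0) > 1e-9:
            raise ValueError(f"posterior must sum to 1, got {p.sum()!r}")

    def __getitem__(self, interval: DevelopmentalInterval | int) -> float:
        idx = interval.index if isinstance(interval, DevelopmentalInterval) else interval
        return float(self.probabilities[idx])


@dataclass
class AgeEstimate:
    """Full inference result for one egg."""

    posterior: IntervalPosterior
    map_interval: DevelopmentalInterval
    credible_set: tuple[DevelopmentalInterval, ...]
    credible_mass: float
    proportion_range: tuple[float, float]
    adh_bounds: tuple[float, float] | None = None
    age_bounds_h: AgeBounds | None = None
    censored: bool = False
    warnings: list[str] = field(default_factory=list)
    egg_id: str | None = None


# ---------------------------------------------------------------------------
# likelihood and posterior
# ---------------------------------------------------------------------------


def _effective_statuses(
    obs: ObservationSet, table: StagingTable
) -> dict[str, Status]:
    """Apply preservation masking: non-HWK-visible landmarks cannot be
    scored on HWK-fixed material and are forced to NOT_ASSESSED."""
    if obs.preservation is PreservationMode.HWK_ETHANOL:
        visible = set(table.hwk_visible_ids)
        return {
            lm: (s if lm in visible else Status.NOT_ASSESSED)
            for lm, s in obs.statuses.items()
        }
    return dict(obs.statuses)


def _resolve_lookup_temp(
    obs: ObservationSet, table: StagingTable, notes: list[str]
) -> float:
    if obs.nominal_temp_c is None:
        fallback = min(table.calibrated_temps)
        notes.append(
            f"no effective temperature given; calibration categories taken "
            f"at {fallback} °C (cooler calibrated regime)"
        )
        return fallback
    nearest = table.nearest_calibrated_temp(obs.nominal_temp_c)
    if nearest != obs.nominal_temp_c:
        notes.append(
            f"effective temperature {obs.nominal_temp_c} °C is not "
            f"calibrated; categories taken from nearest calibrated "
            f"temperature {nearest} °C"
        )
    return nearest


def interval_likelihood(
    obs: ObservationSet,
    table: StagingTable,
    probs: CategoryProbabilities = DEFAULT_CATEGORY_PROBABILITIES,
) -> np.ndarray:
    """Log-likelihood over the 11 intervals for one observation set.

    Assessed landmarks contribute ``log q`` (PRESENT) or ``log(1-q)``
    (ABSENT) with q the category's representative presence probability at
    the nearest calibrated temperature; NOT_ASSESSED landmarks contribute
    nothing. With no assessed landmark at all the flat zero vector is
    returned (with a UserWarning), encoding total ignorance.
    """
    obs.validate_against(table)
    if obs.preservation is PreservationMode.ETHANOL_DIRECT:
        raise ValueError(
            "direct-ethanol samples carry no landmark information below the "
            "90 % interval; use estimate_age, which handles censoring"
        )
    notes: list[str] = []
    temp = _resolve_lookup_temp(obs, table, notes)
    statuses = _effective_statuses(obs, table)
    loglik = np.zeros(11)
    n_assessed = 0
    for lm_id, status in statuses.items():
        if status is Status.NOT_ASSESSED:
            continue
        n_assessed += 1
        for iv in INTERVALS:
            q = probs.prob(table.category(lm_id, iv, temp))
            loglik[iv.index] += math.log(q if status is Status.PRESENT else 1.0 - q)
    if n_assessed == 0:
        warnings.warn(
            "no assessed landmarks: likelihood is flat over all intervals",
            UserWarning,
            stacklevel=2,
        )
    return loglik


def _credible_set(
    posterior: np.ndarray, mass: float = CREDIBLE_MASS
) -> tuple[list[int], float]:
    """Smallest posterior-mass-ordered index set reaching *mass*, then
    extended to a contiguous run (development is monotone; disjoint age
    sets are not actionable). Ties in mass order break toward earlier
    intervals."""
    order = sorted(range(11), key=lambda i: (-posterior[i], i))
    chosen: list[int] = []
    cum = 0.0
    for i in order:
        chosen.append(i)
        cum += posterior[i]
        if cum >= mass - 1e-12:
            break
    lo, hi = min(chosen), max(chosen)
    members = list(range(lo, hi + 1))
    return members, float(posterior[lo : hi + 1].sum())


def estimate_age(
    obs: ObservationSet,
    table: StagingTable,
    profile: TemperatureProfile | None = None,
    prior: Sequence[float] | None = None,
    probs: CategoryProbabilities = DEFAULT_CATEGORY_PROBABILITIES,
) -> AgeEstimate:
    """Infer the developmental interval — and, given a thermal history, the
    chronological age — of one egg.

    The posterior is ``prior x exp(log-likelihood)`` normalized; the MAP
    interval breaks ties toward the earlier interval (conservative for a
    minimum post-mortem interval); the credible set is the smallest
    contiguous set holding >= 95 % posterior mass. Direct-ethanol samples
    bypass the likelihood entirely: with first-instar larval morphology
    PRESENT the estimate is censored to the 90-100 % window, otherwise it is
    fully censored over [0, 1].
    """
    obs.validate_against(table)
    prior_arr = (
        np.full(11, 1.0 / 11.0) if prior is None else np.asarray(prior, dtype=float)
    )
    if prior_arr.shape != (11,) or np.any(prior_arr < 0) or not np.all(
        np.isfinite(prior_arr)
    ):
        raise ValueError("prior must be 11 non-negative finite values")
    if abs(float(prior_arr.sum()) - 1.0) > 1e-9:
        raise ValueError(f"prior must sum to 1, got {prior_arr.sum()!r}")

    notes: list[str] = []

    if obs.preservation is PreservationMode.ETHANOL_DIRECT:
        return _estimate_ethanol_direct(obs, table, profile, prior_arr, notes)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        loglik = interval_likelihood(obs, table, probs)
    notes.extend(str(w.message) for w in caught)
    temp_note: list[str] = []
    _resolve_lookup_temp(obs, table, temp_note)
    notes.extend(temp_note)

    weights = prior_arr * np.exp(loglik - loglik.max())
    total = float(weights.sum())
    if total <= 0.0:
        raise ArithmeticError("posterior normalization failed (all-zero mass)")
    post = weights / total
    posterior = IntervalPosterior(post, prior_arr, loglik)

    map_idx = int(np.argmax(post))  # argmax takes the first (earlier) maximum
    members, cred_mass = _credible_set(post)
    credible = tuple(INTERVALS[i] for i in members)
    p_lo = credible[0].proportion_lo
    p_hi = credible[-1].proportion_hi

    return _attach_chronology(
        AgeEstimate(
            posterior=posterior,
            map_interval=INTERVALS[map_idx],
            credible_set=credible,
            credible_mass=cred_mass,
            proportion_range=(p_lo, p_hi),
            warnings=notes,
            egg_id=obs.egg_id,
        ),
        obs,
        table,
        profile,
    )


def _estimate_ethanol_direct(
    obs: ObservationSet,
    table: StagingTable,
    profile: TemperatureProfile | None,
    prior_arr: np.ndarray,
    notes: list[str],
) -> AgeEstimate:
    if obs.larval_morphology is Status.PRESENT:
        # decomposed but recognisably a first-instar larva: 90-100 % window
        post = np.zeros(11)
        post[9:] = 0.5
        posterior = IntervalPosterior(post, prior_arr, np.zeros(11))
        notes.append(
            "direct-ethanol sample with first-instar larval morphology: "
            "development censored to the 90-100 % window; landmark-level "
            "staging is not possible on such material"
        )
        est = AgeEstimate(
            posterior=posterior,
            map_interval=INTERVALS[9],
            credible_set=(INTERVALS[9], INTERVALS[10]),
            credible_mass=1.0,
            proportion_range=(0.9, 1.0),
            censored=True,
            warnings=notes,
            egg_id=obs.egg_id,
        )
    else:
        posterior = IntervalPosterior(prior_arr.copy(), prior_arr, np.zeros(11))
        notes.append(
            "direct-ethanol preservation causes marked decomposition: no "
            "morphological landmark is discernible below the 90 % interval "
            "and the estimate is fully censored over [0 %, 100 %]; collect "
            "future samples with hot-water killing before ethanol storage"
        )
        est = AgeEstimate(
            posterior=posterior,
            map_interval=INTERVALS[int(np.argmax(prior_arr))],
            credible_set=tuple(INTERVALS),
            credible_mass=1.0,
            proportion_range=(0.0, 1.0),
            censored=True,
            warnings=notes,
            egg_id=obs.egg_id,
        )
    return _attach_chronology(est, obs, table, profile)


def _attach_chronology(
    est: AgeEstimate,
    obs: ObservationSet,
    table: StagingTable,
    profile: TemperatureProfile | None,
) -> AgeEstimate:
    """Convert the proportion range to ADH and hour bounds when thermal
    inputs allow; otherwise return an interval-only estimate with a
    warning."""
    p_lo, p_hi = est.proportion_range

    temp_eff = obs.nominal_temp_c
    if temp_eff is None and profile is not None and profile.is_constant:
        temp_eff = float(profile.temps[0])
    if temp_eff is not None:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ExtrapolationWarning)
            est.adh_bounds = (
                adh_required(p_lo, temp_eff, table),
                adh_required(p_hi, temp_eff, table),
            )
        est.warnings.extend(str(w.message) for w in caught)

    if profile is None:
        est.warnings.append(
            "no thermal history supplied: interval estimate only, no "
            "chronological age bounds"
        )
        return est

    collection = obs.collection_time
    if collection is None:
        if profile.is_constant:
            collection = 0.0
        else:
            collection = float(profile.times[-1])
            est.warnings.append(
                f"collection time not given; assuming the last log "
                f"timestamp ({collection} h)"
            )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ExtrapolationWarning)
        est.age_bounds_h = invert_age((p_lo, p_hi), profile, collection, table)
    est.warnings.extend(str(w.message) for w in caught)
    if est.age_bounds_h.censored:
        est.censored = True
        est.warnings.append(
            "thermal history too short to reach the upper development "
            "bound: age bounds censored at the start of the record"
        )
    return est


# ---------------------------------------------------------------------------
# observation IO and reports
# ---------------------------------------------------------------------------

_META_KEYS = ("preservation", "nominal_temp_c", "collection_time", "egg_id")


def read_observations(
    source: str | Path | TextIO, table: StagingTable
) -> list[ObservationSet]:
    """Read observations from CSV (one egg) or JSON (one egg or a list).

    CSV dialect: leading ``# key: value`` metadata lines, then a
    ``landmark_id,status`` table. A ``first_instar_larva`` row sets the
    larval-morphology indicator. JSON mirrors the same fields.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() == ".json" or text.lstrip()[:1] in "[{":
            return _observations_from_json(json.loads(text), table)
        return [_observation_from_csv(text, table)]
    text = source.read()
    if text.lstrip()[:1] in "[{":
        return _observations_from_json(json.loads(text), table)
    return [_observation_from_csv(text, table)]


def _parse_status(raw: str, where: str) -> Status:
    token = raw.strip().upper()
    aliases = {"NA": "NOT_ASSESSED", "N/A": "NOT_ASSESSED"}
    token = aliases.get(token, token)
    try:
        return Status(token)
    except ValueError:
        raise ValueError(
            f"{where}: invalid status {raw!r}; expected "
            f"PRESENT/ABSENT/NOT_ASSESSED"
        ) from None


def _observation_from_csv(text: str, table: StagingTable) -> ObservationSet:
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("#"):
            payload = stripped.lstrip("#").strip()
            if ":" in payload:
                key, _, val = payload.partition(":")
                if key.strip() in _META_KEYS:
                    meta[key.strip()] = val.strip()
            continue
        if stripped:
            body_lines.append(line)
    reader = csv.DictReader(body_lines)
    if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != [
        "landmark_id",
        "status",
    ]:
        raise ValueError(
            f"observation CSV must have header 'landmark_id,status', got "
            f"{reader.fieldnames}"
        )
    statuses: dict[str, Status] = {}
    larval = Status.NOT_ASSESSED
    for row in reader:
        lm_id = row["landmark_id"].strip()
        status = _parse_status(row["status"], f"landmark {lm_id!r}")
        if lm_id == LARVAL_MORPHOLOGY_ID:
            larval = status
        else:
            statuses[lm_id] = status
    obs = ObservationSet(
        statuses=statuses,
        preservation=PreservationMode(meta.get("preservation", "LIVING")),
        nominal_temp_c=(
            float(meta["nominal_temp_c"]) if "nominal_temp_c" in meta else None
        ),
        collection_time=(
            float(meta["collection_time"]) if "collection_time" in meta else None
        ),
        larval_morphology=larval,
        egg_id=meta.get("egg_id"),
    )
    obs.validate_against(table)
    return obs


def _observations_from_json(payload, table: StagingTable) -> list[ObservationSet]:
    records = payload if isinstance(payload, list) else [payload]
    out = []
    for rec in records:
        statuses = {
            lm: _parse_status(s, f"landmark {lm!r}")
            for lm, s in rec.get("statuses", {}).items()
            if lm != LARVAL_MORPHOLOGY_ID
        }
        larval_raw = rec.get(
            "larval_morphology",
            rec.get("statuses", {}).get(LARVAL_MORPHOLOGY_ID, "NOT_ASSESSED"),
        )
        obs = ObservationSet(
            statuses=statuses,
            preservation=PreservationMode(rec.get("preservation", "LIVING")),
            nominal_temp_c=rec.get("nominal_temp_c"),
            collection_time=rec.get("collection_time"),
            larval_morphology=_parse_status(larval_raw, LARVAL_MORPHOLOGY_ID),
            egg_id=rec.get("egg_id"),
        )
        obs.validate_against(table)
        out.append(obs)
    return out


def write_observation_csv(obs: ObservationSet, dest: TextIO) -> None:
    """Write one observation in the CSV dialect read_observations accepts."""
    if obs.egg_id is not None:
        dest.write(f"# egg_id: {obs.egg_id}\n")
    dest.write(f"# preservation: {obs.preservation.value}\n")
    if obs.nominal_temp_c is not None:
        dest.write(f"# nominal_temp_c: {obs.nominal_temp_c:g}\n")
    if obs.collection_time is not None:
        dest.write(f"# collection_time: {obs.collection_time:g}\n")
    dest.write("landmark_id,status\n")
    for lm_id, status in obs.statuses.items():
        dest.write(f"{lm_id},{status.value}\n")
    if obs.larval_morphology is not Status.NOT_ASSESSED:
        dest.write(f"{LARVAL_MORPHOLOGY_ID},{obs.larval_morphology.value}\n")


def report_dict(est: AgeEstimate) -> dict:
    """JSON-serialisable report for one estimate; every quantity carries
    its units in the key name."""
    d: dict = {
        "egg_id": est.egg_id,
        "map_interval": est.map_interval.label,
        "posterior": {
            iv.label: float(est.posterior.probabilities[iv.index])
            for iv in INTERVALS
        },
        "credible_set": [iv.label for iv in est.credible_set],
        "credible_mass": est.credible_mass,
        "proportion_range": list(est.proportion_range),
        "censored": est.censored,
        "warnings": list(est.warnings),
    }
    if est.adh_bounds is not None:
        d["adh_bounds_degree_hours"] = list(est.adh_bounds)
    if est.age_bounds_h is not None:
        d["age_bounds_hours"] = [est.age_bounds_h.t_min, est.age_bounds_h.t_max]
        d["age_bounds_censored"] = [
            est.age_bounds_h.censored_min,
            est.age_bounds_h.censored_max,
        ]
    return d


def render_report(est: AgeEstimate) -> str:
    """Human-readable rendering of one estimate."""
    lines = []
    if est.egg_id:
        lines.append(f"Egg: {est.egg_id}")
    lines.append(f"MAP developmental interval: {est.map_interval.label}")
    lines.append(
        "95 % credible set: "
        + ", ".join(iv.label for iv in est.credible_set)
        + f" (mass {est.credible_mass:.3f})"
    )
    p_lo, p_hi = est.proportion_range
    lines.append(
        f"Development proportion range: {p_lo:.2f} - {p_hi:.2f} of the egg stage"
    )
    if est.adh_bounds is not None:
        lines.append(
            f"ADH from oviposition: {est.adh_bounds[0]:.1f} - "
            f"{est.adh_bounds[1]:.1f} degree hours (base 1 °C)"
        )
    if est.age_bounds_h is not None:
        lines.append(
            f"Age at collection: {est.age_bounds_h.t_min:.2f} - "
            f"{est.age_bounds_h.t_max:.2f} hours since oviposition"
        )
    if est.censored:
        lines.append("NOTE: estimate is censored (see warnings)")
    for w in est.warnings:
        lines.append(f"warning: {w}")
    return "\n".join(lines)
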