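"""Accumulated-degree-hour (ADH) thermal model for egg development.

Development is driven by thermal time: degree hours accumulated above a
lower developmental threshold (1 °C for the London *C. vicina* population
behind the calibration). The total ADH requirement of the egg stage is
itself temperature dependent — 756 ADH over 120 h at a constant 7.3 °C but
only 384 ADH over 16 h at 25 °C — so fluctuating-temperature development is
handled by rate summation: each log step contributes the fraction of the
(temperature-interpolated) total requirement that its degree hours
represent, rather than being summed against a single fixed total.

Temperature logs use piecewise-constant (left-hold) interpolation, matching
data-logger semantics and keeping all integrals exact.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterator, Sequence, TextIO

import numpy as np

from .staging import BASE_TEMP_C, StagingTable

__all__ = [
    "ExtrapolationWarning",
    "TemperatureProfile",
    "AdhLedger",
    "AgeBounds",
    "accumulate_adh",
    "adh_required",
    "advance_development",
    "invert_age",
    "INVERT_AGE_TOL_H",
]

#: Deterministic bisection tolerance for age inversion, in hours.
INVERT_AGE_TOL_H = 0.01

#: Hard ceiling on the age bracket searched during inversion (hours);
#: development that cannot be reached within it is reported as censored.
_MAX_AGE_H = 1.0e7


class ExtrapolationWarning(UserWarning):
    """Raised when a query leaves the calibrated/logged range and the model
    clamps to the nearest supported value."""


@dataclass(frozen=True)
class TemperatureProfile:
    """A thermal history: ordered (time, °C) samples, left-hold interpolated.

    Times are hours on a continuous axis. The temperature at time ``t`` is
    the value of the latest sample at or before ``t``; the last sample
    extends forward indefinitely. Queries before the first sample hold the
    first value and trigger an :class:`ExtrapolationWarning`.
    """

    times: np.ndarray
    temps: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        temps = np.asarray(self.temps, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "temps", temps)
        if times.ndim != 1 or times.size == 0:
            raise ValueError("profile needs at least one (time, temp) sample")
        if times.shape != temps.shape:
            raise ValueError("times and temps must have equal length")
        if not np.all(np.isfinite(temps)):
            raise ValueError("temperatures must be finite")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @classmethod
    def constant(
        cls, temp_c: float, t_start: float = -np.inf
    ) -> "TemperatureProfile":
        """A constant-temperature profile holding from *t_start* onward."""
        return cls(np.array([t_start]), np.array([float(temp_c)]))

    @property
    def is_constant(self) -> bool:
        return self.temps.size == 1 or bool(np.all(self.temps == self.temps[0]))

    def temperature_at(self, t: float) -> float:
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        if idx < 0:
            warnings.warn(
                f"time {t} h precedes the first profile sample at "
                f"{self.times[0]} h; holding the first temperature",
                ExtrapolationWarning,
                stacklevel=2,
            )
            idx = 0
        return float(self.temps[idx])

    def segments(self, t_start: float, t_end: float) -> Iterator[tuple[float, float]]:
        """Yield (duration_h, temp_c) pieces covering [t_start, t_end]
        exactly under left-hold interpolation."""
        if t_end < t_start:
            raise ValueError(f"reversed interval [{t_start}, {t_end}]")
        if t_end == t_start:
            return
        if t_start < self.times[0]:
            warnings.warn(
                f"interval start {t_start} h precedes the first profile "
                f"sample at {self.times[0]} h; holding the first temperature",
                ExtrapolationWarning,
                stacklevel=2,
            )
        # breakpoints strictly inside the interval
        inner = self.times[(self.times > t_start) & (self.times < t_end)]
        edges = np.concatenate(([t_start], inner, [t_end]))
        for a, b in zip(edges[:-1], edges[1:]):
            idx = int(np.searchsorted(self.times, a, side="right")) - 1
            temp = float(self.temps[max(idx, 0)])
            yield float(b - a), temp

    # -- IO ----------------------------------------------------------------

    @classmethod
    def from_csv(cls, source: str | Path | TextIO) -> "TemperatureProfile":
        """Read a temperature log: header ``timestamp,temp_c``.

        Timestamps may be decimal hours or ISO 8601 date-times
        (auto-detected; ISO times are converted to hours since the first
        record). The detected dialect is recorded on ``profile.dialect``.
        """
        if isinstance(source, (str, Path)):
            with open(source, newline="", encoding="utf-8") as fh:
                return cls.from_csv(fh)
        reader = csv.DictReader(source)
        if reader.fieldnames is None or [
            f.strip() for f in reader.fieldnames
        ] != ["timestamp", "temp_c"]:
            raise ValueError(
                "temperature log must have header 'timestamp,temp_c', got "
                f"{reader.fieldnames}"
            )
        raw_times: list[str] = []
        temps: list[float] = []
        for row in reader:
            raw_times.append(row["timestamp"].strip())
            temps.append(float(row["temp_c"]))
        if not raw_times:
            raise ValueError("temperature log is empty")
        try:
            times = [float(t) for t in raw_times]
            dialect = "decimal_hours"
        except ValueError:
            stamps = [datetime.fromisoformat(t) for t in raw_times]
            t0 = stamps[0]
            times = [(s - t0).total_seconds() / 3600.0 for s in stamps]
            dialect = "iso8601"
        profile = cls(np.array(times), np.array(temps))
        object.__setattr__(profile, "dialect", dialect)
        return profile


@dataclass
class AdhLedger:
    """Bookkeeping for one ADH integration over a time window."""

    t_start: float
    t_end: float
    base_temp_c: float
    adh: float
    per_step: list[tuple[float, float, float]] = field(default_factory=list)
    #: (duration_h, temp_c, degree-hour contribution) per left-hold piece

    def __add__(self, other: "AdhLedger") -> "AdhLedger":
        if other.t_start != self.t_end or other.base_temp_c != self.base_temp_c:
            raise ValueError("ledgers are not adjacent/compatible")
        return AdhLedger(
            self.t_start,
            other.t_end,
            self.base_temp_c,
            self.adh + other.adh,
            self.per_step + other.per_step,
        )


def accumulate_adh(
    profile: TemperatureProfile,
    t_start: float,
    t_end: float,
    base_temp_c: float = BASE_TEMP_C,
) -> AdhLedger:
    """Integrate degree hours above *base_temp_c* over [t_start, t_end].

    Exact under the profile's left-hold interpolation; additive over
    adjacent sub-intervals. Sub-threshold temperatures contribute zero.
    """
    if t_end < t_start:
        raise ValueError(f"reversed interval [{t_start}, {t_end}]")
    per_step: list[tuple[float, float, float]] = []
    total = 0.0
    for dt, temp in profile.segments(t_start, t_end):
        contrib = max(0.0, temp - base_temp_c) * dt
        per_step.append((dt, temp, contrib))
        total += contrib
    return AdhLedger(t_start, t_end, base_temp_c, total, per_step)


def adh_required(
    proportion: float,
    temp_c: float,
    table: StagingTable,
) -> float:
    """Degree hours needed from oviposition to reach *proportion* of total
    development at an effective constant temperature *temp_c*.

    At a calibrated temperature this is
    ``proportion x (temp - base) x total_duration_h``. Between the two
    calibrated temperatures the requirement is interpolated linearly in
    temperature at fixed proportion; outside the calibrated range it clamps
    to the nearest calibrated temperature with an
    :class:`ExtrapolationWarning`.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValueError(f"proportion must lie in [0, 1], got {proportion}")
    temps = sorted(table.temperatures, key=lambda t: t.temp_c)
    lo, hi = temps[0], temps[-1]

    def at(ct) -> float:
        return proportion * (ct.temp_c - ct.base_temp_c) * ct.total_duration_h

    for ct in temps:
        if temp_c == ct.temp_c:
            return at(ct)
    if temp_c < lo.temp_c or temp_c > hi.temp_c:
        nearest = lo if temp_c < lo.temp_c else hi
        warnings.warn(
            f"{temp_c} °C lies outside the calibrated range "
            f"[{lo.temp_c}, {hi.temp_c}] °C; clamping ADH requirement to "
            f"{nearest.temp_c} °C",
            ExtrapolationWarning,
            stacklevel=2,
        )
        return at(nearest)
    w = (temp_c - lo.temp_c) / (hi.temp_c - lo.temp_c)
    return (1.0 - w) * at(lo) + w * at(hi)


def advance_development(
    profile: TemperatureProfile,
    t_start: float,
    t_end: float,
    table: StagingTable,
    *,
    cap: bool = True,
) -> float:
    """Development proportion accrued over [t_start, t_end] by rate
    summation.

    Each left-hold piece at temperature T contributes
    ``max(0, T - base) * dt / adh_required(1.0, T)`` — its degree hours as a
    fraction of the total requirement *at that temperature*. With
    ``cap=True`` (default) the proportion saturates at 1.0 (hatching);
    ``cap=False`` returns the raw sum, useful for detecting hatching
    strictly before ``t_end``.
    """
    if t_end < t_start:
        raise ValueError(f"reversed interval [{t_start}, {t_end}]")
    base = table.base_temp_c
    p = 0.0
    for dt, temp in profile.segments(t_start, t_end):
        total_req = adh_required(1.0, temp, table)
        p += max(0.0, temp - base) * dt / total_req
        if cap and p >= 1.0:
            return 1.0
    return min(p, 1.0) if cap else p


@dataclass(frozen=True)
class AgeBounds:
    """Chronological age bounds (hours before collection) for a development
    proportion range, with censoring flags where the thermal history was too
    short to reach a bound."""

    t_min: float
    t_max: float
    censored_min: bool = False
    censored_max: bool = False

    @property
    def censored(self) -> bool:
        return self.censored_min or self.censored_max


def invert_age(
    target_proportion_range: Sequence[float],
    profile: TemperatureProfile,
    collection_time: float,
    table: StagingTable,
    tol: float = INVERT_AGE_TOL_H,
) -> AgeBounds:
    """Invert the thermal model: ages (hours before *collection_time*) at
    which development equals the bounds of the target proportion range.

    For each target proportion p, finds the smallest age a such that
    development accumulated over [collection_time - a, collection_time]
    reaches p, by deterministic bisection to within *tol* hours. If the
    profile's span (or the search ceiling) cannot reach p, the bound is
    censored at the longest searchable age rather than raising.
    """
    p_lo, p_hi = target_proportion_range
    if not 0.0 <= p_lo <= p_hi <= 1.0:
        raise ValueError(
            f"need 0 <= p_lo <= p_hi <= 1, got [{p_lo}, {p_hi}]"
        )

    span = collection_time - float(profile.times[0])
    max_age = min(span, _MAX_AGE_H) if np.isfinite(span) else _MAX_AGE_H

    def development(age: float) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            return advance_development(
                profile, collection_time - age, collection_time, table
            )

    def solve(p: float) -> tuple[float, bool]:
        if p <= 0.0:
            return 0.0, False
        # grow the bracket geometrically until p is reached
        hi = min(1.0, max_age)
        while development(hi) < p:
            if hi >= max_age:
                return max_age, True
            hi = min(hi * 2.0, max_age)
        lo = 0.0
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if development(mid) >= p:
                hi = mid
            else:
                lo = mid
        return hi, False

    t_min, cens_min = solve(p_lo)
    t_max, cens_max = solve(p_hi)
    return AgeBounds(t_min, t_max, cens_min, cens_max)
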