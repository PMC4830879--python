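"""Staging calibration for *Calliphora vicina* embryogenesis.

The calibration is a table of 15 externally visualisable morphological
landmarks scored over the eleven 10 % intervals of total egg development at
two constant rearing temperatures (7.3 and 25 °C). Each cell holds an
ordinal visibility category — the fraction of examined individuals in which
the landmark was discernible — and each landmark carries a flag saying
whether it survives hot-water-killing (HWK) fixation followed by storage in
80 % ethanol. A correspondence from the 10 % intervals to the classical
*Drosophila melanogaster* embryonic stages (Campos-Ortega & Hartenstein
numbering, stages 1–17) is also provided.

The canonical calibration ships with the package as a human-editable TSV
(:data:`DEFAULT_TABLE_RESOURCE`); :func:`load_staging_table` parses and
validates it.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, TextIO

__all__ = [
    "BASE_TEMP_C",
    "ABSENT_EPSILON_RANGE",
    "VisibilityCategory",
    "Landmark",
    "DevelopmentalInterval",
    "INTERVALS",
    "CalibratedTemperature",
    "StagingTable",
    "StagingError",
    "StagingParseError",
    "StagingSchemaError",
    "load_staging_table",
    "StageCorrespondence",
    "drosophila_stages",
]

#: Lower developmental threshold (°C) below which no development accrues,
#: as established for C. vicina populations in London, UK.
BASE_TEMP_C = 1.0

#: Upper edge of the ABSENT category's frequency range. A landmark scored
#: blank in the calibration is treated as present in [0, this) of
#: individuals; the non-zero width models occasional mis-scoring.
ABSENT_EPSILON_RANGE = 0.05


class VisibilityCategory(enum.IntEnum):
    """Ordinal visibility class of a landmark within an interval.

    The integer order reflects increasing observation frequency.
    """

    ABSENT = 0  # blank cell: character not visible
    RARE = 1  # "+"  : visible in <25 % of individuals
    COMMON = 2  # "++" : visible in 25-75 %
    PREVALENT = 3  # "+++": visible in >75 %

    @property
    def frequency_range(self) -> tuple[float, float]:
        """(lo, hi) proportion range of individuals showing the landmark.

        ABSENT is [0, eps); RARE is (0, 0.25); COMMON is [0.25, 0.75];
        PREVALENT is (0.75, 1]. Endpoint openness is handled by
        :meth:`contains`.
        """
        return _FREQ_RANGES[self]

    def contains(self, p: float) -> bool:
        """True if proportion *p* lies inside this category's range."""
        lo, hi = _FREQ_RANGES[self]
        if self is VisibilityCategory.ABSENT:
            return 0.0 <= p < hi
        if self is VisibilityCategory.COMMON:
            return lo <= p <= hi
        return lo < p <= hi

    @property
    def symbol(self) -> str:
        return _CATEGORY_TO_SYMBOL[self]


_FREQ_RANGES: dict[VisibilityCategory, tuple[float, float]] = {
    VisibilityCategory.ABSENT: (0.0, ABSENT_EPSILON_RANGE),
    VisibilityCategory.RARE: (0.0, 0.25),
    VisibilityCategory.COMMON: (0.25, 0.75),
    VisibilityCategory.PREVALENT: (0.75, 1.0),
}

SYMBOL_TO_CATEGORY: dict[str, VisibilityCategory] = {
    "": VisibilityCategory.ABSENT,
    "+": VisibilityCategory.RARE,
    "++": VisibilityCategory.COMMON,
    "+++": VisibilityCategory.PREVALENT,
}
_CATEGORY_TO_SYMBOL = {v: k for k, v in SYMBOL_TO_CATEGORY.items()}


@dataclass(frozen=True)
class Landmark:
    """One externally visualisable embryonic character."""

    id: str
    name: str
    hwk_visible: bool


@dataclass(frozen=True, order=True)
class DevelopmentalInterval:
    """One of the eleven 10 % intervals of total egg development.

    Interval *i* covers the development-proportion window
    [i/10, (i+1)/10), except the terminal 100 % interval which is the
    hatching point [1.0, 1.0].
    """

    index: int

    def __post_init__(self) -> None:
        if not 0 <= self.index <= 10:
            raise ValueError(f"interval index must be 0..10, got {self.index}")

    @property
    def proportion_lo(self) -> float:
        return self.index / 10.0

    @property
    def proportion_hi(self) -> float:
        return min(1.0, (self.index + 1) / 10.0)

    @property
    def label(self) -> str:
        return f"{self.index * 10} %"


#: The eleven canonical intervals, 0 %..100 %.
INTERVALS: tuple[DevelopmentalInterval, ...] = tuple(
    DevelopmentalInterval(i) for i in range(11)
)


def interval_for_proportion(p: float) -> DevelopmentalInterval:
    """Map a continuous development proportion to its containing interval.

    Half-open bins [i/10, (i+1)/10); p == 1.0 maps to the 100 % interval.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion must lie in [0, 1], got {p}")
    return INTERVALS[min(int(p * 10), 10)]


@dataclass(frozen=True)
class CalibratedTemperature:
    """A constant rearing temperature with its calibrated total duration."""

    temp_c: float
    total_duration_h: float
    base_temp_c: float = BASE_TEMP_C

    def __post_init__(self) -> None:
        if self.temp_c <= self.base_temp_c:
            raise ValueError(
                f"calibrated temperature {self.temp_c} °C must exceed the "
                f"base threshold {self.base_temp_c} °C"
            )
        if self.total_duration_h <= 0:
            raise ValueError("total_duration_h must be positive")

    @property
    def total_adh(self) -> float:
        """Degree hours above base accumulated over the whole egg stage."""
        return (self.temp_c - self.base_temp_c) * self.total_duration_h


class StagingError(ValueError):
    """Base class for calibration-file problems."""


class StagingParseError(StagingError):
    """A cell or field could not be parsed; the message names the cell."""


class StagingSchemaError(StagingError):
    """The parsed table violates the calibration schema or an invariant."""


@dataclass
class StagingTable:
    """The full landmark x interval x temperature visibility calibration."""

    landmarks: tuple[Landmark, ...]
    intervals: tuple[DevelopmentalInterval, ...]
    temperatures: tuple[CalibratedTemperature, ...]
    cells: dict[tuple[str, int, float], VisibilityCategory] = field(repr=False)

    # -- lookup ------------------------------------------------------------

    def landmark(self, landmark_id: str) -> Landmark:
        try:
            return self._landmark_index[landmark_id]
        except KeyError:
            raise KeyError(
                f"unknown landmark id {landmark_id!r}; valid ids: "
                f"{', '.join(self.landmark_ids)}"
            ) from None

    @property
    def landmark_ids(self) -> tuple[str, ...]:
        return tuple(lm.id for lm in self.landmarks)

    @property
    def hwk_visible_ids(self) -> tuple[str, ...]:
        return tuple(lm.id for lm in self.landmarks if lm.hwk_visible)

    @property
    def calibrated_temps(self) -> tuple[float, ...]:
        return tuple(t.temp_c for t in self.temperatures)

    def temperature(self, temp_c: float) -> CalibratedTemperature:
        for t in self.temperatures:
            if t.temp_c == temp_c:
                return t
        raise KeyError(
            f"{temp_c} °C is not a calibrated temperature "
            f"(have {self.calibrated_temps})"
        )

    def nearest_calibrated_temp(self, temp_c: float) -> float:
        """Calibrated temperature nearest to *temp_c*; ties go to the
        cooler (slower, forensically conservative) regime."""
        return min(self.calibrated_temps, key=lambda t: (abs(t - temp_c), t))

    def category(
        self,
        landmark_id: str,
        interval: DevelopmentalInterval | int,
        temp_c: float,
    ) -> VisibilityCategory:
        idx = interval.index if isinstance(interval, DevelopmentalInterval) else interval
        self.landmark(landmark_id)  # raises on unknown id
        return self.cells[(landmark_id, idx, temp_c)]

    @property
    def base_temp_c(self) -> float:
        return self.temperatures[0].base_temp_c

    # -- validation --------------------------------------------------------

    def __post_init__(self) -> None:
        self._landmark_index = {lm.id: lm for lm in self.landmarks}
        self.validate()

    def validate(self) -> None:
        """Check every structural invariant; raise StagingSchemaError
        naming the offending cell or record on failure."""
        ids = [lm.id for lm in self.landmarks]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise StagingSchemaError(f"duplicate landmark ids: {dupes}")
        if len(self.landmarks) != 15:
            raise StagingSchemaError(
                f"expected 15 landmarks, found {len(self.landmarks)}: {ids}"
            )
        if len(self.intervals) != 11:
            raise StagingSchemaError(
                f"expected 11 intervals, found {len(self.intervals)}"
            )
        n_hwk = sum(lm.hwk_visible for lm in self.landmarks)
        if n_hwk != 11:
            raise StagingSchemaError(
                f"expected 11 HWK-visible landmarks, found {n_hwk}"
            )
        bases = {t.base_temp_c for t in self.temperatures}
        if len(bases) != 1:
            raise StagingSchemaError(
                f"inconsistent base temperatures across calibration: {bases}"
            )
        # completeness: one category per triple
        for lm in self.landmarks:
            for iv in self.intervals:
                for t in self.temperatures:
                    key = (lm.id, iv.index, t.temp_c)
                    if key not in self.cells:
                        raise StagingSchemaError(
                            f"missing cell ({lm.id}, {iv.label}, {t.temp_c} °C)"
                        )
        extras = set(self.cells) - {
            (lm.id, iv.index, t.temp_c)
            for lm in self.landmarks
            for iv in self.intervals
            for t in self.temperatures
        }
        if extras:
            raise StagingSchemaError(f"cells outside the schema: {sorted(extras)}")
        # diagnosability: every interval has evidence at every temperature
        for t in self.temperatures:
            for iv in self.intervals:
                if not any(
                    self.cells[(lm.id, iv.index, t.temp_c)] >= VisibilityCategory.RARE
                    for lm in self.landmarks
                ):
                    raise StagingSchemaError(
                        f"interval {iv.label} at {t.temp_c} °C has no visible "
                        f"landmark (undiagnosable)"
                    )

    # -- serialization -----------------------------------------------------

    def serialize(self) -> str:
        """Render back to the TSV calibration dialect (cell-for-cell
        round trip with :func:`load_staging_table`)."""
        out = io.StringIO()
        out.write(f"#! base_temp_c\t{self.base_temp_c:g}\n")
        for t in self.temperatures:
            out.write(f"#! temperature\t{t.temp_c:g}\t{t.total_duration_h:g}\n")
        cols = "\t".join(f"cat_{iv.index * 10}" for iv in self.intervals)
        out.write(f"landmark_id\tlandmark_name\thwk_visible\ttemp_c\t{cols}\n")
        for lm in self.landmarks:
            for t in self.temperatures:
                cats = "\t".join(
                    self.cells[(lm.id, iv.index, t.temp_c)].symbol
                    for iv in self.intervals
                )
                flag = "yes" if lm.hwk_visible else "no"
                out.write(f"{lm.id}\t{lm.name}\t{flag}\t{t.temp_c:g}\t{cats}\n")
        return out.getvalue()


#: importlib.resources anchor of the packaged canonical calibration.
DEFAULT_TABLE_RESOURCE = ("ovistage.data", "staging_table.tsv")


def load_staging_table(
    source: str | Path | TextIO | None = None,
) -> StagingTable:
    """Parse and validate a staging calibration.

    Parameters
    ----------
    source
        Path or open text stream of a calibration TSV. ``None`` loads the
        packaged canonical table.

    Raises
    ------
    StagingParseError
        Malformed symbol or field, with the offending cell named.
    StagingSchemaError
        Missing/duplicate rows or violated structural invariants.
    """
    if source is None:
        pkg, name = DEFAULT_TABLE_RESOURCE
        text = resources.files(pkg).joinpath(name).read_text(encoding="utf-8")
        return _parse_table(text.splitlines(), "<packaged calibration>")
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
        return _parse_table(text.splitlines(), str(source))
    return _parse_table(source.read().splitlines(), getattr(source, "name", "<stream>"))


def _parse_table(lines: Iterable[str], origin: str) -> StagingTable:
    base_temp = BASE_TEMP_C
    temp_specs: list[tuple[float, float]] = []
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if line.startswith("#!"):
            parts = line[2:].strip().split("\t")
            if parts[0] == "base_temp_c":
                base_temp = float(parts[1])
            elif parts[0] == "temperature":
                temp_specs.append((float(parts[1]), float(parts[2])))
            else:
                raise StagingParseError(
                    f"{origin}:{lineno}: unknown directive {parts[0]!r}"
                )
            continue
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            continue
        rows.append((lineno, fields))

    if header is None:
        raise StagingSchemaError(f"{origin}: no header row found")
    expected_cols = ["landmark_id", "landmark_name", "hwk_visible", "temp_c"] + [
        f"cat_{i * 10}" for i in range(11)
    ]
    if header != expected_cols:
        raise StagingSchemaError(
            f"{origin}: header mismatch; expected {expected_cols}, got {header}"
        )
    if not temp_specs:
        raise StagingSchemaError(f"{origin}: no '#! temperature' directives")

    temperatures = tuple(
        CalibratedTemperature(tc, dur, base_temp) for tc, dur in temp_specs
    )
    temp_set = {t.temp_c for t in temperatures}

    landmarks: list[Landmark] = []
    seen: dict[str, Landmark] = {}
    cells: dict[tuple[str, int, float], VisibilityCategory] = {}
    for lineno, fields in rows:
        # short rows: trailing blank cells were trimmed by the editor
        fields = fields + [""] * (len(expected_cols) - len(fields))
        if len(fields) > len(expected_cols):
            raise StagingParseError(
                f"{origin}:{lineno}: {len(fields)} fields, expected "
                f"at most {len(expected_cols)}"
            )
        lm_id, lm_name, hwk_raw, temp_raw = (f.strip() for f in fields[:4])
        if hwk_raw.lower() not in ("yes", "no"):
            raise StagingParseError(
                f"{origin}:{lineno}: hwk_visible must be yes/no, got {hwk_raw!r}"
            )
        try:
            temp_c = float(temp_raw)
        except ValueError:
            raise StagingParseError(
                f"{origin}:{lineno}: bad temp_c {temp_raw!r}"
            ) from None
        if temp_c not in temp_set:
            raise StagingSchemaError(
                f"{origin}:{lineno}: row temperature {temp_c} °C has no "
                f"'#! temperature' directive"
            )
        lm = Landmark(lm_id, lm_name, hwk_raw.lower() == "yes")
        if lm_id in seen:
            if seen[lm_id] != lm:
                raise StagingSchemaError(
                    f"{origin}:{lineno}: landmark {lm_id!r} redefined with "
                    f"different name/flag"
                )
        else:
            seen[lm_id] = lm
            landmarks.append(lm)
        for iv_idx, symbol in enumerate(fields[4:15]):
            symbol = symbol.strip()
            if symbol not in SYMBOL_TO_CATEGORY:
                raise StagingParseError(
                    f"{origin}:{lineno}: invalid symbol {symbol!r} in cell "
                    f"({lm_id}, {iv_idx * 10} %, {temp_c} °C); "
                    f"allowed: blank, +, ++, +++"
                )
            key = (lm_id, iv_idx, temp_c)
            if key in cells:
                raise StagingSchemaError(
                    f"{origin}:{lineno}: duplicate cell "
                    f"({lm_id}, {iv_idx * 10} %, {temp_c} °C)"
                )
            cells[key] = SYMBOL_TO_CATEGORY[symbol]

    return StagingTable(
        landmarks=tuple(landmarks),
        intervals=INTERVALS,
        temperatures=temperatures,
        cells=cells,
    )


# ---------------------------------------------------------------------------
# Drosophila melanogaster stage correspondence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StageCorrespondence:
    """Drosophila embryonic stages spanned by a 10 % interval.

    ``full`` stages fall wholly within the interval; ``partial`` stages are
    only partly contained (the source gives no finer quantitation, so
    membership is a flag rather than a fractional weight).
    """

    full: frozenset[int]
    partial: frozenset[int]

    @property
    def stages(self) -> frozenset[int]:
        return self.full | self.partial


_DROSOPHILA_MAP: dict[int, StageCorrespondence] = {
    0: StageCorrespondence(frozenset({1}), frozenset()),
    1: StageCorrespondence(frozenset({2}), frozenset()),
    2: StageCorrespondence(frozenset({3, 4, 5}), frozenset({6})),
    3: StageCorrespondence(frozenset({6, 7, 8, 9}), frozenset()),
    4: StageCorrespondence(frozenset({10, 11}), frozenset()),
    5: StageCorrespondence(frozenset({12}), frozenset()),
    6: StageCorrespondence(frozenset({13}), frozenset()),
    7: StageCorrespondence(frozenset({14, 15}), frozenset()),
    8: StageCorrespondence(frozenset(), frozenset({16})),
    9: StageCorrespondence(frozenset(), frozenset({16})),
    10: StageCorrespondence(frozenset({17}), frozenset()),
}


def drosophila_stages(
    interval: DevelopmentalInterval | int,
) -> StageCorrespondence:
    """Drosophila (Campos-Ortega & Hartenstein) stages for an interval.

    Raises ValueError for an out-of-range interval index.
    """
    idx = interval.index if isinstance(interval, DevelopmentalInterval) else interval
    if idx not in _DROSOPHILA_MAP:
        raise ValueError(f"interval index must be 0..10, got {idx}")
    return _DROSOPHILA_MAP[idx]
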