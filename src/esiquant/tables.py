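"""Domain types and delimited-text I/O for aligned LC/MS feature tables.

A *feature table* holds one row per (compound, ionization mode, mobile-phase
pH, dilution level): peak area, retention time, the m/z of the detected ion
and a sodium-adduct flag. Rows with empty area/rt cells mean the feature was
not detected under that condition (signal below the detection limit).

Also provides the two preprocessing steps applied before calibration:
merging split chromatographic peaks (areas summed, retention times averaged)
and the per-compound mean retention time over dilutions.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import (
    FormatError,
    UndefinedRetentionTimeError,
    ValidationError,
)

#: Monoisotopic mass of the proton, Da. Detected ions are [M+H]+ / [M-H]-.
PROTON_MASS = 1.00727646677

#: Mobile-phase aqueous pH values of the three chromatographic methods.
VALID_PHS = (2.7, 8.0, 10.0)

#: ESI polarities, in canonical order (positive sorts before negative).
MODES = ("positive", "negative")

#: Instrument scan range, m/z 65-975.
SCAN_RANGE_MZ = (65.0, 975.0)


@dataclass(frozen=True, slots=True)
class ConditionKey:
    """One of the six (polarity, mobile-phase pH) measurement conditions."""

    mode: str
    ph: float

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"unknown ionization mode {self.mode!r}")
        if self.ph not in VALID_PHS:
            raise ValidationError(
                f"pH {self.ph!r} not one of the mobile-phase values {VALID_PHS}"
            )

    @property
    def _sort_key(self) -> tuple[int, float]:
        return (MODES.index(self.mode), self.ph)

    def __lt__(self, other: "ConditionKey") -> bool:
        return self._sort_key < other._sort_key

    def __le__(self, other: "ConditionKey") -> bool:
        return self._sort_key <= other._sort_key

    def __str__(self) -> str:
        return f"{self.mode}/pH{self.ph:g}"


def all_conditions() -> tuple[ConditionKey, ...]:
    """The six valid condition keys: positive before negative, ascending pH."""
    return tuple(ConditionKey(m, ph) for m in MODES for ph in VALID_PHS)


@dataclass(frozen=True, slots=True)
class Compound:
    """A compound (or unidentified feature) and its known dilution series.

    ``neutral_conc_series`` maps dilution factor -> molar concentration of
    the undiluted standard divided by that factor; it is only populated for
    compounds whose concentrations are known (standards, or simulated truth).
    """

    id: str
    mz: float
    neutral_conc_series: Mapping[float, float] = field(default_factory=dict)
    role: str = "standard"

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValidationError(f"m/z must be positive, got {self.mz}")
        if self.role not in ("standard", "unknown"):
            raise ValidationError(f"role must be standard|unknown, got {self.role!r}")
        concs = list(self.neutral_conc_series.values())
        if any(c <= 0 for c in concs):
            raise ValidationError("concentrations must be positive")


@dataclass(frozen=True, slots=True)
class PeakRecord:
    """One detected (or censored) feature under one condition and dilution.

    ``area`` and ``rt`` are ``None`` together when the feature was not
    detected; ``na_adduct`` flags a sodium adduct observed at pH 2.7.
    """

    compound_id: str
    condition: ConditionKey
    dilution_factor: float
    area: float | None
    rt: float | None
    mz_observed: float
    na_adduct: bool = False

    def __post_init__(self) -> None:
        if (self.area is None) != (self.rt is None):
            raise ValidationError(
                f"{self.compound_id}: area and rt must be absent together"
            )
        if self.dilution_factor < 1:
            raise ValidationError("dilution_factor must be >= 1")
        if self.area is not None and self.area <= 0:
            raise ValidationError("detected area must be positive")
        if self.rt is not None and self.rt <= 0:
            raise ValidationError("detected rt must be positive")
        if self.mz_observed <= 0:
            raise ValidationError("mz_observed must be positive")

    @property
    def detected(self) -> bool:
        return self.area is not None


@dataclass(frozen=True, slots=True)
class ResponseFactorRecord:
    """Calibration result for one (compound, condition).

    ``rf`` is the slope of the linear range of the calibration curve
    (peak area vs molar concentration), in M^-1; ``log_rf`` its base-10
    logarithm; ``mean_rt`` the mean retention time over detected dilutions.
    """

    compound_id: str
    condition: ConditionKey
    rf: float
    log_rf: float
    mean_rt: float
    n_points_used: int

    def __post_init__(self) -> None:
        if self.rf <= 0:
            raise ValidationError("response factor must be positive")
        if not math.isclose(self.log_rf, math.log10(self.rf), rel_tol=1e-9):
            raise ValidationError("log_rf must equal log10(rf)")
        if self.n_points_used < 3:
            raise ValidationError("calibration needs at least 3 points")


# ---------------------------------------------------------------------------
# Delimited-text I/O. One unambiguous dialect: comma-separated, UTF-8,
# "." decimal mark, empty cell = not detected.
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = (
    "compound_id",
    "mode",
    "ph",
    "dilution_factor",
    "area",
    "rt",
    "mz",
    "na_adduct",
)

RF_COLUMNS = (
    "compound_id",
    "mode",
    "ph",
    "rf",
    "log_rf",
    "mean_rt",
    "n_points_used",
)

_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n", ""}


def _parse_bool(cell: object) -> bool:
    s = str(cell).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE or s == "nan":
        return False
    raise FormatError(f"cannot parse boolean cell {cell!r}")


def _fmt(x: float | None) -> str:
    return "" if x is None else repr(float(x))


def read_feature_table(path: str | Path) -> list[PeakRecord]:
    """Read a feature-table CSV into :class:`PeakRecord` objects.

    Empty ``area``/``rt`` cells parse to not-detected. Raises
    :class:`FormatError` for a missing column and :class:`ValidationError`
    for a mode or pH outside the six valid conditions.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"feature table missing column(s): {', '.join(missing)}")
    records: list[PeakRecord] = []
    for row in df.itertuples(index=False):
        ph = float(row.ph)
        if ph not in VALID_PHS:
            raise ValidationError(f"pH {ph} not one of {VALID_PHS}")
        area = None if row.area.strip() == "" else float(row.area)
        rt = None if row.rt.strip() == "" else float(row.rt)
        records.append(
            PeakRecord(
                compound_id=str(row.compound_id),
                condition=ConditionKey(str(row.mode), ph),
                dilution_factor=float(row.dilution_factor),
                area=area,
                rt=rt,
                mz_observed=float(row.mz),
                na_adduct=_parse_bool(row.na_adduct),
            )
        )
    return records


def write_feature_table(records: Iterable[PeakRecord], path: str | Path) -> None:
    """Write records as CSV, sorted by (compound_id, condition, dilution)."""
    rows = sorted(
        records, key=lambda r: (r.compound_id, r.condition._sort_key, r.dilution_factor)
    )
    df = pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "mode": r.condition.mode,
                "ph": f"{r.condition.ph:g}",
                "dilution_factor": repr(float(r.dilution_factor)),
                "area": _fmt(r.area),
                "rt": _fmt(r.rt),
                "mz": repr(float(r.mz_observed)),
                "na_adduct": int(r.na_adduct),
            }
            for r in rows
        ],
        columns=list(FEATURE_COLUMNS),
    )
    df.to_csv(path, index=False)


def read_standards_table(path: str | Path) -> dict[tuple[str, float], float]:
    """Read a standards CSV (compound_id, dilution_factor, concentration_M)."""
    df = pd.read_csv(path)
    missing = [
        c for c in ("compound_id", "dilution_factor", "concentration_M")
        if c not in df.columns
    ]
    if missing:
        raise FormatError(f"standards table missing column(s): {', '.join(missing)}")
    out: dict[tuple[str, float], float] = {}
    for row in df.itertuples(index=False):
        out[(str(row.compound_id), float(row.dilution_factor))] = float(
            row.concentration_M
        )
    return out


def write_rf_table(records: Iterable[ResponseFactorRecord], path: str | Path) -> None:
    rows = sorted(records, key=lambda r: (r.compound_id, r.condition._sort_key))
    df = pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "mode": r.condition.mode,
                "ph": f"{r.condition.ph:g}",
                "rf": repr(float(r.rf)),
                "log_rf": repr(float(r.log_rf)),
                "mean_rt": repr(float(r.mean_rt)),
                "n_points_used": r.n_points_used,
            }
            for r in rows
        ],
        columns=list(RF_COLUMNS),
    )
    df.to_csv(path, index=False)


def read_rf_table(path: str | Path) -> list[ResponseFactorRecord]:
    df = pd.read_csv(path)
    missing = [c for c in RF_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"RF table missing column(s): {', '.join(missing)}")
    return [
        ResponseFactorRecord(
            compound_id=str(row.compound_id),
            condition=ConditionKey(str(row.mode), float(row.ph)),
            rf=float(row.rf),
            log_rf=float(row.log_rf),
            mean_rt=float(row.mean_rt),
            n_points_used=int(row.n_points_used),
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def merge_split_peaks(records: Iterable[PeakRecord]) -> list[PeakRecord]:
    """Collapse split chromatographic peaks.

    Within each (compound, condition, dilution) group the detected records
    are merged into one: areas are summed and the retention time is the
    arithmetic mean. Groups with a single detected record pass through
    unchanged; not-detected records are retained as-is. Idempotent, and
    conserves the total detected area of every group.
    """
    groups: dict[tuple, list[PeakRecord]] = defaultdict(list)
    passthrough: list[PeakRecord] = []
    for r in records:
        if r.detected:
            groups[(r.compound_id, r.condition, r.dilution_factor)].append(r)
        else:
            passthrough.append(r)
    merged: list[PeakRecord] = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(members[0])
            continue
        total_area = sum(m.area for m in members)  # type: ignore[misc]
        mean_rt = sum(m.rt for m in members) / len(members)  # type: ignore[misc]
        merged.append(
            replace(
                members[0],
                area=total_area,
                rt=mean_rt,
                na_adduct=any(m.na_adduct for m in members),
            )
        )
    return merged + passthrough


def mean_retention_time(records: Iterable[PeakRecord]) -> float:
    """Arithmetic mean retention time over detected dilutions.

    Raises :class:`UndefinedRetentionTimeError` when no record is detected.
    """
    rts = [r.rt for r in records if r.detected]
    if not rts:
        raise UndefinedRetentionTimeError("no detected record to average")
    return float(sum(rts) / len(rts))
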