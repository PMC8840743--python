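"""The 12 LC/MS descriptors used to predict electrospray response factors.

Per compound, in fixed order:

====================  =====================================================
``ratio_ph2_7``       log10(positive area / negative area) at pH 2.7
``ratio_ph8_0``       ... at pH 8.0
``ratio_ph10_0``      ... at pH 10.0
``rt_ph2_7``          retention time at pH 2.7 (min)
``rt_ph8_0``          retention time at pH 8.0 (min)
``rt_ph10_0``         retention time at pH 10.0 (min)
``d_rt_8_minus_2_7``  rt(pH 8.0) - rt(pH 2.7) (min)
``d_rt_8_minus_10``   rt(pH 8.0) - rt(pH 10.0) (min)
``mz``                m/z of the detected ion (Da)
``na_adduct``         1 if a sodium adduct was seen at pH 2.7
``detected_neg``      1 if detected in negative mode at any pH
``mz_parity``         nominal-mass parity of the ion (odd = 1)
====================  =====================================================

Missing values are encoded with sentinels far outside the continuous range,
so tree ensembles can branch on "not detected" directly: an area ratio is
-999 when the compound was not seen in positive mode at that pH and +999
when not seen in negative mode; missing retention times and retention-time
differences are -999.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, UndefinedRatioError, ValidationError
from .tables import (
    PROTON_MASS,
    VALID_PHS,
    ConditionKey,
    PeakRecord,
    mean_retention_time,
)

#: Sentinel magnitude for missing descriptor values.
SENTINEL = 999.0

DESCRIPTOR_NAMES = (
    "ratio_ph2_7",
    "ratio_ph8_0",
    "ratio_ph10_0",
    "rt_ph2_7",
    "rt_ph8_0",
    "rt_ph10_0",
    "d_rt_8_minus_2_7",
    "d_rt_8_minus_10",
    "mz",
    "na_adduct",
    "detected_neg",
    "mz_parity",
)


@dataclass(frozen=True, slots=True)
class DescriptorVector:
    """Ordered 12-descriptor vector for one compound."""

    ratio_ph2_7: float
    ratio_ph8_0: float
    ratio_ph10_0: float
    rt_ph2_7: float
    rt_ph8_0: float
    rt_ph10_0: float
    d_rt_8_minus_2_7: float
    d_rt_8_minus_10: float
    mz: float
    na_adduct: int
    detected_neg: int
    mz_parity: int

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in DESCRIPTOR_NAMES], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in DESCRIPTOR_NAMES}


assert tuple(f.name for f in fields(DescriptorVector)) == DESCRIPTOR_NAMES


def log_area_ratio(pos_area: float | None, neg_area: float | None) -> float:
    """log10(pos/neg), or the +-999 sentinel when one mode is undetected."""
    if pos_area is None and neg_area is None:
        raise UndefinedRatioError("compound undetected in both modes at this pH")
    if pos_area is None:
        return -SENTINEL
    if neg_area is None:
        return SENTINEL
    if pos_area <= 0 or neg_area <= 0:
        raise ValidationError("areas must be positive when present")
    return math.log10(pos_area / neg_area)


def rt_difference(rt_a: float | None, rt_b: float | None) -> float:
    """rt_a - rt_b in minutes, or -999 when either is missing."""
    if rt_a is None or rt_b is None:
        return -SENTINEL
    return rt_a - rt_b


def mz_parity(mz: float) -> int:
    """Parity of the nominal (integer) ion mass: odd -> 1, even -> 0.

    Nominal mass is the m/z rounded half away from zero.
    """
    if mz <= 0:
        raise ValidationError("m/z must be positive")
    nominal = int(math.floor(mz + 0.5))
    return nominal % 2


def _ratio_for_ph(
    pos: Mapping[float, float], neg: Mapping[float, float]
) -> float:
    """Per-pH area ratio, averaged per-dilution where both modes detected.

    ``pos``/``neg`` map dilution factor -> detected area at this pH. With no
    dilution detected in both modes the ratio falls back to the ratio of
    mean detected areas; with one mode entirely absent it is the +-999
    sentinel, and with both absent -999 (missing-value sentinel).
    """
    if not pos and not neg:
        return -SENTINEL
    if not pos:
        return -SENTINEL
    if not neg:
        return SENTINEL
    shared = sorted(set(pos) & set(neg))
    if shared:
        return float(np.mean([math.log10(pos[d] / neg[d]) for d in shared]))
    return math.log10(np.mean(list(pos.values())) / np.mean(list(neg.values())))


def build_descriptors(records: Iterable[PeakRecord]) -> DescriptorVector:
    """Descriptor vector for one compound from its processed peak records.

    Retention times are means over detected dilutions, taken from the
    positive-mode trace at each pH when available, else negative mode. The
    descriptor m/z is the positive-mode ion m/z when the compound ionizes
    in positive mode, else the negative-mode ion m/z + 2 proton masses.
    """
    records = list(records)
    detected = [r for r in records if r.detected]
    if not detected:
        raise UndefinedRatioError("compound not detected in any condition")
    ids = {r.compound_id for r in records}
    if len(ids) != 1:
        raise ValidationError(f"records span multiple compounds: {sorted(ids)}")

    by_cond: dict[ConditionKey, list[PeakRecord]] = {}
    for r in detected:
        by_cond.setdefault(r.condition, []).append(r)

    ratios: dict[float, float] = {}
    rts: dict[float, float] = {}
    for ph in VALID_PHS:
        pos = {
            r.dilution_factor: r.area
            for r in by_cond.get(ConditionKey("positive", ph), [])
        }
        neg = {
            r.dilution_factor: r.area
            for r in by_cond.get(ConditionKey("negative", ph), [])
        }
        ratios[ph] = _ratio_for_ph(pos, neg)
        for mode in ("positive", "negative"):
            recs = by_cond.get(ConditionKey(mode, ph))
            if recs:
                rts[ph] = mean_retention_time(recs)
                break
        else:
            rts[ph] = -SENTINEL

    def _rt_or_none(ph: float) -> float | None:
        return None if rts[ph] == -SENTINEL else rts[ph]

    pos_records = [r for r in detected if r.condition.mode == "positive"]
    if pos_records:
        ion_mz = float(np.mean([r.mz_observed for r in pos_records]))
    else:
        ion_mz = float(
            np.mean([r.mz_observed for r in detected]) + 2 * PROTON_MASS
        )

    return DescriptorVector(
        ratio_ph2_7=ratios[2.7],
        ratio_ph8_0=ratios[8.0],
        ratio_ph10_0=ratios[10.0],
        rt_ph2_7=rts[2.7],
        rt_ph8_0=rts[8.0],
        rt_ph10_0=rts[10.0],
        d_rt_8_minus_2_7=rt_difference(_rt_or_none(8.0), _rt_or_none(2.7)),
        d_rt_8_minus_10=rt_difference(_rt_or_none(8.0), _rt_or_none(10.0)),
        mz=ion_mz,
        na_adduct=int(
            any(r.na_adduct for r in detected if r.condition.ph == 2.7)
        ),
        detected_neg=int(any(r.condition.mode == "negative" for r in detected)),
        mz_parity=mz_parity(ion_mz),
    )


def build_descriptor_table(records: Iterable[PeakRecord]) -> pd.DataFrame:
    """One descriptor row per compound, indexed-free DataFrame.

    Columns: ``compound_id`` followed by the 12 descriptors in fixed order.
    Compounds with no detected record are omitted.
    """
    by_compound: dict[str, list[PeakRecord]] = {}
    for r in records:
        by_compound.setdefault(r.compound_id, []).append(r)
    rows = []
    for cid in sorted(by_compound):
        try:
            vec = build_descriptors(by_compound[cid])
        except UndefinedRatioError:
            continue
        rows.append({"compound_id": cid, **vec.as_dict()})
    return pd.DataFrame(rows, columns=["compound_id", *DESCRIPTOR_NAMES])


def write_descriptor_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_descriptor_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("compound_id", *DESCRIPTOR_NAMES) if c not in df.columns]
    if missing:
        raise FormatError(f"descriptor table missing column(s): {', '.join(missing)}")
    return df[["compound_id", *DESCRIPTOR_NAMES]]
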