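import pytest
from hypothesis import given
from hypothesis import strategies as st

from esiquant.errors import (
    FormatError,
    UndefinedRetentionTimeError,
    ValidationError,
)
from esiquant.tables import (
    ConditionKey,
    PeakRecord,
    all_conditions,
    mean_retention_time,
    merge_split_peaks,
    read_feature_table,
    write_feature_table,
)

POS27 = ConditionKey("positive", 2.7)


def _rec(cid="c1", cond=POS27, dil=1.0, area=1e6, rt=5.0, mz=200.0, na=False):
    return PeakRecord(cid, cond, dil, area, rt, mz, na)


class TestConditionKey:
    def test_exactly_six_conditions_positive_first_ascending_ph(self):
        conds = all_conditions()
        assert len(conds) == 6
        assert len(set(conds)) == 6
        assert list(conds) == sorted(conds)
        assert [c.mode for c in conds[:3]] == ["positive"] * 3
        assert [c.ph for c in conds[:3]] == [2.7, 8.0, 10.0]
        assert conds[0] < conds[3]  # positive sorts before negative

    @pytest.mark.parametrize("mode,ph", [("pos", 2.7), ("positive", 7.0)])
    def test_invalid_mode_or_ph_rejected(self, mode, ph):
        with pytest.raises(ValidationError):
            ConditionKey(mode, ph)


class TestPeakRecordValidation:
    def test_area_and_rt_must_be_absent_together(self):
        with pytest.raises(ValidationError):
            PeakRecord("c", POS27, 1.0, 1e6, None, 200.0)
        with pytest.raises(ValidationError):
            PeakRecord("c", POS27, 1.0, None, 5.0, 200.0)

    def test_dilution_below_one_rejected(self):
        with pytest.raises(ValidationError):
            _rec(dil=0.5)


class TestFeatureTableIO:
    def test_round_trip_identity(self, tmp_path):
        records = [
            _rec("a", POS27, 1.0, 1.5e6, 5.25, 195.0877, True),
            _rec("a", ConditionKey("negative", 8.0), 2.0, None, None, 193.07),
            _rec("b", POS27, 40.0, 123.456, 0.333, 65.0),
        ]
        path = tmp_path / "features.csv"
        write_feature_table(records, path)
        assert read_feature_table(path) == sorted(
            records,
            key=lambda r: (r.compound_id, r.condition._sort_key, r.dilution_factor),
        )

    def test_empty_area_and_rt_parse_as_not_detected(self, tmp_path):
        path = tmp_path / "f.csv"
        path.write_text(
            "compound_id,mode,ph,dilution_factor,area,rt,mz,na_adduct\n"
            "c1,positive,2.7,1,,,200.0,0\n"
        )
        (rec,) = read_feature_table(path)
        assert not rec.detected and rec.area is None and rec.rt is None

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "f.csv"
        path.write_text("compound_id,mode,ph,dilution_factor,area,rt,mz\nc,positive,2.7,1,,,1\n")
        with pytest.raises(FormatError, match="na_adduct"):
            read_feature_table(path)

    def test_ph_outside_methods_rejected(self, tmp_path):
        path = tmp_path / "f.csv"
        path.write_text(
            "compound_id,mode,ph,dilution_factor,area,rt,mz,na_adduct\n"
            "c1,positive,7.4,1,1e6,5.0,200.0,0\n"
        )
        with pytest.raises(ValidationError):
            read_feature_table(path)

    def test_empty_collection_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_feature_table([], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("compound_id,")
        assert read_feature_table(path) == []


class TestMergeSplitPeaks:
    def test_two_split_peaks_summed_and_rt_averaged(self):
        merged = merge_split_peaks(
            [_rec(area=1e6, rt=5.0), _rec(area=2e6, rt=5.2)]
        )
        assert len(merged) == 1
        assert merged[0].area == pytest.approx(3e6)
        assert merged[0].rt == pytest.approx(5.1)

    def test_three_way_split_uses_same_sum_mean_rule(self):
        merged = merge_split_peaks(
            [_rec(area=1e5, rt=4.0), _rec(area=2e5, rt=4.1), _rec(area=3e5, rt=4.2)]
        )
        assert merged[0].area == pytest.approx(6e5)
        assert merged[0].rt == pytest.approx(4.1)

    def test_single_record_passes_through(self):
        r = _rec()
        assert merge_split_peaks([r]) == [r]

    def test_not_detected_records_are_retained_not_merged(self):
        nd = _rec(area=None, rt=None)
        out = merge_split_peaks([nd, _rec(dil=2.0)])
        assert nd in out and len(out) == 2

    @given(
        areas=st.lists(st.floats(1.0, 1e9), min_size=1, max_size=6),
        rts=st.lists(st.floats(0.1, 20.0), min_size=6, max_size=6),
    )
    def test_idempotent_and_area_conserving(self, areas, rts):
        records = [
            _rec(area=a, rt=rts[i]) for i, a in enumerate(areas)
        ]
        once = merge_split_peaks(records)
        assert sum(r.area for r in once) == pytest.approx(sum(areas))
        assert merge_split_peaks(once) == once
        lo, hi = min(rts[: len(areas)]), max(rts[: len(areas)])
        assert lo - 1e-9 <= once[0].rt <= hi + 1e-9


class TestMeanRetentionTime:
    def test_mean_over_detected_dilutions_only(self):
        records = [
            _rec(dil=1, rt=5.0),
            _rec(dil=2, rt=5.2),
            _rec(dil=4, area=None, rt=None),
            _rec(dil=20, rt=5.1),
            _rec(dil=40, area=None, rt=None),
        ]
        assert mean_retention_time(records) == pytest.approx(5.1)

    def test_single_record_is_identity(self):
        assert mean_retention_time([_rec(rt=7.7)]) == pytest.approx(7.7)

    def test_no_detected_record_raises(self):
        with pytest.raises(UndefinedRetentionTimeError):
            mean_retention_time([_rec(area=None, rt=None)])
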