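"""Plant-record preprocessing: floors, ambiguity partitioning, transforms,
normalization, outlier flags and box aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syncom_screen.design import CommunitySet, DesignSpec
from syncom_screen.records import (
    AXENIC_INFECTED,
    PlantRecord,
    ScreenDataset,
    aggregate_by_box,
    apply_detection_floor,
    flag_outliers,
    floor_cfu_from_dilution,
    log10_transform,
    normalize_pathogen,
    partition_ambiguous,
    total_commensal,
)


def _record(pathogen=1e7, strains=None, flags=None, experiment="e1",
            box="b1", treatment="C1", plant="p1"):
    return PlantRecord(experiment, box, treatment, plant, pathogen,
                       dict(strains or {}), dict(flags or {}))


def _dataset(records, communities=None):
    return ScreenDataset(list(records), communities=communities)


class TestDetectionFloor:
    def test_floor_value_from_dilution(self):
        # nominal count 0.09 converted exactly like a real count
        assert floor_cfu_from_dilution(2.0e5) == pytest.approx(0.09 * 2.0e5)
        with pytest.raises(ValueError):
            floor_cfu_from_dilution(-1.0)

    def test_undetected_strains_floored_and_flagged(self):
        comm = CommunitySet((frozenset({"A", "B"}),), DesignSpec(2, 2, 1),
                            community_ids=("C1",))
        ds = _dataset([_record(strains={"A": 1e7}, flags={"A": "detected"})], comm)
        out = apply_detection_floor(ds, floor_cfu=10 ** 3.5)
        rec = out.records[0]
        assert rec.strain_cfu["B"] == pytest.approx(10 ** 3.5)
        assert rec.strain_flags["B"] == "below_detection"
        assert rec.strain_cfu["A"] == 1e7  # detected strain untouched

    def test_all_detected_identity(self):
        comm = CommunitySet((frozenset({"A", "B"}),), DesignSpec(2, 2, 1),
                            community_ids=("C1",))
        ds = _dataset([_record(strains={"A": 1e7, "B": 2e7},
                               flags={"A": "detected", "B": "detected"})], comm)
        out = apply_detection_floor(ds, floor_cfu=10 ** 3.5)
        assert out.records[0].strain_cfu == ds.records[0].strain_cfu


class TestPartitionAmbiguous:
    @pytest.mark.parametrize("pooled,members,expected_each", [
        (6.0e7, ["A", "B"], 3.0e7),
        (9.0e6, ["A", "B", "C"], 3.0e6),
    ])
    def test_equal_split(self, pooled, members, expected_each):
        rec = _record(strains={m: pooled for m in members},
                      flags={m: "ambiguous:g1" for m in members})
        out = partition_ambiguous(rec)
        for m in members:
            assert out.strain_cfu[m] == pytest.approx(expected_each)
            assert out.strain_flags[m] == "detected"

    @given(pooled=st.floats(1e3, 1e9), size=st.integers(2, 5),
           extra=st.floats(1e3, 1e8))
    @settings(max_examples=30, deadline=None)
    def test_total_commensal_conserved(self, pooled, size, extra):
        members = [f"M{i}" for i in range(size)]
        strains = {m: pooled for m in members}
        strains["X"] = extra
        flags = {m: "ambiguous:g1" for m in members}
        flags["X"] = "detected"
        rec = _record(strains=strains, flags=flags)
        before = total_commensal(rec)
        after = total_commensal(partition_ambiguous(rec))
        assert after == pytest.approx(before, rel=1e-12)
        assert before == pytest.approx(pooled + extra, rel=1e-12)

    def test_singleton_group_rejected(self):
        rec = _record(strains={"A": 1e6}, flags={"A": "ambiguous:g1"})
        with pytest.raises(ValueError):
            partition_ambiguous(rec)


class TestTotalCommensal:
    def test_sum_with_floors(self):
        floor = 10 ** 3.5
        rec = _record(strains={"A": 1e7, "B": 1e7, "C": 2e7, "D": floor, "E": floor},
                      flags={s: "detected" for s in "ABC"} |
                            {s: "below_detection" for s in "DE"})
        assert total_commensal(rec) == pytest.approx(4e7 + 2 * floor)

    def test_axenic_is_none(self):
        assert total_commensal(_record(strains={})) is None


class TestLog10Transform:
    def test_values_and_guard(self):
        ds = _dataset([_record(pathogen=1e6, strains={"A": 1.0},
                               flags={"A": "detected"})])
        out = log10_transform(ds)
        assert out.records[0].pathogen_cfu == pytest.approx(6.0)
        assert out.records[0].strain_cfu["A"] == pytest.approx(0.0)
        with pytest.raises(ValueError):
            log10_transform(out)  # scale marker blocks double transform

    @pytest.mark.parametrize("x", [3.5, 4.0, 9.0])
    def test_round_trip(self, x):
        ds = _dataset([_record(pathogen=10 ** x)])
        assert log10_transform(ds).records[0].pathogen_cfu == pytest.approx(x)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log10_transform(_dataset([_record(pathogen=0.0)]))


class TestNormalizePathogen:
    def _screen(self, sample_value, axenic_values, experiment="e1"):
        recs = [_record(pathogen=sample_value, treatment="C1", box="b1",
                        plant="s1", experiment=experiment)]
        for i, v in enumerate(axenic_values):
            recs.append(_record(pathogen=v, treatment=AXENIC_INFECTED,
                                box=f"ax{i}", plant=f"a{i}", experiment=experiment))
        ds = _dataset(recs)
        ds.scale = "log10"
        return ds

    def test_median_centering(self):
        ds = self._screen(5.0, [7.5, 8.0, 9.5])
        out = normalize_pathogen(ds, center="median")
        assert out.records[0].pathogen_cfu == pytest.approx(5.0 - 8.0)

    def test_control_at_median_maps_to_zero(self):
        ds = self._screen(5.0, [7.5, 8.0, 9.5])
        out = normalize_pathogen(ds, center="median")
        assert out.records[2].pathogen_cfu == pytest.approx(0.0)

    def test_mean_vs_median_differ_by_skew(self):
        ax = [7.0, 7.0, 10.0]
        d_med = normalize_pathogen(self._screen(5.0, ax), center="median")
        d_mean = normalize_pathogen(self._screen(5.0, ax), center="mean")
        skew = np.mean(ax) - np.median(ax)
        assert (d_med.records[0].pathogen_cfu - d_mean.records[0].pathogen_cfu
                ) == pytest.approx(skew)

    def test_translation_equivariance(self):
        a = self._screen(5.0, [7.5, 8.0, 9.5])
        b = self._screen(5.0 + 2.0, [v + 2.0 for v in [7.5, 8.0, 9.5]])
        na = normalize_pathogen(a)
        nb = normalize_pathogen(b)
        assert na.records[0].pathogen_cfu == pytest.approx(nb.records[0].pathogen_cfu)

    def test_missing_controls_rejected(self):
        ds = _dataset([_record()])
        ds.scale = "log10"
        with pytest.raises(ValueError):
            normalize_pathogen(ds)


class TestOutlierFlags:
    def _group(self, values):
        ds = _dataset([_record(pathogen=v, plant=f"p{i}")
                       for i, v in enumerate(values)])
        ds.scale = "log10"
        return flag_outliers(ds)

    def test_far_point_flagged(self):
        out = self._group([1, 2, 3, 100])
        flags = [r.outlier for r in out.records]
        assert flags == [False, False, False, True]

    def test_tight_group_clean(self):
        out = self._group([5.0, 5.1, 5.2, 5.3])
        assert not any(r.outlier for r in out.records)

    def test_boundary_value_kept_closed_interval(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        hi = q3 + 1.5 * (q3 - q1)
        out = self._group(vals + [hi])
        assert not out.records[-1].outlier

    def test_invariant_to_order(self):
        a = self._group([1, 2, 3, 100])
        b = self._group([100, 3, 2, 1])
        assert sorted(r.pathogen_cfu for r in a.records if r.outlier) == \
               sorted(r.pathogen_cfu for r in b.records if r.outlier)


class TestAggregateByBox:
    def _box(self, values):
        ds = _dataset([_record(pathogen=v, plant=f"p{i}")
                       for i, v in enumerate(values)])
        ds.scale = "log10"
        return aggregate_by_box(ds)

    @pytest.mark.parametrize("values,expected", [
        ([5, 6, 7, 8], 6.5),
        ([4.2], 4.2),
    ])
    def test_median(self, values, expected):
        agg = self._box(values)
        assert agg.table["pathogen_median"].item() == pytest.approx(expected)
        assert agg.table["n_plants"].item() == len(values)

    def test_sort_and_middle_oracle(self):
        rng = np.random.default_rng(0)
        vals = list(rng.normal(6, 1, 7))
        agg = self._box(vals)
        mid = sorted(vals)[3]
        assert agg.table["pathogen_median"].item() == pytest.approx(mid)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_by_box(_dataset([]))
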