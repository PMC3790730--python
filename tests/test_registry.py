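"""Registry parsing, encoding and the data-editing rules."""

import numpy as np
import pandas as pd
import pytest

from dogblup import (EditConfig, apply_elbow_edits, apply_hip_edits,
                     dichotomize, parse_registry, transform_elbow)
from dogblup.registry import AGE_GROUP_LABELS, assign_age_group

from conftest import make_records_frame

EC = EditConfig(min_breed_records=1)


def _write_registry(tmp_path, rows, header=None):
    header = header or ("dog_id,breed,sex,birth_date,sire_id,dam_id,"
                        "trait,score,test_date")
    path = tmp_path / "reg.csv"
    path.write_text("\n".join([header] + rows) + "\n")
    return path


class TestParsing:
    def test_textual_grades_are_encoded(self, tmp_path):
        path = _write_registry(tmp_path, [
            "d1,Lab,F,1990-01,,,hip,excellent,1992-03",
            "d2,Lab,M,1990-01,,,hip,severe,1992-03",
            "d3,Lab,F,1990-01,,,elbow,Normal,1992-03",
            "d4,Lab,M,1990-01,,,elbow,DJD III,1992-03",
            "d5,Lab,M,1990-01,,,hip,3,1992-03",
        ])
        recs = parse_registry(path)
        scores = {r.dog_id: r.score for r in recs}
        assert scores == {"d1": 1, "d2": 7, "d3": 1, "d4": 4, "d5": 3}
        assert recs[0].sex == "female"

    def test_malformed_rows_skipped_with_warning(self, tmp_path, caplog):
        path = _write_registry(tmp_path, [
            "d1,Lab,F,1990-01,,,hip,good,1992-03",
            "d2,Lab,F,1990-13,,,hip,good,1992-03",      # bad month
            "d3,Lab,F,1990-01,,,hip,splendid,1992-03",  # unknown grade
            "d4,Lab,F,1990-01,,,hip,9,1992-03",         # out of range
            "d5,Lab,X,1990-01,,,hip,good,1992-03",      # bad sex
            "d6,Lab,F,1995-01,,,hip,good,1992-03",      # test before birth
        ])
        with caplog.at_level("WARNING"):
            recs = parse_registry(path)
        assert [r.dog_id for r in recs] == ["d1"]
        assert "malformed" in caplog.text

    def test_missing_column_is_hard_failure(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("dog_id,breed,sex\nd1,Lab,F\n")
        with pytest.raises(ValueError, match="trait"):
            parse_registry(path)

    def test_empty_file_returns_empty_list(self, tmp_path, caplog):
        path = _write_registry(tmp_path, [])
        with caplog.at_level("WARNING"):
            assert parse_registry(path) == []
        assert "no records" in caplog.text


class TestHipEdits:
    def _base_row(self, dog, **kw):
        row = dict(dog_id=dog, breed="Lab", sex="female", birth_year=1990,
                   birth_month=1, test_year=1992, test_month=6, trait="hip",
                   score=2)
        row.update(kw)
        return tuple(row.values())

    def test_hand_traced_toy_filtering(self):
        # 6 rows: one duplicated, one scored at 70 months, one born 1969,
        # three valid -> 3 dogs retained
        frame = make_records_frame([
            self._base_row("a"),
            self._base_row("a"),                                # duplicate
            self._base_row("b", test_year=1995, test_month=11),  # 70 months
            self._base_row("c", birth_year=1969, test_year=1971),
            self._base_row("d"),
            self._base_row("e", score=5),
        ])
        ds = apply_hip_edits(frame, EC)
        assert sorted(ds.data["dog_id"]) == ["a", "d", "e"]
        assert ds.audit["duplicate_rows"] == 1
        assert ds.audit["age_outside_window"] == 1
        assert ds.audit["birth_year_outside_window"] == 1

    def test_age_window_boundaries_inclusive(self):
        frame = make_records_frame([
            self._base_row("young", test_year=1991, test_month=12),  # 23 mo
            self._base_row("lo", test_year=1992, test_month=1),      # 24 mo
            self._base_row("hi", test_year=1995, test_month=1),      # 60 mo
        ])
        kept = apply_hip_edits(frame, EC).data
        assert sorted(kept["dog_id"]) == ["hi", "lo"]
        assert kept.set_index("dog_id")["age_group"].to_dict() == {
            "lo": AGE_GROUP_LABELS[0], "hi": AGE_GROUP_LABELS[3]}

    def test_last_record_retained(self):
        frame = make_records_frame([
            self._base_row("a", birth_year=1996, test_year=1998, score=2),
            self._base_row("a", birth_year=1996, test_year=2000, score=5),
        ])
        ds = apply_hip_edits(frame, EC)
        assert ds.data["score"].tolist() == [5]
        assert ds.audit["earlier_record_superseded"] == 1

    def test_test_date_tie_keeps_last_in_file_order(self):
        frame = make_records_frame([
            self._base_row("a", score=2),
            self._base_row("a", score=3),
        ])
        assert apply_hip_edits(frame, EC).data["score"].tolist() == [3]

    def test_excluded_and_low_count_breeds_dropped(self):
        rows = [self._base_row(f"lab{i}") for i in range(5)]
        rows += [self._base_row("h1", breed="Havanese")]
        rows += [self._base_row("rare", breed="Boykin Spaniel")]
        cfg = EditConfig(min_breed_records=2)
        ds = apply_hip_edits(make_records_frame(rows), cfg)
        assert set(ds.data["breed"]) == {"Lab"}
        assert ds.audit["breed_excluded_or_low_count"] == 2

    def test_idempotence(self):
        frame = make_records_frame([
            self._base_row("a"), self._base_row("a", test_year=1993),
            self._base_row("b", score=6), self._base_row("c"),
        ])
        once = apply_hip_edits(frame, EC).data
        twice = apply_hip_edits(once, EC).data
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True))

    def test_audit_counts_sum_to_removals(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(200):
            rows.append(self._base_row(
                f"d{rng.integers(0, 120)}",
                birth_year=int(rng.integers(1965, 2010)),
                test_year=int(rng.integers(1970, 2012)),
                test_month=int(rng.integers(1, 13)),
                trait=rng.choice(["hip", "elbow"]),
                score=int(rng.integers(1, 5))))
        frame = make_records_frame(rows)
        # drop rows whose test precedes birth (invalid by construction)
        frame = frame[(frame.test_year * 12 + frame.test_month)
                      >= (frame.birth_year * 12 + frame.birth_month)]
        ds = apply_hip_edits(frame, EC)
        assert sum(ds.audit.values()) == len(frame) - ds.n_records


class TestElbowEdits:
    def _row(self, dog, score, breed="Rott", by=1990, ty=1992):
        return (dog, breed, "male", by, 1, ty, 6, "elbow", score)

    def test_breed_with_few_dysplastic_dogs_removed(self):
        rows = [self._row(f"a{i}", 2) for i in range(9)]       # 9 ED dogs
        rows += [self._row(f"b{i}", 1) for i in range(20)]
        rows += [self._row(f"c{i}", 2, breed="GSD") for i in range(10)]
        rows += [self._row(f"d{i}", 1, breed="GSD") for i in range(10)]
        ds = apply_elbow_edits(make_records_frame(rows), EC)
        assert set(ds.data["breed"]) == {"GSD"}

    def test_breed_without_score_variation_removed(self):
        rows = [self._row(f"a{i}", 1) for i in range(30)]
        rows += [self._row(f"c{i}", 2, breed="GSD") for i in range(10)]
        rows += [self._row(f"d{i}", 1, breed="GSD") for i in range(10)]
        ds = apply_elbow_edits(make_records_frame(rows), EC)
        assert set(ds.data["breed"]) == {"GSD"}

    def test_birth_years_before_floor_grouped_into_1988(self):
        rows = [self._row(f"c{i}", 2, breed="GSD") for i in range(10)]
        rows += [self._row(f"d{i}", 1, breed="GSD") for i in range(10)]
        rows += [self._row("old", 2, breed="GSD", by=1985, ty=1987)]
        ds = apply_elbow_edits(make_records_frame(rows), EC)
        assert ds.data.set_index("dog_id").loc["old", "birth_year"] == 1988


class TestTransforms:
    @pytest.mark.parametrize("kind,expected", [
        ("identity", [1.0, 4.0]),
        ("log", [0.0, np.log(4.0)]),
        ("sqrt", [1.0, 2.0]),
        ("reciprocal", [1.0, 0.25]),
    ])
    def test_unit_and_square_values(self, kind, expected):
        np.testing.assert_allclose(transform_elbow([1, 4], kind), expected)

    def test_reciprocal_reverses_ordering(self):
        scores = np.array([1, 2, 3, 4])
        out = transform_elbow(scores, "reciprocal")
        assert np.all(np.diff(out) < 0)
        # hence any covariance with an untransformed trait flips sign
        other = scores + np.array([0.1, -0.2, 0.3, 0.0])
        assert np.sign(np.cov(scores, other)[0, 1]) == \
            -np.sign(np.cov(out, other)[0, 1])

    def test_unknown_kind_and_nonpositive_scores_fail(self):
        with pytest.raises(ValueError):
            transform_elbow([1, 2], "boxcox")
        with pytest.raises(ValueError):
            transform_elbow([0, 1], "log")


class TestDichotomize:
    def _dataset(self, scores, trait="hip"):
        frame = make_records_frame([
            (f"d{i}", "Lab", "male", 1990, 1, 1992, 6, trait, s)
            for i, s in enumerate(scores)])
        edit = (apply_hip_edits if trait == "hip" else apply_elbow_edits)
        return edit(frame, EC)

    def test_all_normal_scores_give_zero_incidence(self):
        assert dichotomize(self._dataset([1, 1, 1])).proportion == 0.0

    def test_mild_and_worse_are_dysplastic(self):
        inc = dichotomize(self._dataset([1, 2, 5]))
        assert inc.n_dysplastic == 1 and inc.proportion == pytest.approx(1 / 3)

    def test_borderline_counts_in_neither_class(self):
        inc = dichotomize(self._dataset([4, 4, 5, 1]))
        assert inc.n_dysplastic == 1 and inc.n_total == 4

    def test_elbow_grades_two_and_up_are_dysplastic(self):
        rows = [(f"d{i}", "GSD", "male", 1990, 1, 1992, 6, "elbow", s)
                for i, s in enumerate([1] * 10 + [2] * 6 + [3] * 3 + [4])]
        ds = apply_elbow_edits(make_records_frame(rows), EC)
        assert dichotomize(ds).proportion == pytest.approx(0.5)

    def test_empty_dataset_is_signalled(self):
        ds = self._dataset([1])
        ds.data = ds.data.iloc[:0]
        with pytest.raises(ValueError, match="empty"):
            dichotomize(ds)


def test_age_group_bin_edges():
    groups = assign_age_group(np.array([24, 25, 29, 30, 36, 37, 60]))
    assert list(groups) == ["24", "25-29", "25-29", "30-36", "30-36",
                            "37-60", "37-60"]
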