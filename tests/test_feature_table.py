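"""Orchestration, table I/O, modal grade, and inter-rater agreement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import blastoquant as bq
from blastoquant import (
    FEATURE_NAMES,
    ExtractionError,
    GradeRecord,
    InputError,
    TableError,
    extract_all,
    fleiss_kappa,
    light_kappa,
    modal_grade,
    read_deposited_table,
    read_table,
    write_table,
)
from blastoquant.feature_table import grade_report


@pytest.fixture(scope="module")
def phantom_vector(inclusion_phantom):
    return extract_all(inclusion_phantom["image"], image_id="blq_test")


class TestExtractAll:
    def test_exactly_36_named_variables(self, phantom_vector):
        assert tuple(phantom_vector.values.keys()) == FEATURE_NAMES
        assert len(phantom_vector.values) == 36
        arr = phantom_vector.as_array()
        assert arr.shape == (36,)

    def test_counts_are_nonnegative_integers(self, phantom_vector):
        for k in ("DC1", "LC1", "DC2", "LC2", "WSN"):
            v = phantom_vector.values[k]
            assert v == int(v) and v >= 0

    def test_deterministic(self, inclusion_phantom, phantom_vector):
        again = extract_all(inclusion_phantom["image"], image_id="blq_test")
        a, b = phantom_vector.as_array(), again.as_array()
        np.testing.assert_array_equal(a, b)

    def test_blank_image_is_structured_failure(self):
        blank = np.full((480, 640), 200, dtype=np.uint8)
        with pytest.raises(ExtractionError) as err:
            extract_all(blank, image_id="blank")
        assert err.value.stage == "segment"
        assert err.value.image_id == "blank"


class TestTableIO:
    def test_csv_round_trip(self, tmp_path, phantom_vector):
        grades = {"blq_test": GradeRecord("blq_test", 1, 1, 2)}
        path = tmp_path / "features.csv"
        write_table([phantom_vector], path, grades)
        frame = read_table(path)
        assert len(frame) == 1
        for name in FEATURE_NAMES:
            want = phantom_vector.values[name]
            got = frame[name].iloc[0]
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-9)
        assert frame["Mode"].iloc[0] == 1

    def test_rows_without_grades_leave_cells_empty(self, tmp_path, phantom_vector):
        path = tmp_path / "nograde.csv"
        write_table([phantom_vector], path)
        raw = path.read_text().splitlines()
        frame = read_table(path)
        assert frame["Grade 1"].isna().all()
        assert len(raw) == 2  # header + one row

    def test_xlsx_round_trip(self, tmp_path, phantom_vector):
        path = tmp_path / "features.xlsx"
        write_table([phantom_vector], path)
        frame = read_table(path)
        assert frame["Radius ER"].iloc[0] == phantom_vector.values["Radius ER"]

    def test_empty_rows_rejected(self, tmp_path):
        with pytest.raises(InputError):
            write_table([], tmp_path / "x.csv")

    def test_deposited_layout_reader(self, tmp_path, rng):
        # synthetic stand-in table mimicking the deposited column layout:
        # 3 id columns, 36 variables (D..AM), 3 grades (AN..AP), mode (AQ)
        n = 6
        cols = {"id": [f"blq {i+1}" for i in range(n)], "b": 0, "c": 0}
        for k, name in enumerate(FEATURE_NAMES):
            cols[f"v{k}"] = rng.random(n)
        g = rng.integers(1, 4, (n, 3))
        for j in range(3):
            cols[f"g{j}"] = g[:, j]
        cols["mode"] = [modal_grade(*row) for row in g]
        path = tmp_path / "synthetic_deposited.xlsx"
        pd.DataFrame(cols).to_excel(path, index=False)
        frame = read_deposited_table(path)
        assert list(frame["image_id"]) == cols["id"]
        assert frame["Contrast RR"].iloc[0] == pytest.approx(cols["v0"][0])
        assert frame["Mean ICM"].iloc[2] == pytest.approx(cols["v35"][2])
        assert (frame["Mode"] == cols["mode"]).all()


class TestModalGrade:
    @pytest.mark.parametrize("grades,expect", [
        ((1, 1, 2), 1), ((3, 3, 3), 3), ((1, 2, 3), 2),
        ((2, 3, 3), 3), ((1, 3, 1), 1),
    ])
    def test_examples(self, grades, expect):
        assert modal_grade(*grades) == expect

    def test_invalid_grade_rejected(self):
        with pytest.raises(InputError):
            modal_grade(1, 2, 4)

    @given(
        grades=st.tuples(*[st.integers(1, 3)] * 3),
        perm=st.permutations([0, 1, 2]),
    )
    @settings(deadline=None, derandomize=True)
    def test_permutation_invariant_and_equals_median(self, grades, perm):
        shuffled = tuple(grades[i] for i in perm)
        assert modal_grade(*shuffled) == modal_grade(*grades) == sorted(grades)[1]


class TestKappa:
    def test_perfect_agreement(self, rng):
        g = np.tile(rng.integers(1, 4, (60, 1)), (1, 3))
        assert fleiss_kappa(g) == pytest.approx(1.0)
        assert light_kappa(g) == pytest.approx(1.0)

    def test_random_grades_near_zero(self):
        rng = np.random.default_rng(7)
        g = rng.integers(1, 4, (10_000, 3))
        assert abs(fleiss_kappa(g)) < 0.03
        assert abs(light_kappa(g)) < 0.03

    def test_unanimous_single_category_undefined(self):
        assert np.isnan(fleiss_kappa(np.ones((5, 3), dtype=int)))

    def test_category_relabeling_invariance(self, rng):
        g = rng.integers(1, 4, (500, 3))
        relabeled = np.vectorize({1: 2, 2: 3, 3: 1}.get)(g)
        assert fleiss_kappa(relabeled) == pytest.approx(fleiss_kappa(g), abs=1e-12)
        assert light_kappa(relabeled) == pytest.approx(light_kappa(g), abs=1e-12)

    def test_rater_permutation_invariance(self, rng):
        g = rng.integers(1, 4, (300, 3))
        assert fleiss_kappa(g[:, [2, 0, 1]]) == pytest.approx(fleiss_kappa(g), abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(InputError):
            fleiss_kappa(np.array([[1, 2, 5]]))
        with pytest.raises(InputError):
            fleiss_kappa(np.array([[1, 2, 3]]))  # fewer than 2 items


def test_grade_report_counts_and_kappa(rng):
    g = rng.integers(1, 4, (200, 3))
    frame = pd.DataFrame(g, columns=["Grade 1", "Grade 2", "Grade 3"])
    report = grade_report(frame)
    assert report["n"] == 200
    modes = np.array([modal_grade(*row) for row in g])
    assert report["modal_counts"] == {k: int((modes == k).sum()) for k in (1, 2, 3)}
    assert report["fleiss_kappa"] == pytest.approx(fleiss_kappa(g))
    bad = pd.DataFrame([[1, 2, 4]], columns=["Grade 1", "Grade 2", "Grade 3"])
    with pytest.raises(TableError):
        grade_report(pd.concat([bad] * 3))
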