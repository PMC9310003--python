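"""Target properties A/R/P, standardization, ranking, histograms, orientation maps."""

import numpy as np
import pytest

from molvib import (
    EulerOrientation,
    FieldSetup,
    NormalMode,
    ScreeningQuery,
    histogram,
    orientation_map,
    rank_database,
    standardize,
    target_value,
)
from molvib.intensities import ir_intensity, mode_intensity
from molvib.orientation import rotate_mode, rotate_record
from molvib.screening import axis_rotation
from molvib.synthgen import SynthSpec, generate, with_dominant_record
from molvib.vibrecord import MoleculeRecord, VibDatabase

from conftest import random_rotations


def query(target="A", window=(100.0, 3600.0), fields=None, **kw):
    return ScreeningQuery(
        target=target,
        window=window,
        fields=fields or FieldSetup.from_axes(),
        **kw,
    )


def two_mode_record():
    return MoleculeRecord(
        id="two",
        smiles="S[Au]",
        elements=["Au", "S"],
        coordinates=[[0, 0, 0], [0, 0, 2.35]],
        modes=[
            NormalMode(0, 800.0, [0, 0, 0.2], np.diag([1.0, 2.0, 3.0])),
            NormalMode(1, 1600.0, [0.1, 0.1, 0.0], np.diag([2.0, -1.0, 0.5])),
        ],
    )


class TestTargetValue:
    def test_empty_window_is_zero(self):
        assert target_value(two_mode_record(), query(window=(4000.0, 5000.0))) == 0.0

    def test_single_mode_window(self, fields):
        rec = two_mode_record()
        q = query(window=(700.0, 900.0), averaged=False)
        assert target_value(rec, q) == pytest.approx(
            ir_intensity(rec.modes[0], q.fields.e_ir), rel=1e-12
        )

    def test_additive_over_modes(self):
        rec = two_mode_record()
        whole = target_value(rec, query(target="P"))
        first = target_value(rec, query(target="P", window=(100.0, 1000.0)))
        second = target_value(rec, query(target="P", window=(1000.0, 3600.0)))
        assert whole == pytest.approx(first + second, rel=1e-12)

    def test_boundary_ties_included(self):
        rec = two_mode_record()
        assert target_value(rec, query(window=(800.0, 900.0))) > 0.0

    def test_scaling_applied_before_masking(self):
        rec = two_mode_record()  # modes at 800 and 1600
        q = query(window=(750.0, 790.0), scaling=0.97)  # 800·0.97 = 776
        assert target_value(rec, q) > 0.0
        assert target_value(rec, query(window=(750.0, 790.0))) == 0.0

    def test_empty_record_is_zero(self):
        rec = MoleculeRecord("e", "S[Au]", ["Au", "S"],
                             [[0, 0, 0], [0, 0, 2.35]], modes=[])
        assert target_value(rec, query()) == 0.0

    def test_averaged_invariant_under_record_rotation(self, synth_db):
        q = query(target="P")
        for rec in synth_db.records[:3]:
            base = target_value(rec, q)
            for r in random_rotations(5, seed=4):
                assert target_value(rotate_record(rec, r), q) == pytest.approx(
                    base, rel=1e-10
                )


class TestStandardize:
    def test_all_equal_gives_zero_scores(self):
        np.testing.assert_array_equal(standardize([5.0, 5.0, 5.0]), np.zeros(3))

    def test_zero_values_give_zero_scores(self):
        np.testing.assert_array_equal(standardize([0.0, 0.0]), np.zeros(2))

    def test_zscore_moments(self):
        scores = standardize([1.0, 10.0, 100.0, 1000.0])
        assert scores.mean() == pytest.approx(0.0, abs=1e-12)
        assert scores.std() == pytest.approx(1.0, rel=1e-12)

    def test_order_preserved(self, rng):
        values = 10.0 ** rng.uniform(-5, 3, size=50)
        scores = standardize(values)
        np.testing.assert_array_equal(np.argsort(values), np.argsort(scores))


class TestRankDatabase:
    @pytest.mark.parametrize("target", ["A", "R", "P"])
    @pytest.mark.parametrize("averaged", [True, False])
    def test_constructed_dominant_record_ranks_first(self, target, averaged):
        db = with_dominant_record(
            generate(SynthSpec(n_molecules=12, seed=7)), 10.0, "zz-dominant"
        )
        q = query(
            target=target,
            averaged=averaged,
            orientation=EulerOrientation(0.4, 1.1, -0.3),
        )
        table = rank_database(db, q)
        assert table.frame.iloc[0]["id"] == "zz-dominant"
        assert table.frame.iloc[0]["rank"] == 1

    def test_empty_database(self):
        table = rank_database(VibDatabase(records=[], label=""), query())
        assert len(table.frame) == 0

    def test_input_order_invariance(self):
        db = generate(SynthSpec(n_molecules=6, seed=3))
        rev = VibDatabase(records=list(reversed(db.records)), label=db.label)
        q = query(target="R")
        a = rank_database(db, q).frame
        b = rank_database(rev, q).frame
        assert list(a["id"]) == list(b["id"])
        np.testing.assert_allclose(a["value"], b["value"], rtol=1e-14)

    def test_ranks_are_permutation(self):
        db = generate(SynthSpec(n_molecules=9, seed=5))
        table = rank_database(db, query(target="P")).frame
        assert sorted(table["rank"]) == list(range(1, 10))
        assert list(table["value"]) == sorted(table["value"], reverse=True)

    def test_score_rank_matches_value_rank(self):
        db = generate(SynthSpec(n_molecules=10, seed=13))
        table = rank_database(db, query(target="R")).frame
        assert list(table["score"]) == sorted(table["score"], reverse=True)


class TestHistogram:
    def test_empty_input(self):
        edges, counts = histogram([], 5)
        assert counts.sum() == 0 and len(counts) == 5 and len(edges) == 6

    def test_identical_values_in_one_bin(self):
        edges, counts = histogram([2.0, 2.0, 2.0], 4)
        assert counts.sum() == 3 and counts.max() == 3

    def test_counts_conserved_on_synthetic_db(self, synth_db):
        table = rank_database(synth_db, query(target="A")).frame
        edges, counts = histogram(table["value"].to_numpy(), 6)
        assert counts.sum() == len(synth_db)

    def test_log_spacing_for_positive_values(self):
        edges, _ = histogram([1.0, 10.0, 100.0], 2)
        assert edges[1] == pytest.approx(10.0)  # geometric midpoint


class TestOrientationMap:
    def test_angle_zero_is_unrotated_intensity(self, fields):
        m = NormalMode(0, 1000.0, [0.3, 0.1, 0.5], np.diag([1.0, 2.0, 3.0]))
        rows = orientation_map(m, "z", fields, "ir", n_angles=8)
        assert rows[0, 0] == 0.0
        assert rows[0, 1] == pytest.approx(ir_intensity(m, fields.e_ir), rel=1e-12)

    def test_ir_traces_cos_squared_with_period_pi(self):
        # dipole and IR field both perpendicular to the rotation axis
        m = NormalMode(0, 1000.0, [1.0, 0.0, 0.0], np.eye(3))
        f = FieldSetup.from_axes("x", "z", "z")
        rows = orientation_map(m, "z", f, "ir", n_angles=36)
        expected = np.cos(rows[:, 0]) ** 2 * ir_intensity(m, "x")
        np.testing.assert_allclose(rows[:, 1], expected, atol=1e-8)
        # period π
        np.testing.assert_allclose(rows[:18, 1], rows[18:, 1], atol=1e-8)

    def test_circle_mean_matches_quadrature(self, fields, rng):
        from conftest import random_mode

        m = random_mode(rng)
        rows = orientation_map(m, "y", fields, "sfg", n_angles=64)
        # independent dense-rectangle oracle over the same circle
        dense = np.array(
            [
                mode_intensity(rotate_mode(m, axis_rotation("y", a)), fields, "sfg")
                for a in np.linspace(0, 2 * np.pi, 4097)[:-1]
            ]
        )
        assert rows[:, 1].mean() >= 0.0
        assert rows[:, 1].mean() == pytest.approx(dense.mean(), rel=1e-10)

    def test_minimum_angles_enforced(self, fields):
        m = NormalMode(0, 1000.0, [0, 0, 0.1], np.eye(3))
        with pytest.raises(ValueError):
            orientation_map(m, "z", fields, "ir", n_angles=3)
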