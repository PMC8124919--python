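"""Metric definitions against independent oracles; scenario plumbing."""

import numpy as np
import pytest

from kicksense.evaluation import (
    ClassCounts,
    GroundTruthOracle,
    counts_from_predictions,
    f1_class,
    f1_weighted,
    fine_grained_confusion,
    run_segmented_scenario,
    run_window_scenario,
    sensitivity_class,
)
from kicksense.synth import SynthConfig, generate_session
from kicksense.datasets import scaled


def _oracle_f1(tp, fp, fn):
    """Independent brute-force F1: harmonic mean of precision and recall."""
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return 2 * p * r / (p + r) if p + r else 0.0


def _oracle_weighted(counts):
    num = sum((tp + fn) * _oracle_f1(tp, fp, fn) for tp, fp, fn in counts)
    den = sum(tp + fn for tp, _, fn in counts)
    return num / den


class TestF1:
    def test_matches_brute_force_oracle_on_random_contingencies(self, rng):
        for _ in range(100):
            counts = [tuple(int(v) for v in rng.integers(0, 40, 3))
                      for _ in range(3)]
            if sum(tp + fn for tp, _, fn in counts) == 0:
                continue
            d = {
                c: ClassCounts(tp=tp, fp=fp, fn=fn)
                for c, (tp, fp, fn) in zip(("shot", "pass", "null"), counts)
            }
            assert abs(f1_weighted(d) - _oracle_weighted(counts)) < 1e-12

    def test_perfect_predictions_score_one(self):
        y = ["shot", "pass", "null", "null", "pass"]
        assert f1_weighted(counts_from_predictions(y, y)) == pytest.approx(1.0)

    def test_zero_precision_and_recall_is_zero_not_nan(self):
        assert f1_class(ClassCounts(tp=0, fn=5, fp=3)) == 0.0

    def test_three_class_toy_example(self):
        """Supports (10, 20, 70) with (P, R) = (1, .5), (.5, 1), (.9, .9);
        expected value evaluated directly from the defining formulas."""
        d = {
            "shot": ClassCounts(tp=5, fn=5, fp=0),    # P=1.0, R=0.5
            "pass": ClassCounts(tp=20, fn=0, fp=20),  # P=0.5, R=1.0
            "null": ClassCounts(tp=63, fn=7, fp=7),   # P=0.9, R=0.9
        }
        f1s = {"shot": _oracle_f1(5, 0, 5), "pass": _oracle_f1(20, 20, 0),
               "null": _oracle_f1(63, 7, 7)}
        expected = (10 * f1s["shot"] + 20 * f1s["pass"] + 70 * f1s["null"]) / 100
        assert f1_weighted(d) == pytest.approx(expected, abs=1e-12)
        assert f1_weighted(d) == pytest.approx(0.83, abs=1e-12)

    def test_all_supports_zero_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            f1_weighted({"shot": ClassCounts(), "pass": ClassCounts()})

    def test_agrees_with_sklearn_weighted_f1(self, rng):
        from sklearn.metrics import f1_score

        classes = np.array(["shot", "pass", "null"])
        for _ in range(20):
            y_true = classes[rng.integers(0, 3, 60)]
            y_pred = classes[rng.integers(0, 3, 60)]
            ours = f1_weighted(counts_from_predictions(y_true, y_pred))
            ref = f1_score(y_true, y_pred, labels=classes, average="weighted",
                           zero_division=0)
            assert ours == pytest.approx(ref, abs=1e-12)


class TestSensitivity:
    @pytest.mark.parametrize(
        "tp,fn,value", [(10, 0, 1.0), (0, 5, 0.0), (3, 1, 0.75)]
    )
    def test_proportion_of_correctly_identified(self, tp, fn, value):
        assert sensitivity_class(ClassCounts(tp=tp, fn=fn)) == pytest.approx(value)

    def test_zero_support_reports_not_available(self):
        assert sensitivity_class(ClassCounts(tp=0, fn=0, fp=4)) is None


class TestFineGrainedConfusion:
    def test_perfect_classifier_puts_one_in_true_class_rows(self):
        fines = ["shot", "long pass", "light contact", "none"]
        preds = ["shot", "pass", "null", "null"]
        mat = fine_grained_confusion(preds, fines)
        for fine, cls in zip(fines, preds):
            assert mat.loc[cls, fine] == 1.0
        np.testing.assert_allclose(mat.sum(axis=0)[fines], 1.0)

    def test_misclassified_shot_column(self):
        mat = fine_grained_confusion(["pass"], ["shot"])
        assert mat["shot"].tolist() == [0.0, 1.0, 0.0]

    def test_hand_tabulated_twelve_sample_set(self):
        fines = (["shot"] * 3 + ["long pass"] * 3 + ["light contact"] * 4
                 + ["none"] * 2)
        preds = ["shot", "shot", "pass",
                 "pass", "null", "pass",
                 "null", "null", "pass", "null",
                 "null", "shot"]
        mat = fine_grained_confusion(preds, fines)
        assert mat["shot"].tolist() == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert mat["long pass"].tolist() == pytest.approx([0.0, 2 / 3, 1 / 3])
        assert mat["light contact"].tolist() == pytest.approx([0.0, 0.25, 0.75])
        assert mat["none"].tolist() == pytest.approx([0.5, 0.0, 0.5])

    def test_nonempty_columns_sum_to_one(self, rng):
        from kicksense.evaluation import CLASSES, FINE_ORDER

        fines = [FINE_ORDER[i] for i in rng.integers(0, len(FINE_ORDER), 50)]
        preds = [CLASSES[i] for i in rng.integers(0, 3, 50)]
        mat = fine_grained_confusion(preds, fines)
        sums = mat.sum(axis=0)
        for fine in set(fines):
            assert sums[fine] == pytest.approx(1.0, abs=1e-9)

    def test_unknown_fine_type_is_an_error(self):
        with pytest.raises(ValueError, match="unknown ball-contact"):
            fine_grained_confusion(["shot"], ["unknown"])


@pytest.fixture(scope="module")
def lab_sessions():
    return [
        generate_session(SynthConfig(seed=80 + i, session_id=f"lab-{i}"))
        for i in range(2)
    ]


class TestScenarios:
    def test_segmented_evaluates_one_window_per_contact(self, lab_sessions):
        rep = run_segmented_scenario(GroundTruthOracle(), lab_sessions)
        n_expected = sum(
            1 for s in lab_sessions for e in s.events if e.class_label != "excluded"
        )
        assert rep.n_evaluated == n_expected
        assert rep.weighted_f1 == pytest.approx(1.0)

    def test_unknown_contacts_are_excluded_from_segmented(self):
        session = generate_session(
            SynthConfig(seed=85, counts={"shot": 3, "unknown": 2}, session_id="u")
        )
        rep = run_segmented_scenario(GroundTruthOracle(), [session])
        assert rep.n_evaluated == 3

    def test_no_contacts_is_an_error(self):
        session = generate_session(SynthConfig(seed=86, counts={}))
        with pytest.raises(ValueError, match="no labelled"):
            run_segmented_scenario(GroundTruthOracle(), [session])

    def test_window_scenario_oracle_has_unit_shot_pass_sensitivity(
        self, lab_sessions
    ):
        rep = run_window_scenario(GroundTruthOracle(), lab_sessions)
        assert rep.sensitivity["shot"] == pytest.approx(1.0)
        assert rep.sensitivity["pass"] == pytest.approx(1.0)
        stats = rep.candidate_stats
        assert 0 < stats["windows_rejected"] < stats["windows_total"]
        assert stats["candidates"] > 0
        assert stats["labelled_contacts_in_candidates"] > 0

    def test_pure_noise_session_reports_full_rejection(self):
        session = generate_session(
            SynthConfig(seed=87, counts={}, background_mix=(1.0, 0.0, 0.0))
        )
        rep = run_window_scenario(GroundTruthOracle(), [session])
        assert rep.n_evaluated == 0 and rep.weighted_f1 is None
        assert rep.candidate_stats["candidates"] == 0
        assert (rep.candidate_stats["windows_rejected"]
                == rep.candidate_stats["windows_total"])

    def test_segmented_and_window_agree_for_oracle_on_sparse_session(self):
        """With super-threshold events >= 2 s apart, both scenarios see the
        same labelled contacts and an oracle scores 1.0 in each."""
        cfg = SynthConfig(
            seed=88,
            counts={"shot": 3, "long pass": 3, "strong contact": 3},
            min_spacing_s=2.5,
        )
        session = generate_session(cfg)
        seg = run_segmented_scenario(GroundTruthOracle(), [session])
        win = run_window_scenario(GroundTruthOracle(), [session])
        assert seg.weighted_f1 == win.weighted_f1 == pytest.approx(1.0)
        for cls in ("shot", "pass"):
            assert seg.sensitivity[cls] == win.sensitivity[cls] == 1.0

    def test_report_serialization_roundtrip(self, lab_sessions):
        import json

        rep = run_window_scenario(GroundTruthOracle(), lab_sessions)
        doc = json.loads(rep.to_json())
        assert doc["scenario"] == "window_lab"
        assert doc["weighted_f1"] == pytest.approx(1.0)
        assert doc["fine_matrix"]["classes"] == ["shot", "pass", "null"]
        assert "windows_total" in doc["candidate_stats"]
        assert isinstance(rep.render_text(), str)
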