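import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmosdmri.classifiers import as_nmosd_classifier, paty
from nmosdmri.cohort import build_feature_matrix
from nmosdmri.evaluate import (
    REFERENCE_PRINT_CORRECTIONS,
    ConfusionMatrix,
    confusion,
    evaluate_classifier,
    load_reference_model_metrics,
    report_row,
    weighted_metrics,
)

from .conftest import brain_scan, make_patient

counts = st.integers(1, 300)


class TestConfusion:
    def test_all_correct(self):
        cm = confusion(["NMOSD", "MS", "MS"], ["NMOSD", "MS", "MS"])
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (1, 0, 2, 0)

    def test_all_predicted_nmosd(self):
        cm = confusion(["NMOSD", "MS"], ["NMOSD", "NMOSD"])
        assert cm.tn == 0 and cm.fn == 0

    def test_prediction_swap_symmetry(self):
        truths = ["NMOSD"] * 3 + ["MS"] * 5
        preds = ["NMOSD", "MS", "NMOSD", "MS", "NMOSD", "MS", "MS", "NMOSD"]
        cm = confusion(truths, preds)
        flipped = confusion(truths, ["MS" if p == "NMOSD" else "NMOSD" for p in preds])
        assert (flipped.tp, flipped.fp, flipped.tn, flipped.fn) == (cm.fn, cm.tn, cm.fp, cm.tp)

    def test_bad_label_rejected(self):
        with pytest.raises(ValueError):
            confusion(["NMOSD"], ["CIS"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(["NMOSD"], [])


class TestWeightedMetrics:
    def test_paty_style_counts(self):
        """Fixed-criterion counts: weighted precision 0.752, TPR 0.637, ROC 0.689."""
        report = weighted_metrics(ConfusionMatrix(tp=29, fp=9, tn=91, fn=33))
        assert report.weighted.precision == pytest.approx(0.752, abs=1e-3)
        assert report.weighted.tpr == pytest.approx(0.637, abs=1e-3)
        assert report.roc_area == pytest.approx(0.689, abs=1e-3)

    def test_perfect_classifier(self):
        report = weighted_metrics(ConfusionMatrix(tp=62, fp=0, tn=100, fn=0))
        assert report.weighted.tpr == 1.0
        assert report.weighted.precision == 1.0
        assert report.roc_area == 1.0

    def test_score_style_counts(self):
        report = weighted_metrics(ConfusionMatrix(tp=53, fp=9, tn=91, fn=9))
        assert report.weighted.precision == pytest.approx(0.876, abs=1e-3)
        assert report.roc_area == pytest.approx(0.882, abs=1e-3)

    @given(tp=counts, fp=counts, tn=counts, fn=counts)
    @settings(max_examples=200, deadline=None)
    def test_weighted_fpr_identity(self, tp, fp, tn, fn):
        """Under opposite-class weighting, weighted FPR = (FP+FN)/total exactly."""
        cm = ConfusionMatrix(tp, fp, tn, fn)
        report = weighted_metrics(cm)
        assert report.weighted.fpr == pytest.approx((fp + fn) / cm.total, abs=1e-12)

    @given(tp=counts, fp=counts, tn=counts, fn=counts, k=st.integers(2, 8))
    @settings(max_examples=100, deadline=None)
    def test_roc_area_scale_invariance(self, tp, fp, tn, fn, k):
        r1 = weighted_metrics(ConfusionMatrix(tp, fp, tn, fn))
        rk = weighted_metrics(ConfusionMatrix(k * tp, k * fp, k * tn, k * fn))
        assert rk.roc_area == pytest.approx(r1.roc_area, abs=1e-12)

    @given(tp=counts, fp=counts, tn=counts, fn=counts)
    @settings(max_examples=100, deadline=None)
    def test_weighted_lies_between_class_values(self, tp, fp, tn, fn):
        report = weighted_metrics(ConfusionMatrix(tp, fp, tn, fn))
        for metric in ("tpr", "fpr", "precision", "f_measure"):
            lo = min(getattr(report.nmosd, metric), getattr(report.ms, metric))
            hi = max(getattr(report.nmosd, metric), getattr(report.ms, metric))
            assert lo - 1e-12 <= getattr(report.weighted, metric) <= hi + 1e-12

    def test_undefined_precision_propagates_nan(self):
        # nobody predicted NMOSD -> NMOSD precision undefined, not zero
        report = weighted_metrics(ConfusionMatrix(tp=0, fp=0, tn=10, fn=5))
        assert np.isnan(report.nmosd.precision)
        assert np.isnan(report.weighted.precision)

    def test_zero_class_margin_rejected(self):
        with pytest.raises(ValueError):
            weighted_metrics(ConfusionMatrix(tp=3, fp=0, tn=0, fn=2))


class TestReferenceTable:
    def test_reference_counts_reproduce_printed_metrics(self):
        """Every printed weighted metric follows from its counts to +/-0.001,
        apart from the two documented print inconsistencies."""
        table = load_reference_model_metrics()
        checked = 0
        for row in table.itertuples(index=False):
            report = weighted_metrics(ConfusionMatrix(row.tp, row.fp, row.tn, row.fn))
            computed = {
                "tp_rate": report.weighted.tpr,
                "fp_rate": report.weighted.fpr,
                "precision": report.weighted.precision,
                "f_measure": report.weighted.f_measure,
                "roc_area": report.roc_area,
            }
            for col, value in computed.items():
                expected = REFERENCE_PRINT_CORRECTIONS.get(
                    (row.model, col), getattr(row, col)
                )
                assert value == pytest.approx(expected, abs=1e-3), (row.model, col)
                checked += 1
        assert checked == 35

    def test_print_corrections_consistent_with_identity(self):
        """Both corrected cells equal the (FP+FN)/total identity value."""
        table = load_reference_model_metrics().set_index("model")
        for (model, col), corrected in REFERENCE_PRINT_CORRECTIONS.items():
            assert col == "fp_rate"
            row = table.loc[model]
            identity = (row.fp + row.fn) / (row.tp + row.fp + row.tn + row.fn)
            assert corrected == pytest.approx(identity, abs=1e-3)


class TestWeightingConventionOracle:
    def test_only_opposite_class_weighting_reproduces_reference(self):
        """Brute-force discrimination of four candidate weighting schemes."""
        table = load_reference_model_metrics()

        def schemes(cm: ConfusionMatrix):
            n_n, n_m = cm.n_nmosd, cm.n_ms
            pred_n, pred_m = cm.tp + cm.fp, cm.tn + cm.fn
            m_n = weighted_metrics(cm).nmosd
            m_m = weighted_metrics(cm).ms
            total = n_n + n_m
            return {
                "macro": lambda x, y: (x + y) / 2,
                "prevalence": lambda x, y: (x * n_n + y * n_m) / total,
                "prediction": lambda x, y: (x * pred_n + y * pred_m) / total,
                "opposite": lambda x, y: (x * n_m + y * n_n) / total,
            }, m_n, m_m

        matches = {name: True for name in ("macro", "prevalence", "prediction", "opposite")}
        for row in table.itertuples(index=False):
            cm = ConfusionMatrix(row.tp, row.fp, row.tn, row.fn)
            fns, m_n, m_m = schemes(cm)
            for name, combine in fns.items():
                for col, attr in [
                    ("tp_rate", "tpr"),
                    ("fp_rate", "fpr"),
                    ("precision", "precision"),
                    ("f_measure", "f_measure"),
                ]:
                    expected = REFERENCE_PRINT_CORRECTIONS.get(
                        (row.model, col), getattr(row, col)
                    )
                    got = combine(getattr(m_n, attr), getattr(m_m, attr))
                    if abs(got - expected) > 1e-3:
                        matches[name] = False
        assert matches == {
            "macro": False,
            "prevalence": False,
            "prediction": False,
            "opposite": True,
        }


class TestEvaluateClassifier:
    def test_constant_ms_classifier(self, catalog):
        patients = [
            make_patient(f"n{i}", "NMOSD", [brain_scan(f"bn{i}", 0)]) for i in range(4)
        ] + [make_patient(f"m{i}", "MS", [brain_scan(f"bm{i}", 0)]) for i in range(6)]
        m = build_feature_matrix(patients, catalog)
        cm, report, n_excl = evaluate_classifier(lambda f: "MS", m, "first")
        assert report.nmosd.tpr == 0.0 and report.ms.tpr == 1.0
        assert report.roc_area == 0.5
        assert n_excl == 0

    def test_unclassifiable_records_counted(self, catalog):
        patients = [
            make_patient("n0", "NMOSD", [brain_scan("b0", 0, counts={"brain_T2_total": 0})]),
            make_patient("n1", "NMOSD", []),  # no imaging at all
            make_patient("m0", "MS", [brain_scan("b1", 0, counts={"brain_T2_total": 12})]),
        ]
        m = build_feature_matrix(patients, catalog)
        cm, report, n_excl = evaluate_classifier(as_nmosd_classifier(paty), m, "first")
        assert n_excl == 1
        assert cm.total == 2

    def test_perfectly_separable_score(self, catalog, default_matrix):
        from nmosdmri.classifiers import load_default_score_model, score_classify

        model = load_default_score_model(catalog)
        cm, report, _ = evaluate_classifier(
            lambda f: score_classify(f, model)[0], default_matrix, "ever"
        )
        assert report.roc_area > 0.8  # default synthetic cohort is highly separable

    def test_report_row_rounding(self):
        cm = ConfusionMatrix(tp=29, fp=9, tn=91, fn=33)
        row = report_row("Paty", cm, weighted_metrics(cm))
        assert row["Precision"] == 0.752
        assert row["TP"] == 29
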