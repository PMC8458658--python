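import itertools
import math

import pytest

from nmosdmri.classifiers import (
    DecisionNode,
    RuleSet,
    ScoreModel,
    as_nmosd_classifier,
    barkhof,
    external_criteria,
    load_default_score_model,
    load_example_tree,
    load_rulesets,
    load_score_model,
    load_tree,
    paty,
    score_classify,
    tree_classify,
)


def feats(**kwargs):
    return dict(kwargs)


class TestPaty:
    def test_three_large_lesions(self):
        assert paty(feats(n_brain_T2_total=3, n_periventricular_T2=0)) is True

    def test_two_lesions_one_periventricular(self):
        assert paty(feats(n_brain_T2_total=2, n_periventricular_T2=1)) is True

    def test_single_lesion(self):
        assert paty(feats(n_brain_T2_total=1, n_periventricular_T2=1)) is False

    def test_no_brain_counts_is_unclassifiable(self):
        assert paty(feats(n_brain_T2_total=float("nan"))) is None

    def test_truth_table_oracle(self):
        """Exhaustive agreement with a direct enumeration up to counts of 10."""
        for wm, pv in itertools.product(range(11), range(11)):
            pv_used = min(pv, wm)
            expected = wm >= 3 or (wm >= 2 and pv_used >= 1)
            got = paty(feats(n_brain_T2_total=wm, n_periventricular_T2=pv_used))
            assert got == expected, (wm, pv_used)


class TestBarkhof:
    def test_three_of_four(self):
        assert (
            barkhof(
                feats(
                    brain_gd=1.0,
                    n_brain_T2_total=4,
                    n_infratentorial_T2=1,
                    n_juxtacortical_T2=1,
                    n_periventricular_T2=2,
                )
            )
            is True
        )

    def test_nine_t2_alone_is_one_criterion(self):
        assert (
            barkhof(feats(brain_gd=0.0, n_brain_T2_total=9, n_infratentorial_T2=0,
                          n_juxtacortical_T2=0, n_periventricular_T2=0))
            is False
        )

    def test_empty_record(self):
        assert barkhof(feats(n_brain_T2_total=0)) is False

    def test_truth_table_oracle(self):
        """Exhaustive agreement over Gd flag and counts up to 10."""
        for gd, total, infra, jc, pv in itertools.product(
            (0, 1), (0, 2, 8, 9, 10), range(0, 4), range(0, 4), range(0, 5)
        ):
            crit = (gd == 1 or total >= 9) + (infra >= 1) + (jc >= 1) + (pv >= 3)
            expected = crit >= 3
            got = barkhof(
                feats(
                    brain_gd=float(gd),
                    n_brain_T2_total=total,
                    n_infratentorial_T2=infra,
                    n_juxtacortical_T2=jc,
                    n_periventricular_T2=pv,
                )
            )
            assert got == expected


class TestScoreModel:
    def test_boundary_strict_inequality(self, catalog):
        """nmo=2, ms=6 -> 7 > 6 NMOSD; nmo=2, ms=7 -> 7 > 7 false, MS."""
        model6 = ScoreModel(
            nmosd_features={"longitudinal_cord_T2": 2},
            ms_features={"ovoid_T2": 6},
        ).validate(catalog)
        label, nmo, ms = score_classify(feats(longitudinal_cord_T2=1.0, ovoid_T2=1.0), model6)
        assert (nmo, ms) == (2, 6) and label == "NMOSD"
        model7 = ScoreModel(
            nmosd_features={"longitudinal_cord_T2": 2},
            ms_features={"ovoid_T2": 7},
        ).validate(catalog)
        label, nmo, ms = score_classify(feats(longitudinal_cord_T2=1.0, ovoid_T2=1.0), model7)
        assert (nmo, ms) == (2, 7) and label == "MS"

    def test_zero_nmosd_score_is_ms(self, catalog):
        model = load_default_score_model(catalog)
        label, nmo, ms = score_classify(feats(), model)
        assert nmo == 0 and label == "MS"

    def test_all_missing_is_unclassifiable(self, catalog):
        model = ScoreModel(
            nmosd_features={"longitudinal_cord_T2": 1}, ms_features={"ovoid_T2": 1}
        ).validate(catalog)
        nan = float("nan")
        label, nmo, ms = score_classify(feats(longitudinal_cord_T2=nan, ovoid_T2=nan), model)
        assert label is None and math.isnan(nmo)

    def test_monotone_in_class_features(self, catalog):
        """Adding an NMOSD feature never flips NMOSD -> MS, and vice versa."""
        model = load_default_score_model(catalog)
        base = {fid: 0.0 for fid in model.feature_ids}
        for flipped in model.nmosd_features:
            before, *_ = score_classify(base, model)
            after, *_ = score_classify({**base, flipped: 1.0}, model)
            assert not (before == "NMOSD" and after == "MS")
        rich = {**base, "longitudinal_cord_T2": 1.0}
        for flipped in model.ms_features:
            before, *_ = score_classify(rich, model)
            after, *_ = score_classify({**rich, flipped: 1.0}, model)
            assert not (before == "MS" and after == "NMOSD")

    def test_regional_mode_cutoff_gates_contribution(self, catalog):
        model = ScoreModel(
            nmosd_features={"longitudinal_cord_T2": 1, "central_cord_T2": 1,
                            "bilateral_optic_nerve_T2_gd": 1},
            ms_features={"ovoid_T2": 1},
            mode="regional",
            region_cutoffs={"cord": 2},
        ).validate(catalog)
        # one cord feature -> below cord cutoff, contributes nothing
        assert model.nmosd_score(feats(longitudinal_cord_T2=1.0)) == 0.0
        # two cord features -> meets cutoff
        assert model.nmosd_score(feats(longitudinal_cord_T2=1.0, central_cord_T2=1.0)) == 2.0
        # optic region has no cutoff
        assert model.nmosd_score(feats(bilateral_optic_nerve_T2_gd=1.0)) == 1.0

    def test_overlapping_feature_lists_rejected(self):
        with pytest.raises(ValueError, match="both class lists"):
            ScoreModel(nmosd_features={"x": 1}, ms_features={"x": 1})

    def test_unknown_feature_rejected_at_validation(self, catalog):
        model = ScoreModel(nmosd_features={"made_up": 1}, ms_features={"ovoid_T2": 1})
        with pytest.raises(ValueError, match="unknown"):
            model.validate(catalog)

    def test_default_model_loads_and_validates(self, catalog):
        model = load_default_score_model(catalog)
        assert model.combination_ratio == 3.5
        assert model.nmosd_features["longitudinal_cord_T2"] == 2
        assert model.ms_features["ovoid_T2"] == 2


class TestDecisionTree:
    def test_depth_one(self, catalog):
        tree = load_tree(
            {"feature": "longitudinal_cord_T2", "yes": {"leaf": "NMOSD"}, "no": {"leaf": "MS"}},
            catalog,
        )
        assert tree_classify(feats(longitudinal_cord_T2=1.0), tree) == "NMOSD"
        assert tree_classify(feats(longitudinal_cord_T2=0.0), tree) == "MS"
        assert tree_classify(feats(), tree) == "MS"  # missing goes to the N branch

    def test_determinism(self, catalog):
        tree = load_example_tree(catalog)
        record = feats(ovoid_T2=1.0, periventricular_T2=1.0)
        assert tree_classify(record, tree) == tree_classify(dict(record), tree)

    def test_malformed_tree_rejected(self):
        with pytest.raises(ValueError):
            DecisionNode(leaf="NMOSD", feature_id="x")
        with pytest.raises(ValueError):
            load_tree({"feature": "x", "yes": {"leaf": "NMOSD"}})
        with pytest.raises(ValueError):
            load_tree({"leaf": "maybe"})

    def test_tree_unknown_feature_rejected(self, catalog):
        with pytest.raises(ValueError, match="unknown"):
            load_tree({"feature": "bogus", "yes": {"leaf": "NMOSD"}, "no": {"leaf": "MS"}}, catalog)

    def test_tree_reproduces_score_boundary_exhaustively(self, catalog):
        """A hand-built tree encoding a small score model's decision boundary
        agrees with score_classify on every combination of its features."""
        model = ScoreModel(
            nmosd_features={"longitudinal_cord_T2": 2, "cord_gd": 1},
            ms_features={"ovoid_T2": 2, "dawsons_fingers": 1},
            combination_ratio=1.0,
        ).validate(catalog)
        fids = model.feature_ids

        def build(assigned, remaining):
            if not remaining:
                label, _, _ = score_classify(dict(assigned), model)
                return {"leaf": label}
            fid, rest = remaining[0], remaining[1:]
            return {
                "feature": fid,
                "yes": build({**assigned, fid: 1.0}, rest),
                "no": build({**assigned, fid: 0.0}, rest),
            }

        tree = load_tree(build({}, fids), catalog)
        for bits in itertools.product((0.0, 1.0), repeat=len(fids)):
            record = dict(zip(fids, bits))
            assert tree_classify(record, tree) == score_classify(record, model)[0]


class TestRuleSets:
    def test_expression_semantics(self):
        rule = RuleSet("r", "longitudinal_cord_T2 and not dawsons_fingers")
        assert external_criteria(feats(longitudinal_cord_T2=1.0), rule) == "NMOSD"
        assert (
            external_criteria(feats(longitudinal_cord_T2=1.0, dawsons_fingers=1.0), rule) == "MS"
        )

    def test_tautology_and_contradiction(self):
        assert external_criteria(feats(), RuleSet("t", "True")) == "NMOSD"
        assert external_criteria(feats(), RuleSet("f", "False")) == "MS"

    def test_disallowed_syntax_rejected(self):
        with pytest.raises(ValueError):
            RuleSet("bad", "__import__('os')")
        with pytest.raises(ValueError):
            RuleSet("bad", "1 + 1")

    def test_unknown_feature_rejected_at_load(self, catalog):
        with pytest.raises(ValueError, match="unknown"):
            load_rulesets({"r": "not_a_feature"}, catalog)

    def test_example_rulesets_load(self, catalog):
        from importlib import resources
        import yaml

        text = resources.files("nmosdmri.data").joinpath("example_rulesets.yaml").read_text()
        rules = load_rulesets(yaml.safe_load(text), catalog)
        assert "letm_not_dawsons" in rules


class TestCriterionWrapper:
    def test_paty_as_nmosd_classifier(self):
        clf = as_nmosd_classifier(paty)
        assert clf(feats(n_brain_T2_total=12, n_periventricular_T2=3)) == "MS"
        assert clf(feats(n_brain_T2_total=0, n_periventricular_T2=0)) == "NMOSD"
        assert clf(feats(n_brain_T2_total=float("nan"))) is None
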