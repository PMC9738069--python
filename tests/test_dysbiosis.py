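"""ROC thresholds, outlier exclusion and the >=3-of-4 dysbiosis rule."""

import numpy as np
import pandas as pd
import pytest

from gutqs.dysbiosis import (
    ENRICHED,
    DEPLETED,
    Marker,
    MarkerPanel,
    RocCurve,
    build_panel,
    classify_all,
    classify_dysbiosis,
    exclude_outliers,
    roc_curve,
    select_threshold,
)


class TestRoc:
    def test_four_point_toy(self):
        roc = roc_curve([1, 2, 3, 4], [0, 0, 1, 1])
        assert roc.auc == pytest.approx(1.0)
        # some threshold in (2, 3) gives sens = spec = 1
        i = np.argmax(roc.sensitivity + roc.specificity)
        assert 2 < roc.thresholds[i] < 3
        assert roc.sensitivity[i] == roc.specificity[i] == 1.0

    def test_perfectly_separated_scores_auc_one(self, rng):
        neg = rng.normal(0, 1, 50)
        pos = rng.normal(100, 1, 50)
        roc = roc_curve(np.concatenate([neg, pos]), [0] * 50 + [1] * 50)
        assert roc.auc == pytest.approx(1.0)

    def test_random_labels_auc_near_half(self, rng):
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, 200)
        if labels.sum() in (0, 200):
            labels[0] = 1 - labels[0]
        roc = roc_curve(scores, labels)
        assert 0.42 <= roc.auc <= 0.58

    def test_matches_sklearn_auc_both_directions(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, 80)
        labels[0], labels[1] = 0, 1
        assert roc_curve(scores, labels, "greater").auc == pytest.approx(
            sk.roc_auc_score(labels, scores)
        )
        assert roc_curve(scores, labels, "less").auc == pytest.approx(
            sk.roc_auc_score(labels, -scores)
        )

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2, 3], [1, 1, 1])


class TestSelectThreshold:
    def test_unique_youden_maximum(self):
        roc = roc_curve([1, 2, 3, 10], [0, 0, 1, 1])
        t = select_threshold(roc)
        assert 2 < t < 3

    def test_tie_broken_by_specificity(self):
        roc = RocCurve(
            thresholds=np.array([1.0, 2.0]),
            sensitivity=np.array([0.9, 1.0]),
            specificity=np.array([0.9, 0.8]),
            auc=0.9,
            direction="greater",
        )
        # both points have J = 0.8; the 0.9-specificity one wins
        assert select_threshold(roc) == 1.0

    def test_max_specificity_policy(self):
        roc = RocCurve(
            thresholds=np.array([1.0, 2.0]),
            sensitivity=np.array([1.0, 0.6]),
            specificity=np.array([0.7, 0.95]),
            auc=0.9,
            direction="greater",
        )
        assert select_threshold(roc, "max_specificity") == 2.0
        assert select_threshold(roc, "youden") == 1.0


class TestOutliers:
    def _table(self):
        return pd.DataFrame(
            {"SpeciesZ": [75.9, 10.0, 3.0], "Other": [24.1, 90.0, 97.0]},
            index=["outlier", "ok1", "ok2"],
        )

    def test_species_cap_rule(self):
        kept, report = exclude_outliers(self._table(), species_caps={"SpeciesZ": 70.0})
        assert list(kept.index) == ["ok1", "ok2"]
        assert report.iloc[0]["sample_id"] == "outlier"

    def test_empty_rules_identity(self):
        kept, report = exclude_outliers(self._table())
        assert len(kept) == 3 and len(report) == 0

    def test_non_matching_rule_identity(self):
        kept, report = exclude_outliers(self._table(), species_caps={"SpeciesZ": 99.0})
        assert len(kept) == 3 and len(report) == 0

    def test_explicit_ids(self):
        kept, report = exclude_outliers(self._table(), exclude_ids=["ok1"])
        assert list(kept.index) == ["outlier", "ok2"]


def _lefse_frame(features, scores, classes):
    return pd.DataFrame(
        {"kw_p": 0.001, "lda_score": scores, "enriched_class": classes},
        index=pd.Index(features, name="feature"),
    )


class TestPanel:
    def _data(self, rng, n=40):
        labels = np.array(["non-IBD"] * (n // 2) + ["IBD"] * (n // 2))
        ab = pd.DataFrame(
            {
                "up": np.where(labels == "IBD", rng.normal(10, 1, n), rng.normal(2, 1, n)),
                "down": np.where(labels == "IBD", rng.normal(1, 0.3, n), rng.normal(6, 1, n)),
                "x1": rng.normal(5, 1, n),
                "x2": rng.normal(5, 1, n),
            },
            index=[f"s{i}" for i in range(n)],
        )
        return ab, labels

    def test_four_features_give_four_markers_with_directions(self, rng):
        ab, labels = self._data(rng)
        lf = _lefse_frame(["up", "down", "x1", "x2"], [4.0, 3.5, 2.5, 2.1],
                          ["IBD", "non-IBD", "IBD", "non-IBD"])
        panel = build_panel(lf, ab, labels, positive_class="IBD")
        assert len(panel.markers) == 4 and panel.min_markers == 3
        by_name = {m.species: m for m in panel.markers}
        assert by_name["up"].direction == ENRICHED
        assert by_name["down"].direction == DEPLETED
        # thresholds split the class modes
        assert 2 < by_name["up"].threshold < 10
        assert 1 < by_name["down"].threshold < 6

    def test_small_panel_clamps_min_markers(self, rng, caplog):
        ab, labels = self._data(rng)
        lf = _lefse_frame(["up", "down"], [4.0, 3.0], ["IBD", "non-IBD"])
        with caplog.at_level("WARNING"):
            panel = build_panel(lf, ab, labels, positive_class="IBD", top_k=4)
        assert len(panel.markers) == 2 and panel.min_markers == 1

    def test_empty_result_raises(self, rng):
        ab, labels = self._data(rng)
        with pytest.raises(ValueError):
            build_panel(_lefse_frame([], [], []), ab, labels, "IBD")


PANEL = MarkerPanel(
    markers=[
        Marker("a", ENRICHED, 5.0),
        Marker("b", DEPLETED, 2.0),
        Marker("c", DEPLETED, 1.0),
        Marker("d", ENRICHED, 3.0),
    ],
    min_markers=3,
)


class TestClassify:
    @pytest.mark.parametrize(
        "abund,met,label",
        [
            ({"a": 9, "b": 0.5, "c": 0.2, "d": 7}, 4, "D"),
            ({"a": 9, "b": 0.5, "c": 0.2, "d": 1}, 3, "D"),  # exactly 3 of 4
            ({"a": 9, "b": 0.5, "c": 5.0, "d": 1}, 2, "ND"),
            ({"a": 1, "b": 9.0, "c": 5.0, "d": 1}, 0, "ND"),
        ],
    )
    def test_criteria_counting(self, abund, met, label):
        call = classify_dysbiosis(abund, PANEL, "s")
        assert (call.n_criteria_met, call.label) == (met, label)

    def test_missing_marker_counts_as_zero_abundance(self):
        # zero abundance satisfies the two depleted criteria, fails enriched
        call = classify_dysbiosis({"a": 9.0}, PANEL, "s")
        assert call.n_criteria_met == 3 and call.label == "D"

    def test_marker_order_never_changes_calls(self, rng):
        ab = pd.DataFrame(
            rng.uniform(0, 10, size=(30, 4)), columns=list("abcd"),
            index=[f"s{i}" for i in range(30)],
        )
        calls = classify_all(ab, PANEL)
        shuffled = MarkerPanel(markers=PANEL.markers[::-1], min_markers=3)
        pd.testing.assert_frame_equal(calls, classify_all(ab, shuffled))

    def test_raising_min_markers_is_monotone(self, rng):
        ab = pd.DataFrame(
            rng.uniform(0, 10, size=(50, 4)), columns=list("abcd"),
            index=[f"s{i}" for i in range(50)],
        )
        d_sets = []
        for k in (1, 2, 3, 4):
            panel = MarkerPanel(markers=PANEL.markers, min_markers=k)
            calls = classify_all(ab, panel)
            d_sets.append(set(calls.index[calls["label"] == "D"]))
        for lo, hi in zip(d_sets[1:], d_sets[:-1]):
            assert lo <= hi

    def test_panel_json_roundtrip(self):
        restored = MarkerPanel.from_json(PANEL.to_json())
        assert restored == PANEL


def test_dysbiotic_group_has_lower_diversity():
    """With a depletion-dominated marker panel on dominant commensals,
    dysbiotic samples show fewer observed species and lower Shannon."""
    import gutqs
    from gutqs import profiles_diversity as pdv
    from gutqs.synthetic_data import diversity_contrast_markers, simulate_community

    cfg = gutqs.SimConfig(
        seed=31,
        n_samples_per_group={"non-IBD": 20, "CD": 20},
        dysbiosis_fraction={"non-IBD": 0.0, "CD": 1.0},
        marker_spec=diversity_contrast_markers(),
        marker_shares=(0.08, 0.05, 0.04, 0.03),
        reads_mean=200_000,
    )
    profiles, truth = simulate_community(cfg)
    counts = pdv.build_count_table(profiles)
    rare = pdv.rarefy(counts, depth=50_000, seed=np.random.default_rng(0))
    alpha = pdv.alpha_diversity_table(rare)
    dys = np.array([truth.dysbiosis[s] for s in alpha.index])
    assert alpha["shannon"][dys].mean() < alpha["shannon"][~dys].mean()
    assert alpha["observed"][dys].mean() < alpha["observed"][~dys].mean()
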