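"""Labeling, cross-validation, unknown attribution, metrics, info gain."""

import math
from datetime import datetime

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stressense as ss
from stressense.corpus_io import ALL_CATEGORIES, CATEGORIES
from stressense.detection_eval import StressDetection, discretize


def _tweet(tid, text, **kw):
    base = dict(tweet_id=tid, user_id="u1", text=text,
                posted_at=datetime(2014, 3, 10, 12))
    base.update(kw)
    return ss.Tweet(**base)


def _ann(tid, **levels):
    return ss.StressAnnotation(tid, {c: levels.get(c.replace("-", "_"), 0)
                                     for c in CATEGORIES})


# ---------------------------------------------------------------------------
# labeling

def test_make_labels_assigns_levels_by_category(lex):
    corpus = ss.Corpus(
        tweets=[_tweet("t1", "Terrible grade."),
                _tweet("t2", "I still feel sad.",
                       responses=[ss.Response(1, "f1",
                                              "I broke up with my boyfriend")]),
                _tweet("t3", "so sad。"),
                _tweet("t4", "nice day。")],
        annotations=[_ann("t1", academic=2), _ann("t2", affection=1),
                     _ann("t3", affection=1), _ann("t4")],
    )
    labeled = ss.make_labels(corpus, ss.extract_features(corpus, lex))
    lab = labeled.set_index(["tweet_id", "category"])["label"]
    assert lab[("t1", "academic")] == 2
    assert lab[("t1", "unknown")] == 0
    # category revealed by the response: the affection vector is labeled
    assert lab[("t2", "affection")] == 1 and lab[("t2", "unknown")] == 0
    # no category anywhere: the stress is labeled under unknown
    assert lab[("t3", "unknown")] == 1
    assert all(lab[("t4", c)] == 0 for c in ALL_CATEGORIES)


def test_make_labels_excludes_unannotated_tweets(lex, caplog):
    corpus = ss.Corpus(tweets=[_tweet("t1", "x"), _tweet("t2", "y")],
                       annotations=[_ann("t1")])
    feats = ss.extract_features(corpus, lex)
    labeled = ss.make_labels(corpus, feats)
    assert set(labeled["tweet_id"]) == {"t1"}


# ---------------------------------------------------------------------------
# cross-validation

def _separable_frame(n_tweets=40):
    rows = []
    for i in range(n_tweets):
        level = i % 4
        for c in ALL_CATEGORIES:
            row = {col: 0.0 for col in ss.FEATURE_COLUMNS}
            row.update(tweet_id=f"t{i:03d}", category=c)
            if c == "academic":
                row["FWC1"] = float(level)
                row["label"] = level
            else:
                row["label"] = 0
            rows.append(row)
    return pd.DataFrame(rows)


def test_crossvalidate_recovers_separable_labels():
    labeled = _separable_frame()
    det = ss.crossvalidate(labeled, ss.ClassifierSpec("random_forest", seed=1),
                           k=10)
    assert set(det) == set(labeled["tweet_id"])          # each tweet once
    for i in range(40):
        assert det[f"t{i:03d}"].level("academic") == i % 4


def test_crossvalidate_all_zero_labels():
    labeled = _separable_frame()
    labeled["label"] = 0
    det = ss.crossvalidate(labeled, ss.ClassifierSpec("naive_bayes"), k=5)
    assert all(lvl == 0 for d in det.values() for lvl in d.levels.values())


def test_crossvalidate_rejects_too_few_tweets():
    labeled = _separable_frame(n_tweets=5)
    with pytest.raises(ValueError):
        ss.crossvalidate(labeled, ss.ClassifierSpec(), k=10)


@pytest.mark.parametrize("name", ["naive_bayes", "logistic_regression",
                                  "random_forest", "svm"])
def test_all_registered_classifiers_fit_and_predict(name):
    labeled = _separable_frame(n_tweets=20)
    model = ss.fit_classifier(labeled, ss.ClassifierSpec(name, seed=0))
    det = ss.predict(model, labeled)
    assert len(det) == 20


# ---------------------------------------------------------------------------
# unknown attribution

def test_unknown_reassigned_to_exact_matching_category():
    det = StressDetection("t1", {c: 0 for c in ALL_CATEGORIES} | {"unknown": 2})
    ann = _ann("t1", affection=2, academic=3)
    out = ss.attribute_unknown(det, ann)
    assert out.level("affection") == 2 and out.level("unknown") == 0


def test_unknown_tie_breaks_to_highest_annotated_level():
    det = StressDetection("t1", {"unknown": 1})
    ann = _ann("t1", academic=2, interpersonal=3)
    out = ss.attribute_unknown(det, ann)
    assert out.level("interpersonal") == 1


def test_unknown_zero_or_unmatchable_left_alone():
    det0 = StressDetection("t1", {"unknown": 0, "academic": 1})
    assert ss.attribute_unknown(det0, _ann("t1", academic=1)) == det0
    det1 = StressDetection("t2", {"unknown": 1})
    out = ss.attribute_unknown(det1, _ann("t2"))
    assert out.level("unknown") == 1        # stands, hurting precision


def _exact_matches(det, ann):
    matches = 0
    for c in ALL_CATEGORIES:
        a = ann.level(c) if c != "unknown" else 0
        if det.level(c) == a:
            matches += 1
    return matches


def test_attribution_maximizes_exact_matches_vs_bruteforce():
    rng = np.random.default_rng(42)
    for _ in range(300):
        ann = ss.StressAnnotation("t", {
            c: int(rng.integers(0, 4)) if rng.random() < 0.5 else 0
            for c in CATEGORIES})
        det = StressDetection("t", {
            **{c: int(rng.integers(0, 4)) if rng.random() < 0.4 else 0
               for c in CATEGORIES},
            "unknown": int(rng.integers(0, 4))})
        out = ss.attribute_unknown(det, ann)
        # brute-force: best over keeping or any single legal reassignment
        lvl = det.level("unknown")
        options = [det]
        for c in CATEGORIES:
            if lvl > 0 and ann.level(c) > 0 and det.level(c) == 0:
                moved = dict(det.levels)
                moved[c] = lvl
                moved["unknown"] = 0
                options.append(StressDetection("t", moved))
        best = max(_exact_matches(o, ann) for o in options)
        assert _exact_matches(out, ann) == best
        assert _exact_matches(out, ann) >= _exact_matches(det, ann)


# ---------------------------------------------------------------------------
# evaluation reports

@pytest.fixture
def hand_scenario():
    """Six tweets in the academic category with every outcome type."""
    detections = {
        "t1": StressDetection("t1", {"academic": 2}),
        "t2": StressDetection("t2", {"academic": 2}),
        "t3": StressDetection("t3", {"academic": 0}),
        "t4": StressDetection("t4", {"academic": 1}),
        "t5": StressDetection("t5", {"academic": 0}),
        "t6": StressDetection("t6", {"academic": 2}),
    }
    annotations = {
        "t1": _ann("t1", academic=2), "t2": _ann("t2", academic=1),
        "t3": _ann("t3", academic=2), "t4": _ann("t4"),
        "t5": _ann("t5"), "t6": _ann("t6", academic=3),
    }
    return detections, annotations


def test_exact_metrics_match_hand_count(hand_scenario):
    det, ann = hand_scenario
    report = ss.evaluate_exact(det, ann)
    p, r, f = report.per_category["academic"]
    assert (p, r) == (0.25, 0.25)
    assert f == pytest.approx(0.25)


def test_binary_metrics_match_hand_count(hand_scenario):
    det, ann = hand_scenario
    p, r, f = ss.evaluate_binary(det, ann).per_category["academic"]
    assert (p, r) == (0.75, 0.75)
    assert f == pytest.approx(0.75)


def test_level_diff_proportions(hand_scenario):
    det, ann = hand_scenario
    report = ss.evaluate_level_diff(det, ann)
    assert report.n == 3
    assert report.lower == report.equal == report.higher == pytest.approx(1 / 3)


def test_perfect_detections_score_one():
    ann = {f"t{i}": _ann(f"t{i}", academic=1 + i % 3,
                         affection=(i % 2) * 2) for i in range(9)}
    det = {tid: StressDetection(tid, {c: a.level(c) for c in CATEGORIES})
           for tid, a in ann.items()}
    exact = ss.evaluate_exact(det, ann)
    for cat in ("academic", "affection"):
        assert exact.per_category[cat] == (1.0, 1.0, 1.0)
    diff = ss.evaluate_level_diff(det, ann)
    assert (diff.lower, diff.equal, diff.higher) == (0.0, 1.0, 0.0)


def test_all_zero_detections():
    ann = {"t1": _ann("t1", academic=2)}
    det = {"t1": StressDetection("t1", {})}
    report = ss.evaluate_exact(det, ann)
    assert report.per_category["academic"] == (0.0, 0.0, 0.0)
    diff = ss.evaluate_level_diff(det, ann)
    assert diff.n == 0 and diff.lower is None


# ---------------------------------------------------------------------------
# information gain

def _entropy_bruteforce(labels):
    n = len(labels)
    out = 0.0
    for lab in set(labels):
        p = labels.count(lab) / n
        out -= p * math.log(p)
    return out


def _info_gain_bruteforce(values, labels):
    h = _entropy_bruteforce(labels)
    cond = 0.0
    for v in set(values):
        sub = [l for x, l in zip(values, labels) if x == v]
        cond += len(sub) / len(labels) * _entropy_bruteforce(sub)
    return h - cond


def test_info_gain_matches_bruteforce_on_contingency_table():
    # 2-bin x 2-label contingency with counts 30,10 / 10,30
    values = [0] * 40 + [1] * 40
    labels = ["A"] * 30 + ["B"] * 10 + ["A"] * 10 + ["B"] * 30
    expected = _info_gain_bruteforce(values, labels)
    assert ss.info_gain(values, labels) == pytest.approx(expected)
    assert expected > 0


def test_info_gain_zero_for_independent_feature():
    values = [0] * 50 + [1] * 50
    # identical label distribution in each bin
    labels = (["A"] * 25 + ["B"] * 25) * 2
    assert ss.info_gain(values, labels) == pytest.approx(0.0, abs=1e-12)


def test_info_gain_of_determining_feature_equals_label_entropy():
    values = [0] * 30 + [1] * 10 + [2] * 20
    labels = ["x"] * 30 + ["y"] * 10 + ["z"] * 20
    assert ss.info_gain(values, labels) == pytest.approx(
        _entropy_bruteforce(labels))


def test_constant_labels_give_zero_gain():
    assert ss.info_gain([1.0, 2.0, 3.0], ["a", "a", "a"]) == pytest.approx(0.0)


def test_discretize_keeps_small_supports_exact():
    vals = np.array([0, 3, 1, 3, 0])
    assert len(np.unique(discretize(vals))) == 3
    cont = np.linspace(0, 1, 200)
    assert len(np.unique(discretize(cont, bins=10))) == 10


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.floats(-5, 5, allow_nan=False),
                          st.integers(0, 3)),
                min_size=1, max_size=80))
def test_info_gain_bounds_on_random_data(data):
    values = [v for v, _ in data]
    labels = [l for _, l in data]
    gain = ss.info_gain(values, labels)
    h = _entropy_bruteforce(labels)
    assert gain >= -1e-9
    assert gain <= h + 1e-9


def test_feature_impact_constant_features_zero(lex):
    frame = _separable_frame(20)
    frame[ss.FEATURE_COLUMNS] = 0.0
    frame["label"] = 0
    table = ss.feature_impact_report(frame)
    assert (table.gains["info_gain"].abs() < 1e-12).all()
    assert sorted(table.ranking) == sorted(ss.FEATURE_COLUMNS)


def test_feature_impact_ranks_planted_signal_first():
    frame = _separable_frame(60)
    table = ss.feature_impact_report(frame)
    assert table.ranking[0] == "FWC1"
    assert (table.gains["info_gain"] >= -1e-9).all()
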