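"""Stress-level detection, evaluation protocol and feature impact.

A single pluggable classifier (scikit-learn behind a small registry) is
trained on the pooled per-category feature vectors to predict the
ordinal stress level 0-3. Evaluation follows the study protocol:

* 10-fold cross-validation with folds split at the tweet level (all
  five vectors of a tweet share a fold), stratified by stressful-or-not;
* detections in the "unknown" pseudo-category are attributed to an
  annotated category seeking the maximal level match before scoring;
* exact-level precision/recall/F per category, the lower/equal/higher
  level-difference breakdown, and the binary stressful-or-not reduction.

Feature impact is measured by information gain
``InfoGain(L,C|F) = H(L,C) - H(L,C|F)`` of the joint (level, category)
label given the (discretized) feature, averaged across categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .corpus_io import ALL_CATEGORIES, CATEGORIES, Corpus, StressAnnotation
from .features import FEATURE_COLUMNS, TweetFeatures, features_to_frame

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# labeling

def make_labels(corpus: Corpus, features: list[TweetFeatures]) -> pd.DataFrame:
    """Attach ground-truth levels to the per-category vectors.

    Deterministic-category vectors take the annotated level for their
    category. The unknown-category vector takes the maximum annotated
    level only when neither the tweet (CS) nor its responses (CSR)
    reveal a category — the situation in which the stress would have to
    be detected under "unknown" — and 0 otherwise. Tweets without an
    annotation are excluded with a warning.
    """
    if corpus.annotations is None:
        raise ValueError("corpus has no annotations")
    ann = corpus.annotation_index()
    frames = []
    for tf in features:
        if tf.tweet_id not in ann:
            logger.warning("tweet %s has no annotation; excluded", tf.tweet_id)
            continue
        a = ann[tf.tweet_id]
        labels = {c: a.level(c) for c in CATEGORIES}
        unknown_label = 0
        if tf.cs == frozenset({"unknown"}) and not tf.csr:
            unknown_label = max(labels.values(), default=0)
        labels["unknown"] = unknown_label
        rows = []
        for c in ALL_CATEGORIES:
            row = tf.vectors[c].as_row()
            row["label"] = labels[c]
            rows.append(row)
        frames.append(pd.DataFrame(rows))
    if not frames:
        return pd.DataFrame(
            columns=["tweet_id", "category"] + FEATURE_COLUMNS + ["label"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# classifiers

@dataclass
class ClassifierSpec:
    """A registered classifier with hyperparameters and a seed."""

    name: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def build(self):
        try:
            factory = CLASSIFIERS[self.name]
        except KeyError:
            raise KeyError(f"unknown classifier {self.name!r}; "
                           f"registered: {sorted(CLASSIFIERS)}") from None
        return factory(self.seed, **self.hyperparameters)


CLASSIFIERS = {
    "naive_bayes": lambda seed, **hp: GaussianNB(**hp),
    "logistic_regression": lambda seed, **hp: make_pipeline(
        StandardScaler(),
        LogisticRegression(max_iter=2000, random_state=seed, **hp)),
    "random_forest": lambda seed, **hp: RandomForestClassifier(
        n_estimators=hp.pop("n_estimators", 100), random_state=seed, **hp),
    "svm": lambda seed, **hp: make_pipeline(
        StandardScaler(), SVC(random_state=seed, **hp)),
}


@dataclass
class StressDetection:
    """Detected stress level per category for one tweet."""

    tweet_id: str
    levels: dict[str, int]

    def level(self, category: str) -> int:
        return self.levels.get(category, 0)


def _detections_from_predictions(df: pd.DataFrame,
                                 pred: np.ndarray) -> dict[str, StressDetection]:
    out: dict[str, StressDetection] = {}
    for (tid, cat), lvl in zip(df[["tweet_id", "category"]].itertuples(
            index=False), pred):
        out.setdefault(tid, StressDetection(tid, {}))
        out[tid].levels[cat] = int(lvl)
    return out


def fit_classifier(labeled: pd.DataFrame, spec: ClassifierSpec):
    model = spec.build()
    model.fit(labeled[FEATURE_COLUMNS].to_numpy(float),
              labeled["label"].to_numpy(int))
    return model


def predict(model, vectors: pd.DataFrame) -> dict[str, StressDetection]:
    pred = model.predict(vectors[FEATURE_COLUMNS].to_numpy(float))
    return _detections_from_predictions(vectors, pred)


def crossvalidate(labeled: pd.DataFrame, spec: ClassifierSpec,
                  k: int = 10, seed: Optional[int] = None
                  ) -> dict[str, StressDetection]:
    """Out-of-fold detections from k-fold CV split at the tweet level.

    Folds are stratified by tweet stressful-or-not; every tweet is
    predicted exactly once, with all five of its vectors in one fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if seed is None:
        seed = spec.seed
    tweet_ids = labeled["tweet_id"].unique()
    if len(tweet_ids) < k:
        raise ValueError(f"{len(tweet_ids)} tweets < {k} folds")
    stressful = labeled.groupby("tweet_id")["label"].max() > 0
    y_tweet = stressful.loc[tweet_ids].to_numpy(int)
    counts = np.bincount(y_tweet, minlength=2)
    if counts[counts > 0].min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        logger.warning("too few tweets in a stratum for %d folds; "
                       "using unstratified folds", k)
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    base = spec.build()
    detections: dict[str, StressDetection] = {}
    X = labeled[FEATURE_COLUMNS].to_numpy(float)
    y = labeled["label"].to_numpy(int)
    for train_idx, test_idx in splitter.split(tweet_ids, y_tweet):
        train_tweets = set(tweet_ids[train_idx])
        test_tweets = set(tweet_ids[test_idx])
        train_mask = labeled["tweet_id"].isin(train_tweets).to_numpy()
        test_mask = labeled["tweet_id"].isin(test_tweets).to_numpy()
        model = clone(base)
        model.fit(X[train_mask], y[train_mask])
        pred = model.predict(X[test_mask])
        detections.update(_detections_from_predictions(
            labeled.loc[test_mask], pred))
    return detections


# ---------------------------------------------------------------------------
# unknown-category attribution

def attribute_unknown(detection: StressDetection,
                      annotation: StressAnnotation) -> StressDetection:
    """Reassign a nonzero unknown-category detection to an annotated
    stressful category, maximizing exact level matches.

    Preference: a category annotated at exactly the detected level, then
    the highest annotated level, then the fixed category order. Only
    categories currently detected as 0 qualify; if none do, the unknown
    detection stands (and will count against precision).
    """
    lvl = detection.level("unknown")
    if lvl == 0:
        return detection
    candidates = [c for c in CATEGORIES
                  if annotation.level(c) > 0 and detection.level(c) == 0]
    if not candidates:
        return detection
    exact = [c for c in candidates if annotation.level(c) == lvl]
    pool = exact if exact else candidates
    best = max(pool, key=lambda c: (annotation.level(c),
                                    -CATEGORIES.index(c)))
    levels = dict(detection.levels)
    levels[best] = lvl
    levels["unknown"] = 0
    return StressDetection(detection.tweet_id, levels)


def attribute_all(detections: Mapping[str, StressDetection],
                  annotations: Mapping[str, StressAnnotation]
                  ) -> dict[str, StressDetection]:
    out = {}
    for tid, det in detections.items():
        ann = annotations.get(tid)
        out[tid] = attribute_unknown(det, ann) if ann is not None else det
    return out


# ---------------------------------------------------------------------------
# evaluation reports

def _f_measure(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if p + r > 0 else 0.0


@dataclass
class MetricsReport:
    """Per-category precision/recall/F plus macro averages.

    Macro averages are taken over the four deterministic categories;
    the unknown row reports residual unattributed detections.
    """

    per_category: dict[str, tuple[float, float, float]]

    @property
    def macro(self) -> tuple[float, float, float]:
        ps, rs, fs = zip(*(self.per_category[c] for c in CATEGORIES))
        return (float(np.mean(ps)), float(np.mean(rs)), float(np.mean(fs)))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"category": c, "precision": p, "recall": r, "f_measure": f}
                for c, (p, r, f) in self.per_category.items()]
        mp, mr, mf = self.macro
        rows.append({"category": "macro_avg", "precision": mp,
                     "recall": mr, "f_measure": mf})
        return pd.DataFrame(rows)


def _annotated_level(annotations: Mapping[str, StressAnnotation],
                     tid: str, cat: str) -> int:
    ann = annotations.get(tid)
    if ann is None or cat == "unknown":
        return 0
    return ann.level(cat)


def _category_metrics(detections, annotations, cat, exact: bool
                      ) -> tuple[float, float, float]:
    det_pos = match_p = ann_pos = match_r = 0
    for tid, det in detections.items():
        d = det.level(cat)
        a = _annotated_level(annotations, tid, cat)
        hit = (d == a) if exact else (d > 0 and a > 0)
        if d > 0:
            det_pos += 1
            if hit:
                match_p += 1
        if a > 0:
            ann_pos += 1
            if hit:
                match_r += 1
    if det_pos == 0:
        logger.info("category %s: no nonzero detections; precision set to 0", cat)
    p = match_p / det_pos if det_pos else 0.0
    r = match_r / ann_pos if ann_pos else 0.0
    return p, r, _f_measure(p, r)


def evaluate_exact(detections: Mapping[str, StressDetection],
                   annotations: Mapping[str, StressAnnotation]
                   ) -> MetricsReport:
    """Exact-level metrics: a detection counts only when the detected
    level equals the annotated level."""
    return MetricsReport({c: _category_metrics(detections, annotations, c,
                                               exact=True)
                          for c in ALL_CATEGORIES})


def evaluate_binary(detections: Mapping[str, StressDetection],
                    annotations: Mapping[str, StressAnnotation]
                    ) -> MetricsReport:
    """Stressful-or-not metrics: levels 1-3 collapse to 'stressful'."""
    return MetricsReport({c: _category_metrics(detections, annotations, c,
                                               exact=False)
                          for c in ALL_CATEGORIES})


@dataclass
class LevelDiffReport:
    """Lower/equal/higher proportions over (tweet, category) pairs that
    are both annotated stressful and detected nonzero."""

    lower: Optional[float]
    equal: Optional[float]
    higher: Optional[float]
    n: int


def evaluate_level_diff(detections: Mapping[str, StressDetection],
                        annotations: Mapping[str, StressAnnotation]
                        ) -> LevelDiffReport:
    lower = equal = higher = 0
    for tid, det in detections.items():
        for cat in CATEGORIES:
            a = _annotated_level(annotations, tid, cat)
            d = det.level(cat)
            if a > 0 and d > 0:
                if d < a:
                    lower += 1
                elif d == a:
                    equal += 1
                else:
                    higher += 1
    n = lower + equal + higher
    if n == 0:
        return LevelDiffReport(None, None, None, 0)
    return LevelDiffReport(lower / n, equal / n, higher / n, n)


# ---------------------------------------------------------------------------
# information gain

def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def discretize(values: np.ndarray, bins: int = 10) -> np.ndarray:
    """Equal-width binning over the observed range; features with at
    most ``bins`` distinct values (flags, counts, levels) are used
    as-is."""
    values = np.asarray(values, dtype=float)
    uniq = np.unique(values)
    if len(uniq) <= bins:
        return np.searchsorted(uniq, values)
    lo, hi = values.min(), values.max()
    edges = np.linspace(lo, hi, bins + 1)
    return np.clip(np.digitize(values, edges[1:-1]), 0, bins - 1)


def info_gain(feature_values: Sequence[float],
              labels: Sequence, bins: int = 10) -> float:
    """InfoGain(L,C|F) = H(L,C) - H(L,C|F), natural log, 0*log0 = 0."""
    values = np.asarray(feature_values, dtype=float)
    if len(values) == 0:
        raise ValueError("need at least one observation")
    codes = pd.factorize(pd.Series(labels).astype(str))[0]
    n_labels = codes.max() + 1
    h_joint = _entropy(np.bincount(codes, minlength=n_labels))
    binned = discretize(values, bins)
    h_cond = 0.0
    n = len(values)
    for b in np.unique(binned):
        mask = binned == b
        h_cond += mask.sum() / n * _entropy(
            np.bincount(codes[mask], minlength=n_labels))
    return h_joint - h_cond


@dataclass
class InfoGainTable:
    """Average information gain per feature, ranked descending."""

    gains: pd.DataFrame  # columns: feature, info_gain

    @property
    def ranking(self) -> list[str]:
        return self.gains["feature"].tolist()


def feature_impact_report(labeled: pd.DataFrame, bins: int = 10
                          ) -> InfoGainTable:
    """Per feature: information gain of the stress level computed within
    each category's vector subset, averaged across the five categories."""
    if labeled.empty:
        raise ValueError("labeled vectors required")
    records = []
    for feat in FEATURE_COLUMNS:
        gains = []
        for cat in ALL_CATEGORIES:
            sub = labeled[labeled["category"] == cat]
            if sub.empty:
                continue
            gains.append(info_gain(sub[feat].to_numpy(float),
                                   sub["label"].tolist(), bins))
        records.append({"feature": feat, "info_gain": float(np.mean(gains))})
    df = pd.DataFrame(records).sort_values(
        "info_gain", ascending=False, kind="mergesort").reset_index(drop=True)
    return InfoGainTable(gains=df)
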