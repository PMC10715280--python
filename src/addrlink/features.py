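"""Candidate features and the random-forest matching classifier.

Each (input address, gazetteer record) candidate is summarised by 52
features: four alignment metrics for each of the eleven fields (fraction of
the input aligned, fraction of the field aligned, number of insertions,
character-frequency cosine similarity), plus eight overall features (mean
cosine similarity over non-blank fields; digit characters and isolated
single-character tokens left in the input residual and in the unaligned
portions of the record's fields; and the sums of the two aligned fractions
and of the harmonic means).

A random forest is trained on labelled pairs: annotated true matches serve
as positives, and negatives are sampled from records sharing the true
record's postcode — the hardest nearby non-matches, which is exactly the
candidate set the tree search produces at matching time.  The forest's
class-probability output is used directly as the matching confidence score
(no calibration).
"""

from __future__ import annotations

import logging
import random
import re
from dataclasses import dataclass
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import ReferenceLookupError, SchemaError, TrainingError
from .gazetteer import GazetteerRecord, SubsumptionMap
from .preprocess import clean, complete_or_prune
from .schema import SCHEMA_11
from .treedb import CandidateAlignmentSet, align_pair

log = logging.getLogger(__name__)

__all__ = ["CandidateFeatures", "LabeledPair", "MatchModel", "feature_names",
           "make_features", "assemble_training", "train", "score", "score_many",
           "save_model", "load_model"]

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")

_PER_FIELD_METRICS = (
    ("pct aligned in input", "pct_input"),
    ("pct aligned in field", "pct_field"),
    ("n insertions", "insertions"),
    ("char frequency cosine", "char_cos"),
)
_OVERALL = (
    "mean char frequency cosine (non-blank fields)",
    "digits in input residual",
    "single-char tokens in input residual",
    "digits in field residual",
    "single-char tokens in field residual",
    "sum pct aligned in input",
    "sum pct aligned in field",
    "sum harmonic mean",
)


def feature_names(schema: Sequence[str] = SCHEMA_11) -> list[str]:
    """The 52 feature names, grouped metric-by-metric then the 8 overall."""
    names = [f"{label} [{f}]" for label, _ in _PER_FIELD_METRICS for f in schema]
    names.extend(_OVERALL)
    return names


@dataclass(frozen=True)
class CandidateFeatures:
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self):
        if len(self.values) != len(self.names):
            raise SchemaError("feature values and names differ in length")


def _residual_counts(tokens: list[str]) -> tuple[int, int]:
    digits = sum(ch.isdigit() for t in tokens for ch in t)
    singles = sum(1 for t in tokens if len(t) == 1)
    return digits, singles


def make_features(
    cand: CandidateAlignmentSet, schema: Sequence[str] = SCHEMA_11
) -> CandidateFeatures:
    """Turn one candidate alignment set into the 52-dimensional feature vector."""
    missing = [f for f in schema if f not in cand.per_field]
    if missing:
        raise SchemaError(f"candidate lacks alignments for field(s): {', '.join(missing)}")
    fas = [cand.per_field[f] for f in schema]
    values: list[float] = []
    for _, attr in _PER_FIELD_METRICS:
        values.extend(float(getattr(fa, attr)) for fa in fas)

    nonblank = [f for f in schema if cand.record.fields.get(f, "")]
    mean_cos = (
        float(np.mean([cand.per_field[f].char_cos for f in nonblank])) if nonblank else 0.0
    )

    in_tokens = _TOKEN_RE.findall(cand.residual_input)
    digits_in, singles_in = _residual_counts(in_tokens)

    field_tokens: list[str] = []
    for f in nonblank:
        value = cand.record.fields[f]
        covered = set()
        for s, e in cand.per_field[f].field_spans:
            covered.update(range(s, e))
        residual = "".join(ch if i not in covered else " " for i, ch in enumerate(value))
        field_tokens.extend(_TOKEN_RE.findall(residual))
    digits_f, singles_f = _residual_counts(field_tokens)

    values.extend([
        mean_cos,
        float(digits_in),
        float(singles_in),
        float(digits_f),
        float(singles_f),
        float(sum(fa.pct_input for fa in fas)),
        float(sum(fa.pct_field for fa in fas)),
        float(sum(fa.harmonic_mean for fa in fas)),
    ])
    return CandidateFeatures(np.asarray(values, dtype=float), tuple(feature_names(schema)))


@dataclass(frozen=True)
class LabeledPair:
    input_id: str
    uprn: str
    label: int  # 1 = match, 0 = non-match
    features: CandidateFeatures


def best_alignment(
    masked: str, variants: Sequence[GazetteerRecord]
) -> CandidateAlignmentSet:
    """Align the input against every variant of one property; keep the best.

    Mirrors matching time, where a hit on any augmented variant counts for
    the canonical record; "best" is the largest sum of harmonic means, ties
    broken by record key.
    """
    cands = [align_pair(masked, rec) for rec in variants]
    return max(
        cands,
        key=lambda c: (sum(fa.harmonic_mean for fa in c.per_field.values()), c.record.key),
    )


def assemble_training(
    annotations: pd.DataFrame,
    records: Sequence[GazetteerRecord],
    smap: SubsumptionMap,
    seed: int,
    negatives_cap: int = 20,
    schema: Sequence[str] = SCHEMA_11,
) -> list[LabeledPair]:
    """Build labelled (input, record) pairs from an annotation table.

    ``annotations`` needs columns ``input_id``, ``address`` and ``uprn``
    (rows whose ``uprn`` is empty — the not-possible labels — are skipped).
    One positive pair per annotation; up to ``negatives_cap`` negatives drawn
    without replacement from properties sharing the true record's postcode.
    Deterministic for a given seed.
    """
    by_canonical: dict[str, list[GazetteerRecord]] = {}
    for rec in records:
        by_canonical.setdefault(rec.canonical_uprn, []).append(rec)
    by_postcode: dict[str, set[str]] = {}
    for rec in records:
        if not rec.is_augmented:
            by_postcode.setdefault(rec.fields.get("POSTCODE", ""), set()).add(rec.uprn)

    unknown = [
        str(row.uprn)
        for row in annotations.itertuples()
        if str(getattr(row, "uprn", "") or "") and str(row.uprn) not in by_canonical
    ]
    if unknown:
        raise ReferenceLookupError(f"annotation uprn(s) not in gazetteer: {', '.join(unknown)}")

    rng = random.Random(seed)
    pairs: list[LabeledPair] = []
    for row in annotations.itertuples():
        uprn = str(getattr(row, "uprn", "") or "")
        if not uprn:
            continue
        masked = complete_or_prune(clean(str(row.address)), smap)
        input_id = str(getattr(row, "input_id", ""))
        pos = best_alignment(masked, by_canonical[uprn])
        pairs.append(LabeledPair(input_id, uprn, 1, make_features(pos, schema)))
        true_std = next(r for r in by_canonical[uprn] if not r.is_augmented)
        neighbours = sorted(by_postcode.get(true_std.fields.get("POSTCODE", ""), set()) - {uprn})
        if len(neighbours) > negatives_cap:
            neighbours = rng.sample(neighbours, negatives_cap)
        for neg in neighbours:
            cand = best_alignment(masked, by_canonical[neg])
            pairs.append(LabeledPair(input_id, neg, 0, make_features(cand, schema)))
    return pairs


@dataclass
class MatchModel:
    """A trained matching classifier with its feature schema and threshold."""

    classifier: RandomForestClassifier
    names: tuple[str, ...]
    seed: int
    threshold: float = 0.5
    oob_accuracy: float | None = None


def train(
    pairs: Sequence[LabeledPair],
    seed: int = 0,
    n_estimators: int = 500,
    threshold: float = 0.5,
    **rf_params,
) -> MatchModel:
    """Fit the random-forest matcher on labelled pairs.

    Defaults: 500 trees, unlimited depth, sqrt-of-p features per split.  The
    out-of-bag accuracy is logged as a training diagnostic.  Raises
    :class:`TrainingError` if only one class is present.
    """
    if not pairs:
        raise TrainingError("no training pairs")
    labels = {p.label for p in pairs}
    if labels != {0, 1}:
        raise TrainingError(f"training data must contain both classes, got labels {sorted(labels)}")
    names = pairs[0].features.names
    X = np.vstack([p.features.values for p in pairs])
    y = np.array([p.label for p in pairs])
    clf = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        random_state=seed,
        oob_score=True,
        n_jobs=1,
        **rf_params,
    )
    clf.fit(X, y)
    oob = float(getattr(clf, "oob_score_", float("nan")))
    log.info("matcher trained on %d pairs (%d positive); OOB accuracy %.3f",
             len(pairs), int(y.sum()), oob)
    return MatchModel(clf, names, seed, threshold, oob)


def _check_names(model: MatchModel, feats: CandidateFeatures) -> None:
    if tuple(feats.names) != tuple(model.names):
        raise SchemaError("feature names do not match the model's feature schema")


def score(model: MatchModel, feats: CandidateFeatures) -> float:
    """Probability that the candidate pair is a true match."""
    return float(score_many(model, [feats])[0])


def score_many(model: MatchModel, feats_list: Sequence[CandidateFeatures]) -> np.ndarray:
    """Vectorised scoring of many candidates (probability of the match class)."""
    if not feats_list:
        return np.empty(0)
    for feats in feats_list:
        _check_names(model, feats)
    X = np.vstack([f.values for f in feats_list])
    proba = model.classifier.predict_proba(X)
    match_col = list(model.classifier.classes_).index(1)
    return proba[:, match_col]


def save_model(model: MatchModel, path) -> None:
    joblib.dump(
        {"classifier": model.classifier, "names": list(model.names),
         "seed": model.seed, "threshold": model.threshold,
         "oob_accuracy": model.oob_accuracy},
        path,
    )


def load_model(path) -> MatchModel:
    blob = joblib.load(path)
    return MatchModel(blob["classifier"], tuple(blob["names"]), blob["seed"],
                      blob["threshold"], blob.get("oob_accuracy"))
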