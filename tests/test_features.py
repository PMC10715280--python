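"""The 52-feature contract, training-pair assembly, and the matcher."""

import numpy as np
import pandas as pd
import pytest

from addrlink import (CandidateFeatures, GazetteerRecord, LabeledPair,
                      SubsumptionMap, TrainingError, assemble_training,
                      feature_names, make_features, render_address, score,
                      score_many, train)
from addrlink.features import best_alignment, load_model, save_model
from addrlink.schema import SCHEMA_11
from addrlink.treedb import align_pair


def _record(uprn, **fields):
    base = {f: "" for f in SCHEMA_11}
    base.update(fields)
    return GazetteerRecord(uprn=uprn, fields=base)


def test_feature_vector_has_52_stable_names():
    names = feature_names()
    assert len(names) == 52
    assert len(set(names)) == 52
    # 4 per-field metrics x 11 fields, then 8 overall
    assert sum(1 for n in names if "[" in n) == 44


def test_make_features_length_and_order():
    rec = _record("U1", **{"BUILDING NUMBER": "5", "THOROUGHFARE": "BRUNSWICK ROAD",
                           "POST TOWN": "EDINBURGH", "POSTCODE": "ZZ1 1AA"})
    cand = align_pair(render_address(rec), rec)
    feats = make_features(cand)
    assert len(feats.values) == 52
    assert list(feats.names) == feature_names()


def test_all_blank_record_zeroes_alignment_features():
    rec = _record("U1")
    cand = align_pair("SOME TEXT WITHOUT NUMBERS", rec)
    feats = make_features(cand)
    # all 44 per-field metrics, the mean cosine and the three sums are zero
    named = dict(zip(feats.names, feats.values))
    assert all(v == 0 for n, v in named.items() if "[" in n)
    assert named["mean char frequency cosine (non-blank fields)"] == 0
    assert named["sum pct aligned in input"] == 0
    assert named["sum pct aligned in field"] == 0
    assert named["sum harmonic mean"] == 0


def test_perfect_match_sums_equal_field_count():
    rec = _record("U1", **{"BUILDING NUMBER": "5", "THOROUGHFARE": "BRUNSWICK ROAD",
                           "DEPENDENT LOCALITY": "METHIL", "POST TOWN": "LEVEN",
                           "POSTCODE": "ZZ1 1AA"})
    k = sum(1 for f in SCHEMA_11 if rec.fields[f])
    cand = align_pair(render_address(rec), rec)
    feats = make_features(cand)
    named = dict(zip(feats.names, feats.values))
    assert named["sum pct aligned in field"] == pytest.approx(k)
    # every field fully aligned: each harmonic mean is positive, the last
    # field consumes all remaining input (M = 1), and the sum is capped by k
    assert 1.0 <= named["sum harmonic mean"] <= k
    # the whole input is consumed: no residual digits or single characters
    assert named["digits in input residual"] == 0
    assert named["single-char tokens in input residual"] == 0


def test_residual_counts_follow_unaligned_text():
    rec = _record("U1", THOROUGHFARE="BRUNSWICK ROAD", POSTCODE="ZZ1 1AA")
    cand = align_pair("BRUNSWICK ROAD, ZZ1 1AA, EXTRA 42 X", rec)
    feats = make_features(cand)
    named = dict(zip(feats.names, feats.values))
    assert named["digits in input residual"] == 2  # "42"
    assert named["single-char tokens in input residual"] == 1  # "X"


# ---------------------------------------------------------------------------
# Training-pair assembly


@pytest.fixture
def small_world():
    recs = [
        _record(f"U{i}", **{"BUILDING NUMBER": str(i), "THOROUGHFARE": "BRUNSWICK ROAD",
                            "POST TOWN": "EDINBURGH", "POSTCODE": "ZZ1 1AA"})
        for i in range(1, 7)
    ]
    smap = SubsumptionMap()
    ann = pd.DataFrame([{"input_id": "A1", "address": render_address(recs[0]), "uprn": "U1"}])
    return recs, smap, ann


def test_assemble_training_exclusion_rule(small_world):
    recs, smap, ann = small_world
    pairs = assemble_training(ann, recs, smap, seed=0, negatives_cap=10)
    assert sum(p.label == 1 for p in pairs) == 1
    negs = [p for p in pairs if p.label == 0]
    assert len(negs) == 5  # 6 records in the postcode minus the true one
    assert all(p.uprn != "U1" for p in negs)


def test_assemble_training_lone_record_gives_no_negatives():
    rec = _record("U1", **{"BUILDING NUMBER": "1", "THOROUGHFARE": "X ROAD",
                           "POSTCODE": "ZZ1 1AA"})
    ann = pd.DataFrame([{"input_id": "A1", "address": render_address(rec), "uprn": "U1"}])
    pairs = assemble_training(ann, [rec], SubsumptionMap(), seed=0)
    assert [p.label for p in pairs] == [1]


def test_assemble_training_deterministic(small_world):
    recs, smap, ann = small_world
    runs = [assemble_training(ann, recs, smap, seed=3, negatives_cap=3) for _ in range(2)]
    assert [(p.uprn, p.label) for p in runs[0]] == [(p.uprn, p.label) for p in runs[1]]
    assert all(np.array_equal(a.features.values, b.features.values)
               for a, b in zip(*runs))


def test_assemble_training_unknown_uprn_lists_offender(small_world):
    recs, smap, _ = small_world
    ann = pd.DataFrame([{"input_id": "A1", "address": "1 X ROAD", "uprn": "GHOST"}])
    with pytest.raises(Exception, match="GHOST"):
        assemble_training(ann, recs, smap, seed=0)


# ---------------------------------------------------------------------------
# The random-forest matcher


def _fake_pairs(n, rng, separable=True):
    names = tuple(feature_names())
    pairs = []
    for i in range(n):
        label = i % 2
        values = rng.uniform(0, 0.3, 52)
        if separable and label:
            values[-1] = rng.uniform(3.0, 5.0)  # sum of harmonic means high
        pairs.append(LabeledPair(f"I{i}", f"U{i}", label,
                                 CandidateFeatures(values, names)))
    return pairs


def test_train_separable_fixture_perfect_holdout():
    rng = np.random.default_rng(1)
    pairs = _fake_pairs(400, rng)
    model = train(pairs[:300], seed=0, n_estimators=100)
    probs = score_many(model, [p.features for p in pairs[300:]])
    preds = (probs >= 0.5).astype(int)
    truth = np.array([p.label for p in pairs[300:]])
    assert (preds == truth).mean() == 1.0


def test_train_shuffled_labels_near_chance():
    rng = np.random.default_rng(2)
    pairs = _fake_pairs(2000, rng, separable=False)  # labels independent of features
    model = train(pairs[:1600], seed=0, n_estimators=100)
    probs = score_many(model, [p.features for p in pairs[1600:]])
    truth = np.array([p.label for p in pairs[1600:]])
    acc = ((probs >= 0.5).astype(int) == truth).mean()
    assert abs(acc - 0.5) < 0.1


def test_train_single_class_raises():
    rng = np.random.default_rng(3)
    pairs = [p for p in _fake_pairs(20, rng) if p.label == 1]
    with pytest.raises(TrainingError):
        train(pairs, seed=0)


def test_same_seed_identical_predictions():
    rng = np.random.default_rng(4)
    pairs = _fake_pairs(200, rng)
    test_feats = [p.features for p in _fake_pairs(50, np.random.default_rng(5))]
    probs = [score_many(train(pairs, seed=9, n_estimators=100), test_feats)
             for _ in range(2)]
    assert np.array_equal(probs[0], probs[1])


def test_score_bounds_and_name_check():
    rng = np.random.default_rng(6)
    model = train(_fake_pairs(100, rng), seed=0, n_estimators=50)
    for p in _fake_pairs(20, rng):
        assert 0.0 <= score(model, p.features) <= 1.0
    bad = CandidateFeatures(np.zeros(52), tuple(f"f{i}" for i in range(52)))
    with pytest.raises(Exception, match="schema|names"):
        score(model, bad)


def test_model_roundtrip(tmp_path):
    rng = np.random.default_rng(7)
    model = train(_fake_pairs(100, rng), seed=0, n_estimators=50)
    path = tmp_path / "model.joblib"
    save_model(model, path)
    loaded = load_model(path)
    feats = [p.features for p in _fake_pairs(10, rng)]
    assert np.array_equal(score_many(model, feats), score_many(loaded, feats))
    assert loaded.names == model.names and loaded.threshold == model.threshold


def test_class_separation_on_synthetic_pairs(gaz120):
    """True pairs score higher on average than same-postcode false pairs."""
    import addrlink as al
    _, ann = al.make_benchmark(gaz120, 25, al.CorruptionProfile(typo=0.1), seed=77)
    recs = al.augment_gazetteer(gaz120)
    smap = al.build_subsumption_map(recs)
    pairs = assemble_training(ann, recs, smap, seed=77)
    model = train(pairs, seed=77, n_estimators=100)
    pos = score_many(model, [p.features for p in pairs if p.label == 1])
    neg = score_many(model, [p.features for p in pairs if p.label == 0])
    assert pos.mean() > neg.mean()
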