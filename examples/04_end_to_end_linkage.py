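"""Train the matcher and link corrupted free-text addresses end to end.

Workflow: augment the gazetteer, build the blocking trees, assemble labelled
training pairs (annotated true matches + same-postcode negatives), fit the
random forest, then match a held-out corrupted benchmark and evaluate the
predictions: raw and adjusted accuracy, top-5 accuracy, and the
precision/recall/F1 table across confidence thresholds (lift-curve data).
"""

from addrlink import CorruptionProfile, evaluate, make_benchmark, make_toy_gazetteer, train_linker

records = make_toy_gazetteer(300, seed=5)

train_profile = CorruptionProfile(typo=0.1, abbreviation=0.2, flat_flip=0.3,
                                  locality_dropout=0.1, county_insertion=0.1)
_, train_annotations = make_benchmark(records, 80, train_profile, seed=6)
linker = train_linker(records, train_annotations, seed=6)
print(f"matcher trained; out-of-bag accuracy {linker.model.oob_accuracy:.3f}")

eval_profile = CorruptionProfile(typo=0.2, abbreviation=0.3, flat_flip=0.3,
                                 wrong_postcode=0.1, not_in_db=0.05)
inputs, annotations = make_benchmark(records, 60, eval_profile, seed=7)

predictions = linker.match_table(inputs)
print("\nfirst ranked candidates for one input:")
print(predictions[predictions.input_id == "IN00000"].to_string(index=False))

report = evaluate(predictions, annotations)
print("\n" + report.summary())
print("\nthreshold sweep (every 4th row):")
print(report.thresholds.iloc[::4].to_string(index=False))
print("\nRaw accuracy divides correct top-1 matches by all inputs; adjusted")
print("accuracy divides by the inputs a human could match (out-of-database")
print("inputs are excluded there). Raising the threshold trades recall for")
print("precision - the sweep shows where that trade sits for this benchmark.")
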