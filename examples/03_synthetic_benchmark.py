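"""Generate a synthetic gazetteer and a corrupted free-text benchmark.

Real property gazetteers and health-register addresses are licensed, so the
package ships a generator that emulates their structure: multi-property
postcodes in a reserved fake ZZ area, localities nested in post towns, flats
and organisation names.  A corruption profile then produces free-text inputs
exhibiting the documented variation taxonomy (typos, abbreviations,
flat-format flips, wrong postcodes, dropped localities, inserted counties,
out-of-database addresses), with the true identifier as annotation.
"""

from addrlink import CorruptionProfile, make_benchmark, make_toy_gazetteer

records = make_toy_gazetteer(200, seed=42)
postcodes = {r.fields["POSTCODE"] for r in records}
print(f"gazetteer: {len(records)} records across {len(postcodes)} postcodes, "
      f"{len({r.fields['POST TOWN'] for r in records})} post towns")

profile = CorruptionProfile(typo=0.3, abbreviation=0.4, flat_flip=0.5,
                            locality_dropout=0.3, county_insertion=0.2,
                            wrong_postcode=0.1, not_in_db=0.05)
inputs, annotations = make_benchmark(records, 8, profile, seed=1)

print("\ncorrupted inputs (annotation on the right):")
for row in annotations.itertuples():
    truth = row.uprn if row.uprn else row.label
    print(f"  {row.address:<62} -> {truth}")

clean_inputs, _ = make_benchmark(records, 3, CorruptionProfile(), seed=1)
print("\nthe same draw without corruption:")
for row in clean_inputs.itertuples():
    print(f"  {row.address}")
print("\nEach corrupted line is what a busy records clerk might type; the")
print("annotation column is the ground truth the matcher must recover.")
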