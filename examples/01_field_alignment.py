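"""Fuzzy field-to-text alignment: the engine under every matching decision.

Aligns gazetteer field values inside free-text inputs with the dual
token-/string-based approach and prints the alignment metrics: the fraction
of field and input characters aligned, their harmonic mean M, the number of
gap openings I, the character-frequency cosine F, and the summary score
S = M - 0.01*I + 0.1*F that picks between the two methods.
"""

from addrlink import align_field, string_align, token_align

CASES = [
    # (input free text, gazetteer field value)
    ("5/1 BRUNSWICK ROAD EDINBURGH", "BRUNSWICK ROAD"),   # exact containment
    ("5/1 BRUNSWIK ROAD EDINBURGH", "BRUNSWICK ROAD"),    # one typo, fuzzy token
    ("GREENBANK TERRACE", "GREEN BANK TERRACE"),          # word concatenation
    ("17 WILSON ST", "WILSON STREET"),                    # abbreviation (unresolvable here)
]

for input_text, field_value in CASES:
    fa = align_field(input_text, field_value)
    print(f"input  {input_text!r}")
    print(f"field  {field_value!r}")
    print(f"  chosen method: {fa.method}   "
          f"(token S = {token_align(input_text, field_value).score:.3f}, "
          f"string S = {string_align(input_text, field_value).score:.3f})")
    print(f"  pct_field = {fa.pct_field:.2f}  pct_input = {fa.pct_input:.2f}  "
          f"M = {fa.harmonic_mean:.2f}  I = {fa.insertions}  F = {fa.char_cos:.2f}  "
          f"S = {fa.score:.3f}")
    print()

print("pct_field = 1.00 means the whole field value was located in the input;")
print("the concatenation case only reaches that through the string method.")
print("'ST' vs 'STREET' stays unaligned (4 edits in 6 letters exceeds the 0.2")
print("tolerance) - that variation is handled by database augmentation instead.")
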