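# Methods

This note documents the models and procedures implemented in `addrlink`,
their assumptions, the parameters that matter, and the numerical choices
made where the design was genuinely open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Task and assumptions

Given a free-text address *s* and a gazetteer of property records *d* (one
unique identifier plus eleven textual fields), decide which record, if any,
*s* refers to. The pipeline assumes: (i) the gazetteer is authoritative and
internally consistent — every property has exactly one standard rendering;
(ii) inputs are one address per row, UK-style (postcode grammar, post
town / locality / thoroughfare vocabulary); (iii) most inputs contain either
a recognisable postcode or a recognisable post-town/thoroughfare pair —
blocking cannot recover inputs with neither, and such inputs are reported as
unmatchable at the blocking stage rather than guessed.

The eleven-field schema defaults to the Royal Mail PAF premise-element set
(`schema.SCHEMA_11`) and is configurable. Matching is one-to-one; inputs
covering several properties ("too broad") are out of scope and should be
annotated as such.

## Alignment model

Every field value is located inside the input by global alignment, twice:

* **Token pass** — both strings are tokenised on non-word characters and
  aligned by Needleman–Wunsch; tokens are equal when their unrestricted
  Damerau–Levenshtein distance divided by the longer token is ≤ 0.2 ("less
  than one error in five letters"). The unrestricted (Lowrance–Wagner)
  edit distance is used rather than the restricted/OSA variant because it is
  a true metric — the triangle inequality holds, which the property tests
  rely on — and the two only differ on degenerate overlapping-edit cases.
* **String pass** — the raw character sequences are aligned; afterwards each
  field-token span whose characters matched below 80% is discarded (the
  string-level counterpart of the 0.2 token tolerance). This pass handles
  word concatenation (`GREENBANK` vs `GREEN BANK`), which token alignment
  cannot.

Metrics per pass: `pct_input` and `pct_field` (fraction of word characters
aligned on each side), their harmonic mean *M*, gap openings *inside* the
matched region *I* (flanking unaligned input is expected in free text and
not penalised), and the character-frequency cosine *F* between the field and
the concatenated aligned input text (measuring the quality of what was
matched, not of the whole input). The summary score *S = M − 0.01·I + 0.1·F*
selects the better pass; ties go to the token pass. Note that the harmonic
mean lies between min and max of the two percentages (and is ≤ 2·min) — it
is not bounded by the smaller one.

NW scoring is the simplest scheme (match +1, mismatch −1, gap −1, no affine
extension) with a deterministic diagonal-first traceback. `pct_input` is
computed against the not-yet-redacted input at the time of alignment, so the
feature stays comparable across fields as redaction consumes text; a
consequence is that for a perfect full-address match the per-field *M*
values are < 1 for all but the last field aligned (each field can only cover
part of the remaining input), while `pct_field` is 1 for every field.

Empty fields yield zero-metric alignments. Redacted input positions are
masked with NUL, which is not a word character, so redacted text is
invisible to both passes while coordinates stay stable.

## Blocking

The augmented gazetteer is converted to a layered tree twice: a primary tree
with POSTCODE as the first layer and a secondary tree starting POST TOWN →
THOROUGHFARE (the two DFS modes need different top layers). The record key
is appended as a final tiebreak layer so every leaf holds one record even
when two records share all field values. Layer order then runs broad →
specific.

DFS selects one child per step. The selection score is field coverage
penalised like *S* (`pct_field − 0.01·I + 0.1·F`) rather than the *M*-based
*S*: a short node name inside a long input caps *M* far below any usable
floor, so an *M*-based floor would block every input. Floors are 0.5 for the
postcode layer and 0.6 for town/thoroughfare layers (configurable); without
a floor, garbage inputs would always block somewhere. When a parsed hint
exists, children whose name is within the same DL ≤ 0.2 tolerance of the
hint are tried nearest-first before the full align-and-rank scan over
siblings — coverage scores cannot reliably separate one-edit postcode
siblings (the 80% span rule drops a 2/3-covered incode token for every
sibling, leaving the choice to cosine noise), whereas edit distance to the
hint can.

BFS under the chosen node aligns each child name against that branch's
redacted input, redacts the newly aligned positions, and recurses; children
are visited in sorted order, so candidate lists are deterministic. Blank
field values pass through without alignment or redaction. If postcode
blocking yields no candidate above the decision threshold, the matcher
retries the secondary tree and keeps the better result (logged as a
fallback) — this is what recovers inputs whose postcode is simply wrong.

## Features and classifier

52 features per candidate: `pct_input`, `pct_field`, *I*, *F* for each of
the 11 fields (44), plus mean *F* over non-blank fields, digit characters
and isolated single-character tokens in the input residual and in the
unaligned portions of the record's fields, and the sums of `pct_input`,
`pct_field` and *M* (8). Residual counts are counts of characters/tokens
(counts subsume flags); the mean cosine averages over non-blank fields only.
For an all-blank record the 44 per-field features, the mean cosine and the
three sums are zero; the input-residual counts reflect the actual residual
(the whole input, in that case) — residual features describe the input, not
the record.

The classifier is a scikit-learn `RandomForestClassifier`: 500 trees,
unlimited depth, √p features per split, fixed seed, no probability
calibration (the raw vote fraction is the confidence score). A forest
tolerates the many zero-valued features (blank fields) and the strong
co-linearity among alignment metrics. Positives come from annotation;
negatives are sampled per positive from properties sharing the true
record's postcode (cap 20, seeded) — the hardest nearby non-matches and
exactly the candidate population seen at matching time. Training features
are computed against the best-aligning variant of each property, mirroring
matching, where a hit on any variant counts for the canonical identifier.
Out-of-bag accuracy is logged as a training diagnostic. Scores for one
input are deduplicated per canonical identifier (best variant wins), sorted
by descending probability with lexicographic identifier tiebreak, and cut
at top-*n* (default 5) with accept/reject at *t* = 0.5.

## Synthetic data

`make_toy_gazetteer` emulates the gazetteer structure the matcher depends
on: ~7 records per postcode, 2 dependent localities per post town on about
half the records (so subsumption knowledge is learnable), 25% flats, 8%
organisation names, all postcodes in the reserved fake `ZZ` area so fixtures
can never collide with real addresses. `corrupt` applies, at configured
rates: one random character edit per eligible token (alphabetic, ≥ 5
letters — where real typographical errors concentrate), street-type
abbreviation, flat-format flips, one wrong incode digit, locality dropout,
county insertion, and out-of-database injection (label `NOT_IN_DB`).
Benchmarks draw records round-robin across postcodes, emulating
per-postcode stratified sampling at toy scale.

What the generator does *not* emulate: realistic address-frequency
distributions, care-home oversampling beyond the organisation-name share,
non-UK schemas, multi-occupancy ambiguity beyond flats, or free-text noise
outside the taxonomy above. Passing tests therefore show the pipeline's
mechanics are correct and robust to the modelled variations — not that the
published real-data accuracy transfers to any particular register.

## Problem sizes and study conditions

The end-to-end checks run on a 500-record gazetteer: training on 140 inputs
at low corruption (typo 0.1, abbreviation 0.2, flat flip 0.3, locality
dropout 0.1, county insertion 0.1), evaluation on a disjoint 100-input
zero-corruption benchmark (expected perfect recovery) and on 5 seeds × 40
inputs at typo 0.2 + abbreviation 0.3. Unit fixtures use 120 records.
These sizes exercise every code path — multi-town blocking, fuzzy postcode
descent, variant deduplication — while keeping the suite quick.

## Numerical choices and degenerate inputs

* Thresholds: token equality 0.2 (normalised DL), span retention 0.8, DFS
  floors 0.5/0.6, decision threshold 0.5, threshold grid 0 … 1 step 0.05.
* Ties: NW traceback prefers diagonal; align-method tie → token pass; DFS
  sibling tie → alphabetical; candidate score tie → lexicographic
  identifier; subsumption parent conflict → majority, then alphabetical.
* Degenerate inputs: empty/all-stripped input → explicit empty signal;
  *p* = 0 → adjusted accuracy reported as undefined, never a division
  error; precision at `tp+fp = 0` → NaN in the sweep table; F1 at
  P = R = 0 → 0 with a warning.
* Determinism: all randomness flows through explicit seeds (generator,
  negative sampling, forest); identical seeds give byte-identical
  gazetteers, predictions and match tables.

## Known limitations

Blocking requires a usable postcode or town/thoroughfare pair; inputs with
neither are reported unmatchable rather than matched by exhaustive scan.
Token similarity is purely string-based (no semantic similarity between,
e.g., "home" and "house"). Field-to-text alignment is greedy in layer
order — conflicts between fields are not globally optimised. One-to-many
linkage of too-broad inputs is out of scope. The augmentation rule registry
is a default, extensible stand-in: the variation taxonomy it covers
(abbreviations, saint forms, flat formats, ranges) is documented, but site-
specific transformation inventories should be added through the registry and
alias table.
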