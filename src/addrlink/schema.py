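"""The 11-field textual address schema.

The gazetteer presents each property's textual address in eleven fields
(plus the unique property identifier).  The default field names follow the
Royal Mail PAF premise-element set; the set is configurable wherever a
schema argument is accepted, but all defaults below assume these names.
"""

from __future__ import annotations

#: Identifier column name expected in gazetteer tables.
UPRN_COLUMN = "UPRN"

#: The eleven textual address fields, broad → specific reading order reversed.
SCHEMA_11: tuple[str, ...] = (
    "ORGANISATION NAME",
    "DEPARTMENT NAME",
    "SUB BUILDING NAME",
    "BUILDING NAME",
    "BUILDING NUMBER",
    "DEPENDENT THOROUGHFARE",
    "THOROUGHFARE",
    "DOUBLE DEPENDENT LOCALITY",
    "DEPENDENT LOCALITY",
    "POST TOWN",
    "POSTCODE",
)

#: Region-type fields used for subsumption knowledge (child listed before parent).
REGION_FIELDS: tuple[str, ...] = (
    "DOUBLE DEPENDENT LOCALITY",
    "DEPENDENT LOCALITY",
    "POST TOWN",
)

#: Layer order of the primary blocking tree: postcode first (one-step DFS),
#: then broad → specific so structured information narrows the search early.
PRIMARY_LAYERS: tuple[str, ...] = (
    "POSTCODE",
    "POST TOWN",
    "DEPENDENT LOCALITY",
    "DOUBLE DEPENDENT LOCALITY",
    "THOROUGHFARE",
    "DEPENDENT THOROUGHFARE",
    "ORGANISATION NAME",
    "DEPARTMENT NAME",
    "BUILDING NAME",
    "SUB BUILDING NAME",
    "BUILDING NUMBER",
)

#: Layer order of the secondary tree: post town then thoroughfare (two-step DFS
#: for inputs without a usable postcode).
SECONDARY_LAYERS: tuple[str, ...] = (
    "POST TOWN",
    "THOROUGHFARE",
    "POSTCODE",
    "DEPENDENT LOCALITY",
    "DOUBLE DEPENDENT LOCALITY",
    "DEPENDENT THOROUGHFARE",
    "ORGANISATION NAME",
    "DEPARTMENT NAME",
    "BUILDING NAME",
    "SUB BUILDING NAME",
    "BUILDING NUMBER",
)

#: Sentinel layer appended below the last address field so every leaf holds
#: exactly one record even when two records share all eleven values.
RECORD_KEY_LAYER = "__RECORD_KEY__"

#: Annotation labels for inputs a human could not match one-to-one.
NOT_POSSIBLE_LABELS: frozenset[str] = frozenset({"NOT_IN_DB", "TOO_BROAD", "LOW_QUALITY"})
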