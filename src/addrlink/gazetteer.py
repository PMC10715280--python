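"""Structured address gazetteer: loading, augmentation and derived knowledge.

A gazetteer holds one row per property: an opaque unique identifier (UPRN)
plus eleven textual address fields.  Real inputs often use non-standard but
predictable renderings of the same property — abbreviated street types,
``5/1`` for ``FLAT 1, 5``, ``SAINT`` spelled out — so the database is
*augmented* with alternative-form records before matching.  Variants never
receive new identifiers: a hit on a variant is reported under the canonical
identifier of its source record.

Augmentation can also encode *local knowledge*: free-text aliases (a building
name, a local business) mapped by hand to an identifier, which lets inputs
with no textual similarity to the standard address match at all.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import IntegrityError, ReferenceLookupError, SchemaError
from .schema import REGION_FIELDS, SCHEMA_11, UPRN_COLUMN

log = logging.getLogger(__name__)

_WS = re.compile(r"\s+")


@dataclass(frozen=True)
class GazetteerRecord:
    """One property: identifier plus the 11 address fields.

    ``is_augmented`` marks alternative-form variants; ``canonical_uprn`` is
    the identifier of the source record (equal to ``uprn`` for standard
    records).  ``variant`` distinguishes multiple variants of one source and
    makes ``key`` unique across the augmented database.
    """

    uprn: str
    fields: Mapping[str, str]
    is_augmented: bool = False
    canonical_uprn: str = ""
    variant: int = 0

    def __post_init__(self):
        if not self.canonical_uprn:
            object.__setattr__(self, "canonical_uprn", self.uprn)

    @property
    def key(self) -> str:
        """Unique record key (tree leaf tiebreak); canonical uprn for standard rows."""
        return self.uprn if not self.is_augmented else f"{self.canonical_uprn}~{self.variant}"

    def rendered(self) -> str:
        """Canonical full-address string: non-empty fields in schema order."""
        return ", ".join(v for f in SCHEMA_11 if (v := self.fields.get(f, "")))

    def with_fields(self, variant: int, **updates: str) -> "GazetteerRecord":
        new_fields = dict(self.fields)
        new_fields.update(updates)
        return replace(
            self,
            fields=new_fields,
            is_augmented=True,
            canonical_uprn=self.canonical_uprn,
            variant=variant,
        )


@dataclass
class SubsumptionMap:
    """Region containment learned from the gazetteer (e.g. locality → post town)."""

    parent: dict[str, str] = field(default_factory=dict)
    known_regions: set[str] = field(default_factory=set)

    def chain(self, child: str) -> list[str]:
        """All ancestors of ``child``, nearest first."""
        out, seen = [], {child}
        cur = child
        while cur in self.parent and self.parent[cur] not in seen:
            cur = self.parent[cur]
            out.append(cur)
            seen.add(cur)
        return out


def _normalise(value) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    return _WS.sub(" ", str(value)).strip().upper()


def records_to_frame(records: Sequence[GazetteerRecord]) -> pd.DataFrame:
    """Standard (non-augmented) view of a record collection as a table."""
    rows = [
        {UPRN_COLUMN: r.uprn, **{f: r.fields.get(f, "") for f in SCHEMA_11}}
        for r in records
        if not r.is_augmented
    ]
    return pd.DataFrame(rows, columns=[UPRN_COLUMN, *SCHEMA_11])


def load_gazetteer(path, schema: Sequence[str] = SCHEMA_11, sep: str = ",") -> list[GazetteerRecord]:
    """Read a delimiter-separated gazetteer table into records.

    The header must contain the identifier column plus all schema columns.
    Values are upper-cased and whitespace-normalised; empty cells become
    empty strings.  Duplicate identifiers with differing fields raise
    :class:`IntegrityError`; exact duplicate rows are collapsed.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in (UPRN_COLUMN, *schema) if c not in df.columns]
    if missing:
        raise SchemaError(f"gazetteer file is missing column(s): {', '.join(missing)}")
    records: list[GazetteerRecord] = []
    seen: dict[str, GazetteerRecord] = {}
    for _, row in df.iterrows():
        uprn = _normalise(row[UPRN_COLUMN])
        if not uprn:
            raise IntegrityError("empty identifier in gazetteer row")
        rec = GazetteerRecord(uprn=uprn, fields={f: _normalise(row[f]) for f in schema})
        if uprn in seen:
            if seen[uprn].fields != rec.fields:
                raise IntegrityError(f"duplicate identifier {uprn} with differing fields")
            continue
        seen[uprn] = rec
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Augmentation rule registry

#: Street-type abbreviation pairs applied in both directions.
ABBREVIATION_PAIRS: tuple[tuple[str, str], ...] = (
    ("ROAD", "RD"),
    ("STREET", "ST"),
    ("AVENUE", "AVE"),
    ("DRIVE", "DR"),
    ("PLACE", "PL"),
    ("CRESCENT", "CRES"),
    ("GARDENS", "GDNS"),
    ("TERRACE", "TERR"),
    ("COURT", "CT"),
)

_ABBREV = {a: b for a, b in ABBREVIATION_PAIRS} | {b: a for a, b in ABBREVIATION_PAIRS}
_THOROUGHFARE_FIELDS = ("THOROUGHFARE", "DEPENDENT THOROUGHFARE")
_FLAT_RE = re.compile(r"^FLAT (\w+)$")
_RANGE_RE = re.compile(r"^(\d+)-(\d+)$")
_SAINT_FIELDS = ("THOROUGHFARE", "DEPENDENT THOROUGHFARE", "BUILDING NAME", "DEPENDENT LOCALITY", "POST TOWN")


def _rule_abbreviations(rec: GazetteerRecord) -> Iterable[dict[str, str]]:
    """Swap street-type words with their abbreviations (and back)."""
    for f in _THOROUGHFARE_FIELDS:
        value = rec.fields.get(f, "")
        if not value:
            continue
        words = value.split(" ")
        swapped = [_ABBREV.get(w, w) for w in words]
        if swapped != words:
            yield {f: " ".join(swapped)}


def _rule_saint(rec: GazetteerRecord) -> Iterable[dict[str, str]]:
    """``ST.`` / leading ``ST`` stands for ``SAINT`` in the gazetteer."""
    for f in _SAINT_FIELDS:
        value = rec.fields.get(f, "")
        if not value:
            continue
        if "ST." in value:
            yield {f: value.replace("ST.", "SAINT")}
        elif value.startswith("ST ") or value.startswith("SAINT "):
            other = "SAINT" if value.startswith("ST ") else "ST"
            yield {f: other + value[value.index(" "):]}


def _rule_flat_format(rec: GazetteerRecord) -> Iterable[dict[str, str]]:
    """``FLAT m`` + building number ``n`` ↔ ``n/m`` ↔ ``nFm``."""
    sub = rec.fields.get("SUB BUILDING NAME", "")
    num = rec.fields.get("BUILDING NUMBER", "")
    m = _FLAT_RE.match(sub)
    if m and num:
        flat = m.group(1)
        yield {"BUILDING NUMBER": f"{num}/{flat}", "SUB BUILDING NAME": ""}
        yield {"BUILDING NUMBER": f"{num}F{flat}", "SUB BUILDING NAME": ""}


def _rule_number_range(rec: GazetteerRecord, cap: int = 10) -> Iterable[dict[str, str]]:
    """Expand a building-number range ``a-b`` into its individual numbers."""
    m = _RANGE_RE.match(rec.fields.get("BUILDING NUMBER", ""))
    if not m:
        return
    lo, hi = int(m.group(1)), int(m.group(2))
    if lo < hi <= lo + cap:
        for n in range(lo, hi + 1):
            yield {"BUILDING NUMBER": str(n)}


#: Registered transformation rules; a stand-in default set covering street-type
#: abbreviations, saint forms, flat formats and range-like numbers.
RULE_REGISTRY = {
    "abbreviations": _rule_abbreviations,
    "saint": _rule_saint,
    "flat_format": _rule_flat_format,
    "number_range": _rule_number_range,
}

DEFAULT_RULES: tuple[str, ...] = tuple(RULE_REGISTRY)


def augment_gazetteer(
    records: Sequence[GazetteerRecord],
    rules: Sequence[str] | None = None,
    alias_table: pd.DataFrame | None = None,
) -> list[GazetteerRecord]:
    """Add alternative-form variant records to the gazetteer.

    ``rules`` names entries of :data:`RULE_REGISTRY` (default: all).
    ``alias_table`` is an optional two-column table ``(alias_text, uprn)``
    carrying local knowledge; each alias becomes a variant whose organisation
    name holds the alias text while the source's locality and postcode fields
    are kept so blocking still works.

    Variants whose rendered address collides with a record of a *different*
    canonical identifier are dropped and logged (consistency rule); identical
    renderings of the same source are de-duplicated.  With no rules and no
    aliases the input is returned unchanged (as a copy).
    """
    if rules is None:
        rules = DEFAULT_RULES
    unknown = [r for r in rules if r not in RULE_REGISTRY]
    if unknown:
        raise SchemaError(f"unknown augmentation rule(s): {', '.join(unknown)}")

    out = list(records)
    rendered_to_canonical: dict[str, str] = {}
    for rec in records:
        rendered_to_canonical.setdefault(rec.rendered(), rec.canonical_uprn)

    counters: Counter[str] = Counter()

    def _admit(variant: GazetteerRecord) -> None:
        text = variant.rendered()
        owner = rendered_to_canonical.get(text)
        if owner == variant.canonical_uprn:
            return  # duplicate rendering of the same property
        if owner is not None:
            log.warning(
                "dropping augmented variant of %s: rendering collides with %s (%r)",
                variant.canonical_uprn, owner, text,
            )
            return
        rendered_to_canonical[text] = variant.canonical_uprn
        out.append(variant)

    for rec in records:
        for rule_name in rules:
            for updates in RULE_REGISTRY[rule_name](rec):
                counters[rec.canonical_uprn] += 1
                _admit(rec.with_fields(counters[rec.canonical_uprn], **updates))

    if alias_table is not None and len(alias_table):
        by_uprn = {r.uprn: r for r in records if not r.is_augmented}
        cols = list(alias_table.columns[:2])
        for _, row in alias_table.iterrows():
            alias_text = _normalise(row[cols[0]])
            uprn = _normalise(row[cols[1]])
            src = by_uprn.get(uprn)
            if src is None:
                raise ReferenceLookupError(f"alias {alias_text!r} refers to unknown identifier {uprn}")
            counters[uprn] += 1
            keep = {
                f: src.fields.get(f, "")
                for f in ("DOUBLE DEPENDENT LOCALITY", "DEPENDENT LOCALITY", "POST TOWN", "POSTCODE")
            }
            blank = {f: "" for f in SCHEMA_11}
            _admit(src.with_fields(counters[uprn], **{**blank, **keep, "ORGANISATION NAME": alias_text}))

    return out


def check_consistency(records: Sequence[GazetteerRecord]) -> list[list[GazetteerRecord]]:
    """Groups of records whose rendered address collides across identifiers.

    An empty report means the (augmented) gazetteer is consistent: no two
    properties present the same full-address text.
    """
    groups: dict[str, list[GazetteerRecord]] = defaultdict(list)
    for rec in records:
        groups[rec.rendered()].append(rec)
    report = []
    for text, grp in groups.items():
        if len({r.canonical_uprn for r in grp}) > 1:
            report.append(grp)
    return report


def build_subsumption_map(records: Sequence[GazetteerRecord]) -> SubsumptionMap:
    """Learn region containment edges (child region → parent region).

    For every record where a dependent region field and its nearest non-empty
    parent field are both present, a child→parent edge is counted; conflicting
    parents for one child are resolved by majority (ties alphabetically) and
    logged.  ``known_regions`` collects every distinct non-empty region value.
    """
    votes: dict[str, Counter[str]] = defaultdict(Counter)
    known: set[str] = set()
    for rec in records:
        values = [rec.fields.get(f, "") for f in REGION_FIELDS]
        known.update(v for v in values if v)
        for i, child in enumerate(values[:-1]):
            if not child:
                continue
            parent = next((v for v in values[i + 1:] if v and v != child), "")
            if parent:
                votes[child][parent] += 1
    smap = SubsumptionMap(known_regions=known)
    for child, counter in votes.items():
        ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1:
            log.warning("conflicting parents for region %r: %s; keeping %r",
                        child, dict(counter), ranked[0][0])
        parent = ranked[0][0]
        # reject edges that would make a region subsume itself transitively
        if parent != child and child not in smap.chain(parent):
            smap.parent[child] = parent
    return smap
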