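"""Synthetic UK-style gazetteers and corrupted free-text inputs.

Real property gazetteers and the health-register addresses they are linked
against are licensed/confidential, so every stage of the pipeline is
exercised on generated data instead.  The generator emulates the structure
that matters for linkage: multi-property postcodes, post towns containing
dependent localities (giving the preprocessor real subsumption knowledge),
flats sharing a building number, organisation names, and a reserved ``ZZ``
postcode area so fixtures can never collide with real addresses.

``corrupt`` reproduces the input-variation taxonomy observed in free-text
health-register addresses: typographical errors (one character edit in a
word of five or more letters — where real typos concentrate), street-type
abbreviations, flat-format flips (``FLAT 1, 5`` ↔ ``5/1``), wrong postcode
digits, omitted localities, inserted county names, and out-of-database
inputs for which the true label is ``NOT_IN_DB``.  All draws are driven by
one seed, so a profile fully determines the benchmark.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .gazetteer import ABBREVIATION_PAIRS, GazetteerRecord
from .schema import SCHEMA_11

__all__ = ["CorruptionProfile", "make_toy_gazetteer", "render_address",
           "corrupt", "make_benchmark"]

_STREET_STEMS = (
    "BRUNSWICK", "STENHOUSE", "WILSON", "STATION", "CHURCH", "SCHOOL",
    "FOREST", "HARBOUR", "CASTLE", "BRIDGE", "MEADOW", "ORCHARD",
    "WAVERLEY", "GREENBANK", "ROSEBANK", "BURNSIDE", "KINGSWELL",
    "MORVEN", "LOMOND", "STRATHEARN", "BALGAY", "CRAIGIE", "SEAFIELD",
    "NETHERTON", "WESTBURN", "EASTWOOD", "HILLSIDE", "FAIRFIELD",
)
_STREET_TYPES = (
    "ROAD", "STREET", "AVENUE", "DRIVE", "PLACE", "CRESCENT", "GARDENS",
    "TERRACE", "COURT", "LANE",
)
_TOWNS = ("AUCHTERBURN", "KIRKHAVEN", "GLENFORD", "STRATHMORE", "DUNBRAE", "EASTFERRY")
_LOCALITIES = ("MILLHILL", "WESTGATE", "NORTHFIELD", "SOUTHBANK", "CRAIGEND",
               "HILLVIEW", "BROOMLEA", "LADYWELL")
_ORG_NAMES = ("THE ANCHOR HOTEL", "ROSELEA CARE HOME", "VICTORIA SURGERY",
              "STATION GARAGE", "ABBEY PHARMACY", "HARBOUR CAFE",
              "GLEN NURSERY", "CORNER STORES")
_COUNTY = "FIFE"

_ABBREV_FWD = dict(ABBREVIATION_PAIRS)
_FLAT_RE = re.compile(r"^FLAT (\d+)$")
_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class CorruptionProfile:
    """Per-operation corruption rates, each in [0, 1].

    Rates are applied independently; together with a seed and a gazetteer
    they fully determine the generated benchmark.
    """

    typo: float = 0.0             # per eligible token (alphabetic, len >= 5)
    abbreviation: float = 0.0     # per street-type word
    flat_flip: float = 0.0        # render flats as "n/m" instead of "FLAT m, n"
    wrong_postcode: float = 0.0   # per input: swap one incode digit
    locality_dropout: float = 0.0 # per input: drop the dependent locality
    county_insertion: float = 0.0 # per input: insert a county before the postcode
    not_in_db: float = 0.0        # per input: emit an out-of-database address
    too_broad: float = 0.0        # per input: emit a street-only address

    def __post_init__(self):
        for name, value in self.__dict__.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"rate {name} must be in [0, 1], got {value}")


def make_toy_gazetteer(
    n: int,
    seed: int = 0,
    org_share: float = 0.08,
    flat_share: float = 0.25,
    locality_share: float = 0.5,
    records_per_postcode: int = 7,
) -> list[GazetteerRecord]:
    """Generate ``n`` plausible UK-style gazetteer records, deterministically.

    Postcodes use the reserved fake ``ZZ`` area.  Several records share each
    postcode; about half the records sit inside a dependent locality of
    their post town (providing subsumption structure); ``flat_share`` of
    records are flats (which share a building number with their neighbours)
    and ``org_share`` carry an organisation name.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    n_towns = max(2, min(len(_TOWNS), 1 + n // 150))
    towns = list(_TOWNS[:n_towns])
    # disjoint locality pools per town, so subsumption is unambiguous
    per_town = max(1, len(_LOCALITIES) // len(towns))
    town_localities = {
        town: list(_LOCALITIES[i * per_town:(i + 1) * per_town][:2])
        for i, town in enumerate(towns)
    }
    street_names = [f"{stem} {stype}" for stem in _STREET_STEMS for stype in _STREET_TYPES]
    rng.shuffle(street_names)

    records: list[GazetteerRecord] = []
    street_idx = 0
    postcode_serial = 0
    while len(records) < n:
        town = towns[street_idx % len(towns)]
        street = street_names[street_idx % len(street_names)]
        street_idx += 1
        locality = (
            rng.choice(town_localities[town]) if rng.random() < locality_share else ""
        )
        postcode_serial += 1
        outcode = f"ZZ{towns.index(town) + 1}"
        incode = f"{postcode_serial % 10}{_LETTERS[postcode_serial % 26]}{_LETTERS[(postcode_serial * 7) % 26]}"
        postcode = f"{outcode} {incode}"
        number = 0
        for _ in range(min(records_per_postcode, n - len(records))):
            number += rng.randint(1, 3)
            fields = {f: "" for f in SCHEMA_11}
            fields.update({
                "BUILDING NUMBER": str(number),
                "THOROUGHFARE": street,
                "DEPENDENT LOCALITY": locality,
                "POST TOWN": town,
                "POSTCODE": postcode,
            })
            if rng.random() < org_share:
                fields["ORGANISATION NAME"] = rng.choice(_ORG_NAMES)
            if rng.random() < flat_share:
                fields["SUB BUILDING NAME"] = f"FLAT {rng.randint(1, 4)}"
            uprn = f"{900000000 + len(records) + 1}"
            records.append(GazetteerRecord(uprn=uprn, fields=fields))
    # flats may collide on (number, flat) within a street segment; renderings
    # must stay unique for the round trip, so bump duplicates
    seen: set[str] = set()
    unique: list[GazetteerRecord] = []
    for rec in records:
        r = rec
        bump = 0
        while r.rendered() in seen:
            bump += 1
            sub = r.fields.get("SUB BUILDING NAME", "")
            m = _FLAT_RE.match(sub)
            new_sub = f"FLAT {int(m.group(1)) + bump}" if m else f"FLAT {bump}"
            r = GazetteerRecord(uprn=rec.uprn, fields={**rec.fields, "SUB BUILDING NAME": new_sub})
        seen.add(r.rendered())
        unique.append(r)
    return unique


def render_address(record: GazetteerRecord, style: str = "flat") -> str:
    """Render a record as natural comma-separated free text.

    ``style``: ``"flat"`` keeps ``FLAT m`` as its own element; ``"slash"``
    writes ``n/m`` before the thoroughfare; ``"nFm"`` writes ``nFm``.
    """
    f = record.fields
    number = f.get("BUILDING NUMBER", "")
    sub = f.get("SUB BUILDING NAME", "")
    flat = _FLAT_RE.match(sub)
    parts: list[str] = []
    for name in ("ORGANISATION NAME", "DEPARTMENT NAME"):
        if f.get(name):
            parts.append(f[name])
    street = " ".join(x for x in (number, f.get("THOROUGHFARE", "")) if x)
    if flat and number and style in ("slash", "nFm"):
        sep = "/" if style == "slash" else "F"
        street = " ".join(x for x in (f"{number}{sep}{flat.group(1)}", f.get("THOROUGHFARE", "")) if x)
    elif sub:
        parts.append(sub)
    if f.get("BUILDING NAME"):
        parts.append(f["BUILDING NAME"])
    if street:
        parts.append(street)
    for name in ("DEPENDENT THOROUGHFARE", "DOUBLE DEPENDENT LOCALITY",
                 "DEPENDENT LOCALITY", "POST TOWN", "POSTCODE"):
        if f.get(name):
            parts.append(f[name])
    return ", ".join(parts)


def _typo(token: str, rng: random.Random) -> str:
    """One random character edit (substitute / insert / delete / transpose)."""
    op = rng.choice(("sub", "ins", "del", "swap"))
    i = rng.randrange(len(token))
    if op == "sub":
        repl = rng.choice([c for c in _LETTERS if c != token[i]])
        return token[:i] + repl + token[i + 1:]
    if op == "ins":
        return token[:i] + rng.choice(_LETTERS) + token[i:]
    if op == "del":
        return token[:i] + token[i + 1:]
    if i == len(token) - 1:
        i -= 1
    if token[i] == token[i + 1]:  # swapping equal letters is no edit
        return token[:i] + rng.choice([c for c in _LETTERS if c != token[i]]) + token[i + 1:]
    return token[:i] + token[i + 1] + token[i] + token[i + 2:]


def corrupt(
    record: GazetteerRecord,
    profile: CorruptionProfile,
    rng: random.Random,
) -> tuple[str, str, str]:
    """Produce one free-text input for ``record``.

    Returns ``(text, uprn, label)`` where ``label`` is empty for matchable
    inputs and a not-possible category otherwise.  With all rates zero the
    output equals ``render_address(record)`` exactly.
    """
    if rng.random() < profile.not_in_db:
        fake = GazetteerRecord(uprn="", fields={
            **{f: "" for f in SCHEMA_11},
            "BUILDING NUMBER": str(rng.randint(60, 99)),
            "THOROUGHFARE": f"PHANTOM {rng.choice(_STREET_TYPES)}",
            "POST TOWN": record.fields.get("POST TOWN", ""),
            "POSTCODE": record.fields.get("POSTCODE", ""),
        })
        return render_address(fake), "", "NOT_IN_DB"
    if rng.random() < profile.too_broad:
        fake = GazetteerRecord(uprn="", fields={
            **{f: "" for f in SCHEMA_11},
            "THOROUGHFARE": record.fields.get("THOROUGHFARE", ""),
            "POST TOWN": record.fields.get("POST TOWN", ""),
            "POSTCODE": record.fields.get("POSTCODE", ""),
        })
        return render_address(fake), "", "TOO_BROAD"

    style = "flat"
    if record.fields.get("SUB BUILDING NAME") and rng.random() < profile.flat_flip:
        style = rng.choice(("slash", "nFm"))
    text = render_address(record, style)

    segments = [s.strip() for s in text.split(",")]
    locality = record.fields.get("DEPENDENT LOCALITY", "")
    if locality and rng.random() < profile.locality_dropout:
        segments = [s for s in segments if s != locality]
    if rng.random() < profile.county_insertion:
        segments.insert(len(segments) - 1, _COUNTY)
    text = ", ".join(segments)

    if profile.abbreviation:
        words = text.split(" ")
        for i, w in enumerate(words):
            bare = w.rstrip(",")
            if bare in _ABBREV_FWD and rng.random() < profile.abbreviation:
                words[i] = w.replace(bare, _ABBREV_FWD[bare])
        text = " ".join(words)

    if profile.typo:
        words = text.split(" ")
        for i, w in enumerate(words):
            bare = w.rstrip(",")
            if len(bare) >= 5 and bare.isalpha() and rng.random() < profile.typo:
                words[i] = w.replace(bare, _typo(bare, rng))
        text = " ".join(words)

    if rng.random() < profile.wrong_postcode:
        postcode = record.fields.get("POSTCODE", "")
        if postcode and postcode in text:
            digit = postcode[-3]
            text = text.replace(postcode, postcode[:-3] + str((int(digit) + 5) % 10) + postcode[-2:])

    return text, record.canonical_uprn, ""


def make_benchmark(
    records: Sequence[GazetteerRecord],
    n_inputs: int,
    profile: CorruptionProfile,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a benchmark of corrupted inputs stratified across postcodes.

    Postcodes are cycled round-robin (every postcode represented before any
    repeats, emulating per-postcode stratified sampling at toy scale).
    Returns ``(inputs, annotations)``: inputs has columns input_id/address;
    annotations has input_id/address/uprn/label.
    """
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    rng = random.Random(seed)
    by_postcode: dict[str, list[GazetteerRecord]] = {}
    for rec in records:
        if not rec.is_augmented:
            by_postcode.setdefault(rec.fields.get("POSTCODE", ""), []).append(rec)
    postcodes = sorted(by_postcode)
    in_rows, ann_rows = [], []
    i = 0
    while len(in_rows) < n_inputs:
        pc = postcodes[i % len(postcodes)]
        i += 1
        rec = rng.choice(by_postcode[pc])
        text, uprn, label = corrupt(rec, profile, rng)
        input_id = f"IN{len(in_rows):05d}"
        in_rows.append({"input_id": input_id, "address": text})
        ann_rows.append({"input_id": input_id, "address": text, "uprn": uprn, "label": label})
    return pd.DataFrame(in_rows), pd.DataFrame(ann_rows)
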