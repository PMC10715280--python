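"""Tree-structured gazetteer: DFS blocking and BFS candidate scoring.

The (augmented) gazetteer is converted into a layered tree: each layer
corresponds to one address field in a configured order, each node is named
by a field value, and each leaf holds exactly one record.  Blocking is a
short depth-first descent guided by parsed hints — one step on the postcode
layer, or two steps on post town then thoroughfare when no postcode is
available — choosing at each step the child whose name aligns best with the
input.  From the chosen subtree every leaf becomes a candidate: a
breadth-first traversal aligns each node name against the input, *redacts*
the aligned positions before passing the input to that node's children (so
no two fields consume the same characters), and assembles the per-field
alignment metrics at the leaves.

Two trees are kept (postcode-first and town-first) because the two DFS
modes need different top layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .align import (FieldAlignment, align_field, dl_distance, redact,
                    summary_score, tokens_equal)
from .errors import BlockingError
from .gazetteer import GazetteerRecord
from .preprocess import InputAddress
from .schema import PRIMARY_LAYERS, RECORD_KEY_LAYER, SCHEMA_11, SECONDARY_LAYERS

__all__ = ["TreeNode", "CandidateAlignmentSet", "build_tree", "dfs_block",
           "bfs_match", "align_pair", "TreePair"]

#: Minimum DFS selection score (field-coverage based) per layer kind.
POSTCODE_FLOOR = 0.5
LOCALITY_FLOOR = 0.6


@dataclass
class TreeNode:
    layer_field: str | None
    value: str
    children: dict[str, "TreeNode"] = field(default_factory=dict)
    record: GazetteerRecord | None = None

    @property
    def is_leaf(self) -> bool:
        return self.record is not None

    def leaf_count(self) -> int:
        if self.is_leaf:
            return 1
        return sum(c.leaf_count() for c in self.children.values())


@dataclass
class CandidateAlignmentSet:
    """Per-field alignments of one input against one gazetteer record."""

    record: GazetteerRecord
    per_field: Mapping[str, FieldAlignment]
    residual_input: str  # input with all aligned positions redacted


def build_tree(
    records: Sequence[GazetteerRecord],
    layer_order: Sequence[str] = PRIMARY_LAYERS,
) -> TreeNode:
    """Convert records into a layered tree; one leaf per record.

    The record key is appended as a final tiebreak layer so records sharing
    every field value still resolve to distinct leaves.
    """
    layers = [*layer_order, RECORD_KEY_LAYER]
    root = TreeNode(layer_field=None, value="")
    _split(root, list(records), layers, 0)
    return root


def _split(node: TreeNode, records: list[GazetteerRecord], layers: list[str], depth: int) -> None:
    layer = layers[depth]
    if layer == RECORD_KEY_LAYER:
        for rec in records:
            node.children[rec.key] = TreeNode(layer_field=layer, value=rec.key, record=rec)
        return
    groups: dict[str, list[GazetteerRecord]] = {}
    for rec in records:
        groups.setdefault(rec.fields.get(layer, ""), []).append(rec)
    for value, grp in groups.items():
        child = TreeNode(layer_field=layer, value=value)
        node.children[value] = child
        _split(child, grp, layers, depth + 1)


def _selection_score(fa: FieldAlignment) -> float:
    """DFS child-ranking score: field coverage penalised like S.

    Uses ``pct_field`` in place of the harmonic mean so the score does not
    shrink with input length (a short node name inside a long input should
    still be able to reach the floor on an exact occurrence).
    """
    return summary_score(fa.pct_field, fa.insertions, fa.char_cos)


@dataclass
class BlockResult:
    node: TreeNode
    masked: str
    consumed: dict[str, FieldAlignment]
    tree: str  # "primary" | "secondary"


def _dfs_step(node: TreeNode, masked: str, floor: float, hint: str | None):
    """Choose the child whose name best aligns with the input; redact it.

    When a parsed hint exists, children whose name is within the framework's
    fuzzy-token tolerance of the hint (normalised DL-distance <= 0.2) are
    preferred, nearest first — a one-edit postcode still blocks to the right
    area.  Otherwise every child name is aligned against the input and the
    best selection score wins.
    """
    best = None
    if hint is not None:
        near = sorted(
            (dl_distance(hint, value), value)
            for value in node.children
            if value and tokens_equal(hint, value)
        )
        for _, value in near:
            child = node.children[value]
            fa = align_field(masked, child.value, child.layer_field or "")
            if _selection_score(fa) >= floor:
                best = (child, fa)
                break
    if best is None:
        for value in sorted(node.children):
            child = node.children[value]
            if not value:
                continue
            fa = align_field(masked, value, child.layer_field or "")
            if _selection_score(fa) < floor:
                continue
            if best is None or _selection_score(fa) > _selection_score(best[1]):
                best = (child, fa)
    if best is None:
        return None
    child, fa = best
    return child, redact(masked, fa.input_spans), fa


def dfs_block(
    primary_root: TreeNode,
    secondary_root: TreeNode | None,
    addr: InputAddress,
    masked: str | None = None,
    postcode_floor: float = POSTCODE_FLOOR,
    locality_floor: float = LOCALITY_FLOOR,
    force_secondary: bool = False,
) -> BlockResult:
    """Descend to the local-area subtree using parsed hints.

    One step on the postcode layer when a postcode hint exists; otherwise two
    steps (post town, thoroughfare) in the secondary tree.  Raises
    :class:`BlockingError` when no child reaches the floor score.
    """
    masked = addr.cleaned if masked is None else masked
    if addr.postcode and not force_secondary:
        step = _dfs_step(primary_root, masked, postcode_floor, addr.postcode)
        if step is not None:
            node, masked2, fa = step
            return BlockResult(node, masked2, {"POSTCODE": fa}, "primary")
        if secondary_root is None:
            raise BlockingError("postcode blocking failed and no secondary tree")
    if secondary_root is None:
        raise BlockingError("no postcode hint and no secondary tree")
    step = _dfs_step(secondary_root, masked, locality_floor, addr.post_town)
    if step is None:
        raise BlockingError("post-town blocking failed")
    town_node, masked, town_fa = step
    step = _dfs_step(town_node, masked, locality_floor, addr.thoroughfare)
    if step is None:
        raise BlockingError("thoroughfare blocking failed")
    street_node, masked, street_fa = step
    return BlockResult(
        street_node, masked, {"POST TOWN": town_fa, "THOROUGHFARE": street_fa}, "secondary"
    )


def bfs_match(
    node: TreeNode,
    masked: str,
    consumed: Mapping[str, FieldAlignment] | None = None,
    schema: Sequence[str] = SCHEMA_11,
) -> list[CandidateAlignmentSet]:
    """Score every leaf under ``node``: align layer names level by level.

    Aligned input positions are redacted before recursing into a node's
    children, so the spans consumed by different fields of one candidate are
    pairwise disjoint.  Children are visited in sorted order, making the
    candidate list deterministic.
    """
    out: list[CandidateAlignmentSet] = []
    _descend(node, masked, dict(consumed or {}), out, schema)
    return out


def _descend(node, masked, acc, out, schema) -> None:
    if node.is_leaf:
        per_field = {f: acc.get(f) or FieldAlignment.zero(f) for f in schema}
        out.append(CandidateAlignmentSet(node.record, per_field, masked))
        return
    for value in sorted(node.children):
        child = node.children[value]
        layer = child.layer_field or ""
        if child.is_leaf or layer == RECORD_KEY_LAYER:
            _descend(child, masked, acc, out, schema)
            continue
        if value == "" or layer in acc:
            # blank field values pass through; consumed layers are not re-aligned
            fa = acc.get(layer) or FieldAlignment.zero(layer)
            child_masked = masked
        else:
            fa = align_field(masked, value, layer)
            child_masked = redact(masked, fa.input_spans)
        child_acc = dict(acc)
        child_acc.setdefault(layer, fa)
        _descend(child, child_masked, child_acc, out, schema)


def align_pair(
    masked: str,
    record: GazetteerRecord,
    layer_order: Sequence[str] = PRIMARY_LAYERS,
    schema: Sequence[str] = SCHEMA_11,
) -> CandidateAlignmentSet:
    """Align one record's fields against the input in layer order, redacting
    after each field — exactly what a tree traversal would produce for this
    record's leaf.  Used for assembling training pairs."""
    acc: dict[str, FieldAlignment] = {}
    for f in layer_order:
        value = record.fields.get(f, "")
        if not value:
            acc[f] = FieldAlignment.zero(f)
            continue
        fa = align_field(masked, value, f)
        acc[f] = fa
        masked = redact(masked, fa.input_spans)
    per_field = {f: acc.get(f) or FieldAlignment.zero(f) for f in schema}
    return CandidateAlignmentSet(record, per_field, masked)


@dataclass
class TreePair:
    """The two blocking trees built from one (augmented) record collection."""

    primary: TreeNode
    secondary: TreeNode

    @classmethod
    def build(cls, records: Sequence[GazetteerRecord]) -> "TreePair":
        return cls(build_tree(records, PRIMARY_LAYERS), build_tree(records, SECONDARY_LAYERS))
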