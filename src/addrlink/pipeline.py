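"""End-to-end matching workflow and the evaluation suite.

``Linker`` bundles everything matching needs: the augmented gazetteer, the
two blocking trees, the region-subsumption knowledge, the known town and
thoroughfare vocabularies, and a trained matching model.  For one input the
workflow is: clean → complete/prune → parse hints → DFS blocking → BFS
candidate scoring → feature generation → classifier probability; the
candidate with the highest probability is the predicted record.  Hits on
augmented variants are reported under their canonical identifier.

Evaluation compares rank-1 predictions against manual annotations and
reports raw accuracy (correct / all inputs), adjusted accuracy (correct /
humanly-matchable inputs), top-k accuracy, the not-possible breakdown, and
a precision/recall/F1 table over a grid of confidence thresholds (the data
behind a lift curve).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import BlockingError, EmptyInputError, ReferenceLookupError
from .features import (MatchModel, assemble_training, make_features, score_many, train)
from .gazetteer import (GazetteerRecord, SubsumptionMap, augment_gazetteer,
                        build_subsumption_map)
from .preprocess import DEFAULT_REMOVAL_TERMS, clean, complete_or_prune, parse_hints
from .schema import NOT_POSSIBLE_LABELS
from .treedb import TreePair, bfs_match, dfs_block

log = logging.getLogger(__name__)

__all__ = ["MatchResult", "MatchOutcome", "EvalReport", "Linker", "f1",
           "threshold_sweep", "evaluate", "train_linker", "DEFAULT_GRID"]

DEFAULT_GRID: tuple[float, ...] = tuple(round(t, 2) for t in np.arange(0.0, 1.0001, 0.05))


@dataclass(frozen=True)
class MatchResult:
    input_id: str
    uprn: str          # canonical identifier
    score: float       # classifier probability of match
    rank: int          # 1 = best
    accepted: bool     # score >= threshold


@dataclass
class MatchOutcome:
    """Ranked results for one input, or a failure reason when unmatchable."""

    input_id: str
    results: list[MatchResult] = field(default_factory=list)
    failure: str | None = None
    blocking_tree: str | None = None

    @property
    def best(self) -> MatchResult | None:
        return self.results[0] if self.results else None


@dataclass
class Linker:
    """A ready-to-run matcher over one gazetteer."""

    records: list[GazetteerRecord]
    trees: TreePair
    smap: SubsumptionMap
    known_towns: tuple[str, ...]
    known_thoroughfares: tuple[str, ...]
    model: MatchModel | None = None
    threshold: float = 0.5
    top_n: int = 5
    removal_terms: tuple[str, ...] = DEFAULT_REMOVAL_TERMS

    @classmethod
    def build(
        cls,
        records: Sequence[GazetteerRecord],
        model: MatchModel | None = None,
        augment: bool = True,
        alias_table: pd.DataFrame | None = None,
        **kwargs,
    ) -> "Linker":
        recs = augment_gazetteer(records, alias_table=alias_table) if augment else list(records)
        smap = build_subsumption_map(recs)
        towns = tuple(sorted({r.fields.get("POST TOWN", "") for r in recs} - {""}))
        streets = tuple(sorted({r.fields.get("THOROUGHFARE", "") for r in recs} - {""}))
        return cls(list(recs), TreePair.build(recs), smap, towns, streets, model, **kwargs)

    # -- matching -----------------------------------------------------------

    def preprocess(self, raw: str, input_id: str = ""):
        cleaned = complete_or_prune(clean(raw), self.smap, self.removal_terms)
        return parse_hints(cleaned, self.known_towns, self.known_thoroughfares,
                           input_id=input_id, raw=raw)

    def _score_block(self, addr, force_secondary: bool):
        block = dfs_block(self.trees.primary, self.trees.secondary, addr,
                          force_secondary=force_secondary)
        candidates = bfs_match(block.node, block.masked, block.consumed)
        feats = [make_features(c) for c in candidates]
        probs = score_many(self.model, feats)
        best_by_canonical: dict[str, tuple[float, str]] = {}
        for cand, prob in zip(candidates, probs):
            cu = cand.record.canonical_uprn
            entry = (float(prob), cand.record.key)
            if cu not in best_by_canonical or entry[0] > best_by_canonical[cu][0]:
                best_by_canonical[cu] = entry
        ranked = sorted(best_by_canonical.items(), key=lambda kv: (-kv[1][0], kv[0]))
        return ranked, block.tree

    def match(self, raw: str, input_id: str = "", top_n: int | None = None,
              threshold: float | None = None) -> MatchOutcome:
        """Match one free-text address; ties broken by lexicographic identifier."""
        if self.model is None:
            raise ValueError("Linker has no trained model")
        top_n = self.top_n if top_n is None else top_n
        t = self.threshold if threshold is None else threshold
        try:
            addr = self.preprocess(raw, input_id)
        except EmptyInputError:
            return MatchOutcome(input_id, failure="unmatchable: empty")
        ranked, tree_used = [], None
        try:
            ranked, tree_used = self._score_block(addr, force_secondary=False)
        except BlockingError:
            pass
        # fallback: retry the town/thoroughfare tree when postcode blocking
        # failed or produced only low-confidence candidates
        if tree_used != "secondary" and (not ranked or ranked[0][1][0] < t):
            try:
                alt, _ = self._score_block(addr, force_secondary=True)
                if alt and (not ranked or alt[0][1][0] > ranked[0][1][0]):
                    if ranked:
                        log.info("fallback to secondary blocking for %r", input_id or raw)
                    ranked, tree_used = alt, "secondary"
            except BlockingError:
                pass
        if not ranked:
            return MatchOutcome(input_id, failure="unmatchable: blocking")
        results = [
            MatchResult(input_id, uprn, prob, rank, prob >= t)
            for rank, (uprn, (prob, _)) in enumerate(ranked[:top_n], start=1)
        ]
        return MatchOutcome(input_id, results, blocking_tree=tree_used)

    def match_table(self, inputs: pd.DataFrame, top_n: int | None = None,
                    threshold: float | None = None) -> pd.DataFrame:
        """Match a table with columns ``input_id`` and ``address``.

        Returns one row per (input, rank): input_id, rank, uprn, score,
        accepted, failure_reason.  Unmatchable inputs yield a single row with
        an empty identifier and the failure reason.
        """
        rows = []
        counters = {"matched": 0, "unmatchable": 0}
        for row in inputs.itertuples():
            outcome = self.match(str(row.address), str(row.input_id), top_n, threshold)
            if outcome.failure:
                counters["unmatchable"] += 1
                rows.append({"input_id": outcome.input_id, "rank": 1, "uprn": "",
                             "score": np.nan, "accepted": False,
                             "failure_reason": outcome.failure})
                continue
            counters["matched"] += 1
            for r in outcome.results:
                rows.append({"input_id": r.input_id, "rank": r.rank, "uprn": r.uprn,
                             "score": r.score, "accepted": r.accepted, "failure_reason": ""})
        log.info("matched %(matched)d inputs, %(unmatchable)d unmatchable", counters)
        return pd.DataFrame(
            rows, columns=["input_id", "rank", "uprn", "score", "accepted", "failure_reason"]
        )


# ---------------------------------------------------------------------------
# Evaluation


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0, with a warning, at P=R=0)."""
    if precision == 0 and recall == 0:
        warnings.warn("F1 undefined at precision = recall = 0; returning 0", stacklevel=2)
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def threshold_sweep(top1: pd.DataFrame, grid: Sequence[float] = DEFAULT_GRID) -> pd.DataFrame:
    """Cross-tabulate correctness against score >= t for each threshold t.

    ``top1`` needs boolean column ``correct`` and float column ``score``
    (NaN counts as below every threshold).  The returned table has one row
    per threshold with tp/fp/fn/tn, precision, recall and F1; recall is
    non-increasing down the grid.
    """
    correct = top1["correct"].to_numpy(dtype=bool)
    scores = top1["score"].to_numpy(dtype=float)
    scores = np.where(np.isnan(scores), -np.inf, scores)
    rows = []
    for t in grid:
        above = scores >= t
        tp = int(np.sum(correct & above))
        fp = int(np.sum(~correct & above))
        fn = int(np.sum(correct & ~above))
        tn = int(np.sum(~correct & ~above))
        precision = tp / (tp + fp) if tp + fp else np.nan
        recall = tp / (tp + fn) if tp + fn else np.nan
        f1_val = f1(precision, recall) if not (np.isnan(precision) or np.isnan(recall)) else np.nan
        rows.append({"threshold": t, "tp": tp, "fp": fp, "fn": fn, "tn": tn,
                     "precision": precision, "recall": recall, "f1": f1_val})
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    """Accuracy summary of predictions against manual annotation."""

    n: int                       # all sampled inputs
    p: int                       # inputs a human could match
    c: int                       # correct rank-1 matches
    raw_accuracy: float
    adjusted_accuracy: float | None   # None when p == 0 (undefined)
    top_k_correct: dict[int, int]
    top_k_adjusted: dict[int, float | None]
    not_possible: dict[str, int]
    not_possible_pct: float           # % of the whole set
    not_possible_shares_pct: dict[str, float]  # % within the not-possible group
    thresholds: pd.DataFrame

    def summary(self) -> str:
        lines = [
            f"n = {self.n}, matchable p = {self.p}, correct c = {self.c}",
            f"raw accuracy      c/n = {self.raw_accuracy:.3f}",
            "adjusted accuracy c/p = "
            + ("undefined (p = 0)" if self.adjusted_accuracy is None
               else f"{self.adjusted_accuracy:.3f}"),
        ]
        for k in sorted(self.top_k_adjusted):
            v = self.top_k_adjusted[k]
            lines.append(f"adjusted accuracy in top {k} = "
                         + ("undefined" if v is None else f"{v:.3f}"))
        lines.append(f"not possible: {sum(self.not_possible.values())} ({self.not_possible_pct:.2f}%)")
        for label, cnt in sorted(self.not_possible.items()):
            lines.append(f"  {label}: {cnt} ({self.not_possible_shares_pct[label]:.1f}% of not-possible)")
        return "\n".join(lines)


def evaluate(
    predictions: pd.DataFrame,
    annotations: pd.DataFrame,
    grid: Sequence[float] = DEFAULT_GRID,
    ks: Sequence[int] = (1, 5),
) -> EvalReport:
    """Score a prediction table against an annotation table.

    ``predictions``: columns input_id, rank, uprn, score (the match_table
    format).  ``annotations``: columns input_id, uprn, label — ``uprn`` empty
    and ``label`` one of NOT_IN_DB / TOO_BROAD / LOW_QUALITY for inputs a
    human could not match.  Every prediction id must appear in annotations.
    """
    ann = annotations.copy()
    ann["input_id"] = ann["input_id"].astype(str)
    for col in ("uprn", "label"):
        ann[col] = ann[col].fillna("").astype(str) if col in ann else ""
    known_ids = set(ann["input_id"])
    pred_ids = set(predictions["input_id"].astype(str))
    stray = pred_ids - known_ids
    if stray:
        raise ReferenceLookupError(
            f"{len(stray)} prediction id(s) missing from annotations, e.g. {sorted(stray)[:3]}"
        )

    n = len(ann)
    matchable = ~ann["label"].isin(NOT_POSSIBLE_LABELS) & (ann["uprn"] != "")
    p = int(matchable.sum())

    preds = predictions.copy()
    preds["input_id"] = preds["input_id"].astype(str)
    preds["uprn"] = preds["uprn"].fillna("").astype(str)

    truth = ann.set_index("input_id")["uprn"]
    top_k_correct: dict[int, int] = {}
    for k in sorted(set(ks)):
        sub = preds[(preds["rank"] <= k) & (preds["uprn"] != "")]
        hit = sub["uprn"].to_numpy() == truth.reindex(sub["input_id"]).fillna("").to_numpy()
        top_k_correct[k] = int(sub.loc[hit, "input_id"].nunique())
    c = top_k_correct.get(1, 0)

    top1 = preds[preds["rank"] == 1].set_index("input_id").reindex(ann["input_id"])
    correct1 = (top1["uprn"].fillna("") != "") & (
        top1["uprn"].fillna("").to_numpy() == ann["uprn"].to_numpy()
    ) & matchable.to_numpy()
    sweep = threshold_sweep(
        pd.DataFrame({"correct": correct1.to_numpy(), "score": top1["score"].to_numpy()}),
        grid,
    )

    not_possible = (
        ann.loc[ann["label"].isin(NOT_POSSIBLE_LABELS), "label"].value_counts().to_dict()
    )
    np_total = sum(not_possible.values())
    shares = {k: 100.0 * v / np_total for k, v in not_possible.items()} if np_total else {}

    return EvalReport(
        n=n,
        p=p,
        c=c,
        raw_accuracy=c / n if n else float("nan"),
        adjusted_accuracy=(c / p) if p else None,
        top_k_correct=top_k_correct,
        top_k_adjusted={k: (v / p if p else None) for k, v in top_k_correct.items()},
        not_possible=not_possible,
        not_possible_pct=100.0 * np_total / n if n else float("nan"),
        not_possible_shares_pct=shares,
        thresholds=sweep,
    )


# ---------------------------------------------------------------------------
# Convenience: train a full linker from a gazetteer + annotation table


def train_linker(
    records: Sequence[GazetteerRecord],
    annotations: pd.DataFrame,
    seed: int = 0,
    n_estimators: int = 500,
    negatives_cap: int = 20,
    augment: bool = True,
    alias_table: pd.DataFrame | None = None,
) -> Linker:
    """Augment the gazetteer, assemble labelled pairs, fit the matcher."""
    linker = Linker.build(records, augment=augment, alias_table=alias_table)
    pairs = assemble_training(annotations, linker.records, linker.smap,
                              seed=seed, negatives_cap=negatives_cap)
    linker.model = train(pairs, seed=seed, n_estimators=n_estimators)
    return linker
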