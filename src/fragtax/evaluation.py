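"""Leave-one-out clade exclusion and classification performance metrics.

The leave-one-out protocol removes an entire lineage (say, one genus) from
the training set and asks whether fragments from it are still placed
sensibly at more general ranks.  Fragments from a lineage with no sister at
the excluded rank are dropped, since no meaningful parent-level assignment
exists for them.

Per evaluation rank, each fragment contributes to its true lineage's tally
as a true positive (correct label), a false negative (wrong label, which
simultaneously counts as a false positive for the predicted lineage) or an
unclassified.  With Z_i = TP_i + FN_i + U_i, the per-lineage rates are

    Sn_i = TP_i / Z_i            sensitivity
    Sp_i = TP_i / (TP_i + FP_i)  specificity (undefined when TP+FP = 0)
    FNr_i = FN_i / Z_i           false negative rate
    Ur_i = U_i / Z_i             unclassified rate

and are reported both averaged over lineages (each lineage weighted
equally; undefined values skipped) and pooled absolutely over fragments.
Averages are preferred since lineages are rarely evenly represented.

The correctness categories distinguish, for each fragment, the deepest
rank r it shares with any training genome: an assignment exactly at r and
inside the true lineage is "correct rank"; deeper but still inside the
rank-r clade is "correct lineage" (over-specific); an assignment at r or
deeper that leaves the lineage is "incorrect"; anything shallower is
"unclassified at r".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classifiers import Prediction
from .taxonomy import Lineage, Rank, TaxonomyTree, common_rank


@dataclass(frozen=True)
class ExclusionScheme:
    """One leave-one-out exclusion: a lineage prefix removed at a rank."""

    excluded_rank: Rank
    excluded_lineage: Lineage

    def __post_init__(self) -> None:
        if self.excluded_lineage.depth != self.excluded_rank.value + 1:
            raise ValueError(
                "excluded_lineage must be rank-complete down to excluded_rank "
                f"(depth {self.excluded_rank.value + 1}, got "
                f"{self.excluded_lineage.depth})"
            )


def apply_exclusion(
    tree: TaxonomyTree,
    scheme: ExclusionScheme,
    query_sources: Mapping[str, str],
) -> tuple[frozenset[str], tuple[str, ...]]:
    """Split genomes into a training set and filter the query set.

    Returns (training genome ids, retained query fragment ids).  Training
    genomes are those outside the excluded lineage.  A query whose lineage
    at the excluded rank is the only child of its parent is dropped: with
    no sister clade, classification to the parent is vacuous.
    """
    excluded = scheme.excluded_lineage
    if not tree.genomes_under(excluded):
        raise KeyError(f"excluded lineage not present in taxonomy: {excluded}")
    training = frozenset(
        gid for gid in tree.genome_ids
        if not tree.lineage(gid).starts_with(excluded)
    )
    retained: list[str] = []
    for qid, src in query_sources.items():
        prefix = tree.lineage(src).prefix(scheme.excluded_rank)
        if tree.has_sister(prefix):
            retained.append(qid)
    return training, tuple(retained)


def exclusion_schemes(tree: TaxonomyTree, rank: Rank) -> tuple[ExclusionScheme, ...]:
    """Every eligible (sister-bearing) exclusion scheme at a rank."""
    return tuple(
        ExclusionScheme(excluded_rank=rank, excluded_lineage=prefix)
        for prefix in tree.prefixes_at(rank)
        if tree.has_sister(prefix)
    )


@dataclass
class LineageTally:
    """Confusion counts for one lineage at one evaluation rank."""

    label: str
    tp: int = 0
    fp: int = 0
    fn: int = 0
    u: int = 0

    @property
    def z(self) -> int:
        """Number of query fragments whose true lineage this is."""
        return self.tp + self.fn + self.u


def tally(
    predictions: Iterable[Prediction],
    truths: Mapping[str, Lineage],
    eval_rank: Rank,
) -> list[LineageTally]:
    """Confusion tallies per lineage at one rank.

    Each fragment with a label at eval_rank matching its truth is a TP of
    the true lineage; a mismatching label is an FN of the true lineage and
    an FP of the predicted lineage; no label is a U of the true lineage.
    """
    tallies: dict[str, LineageTally] = {}

    def get(label: str) -> LineageTally:
        if label not in tallies:
            tallies[label] = LineageTally(label=label)
        return tallies[label]

    for pred in predictions:
        if pred.fragment_id not in truths:
            raise KeyError(f"no truth lineage for fragment {pred.fragment_id!r}")
        truth_label = truths[pred.fragment_id].label_at(eval_rank)
        if truth_label is None:
            raise ValueError(
                f"truth lineage for {pred.fragment_id!r} is truncated above "
                f"{eval_rank.rank_name}"
            )
        pred_label = pred.assigned.label_at(eval_rank)
        if pred_label is None:
            get(truth_label).u += 1
        elif pred_label == truth_label:
            get(truth_label).tp += 1
        else:
            get(truth_label).fn += 1
            get(pred_label).fp += 1
    return sorted(tallies.values(), key=lambda t: t.label)


@dataclass(frozen=True)
class MetricsSummary:
    """Per-lineage and aggregate sensitivity/specificity/FNr/Ur."""

    per_lineage: pd.DataFrame  # index=label; TP FP FN U Z Sn Sp FNr Ur
    sn_avg: float
    sp_avg: float
    fnr_avg: float
    ur_avg: float
    sn_abs: float
    sp_abs: float
    fnr_abs: float
    ur_abs: float


def _mean(values: list[float]) -> float:
    return sum(values) / len(values) if values else math.nan


def summarize(tallies: Sequence[LineageTally]) -> MetricsSummary:
    """Aggregate tallies into per-lineage rates plus averages and absolutes.

    Per-lineage rates with a zero denominator (Sn/FNr/Ur when Z = 0, Sp
    when TP + FP = 0) are undefined (NaN) and skipped by the averages
    rather than imputed as zero.
    """
    if not tallies:
        raise ValueError("summarize requires at least one lineage tally")
    rows = []
    for t in tallies:
        sn = t.tp / t.z if t.z else math.nan
        fnr = t.fn / t.z if t.z else math.nan
        ur = t.u / t.z if t.z else math.nan
        sp = t.tp / (t.tp + t.fp) if (t.tp + t.fp) else math.nan
        rows.append(
            {
                "lineage": t.label,
                "TP": t.tp,
                "FP": t.fp,
                "FN": t.fn,
                "U": t.u,
                "Z": t.z,
                "Sn": sn,
                "Sp": sp,
                "FNr": fnr,
                "Ur": ur,
            }
        )
    frame = pd.DataFrame(rows).set_index("lineage")
    tot_tp = int(frame["TP"].sum())
    tot_fp = int(frame["FP"].sum())
    tot_fn = int(frame["FN"].sum())
    tot_u = int(frame["U"].sum())
    tot_z = int(frame["Z"].sum())
    return MetricsSummary(
        per_lineage=frame,
        sn_avg=_mean([v for v in frame["Sn"] if not math.isnan(v)]),
        sp_avg=_mean([v for v in frame["Sp"] if not math.isnan(v)]),
        fnr_avg=_mean([v for v in frame["FNr"] if not math.isnan(v)]),
        ur_avg=_mean([v for v in frame["Ur"] if not math.isnan(v)]),
        sn_abs=tot_tp / tot_z if tot_z else math.nan,
        sp_abs=tot_tp / (tot_tp + tot_fp) if (tot_tp + tot_fp) else math.nan,
        fnr_abs=tot_fn / tot_z if tot_z else math.nan,
        ur_abs=tot_u / tot_z if tot_z else math.nan,
    )


CATEGORY_CORRECT_RANK = "correct_rank"
CATEGORY_CORRECT_LINEAGE = "correct_lineage"
CATEGORY_INCORRECT = "incorrect"
CATEGORY_UNCLASSIFIED = "unclassified_at_r"

CATEGORIES = (
    CATEGORY_CORRECT_RANK,
    CATEGORY_CORRECT_LINEAGE,
    CATEGORY_INCORRECT,
    CATEGORY_UNCLASSIFIED,
)


@dataclass(frozen=True)
class CorrectnessCategory:
    """Outcome of one fragment relative to rank r, the deepest rank its
    true lineage shares with any training genome."""

    category: str
    r: Rank | None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category: {self.category!r}")


def categorize(
    pred: Prediction,
    truth: Lineage,
    training_lineages: Sequence[Lineage],
) -> CorrectnessCategory:
    """Classify one prediction as correct rank / correct lineage /
    incorrect / unclassified at r.

    r is the deepest rank the truth shares with any post-exclusion
    training lineage.  A prediction disagreeing with the truth at r or any
    more general rank is incorrect; agreeing exactly down to r is correct
    rank when it stops there and correct lineage (over-specific but
    contained within the rank-r clade) when it goes deeper.
    """
    if not training_lineages:
        raise ValueError("training set must be nonempty")
    r: Rank | None = None
    for t in training_lineages:
        cr = common_rank(truth, t)
        if cr is not None and (r is None or cr > r):
            r = cr
    if r is None:
        # Truth shares nothing with the training set, even at domain: any
        # assignment necessarily leaves the lineage.
        if pred.assigned.is_empty:
            return CorrectnessCategory(CATEGORY_UNCLASSIFIED, None)
        return CorrectnessCategory(CATEGORY_INCORRECT, None)
    cls_rank = pred.classified_rank
    if cls_rank is None or cls_rank < r:
        return CorrectnessCategory(CATEGORY_UNCLASSIFIED, r)
    if pred.assigned.labels[: r.value + 1] != truth.labels[: r.value + 1]:
        return CorrectnessCategory(CATEGORY_INCORRECT, r)
    if cls_rank == r:
        return CorrectnessCategory(CATEGORY_CORRECT_RANK, r)
    return CorrectnessCategory(CATEGORY_CORRECT_LINEAGE, r)
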