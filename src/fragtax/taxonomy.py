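"""Eight-rank taxonomic lineages and the lowest-taxonomic-rank (LTR) algebra.

Every reference genome carries a rank-complete lineage over the fixed schema
domain > phylum > class > order > family > genus > species > strain.  The
rank-flexible classifiers all reduce a set of candidate genomes to the
deepest rank on which their lineages agree (the LTR, also called the lowest
common ancestor); this module provides that operation together with a
validated genome -> lineage table that enforces the tree property (a label
at one rank may not recur under two different parents).

Labels are opaque, case-sensitive strings; no name normalisation is
performed.  When a data set supplies no separate strain label the strain
rank is conventionally identified with the genome id.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

RANK_NAMES: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "strain",
)

N_RANKS = len(RANK_NAMES)


class Rank(enum.IntEnum):
    """Taxonomic rank; larger values are more specific."""

    DOMAIN = 0
    PHYLUM = 1
    CLASS = 2
    ORDER = 3
    FAMILY = 4
    GENUS = 5
    SPECIES = 6
    STRAIN = 7

    @property
    def rank_name(self) -> str:
        return RANK_NAMES[self.value]

    @classmethod
    def from_name(cls, name: str) -> "Rank":
        try:
            return cls(RANK_NAMES.index(name))
        except ValueError:
            raise ValueError(f"unknown rank name: {name!r}") from None

    def is_more_specific_than(self, other: "Rank") -> bool:
        return self.value > other.value

    def is_more_general_than(self, other: "Rank") -> bool:
        return self.value < other.value


class TaxonomyError(ValueError):
    """Raised when a lineage or taxonomy table violates its invariants."""


@dataclass(frozen=True)
class Lineage:
    """A contiguous rank-prefix of labels starting at domain.

    A lineage may be truncated: labels are present from domain down to some
    rank and absent below (the fragment is "unclassified" at those ranks).
    An empty lineage means unclassified at all ranks.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) > N_RANKS:
            raise TaxonomyError(
                f"lineage has {len(self.labels)} labels; at most {N_RANKS} allowed"
            )
        for i, lab in enumerate(self.labels):
            if not isinstance(lab, str) or lab == "":
                raise TaxonomyError(
                    f"gapped lineage: empty label at rank {RANK_NAMES[i]}"
                )

    @classmethod
    def of(cls, *labels: str) -> "Lineage":
        return cls(tuple(labels))

    @property
    def depth(self) -> int:
        return len(self.labels)

    @property
    def is_empty(self) -> bool:
        return not self.labels

    @property
    def is_full(self) -> bool:
        return len(self.labels) == N_RANKS

    @property
    def deepest_rank(self) -> Rank | None:
        """Deepest rank carrying a label, or None for an empty lineage."""
        return Rank(len(self.labels) - 1) if self.labels else None

    def label_at(self, rank: Rank) -> str | None:
        return self.labels[rank.value] if rank.value < len(self.labels) else None

    def prefix(self, rank: Rank) -> "Lineage":
        """Truncate to ranks domain..rank (inclusive)."""
        return Lineage(self.labels[: rank.value + 1])

    def starts_with(self, other: "Lineage") -> bool:
        return self.labels[: len(other.labels)] == other.labels

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __str__(self) -> str:
        return ";".join(self.labels) if self.labels else "<unclassified>"


EMPTY_LINEAGE = Lineage(())


def ltr(lineages: Iterable[Lineage]) -> Lineage:
    """Lowest taxonomic rank (deepest common prefix) of a set of lineages.

    Returns the longest rank-prefix on which all inputs agree; disagreement
    at the domain rank yields the empty lineage.  Raises on an empty input
    set, for which the operation is undefined.
    """
    it = iter(lineages)
    try:
        first = next(it)
    except StopIteration:
        raise ValueError("ltr of an empty set of lineages is undefined") from None
    common = list(first.labels)
    for lin in it:
        limit = min(len(common), len(lin.labels))
        k = 0
        while k < limit and common[k] == lin.labels[k]:
            k += 1
        del common[k:]
        if not common:
            break
    return Lineage(tuple(common))


def common_rank(a: Lineage, b: Lineage) -> Rank | None:
    """Deepest rank at which two full-depth lineages agree (None: disjoint)."""
    if not (a.is_full and b.is_full):
        raise TaxonomyError("common_rank requires full-depth lineages")
    return ltr([a, b]).deepest_rank


class TaxonomyTree:
    """A validated genome-id -> full 8-rank Lineage mapping.

    Validation enforces rank-completeness and the tree property: two
    genomes sharing a label at rank k must share all labels above k.
    """

    def __init__(self, lineages: Mapping[str, Lineage]):
        self._lineages: dict[str, Lineage] = {}
        # (rank index, label) -> prefix of labels above; detects a label
        # reused under a different parent.
        seen: dict[tuple[int, str], tuple[str, ...]] = {}
        for gid, lin in lineages.items():
            if not lin.is_full:
                raise TaxonomyError(
                    f"genome {gid!r}: lineage must carry labels at all {N_RANKS} ranks"
                )
            for k in range(1, N_RANKS):
                key = (k, lin.labels[k])
                parent = lin.labels[:k]
                prev = seen.get(key)
                if prev is None:
                    seen[key] = parent
                elif prev != parent:
                    raise TaxonomyError(
                        f"tree-property violation: label {lin.labels[k]!r} at rank "
                        f"{RANK_NAMES[k]} appears under both {prev!r} and {parent!r} "
                        f"(genome {gid!r})"
                    )
            self._lineages[gid] = lin
        # children index: prefix tuple -> set of child labels
        self._children: dict[tuple[str, ...], set[str]] = {}
        for lin in self._lineages.values():
            for k in range(N_RANKS):
                self._children.setdefault(lin.labels[:k], set()).add(lin.labels[k])

    def __len__(self) -> int:
        return len(self._lineages)

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self._lineages

    def __iter__(self) -> Iterator[str]:
        return iter(self._lineages)

    @property
    def genome_ids(self) -> tuple[str, ...]:
        return tuple(self._lineages)

    def lineage(self, genome_id: str) -> Lineage:
        try:
            return self._lineages[genome_id]
        except KeyError:
            raise KeyError(f"unknown genome id: {genome_id!r}") from None

    def items(self):
        return self._lineages.items()

    def lineages(self) -> tuple[Lineage, ...]:
        return tuple(self._lineages.values())

    def genomes_under(self, prefix: Lineage) -> tuple[str, ...]:
        """Genome ids whose lineage starts with the given prefix."""
        return tuple(
            gid for gid, lin in self._lineages.items() if lin.starts_with(prefix)
        )

    def has_sister(self, prefix: Lineage) -> bool:
        """True if the prefix's parent has another child at the same rank."""
        if prefix.is_empty:
            raise TaxonomyError("empty prefix has no parent")
        if prefix.labels not in self._children and prefix.labels[-1] not in (
            self._children.get(prefix.labels[:-1], set())
        ):
            raise KeyError(f"lineage prefix not in tree: {prefix}")
        return len(self._children.get(prefix.labels[:-1], set())) > 1

    def prefixes_at(self, rank: Rank) -> tuple[Lineage, ...]:
        """Distinct lineage prefixes truncated at a rank, in first-seen order."""
        seen: dict[tuple[str, ...], None] = {}
        for lin in self._lineages.values():
            seen.setdefault(lin.labels[: rank.value + 1], None)
        return tuple(Lineage(p) for p in seen)

    def subset(self, genome_ids: Iterable[str]) -> "TaxonomyTree":
        return TaxonomyTree({gid: self._lineages[gid] for gid in genome_ids})


def load_taxonomy(rows: Iterable[Sequence[str]]) -> TaxonomyTree:
    """Build a TaxonomyTree from (genome_id, 8 rank labels) rows.

    Each row must have 9 non-empty fields.  Duplicate genome ids, gapped
    (empty-label) lineages and tree-property violations are rejected with
    an error naming the offending row.
    """
    lineages: dict[str, Lineage] = {}
    for i, row in enumerate(rows, start=1):
        fields = list(row)
        if len(fields) != N_RANKS + 1:
            raise TaxonomyError(
                f"row {i}: expected {N_RANKS + 1} fields, got {len(fields)}"
            )
        gid, labels = fields[0], fields[1:]
        if gid == "":
            raise TaxonomyError(f"row {i}: empty genome id")
        if gid in lineages:
            raise TaxonomyError(f"row {i}: duplicate genome id {gid!r}")
        if any(lab == "" for lab in labels):
            k = labels.index("")
            raise TaxonomyError(
                f"row {i} (genome {gid!r}): gapped lineage — empty label at rank "
                f"{RANK_NAMES[k]}"
            )
        lineages[gid] = Lineage(tuple(labels))
    return TaxonomyTree(lineages)
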