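"""Rank-specific and rank-flexible classifiers for genomic fragments.

Rank-specific classifiers (NB, NN, NB-BL) always assign a full 8-rank
lineage, i.e. one reference genome.  Rank-flexible classifiers (epsilon-NB,
BLAST best-hit, LCA, the consensus hybrids) may stop at a shallower rank,
leaving more specific ranks unclassified, when the evidence is ambiguous.

Conventions shared by every classifier:

* E-value thresholds are strict ("an E-value less than the threshold");
  E = 0.0 passes every threshold.  Bit-score intervals are inclusive at
  the boundary.
* When several hits map to the same genome, the genome's E-value is the
  minimum and its bit score the maximum over its hits.
* All ties break lexicographically on genome id.
* An unscorable fragment (no valid n-mer) yields a fully unclassified
  prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .composition import (
    FrequencyProfile,
    NBModel,
    UnscorableFragmentError,
    kmer_codes,
)
from .taxonomy import EMPTY_LINEAGE, Lineage, Rank, TaxonomyTree, ltr


@dataclass(frozen=True)
class Prediction:
    """A per-fragment taxonomic assignment.

    ``assigned`` is a (possibly empty) rank-prefix of some training-genome
    lineage; ranks below ``classified_rank`` are unclassified by
    construction.
    """

    fragment_id: str
    assigned: Lineage

    @property
    def classified_rank(self) -> Rank | None:
        return self.assigned.deepest_rank

    def is_unclassified_at(self, rank: Rank) -> bool:
        return self.assigned.label_at(rank) is None


@dataclass(frozen=True)
class BlastHit:
    """One homology-evidence record distilled from tabular BLAST output."""

    query_id: str
    genome_id: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value: {self.evalue}")
        if self.bitscore <= 0:
            raise ValueError(f"non-positive bit score: {self.bitscore}")


@dataclass(frozen=True)
class ClassifierParams:
    """Tunable parameters of the classifier family, with their defaults.

    epsilon: likelihood-ratio width of the epsilon-NB interval (>= 1);
        the default 1e5 yields conservative, high-confidence assignments.
    lca_percent: bit-score window p of the LCA classifier, as a percentage
        of the top bit score.
    evalue_max: maximum E-value for a BLAST hit to count as homology
        evidence (strict comparison).
    conservative_evalue_max: E-value cut-off of the conservative LCA
        variant, which pools every surviving hit (p = 100).
    nbbl_fallback_evalue: hits at or above this E-value are ignored by
        NB-BL; a fragment with no hit below it falls back to plain NB.
    nbbl_coeff / nbbl_offset: constants of the NB-BL combined score
        NB - coeff * ln(E) + offset.
    nn_n: n-mer length of the nearest-neighbour frequency profiles.
    """

    epsilon: float = 1e5
    lca_percent: float = 15.0
    evalue_max: float = 1e-5
    conservative_evalue_max: float = 1e-2
    nbbl_fallback_evalue: float = 10.0
    nbbl_coeff: float = 12.0
    nbbl_offset: float = 4.8
    nn_n: int = 4

    def __post_init__(self) -> None:
        if self.epsilon < 1:
            raise ValueError("epsilon must be >= 1")
        if not 0 <= self.lca_percent <= 100:
            raise ValueError("lca_percent must be in [0, 100]")
        if self.evalue_max <= 0 or self.conservative_evalue_max <= 0:
            raise ValueError("E-value thresholds must be positive")


DEFAULT_PARAMS = ClassifierParams()


def _unclassified(fragment_id: str) -> Prediction:
    return Prediction(fragment_id=fragment_id, assigned=EMPTY_LINEAGE)


def nb_scores(models: Sequence[NBModel], fragment: str) -> dict[str, float]:
    """Log-likelihood of a fragment under each genome model.

    Raises UnscorableFragmentError when the fragment has no valid n-mer.
    """
    if not models:
        raise ValueError("at least one genome model is required")
    n = models[0].n
    if any(m.n != n for m in models):
        raise ValueError("all models must share the same n-mer length")
    codes = kmer_codes(fragment, n)
    if codes.size == 0:
        raise UnscorableFragmentError(f"fragment yields no valid {n}-mers")
    return {m.genome_id: m.log_likelihood_codes(codes) for m in models}


def _argmax_genome(scores: Mapping[str, float]) -> str:
    """Genome with the maximum score; ties go to the smallest genome id."""
    best = max(scores.values())
    return min(g for g, s in scores.items() if s == best)


def nb_classify_from_scores(
    scores: Mapping[str, float], taxonomy: TaxonomyTree, fragment_id: str
) -> Prediction:
    if not scores:
        raise ValueError("empty score set")
    winner = _argmax_genome(scores)
    return Prediction(fragment_id=fragment_id, assigned=taxonomy.lineage(winner))


def nb_classify(
    models: Sequence[NBModel],
    taxonomy: TaxonomyTree,
    fragment_id: str,
    fragment: str,
) -> Prediction:
    """Maximum-likelihood NB assignment to a single genome (full depth)."""
    try:
        scores = nb_scores(models, fragment)
    except UnscorableFragmentError:
        return _unclassified(fragment_id)
    return nb_classify_from_scores(scores, taxonomy, fragment_id)


def epsilon_set(scores: Mapping[str, float], epsilon: float) -> set[str]:
    """Genomes whose likelihood is within a factor epsilon of the maximum.

    In log space: all genomes with logL >= max(logL) - ln(epsilon),
    inclusive at the boundary.
    """
    if epsilon < 1:
        raise ValueError("epsilon must be >= 1")
    cutoff = max(scores.values()) - math.log(epsilon)
    return {g for g, s in scores.items() if s >= cutoff}


def epsilon_nb_classify_from_scores(
    scores: Mapping[str, float],
    taxonomy: TaxonomyTree,
    fragment_id: str,
    epsilon: float = DEFAULT_PARAMS.epsilon,
) -> Prediction:
    members = epsilon_set(scores, epsilon)
    assigned = ltr(taxonomy.lineage(g) for g in sorted(members))
    return Prediction(fragment_id=fragment_id, assigned=assigned)


def epsilon_nb_classify(
    models: Sequence[NBModel],
    taxonomy: TaxonomyTree,
    fragment_id: str,
    fragment: str,
    epsilon: float = DEFAULT_PARAMS.epsilon,
) -> Prediction:
    """Rank-flexible NB: assign the LTR of all genomes in the epsilon set.

    Every genome whose likelihood is at most epsilon times smaller than
    the maximum-likelihood genome influences the assignment; the fragment
    is unclassified below the LTR of this set.
    """
    try:
        scores = nb_scores(models, fragment)
    except UnscorableFragmentError:
        return _unclassified(fragment_id)
    return epsilon_nb_classify_from_scores(scores, taxonomy, fragment_id, epsilon)


def nn_classify(
    profiles: Mapping[str, FrequencyProfile],
    taxonomy: TaxonomyTree,
    fragment_id: str,
    fragment: str,
) -> Prediction:
    """Nearest-neighbour assignment by Manhattan distance of frequency profiles.

    The fragment is assigned to the strain of the closest training genome.
    Distances are over the full 4**n frequency vectors (n = 4 by default
    elsewhere; any n <= 8 is accepted here).
    """
    if not profiles:
        raise ValueError("at least one training profile is required")
    ns = {p.n for p in profiles.values()}
    if len(ns) != 1:
        raise ValueError("training profiles must share one n-mer length")
    n = ns.pop()
    codes = kmer_codes(fragment, n)
    if codes.size == 0:
        return _unclassified(fragment_id)
    from .composition import OccurrenceProfile, to_frequency

    frag_vec = to_frequency(OccurrenceProfile.from_codes(codes, n)).dense()
    best_gid: str | None = None
    best_dist = math.inf
    for gid in sorted(profiles):
        dist = float(np.abs(profiles[gid].dense() - frag_vec).sum())
        if dist < best_dist:
            best_dist, best_gid = dist, gid
    assert best_gid is not None
    return Prediction(fragment_id=fragment_id, assigned=taxonomy.lineage(best_gid))


def reduce_hits_by_genome(
    hits: Iterable[BlastHit],
) -> dict[str, tuple[float, float]]:
    """Per-genome (min E-value, max bit score) over a query's hits."""
    out: dict[str, tuple[float, float]] = {}
    for h in hits:
        prev = out.get(h.genome_id)
        if prev is None:
            out[h.genome_id] = (h.evalue, h.bitscore)
        else:
            out[h.genome_id] = (min(prev[0], h.evalue), max(prev[1], h.bitscore))
    return out


def _check_one_query(hits: Sequence[BlastHit]) -> None:
    qids = {h.query_id for h in hits}
    if len(qids) > 1:
        raise ValueError(f"hits span multiple queries: {sorted(qids)}")


def blast_best_hit_classify(
    hits: Sequence[BlastHit],
    taxonomy: TaxonomyTree,
    fragment_id: str,
    evalue_max: float = DEFAULT_PARAMS.evalue_max,
) -> Prediction:
    """Assign by the top-scoring BLAST E-value.

    Hits with E-value >= evalue_max are discarded; with none left the
    fragment is unclassified at all ranks.  When several genomes attain
    the minimum E-value, the fragment goes to the LTR they share.
    """
    _check_one_query(hits)
    surviving = [h for h in hits if h.evalue < evalue_max]
    if not surviving:
        return _unclassified(fragment_id)
    per_genome = reduce_hits_by_genome(surviving)
    best_e = min(e for e, _ in per_genome.values())
    winners = sorted(g for g, (e, _) in per_genome.items() if e == best_e)
    assigned = ltr(taxonomy.lineage(g) for g in winners)
    return Prediction(fragment_id=fragment_id, assigned=assigned)


def lca_classify(
    hits: Sequence[BlastHit],
    taxonomy: TaxonomyTree,
    fragment_id: str,
    evalue_max: float = DEFAULT_PARAMS.evalue_max,
    p: float = DEFAULT_PARAMS.lca_percent,
) -> Prediction:
    """LCA assignment: LTR of all hits within p% of the top bit score.

    Hits are first filtered by E-value (strict < evalue_max); among the
    survivors, hits with bit score >= (1 - p/100) * max bit score
    (inclusive) contribute their genomes to the LTR.
    """
    if not 0 <= p <= 100:
        raise ValueError("p must be in [0, 100]")
    _check_one_query(hits)
    surviving = [h for h in hits if h.evalue < evalue_max]
    if not surviving:
        return _unclassified(fragment_id)
    top = max(h.bitscore for h in surviving)
    threshold = (1.0 - p / 100.0) * top
    kept = sorted({h.genome_id for h in surviving if h.bitscore >= threshold})
    assigned = ltr(taxonomy.lineage(g) for g in kept)
    return Prediction(fragment_id=fragment_id, assigned=assigned)


def conservative_lca_classify(
    hits: Sequence[BlastHit],
    taxonomy: TaxonomyTree,
    fragment_id: str,
    evalue_max: float = DEFAULT_PARAMS.conservative_evalue_max,
) -> Prediction:
    """Conservative LCA: LTR of every hit with E-value below 1e-2."""
    return lca_classify(hits, taxonomy, fragment_id, evalue_max=evalue_max, p=100.0)


def nbbl_score(nb_loglik: float, evalue: float, params: ClassifierParams) -> float:
    """Combined composition+homology score NB - coeff*ln(E) + offset."""
    return nb_loglik - params.nbbl_coeff * math.log(evalue) + params.nbbl_offset


def nbbl_classify(
    models: Sequence[NBModel],
    taxonomy: TaxonomyTree,
    hits: Sequence[BlastHit],
    fragment_id: str,
    fragment: str,
    params: ClassifierParams = DEFAULT_PARAMS,
) -> Prediction:
    """Rank-specific NB-BL: NB log-likelihoods boosted by BLAST E-values.

    Three regimes:
    (a) no hit with E below the fallback threshold (10): plain NB result;
    (b) one or more hits with E exactly 0.0: among genomes holding such a
        hit, pick the one with the largest NB log-likelihood (ln 0 is
        never evaluated);
    (c) otherwise each genome with a usable hit scores
        NB - coeff*ln(Emin) + offset, genomes without a hit compete on
        their plain NB log-likelihood, and the argmax wins.
    """
    _check_one_query(hits)
    try:
        scores = nb_scores(models, fragment)
    except UnscorableFragmentError:
        return _unclassified(fragment_id)
    usable = [h for h in hits if h.evalue < params.nbbl_fallback_evalue]
    if not usable:
        return nb_classify_from_scores(scores, taxonomy, fragment_id)
    zero_genomes = sorted(
        {h.genome_id for h in usable if h.evalue == 0.0} & scores.keys()
    )
    if zero_genomes:
        winner = _argmax_genome({g: scores[g] for g in zero_genomes})
        return Prediction(fragment_id=fragment_id, assigned=taxonomy.lineage(winner))
    per_genome = reduce_hits_by_genome(usable)
    combined: dict[str, float] = {}
    for gid, nb in scores.items():
        if gid in per_genome:
            combined[gid] = nbbl_score(nb, per_genome[gid][0], params)
        else:
            combined[gid] = nb
    winner = _argmax_genome(combined)
    return Prediction(fragment_id=fragment_id, assigned=taxonomy.lineage(winner))


def consensus_classify(a: Prediction, b: Prediction) -> Prediction:
    """Hybrid consensus: longest common prefix of two predictions.

    Agreement is required label by label; a rank where either input is
    unclassified terminates the prefix.  Used for the four hybrids
    BLASTN+NB, BLASTN+epsilon-NB, LCA+NB and LCA+epsilon-NB.
    """
    if a.fragment_id != b.fragment_id:
        raise ValueError(
            f"fragment-id mismatch: {a.fragment_id!r} vs {b.fragment_id!r}"
        )
    limit = min(a.assigned.depth, b.assigned.depth)
    k = 0
    while k < limit and a.assigned.labels[k] == b.assigned.labels[k]:
        k += 1
    return Prediction(fragment_id=a.fragment_id, assigned=Lineage(a.assigned.labels[:k]))
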