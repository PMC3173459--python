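"""Synthetic taxonomies, genomes, fragment samples, noise and BLAST-like hits.

The generator builds a rank-complete taxonomy whose genomes have
hierarchically drifting base composition: each clade perturbs its parent's
GC fraction and strand skews by a per-rank divergence, so related genomes
are compositionally similar and distant ones are not — the signal the
composition classifiers exploit.  Fragments are sampled per species with
contig choice proportional to the number of eligible start positions, and
substitution noise changes an exact number of distinct positions.

Homology evidence is emulated rather than computed: for each fragment and
reference genome a hit is emitted with probability, percent identity and
alignment fraction that decay with the taxonomic distance between the
fragment's source and the reference.  Bit scores follow a match/mismatch
scoring of the implied alignment and E-values the usual exponential decay
in the bit score, so the statistical shape of real tabular BLAST output is
preserved: bit scores fall and E-values rise with taxonomic distance, and
the source genome (when present in the reference set) holds the best hit.

Every stochastic operation takes an explicit integer seed; there is no
global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .classifiers import BlastHit
from .taxonomy import (
    Lineage,
    Rank,
    TaxonomyTree,
    common_rank,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

MARKOV_ORDER = 2  # emission context length of the genome sequence model
_N_CONTEXTS = 4**MARKOV_ORDER

# Per-rank composition drift: std. dev. of the perturbation applied to a
# child clade's GC fraction (and, at half scale, its strand skews) when the
# child is created at that rank.  Deeper ranks drift less, so sibling
# species are compositionally closer than cross-phylum pairs.
DEFAULT_DIVERGENCE: dict[Rank, float] = {
    Rank.PHYLUM: 0.08,
    Rank.CLASS: 0.05,
    Rank.ORDER: 0.04,
    Rank.FAMILY: 0.03,
    Rank.GENUS: 0.02,
    Rank.SPECIES: 0.012,
    Rank.STRAIN: 0.004,
}

# Drift of the order-2 Markov signature logits, same convention.  The
# signature is what gives each clade an oligonucleotide "dialect" beyond raw
# GC, the kind of genome-level compositional structure k-mer classifiers
# rely on.
DEFAULT_SIGNATURE_DIVERGENCE: dict[Rank, float] = {
    Rank.PHYLUM: 0.40,
    Rank.CLASS: 0.25,
    Rank.ORDER: 0.20,
    Rank.FAMILY: 0.15,
    Rank.GENUS: 0.10,
    Rank.SPECIES: 0.06,
    Rank.STRAIN: 0.02,
}


@dataclass(frozen=True)
class CladeCompositionSpec:
    """Composition parameters of one clade or genome.

    gc is the target GC fraction of generated sequence; at_skew and
    gc_skew split the AT and GC mass between the two bases of each pair.
    signature_logits (contexts x 4) modulate the emission probabilities of
    an order-2 Markov chain, giving the clade an oligonucleotide signature
    on top of its base composition; when None the chain degenerates to
    i.i.d. draws from the base probabilities.  Emission probabilities are
    calibrated so the chain's stationary GC matches ``gc``.
    """

    gc: float
    at_skew: float = 0.0
    gc_skew: float = 0.0
    signature_logits: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"gc must be in [0, 1], got {self.gc}")
        if not -1.0 <= self.at_skew <= 1.0 or not -1.0 <= self.gc_skew <= 1.0:
            raise ValueError("skews must be in [-1, 1]")
        if self.signature_logits is not None and self.signature_logits.shape != (
            _N_CONTEXTS,
            4,
        ):
            raise ValueError(
                f"signature_logits must have shape ({_N_CONTEXTS}, 4)"
            )

    def _base_weights(self, gc: float) -> np.ndarray:
        at = 1.0 - gc
        pa = at / 2.0 * (1.0 + self.at_skew)
        pt = at - pa
        pg = gc / 2.0 * (1.0 + self.gc_skew)
        pc = gc - pg
        return np.array([pa, pc, pg, pt])

    @property
    def base_probs(self) -> np.ndarray:
        """Target marginal probabilities over (A, C, G, T)."""
        return self._base_weights(self.gc)

    def _emission(self, gc_knob: float) -> np.ndarray:
        """Per-context emission probabilities for a GC calibration knob."""
        weights = self._base_weights(gc_knob)
        if self.signature_logits is None:
            sig = np.ones((_N_CONTEXTS, 4))
        else:
            sig = np.exp(self.signature_logits)
        probs = sig * weights
        totals = probs.sum(axis=1, keepdims=True)
        return probs / totals

    @staticmethod
    def _stationary_gc(emission: np.ndarray) -> float:
        """Stationary GC of the context chain, by power iteration."""
        pi = np.full(_N_CONTEXTS, 1.0 / _N_CONTEXTS)
        for _ in range(60):
            nxt = np.zeros(_N_CONTEXTS)
            for ctx in range(_N_CONTEXTS):
                if pi[ctx] == 0.0:
                    continue
                for b in range(4):
                    nxt[(ctx * 4 + b) % _N_CONTEXTS] += pi[ctx] * emission[ctx, b]
            pi = nxt
        base_marginal = pi.reshape(-1, 4).sum(axis=0)  # last base of context
        return float(base_marginal[1] + base_marginal[2])

    def emission_probs(self) -> np.ndarray:
        """GC-calibrated (contexts x 4) emission probabilities.

        The calibration bisects the base-weight GC knob so the chain's
        stationary GC matches the spec's target within 1e-4 (exact at the
        degenerate endpoints 0 and 1, where the other pair has zero mass).
        """
        if self.signature_logits is None or self.gc in (0.0, 1.0):
            return self._emission(self.gc)
        lo, hi = 0.0, 1.0
        for _ in range(40):
            mid = (lo + hi) / 2.0
            if self._stationary_gc(self._emission(mid)) < self.gc:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-6:
                break
        return self._emission((lo + hi) / 2.0)


def _drift(
    spec: CladeCompositionSpec,
    sigma: float,
    sig_sigma: float,
    rng: np.random.Generator,
) -> CladeCompositionSpec:
    if spec.signature_logits is None:
        logits = np.zeros((_N_CONTEXTS, 4))
    else:
        logits = spec.signature_logits
    return CladeCompositionSpec(
        gc=float(np.clip(spec.gc + rng.normal(0.0, sigma), 0.15, 0.85)),
        at_skew=float(np.clip(spec.at_skew + rng.normal(0.0, sigma / 2), -0.5, 0.5)),
        gc_skew=float(np.clip(spec.gc_skew + rng.normal(0.0, sigma / 2), -0.5, 0.5)),
        signature_logits=logits + rng.normal(0.0, sig_sigma, size=logits.shape),
    )


def generate_taxonomy(
    seed: int,
    n_domains: int = 1,
    n_phyla: int = 3,
    n_classes: int = 1,
    n_orders: int = 1,
    n_families: int = 2,
    n_genera: int = 2,
    n_species: int = 3,
    n_strains: int = 1,
    divergence: Mapping[Rank, float] = DEFAULT_DIVERGENCE,
    signature_divergence: Mapping[Rank, float] = DEFAULT_SIGNATURE_DIVERGENCE,
) -> tuple[TaxonomyTree, dict[str, CladeCompositionSpec]]:
    """Deterministic rank-complete taxonomy with per-genome composition specs.

    Counts are children per parent (n_phyla phyla under each domain, and
    so on down to n_strains strains per species; the strain label is the
    genome id).  Composition specs drift hierarchically so that sibling
    clades resemble each other more than distant ones.
    """
    counts = (
        n_domains,
        n_phyla,
        n_classes,
        n_orders,
        n_families,
        n_genera,
        n_species,
        n_strains,
    )
    if any(c < 1 for c in counts):
        raise ValueError("all clade counts must be >= 1")
    rng = np.random.default_rng(seed)
    prefixes = ("dom", "phy", "cls", "ord", "fam", "gen", "sp")
    counters = [0] * 7
    lineages: dict[str, Lineage] = {}
    specs: dict[str, CladeCompositionSpec] = {}
    n_genome = 0

    def recurse(
        labels: tuple[str, ...], spec: CladeCompositionSpec, rank_idx: int
    ) -> None:
        nonlocal n_genome
        if rank_idx == 7:  # strain level: one genome per strain
            for _ in range(counts[7]):
                n_genome += 1
                gid = f"G{n_genome:03d}"
                gspec = _drift(
                    spec,
                    divergence.get(Rank.STRAIN, 0.0),
                    signature_divergence.get(Rank.STRAIN, 0.0),
                    rng,
                )
                lineages[gid] = Lineage(labels + (gid,))
                specs[gid] = gspec
            return
        for _ in range(counts[rank_idx]):
            counters[rank_idx] += 1
            label = f"{prefixes[rank_idx]}{counters[rank_idx]:02d}"
            if rank_idx == 0:
                child = CladeCompositionSpec(
                    gc=float(rng.uniform(0.35, 0.65)),
                    at_skew=float(rng.normal(0.0, 0.05)),
                    gc_skew=float(rng.normal(0.0, 0.05)),
                    signature_logits=rng.normal(0.0, 0.6, size=(_N_CONTEXTS, 4)),
                )
            else:
                rank = Rank(rank_idx)
                child = _drift(
                    spec,
                    divergence.get(rank, 0.0),
                    signature_divergence.get(rank, 0.0),
                    rng,
                )
            recurse(labels + (label,), child, rank_idx + 1)

    recurse((), CladeCompositionSpec(gc=0.5), 0)
    return TaxonomyTree(lineages), specs


def generate_genome(
    spec: CladeCompositionSpec, length: int, n_contigs: int = 1, seed: int = 0
) -> list[str]:
    """ACGT-only contigs drawn from the spec's sequence process.

    The sequence follows the spec's GC-calibrated order-2 Markov chain (or
    i.i.d. base draws when no signature is set).  The total length is
    exactly ``length`` split into ``n_contigs`` near-equal pieces.
    """
    if n_contigs < 1 or length < n_contigs:
        raise ValueError("require length >= n_contigs >= 1")
    rng = np.random.default_rng(seed)
    if spec.signature_logits is None:
        draws = rng.choice(4, size=length, p=spec.base_probs)
        seq = _BASES[draws].tobytes().decode("ascii")
    else:
        cum = spec.emission_probs().cumsum(axis=1)
        # flat lists for a fast inner loop
        c0 = cum[:, 0].tolist()
        c1 = cum[:, 1].tolist()
        c2 = cum[:, 2].tolist()
        u = rng.random(length)
        out = bytearray(length)
        bases = b"ACGT"
        ctx = int(rng.integers(0, _N_CONTEXTS))
        mod = _N_CONTEXTS
        for i in range(length):
            ui = u[i]
            if ui < c0[ctx]:
                b = 0
            elif ui < c1[ctx]:
                b = 1
            elif ui < c2[ctx]:
                b = 2
            else:
                b = 3
            out[i] = bases[b]
            ctx = (ctx * 4 + b) % mod
        seq = out.decode("ascii")
    base, extra = divmod(length, n_contigs)
    contigs = []
    pos = 0
    for i in range(n_contigs):
        size = base + (1 if i < extra else 0)
        contigs.append(seq[pos : pos + size])
        pos += size
    return contigs


@dataclass(frozen=True)
class Fragment:
    """A query fragment with its source coordinates (0-based, half-open)."""

    fragment_id: str
    genome_id: str
    contig_index: int
    start: int
    end: int
    sequence: str

    @property
    def contig_id(self) -> str:
        return f"{self.genome_id}_c{self.contig_index}"

    def fasta_id(self) -> str:
        return (
            f"{self.fragment_id}|genome={self.genome_id}"
            f"|contig={self.contig_id}|start={self.start}|end={self.end}"
        )


def parse_fragment_fasta_id(header: str) -> dict[str, str]:
    """Invert Fragment.fasta_id: returns fragment_id, genome, contig, start, end."""
    parts = header.split("|")
    out = {"fragment_id": parts[0]}
    for p in parts[1:]:
        k, _, v = p.partition("=")
        out[k] = v
    return out


def sample_fragments(
    genomes: Mapping[str, Sequence[str]],
    tree: TaxonomyTree,
    fragment_length: int,
    per_species_count: int,
    seed: int,
) -> list[Fragment]:
    """Length-weighted fragment sampling: a fixed count per species.

    Within each species the source contig is drawn with probability
    proportional to its number of eligible start positions
    (L - fragment_length + 1); the start is then uniform.  Contigs shorter
    than the fragment length are ineligible; a species with no eligible
    contig raises.
    """
    if fragment_length < 1 or per_species_count < 0:
        raise ValueError("fragment_length >= 1 and per_species_count >= 0 required")
    rng = np.random.default_rng(seed)
    # species prefix -> ordered list of member genomes present in `genomes`
    species: dict[tuple[str, ...], list[str]] = {}
    for gid in sorted(genomes):
        prefix = tree.lineage(gid).prefix(Rank.SPECIES).labels
        species.setdefault(prefix, []).append(gid)
    fragments: list[Fragment] = []
    counter = 0
    for prefix in sorted(species):
        pool: list[tuple[str, int, int]] = []  # (gid, contig index, n starts)
        for gid in species[prefix]:
            for ci, contig in enumerate(genomes[gid]):
                n_starts = len(contig) - fragment_length + 1
                if n_starts >= 1:
                    pool.append((gid, ci, n_starts))
        if not pool:
            raise ValueError(
                f"species {';'.join(prefix)} has no contig of length >= "
                f"{fragment_length}"
            )
        weights = np.array([p[2] for p in pool], dtype=np.float64)
        weights /= weights.sum()
        picks = rng.choice(len(pool), size=per_species_count, p=weights)
        for pick in picks:
            gid, ci, n_starts = pool[int(pick)]
            start = int(rng.integers(0, n_starts))
            counter += 1
            fragments.append(
                Fragment(
                    fragment_id=f"frag{counter:05d}",
                    genome_id=gid,
                    contig_index=ci,
                    start=start,
                    end=start + fragment_length,
                    sequence=genomes[gid][ci][start : start + fragment_length],
                )
            )
    return fragments


def add_noise(sequence: str, noise_pct: float, seed: int) -> str:
    """Substitute exactly round(noise_pct/100 * L) distinct positions.

    Each chosen position is replaced by a base drawn uniformly from the
    three alternatives, so 1% noise on a 200 nt fragment alters exactly
    two bases.  The substitution set is nested in the noise level: for a
    fixed seed, a higher noise_pct applies a superset of the substitutions
    of a lower one, so noise series generated from one seed are coupled
    and directly comparable.
    """
    if not 0.0 <= noise_pct <= 100.0:
        raise ValueError("noise_pct must be in [0, 100]")
    length = len(sequence)
    k = int(math.floor(noise_pct / 100.0 * length + 0.5))
    if k == 0:
        return sequence
    rng = np.random.default_rng(seed)
    order = rng.permutation(length)
    offsets = rng.integers(1, 4, size=length)  # 1..3 bases away from current
    out = list(sequence)
    bases = "ACGT"
    index = {b: i for i, b in enumerate(bases)}
    if any(b not in index for b in set(sequence)):
        raise ValueError("add_noise requires an ACGT-only sequence")
    for pos, off in zip(order[:k], offsets[:k]):
        out[pos] = bases[(index[out[pos]] + int(off)) % 4]
    return "".join(out)


# --- emulated homology evidence -------------------------------------------

N_DISTANCES = 9  # 0 = same genome .. 8 = different domain


@dataclass(frozen=True)
class SyntheticHitModel:
    """Parameters of the emulated BLAST hit generator, indexed by the
    taxonomic distance d between a fragment's source and a reference genome
    (d = 0 same genome, 1 same species, ..., 8 different domain).

    In expectation the percent identity and alignment fraction — hence the
    bit score — decrease with d, while the E-value increases.  The source
    genome's own hit (d = 0) is a full-length perfect match, so it is
    always at least as good as any other hit.
    """

    emit_prob: tuple[float, ...] = (1.0, 1.0, 0.95, 0.75, 0.5, 0.3, 0.15, 0.08, 0.02)
    identity_mean: tuple[float, ...] = (
        1.0, 0.98, 0.94, 0.89, 0.84, 0.79, 0.74, 0.69, 0.64,
    )
    aln_frac_mean: tuple[float, ...] = (
        1.0, 0.97, 0.85, 0.65, 0.50, 0.40, 0.30, 0.22, 0.18,
    )
    identity_sd: float = 0.02
    aln_frac_sd: float = 0.05
    db_size: float = 1e7
    match_score: float = 1.2
    mismatch_penalty: float = 2.0

    def __post_init__(self) -> None:
        for name in ("emit_prob", "identity_mean", "aln_frac_mean"):
            vals = getattr(self, name)
            if len(vals) != N_DISTANCES:
                raise ValueError(f"{name} must have {N_DISTANCES} entries")
        for seq in (self.identity_mean, self.aln_frac_mean):
            if any(b > a for a, b in zip(seq, seq[1:])):
                raise ValueError(
                    "identity and alignment fraction must be non-increasing "
                    "in taxonomic distance"
                )

    def bitscore(self, matches: int, mismatches: int) -> float:
        raw = self.match_score * matches - self.mismatch_penalty * mismatches
        return round(max(20.0, raw), 1)

    def evalue(self, query_length: int, bits: float) -> float:
        log10_e = math.log10(query_length * self.db_size) - bits * math.log10(2.0)
        if log10_e < -180.0:
            return 0.0
        return 10.0**log10_e


DEFAULT_HIT_MODEL = SyntheticHitModel()


@dataclass(frozen=True)
class SyntheticAlignment:
    """One emulated local alignment, carrying all 12 tabular columns."""

    query_id: str
    subject_id: str
    genome_id: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def to_hit(self) -> BlastHit:
        return BlastHit(
            query_id=self.query_id,
            genome_id=self.genome_id,
            evalue=self.evalue,
            bitscore=self.bitscore,
        )


def as_hits(alignments: Sequence[SyntheticAlignment]) -> list[BlastHit]:
    return [a.to_hit() for a in alignments]


def taxonomic_distance(a: Lineage, b: Lineage) -> int:
    """0 for identical lineages up to 8 for disagreement at domain."""
    cr = common_rank(a, b)
    return 8 - (cr.value + 1) if cr is not None else 8


def subject_map(genomes: Mapping[str, Sequence[str]]) -> dict[str, str]:
    """Contig id -> genome id mapping for a genome set."""
    return {
        f"{gid}_c{ci}": gid
        for gid in genomes
        for ci in range(len(genomes[gid]))
    }


def synth_blast_hits(
    fragments: Sequence[Fragment],
    genomes: Mapping[str, Sequence[str]],
    tree: TaxonomyTree,
    hit_model: SyntheticHitModel = DEFAULT_HIT_MODEL,
    seed: int = 0,
) -> list[SyntheticAlignment]:
    """Emulate a tabular BLAST search of fragments against a genome set.

    For every (fragment, reference genome) pair a hit is emitted with
    probability emit_prob[d] where d is the taxonomic distance from the
    fragment's source.  The source genome, when present in the reference
    set, receives a deterministic full-length perfect hit; all other
    identities are capped below 1, so the source hit is never beaten.
    """
    rng = np.random.default_rng(seed)
    ref_ids = sorted(genomes)
    out: list[SyntheticAlignment] = []
    for frag in fragments:
        src_lineage = tree.lineage(frag.genome_id)
        qlen = len(frag.sequence)
        for gid in ref_ids:
            if gid == frag.genome_id:
                d = 0
            else:
                d = taxonomic_distance(src_lineage, tree.lineage(gid))
            if d > 0 and rng.random() >= hit_model.emit_prob[d]:
                continue
            if d == 0:
                identity, frac = 1.0, 1.0
            else:
                identity = float(
                    np.clip(
                        rng.normal(hit_model.identity_mean[d], hit_model.identity_sd),
                        0.5,
                        0.995,
                    )
                )
                frac = float(
                    np.clip(
                        rng.normal(hit_model.aln_frac_mean[d], hit_model.aln_frac_sd),
                        0.05,
                        0.99,
                    )
                )
            aln_len = max(15, int(round(frac * qlen)))
            aln_len = min(aln_len, qlen)
            matches = int(round(identity * aln_len))
            mismatches = aln_len - matches
            bits = hit_model.bitscore(matches, mismatches)
            evalue = hit_model.evalue(qlen, bits)
            contigs = genomes[gid]
            ci = int(rng.integers(0, len(contigs)))
            if d == 0:
                ci = frag.contig_index
                sstart = frag.start + 1
            else:
                max_start = max(1, len(contigs[ci]) - aln_len + 1)
                sstart = int(rng.integers(1, max_start + 1))
            out.append(
                SyntheticAlignment(
                    query_id=frag.fragment_id,
                    subject_id=f"{gid}_c{ci}",
                    genome_id=gid,
                    pident=round(identity * 100.0, 2),
                    length=aln_len,
                    mismatch=mismatches,
                    gapopen=0,
                    qstart=1,
                    qend=aln_len,
                    sstart=sstart,
                    send=sstart + aln_len - 1,
                    evalue=evalue,
                    bitscore=bits,
                )
            )
    return out


# --- convenience world builder --------------------------------------------


@dataclass(frozen=True)
class SyntheticWorld:
    """A taxonomy, its composition specs and the generated genome sequences."""

    tree: TaxonomyTree
    specs: dict[str, CladeCompositionSpec]
    genomes: dict[str, list[str]]


def build_world(
    seed: int,
    genome_length: int = 50_000,
    n_contigs: int = 1,
    **taxonomy_shape,
) -> SyntheticWorld:
    """Generate the default study conditions: a 3-phylum taxonomy
    (2 families per class, 2 genera per family, 3 species per genus, one
    strain each = 36 genomes) of ~50 kb single-contig genomes.

    Shape keywords are forwarded to generate_taxonomy.
    """
    tree, specs = generate_taxonomy(seed=seed, **taxonomy_shape)
    genomes: dict[str, list[str]] = {}
    for i, gid in enumerate(sorted(tree.genome_ids)):
        genomes[gid] = generate_genome(
            specs[gid], genome_length, n_contigs, seed=seed * 100_003 + i
        )
    return SyntheticWorld(tree=tree, specs=specs, genomes=genomes)
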