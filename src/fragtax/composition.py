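"""Oligonucleotide composition profiles and naive Bayes genome models.

A genome's compositional signature is the occurrence profile of its
overlapping n-mers, counted over both strands of every contig.  Windows
containing any character outside {A, C, G, T} are discarded and do not
contribute to the total count M.  The naive Bayes (NB) model of a genome
stores Laplace-smoothed (add-one) log conditional probabilities

    ln P(w_j | G_i) = ln[ (f(w_j|G_i) + 1) / (M_i + N) ],   N = 4**n,

so that unobserved n-mers share the constant ln[1 / (M_i + N)] and the N
probabilities sum to one exactly.  Fragment log-likelihoods are sums of
these terms over the fragment's valid n-mers, counted on the given strand
only (strand invariance is supplied by the both-strand genome counts).
All arithmetic is in natural-log space; probability products are never
formed, since a product of hundreds of n-mer probabilities underflows
double precision.

n-mers are stored sparsely as base-4 integer codes (A=0, C=1, G=2, T=3,
most-significant base first); at the default n = 10 the full space has
4**10 = 1,048,576 dimensions of which a genome typically occupies a small
fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

_LUT = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

MAX_N = 15  # 4**15 still fits comfortably in int64 codes


class UnscorableFragmentError(ValueError):
    """A fragment yielded zero valid n-mers at the model's n."""


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _check_n(n: int) -> None:
    if not 1 <= n <= MAX_N:
        raise ValueError(f"n-mer length must be in 1..{MAX_N}, got {n}")


def encode_bases(sequence: str) -> np.ndarray:
    """Map a sequence to base codes; non-ACGT characters become -1."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


def kmer_codes(sequence: str, n: int) -> np.ndarray:
    """Integer codes of all valid overlapping n-mers of one strand.

    Windows overlapping a non-ACGT character are dropped.  Returns an
    empty array when the sequence is shorter than n.
    """
    _check_n(n)
    arr = encode_bases(sequence)
    length = arr.size
    if length < n:
        return np.empty(0, dtype=np.int64)
    valid = arr >= 0
    vals = np.where(valid, arr, 0)
    m = length - n + 1
    codes = np.zeros(m, dtype=np.int64)
    ok = np.ones(m, dtype=bool)
    for j in range(n):
        codes = codes * 4 + vals[j : j + m]
        ok &= valid[j : j + m]
    return codes[ok]


def code_to_kmer(code: int, n: int) -> str:
    bases = "ACGT"
    out = []
    for _ in range(n):
        out.append(bases[code & 3])
        code >>= 2
    return "".join(reversed(out))


def kmer_to_code(kmer: str) -> int:
    code = 0
    for ch in kmer:
        v = int(_LUT[ord(ch)])
        if v < 0:
            raise ValueError(f"non-ACGT character in n-mer: {kmer!r}")
        code = code * 4 + v
    return code


@dataclass(frozen=True)
class OccurrenceProfile:
    """Sparse counts of the N = 4**n possible n-mers in a sequence set."""

    n: int
    codes: np.ndarray  # sorted unique int64 codes of observed n-mers
    counts: np.ndarray  # parallel int64 counts, all > 0

    def __post_init__(self) -> None:
        _check_n(self.n)
        if self.codes.shape != self.counts.shape:
            raise ValueError("codes and counts must be parallel arrays")

    @classmethod
    def from_codes(cls, codes: np.ndarray, n: int) -> "OccurrenceProfile":
        uniq, cnt = np.unique(codes, return_counts=True)
        return cls(n=n, codes=uniq.astype(np.int64), counts=cnt.astype(np.int64))

    @property
    def M(self) -> int:
        """Total number of retained (valid) n-mers."""
        return int(self.counts.sum())

    @property
    def N(self) -> int:
        return 4**self.n

    def count(self, kmer: str) -> int:
        idx = np.searchsorted(self.codes, kmer_to_code(kmer))
        if idx < self.codes.size and self.codes[idx] == kmer_to_code(kmer):
            return int(self.counts[idx])
        return 0

    def as_dict(self) -> dict[str, int]:
        return {
            code_to_kmer(int(c), self.n): int(v)
            for c, v in zip(self.codes, self.counts)
        }

    def __add__(self, other: "OccurrenceProfile") -> "OccurrenceProfile":
        if other.n != self.n:
            raise ValueError("cannot merge profiles with different n")
        codes = np.concatenate([self.codes, other.codes])
        counts = np.concatenate([self.counts, other.counts])
        uniq, inverse = np.unique(codes, return_inverse=True)
        summed = np.zeros(uniq.size, dtype=np.int64)
        np.add.at(summed, inverse, counts)
        return OccurrenceProfile(n=self.n, codes=uniq, counts=summed)


@dataclass(frozen=True)
class FrequencyProfile:
    """Occurrence profile normalised by the total n-mer count M."""

    n: int
    codes: np.ndarray
    frequencies: np.ndarray  # parallel floats summing to 1

    @property
    def N(self) -> int:
        return 4**self.n

    def frequency(self, kmer: str) -> float:
        code = kmer_to_code(kmer)
        idx = np.searchsorted(self.codes, code)
        if idx < self.codes.size and self.codes[idx] == code:
            return float(self.frequencies[idx])
        return 0.0

    def dense(self) -> np.ndarray:
        """Full 4**n frequency vector (absent n-mers are zero)."""
        if self.n > 8:
            raise ValueError("dense vectors limited to n <= 8")
        out = np.zeros(self.N, dtype=np.float64)
        out[self.codes] = self.frequencies
        return out

    def as_dict(self) -> dict[str, float]:
        return {
            code_to_kmer(int(c), self.n): float(v)
            for c, v in zip(self.codes, self.frequencies)
        }


def count_nmers(
    sequence: str, n: int, both_strands: bool = False
) -> OccurrenceProfile:
    """Count all overlapping n-mers of a sequence (one or both strands).

    A sequence of length L contributes L - n + 1 windows per strand, minus
    any window containing a non-ACGT character.  A sequence shorter than n
    yields an empty profile (M = 0), not an error.
    """
    codes = kmer_codes(sequence, n)
    if both_strands:
        codes = np.concatenate([codes, kmer_codes(reverse_complement(sequence), n)])
    return OccurrenceProfile.from_codes(codes, n)


def genome_profile(contigs: Sequence[str], n: int) -> OccurrenceProfile:
    """Both-strand occurrence profile pooled over all contigs of a genome."""
    if not contigs:
        raise ValueError("genome must have at least one contig")
    parts = [kmer_codes(c, n) for c in contigs]
    parts += [kmer_codes(reverse_complement(c), n) for c in contigs]
    return OccurrenceProfile.from_codes(np.concatenate(parts), n)


def to_frequency(profile: OccurrenceProfile) -> FrequencyProfile:
    m = profile.M
    if m == 0:
        raise ValueError("cannot normalise an empty profile (M = 0)")
    return FrequencyProfile(
        n=profile.n,
        codes=profile.codes.copy(),
        frequencies=profile.counts.astype(np.float64) / m,
    )


@dataclass(frozen=True)
class NBModel:
    """Laplace-smoothed log conditional n-mer probabilities for one genome.

    Observed n-mers carry ln[(f+1)/(M+N)]; the 4**n - k unobserved n-mers
    share ``default_logp`` = ln[1/(M+N)].  The prior over genomes is flat
    and therefore never stored.
    """

    genome_id: str
    n: int
    codes: np.ndarray  # sorted codes of observed n-mers
    logcond: np.ndarray  # ln P(w|G) for observed n-mers
    counts: np.ndarray  # observed occurrence counts f(w|G), parallel to codes
    M: int

    @property
    def N(self) -> int:
        return 4**self.n

    @property
    def default_logp(self) -> float:
        """ln P(w|G) for any n-mer never observed in the genome."""
        return -math.log(self.M + self.N)

    def log_prob(self, kmer: str) -> float:
        code = kmer_to_code(kmer)
        idx = np.searchsorted(self.codes, code)
        if idx < self.codes.size and self.codes[idx] == code:
            return float(self.logcond[idx])
        return self.default_logp

    def log_likelihood_codes(self, codes: np.ndarray) -> float:
        """Sum of ln P(w|G) over pre-encoded fragment n-mer codes."""
        if codes.size == 0:
            raise UnscorableFragmentError(
                f"fragment yields no valid {self.n}-mers"
            )
        idx = np.searchsorted(self.codes, codes)
        idx_c = np.minimum(idx, self.codes.size - 1) if self.codes.size else idx
        if self.codes.size:
            hit = self.codes[idx_c] == codes
        else:
            hit = np.zeros(codes.shape, dtype=bool)
        n_miss = int((~hit).sum())
        total = float(self.logcond[idx_c[hit]].sum()) + n_miss * self.default_logp
        return total


def build_nb_model(genome_id: str, contigs: Sequence[str], n: int) -> NBModel:
    """Build the NB model of a genome from its contigs.

    An empty genome (M = 0) is allowed: smoothing gives every n-mer
    probability 1/4**n.
    """
    _check_n(n)
    if contigs:
        profile = genome_profile(contigs, n)
    else:
        profile = OccurrenceProfile.from_codes(np.empty(0, dtype=np.int64), n)
    return nb_model_from_profile(genome_id, profile)


def nb_model_from_profile(genome_id: str, profile: OccurrenceProfile) -> NBModel:
    denom = math.log(profile.M + profile.N)
    logcond = np.log1p(profile.counts.astype(np.float64)) - denom
    return NBModel(
        genome_id=genome_id,
        n=profile.n,
        codes=profile.codes.copy(),
        logcond=logcond,
        counts=profile.counts.copy(),
        M=profile.M,
    )


def nb_log_likelihood(model: NBModel, fragment: str) -> float:
    """Log-likelihood (nats) of a fragment under a genome's NB model.

    The fragment's n-mers are counted on the given strand only.  Raises
    UnscorableFragmentError when no valid n-mer exists — a distinct signal
    from a merely low score.
    """
    return model.log_likelihood_codes(kmer_codes(fragment, model.n))
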