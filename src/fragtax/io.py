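"""Readers and writers for the package's on-disk formats.

Formats handled here: FASTA (genomes and query fragments, via Biopython),
the 9-column taxonomy TSV, 12-column tabular BLAST output (the outfmt-6
dialect), the 2-column subject-to-genome mapping TSV, prediction and
metrics TSVs, and the plain-text NB model store.  All parsers report
errors with file and line provenance; all writers are deterministic so
identical inputs produce byte-identical files.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .classifiers import BlastHit, Prediction
from .composition import NBModel, OccurrenceProfile, nb_model_from_profile
from .evaluation import CorrectnessCategory, MetricsSummary
from .taxonomy import (
    Lineage,
    N_RANKS,
    RANK_NAMES,
    TaxonomyTree,
    load_taxonomy,
)

UNCLASSIFIED = "unclassified"


class ParseError(ValueError):
    """A malformed input file; the message carries file and line context."""


# --- FASTA -----------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercased sequence), order preserved.

    Multi-line wrapping and CRLF line endings are accepted.  An empty file
    or a record with an empty sequence is an error.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append((rec.id, seq))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    path: str | Path, records: Iterable[tuple[str, str]], width: int = 70
) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --- taxonomy TSV ----------------------------------------------------------

TAXONOMY_HEADER = ("genome_id",) + RANK_NAMES


def read_taxonomy_tsv(path: str | Path) -> TaxonomyTree:
    """Read the 9-column taxonomy table (header line required)."""
    path = Path(path)
    with open(path, newline="") as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]
    if not lines:
        raise ParseError(f"{path}: empty taxonomy file")
    header = tuple(lines[0].split("\t"))
    if header != TAXONOMY_HEADER:
        expected = "\t".join(TAXONOMY_HEADER)
        raise ParseError(f"{path}:1: expected header {expected!r}")
    rows = [ln.split("\t") for ln in lines[1:] if ln]
    return load_taxonomy(rows)


def write_taxonomy_tsv(path: str | Path, tree: TaxonomyTree) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TAXONOMY_HEADER) + "\n")
        for gid in sorted(tree.genome_ids):
            fh.write(gid + "\t" + "\t".join(tree.lineage(gid).labels) + "\n")


# --- subject map TSV -------------------------------------------------------


def read_subject_map(path: str | Path) -> dict[str, str]:
    """Read the 2-column subject-id -> genome-id mapping (header required)."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        for i, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\r\n")
            if not ln:
                continue
            fields = ln.split("\t")
            if i == 1:
                if fields != ["subject_id", "genome_id"]:
                    raise ParseError(
                        f"{path}:1: expected header 'subject_id\\tgenome_id'"
                    )
                continue
            if len(fields) != 2:
                raise ParseError(f"{path}:{i}: expected 2 columns, got {len(fields)}")
            mapping[fields[0]] = fields[1]
    return mapping


def write_subject_map(path: str | Path, mapping: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("subject_id\tgenome_id\n")
        for sid in sorted(mapping):
            fh.write(f"{sid}\t{mapping[sid]}\n")


# --- tabular BLAST ---------------------------------------------------------

BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def parse_blast_tabular(
    path: str | Path, subject_to_genome: Mapping[str, str]
) -> list[BlastHit]:
    """Parse 12-column tabular BLAST output into BlastHit records.

    Column 11 is the E-value (scientific notation; the string "0.0" —
    exact zero — is allowed) and column 12 the bit score.  Subject ids are
    mapped to genome ids through the supplied table.  All hits are kept;
    thresholding happens in the classifiers.
    """
    path = Path(path)
    hits: list[BlastHit] = []
    with open(path, newline="") as fh:
        for i, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\r\n")
            if not ln:
                continue
            fields = ln.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path}:{i}: expected 12 tab-separated columns, got "
                    f"{len(fields)}"
                )
            sseqid = fields[1]
            if sseqid not in subject_to_genome:
                raise ParseError(
                    f"{path}:{i}: subject id {sseqid!r} not in the "
                    "subject-to-genome mapping"
                )
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: unparsable number: {exc}") from None
            try:
                hits.append(
                    BlastHit(
                        query_id=fields[0],
                        genome_id=subject_to_genome[sseqid],
                        evalue=evalue,
                        bitscore=bitscore,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: {exc}") from None
    return hits


def format_evalue(evalue: float) -> str:
    """E-value formatting matching the tabular BLAST dialect ("0.0" at zero)."""
    if evalue == 0.0:
        return "0.0"
    if evalue >= 0.001:
        return f"{evalue:.3g}"
    return f"{evalue:.2e}"


def write_blast_tabular(path: str | Path, alignments: Sequence) -> None:
    """Write SyntheticAlignment records as 12-column tabular output."""
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(
                "\t".join(
                    (
                        a.query_id,
                        a.subject_id,
                        f"{a.pident:.2f}",
                        str(a.length),
                        str(a.mismatch),
                        str(a.gapopen),
                        str(a.qstart),
                        str(a.qend),
                        str(a.sstart),
                        str(a.send),
                        format_evalue(a.evalue),
                        f"{a.bitscore:.1f}",
                    )
                )
                + "\n"
            )


# --- predictions -----------------------------------------------------------


def write_predictions_tsv(path: str | Path, predictions: Sequence[Prediction]) -> None:
    """Prediction table: fragment_id then one label (or 'unclassified') per rank."""
    with open(path, "w") as fh:
        fh.write("fragment_id\t" + "\t".join(RANK_NAMES) + "\n")
        for pred in predictions:
            labels = list(pred.assigned.labels)
            labels += [UNCLASSIFIED] * (N_RANKS - len(labels))
            fh.write(pred.fragment_id + "\t" + "\t".join(labels) + "\n")


def read_predictions_tsv(path: str | Path) -> list[Prediction]:
    path = Path(path)
    out: list[Prediction] = []
    with open(path, newline="") as fh:
        for i, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\r\n")
            if not ln:
                continue
            fields = ln.split("\t")
            if i == 1:
                if fields != ["fragment_id", *RANK_NAMES]:
                    raise ParseError(f"{path}:1: unexpected prediction header")
                continue
            if len(fields) != N_RANKS + 1:
                raise ParseError(
                    f"{path}:{i}: expected {N_RANKS + 1} columns, got {len(fields)}"
                )
            labels = []
            for lab in fields[1:]:
                if lab == UNCLASSIFIED:
                    break
                labels.append(lab)
            out.append(Prediction(fragment_id=fields[0], assigned=Lineage(tuple(labels))))
    return out


def read_truth_tsv(path: str | Path) -> dict[str, str]:
    """fragment_id -> source genome id table (header required)."""
    path = Path(path)
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        for i, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\r\n")
            if not ln:
                continue
            fields = ln.split("\t")
            if i == 1:
                if fields != ["fragment_id", "genome_id"]:
                    raise ParseError(
                        f"{path}:1: expected header 'fragment_id\\tgenome_id'"
                    )
                continue
            if len(fields) != 2:
                raise ParseError(f"{path}:{i}: expected 2 columns")
            out[fields[0]] = fields[1]
    return out


def write_truth_tsv(path: str | Path, truth: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("fragment_id\tgenome_id\n")
        for fid, gid in truth.items():
            fh.write(f"{fid}\t{gid}\n")


# --- metrics / categorization ----------------------------------------------


def write_metrics_tsv(path: str | Path, summary: MetricsSummary, rank_name: str) -> None:
    """Per-lineage confusion table plus average and absolute summary rows."""

    def fmt(x: float) -> str:
        return "NA" if math.isnan(x) else f"{x:.6f}"

    with open(path, "w") as fh:
        fh.write("lineage\trank\tTP\tFP\tFN\tU\tZ\tSn\tSp\tFNr\tUr\n")
        frame = summary.per_lineage
        for label, row in frame.iterrows():
            fh.write(
                f"{label}\t{rank_name}\t{int(row.TP)}\t{int(row.FP)}\t"
                f"{int(row.FN)}\t{int(row.U)}\t{int(row.Z)}\t"
                f"{fmt(row.Sn)}\t{fmt(row.Sp)}\t{fmt(row.FNr)}\t{fmt(row.Ur)}\n"
            )
        tot = frame[["TP", "FP", "FN", "U", "Z"]].sum()
        for name, sn, sp, fnr, ur in (
            ("<average>", summary.sn_avg, summary.sp_avg, summary.fnr_avg, summary.ur_avg),
            ("<absolute>", summary.sn_abs, summary.sp_abs, summary.fnr_abs, summary.ur_abs),
        ):
            fh.write(
                f"{name}\t{rank_name}\t{int(tot.TP)}\t{int(tot.FP)}\t{int(tot.FN)}\t"
                f"{int(tot.U)}\t{int(tot.Z)}\t{fmt(sn)}\t{fmt(sp)}\t{fmt(fnr)}\t{fmt(ur)}\n"
            )


def write_categories_tsv(
    path: str | Path,
    categories: Mapping[str, CorrectnessCategory],
) -> None:
    with open(path, "w") as fh:
        fh.write("fragment_id\tr\tcategory\n")
        for fid, cat in categories.items():
            rname = cat.r.rank_name if cat.r is not None else "NA"
            fh.write(f"{fid}\t{rname}\t{cat.category}\n")


# --- NB model store --------------------------------------------------------

MODEL_STORE_VERSION = 1
_MANIFEST = "manifest.tsv"


def _safe_filename(genome_id: str) -> str:
    if not genome_id or any(ch in genome_id for ch in "/\\\0\n\t"):
        raise ValueError(f"genome id not usable as a filename: {genome_id!r}")
    return f"{genome_id}.counts.tsv"


def save_models(models: Sequence[NBModel], directory: str | Path) -> None:
    """Persist NB models: one counts file per genome plus a manifest.

    Each genome file holds n, M and the nonzero n-mer counts keyed by the
    base-4 integer code of the n-mer; the round trip is bit-exact since
    only integers are stored (log probabilities are recomputed on load).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ns = {m.n for m in models}
    if len(ns) != 1:
        raise ValueError("a model store holds models of a single n-mer length")
    n = ns.pop()
    with open(directory / _MANIFEST, "w") as fh:
        fh.write(f"# model_store_version={MODEL_STORE_VERSION}\n")
        fh.write(f"# n={n}\n")
        fh.write("genome_id\tfile\tM\n")
        for m in sorted(models, key=lambda m: m.genome_id):
            fh.write(f"{m.genome_id}\t{_safe_filename(m.genome_id)}\t{m.M}\n")
    for m in models:
        counts = m.counts
        with open(directory / _safe_filename(m.genome_id), "w") as fh:
            fh.write(f"# genome_id={m.genome_id}\n")
            fh.write(f"# n={m.n}\n")
            fh.write(f"# M={m.M}\n")
            fh.write("code\tcount\n")
            for code, cnt in zip(m.codes, counts):
                fh.write(f"{int(code)}\t{int(cnt)}\n")


def load_models(directory: str | Path) -> dict[str, NBModel]:
    """Load a model store written by save_models."""
    directory = Path(directory)
    manifest = directory / _MANIFEST
    if not manifest.exists():
        raise ParseError(f"{manifest}: model store manifest not found")
    entries: list[tuple[str, str]] = []
    with open(manifest) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if ln.startswith("#") or ln.startswith("genome_id") or not ln:
                continue
            fields = ln.split("\t")
            entries.append((fields[0], fields[1]))
    models: dict[str, NBModel] = {}
    for gid, fname in entries:
        fpath = directory / fname
        n = None
        m_total = None
        codes: list[int] = []
        counts: list[int] = []
        with open(fpath) as fh:
            for i, ln in enumerate(fh, start=1):
                ln = ln.rstrip("\n")
                if not ln:
                    continue
                if ln.startswith("#"):
                    key, _, val = ln[1:].strip().partition("=")
                    if key == "n":
                        n = int(val)
                    elif key == "M":
                        m_total = int(val)
                    continue
                if ln.startswith("code\t"):
                    continue
                c, _, v = ln.partition("\t")
                codes.append(int(c))
                counts.append(int(v))
        if n is None or m_total is None:
            raise ParseError(f"{fpath}: missing n or M header")
        profile = OccurrenceProfile(
            n=n,
            codes=np.array(codes, dtype=np.int64),
            counts=np.array(counts, dtype=np.int64),
        )
        if profile.M != m_total:
            raise ParseError(
                f"{fpath}: stored M={m_total} disagrees with the sum of counts "
                f"({profile.M})"
            )
        models[gid] = nb_model_from_profile(gid, profile)
    return models
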