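"""Sequence / annotation / tabular I/O and assembly-level statistics.

All coordinates handled here are 1-based inclusive, matching the FASTA-,
GFF3- and VCF-style conventions of the file formats themselves.  Sequences
are normalised on ingest to uppercase over the {A,C,G,T,N} alphabet.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (scaffold, pseudomolecule or read)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AssemblySummary:
    n_seqs: int
    total_len: int
    n50: int
    longest: int
    gc_percent: float
    n_len: int

    @property
    def non_n_length(self) -> int:
        return self.total_len - self.n_len


@dataclass
class GeneModel:
    """A protein-coding (or non-coding) gene model on one sequence.

    ``cds_segments`` / ``exon_segments`` are ordered lists of 1-based
    inclusive (start, end) pairs, ascending by start.
    """

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    cds_segments: list[tuple[int, int]] = field(default_factory=list)
    exon_segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        prev_end = 0
        for s, e in self.cds_segments:
            if s > e or s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: CDS segment ({s},{e}) out of bounds")
            if s <= prev_end:
                raise ValueError(f"gene {self.gene_id}: CDS segments overlap or unsorted")
            prev_end = e

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds_segments)


@dataclass(frozen=True)
class GeneticMapLocus:
    """A mapped marker: linkage-group/cM placement plus scaffold/bp placement."""

    marker_id: str
    linkage_group: str
    cM: float
    scaffold_id: str | None
    position_bp: int | None

    @property
    def placed(self) -> bool:
        return self.scaffold_id is not None


@dataclass(frozen=True)
class OrthologHit:
    """A scored correspondence between a query gene and a reference gene."""

    query_gene_id: str
    ref_gene_id: str
    ref_chrom: str
    ref_start_bp: int
    ref_end_bp: int
    evalue: float
    bitscore: float

    @property
    def ref_mid(self) -> float:
        return (self.ref_start_bp + self.ref_end_bp) / 2.0


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def normalize_sequence(seq: str) -> tuple[str, int]:
    """Uppercase and replace characters outside {A,C,G,T,N} by N.

    Returns the normalised sequence and the number of replacements.
    """
    up = seq.upper()
    if set(up) <= ALPHABET:
        return up, 0
    cleaned = "".join(c if c in ALPHABET else "N" for c in up)
    n_replaced = sum(1 for a, b in zip(up, cleaned) if a != b)
    return cleaned, n_replaced


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into normalised :class:`SequenceRecord` objects.

    Raises on duplicate ids and on empty files; characters outside the
    alphabet are replaced by N with a logged count.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    total_replaced = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq, n_replaced = normalize_sequence(str(rec.seq))
        total_replaced += n_replaced
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    if total_replaced:
        logger.warning("%s: replaced %d non-ACGTN characters with N", path, total_replaced)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read FASTQ reads (qualities discarded), normalised like FASTA input."""
    records = []
    seen: set[str] = set()
    total_replaced = 0
    for rec in SeqIO.parse(str(path), "fastq"):
        if rec.id in seen:
            raise ValueError(f"duplicate read id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq, n_replaced = normalize_sequence(str(rec.seq))
        total_replaced += n_replaced
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise ValueError(f"no reads found in {path}")
    if total_replaced:
        logger.warning("%s: replaced %d non-ACGTN characters with N", path, total_replaced)
    return records


def read_reads(path: str | Path) -> list[SequenceRecord]:
    """Read either FASTA or FASTQ, sniffing the first character."""
    with open(path) as fh:
        first = fh.read(1)
    return read_fastq(path) if first == "@" else read_fasta(path)


# ---------------------------------------------------------------------------
# assembly statistics and filters
# ---------------------------------------------------------------------------

def filter_by_length(
    records: Sequence[SequenceRecord], min_len: int
) -> tuple[list[SequenceRecord], list[SequenceRecord], int]:
    """Partition records at a minimum length (boundary inclusive: >= min_len).

    Returns (kept, removed, removed_total_bp).
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [r for r in records if len(r) >= min_len]
    removed = [r for r in records if len(r) < min_len]
    return kept, removed, sum(len(r) for r in removed)


def n50(lengths: Sequence[int]) -> int:
    """Smallest length L such that sequences of length >= L cover >= half the total."""
    if not lengths:
        raise ValueError("n50 of an empty set is undefined")
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if 2 * acc >= total:
            return length
    raise AssertionError("unreachable")


def assembly_summary(records: Sequence[SequenceRecord]) -> AssemblySummary:
    """Assembly statistics; GC% over non-N bases only."""
    if not records:
        raise ValueError("cannot summarise an empty assembly")
    lengths = [len(r) for r in records]
    gc = at = n_count = 0
    for rec in records:
        gc += rec.seq.count("G") + rec.seq.count("C")
        at += rec.seq.count("A") + rec.seq.count("T")
        n_count += rec.seq.count("N")
    denom = gc + at
    if denom == 0:
        logger.warning("assembly contains only N bases; GC%% reported as 0")
        gc_percent = 0.0
    else:
        gc_percent = 100.0 * gc / denom
    return AssemblySummary(
        n_seqs=len(records),
        total_len=sum(lengths),
        n50=n50(lengths),
        longest=max(lengths),
        gc_percent=gc_percent,
        n_len=n_count,
    )


# ---------------------------------------------------------------------------
# genetic-map and ortholog-hit tables
# ---------------------------------------------------------------------------

MAP_COLUMNS = ["marker_id", "linkage_group", "cM", "scaffold_id", "position_bp"]
HIT_COLUMNS = [
    "query_gene_id", "ref_gene_id", "ref_chrom",
    "ref_start_bp", "ref_end_bp", "evalue", "bitscore",
]


def read_genetic_map(path: str | Path) -> list[GeneticMapLocus]:
    """Read the marker/linkage-group/cM/scaffold/bp TSV.

    Rows without a scaffold placement are retained, flagged unplaced.
    Malformed numeric fields raise with the offending line number.
    """
    loci: list[GeneticMapLocus] = []
    seen: set[str] = set()
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != MAP_COLUMNS:
            raise ValueError(f"{path}: expected header {MAP_COLUMNS}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(MAP_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected {len(MAP_COLUMNS)} fields, got {len(row)}")
            marker_id, lg, cm_s, scaffold_id, pos_s = (f.strip() for f in row)
            if marker_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate marker id {marker_id!r}")
            seen.add(marker_id)
            try:
                cm = float(cm_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed cM value {cm_s!r}") from exc
            if not math.isfinite(cm) or cm < 0:
                raise ValueError(f"{path}:{lineno}: cM must be finite and >= 0, got {cm_s!r}")
            if scaffold_id in ("", ".", "NA"):
                loci.append(GeneticMapLocus(marker_id, lg, cm, None, None))
                continue
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed position {pos_s!r}") from exc
            if pos < 1:
                raise ValueError(f"{path}:{lineno}: position_bp must be >= 1, got {pos}")
            loci.append(GeneticMapLocus(marker_id, lg, cm, scaffold_id, pos))
    n_unplaced = sum(1 for l in loci if not l.placed)
    if n_unplaced:
        logger.info("%s: %d loci without scaffold placement", path, n_unplaced)
    return loci


def write_genetic_map(loci: Iterable[GeneticMapLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(MAP_COLUMNS) + "\n")
        for l in loci:
            sc = l.scaffold_id if l.placed else ""
            pos = str(l.position_bp) if l.placed else ""
            fh.write(f"{l.marker_id}\t{l.linkage_group}\t{l.cM:g}\t{sc}\t{pos}\n")


def read_hit_table(
    path: str | Path, evalue_ceiling: float = 1e-5
) -> list[OrthologHit]:
    """Read the BLAST-tabular-like ortholog hit TSV.

    Hits with an E-value above ``evalue_ceiling`` are dropped and counted.
    """
    hits: list[OrthologHit] = []
    n_dropped = 0
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != HIT_COLUMNS:
            raise ValueError(f"{path}: expected header {HIT_COLUMNS}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(HIT_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected {len(HIT_COLUMNS)} fields")
            q, ref_gene, ref_chrom, s_s, e_s, ev_s, bs_s = (f.strip() for f in row)
            try:
                start, end = int(s_s), int(e_s)
                evalue, bitscore = float(ev_s), float(bs_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field") from exc
            if start < 0 or end < 0:
                raise ValueError(f"{path}:{lineno}: negative coordinate")
            if start > end:
                raise ValueError(f"{path}:{lineno}: ref_start > ref_end")
            if evalue < 0:
                raise ValueError(f"{path}:{lineno}: negative E-value")
            if evalue > evalue_ceiling:
                n_dropped += 1
                continue
            hits.append(OrthologHit(q, ref_gene, ref_chrom, start, end, evalue, bitscore))
    if n_dropped:
        logger.info("%s: dropped %d hits above E-value ceiling %g", path, n_dropped, evalue_ceiling)
    if not hits:
        logger.warning("%s: no hits retained", path)
    return hits


def write_hit_table(hits: Iterable[OrthologHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.query_gene_id}\t{h.ref_gene_id}\t{h.ref_chrom}\t"
                f"{h.ref_start_bp}\t{h.ref_end_bp}\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def _parse_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene / mRNA / exon / CDS features).

    exon/CDS features are attached to their gene through Parent chains
    (exon -> mRNA -> gene or exon -> gene directly).
    """
    genes: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    pending: list[tuple[str, str, int, int]] = []  # (ftype, parent, start, end)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seq_id, _src, ftype, start_s, end_s, _score, strand, _frame, attr_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            attrs = _parse_attributes(attr_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ValueError(f"{path}:{lineno}: gene feature without ID")
                if gid in genes:
                    raise ValueError(f"{path}:{lineno}: duplicate gene id {gid!r}")
                genes[gid] = dict(seq_id=seq_id, start=start, end=end, strand=strand,
                                  cds=[], exons=[])
            elif ftype == "mRNA":
                mid, parent = attrs.get("ID"), attrs.get("Parent")
                if mid and parent:
                    mrna_to_gene[mid] = parent
            elif ftype in ("exon", "CDS"):
                parent = attrs.get("Parent")
                if parent is None:
                    raise ValueError(f"{path}:{lineno}: {ftype} without Parent")
                pending.append((ftype, parent, start, end))
    for ftype, parent, start, end in pending:
        gid = mrna_to_gene.get(parent, parent)
        if gid not in genes:
            raise ValueError(f"{path}: {ftype} Parent {parent!r} resolves to unknown gene")
        key = "cds" if ftype == "CDS" else "exons"
        genes[gid][key].append((start, end))
    models = []
    for gid, g in genes.items():
        models.append(GeneModel(
            gene_id=gid, seq_id=g["seq_id"], start=g["start"], end=g["end"],
            strand=g["strand"],
            cds_segments=sorted(g["cds"]),
            exon_segments=sorted(g["exons"]),
        ))
    models.sort(key=lambda m: (m.seq_id, m.start, m.gene_id))
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(f"{m.seq_id}\t.\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\tID={m.gene_id}\n")
            mrna_id = f"{m.gene_id}.t1"
            fh.write(f"{m.seq_id}\t.\tmRNA\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                     f"ID={mrna_id};Parent={m.gene_id}\n")
            for s, e in m.exon_segments:
                fh.write(f"{m.seq_id}\t.\texon\t{s}\t{e}\t.\t{m.strand}\t.\tParent={mrna_id}\n")
            for s, e in m.cds_segments:
                fh.write(f"{m.seq_id}\t.\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\tParent={mrna_id}\n")
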