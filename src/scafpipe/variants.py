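"""VCF hard filtering, variant summaries and effect classification.

Two hard-filter presets mirror a ddRAD genotyping run (per-line depth >= 5,
site quality strictly > 10, MAF >= 0.2, missing rate < 0.5) and a
resequencing run (quality >= 50, GQ >= 20, depth in [10, 100]).  Effects are
classified against gene models into sequence-ontology terms and the four
impact tiers HIGH / MODERATE / LOW / MODIFIER.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .genome_io import GeneModel, SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)

IMPACT_BY_TERM = {
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "start_lost": "HIGH",
    "frameshift_variant": "HIGH",
    "missense_variant": "MODERATE",
    "inframe_insertion": "MODERATE",
    "inframe_deletion": "MODERATE",
    "synonymous_variant": "LOW",
    "intron_variant": "MODIFIER",
    "intergenic_variant": "MODIFIER",
    "noncoding_exon_variant": "MODIFIER",
}

_IMPACT_RANK = {"HIGH": 0, "MODERATE": 1, "LOW": 2, "MODIFIER": 3}

TRANSITIONS = {"AG", "CT"}


@dataclass
class VariantRecord:
    """One VCF site with per-sample genotype / depth / genotype-quality."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: float | None = None
    genotypes: list[tuple[int | None, int | None]] = field(default_factory=list)
    dp: list[int | None] = field(default_factory=list)
    gq: list[int | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or set(self.ref) - set("ACGT"):
            raise ValueError(f"bad ref allele {self.ref!r} at {self.chrom}:{self.pos}")
        for alt in self.alts:
            if alt == self.ref:
                raise ValueError(f"alt equals ref at {self.chrom}:{self.pos}")

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    def indel_length(self, alt_index: int = 0) -> int:
        return abs(len(self.ref) - len(self.alts[alt_index]))


@dataclass(frozen=True)
class FilterParams:
    min_dp: int = 0
    max_dp: int | None = None
    min_site_q: float | None = None
    site_q_strict: bool = False  # True: qual must be strictly > min_site_q
    min_gq: int | None = None
    min_maf: float | None = None
    max_missing_rate: float | None = None

    def __post_init__(self) -> None:
        if self.min_dp < 0:
            raise ValueError("min_dp must be >= 0")
        if self.max_dp is not None and self.max_dp < self.min_dp:
            raise ValueError("max_dp must be >= min_dp")
        if self.min_maf is not None and not 0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if self.max_missing_rate is not None and not 0 <= self.max_missing_rate <= 1:
            raise ValueError("max_missing_rate must be in [0, 1]")

    @classmethod
    def ddrad(cls) -> "FilterParams":
        """ddRAD genotyping preset: DP>=5 per line, quality strictly >10,
        MAF>=0.2, missing rate <0.5."""
        return cls(min_dp=5, min_site_q=10, site_q_strict=True,
                   min_maf=0.2, max_missing_rate=0.5)

    @classmethod
    def reseq(cls) -> "FilterParams":
        """Resequencing preset: quality >=50, GQ>=20, DP in [10, 100]."""
        return cls(min_dp=10, max_dp=100, min_site_q=50, min_gq=20)


@dataclass(frozen=True)
class EffectCall:
    so_term: str
    impact: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if IMPACT_BY_TERM.get(self.so_term) != self.impact:
            raise ValueError(f"impact {self.impact!r} inconsistent with term {self.so_term!r}")


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> tuple[list[str], list[VariantRecord]]:
    """Read a VCF 4.x file; returns (sample names, variant records)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    for v in vcf:
        genotypes: list[tuple[int | None, int | None]] = []
        for g in v.genotypes:
            a, b = g[0], g[1]
            genotypes.append((None if a < 0 else int(a), None if b < 0 else int(b)))
        dp_arr = v.format("DP")
        gq_arr = v.format("GQ")
        dp = [None if dp_arr is None or int(x) < 0 else int(x)
              for x in (dp_arr[:, 0] if dp_arr is not None else [-1] * len(samples))]
        gq = [None if gq_arr is None or int(x) < 0 else int(x)
              for x in (gq_arr[:, 0] if gq_arr is not None else [-1] * len(samples))]
        variants.append(VariantRecord(
            chrom=v.CHROM, pos=v.POS, ref=v.REF, alts=tuple(v.ALT),
            qual=None if v.QUAL is None else float(v.QUAL),
            genotypes=genotypes, dp=dp, gq=gq,
        ))
    return samples, variants


def write_vcf(samples: Sequence[str], variants: Sequence[VariantRecord],
              path: str | Path, contigs: Mapping[str, int] | None = None) -> None:
    """Write an uncompressed VCF 4.2 with GT/DP/GQ per sample."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=scafpipe\n")
        for chrom, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + list(samples)) + "\n")
        for v in variants:
            qual = "." if v.qual is None else f"{v.qual:g}"
            fields = [v.chrom, str(v.pos), ".", v.ref, ",".join(v.alts) or ".",
                      qual, ".", ".", "GT:DP:GQ"]
            for i in range(len(samples)):
                gt = v.genotypes[i] if i < len(v.genotypes) else (None, None)
                gt_s = "/".join("." if a is None else str(a) for a in gt)
                dp = v.dp[i] if i < len(v.dp) and v.dp[i] is not None else "."
                gq = v.gq[i] if i < len(v.gq) and v.gq[i] is not None else "."
                fields.append(f"{gt_s}:{dp}:{gq}")
            fh.write("\t".join(fields) + "\n")


def split_multiallelic(variants: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Split multi-allelic sites into biallelic records.

    Genotype allele indices are remapped: the kept alt becomes 1, other alt
    alleles become missing.
    """
    out = []
    for v in variants:
        if v.is_biallelic:
            out.append(v)
            continue
        for alt_idx, alt in enumerate(v.alts, start=1):
            def remap(a: int | None) -> int | None:
                if a is None or (a != 0 and a != alt_idx):
                    return None if a != 0 else 0
                return 0 if a == 0 else 1
            genotypes = [(remap(a), remap(b)) for a, b in v.genotypes]
            out.append(replace(v, alts=(alt,), genotypes=genotypes))
    return out


# ---------------------------------------------------------------------------
# hard filtering
# ---------------------------------------------------------------------------

CRITERIA_ORDER = ("quality", "depth", "gq", "missing", "maf")


def hard_filter(
    variants: Sequence[VariantRecord], params: FilterParams
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Apply the hard-filter criteria in fixed order; a variant is counted
    against the first criterion it fails."""
    counts = {c: 0 for c in CRITERIA_ORDER}
    passing: list[VariantRecord] = []
    for v in variants:
        reason = _first_failure(v, params)
        if reason is None:
            passing.append(v)
        else:
            counts[reason] += 1
    return passing, counts


def _first_failure(v: VariantRecord, p: FilterParams) -> str | None:
    if p.min_site_q is not None:
        if v.qual is None:
            raise ValueError(f"site quality filter configured but QUAL missing at {v.chrom}:{v.pos}")
        ok = v.qual > p.min_site_q if p.site_q_strict else v.qual >= p.min_site_q
        if not ok:
            return "quality"
    called = [i for i, (a, b) in enumerate(v.genotypes) if a is not None and b is not None]
    if p.min_dp or p.max_dp is not None:
        if not v.dp and called:
            raise ValueError(f"depth filter configured but DP missing at {v.chrom}:{v.pos}")
        for i in called:
            d = v.dp[i]
            if d is None or d < p.min_dp or (p.max_dp is not None and d > p.max_dp):
                return "depth"
    if p.min_gq is not None:
        if not v.gq and called:
            raise ValueError(f"GQ filter configured but GQ missing at {v.chrom}:{v.pos}")
        for i in called:
            q = v.gq[i]
            if q is None or q < p.min_gq:
                return "gq"
    if p.max_missing_rate is not None and v.genotypes:
        missing = sum(1 for a, b in v.genotypes if a is None or b is None)
        if not missing / len(v.genotypes) < p.max_missing_rate:
            return "missing"
    if p.min_maf is not None:
        alleles: list[int] = []
        for a, b in v.genotypes:
            if a is not None and b is not None:
                alleles.extend((a, b))
        if not alleles:
            return "maf"
        freqs: dict[int, int] = {}
        for a in alleles:
            freqs[a] = freqs.get(a, 0) + 1
        maf = 1.0 - max(freqs.values()) / len(alleles)
        if maf < p.min_maf:
            return "maf"
    return None


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class SpectrumSummary:
    counts: dict[str, int]          # unordered base pair, e.g. "AG" -> count
    transitions: int
    transversions: int
    ts_tv: float                    # inf when transversions == 0


def substitution_spectrum(snps: Sequence[VariantRecord]) -> SpectrumSummary:
    """Count the six unordered substitution classes and the Ts/Tv ratio.

    Input must be biallelic SNPs (split multi-allelic sites first).
    """
    counts = {c: 0 for c in ("AC", "AG", "AT", "CG", "CT", "GT")}
    for v in snps:
        if not (v.is_snp and v.is_biallelic):
            raise ValueError(f"substitution_spectrum expects biallelic SNPs; got {v.ref}>{v.alts}")
        key = "".join(sorted((v.ref, v.alts[0])))
        counts[key] += 1
    ts = sum(counts[c] for c in TRANSITIONS)
    tv = sum(c for k, c in counts.items() if k not in TRANSITIONS)
    if tv == 0:
        if ts:
            logger.warning("zero transversions; Ts/Tv reported as infinity")
            ratio = math.inf
        else:
            logger.warning("empty SNP set; Ts/Tv undefined, reported as nan")
            ratio = math.nan
    else:
        ratio = ts / tv
    return SpectrumSummary(counts=counts, transitions=ts, transversions=tv, ts_tv=ratio)


def variant_density(variant_count: int, non_n_length_bp: int, per_bp: int = 100_000) -> float:
    """Variants per ``per_bp`` of non-ambiguous sequence, to one decimal."""
    if non_n_length_bp <= 0:
        raise ValueError("non_n_length_bp must be > 0")
    return round(variant_count * per_bp / non_n_length_bp, 1)


def heterozygosity_summary(
    variants: Sequence[VariantRecord],
    samples: Sequence[str],
    chrom_non_n_lengths: Mapping[str, int] | None = None,
    per_bp: int = 100_000,
):
    """Per-sample heterozygous-site counts and a per-chromosome breakdown.

    Returns (per_sample_counts, dataframe with chrom x sample het counts and,
    when lengths are given, densities per ``per_bp``).
    """
    import pandas as pd

    per_sample = {s: 0 for s in samples}
    per_chrom: dict[tuple[str, str], int] = {}
    for v in variants:
        for i, s in enumerate(samples):
            if i >= len(v.genotypes):
                continue
            a, b = v.genotypes[i]
            if (a is None) != (b is None):
                raise ValueError(f"haploid genotype for {s} at {v.chrom}:{v.pos}")
            if a is None:
                continue
            if a != b:
                per_sample[s] += 1
                per_chrom[(v.chrom, s)] = per_chrom.get((v.chrom, s), 0) + 1
    rows = []
    for (chrom, s), count in sorted(per_chrom.items()):
        row = {"chromosome": chrom, "sample": s, "het_sites": count}
        if chrom_non_n_lengths and chrom in chrom_non_n_lengths:
            row["het_density"] = variant_density(count, chrom_non_n_lengths[chrom], per_bp)
        rows.append(row)
    return per_sample, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# effect classification
# ---------------------------------------------------------------------------

def _cds_sequence(gene: GeneModel, chrom_seq: str) -> str:
    """Spliced CDS in translation order (5'->3' of the coding strand)."""
    parts = [chrom_seq[s - 1:e] for s, e in gene.cds_segments]
    cds = "".join(parts)
    return reverse_complement(cds) if gene.strand == "-" else cds


def _cds_offset(gene: GeneModel, pos: int) -> int | None:
    """0-based offset of genomic ``pos`` within the spliced CDS, or None."""
    acc = 0
    for s, e in gene.cds_segments:
        if s <= pos <= e:
            fwd = acc + (pos - s)
            if gene.strand == "+":
                return fwd
            return gene.cds_length - 1 - fwd
        acc += e - s + 1
    return None


def _classify_in_gene(v: VariantRecord, gene: GeneModel, chrom_seq: str) -> str:
    ref_interval = (v.pos, v.pos + len(v.ref) - 1)
    alt = v.alts[0]
    in_cds = any(s <= ref_interval[1] and ref_interval[0] <= e for s, e in gene.cds_segments)
    if in_cds and gene.is_coding:
        if len(v.ref) != len(alt):
            diff = abs(len(v.ref) - len(alt))
            if diff % 3 != 0:
                return "frameshift_variant"
            return "inframe_insertion" if len(alt) > len(v.ref) else "inframe_deletion"
        if len(v.ref) == 1:
            offset = _cds_offset(gene, v.pos)
            if offset is None:  # anchor base outside CDS despite interval overlap
                return "intron_variant"
            cds = _cds_sequence(gene, chrom_seq)
            codon_idx = offset // 3
            codon = cds[codon_idx * 3:codon_idx * 3 + 3]
            if len(codon) < 3:
                return "synonymous_variant"  # trailing partial codon: no aa change computable
            alt_base = alt if gene.strand == "+" else reverse_complement(alt)
            within = offset % 3
            alt_codon = codon[:within] + alt_base + codon[within + 1:]
            aa_ref = str(Seq(codon).translate())
            aa_alt = str(Seq(alt_codon).translate())
            if aa_ref == aa_alt:
                return "synonymous_variant"
            if aa_ref == "*":
                return "stop_lost"
            if aa_alt == "*":
                return "stop_gained"
            if codon_idx == 0:
                return "start_lost"
            return "missense_variant"
        # same-length multi-base substitution: treat per aa change of first codon
        return "missense_variant"
    in_exon = any(s <= ref_interval[1] and ref_interval[0] <= e for s, e in gene.exon_segments)
    if in_exon:
        return "noncoding_exon_variant"
    return "intron_variant"


def classify_effect(
    v: VariantRecord,
    gene_models: Sequence[GeneModel],
    genome: Mapping[str, str] | Sequence[SequenceRecord],
) -> EffectCall:
    """Classify one (biallelic, normalised) variant against gene models.

    Precedence within a gene: CDS > intron > non-coding exon > intergenic.
    Across overlapping genes the most severe call wins; ties break by gene id.
    """
    if not isinstance(genome, Mapping):
        genome = {r.id: r.seq for r in genome}
    chrom_seq = genome.get(v.chrom)
    if chrom_seq is None:
        raise ValueError(f"variant chromosome {v.chrom!r} not in genome")
    if v.pos + len(v.ref) - 1 > len(chrom_seq):
        raise ValueError(f"variant at {v.chrom}:{v.pos} extends beyond sequence end")
    if not v.is_biallelic:
        raise ValueError("classify_effect expects biallelic variants; split first")
    ref_interval = (v.pos, v.pos + len(v.ref) - 1)
    calls: list[tuple[int, str, str]] = []
    for gene in gene_models:
        if gene.seq_id != v.chrom:
            continue
        if not (gene.start <= ref_interval[1] and ref_interval[0] <= gene.end):
            continue
        term = _classify_in_gene(v, gene, chrom_seq)
        calls.append((_IMPACT_RANK[IMPACT_BY_TERM[term]], gene.gene_id, term))
    if not calls:
        return EffectCall("intergenic_variant", "MODIFIER", None)
    calls.sort(key=lambda c: (c[0], c[1]))
    _, gene_id, term = calls[0]
    return EffectCall(term, IMPACT_BY_TERM[term], gene_id)


def classify_all(
    variants: Sequence[VariantRecord],
    gene_models: Sequence[GeneModel],
    genome: Mapping[str, str] | Sequence[SequenceRecord],
) -> list[EffectCall]:
    if not isinstance(genome, Mapping):
        genome = {r.id: r.seq for r in genome}
    return [classify_effect(v, gene_models, genome) for v in split_multiallelic(variants)]
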