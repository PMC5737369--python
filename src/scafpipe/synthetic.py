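"""Seeded generators for genomes, fragmentations, maps, hit tables, variants
and reads, each paired with a full truth table so every pipeline stage can be
tested closed-loop without external data.

Every generator is a pure function of its parameters plus a mandatory seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genome_io import (
    GeneModel,
    GeneticMapLocus,
    OrthologHit,
    SequenceRecord,
    reverse_complement,
)
from .variants import VariantRecord

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOP_CODONS = ("TAA", "TAG", "TGA")
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_NONSTOP_CODONS = [c for c in _CODONS if c not in _STOP_CODONS]

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass
class SsrImplant:
    motif: str
    copies: int
    chrom: str | None = None
    pos: int | None = None  # 1-based start; auto-placed when None


@dataclass
class ImplantedSsr:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    motif: str
    copies: int


@dataclass
class ScaffoldTruth:
    scaffold_id: str
    chrom: str
    start: int        # 1-based start of the scaffold on its chromosome
    orientation: str  # '+' or '-'
    length: int


@dataclass
class GenomeTruth:
    chrom_lengths: dict[str, int]
    genes: list[GeneModel]
    ssr_loci: list[ImplantedSsr] = field(default_factory=list)


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _make_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons - 2) random non-stop codons + a stop codon."""
    body = rng.choice(len(_NONSTOP_CODONS), size=n_codons - 2)
    stop = _STOP_CODONS[rng.integers(len(_STOP_CODONS))]
    return "ATG" + "".join(_NONSTOP_CODONS[i] for i in body) + stop


def generate_genome(
    n_chrom: int,
    chrom_len: int,
    gc: float = 0.38,
    gene_density: float = 4e-4,
    ssr_implants: Sequence[SsrImplant] = (),
    seed: int | None = None,
    min_intergenic: int = 50,
) -> tuple[list[SequenceRecord], list[GeneModel], GenomeTruth]:
    """Generate an i.i.d.-base reference genome with implanted gene models
    (valid ATG..stop CDS, 1-3 exons) and optional SSR implants.

    gene_density is genes per bp.  Identical seed => identical output.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    if n_chrom < 1 or chrom_len < 1000 or not 0 < gc < 1:
        raise ValueError("bad genome parameters")
    rng = np.random.default_rng(seed)
    chroms: list[SequenceRecord] = []
    genes: list[GeneModel] = []
    truth = GenomeTruth(chrom_lengths={}, genes=[])
    n_genes_per_chrom = int(round(gene_density * chrom_len))
    for ci in range(1, n_chrom + 1):
        name = f"chr{ci}"
        arr = _random_bases(rng, chrom_len, gc)
        # place non-overlapping genes left to right
        placed: list[tuple[int, int]] = []  # 0-based half-open gene spans
        cursor = min_intergenic
        gi = 0
        attempts = 0
        while gi < n_genes_per_chrom and attempts < n_genes_per_chrom * 20:
            attempts += 1
            n_exons = int(rng.integers(1, 4))
            exon_codons = [int(rng.integers(20, 80)) for _ in range(n_exons)]
            introns = [int(rng.integers(40, 200)) for _ in range(n_exons - 1)]
            gene_len = sum(c * 3 for c in exon_codons) + sum(introns)
            gap = int(rng.integers(min_intergenic, max(min_intergenic + 1,
                                                       (chrom_len // max(1, n_genes_per_chrom)) // 2)))
            start0 = cursor + gap
            if start0 + gene_len + min_intergenic > chrom_len:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            gi += 1
            gene_id = f"g{ci:02d}_{gi:04d}"
            cds = _make_cds(rng, sum(exon_codons))
            # lay CDS across exons (strand-aware: first codon at 5' end)
            segs: list[tuple[int, int]] = []
            p = start0
            for k, codons in enumerate(exon_codons):
                seg_len = codons * 3
                segs.append((p + 1, p + seg_len))  # 1-based inclusive
                p += seg_len
                if k < n_exons - 1:
                    p += introns[k]
            end0 = p
            genomic_cds = cds if strand == "+" else reverse_complement(cds)
            # write CDS bases into the exon segments in genomic order
            offset = 0
            for s, e in segs:
                seg_len = e - s + 1
                arr[s - 1:e] = np.frombuffer(
                    genomic_cds[offset:offset + seg_len].encode(), dtype=np.uint8)
                offset += seg_len
            genes.append(GeneModel(
                gene_id=gene_id, seq_id=name, start=start0 + 1, end=end0,
                strand=strand, cds_segments=segs, exon_segments=list(segs),
            ))
            placed.append((start0, end0))
            cursor = end0
        if gi < n_genes_per_chrom:
            raise ValueError(
                f"gene_density {gene_density:g} infeasible for chrom_len {chrom_len}")
        # implant SSRs destined for this chromosome
        for implant in ssr_implants:
            if implant.chrom not in (None, name):
                continue
            if implant.chrom is None and ci != 1:
                continue
            motif_arr = np.frombuffer((implant.motif * implant.copies).encode(), dtype=np.uint8)
            if implant.pos is not None:
                s0 = implant.pos - 1
            else:
                s0 = _find_intergenic_slot(rng, placed, chrom_len, len(motif_arr))
            if s0 is None or s0 + len(motif_arr) > chrom_len:
                raise ValueError(f"no room to implant SSR {implant.motif}x{implant.copies}")
            arr[s0:s0 + len(motif_arr)] = motif_arr
            # break accidental continuation at the borders
            if s0 > 0:
                arr[s0 - 1] = ord(_other_base(chr(arr[s0])))
            if s0 + len(motif_arr) < chrom_len:
                expected = implant.motif[len(motif_arr) % len(implant.motif)]
                arr[s0 + len(motif_arr)] = ord(_other_base(expected))
            truth.ssr_loci.append(ImplantedSsr(
                chrom=name, start=s0 + 1, end=s0 + len(motif_arr),
                motif=implant.motif, copies=implant.copies,
            ))
        chroms.append(SequenceRecord(name, arr.tobytes().decode("ascii")))
        truth.chrom_lengths[name] = chrom_len
    truth.genes = genes
    return chroms, genes, truth


def _other_base(base: str) -> str:
    return "C" if base in "AGT" else "A"


def _find_intergenic_slot(
    rng: np.random.Generator, placed: Sequence[tuple[int, int]],
    chrom_len: int, needed: int,
) -> int | None:
    for _ in range(200):
        s0 = int(rng.integers(0, max(1, chrom_len - needed)))
        if all(not (s0 < e + 2 and s < s0 + needed + 2) for s, e in placed):
            return s0
    return None


# ---------------------------------------------------------------------------
# fragmentation into scaffolds
# ---------------------------------------------------------------------------

def fragment_scaffolds(
    reference: Sequence[SequenceRecord],
    gene_models: Sequence[GeneModel],
    size_range: tuple[int, int],
    seed: int | None = None,
) -> tuple[list[SequenceRecord], list[GeneModel], list[ScaffoldTruth]]:
    """Cut chromosomes at sampled breakpoints (nudged off gene bodies), flip
    each scaffold with probability 0.5, and shuffle the scaffold order.

    Returns (scaffold records, gene models re-coordinated onto scaffolds,
    truth table).  Concatenating truth-ordered, truth-oriented scaffolds with
    no spacer reproduces the reference exactly.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    lo, hi = size_range
    if not 1 <= lo <= hi:
        raise ValueError("bad size range")
    rng = np.random.default_rng(seed)
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        genes_by_chrom.setdefault(g.seq_id, []).append(g)
    pieces: list[tuple[str, int, int]] = []  # (chrom, start0, end0) half-open
    for rec in reference:
        spans = sorted((g.start - 1, g.end) for g in genes_by_chrom.get(rec.id, []))
        pos = 0
        n = len(rec.seq)
        while pos < n:
            size = int(rng.integers(lo, hi + 1))
            cut = min(pos + size, n)
            # nudge the cut off any gene body
            for s, e in spans:
                if s < cut < e:
                    cut = e
                    break
            cut = min(cut, n)
            pieces.append((rec.id, pos, cut))
            pos = cut
    order = rng.permutation(len(pieces))
    flips = rng.random(len(pieces)) < 0.5
    seq_by_chrom = {r.id: r.seq for r in reference}
    scaffolds: list[SequenceRecord] = []
    truth: list[ScaffoldTruth] = []
    scaffold_genes: list[GeneModel] = []
    for rank, pi in enumerate(order, start=1):
        chrom, s0, e0 = pieces[pi]
        sid = f"sc{rank:04d}"
        seq = seq_by_chrom[chrom][s0:e0]
        orientation = "-" if flips[pi] else "+"
        if orientation == "-":
            seq = reverse_complement(seq)
        scaffolds.append(SequenceRecord(sid, seq))
        truth.append(ScaffoldTruth(sid, chrom, s0 + 1, orientation, e0 - s0))
        scaf_len = e0 - s0
        for g in genes_by_chrom.get(chrom, []):
            if g.start - 1 >= s0 and g.end <= e0:
                scaffold_genes.append(_recoordinate_gene(g, sid, s0, scaf_len, orientation))
    scaffold_genes.sort(key=lambda g: (g.seq_id, g.start))
    return scaffolds, scaffold_genes, truth


def _recoordinate_gene(g: GeneModel, sid: str, s0: int, scaf_len: int, orientation: str) -> GeneModel:
    def shift(iv: tuple[int, int]) -> tuple[int, int]:
        a, b = iv[0] - s0, iv[1] - s0
        if orientation == "-":
            a, b = scaf_len - b + 1, scaf_len - a + 1
        return a, b

    start, end = shift((g.start, g.end))
    strand = g.strand
    if orientation == "-":
        strand = "+" if strand == "-" else "-"
    return GeneModel(
        gene_id=g.gene_id, seq_id=sid, start=start, end=end, strand=strand,
        cds_segments=sorted(shift(iv) for iv in g.cds_segments),
        exon_segments=sorted(shift(iv) for iv in g.exon_segments),
    )


# ---------------------------------------------------------------------------
# genetic map simulation
# ---------------------------------------------------------------------------

def simulate_map(
    scaffold_truth: Sequence[ScaffoldTruth],
    chrom_lengths: Mapping[str, int],
    markers_per_chrom: int,
    cM_per_Mb: float = 4.0,
    positional_noise_cM: float = 0.0,
    seed: int | None = None,
) -> list[GeneticMapLocus]:
    """Uniform marker positions per chromosome; cM = bp-proportional plus
    Gaussian noise; scaffold placements derived from the fragmentation truth."""
    if seed is None:
        raise ValueError("seed is mandatory")
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[ScaffoldTruth]] = {}
    for t in scaffold_truth:
        by_chrom.setdefault(t.chrom, []).append(t)
    loci: list[GeneticMapLocus] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        scafs = sorted(by_chrom.get(chrom, []), key=lambda t: t.start)
        positions = sorted(int(p) for p in rng.integers(1, length + 1, size=markers_per_chrom))
        for mi, bp in enumerate(positions, start=1):
            cm = bp * cM_per_Mb / 1e6
            if positional_noise_cM > 0:
                cm += float(rng.normal(0, positional_noise_cM))
            cm = max(cm, 0.0)
            scaffold_id = position = None
            for t in scafs:
                if t.start <= bp < t.start + t.length:
                    local = bp - t.start + 1
                    if t.orientation == "-":
                        local = t.length - local + 1
                    scaffold_id, position = t.scaffold_id, local
                    break
            loci.append(GeneticMapLocus(
                marker_id=f"m_{chrom}_{mi:04d}", linkage_group=chrom,
                cM=round(cm, 4), scaffold_id=scaffold_id, position_bp=position,
            ))
    return loci


# ---------------------------------------------------------------------------
# ortholog hit simulation
# ---------------------------------------------------------------------------

def simulate_hits(
    scaffold_genes: Sequence[GeneModel],
    ref_genes: Sequence[GeneModel],
    miss_rate: float = 0.0,
    spurious_rate: float = 0.0,
    seed: int | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[OrthologHit]:
    """Each scaffold gene hits its true ortholog (the identically named
    reference gene) with probability 1 - miss_rate at a strong E-value;
    spurious hits to random chromosome positions are added at
    ``spurious_rate`` with scores that occasionally beat a true hit, so a
    non-zero rate genuinely perturbs best-hit choices."""
    if seed is None:
        raise ValueError("seed is mandatory")
    if not 0 <= miss_rate <= 1 or not 0 <= spurious_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ref_by_id = {g.gene_id: g for g in ref_genes}
    chroms = sorted({g.seq_id for g in ref_genes})
    if chrom_lengths is None:
        chrom_lengths = {c: max(g.end for g in ref_genes if g.seq_id == c) for c in chroms}
    hits: list[OrthologHit] = []
    for g in scaffold_genes:
        ref = ref_by_id.get(g.gene_id)
        if ref is not None and rng.random() >= miss_rate:
            hits.append(OrthologHit(
                query_gene_id=g.gene_id, ref_gene_id=ref.gene_id, ref_chrom=ref.seq_id,
                ref_start_bp=ref.start, ref_end_bp=ref.end,
                evalue=float(10.0 ** -rng.uniform(45, 60)),
                bitscore=float(rng.uniform(300, 800)),
            ))
        if rng.random() < spurious_rate:
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(1, max(2, chrom_lengths[chrom] - 500)))
            hits.append(OrthologHit(
                query_gene_id=g.gene_id, ref_gene_id=f"spur_{g.gene_id}", ref_chrom=chrom,
                ref_start_bp=start, ref_end_bp=start + int(rng.integers(200, 500)),
                evalue=float(10.0 ** -rng.uniform(6, 55)),
                bitscore=float(rng.uniform(50, 300)),
            ))
    return hits


# ---------------------------------------------------------------------------
# variant simulation
# ---------------------------------------------------------------------------

@dataclass
class VariantTruth:
    chrom: str
    pos: int
    kind: str                   # 'snp' or 'indel'
    genotypes: list[tuple[int, int]]


def simulate_variants(
    genome: Sequence[SequenceRecord],
    gene_models: Sequence[GeneModel],
    snp_rate: float,
    indel_rate: float,
    ts_tv: float = 1.5,
    het_fraction: float = 0.3,
    n_samples: int = 2,
    seed: int | None = None,
    dp_mean: float = 30.0,
    gq_range: tuple[int, int] = (30, 99),
    qual_range: tuple[float, float] = (60.0, 500.0),
    max_indel_len: int = 15,
) -> tuple[list[str], list[VariantRecord], list[VariantTruth]]:
    """Draw SNPs (transition probability ts_tv/(1+ts_tv)) and 1-15 bp indels
    at the given per-bp rates, with per-sample genotypes heterozygous at
    ``het_fraction`` and DP/GQ/QUAL sampled so hard filters are exercisable.

    Returns (sample names, VCF-style records sorted by position, truth).
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    rng = np.random.default_rng(seed)
    samples = [f"line{i + 1}" for i in range(n_samples)]
    p_ts = ts_tv / (1.0 + ts_tv)
    variants: list[VariantRecord] = []
    truth: list[VariantTruth] = []
    for rec in genome:
        n = len(rec.seq)
        n_snp = rng.poisson(snp_rate * n)
        n_indel = rng.poisson(indel_rate * n)
        occupied: set[int] = set()
        events: list[tuple[int, str]] = []
        budget = (n_snp + n_indel) * 50 + 100
        want = [("snp", n_snp), ("indel", n_indel)]
        for kind, count in want:
            made = 0
            while made < count:
                budget -= 1
                if budget <= 0:
                    raise ValueError("could not place all variants without overlap")
                pos = int(rng.integers(2, n - max_indel_len - 1))
                span = range(pos - 1, pos + (max_indel_len + 1 if kind == "indel" else 1))
                if any(p in occupied for p in span):
                    continue
                occupied.update(span)
                events.append((pos, kind))
                made += 1
        for pos, kind in sorted(events):
            ref_base = rec.seq[pos - 1]
            if ref_base == "N":
                continue
            if kind == "snp":
                if rng.random() < p_ts:
                    alt = _TRANSITION[ref_base]
                else:
                    opts = _TRANSVERSIONS[ref_base]
                    alt = opts[int(rng.integers(2))]
                ref, alt_allele = ref_base, alt
            else:
                length = int(rng.integers(1, max_indel_len + 1))
                if rng.random() < 0.5:  # deletion
                    ref = rec.seq[pos - 1: pos + length]
                    alt_allele = ref_base
                    if "N" in ref:
                        continue
                else:  # insertion
                    ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
                    ref, alt_allele = ref_base, ref_base + ins
            genotypes: list[tuple[int, int]] = []
            for _ in range(n_samples):
                if rng.random() < het_fraction:
                    genotypes.append((0, 1))
                else:
                    genotypes.append((1, 1) if rng.random() < 0.5 else (0, 0))
            dp = [int(max(0, rng.poisson(dp_mean))) for _ in range(n_samples)]
            gq = [int(rng.integers(gq_range[0], gq_range[1] + 1)) for _ in range(n_samples)]
            qual = float(rng.uniform(*qual_range))
            variants.append(VariantRecord(
                chrom=rec.id, pos=pos, ref=ref, alts=(alt_allele,),
                qual=qual, genotypes=genotypes, dp=dp, gq=gq,
            ))
            truth.append(VariantTruth(rec.id, pos, kind, genotypes))
    return samples, variants, truth


def implant_effect_variants(
    genome: Sequence[SequenceRecord],
    gene_models: Sequence[GeneModel],
    n_variants: int,
    seed: int | None = None,
) -> tuple[list[VariantRecord], list[str]]:
    """Construct variants with a priori known effect classes by direct codon
    surgery: for each case a coding gene, a codon and a desired outcome are
    drawn, and an alt allele guaranteeing that outcome is built from the
    genetic code (independently of the effect classifier).

    Returns (variants, true SO terms, one per variant).
    """
    from Bio.Seq import Seq

    if seed is None:
        raise ValueError("seed is mandatory")
    rng = np.random.default_rng(seed)
    seq_by_id = {r.id: r.seq for r in genome}
    coding = [g for g in gene_models if g.is_coding and g.cds_length >= 30]
    if not coding:
        raise ValueError("no coding genes to implant into")
    single_exon = [g for g in coding if len(g.cds_segments) == 1]
    variants: list[VariantRecord] = []
    terms: list[str] = []
    kinds = ["synonymous_variant", "missense_variant", "stop_gained", "stop_lost",
             "start_lost", "frameshift_variant", "inframe_insertion", "inframe_deletion",
             "intron_variant", "intergenic_variant"]
    attempts = 0
    while len(variants) < n_variants and attempts < n_variants * 100:
        attempts += 1
        kind = kinds[int(rng.integers(len(kinds)))]
        if kind == "intergenic_variant":
            v = _implant_intergenic(rng, genome, gene_models)
        elif kind == "intron_variant":
            v = _implant_intron(rng, seq_by_id, coding)
        elif kind in ("frameshift_variant", "inframe_insertion", "inframe_deletion"):
            v = _implant_indel(rng, seq_by_id, single_exon, kind)
        else:
            v = _implant_coding_snp(rng, seq_by_id, coding, kind)
        if v is not None:
            variants.append(v)
            terms.append(kind)
    if len(variants) < n_variants:
        raise ValueError("could not implant the requested number of effect variants")
    return variants, terms


def _codon_positions(gene: GeneModel) -> list[int]:
    """Genomic positions of the spliced CDS in translation order."""
    positions: list[int] = []
    for s, e in gene.cds_segments:
        positions.extend(range(s, e + 1))
    if gene.strand == "-":
        positions.reverse()
    return positions


def _implant_coding_snp(rng, seq_by_id, coding, kind) -> VariantRecord | None:
    from Bio.Seq import Seq

    gene = coding[int(rng.integers(len(coding)))]
    seq = seq_by_id[gene.seq_id]
    positions = _codon_positions(gene)
    n_codons = len(positions) // 3
    if kind == "start_lost":
        codon_idx = 0
    elif kind == "stop_lost":
        codon_idx = n_codons - 1
    else:
        codon_idx = int(rng.integers(1, n_codons - 1))
    codon_pos = positions[codon_idx * 3: codon_idx * 3 + 3]
    codon = "".join(
        seq[p - 1] if gene.strand == "+" else reverse_complement(seq[p - 1])
        for p in codon_pos
    )
    aa = str(Seq(codon).translate())
    choices = []
    for within in range(3):
        for base in "ACGT":
            if base == codon[within]:
                continue
            alt_codon = codon[:within] + base + codon[within + 1:]
            alt_aa = str(Seq(alt_codon).translate())
            if kind == "synonymous_variant" and alt_aa == aa and aa != "*":
                choices.append((within, base))
            elif kind == "missense_variant" and alt_aa not in (aa, "*") and aa != "*" and codon_idx > 0:
                choices.append((within, base))
            elif kind == "stop_gained" and alt_aa == "*" and aa != "*":
                choices.append((within, base))
            elif kind == "stop_lost" and aa == "*" and alt_aa != "*":
                choices.append((within, base))
            elif kind == "start_lost" and codon_idx == 0 and alt_aa != aa:
                choices.append((within, base))
    if not choices:
        return None
    within, base = choices[int(rng.integers(len(choices)))]
    gpos = codon_pos[within]
    ref = seq[gpos - 1]
    alt = base if gene.strand == "+" else reverse_complement(base)
    if alt == ref:
        return None
    return VariantRecord(chrom=gene.seq_id, pos=gpos, ref=ref, alts=(alt,),
                         qual=100.0, genotypes=[(0, 1)], dp=[30], gq=[60])


def _implant_indel(rng, seq_by_id, single_exon, kind) -> VariantRecord | None:
    if not single_exon:
        return None
    gene = single_exon[int(rng.integers(len(single_exon)))]
    seq = seq_by_id[gene.seq_id]
    s, e = gene.cds_segments[0]
    pos = int(rng.integers(s + 3, e - 20))
    if kind == "frameshift_variant":
        length = int(rng.choice([1, 2, 4, 5]))
        insert = rng.random() < 0.5
    else:
        length = int(rng.choice([3, 6]))
        insert = kind == "inframe_insertion"
    anchor = seq[pos - 1]
    if insert:
        ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
        return VariantRecord(chrom=gene.seq_id, pos=pos, ref=anchor, alts=(anchor + ins,),
                             qual=100.0, genotypes=[(0, 1)], dp=[30], gq=[60])
    ref = seq[pos - 1: pos + length]
    if len(ref) != length + 1 or "N" in ref:
        return None
    if pos + length > e:  # deletion must stay inside the CDS
        return None
    return VariantRecord(chrom=gene.seq_id, pos=pos, ref=ref, alts=(anchor,),
                         qual=100.0, genotypes=[(0, 1)], dp=[30], gq=[60])


def _implant_intron(rng, seq_by_id, coding) -> VariantRecord | None:
    multi = [g for g in coding if len(g.cds_segments) >= 2]
    if not multi:
        return None
    gene = multi[int(rng.integers(len(multi)))]
    (s1, e1), (s2, _) = gene.cds_segments[0], gene.cds_segments[1]
    if s2 - e1 < 7:
        return None
    pos = int(rng.integers(e1 + 3, s2 - 2))
    ref = seq_by_id[gene.seq_id][pos - 1]
    if ref == "N":
        return None
    alt = _TRANSITION[ref]
    return VariantRecord(chrom=gene.seq_id, pos=pos, ref=ref, alts=(alt,),
                         qual=100.0, genotypes=[(0, 1)], dp=[30], gq=[60])


def _implant_intergenic(rng, genome, gene_models) -> VariantRecord | None:
    rec = genome[int(rng.integers(len(genome)))]
    spans = sorted((g.start, g.end) for g in gene_models if g.seq_id == rec.id)
    for _ in range(50):
        pos = int(rng.integers(2, len(rec.seq)))
        if any(s <= pos <= e for s, e in spans):
            continue
        ref = rec.seq[pos - 1]
        if ref == "N":
            continue
        return VariantRecord(chrom=rec.id, pos=pos, ref=ref, alts=(_TRANSITION[ref],),
                             qual=100.0, genotypes=[(0, 1)], dp=[30], gq=[60])
    return None


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    genome: Sequence[SequenceRecord],
    coverage: float,
    read_len: int = 93,
    error_rate: float = 0.0,
    seed: int | None = None,
) -> list[SequenceRecord]:
    """Uniform-start single-end reads from both strands with i.i.d. base errors."""
    if seed is None:
        raise ValueError("seed is mandatory")
    rng = np.random.default_rng(seed)
    total = sum(len(r.seq) for r in genome)
    if any(read_len > len(r.seq) for r in genome):
        raise ValueError("read_len exceeds a genome sequence length")
    n_reads = int(round(coverage * total / read_len))
    weights = np.array([len(r.seq) for r in genome], dtype=float)
    weights /= weights.sum()
    which = rng.choice(len(genome), size=n_reads, p=weights)
    reads: list[SequenceRecord] = []
    for i in range(n_reads):
        rec = genome[which[i]]
        start = int(rng.integers(0, len(rec.seq) - read_len + 1))
        seq = rec.seq[start:start + read_len]
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        if error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            hits = np.nonzero(rng.random(read_len) < error_rate)[0]
            for h in hits:
                base = chr(arr[h])
                options = [b for b in "ACGT" if b != base]
                arr[h] = ord(options[int(rng.integers(3))])
            seq = arr.tobytes().decode("ascii")
        reads.append(SequenceRecord(f"read{i + 1}", seq))
    return reads


def write_fastq(reads: Sequence[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")
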