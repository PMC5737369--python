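"""Scaffold-to-chromosome anchoring and pseudomolecule construction.

Two evidence routes assign scaffolds to chromosomes: genetic-map loci
(majority linkage group, orientation from the cM-vs-bp slope) and synteny
(runs of >= ``min_genes`` consecutive genes whose best ortholog hits are
collinear on one reference chromosome with R^2 above threshold).  Map
evidence outranks synteny on conflict.  Accepted scaffolds are ordered,
oriented and concatenated with fixed N spacers into pseudomolecules, with
AGP output and coordinate liftover for gene models and map loci.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_io import (
    AssemblySummary,
    GeneModel,
    GeneticMapLocus,
    OrthologHit,
    SequenceRecord,
    reverse_complement,
)

logger = logging.getLogger(__name__)


@dataclass
class AnchoringParams:
    min_genes: int = 5
    r2_threshold: float = 0.6
    spacer_len: int = 10_000
    min_markers_to_orient: int = 2

    def __post_init__(self) -> None:
        if self.min_genes < 2:
            raise ValueError("min_genes must be >= 2")
        if not 0 < self.r2_threshold < 1:
            raise ValueError("r2_threshold must be in (0, 1)")
        if self.spacer_len < 0:
            raise ValueError("spacer_len must be >= 0")


@dataclass
class ScaffoldAssignment:
    scaffold_id: str
    chromosome: str
    orientation: str  # '+', '-' or '?' (unknown)
    evidence: str  # 'map' or 'synteny'
    n_support: int
    order_key_bp: float | None = None   # projected reference bp
    order_key_cm: float | None = None   # median cM of supporting loci
    r2: float | None = None
    conflict: bool = False

    def __post_init__(self) -> None:
        if self.orientation not in "+-?":
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.evidence not in ("map", "synteny"):
            raise ValueError(f"bad evidence {self.evidence!r}")


@dataclass
class CollinearRun:
    """A maximal block of consecutive hit-bearing genes sharing one ref chromosome."""

    scaffold_id: str
    ref_chrom: str
    gene_ids: list[str]
    scaffold_mids: list[float]
    ref_mids: list[float]

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class PseudomoleculeLayout:
    chromosomes: dict[str, list[tuple[str, str]]]  # chrom -> [(scaffold_id, orientation)]
    spacer_len: int
    unplaced: list[str] = field(default_factory=list)
    orientation_uncertain: set[str] = field(default_factory=set)

    def placed_scaffolds(self) -> list[str]:
        return [sid for members in self.chromosomes.values() for sid, _ in members]


# ---------------------------------------------------------------------------
# map-based assignment
# ---------------------------------------------------------------------------

def map_assign(
    map_loci: Sequence[GeneticMapLocus],
    params: AnchoringParams | None = None,
    lg_to_chrom: Mapping[str, str] | None = None,
) -> list[ScaffoldAssignment]:
    """Assign scaffolds to the linkage group holding a strict majority of their loci.

    Orientation is the sign of the least-squares slope of cM on scaffold bp
    when the scaffold carries >= ``min_markers_to_orient`` loci at distinct
    cM and distinct bp; otherwise unknown.  The order key is the median cM.
    """
    params = params or AnchoringParams()
    by_scaffold: dict[str, list[GeneticMapLocus]] = {}
    for locus in map_loci:
        if locus.placed:
            by_scaffold.setdefault(locus.scaffold_id, []).append(locus)
    out: list[ScaffoldAssignment] = []
    for sid in sorted(by_scaffold):
        loci = by_scaffold[sid]
        lg_counts: dict[str, int] = {}
        for l in loci:
            lg_counts[l.linkage_group] = lg_counts.get(l.linkage_group, 0) + 1
        best_lg, best_n = max(lg_counts.items(), key=lambda kv: (kv[1], kv[0]))
        if 2 * best_n <= len(loci):
            logger.warning("scaffold %s: no strict-majority linkage group %s; unassigned",
                           sid, dict(lg_counts))
            continue
        chrom = lg_to_chrom[best_lg] if lg_to_chrom else best_lg
        support = sorted((l for l in loci if l.linkage_group == best_lg),
                         key=lambda l: l.position_bp)
        orientation = "?"
        cms = [l.cM for l in support]
        bps = [float(l.position_bp) for l in support]
        if (len(support) >= params.min_markers_to_orient
                and len(set(cms)) >= 2 and len(set(bps)) >= 2):
            bp_arr, cm_arr = np.asarray(bps), np.asarray(cms)
            slope = float(np.sum((bp_arr - bp_arr.mean()) * (cm_arr - cm_arr.mean())))
            if slope > 0:
                orientation = "+"
            elif slope < 0:
                orientation = "-"
        out.append(ScaffoldAssignment(
            scaffold_id=sid, chromosome=chrom, orientation=orientation,
            evidence="map", n_support=len(support),
            order_key_cm=float(statistics.median(cms)),
        ))
    return out


# ---------------------------------------------------------------------------
# synteny-based assignment
# ---------------------------------------------------------------------------

def best_hits(hits: Iterable[OrthologHit]) -> dict[str, OrthologHit]:
    """Best hit per query gene: lowest E-value, then highest bitscore, then
    smallest ref_start, then lexicographic ref_gene_id."""
    best: dict[str, OrthologHit] = {}
    for h in hits:
        cur = best.get(h.query_gene_id)
        if cur is None:
            best[h.query_gene_id] = h
            continue
        key = (h.evalue, -h.bitscore, h.ref_start_bp, h.ref_gene_id)
        cur_key = (cur.evalue, -cur.bitscore, cur.ref_start_bp, cur.ref_gene_id)
        if key < cur_key:
            best[h.query_gene_id] = h
    return best


def collinear_runs(
    genes_by_scaffold: Mapping[str, Sequence[GeneModel]],
    best: Mapping[str, OrthologHit],
    params: AnchoringParams | None = None,
) -> list[CollinearRun]:
    """Segment each scaffold's ordered genes into same-chromosome hit runs.

    Genes without a best hit are transparent (skipped without breaking a
    run); a best hit on a different chromosome terminates the run.  Runs
    shorter than ``min_genes`` are discarded.
    """
    params = params or AnchoringParams()
    runs: list[CollinearRun] = []
    for sid in sorted(genes_by_scaffold):
        genes = sorted(genes_by_scaffold[sid], key=lambda g: (g.start, g.gene_id))
        current: CollinearRun | None = None
        for gene in genes:
            hit = best.get(gene.gene_id)
            if hit is None:
                continue
            mid = (gene.start + gene.end) / 2.0
            if current is not None and hit.ref_chrom == current.ref_chrom:
                current.gene_ids.append(gene.gene_id)
                current.scaffold_mids.append(mid)
                current.ref_mids.append(hit.ref_mid)
            else:
                if current is not None and len(current) >= params.min_genes:
                    runs.append(current)
                current = CollinearRun(sid, hit.ref_chrom, [gene.gene_id], [mid], [hit.ref_mid])
        if current is not None and len(current) >= params.min_genes:
            runs.append(current)
    return runs


def synteny_assign(run: CollinearRun, params: AnchoringParams | None = None) -> ScaffoldAssignment | None:
    """Regress reference midpoints on scaffold midpoints; accept iff R^2 > threshold.

    Returns None (logged, with the R^2) on rejection.
    """
    params = params or AnchoringParams()
    if len(run) < params.min_genes:
        raise ValueError(f"run of {len(run)} genes is below min_genes={params.min_genes}")
    x = np.asarray(run.scaffold_mids, dtype=float)
    y = np.asarray(run.ref_mids, dtype=float)
    if np.ptp(x) == 0:
        logger.warning("scaffold %s: zero variance in gene positions; run rejected", run.scaffold_id)
        return None
    sxx = float(np.sum((x - x.mean()) ** 2))
    syy = float(np.sum((y - y.mean()) ** 2))
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    if syy == 0:
        logger.warning("scaffold %s: zero variance in reference positions; run rejected",
                       run.scaffold_id)
        return None
    r2 = sxy * sxy / (sxx * syy)
    if not r2 > params.r2_threshold:
        logger.info("scaffold %s: run on %s rejected (R^2=%.3f <= %.2f)",
                    run.scaffold_id, run.ref_chrom, r2, params.r2_threshold)
        return None
    orientation = "+" if sxy > 0 else "-"
    return ScaffoldAssignment(
        scaffold_id=run.scaffold_id, chromosome=run.ref_chrom,
        orientation=orientation, evidence="synteny", n_support=len(run),
        order_key_bp=float(statistics.median(run.ref_mids)), r2=r2,
    )


def synteny_assign_all(
    runs: Sequence[CollinearRun], params: AnchoringParams | None = None
) -> list[ScaffoldAssignment]:
    """Assign each scaffold from its accepted runs.

    When a scaffold has several accepted runs the one with most genes (then
    highest R^2, then chromosome name) wins; disagreement on chromosome sets
    the conflict flag.
    """
    params = params or AnchoringParams()
    accepted: dict[str, list[ScaffoldAssignment]] = {}
    for run in runs:
        a = synteny_assign(run, params)
        if a is not None:
            accepted.setdefault(a.scaffold_id, []).append(a)
    out = []
    for sid in sorted(accepted):
        cands = sorted(accepted[sid], key=lambda a: (-a.n_support, -(a.r2 or 0), a.chromosome))
        winner = cands[0]
        if len({a.chromosome for a in cands}) > 1:
            winner.conflict = True
            logger.warning("scaffold %s: accepted synteny runs on multiple chromosomes; "
                           "keeping %s", sid, winner.chromosome)
        out.append(winner)
    return out


# ---------------------------------------------------------------------------
# merging and layout
# ---------------------------------------------------------------------------

def merge_assignments(
    map_assigns: Sequence[ScaffoldAssignment],
    synteny_assigns: Sequence[ScaffoldAssignment],
) -> list[ScaffoldAssignment]:
    """Merge the two evidence routes; map evidence takes precedence.

    Same chromosome from both: keep the map chromosome/orientation (filling
    an unknown map orientation from synteny) and inherit the synteny
    reference-bp order key.  Different chromosomes: map wins, conflict
    flagged.  Single-evidence scaffolds pass through.
    """
    by_scaffold: dict[str, ScaffoldAssignment] = {a.scaffold_id: a for a in map_assigns}
    out: dict[str, ScaffoldAssignment] = dict(by_scaffold)
    for syn in synteny_assigns:
        m = by_scaffold.get(syn.scaffold_id)
        if m is None:
            out[syn.scaffold_id] = syn
        elif m.chromosome == syn.chromosome:
            orientation = m.orientation if m.orientation != "?" else syn.orientation
            out[syn.scaffold_id] = ScaffoldAssignment(
                scaffold_id=m.scaffold_id, chromosome=m.chromosome,
                orientation=orientation, evidence="map", n_support=m.n_support,
                order_key_bp=syn.order_key_bp, order_key_cm=m.order_key_cm,
                r2=syn.r2,
            )
        else:
            logger.warning("scaffold %s: map says %s, synteny says %s; map wins",
                           syn.scaffold_id, m.chromosome, syn.chromosome)
            m.conflict = True
    return sorted(out.values(), key=lambda a: a.scaffold_id)


def refine_order_keys(
    assignments: Sequence[ScaffoldAssignment],
    genes_by_scaffold: Mapping[str, Sequence[GeneModel]],
    best: Mapping[str, OrthologHit],
) -> list[ScaffoldAssignment]:
    """Give bp-less assignments an ordering key from their genes' best hits.

    A map-assigned scaffold with fewer hit-bearing genes than a collinear
    run requires has no synteny order key, yet any best hits it does carry
    on its assigned chromosome pin its reference position far better than
    cM interpolation; the median reference midpoint of those hits is used.
    Chromosome, orientation and evidence are left untouched.
    """
    out = []
    for a in assignments:
        if a.order_key_bp is None:
            mids = [best[g.gene_id].ref_mid
                    for g in genes_by_scaffold.get(a.scaffold_id, ())
                    if g.gene_id in best and best[g.gene_id].ref_chrom == a.chromosome]
            if mids:
                a = ScaffoldAssignment(
                    scaffold_id=a.scaffold_id, chromosome=a.chromosome,
                    orientation=a.orientation, evidence=a.evidence,
                    n_support=a.n_support, order_key_bp=float(statistics.median(mids)),
                    order_key_cm=a.order_key_cm, r2=a.r2, conflict=a.conflict,
                )
        out.append(a)
    return out


def _cm_to_bp_projector(
    anchors: Sequence[tuple[float, float]],  # (cM, bp)
    ref_len: int,
):
    """Least-squares linear map cM -> bp over all anchors, clamped to
    [0, ref_len].  A global fit is used rather than bracketing interpolation:
    anchor bp keys are gene-midpoint medians, so per-anchor scatter is of the
    order of half a scaffold and local extrapolation amplifies it."""
    if len(anchors) < 2:
        raise ValueError("need >= 2 anchors to project")
    cms = np.array([a[0] for a in anchors], dtype=float)
    bps = np.array([a[1] for a in anchors], dtype=float)
    var = float(np.sum((cms - cms.mean()) ** 2))
    if var == 0:
        mean_bp = float(bps.mean())
        return lambda cm: mean_bp
    slope = float(np.sum((cms - cms.mean()) * (bps - bps.mean()))) / var
    intercept = float(bps.mean() - slope * cms.mean())
    return lambda cm: min(max(slope * cm + intercept, 0.0), float(ref_len))


def build_layout(
    assignments: Sequence[ScaffoldAssignment],
    ref_chrom_lengths: Mapping[str, int],
    scaffold_lengths: Mapping[str, int] | None = None,
    spacer_len: int = 10_000,
    map_loci: Sequence[GeneticMapLocus] = (),
) -> PseudomoleculeLayout:
    """Order scaffolds within each chromosome by projected reference bp.

    Scaffolds carrying only a cM key are projected onto bp through a per-
    chromosome linear cM->bp fit anchored on scaffolds that carry both keys
    (and, when ``map_loci`` is given, on every locus landing on a bp-keyed
    scaffold); with fewer than two anchors the cM axis is scaled linearly
    onto [0, ref_len].  Ties break by descending scaffold length then id.
    Unknown orientations are emitted as '+' and flagged.
    """
    scaffold_lengths = scaffold_lengths or {}
    by_chrom: dict[str, list[ScaffoldAssignment]] = {}
    for a in assignments:
        if a.chromosome not in ref_chrom_lengths:
            raise ValueError(f"chromosome {a.chromosome!r} missing from reference lengths")
        by_chrom.setdefault(a.chromosome, []).append(a)
    bp_key_by_scaffold = {a.scaffold_id: (a.chromosome, a.order_key_bp)
                         for a in assignments if a.order_key_bp is not None}
    layout = PseudomoleculeLayout(chromosomes={}, spacer_len=spacer_len)
    for chrom in sorted(by_chrom):
        members = by_chrom[chrom]
        ref_len = ref_chrom_lengths[chrom]
        anchors = sorted(
            (a.order_key_cm, a.order_key_bp)
            for a in members
            if a.order_key_cm is not None and a.order_key_bp is not None
        )
        for locus in map_loci:
            if locus.placed and locus.scaffold_id in bp_key_by_scaffold:
                l_chrom, l_bp = bp_key_by_scaffold[locus.scaffold_id]
                if l_chrom == chrom:
                    anchors.append((locus.cM, l_bp))
        anchors.sort()
        max_cm = max((a.order_key_cm for a in members if a.order_key_cm is not None),
                     default=0.0)
        project = _cm_to_bp_projector(anchors, ref_len) if len(anchors) >= 2 else None
        keyed: list[tuple[float, ScaffoldAssignment]] = []
        for a in members:
            if a.order_key_bp is not None:
                key = a.order_key_bp
            elif project is not None:
                key = project(a.order_key_cm)
            elif max_cm > 0:
                key = a.order_key_cm * ref_len / max_cm
            else:
                key = 0.0
            keyed.append((key, a))
        keyed.sort(key=lambda ka: (ka[0], -scaffold_lengths.get(ka[1].scaffold_id, 0),
                                   ka[1].scaffold_id))
        placed = []
        for _, a in keyed:
            orientation = a.orientation
            if orientation == "?":
                orientation = "+"
                layout.orientation_uncertain.add(a.scaffold_id)
            placed.append((a.scaffold_id, orientation))
        layout.chromosomes[chrom] = placed
    return layout


# ---------------------------------------------------------------------------
# pseudomolecule emission, AGP and liftover
# ---------------------------------------------------------------------------

AGP_HEADER = "##agp-version\t2.1\n"


@dataclass
class EmitResult:
    pseudomolecules: list[SequenceRecord]
    agp_rows: list[tuple]
    lifted_genes: list[GeneModel]
    lifted_loci: list[GeneticMapLocus]
    unplaced: list[SequenceRecord]


def _lift_interval(start: int, end: int, scaf_len: int, offset: int, orientation: str) -> tuple[int, int]:
    """Lift a 1-based inclusive scaffold interval onto the pseudomolecule."""
    if orientation == "+":
        return offset + start, offset + end
    return offset + (scaf_len - end + 1), offset + (scaf_len - start + 1)


def emit_pseudomolecules(
    layout: PseudomoleculeLayout,
    scaffolds: Sequence[SequenceRecord],
    gene_models: Sequence[GeneModel] = (),
    map_loci: Sequence[GeneticMapLocus] = (),
) -> EmitResult:
    """Concatenate oriented scaffolds with N spacers; emit AGP rows and lift
    gene-model and map coordinates onto the pseudomolecules."""
    seq_by_id = {r.id: r for r in scaffolds}
    placed_ids = set(layout.placed_scaffolds())
    for sid in placed_ids:
        if sid not in seq_by_id:
            raise ValueError(f"scaffold {sid!r} in layout but missing from sequence set")
    offsets: dict[str, tuple[str, int, str]] = {}  # scaffold -> (chrom, 0-based offset, orient)
    pseudo: list[SequenceRecord] = []
    agp_rows: list[tuple] = []
    spacer = "N" * layout.spacer_len
    for chrom, members in layout.chromosomes.items():
        if not members:
            logger.warning("chromosome %s has no assigned scaffolds; skipped", chrom)
            continue
        parts: list[str] = []
        pos = 0  # length emitted so far
        part_number = 0
        for i, (sid, orientation) in enumerate(members):
            if i > 0 and layout.spacer_len:
                part_number += 1
                agp_rows.append((chrom, pos + 1, pos + layout.spacer_len, part_number,
                                 "U", layout.spacer_len, "contig", "no", "na"))
                parts.append(spacer)
                pos += layout.spacer_len
            seq = seq_by_id[sid].seq
            if orientation == "-":
                seq = reverse_complement(seq)
            part_number += 1
            agp_rows.append((chrom, pos + 1, pos + len(seq), part_number,
                             "W", sid, 1, len(seq), orientation))
            offsets[sid] = (chrom, pos, orientation)
            parts.append(seq)
            pos += len(seq)
        pseudo.append(SequenceRecord(chrom, "".join(parts)))
    lifted_genes: list[GeneModel] = []
    for gene in gene_models:
        placement = offsets.get(gene.seq_id)
        if placement is None:
            continue
        chrom, offset, orientation = placement
        scaf_len = len(seq_by_id[gene.seq_id])
        start, end = _lift_interval(gene.start, gene.end, scaf_len, offset, orientation)
        strand = gene.strand
        if orientation == "-":
            strand = "+" if strand == "-" else "-"
        lifted_genes.append(GeneModel(
            gene_id=gene.gene_id, seq_id=chrom, start=start, end=end, strand=strand,
            cds_segments=sorted(_lift_interval(s, e, scaf_len, offset, orientation)
                                for s, e in gene.cds_segments),
            exon_segments=sorted(_lift_interval(s, e, scaf_len, offset, orientation)
                                 for s, e in gene.exon_segments),
        ))
    lifted_loci: list[GeneticMapLocus] = []
    for locus in map_loci:
        placement = offsets.get(locus.scaffold_id) if locus.placed else None
        if placement is None:
            continue
        chrom, offset, orientation = placement
        scaf_len = len(seq_by_id[locus.scaffold_id])
        pos, _ = _lift_interval(locus.position_bp, locus.position_bp, scaf_len, offset, orientation)
        lifted_loci.append(GeneticMapLocus(locus.marker_id, locus.linkage_group,
                                           locus.cM, chrom, pos))
    unplaced = [r for r in scaffolds if r.id not in placed_ids]
    return EmitResult(pseudo, agp_rows, lifted_genes, lifted_loci, unplaced)


def write_agp(agp_rows: Iterable[tuple], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(AGP_HEADER)
        for row in agp_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_agp(path: str | Path) -> list[tuple]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[4] == "W":
                rows.append((f[0], int(f[1]), int(f[2]), int(f[3]), "W",
                             f[5], int(f[6]), int(f[7]), f[8]))
            else:
                rows.append((f[0], int(f[1]), int(f[2]), int(f[3]), f[4],
                             int(f[5]), f[6], f[7], f[8]))
    return rows


def rebuild_from_agp(agp_rows: Sequence[tuple], scaffolds: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Reconstruct pseudomolecule sequences from AGP rows plus components."""
    seq_by_id = {r.id: r.seq for r in scaffolds}
    objects: dict[str, list[str]] = {}
    order: list[str] = []
    for row in agp_rows:
        obj = row[0]
        if obj not in objects:
            objects[obj] = []
            order.append(obj)
        if row[4] == "W":
            _, _, _, _, _, cid, cbeg, cend, orientation = row
            seq = seq_by_id[cid][cbeg - 1:cend]
            if orientation == "-":
                seq = reverse_complement(seq)
            objects[obj].append(seq)
        else:
            objects[obj].append("N" * int(row[5]))
    return [SequenceRecord(obj, "".join(objects[obj])) for obj in order]


# ---------------------------------------------------------------------------
# per-chromosome report
# ---------------------------------------------------------------------------

def table2_report(
    layout: PseudomoleculeLayout,
    scaffolds: Sequence[SequenceRecord],
    gene_models: Sequence[GeneModel],
    summary: AssemblySummary,
    total_gene_count: int | None = None,
):
    """Per-chromosome assigned scaffold/bp/gene counts with percentages of the
    whole assembly, plus a Total row.  Percentages are to one decimal."""
    import pandas as pd

    lengths = {r.id: len(r) for r in scaffolds}
    genes_per_scaffold: dict[str, int] = {}
    for g in gene_models:
        genes_per_scaffold[g.seq_id] = genes_per_scaffold.get(g.seq_id, 0) + 1
    if total_gene_count is None:
        total_gene_count = len(gene_models)
    rows = []
    tot_sc = tot_bp = tot_genes = 0
    for chrom in sorted(layout.chromosomes):
        members = layout.chromosomes[chrom]
        n_sc = len(members)
        bp = sum(lengths[sid] for sid, _ in members)
        n_genes = sum(genes_per_scaffold.get(sid, 0) for sid, _ in members)
        tot_sc += n_sc
        tot_bp += bp
        tot_genes += n_genes
        rows.append((chrom, n_sc, bp, n_genes))
    rows.append(("Total", tot_sc, tot_bp, tot_genes))
    df = pd.DataFrame(rows, columns=["chromosome", "n_scaffolds", "assigned_bp", "n_genes"])
    df["pct_scaffolds"] = (100.0 * df["n_scaffolds"] / summary.n_seqs).round(1)
    df["pct_bp"] = (100.0 * df["assigned_bp"] / summary.total_len).round(1)
    df["pct_genes"] = (
        (100.0 * df["n_genes"] / total_gene_count).round(1) if total_gene_count else 0.0
    )
    return df[["chromosome", "n_scaffolds", "pct_scaffolds",
               "assigned_bp", "pct_bp", "n_genes", "pct_genes"]]
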