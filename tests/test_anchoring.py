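import numpy as np
import pytest

from conftest import run_anchoring
from oracles import ols_r2_slope

from scafpipe.anchoring import (
    AnchoringParams,
    CollinearRun,
    ScaffoldAssignment,
    best_hits,
    build_layout,
    collinear_runs,
    emit_pseudomolecules,
    map_assign,
    merge_assignments,
    read_agp,
    rebuild_from_agp,
    synteny_assign,
    synteny_assign_all,
    table2_report,
    write_agp,
)
from scafpipe.genome_io import (
    GeneModel,
    GeneticMapLocus,
    OrthologHit,
    SequenceRecord,
    assembly_summary,
    reverse_complement,
)


def locus(marker, lg, cm, sc, bp):
    return GeneticMapLocus(marker, lg, cm, sc, bp)


def hit(q, chrom, start, end=None, evalue=1e-50, bitscore=500, ref_gene=None):
    return OrthologHit(q, ref_gene or f"ref_{q}", chrom, start, end or start + 100,
                       evalue, bitscore)


class TestMapAssign:
    def test_three_loci_positive_slope(self):
        loci = [locus("m1", "LG2", 5, "sc1", 1000),
                locus("m2", "LG2", 7, "sc1", 5000),
                locus("m3", "LG2", 9, "sc1", 9000)]
        (a,) = map_assign(loci)
        assert a.chromosome == "LG2"
        assert a.orientation == "+"
        assert a.order_key_cm == 7
        assert a.n_support == 3

    def test_two_loci_negative_slope(self):
        loci = [locus("m1", "LG1", 9, "sc1", 1000), locus("m2", "LG1", 5, "sc1", 8000)]
        (a,) = map_assign(loci)
        assert a.orientation == "-"

    def test_tied_linkage_groups_unassigned(self, caplog):
        loci = [locus("m1", "LG1", 1, "sc1", 100), locus("m2", "LG3", 2, "sc1", 200)]
        with caplog.at_level("WARNING"):
            assert map_assign(loci) == []
        assert "sc1" in caplog.text

    def test_single_locus_orientation_unknown(self):
        (a,) = map_assign([locus("m1", "LG1", 3, "sc1", 50)])
        assert a.orientation == "?"
        assert a.n_support == 1

    def test_min_markers_to_orient_configurable(self):
        loci = [locus("m1", "LG1", 1, "sc1", 100), locus("m2", "LG1", 2, "sc1", 900)]
        (a,) = map_assign(loci, AnchoringParams(min_markers_to_orient=3))
        assert a.orientation == "?"


class TestBestHits:
    def test_lowest_evalue_wins(self):
        h = best_hits([hit("q", "c1", 10, evalue=1e-20), hit("q", "c1", 900, evalue=1e-8)])
        assert h["q"].ref_start_bp == 10

    def test_bitscore_breaks_evalue_tie(self):
        h = best_hits([hit("q", "c1", 10, evalue=1e-9, bitscore=200),
                       hit("q", "c1", 900, evalue=1e-9, bitscore=150)])
        assert h["q"].bitscore == 200

    def test_fully_tied_smaller_ref_start(self):
        h = best_hits([hit("q", "c1", 500, ref_gene="r1"), hit("q", "c1", 100, ref_gene="r1")])
        assert h["q"].ref_start_bp == 100


def _gene(gid, sc, start):
    return GeneModel(gid, sc, start, start + 50, "+")


class TestCollinearRuns:
    def make(self, chrom_per_gene, min_genes=5):
        genes = [_gene(f"g{i}", "sc1", 100 * (i + 1)) for i in range(len(chrom_per_gene))]
        bh = {}
        for g, c in zip(genes, chrom_per_gene):
            if c is not None:
                bh[g.gene_id] = hit(g.gene_id, c, 1000)
        return collinear_runs({"sc1": genes}, bh, AnchoringParams(min_genes=min_genes))

    def test_six_genes_one_run(self):
        runs = self.make(["chr3"] * 6)
        assert len(runs) == 1 and len(runs[0]) == 6

    def test_interrupting_chromosome_splits(self):
        # chr3,chr3,chr1,chr3,chr3,chr3,chr3 -> runs of 2 and 4, both below 5
        assert self.make(["chr3", "chr3", "chr1", "chr3", "chr3", "chr3", "chr3"]) == []

    def test_hitless_gene_transparent(self):
        runs = self.make(["chr3", None, "chr3", "chr3", "chr3", "chr3"])
        assert len(runs) == 1 and len(runs[0]) == 5

    def test_min_genes_monotonicity(self):
        pattern = ["chr1"] * 6 + ["chr2"] + ["chr1"] * 8
        counts = [len(self.make(pattern, min_genes=m)) for m in (5, 6, 7, 9)]
        assert counts == sorted(counts, reverse=True)


class TestSyntenyAssign:
    def run_of(self, scaffold_mids, ref_mids):
        return CollinearRun("sc1", "chr2", [f"g{i}" for i in range(len(ref_mids))],
                            list(scaffold_mids), list(ref_mids))

    def test_perfect_collinearity_positive(self):
        a = synteny_assign(self.run_of([1000, 2000, 3000, 4000, 5000],
                                       [10_000, 20_000, 30_000, 40_000, 50_000]))
        assert a is not None
        assert a.orientation == "+"
        assert a.r2 == pytest.approx(1.0)
        assert a.order_key_bp == 30_000

    def test_descending_reference_negative(self):
        a = synteny_assign(self.run_of([1000, 2000, 3000, 4000, 5000],
                                       [50_000, 40_000, 30_000, 20_000, 10_000]))
        assert a.orientation == "-"

    def test_permuted_reference_rejected_and_matches_oracle(self):
        rng = np.random.default_rng(5)
        x = [1000.0, 2000.0, 3000.0, 4000.0, 5000.0]
        y = list(rng.permutation([10_000.0, 50_000.0, 20_000.0, 40_000.0, 30_000.0]))
        r2, _ = ols_r2_slope(x, y)
        assert r2 <= 0.6  # the seeded permutation is genuinely non-collinear
        assert synteny_assign(self.run_of(x, y)) is None

    def test_r2_matches_independent_ols(self):
        rng = np.random.default_rng(9)
        x = list(rng.uniform(0, 10_000, size=8))
        y = [3 * xi + rng.normal(0, 2000) for xi in x]
        a = synteny_assign(self.run_of(x, y), AnchoringParams(r2_threshold=0.01))
        r2, slope = ols_r2_slope(x, y)
        assert a.r2 == pytest.approx(r2)
        assert a.orientation == ("+" if slope > 0 else "-")

    def test_zero_variance_rejected(self, caplog):
        with caplog.at_level("WARNING"):
            assert synteny_assign(self.run_of([5.0] * 5, [1, 2, 3, 4, 5])) is None

    def test_strict_inequality_at_threshold(self):
        # construct a run whose R^2 is exactly the threshold: must be rejected
        run = self.run_of([1000, 2000, 3000, 4000, 5000],
                          [10_000, 20_000, 30_000, 40_000, 50_000])
        r2, _ = ols_r2_slope(run.scaffold_mids, run.ref_mids)
        assert synteny_assign(run, AnchoringParams(r2_threshold=r2 - 1e-12)) is not None
        # r2 == 1.0 here; a threshold of exactly 1.0 is invalid, so emulate by
        # requiring strictness on a sub-threshold run
        noisy = self.run_of([1, 2, 3, 4, 5], [1, 2, 3, 5, 4])
        r2n, _ = ols_r2_slope(noisy.scaffold_mids, noisy.ref_mids)
        assert synteny_assign(noisy, AnchoringParams(r2_threshold=r2n)) is None


class TestMergeAssignments:
    def m(self, chrom, orientation="+", cm=5.0):
        return ScaffoldAssignment("sc1", chrom, orientation, "map", 3, order_key_cm=cm)

    def s(self, chrom, bp=2.3e6, orientation="-"):
        return ScaffoldAssignment("sc1", chrom, orientation, "synteny", 6,
                                  order_key_bp=bp, r2=0.95)

    def test_same_chromosome_inherits_synteny_key(self):
        (a,) = merge_assignments([self.m("chr1")], [self.s("chr1")])
        assert a.chromosome == "chr1"
        assert a.orientation == "+"  # map orientation kept
        assert a.order_key_bp == 2.3e6

    def test_conflict_map_wins(self):
        merged = merge_assignments([self.m("chr1")], [self.s("chr2")])
        (a,) = merged
        assert a.chromosome == "chr1"
        assert a.conflict

    def test_synteny_only_passes_through(self):
        (a,) = merge_assignments([], [self.s("chr2")])
        assert a.evidence == "synteny"
        assert a.chromosome == "chr2"

    def test_unknown_map_orientation_filled_from_synteny(self):
        (a,) = merge_assignments([self.m("chr1", orientation="?")], [self.s("chr1")])
        assert a.orientation == "-"


class TestBuildLayout:
    def test_sort_by_bp_key(self):
        assigns = [
            ScaffoldAssignment(f"s{i}", "chr1", "+", "synteny", 5, order_key_bp=bp, r2=0.9)
            for i, bp in enumerate([5e6, 1e6, 3e6])
        ]
        layout = build_layout(assigns, {"chr1": 10_000_000})
        assert [sid for sid, _ in layout.chromosomes["chr1"]] == ["s1", "s2", "s0"]

    def test_tie_broken_by_descending_length(self):
        assigns = [
            ScaffoldAssignment("a", "chr1", "+", "synteny", 5, order_key_bp=100.0, r2=0.9),
            ScaffoldAssignment("b", "chr1", "+", "synteny", 5, order_key_bp=100.0, r2=0.9),
        ]
        layout = build_layout(assigns, {"chr1": 1000}, scaffold_lengths={"a": 8000, "b": 10_000})
        assert [sid for sid, _ in layout.chromosomes["chr1"]] == ["b", "a"]

    def test_unknown_chromosome_error(self):
        assigns = [ScaffoldAssignment("a", "chrX", "+", "map", 2, order_key_cm=1.0)]
        with pytest.raises(ValueError, match="chrX"):
            build_layout(assigns, {"chr1": 1000})

    def test_unknown_orientation_flagged_plus(self):
        assigns = [ScaffoldAssignment("a", "chr1", "?", "map", 1, order_key_cm=1.0)]
        layout = build_layout(assigns, {"chr1": 1000})
        assert layout.chromosomes["chr1"] == [("a", "+")]
        assert "a" in layout.orientation_uncertain


class TestEmitPseudomolecules:
    def two_scaffold_layout(self, spacer=10_000):
        from scafpipe.anchoring import PseudomoleculeLayout
        return PseudomoleculeLayout(
            chromosomes={"chr1": [("s1", "+"), ("s2", "+")]}, spacer_len=spacer)

    def test_spacer_arithmetic(self):
        scaffolds = [SequenceRecord("s1", "A" * 100), SequenceRecord("s2", "G" * 100)]
        emit = emit_pseudomolecules(self.two_scaffold_layout(), scaffolds)
        (p,) = emit.pseudomolecules
        assert len(p.seq) == 10_200
        assert emit.agp_rows[0][:5] == ("chr1", 1, 100, 1, "W")
        assert emit.agp_rows[1][:7] == ("chr1", 101, 10_100, 2, "U", 10_000, "contig")
        assert emit.agp_rows[2][:5] == ("chr1", 10_101, 10_200, 3, "W")

    def test_minus_orientation_liftover(self):
        from scafpipe.anchoring import PseudomoleculeLayout
        rng = np.random.default_rng(3)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=60))
        scaffold = SequenceRecord("s1", seq)
        gene = GeneModel("g1", "s1", 10, 20, "+", [(10, 20)], [(10, 20)])
        layout = PseudomoleculeLayout(chromosomes={"chr1": [("s1", "-")]}, spacer_len=10_000)
        emit = emit_pseudomolecules(layout, [scaffold], [gene])
        (p,) = emit.pseudomolecules
        assert p.seq == reverse_complement(seq)
        (lifted,) = emit.lifted_genes
        L = len(seq)
        assert (lifted.start, lifted.end, lifted.strand) == (L - 19, L - 9, "-")
        # liftover round trip: the lifted interval spells the reverse
        # complement of the original gene sequence
        original = seq[9:20]
        lifted_seq = p.seq[lifted.start - 1:lifted.end]
        assert lifted_seq == reverse_complement(original)

    def test_missing_scaffold_error(self):
        with pytest.raises(ValueError, match="s2"):
            emit_pseudomolecules(self.two_scaffold_layout(), [SequenceRecord("s1", "A" * 10)])

    def test_empty_chromosome_warning(self, caplog):
        from scafpipe.anchoring import PseudomoleculeLayout
        layout = PseudomoleculeLayout(chromosomes={"chr9": []}, spacer_len=10)
        with caplog.at_level("WARNING"):
            emit = emit_pseudomolecules(layout, [SequenceRecord("s1", "ACGT")])
        assert emit.pseudomolecules == []
        assert [r.id for r in emit.unplaced] == ["s1"]


class TestEndToEnd:
    def test_length_conservation(self, small_scene, genes_by_scaffold):
        merged, layout = run_anchoring(small_scene, genes_by_scaffold)
        emit = emit_pseudomolecules(layout, small_scene["scaffolds"])
        lengths = {s.id: len(s.seq) for s in small_scene["scaffolds"]}
        for p in emit.pseudomolecules:
            members = layout.chromosomes[p.id]
            expected = sum(lengths[sid] for sid, _ in members) \
                + (len(members) - 1) * layout.spacer_len
            assert len(p.seq) == expected

    def test_agp_round_trip_byte_identical(self, small_scene, genes_by_scaffold, tmp_path):
        merged, layout = run_anchoring(small_scene, genes_by_scaffold)
        emit = emit_pseudomolecules(layout, small_scene["scaffolds"])
        agp_path = tmp_path / "out.agp"
        write_agp(emit.agp_rows, agp_path)
        rebuilt = rebuild_from_agp(read_agp(agp_path), small_scene["scaffolds"])
        assert [(r.id, r.seq) for r in rebuilt] == \
            [(p.id, p.seq) for p in emit.pseudomolecules]

    def test_liftover_round_trip_sequences(self, small_scene, genes_by_scaffold):
        merged, layout = run_anchoring(small_scene, genes_by_scaffold)
        emit = emit_pseudomolecules(layout, small_scene["scaffolds"], small_scene["sgenes"])
        pseudo = {p.id: p.seq for p in emit.pseudomolecules}
        scaffold_seq = {s.id: s.seq for s in small_scene["scaffolds"]}
        orient = {sid: o for members in layout.chromosomes.values() for sid, o in members}
        originals = {g.gene_id: g for g in small_scene["sgenes"]}
        checked = 0
        for lifted in emit.lifted_genes:
            g = originals[lifted.gene_id]
            source = scaffold_seq[g.seq_id][g.start - 1:g.end]
            if orient[g.seq_id] == "-":
                source = reverse_complement(source)
            assert pseudo[lifted.seq_id][lifted.start - 1:lifted.end] == source
            checked += 1
        assert checked > 10

    def test_noise_free_recovery_is_exact(self, small_scene, genes_by_scaffold):
        merged, layout = run_anchoring(small_scene, genes_by_scaffold)
        tru = {t.scaffold_id: t for t in small_scene["struth"]}
        from collections import Counter
        marker_count = Counter(l.scaffold_id for l in small_scene["loci"] if l.placed)
        bh = best_hits(small_scene["hits"])
        gene_count = Counter(g.seq_id for g in small_scene["sgenes"] if g.gene_id in bh)
        qualifying = ({s for s, c in marker_count.items() if c >= 2}
                      | {s for s, c in gene_count.items() if c >= 5})
        placed = set(layout.placed_scaffolds())
        assert qualifying <= placed
        for chrom, members in layout.chromosomes.items():
            q = [(sid, o) for sid, o in members if sid in qualifying]
            for sid, o in q:
                assert tru[sid].chrom == chrom
                assert o == tru[sid].orientation
            starts = [tru[sid].start for sid, _ in q]
            assert starts == sorted(starts)

    def test_threshold_monotonicity(self, small_scene, genes_by_scaffold):
        bh = best_hits(small_scene["hits"])
        counts = []
        for r2 in (0.3, 0.6, 0.9):
            params = AnchoringParams(r2_threshold=r2)
            runs = collinear_runs(genes_by_scaffold, bh, params)
            counts.append(len(synteny_assign_all(runs, params)))
        assert counts == sorted(counts, reverse=True)
        counts_g = []
        for mg in (3, 5, 8):
            params = AnchoringParams(min_genes=mg)
            runs = collinear_runs(genes_by_scaffold, bh, params)
            counts_g.append(len(synteny_assign_all(runs, params)))
        assert counts_g == sorted(counts_g, reverse=True)


class TestTable2Report:
    def test_totals_are_column_sums(self, small_scene, genes_by_scaffold):
        merged, layout = run_anchoring(small_scene, genes_by_scaffold)
        summary = assembly_summary(small_scene["scaffolds"])
        df = table2_report(layout, small_scene["scaffolds"], small_scene["sgenes"], summary)
        body = df[df.chromosome != "Total"]
        total = df[df.chromosome == "Total"].iloc[0]
        assert total.n_scaffolds == body.n_scaffolds.sum()
        assert total.assigned_bp == body.assigned_bp.sum()
        assert total.n_genes == body.n_genes.sum()

    def test_percentages_one_decimal(self, small_scene, genes_by_scaffold):
        merged, layout = run_anchoring(small_scene, genes_by_scaffold)
        summary = assembly_summary(small_scene["scaffolds"])
        df = table2_report(layout, small_scene["scaffolds"], small_scene["sgenes"], summary)
        for col in ("pct_scaffolds", "pct_bp", "pct_genes"):
            assert all(abs(v - round(v, 1)) < 1e-9 for v in df[col])

    def test_empty_layout_zero_rows(self, small_scene):
        from scafpipe.anchoring import PseudomoleculeLayout
        layout = PseudomoleculeLayout(chromosomes={}, spacer_len=10_000)
        summary = assembly_summary(small_scene["scaffolds"])
        df = table2_report(layout, small_scene["scaffolds"], small_scene["sgenes"], summary)
        assert list(df.chromosome) == ["Total"]
        assert df.iloc[0].n_scaffolds == 0
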