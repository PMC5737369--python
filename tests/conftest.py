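import pytest

from scafpipe import anchoring as anc
from scafpipe import synthetic as syn


@pytest.fixture(scope="session")
def small_scene():
    """A small fragmented synthetic genome with map, hits and truth tables."""
    ref, genes, truth = syn.generate_genome(
        n_chrom=2, chrom_len=120_000, gene_density=4e-4, seed=11)
    scaffolds, sgenes, struth = syn.fragment_scaffolds(ref, genes, (4000, 9000), seed=12)
    loci = syn.simulate_map(struth, truth.chrom_lengths, markers_per_chrom=12, seed=13)
    hits = syn.simulate_hits(sgenes, genes, seed=14)
    return dict(ref=ref, genes=genes, truth=truth, scaffolds=scaffolds,
                sgenes=sgenes, struth=struth, loci=loci, hits=hits)


@pytest.fixture(scope="session")
def genes_by_scaffold(small_scene):
    gb = {}
    for g in small_scene["sgenes"]:
        gb.setdefault(g.seq_id, []).append(g)
    return gb


def run_anchoring(scene, genes_by_scaffold, params=None, loci=None, hits=None):
    """Full anchoring pipeline on a synthetic scene; returns (merged, layout)."""
    params = params or anc.AnchoringParams()
    loci = scene["loci"] if loci is None else loci
    hits = scene["hits"] if hits is None else hits
    map_a = anc.map_assign(loci, params)
    bh = anc.best_hits(hits)
    runs = anc.collinear_runs(genes_by_scaffold, bh, params)
    syn_a = anc.synteny_assign_all(runs, params)
    merged = anc.merge_assignments(map_a, syn_a)
    merged = anc.refine_order_keys(merged, genes_by_scaffold, bh)
    lengths = {s.id: len(s.seq) for s in scene["scaffolds"]}
    layout = anc.build_layout(merged, scene["truth"].chrom_lengths,
                              scaffold_lengths=lengths, map_loci=loci)
    return merged, layout
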