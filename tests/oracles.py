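"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a different route than the production
code: brute-force digestion for CAPS, segment-extraction dynamic programming
for SSRs, full-CDS retranslation for effect calls, Biopython thermodynamics
plus fresh constraint checks for primers, and closed-form OLS for synteny.
"""

from __future__ import annotations

import itertools
import math
import re

from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as mt

from scafpipe.genome_io import GeneModel, reverse_complement
from scafpipe.markers import IUPAC, PrimerConstraints, SsrParams
from scafpipe.variants import VariantRecord

# ---------------------------------------------------------------------------
# CAPS digest oracle
# ---------------------------------------------------------------------------


def digest_count(window: str, site: str) -> int:
    """Count site occurrences by expanding every IUPAC combination and
    checking each window position explicitly."""
    expansions = ["".join(p) for p in itertools.product(*(IUPAC[c] for c in site))]
    count = 0
    for i in range(len(window) - len(site) + 1):
        sub = window[i:i + len(site)]
        if any(sub == e for e in expansions):
            count += 1
    return count


def caps_oracle(seq: str, pos: int, ref: str, alt: str, site: str) -> bool | None:
    """True iff the enzyme distinguishes the alleles; None when the SNP sits
    too close to the sequence end for this enzyme."""
    m = len(site)
    idx = pos - 1
    if idx - (m - 1) < 0 or idx + (m - 1) >= len(seq):
        return None
    window = seq[idx - (m - 1): idx + m]
    assert window[m - 1] == ref
    alt_window = window[:m - 1] + alt + window[m:]
    return digest_count(window, site) != digest_count(alt_window, site)


# ---------------------------------------------------------------------------
# SSR oracles
# ---------------------------------------------------------------------------


def _oracle_seeds(seq: str, params: SsrParams) -> set[str]:
    """Distinct primitive units appearing as >= seed_repeats perfect copies."""
    units: set[str] = set()
    for u in range(params.unit_min, params.unit_max + 1):
        span = u * params.seed_repeats
        for i in range(len(seq) - span + 1):
            window = seq[i:i + span]
            if "N" in window:
                continue
            unit = window[:u]
            if window == unit * params.seed_repeats:
                primitive = all(not (u % d == 0 and unit == unit[:d] * (u // d))
                                for d in range(1, u))
                if primitive:
                    units.add(unit)
    return units


def _segments_for_unit(seq: str, unit: str, params: SsrParams) -> list[tuple[int, int, float]]:
    """All non-overlapping maximal-score segments for one unit via iterated
    forward DP with restarts (local-alignment style), 0-based half-open."""
    penalty = params.mismatch_penalty
    u = len(unit)
    work = list(seq)
    found: list[tuple[int, int, float]] = []

    def better(cand: tuple[float, int], cur: tuple[float, int]) -> bool:
        # on score ties prefer the later start: the shortest max-score extent
        return cand[0] > cur[0] or (cand[0] == cur[0] and cand[1] > cur[1])

    while True:
        neg = -math.inf
        cur: list[tuple[float, int]] = [(neg, -1)] * u  # (score, start) per phase
        best = (0.0, -1, -1)  # (score, start, end-exclusive); earliest end on ties
        for j, ch in enumerate(work):
            new: list[tuple[float, int]] = [(neg, -1)] * u
            for ph in range(u):
                score, start = cur[ph]
                nxt = (ph + 1) % u
                if score != neg:
                    if ch == unit[ph] and better((score + 1, start), new[nxt]):
                        new[nxt] = (score + 1, start)
                    if penalty != math.inf:
                        if better((score - penalty, start), new[nxt]):
                            new[nxt] = (score - penalty, start)
                        if better((score - penalty, start), new[ph]):
                            new[ph] = (score - penalty, start)
                # fresh start at j (first consumed char must be a match)
                if ch == unit[ph] and better((1.0, j), new[nxt]):
                    new[nxt] = (1.0, j)
            if penalty != math.inf:
                for _ in range(u - 1):
                    changed = False
                    for ph in range(u):
                        score, start = new[ph]
                        if score == neg:
                            continue
                        nxt = (ph + 1) % u
                        if better((score - penalty, start), new[nxt]):
                            new[nxt] = (score - penalty, start)
                            changed = True
                    if not changed:
                        break
            cur = new
            for ph in range(u):
                score, start = cur[ph]
                if score > best[0] or (score == best[0] and j + 1 == best[2] and start > best[1]):
                    best = (score, start, j + 1)
        score, start, end = best
        if start < 0 or score < params.min_score:
            break
        seg = "".join(work[start:end])
        rotations = [unit[i:] + unit[:i] for i in range(u)]
        if any(r * params.seed_repeats in seg for r in rotations):
            found.append((start, end, score))
        for i in range(start, end):
            work[i] = "\x00"  # matches nothing, splits segments
    return found


def ssr_dp_oracle(seq: str, params: SsrParams):
    """Independent SSR caller: per seeded unit, extract maximal segments by
    restartable DP, then resolve overlaps with the published ranking
    (score desc, unit length asc, leftmost)."""
    from scafpipe.markers import canonical_motif

    candidates = []
    for unit in sorted(_oracle_seeds(seq, params)):
        for start, end, score in _segments_for_unit(seq, unit, params):
            candidates.append(dict(start=start + 1, end=end, score=score,
                                   unit_len=len(unit), motif=canonical_motif(unit)))
    # deduplicate identical intervals from rotated units
    uniq = {}
    for c in candidates:
        key = (c["start"], c["end"], c["motif"])
        if key not in uniq or c["score"] > uniq[key]["score"]:
            uniq[key] = c
    ordered = sorted(uniq.values(),
                     key=lambda c: (-c["score"], c["unit_len"], c["start"], c["end"], c["motif"]))
    accepted = []
    for c in ordered:
        if any(c["start"] <= a["end"] and a["start"] <= c["end"] for a in accepted):
            continue
        accepted.append(c)
    accepted.sort(key=lambda c: (c["start"], c["end"]))
    return accepted


def ssr_regex_oracle(seq: str, params: SsrParams):
    """Perfect-repeat oracle (valid when mismatch_penalty is infinite):
    maximal runs of a unit repeated, including a trailing partial copy."""
    from scafpipe.markers import canonical_motif

    candidates = []
    for unit in sorted(_oracle_seeds(seq, params)):
        u = len(unit)
        pattern = re.compile(f"(?:{unit})+")
        for m in pattern.finditer(seq):
            start, end = m.start(), m.end()
            # extend with a partial unit copy on the right
            k = 0
            while end + k < len(seq) and seq[end + k] == unit[k % u]:
                k += 1
            end += k
            # and on the left
            k = 0
            while start - 1 - k >= 0 and seq[start - 1 - k] == unit[(-1 - k) % u]:
                k += 1
            start -= k
            score = float(end - start)
            rotations = [unit[i:] + unit[:i] for i in range(u)]
            has_seed = any(r * params.seed_repeats in seq[start:end] for r in rotations)
            if score >= params.min_score and has_seed:
                candidates.append(dict(start=start + 1, end=end, score=score,
                                       unit_len=u, motif=canonical_motif(unit)))
    uniq = {}
    for c in candidates:
        key = (c["start"], c["end"], c["motif"])
        uniq[key] = c
    ordered = sorted(uniq.values(),
                     key=lambda c: (-c["score"], c["unit_len"], c["start"], c["end"], c["motif"]))
    accepted = []
    for c in ordered:
        if any(c["start"] <= a["end"] and a["start"] <= c["end"] for a in accepted):
            continue
        accepted.append(c)
    accepted.sort(key=lambda c: (c["start"], c["end"]))
    return accepted


# ---------------------------------------------------------------------------
# effect retranslation oracle
# ---------------------------------------------------------------------------


def _splice(seq: str, segments, strand: str) -> str:
    cds = "".join(seq[s - 1:e] for s, e in segments)
    return reverse_complement(cds) if strand == "-" else cds


def effect_oracle(v: VariantRecord, gene: GeneModel, chrom_seq: str) -> str:
    """Classify by rebuilding the mutant chromosome, re-splicing and fully
    retranslating the CDS.  Valid for variants confined to a single feature
    (the generated suite guarantees that)."""
    alt = v.alts[0]
    var_start, var_end = v.pos, v.pos + len(v.ref) - 1
    in_cds = any(s <= var_end and var_start <= e for s, e in gene.cds_segments)
    if not in_cds:
        if any(s <= var_end and var_start <= e for s, e in gene.exon_segments):
            return "noncoding_exon_variant"
        if gene.start <= var_end and var_start <= gene.end:
            return "intron_variant"
        return "intergenic_variant"
    delta = len(alt) - len(v.ref)
    if delta != 0:
        if delta % 3 != 0:
            return "frameshift_variant"
        return "inframe_insertion" if delta > 0 else "inframe_deletion"
    mutant = chrom_seq[:v.pos - 1] + alt + chrom_seq[v.pos - 1 + len(v.ref):]
    prot_ref = str(Seq(_splice(chrom_seq, gene.cds_segments, gene.strand)).translate())
    prot_alt = str(Seq(_splice(mutant, gene.cds_segments, gene.strand)).translate())
    if prot_ref == prot_alt:
        return "synonymous_variant"
    diff = [i for i, (a, b) in enumerate(zip(prot_ref, prot_alt)) if a != b]
    i = diff[0]
    if prot_ref[i] == "*":
        return "stop_lost"
    if prot_alt[i] == "*":
        return "stop_gained"
    if i == 0:
        return "start_lost"
    return "missense_variant"


# ---------------------------------------------------------------------------
# primer oracle
# ---------------------------------------------------------------------------


def oracle_tm(seq: str) -> float:
    """Biopython nearest-neighbour Tm with the same model assumptions:
    unified 1998 table, 50 mM Na+, total strand concentration 50 nM (C/4)."""
    return mt.Tm_NN(seq, nn_table=mt.DNA_NN3, Na=50, dnac1=25, dnac2=25, saltcorr=5)


def _oracle_primer_ok(seq: str, c: PrimerConstraints) -> bool:
    if re.search(r"[^ACGT]", seq):
        return False
    gc = 100.0 * sum(seq.count(b) for b in "GC") / len(seq)
    if gc < c.min_gc or gc > c.max_gc:
        return False
    if re.search(r"(.)\1{%d,}" % c.max_homopolymer, seq):
        return False
    tm = oracle_tm(seq)
    if tm < c.min_tm or tm > c.max_tm:
        return False
    tail = seq[-5:]
    for i in range(len(tail) - 3):
        four = tail[i:i + 4]
        if four == str(Seq(four).reverse_complement()):
            return False
    return True


def primer_oracle(template: str, target: tuple[int, int], c: PrimerConstraints | None = None):
    """Exhaustive, independently coded primer-pair search returning the same
    deterministic ranking key; None when no pair is feasible."""
    c = c or PrimerConstraints()
    t_start, t_end = target
    lefts, rights = [], []
    for start in range(len(template)):
        for length in range(c.min_len, c.max_len + 1):
            if start + length > t_start - 1:
                break
            s = template[start:start + length]
            if _oracle_primer_ok(s, c):
                lefts.append((start + 1, s, oracle_tm(s)))
    for end in range(t_end, len(template)):
        for length in range(c.min_len, c.max_len + 1):
            if end + length > len(template):
                break
            s = str(Seq(template[end:end + length]).reverse_complement())
            if _oracle_primer_ok(s, c):
                rights.append((end + length, s, oracle_tm(s)))
    best_key, best = None, None
    for l_start, l_seq, l_tm in lefts:
        for r_end, r_seq, r_tm in rights:
            product = r_end - l_start + 1
            if product < c.min_product or product > c.max_product:
                continue
            dtm = abs(l_tm - r_tm)
            if dtm > c.max_tm_diff:
                continue
            key = (round(dtm, 6), product, l_start, len(l_seq), r_end, len(r_seq))
            if best_key is None or key < best_key:
                best_key = key
                best = (l_seq, r_seq, l_start, r_end, product)
    return best


# ---------------------------------------------------------------------------
# regression oracle
# ---------------------------------------------------------------------------


def ols_r2_slope(x, y) -> tuple[float, float]:
    """Closed-form simple OLS R^2 and slope."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    syy = sum((yi - my) ** 2 for yi in y)
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    slope = sxy / sxx
    r2 = sxy * sxy / (sxx * syy) if syy > 0 else float("nan")
    return r2, slope
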