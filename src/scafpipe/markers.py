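"""CAPS, indel and SSR marker derivation plus simple primer design.

The CAPS scan asks, per restriction enzyme, whether the two alleles of a SNP
leave different numbers of recognition sites in the window the enzyme could
possibly cut around the SNP.  The SSR finder seeds on perfect tandem
repeats and extends through scattered interruptions under a +1 match /
-penalty mismatch score.  The primer designer is a deterministic exhaustive
scanner with nearest-neighbour melting temperatures; it is intentionally
much simpler than a full thermodynamic design tool.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .genome_io import GeneModel, reverse_complement
from .variants import VariantRecord

logger = logging.getLogger(__name__)

# The shipped digest panel: 19 enzymes with 4-6 bp palindromic sites.
DEFAULT_ENZYMES: tuple[tuple[str, str], ...] = (
    ("AfaI", "GTAC"), ("AluI", "AGCT"), ("ApaI", "GGGCCC"), ("BamHI", "GGATCC"),
    ("BglII", "AGATCT"), ("DraI", "TTTAAA"), ("EcoRI", "GAATTC"), ("EcoRV", "GATATC"),
    ("HaeIII", "GGCC"), ("HhaI", "GCGC"), ("HindIII", "AAGCTT"), ("KpnI", "GGTACC"),
    ("MboI", "GATC"), ("MspI", "CCGG"), ("PstI", "CTGCAG"), ("SacI", "GAGCTC"),
    ("SalI", "GTCGAC"), ("XbaI", "TCTAGA"), ("XhoI", "CTCGAG"),
)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class EnzymeDef:
    name: str
    recognition_site: str

    def __post_init__(self) -> None:
        if not 4 <= len(self.recognition_site) <= 6:
            raise ValueError(f"{self.name}: site length must be 4-6")
        for c in self.recognition_site:
            if c not in IUPAC:
                raise ValueError(f"{self.name}: invalid IUPAC code {c!r}")

    @property
    def is_palindromic(self) -> bool:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        site = self.recognition_site
        return all(c in comp and comp[c] == site[-1 - i] for i, c in enumerate(site))


def load_enzymes(pairs: Iterable[tuple[str, str]] = DEFAULT_ENZYMES) -> list[EnzymeDef]:
    """Build the enzyme table, asserting every site is palindromic (the scan
    counts forward-strand occurrences only, which is valid only then)."""
    enzymes = [EnzymeDef(name, site) for name, site in pairs]
    for e in enzymes:
        if not e.is_palindromic:
            raise ValueError(f"enzyme {e.name}: site {e.recognition_site} is not palindromic")
    return enzymes


def _site_regex(site: str) -> re.Pattern:
    pattern = "".join(c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in site)
    return re.compile(f"(?=({pattern}))")  # overlapping matches


def count_sites(window: str, site: str) -> int:
    return sum(1 for _ in _site_regex(site).finditer(window))


@dataclass
class CapsResult:
    enzymes: list[str]        # enzymes for which the SNP is a CAPS
    skipped: list[str]        # enzymes skipped for lack of flanking sequence


def caps_scan(
    snp: VariantRecord,
    genome: Mapping[str, str],
    enzymes: Sequence[EnzymeDef] | None = None,
) -> CapsResult:
    """Which enzymes distinguish the two alleles of a biallelic SNP?

    For each enzyme the window of length 2*(|site|-1)+1 centred on the SNP is
    digested in silico under both alleles; the enzyme qualifies iff the
    occurrence counts differ.
    """
    if not (snp.is_snp and snp.is_biallelic):
        raise ValueError("caps_scan expects a biallelic SNP")
    enzymes = enzymes if enzymes is not None else load_enzymes()
    seq = genome[snp.chrom]
    idx = snp.pos - 1
    if seq[idx] != snp.ref:
        raise ValueError(f"reference mismatch at {snp.chrom}:{snp.pos}: "
                         f"genome has {seq[idx]!r}, variant says {snp.ref!r}")
    qualifying, skipped = [], []
    for enz in enzymes:
        m = len(enz.recognition_site)
        flank = m - 1
        if idx - flank < 0 or idx + flank >= len(seq):
            skipped.append(enz.name)
            continue
        window = seq[idx - flank: idx + flank + 1]
        alt_window = window[:flank] + snp.alts[0] + window[flank + 1:]
        if count_sites(window, enz.recognition_site) != count_sites(alt_window, enz.recognition_site):
            qualifying.append(enz.name)
    if skipped:
        logger.debug("SNP %s:%d: %d enzymes skipped (too close to sequence end)",
                     snp.chrom, snp.pos, len(skipped))
    return CapsResult(qualifying, skipped)


def select_indel_markers(
    variants: Sequence[VariantRecord], max_len: int = 15
) -> list[VariantRecord]:
    """Keep biallelic indels with 1 <= |len(ref) - len(alt)| <= max_len."""
    out = []
    for v in variants:
        if not v.is_biallelic:
            continue
        diff = v.indel_length()
        if 1 <= diff <= max_len:
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# SSR detection
# ---------------------------------------------------------------------------

@dataclass
class SsrParams:
    unit_min: int = 2
    unit_max: int = 6
    min_score: float = 15
    mismatch_penalty: float = 5
    seed_repeats: int = 3
    xdrop: float = 30  # stop extending once the running score falls this far below the best

    def __post_init__(self) -> None:
        if not 1 <= self.unit_min <= self.unit_max:
            raise ValueError("need 1 <= unit_min <= unit_max")
        if self.min_score <= 0:
            raise ValueError("min_score must be > 0")


@dataclass
class SsrLocus:
    seq_id: str
    start: int  # 1-based inclusive
    end: int
    canonical_motif: str
    unit_len: int
    score: float
    n_mismatches: int
    genic: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _is_primitive(unit: str) -> bool:
    for d in range(1, len(unit)):
        if len(unit) % d == 0 and unit == unit[:d] * (len(unit) // d):
            return False
    return True


def canonical_motif(unit: str) -> str:
    """Lexicographic minimum over all rotations of the unit and of its
    reverse complement.  Degenerate (non-primitive) units are rejected."""
    if not unit or len(unit) > 6 or set(unit) - set("ACGT"):
        raise ValueError(f"bad repeat unit {unit!r}")
    if not _is_primitive(unit):
        raise ValueError(f"unit {unit!r} is a repeat of a shorter unit")
    rc = reverse_complement(unit)
    candidates = [unit[i:] + unit[:i] for i in range(len(unit))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


def _extend(seq: str, pos: int, unit: str, phase: int, penalty: float,
            xdrop: float) -> tuple[float, int, int]:
    """Extend rightward from ``pos`` expecting ``unit[phase]`` next.

    Phase-state dynamic programming: at each base the best continuation over
    match / substitution / insertion / deletion is kept per phase.  Returns
    (best gain, bases consumed at the best point, mismatch events there).
    Extension stops at the sequence end or when the running best falls
    ``xdrop`` below the overall best (never, when penalty is infinite).
    """
    u = len(unit)
    neg = -math.inf
    score = [neg] * u
    mism = [0] * u
    score[phase] = 0.0
    best_gain, best_used, best_mism = 0.0, 0, 0
    used = 0
    for j in range(pos, len(seq)):
        c = seq[j]
        new = [neg] * u
        new_m = [0] * u
        for ph in range(u):
            if score[ph] == neg:
                continue
            nxt = (ph + 1) % u
            # match
            if c == unit[ph]:
                cand = score[ph] + 1
                if cand > new[nxt] or (cand == new[nxt] and mism[ph] < new_m[nxt]):
                    new[nxt], new_m[nxt] = cand, mism[ph]
            # substitution (consume c in place of unit[ph])
            cand = score[ph] - penalty
            if cand > new[nxt] or (cand == new[nxt] and mism[ph] + 1 < new_m[nxt]):
                new[nxt], new_m[nxt] = cand, mism[ph] + 1
            # insertion (c is an extra base; phase unchanged)
            if cand > new[ph] or (cand == new[ph] and mism[ph] + 1 < new_m[ph]):
                new[ph], new_m[ph] = cand, mism[ph] + 1
        if penalty != math.inf:
            # deletions: skip expected unit characters without consuming sequence
            for _ in range(u - 1):
                improved = False
                for ph in range(u):
                    if new[ph] == neg:
                        continue
                    nxt = (ph + 1) % u
                    cand = new[ph] - penalty
                    if cand > new[nxt] or (cand == new[nxt] and new_m[ph] + 1 < new_m[nxt]):
                        new[nxt], new_m[nxt] = cand, new_m[ph] + 1
                        improved = True
                if not improved:
                    break
        score, mism = new, new_m
        used += 1
        col_best = max(score)
        if col_best == neg:
            break
        if col_best > best_gain:
            best_gain = col_best
            best_used = used
            best_mism = min(m for s, m in zip(score, mism) if s == col_best)
        if col_best < best_gain - xdrop:
            break
    return best_gain, best_used, best_mism


def _find_seeds(seq: str, params: SsrParams) -> list[tuple[int, str]]:
    """(position, unit) of every maximal-start perfect seed of
    ``seed_repeats`` copies of a primitive unit."""
    seeds = []
    n = len(seq)
    for u in range(params.unit_min, params.unit_max + 1):
        span = u * params.seed_repeats
        i = 0
        while i + span <= n:
            window = seq[i:i + span]
            if "N" not in window and seq[i:i + span - u] == seq[i + u:i + span]:
                unit = seq[i:i + u]
                if _is_primitive(unit):
                    seeds.append((i, unit))
                    # skip ahead within this perfect run; interior seeds are redundant
                    j = i + span
                    while j < n and seq[j] == seq[j - u]:
                        j += 1
                    i = j - span + 1
                    continue
            i += 1
    return seeds


def find_ssrs(seq: str, params: SsrParams | None = None, seq_id: str = "seq") -> list[SsrLocus]:
    """Detect (imperfect) SSR loci.

    Seeds of ``seed_repeats`` perfect unit copies are extended in both
    directions under +1/match, -penalty/interruption scoring (interruptions
    may substitute, insert or delete bases, so phase shifts are tolerated),
    trimmed to the maximum-score extent.  Overlapping candidates are resolved
    by highest score, then shortest unit, then leftmost position.
    """
    params = params or SsrParams()
    penalty = params.mismatch_penalty
    candidates: dict[tuple[int, int, str], SsrLocus] = {}
    for pos, unit in _find_seeds(seq, params):
        u = len(unit)
        span = u * params.seed_repeats
        right_gain, right_used, right_mism = _extend(
            seq, pos + span, unit, 0, penalty, params.xdrop)
        # leftward: extend rightward on the reversed sequence with the reversed unit
        rev_unit = unit[::-1]
        left_gain, left_used, left_mism = _extend(
            seq[:pos][::-1], 0, rev_unit, 0, penalty, params.xdrop)
        start = pos - left_used
        end = pos + span + right_used - 1
        score = span + left_gain + right_gain
        if score < params.min_score:
            continue
        locus = SsrLocus(
            seq_id=seq_id, start=start + 1, end=end + 1,
            canonical_motif=canonical_motif(unit), unit_len=u,
            score=score, n_mismatches=left_mism + right_mism,
        )
        key = (locus.start, locus.end, locus.canonical_motif)
        prev = candidates.get(key)
        if prev is None or locus.score > prev.score:
            candidates[key] = locus
    # overlap resolution: highest score, then shortest unit, then leftmost
    ordered = sorted(candidates.values(),
                     key=lambda l: (-l.score, l.unit_len, l.start, l.end, l.canonical_motif))
    accepted: list[SsrLocus] = []
    for locus in ordered:
        if any(locus.start <= a.end and a.start <= locus.end for a in accepted):
            continue
        accepted.append(locus)
    accepted.sort(key=lambda l: (l.start, l.end))
    return accepted


def classify_genic(locus: SsrLocus, gene_models: Sequence[GeneModel]) -> bool:
    """Genic iff the locus overlaps any gene span (introns included) by >= 1 bp."""
    return any(
        g.seq_id == locus.seq_id and locus.start <= g.end and g.start <= locus.end
        for g in gene_models
    )


# ---------------------------------------------------------------------------
# primer design
# ---------------------------------------------------------------------------

# Unified nearest-neighbour parameters (kcal/mol for dH; cal/mol/K for dS).
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_AT = (2.3, 4.1)
_INIT_GC = (0.1, -2.8)
_R = 1.987  # cal/mol/K


def melting_temperature(seq: str, na_molar: float = 0.05, oligo_molar: float = 50e-9) -> float:
    """Nearest-neighbour Tm (degC), unified parameters with a Na+ entropy
    correction, for a non-self-complementary oligo."""
    if len(seq) < 2 or set(seq) - set("ACGT"):
        raise ValueError(f"cannot compute Tm of {seq!r}")
    dh, ds = 0.0, 0.0
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i:i + 2]]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = _INIT_AT if terminal in "AT" else _INIT_GC
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_molar)
    return dh * 1000.0 / (ds + _R * math.log(oligo_molar / 4.0)) - 273.15


@dataclass
class PrimerConstraints:
    min_len: int = 18
    max_len: int = 25
    min_tm: float = 55.0
    max_tm: float = 62.0
    min_gc: float = 30.0
    max_gc: float = 70.0
    max_homopolymer: int = 4
    max_tm_diff: float = 3.0
    min_product: int = 80
    max_product: int = 300


@dataclass
class PrimerPair:
    left_seq: str
    right_seq: str
    left_start: int   # 1-based position of the left primer's 5' end on the template
    right_start: int  # 1-based position of the right primer's 3' end on the template
    left_tm: float
    right_tm: float
    left_gc: float
    right_gc: float
    product_len: int


def _gc_percent(seq: str) -> float:
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _three_prime_self_complementary(seq: str) -> bool:
    """True when any 4-mer inside the 3'-terminal 5-mer equals its own
    reverse complement (a self-annealing-prone 3' end)."""
    tail = seq[-5:]
    return any(reverse_complement(tail[i:i + 4]) == tail[i:i + 4]
               for i in range(len(tail) - 3))


def check_primer(seq: str, c: PrimerConstraints) -> str | None:
    """First violated constraint name, or None when the primer is feasible."""
    if set(seq) - set("ACGT"):
        return "alphabet"
    if not c.min_gc <= _gc_percent(seq) <= c.max_gc:
        return "gc"
    if _max_homopolymer(seq) > c.max_homopolymer:
        return "homopolymer"
    tm = melting_temperature(seq)
    if not c.min_tm <= tm <= c.max_tm:
        return "tm"
    if _three_prime_self_complementary(seq):
        return "self3"
    return None


def design_primer_pair(
    template: str,
    target_interval: tuple[int, int],  # 1-based inclusive
    constraints: PrimerConstraints | None = None,
) -> tuple[PrimerPair | None, dict[str, int]]:
    """Exhaustively scan the flanks for the best feasible primer pair.

    Feasible pairs must bracket the target with a product of 80-300 bp and a
    pair Tm difference <= 3 degC; among them the pair with the smallest Tm
    difference, then the shortest product, then the leftmost coordinates
    wins.  Returns (pair or None, per-constraint failure tally).
    """
    c = constraints or PrimerConstraints()
    t_start, t_end = target_interval
    if not 1 <= t_start <= t_end <= len(template):
        raise ValueError("target interval outside template")
    tally: dict[str, int] = {k: 0 for k in
                             ("alphabet", "gc", "homopolymer", "tm", "self3", "dtm", "product")}
    lefts: list[tuple[int, str, float]] = []   # (1-based start, seq, tm)
    for start in range(0, t_start - c.min_len):
        for length in range(c.min_len, c.max_len + 1):
            end = start + length  # exclusive
            if end > t_start - 1:
                break
            seq = template[start:end]
            fail = check_primer(seq, c)
            if fail:
                tally[fail] += 1
            else:
                lefts.append((start + 1, seq, melting_temperature(seq)))
    rights: list[tuple[int, str, float]] = []  # (1-based template end, seq, tm)
    for end in range(t_end, len(template)):  # primer occupies template[end .. end+len)
        for length in range(c.min_len, c.max_len + 1):
            stop = end + length
            if stop > len(template):
                break
            seq = reverse_complement(template[end:stop])
            fail = check_primer(seq, c)
            if fail:
                tally[fail] += 1
            else:
                rights.append((stop, seq, melting_temperature(seq)))
    best: tuple | None = None
    best_pair: PrimerPair | None = None
    any_pair = False
    for l_start, l_seq, l_tm in lefts:
        for r_end, r_seq, r_tm in rights:
            product = r_end - l_start + 1
            if not c.min_product <= product <= c.max_product:
                tally["product"] += 1
                continue
            dtm = abs(l_tm - r_tm)
            if dtm > c.max_tm_diff:
                tally["dtm"] += 1
                continue
            any_pair = True
            # dtm quantised so that sub-micro-degree float noise cannot
            # reorder otherwise-tied pairs
            key = (round(dtm, 6), product, l_start, len(l_seq), r_end, len(r_seq))
            if best is None or key < best:
                best = key
                best_pair = PrimerPair(
                    left_seq=l_seq, right_seq=r_seq,
                    left_start=l_start, right_start=r_end,
                    left_tm=l_tm, right_tm=r_tm,
                    left_gc=_gc_percent(l_seq), right_gc=_gc_percent(r_seq),
                    product_len=product,
                )
    if not any_pair:
        return None, tally
    return best_pair, tally
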