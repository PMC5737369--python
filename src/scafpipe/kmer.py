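"""Canonical k-mer counting, coverage-peak detection and genome-size estimation.

Counting is strand-collapsed: every k-mer is recorded under the lexicographic
minimum of itself and its reverse complement.  Windows containing N are
skipped.  The counter is vectorised (2-bit packed codes, k <= 31) so that
tens of millions of read k-mers are countable in seconds, but it is an
in-memory counter aimed at desk-scale inputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_io import SequenceRecord

logger = logging.getLogger(__name__)

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


@dataclass
class KmerHistogram:
    """Depth (multiplicity) -> number of distinct canonical k-mers."""

    k: int
    counts: dict[int, int]

    def __post_init__(self) -> None:
        for depth, count in self.counts.items():
            if depth < 1:
                raise ValueError(f"depth {depth} < 1 in histogram")
            if count < 0:
                raise ValueError(f"negative count at depth {depth}")

    @property
    def n_distinct(self) -> int:
        return sum(self.counts.values())

    @property
    def total_kmers(self) -> int:
        return sum(d * c for d, c in self.counts.items())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for depth in sorted(self.counts):
                fh.write(f"{depth}\t{self.counts[depth]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, k: int) -> "KmerHistogram":
        counts: dict[int, int] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                d, c = line.split("\t")
                counts[int(d)] = int(c)
        return cls(k=k, counts=counts)


@dataclass
class PeakCall:
    """Error cutoff plus homozygous (and optional heterozygous) coverage peaks.

    ``hom_depth_refined`` is a sub-integer refinement of the homozygous peak
    (count-weighted centroid of the depths within +/-25% of the modal peak);
    the integer mode of a sampled depth distribution sits systematically
    below its mean, and the refined value is what the size estimator divides by.
    """

    hom_depth: int
    error_cutoff: int
    het_depth: int | None = None
    hom_depth_refined: float | None = None

    def __post_init__(self) -> None:
        if self.error_cutoff >= self.hom_depth:
            raise ValueError("error_cutoff must be below hom_depth")
        if self.het_depth is not None and not (self.error_cutoff < self.het_depth < self.hom_depth):
            raise ValueError("het_depth must lie between error_cutoff and hom_depth")


def _kmer_codes(seqs: Iterable[str], k: int) -> np.ndarray:
    """Canonical 2-bit-packed codes of every N-free k-mer window."""
    big = "N".join(seqs)
    arr = np.frombuffer(big.encode("ascii"), dtype=np.uint8)
    code = _BASE_CODE[arr].astype(np.int64)
    invalid = code < 0
    code[invalid] = 0
    n = len(code)
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.int64)
    fwd = np.zeros(m, dtype=np.int64)
    for j in range(k):
        fwd = (fwd << 2) | code[j:j + m]
    # reverse complement codes: pack the complemented, reversed base array and
    # read windows back in mirrored order
    comp = (3 - code)[::-1].copy()
    comp[invalid[::-1]] = 0
    rev = np.zeros(m, dtype=np.int64)
    for j in range(k):
        rev = (rev << 2) | comp[j:j + m]
    rc = rev[::-1]
    canonical = np.minimum(fwd, rc)
    # drop windows containing any invalid base
    bad = np.concatenate(([0], np.cumsum(invalid)))
    window_bad = bad[k:] - bad[:-k]
    return canonical[window_bad == 0]


def count_kmers(records: Sequence[SequenceRecord | str], k: int = 17) -> KmerHistogram:
    """Count canonical k-mers and aggregate into a depth histogram."""
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31]")
    seqs = [r.seq if isinstance(r, SequenceRecord) else str(r) for r in records]
    if not seqs:
        raise ValueError("no input sequences")
    if k > max(len(s) for s in seqs):
        raise ValueError(f"k={k} is longer than every input sequence")
    codes = _kmer_codes(seqs, k)
    if codes.size == 0:
        return KmerHistogram(k=k, counts={})
    _, per_kmer = np.unique(codes, return_counts=True)
    depths, n_at_depth = np.unique(per_kmer, return_counts=True)
    return KmerHistogram(k=k, counts={int(d): int(c) for d, c in zip(depths, n_at_depth)})


def _dense_counts(hist: KmerHistogram) -> np.ndarray:
    """counts[d] for d = 0..max_depth (index 0 unused)."""
    max_depth = max(hist.counts)
    dense = np.zeros(max_depth + 1, dtype=float)
    for d, c in hist.counts.items():
        dense[d] = c
    return dense


def _smooth(y: np.ndarray, window: int = 3) -> np.ndarray:
    """Moving average; edges averaged over the available neighbours."""
    kernel = np.ones(window)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den


def detect_peaks(hist: KmerHistogram, smooth_window: int = 3,
                 het_band: tuple[float, float] = (0.4, 0.6),
                 min_peak_fraction: float = 0.1) -> PeakCall:
    """Locate the error trough and the coverage peak(s) of a k-mer histogram.

    The error cutoff is the first local minimum of the raw counts as depth
    increases; peaks are local maxima of the window-smoothed counts above the
    cutoff.  The homozygous peak is the deeper of the top two maxima by
    height; the shallower one is called heterozygous only if it sits within
    ``het_band`` of the homozygous depth.
    """
    if not hist.counts:
        raise ValueError("empty histogram")
    dense = _dense_counts(hist)
    max_depth = len(dense) - 1
    # error trough: first depth where counts stop decreasing
    cutoff = None
    for d in range(1, max_depth):
        if dense[d + 1] > dense[d]:
            cutoff = d
            break
    if cutoff is None:
        raise ValueError("no coverage peak: histogram is monotone decreasing")
    smoothed = _smooth(dense, smooth_window)
    peaks: list[tuple[float, int]] = []  # (height, depth)
    for d in range(cutoff + 1, max_depth + 1):
        left = smoothed[d - 1] if d - 1 >= 0 else 0.0
        right = smoothed[d + 1] if d + 1 <= max_depth else 0.0
        if smoothed[d] > left and smoothed[d] >= right:
            peaks.append((smoothed[d], d))
    if not peaks:
        raise ValueError("no coverage peak above the error cutoff")
    # sampling noise in the deep tail produces tiny local maxima; only maxima
    # of comparable height to the main peak are peak candidates
    tallest = max(h for h, _ in peaks)
    peaks = [(h, d) for h, d in peaks if h >= min_peak_fraction * tallest]
    top2 = sorted(peaks, key=lambda p: (-p[0], p[1]))[:2]
    hom_depth = max(d for _, d in top2)
    het_depth: int | None = None
    if len(top2) == 2:
        lower = min(d for _, d in top2)
        ratio = lower / hom_depth
        if het_band[0] <= ratio <= het_band[1]:
            het_depth = lower
    # refined homozygous depth: centroid of raw counts within ~3 Poisson
    # standard deviations of the modal peak (but kept above any half-depth
    # heterozygous peak and the error trough)
    half_width = 3.0 * math.sqrt(hom_depth)
    lo = max(cutoff + 1, int(math.ceil(max(hom_depth - half_width, 0.55 * hom_depth))))
    hi = min(max_depth, int(hom_depth + half_width))
    window = np.arange(lo, hi + 1)
    weights = dense[lo:hi + 1]
    refined = float(np.average(window, weights=weights)) if weights.sum() > 0 else float(hom_depth)
    return PeakCall(hom_depth=hom_depth, error_cutoff=cutoff,
                    het_depth=het_depth, hom_depth_refined=refined)


def estimate_genome_size(hist: KmerHistogram, peaks: PeakCall,
                         error_cutoff: int | None = None,
                         use_refined: bool = True) -> int:
    """Estimate genome size as (k-mer mass above the error cutoff) / hom depth.

    ``error_cutoff`` overrides the cutoff from ``peaks`` when given.
    """
    cutoff = peaks.error_cutoff if error_cutoff is None else error_cutoff
    hom = peaks.hom_depth_refined if (use_refined and peaks.hom_depth_refined) else peaks.hom_depth
    if hom == 0:
        raise ValueError("homozygous depth is zero")
    mass = sum(d * c for d, c in hist.counts.items() if d >= cutoff)
    return int(round(mass / hom))
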