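"""Distance auto- and cross-correlation of dinucleotide classes.

The distance auto-correlation (DAC) of a dinucleotide class counts, for
every separation d = 1..150 bp, how many ordered pairs of class occurrences
sit d apart (distance measured between dinucleotide start coordinates,
never across sequence boundaries).  The cross-correlation (DCC) does the
same between two different classes.  In sequence with nucleosome-phased
~10-bp WW/SS periodicity the DAC peaks at d ~ 10n and the WW-vs-SS DCC at
d ~ 10n + 5, reflecting WW and SS oscillating in counter-phase.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import _seq

logger = logging.getLogger(__name__)

MAX_DISTANCE = 150


@dataclass
class CorrelationProfile:
    """Pair counts per separation distance d = 1..max_d.

    ``normalized`` divides each count by the total number of valid position
    pairs at that distance over all sequences (so a flat random sequence
    gives a flat profile); ``smoothed`` is its 3-point running average.  Raw
    counts are always retained.
    """

    kind: str  # 'DAC' | 'DCC'
    class_a: str
    class_b: str
    distance: np.ndarray
    count: np.ndarray
    normalized: np.ndarray
    smoothed: np.ndarray

    def peak_distances(self, k: int = 3, use_smoothed: bool = True) -> np.ndarray:
        """Distances of the k largest local maxima (for period diagnostics)."""
        y = self.smoothed if use_smoothed else self.normalized
        interior = (y[1:-1] >= y[:-2]) & (y[1:-1] >= y[2:])
        idx = np.flatnonzero(interior) + 1
        if idx.size == 0:
            return np.array([], dtype=int)
        order = np.argsort(y[idx])[::-1]
        return self.distance[idx[order[:k]]]


def _segments(codes: np.ndarray) -> Iterable[np.ndarray]:
    """Split a code array at non-ACGT positions; pairs never span a break."""
    bad = np.flatnonzero(codes == _seq.OTHER)
    if bad.size == 0:
        yield codes
        return
    prev = 0
    for b in bad:
        if b > prev:
            yield codes[prev:b]
        prev = b + 1
    if prev < len(codes):
        yield codes[prev:]


def _to_codes(seq) -> np.ndarray:
    return seq if isinstance(seq, np.ndarray) else _seq.encode(str(seq))


def _smooth3(x: np.ndarray) -> np.ndarray:
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = len(x)
    lo = np.maximum(np.arange(n) - 1, 0)
    hi = np.minimum(np.arange(n) + 2, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _pair_counts(
    sequences: Sequence, class_a: str, class_b: str, max_d: int, symmetric: bool
) -> tuple[np.ndarray, np.ndarray]:
    if len(sequences) == 0:
        raise ValueError("correlation requires at least one sequence")
    counts = np.zeros(max_d, dtype=np.int64)
    valid_pairs = np.zeros(max_d, dtype=np.int64)
    d_axis = np.arange(1, max_d + 1)
    for seq in sequences:
        for seg in _segments(_to_codes(seq)):
            n_pos = len(seg) - 1
            if n_pos < 1:
                continue
            a = _seq.dinuc_class_starts(seg, class_a)
            b = a if class_a == class_b else _seq.dinuc_class_starts(seg, class_b)
            dmax = min(max_d, n_pos - 1)
            for d in range(1, dmax + 1):
                c = np.count_nonzero(a[:-d] & b[d:])
                if symmetric and class_a != class_b:
                    c += np.count_nonzero(b[:-d] & a[d:])
                counts[d - 1] += c
            np.add(
                valid_pairs,
                np.maximum(n_pos - d_axis, 0) * (2 if symmetric and class_a != class_b else 1),
                out=valid_pairs,
            )
    return counts, valid_pairs


def _profile(kind, class_a, class_b, counts, valid_pairs, max_d) -> CorrelationProfile:
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(valid_pairs > 0, counts / np.maximum(valid_pairs, 1), 0.0)
    return CorrelationProfile(
        kind=kind,
        class_a=class_a,
        class_b=class_b,
        distance=np.arange(1, max_d + 1),
        count=counts,
        normalized=normalized,
        smoothed=_smooth3(normalized),
    )


def dac(sequences: Sequence, dinuc_class: str = "WW", max_d: int = MAX_DISTANCE) -> CorrelationProfile:
    """Distance auto-correlation of one dinucleotide class over sequences.

    For every ordered pair of class occurrences at dinucleotide starts
    (i, j) with j - i = d, one occurrence is counted at d; counts are pooled
    over sequences and never cross sequence (or N-break) boundaries.
    """
    cls = dinuc_class.upper()
    counts, valid = _pair_counts(sequences, cls, cls, max_d, symmetric=False)
    return _profile("DAC", cls, cls, counts, valid, max_d)


def dcc(
    sequences: Sequence,
    class_a: str = "WW",
    class_b: str = "SS",
    max_d: int = MAX_DISTANCE,
    orientation: str = "both",
) -> CorrelationProfile:
    """Distance cross-correlation between two dinucleotide classes.

    ``orientation='both'`` (default) counts unordered separation |i - j|,
    i.e. both a-then-b and b-then-a; ``'forward'`` counts only pairs with
    the class-b occurrence downstream of the class-a one.
    """
    if orientation not in ("both", "forward"):
        raise ValueError("orientation must be 'both' or 'forward'")
    a, b = class_a.upper(), class_b.upper()
    counts, valid = _pair_counts(sequences, a, b, max_d, symmetric=(orientation == "both"))
    return _profile("DCC", a, b, counts, valid, max_d)


def tss_region_extract(
    genome,
    genes,
    window: tuple[int, int] = (-500, 1000),
) -> list[tuple[str, str]]:
    """Extract strand-oriented TSS-anchored sequences for correlation analysis.

    ``window`` is (upstream, downstream) in TSS-relative coordinates, both
    inclusive, so the default (-500, 1000) yields 1501-bp sequences.  Minus
    strand genes are reverse-complemented so downstream is positive.  Windows
    running off a contig end are clipped (and logged); empty windows are
    skipped.  Returns ``(gene_id, sequence)`` pairs.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError("window must satisfy lo <= hi")
    out: list[tuple[str, str]] = []
    for gene in genes:
        contig = genome[gene.chrom]
        clen = len(contig)
        if gene.strand == "+":
            start, end = gene.tss + lo, gene.tss + hi + 1
        else:
            start, end = gene.tss - hi, gene.tss - lo + 1
        cstart, cend = max(0, start), min(clen, end)
        if cstart >= cend:
            logger.warning("gene %s: TSS window entirely off contig %s; skipped", gene.gene_id, gene.chrom)
            continue
        if (cstart, cend) != (start, end):
            logger.warning("gene %s: TSS window clipped to contig bounds", gene.gene_id)
        seq = str(contig[cstart:cend]).upper()
        if gene.strand == "-":
            seq = _seq.revcomp(seq)
        out.append((gene.gene_id, seq))
    return out
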