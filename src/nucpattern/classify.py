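"""WW/SS pattern classification of 147-bp nucleosome core particle sequences.

Each fragment is scored by counting WW (AA/AT/TA/TT) and SS (CC/CG/GC/GG)
dinucleotides that fall fully inside minor- and major-groove bending sites,
then assigned one of four rotational sequence patterns:

====  =============================  =============================
Type  WW predicate                   SS predicate
====  =============================  =============================
1     minor WW >= major WW * coef    minor SS <= major SS * coef
2     minor WW >= major WW * coef    minor SS >  major SS * coef
3     minor WW <  major WW * coef    minor SS <= major SS * coef
4     minor WW <  major WW * coef    minor SS >  major SS * coef
====  =============================  =============================

with coef = 1.125 = 36/32 compensating the different dinucleotide
capacities of the two groove classes.  Type 1 is the canonical WW/SS
rotational pattern; Type 4 is its inverse (anti-WW/SS).  The quantity
dNPS = Type 1 (%) - Type 4 (%) summarises a region's balance between them.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import _seq
from ._seq import NCP_LEN
from .geometry import GBSMap, MAJOR_CAPACITY, MINOR_CAPACITY

logger = logging.getLogger(__name__)

WW_DINUCS = frozenset({"AA", "AT", "TA", "TT"})
SS_DINUCS = frozenset({"CC", "CG", "GC", "GG"})

DEFAULT_COEF = MINOR_CAPACITY / MAJOR_CAPACITY  # 1.125


class EmptyInputError(ValueError):
    """Raised when a summary is requested over zero fragments."""


@dataclass(frozen=True)
class NCPFragment:
    """One 147-bp nucleosomal sequence with genomic provenance.

    ``start`` is the 0-based genomic coordinate of the first base; the dyad
    sits at ``start + 73``.  ``source`` records whether the fragment came
    from a 147-bp paired-end interval or a chemical-map dyad position.
    """

    chrom: str
    start: int
    sequence: str
    source: str = "mnase_147bp"

    def __post_init__(self):
        if len(self.sequence) != NCP_LEN:
            raise ValueError(f"NCP fragment must be {NCP_LEN} bp, got {len(self.sequence)}")
        if any(b not in "ACGTacgt" for b in self.sequence):
            raise ValueError("NCP fragment contains non-ACGT characters")

    @property
    def dyad(self) -> int:
        return self.start + _seq.DYAD_INDEX

    @property
    def end(self) -> int:
        return self.start + NCP_LEN


@dataclass(frozen=True)
class PatternCounts:
    """WW/SS dinucleotide counts per groove class for one fragment."""

    ww_minor: int
    ww_major: int
    ss_minor: int
    ss_major: int

    def __post_init__(self):
        for name in ("ww_minor", "ww_major", "ss_minor", "ss_major"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.ww_minor + self.ss_minor > MINOR_CAPACITY:
            raise ValueError("minor-groove counts exceed capacity 36")
        if self.ww_major + self.ss_major > MAJOR_CAPACITY:
            raise ValueError("major-groove counts exceed capacity 32")


@dataclass(frozen=True)
class NPSSummary:
    """Type composition of a fragment collection, in percent."""

    n_fragments: int
    fraction_type: tuple[float, float, float, float]

    @property
    def dnps(self) -> float:
        """Type 1 (%) minus Type 4 (%)."""
        return self.fraction_type[0] - self.fraction_type[3]

    def as_dict(self) -> dict:
        d = {"n_fragments": self.n_fragments}
        d.update({f"type{i + 1}_pct": f for i, f in enumerate(self.fraction_type)})
        d["dnps_pct"] = self.dnps
        return d


@dataclass
class DyadFrequencyProfile:
    """Per-position WW/SS dinucleotide frequency, dyad-symmetrized and smoothed.

    ``position`` indexes dinucleotide starts 0..145 of the 147-bp frame;
    symmetrization averages position i with 145-i.
    """

    position: np.ndarray
    ww_freq: np.ndarray
    ss_freq: np.ndarray
    ww_raw: np.ndarray
    ss_raw: np.ndarray
    smoothing: int


def _as_code_matrix(fragments: Sequence[NCPFragment] | np.ndarray) -> np.ndarray:
    if isinstance(fragments, np.ndarray):
        return fragments
    return np.vstack([_seq.encode(f.sequence) for f in fragments])


def count_batch(codes: np.ndarray, gbs_map: GBSMap) -> dict[str, np.ndarray]:
    """Vectorised WW/SS counts for a (n, 147) uint8 code matrix."""
    codes = np.atleast_2d(codes)
    ww = _seq.ww_starts(codes)
    ss = _seq.ss_starts(codes)
    minor_slots = np.asarray(gbs_map.slot_starts("minor"))
    major_slots = np.asarray(gbs_map.slot_starts("major"))
    return {
        "ww_minor": ww[:, minor_slots].sum(axis=1),
        "ww_major": ww[:, major_slots].sum(axis=1),
        "ss_minor": ss[:, minor_slots].sum(axis=1),
        "ss_major": ss[:, major_slots].sum(axis=1),
    }


def count_dinucleotides(fragment: NCPFragment, gbs_map: GBSMap) -> PatternCounts:
    """Count WW and SS dinucleotides fully internal to minor/major GBS.

    A dinucleotide at start i occupies bases (i, i+1); it belongs to a site
    only if both bases lie inside it, so a k-bp site contributes k-1 slots.
    """
    c = count_batch(_seq.encode(fragment.sequence), gbs_map)
    return PatternCounts(
        ww_minor=int(c["ww_minor"][0]),
        ww_major=int(c["ww_major"][0]),
        ss_minor=int(c["ss_minor"][0]),
        ss_major=int(c["ss_major"][0]),
    )


def classify_counts(
    ww_minor, ww_major, ss_minor, ss_major, coef: float = DEFAULT_COEF
) -> np.ndarray:
    """Vectorised four-way pattern assignment from raw counts.

    Ties sit on the >= / <= branches exactly as the classification table
    prints them; a consequence is that homopolymer-like fragments (all
    counts tied at capacity on one side) fall into Type 1.
    """
    ww_pref_minor = np.asarray(ww_minor) >= np.asarray(ww_major) * coef
    ss_pref_minor = np.asarray(ss_minor) > np.asarray(ss_major) * coef
    # (True, False)->1  (True, True)->2  (False, False)->3  (False, True)->4
    return np.where(ww_pref_minor, np.where(ss_pref_minor, 2, 1), np.where(ss_pref_minor, 4, 3))


def classify_fragment(counts: PatternCounts, coef: float = DEFAULT_COEF) -> int:
    """Assign the rotational pattern type (1-4) for one fragment's counts."""
    return int(classify_counts(counts.ww_minor, counts.ww_major, counts.ss_minor, counts.ss_major, coef))


def classify_fragments(
    fragments: Sequence[NCPFragment] | np.ndarray,
    gbs_map: GBSMap,
    coef: float | None = None,
) -> np.ndarray:
    """Type labels (1-4) for a fragment collection (or code matrix)."""
    if coef is None:
        coef = gbs_map.capacity_ratio
    codes = _as_code_matrix(fragments)
    c = count_batch(codes, gbs_map)
    return classify_counts(c["ww_minor"], c["ww_major"], c["ss_minor"], c["ss_major"], coef)


def summarize_types(types: np.ndarray) -> NPSSummary:
    """NPSSummary from an array of type labels."""
    types = np.asarray(types)
    n = types.size
    if n == 0:
        raise EmptyInputError("cannot summarise an empty fragment collection")
    fractions = tuple(100.0 * np.count_nonzero(types == t) / n for t in (1, 2, 3, 4))
    return NPSSummary(n_fragments=int(n), fraction_type=fractions)


def summarize(
    fragments: Sequence[NCPFragment] | np.ndarray,
    gbs_map: GBSMap,
    coef: float | None = None,
) -> NPSSummary:
    """Type fractions (%) and dNPS for a fragment collection."""
    if not isinstance(fragments, np.ndarray) and len(fragments) == 0:
        raise EmptyInputError("cannot summarise an empty fragment collection")
    return summarize_types(classify_fragments(fragments, gbs_map, coef))


def _running_mean(x: np.ndarray, window: int) -> np.ndarray:
    # centred running mean; edges use the positions actually available so a
    # symmetric input stays exactly symmetric
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = len(x)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def dyad_frequency_profile(
    fragments: Sequence[NCPFragment] | np.ndarray, smooth_window: int = 3
) -> DyadFrequencyProfile:
    """Dyad-symmetrized WW/SS frequency per dinucleotide position.

    The raw frequency at position i is the fraction of fragments whose
    dinucleotide (i, i+1) is WW (resp. SS).  Symmetrization averages i with
    145-i, then a centred running mean of width ``smooth_window`` is applied.
    """
    if smooth_window % 2 == 0 or smooth_window < 1:
        raise ValueError("smooth_window must be a positive odd integer")
    codes = _as_code_matrix(fragments)
    if codes.shape[0] == 0:
        raise EmptyInputError("cannot profile an empty fragment collection")
    ww_raw = _seq.ww_starts(codes).mean(axis=0)
    ss_raw = _seq.ss_starts(codes).mean(axis=0)
    out = {}
    for name, raw in (("ww", ww_raw), ("ss", ss_raw)):
        sym = 0.5 * (raw + raw[::-1])
        out[name] = _running_mean(sym, smooth_window)
    return DyadFrequencyProfile(
        position=np.arange(NCP_LEN - 1),
        ww_freq=out["ww"],
        ss_freq=out["ss"],
        ww_raw=ww_raw,
        ss_raw=ss_raw,
        smoothing=smooth_window,
    )
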