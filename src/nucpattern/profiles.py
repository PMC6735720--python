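"""TSS-aligned occupancy and dNPS profiles, repeat-family summaries, strain comparison.

Genes are stratified into expression quartiles; nucleosome fragments are
assigned to TSS-anchored zones (-1, +1 ... +5) by their dyad position, and
each zone's Type 1-4 composition and dNPS are compared with the genomic
background.  Repeat-family summaries assign fragments to repeat elements by
midpoint; strain comparison computes per-chromosome dNPS and a two-sample
Student's t-test against a reference strain.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from ._seq import DYAD_INDEX, NCP_LEN
from .classify import NCPFragment, NPSSummary, classify_fragments, summarize_types
from .genomic_io import GeneRecord, REPEAT_FAMILIES, RepeatElement
from .geometry import GBSMap

logger = logging.getLogger(__name__)

QUARTILE_LABELS = ("1", "2", "3", "4", "all")
UNASSIGNED_FAMILY = "genic/other"

#: fragment-to-family priority when elements nest (most specific first)
DEFAULT_FAMILY_PRIORITY = ("Simple Repeat", "SINE", "LINE", "LTR", "Other")


@dataclass(frozen=True)
class NucleosomeZone:
    """A TSS-relative half-open offset range to which fragment dyads map."""

    label: str
    lo: int
    hi: int

    def __post_init__(self):
        if self.lo >= self.hi:
            raise ValueError(f"zone {self.label}: lo must be < hi")


def _zones(spacing: int) -> tuple[NucleosomeZone, ...]:
    zones = [NucleosomeZone("-1", -300, -80), NucleosomeZone("+1", -80, 120)]
    lo = 120
    for i in range(2, 6):
        zones.append(NucleosomeZone(f"+{i}", lo, lo + spacing))
        lo += spacing
    return tuple(zones)


#: yeast-like preset: 165-bp repeat length downstream of the +1 nucleosome
ZONES_YEAST = _zones(165)
#: mammal-like preset: wider ~185-bp repeat length
ZONES_MAMMAL = _zones(185)


def zone_preset(name: str) -> tuple[NucleosomeZone, ...]:
    presets = {"yeast": ZONES_YEAST, "mammal": ZONES_MAMMAL}
    if name not in presets:
        raise ValueError(f"unknown zone preset {name!r}; expected one of {sorted(presets)}")
    return presets[name]


def validate_zones(zones: Sequence[NucleosomeZone]) -> None:
    ordered = sorted(zones, key=lambda z: z.lo)
    for a, b in zip(ordered, ordered[1:]):
        if a.hi > b.lo:
            raise ValueError(f"zones {a.label} and {b.label} overlap")


def assign_quartiles(genes: Sequence[GeneRecord]) -> dict[str, int]:
    """Rank-based expression quartiles; 1 = least expressed, 4 = most.

    Ties are broken stably by (expression, gene_id) so assignment is
    deterministic.  All-identical expression values cannot be stratified
    and raise.
    """
    if len(genes) < 4:
        raise ValueError("need at least 4 genes to form quartiles")
    if len({g.expression for g in genes}) == 1:
        raise ValueError("all genes have identical expression; quartiles are undefined")
    ordered = sorted(genes, key=lambda g: (g.expression, g.gene_id))
    n = len(ordered)
    return {g.gene_id: 1 + (rank * 4) // n for rank, g in enumerate(ordered)}


@dataclass
class TSSProfileMatrix:
    """Mean per-gene fragment coverage at each TSS-relative offset."""

    offsets: np.ndarray
    occupancy: dict[str, np.ndarray]  # quartile label ('1'..'4', 'all') -> array
    n_genes: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"offset": self.offsets})
        for label in QUARTILE_LABELS:
            if label in self.occupancy:
                df[f"q{label}"] = self.occupancy[label]
        return df


def _fragments_by_chrom(fragments: Sequence[NCPFragment]):
    by_chrom: dict[str, list[NCPFragment]] = defaultdict(list)
    for f in fragments:
        by_chrom[f.chrom].append(f)
    return by_chrom


def occupancy_profile(
    fragments: Sequence[NCPFragment],
    genes: Sequence[GeneRecord],
    window: int = 1000,
    quartiles: Mapping[str, int] | None = None,
) -> TSSProfileMatrix:
    """Mean fragment-body coverage per bp per gene, +/- window around the TSS.

    Coverage at a TSS-relative offset counts the 147-bp fragment bodies
    overlapping it; minus-strand genes are flipped so downstream is
    positive.  Averages are reported per expression quartile and overall.
    """
    if quartiles is None:
        quartiles = assign_quartiles(genes)
    width = 2 * window + 1
    by_chrom = _fragments_by_chrom(fragments)
    # per-chromosome body coverage via the difference-array trick
    cov: dict[str, np.ndarray] = {}
    for chrom, frags in by_chrom.items():
        span = max(max(f.end for f in frags), max((g.tss for g in genes if g.chrom == chrom), default=0) + window + 2)
        diff = np.zeros(span + 1, dtype=np.float64)
        for f in frags:
            diff[f.start] += 1
            diff[f.end] -= 1
        cov[chrom] = np.cumsum(diff)[:-1]
    sums = {label: np.zeros(width) for label in QUARTILE_LABELS}
    counts = {label: 0 for label in QUARTILE_LABELS}
    any_cov = False
    for g in genes:
        track = cov.get(g.chrom)
        gene_cov = np.zeros(width)
        if track is not None:
            lo, hi = g.tss - window, g.tss + window + 1
            s, e = max(0, lo), min(len(track), hi)
            if s < e:
                gene_cov[s - lo : e - lo] = track[s:e]
                any_cov = any_cov or bool(gene_cov.any())
        if g.strand == "-":
            gene_cov = gene_cov[::-1]
        for label in (str(quartiles[g.gene_id]), "all"):
            sums[label] += gene_cov
            counts[label] += 1
    if not any_cov:
        logger.warning("occupancy_profile: no fragment overlaps any gene window; profile is all zero")
    occupancy = {
        label: (sums[label] / counts[label] if counts[label] else np.zeros(width))
        for label in QUARTILE_LABELS
    }
    return TSSProfileMatrix(offsets=np.arange(-window, window + 1), occupancy=occupancy, n_genes=counts)


@dataclass
class ZoneDNPSResult:
    """Per-zone, per-quartile type composition against the genomic reference."""

    zones: tuple[NucleosomeZone, ...]
    summaries: dict[str, dict[str, NPSSummary | None]]  # zone label -> quartile label -> summary
    genomic: NPSSummary
    #: mean over zones of (all-gene zone dNPS - genomic dNPS)
    mean_zone_deviation: float

    def zone_dnps(self, label: str, quartile: str = "all") -> float | None:
        s = self.summaries[label][quartile]
        return None if s is None else s.dnps

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for zone in self.zones:
            for q in QUARTILE_LABELS:
                s = self.summaries[zone.label][q]
                row = {"zone": zone.label, "zone_lo": zone.lo, "zone_hi": zone.hi, "quartile": q}
                if s is None:
                    row.update({"n_fragments": 0})
                else:
                    row.update(s.as_dict())
                rows.append(row)
        df = pd.DataFrame(rows)
        df.attrs["genomic_dnps_pct"] = self.genomic.dnps
        return df


def zone_dnps(
    fragments: Sequence[NCPFragment],
    genes: Sequence[GeneRecord],
    zones: Sequence[NucleosomeZone] = ZONES_YEAST,
    gbs_map: GBSMap | None = None,
    coef: float | None = None,
    quartiles: Mapping[str, int] | None = None,
) -> ZoneDNPSResult:
    """Type composition and dNPS per nucleosome zone and expression quartile.

    A fragment belongs to a gene's zone iff its dyad (start + 73), expressed
    as a strand-corrected TSS offset, falls in the zone's half-open range.
    The genomic reference summary is computed over all input fragments.
    """
    if gbs_map is None:
        raise ValueError("gbs_map is required")
    validate_zones(zones)
    if quartiles is None:
        quartiles = assign_quartiles(genes)
    types = classify_fragments(fragments, gbs_map, coef)
    genomic = summarize_types(types)

    by_chrom: dict[str, list[int]] = defaultdict(list)
    for i, f in enumerate(fragments):
        by_chrom[f.chrom].append(i)
    dyads: dict[str, np.ndarray] = {}
    type_by_chrom: dict[str, np.ndarray] = {}
    for chrom, idx in by_chrom.items():
        idx = np.asarray(idx)
        d = np.array([fragments[i].dyad for i in idx])
        order = np.argsort(d)
        dyads[chrom] = d[order]
        type_by_chrom[chrom] = types[idx[order]]

    collected: dict[str, dict[str, list[np.ndarray]]] = {
        z.label: {q: [] for q in QUARTILE_LABELS} for z in zones
    }
    for g in genes:
        if g.chrom not in dyads:
            continue
        d = dyads[g.chrom]
        t = type_by_chrom[g.chrom]
        for zone in zones:
            if g.strand == "+":
                lo, hi = g.tss + zone.lo, g.tss + zone.hi
            else:
                # offset = tss - dyad in [lo, hi)  <=>  dyad in (tss-hi, tss-lo]
                lo, hi = g.tss - zone.hi + 1, g.tss - zone.lo + 1
            s, e = np.searchsorted(d, [lo, hi])
            if s < e:
                zone_types = t[s:e]
                collected[zone.label][str(quartiles[g.gene_id])].append(zone_types)
                collected[zone.label]["all"].append(zone_types)

    summaries: dict[str, dict[str, NPSSummary | None]] = {}
    deviations = []
    for zone in zones:
        summaries[zone.label] = {}
        for q in QUARTILE_LABELS:
            chunks = collected[zone.label][q]
            if not chunks:
                logger.warning("zone %s quartile %s: no fragments (n=0)", zone.label, q)
                summaries[zone.label][q] = None
            else:
                summaries[zone.label][q] = summarize_types(np.concatenate(chunks))
        all_summary = summaries[zone.label]["all"]
        if all_summary is not None:
            deviations.append(all_summary.dnps - genomic.dnps)
    mean_dev = float(np.mean(deviations)) if deviations else float("nan")
    return ZoneDNPSResult(
        zones=tuple(zones), summaries=summaries, genomic=genomic, mean_zone_deviation=mean_dev
    )


@dataclass
class RepeatOverlapResult:
    """Per-family fragment fraction and type composition."""

    summaries: dict[str, NPSSummary | None]  # family (incl. 'genic/other') -> summary
    fractions: dict[str, float]
    n_fragments: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for family, frac in self.fractions.items():
            s = self.summaries[family]
            row = {"family": family, "fraction": frac}
            row.update(s.as_dict() if s is not None else {"n_fragments": 0})
            rows.append(row)
        return pd.DataFrame(rows)


def repeat_overlap(
    fragments: Sequence[NCPFragment],
    repeats: Sequence[RepeatElement],
    gbs_map: GBSMap,
    min_len: int = 150,
    priority: Sequence[str] = DEFAULT_FAMILY_PRIORITY,
    coef: float | None = None,
) -> RepeatOverlapResult:
    """Assign fragments to repeat families by midpoint and summarise each.

    Only elements longer than ``min_len`` bp (about one nucleosome) are
    considered.  A fragment resides in a family if its midpoint (dyad) lies
    inside an element; nested elements are resolved by ``priority`` (most
    specific family wins).  Fragments in no element are pooled under
    ``'genic/other'``.
    """
    rank = {fam: i for i, fam in enumerate(priority)}
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for r in repeats:
        if r.length > min_len:
            trees[r.chrom].addi(r.start, r.end, r.family)
    types = classify_fragments(fragments, gbs_map, coef)
    assigned: dict[str, list[int]] = defaultdict(list)
    for i, f in enumerate(fragments):
        hits = trees[f.chrom][f.dyad] if f.chrom in trees else ()
        if hits:
            family = min((h.data for h in hits), key=lambda fam: rank.get(fam, len(rank)))
        else:
            family = UNASSIGNED_FAMILY
        assigned[family].append(i)
    n = len(fragments)
    families = list(REPEAT_FAMILIES) + [UNASSIGNED_FAMILY]
    summaries: dict[str, NPSSummary | None] = {}
    fractions: dict[str, float] = {}
    for family in families:
        idx = assigned.get(family, [])
        fractions[family] = len(idx) / n if n else 0.0
        summaries[family] = summarize_types(types[np.asarray(idx)]) if idx else None
    return RepeatOverlapResult(summaries=summaries, fractions=fractions, n_fragments=n)


@dataclass
class StrainComparisonResult:
    """Per-chromosome dNPS by strain with t-tests against the reference."""

    table: pd.DataFrame  # columns: strain, chrom, n_fragments, dnps_pct
    genomic_dnps: dict[str, float]  # strain -> mean over chromosomes
    tests: dict[str, tuple[float, float]]  # strain -> (t, p) vs reference
    mean_abs_deviation: float
    reference: str


def compare_strains(
    fragments_by_strain: Mapping[str, Sequence[NCPFragment]],
    gbs_map: GBSMap,
    reference: str = "WT",
    equal_var: bool = True,
    coef: float | None = None,
) -> StrainComparisonResult:
    """Per-chromosome dNPS per strain plus Student's t-test vs the reference.

    The genomic dNPS of a strain is the mean of its per-chromosome values
    (the box-plot mean).  ``equal_var=False`` switches to Welch's t-test.
    """
    if reference not in fragments_by_strain:
        raise ValueError(f"reference strain {reference!r} not among inputs")
    rows = []
    per_strain: dict[str, np.ndarray] = {}
    for strain, frags in fragments_by_strain.items():
        types = classify_fragments(frags, gbs_map, coef)
        chroms = sorted({f.chrom for f in frags})
        values = []
        for chrom in chroms:
            mask = np.array([f.chrom == chrom for f in frags])
            s = summarize_types(types[mask])
            rows.append(
                {"strain": strain, "chrom": chrom, "n_fragments": s.n_fragments, "dnps_pct": s.dnps}
            )
            values.append(s.dnps)
        per_strain[strain] = np.asarray(values)
    ref_values = per_strain[reference]
    if len(ref_values) < 2:
        raise ValueError("reference strain must cover at least 2 chromosomes")
    tests: dict[str, tuple[float, float]] = {}
    deviations = []
    genomic = {strain: float(np.mean(v)) for strain, v in per_strain.items()}
    for strain, values in per_strain.items():
        if strain == reference:
            continue
        deviations.append(abs(genomic[strain] - genomic[reference]))
        if len(values) < 2:
            logger.warning("strain %s has a single chromosome; t-test skipped", strain)
            continue
        t, p = stats.ttest_ind(values, ref_values, equal_var=equal_var)
        tests[strain] = (float(t), float(p))
    mad = float(np.mean(deviations)) if deviations else float("nan")
    return StrainComparisonResult(
        table=pd.DataFrame(rows),
        genomic_dnps=genomic,
        tests=tests,
        mean_abs_deviation=mad,
        reference=reference,
    )
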