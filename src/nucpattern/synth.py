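"""Synthetic genomes with planted rotational-positioning structure.

The generator emulates the features the analysis assumes so that every
pipeline stage can be tested against known ground truth:

* ~10-bp periodic WW/SS placement inside groove-bending sites, with a
  controllable planting strength and all four pattern types;
* phased nucleosome arrays around TSSs behind a nucleosome-depleted region
  (NDR), with genes stratified by an RPKM-like expression value;
* a mammal-like regime in which anti-WW/SS (Type 4) nucleosomes are
  enriched in the TSS-proximal zones in proportion to expression quartile,
  while sequences carry no positional periodicity (they are drawn by
  rejection sampling rather than slot planting);
* a non-mammal regime in which genic zones share the genomic type mixture
  and genic DNA carries the periodic WW/SS signal;
* a remodeler-mutant regime that uniformly boosts the Type-4 fraction
  without changing the spatial profile;
* repeat elements carrying a Type-1-enriched, periodicity-planted mixture.

Identical config + seed gives byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _seq
from ._seq import DYAD_INDEX, NCP_LEN
from .classify import NCPFragment, classify_fragments
from .genomic_io import GeneRecord, RepeatElement, write_fasta
from .geometry import GBSMap, build_gbs_map
from .profiles import NucleosomeZone, assign_quartiles, zone_preset

_W_BASES = np.array([_seq.A, _seq.T], dtype=np.uint8)
_S_BASES = np.array([_seq.C, _seq.G], dtype=np.uint8)

#: genomic type mixtures (Type 1..4) per regime
MIXTURE_NON_MAMMAL = (0.45, 0.21, 0.09, 0.25)  # genomic dNPS ~ 20%
MIXTURE_MAMMAL = (0.47, 0.21, 0.13, 0.19)  # genomic dNPS ~ 28%
MIXTURE_REPEAT = (0.55, 0.20, 0.10, 0.15)  # Type-1 enriched, dNPS ~ 40%

#: mammal regime: mean Type1 -> Type4 probability shift per zone (scaled by
#: expression quartile q/2.5, so the quartile mean equals the listed value)
ZONE_TYPE4_SHIFT = {"-1": 0.03, "+1": 0.07, "+2": 0.05, "+3": 0.04, "+4": 0.035, "+5": 0.03}

DEFAULT_FAMILY_MIX = {"SINE": 0.40, "LINE": 0.30, "LTR": 0.15, "Simple Repeat": 0.10, "Other": 0.05}


class SizingError(ValueError):
    """The requested genes do not fit into the requested genome."""


@dataclass
class SynthConfig:
    """Study-level knobs; defaults define the standard synthetic conditions."""

    seed: int = 0
    mode: str = "non_mammal"  # 'non_mammal' | 'mammal' | 'remodeler_mutant'
    genome_length: int = 4_000_000
    n_chromosomes: int = 16  # yeast-like karyotype; per-chromosome dNPS statistics
    gc_content: float = 0.5
    n_genes: int = 1000
    nucleosome_spacing: int | None = None  # 165 bp (non-mammal) / 185 bp (mammal)
    ndr_width: int = 200
    phasing_strength: float = 0.9
    mixture: tuple[float, float, float, float] | None = None
    zone_type4_shift: dict[str, float] = field(default_factory=lambda: dict(ZONE_TYPE4_SHIFT))
    type4_boost: float = 0.0165  # remodeler-mutant regime only
    repeat_fraction: float | None = None  # 0.05 (non-mammal) / 0.15 (mammal)
    family_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FAMILY_MIX))
    repeat_mixture: tuple[float, float, float, float] = MIXTURE_REPEAT
    dyad_jitter_sd: float = 0.0
    # background (non-genic) nucleosomes dominate the genomic reference, as
    # the TSS-proximal -1..+5 set is a small minority of a real genome
    n_background_fragments: int = 8000

    def __post_init__(self):
        if self.mode not in ("non_mammal", "mammal", "remodeler_mutant"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.phasing_strength <= 1.0:
            raise ValueError("phasing_strength must lie in [0, 1]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie in (0, 1)")
        if self.nucleosome_spacing is None:
            self.nucleosome_spacing = 185 if self.mode == "mammal" else 165
        if self.repeat_fraction is None:
            # repeat content scales with the regime: low in compact
            # yeast-like genomes, higher in mammal-like ones
            self.repeat_fraction = 0.15 if self.mode == "mammal" else 0.05
        if self.mixture is None:
            base = MIXTURE_MAMMAL if self.mode == "mammal" else MIXTURE_NON_MAMMAL
            if self.mode == "remodeler_mutant":
                e = self.type4_boost
                base = (base[0] - e, base[1], base[2], base[3] + e)
            self.mixture = base
        if abs(sum(self.mixture) - 1.0) > 1e-9 or any(p < 0 for p in self.mixture):
            raise ValueError("mixture proportions must be non-negative and sum to 1")

    @property
    def zones(self) -> tuple[NucleosomeZone, ...]:
        return zone_preset("mammal" if self.mode == "mammal" else "yeast")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mixture"] = list(self.mixture)
        d["repeat_mixture"] = list(self.repeat_mixture)
        return d


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_codes(rng: np.random.Generator, shape, gc: float) -> np.ndarray:
    return rng.choice(4, size=shape, p=_base_probs(gc)).astype(np.uint8)


def _site_base_plan(gbs_map: GBSMap) -> dict[int, dict[str, np.ndarray]]:
    """Per-type planting plan: positions to set W, to set S, and to alternate."""
    minor_pos, major_pos = [], []
    minor_pos_by_sign, major_pos_by_sign = {1: [], -1: []}, {1: [], -1: []}
    for s in gbs_map.sites:
        pos = list(range(s.start, s.end))
        sign = 1 if s.shl > 0 else -1
        if s.groove == "minor":
            minor_pos.extend(pos)
            minor_pos_by_sign[sign].extend(pos)
        else:
            major_pos.extend(pos)
            major_pos_by_sign[sign].extend(pos)
    alt_minor_w = [p for s in gbs_map.minor_sites for p in range(s.start, s.end) if (p - s.start) % 2 == 0]
    alt_minor_s = [p for s in gbs_map.minor_sites for p in range(s.start, s.end) if (p - s.start) % 2 == 1]
    alt_major_w = [p for s in gbs_map.major_sites for p in range(s.start, s.end) if (p - s.start) % 2 == 0]
    alt_major_s = [p for s in gbs_map.major_sites for p in range(s.start, s.end) if (p - s.start) % 2 == 1]
    arr = lambda x: np.asarray(sorted(x), dtype=np.intp)
    return {
        # type 1: WW in minor sites, SS in major sites
        1: {"w": arr(minor_pos), "s": arr(major_pos)},
        # type 2: both classes in minor sites (positive-SHL W, negative-SHL S);
        # major sites alternate W/S so their internal dinucleotides are neither
        2: {"w": arr(minor_pos_by_sign[1] + alt_major_w), "s": arr(minor_pos_by_sign[-1] + alt_major_s)},
        # type 3: both classes in major sites; minor sites alternate
        3: {"w": arr(major_pos_by_sign[1] + alt_minor_w), "s": arr(major_pos_by_sign[-1] + alt_minor_s)},
        # type 4: anti pattern — SS in minor sites, WW in major sites
        4: {"w": arr(major_pos), "s": arr(minor_pos)},
    }


def planted_fragment_batch(
    types: np.ndarray,
    strength: float,
    gbs_map: GBSMap,
    rng: np.random.Generator,
    gc: float = 0.5,
) -> np.ndarray:
    """(n, 147) code matrix with groove-slot planting at the given strength.

    Each base inside a groove-bending site is set to its planted letter set
    (W or S, drawn uniformly within the set) with probability ``strength``,
    otherwise left as iid background.  At strength 1 the classification of
    the output equals the requested type.
    """
    types = np.asarray(types)
    n = types.size
    codes = _random_codes(rng, (n, NCP_LEN), gc)
    plan = _site_base_plan(gbs_map)
    # pre-draw per-base coins and letters for determinism regardless of type mix
    keep = rng.random((n, NCP_LEN)) < strength
    w_letters = _W_BASES[rng.integers(0, 2, size=(n, NCP_LEN))]
    s_letters = _S_BASES[rng.integers(0, 2, size=(n, NCP_LEN))]
    for t in (1, 2, 3, 4):
        rows = np.flatnonzero(types == t)
        if rows.size == 0:
            continue
        for kind, letters in (("w", w_letters), ("s", s_letters)):
            cols = plan[t][kind]
            sub = np.ix_(rows, cols)
            codes[sub] = np.where(keep[sub], letters[sub], codes[sub])
    return codes


def synth_fragment(
    pattern_type: int,
    strength: float,
    gbs_map: GBSMap | None = None,
    seed: int | np.random.Generator = 0,
    gc: float = 0.5,
) -> NCPFragment:
    """One synthetic 147-bp fragment with the requested planted pattern type."""
    if pattern_type not in (1, 2, 3, 4):
        raise ValueError("pattern_type must be 1..4")
    if gbs_map is None:
        gbs_map = build_gbs_map()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = planted_fragment_batch(np.array([pattern_type]), strength, gbs_map, rng, gc)[0]
    return NCPFragment(chrom="synth", start=0, sequence=_seq.decode(codes), source="mnase_147bp")


def rejection_fragment_batch(
    types: np.ndarray,
    gbs_map: GBSMap,
    rng: np.random.Generator,
    gc: float = 0.5,
    batch: int = 4096,
    max_batches: int = 2000,
) -> np.ndarray:
    """(n, 147) code matrix of iid-background sequences conditioned on type.

    Sequences are drawn uniformly at the configured GC and kept when they
    classify as the requested type, so the output carries the requested
    composition but no positional periodicity beyond what the type itself
    implies (the mammal-like regime).
    """
    types = np.asarray(types)
    need = {t: int(np.count_nonzero(types == t)) for t in (1, 2, 3, 4)}
    buckets: dict[int, list[np.ndarray]] = {t: [] for t in (1, 2, 3, 4)}
    have = {t: 0 for t in (1, 2, 3, 4)}
    for _ in range(max_batches):
        if all(have[t] >= need[t] for t in need):
            break
        draw = _random_codes(rng, (batch, NCP_LEN), gc)
        labels = classify_fragments(draw, gbs_map)
        for t in (1, 2, 3, 4):
            if have[t] < need[t]:
                rows = draw[labels == t]
                buckets[t].append(rows)
                have[t] += len(rows)
    else:
        raise RuntimeError("rejection sampling did not converge; check gc_content")
    pools = {t: (np.concatenate(buckets[t])[: need[t]] if need[t] else np.empty((0, NCP_LEN), np.uint8)) for t in need}
    out = np.empty((types.size, NCP_LEN), dtype=np.uint8)
    used = {t: 0 for t in need}
    for i, t in enumerate(types):
        out[i] = pools[int(t)][used[int(t)]]
        used[int(t)] += 1
    return out


@dataclass
class SynthStudy:
    """In-memory synthetic study: genome, fragments, annotation and truth."""

    config: SynthConfig
    genome_codes: dict[str, np.ndarray]
    fragment_rows: list[tuple[str, int, int, int]]  # chrom, start, end, planted type
    genes: list[GeneRecord]
    repeats: list[RepeatElement]
    truth: dict

    @property
    def genome(self) -> dict[str, str]:
        return {name: _seq.decode(codes) for name, codes in self.genome_codes.items()}

    def fragments(self) -> list[NCPFragment]:
        """Fragments with sequences read from the genome at reported coords."""
        out = []
        for chrom, start, end, _t in self.fragment_rows:
            seq = _seq.decode(self.genome_codes[chrom][start:end])
            out.append(NCPFragment(chrom=chrom, start=start, sequence=seq))
        return out

    def fragments_by_strain(self) -> dict[str, list[NCPFragment]]:
        return {self.truth["strain"]: self.fragments()}

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write genome.fa, fragments.bed, genes.tsv, repeats.tsv, truth.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fa",
            "fragments": out / "fragments.bed",
            "genes": out / "genes.tsv",
            "repeats": out / "repeats.tsv",
            "truth": out / "truth.json",
        }
        write_fasta(paths["genome"], self.genome)
        with open(paths["fragments"], "w") as fh:
            for chrom, start, end, t in self.fragment_rows:
                fh.write(f"{chrom}\t{start}\t{end}\ttype{t}\n")
        with open(paths["genes"], "w") as fh:
            fh.write("gene_id\tchrom\ttss\tstrand\texpression\n")
            for g in self.genes:
                fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\t{g.expression!r}\n")
        with open(paths["repeats"], "w") as fh:
            fh.write("chrom\tstart\tend\tfamily\tsubfamily\n")
            for r in self.repeats:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.family}\t{r.subfamily}\n")
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def _zone_mixture(cfg: SynthConfig, zone_label: str, quartile: int) -> tuple:
    """Type mixture for a genic nucleosome in one zone of one gene."""
    p1, p2, p3, p4 = cfg.mixture
    if cfg.mode == "mammal":
        shift = cfg.zone_type4_shift.get(zone_label, 0.0) * quartile / 2.5
        shift = min(shift, p1)
        p1, p4 = p1 - shift, p4 + shift
    return (p1, p2, p3, p4)


def synth_study(config: SynthConfig | None = None, out_dir: str | Path | None = None) -> SynthStudy:
    """Generate a full synthetic study under one seed.

    Genes are laid out in fixed-width slots with an NDR at the TSS and a
    phased array of six nucleosomes (-1, +1 ... +5) whose dyads sit inside
    the corresponding analysis zones; the remainder of each chromosome
    carries background nucleosomes at the genomic type mixture, a fraction
    of which fall inside generated repeat elements.  Returns the study in
    memory; ``out_dir`` additionally writes FASTA/BED/TSV plus truth.json.
    """
    cfg = config if config is not None else SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    gbs_map = build_gbs_map()
    spacing = cfg.nucleosome_spacing
    zones = cfg.zones
    zone_labels = [z.label for z in zones]
    # dyad offsets placed mid-zone: -1 sits one nucleosome + NDR upstream of +1
    dyad_offsets = [60 - NCP_LEN - cfg.ndr_width] + [60 + k * spacing for k in range(5)]
    half_slot = 60 + 4 * spacing + DYAD_INDEX + 80
    slot = 2 * half_slot
    pad = 1100  # keeps +/-1kb TSS windows of edge genes on-contig

    n_chrom = cfg.n_chromosomes
    chrom_len = cfg.genome_length // n_chrom
    genes_per_chrom = [cfg.n_genes // n_chrom + (1 if i < cfg.n_genes % n_chrom else 0) for i in range(n_chrom)]
    for i, gpc in enumerate(genes_per_chrom):
        if gpc * slot + 2 * pad + 10_000 > chrom_len:
            raise SizingError(
                f"chromosome {i + 1}: {gpc} gene slots of {slot} bp do not fit into {chrom_len} bp"
            )

    genome_codes: dict[str, np.ndarray] = {}
    genes: list[GeneRecord] = []
    repeats: list[RepeatElement] = []
    fragment_rows: list[tuple[str, int, int, int]] = []

    # expression values drawn once for all genes (RPKM-like, heavy-tailed)
    expression = rng.lognormal(mean=1.0, sigma=2.0, size=cfg.n_genes)
    gene_idx = 0
    gene_meta: list[tuple[str, int, str, int]] = []  # chrom, tss, strand, index

    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        codes = _random_codes(rng, chrom_len, cfg.gc_content)
        genome_codes[chrom] = codes
        for gi in range(genes_per_chrom[ci]):
            tss = pad + gi * slot + half_slot
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"gene{gene_idx + 1:05d}"
            genes.append(GeneRecord(gene_id=gid, chrom=chrom, tss=tss, strand=strand, expression=float(expression[gene_idx])))
            gene_meta.append((chrom, tss, strand, gene_idx))
            gene_idx += 1

    quartiles = assign_quartiles(genes)

    # --- genic nucleosome arrays -------------------------------------------
    genic_types: list[int] = []
    genic_pos: list[tuple[str, int]] = []  # chrom, planted fragment start
    for (chrom, tss, strand, gi), gene in zip(gene_meta, genes):
        q = quartiles[gene.gene_id]
        for zone_label, off in zip(zone_labels, dyad_offsets):
            dyad = tss + off if strand == "+" else tss - off
            probs = _zone_mixture(cfg, zone_label, q)
            t = int(rng.choice(4, p=probs)) + 1
            genic_types.append(t)
            genic_pos.append((chrom, dyad - DYAD_INDEX))
    genic_types_arr = np.asarray(genic_types)
    if cfg.mode == "mammal":
        genic_seqs = rejection_fragment_batch(genic_types_arr, gbs_map, rng, cfg.gc_content)
    else:
        genic_seqs = planted_fragment_batch(genic_types_arr, cfg.phasing_strength, gbs_map, rng, cfg.gc_content)

    # --- background region: repeats + background nucleosomes ---------------
    bg_types: list[int] = []
    bg_pos: list[tuple[str, int]] = []
    bg_is_repeat: list[bool] = []
    families = list(cfg.family_mix)
    fam_probs = np.array([cfg.family_mix[f] for f in families])
    fam_probs = fam_probs / fam_probs.sum()
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        bg_start = pad + genes_per_chrom[ci] * slot + 1000
        bg_len = chrom_len - bg_start - 1000
        # carve repeat elements covering the target fraction, spread over the
        # whole background region by randomly apportioning the gap budget
        target = cfg.repeat_fraction * bg_len
        lengths = []
        while sum(lengths) < target:
            lengths.append(int(rng.integers(300, 2000)))
        gap_budget = max(bg_len - sum(lengths) - 2000, 0)
        weights = rng.random(len(lengths) + 1)
        gaps = np.floor(weights / weights.sum() * gap_budget).astype(int)
        cursor = bg_start
        for length, gap in zip(lengths, gaps):
            cursor += int(gap)
            if cursor + length > chrom_len - 2000:
                break
            family = families[int(rng.choice(len(families), p=fam_probs))]
            repeats.append(RepeatElement(chrom=chrom, start=cursor, end=cursor + length, family=family, subfamily="synthetic"))
            cursor += length
        # a few sub-threshold elements to exercise the >150-bp selection rule
        for _ in range(3):
            pos = int(rng.integers(bg_start, chrom_len - 2000))
            repeats.append(RepeatElement(chrom=chrom, start=pos, end=pos + 140, family="Other", subfamily="synthetic-short"))
        repeat_lookup = sorted((r.start, r.end) for r in repeats if r.chrom == chrom and r.length > 150)
        starts = np.array([s for s, _ in repeat_lookup])
        ends = np.array([e for _, e in repeat_lookup])

        n_bg = cfg.n_background_fragments // n_chrom
        grid = np.arange(bg_start, chrom_len - NCP_LEN - 1000, NCP_LEN + 20)
        if len(grid) > n_bg:  # spread evenly across the whole background
            take = grid[np.linspace(0, len(grid) - 1, n_bg).round().astype(int)]
        else:
            take = grid
        for start in take:
            dyad = int(start) + DYAD_INDEX
            j = np.searchsorted(starts, dyad, side="right") - 1
            inside = j >= 0 and dyad < ends[j]
            mix = cfg.repeat_mixture if inside else cfg.mixture
            t = int(rng.choice(4, p=np.asarray(mix))) + 1
            bg_types.append(t)
            bg_pos.append((chrom, int(start)))
            bg_is_repeat.append(bool(inside))
    bg_types_arr = np.asarray(bg_types)
    bg_repeat_mask = np.asarray(bg_is_repeat)
    bg_seqs = np.empty((len(bg_types), NCP_LEN), dtype=np.uint8)
    # repeat nucleosomes always carry the planted (periodic) signal
    if bg_repeat_mask.any():
        bg_seqs[bg_repeat_mask] = planted_fragment_batch(
            bg_types_arr[bg_repeat_mask], cfg.phasing_strength, gbs_map, rng, cfg.gc_content
        )
    nonrep = ~bg_repeat_mask
    if nonrep.any():
        if cfg.mode == "mammal":
            bg_seqs[nonrep] = rejection_fragment_batch(bg_types_arr[nonrep], gbs_map, rng, cfg.gc_content)
        else:
            bg_seqs[nonrep] = planted_fragment_batch(
                bg_types_arr[nonrep], cfg.phasing_strength, gbs_map, rng, cfg.gc_content
            )

    # --- plant into the genome and emit fragment intervals -----------------
    all_pos = genic_pos + bg_pos
    all_types = np.concatenate([genic_types_arr, bg_types_arr])
    all_seqs = np.concatenate([genic_seqs, bg_seqs])
    jitter = (
        np.rint(rng.normal(0.0, cfg.dyad_jitter_sd, size=len(all_pos))).astype(int)
        if cfg.dyad_jitter_sd > 0
        else np.zeros(len(all_pos), dtype=int)
    )
    for (chrom, start), seq, t, dj in zip(all_pos, all_seqs, all_types, jitter):
        genome_codes[chrom][start : start + NCP_LEN] = seq
        rstart = int(np.clip(start + dj, 0, chrom_len - NCP_LEN))
        fragment_rows.append((chrom, rstart, rstart + NCP_LEN, int(t)))

    strain = {"non_mammal": "WT", "mammal": "WT", "remodeler_mutant": "remodeler-mutant"}[cfg.mode]
    truth = {
        "config": cfg.to_dict(),
        "strain": strain,
        "zone_labels": zone_labels,
        "dyad_offsets": dyad_offsets,
        "quartiles": quartiles,
        "n_genic_fragments": len(genic_pos),
        "n_background_fragments": len(bg_pos),
        "n_repeat_fragments": int(bg_repeat_mask.sum()),
        "planted_genomic_dnps_pct": 100.0 * (cfg.mixture[0] - cfg.mixture[3]),
        "planted_repeat_dnps_pct": 100.0 * (cfg.repeat_mixture[0] - cfg.repeat_mixture[3]),
        "zone_type4_shift": cfg.zone_type4_shift if cfg.mode == "mammal" else {},
    }
    study = SynthStudy(
        config=cfg,
        genome_codes=genome_codes,
        fragment_rows=fragment_rows,
        genes=genes,
        repeats=repeats,
        truth=truth,
    )
    if out_dir is not None:
        study.write(out_dir)
    return study
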