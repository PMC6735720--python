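"""Readers and writers for genomes, fragments, genes, repeats and result tables.

All internal coordinates are 0-based half-open.  BED-style inputs are
consumed as-is; 1-based dyad tables (chemical-map convention) are converted
at the boundary.  A dyad at 0-based position p expands to the interval
[p - 73, p + 74) so the dyad is frame index 73 of the 147-bp fragment.
"""
from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from pyfaidx import Fasta

from ._seq import DYAD_INDEX, NCP_LEN
from .classify import NCPFragment, NPSSummary

logger = logging.getLogger(__name__)

REPEAT_FAMILIES = ("SINE", "LINE", "LTR", "Simple Repeat", "Other")

_VALID_BASES = frozenset("ACGT")


class ParseError(ValueError):
    """Malformed input table (message carries the offending line number)."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene: TSS position (0-based), strand and an RPKM-like expression value."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    expression: float

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if self.expression < 0:
            raise ValueError(f"gene {self.gene_id}: negative expression")


@dataclass(frozen=True)
class RepeatElement:
    """One repeat-masked interval with its family label."""

    chrom: str
    start: int
    end: int
    family: str
    subfamily: str = ""

    def __post_init__(self):
        if self.end - self.start < 1:
            raise ValueError("repeat element must span at least 1 bp")
        if self.family not in REPEAT_FAMILIES:
            raise ValueError(f"unknown repeat family {self.family!r}; expected one of {REPEAT_FAMILIES}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FragmentIngest:
    """Accepted fragments plus per-reason skip counts from one read pass."""

    fragments: list[NCPFragment] = field(default_factory=list)
    skipped: Counter = field(default_factory=Counter)


def load_genome(path: str | Path) -> Fasta:
    """Open an (uncompressed) FASTA with random access."""
    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


def _fetch(genome, chrom: str, start: int, end: int) -> str | None:
    if chrom not in genome:
        raise KeyError(f"contig {chrom!r} not found in genome FASTA")
    if start < 0 or end > len(genome[chrom]):
        return None
    return str(genome[chrom][start:end])


def read_fragments(
    path: str | Path,
    genome,
    mode: str = "interval_147",
    dyad_one_based: bool = True,
) -> FragmentIngest:
    """Read nucleosome fragments as 147-bp intervals (BED) or dyad positions.

    ``interval_147`` mode expects BED3+ rows and keeps only rows with
    end - start == 147; ``dyad`` mode expects (chrom, position) rows and
    expands each dyad to [dyad - 73, dyad + 74).  Rows are skipped (and
    counted by reason) when the interval has the wrong length, runs out of
    contig bounds, or the sequence contains non-ACGT bases.  A missing
    contig is a hard error.
    """
    if mode not in ("interval_147", "dyad"):
        raise ValueError(f"unknown mode {mode!r}")
    result = FragmentIngest()
    source = "mnase_147bp" if mode == "interval_147" else "chemical_dyad"
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if mode == "interval_147":
                if len(parts) < 3:
                    raise ParseError(f"{path}:{lineno}: expected at least 3 BED columns")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                if end - start != NCP_LEN:
                    result.skipped["length"] += 1
                    continue
            else:
                if len(parts) < 2:
                    raise ParseError(f"{path}:{lineno}: expected chrom and dyad position")
                chrom, dyad = parts[0], int(parts[1])
                if dyad_one_based:
                    dyad -= 1
                start, end = dyad - DYAD_INDEX, dyad - DYAD_INDEX + NCP_LEN
            seq = _fetch(genome, chrom, start, end)
            if seq is None:
                result.skipped["out_of_bounds"] += 1
                continue
            if not _VALID_BASES.issuperset(seq):
                result.skipped["n_content"] += 1
                continue
            result.fragments.append(NCPFragment(chrom=chrom, start=start, sequence=seq, source=source))
    if result.skipped:
        logger.info("read_fragments %s: skipped %s", path, dict(result.skipped))
    return result


_GENE_COLUMNS = ("gene_id", "chrom", "tss", "strand", "expression")


def read_genes(path: str | Path) -> list[GeneRecord]:
    """Read a tab-delimited gene table (gene_id, chrom, tss, strand, expression)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False), 2):  # header is line 1
        try:
            rec = GeneRecord(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                tss=int(row.tss),
                strand=str(row.strand),
                expression=float(row.expression),
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}:{idx}: {exc}") from exc
        if rec.gene_id in seen:
            raise ParseError(f"{path}:{idx}: duplicate gene_id {rec.gene_id!r}")
        seen.add(rec.gene_id)
        genes.append(rec)
    return genes


def read_repeats(path: str | Path, column_map: dict | None = None) -> list[RepeatElement]:
    """Read a tab-delimited repeat table (chrom, start, end, family[, subfamily]).

    ``column_map`` renames RepeatMasker-style headers onto the expected
    names, e.g. ``{"genoName": "chrom", "repClass": "family"}``.  Elements
    of any length are retained here; the >150-bp selection rule is applied
    downstream at analysis time.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        df = df.rename(columns=column_map)
    required = {"chrom", "start", "end", "family"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    repeats: list[RepeatElement] = []
    for idx, row in enumerate(df.itertuples(index=False), 2):
        try:
            repeats.append(
                RepeatElement(
                    chrom=str(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    family=str(row.family),
                    subfamily=str(getattr(row, "subfamily", "")),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}:{idx}: {exc}") from exc
    return repeats


def write_type_table(path: str | Path, fragments: Sequence[NCPFragment], counts, types) -> None:
    """Write the per-fragment classification table (TSV)."""
    df = pd.DataFrame(
        {
            "chrom": [f.chrom for f in fragments],
            "start": [f.start for f in fragments],
            "end": [f.end for f in fragments],
            "ww_minor": counts["ww_minor"],
            "ww_major": counts["ww_major"],
            "ss_minor": counts["ss_minor"],
            "ss_major": counts["ss_major"],
            "type": types,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_summary(path: str | Path, summary: NPSSummary) -> None:
    """Write an NPSSummary as JSON."""
    with open(path, "w") as fh:
        json.dump(summary.as_dict(), fh, indent=2)
        fh.write("\n")


def read_summary(path: str | Path) -> NPSSummary:
    with open(path) as fh:
        d = json.load(fh)
    return NPSSummary(
        n_fragments=int(d["n_fragments"]),
        fraction_type=tuple(float(d[f"type{i}_pct"]) for i in (1, 2, 3, 4)),
    )


def write_profile(path: str | Path, df: pd.DataFrame) -> None:
    """Write any tidy profile table (occupancy, correlation, zones) as TSV."""
    df.to_csv(path, sep="\t", index=False)


def read_profile(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fasta(path: str | Path, contigs: dict[str, str], width: int = 70) -> None:
    """Write contigs to FASTA (used by the synthetic-study writer)."""
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
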