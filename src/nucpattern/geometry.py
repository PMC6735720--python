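"""Minor- and major-groove bending-site geometry of the nucleosome core particle.

As nucleosomal DNA wraps the histone octamer it bends alternately into the
minor and the major groove, roughly every half helical turn.  The positions
where the minor groove faces the histone core (minor groove-bending sites,
minor-GBS) sit at half-integer superhelical locations (SHL ±1.5 ... ±6.5;
the two sites at SHL ±0.5 are defined but excluded from counting because
their WW/SS preference runs out of phase with the rest).  Major-GBS sit at
integer SHL ±1 ... ±6.  Each site spans 3 or 4 bp.

The counted map holds 12 minor sites covering 48 bp (capacity 36 internal
dinucleotides) and 12 major sites covering 44 bp (capacity 32), giving the
capacity ratio 36/32 = 1.125 used to balance WW/SS counts between the two
groove classes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from ._seq import DYAD_INDEX, NCP_LEN

MINOR_CAPACITY = 36
MAJOR_CAPACITY = 32
MINOR_COVERAGE_BP = 48
MAJOR_COVERAGE_BP = 44

HELICAL_PERIOD = 10.3
#: SHL magnitudes whose major-groove site is 3 bp rather than 4 bp
SHORT_MAJOR_SHL = frozenset({3.0, 6.0})

_DATA_DIR = Path(__file__).parent / "data"
DEFAULT_LAYOUT_PATH = _DATA_DIR / "gbs_default.yaml"


class LayoutError(ValueError):
    """A groove-bending-site layout violates a structural invariant."""


@dataclass(frozen=True, order=True)
class GBSite:
    """One groove-bending site in the 147-bp NCP frame (0-based, half-open)."""

    start: int
    length: int
    groove: str  # 'minor' | 'major'
    shl: float

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def capacity(self) -> int:
        """Internal dinucleotides: a k-bp site holds k-1."""
        return self.length - 1

    def mirror(self) -> "GBSite":
        """Reflection through the dyad of the 147-bp frame."""
        return GBSite(
            start=NCP_LEN - self.start - self.length,
            length=self.length,
            groove=self.groove,
            shl=-self.shl,
        )


@dataclass(frozen=True)
class GBSMap:
    """The set of counted groove-bending sites within one 147-bp NCP frame."""

    sites: tuple[GBSite, ...]
    dyad_index: int = DYAD_INDEX

    def __post_init__(self):
        report = validate_gbs_map(self)
        if not report.passed:
            raise LayoutError("invalid GBS layout: " + "; ".join(report.failures))

    @property
    def minor_sites(self) -> tuple[GBSite, ...]:
        return tuple(s for s in self.sites if s.groove == "minor")

    @property
    def major_sites(self) -> tuple[GBSite, ...]:
        return tuple(s for s in self.sites if s.groove == "major")

    def slot_starts(self, groove: str) -> list[int]:
        """Dinucleotide start offsets fully internal to sites of one class."""
        out: list[int] = []
        for s in self.sites:
            if s.groove == groove:
                out.extend(range(s.start, s.end - 1))
        return sorted(out)

    @property
    def minor_capacity(self) -> int:
        return sum(s.capacity for s in self.minor_sites)

    @property
    def major_capacity(self) -> int:
        return sum(s.capacity for s in self.major_sites)

    @property
    def capacity_ratio(self) -> float:
        """Default classification coefficient (1.125 for the canonical map)."""
        return self.minor_capacity / self.major_capacity

    def to_records(self) -> list[dict]:
        return [
            {"groove": s.groove, "shl": s.shl, "start": s.start, "length": s.length}
            for s in sorted(self.sites)
        ]


@dataclass
class ValidationReport:
    """Per-invariant outcome of a GBS layout check."""

    checks: list[dict] = field(default_factory=list)

    def add(self, name: str, ok: bool, measured):
        self.checks.append({"invariant": name, "passed": bool(ok), "measured": measured})

    @property
    def passed(self) -> bool:
        return all(c["passed"] for c in self.checks)

    @property
    def failures(self) -> list[str]:
        return [f"{c['invariant']} (measured: {c['measured']})" for c in self.checks if not c["passed"]]


def _default_site_records() -> list[dict]:
    # Positive-SHL sites placed at round(10.3 * SHL) from the dyad; 4-bp sites
    # start at centre-2, 3-bp sites at centre-1.  The negative side is the
    # mirror image, which makes dyad symmetry exact by construction.
    records = []
    for shl10 in range(15, 70, 10):  # SHL 1.5 .. 6.5
        shl = shl10 / 10.0
        k = round(HELICAL_PERIOD * shl)
        records.append({"groove": "minor", "shl": shl, "start": DYAD_INDEX + k - 2, "length": 4})
    for ishl in range(1, 7):  # SHL 1 .. 6
        shl = float(ishl)
        k = round(HELICAL_PERIOD * shl)
        length = 3 if shl in SHORT_MAJOR_SHL else 4
        offset = 1 if length == 3 else 2
        records.append({"groove": "major", "shl": shl, "start": DYAD_INDEX + k - offset, "length": length})
    mirrored = [
        {
            "groove": r["groove"],
            "shl": -r["shl"],
            "start": NCP_LEN - r["start"] - r["length"],
            "length": r["length"],
        }
        for r in records
    ]
    return sorted(records + mirrored, key=lambda r: r["start"])


def build_gbs_map(layout_config: str | Path | Sequence[dict] | None = None) -> GBSMap:
    """Build a groove-bending-site map.

    Parameters
    ----------
    layout_config
        ``None`` for the canonical default layout; a path to a YAML file or a
        sequence of records ``{groove, shl, start, length}`` to override it
        (for users who hold the reference per-site coordinate table).

    Raises
    ------
    LayoutError
        If the layout violates any structural invariant (site counts,
        coverage, capacity, symmetry, overlap, bounds).
    """
    if layout_config is None:
        records = _default_site_records()
    elif isinstance(layout_config, (str, Path)):
        with open(layout_config) as fh:
            loaded = yaml.safe_load(fh)
        records = loaded["sites"] if isinstance(loaded, dict) else loaded
    else:
        records = list(layout_config)
    sites = tuple(
        GBSite(start=int(r["start"]), length=int(r["length"]), groove=str(r["groove"]), shl=float(r["shl"]))
        for r in records
    )
    return GBSMap(sites=sites)


def validate_gbs_map(gbs_map) -> ValidationReport:
    """Check every structural invariant of a GBS map; always returns a report."""
    rep = ValidationReport()
    sites: Iterable[GBSite] = gbs_map.sites
    minor = [s for s in sites if s.groove == "minor"]
    major = [s for s in sites if s.groove == "major"]

    rep.add("12 minor sites", len(minor) == 12, len(minor))
    rep.add("12 major sites", len(major) == 12, len(major))
    rep.add(
        "site lengths are 3 or 4 bp",
        all(s.length in (3, 4) for s in sites),
        sorted({s.length for s in sites}),
    )
    rep.add("minor sites all 4 bp", all(s.length == 4 for s in minor), [s.length for s in minor])
    n_major_short = sum(1 for s in major if s.length == 3)
    rep.add("4 short (3-bp) major sites", n_major_short == 4, n_major_short)
    cov_minor = sum(s.length for s in minor)
    cov_major = sum(s.length for s in major)
    rep.add("minor coverage 48 bp", cov_minor == MINOR_COVERAGE_BP, cov_minor)
    rep.add("major coverage 44 bp", cov_major == MAJOR_COVERAGE_BP, cov_major)
    cap_minor = sum(s.capacity for s in minor)
    cap_major = sum(s.capacity for s in major)
    rep.add("minor dinucleotide capacity 36", cap_minor == MINOR_CAPACITY, cap_minor)
    rep.add("major dinucleotide capacity 32", cap_major == MAJOR_CAPACITY, cap_major)
    rep.add(
        "no counted site at SHL +/-0.5",
        all(abs(s.shl) != 0.5 for s in sites),
        sorted({abs(s.shl) for s in sites}),
    )
    in_bounds = all(0 <= s.start and s.end <= NCP_LEN for s in sites)
    rep.add("sites within the 147-bp frame", in_bounds, [(s.start, s.end) for s in sites if not (0 <= s.start and s.end <= NCP_LEN)])

    for groove, group in (("minor", minor), ("major", major)):
        ordered = sorted(group)
        overlap = any(a.end > b.start for a, b in zip(ordered, ordered[1:]))
        rep.add(f"{groove} sites non-overlapping", not overlap, overlap)

    site_set = {(s.start, s.length, s.groove) for s in sites}
    mirror_set = {(s.mirror().start, s.length, s.groove) for s in sites}
    rep.add("mirror-symmetric about the dyad", site_set == mirror_set, sorted(site_set ^ mirror_set))
    return rep


def write_layout(gbs_map: GBSMap, path: str | Path) -> None:
    """Write a layout YAML usable as ``layout_config``."""
    with open(path, "w") as fh:
        yaml.safe_dump({"sites": gbs_map.to_records()}, fh, sort_keys=False)
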