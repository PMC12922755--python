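"""Coordinate scaffolding: chromosomes, arms, fixed-width bins, and named loci.

All coordinates are 1-based inclusive. BED I/O converts from/to the on-disk
0-based half-open convention at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Chromosome",
    "GenomeBuild",
    "Bin",
    "ArmDef",
    "Locus",
    "ACROCENTRIC_ARMS",
    "DEFAULT_BIN_SIZE",
    "LOCUS_1Q23_2",
    "LOCUS_1Q42_13",
    "LOCUS_8Q24_21",
    "LOCUS_MYC",
    "make_bins",
    "arm_defs",
    "assign_bins_to_arms",
    "arm_bin_ranges",
    "overlapping_bins",
    "read_bed_loci",
    "write_bed_loci",
]

DEFAULT_BIN_SIZE = 500_000

#: short arms of the acrocentric autosomes; excluded from arm-level reporting
ACROCENTRIC_ARMS = frozenset({"13p", "14p", "15p", "21p", "22p"})


def _norm_chrom(name: str) -> str:
    name = str(name).strip()
    return name[3:] if name.lower().startswith("chr") else name


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be > 0")
        if not 1 < self.centromere < self.length:
            raise ValueError(
                f"chromosome {self.name}: centromere {self.centromere} not "
                f"strictly inside [1, {self.length}]"
            )


@dataclass(frozen=True)
class GenomeBuild:
    """Autosome-only genome build (chr1-chr22)."""

    name: str
    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        seen = set()
        for c in self.chromosomes:
            if c.name in seen:
                raise ValueError(f"duplicate chromosome {c.name}")
            seen.add(c.name)

    def chromosome(self, name: str) -> Chromosome:
        name = _norm_chrom(name)
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r} in build {self.name}")

    @classmethod
    def hg19(cls) -> "GenomeBuild":
        """Packaged hg19 autosome table (lengths + centromere midpoints)."""
        text = (
            resources.files("aneucall.data")
            .joinpath("hg19_chromosomes.tsv")
            .read_text()
        )
        chroms = []
        for line in text.strip().splitlines()[1:]:
            name, length, cen = line.split("\t")
            chroms.append(Chromosome(name, int(length), int(cen)))
        return cls("hg19", tuple(chroms))


@dataclass(frozen=True)
class Bin:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # inclusive
    index: int  # ordinal within chromosome, 0-based

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class ArmDef:
    chrom: str
    arm: str  # "p" | "q"
    start: int
    end: int
    n_bins: int
    excluded: bool = False

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.arm}"


@dataclass(frozen=True)
class Locus:
    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"locus {self.name}: start > end")


# Published driver-locus coordinates (hg19, 1-based inclusive).
LOCUS_1Q23_2 = Locus("1q23.2", "1", 159_100_001, 160_500_000)
LOCUS_1Q42_13 = Locus("1q42.13", "1", 227_000_001, 230_700_000)
LOCUS_8Q24_21 = Locus("8q24.21", "8", 127_300_001, 131_500_000)
LOCUS_MYC = Locus("MYC", "8", 128_747_681, 128_755_197)


def make_bins(build: GenomeBuild, bin_size: int = DEFAULT_BIN_SIZE) -> list[Bin]:
    """Tile every chromosome with fixed-width bins anchored at position 1.

    The last bin of each chromosome may be shorter. Ordering is build order
    (chr1..chr22), ascending start.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    bins: list[Bin] = []
    for chrom in build.chromosomes:
        idx = 0
        for start in range(1, chrom.length + 1, bin_size):
            end = min(start + bin_size - 1, chrom.length)
            bins.append(Bin(chrom.name, start, end, idx))
            idx += 1
    return bins


def arm_defs(build: GenomeBuild, bins: Sequence[Bin]) -> list[ArmDef]:
    """Derive p/q arm definitions from centromere positions and the bin grid.

    A bin containing the centromere coordinate belongs to neither arm.
    """
    out: list[ArmDef] = []
    for chrom in build.chromosomes:
        cbins = [b for b in bins if b.chrom == chrom.name]
        cen = chrom.centromere
        p_bins = [b for b in cbins if b.end < cen]
        q_bins = [b for b in cbins if b.start > cen]
        if p_bins:
            out.append(
                ArmDef(
                    chrom.name, "p", p_bins[0].start, p_bins[-1].end,
                    len(p_bins), excluded=f"{chrom.name}p" in ACROCENTRIC_ARMS,
                )
            )
        if q_bins:
            out.append(
                ArmDef(
                    chrom.name, "q", q_bins[0].start, q_bins[-1].end,
                    len(q_bins), excluded=f"{chrom.name}q" in ACROCENTRIC_ARMS,
                )
            )
    return out


def assign_bins_to_arms(
    bins: Sequence[Bin], arms: Iterable[ArmDef]
) -> dict[int, str | None]:
    """Map global bin index -> arm name, or None for centromere-straddling bins.

    Partition property: every bin maps to exactly one arm or to None.
    """
    by_chrom: dict[str, list[ArmDef]] = {}
    for a in arms:
        by_chrom.setdefault(a.chrom, []).append(a)
    assignment: dict[int, str | None] = {}
    for gi, b in enumerate(bins):
        assignment[gi] = None
        for a in by_chrom.get(b.chrom, ()):
            if a.start <= b.start and b.end <= a.end:
                assignment[gi] = a.name
                break
    return assignment


def arm_bin_ranges(
    bins: Sequence[Bin], arms: Iterable[ArmDef]
) -> dict[str, range]:
    """Arm name -> contiguous range of global bin indices (bins are sorted)."""
    assignment = assign_bins_to_arms(bins, arms)
    ranges: dict[str, range] = {}
    for gi in range(len(bins)):
        arm = assignment[gi]
        if arm is None:
            continue
        if arm in ranges:
            r = ranges[arm]
            if gi != r.stop:
                raise ValueError(f"bins of arm {arm} are not contiguous")
            ranges[arm] = range(r.start, gi + 1)
        else:
            ranges[arm] = range(gi, gi + 1)
    return ranges


def overlapping_bins(locus: Locus, bins: Sequence[Bin]) -> list[int]:
    """Global indices of every bin overlapping `locus` by >= 1 bp.

    A zero-length convention is not used: a query with start == end overlaps
    the single bin containing that coordinate.
    """
    chrom = _norm_chrom(locus.chrom)
    if not any(b.chrom == chrom for b in bins):
        raise KeyError(f"locus chromosome {chrom!r} absent from bin grid")
    chrom_max = max(b.end for b in bins if b.chrom == chrom)
    if locus.start < 1 or locus.end > chrom_max:
        raise ValueError(
            f"locus {locus.name} [{locus.start}, {locus.end}] outside "
            f"chromosome {chrom} bounds [1, {chrom_max}]"
        )
    return [
        gi
        for gi, b in enumerate(bins)
        if b.chrom == chrom and b.start <= locus.end and b.end >= locus.start
    ]


def read_bed_loci(path) -> list[Locus]:
    """Read loci from BED (0-based half-open on disk -> 1-based inclusive)."""
    loci = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            loci.append(Locus(name, _norm_chrom(chrom), start + 1, end))
    return loci


def write_bed_loci(loci: Iterable[Locus], path) -> None:
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(f"chr{loc.chrom}\t{loc.start - 1}\t{loc.end}\t{loc.name}\n")
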