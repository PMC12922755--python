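"""Duplex (Watson/Crick UID family) consensus mutation calling.

A template molecule is identified by its 14-nt exogenous barcode (UID); its
two strands yield separate read families. A duplex-supported variant must
have the same alt allele at > 80% (strictly) of reads in BOTH families.
Position-level calls then pass through template-count, coverage,
end-distance, catalog-annotation and sample-level filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Amplicon",
    "StrandFamily",
    "DuplexGroup",
    "MutationCall",
    "UID_LENGTH",
    "GENES",
    "extract_uid",
    "assign_strand",
    "match_amplicon",
    "build_duplex_groups",
    "call_duplex_variant",
    "collect_candidates",
    "apply_filters",
    "sample_assessable",
    "call_sample",
    "lesion_mutation_table",
    "read_amplicons_tsv",
    "write_amplicons_tsv",
    "read_cosmic_tsv",
    "read_fastq_pairs",
    "make_synthetic_amplicons",
    "make_matching_cosmic",
]

UID_LENGTH = 14
GENES = ("KRAS", "NRAS", "GNAS", "CDKN2A", "SMAD4", "TP53")
TS_GENES = ("CDKN2A", "TP53", "SMAD4")

DUPLEX_MIN_FRACTION = 0.8   # strictly greater than
MIN_MUTANT_TEMPLATES = 3    # "more than two" template molecules
MIN_COVERAGE = 5            # template molecules (duplex groups), inclusive
MIN_END_DISTANCE = 30       # bp from either template end, inclusive
MIN_COSMIC_ANNOTATIONS = 2  # inclusive
MIN_KRAS_TEMPLATES = 10     # inclusive

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Amplicon:
    gene: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    ref_seq: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("amplicon end must exceed start")
        if len(self.ref_seq) != self.end - self.start + 1:
            raise ValueError("reference length does not match span")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class StrandFamily:
    uid: str
    strand: str  # WATSON | CRICK
    amplicon: Amplicon
    n_reads: int = 0
    tallies: np.ndarray | None = None  # (length, 4) base counts, plus orientation

    def add(self, insert_plus: str) -> None:
        if self.tallies is None:
            self.tallies = np.zeros((self.amplicon.length, 4), dtype=int)
        for i, b in enumerate(insert_plus):
            j = _BASE_INDEX.get(b)
            if j is not None:
                self.tallies[i, j] += 1
        self.n_reads += 1

    def allele_fraction(self, offset: int, base: str) -> float:
        if self.tallies is None or self.n_reads == 0:
            return 0.0
        total = self.tallies[offset].sum()
        if total == 0:
            return 0.0
        return self.tallies[offset, _BASE_INDEX[base]] / total


@dataclass
class DuplexGroup:
    uid: str
    amplicon: Amplicon
    watson: StrandFamily | None = None
    crick: StrandFamily | None = None

    def family(self, strand: str) -> StrandFamily:
        attr = "watson" if strand == "WATSON" else "crick"
        fam = getattr(self, attr)
        if fam is None:
            fam = StrandFamily(self.uid, strand, self.amplicon)
            setattr(self, attr, fam)
        return fam

    def is_duplex(self, min_reads_per_strand: int = 1) -> bool:
        return (
            self.watson is not None
            and self.crick is not None
            and self.watson.n_reads >= min_reads_per_strand
            and self.crick.n_reads >= min_reads_per_strand
        )


@dataclass
class MutationCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    mutant_templates: int
    total_templates: int
    filters: dict[str, bool] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.filters.values())


def extract_uid(r1: str, r2: str) -> tuple[str, tuple[str, str]]:
    """UID = first 14 bases of read 1; returns (uid, trimmed pair)."""
    if len(r1) <= UID_LENGTH:
        raise ValueError(f"read 1 length {len(r1)} must exceed {UID_LENGTH}")
    return r1[:UID_LENGTH], (r1[UID_LENGTH:], r2)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def assign_strand(insert: str, amplicon: Amplicon) -> str:
    """WATSON when the UID-bearing read matches the amplicon's plus
    orientation more closely than the minus orientation; deterministic."""
    if len(insert) != amplicon.length:
        raise ValueError("insert length does not match amplicon")
    d_plus = _hamming(insert, amplicon.ref_seq)
    d_minus = _hamming(insert, _revcomp(amplicon.ref_seq))
    return "WATSON" if d_plus <= d_minus else "CRICK"


def match_amplicon(insert: str, amplicons: Sequence[Amplicon]) -> tuple[Amplicon, str]:
    """Anchor a read to the best-matching amplicon (either orientation)."""
    best = None
    for amp in amplicons:
        if len(insert) != amp.length:
            continue
        d_plus = _hamming(insert, amp.ref_seq)
        d_minus = _hamming(insert, _revcomp(amp.ref_seq))
        d = min(d_plus, d_minus)
        strand = "WATSON" if d_plus <= d_minus else "CRICK"
        if best is None or d < best[0]:
            best = (d, amp, strand)
    if best is None:
        raise ValueError("read matches no amplicon (length mismatch)")
    return best[1], best[2]


def build_duplex_groups(
    read_pairs: Iterable[tuple[str, str]],
    amplicons: Sequence[Amplicon],
) -> list[DuplexGroup]:
    """Group reads into one DuplexGroup per (UID, amplicon).

    Single-strand groups are retained (they count toward nothing duplex).
    Grouping is permutation-invariant: output is sorted by (amplicon, uid).
    """
    groups: dict[tuple[str, str], DuplexGroup] = {}
    for r1, r2 in read_pairs:
        uid, (insert, _) = extract_uid(r1, r2)
        amp, strand = match_amplicon(insert, amplicons)
        key = (amp.gene + f":{amp.start}", uid)
        grp = groups.get(key)
        if grp is None:
            grp = groups[key] = DuplexGroup(uid, amp)
        plus = insert if strand == "WATSON" else _revcomp(insert)
        grp.family(strand).add(plus)
    return [groups[k] for k in sorted(groups)]


def call_duplex_variant(
    group: DuplexGroup,
    pos: int,
    min_fraction: float = DUPLEX_MIN_FRACTION,
    min_reads_per_strand: int = 1,
) -> str | None:
    """The alt allele supported by this template at `pos`, or None.

    Support requires both strand families present (>= min_reads_per_strand
    reads) and the SAME non-reference allele at a fraction strictly greater
    than `min_fraction` in each family.
    """
    if not group.is_duplex(min_reads_per_strand):
        return None
    offset = pos - group.amplicon.start
    if not 0 <= offset < group.amplicon.length:
        raise ValueError("position outside amplicon")
    ref = group.amplicon.ref_seq[offset]
    for base in _BASES:
        if base == ref:
            continue
        fw = group.watson.allele_fraction(offset, base)
        fc = group.crick.allele_fraction(offset, base)
        if fw > min_fraction and fc > min_fraction:
            return base
    return None


def collect_candidates(
    groups: Sequence[DuplexGroup],
    min_fraction: float = DUPLEX_MIN_FRACTION,
    min_reads_per_strand: int = 1,
) -> list[MutationCall]:
    """Aggregate duplex-supported alleles into per-position candidates.

    total_templates at a position = duplex-complete groups covering it.
    """
    by_amp: dict[str, list[DuplexGroup]] = {}
    for g in groups:
        by_amp.setdefault(f"{g.amplicon.gene}:{g.amplicon.start}", []).append(g)
    candidates: list[MutationCall] = []
    for key in sorted(by_amp):
        amp_groups = by_amp[key]
        amp = amp_groups[0].amplicon
        duplex = [g for g in amp_groups if g.is_duplex(min_reads_per_strand)]
        coverage = len(duplex)
        support: dict[tuple[int, str], int] = {}
        for g in duplex:
            for offset in range(amp.length):
                pos = amp.start + offset
                alt = call_duplex_variant(g, pos, min_fraction, min_reads_per_strand)
                if alt is not None:
                    support[(pos, alt)] = support.get((pos, alt), 0) + 1
        for (pos, alt), n_mut in sorted(support.items()):
            candidates.append(
                MutationCall(
                    chrom=amp.chrom,
                    pos=pos,
                    ref=amp.ref_seq[pos - amp.start],
                    alt=alt,
                    gene=amp.gene,
                    mutant_templates=n_mut,
                    total_templates=coverage,
                    filters={"duplex_frac": True},
                )
            )
    return candidates


def sample_assessable(
    groups: Sequence[DuplexGroup],
    min_kras_templates: int = MIN_KRAS_TEMPLATES,
) -> bool:
    """A sample is assessable when >= 10 distinct duplex template molecules
    overlap a KRAS amplicon."""
    n = sum(1 for g in groups if g.amplicon.gene == "KRAS" and g.is_duplex())
    return n >= min_kras_templates


def apply_filters(
    candidates: Sequence[MutationCall],
    cosmic: pd.DataFrame,
    amplicons: Sequence[Amplicon],
    sample_ok: bool = True,
    min_mutant_templates: int = MIN_MUTANT_TEMPLATES,
    min_coverage: int = MIN_COVERAGE,
    min_end_distance: int = MIN_END_DISTANCE,
    min_cosmic: int = MIN_COSMIC_ANNOTATIONS,
    genome_wide_only: bool = False,
) -> list[MutationCall]:
    """Annotate every candidate with pass/fail flags for each filter.

    min_mut_templates: mutant duplex groups >= 3 ("more than two");
    coverage: template molecules >= 5; end_distance: >= 30 bp from both
    template ends; cosmic: >= 2 annotations with a confirmed-somatic flag
    (optionally counting only genome-wide-study annotations); sample_qc:
    the KRAS template-count gate.
    """
    amp_by_span = {(a.chrom, a.start, a.end): a for a in amplicons}
    cosmic_idx = {}
    for _, row in cosmic.iterrows():
        key = (str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        cosmic_idx[key] = row
    out = []
    for cand in candidates:
        amp = None
        for (chrom, s, e), a in amp_by_span.items():
            if chrom == cand.chrom and s <= cand.pos <= e:
                amp = a
                break
        if amp is None:
            raise ValueError(f"candidate at {cand.chrom}:{cand.pos} outside amplicons")
        filters = dict(cand.filters)
        filters["min_mut_templates"] = cand.mutant_templates >= min_mutant_templates
        filters["coverage"] = cand.total_templates >= min_coverage
        filters["end_distance"] = (
            cand.pos - amp.start >= min_end_distance
            and amp.end - cand.pos >= min_end_distance
        )
        row = cosmic_idx.get((cand.chrom, cand.pos, cand.ref, cand.alt))
        if row is None:
            filters["cosmic"] = False
        else:
            count_col = "genome_wide_count" if genome_wide_only else "annotation_count"
            filters["cosmic"] = (
                int(row[count_col]) >= min_cosmic and bool(row["confirmed_somatic"])
            )
        filters["sample_qc"] = bool(sample_ok)
        out.append(
            MutationCall(cand.chrom, cand.pos, cand.ref, cand.alt, cand.gene,
                         cand.mutant_templates, cand.total_templates, filters)
        )
    return out


def call_sample(
    read_pairs: Iterable[tuple[str, str]],
    amplicons: Sequence[Amplicon],
    cosmic: pd.DataFrame,
    **filter_kwargs,
) -> tuple[list[MutationCall], list[DuplexGroup]]:
    """End-to-end per-sample calling: group, candidate, filter."""
    groups = build_duplex_groups(read_pairs, amplicons)
    ok = sample_assessable(groups)
    candidates = collect_candidates(groups)
    calls = apply_filters(candidates, cosmic, amplicons, sample_ok=ok,
                          **filter_kwargs)
    return calls, groups


def lesion_mutation_table(
    calls_by_sample: Mapping[str, Sequence[MutationCall]],
    meta: pd.DataFrame,
    arm_calls: pd.DataFrame | None = None,
    arm: str = "1q",
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-sample gene mutation status plus (optionally) the cross-tab of
    1q gain against tumor-suppressor (CDKN2A/TP53/SMAD4) mutation status."""
    known = set(meta["sample_id"])
    rows = []
    for sample in sorted(calls_by_sample):
        if sample not in known:
            warnings.warn(f"sample {sample!r} missing from metadata; excluded")
            continue
        status = {g: False for g in GENES}
        for call in calls_by_sample[sample]:
            if call.passed:
                status[call.gene] = True
        rows.append({"sample_id": sample, **status})
    status_df = pd.DataFrame(rows, columns=["sample_id", *GENES])
    if arm_calls is None:
        return status_df, None
    gained = set(
        arm_calls[(arm_calls["arm"] == arm) & arm_calls["has_gain"]]["sample_id"]
    )
    xt_rows = []
    for _, r in status_df.iterrows():
        xt_rows.append(
            {
                "sample_id": r["sample_id"],
                "arm_gained": r["sample_id"] in gained,
                "ts_mutated": any(r[g] for g in TS_GENES),
            }
        )
    xt = pd.DataFrame(xt_rows)
    crosstab = pd.crosstab(xt["arm_gained"], xt["ts_mutated"])
    return status_df, crosstab


# ---------------------------------------------------------------------------
# I/O and synthetic fixtures


def read_amplicons_tsv(path) -> list[Amplicon]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        Amplicon(str(r["gene"]), str(r["chrom"]), int(r["start"]), int(r["end"]),
                 str(r["ref_seq"]))
        for _, r in df.iterrows()
    ]


def write_amplicons_tsv(amplicons: Sequence[Amplicon], path) -> None:
    pd.DataFrame(
        [
            {"gene": a.gene, "chrom": a.chrom, "start": a.start, "end": a.end,
             "ref_seq": a.ref_seq}
            for a in amplicons
        ]
    ).to_csv(path, sep="\t", index=False)


def read_cosmic_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    needed = {"chrom", "pos", "ref", "alt", "annotation_count",
              "genome_wide_count", "confirmed_somatic"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"catalog lookup missing columns {sorted(missing)}")
    return df


def read_fastq_pairs(path_r1, path_r2) -> list[tuple[str, str]]:
    """Read paired plain-text FASTQ into (r1_seq, r2_seq) tuples."""

    def seqs(path):
        out = []
        with open(path) as fh:
            for i, line in enumerate(fh):
                if i % 4 == 1:
                    out.append(line.strip())
        return out

    s1, s2 = seqs(path_r1), seqs(path_r2)
    if len(s1) != len(s2):
        raise ValueError("R1/R2 read counts differ")
    return list(zip(s1, s2))


def make_synthetic_amplicons(
    rng: np.random.Generator,
    genes: Sequence[str] = GENES,
    length: int = 120,
) -> list[Amplicon]:
    """Random-sequence amplicons, one per gene, on arbitrary coordinates."""
    bases = np.array(list("ACGT"))
    out = []
    for i, gene in enumerate(genes):
        start = 1_000_000 + i * 10_000
        seq = "".join(rng.choice(bases, size=length))
        out.append(Amplicon(gene, "12", start, start + length - 1, seq))
    return out


def make_matching_cosmic(
    variants: Sequence[tuple[Amplicon, int, str]],
    annotation_count: int = 5,
    genome_wide_count: int = 5,
) -> pd.DataFrame:
    """Catalog lookup covering the given (amplicon, pos, alt) variants."""
    rows = []
    for amp, pos, alt in variants:
        rows.append(
            {
                "chrom": amp.chrom,
                "pos": pos,
                "ref": amp.ref_seq[pos - amp.start],
                "alt": alt,
                "annotation_count": annotation_count,
                "genome_wide_count": genome_wide_count,
                "confirmed_somatic": True,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "annotation_count",
                 "genome_wide_count", "confirmed_somatic"],
    )
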