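"""Ground-truthed synthetic cohort generation.

Emits karyotypes, median-normalized bin-call matrices (with purity admixture
and Gaussian log-ratio noise), per-nucleus FISH counts, dosage-responsive
expression matrices, and UID-barcoded duplex amplicon reads, together with a
truth table so downstream callers can be verified end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cna_calls import BinCallMatrix, GRADES
from .genome_model import (
    Bin,
    GenomeBuild,
    LOCUS_1Q23_2,
    LOCUS_1Q42_13,
    LOCUS_8Q24_21,
    Locus,
    arm_bin_ranges,
    arm_defs,
    make_bins,
    overlapping_bins,
)

__all__ = [
    "Segment",
    "Karyotype",
    "CohortConfig",
    "CohortData",
    "ReadPair",
    "DEFAULT_FISH_PROBE",
    "simulate_karyotype",
    "copies_per_bin",
    "render_bin_profile",
    "simulate_fish_counts",
    "simulate_expression",
    "simulate_duplex_reads",
    "simulate_cohort",
    "write_cohort",
    "write_fastq",
]

# ABL2 at 1q25, the probe used for chromosome-1q enumeration
DEFAULT_FISH_PROBE = Locus("1q25/ABL2", "1", 179_068_462, 179_198_819)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# (build name, bin size) -> (bins, arm bin ranges); grids are immutable
_GRID_CACHE: dict[tuple[str, int], tuple[list, dict]] = {}


def _grid(build: GenomeBuild, bin_size: int):
    key = (build.name, bin_size)
    if key not in _GRID_CACHE:
        bins = make_bins(build, bin_size)
        _GRID_CACHE[key] = (bins, arm_bin_ranges(bins, arm_defs(build, bins)))
    return _GRID_CACHE[key]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int
    copies: int

    def __post_init__(self) -> None:
        if self.copies < 0:
            raise ValueError("copies must be >= 0")


@dataclass
class Karyotype:
    sample_id: str
    grade: str
    base_ploidy: int  # 2, or 4 after whole-genome doubling
    segments: list[Segment]

    def copies_at(self, chrom: str, pos: int) -> int:
        chrom = str(chrom).removeprefix("chr")
        for seg in self.segments:
            if seg.chrom == chrom and seg.start <= pos <= seg.end:
                return seg.copies
        raise KeyError(f"position {chrom}:{pos} not covered by karyotype")


@dataclass
class ArmEventTruth:
    arm: str
    direction: str  # GAIN | LOSS
    full: bool
    start: int
    end: int
    anchor: str | None = None


def _default_gain_probs() -> dict[str, dict[str, float]]:
    return {
        "1q": {"LG_PANIN": 0.07, "HG_PANIN": 0.49, "LG_IPMN": 0.33,
               "HG_IPMN": 0.36, "PDAC": 0.40},
        "8q": {"LG_PANIN": 0.02, "HG_PANIN": 0.20, "LG_IPMN": 0.03,
               "HG_IPMN": 0.20, "PDAC": 0.467},
    }


def _default_loss_probs() -> dict[str, dict[str, float]]:
    return {
        "9p": {"HG_PANIN": 0.25, "HG_IPMN": 0.30, "PDAC": 0.604},
        "17p": {"HG_PANIN": 0.25, "HG_IPMN": 0.30, "PDAC": 0.699},
        "18q": {"HG_PANIN": 0.25, "HG_IPMN": 0.30, "PDAC": 0.742},
        "3p": {"SCA": 0.50},
        "6q": {"MCN": 0.30},
    }


def _default_purity() -> dict[str, tuple[float, float]]:
    return {g: (0.6, 0.9) for g in GRADES}


@dataclass
class CohortConfig:
    n_per_grade: dict[str, int] = field(
        default_factory=lambda: {"NORMAL": 10, "LG_PANIN": 30, "HG_PANIN": 30,
                                 "LG_IPMN": 30, "HG_IPMN": 30, "MCN": 5,
                                 "SCA": 5, "PDAC": 60}
    )
    purity: dict[str, tuple[float, float]] = field(default_factory=_default_purity)
    noise_sd: float = 0.05
    arm_gain_probs: dict[str, dict[str, float]] = field(default_factory=_default_gain_probs)
    arm_loss_probs: dict[str, dict[str, float]] = field(default_factory=_default_loss_probs)
    focal_fraction: dict[str, float] = field(
        default_factory=lambda: {"1q": 0.34, "8q": 0.50}
    )
    anchors: dict[str, tuple[Locus, ...]] = field(
        default_factory=lambda: {"1q": (LOCUS_1Q23_2, LOCUS_1Q42_13),
                                 "8q": (LOCUS_8Q24_21,)}
    )
    wgd_prob: dict[str, float] = field(
        default_factory=lambda: {g: (0.2 if g == "PDAC" else 0.0) for g in GRADES}
    )
    # mean extension (bins) of a focal segment beyond its anchor locus, per
    # side; geometric so the gain-fraction profile peaks at the anchors
    focal_extension_mean_bins: float = 20.0
    # tumor-suppressor point-mutation probability (any of CDKN2A/TP53/SMAD4)
    ts_mutation_prob: dict[str, float] = field(
        default_factory=lambda: {"LG_PANIN": 0.05, "HG_PANIN": 0.3, "LG_IPMN": 0.1,
                                 "HG_IPMN": 0.35, "PDAC": 0.8}
    )
    # UID-barcoded amplicon read emission (off by default: read sets are
    # bulky relative to the rest of the cohort)
    simulate_reads: bool = False
    reads_n_templates: int = 15
    reads_per_strand: int = 3
    reads_error: float = 1e-3
    bin_size: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        for tbl in (self.arm_gain_probs, self.arm_loss_probs):
            for arm, probs in tbl.items():
                for g, p in probs.items():
                    if not 0 <= p <= 1:
                        raise ValueError(f"probability out of range: {arm}/{g}")
        for g, (lo, hi) in self.purity.items():
            if not (0 < lo <= hi <= 1):
                raise ValueError(f"purity range invalid for {g}")


def simulate_karyotype(
    sample_id: str,
    grade: str,
    config: CohortConfig,
    rng: np.random.Generator,
    build: GenomeBuild | None = None,
) -> tuple[Karyotype, list[ArmEventTruth]]:
    """Draw arm/focal events per the configured grade probabilities.

    NORMAL samples are always copy-neutral. Gains add base_ploidy/2 copies
    (so a relative single-copy gain on a doubled genome stays a relative
    gain); losses subtract the same. A focal segment contains a randomly
    chosen anchor locus and extends a geometric number of bins beyond it on
    each side (clipped to the arm), so cohort gain-fraction profiles peak at
    the anchors.
    """
    if grade not in GRADES:
        raise KeyError(f"unknown grade {grade!r}")
    build = build or GenomeBuild.hg19()
    bins, ranges = _grid(build, config.bin_size)

    wgd = grade != "NORMAL" and rng.random() < config.wgd_prob.get(grade, 0.0)
    base = 4 if wgd else 2
    delta = base // 2
    copies = np.full(len(bins), base, dtype=int)
    truth: list[ArmEventTruth] = []

    if grade != "NORMAL":
        for direction, table in (("GAIN", config.arm_gain_probs),
                                 ("LOSS", config.arm_loss_probs)):
            for arm in sorted(table):
                p = table[arm].get(grade, 0.0)
                if rng.random() >= p:
                    continue
                rng_arm = ranges[arm]
                focal_p = config.focal_fraction.get(arm, 0.0)
                anchors = config.anchors.get(arm, ())
                if direction == "GAIN" and anchors and rng.random() < focal_p:
                    anchor = anchors[rng.integers(len(anchors))]
                    aidx = overlapping_bins(anchor, bins)
                    p_ext = 1.0 / max(config.focal_extension_mean_bins, 1.0)
                    lo = max(rng_arm.start, aidx[0] - int(rng.geometric(p_ext)))
                    hi = min(rng_arm.stop - 1, aidx[-1] + int(rng.geometric(p_ext)))
                    copies[lo:hi + 1] += delta
                    truth.append(ArmEventTruth(arm, "GAIN", False,
                                               bins[lo].start, bins[hi].end,
                                               anchor.name))
                else:
                    sl = slice(rng_arm.start, rng_arm.stop)
                    if direction == "GAIN":
                        copies[sl] += delta
                    else:
                        copies[sl] = np.maximum(copies[sl] - delta, 0)
                    truth.append(ArmEventTruth(
                        arm, direction, True,
                        bins[rng_arm.start].start, bins[rng_arm.stop - 1].end))

    segments: list[Segment] = []
    for chrom in build.chromosomes:
        cidx = [i for i, b in enumerate(bins) if b.chrom == chrom.name]
        run_start = prev = cidx[0]
        for i in cidx[1:]:
            if copies[i] != copies[run_start]:
                segments.append(Segment(chrom.name, bins[run_start].start,
                                        bins[prev].end, int(copies[run_start])))
                run_start = i
            prev = i
        segments.append(Segment(chrom.name, bins[run_start].start,
                                bins[prev].end, int(copies[run_start])))
    return Karyotype(sample_id, grade, base, segments), truth


def copies_per_bin(karyotype: Karyotype, bins: Sequence[Bin]) -> np.ndarray:
    """Integer copy number at each bin midpoint."""
    out = np.empty(len(bins), dtype=int)
    for i, b in enumerate(bins):
        out[i] = karyotype.copies_at(b.chrom, int(b.midpoint))
    return out


def render_bin_profile(
    karyotype: Karyotype,
    bins: Sequence[Bin],
    purity: float,
    noise_sd: float,
    rng: np.random.Generator,
    normalization: str = "median",
    max_copy: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Render per-bin log-ratios and discretized {G,N,L} calls.

    raw log-ratio = log2((purity*c + (1-purity)*2) / 2) + Gaussian noise.
    Median normalization subtracts the genome-wide median before
    discretization, emulating relative (ploidy-blind) calling: the centered
    value is matched to the nearest expected log-ratio of an integer copy
    state under a diploid baseline, then mapped >2 -> G, 2 -> N, <2 -> L.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    if not karyotype.segments:
        raise ValueError("empty karyotype")
    copies = copies_per_bin(karyotype, bins)
    mix = purity * copies + (1 - purity) * 2.0
    raw = np.log2(mix / 2.0)
    if noise_sd > 0:
        raw = raw + rng.normal(0.0, noise_sd, size=raw.shape)
    if normalization == "median":
        centered = raw - np.median(raw)
    elif normalization == "none":
        centered = raw
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    states = np.arange(0, max_copy + 1)
    expected = np.log2(np.maximum(purity * states + (1 - purity) * 2.0, 1e-9) / 2.0)
    nearest = np.abs(centered[:, None] - expected[None, :]).argmin(axis=1)
    called = states[nearest]
    calls = np.where(called > 2, "G", np.where(called < 2, "L", "N")).astype("<U1")
    return centered, calls


def simulate_fish_counts(
    karyotype: Karyotype,
    probe_locus: Locus,
    n_nuclei: int,
    p_detect: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-nucleus probe signal counts ~ Binomial(copies at locus, p_detect).

    Counts are returned uncapped; capping at 10 is a scoring-stage rule.
    """
    if not 0 < p_detect <= 1:
        raise ValueError("p_detect must be in (0, 1]")
    mid = (probe_locus.start + probe_locus.end) // 2
    copies = karyotype.copies_at(probe_locus.chrom, mid)
    return rng.binomial(copies, p_detect, size=n_nuclei)


def simulate_expression(
    copy_number: pd.DataFrame,
    effect_size: float,
    noise_sd: float,
    rng: np.random.Generator,
    responsive: Mapping[str, bool] | None = None,
    responsive_fraction: float = 0.5,
    baseline: float = 10.0,
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Gene x sample expression with dosage response for a subset of genes.

    Responsive genes: expression = baseline + effect_size*(copies - 2) + noise;
    non-responsive genes are baseline + noise regardless of copy number.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if copy_number.shape[1] < 2:
        raise ValueError("degenerate cohort: need >= 2 samples for association")
    genes = list(copy_number.index)
    if responsive is None:
        flags = rng.random(len(genes)) < responsive_fraction
        responsive = {g: bool(f) for g, f in zip(genes, flags)}
    expr = pd.DataFrame(index=genes, columns=copy_number.columns, dtype=float)
    for g in genes:
        cn = copy_number.loc[g].to_numpy(dtype=float)
        noise = rng.normal(0.0, noise_sd, size=cn.size)
        if responsive[g]:
            expr.loc[g] = baseline + effect_size * (cn - 2.0) + noise
        else:
            expr.loc[g] = baseline + noise
    return expr, dict(responsive)


@dataclass(frozen=True)
class ReadPair:
    name: str
    r1: str
    r2: str


_BASES = np.array(list("ACGT"))


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def simulate_duplex_reads(
    amplicon,
    n_templates: int,
    reads_per_strand: int,
    true_variants: Sequence[tuple[int, str, float]],
    per_base_error: float,
    rng: np.random.Generator,
    family_size_dist: str = "fixed",
) -> tuple[list[ReadPair], dict]:
    """Simulate UID-barcoded paired reads for one amplicon.

    Each template gets a distinct random 14-nt UID and a Watson plus a Crick
    read family. `true_variants` is a list of (genomic pos, alt base,
    template fraction); carriers (round(fraction*n) templates each) propagate
    the variant to both strands. Sequencing errors are drawn independently
    per read per base on the insert (strand-independent).
    With family_size_dist="geometric", family sizes are 1 + Geometric with
    mean ~= reads_per_strand.
    """
    if n_templates < 1:
        raise ValueError("n_templates must be >= 1")
    if not 0 <= per_base_error <= 0.05:
        raise ValueError("per_base_error must be in [0, 0.05]")
    ref = amplicon.ref_seq
    length = len(ref)
    for pos, alt, frac in true_variants:
        if not amplicon.start <= pos <= amplicon.end:
            raise ValueError(f"variant position {pos} outside amplicon")
        if not 0 <= frac <= 1:
            raise ValueError("variant fraction out of range")

    carriers: dict[int, list[tuple[int, str]]] = {i: [] for i in range(n_templates)}
    for pos, alt, frac in true_variants:
        n_carriers = int(round(frac * n_templates))
        chosen = rng.choice(n_templates, size=n_carriers, replace=False)
        for t in chosen:
            carriers[int(t)].append((pos, alt))

    uids: set[str] = set()
    reads: list[ReadPair] = []
    truth = {"uids": [], "carriers": {}}
    for t in range(n_templates):
        while True:
            uid = _random_seq(14, rng)
            if uid not in uids:
                uids.add(uid)
                break
        tmpl = list(ref)
        for pos, alt in carriers[t]:
            tmpl[pos - amplicon.start] = alt
        tmpl_seq = "".join(tmpl)
        truth["uids"].append(uid)
        if carriers[t]:
            truth["carriers"][uid] = list(carriers[t])
        for strand, insert in (("W", tmpl_seq), ("C", revcomp(tmpl_seq))):
            if family_size_dist == "geometric":
                n_reads = 1 + int(rng.geometric(1.0 / max(reads_per_strand, 1)) - 1)
            else:
                n_reads = reads_per_strand
            for r in range(n_reads):
                obs = _add_errors(insert, per_base_error, rng)
                reads.append(
                    ReadPair(
                        name=f"{amplicon.gene}:{t}:{strand}:{r}",
                        r1=uid + obs,
                        r2=revcomp(obs),
                    )
                )
    return reads, truth


@dataclass
class CohortData:
    config: CohortConfig
    build: GenomeBuild
    bins: list[Bin]
    karyotypes: list[Karyotype]
    matrix: BinCallMatrix
    meta: pd.DataFrame
    fish: pd.DataFrame
    expression: pd.DataFrame
    gene_copy_number: pd.DataFrame
    truth: dict
    amplicons: list = field(default_factory=list)
    cosmic: pd.DataFrame | None = None
    reads: dict[str, list[ReadPair]] = field(default_factory=dict)


def _gene_panel() -> list[tuple[str, Locus]]:
    """Small synthetic panel: genes inside each 1q critical region plus
    off-target genes on 1p."""
    genes = []
    for i in range(6):
        s = LOCUS_1Q23_2.start + i * 200_000
        genes.append((f"G1Q23_{i}", Locus(f"G1Q23_{i}", "1", s, s + 1000)))
    for i in range(6):
        s = LOCUS_1Q42_13.start + i * 500_000
        genes.append((f"G1Q42_{i}", Locus(f"G1Q42_{i}", "1", s, s + 1000)))
    for i in range(4):
        s = 10_000_000 + i * 1_000_000
        genes.append((f"G1P_{i}", Locus(f"G1P_{i}", "1", s, s + 1000)))
    return genes


def simulate_cohort(config: CohortConfig, build: GenomeBuild | None = None) -> CohortData:
    """Generate a fully reproducible cohort (same config + seed -> identical).

    Produces the bin-call matrix, lesion metadata, per-nucleus FISH counts at
    the 1q25 probe, a gene-level copy-number/expression pair, and a truth
    table covering arm events, focal regions, WGD, purity and mutations.
    """
    build = build or GenomeBuild.hg19()
    rng = np.random.default_rng(config.seed)
    bins, _ = _grid(build, config.bin_size)

    karyotypes: list[Karyotype] = []
    meta_rows = []
    fish_rows = []
    calls_cols = []
    truth: dict[str, dict] = {}
    counter = 0
    for grade in GRADES:
        n = config.n_per_grade.get(grade, 0)
        for k in range(n):
            counter += 1
            sid = f"S{counter:04d}_{grade}"
            kt, events = simulate_karyotype(sid, grade, config, rng, build)
            lo, hi = config.purity.get(grade, (0.6, 0.9))
            purity = float(rng.uniform(lo, hi))
            _, calls = render_bin_profile(kt, bins, purity, config.noise_sd, rng)
            calls_cols.append(calls)
            karyotypes.append(kt)
            meta_rows.append({"sample_id": sid, "patient_id": f"P{counter:04d}",
                              "grade": grade, "preservation": "FFPE"})
            counts = simulate_fish_counts(kt, DEFAULT_FISH_PROBE, 60, 0.95, rng)
            for ni, c in enumerate(counts):
                fish_rows.append({"sample_id": sid, "probe": DEFAULT_FISH_PROBE.name,
                                  "compartment": "neoplastic",
                                  "nucleus_index": ni, "signals": int(c)})
            muts = {g: False for g in
                    ("KRAS", "NRAS", "GNAS", "CDKN2A", "TP53", "SMAD4")}
            if grade not in ("NORMAL", "SCA"):
                if rng.random() < 0.8:
                    muts["KRAS"] = True
                else:
                    muts["GNAS"] = True
                if rng.random() < config.ts_mutation_prob.get(grade, 0.0):
                    muts[("CDKN2A", "TP53", "SMAD4")[rng.integers(3)]] = True
            truth[sid] = {
                "grade": grade,
                "purity": purity,
                "wgd": kt.base_ploidy == 4,
                "base_ploidy": kt.base_ploidy,
                "arm_events": [
                    {"arm": e.arm, "direction": e.direction, "full": e.full,
                     "start": e.start, "end": e.end, "anchor": e.anchor}
                    for e in events
                ],
                "mutations": muts,
            }

    samples = [m["sample_id"] for m in meta_rows]
    if calls_cols:
        calls = np.stack(calls_cols, axis=1)
    else:
        calls = np.empty((len(bins), 0), dtype="<U1")
    matrix = BinCallMatrix(bins, samples, calls)
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "patient_id", "grade", "preservation"]
    )
    fish = pd.DataFrame(
        fish_rows,
        columns=["sample_id", "probe", "compartment", "nucleus_index", "signals"],
    )

    panel = _gene_panel()
    cn = pd.DataFrame(index=[g for g, _ in panel], columns=samples, dtype=float)
    for g, loc in panel:
        mid = (loc.start + loc.end) // 2
        for kt in karyotypes:
            cn.loc[g, kt.sample_id] = kt.copies_at(loc.chrom, mid)
    if samples:
        expr, responsive = simulate_expression(cn, effect_size=2.0, noise_sd=0.5,
                                               rng=rng)
    else:
        expr, responsive = cn.copy(), {}
    truth["_genes"] = {"responsive": responsive}

    amplicons: list = []
    cosmic = None
    reads: dict[str, list[ReadPair]] = {}
    if config.simulate_reads:
        from .duplex_caller import make_matching_cosmic, make_synthetic_amplicons

        amplicons = make_synthetic_amplicons(rng)
        canonical = {}
        for amp in amplicons:
            offset = 60
            ref_base = amp.ref_seq[offset]
            alt = "ACGT"[("ACGT".index(ref_base) + 1) % 4]
            canonical[amp.gene] = (amp, amp.start + offset, alt)
        cosmic = make_matching_cosmic(list(canonical.values()))
        for sid in samples:
            muts = truth[sid]["mutations"]
            sample_reads: list[ReadPair] = []
            for amp in amplicons:
                _, pos, alt = canonical[amp.gene]
                variants = [(pos, alt, 0.5)] if muts.get(amp.gene) else []
                amp_reads, _ = simulate_duplex_reads(
                    amp, config.reads_n_templates, config.reads_per_strand,
                    variants, config.reads_error, rng,
                )
                sample_reads.extend(amp_reads)
            reads[sid] = sample_reads

    return CohortData(config, build, bins, karyotypes, matrix, meta, fish,
                      expr, cn, truth, amplicons, cosmic, reads)


def write_fastq(reads: Sequence[ReadPair], path_r1, path_r2) -> None:
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for rp in reads:
            f1.write(f"@{rp.name}/1\n{rp.r1}\n+\n{'I' * len(rp.r1)}\n")
            f2.write(f"@{rp.name}/2\n{rp.r2}\n+\n{'I' * len(rp.r2)}\n")


def write_cohort(data: CohortData, outdir) -> dict[str, str]:
    """Write all cohort artifacts as plain-text files; returns path map."""
    import os

    from .cna_calls import write_bin_call_matrix

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "bins": os.path.join(outdir, "bin_calls.tsv"),
        "meta": os.path.join(outdir, "lesion_meta.tsv"),
        "fish": os.path.join(outdir, "fish_counts.tsv"),
        "expression": os.path.join(outdir, "expression.tsv"),
        "gene_cn": os.path.join(outdir, "gene_copy_number.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_bin_call_matrix(data.matrix, paths["bins"])
    data.meta.to_csv(paths["meta"], sep="\t", index=False)
    data.fish.to_csv(paths["fish"], sep="\t", index=False)
    data.expression.to_csv(paths["expression"], sep="\t", index_label="gene")
    data.gene_copy_number.to_csv(paths["gene_cn"], sep="\t", index_label="gene")
    with open(paths["truth"], "w") as fh:
        json.dump(data.truth, fh, indent=1, sort_keys=True)
    if data.reads:
        from .duplex_caller import write_amplicons_tsv

        paths["amplicons"] = os.path.join(outdir, "amplicons.tsv")
        write_amplicons_tsv(data.amplicons, paths["amplicons"])
        paths["cosmic"] = os.path.join(outdir, "cosmic_lookup.tsv")
        data.cosmic.to_csv(paths["cosmic"], sep="\t", index=False)
        reads_dir = os.path.join(outdir, "reads")
        os.makedirs(reads_dir, exist_ok=True)
        for sid, sample_reads in data.reads.items():
            write_fastq(sample_reads,
                        os.path.join(reads_dir, f"{sid}_R1.fastq"),
                        os.path.join(reads_dir, f"{sid}_R2.fastq"))
        paths["reads_dir"] = reads_dir
    return paths
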