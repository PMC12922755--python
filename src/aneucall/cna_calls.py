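"""Bin-call ingest, sample QC, arm-level gain/loss calling and cohort tables.

Arm calling implements the full-arm rule (gained bins >= arm bins - 3,
i.e. at most 3 non-gained bins on the arm) and a minimum-run criterion
for partial events (default 6 bins = 3 Mb).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_model import (
    ArmDef,
    Bin,
    GenomeBuild,
    arm_bin_ranges,
    arm_defs,
    make_bins,
)

__all__ = [
    "BinCallMatrix",
    "SampleQC",
    "LesionMeta",
    "GRADES",
    "FULL_ARM_SLACK",
    "DEFAULT_MIN_RUN",
    "DEFAULT_MAD_MAX",
    "read_bin_call_matrix",
    "write_bin_call_matrix",
    "read_lesion_meta",
    "read_sample_qc",
    "qc_sample",
    "call_arm",
    "call_arms",
    "cohort_arm_frequencies",
    "full_vs_partial_breakdown",
]

GRADES = (
    "NORMAL", "LG_PANIN", "HG_PANIN", "LG_IPMN", "HG_IPMN", "MCN", "SCA", "PDAC",
)

VALID_CALLS = frozenset("GNL")

#: non-gained bins tolerated by the full-arm rule
FULL_ARM_SLACK = 3
#: minimum consecutive altered bins for a (partial) arm event; 6 bins = 3 Mb
DEFAULT_MIN_RUN = 6
#: strict GC-correction MAD cutoff: samples with mad >= this are dropped
DEFAULT_MAD_MAX = 0.15
#: observed/expected variance ratio above which a sample is flagged (not dropped)
DEFAULT_VARIANCE_RATIO_MAX = 2.0


@dataclass
class BinCallMatrix:
    """bins x samples matrix of discrete copy-number calls {G, N, L}."""

    bins: list[Bin]
    samples: list[str]
    calls: np.ndarray  # shape (n_bins, n_samples), dtype '<U1'

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype="<U1")
        if self.calls.shape != (len(self.bins), len(self.samples)):
            raise ValueError("calls shape does not match bins x samples")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        bad = set(np.unique(self.calls)) - VALID_CALLS
        if bad:
            raise ValueError(f"invalid call symbols: {sorted(bad)}")

    def column(self, sample_id: str) -> np.ndarray:
        return self.calls[:, self.samples.index(sample_id)]

    def subset_samples(self, sample_ids: Sequence[str]) -> "BinCallMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return BinCallMatrix(self.bins, list(sample_ids), self.calls[:, idx])


@dataclass(frozen=True)
class SampleQC:
    sample_id: str
    mad: float
    expected_variance: float | None = None
    observed_variance: float | None = None
    n_segments: int | None = None

    def __post_init__(self) -> None:
        if self.mad < 0:
            raise ValueError("mad must be >= 0")


@dataclass(frozen=True)
class LesionMeta:
    sample_id: str
    patient_id: str
    grade: str
    preservation: str = "FFPE"

    def __post_init__(self) -> None:
        if self.grade not in GRADES:
            raise ValueError(f"unknown grade {self.grade!r}")


def read_bin_call_matrix(path, build: GenomeBuild | None = None) -> BinCallMatrix:
    """Read a bin-call TSV (chrom, start, end, one column per sample).

    When a build is given the rows are reconciled against its 500-kb grid.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["chrom", "start", "end"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"first columns must be {required}, got {list(df.columns[:3])}")
    samples = list(df.columns[3:])
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample columns")
    bins: list[Bin] = []
    idx_within = {}
    for _, row in df.iterrows():
        chrom = str(row["chrom"]).removeprefix("chr")
        i = idx_within.get(chrom, 0)
        idx_within[chrom] = i + 1
        bins.append(Bin(chrom, int(row["start"]), int(row["end"]), i))
    calls = df[samples].to_numpy(dtype="<U1")
    for bi in range(calls.shape[0]):
        for si in range(calls.shape[1]):
            if calls[bi, si] not in VALID_CALLS:
                raise ValueError(
                    f"invalid call {calls[bi, si]!r} at bin "
                    f"{bins[bi].chrom}:{bins[bi].start} sample {samples[si]!r}"
                )
    if build is not None:
        expected = make_bins(build)
        got = [(b.chrom, b.start, b.end) for b in bins]
        want = [(b.chrom, b.start, b.end) for b in expected]
        if got != want:
            raise ValueError("bin grid does not match the build's 500-kb grid")
        bins = expected
    return BinCallMatrix(bins, samples, calls)


def write_bin_call_matrix(matrix: BinCallMatrix, path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [b.chrom for b in matrix.bins],
            "start": [b.start for b in matrix.bins],
            "end": [b.end for b in matrix.bins],
        }
    )
    for si, s in enumerate(matrix.samples):
        df[s] = matrix.calls[:, si]
    df.to_csv(path, sep="\t", index=False)


def read_lesion_meta(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "patient_id", "grade"):
        if col not in df.columns:
            raise ValueError(f"metadata missing column {col!r}")
    bad = set(df["grade"]) - set(GRADES)
    if bad:
        raise ValueError(f"unknown grades in metadata: {sorted(bad)}")
    return df


def read_sample_qc(path) -> list[SampleQC]:
    """QC TSV: sample_id, mad, and optional expected_variance,
    observed_variance, n_segments columns."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "mad"} <= set(df.columns):
        raise ValueError("QC table needs sample_id and mad columns")

    def opt(row, col, cast):
        return cast(row[col]) if col in df.columns and pd.notna(row[col]) else None

    return [
        SampleQC(
            str(r["sample_id"]), float(r["mad"]),
            opt(r, "expected_variance", float),
            opt(r, "observed_variance", float),
            opt(r, "n_segments", int),
        )
        for _, r in df.iterrows()
    ]


def qc_sample(
    qc: SampleQC,
    mad_max: float = DEFAULT_MAD_MAX,
    variance_ratio_max: float = DEFAULT_VARIANCE_RATIO_MAX,
) -> tuple[bool, list[str]]:
    """Return (keep, flags). Drop only on the strict MAD rule (mad < mad_max
    required); a high observed/expected variance ratio is flagged, never
    auto-dropped."""
    if mad_max <= 0 or variance_ratio_max <= 0:
        raise ValueError("thresholds must be > 0")
    flags: list[str] = []
    keep = True
    if qc.mad >= mad_max:
        keep = False
        flags.append(f"mad>={mad_max}")
    if (
        qc.observed_variance is not None
        and qc.expected_variance not in (None, 0)
        and qc.observed_variance / qc.expected_variance > variance_ratio_max
    ):
        flags.append("high_variance_ratio")
    return keep, flags


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def call_arm(arm_calls: Sequence[str], min_run: int = DEFAULT_MIN_RUN) -> dict:
    """Call one sample's events on one arm from its ordered G/N/L bin calls.

    full-arm gain: gained bins >= arm bins - FULL_ARM_SLACK; analogous for
    losses. A partial event requires a run of >= min_run consecutive altered
    bins. GAIN takes precedence over LOSS in `state`; both directions are
    recorded in has_gain/has_loss.
    """
    arr = np.asarray(list(arm_calls), dtype="<U1")
    n = arr.size
    if n == 0:
        raise ValueError("empty arm")
    gained = int(np.sum(arr == "G"))
    lost = int(np.sum(arr == "L"))
    full_gain = gained >= n - FULL_ARM_SLACK
    full_loss = lost >= n - FULL_ARM_SLACK
    has_gain = full_gain or _longest_run(arr == "G") >= min_run
    has_loss = full_loss or _longest_run(arr == "L") >= min_run
    if has_gain:
        state, full = "GAIN", full_gain
    elif has_loss:
        state, full = "LOSS", full_loss
    else:
        state, full = "NEUTRAL", False
    return {
        "state": state,
        "full_arm": full,
        "has_gain": has_gain,
        "has_loss": has_loss,
        "full_gain": full_gain,
        "full_loss": full_loss,
        "gained_bins": gained,
        "lost_bins": lost,
        "arm_bins": n,
    }


def call_arms(
    matrix: BinCallMatrix,
    build: GenomeBuild,
    min_run: int = DEFAULT_MIN_RUN,
    include_excluded_arms: bool = False,
) -> pd.DataFrame:
    """Arm-call table over all samples and reportable arms."""
    arms = arm_defs(build, matrix.bins)
    ranges = arm_bin_ranges(matrix.bins, arms)
    rows = []
    for a in arms:
        if a.excluded and not include_excluded_arms:
            continue
        rng = ranges.get(a.name)
        if rng is None:
            continue
        idx = np.arange(rng.start, rng.stop)
        for si, sample in enumerate(matrix.samples):
            res = call_arm(matrix.calls[idx, si], min_run=min_run)
            rows.append({"sample_id": sample, "arm": a.name, **res})
    return pd.DataFrame(rows)


def _filter_samples(arm_table: pd.DataFrame, meta: pd.DataFrame | None, grades):
    if meta is None or grades is None:
        return sorted(arm_table["sample_id"].unique())
    grades = {grades} if isinstance(grades, str) else set(grades)
    keep = set(meta.loc[meta["grade"].isin(grades), "sample_id"])
    return sorted(s for s in arm_table["sample_id"].unique() if s in keep)


def cohort_arm_frequencies(
    arm_table: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    grades=None,
) -> pd.DataFrame:
    """Per-arm gain/loss fractions over a stratum (any gain counts, full or
    partial); gains and losses are tallied independently."""
    samples = _filter_samples(arm_table, meta, grades)
    if not samples:
        raise ValueError("empty stratum")
    sub = arm_table[arm_table["sample_id"].isin(samples)]
    n = len(samples)
    rows = []
    for arm in _sorted_arms(sub["arm"].unique()):
        aa = sub[sub["arm"] == arm]
        n_gain = int(aa["has_gain"].sum())
        n_loss = int(aa["has_loss"].sum())
        rows.append(
            {
                "arm": arm,
                "n_samples": n,
                "n_gain": n_gain,
                "n_loss": n_loss,
                "gain_frac": n_gain / n,
                "loss_frac": n_loss / n,
            }
        )
    return pd.DataFrame(rows)


def _sorted_arms(arms: Iterable[str]) -> list[str]:
    def key(a: str):
        chrom = a[:-1]
        return (int(chrom), a[-1])

    return sorted(arms, key=key)


def full_vs_partial_breakdown(
    arm_table: pd.DataFrame,
    arm: str,
    direction: str = "GAIN",
    meta: pd.DataFrame | None = None,
    grades=None,
) -> tuple[int, int]:
    """(n_full, n_partial) among samples carrying the event on `arm`."""
    samples = _filter_samples(arm_table, meta, grades)
    sub = arm_table[(arm_table["arm"] == arm) & arm_table["sample_id"].isin(samples)]
    if direction.upper() == "GAIN":
        carriers = sub[sub["has_gain"]]
        n_full = int(carriers["full_gain"].sum())
    else:
        carriers = sub[sub["has_loss"]]
        n_full = int(carriers["full_loss"].sum())
    return n_full, len(carriers) - n_full
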