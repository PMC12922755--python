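"""Minimal-common-region localization on an arm and dosage-expression screen.

Gain-fraction profiles are computed from tumors with subchromosomal gains
(or from all gained tumors, selectable), peaks are plateaus within a relative
tolerance of the profile maximum, and locus inclusion uses a strict majority
of the bins overlapping the locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cna_calls import BinCallMatrix
from .genome_model import GenomeBuild, Locus, arm_bin_ranges, arm_defs, overlapping_bins

__all__ = [
    "GainFractionProfile",
    "PeakRegion",
    "LocusInclusionCall",
    "gain_fraction_profile",
    "detect_peaks",
    "locus_included",
    "joint_locus_classification",
    "dosage_expression_association",
]

DEFAULT_REL_TOL = 0.02
DEFAULT_MERGE_GAP_BINS = 4
DEFAULT_ALPHA = 1e-5


@dataclass
class GainFractionProfile:
    arm: str
    bin_indices: np.ndarray       # global bin indices, contiguous
    fractions: np.ndarray         # per-bin gained fraction in [0, 1]
    n_samples: int
    mode: str                     # "partial_only" | "any_gain"


@dataclass(frozen=True)
class PeakRegion:
    chrom: str
    start: int
    end: int
    height: float
    member_bins: tuple[int, ...]


@dataclass(frozen=True)
class LocusInclusionCall:
    sample_id: str
    locus: str
    included: bool
    gained_overlapping: int
    total_overlapping: int


def _select_arm_samples(arm_calls: pd.DataFrame, arm: str, mode: str) -> list[str]:
    sub = arm_calls[(arm_calls["arm"] == arm) & arm_calls["has_gain"]]
    if mode == "partial_only":
        sub = sub[~sub["full_gain"]]
    elif mode != "any_gain":
        raise ValueError(f"unknown mode {mode!r}")
    return list(sub["sample_id"])


def gain_fraction_profile(
    matrix: BinCallMatrix,
    arm_calls: pd.DataFrame,
    arm: str,
    build: GenomeBuild,
    mode: str = "partial_only",
) -> GainFractionProfile:
    """Per-bin fraction of selected gained samples with a G call at the bin."""
    selected = _select_arm_samples(arm_calls, arm, mode)
    if not selected:
        raise ValueError(f"no samples in denominator for arm {arm} mode {mode}")
    ranges = arm_bin_ranges(matrix.bins, arm_defs(build, matrix.bins))
    rng = ranges[arm]
    idx = np.arange(rng.start, rng.stop)
    cols = [matrix.samples.index(s) for s in selected]
    gained = matrix.calls[np.ix_(idx, cols)] == "G"
    return GainFractionProfile(
        arm=arm,
        bin_indices=idx,
        fractions=gained.mean(axis=1),
        n_samples=len(selected),
        mode=mode,
    )


def detect_peaks(
    profile: GainFractionProfile,
    matrix_bins,
    rel_tol: float = DEFAULT_REL_TOL,
    merge_gap_bins: int = DEFAULT_MERGE_GAP_BINS,
    max_peaks: int | None = None,
) -> list[PeakRegion]:
    """Plateaus of bins with fraction >= max * (1 - rel_tol); nearby runs are
    merged; result sorted by height then width, truncated to max_peaks."""
    frac = np.asarray(profile.fractions, dtype=float)
    if frac.size == 0:
        raise ValueError("empty profile")
    peak_max = frac.max()
    if peak_max == 0:
        return []
    thresh = peak_max * (1.0 - rel_tol)
    above = frac >= thresh
    runs: list[list[int]] = []
    for i, flag in enumerate(above):
        if not flag:
            continue
        if runs and i - runs[-1][-1] <= 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][-1] - 1 < merge_gap_bins:
            merged[-1] = list(range(merged[-1][0], run[-1] + 1))
        else:
            merged.append(run)
    peaks = []
    for run in merged:
        gidx = [int(profile.bin_indices[i]) for i in run]
        b0, b1 = matrix_bins[gidx[0]], matrix_bins[gidx[-1]]
        peaks.append(
            PeakRegion(
                chrom=b0.chrom,
                start=b0.start,
                end=b1.end,
                height=float(frac[run].max()),
                member_bins=tuple(gidx),
            )
        )
    peaks.sort(key=lambda p: (-p.height, -(p.end - p.start)))
    return peaks[:max_peaks] if max_peaks else peaks


def locus_included(
    matrix: BinCallMatrix,
    sample_id: str,
    locus: Locus,
    rule: str = "majority",
) -> LocusInclusionCall:
    """A sample's gain includes a locus when more than half (rule="majority")
    or all (rule="all") of the overlapping bins are G."""
    idx = overlapping_bins(locus, matrix.bins)
    if not idx:
        raise ValueError(f"locus {locus.name} overlaps no bins")
    col = matrix.column(sample_id)
    gained = int(np.sum(col[idx] == "G"))
    if rule == "majority":
        included = gained > len(idx) / 2
    elif rule == "all":
        included = gained == len(idx)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return LocusInclusionCall(sample_id, locus.name, included, gained, len(idx))


def joint_locus_classification(
    matrix: BinCallMatrix,
    arm_calls: pd.DataFrame,
    locus_a: Locus,
    locus_b: Locus,
    arm: str,
    sample_ids=None,
    rule: str = "majority",
) -> dict[str, int]:
    """Counts {both, A_only, B_only, neither} over samples with any gain on
    the arm (optionally restricted to `sample_ids`)."""
    carriers = _select_arm_samples(arm_calls, arm, "any_gain")
    if sample_ids is not None:
        keep = set(sample_ids)
        carriers = [s for s in carriers if s in keep]
    counts = {"both": 0, "A_only": 0, "B_only": 0, "neither": 0}
    for s in carriers:
        a = locus_included(matrix, s, locus_a, rule).included
        b = locus_included(matrix, s, locus_b, rule).included
        key = {(True, True): "both", (True, False): "A_only",
               (False, True): "B_only", (False, False): "neither"}[(a, b)]
        counts[key] += 1
    counts["n"] = len(carriers)
    return counts


def dosage_expression_association(
    copy_number: pd.DataFrame,
    expression: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    method: str = "pearson",
) -> pd.DataFrame:
    """Per-gene correlation test of expression against copy number.

    Genes (rows) must align between the two matrices; samples are matched by
    column name. Zero-variance genes are flagged and excluded from the
    significant set. Returns a table with statistic, p and significance at
    p < alpha.
    """
    common = [c for c in copy_number.columns if c in set(expression.columns)]
    if len(common) < 3:
        raise ValueError("need >= 3 shared samples")
    genes = list(copy_number.index)
    if set(genes) != set(expression.index):
        raise ValueError("gene sets differ between matrices")
    rows = []
    for g in genes:
        cn = copy_number.loc[g, common].to_numpy(dtype=float)
        ex = expression.loc[g, common].to_numpy(dtype=float)
        if np.std(cn) == 0 or np.std(ex) == 0:
            rows.append({"gene": g, "statistic": np.nan, "p": np.nan,
                         "significant": False, "flag": "zero_variance"})
            continue
        if method == "pearson":
            r, p = stats.pearsonr(cn, ex)
        elif method == "spearman":
            r, p = stats.spearmanr(cn, ex)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({"gene": g, "statistic": float(r), "p": float(p),
                     "significant": bool(p < alpha), "flag": ""})
    return pd.DataFrame(rows)
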