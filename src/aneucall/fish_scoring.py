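"""Per-nucleus FISH signal scoring, positivity rules, and WGS concordance."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FishSample",
    "FishSummary",
    "SIGNAL_CAP",
    "POSITIVITY_RULES",
    "cap_counts",
    "summarize",
    "classify_positive",
    "wgs_fish_concordance",
    "read_fish_table",
    "write_fish_summaries",
]

#: nuclei with more signals than this are recorded as exactly this many
SIGNAL_CAP = 10

POSITIVITY_RULES = ("ge3_at_20pct", "ge4_at_10pct", "majority_ge3")

#: tumor fraction below which a FISH+/WGS- discordance is blamed on purity
DEFAULT_PURITY_MIN = 0.2


@dataclass
class FishSample:
    sample_id: str
    probe: str
    compartment: str  # "neoplastic" | "nonneoplastic"
    counts: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.compartment not in ("neoplastic", "nonneoplastic"):
            raise ValueError(f"bad compartment {self.compartment!r}")
        if any(c < 0 for c in self.counts):
            raise ValueError("negative signal count")


@dataclass(frozen=True)
class FishSummary:
    mean_signals: float
    frac_ge3: float
    frac_ge4: float
    n_nuclei: int


def cap_counts(raw: Sequence[int], cap: int = SIGNAL_CAP) -> list[int]:
    """Replace every count above the cap by the cap value."""
    out = []
    for c in raw:
        if c < 0:
            raise ValueError("negative signal count")
        out.append(min(int(c), cap))
    return out


def summarize(sample: FishSample) -> FishSummary:
    counts = np.asarray(cap_counts(sample.counts))
    if counts.size == 0:
        raise ValueError("empty counts")
    return FishSummary(
        mean_signals=float(counts.mean()),
        frac_ge3=float(np.mean(counts >= 3)),
        frac_ge4=float(np.mean(counts >= 4)),
        n_nuclei=int(counts.size),
    )


def classify_positive(summary: FishSummary, rule: str = "ge3_at_20pct") -> bool:
    """Positivity rules: >=3 signals in >=20% of nuclei (inclusive), >=4 in
    >=10% (inclusive), or >=3 in a strict majority."""
    if rule == "ge3_at_20pct":
        return summary.frac_ge3 >= 0.20
    if rule == "ge4_at_10pct":
        return summary.frac_ge4 >= 0.10
    if rule == "majority_ge3":
        return summary.frac_ge3 > 0.5
    raise ValueError(f"unknown rule {rule!r}")


def wgs_fish_concordance(
    wgs_state: str,
    fish_positive: bool,
    tumor_fraction: float | None = None,
    purity_min: float = DEFAULT_PURITY_MIN,
) -> str:
    """Classify a (WGS arm call, FISH positivity) pair.

    FISH-positive / WGS-non-gain pairs are attributed to low purity when the
    tumor fraction is known and below `purity_min`, otherwise to the
    relative-vs-absolute copy-number blindness of median-normalized WGS calls
    (e.g. whole-genome doubling).
    """
    wgs_gain = wgs_state.upper() == "GAIN"
    if wgs_gain == fish_positive:
        return "concordant"
    if fish_positive and not wgs_gain:
        if tumor_fraction is not None and tumor_fraction < purity_min:
            return "discordant_low_purity"
        return "discordant_relative_cn"
    return "discordant_other"


def read_fish_table(path) -> list[FishSample]:
    """Read a per-nucleus TSV (sample_id, probe, compartment, nucleus_index,
    signals); nuclei from multiple analysts are pooled by concatenation."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for (sid, probe, comp), grp in df.groupby(
        ["sample_id", "probe", "compartment"], sort=True
    ):
        out.append(
            FishSample(str(sid), str(probe), str(comp), [int(v) for v in grp["signals"]])
        )
    return out


def write_fish_summaries(samples: Sequence[FishSample], path) -> pd.DataFrame:
    rows = []
    for s in samples:
        summ = summarize(s)
        rows.append(
            {
                "sample_id": s.sample_id,
                "probe": s.probe,
                "compartment": s.compartment,
                "n_nuclei": summ.n_nuclei,
                "mean_signals": summ.mean_signals,
                "frac_ge3": summ.frac_ge3,
                "frac_ge4": summ.frac_ge4,
                "positive_ge3_at_20pct": classify_positive(summ, "ge3_at_20pct"),
                "positive_ge4_at_10pct": classify_positive(summ, "ge4_at_10pct"),
                "positive_majority_ge3": classify_positive(summ, "majority_ge3"),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
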