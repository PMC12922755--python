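"""Co-occurrence and progression-context statistics.

The exact two-tailed Fisher test is implemented from first principles
(hypergeometric enumeration, method of small p-values) rather than delegated,
because the tail definition is part of the contract; tests cross-check it
against brute-force enumeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContingencyTable2x2",
    "ContextRule",
    "fisher_exact_two_tailed",
    "context_fraction",
    "compare_context_between_strata",
    "pairwise_event_independence",
]

_TIE_REL_TOL = 1e-12


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows = group, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("cell counts must be non-negative integers")
        if self.total < 1:
            raise ValueError("table total must be >= 1")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_list(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


@dataclass(frozen=True)
class ContextRule:
    """A focal event plus the context events whose co-presence is scored."""

    focal: tuple[str, str] = ("1q", "GAIN")
    context: tuple[tuple[str, str], ...] = (
        ("8q", "GAIN"),
        ("9p", "LOSS"),
        ("17p", "LOSS"),
        ("18q", "LOSS"),
    )

    def __post_init__(self) -> None:
        if self.focal in self.context:
            raise ValueError("focal event must not appear among context events")


def _log_hypergeom_pmf(k: int, r1: int, r2: int, c1: int) -> float:
    # P(X = k) for X ~ Hypergeom(n = r1 + r2, K = c1, draws = r1)
    n = r1 + r2
    return (
        math.lgamma(r1 + 1) - math.lgamma(k + 1) - math.lgamma(r1 - k + 1)
        + math.lgamma(r2 + 1) - math.lgamma(c1 - k + 1)
        - math.lgamma(r2 - c1 + k + 1)
        + math.lgamma(c1 + 1) + math.lgamma(n - c1 + 1) - math.lgamma(n + 1)
    )


def fisher_exact_two_tailed(table) -> float:
    """Exact two-tailed Fisher p-value (method of small p-values).

    Sums hypergeometric probabilities of all tables with the observed margins
    whose probability is <= the observed table's probability, with a 1e-12
    relative tolerance for ties. Degenerate margins give p = 1.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        return 1.0
    kmin = max(0, c1 - r2)
    kmax = min(r1, c1)
    logp = np.array([_log_hypergeom_pmf(k, r1, r2, c1) for k in range(kmin, kmax + 1)])
    p_obs = logp[a - kmin]
    cutoff = p_obs + math.log1p(_TIE_REL_TOL)
    p = float(np.exp(logp[logp <= cutoff]).sum())
    return min(p, 1.0)


def _has_event(arm_calls: pd.DataFrame, sample: str, arm: str, direction: str) -> bool:
    row = arm_calls[(arm_calls["sample_id"] == sample) & (arm_calls["arm"] == arm)]
    if row.empty:
        return False
    col = "has_gain" if direction.upper() == "GAIN" else "has_loss"
    return bool(row.iloc[0][col])


def _stratum_samples(meta: pd.DataFrame, grades) -> list[str]:
    if grades is None:
        return list(meta["sample_id"])
    grades = {grades} if isinstance(grades, str) else set(grades)
    return list(meta.loc[meta["grade"].isin(grades), "sample_id"])


def context_fraction(
    arm_calls: pd.DataFrame,
    meta: pd.DataFrame,
    rule: ContextRule = ContextRule(),
    grades=None,
) -> tuple[int, int, float]:
    """Among samples carrying the focal event, the share with >= 1 context event.

    Returns (n_focal, n_with_context, fraction); fraction is NaN when no
    sample has the focal event.
    """
    samples = _stratum_samples(meta, grades)
    if not samples:
        raise ValueError("empty stratum")
    focal_arm, focal_dir = rule.focal
    n_focal = 0
    n_ctx = 0
    for s in samples:
        if not _has_event(arm_calls, s, focal_arm, focal_dir):
            continue
        n_focal += 1
        if any(_has_event(arm_calls, s, arm, d) for arm, d in rule.context):
            n_ctx += 1
    frac = n_ctx / n_focal if n_focal else float("nan")
    return n_focal, n_ctx, frac


def compare_context_between_strata(
    arm_calls: pd.DataFrame,
    meta: pd.DataFrame,
    rule: ContextRule,
    grades_a,
    grades_b,
) -> tuple[ContingencyTable2x2, float]:
    """2x2 of (with/without context) x stratum among focal-event carriers."""
    na, ka, _ = context_fraction(arm_calls, meta, rule, grades_a)
    nb, kb, _ = context_fraction(arm_calls, meta, rule, grades_b)
    table = ContingencyTable2x2(ka, na - ka, kb, nb - kb)
    return table, fisher_exact_two_tailed(table)


def pairwise_event_independence(
    arm_calls: pd.DataFrame,
    events: Sequence[tuple[str, str]],
    samples: Sequence[str] | None = None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Pairwise 2x2 association of events across samples.

    Odds ratios use a +0.5 Haldane correction only when a zero cell occurs;
    p-values are exact Fisher, uncorrected by default (Benjamini-Hochberg
    optional).
    """
    if len(events) < 2:
        raise ValueError("need >= 2 events")
    if samples is None:
        samples = sorted(arm_calls["sample_id"].unique())
    presence = {
        ev: np.array([_has_event(arm_calls, s, ev[0], ev[1]) for s in samples])
        for ev in events
    }
    rows = []
    for i, e1 in enumerate(events):
        for e2 in events[i + 1:]:
            x, y = presence[e1], presence[e2]
            a = int(np.sum(x & y))
            b = int(np.sum(x & ~y))
            c = int(np.sum(~x & y))
            d = int(np.sum(~x & ~y))
            p = fisher_exact_two_tailed(ContingencyTable2x2(a, b, c, d))
            if min(a, b, c, d) == 0:
                orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
            else:
                orr = (a * d) / (b * c)
            rows.append(
                {
                    "event_a": f"{e1[0]}:{e1[1]}",
                    "event_b": f"{e2[0]}:{e2[1]}",
                    "a": a, "b": b, "c": c, "d": d,
                    "odds_ratio": orr,
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    if bh_correct and len(out):
        m = len(out)
        order = np.argsort(out["p"].to_numpy())
        q = np.empty(m)
        prev = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            prev = min(prev, out["p"].iloc[i] * m / (rank_idx + 1))
            q[i] = prev
        out["q_bh"] = q
    return out
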