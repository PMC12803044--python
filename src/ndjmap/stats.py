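"""Inferential statistics and crossover-landscape summaries.

The two-proportion Z-test is coded directly from the pooled-variance
formula (continuity correction off by default, switchable, since the
common R convenience wrapper applies one silently).  Mann-Whitney rank
tests delegate to scipy (exact enumeration for small tie-free samples,
normal approximation with tie correction otherwise).  Landscape summaries
bin crossover calls into fixed-width intervals as per-event exchange
rates (the "coefficient of exchange" per Mb).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, norm

from .chromosome_model import ChromosomeModel
from .xo_caller import CrossoverCall


@dataclass(frozen=True)
class ProportionTestResult:
    z: float
    p_one_tailed: float
    counts: tuple[int, int, int, int]
    direction: str
    continuity: bool


def two_proportion_z(x1: int, n1: int, x2: int, n2: int, direction: str = "greater",
                     continuity: bool = False) -> ProportionTestResult:
    """One-tailed two-proportion Z-test with pooled variance.

    z = (p1 - p2) / sqrt(phat (1 - phat) (1/n1 + 1/n2)) with
    phat = (x1 + x2) / (n1 + n2).  ``direction`` states which proportion is
    hypothesised larger: ``"greater"`` means H1: p1 > p2 and the p-value is
    the upper normal tail of z; ``"less"`` the lower tail.  With
    ``continuity`` a Yates-style correction of 0.5 (1/n1 + 1/n2) shrinks the
    numerator toward zero.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    d = p1 - p2
    if continuity:
        cc = 0.5 * (1 / n1 + 1 / n2)
        d = math.copysign(max(0.0, abs(d) - cc), d)
    z = d / se if se > 0 else 0.0
    p = float(norm.sf(z)) if direction == "greater" else float(norm.cdf(z))
    return ProportionTestResult(z=z, p_one_tailed=p, counts=(x1, n1, x2, n2),
                                direction=direction, continuity=continuity)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    alternative: str
    method: str


def mann_whitney(sample1: Sequence[float], sample2: Sequence[float],
                 direction: str = "two-sided") -> MannWhitneyResult:
    """Mann-Whitney U test of ``sample1`` against ``sample2``.

    ``direction``: ``"greater"`` (sample1 tends larger), ``"less"`` or
    ``"two-sided"``.  Uses exact enumeration when the pooled sample has at
    most 20 values and no ties, otherwise the normal approximation with
    midrank tie correction.
    """
    x = np.asarray(list(sample1), dtype=float)
    y = np.asarray(list(sample2), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if direction not in ("two-sided", "greater", "less"):
        raise ValueError("direction must be 'two-sided', 'greater' or 'less'")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative=direction, method=method)
    return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue),
                             alternative=direction, method=method)


def interval_density(calls: Sequence[CrossoverCall], n_events: int,
                     model: ChromosomeModel, width: int = 1_000_000) -> pd.DataFrame:
    """Per-interval crossover counts and per-event exchange rate.

    Call midpoints are binned into ``width``-sized windows tiling each
    arm's assembly span; rate = count / n_events.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    rows = []
    for arm in model.arms:
        a0, a1 = arm.assembly_span
        edges = list(range(a0, a1, width)) + [a1]
        mids = [c.midpoint for c in calls if c.chrom == arm.contig and c.arm != "gap"]
        counts, _ = np.histogram(mids, bins=edges)
        for (lo, hi), k in zip(zip(edges, edges[1:]), counts):
            rows.append({"chrom": arm.contig, "start": lo, "end": hi,
                         "count": int(k), "rate": k / n_events})
    return pd.DataFrame(rows)


def density_to_bedgraph(density: pd.DataFrame, path) -> None:
    density.to_csv(path, sep="\t", header=False, index=False,
                   columns=["chrom", "start", "end", "rate"])
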