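"""Rule-based binning of NDJ events by their most likely recombinational cause.

Events are assigned, in strict order of precedence:

1. ``no_crossover`` - no observable recombination on the nondisjoined
   chromosome (loss of the obligate chiasma);
2. ``distal_crossover`` - every call lies within the distal fraction of its
   arm (default 24% from the telomere), where a chiasma is least effective
   at holding the bivalent together;
3. ``pericentric_crossover`` - any call inside the pericentric zone
   (heterochromatin plus the centromere-proximal 15% of the adjacent
   euchromatin), where a chiasma interferes with centromeric cohesion;
4. ``unrelated`` - everything else.

On a metacentric chromosome both arms' distal and pericentric zones are
active.  Call positions are taken as the interval midpoint; calls whose
interval straddles a zone boundary are decided by midpoint and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .chromosome_model import ChromosomeModel
from .xo_caller import CrossoverCall

NO_CROSSOVER = "no_crossover"
DISTAL_CROSSOVER = "distal_crossover"
PERICENTRIC_CROSSOVER = "pericentric_crossover"
UNRELATED = "unrelated"

CATEGORIES = (NO_CROSSOVER, DISTAL_CROSSOVER, PERICENTRIC_CROSSOVER, UNRELATED)


@dataclass(frozen=True)
class CategorizerThresholds:
    """Positional thresholds for the cause rules.

    ``distal_fraction``: telomere-anchored arm fraction bounding the distal
    zone.  ``pericentric_euchromatin_fraction``: proportion of each arm's
    euchromatin, adjacent to the heterochromatin, included in the
    pericentric zone.  Both were calibrated on the telocentric X (distalmost
    and *car*-to-*su(f)* map intervals) and applied per arm here.
    """

    distal_fraction: float = 0.24
    pericentric_euchromatin_fraction: float = 0.15
    distal_scope: str = "arm"  # "arm": fraction of the arm; "chromosome": of the whole assembly

    def __post_init__(self) -> None:
        for v in (self.distal_fraction, self.pericentric_euchromatin_fraction):
            if not 0.0 < v < 1.0:
                raise ValueError("threshold fractions must be in (0, 1)")
        if self.distal_scope not in ("arm", "chromosome"):
            raise ValueError("distal_scope must be 'arm' or 'chromosome'")


@dataclass
class CauseCategory:
    category: str
    rule_fired: str
    supporting_calls: list = field(default_factory=list)
    straddled_boundary: bool = False


def _in_interval(x: float, intervals) -> bool:
    return any(a <= x < b for a, b in intervals)


def _is_distal(call: CrossoverCall, model: ChromosomeModel, frac: float,
               scope: str = "arm") -> tuple[bool, bool]:
    """(distal-by-midpoint, interval-straddles-the-boundary)."""
    if call.arm == "gap":
        return False, False
    arm = model.arm_for(call.chrom)
    # distance from the telomere, measured either per arm or against the
    # whole assembled chromosome length
    denom = arm.length if scope == "arm" else sum(a.length for a in model.arms)
    mid = arm.fraction_from_telomere(call.midpoint) * arm.length / denom
    f_left = arm.fraction_from_telomere(max(call.left_snp, arm.assembly_span[0]))
    f_right = arm.fraction_from_telomere(min(call.right_snp, arm.assembly_span[1]))
    lo, hi = sorted(f * arm.length / denom for f in (f_left, f_right))
    return mid <= frac, lo <= frac < hi


def _is_pericentric(call: CrossoverCall, model: ChromosomeModel, frac: float) -> tuple[bool, bool]:
    if call.arm == "gap":
        return True, False
    zone = model.pericentric_zone(frac).get(call.chrom, [])
    mid_in = _in_interval(call.midpoint, zone)
    endpoints_in = {_in_interval(call.left_snp, zone), _in_interval(call.right_snp, zone)}
    return mid_in, len(endpoints_in) > 1


def categorize_event(
    calls: Sequence[CrossoverCall],
    model: ChromosomeModel,
    thresholds: CategorizerThresholds = CategorizerThresholds(),
) -> CauseCategory:
    """Apply the cause rules, in order, to one event's crossover calls.

    Deterministic and invariant to call order.  All calls must lie on the
    modelled chromosome.
    """
    known = set(model.contigs) | {model.name}
    for c in calls:
        if c.chrom not in known:
            raise ValueError(f"call on {c.chrom} does not belong to chromosome {model.name}")
    calls = sorted(calls, key=lambda c: (c.chrom, c.midpoint))

    if len(calls) == 0:
        return CauseCategory(NO_CROSSOVER, "no observable recombination")

    distal_flags = [
        _is_distal(c, model, thresholds.distal_fraction, thresholds.distal_scope)
        for c in calls
    ]
    if all(d for d, _ in distal_flags):
        return CauseCategory(
            DISTAL_CROSSOVER,
            f"all calls within the distal {thresholds.distal_fraction:.0%} of their arm",
            supporting_calls=list(calls),
            straddled_boundary=any(s for _, s in distal_flags),
        )

    peri = [_is_pericentric(c, model, thresholds.pericentric_euchromatin_fraction)
            for c in calls]
    hits = [c for c, (p, _) in zip(calls, peri) if p]
    if hits:
        return CauseCategory(
            PERICENTRIC_CROSSOVER,
            "call within the pericentric heterochromatin or adjacent euchromatin",
            supporting_calls=hits,
            straddled_boundary=any(s for _, s in peri),
        )

    return CauseCategory(UNRELATED, "calls present but neither distal-only nor pericentric",
                         supporting_calls=list(calls))


def cohort_breakdown(categories: Sequence[CauseCategory],
                     labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Category fractions for a cohort, with explicit zero rows.

    ``labels`` optionally groups events (e.g. by MI/MII or by chromosome);
    fractions then sum to 1 within each group.
    """
    if len(categories) == 0:
        raise ValueError("empty cohort")
    if labels is None:
        labels = ["all"] * len(categories)
    if len(labels) != len(categories):
        raise ValueError("labels must align with categories")
    rows = []
    for group in sorted(set(labels)):
        cats = [c.category for c, l in zip(categories, labels) if l == group]
        n = len(cats)
        for cat in CATEGORIES:
            k = sum(1 for c in cats if c == cat)
            rows.append({"cohort": group, "category": cat, "n": k, "fraction": k / n})
    return pd.DataFrame(rows)
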