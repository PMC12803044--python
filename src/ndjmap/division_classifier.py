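"""MI/MII origin classification from pericentric genotype states.

A disomic NDJ progeny that is heterozygous across the centromere must have
received one chromatid from each homolog (a meiosis-I error); homozygosity
for a single parental genotype across the centromere indicates both sister
chromatids of one homolog (a meiosis-II error).  Conflicting pericentric
states - homozygosity for *different* parents on the two arms, or a
HET/HOM mix - are reported as ``ambiguous`` rather than forced into a
class, since those are precisely the signatures of pericentric exchange.

A fully homozygous chromosome is compatible with either MII NDJ or
monosomy rescue (an early mitotic duplication of a single chromatid); the
two are distinguishable only when a recombinant chromatid was duplicated,
which shows up as a direct HOM_P1 <-> HOM_P2 switch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .chromosome_model import ChromosomeModel, CENTROMERE_TO_TELOMERE
from .xo_caller import CrossoverCall, GenotypeSegmentation, HOM_LABELS
from . import stats

MI = "MI"
MII = "MII"
AMBIGUOUS = "ambiguous"
RESCUE_SUSPECT = "rescue_suspect"


@dataclass
class DivisionCall:
    origin: str
    pericentric_states: tuple[str, str]
    evidence: dict = field(default_factory=dict)
    rescue_flag: Optional[bool] = None
    rescue_reason: Optional[str] = None
    reason: Optional[str] = None
    individual: Optional[str] = None


def _proximal_window_state(seg: GenotypeSegmentation, model: ChromosomeModel,
                           window_bp: float, min_markers: int):
    """(state, evidence) of the centromere-proximal window of one arm."""
    arm = model.arm_for(seg.contig)
    a0, a1 = arm.assembly_span
    if arm.orientation == CENTROMERE_TO_TELOMERE:
        lo, hi = a0, a0 + window_bp
    else:
        lo, hi = a1 - window_bp, a1
    inside = (seg.positions >= lo) & (seg.positions <= hi)
    n = int(inside.sum())
    # mean frequency over window markers, from segment means weighted by
    # in-window support
    total, wsum = 0.0, 0
    for s in seg.segments:
        k = int(inside[s.start:s.stop].sum())
        total += s.mean_freq * k
        wsum += k
    mean_freq = total / wsum if wsum else float("nan")
    evidence = {"n_markers": n, "mean_freq": mean_freq}
    if n < min_markers:
        return None, evidence
    state = seg.proximal_terminal_state(model)
    return state, evidence


def classify_division(
    seg_left: GenotypeSegmentation,
    seg_right: GenotypeSegmentation,
    model: ChromosomeModel,
    window_bp: float = 1_000_000,
    min_markers: int = 10,
) -> DivisionCall:
    """Assign MI/MII/ambiguous from the two arms' pericentric states.

    Invariant to arm order.  Insufficient pericentric marker support on
    either arm yields ``ambiguous`` with a reason.
    """
    by_contig = {s.contig: s for s in (seg_left, seg_right)}
    ordered = [by_contig[a.contig] for a in model.arms]
    states, evid = [], {}
    for seg in ordered:
        st, ev = _proximal_window_state(seg, model, window_bp, min_markers)
        states.append(st)
        evid[seg.contig] = ev
    if len(states) == 1:  # telocentric: one pericentric window serves both roles
        states = states * 2
    if any(s is None for s in states):
        return DivisionCall(AMBIGUOUS, tuple(s or "NA" for s in states), evid,
                            reason="insufficient pericentric markers")
    s1, s2 = states
    if s1 == "HET" and s2 == "HET":
        return DivisionCall(MI, (s1, s2), evid)
    if s1 in HOM_LABELS and s2 in HOM_LABELS:
        if s1 == s2:
            return DivisionCall(MII, (s1, s2), evid)
        return DivisionCall(AMBIGUOUS, (s1, s2), evid,
                            reason="conflicting homozygous classes across the centromere")
    return DivisionCall(AMBIGUOUS, (s1, s2), evid,
                        reason="mixed HET/HOM pericentric states")


def flag_monosomy_rescue(
    calls: Sequence[CrossoverCall],
    seg_left: GenotypeSegmentation,
    seg_right: GenotypeSegmentation,
) -> tuple[bool, str]:
    """Whether the event is compatible with monosomy rescue, and why.

    Any heterozygous segment anywhere excludes rescue.  A fully homozygous
    chromosome is flagged: with a direct homozygous-class switch
    (HOM_P1 <-> HOM_P2) the duplicated chromatid was recombinant and the
    event is positively a rescue; without one it is indistinguishable from
    a non-recombinant MII event.
    """
    labels = seg_left.state_labels + seg_right.state_labels
    if any(l == "HET" for l in labels):
        return False, "heterozygous segment present"
    for c in calls:
        if c.from_state in HOM_LABELS and c.to_state in HOM_LABELS:
            return True, "homozygous-class switch"
    return True, "non-recombinant"


def classify_ndj_event(
    seg_left: GenotypeSegmentation,
    seg_right: GenotypeSegmentation,
    model: ChromosomeModel,
    calls: Sequence[CrossoverCall] = (),
    window_bp: float = 1_000_000,
    min_markers: int = 10,
) -> DivisionCall:
    """Division call plus monosomy-rescue assessment for one event.

    A fully homozygous chromosome exhibiting a homozygous-class switch is
    re-labelled ``rescue_suspect``: no meiotic disomy produces that pattern.
    """
    call = classify_division(seg_left, seg_right, model, window_bp, min_markers)
    rescue, reason = flag_monosomy_rescue(calls, seg_left, seg_right)
    call.rescue_flag = rescue
    call.rescue_reason = reason
    if rescue and reason == "homozygous-class switch":
        call.origin = RESCUE_SUSPECT
    return call


def division_summary(
    cohort: Sequence[DivisionCall],
    comparison: Optional[tuple[int, int]] = None,
    direction: str = "greater",
) -> dict:
    """Counts and fractions of MI/MII (ambiguous and rescue counted apart).

    ``comparison`` is another cohort's ``(n_MII, n_total)``; when given, a
    one-tailed two-proportion Z-test on the MII fraction is attached.
    """
    if not cohort:
        raise ValueError("empty cohort")
    counts = {k: 0 for k in (MI, MII, AMBIGUOUS, RESCUE_SUSPECT)}
    for c in cohort:
        counts[c.origin] += 1
    n_meiotic = counts[MI] + counts[MII]
    out = {
        "counts": counts,
        "n_meiotic": n_meiotic,
        "mi_fraction": counts[MI] / n_meiotic if n_meiotic else float("nan"),
        "mii_fraction": counts[MII] / n_meiotic if n_meiotic else float("nan"),
        "ztest": None,
    }
    if comparison is not None:
        x2, n2 = comparison
        if n2 == 0 or n_meiotic == 0:
            warnings.warn("empty comparison cohort; Z-test skipped")
        else:
            out["ztest"] = stats.two_proportion_z(counts[MII], n_meiotic, x2, n2,
                                                  direction=direction)
    return out
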