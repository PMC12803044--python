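"""Exact enumeration of crossover detectability under each inheritance mode.

Progeny of a normal meiosis, MI NDJ, and MII NDJ inherit different numbers
of chromatids from the bivalent (one of four; one from each homolog; both
sisters of one homolog) and therefore carry unequal information about the
crossovers that occurred.  For a single inter-homolog crossover:

* normal meiosis - the recombinant chromatid is inherited with probability
  1/2, so a single crossover is detected 50% of the time;
* MI NDJ - 50% chance of one recombinant plus one non-recombinant chromatid
  (detectable), 25% reciprocal recombinants and 25% two non-recombinants
  (both fully heterozygous along the chromosome, hence undetectable in the
  pooled frequencies), so detection is again 50%;
* MII NDJ - the sister pair always contains exactly one recombinant
  product of each inter-homolog crossover, so every crossover is
  detectable.

These are exact statements; probabilities are carried as
:class:`fractions.Fraction` throughout and only rendered as floats at the
interface.  The MII excess of observable single crossovers is compensated
by halving the MII single-crossover fraction when comparing crossover
spectra between modes; doubles are left unadjusted (they are rare and the
corresponding correction is not well defined).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import pandas as pd

NORMAL = "normal"
MI_NDJ = "MI_NDJ"
MII_NDJ = "MII_NDJ"

_MODE_ALIASES = {
    "normal": NORMAL, "none": NORMAL,
    "mi": MI_NDJ, "mi_ndj": MI_NDJ,
    "mii": MII_NDJ, "mii_ndj": MII_NDJ,
}

#: Outcome classes of a single meiosis as seen in the pooled frequencies.
DETECTABLE = "detectable"
RECOMBINANT_UNDETECTABLE = "recombinant_undetectable"
NON_RECOMBINANT_UNDETECTABLE = "non_recombinant_undetectable"


def normalize_mode(mode: str) -> str:
    try:
        return _MODE_ALIASES[mode.lower()]
    except KeyError:
        raise ValueError(f"unknown inheritance mode {mode!r}") from None


class CrossoverConfigError(ValueError):
    """The abstract crossover configuration is not a valid bivalent."""


@dataclass(frozen=True)
class DetectionDistribution:
    """Exact outcome probabilities for one inheritance mode and CO layout."""

    probs: dict

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if total != 1:
            raise AssertionError(f"probabilities sum to {total}, not 1")

    def p(self, outcome: str) -> Fraction:
        return self.probs.get(outcome, Fraction(0))

    @property
    def p_detectable(self) -> Fraction:
        return self.p(DETECTABLE)


# chromatid indices: 0,1 = homolog 0 sisters; 2,3 = homolog 1 sisters
_HOMOLOG = (0, 0, 1, 1)


def _validate_config(crossover_config) -> list[tuple[int, tuple[int, int]]]:
    cfg = []
    for arm, pair in crossover_config:
        i, j = pair
        if _HOMOLOG[i] == _HOMOLOG[j]:
            raise CrossoverConfigError(
                f"crossover {pair} joins sister chromatids; exchanges are inter-homolog"
            )
        if _HOMOLOG[i] == 1:
            i, j = j, i
        cfg.append((int(arm), (i, j)))
    return cfg


def _chromatid_profiles(cfg: list[tuple[int, tuple[int, int]]]) -> dict[int, dict[int, list[int]]]:
    """Per-arm parental-origin profile of each chromatid.

    For an arm with k crossovers (listed distal to proximal) the arm is cut
    into k+1 regions, region 0 at the telomere.  Crossover m sits between
    regions m and m+1 and exchanges the distal regions 0..m between the two
    involved chromatids; exchanges are applied distal-first (the strand-path
    model), so chromatid identity stays anchored at the centromere.
    """
    arms = sorted({arm for arm, _ in cfg}) or [0]
    per_arm = {arm: [pair for a, pair in cfg if a == arm] for arm in arms}
    profiles: dict[int, dict[int, list[int]]] = {c: {} for c in range(4)}
    for arm in arms:
        colist = per_arm[arm]
        k = len(colist)
        prof = {c: [_HOMOLOG[c]] * (k + 1) for c in range(4)}
        for m in range(k):
            i, j = colist[m]
            for r in range(m + 1):
                prof[i][r], prof[j][r] = prof[j][r], prof[i][r]
        for c in range(4):
            profiles[c][arm] = prof[c]
    return profiles


def _outcome(inherited: Sequence[int], profiles, cfg) -> tuple[int, int]:
    """(n recombinant chromatids inherited, n detectable crossovers)."""
    n_rec = 0
    for c in inherited:
        if any(len(set(p)) > 1 for p in profiles[c].values()):
            n_rec += 1
    arms = sorted({arm for arm, _ in cfg}) or [0]
    n_det = 0
    for arm in arms:
        k = len([1 for a, _ in cfg if a == arm])
        for m in range(k):
            s_up = sum(profiles[c][arm][m] for c in inherited)
            s_dn = sum(profiles[c][arm][m + 1] for c in inherited)
            if s_up != s_dn:
                n_det += 1
    return n_rec, n_det


def _inheritance_outcomes(mode: str):
    """Equally likely inherited chromatid sets for a mode."""
    if mode == NORMAL:
        return [((c,), Fraction(1, 4)) for c in range(4)]
    if mode == MI_NDJ:
        return [((a, b), Fraction(1, 4)) for a in (0, 1) for b in (2, 3)]
    if mode == MII_NDJ:
        return [((0, 1), Fraction(1, 2)), ((2, 3), Fraction(1, 2))]
    raise ValueError(mode)


def enumerate_detection(mode: str, crossover_config) -> DetectionDistribution:
    """Exact outcome distribution over the mode's inheritance outcomes.

    ``crossover_config`` is a list of ``(arm, (chromatid_i, chromatid_j))``
    with one chromatid index from each homolog per crossover, ordered distal
    to proximal within an arm.  Outcomes are classed ``detectable`` (at
    least one crossover shows as a frequency-state change),
    ``recombinant_undetectable`` (recombinant chromatids inherited, but the
    changes cancel - e.g. an MI reciprocal pair) or
    ``non_recombinant_undetectable``.
    """
    mode = normalize_mode(mode)
    cfg = _validate_config(crossover_config)
    profiles = _chromatid_profiles(cfg)
    probs: dict[str, Fraction] = {}
    for inherited, p in _inheritance_outcomes(mode):
        n_rec, n_det = _outcome(inherited, profiles, cfg)
        if n_det > 0:
            label = DETECTABLE
        elif n_rec > 0:
            label = RECOMBINANT_UNDETECTABLE
        else:
            label = NON_RECOMBINANT_UNDETECTABLE
        probs[label] = probs.get(label, Fraction(0)) + p
    return DetectionDistribution(probs)


def detection_probability(mode: str, n_crossovers: int,
                          arms: Optional[Sequence[int]] = None) -> Fraction:
    """P(at least one crossover detectable), chromatid pairs uniform.

    The chromatids involved in each crossover are drawn uniformly and
    independently (no chromatid interference); the result is the exact
    average of :func:`enumerate_detection` over all 4^n pair assignments.
    ``arms`` assigns each crossover to an arm (default: all on one arm).
    """
    mode = normalize_mode(mode)
    if n_crossovers < 0:
        raise ValueError("n_crossovers must be >= 0")
    if n_crossovers == 0:
        return Fraction(0)
    arms = list(arms) if arms is not None else [0] * n_crossovers
    if len(arms) != n_crossovers:
        raise ValueError("arms must have one entry per crossover")
    pairs = [(i, j) for i in (0, 1) for j in (2, 3)]
    total = Fraction(0)
    n_assign = 0
    for assignment in itertools.product(pairs, repeat=n_crossovers):
        cfg = list(zip(arms, assignment))
        total += enumerate_detection(mode, cfg).p_detectable
        n_assign += 1
    return total / n_assign


def adjust_mii_single_fraction(observed_single_fraction: float) -> float:
    """Halve the MII single-crossover fraction for cross-mode comparison.

    MII progeny reveal every inter-homolog crossover whereas normal and MI
    progeny reveal a single crossover only half the time; halving puts the
    single-crossover classes on a common footing.  Double-crossover
    fractions pass through unadjusted.
    """
    if not 0.0 <= observed_single_fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    return observed_single_fraction / 2.0


def arm_crossover_spectrum(arm_counts: Sequence[int], mode: str) -> pd.DataFrame:
    """Fractions of arms with 0/1/2+ observed crossovers, raw and adjusted.

    ``arm_counts`` is one observed crossover count per chromosome arm.  The
    count is of segmentation boundaries, so an MII reciprocal pair appears
    as two.  The adjustment halves the MII single-crossover fraction only.
    """
    mode = normalize_mode(mode)
    if len(arm_counts) == 0:
        raise ValueError("no arms")
    n = len(arm_counts)
    classes = [0, 1, 2]
    tallies = {c: 0 for c in classes}
    for k in arm_counts:
        tallies[min(int(k), 2)] += 1
    rows = []
    for c in classes:
        raw = tallies[c] / n
        adj = adjust_mii_single_fraction(raw) if (mode == MII_NDJ and c == 1) else raw
        rows.append({"n_crossovers": c, "n_arms": tallies[c],
                     "raw_fraction": raw, "adjusted_fraction": adj})
    df = pd.DataFrame(rows)
    df.attrs["mode"] = mode
    df.attrs["total_arms"] = n
    return df


def zero_co_chromosome_fraction(n_zero_left: int, right_co_rate_given_zero_left: float,
                                n_with_left_co: int) -> Fraction:
    """Fraction of whole chromosomes with no detectable crossover on either arm.

    Reconstructed from arm-level summaries: of the ``n_zero_left`` events
    with no left-arm crossover, a fraction ``right_co_rate_given_zero_left``
    had a right-arm crossover; the remainder (rounded to a whole count) had
    none anywhere.  Events with a left-arm crossover cannot be
    zero-crossover chromosomes.
    """
    if not 0 <= right_co_rate_given_zero_left <= 1:
        raise ValueError("rate must be in [0, 1]")
    n_zero_both = n_zero_left - round(n_zero_left * right_co_rate_given_zero_left)
    return Fraction(int(n_zero_both), int(n_zero_left + n_with_left_co))
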