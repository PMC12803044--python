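"""Genotype segmentation of pooled allele-frequency tracks and crossover calls.

The caller replaces by-eye identification of "persistent" allele-frequency
shifts with a deterministic minimum-cost state path.  Each marker emits its
alternate-read count under a binomial whose success probability is the
segment state's expected pooled frequency blended with a per-read error
rate; switching state between adjacent markers costs a fixed log penalty.
The exact maximum a posteriori path is found by dynamic programming
(Viterbi), after which segments with insufficient marker support are merged
into their dominant neighbour - the reproducible analogue of requiring a
*persistent* change.

A crossover call is the interval between the nearest flanking markers that
carry decisive evidence (cumulative emission log-odds >= a threshold) for
their segment's state, so the reported 5'/3' SNP interval is a conservative
credible bound on the true breakpoint rather than the raw Viterbi boundary,
whose immediate neighbours are frequently ambiguous at modest depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .chromosome_model import ChromosomeModel, CENTROMERE_TO_TELOMERE


@dataclass(frozen=True)
class GenotypeState:
    """A pooled genotype class and its expected alternate-allele frequency."""

    label: str
    expected_freq: float


#: Autosomal maternal-disomy design: father HOM_P1 / HET / HOM_P2.
DEFAULT_STATES = (
    GenotypeState("HOM_P1", 0.0),
    GenotypeState("HET", 0.25),
    GenotypeState("HOM_P2", 0.5),
)

HOM_LABELS = ("HOM_P1", "HOM_P2")


def states_for_freqs(freqs: Sequence[float]) -> tuple[GenotypeState, ...]:
    labels = ("HOM_P1", "HET", "HOM_P2")
    fs = tuple(float(f) for f in freqs)
    if list(fs) != sorted(fs):
        raise ValueError("state frequencies must be strictly increasing")
    return tuple(GenotypeState(l, f) for l, f in zip(labels, fs))


@dataclass
class SegmentationParams:
    """Tunables of the segmentation.

    ``epsilon`` blends each state's expected frequency toward the error
    floor (f -> f(1-eps) + (1-f)eps).  ``switch_penalty`` is the log-cost of
    a state change between adjacent markers (default ln 1e-6: crossovers are
    rare relative to marker count).  ``min_segment_markers`` is the support
    needed by an internal segment; terminal segments only need
    ``min_terminal_markers`` so that genuinely distal crossovers - which have
    a single flanking boundary - are not silently absorbed.
    ``boundary_log_odds`` sets how much cumulative per-marker evidence the
    flanking SNPs of a reported call interval must carry.
    """

    states: tuple[GenotypeState, ...] = DEFAULT_STATES
    epsilon: float = 0.01
    switch_penalty: float = float(np.log(1e-6))
    min_segment_markers: int = 10
    min_terminal_markers: int = 2
    boundary_log_odds: float = float(np.log(1e6))


@dataclass
class Segment:
    start: int  # marker index, inclusive
    stop: int   # marker index, exclusive
    state: str
    mean_freq: float
    n_markers: int


@dataclass
class GenotypeSegmentation:
    """Piecewise-constant genotype path over one contig's marker track."""

    contig: str
    positions: np.ndarray
    segments: list[Segment]
    params: SegmentationParams
    loglik: np.ndarray = field(repr=False, default=None)  # markers x states

    @property
    def state_labels(self) -> list[str]:
        return [s.state for s in self.segments]

    def proximal_terminal_state(self, model: ChromosomeModel) -> str:
        """State of the centromere-proximal terminal segment of this arm."""
        arm = model.arm_for(self.contig)
        if arm.orientation == CENTROMERE_TO_TELOMERE:
            return self.segments[0].state
        return self.segments[-1].state


def emission_loglik(track: pd.DataFrame, params: SegmentationParams) -> np.ndarray:
    """Per-marker binomial log-likelihood under each genotype state."""
    depth = track["depth"].to_numpy(dtype=np.int64)
    alt = np.rint(track["freq"].to_numpy() * depth).astype(np.int64)
    eps = params.epsilon
    p = np.array([s.expected_freq * (1 - eps) + (1 - s.expected_freq) * eps
                  for s in params.states])
    return binom.logpmf(alt[:, None], depth[:, None], p[None, :])


def viterbi_path(loglik: np.ndarray, switch_penalty: float) -> np.ndarray:
    """Exact maximum-score state path.

    Score = sum of emissions + switch_penalty per adjacent-marker state
    change.  Ties are broken toward staying in the current state (the
    fewer-segment path), then toward the lower state index.
    """
    n, k = loglik.shape
    score = loglik[0].copy()
    back = np.zeros((n, k), dtype=np.int8)
    for t in range(1, n):
        prev = score
        switch_best = int(np.argmax(prev))  # lowest index wins numpy ties
        new = np.empty(k)
        for j in range(k):
            stay = prev[j]
            sw = prev[switch_best] + switch_penalty
            if switch_best != j and sw > stay:
                back[t, j] = switch_best
                new[j] = sw
            else:
                back[t, j] = j
                new[j] = stay
        score = new + loglik[t]
    path = np.zeros(n, dtype=np.int8)
    path[-1] = int(np.argmax(score))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def _rle(path: np.ndarray) -> list[tuple[int, int, int]]:
    """(start, stop, state) runs of a state path."""
    runs = []
    start = 0
    for i in range(1, len(path) + 1):
        if i == len(path) or path[i] != path[start]:
            runs.append((start, i, int(path[start])))
            start = i
    return runs


def _merge_small_runs(runs: list[tuple[int, int, int]], min_internal: int,
                      min_terminal: int) -> list[tuple[int, int, int]]:
    """Merge under-supported runs into their dominant (larger) neighbour."""
    runs = list(runs)
    while len(runs) > 1:
        sizes = [stop - start for start, stop, _ in runs]
        worst = None
        for i, n in enumerate(sizes):
            need = min_terminal if i in (0, len(runs) - 1) else min_internal
            if n < need and (worst is None or n < sizes[worst]):
                worst = i
        if worst is None:
            break
        start, stop, _ = runs[worst]
        if worst == 0:
            absorber = 1
        elif worst == len(runs) - 1:
            absorber = worst - 1
        else:
            left_n, right_n = sizes[worst - 1], sizes[worst + 1]
            absorber = worst - 1 if left_n >= right_n else worst + 1
        a_start, a_stop, a_state = runs[absorber]
        merged = (min(start, a_start), max(stop, a_stop), a_state)
        lo, hi = sorted((worst, absorber))
        runs[lo:hi + 1] = [merged]
        # coalesce neighbours that now share a state
        i = 0
        while i < len(runs) - 1:
            if runs[i][2] == runs[i + 1][2]:
                runs[i:i + 2] = [(runs[i][0], runs[i + 1][1], runs[i][2])]
            else:
                i += 1
    return runs


def segment_track(track: pd.DataFrame, params: Optional[SegmentationParams] = None,
                  contig: str = "") -> GenotypeSegmentation:
    """Segment one allele-frequency track into genotype states.

    Deterministic given inputs and parameters.  Tracks shorter than the
    internal support threshold fall back to a single segment (with a
    warning): no persistent change can be established on them.
    """
    params = params or SegmentationParams()
    n = len(track)
    if n == 0:
        raise ValueError("empty track")
    ll = emission_loglik(track, params)
    positions = track["pos"].to_numpy()
    freqs = track["freq"].to_numpy()

    if n < params.min_segment_markers:
        warnings.warn(
            f"track on {contig or '?'} has {n} < {params.min_segment_markers} markers; "
            "returning a single segment"
        )
        best = int(np.argmax(ll.sum(axis=0)))
        seg = Segment(0, n, params.states[best].label, float(freqs.mean()), n)
        return GenotypeSegmentation(contig, positions, [seg], params, ll)

    path = viterbi_path(ll.copy(), params.switch_penalty)
    runs = _merge_small_runs(_rle(path), params.min_segment_markers,
                             params.min_terminal_markers)
    segments = [
        Segment(start, stop, params.states[state].label,
                float(freqs[start:stop].mean()), stop - start)
        for start, stop, state in runs
    ]
    return GenotypeSegmentation(contig, positions, segments, params, ll)


# ---------------------------------------------------------------------------
# crossover calls


@dataclass
class CrossoverCall:
    """A crossover localised between two flanking markers.

    ``left_snp``/``right_snp`` are marker positions (contig coordinates)
    bounding the breakpoint; ``flags`` may include ``pericentric``,
    ``heterochromatic``, ``double_CO_member`` and ``gap_shift``.
    """

    chrom: str
    arm: str
    left_snp: float
    right_snp: float
    from_state: str
    to_state: str
    flags: set = field(default_factory=set)
    individual: Optional[str] = None
    cM_span: Optional[float] = None
    bp_sep: Optional[float] = None
    cM_sep: Optional[float] = None
    within_normal_range: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.left_snp < self.right_snp:
            raise ValueError("call interval must have positive width")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.left_snp + self.right_snp)


def _state_index(params: SegmentationParams, label: str) -> int:
    for i, s in enumerate(params.states):
        if s.label == label:
            return i
    raise KeyError(label)


def _confident_bound(seg: GenotypeSegmentation, boundary: int, upstream: Segment,
                     downstream: Segment) -> tuple[float, float]:
    """Flanking-marker interval around a Viterbi boundary.

    Walk outward from the boundary on each side, accumulating the emission
    log-odds of that side's state against the opposite state, and stop at
    the first marker where the cumulative evidence reaches
    ``boundary_log_odds``; clamp at the segment's far end.
    """
    params = seg.params
    ll = seg.loglik
    iu = _state_index(params, upstream.state)
    idn = _state_index(params, downstream.state)
    theta = params.boundary_log_odds

    left = boundary - 1
    acc = 0.0
    for m in range(boundary - 1, upstream.start - 1, -1):
        acc += ll[m, iu] - ll[m, idn]
        left = m
        if acc >= theta:
            break
    right = boundary
    acc = 0.0
    for m in range(boundary, downstream.stop):
        acc += ll[m, idn] - ll[m, iu]
        right = m
        if acc >= theta:
            break
    return float(seg.positions[left]), float(seg.positions[right])


def _overlaps(lo: float, hi: float, intervals) -> bool:
    return any(lo < b and hi > a for a, b in intervals)


def calls_from_segmentation(
    seg: GenotypeSegmentation,
    model: ChromosomeModel,
    individual: Optional[str] = None,
    pericentric_euchromatin_fraction: float = 0.15,
) -> list[CrossoverCall]:
    """One crossover call per adjacent-segment boundary, with zone flags.

    ``heterochromatic``/``pericentric`` flags are set when the call interval
    overlaps the arm's heterochromatin blocks or the pericentric zone
    (heterochromatin plus the proximal euchromatin fraction).  When an arm
    carries two or more calls they are flagged ``double_CO_member`` and the
    genetic-map span between consecutive midpoints is annotated.
    """
    arm = model.arm_for(seg.contig)
    zone = model.pericentric_zone(pericentric_euchromatin_fraction)[seg.contig]
    calls: list[CrossoverCall] = []
    for up, down in zip(seg.segments, seg.segments[1:]):
        left, right = _confident_bound(seg, down.start, up, down)
        flags = set()
        if _overlaps(left, right, arm.heterochromatin_intervals):
            flags.add("heterochromatic")
        if _overlaps(left, right, zone):
            flags.add("pericentric")
        calls.append(
            CrossoverCall(
                chrom=seg.contig, arm=arm.label, left_snp=left, right_snp=right,
                from_state=up.state, to_state=down.state, flags=flags,
                individual=individual,
            )
        )
    if len(calls) >= 2:
        for c in calls:
            c.flags.add("double_CO_member")
        try:
            for a, b in zip(calls, calls[1:]):
                span = abs(
                    model.bp_to_cM(seg.contig, b.midpoint)
                    - model.bp_to_cM(seg.contig, a.midpoint)
                )
                a.cM_span = b.cM_span = span
        except Exception:  # no usable anchors on this arm
            pass
    return calls


def detect_gap_shift(
    seg_left: GenotypeSegmentation,
    seg_right: GenotypeSegmentation,
    model: ChromosomeModel,
    individual: Optional[str] = None,
) -> Optional[CrossoverCall]:
    """Crossover hidden in the unassembled centromere gap.

    If the centromere-proximal terminal segments of the two arms are in
    different genotype states, the state must have changed somewhere in the
    intervening satellite sequence; emit a call spanning the gap.
    """
    s_left = seg_left.proximal_terminal_state(model)
    s_right = seg_right.proximal_terminal_state(model)
    if s_left == s_right:
        return None
    return CrossoverCall(
        chrom=model.name,
        arm="gap",
        left_snp=float(seg_left.positions[-1]),
        right_snp=float(seg_left.positions[-1]) + model.centromere_gap_bp
        + float(seg_right.positions[0]) + 1.0,
        from_state=s_left,
        to_state=s_right,
        flags={"gap_shift", "pericentric"},
        individual=individual,
    )


def annotate_double_crossovers(
    calls: list[CrossoverCall],
    model: ChromosomeModel,
    min_bp: float = 2_000_000,
    min_cM: float = 10.0,
) -> list[CrossoverCall]:
    """Annotate intra-arm consecutive call pairs with their separation.

    ``within_normal_range`` is True when the pair is at least ``min_bp``
    and ``min_cM`` apart - the smallest spacings seen among normal-meiosis
    double crossovers.  Annotation only; nothing is filtered.
    """
    by_arm: dict[tuple, list[CrossoverCall]] = {}
    for c in calls:
        if c.arm == "gap":
            continue
        by_arm.setdefault((c.individual, c.chrom, c.arm), []).append(c)
    for group in by_arm.values():
        group.sort(key=lambda c: c.midpoint)
        for a, b in zip(group, group[1:]):
            bp_sep = b.midpoint - a.midpoint
            try:
                cm_sep = abs(
                    model.bp_to_cM(b.chrom, b.midpoint) - model.bp_to_cM(a.chrom, a.midpoint)
                )
            except Exception:
                cm_sep = float("nan")
            ok = bool(bp_sep >= min_bp and cm_sep >= min_cM)
            for c in (a, b):
                c.bp_sep = bp_sep
                c.cM_sep = cm_sep
                c.within_normal_range = ok
    return calls


def calls_to_frame(calls: list[CrossoverCall]) -> pd.DataFrame:
    """Flatten calls to a Table S3-style frame (5'/3' SNPs, 1-based out)."""
    rows = []
    for c in calls:
        rows.append(
            {
                "individual": c.individual,
                "chrom": c.chrom,
                "arm": c.arm,
                "type": "double" if "double_CO_member" in c.flags else "single",
                "five_prime_snp": int(c.left_snp) + 1,
                "three_prime_snp": int(c.right_snp) + 1,
                "from_state": c.from_state,
                "to_state": c.to_state,
                "flags": ",".join(sorted(c.flags)),
                "cM_span": c.cM_span,
                "bp_sep": c.bp_sep,
                "cM_sep": c.cM_sep,
                "within_normal_range": c.within_normal_range,
            }
        )
    return pd.DataFrame(rows)


def calls_to_bed(calls: list[CrossoverCall], path) -> None:
    """Write call intervals as BED (contig, 0-based half-open, name)."""
    with open(path, "w") as fh:
        for c in sorted(calls, key=lambda c: (c.chrom, c.left_snp)):
            name = f"{c.individual or '.'}|{c.from_state}>{c.to_state}"
            fh.write(f"{c.chrom}\t{int(c.left_snp)}\t{int(c.right_snp) + 1}\t{name}\n")
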