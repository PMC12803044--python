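"""Synthetic meiosis and nondisjunction simulator with chromatid resolution.

This module is the package's synthetic-data generator.  It simulates a
female meiosis as a bivalent of four chromatids (two sisters per homolog,
parental origins ``P1``/``P2``), places inter-homolog crossovers with a
hard-minimum-gap interference model, draws a gamete under normal
segregation, meiosis-I NDJ (one chromatid from each homolog) or meiosis-II
NDJ (both sister chromatids of one homolog), and then emulates the
backcross-and-pool sequencing design: a disomic NDJ male is crossed to
tester females homozygous for the ``P1`` haplotype and the pooled offspring
are sequenced.  At a biallelic marker the father carries 0, 1 or 2 copies
of the ``P2`` allele, so the ideal pooled alternate-allele frequency is
0, 0.25 or 0.5; the simulator adds finite-pool composition noise, Poisson
depth and binomial read sampling with a symmetric per-read error rate.

All latent values (division origin, crossover positions, chromatid
origins, ideal per-marker frequencies) are recorded in :class:`SimTruth`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chromosome_model import ChromosomeModel, dm6_chr2, GAP

P1 = 0
P2 = 1

NDJ_NONE = "none"
NDJ_MI = "MI"
NDJ_MII = "MII"


class SimConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class Chromatid:
    """One chromatid as parental-origin segments tiling the global axis.

    ``segments`` is an ordered tuple of ``(g_start, g_end, origin)`` with
    alternating origins; ``centromere_origin`` identifies the sister pair the
    chromatid belongs to (exchanges are applied distally, so it is stable).
    """

    segments: tuple[tuple[float, float, int], ...]
    centromere_origin: int

    @property
    def breakpoints(self) -> tuple[float, ...]:
        return tuple(s[0] for s in self.segments[1:])

    @property
    def is_recombinant(self) -> bool:
        return len(self.segments) > 1

    def origin_at(self, g: float) -> int:
        for s0, s1, origin in self.segments:
            if s0 <= g < s1:
                return origin
        # right edge belongs to the last segment
        if g == self.segments[-1][1]:
            return self.segments[-1][2]
        raise ValueError(f"position {g} outside chromatid span")

    def origins_at(self, gs: np.ndarray) -> np.ndarray:
        starts = np.array([s[0] for s in self.segments])
        origins = np.array([s[2] for s in self.segments], dtype=np.int8)
        idx = np.clip(np.searchsorted(starts, gs, side="right") - 1, 0, len(origins) - 1)
        return origins[idx]


def _merge_segments(segs: list[tuple[float, float, int]]) -> tuple[tuple[float, float, int], ...]:
    out: list[tuple[float, float, int]] = []
    for s in segs:
        if s[0] >= s[1]:
            continue
        if out and out[-1][2] == s[2] and out[-1][1] == s[0]:
            out[-1] = (out[-1][0], s[1], s[2])
        else:
            out.append(tuple(s))
    return tuple(out)


def _exchange_distal(a: Chromatid, b: Chromatid, x: float, side: str) -> tuple[Chromatid, Chromatid]:
    """Reciprocally exchange the parts of two chromatids distal to ``x``.

    ``side`` is ``"left"`` when the distal (telomeric) side of the crossover
    is the low-coordinate side of the global axis, ``"right"`` otherwise.
    """

    def split(ch: Chromatid):
        lo, hi = [], []
        for s0, s1, o in ch.segments:
            if s1 <= x:
                lo.append((s0, s1, o))
            elif s0 >= x:
                hi.append((s0, s1, o))
            else:
                lo.append((s0, x, o))
                hi.append((x, s1, o))
        return lo, hi

    a_lo, a_hi = split(a)
    b_lo, b_hi = split(b)
    if side == "left":
        new_a = _merge_segments(b_lo + a_hi)
        new_b = _merge_segments(a_lo + b_hi)
    else:
        new_a = _merge_segments(a_lo + b_hi)
        new_b = _merge_segments(b_lo + a_hi)
    return (
        Chromatid(new_a, a.centromere_origin),
        Chromatid(new_b, b.centromere_origin),
    )


@dataclass(frozen=True)
class CrossoverSite:
    """A simulated inter-homolog crossover."""

    g: float
    contig: str
    pos: float
    arm_label: str
    chromatids: tuple[int, int]  # indices into Bivalent.chromatids


@dataclass
class Bivalent:
    """Four chromatids (indices 0,1 = homolog P1 sisters; 2,3 = P2 sisters)."""

    chromatids: tuple[Chromatid, Chromatid, Chromatid, Chromatid]
    crossovers: list[CrossoverSite]
    model: ChromosomeModel


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    ``crossover_dist`` maps per-arm crossover counts (0/1/2) to
    probabilities, applied independently to each arm; a list of dicts gives
    per-arm distributions.  ``interference_min_gap_bp`` is a hard minimum
    spacing for intra-arm double crossovers.  ``mean_depth`` and
    ``seq_error`` describe the sequencing of the pool; reads are sampled
    binomially around the ideal pooled frequencies (0 / 0.25 / 0.5).
    ``n_pool_offspring`` optionally adds finite-pool composition noise (a
    shared binomial split of which paternal copy each offspring received);
    the default of ``None`` models the effectively large pools of a fly
    backcross.
    """

    model: ChromosomeModel = field(default_factory=dm6_chr2)
    crossover_dist: dict | list = field(default_factory=lambda: {0: 0.12, 1: 0.78, 2: 0.10})
    interference_min_gap_bp: int = 2_000_000
    ndj_type: str = NDJ_MI
    n_pool_offspring: Optional[int] = None
    mean_depth: float = 30.0
    seq_error: float = 0.01
    marker_spacing_bp: int = 5_000
    state_freqs: tuple[float, float, float] = (0.0, 0.25, 0.5)
    allow_heterochromatin: bool = False
    position_weights: Optional[Sequence[tuple[float, float, float]]] = None

    def arm_dist(self, arm_index: int) -> dict:
        d = self.crossover_dist
        if isinstance(d, (list, tuple)):
            d = d[arm_index]
        return {int(k): float(v) for k, v in d.items()}

    def validate(self) -> None:
        for i in range(len(self.model.arms)):
            d = self.arm_dist(i)
            if abs(sum(d.values()) - 1.0) > 1e-9:
                raise SimConfigError(f"arm {i}: crossover-count probabilities must sum to 1")
            if any(k < 0 for k in d):
                raise SimConfigError("crossover counts must be >= 0")
        if self.interference_min_gap_bp < 0:
            raise SimConfigError("interference_min_gap_bp must be >= 0")
        if self.ndj_type not in (NDJ_NONE, NDJ_MI, NDJ_MII):
            raise SimConfigError(f"bad ndj_type {self.ndj_type!r}")
        if not 0.0 <= self.seq_error < 0.5:
            raise SimConfigError("seq_error must be in [0, 0.5)")
        fs = self.state_freqs
        if not (0 <= fs[0] < fs[1] < fs[2] <= 1):
            raise SimConfigError("state_freqs must be strictly increasing in [0, 1]")


@dataclass
class SimTruth:
    """Latent state of one simulated NDJ event."""

    division_origin: str
    crossovers: list[dict]
    chromatid_centromere_origins: tuple[int, ...]
    state_counts: np.ndarray  # per-marker paternal P2-copy count (0/1/2)
    ideal_freqs: np.ndarray   # per-marker ideal pooled alt frequency
    observable_changes: list[tuple[str, float]]  # (contig, pos) of true state changes

    def to_jsonable(self) -> dict:
        return {
            "division_origin": self.division_origin,
            "crossovers": self.crossovers,
            "chromatid_centromere_origins": list(self.chromatid_centromere_origins),
            "observable_changes": [[c, float(p)] for c, p in self.observable_changes],
        }


# ---------------------------------------------------------------------------
# bivalent simulation


def _permitted_intervals(config: SimConfig, arm_index: int) -> list[tuple[float, float]]:
    model = config.model
    if config.allow_heterochromatin:
        return [model.arm_global_span(arm_index)]
    return [model.euchromatin_global_intervals()[arm_index]]


def _draw_positions(n: int, intervals: list[tuple[float, float]], min_gap: float,
                    rng: np.random.Generator,
                    weights: Optional[Sequence[tuple[float, float, float]]] = None,
                    max_tries: int = 1000) -> list[float]:
    """Rejection-sample ``n`` crossover positions with pairwise gap >= min_gap."""
    if n == 0:
        return []
    spans = [(lo, hi) for lo, hi in intervals]
    total = sum(hi - lo for lo, hi in spans)
    if n >= 2:
        extent = max(hi for _, hi in spans) - min(lo for lo, _ in spans)
        if min_gap >= extent:
            raise SimConfigError(
                f"cannot place {n} crossovers with a {min_gap:.0f} bp minimum gap "
                f"inside a {extent:.0f} bp region"
            )
    if weights is not None:
        wiv = [(lo, hi, w) for lo, hi, w in weights if w > 0]
        wts = np.array([w * (hi - lo) for lo, hi, w in wiv], dtype=float)
        wts /= wts.sum()

    def draw_one() -> float:
        if weights is not None:
            lo, hi, _ = wiv[rng.choice(len(wiv), p=wts)]
            return float(rng.uniform(lo, hi))
        u = rng.uniform(0, total)
        for lo, hi in spans:
            if u < hi - lo:
                return float(lo + u)
            u -= hi - lo
        return float(spans[-1][1])

    for _ in range(max_tries):
        pos = sorted(draw_one() for _ in range(n))
        if all(b - a >= min_gap for a, b in zip(pos, pos[1:])):
            return pos
    raise SimConfigError(
        f"could not satisfy the {min_gap:.0f} bp interference gap with {n} "
        f"crossovers after {max_tries} attempts"
    )


def simulate_bivalent(config: SimConfig, rng: np.random.Generator) -> Bivalent:
    """Simulate one bivalent: 4 chromatids plus inter-homolog crossovers.

    Crossover counts are drawn per arm from the configured distribution,
    positions uniformly over the permitted region (euchromatin by default,
    optionally weighted by a density table), resampled until every intra-arm
    pair is at least ``interference_min_gap_bp`` apart.  For each crossover
    one chromatid of each homolog is chosen uniformly and their segments are
    exchanged distal (telomere-ward) to the crossover position.
    """
    config.validate()
    model = config.model
    T = float(model.axis_length)
    chromatids: list[Chromatid] = [
        Chromatid(((0.0, T, origin),), origin) for origin in (P1, P1, P2, P2)
    ]
    crossovers: list[CrossoverSite] = []

    for arm_index, arm in enumerate(model.arms):
        dist = config.arm_dist(arm_index)
        counts = sorted(dist)
        n = int(rng.choice(counts, p=[dist[c] for c in counts]))
        positions = _draw_positions(
            n, _permitted_intervals(config, arm_index),
            float(config.interference_min_gap_bp), rng,
            weights=config.position_weights,
        )
        # distal side: low-coordinate for the first arm (telomere at 0),
        # high-coordinate for the second arm.  Exchanges are applied
        # distal-first so that each one swaps the already-exchanged distal
        # remainders (the strand-path model of a multi-chiasma bivalent).
        side = "left" if arm_index == 0 else "right"
        order = sorted(positions, reverse=(side == "right"))
        pairs = [(int(rng.integers(2)), 2 + int(rng.integers(2))) for _ in positions]
        pair_by_pos = dict(zip(positions, pairs))
        for x in order:
            i, j = pair_by_pos[x]
            chromatids[i], chromatids[j] = _exchange_distal(chromatids[i], chromatids[j], x, side)
        for x in positions:
            contig, pos = model.from_global(x)
            crossovers.append(
                CrossoverSite(g=x, contig=contig, pos=float(pos), arm_label=arm.label,
                              chromatids=pair_by_pos[x])
            )

    crossovers.sort(key=lambda c: c.g)
    return Bivalent(chromatids=tuple(chromatids), crossovers=crossovers, model=model)


def draw_gamete(bivalent: Bivalent, ndj_type: str, rng: np.random.Generator) -> list[Chromatid]:
    """Segregate the bivalent.

    ``none``: one uniformly chosen chromatid.  ``MI``: one chromatid chosen
    uniformly from each homolog.  ``MII``: the two chromatids sharing a
    centromere origin, from one uniformly chosen homolog.
    """
    ch = bivalent.chromatids
    if ndj_type == NDJ_NONE:
        return [ch[int(rng.integers(4))]]
    if ndj_type == NDJ_MI:
        return [ch[int(rng.integers(2))], ch[2 + int(rng.integers(2))]]
    if ndj_type == NDJ_MII:
        h = int(rng.integers(2))
        return [ch[2 * h], ch[2 * h + 1]]
    raise SimConfigError(f"bad ndj_type {ndj_type!r}")


# ---------------------------------------------------------------------------
# pooled-sequencing observables


def pooled_state_counts(gamete: Sequence[Chromatid], gs: np.ndarray) -> np.ndarray:
    """Number of P2-origin chromatids among the gamete at each global position."""
    counts = np.zeros(len(gs), dtype=np.int8)
    for ch in gamete:
        counts += ch.origins_at(gs)
    return counts


def observable_breakpoints(gamete: Sequence[Chromatid]) -> list[float]:
    """Global positions where the combined P2-copy count changes.

    These are the crossovers a pooled-frequency caller can in principle see
    for this gamete (a reciprocal recombinant pair cancels out, for example).
    """
    bks = sorted({b for ch in gamete for b in ch.breakpoints})
    if not bks:
        return []
    probes = np.array([0.0] + bks) + 0.5 * np.diff(
        np.array([0.0] + bks + [max(s[1] for ch in gamete for s in ch.segments)])
    )
    counts = pooled_state_counts(gamete, probes)
    return [bk for i, bk in enumerate(bks) if counts[i + 1] != counts[i]]


def is_detectable(gamete: Sequence[Chromatid]) -> bool:
    """Whether the gamete shows any pooled frequency-state change.

    For a single chromatid (normal meiosis) this is simply whether the
    chromatid is recombinant.
    """
    if len(gamete) == 1:
        return gamete[0].is_recombinant
    return len(observable_breakpoints(gamete)) > 0


def default_panel(model: ChromosomeModel, spacing_bp: int) -> pd.DataFrame:
    """Evenly spaced marker positions over the assembled arm spans."""
    rows = []
    for arm in model.arms:
        a0, a1 = arm.assembly_span
        for pos in range(a0 + spacing_bp // 2, a1, spacing_bp):
            rows.append((arm.contig, pos))
    return pd.DataFrame(rows, columns=["chrom", "pos"])


def simulate_backcross_pool(
    gamete: Sequence[Chromatid],
    panel: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    ndj_type: Optional[str] = None,
    crossovers: Optional[list[CrossoverSite]] = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Sequence the pooled backcross offspring of a disomic NDJ male.

    Each offspring inherits one of the father's two chromosome copies
    (uniformly) plus a maternal ``P1`` copy; with an infinite pool the
    alternate-allele frequency is therefore ``state_freqs[c]`` where ``c``
    is the father's P2-copy count at the marker.  A finite pool of
    ``n_pool_offspring`` adds a shared binomial composition deviation.
    Read depth is Poisson(``mean_depth``); alternate reads are binomial
    with a symmetric per-read flip probability ``seq_error``.
    """
    if len(gamete) != 2:
        raise ValueError("the backcross father must carry exactly 2 chromosome copies")
    if len(panel) == 0:
        raise ValueError("empty marker panel")
    model = config.model

    gs = np.empty(len(panel), dtype=float)
    for contig in panel["chrom"].unique():
        sel = (panel["chrom"] == contig).to_numpy()
        gs[sel] = model.to_global(contig, panel.loc[sel, "pos"].to_numpy())

    o1 = gamete[0].origins_at(gs)
    o2 = gamete[1].origins_at(gs)
    counts = (o1 + o2).astype(np.int8)
    freqs = np.asarray(config.state_freqs, dtype=float)
    ideal = freqs[counts]

    if config.n_pool_offspring and config.n_pool_offspring > 0:
        n = config.n_pool_offspring
        k = int(rng.binomial(n, 0.5))  # offspring that received the father's first copy
        carriers = k * (o1 == P2) + (n - k) * (o2 == P2)
        pool_freq = carriers / (2.0 * n)
    else:
        pool_freq = ideal

    e = config.seq_error
    p_obs = pool_freq * (1 - e) + (1 - pool_freq) * e
    depth = rng.poisson(config.mean_depth, size=len(panel))
    alt = rng.binomial(depth, p_obs)
    table = pd.DataFrame(
        {
            "chrom": panel["chrom"].to_numpy(),
            "pos": panel["pos"].to_numpy(),
            "ref_depth": depth - alt,
            "alt_depth": alt,
        }
    )

    changes = []
    for g in observable_breakpoints(gamete):
        contig, pos = model.from_global(g)
        changes.append((contig, float(pos) if pos is not GAP else float("nan")))
    truth = SimTruth(
        division_origin=ndj_type if ndj_type is not None else config.ndj_type,
        crossovers=[
            {"contig": c.contig, "pos": c.pos, "arm": c.arm_label, "chromatids": list(c.chromatids)}
            for c in (crossovers or [])
        ],
        chromatid_centromere_origins=tuple(ch.centromere_origin for ch in gamete),
        state_counts=counts,
        ideal_freqs=ideal,
        observable_changes=changes,
    )
    return table, truth


def simulate_event(
    config: SimConfig,
    rng: np.random.Generator,
    panel: Optional[pd.DataFrame] = None,
    ndj_type: Optional[str] = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """One full NDJ event: bivalent -> NDJ gamete -> pooled depth table."""
    ndj = ndj_type if ndj_type is not None else config.ndj_type
    if ndj not in (NDJ_MI, NDJ_MII):
        raise SimConfigError("a pooled backcross event requires ndj_type MI or MII")
    if panel is None:
        panel = default_panel(config.model, config.marker_spacing_bp)
    bivalent = simulate_bivalent(config, rng)
    gamete = draw_gamete(bivalent, ndj, rng)
    return simulate_backcross_pool(
        gamete, panel, config, rng, ndj_type=ndj, crossovers=bivalent.crossovers
    )


def _config_echo(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["model"] = {
        "name": config.model.name,
        "shape": config.model.shape,
        "contigs": config.model.contigs,
    }
    d["position_weights"] = (
        None if config.position_weights is None else [list(w) for w in config.position_weights]
    )
    return d


def simulate_cohort(
    config: SimConfig,
    n_events: int,
    seed: int,
    ndj_probs: Optional[dict[str, float]] = None,
    outdir: Optional[Path] = None,
) -> list[tuple[pd.DataFrame, SimTruth]]:
    """Simulate a cohort of NDJ events, optionally writing TSVs and a manifest.

    ``ndj_probs`` mixes division origins (e.g. ``{"MI": 49/63, "MII": 14/63}``);
    by default every event uses ``config.ndj_type``.  Reproducible under a
    fixed seed: re-running writes byte-identical outputs.
    """
    rng = np.random.default_rng(seed)
    panel = default_panel(config.model, config.marker_spacing_bp)
    out: list[tuple[pd.DataFrame, SimTruth]] = []
    types = None
    if ndj_probs is not None:
        labels = sorted(ndj_probs)
        p = np.array([ndj_probs[l] for l in labels], dtype=float)
        p /= p.sum()
        types = [labels[i] for i in rng.choice(len(labels), size=n_events, p=p)]
    for i in range(n_events):
        ndj = types[i] if types is not None else config.ndj_type
        out.append(simulate_event(config, rng, panel=panel, ndj_type=ndj))

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {"seed": seed, "n_events": n_events, "config": _config_echo(config),
                    "events": []}
        for i, (table, truth) in enumerate(out):
            name = f"event_{i:04d}.tsv"
            write_depth_table(table, outdir / name)
            entry = truth.to_jsonable()
            entry["table"] = name
            manifest["events"].append(entry)
        with open(outdir / "truth_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


# ---------------------------------------------------------------------------
# depth-table I/O (TSV, 1-based positions at the boundary)


def write_depth_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False,
               columns=["chrom", "pos", "ref_depth", "alt_depth"])


def read_depth_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["pos"] = df["pos"] - 1
    return df
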