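"""Chromosome geometry, coordinates, and genetic-map interpolation.

A :class:`ChromosomeModel` describes one chromosome as one (telocentric) or
two (metacentric) assembled arms.  Each arm lives on its own assembly contig
(dm6-style, e.g. ``2L``/``2R``) with contig-local, 0-based half-open
coordinates; BED input is consumed as-is and VCF positions are shifted down
by one at the I/O boundary.

The metacentric layout is canonical and mirrors dm6 chromosome 2: the first
arm runs telomere -> centromere in ascending coordinates, the second arm
centromere -> telomere, with an unassembled pericentromeric satellite gap of
``centromere_gap_bp`` between the two assembled arm ends.  A telocentric
chromosome (e.g. the dm6 X) has a single telomere -> centromere arm.

The model also provides a *global axis*: a single linear coordinate running
from the first arm's telomere through the centromere gap to the second arm's
telomere.  The meiosis simulator places crossovers on this axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

TELOMERE_TO_CENTROMERE = "telomere_to_centromere"
CENTROMERE_TO_TELOMERE = "centromere_to_telomere"

METACENTRIC = "metacentric"
TELOCENTRIC = "telocentric"


class ModelValidationError(ValueError):
    """A chromosome-model invariant was violated."""


class GeneticMapError(RuntimeError):
    """Genetic-map interpolation was requested on an arm without anchors."""


class _GapPosition:
    """Sentinel for positions falling in the unassembled centromere gap."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "GAP"


#: Returned by :meth:`ChromosomeModel.arm_fraction` for gap positions.
GAP = _GapPosition()


@dataclass(frozen=True)
class GeneticMapAnchor:
    """A physical/genetic coordinate pair, e.g. a gene with a known map position."""

    marker_name: str
    position_bp: int
    position_cM: float


@dataclass
class ArmSpec:
    """One chromosome arm on one assembly contig.

    ``assembly_span``/``euchromatin_span`` are 0-based half-open intervals in
    contig coordinates.  ``heterochromatin_intervals`` are the pericentric
    H3K9me3-like blocks; they must fall inside the assembly span and must not
    overlap the euchromatin span.
    """

    label: str
    contig: str
    assembly_span: tuple[int, int]
    euchromatin_span: tuple[int, int]
    orientation: str
    heterochromatin_intervals: list[tuple[int, int]] = field(default_factory=list)
    anchors: list[GeneticMapAnchor] = field(default_factory=list)

    def validate(self) -> None:
        a0, a1 = self.assembly_span
        e0, e1 = self.euchromatin_span
        if not a0 < a1:
            raise ModelValidationError(f"arm {self.label}: empty assembly_span {self.assembly_span}")
        if not (a0 <= e0 < e1 <= a1):
            raise ModelValidationError(
                f"arm {self.label}: euchromatin_span {self.euchromatin_span} "
                f"not contained in assembly_span {self.assembly_span}"
            )
        if self.orientation not in (TELOMERE_TO_CENTROMERE, CENTROMERE_TO_TELOMERE):
            raise ModelValidationError(f"arm {self.label}: bad orientation {self.orientation!r}")
        for h0, h1 in self.heterochromatin_intervals:
            if not (a0 <= h0 < h1 <= a1):
                raise ModelValidationError(
                    f"arm {self.label}: heterochromatin interval ({h0}, {h1}) "
                    f"outside assembly_span {self.assembly_span}"
                )
            if h0 < e1 and h1 > e0:
                raise ModelValidationError(
                    f"arm {self.label}: heterochromatin interval ({h0}, {h1}) "
                    f"overlaps euchromatin_span {self.euchromatin_span}"
                )
        cms = [a.position_cM for a in sorted(self.anchors, key=lambda a: a.position_bp)]
        if any(b < a for a, b in zip(cms, cms[1:])):
            raise ModelValidationError(f"arm {self.label}: anchor cM not non-decreasing in bp")

    # -- geometry -----------------------------------------------------------

    @property
    def length(self) -> int:
        return self.assembly_span[1] - self.assembly_span[0]

    def contains(self, pos: float) -> bool:
        return self.assembly_span[0] <= pos <= self.assembly_span[1]

    def fraction_from_telomere(self, pos: float) -> float:
        """Linear position along the arm: 0 at the telomere, 1 at the centromere."""
        a0, a1 = self.assembly_span
        if not self.contains(pos):
            raise ValueError(f"position {pos} outside arm {self.label} span {self.assembly_span}")
        frac = (pos - a0) / (a1 - a0)
        return frac if self.orientation == TELOMERE_TO_CENTROMERE else 1.0 - frac

    def pericentric_euchromatin(self, fraction: float) -> tuple[float, float]:
        """The centromere-proximal ``fraction`` of the euchromatin span (contig coords)."""
        e0, e1 = self.euchromatin_span
        w = (e1 - e0) * fraction
        if self.orientation == TELOMERE_TO_CENTROMERE:
            return (e1 - w, e1)
        return (e0, e0 + w)

    def bp_to_cM(self, pos: float) -> float:
        """Piecewise-linear interpolation between anchors, clamped at the ends."""
        if len(self.anchors) < 2:
            raise GeneticMapError(
                f"arm {self.label}: need >= 2 genetic-map anchors, have {len(self.anchors)}"
            )
        anchors = sorted(self.anchors, key=lambda a: a.position_bp)
        xs = np.array([a.position_bp for a in anchors], dtype=float)
        ys = np.array([a.position_cM for a in anchors], dtype=float)
        return float(np.interp(pos, xs, ys))


@dataclass
class ChromosomeModel:
    """Arm geometry, centromere gap, and genetic map for one chromosome."""

    name: str
    arms: list[ArmSpec]
    shape: str
    centromere_gap_bp: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.shape == METACENTRIC:
            if len(self.arms) != 2:
                raise ModelValidationError("metacentric model requires exactly 2 arms")
            if self.arms[0].orientation != TELOMERE_TO_CENTROMERE or (
                self.arms[1].orientation != CENTROMERE_TO_TELOMERE
            ):
                raise ModelValidationError(
                    "canonical metacentric layout: first arm telomere_to_centromere, "
                    "second arm centromere_to_telomere"
                )
        elif self.shape == TELOCENTRIC:
            if len(self.arms) != 1:
                raise ModelValidationError("telocentric model requires exactly 1 arm")
            if self.arms[0].orientation != TELOMERE_TO_CENTROMERE:
                raise ModelValidationError("telocentric arm must run telomere_to_centromere")
        else:
            raise ModelValidationError(f"unknown shape {self.shape!r}")
        if self.centromere_gap_bp < 0:
            raise ModelValidationError("centromere_gap_bp must be >= 0")
        seen: dict[str, ArmSpec] = {}
        for arm in self.arms:
            arm.validate()
            if arm.contig in seen:
                o = seen[arm.contig]
                if arm.assembly_span[0] < o.assembly_span[1] and arm.assembly_span[1] > o.assembly_span[0]:
                    raise ModelValidationError(
                        f"arms {o.label} and {arm.label} overlap on contig {arm.contig}"
                    )
            seen[arm.contig] = arm

    # -- lookup -------------------------------------------------------------

    @property
    def contigs(self) -> list[str]:
        return [a.contig for a in self.arms]

    def arm_for(self, contig: str, pos: Optional[float] = None) -> ArmSpec:
        for arm in self.arms:
            if arm.contig == contig and (pos is None or arm.contains(pos)):
                return arm
        raise KeyError(f"no arm covering {contig}:{pos}")

    def arm_by_label(self, label: str) -> ArmSpec:
        for arm in self.arms:
            if arm.label == label:
                return arm
        raise KeyError(f"no arm labelled {label!r}")

    def bp_to_cM(self, contig: str, pos: float) -> float:
        return self.arm_for(contig, pos).bp_to_cM(pos)

    def arm_fraction(self, contig: str, pos: Optional[float] = None):
        """Fraction from the telomere along the arm containing ``(contig, pos)``.

        Positions in the unassembled centromere gap (addressed with the
        chromosome name, or any contig not covered by an arm of a metacentric
        model) return the :data:`GAP` sentinel rather than raising.
        """
        for arm in self.arms:
            if arm.contig == contig and pos is not None and arm.contains(pos):
                return arm.fraction_from_telomere(pos)
        if self.shape == METACENTRIC:
            return GAP
        raise ValueError(f"position {contig}:{pos} outside the telocentric arm")

    # -- global axis --------------------------------------------------------

    @property
    def axis_length(self) -> int:
        return sum(a.length for a in self.arms) + (
            self.centromere_gap_bp if self.shape == METACENTRIC else 0
        )

    def _arm_offset(self, index: int) -> int:
        if index == 0:
            return 0
        return self.arms[0].length + self.centromere_gap_bp

    def arm_global_span(self, index: int) -> tuple[float, float]:
        off = self._arm_offset(index)
        return (off, off + self.arms[index].length)

    @property
    def centromere_global(self) -> float:
        if self.shape == TELOCENTRIC:
            return float(self.arms[0].length)
        return self.arms[0].length + self.centromere_gap_bp / 2.0

    def to_global(self, contig: str, pos) -> np.ndarray | float:
        """Map contig-local position(s) onto the global telomere-to-telomere axis."""
        for i, arm in enumerate(self.arms):
            if arm.contig == contig:
                off = self._arm_offset(i)
                return off + (np.asarray(pos, dtype=float) - arm.assembly_span[0])
        raise KeyError(f"unknown contig {contig!r}")

    def from_global(self, g: float):
        """Inverse of :meth:`to_global`; gap positions return ``(name, GAP)``."""
        for i, arm in enumerate(self.arms):
            lo, hi = self.arm_global_span(i)
            if lo <= g <= hi:
                return arm.contig, arm.assembly_span[0] + (g - lo)
        return self.name, GAP

    def euchromatin_global_intervals(self) -> list[tuple[float, float]]:
        out = []
        for i, arm in enumerate(self.arms):
            off = self._arm_offset(i)
            e0, e1 = arm.euchromatin_span
            out.append((off + e0 - arm.assembly_span[0], off + e1 - arm.assembly_span[0]))
        return out

    def pericentric_zone(self, euchromatin_fraction: float = 0.15) -> dict[str, list[tuple[float, float]]]:
        """Per-contig pericentric zone: heterochromatin plus the proximal
        ``euchromatin_fraction`` of each arm's euchromatin."""
        zone: dict[str, list[tuple[float, float]]] = {}
        for arm in self.arms:
            ivals = list(arm.heterochromatin_intervals)
            ivals.append(arm.pericentric_euchromatin(euchromatin_fraction))
            zone.setdefault(arm.contig, []).extend(ivals)
        return zone


# ---------------------------------------------------------------------------
# file loading


def _load_bed(path: Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"], dtype={0: str},
    )
    return df


def load_chromosome_model(path) -> ChromosomeModel:
    """Read a YAML chromosome-model config.

    The config names the chromosome, its shape and centromere gap, the arms
    (contig, spans, orientation), and optionally a heterochromatin BED file
    and a genetic-map anchor TSV (columns ``marker_name chrom position_bp
    position_cM``).  Relative file paths are resolved against the config file.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)

    def _resolve(p):
        p = Path(p)
        return p if p.is_absolute() else path.parent / p

    het = pd.DataFrame(columns=["chrom", "start", "end"])
    if cfg.get("heterochromatin_bed"):
        het = _load_bed(_resolve(cfg["heterochromatin_bed"]))
    anchors = pd.DataFrame(columns=["marker_name", "chrom", "position_bp", "position_cM"])
    if cfg.get("anchors_tsv"):
        anchors = pd.read_csv(_resolve(cfg["anchors_tsv"]), sep="\t", dtype={"chrom": str})

    arms = []
    for a in cfg["arms"]:
        contig = str(a["contig"])
        h = [
            (int(r.start), int(r.end))
            for r in het[het["chrom"] == contig].itertuples()
        ]
        anc = [
            GeneticMapAnchor(str(r.marker_name), int(r.position_bp), float(r.position_cM))
            for r in anchors[anchors["chrom"] == contig].itertuples()
        ]
        arms.append(
            ArmSpec(
                label=str(a["label"]),
                contig=contig,
                assembly_span=tuple(int(x) for x in a["assembly_span"]),
                euchromatin_span=tuple(int(x) for x in a["euchromatin_span"]),
                orientation=str(a["orientation"]),
                heterochromatin_intervals=h,
                anchors=anc,
            )
        )
    return ChromosomeModel(
        name=str(cfg["name"]),
        arms=arms,
        shape=str(cfg["shape"]),
        centromere_gap_bp=int(cfg.get("centromere_gap_bp", 0)),
    )


# ---------------------------------------------------------------------------
# built-in dm6-like models (approximate coordinates; for simulation and tests)


def _anchors(contig: str, pairs: Sequence[tuple[float, float]]) -> list[GeneticMapAnchor]:
    return [
        GeneticMapAnchor(f"{contig}_a{i}", int(mb * 1e6), cm)
        for i, (mb, cm) in enumerate(pairs)
    ]


def dm6_chr2() -> ChromosomeModel:
    """A dm6-like metacentric chromosome 2.

    Assembly lengths match dm6 2L/2R; pericentric heterochromatin boundaries
    and the genetic-map anchors are approximate (standard-map scale, ~55 cM
    per arm) and intended for simulation, not for lift-over-grade analysis.
    """
    left = ArmSpec(
        label="2L",
        contig="2L",
        assembly_span=(0, 23_513_712),
        euchromatin_span=(0, 22_000_000),
        orientation=TELOMERE_TO_CENTROMERE,
        heterochromatin_intervals=[(22_000_000, 23_513_712)],
        anchors=_anchors(
            "2L",
            [(0.1, 0.0), (5.0, 13.0), (10.0, 36.0), (15.0, 50.0), (20.0, 54.3), (21.9, 55.0)],
        ),
    )
    right = ArmSpec(
        label="2R",
        contig="2R",
        assembly_span=(0, 25_286_936),
        euchromatin_span=(6_000_000, 25_286_936),
        orientation=CENTROMERE_TO_TELOMERE,
        heterochromatin_intervals=[(0, 6_000_000)],
        anchors=_anchors(
            "2R",
            [(6.0, 55.0), (10.0, 57.5), (15.0, 67.5), (20.0, 87.5), (25.2, 107.5)],
        ),
    )
    return ChromosomeModel(name="2", arms=[left, right], shape=METACENTRIC,
                           centromere_gap_bp=4_000_000)


def dm6_chrX() -> ChromosomeModel:
    """A dm6-like telocentric X chromosome (centromere at the high-coordinate end)."""
    arm = ArmSpec(
        label="X",
        contig="X",
        assembly_span=(0, 23_542_271),
        euchromatin_span=(0, 21_400_000),
        orientation=TELOMERE_TO_CENTROMERE,
        heterochromatin_intervals=[(21_400_000, 23_542_271)],
        anchors=_anchors(
            "X",
            [(0.3, 0.0), (5.0, 15.0), (10.0, 36.0), (15.0, 52.0), (20.0, 62.0), (21.3, 66.0)],
        ),
    )
    return ChromosomeModel(name="X", arms=[arm], shape=TELOCENTRIC, centromere_gap_bp=0)
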