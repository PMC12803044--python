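"""End-to-end orchestration: depth tables -> panel -> calls -> summaries.

These functions chain the analysis modules in the order a cohort run uses
them: panel assembly and filtering, per-individual segmentation and
crossover calling (including the centromere-gap check on metacentric
chromosomes), division classification with the monosomy-rescue flag, cause
categorisation, and cohort summaries.  Individuals whose chromosome-wide
marker coverage is insufficient are excluded with a logged reason rather
than silently dropped; per-individual failures are logged and skipped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import stats
from .cause_categorizer import CategorizerThresholds, CauseCategory, categorize_event, cohort_breakdown
from .chromosome_model import ChromosomeModel
from .division_classifier import DivisionCall, classify_ndj_event, division_summary
from .inheritance_model import arm_crossover_spectrum
from .meiosis_sim import read_depth_table
from .snp_panel import (SnpPanel, allele_frequency_track, apply_depth_variance_filter,
                        panel_from_depth_tables)
from .xo_caller import (CrossoverCall, GenotypeSegmentation, SegmentationParams,
                        annotate_double_crossovers, calls_from_segmentation,
                        calls_to_bed, calls_to_frame, detect_gap_shift, segment_track)

log = logging.getLogger("ndjmap")


@dataclass
class NdjEvent:
    """One progeny's full call set."""

    individual: str
    division: DivisionCall
    calls: list[CrossoverCall]
    segmentations: dict[str, GenotypeSegmentation]
    arm_counts: dict[str, int]
    category: Optional[CauseCategory] = None

    @property
    def origin(self) -> str:
        return self.division.origin


@dataclass
class AnalysisParams:
    seg_params: SegmentationParams = field(default_factory=SegmentationParams)
    thresholds: CategorizerThresholds = field(default_factory=CategorizerThresholds)
    pericentric_window_bp: float = 1_000_000
    min_unmasked_fraction: float = 0.2
    double_co_min_bp: float = 2_000_000
    double_co_min_cM: float = 10.0


def analyze_individual(panel: SnpPanel, individual: str, model: ChromosomeModel,
                       params: Optional[AnalysisParams] = None) -> NdjEvent:
    """Segment, call crossovers, classify, and categorise one individual."""
    params = params or AnalysisParams()
    segs: dict[str, GenotypeSegmentation] = {}
    calls: list[CrossoverCall] = []
    for arm in model.arms:
        track = allele_frequency_track(panel, individual, arm.contig)
        seg = segment_track(track, params.seg_params, contig=arm.contig)
        segs[arm.contig] = seg
        calls.extend(
            calls_from_segmentation(
                seg, model, individual=individual,
                pericentric_euchromatin_fraction=params.thresholds.pericentric_euchromatin_fraction,
            )
        )
    if len(model.arms) == 2:
        gap = detect_gap_shift(segs[model.arms[0].contig], segs[model.arms[1].contig],
                               model, individual=individual)
        if gap is not None:
            calls.append(gap)
        division = classify_ndj_event(
            segs[model.arms[0].contig], segs[model.arms[1].contig], model, calls,
            window_bp=params.pericentric_window_bp,
            min_markers=params.seg_params.min_segment_markers,
        )
    else:
        seg = segs[model.arms[0].contig]
        division = classify_ndj_event(seg, seg, model, calls,
                                      window_bp=params.pericentric_window_bp,
                                      min_markers=params.seg_params.min_segment_markers)
    division.individual = individual
    annotate_double_crossovers(calls, model, params.double_co_min_bp, params.double_co_min_cM)
    arm_counts = {
        arm.label: sum(1 for c in calls if c.arm == arm.label) for arm in model.arms
    }
    category = categorize_event(calls, model, params.thresholds)
    return NdjEvent(individual=individual, division=division, calls=calls,
                    segmentations=segs, arm_counts=arm_counts, category=category)


@dataclass
class CohortResult:
    events: list[NdjEvent]
    excluded: dict[str, str]
    panel: SnpPanel
    summaries: dict


def analyze_cohort(panel: SnpPanel, model: ChromosomeModel,
                   params: Optional[AnalysisParams] = None,
                   comparison_mii: Optional[tuple[int, int]] = None,
                   prefiltered: bool = False) -> CohortResult:
    """Run the full analysis chain over every individual in the panel.

    Applies the depth/variance filter (unless ``prefiltered``), excludes
    individuals with unmasked-marker fraction below
    ``min_unmasked_fraction`` on the modelled chromosome, and summarises
    the cohort (division counts, per-origin crossover spectra, cause
    breakdown, 1 Mb exchange-rate track).
    """
    params = params or AnalysisParams()
    if not prefiltered:
        panel = apply_depth_variance_filter(panel)
    events: list[NdjEvent] = []
    excluded: dict[str, str] = {}
    for ind in panel.individuals:
        frac = panel.unmasked_fraction(ind, model.contigs)
        if frac < params.min_unmasked_fraction:
            excluded[ind] = f"insufficient coverage (unmasked fraction {frac:.3f})"
            log.warning("excluding %s: %s", ind, excluded[ind])
            continue
        try:
            events.append(analyze_individual(panel, ind, model, params))
        except Exception as exc:  # logged, never silently dropped
            excluded[ind] = f"analysis failed: {exc}"
            log.error("individual %s failed: %s", ind, exc)

    summaries: dict = {"n_events": len(events), "n_excluded": len(excluded)}
    if events:
        summaries["division"] = division_summary([e.division for e in events],
                                                 comparison=comparison_mii)
        spectra = {}
        for origin in ("MI", "MII"):
            sel = [e for e in events if e.origin == origin]
            if sel:
                counts = [k for e in sel for k in e.arm_counts.values()]
                spectra[origin] = arm_crossover_spectrum(counts, origin)
        summaries["spectra"] = spectra
        summaries["cause_breakdown"] = cohort_breakdown(
            [e.category for e in events], labels=[e.origin for e in events]
        )
        all_calls = [c for e in events for c in e.calls]
        summaries["density"] = stats.interval_density(all_calls, len(events), model)
    return CohortResult(events=events, excluded=excluded, panel=panel, summaries=summaries)


# ---------------------------------------------------------------------------
# cohort I/O


def load_depth_table_dir(path) -> dict[str, pd.DataFrame]:
    """Read every ``*.tsv`` depth table in a directory, keyed by stem."""
    path = Path(path)
    tables = {p.stem: read_depth_table(p) for p in sorted(path.glob("*.tsv"))}
    if not tables:
        raise FileNotFoundError(f"no depth tables (*.tsv) found in {path}")
    return tables


def events_to_frame(events: Sequence[NdjEvent], excluded: dict[str, str]) -> pd.DataFrame:
    rows = []
    for e in events:
        states = e.division.pericentric_states
        rows.append(
            {
                "individual": e.individual,
                "origin": e.origin,
                "proximal_state_arm1": states[0],
                "proximal_state_arm2": states[1] if len(states) > 1 else states[0],
                "rescue_flag": e.division.rescue_flag,
                "rescue_reason": e.division.rescue_reason,
                "n_crossovers": sum(e.arm_counts.values()),
                "category": e.category.category if e.category else None,
                "rule_fired": e.category.rule_fired if e.category else None,
                "excluded_reason": None,
            }
        )
    for ind, reason in sorted(excluded.items()):
        rows.append({"individual": ind, "excluded_reason": reason})
    return pd.DataFrame(rows)


def write_cohort_outputs(result: CohortResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_calls = [c for e in result.events for c in e.calls]
    calls_to_frame(all_calls).to_csv(outdir / "calls.tsv", sep="\t", index=False)
    calls_to_bed([c for c in all_calls if c.arm != "gap"], outdir / "calls.bed")
    events_to_frame(result.events, result.excluded).to_csv(
        outdir / "events.tsv", sep="\t", index=False
    )
    if "spectra" in result.summaries:
        frames = []
        for origin, df in result.summaries["spectra"].items():
            df = df.copy()
            df.insert(0, "cohort", origin)
            frames.append(df)
        pd.concat(frames).to_csv(outdir / "spectra.tsv", sep="\t", index=False)
    if "cause_breakdown" in result.summaries:
        result.summaries["cause_breakdown"].to_csv(
            outdir / "cause_breakdown.tsv", sep="\t", index=False
        )
    summ = {"n_events": result.summaries.get("n_events", 0),
            "n_excluded": result.summaries.get("n_excluded", 0),
            "excluded": result.excluded}
    if "division" in result.summaries:
        div = result.summaries["division"]
        summ["division"] = {
            "counts": div["counts"],
            "mi_fraction": div["mi_fraction"],
            "mii_fraction": div["mii_fraction"],
            "ztest": None if div["ztest"] is None else {
                "z": div["ztest"].z, "p_one_tailed": div["ztest"].p_one_tailed,
            },
        }
        summ["spectra"] = {
            k: v.to_dict(orient="records") for k, v in result.summaries["spectra"].items()
        }
        summ["cause_breakdown"] = result.summaries["cause_breakdown"].to_dict(orient="records")
        stats.density_to_bedgraph(result.summaries["density"], outdir / "density.bedgraph")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summ, fh, indent=1, sort_keys=True)
    with open(outdir / "filter_log.json", "w") as fh:
        json.dump(result.panel.filter_log, fh, indent=1, sort_keys=True)


def analyze_table_dir(tables_dir, model: ChromosomeModel,
                      params: Optional[AnalysisParams] = None,
                      outdir=None) -> CohortResult:
    """Convenience chain: depth-table directory -> cohort result (+files)."""
    tables = load_depth_table_dir(tables_dir)
    panel = panel_from_depth_tables(tables)
    result = analyze_cohort(panel, model, params)
    if outdir is not None:
        write_cohort_outputs(result, outdir)
    return result
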