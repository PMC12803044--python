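"""Biallelic SNP panel construction and the depth/variance marker filters.

The panel is the set of single-nucleotide markers at which the two parental
stocks are homozygous for different alleles.  Per-individual allele depths
from the pooled backcross sequencing are aligned to the panel, then two
filters are applied in a fixed, declared order:

1. *depth mask* (per individual): a marker is masked for an individual when
   its total depth there is below ``min_depth`` (default 8);
2. *variance filter* (panel-wide): a marker is dropped outright when the
   population variance (ddof=0) of the observed alternate-allele frequency
   across the unmasked individuals is below ``min_variance`` (default 0.01),
   which removes uninformative/fixed sites.

Both thresholds are strict "less than" comparisons.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import pysam


class VcfContigMismatchError(ValueError):
    """The parental VCFs do not declare the same contigs."""


@dataclass(frozen=True)
class SnpMarker:
    chrom: str
    pos: int  # 0-based
    p1_allele: str
    p2_allele: str


@dataclass
class SnpPanel:
    """Ordered markers with per-individual allele-depth matrices.

    ``markers`` has columns ``chrom, pos, p1_allele, p2_allele`` sorted by
    (chrom, pos); ``ref_depth``/``alt_depth`` are marker x individual frames
    sharing the marker index; ``mask`` is True where an observation is
    usable.  ``filter_log`` accumulates counts removed by each rule.
    """

    markers: pd.DataFrame
    ref_depth: pd.DataFrame
    alt_depth: pd.DataFrame
    mask: pd.DataFrame
    filter_log: dict = field(default_factory=dict)

    @property
    def individuals(self) -> list[str]:
        return list(self.ref_depth.columns)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def total_depth(self) -> pd.DataFrame:
        return self.ref_depth + self.alt_depth

    def frequencies(self) -> pd.DataFrame:
        depth = self.total_depth()
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.alt_depth / depth

    def unmasked_fraction(self, individual: str, chroms: Optional[Iterable[str]] = None) -> float:
        sel = slice(None) if chroms is None else self.markers["chrom"].isin(list(chroms)).to_numpy()
        col = self.mask[individual].to_numpy()[sel]
        return float(col.mean()) if len(col) else 0.0


# ---------------------------------------------------------------------------
# parental VCF -> marker list


def _parental_alleles(vcf_path) -> tuple[dict, set]:
    """Map (chrom, pos0) -> homozygous allele for one parental VCF.

    Heterozygous, multi-allelic or non-SNP records poison their site (the
    site is dropped panel-wide).  A single-sample GT is used when present;
    a sites-only VCF is read as homozygous-alternate calls.
    """
    alleles: dict[tuple[str, int], tuple[str, str]] = {}  # key -> (ref, allele)
    bad: set[tuple[str, int]] = set()
    with pysam.VariantFile(str(vcf_path)) as vcf:
        n_samples = len(vcf.header.samples)
        for rec in vcf:
            key = (rec.chrom, rec.start)
            alts = [a for a in (rec.alts or ())]
            if len(rec.ref) != 1 or len(alts) > 1 or any(len(a) != 1 for a in alts):
                bad.add(key)
                continue
            if n_samples == 0:
                if not alts:
                    bad.add(key)
                else:
                    alleles[key] = (rec.ref, alts[0])
                continue
            gt = rec.samples[0].get("GT")
            if gt is None or any(g is None for g in gt):
                bad.add(key)
                continue
            if len(set(gt)) != 1:
                bad.add(key)  # not homozygous in the parental stock
                continue
            allele = rec.alleles[gt[0]]
            if len(allele) != 1:
                bad.add(key)
                continue
            alleles[key] = (rec.ref, allele)
    return alleles, bad


def _variant_sites(vcf_path) -> set:
    sites = set()
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            sites.add((rec.chrom, rec.start))
    return sites


def call_biallelic_panel(
    p1_vcf,
    p2_vcf,
    exclusion_vcf=None,
    exclusion_chroms: Iterable[str] = (),
) -> pd.DataFrame:
    """Sites where the two parents are homozygous for different SNP alleles.

    A site present in only one parental VCF is read as homozygous-reference
    in the other parent (the usual convention for variants called against a
    shared reference).  On ``exclusion_chroms``, sites that appear as
    variants in ``exclusion_vcf`` (e.g. the compound-chromosome paternal
    stock) are disregarded.

    Returns a markers frame (``chrom, pos, p1_allele, p2_allele``) with the
    per-rule removal counts in ``df.attrs["filter_log"]``.
    """
    with pysam.VariantFile(str(p1_vcf)) as v1, pysam.VariantFile(str(p2_vcf)) as v2:
        c1, c2 = set(v1.header.contigs), set(v2.header.contigs)
    if c1 != c2:
        unshared = sorted(c1.symmetric_difference(c2))
        raise VcfContigMismatchError(f"parental VCFs disagree on contigs: {unshared}")

    a1, bad1 = _parental_alleles(p1_vcf)
    a2, bad2 = _parental_alleles(p2_vcf)
    bad = bad1 | bad2
    excl = _variant_sites(exclusion_vcf) if exclusion_vcf is not None else set()
    exclusion_chroms = set(exclusion_chroms)

    log = {"not_biallelic_snp_or_het": 0, "identical_alleles": 0, "exclusion_stock": 0,
           "retained": 0}
    rows = []
    for key in sorted(set(a1) | set(a2) | bad):
        if key in bad:
            log["not_biallelic_snp_or_het"] += 1
            continue
        ref = (a1.get(key) or a2.get(key))[0]
        p1 = a1[key][1] if key in a1 else ref
        p2 = a2[key][1] if key in a2 else ref
        if p1 == p2:
            log["identical_alleles"] += 1
            continue
        if key[0] in exclusion_chroms and key in excl:
            log["exclusion_stock"] += 1
            continue
        rows.append((key[0], key[1], p1, p2))
        log["retained"] += 1

    markers = pd.DataFrame(rows, columns=["chrom", "pos", "p1_allele", "p2_allele"])
    markers.attrs["filter_log"] = log
    return markers


# ---------------------------------------------------------------------------
# panel assembly and filtering


def panel_from_depth_tables(tables: dict[str, pd.DataFrame],
                            markers: Optional[pd.DataFrame] = None) -> SnpPanel:
    """Align per-individual ``chrom,pos,ref_depth,alt_depth`` tables on a panel.

    Without an explicit marker list the union of observed sites is used
    (alleles recorded as placeholders).  Missing observations get zero depth
    and start masked.
    """
    if markers is None:
        keys = pd.concat([t[["chrom", "pos"]] for t in tables.values()])
        markers = keys.drop_duplicates().sort_values(["chrom", "pos"]).reset_index(drop=True)
        markers["p1_allele"] = "A"
        markers["p2_allele"] = "T"
    else:
        markers = markers.sort_values(["chrom", "pos"]).reset_index(drop=True)

    index = pd.MultiIndex.from_frame(markers[["chrom", "pos"]])
    ref = pd.DataFrame(0, index=index, columns=sorted(tables), dtype=np.int64)
    alt = ref.copy()
    for ind in sorted(tables):
        t = tables[ind].set_index(["chrom", "pos"])
        t = t[~t.index.duplicated()]
        ref[ind] = t["ref_depth"].reindex(index).fillna(0).astype(np.int64)
        alt[ind] = t["alt_depth"].reindex(index).fillna(0).astype(np.int64)
    ref.index = alt.index = markers.index
    mask = (ref + alt) > 0
    return SnpPanel(markers=markers, ref_depth=ref, alt_depth=alt, mask=mask,
                    filter_log={"n_input_markers": len(markers)})


def apply_depth_variance_filter(panel: SnpPanel, min_depth: int = 8,
                                min_variance: float = 0.01) -> SnpPanel:
    """Mask low-depth observations, then drop low-variance markers.

    The order is fixed: the per-individual depth mask is applied first and
    the cross-individual frequency variance is computed on the remaining
    unmasked observations only.  Markers with fewer than two unmasked
    observations are dropped (their variance is indeterminate and they carry
    no segregation information).
    """
    depth = panel.total_depth()
    mask = panel.mask & (depth >= min_depth)
    n_masked = int((panel.mask & ~mask).to_numpy().sum())

    freq = panel.frequencies().where(mask)
    n_obs = mask.sum(axis=1)
    variance = freq.var(axis=1, ddof=0)
    keep = (variance >= min_variance) & (n_obs >= 2)
    n_dropped = int((~keep).sum())

    idx = panel.markers.index[keep]
    log = dict(panel.filter_log)
    log.update(
        {
            "min_depth": min_depth,
            "min_variance": min_variance,
            "n_observations_masked_low_depth": n_masked,
            "n_markers_dropped_low_variance": n_dropped,
            "n_markers_retained": int(keep.sum()),
        }
    )
    return SnpPanel(
        markers=panel.markers.loc[idx].reset_index(drop=True),
        ref_depth=panel.ref_depth.loc[idx].reset_index(drop=True),
        alt_depth=panel.alt_depth.loc[idx].reset_index(drop=True),
        mask=mask.loc[idx].reset_index(drop=True),
        filter_log=log,
    )


def allele_frequency_track(panel: SnpPanel, individual: str, chrom: str) -> pd.DataFrame:
    """Ordered ``pos, freq, depth`` at this individual's unmasked markers."""
    if individual not in panel.ref_depth.columns:
        raise KeyError(f"unknown individual {individual!r}")
    sel = (panel.markers["chrom"] == chrom).to_numpy() & panel.mask[individual].to_numpy()
    pos = panel.markers.loc[sel, "pos"].to_numpy()
    ref = panel.ref_depth.loc[sel, individual].to_numpy()
    alt = panel.alt_depth.loc[sel, individual].to_numpy()
    depth = ref + alt
    if len(pos) == 0:
        warnings.warn(f"no unmasked markers for {individual} on {chrom}")
        return pd.DataFrame(columns=["pos", "freq", "depth"])
    return pd.DataFrame({"pos": pos, "freq": alt / depth, "depth": depth})


# ---------------------------------------------------------------------------
# I/O


def write_panel_tsv(markers: pd.DataFrame, path) -> None:
    out = markers.copy()
    out["pos"] = out["pos"] + 1  # 1-based at the boundary
    out.to_csv(path, sep="\t", index=False)


def write_filter_log(log: dict, path) -> None:
    with open(Path(path), "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
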