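"""Per-sample QC, multi-algorithm CNV merging, filter tiers, rarity and
annotation.

CNV callers on array data disagree both on which events exist and on their
boundaries. This module groups same-sample, same-state calls from different
algorithms that overlap by at least 1 bp (transitively), takes the
intersection of the group as the conservative consensus interval (the union
is available as ``boundary_rule="outer"``), and records which algorithms
support each consensus event. Two filter tiers mirror the two analysis
layers downstream:

* ``large``     — length > 1 Mb and > 100 markers (any algorithm support);
* ``phenotype`` — length > 100 kb, at least 10 markers, and support from
  all three algorithms.

Rarity classes cluster events across the cohort by reciprocal overlap:
a cluster of one is a singleton; a cluster seen in more than ``common_freq``
of samples is common; everything else is rare.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import (
    AUTOSOMES,
    CnvCall,
    IntensityProfile,
    MarkerMap,
    Region,
    RegionSet,
)


@dataclass(frozen=True)
class QcThresholds:
    """Sample-level QC gates. A sample passes iff its genome-wide LRR SD,
    BAF drift (mass in (0.2,0.25) ∪ (0.75,0.8)) and per-algorithm call count
    are all at or below these bounds."""

    lrr_sd_max: float = 0.30
    baf_drift_max: float = 0.01
    max_call_count: int = 30


@dataclass
class SampleQc:
    sample_id: str
    lrr_sd: float
    baf_drift: float
    call_count: dict[str, int]
    passed: bool
    failed_metrics: tuple[str, ...]
    thresholds: QcThresholds


def sample_qc(
    profile: IntensityProfile,
    callsets: Mapping[str, Sequence[CnvCall]],
    thresholds: QcThresholds = QcThresholds(),
) -> SampleQc:
    """Evaluate one sample against the QC gates; the thresholds used are
    recorded with the result."""
    if not callsets:
        raise ValueError("sample_qc requires at least one call set")
    # autosomes only: sex-chromosome intensity (e.g. absent-Y probes) would
    # swamp the genome-wide noise estimate
    mmap = profile.map_ref
    auto = np.isin(mmap.chrom.astype(str), AUTOSOMES)
    lrr = profile.lrr[auto & profile.lrr_mask]
    baf = profile.baf[auto & profile.baf_mask]
    lrr_sd = float(np.std(lrr, ddof=1)) if len(lrr) > 1 else math.nan
    drift = float(
        np.mean(((baf > 0.20) & (baf < 0.25)) | ((baf > 0.75) & (baf < 0.80)))
    ) if len(baf) else math.nan
    counts = {
        algo: sum(1 for c in calls if c.sample_id == profile.sample_id)
        for algo, calls in callsets.items()
    }
    failed = []
    if lrr_sd > thresholds.lrr_sd_max:
        failed.append(f"lrr_sd={lrr_sd:.3f}>{thresholds.lrr_sd_max}")
    if drift > thresholds.baf_drift_max:
        failed.append(f"baf_drift={drift:.4f}>{thresholds.baf_drift_max}")
    if max(counts.values(), default=0) > thresholds.max_call_count:
        worst = max(counts, key=counts.get)
        failed.append(f"call_count[{worst}]={counts[worst]}>{thresholds.max_call_count}")
    return SampleQc(
        sample_id=profile.sample_id, lrr_sd=lrr_sd, baf_drift=drift,
        call_count=counts, passed=not failed, failed_metrics=tuple(failed),
        thresholds=thresholds,
    )


# ---------------------------------------------------------------------------
# consensus merging
# ---------------------------------------------------------------------------


@dataclass
class ConsensusCnv:
    sample_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    state: str  # deletion | duplication
    cn: int
    n_markers: int
    support: frozenset[str]
    rarity: str = ""          # common | rare | singleton, set by classify_rarity
    region_hits: tuple[str, ...] = ()
    gene_count: int = -1      # -1 = not annotated yet

    def __post_init__(self) -> None:
        if not self.support:
            raise ValueError("consensus CNV requires non-empty algorithm support")
        if self.end < self.start:
            raise ValueError("consensus CNV with end < start")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def merge_callsets(
    callsets: Mapping[str, Sequence[CnvCall]],
    mmap: MarkerMap,
    min_support: int = 1,
    boundary_rule: str = "strict",
) -> list[ConsensusCnv]:
    """Merge per-algorithm call sets into consensus CNVs.

    Same-sample, same-state (deletion vs duplication) calls whose intervals
    overlap by >= 1 bp are grouped transitively. The consensus interval is
    the group intersection under ``boundary_rule="strict"`` (falling back to
    the union for the rare chained group whose intersection is empty) or the
    union under ``"outer"``. Groups supported by fewer than ``min_support``
    distinct algorithms are dropped. Marker counts are recomputed from the
    map over the consensus interval; mixed-state overlaps are never merged.
    """
    if boundary_rule not in ("strict", "outer"):
        raise ValueError(f"unknown boundary_rule {boundary_rule!r}")
    buckets: dict[tuple[str, str, str], list[CnvCall]] = defaultdict(list)
    for calls in callsets.values():
        for c in calls:
            buckets[(c.sample_id, c.chrom, c.state)].append(c)
    out: list[ConsensusCnv] = []
    for (sid, chrom, state), calls in sorted(buckets.items()):
        calls = sorted(calls, key=lambda c: (c.start, c.end, c.algorithm))
        group: list[CnvCall] = []
        reach = -1
        for c in calls + [None]:  # sentinel flushes the last group
            if c is not None and group and c.start <= reach:
                group.append(c)
                reach = max(reach, c.end)
                continue
            if group:
                cons = _consensus_of(group, mmap, min_support, boundary_rule)
                if cons is not None:
                    out.append(cons)
            if c is not None:
                group = [c]
                reach = c.end
    return out


def _consensus_of(
    group: list[CnvCall], mmap: MarkerMap, min_support: int, rule: str
) -> ConsensusCnv | None:
    support = frozenset(c.algorithm for c in group)
    if len(support) < min_support:
        return None
    if rule == "strict":
        start = max(c.start for c in group)
        end = min(c.end for c in group)
        if start > end:  # chained group with empty common core
            start = min(c.start for c in group)
            end = max(c.end for c in group)
    else:
        start = min(c.start for c in group)
        end = max(c.end for c in group)
    cns = sorted(c.cn for c in group)
    cn = cns[len(cns) // 2]  # median copy number of the group
    nm = mmap.n_markers_in(group[0].chrom, start, end)
    return ConsensusCnv(
        sample_id=group[0].sample_id, chrom=group[0].chrom,
        start=start, end=end, state=group[0].state, cn=cn,
        n_markers=nm, support=support,
    )


# ---------------------------------------------------------------------------
# filter tiers
# ---------------------------------------------------------------------------

TIERS = {
    # (min length exclusive, min markers, marker bound strict?, required support)
    "large": dict(min_length_bp=1_000_000, min_markers=100,
                  markers_strict=True, min_support=1),
    "phenotype": dict(min_length_bp=100_000, min_markers=10,
                      markers_strict=False, min_support=3),
}


def filter_tier(cnvs: Iterable[ConsensusCnv], tier: str) -> list[ConsensusCnv]:
    """Apply one of the two published filter tiers.

    ``large``: length strictly > 1 Mb and strictly > 100 markers, any
    support. ``phenotype``: length strictly > 100 kb, >= 10 markers, and
    three-algorithm support.
    """
    if tier not in TIERS:
        raise ValueError(f"unknown tier {tier!r}; expected one of {sorted(TIERS)}")
    t = TIERS[tier]
    kept = []
    for c in cnvs:
        if c.length_bp <= t["min_length_bp"]:
            continue
        if t["markers_strict"]:
            if c.n_markers <= t["min_markers"]:
                continue
        elif c.n_markers < t["min_markers"]:
            continue
        if len(c.support) < t["min_support"]:
            continue
        kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# rarity classes
# ---------------------------------------------------------------------------


def reciprocal_overlap(a: ConsensusCnv, b: ConsensusCnv) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 when disjoint or cross-chromosome."""
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start) + 1
    if ov <= 0:
        return 0.0
    return min(ov / a.length_bp, ov / b.length_bp)


def classify_rarity(
    cnvs: Sequence[ConsensusCnv],
    n_samples: int,
    overlap_frac: float = 0.5,
    common_freq: float = 0.01,
) -> list[ConsensusCnv]:
    """Cluster events cohort-wide by reciprocal overlap and set rarity.

    Same-state CNVs with reciprocal overlap >= ``overlap_frac`` join one
    cluster (transitively). Cluster of one event => singleton; cluster
    carried by more than ``common_freq`` of samples => common; else rare.
    Returns new ConsensusCnv objects in the input order.
    """
    if not 0.0 < overlap_frac <= 1.0:
        raise ValueError("overlap_frac must be in (0, 1]")
    parent = list(range(len(cnvs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_key: dict[tuple[str, str], list[int]] = defaultdict(list)
    for i, c in enumerate(cnvs):
        by_key[(c.chrom, c.state)].append(i)
    for idxs in by_key.values():
        idxs = sorted(idxs, key=lambda i: cnvs[i].start)
        for a_pos, i in enumerate(idxs):
            for j in idxs[a_pos + 1:]:
                if cnvs[j].start > cnvs[i].end:
                    break
                if reciprocal_overlap(cnvs[i], cnvs[j]) >= overlap_frac:
                    union(i, j)
    clusters: dict[int, list[int]] = defaultdict(list)
    for i in range(len(cnvs)):
        clusters[find(i)].append(i)
    out = list(cnvs)
    for members in clusters.values():
        carriers = len({cnvs[i].sample_id for i in members})
        if len(members) == 1:
            rarity = "singleton"
        elif n_samples > 0 and carriers / n_samples > common_freq:
            rarity = "common"
        else:
            rarity = "rare"
        for i in members:
            out[i] = replace(out[i], rarity=rarity)
    return out


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def annotate(
    cnvs: Sequence[ConsensusCnv],
    genes: RegionSet | None = None,
    regions: RegionSet | None = None,
) -> list[ConsensusCnv]:
    """Set gene_count (genes overlapping by >= 1 bp) and region_hits labels."""
    gene_by_chrom = _index_regions(genes) if genes is not None else {}
    region_by_chrom = _index_regions(regions) if regions is not None else {}
    out = []
    for c in cnvs:
        gc = sum(
            1 for r in gene_by_chrom.get(c.chrom, ())
            if r.start <= c.end and r.end >= c.start
        ) if genes is not None else c.gene_count
        hits = tuple(
            r.label for r in region_by_chrom.get(c.chrom, ())
            if r.start <= c.end and r.end >= c.start
        ) if regions is not None else c.region_hits
        out.append(replace(c, gene_count=gc, region_hits=hits))
    return out


def _index_regions(rset: RegionSet) -> dict[str, list[Region]]:
    idx: dict[str, list[Region]] = defaultdict(list)
    for r in rset:
        idx[r.chrom].append(r)
    for v in idx.values():
        v.sort(key=lambda r: r.start)
    return idx
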