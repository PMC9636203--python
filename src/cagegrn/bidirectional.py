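"""Bidirectional (enhancer) region calling from pooled CTSS signal.

The balance statistic at a candidate midpoint ``m`` with half-window
``h = (window - 1) // 2`` is the Bhattacharyya coefficient between the
observed divergent signal fractions and the ideal (0.5, 0.5) split:

    D = minus-strand TPM in [m - h, m)        (upstream arm)
    U = plus-strand TPM in (m, m + h]         (downstream arm)
    T = total TPM, both strands, [m - h, m + h]
    B = sqrt(0.5 * D / T) + sqrt(0.5 * U / T)     (B = 0 when T = 0)

The midpoint base itself belongs to neither arm. Signal on the "wrong" arms
(plus upstream, minus downstream) contributes only to T, lowering B, which
penalizes embedded unidirectional TSS clusters. B is maximal (1.0) for a
perfectly balanced divergent site and sqrt(0.5) ~ 0.707 for a fully
unidirectional one, below the 0.95 calling threshold.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .ctss_clustering import CtssProfile
from .formats_io import AnnotationRecord, IntervalSet

__all__ = [
    "BidirectionalRegion",
    "RegionAnnotation",
    "balance_score",
    "call_bidirectional",
    "filter_bidirectional",
    "normalize_width",
    "annotate_nearest_gene",
    "categorize_regions",
    "overlap_upset",
]


@dataclass
class BidirectionalRegion:
    """A candidate enhancer called from balanced divergent transcription."""

    chrom: str
    mid: int
    start: int  # called extent, half-open
    end: int
    balance: float
    tpm: float  # pooled TPM, both strands, over the called extent
    support: int
    norm_start: Optional[int] = None  # normalized 200-bp window
    norm_end: Optional[int] = None
    region_id: str = ""

    def __post_init__(self):
        if not self.region_id:
            self.region_id = f"BD:{self.chrom}:{self.mid}"

    @property
    def interval(self) -> Tuple[int, int]:
        if self.norm_start is not None:
            return (self.norm_start, self.norm_end)
        return (self.start, self.end)


def balance_score(
    pooled: CtssProfile, chrom: str, midpoint: int, window: int = 201
) -> float:
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    h = (window - 1) // 2
    d = pooled.range_sum(chrom, "-", midpoint - h, midpoint)
    u = pooled.range_sum(chrom, "+", midpoint + 1, midpoint + h + 1)
    t = pooled.range_sum(chrom, "-", midpoint - h, midpoint + h + 1) + pooled.range_sum(
        chrom, "+", midpoint - h, midpoint + h + 1
    )
    if t <= 0:
        return 0.0
    return float(np.sqrt(0.5 * d / t) + np.sqrt(0.5 * u / t))


def _candidate_midpoints(pooled: CtssProfile, chrom: str, h: int) -> np.ndarray:
    """Bases with pooled signal within h bp on either strand."""
    pos_m, _ = pooled.arrays(chrom, "-")
    pos_p, _ = pooled.arrays(chrom, "+")
    pos = np.union1d(pos_m, pos_p)
    if pos.size == 0:
        return pos
    # union of [p - h, p + h] windows, as sorted unique candidate bases
    segs = []
    cur_lo, cur_hi = int(pos[0]) - h, int(pos[0]) + h
    for p in pos[1:].tolist():
        if p - h <= cur_hi + 1:
            cur_hi = p + h
        else:
            segs.append((cur_lo, cur_hi))
            cur_lo, cur_hi = p - h, p + h
    segs.append((cur_lo, cur_hi))
    return np.concatenate([np.arange(max(0, lo), hi + 1) for lo, hi in segs])


def _balance_vector(
    pooled: CtssProfile, chrom: str, mids: np.ndarray, window: int
) -> np.ndarray:
    """Vectorized balance at each midpoint; same prefix-sum arithmetic as
    :func:`balance_score`, so scalar and vector paths agree exactly."""
    h = (window - 1) // 2
    d = pooled.range_sums(chrom, "-", mids - h, mids)
    u = pooled.range_sums(chrom, "+", mids + 1, mids + h + 1)
    t = pooled.range_sums(chrom, "-", mids - h, mids + h + 1) + pooled.range_sums(
        chrom, "+", mids - h, mids + h + 1
    )
    b = np.zeros(len(mids))
    nz = t > 0
    b[nz] = np.sqrt(0.5 * d[nz] / t[nz]) + np.sqrt(0.5 * u[nz] / t[nz])
    return b


def _region_support(
    samples: Optional[List[CtssProfile]], chrom: str, start: int, end: int
) -> int:
    if not samples:
        return 1
    n = 0
    for s in samples:
        if (
            s.range_sum(chrom, "+", start, end) > 0
            or s.range_sum(chrom, "-", start, end) > 0
        ):
            n += 1
    return n


def call_bidirectional(
    pooled: CtssProfile,
    window: int = 201,
    balance_threshold: float = 0.95,
    max_gap: int = 20,
) -> List[BidirectionalRegion]:
    """Scan candidate midpoints, threshold on balance, slice-reduce merge.

    Qualifying midpoints <= max_gap apart merge into one region whose
    midpoint is the qualifying base with maximal B (leftmost on ties) and
    whose extent spans all qualifying midpoints in the run. Pooled TPM and
    sample support are measured over the union of the qualifying windows
    (the extent expanded by (window-1)/2 on each side), which contains the
    divergent arms; extents themselves never overlap after merging.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    h = (window - 1) // 2
    regions: List[BidirectionalRegion] = []
    for chrom in pooled.chroms:
        mids = _candidate_midpoints(pooled, chrom, h)
        if mids.size == 0:
            continue
        b = _balance_vector(pooled, chrom, mids, window)
        keep = b >= balance_threshold
        mids, b = mids[keep], b[keep]
        if mids.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(mids) > max_gap) + 1
        for seg_m, seg_b in zip(np.split(mids, breaks), np.split(b, breaks)):
            best = int(np.argmax(seg_b))  # leftmost on ties
            start, end = int(seg_m[0]), int(seg_m[-1]) + 1
            tpm = pooled.range_sum(chrom, "+", start - h, end + h) + pooled.range_sum(
                chrom, "-", start - h, end + h
            )
            regions.append(
                BidirectionalRegion(
                    chrom,
                    int(seg_m[best]),
                    start,
                    end,
                    float(seg_b[best]),
                    float(tpm),
                    _region_support(pooled.samples, chrom, start - h, end + h),
                )
            )
    regions.sort(key=lambda r: (r.chrom, r.mid))
    return regions


def filter_bidirectional(
    regions: Sequence[BidirectionalRegion],
    per_sample_profiles: Sequence[CtssProfile],
    min_support: int = 2,
    window: int = 201,
) -> List[BidirectionalRegion]:
    """Keep regions with >= 1 tag (either strand, within the expanded extent
    that contains the divergent arms) in at least ``min_support`` samples."""
    h = (window - 1) // 2
    out = []
    for r in regions:
        support = _region_support(
            list(per_sample_profiles), r.chrom, r.start - h, r.end + h
        )
        if support >= min_support:
            r.support = support
            out.append(r)
    return out


def normalize_width(
    regions: Sequence[BidirectionalRegion],
    width: int = 200,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> List[BidirectionalRegion]:
    """Set each region's normalized interval to [mid - w/2, mid + w/2),
    clipped at chromosome edges with a warning."""
    half = width // 2
    for r in regions:
        lo, hi = r.mid - half, r.mid + (width - half)
        clip_hi = chrom_lengths.get(r.chrom) if chrom_lengths else None
        if lo < 0 or (clip_hi is not None and hi > clip_hi):
            warnings.warn(
                f"region {r.region_id} clipped at chromosome edge", stacklevel=2
            )
            lo = max(0, lo)
            if clip_hi is not None:
                hi = min(hi, clip_hi)
        r.norm_start, r.norm_end = lo, hi
    return list(regions)


@dataclass
class RegionAnnotation:
    region_id: str
    gene: Optional[str]
    signed_distance: Optional[int]  # midpoint - TSS, sign flipped for '-' genes
    distance_bin: Optional[int]  # floor(|d| / 5000)
    category: Optional[str] = None


def annotate_nearest_gene(
    regions: Sequence[BidirectionalRegion],
    annotation: Sequence[AnnotationRecord],
    max_distance: int = 1_000_000,
    bin_size: int = 5000,
) -> List[RegionAnnotation]:
    """Single nearest gene by |midpoint - TSS|; regions farther than
    ``max_distance`` from every TSS are flagged (gene None) for removal."""
    by_chrom: Dict[str, List[AnnotationRecord]] = {}
    for a in annotation:
        by_chrom.setdefault(a.chrom, []).append(a)
    tss_sorted = {
        c: sorted(((a.tss, a.gene, a.strand) for a in recs))
        for c, recs in by_chrom.items()
    }
    out: List[RegionAnnotation] = []
    for r in regions:
        recs = tss_sorted.get(r.chrom)
        if not recs:
            out.append(RegionAnnotation(r.region_id, None, None, None))
            continue
        tss_arr = np.array([t[0] for t in recs])
        idx = int(np.searchsorted(tss_arr, r.mid))
        best = None
        for j in (idx - 1, idx):
            if 0 <= j < len(recs):
                tss, gene, strand = recs[j]
                d = abs(r.mid - tss)
                cand = (d, gene, tss, strand)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        d, gene, tss, strand = best
        if d > max_distance:
            out.append(RegionAnnotation(r.region_id, None, None, None))
            continue
        signed = (r.mid - tss) if strand == "+" else (tss - r.mid)
        out.append(RegionAnnotation(r.region_id, gene, signed, d // bin_size))
    return out


def categorize_regions(
    regions: Sequence[BidirectionalRegion],
    annotation: Sequence[AnnotationRecord],
    promoter_window: int = 1000,
    proximal_window: int = 5000,
) -> Counter:
    """Partition regions into promoter > proximal > gene-body > distal.

    Precedence is by nearest-TSS distance first, gene-span overlap second;
    the counts always sum to the number of input regions.
    """
    ann = annotate_nearest_gene(regions, annotation, max_distance=10**12)
    spans: Dict[str, List[Tuple[int, int]]] = {}
    for a in annotation:
        spans.setdefault(a.chrom, []).append((a.start, a.end))
    counts: Counter = Counter()
    for r, ra in zip(regions, ann):
        d = abs(ra.signed_distance) if ra.signed_distance is not None else None
        if d is not None and d <= promoter_window:
            counts["promoter"] += 1
        elif d is not None and d <= proximal_window:
            counts["proximal"] += 1
        elif any(
            s < r.mid + 1 and r.mid < e for s, e in spans.get(r.chrom, [])
        ):
            counts["gene-body"] += 1
        else:
            counts["distal"] += 1
    return counts


def overlap_upset(
    regions: Sequence[BidirectionalRegion],
    peak_sets: Mapping[str, IntervalSet],
) -> Dict[Tuple[str, ...], int]:
    """For every subset of peak tracks, count regions overlapping exactly that
    subset (>= 1 bp against the region's working interval)."""
    names = sorted(peak_sets)
    counts: Dict[Tuple[str, ...], int] = {
        tuple(sub): 0 for k in range(len(names) + 1) for sub in combinations(names, k)
    }
    for r in regions:
        start, end = r.interval
        member = []
        for name in names:
            ivs = peak_sets[name].get(r.chrom)
            hit = False
            if ivs is not None and len(ivs):
                hit = bool(((ivs[:, 0] < end) & (ivs[:, 1] > start)).any())
            if hit:
                member.append(name)
        counts[tuple(member)] += 1
    return counts
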