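"""Normalization, pooling and unidirectional slice-reduce clustering of CTSS signal.

A :class:`CtssProfile` stores, per (chromosome, strand), sorted positions and
their values (raw tag counts or TPM) as parallel numpy arrays, with cached
prefix sums so interval sums are O(log n). Pooled profiles keep references to
the per-sample profiles they were built from, which is what the sample-support
filters consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .formats_io import AnnotationRecord, CtssRecord

__all__ = [
    "CtssProfile",
    "TagCluster",
    "GeneExpressionTable",
    "tpm_normalize",
    "pool_profiles",
    "prefilter_positions",
    "slice_unidirectional",
    "filter_tcs",
    "quantify_genes",
]

Key = Tuple[str, str]  # (chrom, strand)


class CtssProfile:
    """Stranded per-base 5'-tag signal for one sample or a pooled set."""

    def __init__(
        self,
        data: Mapping[Key, Tuple[np.ndarray, np.ndarray]],
        *,
        is_tpm: bool,
        library_size: Optional[float] = None,
        sample_id: Optional[str] = None,
        samples: Optional[List["CtssProfile"]] = None,
    ):
        self._data: Dict[Key, Tuple[np.ndarray, np.ndarray]] = {}
        for key, (pos, val) in data.items():
            pos = np.asarray(pos, dtype=np.int64)
            val = np.asarray(val, dtype=float)
            order = np.argsort(pos, kind="stable")
            self._data[key] = (pos[order], val[order])
        self.is_tpm = is_tpm
        self.library_size = library_size
        self.sample_id = sample_id
        self.samples = samples  # per-sample profiles backing a pooled profile
        self._cumsums: Dict[Key, np.ndarray] = {}

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(
        cls, records: Iterable[CtssRecord], sample_id: Optional[str] = None
    ) -> "CtssProfile":
        acc: Dict[Key, Dict[int, float]] = {}
        total = 0.0
        for r in records:
            acc.setdefault((r.chrom, r.strand), {})
            acc[(r.chrom, r.strand)][r.pos] = (
                acc[(r.chrom, r.strand)].get(r.pos, 0.0) + r.count
            )
            total += r.count
        data = {
            key: (
                np.fromiter(d.keys(), dtype=np.int64, count=len(d)),
                np.fromiter(d.values(), dtype=float, count=len(d)),
            )
            for key, d in acc.items()
        }
        return cls(data, is_tpm=False, library_size=total, sample_id=sample_id)

    # -- access -----------------------------------------------------------

    @property
    def keys(self) -> List[Key]:
        return sorted(self._data)

    @property
    def chroms(self) -> List[str]:
        return sorted({c for c, _ in self._data})

    def arrays(self, chrom: str, strand: str) -> Tuple[np.ndarray, np.ndarray]:
        return self._data.get(
            (chrom, strand),
            (np.empty(0, dtype=np.int64), np.empty(0, dtype=float)),
        )

    def total(self) -> float:
        return float(sum(v.sum() for _, v in self._data.values()))

    def _cumsum(self, key: Key) -> np.ndarray:
        cs = self._cumsums.get(key)
        if cs is None:
            _, val = self._data.get(key, (None, np.empty(0)))
            cs = np.concatenate(([0.0], np.cumsum(val)))
            self._cumsums[key] = cs
        return cs

    def range_sum(self, chrom: str, strand: str, start: int, end: int) -> float:
        """Sum of signal at positions in [start, end) on one strand.

        Computed as a prefix-sum difference; the vectorized scan in the
        bidirectional caller uses identical arithmetic so the two agree exactly.
        """
        pos, _ = self.arrays(chrom, strand)
        if pos.size == 0 or end <= start:
            return 0.0
        cs = self._cumsum((chrom, strand))
        i = np.searchsorted(pos, start, side="left")
        j = np.searchsorted(pos, end, side="left")
        return float(cs[j] - cs[i])

    def range_sums(
        self, chrom: str, strand: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Vectorized :meth:`range_sum` over aligned start/end arrays."""
        pos, _ = self.arrays(chrom, strand)
        if pos.size == 0:
            return np.zeros(len(starts))
        cs = self._cumsum((chrom, strand))
        i = np.searchsorted(pos, starts, side="left")
        j = np.searchsorted(pos, ends, side="left")
        return cs[j] - cs[i]

    def scale(self, factor: float) -> "CtssProfile":
        return CtssProfile(
            {k: (p.copy(), v * factor) for k, (p, v) in self._data.items()},
            is_tpm=self.is_tpm,
            library_size=self.library_size,
            sample_id=self.sample_id,
            samples=self.samples,
        )


def tpm_normalize(profile: CtssProfile) -> CtssProfile:
    """Counts -> tags-per-million; the normalized profile sums to 1e6."""
    if profile.is_tpm:
        return profile
    lib = profile.library_size
    if lib is None:
        lib = profile.total()
    if lib <= 0:
        raise ValueError("cannot TPM-normalize a profile with zero library size")
    data = {
        k: (p.copy(), v * (1e6 / lib)) for k, (p, v) in profile._data.items()
    }
    return CtssProfile(
        data, is_tpm=True, library_size=lib, sample_id=profile.sample_id
    )


def pool_profiles(profiles: Sequence[CtssProfile]) -> CtssProfile:
    """Positionwise sum of TPM-normalized profiles; inputs are retained for
    sample-support counting."""
    if not profiles:
        raise ValueError("no profiles to pool")
    for p in profiles:
        if not p.is_tpm:
            raise ValueError("pool_profiles requires TPM-normalized inputs")
    keys = sorted({k for p in profiles for k in p._data})
    data: Dict[Key, Tuple[np.ndarray, np.ndarray]] = {}
    for key in keys:
        acc: Dict[int, float] = {}
        for p in profiles:
            pos, val = p.arrays(*key)
            for q, v in zip(pos.tolist(), val.tolist()):
                acc[q] = acc.get(q, 0.0) + v
        positions = np.fromiter(acc.keys(), dtype=np.int64, count=len(acc))
        values = np.fromiter(acc.values(), dtype=float, count=len(acc))
        data[key] = (positions, values)
    return CtssProfile(data, is_tpm=True, samples=list(profiles))


def prefilter_positions(pooled: CtssProfile, floor_tpm: float = 0.1) -> CtssProfile:
    """Drop pooled positions with pooled TPM < floor (reference-default pre-filter)."""
    data = {}
    for key, (pos, val) in pooled._data.items():
        keep = val >= floor_tpm
        if keep.any():
            data[key] = (pos[keep], val[keep])
    return CtssProfile(data, is_tpm=True, samples=pooled.samples)


@dataclass
class TagCluster:
    """A maximal same-strand run of CTSSs with inter-position gaps <= max_gap."""

    chrom: str
    strand: str
    start: int  # half-open interval covering member positions
    end: int
    summit: int  # position of max pooled TPM, leftmost on ties
    tpm: float  # pooled TPM summed over the cluster
    support: int  # samples with >= 1 tag inside the cluster
    cluster_id: str = ""

    def __post_init__(self):
        if not self.cluster_id:
            self.cluster_id = f"TC:{self.chrom}:{self.start}-{self.end},{self.strand}"


def _support(
    samples: Optional[List[CtssProfile]], chrom: str, strand: str, start: int, end: int
) -> int:
    if not samples:
        return 1
    n = 0
    for s in samples:
        if s.range_sum(chrom, strand, start, end) > 0:
            n += 1
    return n


def slice_unidirectional(pooled: CtssProfile, max_gap: int = 20) -> List[TagCluster]:
    """Slice-reduce: per strand, merge consecutive CTSSs with gap <= max_gap.

    Gap semantics: positions p, q (p < q) belong to the same cluster iff
    q - p <= max_gap, transitively. Strands never merge.
    """
    clusters: List[TagCluster] = []
    for chrom, strand in pooled.keys:
        pos, val = pooled.arrays(chrom, strand)
        if pos.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
        for seg_pos, seg_val in zip(np.split(pos, breaks), np.split(val, breaks)):
            summit = int(seg_pos[np.argmax(seg_val)])  # argmax -> leftmost tie
            start, end = int(seg_pos[0]), int(seg_pos[-1]) + 1
            clusters.append(
                TagCluster(
                    chrom,
                    strand,
                    start,
                    end,
                    summit,
                    float(seg_val.sum()),
                    _support(pooled.samples, chrom, strand, start, end),
                )
            )
    clusters.sort(key=lambda c: (c.chrom, c.start, c.strand))
    return clusters


def filter_tcs(
    clusters: Sequence[TagCluster],
    min_support: int = 2,
    min_pooled_tpm: float = 1.0,
) -> List[TagCluster]:
    """Keep clusters with support >= min_support AND pooled TPM strictly > cutoff."""
    return [
        c for c in clusters if c.support >= min_support and c.tpm > min_pooled_tpm
    ]


@dataclass
class GeneExpressionTable:
    """Gene-level TPM built by summing assigned tag clusters."""

    pooled_tpm: Dict[str, float]
    per_sample_tpm: Dict[str, Dict[str, float]] = field(default_factory=dict)
    contributing_tcs: Dict[str, List[str]] = field(default_factory=dict)
    intergenic_tcs: List[str] = field(default_factory=list)

    def tpm(self, gene: str) -> float:
        return self.pooled_tpm.get(gene, 0.0)

    def to_tsv(self, path: str) -> None:
        samples = sorted(self.per_sample_tpm)
        with open(path, "w") as fh:
            fh.write("gene\tpooled_tpm")
            for s in samples:
                fh.write(f"\t{s}")
            fh.write("\n")
            for gene in sorted(self.pooled_tpm):
                fh.write(f"{gene}\t{self.pooled_tpm[gene]:.6g}")
                for s in samples:
                    fh.write(f"\t{self.per_sample_tpm[s].get(gene, 0.0):.6g}")
                fh.write("\n")


def quantify_genes(
    clusters: Sequence[TagCluster],
    annotation: Sequence[AnnotationRecord],
    assignment_window: int = 500,
    per_sample_profiles: Optional[Sequence[CtssProfile]] = None,
) -> GeneExpressionTable:
    """Sum tag-cluster TPM per gene.

    A cluster is assigned to a same-strand gene whose span, extended upstream
    by ``assignment_window``, contains the cluster summit. When several genes
    qualify, the one with the nearest TSS wins (smaller gene id on exact ties).
    Unassigned clusters land in the intergenic bucket.
    """
    if not annotation:
        raise ValueError("empty annotation")
    by_key: Dict[Key, List[AnnotationRecord]] = {}
    for a in annotation:
        by_key.setdefault((a.chrom, a.strand), []).append(a)

    table = GeneExpressionTable(pooled_tpm={})
    assigned: Dict[str, List[TagCluster]] = {}
    for c in clusters:
        candidates = []
        for a in by_key.get((c.chrom, c.strand), []):
            if a.strand == "+":
                span = (a.start - assignment_window, a.end)
            else:
                span = (a.start, a.end + assignment_window)
            if span[0] <= c.summit < span[1]:
                candidates.append((abs(c.summit - a.tss), a.gene))
        if not candidates:
            table.intergenic_tcs.append(c.cluster_id)
            continue
        candidates.sort()
        gene = candidates[0][1]
        table.pooled_tpm[gene] = table.pooled_tpm.get(gene, 0.0) + c.tpm
        table.contributing_tcs.setdefault(gene, []).append(c.cluster_id)
        assigned.setdefault(gene, []).append(c)

    if per_sample_profiles:
        for s in per_sample_profiles:
            sid = s.sample_id or f"sample{id(s)}"
            col: Dict[str, float] = {}
            for gene, tcs in assigned.items():
                col[gene] = sum(
                    s.range_sum(c.chrom, c.strand, c.start, c.end) for c in tcs
                )
            table.per_sample_tpm[sid] = col
    return table
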