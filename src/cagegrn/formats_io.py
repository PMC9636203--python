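"""Readers/writers for the external formats the pipeline touches.

All interval arithmetic in this package is 0-based half-open (BED-native).
Conversion to 1-based display coordinates happens only at output, via
:func:`to_display_coords`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO, motifs as bio_motifs

__all__ = [
    "GenomeIndex",
    "CtssRecord",
    "AnnotationRecord",
    "MotifRecord",
    "CoverageTrack",
    "FormatError",
    "read_ctss",
    "read_bed_intervals",
    "read_coverage_track",
    "read_annotation",
    "read_motifs",
    "read_motif2tf",
    "write_grn",
    "read_grn",
    "write_regions",
    "read_regions",
    "to_display_coords",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FormatError(ValueError):
    """Raised on malformed input files; the message names the offending line."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def to_display_coords(start: int, end: int) -> Tuple[int, int]:
    """0-based half-open -> 1-based inclusive, for human-facing output only."""
    return start + 1, end


class GenomeIndex:
    """In-memory genome with interval/strand-aware sequence access."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: str(s).upper() for name, s in sequences.items()}
        self.chrom_lengths: Dict[str, int] = {c: len(s) for c, s in self._seqs.items()}

    @property
    def chroms(self) -> List[str]:
        return list(self._seqs)

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeIndex":
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
        if not seqs:
            raise FormatError(f"{path}: no FASTA records found")
        return cls(seqs)

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end) on ``strand``; '-' returns the reverse complement."""
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        n = self.chrom_lengths[chrom]
        if not (0 <= start <= end <= n):
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome of length {n}"
            )
        seq = self._seqs[chrom][start:end]
        if strand == "-":
            return reverse_complement(seq)
        if strand != "+":
            raise ValueError(f"unknown strand {strand!r}")
        return seq


@dataclass(frozen=True)
class CtssRecord:
    """A single CAGE-defined TSS: one stranded genomic base with a tag count."""

    chrom: str
    pos: int  # 0-based position of the 5' base
    strand: str
    count: int
    sample: str


@dataclass
class AnnotationRecord:
    gene: str
    chrom: str
    strand: str
    tss: int  # 0-based
    start: int
    end: int
    exons: Optional[List[Tuple[int, int]]] = None


@dataclass
class MotifRecord:
    motif_id: str
    tfs: List[str]
    pfm: np.ndarray  # shape (4, width), rows A,C,G,T

    @property
    def width(self) -> int:
        return self.pfm.shape[1]


def read_ctss(path: str, sample_id: str) -> List[CtssRecord]:
    """Parse a CTSS BED6 file (chrom, start, end=start+1, name, count, strand).

    Malformed lines raise :class:`FormatError` naming the 1-based line number.
    """
    records: List[CtssRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 BED fields")
            chrom, start_s, end_s, _name, count_s, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if end != start + 1:
                raise FormatError(
                    f"{path}:{lineno}: CTSS interval must have width 1 "
                    f"(got {start}-{end})"
                )
            try:
                count = int(count_s)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer count {count_s!r}"
                ) from None
            if count < 0:
                raise FormatError(f"{path}:{lineno}: negative count {count}")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            records.append(CtssRecord(chrom, start, strand, count, sample_id))
    return records


def write_ctss(records: Iterable[CtssRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.strand)):
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t.\t{r.count}\t{r.strand}\n")


IntervalSet = Dict[str, np.ndarray]  # chrom -> (n, 2) int array, sorted by start


def read_bed_intervals(path: str) -> IntervalSet:
    """BED3+ -> per-chromosome sorted (start, end) arrays. No merging is done."""
    per_chrom: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            per_chrom.setdefault(chrom, []).append((start, end))
    return {
        c: np.array(sorted(ivs), dtype=np.int64).reshape(-1, 2)
        for c, ivs in per_chrom.items()
    }


def intervals_from_tuples(tuples: Mapping[str, Sequence[Tuple[int, int]]]) -> IntervalSet:
    return {
        c: np.array(sorted(ivs), dtype=np.int64).reshape(-1, 2)
        for c, ivs in tuples.items()
    }


class CoverageTrack:
    """Per-base coverage backed by bedGraph-style intervals; gaps read as 0."""

    def __init__(self, data: Mapping[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # chrom -> (starts, ends, values), sorted, non-overlapping
        self._data = dict(data)

    @classmethod
    def from_bedgraph(cls, path: str) -> "CoverageTrack":
        per_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split()
                if len(fields) < 4:
                    raise FormatError(f"{path}:{lineno}: expected 4 bedGraph fields")
                chrom = fields[0]
                try:
                    start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: malformed bedGraph line") from None
                if start >= end:
                    raise FormatError(f"{path}:{lineno}: start >= end")
                per_chrom.setdefault(chrom, []).append((start, end, value))
        data = {}
        for chrom, rows in per_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=float)
            data[chrom] = (starts, ends, values)
        return cls(data)

    @classmethod
    def from_intervals(
        cls, rows: Iterable[Tuple[str, int, int, float]]
    ) -> "CoverageTrack":
        per_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
        for chrom, start, end, value in rows:
            per_chrom.setdefault(chrom, []).append((start, end, value))
        data = {}
        for chrom, rws in per_chrom.items():
            rws.sort()
            data[chrom] = (
                np.array([r[0] for r in rws], dtype=np.int64),
                np.array([r[1] for r in rws], dtype=np.int64),
                np.array([r[2] for r in rws], dtype=float),
            )
        return cls(data)

    def to_bedgraph(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._data):
                starts, ends, values = self._data[chrom]
                for s, e, v in zip(starts, ends, values):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base coverage over [start, end); unknown chromosomes read as 0."""
        if end <= start:
            raise ValueError(f"zero-length interval {chrom}:{start}-{end}")
        if chrom not in self._data:
            return 0.0
        starts, ends, values = self._data[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if hi <= lo:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        ov = np.clip(ov, 0, None)
        return float(np.dot(ov, values[lo:hi]) / (end - start))


def read_coverage_track(path: str) -> CoverageTrack:
    return CoverageTrack.from_bedgraph(path)


def read_annotation(path: str) -> List[AnnotationRecord]:
    """Gene annotation from BED12 (or BED6) with the gene id in the name column.

    TSS is the 5'-most base with respect to the gene's strand. Duplicate gene
    ids keep the first record in file order as the canonical TSS.
    """
    records: List[AnnotationRecord] = []
    seen = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 BED fields")
            chrom, start_s, end_s, gene, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            if gene in seen:
                continue
            seen.add(gene)
            exons = None
            if len(fields) >= 12:
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offs = [int(x) for x in fields[11].rstrip(",").split(",")]
                exons = [(start + o, start + o + sz) for o, sz in zip(offs, sizes)]
            tss = start if strand == "+" else end - 1
            records.append(AnnotationRecord(gene, chrom, strand, tss, start, end, exons))
    return records


def write_annotation(records: Iterable[AnnotationRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}\t0\t{r.strand}\n")


def read_motifs(path: str) -> List[MotifRecord]:
    """JASPAR-format PFMs; TF names come from the motif name field.

    The matrix id maps to ``motif_id``; associated TFs can be extended with a
    motif->TF mapping file (:func:`read_motif2tf`).
    """
    out: List[MotifRecord] = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            pfm = np.array([m.counts[b] for b in "ACGT"], dtype=float)
            if pfm.min() < 0 or (pfm.sum(axis=0) <= 0).any():
                raise FormatError(f"{path}: motif {m.matrix_id}: invalid PFM")
            name = m.name or m.matrix_id
            out.append(MotifRecord(m.matrix_id, [name], pfm))
    if not out:
        raise FormatError(f"{path}: no motifs parsed")
    return out


def write_motifs(records: Iterable[MotifRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.motif_id} {r.tfs[0] if r.tfs else r.motif_id}\n")
            for base, row in zip("ACGT", r.pfm):
                vals = " ".join(f"{int(round(v)):6d}" for v in row)
                fh.write(f"{base} [{vals} ]\n")


def read_motif2tf(path: str) -> Dict[str, List[str]]:
    """Two-column TSV motif_id -> TF; multiple rows per motif accumulate."""
    mapping: Dict[str, List[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            mapping.setdefault(fields[0], []).append(fields[1])
    return mapping


def write_grn(edges: Iterable, path: str) -> None:
    """TSV ``tf<TAB>gene<TAB>interaction_score`` sorted by score descending.

    Accepts objects with .tf/.gene/.score attributes or (tf, gene, score) tuples.
    """
    rows = []
    for e in edges:
        if hasattr(e, "tf"):
            tf, gene, score = e.tf, e.gene, e.score
        else:
            tf, gene, score = e
        if score is None or (isinstance(score, float) and math.isnan(score)):
            raise ValueError(f"NaN interaction score for edge {tf}->{gene}")
        rows.append((tf, gene, float(score)))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("tf\tgene\tinteraction_score\n")
        for tf, gene, score in rows:
            fh.write(f"{tf}\t{gene}\t{score:.6g}\n")


def read_grn(path: str) -> List[Tuple[str, str, float]]:
    rows = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("tf\t"):
            raise FormatError(f"{path}: missing GRN header")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            rows.append((fields[0], fields[1], float(fields[2])))
    return rows


def write_regions(regions: Iterable, path: str) -> None:
    """BED6 with the balance score scaled to a 0-1000 integer, floor convention."""
    with open(path, "w") as fh:
        for r in regions:
            b = float(r.balance)
            if math.isnan(b):
                raise ValueError(f"NaN balance score for region at {r.chrom}:{r.mid}")
            score = min(1000, int(math.floor(b * 1000)))
            start, end = (
                (r.norm_start, r.norm_end)
                if getattr(r, "norm_start", None) is not None
                else (r.start, r.end)
            )
            fh.write(f"{r.chrom}\t{start}\t{end}\t{r.region_id}\t{score}\t.\n")


def read_regions(path: str) -> List[Tuple[str, int, int, str, int]]:
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected BED6")
            out.append(
                (fields[0], int(fields[1]), int(fields[2]), fields[3], int(fields[4]))
            )
    return out
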