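"""Genomic interval and peak-set handling.

Peaks from different conditions are merged into a non-overlapping reference
region set, and condition-level peak sets are compared by overlap: a peak is
"shared" when it overlaps a peak from the other condition by at least one
base, otherwise "unique".  All coordinates are 0-based half-open (BED
convention); two intervals overlap iff ``a.start < b.end and b.start < a.end``.
Strand is ignored for peak overlap.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "ReferenceRegions",
    "OverlapCounts",
    "read_narrowpeak",
    "read_bed",
    "write_bed3",
    "merge_reference",
    "overlap_classify",
    "median_pairwise_overlap",
    "multiway_overlap_counts",
]

_STRANDS = {"+", "-", "."}


class ParseError(ValueError):
    """Raised for malformed BED-family input, naming the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A called binding peak; summit_offset is 0-based relative to start."""

    interval: GenomicInterval
    summit_offset: int | None = None
    score: float | None = None
    neglog10_q: float | None = None

    def __post_init__(self) -> None:
        if self.summit_offset is not None:
            if self.summit_offset < 0:
                raise ValueError("summit_offset must be >= 0 (use None for absent)")
            if self.interval.start + self.summit_offset >= self.interval.end:
                raise ValueError("summit_offset falls outside the peak interval")

    @property
    def summit(self) -> int | None:
        if self.summit_offset is None:
            return None
        return self.interval.start + self.summit_offset


def _sort_key(p: Peak):
    return (p.interval.chrom, p.interval.start, p.interval.end)


@dataclass
class PeakSet:
    """An ordered collection of peaks for one sample or condition."""

    label: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=_sort_key)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def chroms(self) -> set[str]:
        return {p.interval.chrom for p in self.peaks}

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]


@dataclass
class ReferenceRegions:
    """Sorted, pairwise non-overlapping reference binding regions."""

    regions: list[GenomicInterval]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        regs = sorted(self.regions, key=lambda r: (r.chrom, r.start, r.end))
        for a, b in zip(regs, regs[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(
                    f"reference regions overlap: {a.chrom}:{a.start}-{a.end} and "
                    f"{b.chrom}:{b.start}-{b.end}"
                )
        self.regions = regs

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends, global indices), each sorted."""
        out: dict[str, tuple[list, list, list]] = {}
        for i, r in enumerate(self.regions):
            out.setdefault(r.chrom, ([], [], []))
            s, e, idx = out[r.chrom]
            s.append(r.start)
            e.append(r.end)
            idx.append(i)
        return {
            c: (np.asarray(s), np.asarray(e), np.asarray(i))
            for c, (s, e, i) in out.items()
        }


# ---------------------------------------------------------------------------
# File input / output
# ---------------------------------------------------------------------------


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_narrowpeak(path, label: str | None = None) -> PeakSet:
    """Read a narrowPeak (BED6+4) or plain BED3/BED6 file into a PeakSet.

    Column 10, when present, is the summit offset; -1 maps to absent.
    An empty file yields an empty PeakSet.
    """
    path = Path(path)
    label = label if label is not None else path.name
    peaks: list[Peak] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise ParseError(f"{path}:{lineno}: invalid interval [{start},{end})")
            strand = cols[5] if len(cols) >= 6 and cols[5] in _STRANDS else "."
            score = None
            if len(cols) >= 5 and cols[4] not in ("", "."):
                try:
                    score = float(cols[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            neglog10_q = None
            if len(cols) >= 9 and cols[8] not in ("", "."):
                try:
                    q = float(cols[8])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric qValue") from exc
                neglog10_q = q if q >= 0 else None
            summit = None
            if len(cols) >= 10 and cols[9] not in ("", "."):
                try:
                    s = int(cols[9])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-integer summit") from exc
                if s >= 0:
                    summit = s
            peaks.append(
                Peak(
                    interval=GenomicInterval(cols[0], start, end, strand),
                    summit_offset=summit,
                    score=score,
                    neglog10_q=neglog10_q,
                )
            )
    return PeakSet(label=label, peaks=peaks)


read_bed = read_narrowpeak  # plain BED3/BED6 is a prefix of narrowPeak


def write_bed3(regions: ReferenceRegions, path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


# ---------------------------------------------------------------------------
# Merging and overlap
# ---------------------------------------------------------------------------


def _merged_arrays(intervals: Iterable[GenomicInterval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merge intervals sharing >=1 base; per-chrom sorted (starts, ends)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts, ends = [], []
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s < cur_e:  # shares >= 1 base (half-open, strict)
                cur_e = max(cur_e, e)
            else:
                starts.append(cur_s)
                ends.append(cur_e)
                cur_s, cur_e = s, e
        starts.append(cur_s)
        ends.append(cur_e)
        out[chrom] = (np.asarray(starts), np.asarray(ends))
    return out


def merge_reference(peaksets: Sequence[PeakSet]) -> ReferenceRegions:
    """Merge peaks overlapping by >= 1 base across all sets into reference regions.

    Any two input peaks sharing a base (transitively) end up in one region;
    the output covers every input base exactly once.
    """
    if not peaksets:
        raise ValueError("at least one PeakSet is required")
    all_ivs = [iv for ps in peaksets for iv in ps.intervals()]
    if not all_ivs:
        warnings.warn("all input peak sets are empty; empty reference returned")
        return ReferenceRegions(regions=[], provenance=[ps.label for ps in peaksets])
    _warn_disjoint_chroms(peaksets)
    merged = _merged_arrays(all_ivs)
    regions = [
        GenomicInterval(chrom, int(s), int(e))
        for chrom in sorted(merged)
        for s, e in zip(*merged[chrom])
    ]
    return ReferenceRegions(regions=regions, provenance=[ps.label for ps in peaksets])


def _warn_disjoint_chroms(peaksets: Sequence[PeakSet]) -> None:
    named = [(ps.label, ps.chroms()) for ps in peaksets if len(ps)]
    for i in range(len(named)):
        for j in range(i + 1, len(named)):
            if not (named[i][1] & named[j][1]):
                warnings.warn(
                    f"peak sets {named[i][0]!r} and {named[j][0]!r} share no "
                    "chromosome names; check naming conventions"
                )


def _overlaps_union(
    intervals: Iterable[GenomicInterval],
    union: dict[str, tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Boolean per interval: overlaps >=1 base of the (merged) union."""
    flags = []
    for iv in intervals:
        if iv.chrom not in union:
            flags.append(False)
            continue
        starts, ends = union[iv.chrom]
        # union regions are disjoint & sorted: the only candidate is the last
        # region starting before iv.end
        k = int(np.searchsorted(starts, iv.end, side="left")) - 1
        flags.append(k >= 0 and ends[k] > iv.start)
    return np.asarray(flags, dtype=bool)


@dataclass
class OverlapCounts:
    """Per-set shared/unique peak counts from a pairwise comparison."""

    a_unique: int
    a_shared: int
    b_unique: int
    b_shared: int
    a_shared_mask: np.ndarray | None = None
    b_shared_mask: np.ndarray | None = None


def overlap_classify(a: PeakSet, b: PeakSet) -> OverlapCounts:
    """Label each peak of `a` shared/unique vs `b`, and symmetrically.

    Counts are reference-dependent: one peak of `a` spanning two peaks of
    `b` contributes 1 to a_shared but 2 to b_shared.
    """
    union_b = _merged_arrays(b.intervals()) if len(b) else {}
    union_a = _merged_arrays(a.intervals()) if len(a) else {}
    a_mask = _overlaps_union(a.intervals(), union_b) if len(a) else np.zeros(0, bool)
    b_mask = _overlaps_union(b.intervals(), union_a) if len(b) else np.zeros(0, bool)
    return OverlapCounts(
        a_unique=int((~a_mask).sum()),
        a_shared=int(a_mask.sum()),
        b_unique=int((~b_mask).sum()),
        b_shared=int(b_mask.sum()),
        a_shared_mask=a_mask,
        b_shared_mask=b_mask,
    )


def median_pairwise_overlap(peaksets: Sequence[PeakSet]) -> int:
    """Lower median of shared-peak counts over all ordered (reference, other) pairs."""
    if len(peaksets) < 2:
        raise ValueError("need at least 2 peak sets")
    counts = []
    for i, ref in enumerate(peaksets):
        for j, other in enumerate(peaksets):
            if i == j:
                continue
            counts.append(overlap_classify(ref, other).a_shared)
    counts.sort()
    n = len(counts)
    return counts[(n + 1) // 2 - 1]  # lower median


def multiway_overlap_counts(peaksets: Sequence[PeakSet]) -> dict[tuple[str, ...], int]:
    """Venn-style partition of merged reference regions by contributing sets.

    Each merged region is assigned the tuple of input labels whose peak sets
    contribute >= 1 overlapping peak; returns a count per membership pattern
    over all non-empty label subsets (zeros included).  Supports 2-4 sets.
    """
    if not 2 <= len(peaksets) <= 4:
        raise ValueError("multiway_overlap_counts supports 2-4 peak sets")
    labels = [ps.label for ps in peaksets]
    if len(set(labels)) != len(labels):
        raise ValueError("peak set labels must be unique")
    reference = merge_reference(peaksets)
    membership = np.zeros((len(reference), len(peaksets)), dtype=bool)
    for k, ps in enumerate(peaksets):
        union = _merged_arrays(ps.intervals()) if len(ps) else {}
        membership[:, k] = _overlaps_union(reference.regions, union)
    patterns: dict[tuple[str, ...], int] = {}
    for size in range(1, len(labels) + 1):
        from itertools import combinations

        for combo in combinations(range(len(labels)), size):
            patterns[tuple(labels[i] for i in combo)] = 0
    for row in membership:
        key = tuple(lab for lab, m in zip(labels, row) if m)
        if key:
            patterns[key] += 1
    return patterns
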