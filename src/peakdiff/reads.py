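"""Aligned-read handling and the peaks x samples count matrix.

Single-end reads (tagAlign/BED6) are stored column-wise in numpy arrays.
Before counting, reads are either shifted (each read collapses to the
1-base position ``5' end + shift`` in the strand direction, approximating
the fragment midpoint) or extended to an assumed fragment length from the
5' end.  Counting is coverageBed-style: a read contributes 1 to every
reference region it overlaps by at least one base (with shift
preprocessing a read can hit at most one region, so the effective library
size — in-peak reads — never exceeds the full library size).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, ParseError, ReferenceRegions

__all__ = [
    "TagAlignRead",
    "ReadSet",
    "CountMatrix",
    "read_tagalign",
    "write_tagalign",
    "shift_reads",
    "extend_reads",
    "subsample_reads",
    "pool_reads",
    "count_reads_in_regions",
]

SAMPLE_COLUMNS = ["sample_id", "condition", "replicate", "full_library_size", "input_sample_id"]


@dataclass(frozen=True)
class TagAlignRead:
    """One aligned single-end read (stranded)."""

    interval: GenomicInterval
    strand: str
    sequence: str = "N"
    score: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("read strand must be '+' or '-'")


class ReadSet:
    """Aligned reads for one sample, stored as parallel numpy arrays."""

    def __init__(self, sample_id: str, chrom, start, end, strand) -> None:
        self.sample_id = sample_id
        self.chrom = np.asarray(chrom, dtype=object)
        self.start = np.asarray(start, dtype=np.int64)
        self.end = np.asarray(end, dtype=np.int64)
        self.strand = np.asarray(strand, dtype=object)
        n = len(self.chrom)
        if not (len(self.start) == len(self.end) == len(self.strand) == n):
            raise ValueError("read arrays must have equal length")
        if n and not np.all(self.start < self.end):
            raise ValueError("reads must satisfy start < end")

    def __len__(self) -> int:
        return len(self.chrom)

    @property
    def full_library_size(self) -> int:
        return len(self)

    def __iter__(self):
        for c, s, e, st in zip(self.chrom, self.start, self.end, self.strand):
            yield TagAlignRead(GenomicInterval(str(c), int(s), int(e), str(st)), str(st))

    @classmethod
    def from_reads(cls, sample_id: str, reads: Sequence[TagAlignRead]) -> "ReadSet":
        return cls(
            sample_id,
            [r.interval.chrom for r in reads],
            [r.interval.start for r in reads],
            [r.interval.end for r in reads],
            [r.strand for r in reads],
        )


def read_tagalign(path, sample_id: str | None = None) -> ReadSet:
    """Read a tagAlign file (BED6 with a sequence column); gzip accepted."""
    path = Path(path)
    sample_id = sample_id if sample_id is not None else path.name
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "sequence", "score", "strand"],
            dtype={"chrom": str, "sequence": str, "strand": str},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        return ReadSet(sample_id, [], [], [], [])
    if len(df) == 0:
        return ReadSet(sample_id, [], [], [], [])
    for col in ("start", "end"):
        if not np.issubdtype(df[col].dtype, np.integer):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() | (coerced != np.floor(coerced))]
            if len(bad):
                raise ParseError(f"{path}:{int(bad[0]) + 1}: non-integer {col} coordinate")
            df[col] = coerced.astype(np.int64)
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ParseError(f"{path}:{int(bad[0]) + 1}: start >= end")
    bad = df.index[~df["strand"].isin(["+", "-"])]
    if len(bad):
        raise ParseError(f"{path}:{int(bad[0]) + 1}: strand must be '+' or '-'")
    return ReadSet(
        sample_id,
        df["chrom"].to_numpy(dtype=object),
        df["start"].to_numpy(np.int64),
        df["end"].to_numpy(np.int64),
        df["strand"].to_numpy(dtype=object),
    )


def write_tagalign(reads: ReadSet, path, sequence: str = "N", score: int = 1000) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for c, s, e, st in zip(reads.chrom, reads.start, reads.end, reads.strand):
            fh.write(f"{c}\t{s}\t{e}\t{sequence}\t{score}\t{st}\n")


def _five_prime(reads: ReadSet) -> np.ndarray:
    plus = reads.strand == "+"
    return np.where(plus, reads.start, reads.end - 1)


def shift_reads(reads: ReadSet, shift: int) -> ReadSet:
    """Collapse each read to the 1-base position `5' + shift` along its strand.

    Positions are clipped at 0 (chromosome start); minus-strand reads shift
    toward lower coordinates.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    p5 = _five_prime(reads)
    pos = np.where(reads.strand == "+", p5 + shift, p5 - shift)
    pos = np.maximum(pos, 0)
    return ReadSet(reads.sample_id, reads.chrom, pos, pos + 1, reads.strand)


def extend_reads(reads: ReadSet, fragment_length: int) -> ReadSet:
    """Extend each read to `fragment_length` bases from its 5' end, clipped at 0."""
    if fragment_length < 1:
        raise ValueError("fragment_length must be >= 1")
    plus = reads.strand == "+"
    start = np.where(plus, reads.start, np.maximum(reads.end - fragment_length, 0))
    end = np.where(plus, reads.start + fragment_length, reads.end)
    return ReadSet(reads.sample_id, reads.chrom, start, end, reads.strand)


def subsample_reads(reads: ReadSet, n: int, seed: int) -> ReadSet:
    """Uniform sample of exactly n reads without replacement; seed-deterministic."""
    if not 0 <= n <= len(reads):
        raise ValueError(f"cannot sample {n} of {len(reads)} reads")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(reads))[:n]
    idx.sort()
    return ReadSet(
        reads.sample_id, reads.chrom[idx], reads.start[idx], reads.end[idx], reads.strand[idx]
    )


def pool_reads(readsets: Sequence[ReadSet], sample_id: str | None = None) -> ReadSet:
    """Concatenate read sets; full library size is the sum of the inputs."""
    if not readsets:
        raise ValueError("need at least one ReadSet")
    sample_id = sample_id if sample_id is not None else "+".join(r.sample_id for r in readsets)
    return ReadSet(
        sample_id,
        np.concatenate([r.chrom for r in readsets]),
        np.concatenate([r.start for r in readsets]),
        np.concatenate([r.end for r in readsets]),
        np.concatenate([r.strand for r in readsets]),
    )


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Integer read counts over reference regions (rows) per sample (columns)."""

    regions: ReferenceRegions
    samples: pd.DataFrame
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integer-valued")
            self.counts = np.round(self.counts).astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.shape != (len(self.regions), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.regions)} regions x {len(self.samples)} samples"
            )
        self.samples = self.samples.reset_index(drop=True)
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                self.samples[col] = None
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("sample_id values must be unique")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def effective_library_sizes(self) -> np.ndarray:
        """Reads falling in the reference regions, per sample (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def full_library_sizes(self) -> np.ndarray:
        return self.samples["full_library_size"].to_numpy(dtype=np.float64)

    def sample_index(self, sample_id: str) -> int:
        hits = self.samples.index[self.samples["sample_id"] == sample_id]
        if len(hits) != 1:
            raise KeyError(f"unknown sample {sample_id!r}")
        return int(hits[0])

    def condition_columns(self, condition: str) -> np.ndarray:
        cols = self.samples.index[self.samples["condition"] == condition].to_numpy()
        if len(cols) == 0:
            raise KeyError(f"no samples for condition {condition!r}")
        return cols

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.samples["condition"]:
            if c not in seen and c is not None:
                seen.append(c)
        return seen

    def to_tsv(self, counts_path, libsizes_path=None) -> None:
        df = pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
            }
        )
        for j, sid in enumerate(self.samples["sample_id"]):
            df[sid] = self.counts[:, j]
        df.to_csv(counts_path, sep="\t", index=False)
        if libsizes_path is not None:
            side = self.samples.copy()
            side["effective_library_size"] = self.effective_library_sizes
            side.to_csv(libsizes_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path, libsizes_path) -> "CountMatrix":
        df = pd.read_csv(counts_path, sep="\t")
        samples = pd.read_csv(libsizes_path, sep="\t")
        regions = ReferenceRegions(
            [
                GenomicInterval(str(c), int(s), int(e))
                for c, s, e in zip(df["chrom"], df["start"], df["end"])
            ]
        )
        sids = list(samples["sample_id"])
        counts = df[sids].to_numpy(np.int64)
        keep = [c for c in SAMPLE_COLUMNS if c in samples.columns]
        return cls(regions=regions, samples=samples[keep], counts=counts)


def _apply_preprocess(rs: ReadSet, preprocess: str, shift: int, fragment_length: int) -> ReadSet:
    if preprocess == "none":
        return rs
    if preprocess == "shift":
        return shift_reads(rs, shift)
    if preprocess == "extend":
        return extend_reads(rs, fragment_length)
    raise ValueError(f"unknown preprocess {preprocess!r}; use shift/extend/none")


def count_reads_in_regions(
    regions: ReferenceRegions,
    readsets: Sequence[ReadSet],
    preprocess: str = "none",
    shift: int = 75,
    fragment_length: int = 200,
    samples: pd.DataFrame | None = None,
) -> CountMatrix:
    """Count (preprocessed) reads overlapping each reference region.

    coverageBed semantics: a read contributes 1 to every region it overlaps
    by >= 1 base (an extended read spanning two adjacent regions counts once
    in each).  Full library sizes are the pre-preprocessing read counts.
    """
    by_chrom = regions.by_chrom()
    counts = np.zeros((len(regions), len(readsets)), dtype=np.int64)
    for col, rs in enumerate(readsets):
        prepped = _apply_preprocess(rs, preprocess, shift, fragment_length)
        for chrom in np.unique(prepped.chrom):
            if chrom not in by_chrom:
                continue
            rstarts, rends, ridx = by_chrom[chrom]
            sel = prepped.chrom == chrom
            qs = prepped.start[sel]
            qe = prepped.end[sel]
            # first region with end > read.start; last region with start < read.end
            i = np.searchsorted(rends, qs, side="right")
            j = np.searchsorted(rstarts, qe, side="left") - 1
            hit = i <= j
            single = hit & (i == j)
            if single.any():
                counts[:, col][ridx] += np.bincount(i[single], minlength=len(ridx))
            multi = hit & (i < j)
            for a, b in zip(i[multi], j[multi]):
                counts[ridx[a : b + 1], col] += 1
    if samples is None:
        samples = pd.DataFrame({"sample_id": [rs.sample_id for rs in readsets]})
    else:
        samples = samples.copy()
    samples["full_library_size"] = [rs.full_library_size for rs in readsets]
    return CountMatrix(regions=regions, samples=samples, counts=counts)
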