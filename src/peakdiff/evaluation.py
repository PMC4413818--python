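"""Method-comparison analytics.

Given several differential runs aligned to one reference region set:
MA values for plotting, Venn-style overlap of the significant sets,
hierarchical clustering of fold-change estimates under a significance-
weighted Gower distance, enrichment of significant regions in copy-number
altered (CNA) intervals, and concordance against ChIP-qPCR fold changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from .intervals import PeakSet, ReferenceRegions, _merged_arrays, _overlaps_union
from .normalization import OffsetModel
from .reads import CountMatrix
from .differential import DiffResult

__all__ = [
    "MethodRun",
    "ma_values",
    "significant_set_overlap",
    "weighted_fc_clustering",
    "ClusteringResult",
    "cna_fraction",
    "qpcr_concordance",
]


@dataclass
class MethodRun:
    """One method's differential results on the shared reference regions."""

    method_name: str
    results: list[DiffResult]

    def log2fc(self) -> np.ndarray:
        return np.array([r.log2fc for r in self.results])

    def fdr(self) -> np.ndarray:
        return np.array([r.fdr for r in self.results])

    def significant(self, threshold: float = 0.05) -> np.ndarray:
        return np.array([r.fdr < threshold for r in self.results])


def _check_aligned(runs: list[MethodRun]) -> None:
    ref = [(r.region.chrom, r.region.start, r.region.end) for r in runs[0].results]
    for run in runs[1:]:
        coords = [(r.region.chrom, r.region.start, r.region.end) for r in run.results]
        if coords != ref:
            raise ValueError(
                f"run {run.method_name!r} is not aligned to the shared region list"
            )


def ma_values(
    cm: CountMatrix, offsets: OffsetModel, cond_a: str, cond_b: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-region (M, A): log2 normalized condition-mean ratio and average.

    Condition means are offset-normalized counts scaled to CPM-like units
    with a 0.5 pseudo-count.
    """
    off = offsets.total_log_offsets(cm.n_regions)
    cols_a = cm.condition_columns(cond_a)
    cols_b = cm.condition_columns(cond_b)
    norm = (cm.counts + 0.5) / np.exp(off) * 1e6
    mean_a = norm[:, cols_a].mean(axis=1)
    mean_b = norm[:, cols_b].mean(axis=1)
    m = np.log2(mean_a / mean_b)
    a = 0.5 * np.log2(mean_a * mean_b)
    return m, a


def significant_set_overlap(
    runs: list[MethodRun], threshold: float = 0.05
) -> dict[tuple[str, ...], int]:
    """Counts of regions significant under each non-empty subset of methods."""
    if len(runs) < 2:
        raise ValueError("need at least 2 runs")
    _check_aligned(runs)
    names = [r.method_name for r in runs]
    if len(set(names)) != len(names):
        raise ValueError("method names must be unique")
    sig = np.column_stack([r.significant(threshold) for r in runs])
    patterns: dict[tuple[str, ...], int] = {}
    for size in range(1, len(names) + 1):
        for combo in combinations(range(len(names)), size):
            patterns[tuple(names[i] for i in combo)] = 0
    for row in sig:
        key = tuple(n for n, s in zip(names, row) if s)
        if key:
            patterns[key] += 1
    return patterns


@dataclass
class ClusteringResult:
    """Average-linkage dendrogram over method runs."""

    labels: list[str]
    linkage_matrix: np.ndarray
    distance_matrix: np.ndarray
    newick: str

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage_matrix, columns=["node_i", "node_j", "height", "n_leaves"]
        )


def gower_distance_matrix(
    fc: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Weighted Gower distance between runs (rows of fc are regions).

    d(i,j) = sum_g w_g |fc_gi - fc_gj| / range_g / sum_g w_g over regions
    with non-zero fold-change range across runs.
    """
    rng = fc.max(axis=1) - fc.min(axis=1)
    keep = rng > 0
    if not keep.any():
        raise ValueError("all regions have zero fold-change range; clustering degenerate")
    fcn = fc[keep] / rng[keep][:, None]
    w = weights[keep]
    n = fc.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = np.sum(w * np.abs(fcn[:, i] - fcn[:, j])) / np.sum(w)
    return d


def _linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for k, (i, j, h, _) in enumerate(z):
        i, j = int(i), int(j)
        li = h - heights[i]
        lj = h - heights[j]
        nodes[n + k] = f"({nodes[i]}:{li:.6g},{nodes[j]}:{lj:.6g})"
        heights[n + k] = h
    return nodes[n + len(z) - 1] + ";"


def weighted_fc_clustering(
    runs: list[MethodRun], top_k: int = 100, threshold: float = 0.05
) -> ClusteringResult:
    """Cluster methods by fold changes of their top differential regions.

    The region set is the union of each run's top-k regions ranked by FDR
    (|log2fc| breaking ties); each region is weighted by the fraction of
    runs calling it significant (regions significant nowhere get weight
    1/(2*n_runs)); average-linkage clustering on the weighted Gower
    distance between the runs' fold-change vectors.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    _check_aligned(runs)
    n_regions = len(runs[0].results)
    selected = np.zeros(n_regions, dtype=bool)
    for run in runs:
        order = sorted(
            range(n_regions),
            key=lambda g: (run.results[g].fdr, -abs(run.results[g].log2fc)),
        )
        selected[order[: min(top_k, n_regions)]] = True
    idx = np.flatnonzero(selected)
    fc = np.column_stack([run.log2fc()[idx] for run in runs])
    sig = np.column_stack([run.significant(threshold)[idx] for run in runs])
    weights = sig.sum(axis=1) / len(runs)
    weights[weights == 0] = 1.0 / (2 * len(runs))
    d = gower_distance_matrix(fc, weights)
    z = linkage(squareform(d, checks=False), method="average")
    labels = [run.method_name for run in runs]
    return ClusteringResult(
        labels=labels,
        linkage_matrix=z,
        distance_matrix=d,
        newick=_linkage_to_newick(z, labels),
    )


def cna_fraction(
    run: MethodRun, cna_regions: PeakSet | ReferenceRegions, threshold: float = 0.05
) -> tuple[float, float]:
    """(fraction of significant regions in CNA intervals, same over all regions).

    The ratio of the two is the CNA enrichment of the significant set.
    """
    if isinstance(cna_regions, PeakSet):
        ivs = cna_regions.intervals()
    else:
        ivs = list(cna_regions)
    if not ivs:
        warnings.warn("empty CNA region set; fractions are 0")
        return 0.0, 0.0
    union = _merged_arrays(ivs)
    regions = [r.region for r in run.results]
    in_cna = _overlaps_union(regions, union)
    sig = run.significant(threshold)
    frac_all = float(in_cna.mean()) if len(in_cna) else 0.0
    frac_sig = float(in_cna[sig].mean()) if sig.any() else 0.0
    return frac_sig, frac_all


@dataclass
class ConcordanceResult:
    rmse: float
    pearson_r: float
    table: pd.DataFrame


def qpcr_concordance(run: MethodRun, qpcr_table: pd.DataFrame) -> ConcordanceResult:
    """Compare method log2 fold changes against qPCR-derived ones.

    `qpcr_table` needs columns chrom/start/end/log2fc; each qPCR region is
    matched to the reference region it overlaps (>= 1 bp, unique match
    required).  Returns RMSE, Pearson correlation and the paired table.
    """
    required = {"chrom", "start", "end", "log2fc"}
    if not required.issubset(qpcr_table.columns):
        raise ValueError(f"qPCR table must have columns {sorted(required)}")
    rows = []
    for _, q in qpcr_table.iterrows():
        hits = [
            r
            for r in run.results
            if r.region.chrom == str(q["chrom"])
            and r.region.start < int(q["end"])
            and int(q["start"]) < r.region.end
        ]
        if len(hits) == 0:
            continue
        if len(hits) > 1:
            raise ValueError(
                f"qPCR region {q['chrom']}:{q['start']}-{q['end']} maps to "
                f"{len(hits)} reference regions; mapping must be unique"
            )
        rows.append(
            {
                "chrom": q["chrom"],
                "start": q["start"],
                "end": q["end"],
                "qpcr_log2fc": float(q["log2fc"]),
                "method_log2fc": hits[0].log2fc,
                "delta": hits[0].log2fc - float(q["log2fc"]),
            }
        )
    if not rows:
        raise ValueError("no qPCR regions map to the reference regions")
    table = pd.DataFrame(rows)
    rmse = float(np.sqrt(np.mean(table["delta"] ** 2)))
    if len(table) >= 2 and table["qpcr_log2fc"].std() > 0 and table["method_log2fc"].std() > 0:
        r = float(pearsonr(table["qpcr_log2fc"], table["method_log2fc"])[0])
    else:
        r = np.nan
    return ConcordanceResult(rmse=rmse, pearson_r=r, table=table)
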