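"""Between-sample normalization strategies for differential binding.

All strategies are expressed as log-scale offsets that enter the count
model multiplicatively (mean = abundance * exp(offset)), so downstream
tests share one code path:

* full library size      — offset = log(total mapped reads),
* effective library size — offset = log(reads in reference regions),
* TMM                    — trimmed mean of M-values scaling factors on top
                           of a library size,
* shared-peak MA regression ("MAnorm3") — an OLS fit of log2 fold change
  (M) on average log2 abundance (A) over peaks shared by both conditions,
  split symmetrically between the conditions as per-region offsets so the
  adjusted M of shared peaks is centred at zero with zero slope.

Scaled input subtraction (``input_subtract``) removes background counts
before normalization, scaling input down to the ChIP sample's full
library depth (never up).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import PeakSet, ReferenceRegions, _merged_arrays, _overlaps_union
from .reads import CountMatrix

__all__ = [
    "OffsetModel",
    "MAFit",
    "library_size_offsets",
    "tmm_factors",
    "shared_peak_ma_fit",
    "manorm3_offsets",
    "input_subtract",
]

LN2 = float(np.log(2.0))


@dataclass
class OffsetModel:
    """Log-scale normalization offsets (natural log)."""

    method: str
    sample_log_offsets: np.ndarray
    peak_sample_log_offsets: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_log_offsets = np.asarray(self.sample_log_offsets, dtype=float)
        if not np.all(np.isfinite(self.sample_log_offsets)):
            raise ValueError("sample_log_offsets must be finite")

    def total_log_offsets(self, n_regions: int) -> np.ndarray:
        """Regions x samples matrix of sample + per-region offsets."""
        base = np.broadcast_to(
            self.sample_log_offsets, (n_regions, len(self.sample_log_offsets))
        )
        if self.peak_sample_log_offsets is None:
            return np.array(base)
        return base + self.peak_sample_log_offsets

    def to_tsv(self, cm: CountMatrix, path) -> None:
        pd.DataFrame(
            {
                "sample_id": cm.samples["sample_id"],
                "method": self.method,
                "log_offset": self.sample_log_offsets,
            }
        ).to_csv(path, sep="\t", index=False)


def library_size_offsets(cm: CountMatrix, kind: str = "full") -> OffsetModel:
    """Offsets equal to log library size ('full' = mapped reads, 'effective' = in-peak reads)."""
    if kind == "full":
        sizes = cm.full_library_sizes
        method = "full_lib"
    elif kind == "effective":
        sizes = cm.effective_library_sizes.astype(float)
        method = "effective_lib"
    else:
        raise ValueError("kind must be 'full' or 'effective'")
    bad = np.flatnonzero(~(sizes > 0))
    if len(bad):
        sid = cm.samples["sample_id"].iloc[bad[0]]
        raise ValueError(f"sample {sid!r} has non-positive {kind} library size")
    return OffsetModel(method=method, sample_log_offsets=np.log(sizes))


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> float:
    """TMM scaling factor of one sample against the reference column."""
    pos = (obs > 0) & (ref > 0)
    if pos.sum() == 0:
        return 1.0
    y_s, y_r = obs[pos].astype(float), ref[pos].astype(float)
    m = np.log2((y_s / n_obs) / (y_r / n_ref))
    a = 0.5 * np.log2((y_s / n_obs) * (y_r / n_ref))
    w = (n_obs - y_s) / (n_obs * y_s) + (n_ref - y_r) / (n_ref * y_r)
    # double trim: drop the extreme 30% of M on each tail and 5% of A
    n = len(m)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep.sum() < 10:
        warnings.warn("fewer than 10 regions survive TMM trimming; factor set to 1")
        return 1.0
    with np.errstate(divide="ignore"):
        inv_w = 1.0 / w[keep]
    return float(2 ** (np.sum(m[keep] * inv_w) / np.sum(inv_w)))


def tmm_factors(
    cm: CountMatrix, reference_sample: str = "auto", lib: str = "effective"
) -> OffsetModel:
    """Trimmed-mean-of-M-values scaling factors, anchored to geometric mean 1.

    M-values are log2 ratios of library-size-normalized counts against a
    reference column over regions positive in both; the extreme 30% of M
    and 5% of A are trimmed and the remainder averaged with inverse
    asymptotic-variance weights.  Offsets are log(libsize * factor), with
    `lib` choosing full or effective library sizes.
    """
    if cm.n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    if lib == "effective":
        sizes = cm.effective_library_sizes.astype(float)
    elif lib == "full":
        sizes = cm.full_library_sizes
    else:
        raise ValueError("lib must be 'full' or 'effective'")
    if not np.all(sizes > 0):
        raise ValueError("library sizes must be positive for TMM")
    if reference_sample == "auto":
        # column whose 75th count percentile (scaled) is closest to the mean
        f75 = np.array(
            [np.quantile(cm.counts[:, j] / sizes[j], 0.75) for j in range(cm.n_samples)]
        )
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = cm.sample_index(reference_sample)
    factors = np.ones(cm.n_samples)
    for j in range(cm.n_samples):
        if j == ref_idx:
            continue
        factors[j] = _tmm_pair_factor(
            cm.counts[:, j], cm.counts[:, ref_idx], sizes[j], sizes[ref_idx]
        )
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return OffsetModel(
        method="tmm",
        sample_log_offsets=np.log(sizes * factors),
        diagnostics={
            "factors": factors.tolist(),
            "reference_sample": str(cm.samples["sample_id"].iloc[ref_idx]),
            "lib": lib,
        },
    )


# ---------------------------------------------------------------------------
# Shared-peak MA regression (MAnorm3-style)
# ---------------------------------------------------------------------------


@dataclass
class MAFit:
    """OLS fit of M on A over shared peaks (log2 units)."""

    intercept: float
    slope: float
    n_shared_peaks: int
    base_scale: float  # mean of log effective library sizes (natural log)
    shared_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_shared_peaks < 2:
            raise ValueError("MA fit needs at least 2 shared peaks")


def shared_regions_mask(
    regions: ReferenceRegions, peaksets_by_condition: dict[str, PeakSet]
) -> np.ndarray:
    """Regions overlapping >= 1 peak from every condition's peak set."""
    mask = np.ones(len(regions), dtype=bool)
    for ps in peaksets_by_condition.values():
        union = _merged_arrays(ps.intervals()) if len(ps) else {}
        mask &= _overlaps_union(regions.regions, union)
    return mask


def _condition_log2_cpm_means(cm: CountMatrix, cond: str) -> np.ndarray:
    cols = cm.condition_columns(cond)
    n_eff = cm.effective_library_sizes.astype(float)
    vals = np.log2((cm.counts[:, cols] + 0.5) / n_eff[cols] * 1e6)
    return vals.mean(axis=1)


def shared_peak_ma_fit(
    cm: CountMatrix,
    cond_a: str,
    cond_b: str,
    peaksets_by_condition: dict[str, PeakSet] | None = None,
    shared_mask: np.ndarray | None = None,
) -> MAFit:
    """Regress log2 fold change on average log2 binding over shared peaks.

    Condition means are log2 CPM (0.5 pseudo-count, per-sample effective
    library size).  When neither peak sets nor an explicit mask are given
    all regions are treated as shared.
    """
    if shared_mask is None:
        if peaksets_by_condition is not None:
            shared_mask = shared_regions_mask(cm.regions, peaksets_by_condition)
        else:
            shared_mask = np.ones(cm.n_regions, dtype=bool)
    shared_mask = np.asarray(shared_mask, dtype=bool)
    if shared_mask.sum() < 2:
        raise ValueError("need at least 2 shared regions for the MA fit")
    xa = _condition_log2_cpm_means(cm, cond_a)
    xb = _condition_log2_cpm_means(cm, cond_b)
    m = (xa - xb)[shared_mask]
    a = (0.5 * (xa + xb))[shared_mask]
    base_scale = float(np.mean(np.log(cm.effective_library_sizes.astype(float))))
    if np.ptp(a) == 0:
        warnings.warn("zero-variance A in MA fit; slope set to 0")
        slope, intercept = 0.0, float(np.mean(m))
    else:
        slope, intercept = np.polyfit(a, m, 1)
    return MAFit(
        intercept=float(intercept),
        slope=float(slope),
        n_shared_peaks=int(shared_mask.sum()),
        base_scale=base_scale,
        shared_mask=shared_mask,
    )


def manorm3_offsets(cm: CountMatrix, fit: MAFit, cond_a: str, cond_b: str) -> OffsetModel:
    """Turn a shared-peak MA fit into per-region regression offsets.

    The fitted trend intercept + slope*A is split symmetrically: +ln2*trend/2
    for condition-a samples and -ln2*trend/2 for condition-b samples, so the
    adjusted M of shared peaks is centred on zero with zero slope.  Sample
    offsets are per-sample log effective library sizes (the A/M values are
    computed on effective-size-normalized counts, so depth enters here;
    `fit.base_scale` records the common scale).  Regions outside the
    shared-peak fit get the trend evaluated at their own A.
    """
    xa = _condition_log2_cpm_means(cm, cond_a)
    xb = _condition_log2_cpm_means(cm, cond_b)
    a_all = 0.5 * (xa + xb)
    adj = LN2 * (fit.intercept + fit.slope * a_all) / 2.0
    peak = np.zeros((cm.n_regions, cm.n_samples))
    peak[:, cm.condition_columns(cond_a)] = adj[:, None]
    peak[:, cm.condition_columns(cond_b)] = -adj[:, None]
    return OffsetModel(
        method="manorm3",
        sample_log_offsets=np.log(cm.effective_library_sizes.astype(float)),
        peak_sample_log_offsets=peak,
        diagnostics={
            "intercept": fit.intercept,
            "slope": fit.slope,
            "n_shared_peaks": fit.n_shared_peaks,
            "base_scale": fit.base_scale,
        },
    )


# ---------------------------------------------------------------------------
# Input subtraction
# ---------------------------------------------------------------------------


def input_subtract(cm: CountMatrix, input_cm: CountMatrix, floor: int = 1) -> CountMatrix:
    """Subtract scaled input (background) counts from ChIP counts.

    Input is scaled by min(1, N_chip / N_input) using full library sizes —
    background is only ever scaled down — then subtracted, rounded, and
    floored (default 1 so every region remains testable).
    """
    if floor < 0:
        raise ValueError("floor must be >= 0")
    if len(input_cm.regions) != len(cm.regions) or any(
        (r1.chrom, r1.start, r1.end) != (r2.chrom, r2.start, r2.end)
        for r1, r2 in zip(cm.regions, input_cm.regions)
    ):
        raise ValueError("ChIP and input count matrices must share identical regions")
    adjusted = np.empty_like(cm.counts)
    n_chip = cm.full_library_sizes
    for j in range(cm.n_samples):
        input_id = cm.samples["input_sample_id"].iloc[j]
        if input_id is None or (isinstance(input_id, float) and np.isnan(input_id)):
            sid = cm.samples["sample_id"].iloc[j]
            raise ValueError(f"sample {sid!r} has no input mapping")
        k = input_cm.sample_index(str(input_id))
        n_input = float(input_cm.samples["full_library_size"].iloc[k])
        scale = min(1.0, float(n_chip[j]) / n_input)
        adjusted[:, j] = np.maximum(
            np.rint(cm.counts[:, j] - input_cm.counts[:, k] * scale), floor
        ).astype(np.int64)
    return CountMatrix(regions=cm.regions, samples=cm.samples.copy(), counts=adjusted)
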