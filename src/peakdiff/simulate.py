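"""Synthetic differential-binding experiments with ground truth.

The count simulator emulates the study designs the workflow is sensitive
to, on one synthetic chromosome ("chrSim"):

* ``null_equal_depth`` — replicate negative control, equal sequencing depth;
* ``null_depth_imbalance`` — the same null with a 5x depth difference
  between conditions (the in-silico pooling/sub-sampling design);
* ``global_gain`` — a hormone-response-like experiment where most shared
  peaks gain binding in condition a, so total in-peak signal differs while
  nominal library sizes do not;
* ``celltype_cna`` — no true binding change, but a fraction of regions sit
  in copy-number-altered DNA in one condition, inflating background there;
* ``shared_unique`` — peaks present in only one condition alongside shared
  peaks.

Counts are NB(mu, phi) with variance mu + phi*mu^2 (Poisson at phi = 0).
Per-region ChIP means are baseline * (present*2^(+-delta/2) + beta*cna)
scaled to the sample's library size; the beta fraction is non-specific
background that carries the CNA dosage, and matched input libraries
measure exactly that background, so scaled input subtraction removes it.
The read-level simulator emits tagAlign reads whose 5' ends sit a half
fragment length from the peak summit (by strand) plus uniform background,
together with per-condition narrowPeak files, for end-to-end pipeline
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Peak, PeakSet, ReferenceRegions
from .reads import CountMatrix, ReadSet, write_tagalign

__all__ = ["SimConfig", "SimTruth", "simulate_count_experiment", "simulate_read_experiment"]

SCENARIOS = (
    "null_equal_depth",
    "null_depth_imbalance",
    "global_gain",
    "celltype_cna",
    "shared_unique",
)

CHROM = "chrSim"


@dataclass
class SimConfig:
    """Study-design parameters for a simulated two-condition experiment.

    Defaults are the desk-scale analogues of the evaluated designs:
    16,000 reference regions, 3 replicates per condition, 5e6-read
    libraries (1e6 vs 5e6 for the depth-imbalance null), NB dispersion
    0.05, and for the global-gain design 80% of regions increased 4-fold
    (delta = 2 on the log2 scale, applied symmetrically as +-1).
    """

    scenario: str = "null_equal_depth"
    n_regions: int = 16000
    n_reps: int = 3
    library_size_a: float = 5e6
    library_size_b: float = 5e6
    dispersion: float = 0.05
    fraction_changed: float = 0.8
    effect_log2: float = 2.0
    cna_fraction: float = 0.15
    cna_multiplier: float = 2.0
    background_beta: float = 0.1
    unique_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if not 0 <= self.fraction_changed <= 1:
            raise ValueError("fraction_changed must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.library_size_a <= 0 or self.library_size_b <= 0:
            raise ValueError("library sizes must be positive")
        if self.scenario == "null_depth_imbalance" and self.library_size_a == self.library_size_b:
            # the design point of this scenario is a 5x depth difference
            self.library_size_a = 1e6
            self.library_size_b = 5e6


@dataclass
class SimTruth:
    """Latent values behind a simulated experiment."""

    scenario: str
    seed: int
    baseline: np.ndarray
    true_log2fc: np.ndarray
    changed: np.ndarray
    cna_a: np.ndarray
    cna_b: np.ndarray
    present_a: np.ndarray
    present_b: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "baseline": self.baseline,
                "true_log2fc": self.true_log2fc,
                "changed": self.changed,
                "cna_a": self.cna_a,
                "cna_b": self.cna_b,
                "present_a": self.present_a,
                "present_b": self.present_b,
            }
        )


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0:
        return rng.poisson(mu).astype(np.int64)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu)).astype(np.int64)


def _latents(config: SimConfig, rng: np.random.Generator):
    g = config.n_regions
    baseline = 2.0 ** rng.normal(6.0, 2.0, g)
    changed = np.zeros(g, dtype=bool)
    delta = np.zeros(g)
    cna_a = np.zeros(g, dtype=bool)
    cna_b = np.zeros(g, dtype=bool)
    present_a = np.ones(g, dtype=bool)
    present_b = np.ones(g, dtype=bool)
    if config.scenario == "global_gain":
        changed = rng.random(g) < config.fraction_changed
        delta[changed] = config.effect_log2
    elif config.scenario == "celltype_cna":
        cna_a = rng.random(g) < config.cna_fraction
    elif config.scenario == "shared_unique":
        u = rng.random(g)
        a_only = u < config.unique_fraction
        b_only = (u >= config.unique_fraction) & (u < 2 * config.unique_fraction)
        present_b[a_only] = False
        present_a[b_only] = False
    beta = config.background_beta
    # recorded truth: the designed binding change; for unique peaks the
    # signal-vs-background contrast
    true_fc = np.array(delta)
    unique_fc = np.log2((1 + beta) / beta) if beta > 0 else np.inf
    true_fc[~present_b] = unique_fc
    true_fc[~present_a] = -unique_fc
    return baseline, changed, delta, cna_a, cna_b, present_a, present_b, true_fc


def _region_means(config: SimConfig, baseline, delta, cna, present, condition_sign: float):
    """Per-region expected in-peak rate for one condition (unit library)."""
    beta = config.background_beta
    mult = np.where(cna, config.cna_multiplier, 1.0)
    # the treatment effect scales the whole in-peak bundle so the designed
    # log2 fold change is exact; the CNA dosage rides on the background only
    return baseline * (present + beta * mult) * 2.0 ** (condition_sign * delta / 2.0)


def simulate_count_experiment(
    config: SimConfig,
) -> tuple[CountMatrix, CountMatrix, SimTruth]:
    """Simulate (ChIP counts, matched input counts, truth) for one design.

    Deterministic given ``config.seed``.  Input libraries default to the
    matched ChIP sample's library size; their counts reflect only the
    background component (with CNA dosage), so full-library-scaled input
    subtraction removes the background in expectation.
    """
    rng = np.random.default_rng(config.seed)
    baseline, changed, delta, cna_a, cna_b, present_a, present_b, true_fc = _latents(
        config, rng
    )
    beta = config.background_beta
    norm = float(np.sum(baseline) * (1.0 + beta))
    rate_a = _region_means(config, baseline, delta, cna_a, present_a, +1.0)
    rate_b = _region_means(config, baseline, delta, cna_b, present_b, -1.0)
    bg_a = baseline * beta * np.where(cna_a, config.cna_multiplier, 1.0)
    bg_b = baseline * beta * np.where(cna_b, config.cna_multiplier, 1.0)

    n = config.n_reps
    chip_cols, input_cols, rows = [], [], []
    for cond, rate, bg, lib in (
        ("a", rate_a, bg_a, config.library_size_a),
        ("b", rate_b, bg_b, config.library_size_b),
    ):
        for rep in range(1, n + 1):
            mu = rate * lib / norm
            chip_cols.append(_draw_counts(rng, mu, config.dispersion))
            mu_in = bg * lib / norm
            input_cols.append(_draw_counts(rng, mu_in, config.dispersion))
            rows.append(
                {
                    "sample_id": f"{cond}_{rep}",
                    "condition": cond,
                    "replicate": rep,
                    "full_library_size": lib,
                    "input_sample_id": f"input_{cond}_{rep}",
                }
            )
    regions = ReferenceRegions(
        [GenomicInterval(CHROM, i * 1000, i * 1000 + 500) for i in range(config.n_regions)]
    )
    samples = pd.DataFrame(rows)
    cm = CountMatrix(regions=regions, samples=samples, counts=np.column_stack(chip_cols))
    input_samples = pd.DataFrame(
        {
            "sample_id": [f"input_{r['sample_id']}" for r in rows],
            "condition": [r["condition"] for r in rows],
            "replicate": [r["replicate"] for r in rows],
            "full_library_size": [r["full_library_size"] for r in rows],
            "input_sample_id": None,
        }
    )
    input_cm = CountMatrix(
        regions=regions, samples=input_samples, counts=np.column_stack(input_cols)
    )
    truth = SimTruth(
        scenario=config.scenario,
        seed=config.seed,
        baseline=baseline,
        true_log2fc=true_fc,
        changed=changed if config.scenario == "global_gain" else (true_fc != 0),
        cna_a=cna_a,
        cna_b=cna_b,
        present_a=present_a,
        present_b=present_b,
    )
    return cm, input_cm, truth


# ---------------------------------------------------------------------------
# Read-level simulation
# ---------------------------------------------------------------------------


def simulate_read_experiment(
    config: SimConfig,
    out_dir,
    genome_length: int = 1_000_000,
    n_peaks: int = 200,
    fragment_length: int = 200,
    peak_width: int = 200,
    read_length: int = 36,
    summit_jitter: int = 20,
) -> tuple[dict, SimTruth]:
    """Write a read-level dataset (tagAlign + narrowPeak + sample sheet).

    Peaks are placed without overlap on one synthetic chromosome; each
    signal read's 5' end sits fragment_length/2 upstream of the summit on
    its strand (plus a small uniform jitter), so shifting reads by
    fragment_length/2 recovers the summit.  A ``background_beta`` fraction
    of each library is uniform background.  Returns a dict of written
    paths (sample_sheet, reads, peaks, truth) and the SimTruth.
    """
    if n_peaks * (peak_width + 100) >= genome_length:
        raise ValueError("peaks do not fit in the genome; increase genome_length")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = replace(config, n_regions=n_peaks)
    rng = np.random.default_rng(cfg.seed)
    baseline, changed, delta, cna_a, cna_b, present_a, present_b, true_fc = _latents(cfg, rng)

    slot = peak_width + 100
    n_slots = genome_length // slot
    slots = np.sort(rng.permutation(n_slots)[:n_peaks])
    starts = slots * slot + rng.integers(0, 100, n_peaks)
    summits = starts + peak_width // 2

    rate_a = _region_means(cfg, baseline, delta, cna_a, present_a, +1.0)
    rate_b = _region_means(cfg, baseline, delta, cna_b, present_b, -1.0)
    norm = float(np.sum(baseline) * (1.0 + cfg.background_beta))

    paths: dict[str, object] = {"reads": {}, "peaks": {}}
    sheet_rows = []
    half = fragment_length // 2
    for cond, rate, lib in (("a", rate_a, cfg.library_size_a), ("b", rate_b, cfg.library_size_b)):
        for rep in range(1, cfg.n_reps + 1):
            sid = f"{cond}_{rep}"
            mu = rate * lib / norm
            counts = _draw_counts(rng, mu, cfg.dispersion)
            read_start, read_end, strand = [], [], []
            for p in range(n_peaks):
                k = int(counts[p])
                if k == 0:
                    continue
                plus = rng.random(k) < 0.5
                jit = rng.integers(-summit_jitter, summit_jitter + 1, k)
                p5 = np.where(plus, summits[p] - half, summits[p] + half) + jit
                s = np.where(plus, p5, p5 - read_length + 1)
                s = np.maximum(s, 0)
                read_start.append(s)
                read_end.append(s + read_length)
                strand.append(np.where(plus, "+", "-"))
            n_bg = rng.poisson(cfg.background_beta * lib / (1.0 + cfg.background_beta))
            if n_bg:
                s = rng.integers(0, genome_length - read_length, n_bg)
                read_start.append(s)
                read_end.append(s + read_length)
                strand.append(np.where(rng.random(n_bg) < 0.5, "+", "-"))
            if read_start:
                starts_all = np.concatenate(read_start)
                order = np.argsort(starts_all, kind="stable")
                rs = ReadSet(
                    sid,
                    np.full(len(starts_all), CHROM, dtype=object),
                    starts_all[order],
                    np.concatenate(read_end)[order],
                    np.concatenate(strand)[order],
                )
            else:
                rs = ReadSet(sid, [], [], [], [])
            reads_path = out_dir / f"{sid}.tagAlign"
            write_tagalign(rs, reads_path)
            paths["reads"][sid] = reads_path
            sheet_rows.append(
                {
                    "sample_id": sid,
                    "condition": cond,
                    "replicate": rep,
                    "reads_path": str(reads_path),
                    "peaks_path": str(out_dir / f"peaks_{cond}.narrowPeak"),
                    "input_reads_path": "",
                }
            )

    for cond, present in (("a", present_a), ("b", present_b)):
        peaks_path = out_dir / f"peaks_{cond}.narrowPeak"
        with open(peaks_path, "w") as fh:
            for p in np.flatnonzero(present):
                fh.write(
                    f"{CHROM}\t{starts[p]}\t{starts[p] + peak_width}\tpeak_{p}\t"
                    f"{int(min(baseline[p], 1000))}\t.\t{baseline[p]:.2f}\t-1\t2.0\t"
                    f"{peak_width // 2}\n"
                )
        paths["peaks"][cond] = peaks_path

    truth = SimTruth(
        scenario=cfg.scenario,
        seed=cfg.seed,
        baseline=baseline,
        true_log2fc=true_fc,
        changed=changed if cfg.scenario == "global_gain" else (true_fc != 0),
        cna_a=cna_a,
        cna_b=cna_b,
        present_a=present_a,
        present_b=present_b,
    )
    sheet = pd.DataFrame(sheet_rows)
    sheet_path = out_dir / "sample_sheet.tsv"
    sheet.to_csv(sheet_path, sep="\t", index=False)
    truth_path = out_dir / "truth.tsv"
    tf = truth.to_frame()
    tf.insert(0, "chrom", CHROM)
    tf.insert(1, "start", starts)
    tf.insert(2, "end", starts + peak_width)
    tf.to_csv(truth_path, sep="\t", index=False)
    paths["sample_sheet"] = sheet_path
    paths["truth"] = truth_path
    return paths, truth
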