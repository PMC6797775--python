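"""Synthetic case-control ChIP-seq cohorts with known ground truth.

The generator emulates the statistical structure the outlier rules
assume, not real genome sequence or peak shapes:

* per-peak baseline normalized coverage is log-normal (median 20, log-sd
  1.0 by default), mimicking the heavy-tailed spread of promoter-mark
  signal across loci;
* each sample multiplies the baseline by independent log-normal noise
  with a given coefficient of variation (default 15%, a typical
  between-brain-sample spread for a well-behaved mark);
* spiked (peak, case) pairs multiply by a fold factor (up > 1, down < 1)
  and are recorded in a truth table;
* per-sample library-size factors scale raw coverage and the promoter
  read tally jointly, so normalization cancels them exactly;
* a small fraction of peaks are mappability artifacts carrying a pooled
  low-MAPQ read fraction >= 0.75.

Cohort defaults mirror the study design the detector targets: 16 cases,
16 controls, thousands of peaks. Two constructions keep recovery tests
meaningful: down-spiked peaks get a raised baseline (and controls floored
at coverage 5) so the every-control >= 5 clause of the down rule can
fire, and mappability artifacts are drawn from non-spiked peaks so the
artifact filter tests filtering, not spike placement.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .io import (
    GeneSet,
    GwasVariant,
    SampleSheet,
    TssRecord,
    write_bed,
    write_bedgraph,
    write_gmt,
    write_gwas_tsv,
    write_matrix_tsv,
    write_sample_sheet,
    write_tss_table,
)

__all__ = [
    "Spike",
    "SimulationConfig",
    "CohortBundle",
    "random_spikes",
    "simulate_cohort",
    "simulate_annotation",
    "simulate_gwas",
    "simulate_gene_sets",
    "write_bundle",
]

CHROM = "chrS"
PEAK_GAP = 10_000  # bp between simulated peaks; keeps 2-kb TSS links unambiguous
DOWN_BASELINE_FLOOR = 25.0  # down-spiked peaks need every control >= 5
CONTROL_FLOOR_DOWN = 5.0


@dataclass(frozen=True)
class Spike:
    peak_index: int
    case_index: int
    direction: str  # "up" | "down"
    fold: float

    def __post_init__(self) -> None:
        if self.direction == "up":
            if not self.fold > 1:
                raise ValueError("up spike fold must exceed 1")
        elif self.direction == "down":
            if not 0 < self.fold < 1:
                raise ValueError("down spike fold must be in (0, 1)")
        else:
            raise ValueError(f"spike direction must be up/down, got {self.direction!r}")


@dataclass
class SimulationConfig:
    n_cases: int = 16
    n_controls: int = 16
    n_peaks: int = 5000
    peak_width_bp: int = 1500
    baseline_log_mean: float = float(np.log(20.0))
    baseline_log_sd: float = 1.0
    sample_noise_cv: float = 0.15
    library_factor_range: Tuple[float, float] = (0.5, 2.0)
    spikes: List[Spike] = field(default_factory=list)
    mapq_artifact_fraction: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_cases, self.n_controls, self.n_peaks, self.peak_width_bp) < 1:
            raise ValueError("cohort counts and peak width must be >= 1")
        if self.sample_noise_cv < 0:
            raise ValueError("sample_noise_cv must be >= 0")
        lo, hi = self.library_factor_range
        if not 0 < lo <= hi:
            raise ValueError("library_factor_range must satisfy 0 < lo <= hi")
        if not 0 <= self.mapq_artifact_fraction <= 1:
            raise ValueError("mapq_artifact_fraction must be in [0, 1]")
        for sp in self.spikes:
            if not 0 <= sp.peak_index < self.n_peaks:
                raise ValueError(f"spike peak index {sp.peak_index} out of range")
            if not 0 <= sp.case_index < self.n_cases:
                raise ValueError(f"spike case index {sp.case_index} out of range")


@dataclass
class CohortBundle:
    config: SimulationConfig
    peaks: List[GenomicInterval]
    matrix: pd.DataFrame  # peaks x samples, normalized coverage q
    sample_sheet: SampleSheet
    mapq_summary: pd.Series
    truth: pd.DataFrame  # peak_id, sample_id, direction, fold
    library_factors: pd.Series  # per sample
    promoter_tallies: pd.Series  # per sample, reads in promoter windows

    @property
    def case_ids(self) -> List[str]:
        return self.sample_sheet.cases

    @property
    def control_ids(self) -> List[str]:
        return self.sample_sheet.controls


def random_spikes(
    rng: np.random.Generator,
    n_peaks: int,
    n_cases: int,
    n_up: int,
    n_down: int,
    up_fold: float = 4.0,
    down_fold: float = 0.2,
) -> List[Spike]:
    """Distinct spiked peaks, one random case each; up spikes first."""
    if n_up + n_down > n_peaks:
        raise ValueError("more spikes requested than peaks")
    peak_idx = rng.choice(n_peaks, size=n_up + n_down, replace=False)
    spikes = []
    for k, pi in enumerate(peak_idx):
        direction = "up" if k < n_up else "down"
        fold = up_fold if direction == "up" else down_fold
        spikes.append(Spike(int(pi), int(rng.integers(n_cases)), direction, fold))
    return spikes


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return rng.lognormal(mean=-sigma * sigma / 2, sigma=sigma, size=size)


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate a full cohort bundle; deterministic for a fixed seed.

    Randomness is split into named child streams (baseline, per-sample
    noise, spikes/artifacts, library factors) so that, e.g., changing the
    library-factor range cannot perturb the noise draws.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_baseline, ss_noise, ss_aux, ss_library = root.spawn(4)
    n = config.n_peaks
    n_samples = config.n_cases + config.n_controls
    case_ids = [f"S{i + 1}" for i in range(config.n_cases)]
    ctrl_ids = [f"C{i + 1}" for i in range(config.n_controls)]
    samples = case_ids + ctrl_ids

    rng_b = np.random.default_rng(ss_baseline)
    baseline = rng_b.lognormal(config.baseline_log_mean, config.baseline_log_sd, n)
    down_peaks = sorted({sp.peak_index for sp in config.spikes if sp.direction == "down"})
    baseline[down_peaks] = np.maximum(baseline[down_peaks], DOWN_BASELINE_FLOOR)

    noise = np.empty((n, n_samples))
    for j, child in enumerate(ss_noise.spawn(n_samples)):
        noise[:, j] = _lognormal_noise(np.random.default_rng(child), config.sample_noise_cv, n)

    Q = baseline[:, None] * noise
    for sp in config.spikes:
        Q[sp.peak_index, sp.case_index] *= sp.fold
    # guarantee the down rule is exercisable: controls at down-spiked peaks >= 5
    if down_peaks:
        Q[np.ix_(down_peaks, range(config.n_cases, n_samples))] = np.maximum(
            Q[np.ix_(down_peaks, range(config.n_cases, n_samples))], CONTROL_FLOOR_DOWN
        )

    rng_aux = np.random.default_rng(ss_aux)
    n_art = int(round(config.mapq_artifact_fraction * n))
    spiked = {sp.peak_index for sp in config.spikes}
    candidates = np.array([i for i in range(n) if i not in spiked])
    if n_art > len(candidates):
        raise ValueError("mapq_artifact_fraction too high for the number of unspiked peaks")
    artifact_idx = rng_aux.choice(candidates, size=n_art, replace=False) if n_art else np.array([], dtype=int)
    mapq = rng_aux.uniform(0.0, 0.5, size=n)
    mapq[artifact_idx] = rng_aux.uniform(0.75, 1.0, size=n_art)

    rng_lib = np.random.default_rng(ss_library)
    lo, hi = config.library_factor_range
    lib = rng_lib.uniform(lo, hi, size=n_samples)
    tallies = np.round(lib * 1e7).astype(np.int64)

    step = config.peak_width_bp + PEAK_GAP
    peaks = [
        GenomicInterval(CHROM, PEAK_GAP + i * step, PEAK_GAP + i * step + config.peak_width_bp, f"peak_{i + 1}")
        for i in range(n)
    ]
    peak_ids = [p.id for p in peaks]

    matrix = pd.DataFrame(Q, index=pd.Index(peak_ids, name="peak_id"), columns=samples)
    sheet = SampleSheet(
        pd.DataFrame(
            {"sample_id": samples, "group": ["case"] * config.n_cases + ["control"] * config.n_controls}
        )
    )
    truth = pd.DataFrame(
        [
            {
                "peak_id": peak_ids[sp.peak_index],
                "sample_id": case_ids[sp.case_index],
                "direction": sp.direction,
                "fold": sp.fold,
            }
            for sp in config.spikes
        ],
        columns=["peak_id", "sample_id", "direction", "fold"],
    )
    truth["artifact"] = False
    mapq_series = pd.Series(mapq, index=matrix.index, name="low_mapq_fraction")
    return CohortBundle(
        config=config,
        peaks=peaks,
        matrix=matrix,
        sample_sheet=sheet,
        mapq_summary=mapq_series,
        truth=truth,
        library_factors=pd.Series(lib, index=samples, name="library_factor"),
        promoter_tallies=pd.Series(tallies, index=samples, name="promoter_tally"),
    )


def bedgraph_records(bundle: CohortBundle, sample_id: str):
    """Rectangular per-peak raw-coverage profile for one sample.

    Per-base raw value is q * s / width, so quantification (sum over bases
    divided by s) returns exactly q.
    """
    s = bundle.promoter_tallies[sample_id] / 1e7
    for peak in bundle.peaks:
        q = float(bundle.matrix.loc[peak.id, sample_id])
        yield (peak.chrom, peak.start, peak.end, q * s / peak.length)


def simulate_annotation(
    peaks: Sequence[GenomicInterval],
    proportions: Tuple[float, float, float] = (0.565, 0.13, 0.305),
    seed: int = 0,
) -> List[TssRecord]:
    """Assign peaks to protein-coding / noncoding / no-gene categories.

    Proportions (protein_coding, noncoding, none) are realized exactly up
    to rounding; linked peaks get one TSS at their center. The default
    split approximates a promoter-mark catalog where roughly two-thirds of
    peaks sit at annotated genes.
    """
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    rng = np.random.default_rng(seed)
    n = len(peaks)
    n_pc = int(round(proportions[0] * n))
    n_nc = int(round(proportions[1] * n))
    n_pc = min(n_pc, n)
    n_nc = min(n_nc, n - n_pc)
    order = rng.permutation(n)
    records = []
    for rank, i in enumerate(order):
        peak = peaks[i]
        if rank < n_pc:
            biotype = "protein_coding"
        elif rank < n_pc + n_nc:
            biotype = "lincRNA"
        else:
            continue
        center = (peak.start + peak.end) // 2
        gene = f"GENE_{peak.id}"
        records.append(TssRecord(gene, f"TX_{peak.id}", biotype, peak.chrom, center, "+"))
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def simulate_gwas(
    peaks: Sequence[GenomicInterval],
    significant_peak_indices: Sequence[int],
    n_background: int = 100,
    seed: int = 0,
    significant_p: float = 1e-10,
) -> List[GwasVariant]:
    """Variants with genome-wide-significant hits placed at chosen peak centers
    plus background variants at random positions with null p-values."""
    rng = np.random.default_rng(seed)
    variants = []
    for k, i in enumerate(significant_peak_indices):
        peak = peaks[i]
        variants.append(
            GwasVariant(f"rs_sig_{k + 1}", peak.chrom, (peak.start + peak.end) // 2, significant_p)
        )
    span = max(p.end for p in peaks) + PEAK_GAP
    for k in range(n_background):
        pos = int(rng.integers(0, span))
        p = float(rng.uniform(1e-5, 1.0))
        variants.append(GwasVariant(f"rs_bg_{k + 1}", peaks[0].chrom, pos, p))
    return variants


def simulate_gene_sets(
    genes: Sequence[str],
    n_sets: int = 10,
    set_size: int = 20,
    seed: int = 0,
) -> List[GeneSet]:
    rng = np.random.default_rng(seed)
    genes = list(genes)
    if set_size > len(genes):
        raise ValueError("set_size exceeds the gene universe")
    return [
        GeneSet(f"SET_{k + 1}", frozenset(rng.choice(genes, size=set_size, replace=False)))
        for k in range(n_sets)
    ]


def write_bundle(
    bundle: CohortBundle, outdir: str | Path, emit_bedgraph: bool = False
) -> Path:
    """Write the bundle as plain-text files plus a manifest with checksums."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bed(outdir / "peaks.bed", bundle.peaks)
    write_matrix_tsv(outdir / "matrix.tsv", bundle.matrix)
    write_sample_sheet(outdir / "samples.tsv", bundle.sample_sheet)
    bundle.mapq_summary.to_frame().to_csv(
        outdir / "mapq.tsv", sep="\t", index_label="peak_id", float_format="%.6g"
    )
    bundle.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    bundle.promoter_tallies.to_frame().to_csv(
        outdir / "promoter_tallies.tsv", sep="\t", index_label="sample_id"
    )
    files = ["peaks.bed", "matrix.tsv", "samples.tsv", "mapq.tsv", "truth.tsv", "promoter_tallies.tsv"]
    if emit_bedgraph:
        for sample in bundle.matrix.columns:
            name = f"{sample}.bedgraph"
            write_bedgraph(outdir / name, bedgraph_records(bundle, sample))
            files.append(name)
    checksums = {
        name: hashlib.sha256((outdir / name).read_bytes()).hexdigest() for name in files
    }
    manifest = {
        "seed": bundle.config.seed,
        "config": {
            **{k: v for k, v in asdict(bundle.config).items() if k != "spikes"},
            "n_spikes": len(bundle.config.spikes),
        },
        "checksums": checksums,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
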