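"""End-to-end orchestration: quantify -> filter -> detect -> summarize -> enrich.

A run is driven by one declarative YAML config. Inputs are either a
precomputed peaks x samples matrix or per-sample bedGraph coverage plus
promoter read tallies. Case subgroups (e.g. a divergent case pair
analyzed separately from the rest) are expressed as named case-subset
lists; each subset is run independently against the full control panel.
Outputs are written atomically (tmp + rename) and a log records every
threshold actually used, so identical inputs reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import enrich, io, quantify
from .detect import (
    DetectionResult,
    DetectionThresholds,
    detect_outliers,
    flag_subgroups,
    sample_correlation,
    summarize_recurrence,
)
from .intervals import GenomicInterval

__all__ = ["GwasDatasetConfig", "RunConfig", "run_full", "write_report"]

logger = logging.getLogger(__name__)


@dataclass
class GwasDatasetConfig:
    name: str
    path: str
    significant_p: float = 5e-8
    flank: int = 100_000


@dataclass
class RunConfig:
    peaks: str
    sample_sheet: str
    output_dir: str
    matrix: Optional[str] = None
    coverage_dir: Optional[str] = None
    promoter_tallies: Optional[str] = None
    tss_table: Optional[str] = None
    mapq: Optional[str] = None
    gene_sets: Optional[str] = None
    gwas: List[GwasDatasetConfig] = field(default_factory=list)
    thresholds: DetectionThresholds = field(default_factory=DetectionThresholds)
    case_subsets: Dict[str, List[str]] = field(default_factory=dict)
    subgroup_delta: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        inputs = raw.get("inputs", {})
        kwargs = dict(
            peaks=inputs.get("peaks"),
            sample_sheet=inputs.get("sample_sheet"),
            matrix=inputs.get("matrix"),
            coverage_dir=inputs.get("coverage_dir"),
            promoter_tallies=inputs.get("promoter_tallies"),
            tss_table=inputs.get("tss_table"),
            mapq=inputs.get("mapq"),
            gene_sets=inputs.get("gene_sets"),
            output_dir=raw.get("output_dir", "epivariant_out"),
            case_subsets=raw.get("case_subsets", {}) or {},
            subgroup_delta=float(raw.get("subgroup_delta", 0.05)),
        )
        kwargs["gwas"] = [GwasDatasetConfig(**g) for g in inputs.get("gwas", []) or []]
        kwargs["thresholds"] = DetectionThresholds(**(raw.get("thresholds", {}) or {}))
        cfg = cls(**kwargs)
        cfg.validate(base=Path(path).parent)
        return cfg

    def validate(self, base: Path | None = None) -> None:
        if not self.peaks or not self.sample_sheet:
            raise ValueError("config must name peaks and sample_sheet inputs")
        if self.matrix is None and self.coverage_dir is None:
            raise ValueError("config must name either a matrix or a coverage_dir")
        if self.coverage_dir is not None and self.promoter_tallies is None:
            raise ValueError("coverage_dir input requires promoter_tallies")
        if base is not None:
            self._resolve(base)
        for name in ("peaks", "sample_sheet", "matrix", "coverage_dir",
                     "promoter_tallies", "tss_table", "mapq", "gene_sets"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"config input {name!r}: no such path: {value}")
        for g in self.gwas:
            if not Path(g.path).exists():
                raise FileNotFoundError(f"GWAS dataset {g.name!r}: no such path: {g.path}")

    def _resolve(self, base: Path) -> None:
        for name in ("peaks", "sample_sheet", "matrix", "coverage_dir",
                     "promoter_tallies", "tss_table", "mapq", "gene_sets", "output_dir"):
            value = getattr(self, name)
            if value is not None and not os.path.isabs(value):
                setattr(self, name, str(base / value))
        for g in self.gwas:
            if not os.path.isabs(g.path):
                g.path = str(base / g.path)


def _atomic_write(path: Path, writer) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    writer(tmp)
    os.replace(tmp, path)


def _load_matrix(config: RunConfig, peaks: Sequence[GenomicInterval],
                 sheet: io.SampleSheet) -> pd.DataFrame:
    if config.matrix is not None:
        matrix = io.read_matrix_tsv(config.matrix)
        missing = [s for s in sheet.sample_ids if s not in matrix.columns]
        if missing:
            raise ValueError(f"matrix lacks samples from the sheet: {missing}")
        return matrix[sheet.sample_ids]
    tallies = pd.read_csv(config.promoter_tallies, sep="\t", index_col=0).iloc[:, 0]
    tracks = {}
    factors = {}
    for sample in sheet.sample_ids:
        path = Path(config.coverage_dir) / f"{sample}.bedgraph"
        if not path.exists():
            raise FileNotFoundError(f"no coverage track for sample {sample}: {path}")
        tracks[sample] = io.read_bedgraph(path)
        factors[sample] = quantify.NormalizationFactor(sample, int(tallies[sample]))
    return quantify.build_peak_matrix(tracks, peaks, factors, sheet.sample_ids)


def _calls_table(result: DetectionResult,
                 peaks_by_id: Dict[str, GenomicInterval]) -> pd.DataFrame:
    rows = []
    for call in result.calls:
        iv = peaks_by_id[call.peak_id]
        rows.append({
            "peak_id": call.peak_id, "chrom": iv.chrom,
            "start_1based": iv.start + 1, "end_1based": iv.end,
            "sample_id": call.sample_id, "direction": call.direction,
            "extreme_fold": call.extreme_fold, "nominal_p": call.nominal_p,
            "control_mean": call.control_mean, "control_sd": call.control_sd,
            "excluded_reason": "",
        })
    excluded = result.eligibility[~result.eligibility["eligible"]]
    for peak_id, row in excluded.iterrows():
        iv = peaks_by_id[str(peak_id)]
        rows.append({
            "peak_id": str(peak_id), "chrom": iv.chrom,
            "start_1based": iv.start + 1, "end_1based": iv.end,
            "sample_id": "", "direction": "", "extreme_fold": float("nan"),
            "nominal_p": float("nan"), "control_mean": float("nan"),
            "control_sd": float("nan"), "excluded_reason": row["excluded_reason"],
        })
    return pd.DataFrame(rows, columns=io.CALLS_COLUMNS)


def run_full(config: RunConfig) -> Dict[str, object]:
    """Execute the whole pipeline; returns the per-subset results in memory."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("epivariant")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_full(config, outdir)
    except Exception:
        (outdir / "FAILED").write_text("run aborted; outputs may be partial\n")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_full(config: RunConfig, outdir: Path) -> Dict[str, object]:
    logger.info("thresholds in effect: %s", dataclasses.asdict(config.thresholds))
    logger.info("subgroup_delta: %s", config.subgroup_delta)
    peaks = io.read_bed(config.peaks)
    peaks_by_id = {p.id: p for p in peaks}
    sheet = io.read_sample_sheet(config.sample_sheet)
    matrix = _load_matrix(config, peaks, sheet)
    mapq = None
    if config.mapq is not None:
        mapq = pd.read_csv(config.mapq, sep="\t", index_col=0).iloc[:, 0]

    # correlation screen first: it can motivate the subset split
    pcc = sample_correlation(matrix)
    _atomic_write(outdir / "correlation.tsv",
                  lambda p: pcc.to_csv(p, sep="\t", float_format="%.6g"))
    groups = flag_subgroups(pcc, sheet.cases, delta=config.subgroup_delta)
    _atomic_write(outdir / "subgroups.json",
                  lambda p: Path(p).write_text(json.dumps(groups, indent=2) + "\n"))
    logger.info("flagged case subgroups: %s", groups["flagged"])

    subsets = dict(config.case_subsets) or {"all": sheet.cases}
    annotations = None
    tss_index = None
    if config.tss_table is not None:
        tss_index = io.read_tss_table(config.tss_table)
        annotations = enrich.annotate_peaks(peaks, tss_index, config.thresholds.gene_link_dist)

    results: Dict[str, object] = {"correlation": pcc, "subgroups": groups, "subsets": {}}
    for subset_name, case_ids in subsets.items():
        det = detect_outliers(matrix, sheet, mapq, config.thresholds, case_subset=case_ids)
        logger.info("subset %s: %d calls", subset_name, len(det.calls))
        calls_table = _calls_table(det, peaks_by_id)
        _atomic_write(outdir / f"calls_{subset_name}.tsv",
                      lambda p, t=calls_table: io.write_calls_tsv(p, t))
        rec = summarize_recurrence(det.calls)
        _atomic_write(outdir / f"recurrence_{subset_name}.tsv",
                      lambda p, r=rec: r.by_locus_direction.to_csv(p, sep="\t", index=False))
        subset_out: Dict[str, object] = {"detection": det, "recurrence": rec}

        if annotations is not None and det.calls:
            altered = sorted({c.peak_id for c in det.calls})
            cat = enrich.category_enrichment(annotations, altered)
            _atomic_write(outdir / f"category_enrichment_{subset_name}.tsv",
                          lambda p, c=cat: io.write_enrichment_tsv(p, enrich.results_table(c)))
            subset_out["category_enrichment"] = cat

            battery: List[enrich.ContingencyResult] = []
            for g in config.gwas:
                variants = io.read_gwas_tsv(g.path)
                sig = enrich.build_region_set(variants, g.significant_p, g.flank,
                                              name=f"{g.name}_significant")
                background = enrich.build_region_set(variants, 1.1, g.flank,
                                                     name=f"{g.name}_background")
                for direction in ("up", "down", "all"):
                    ids = sorted({c.peak_id for c in det.calls
                                  if direction == "all" or c.direction == direction})
                    if not ids:
                        continue
                    battery.append(enrich.region_overlap_test(
                        peaks, ids, sig, background,
                        test_name=f"{g.name}:{subset_name}:{direction}"))
            if battery:
                enrich.run_test_battery(battery)
                _atomic_write(outdir / f"gwas_overlap_{subset_name}.tsv",
                              lambda p, b=battery: io.write_enrichment_tsv(p, enrich.results_table(b)))
                subset_out["gwas_overlap"] = battery

            if config.gene_sets is not None:
                gene_sets = io.read_gmt(config.gene_sets)
                ann_by_id = {a.peak_id: a for a in annotations}
                altered_genes = sorted({
                    gene for pid in altered for gene in ann_by_id[pid].linked_genes
                    if _gene_is_coding(tss_index, gene)
                })
                background_genes = sorted({
                    r.gene_id for r in tss_index.records if r.is_protein_coding
                })
                if altered_genes:
                    ora = enrich.run_ora(altered_genes, gene_sets, background_genes)
                    _atomic_write(outdir / f"ora_{subset_name}.tsv",
                                  lambda p, o=ora: io.write_enrichment_tsv(p, enrich.results_table(o)))
                    subset_out["ora"] = ora
        results["subsets"][subset_name] = subset_out
    return results


def _gene_is_coding(tss_index: io.AnnotationIndex, gene_id: str) -> bool:
    return any(r.is_protein_coding for r in tss_index.records if r.gene_id == gene_id)


def write_report(outdir: str | Path, path: str | Path | None = None) -> str:
    """Human-readable digest of a finished run directory."""
    outdir = Path(outdir)
    lines = ["epivariant run report", "=" * 40]
    for calls_path in sorted(outdir.glob("calls_*.tsv")):
        subset = calls_path.stem.replace("calls_", "")
        table = io.read_calls_tsv(calls_path)
        called = table[table["excluded_reason"] == ""]
        n_up = int((called["direction"] == "up").sum())
        n_down = int((called["direction"] == "down").sum())
        loci = called.groupby(["peak_id", "direction"]).size() if len(called) else pd.Series(dtype=int)
        n_single = int((loci == 1).sum()) if len(loci) else 0
        lines.append(f"subset {subset}: {len(called)} calls "
                     f"({n_up} up, {n_down} down) across {called['peak_id'].nunique()} peaks")
        if len(loci):
            lines.append(f"  loci altered in a single case: {n_single}/{len(loci)} "
                         f"({100 * n_single / len(loci):.0f}%)")
        n_excluded = int((table["excluded_reason"] != "").sum())
        lines.append(f"  peaks excluded by locus filters: {n_excluded}")
    sub_path = outdir / "subgroups.json"
    if sub_path.exists():
        groups = json.loads(sub_path.read_text())
        if groups.get("flagged"):
            lines.append(f"flagged correlated case subgroups: {groups['flagged']}")
        else:
            lines.append("no correlated case subgroup flagged")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
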