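"""Readers and writers for every external format the pipeline touches.

All tables are plain TSV with headers (except BED/bedGraph/GMT, which
follow their standard header-less dialects). Readers validate rather than
coerce: malformed coordinates, duplicate sample ids or missing columns
raise with the offending line or column named.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Set

import numpy as np
import pandas as pd

from .intervals import CoverageTrack, GenomicInterval

__all__ = [
    "TssRecord",
    "AnnotationIndex",
    "SampleSheet",
    "GwasVariant",
    "GeneSet",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_tss_table",
    "write_tss_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gwas_tsv",
    "write_gwas_tsv",
    "read_gmt",
    "write_gmt",
    "read_chrom_sizes",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_calls_tsv",
    "read_calls_tsv",
    "write_enrichment_tsv",
]

PROTEIN_CODING = "protein_coding"


@dataclass(frozen=True)
class TssRecord:
    """One transcript's start site with its gene and biotype."""

    gene_id: str
    transcript_id: str
    biotype: str
    chrom: str
    pos: int  # 0-based
    strand: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"TSS position must be >= 0, got {self.pos}")
        if not self.biotype:
            raise ValueError(f"empty biotype for transcript {self.transcript_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def is_protein_coding(self) -> bool:
        return self.biotype == PROTEIN_CODING


class AnnotationIndex:
    """TSS records indexed per chromosome for proximity queries."""

    def __init__(self, records: Sequence[TssRecord]):
        self.records: List[TssRecord] = list(records)
        self._pos: Dict[str, np.ndarray] = {}
        self._idx: Dict[str, np.ndarray] = {}
        by_chrom: Dict[str, List[int]] = {}
        for i, rec in enumerate(self.records):
            by_chrom.setdefault(rec.chrom, []).append(i)
        for chrom, idxs in by_chrom.items():
            pos = np.array([self.records[i].pos for i in idxs], dtype=np.int64)
            order = np.argsort(pos, kind="stable")
            self._pos[chrom] = pos[order]
            self._idx[chrom] = np.array(idxs, dtype=np.int64)[order]

    def __len__(self) -> int:
        return len(self.records)

    def near_interval(self, iv: GenomicInterval, max_dist: int) -> List[TssRecord]:
        """All TSSs whose distance to [start, end) is strictly less than max_dist."""
        if iv.chrom not in self._pos:
            return []
        pos = self._pos[iv.chrom]
        # point-to-interval distance: 0 inside; pos >= iv.end has distance pos-end+1
        lo = int(np.searchsorted(pos, iv.start - max_dist + 1, side="left"))
        hi = int(np.searchsorted(pos, iv.end + max_dist - 1, side="left"))
        return [self.records[int(i)] for i in self._idx[iv.chrom][lo:hi]]


@dataclass
class SampleSheet:
    """Cohort description: sample ids, case/control labels, optional covariates."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        ids = self.table["sample_id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dups}")
        bad = set(self.table["group"]) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> List[str]:
        return list(self.table["sample_id"])

    @property
    def cases(self) -> List[str]:
        return list(self.table.loc[self.table["group"] == "case", "sample_id"])

    @property
    def controls(self) -> List[str]:
        return list(self.table.loc[self.table["group"] == "control", "sample_id"])

    def validate_for_detection(self) -> None:
        if len(self.cases) < 1 or len(self.controls) < 2:
            raise ValueError(
                "detection requires at least 1 case and 2 controls, got "
                f"{len(self.cases)} cases / {len(self.controls)} controls"
            )


@dataclass(frozen=True)
class GwasVariant:
    rsid: str
    chrom: str
    pos: int  # 0-based
    pvalue: float

    def __post_init__(self) -> None:
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"p-value must be in (0, 1], got {self.pvalue}")
        if self.pos < 0:
            raise ValueError(f"variant position must be >= 0, got {self.pos}")


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


# ---------------------------------------------------------------------------
# BED / bedGraph


def _parse_int(text: str, what: str, path: Path, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise ValueError(f"{path}:{lineno}: malformed {what}: {text!r}") from None


def read_bed(path: str | Path) -> List[GenomicInterval]:
    """Read 3+ column BED; IDs from column 4 or synthesized as peak_<n>."""
    path = Path(path)
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            start = _parse_int(fields[1], "start", path, lineno)
            end = _parse_int(fields[2], "end", path, lineno)
            name = fields[3] if len(fields) >= 4 and fields[3] else f"peak_{len(intervals) + 1}"
            try:
                intervals.append(GenomicInterval(fields[0], start, end, name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return intervals


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.id if iv.id is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_bedgraph(path: str | Path) -> CoverageTrack:
    """Read a 4-column bedGraph into a step-function coverage track."""
    path = Path(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            start = _parse_int(fields[1], "start", path, lineno)
            end = _parse_int(fields[2], "end", path, lineno)
            try:
                value = float(fields[3])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: malformed value: {fields[3]!r}"
                ) from None
            records.append((fields[0], start, end, value))
    return CoverageTrack.from_records(records)


def write_bedgraph(
    path: str | Path, records: Iterable[tuple[str, int, int, float]]
) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


# ---------------------------------------------------------------------------
# TSV tables


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in ("chrom", "sample_id")})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    return df


def read_tss_table(path: str | Path) -> AnnotationIndex:
    """TSS table TSV: gene_id, transcript_id, biotype, chrom, tss_pos_1based, strand."""
    df = _read_tsv(
        path, ["gene_id", "transcript_id", "biotype", "chrom", "tss_pos_1based", "strand"]
    )
    records = [
        TssRecord(
            gene_id=str(r.gene_id),
            transcript_id=str(r.transcript_id),
            biotype=str(r.biotype),
            chrom=str(r.chrom),
            pos=int(r.tss_pos_1based) - 1,
            strand=str(r.strand),
        )
        for r in df.itertuples()
    ]
    return AnnotationIndex(records)


def write_tss_table(path: str | Path, records: Iterable[TssRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttranscript_id\tbiotype\tchrom\ttss_pos_1based\tstrand\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.transcript_id}\t{r.biotype}\t{r.chrom}\t{r.pos + 1}\t{r.strand}\n"
            )


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(_read_tsv(path, ["sample_id", "group"]))


def write_sample_sheet(path: str | Path, sheet: SampleSheet) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def read_gwas_tsv(path: str | Path) -> List[GwasVariant]:
    """GWAS summary TSV: rsid, chrom, pos_1based, pvalue."""
    df = _read_tsv(path, ["rsid", "chrom", "pos_1based", "pvalue"])
    return [
        GwasVariant(str(r.rsid), str(r.chrom), int(r.pos_1based) - 1, float(r.pvalue))
        for r in df.itertuples()
    ]


def write_gwas_tsv(path: str | Path, variants: Iterable[GwasVariant]) -> None:
    with open(path, "w") as fh:
        fh.write("rsid\tchrom\tpos_1based\tpvalue\n")
        for v in variants:
            fh.write(f"{v.rsid}\t{v.chrom}\t{v.pos + 1}\t{v.pvalue:.6g}\n")


def read_gmt(path: str | Path) -> List[GeneSet]:
    """GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: List[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >= 1 gene")
            sets.append(GeneSet(fields[0], frozenset(g for g in fields[2:] if g)))
    return sets


def write_gmt(path: str | Path, sets: Iterable[GeneSet]) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            genes = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.name}\tna\t{genes}\n")


def read_chrom_sizes(path: str | Path) -> Dict[str, int]:
    """Chromosome-sizes TSV (chrom, length); used for whole-genome backgrounds."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected chrom<TAB>length")
            sizes[fields[0]] = _parse_int(fields[1], "length", Path(path), lineno)
    return sizes


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Peaks x samples normalized-coverage matrix, peak ids in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError(f"{path}: matrix contains non-finite values")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: matrix contains negative values")
    return df


def write_matrix_tsv(path: str | Path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t", index_label="peak_id", float_format="%.10g")


# ---------------------------------------------------------------------------
# Pipeline output tables

CALLS_COLUMNS = [
    "peak_id",
    "chrom",
    "start_1based",
    "end_1based",
    "sample_id",
    "direction",
    "extreme_fold",
    "nominal_p",
    "control_mean",
    "control_sd",
    "excluded_reason",
]


def write_calls_tsv(path: str | Path, calls_table: pd.DataFrame) -> None:
    """Write the outlier-calls table; column order is fixed for round-tripping."""
    missing = [c for c in CALLS_COLUMNS if c not in calls_table.columns]
    if missing:
        raise ValueError(f"calls table missing columns: {missing}")
    calls_table[CALLS_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format="%.10g", quoting=csv.QUOTE_NONE
    )


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, CALLS_COLUMNS)
    df["excluded_reason"] = df["excluded_reason"].fillna("")
    return df


def write_enrichment_tsv(path: str | Path, table: pd.DataFrame) -> None:
    cols = [
        "test_name",
        "a",
        "b",
        "c",
        "d",
        "odds_ratio",
        "p",
        "p_adjusted",
        "method",
        "significant_flag",
    ]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"enrichment table missing columns: {missing}")
    table[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")
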