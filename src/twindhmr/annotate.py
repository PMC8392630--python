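"""Genomic annotation of DhMRs against a gene model.

Each region is assigned exactly one annotation category from its midpoint
with the precedence promoter-TSS > TTS > exon (5'UTR > 3'UTR > coding exon,
or non-coding for ncRNA exons) > intron > intergenic, using strand-aware
windows around transcription start and termination sites.  A Table-1-style
summary tabulates counts and percentages per category and per gene type for
all regions and for the hyper/hypo subtypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .windows import GenomicInterval

logger = logging.getLogger(__name__)

CATEGORIES = (
    "TSS",
    "TTS",
    "5'UTR",
    "3'UTR",
    "exon",
    "non-coding",
    "intron",
    "intergenic",
)
# midpoint assignment precedence, best first
_PRECEDENCE = {
    "TSS": 0,
    "TTS": 1,
    "5'UTR": 2,
    "3'UTR": 3,
    "exon": 4,
    "non-coding": 4,
    "intron": 5,
    "intergenic": 6,
}

GENE_TYPES = ("ncRNA", "protein-coding", "pseudo", "snoRNA", "other")

DEFAULT_BIOTYPE_MAP = {
    "protein_coding": "protein-coding",
    "lncRNA": "ncRNA",
    "lincRNA": "ncRNA",
    "ncRNA": "ncRNA",
    "antisense": "ncRNA",
    "miRNA": "ncRNA",
    "misc_RNA": "ncRNA",
    "snRNA": "ncRNA",
    "snoRNA": "snoRNA",
    "pseudogene": "pseudo",
    "processed_pseudogene": "pseudo",
    "unprocessed_pseudogene": "pseudo",
}


@dataclass(frozen=True)
class Transcript:
    """One transcript of the gene model (0-based half-open coordinates)."""

    transcript_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_type: str
    exons: tuple[tuple[int, int], ...]
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class GeneModel:
    transcripts: list[Transcript]
    _by_chrom: dict[str, list[Transcript]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in self.transcripts:
            self._by_chrom.setdefault(t.chrom, []).append(t)

    def on_chrom(self, chrom: str) -> list[Transcript]:
        return self._by_chrom.get(chrom, [])


def read_gene_model(
    gtf_path: str,
    biotype_map: Mapping[str, str] | None = None,
    gene_id_key: str = "gene_id",
    biotype_key: str = "gene_biotype",
) -> GeneModel:
    """Load transcripts, exons and UTRs from a GTF file."""
    import pyranges as pr

    if biotype_map is None:
        biotype_map = DEFAULT_BIOTYPE_MAP
    df = pr.read_gtf(gtf_path).df
    if biotype_key not in df.columns:
        df[biotype_key] = None
    if "transcript_id" not in df.columns:
        raise ValueError("GTF lacks transcript_id attributes")

    n_missing_biotype = 0
    transcripts: list[Transcript] = []
    tdf = df[df["Feature"] == "transcript"]
    exon_groups = {
        tid: g for tid, g in df[df["Feature"] == "exon"].groupby(
            "transcript_id"
        )
    }

    def _intervals(feature: str) -> dict[str, list[tuple[int, int]]]:
        sub = df[df["Feature"] == feature]
        out: dict[str, list[tuple[int, int]]] = {}
        for _, row in sub.iterrows():
            out.setdefault(row["transcript_id"], []).append(
                (int(row["Start"]), int(row["End"]))
            )
        return out

    utr5_by_tid = _intervals("five_prime_utr")
    utr3_by_tid = _intervals("three_prime_utr")

    for _, row in tdf.iterrows():
        tid = row["transcript_id"]
        biotype = row[biotype_key]
        if biotype is None or (isinstance(biotype, float) and pd.isna(biotype)):
            n_missing_biotype += 1
            gene_type = "other"
        else:
            gene_type = biotype_map.get(str(biotype), "other")
        exons = exon_groups.get(tid)
        exon_tuples = (
            tuple(
                sorted(
                    (int(r.Start), int(r.End)) for r in exons.itertuples()
                )
            )
            if exons is not None
            else ()
        )
        transcripts.append(
            Transcript(
                transcript_id=str(tid),
                gene_id=str(row[gene_id_key]),
                chrom=str(row["Chromosome"]),
                start=int(row["Start"]),
                end=int(row["End"]),
                strand=str(row["Strand"]),
                gene_type=gene_type,
                exons=exon_tuples,
                utr5=tuple(utr5_by_tid.get(tid, ())),
                utr3=tuple(utr3_by_tid.get(tid, ())),
            )
        )
    if n_missing_biotype:
        logger.warning(
            "%d transcripts without a %s attribute mapped to gene type "
            "'other'", n_missing_biotype, biotype_key,
        )
    return GeneModel(transcripts)


@dataclass(frozen=True)
class AnnotationRecord:
    region: GenomicInterval
    category: str
    gene_id: str | None
    gene_type: str | None
    distance_to_tss: int | None
    pattern: str | None = None


def _site_window(
    site: int, strand: str, window: tuple[int, int]
) -> tuple[int, int]:
    """Strand-aware half-open window around a point (upstream neg offsets)."""
    lo, hi = window
    if strand == "+":
        return site + lo, site + hi + 1
    return site - hi, site - lo + 1


def _categorize_in_transcript(
    mid: int,
    t: Transcript,
    promoter_window: tuple[int, int],
    tts_window: tuple[int, int],
) -> str | None:
    s, e = _site_window(t.tss, t.strand, promoter_window)
    if s <= mid < e:
        return "TSS"
    s, e = _site_window(t.tts, t.strand, tts_window)
    if s <= mid < e:
        return "TTS"
    if not (t.start <= mid < t.end):
        return None
    for lo, hi in t.utr5:
        if lo <= mid < hi:
            return "5'UTR"
    for lo, hi in t.utr3:
        if lo <= mid < hi:
            return "3'UTR"
    for lo, hi in t.exons:
        if lo <= mid < hi:
            return "non-coding" if t.gene_type != "protein-coding" else "exon"
    return "intron"


def annotate_region(
    region: GenomicInterval,
    model: GeneModel,
    promoter_window: tuple[int, int] = (-1000, 100),
    tts_window: tuple[int, int] = (-100, 1000),
    strict: bool = False,
    pattern: str | None = None,
) -> AnnotationRecord:
    """Assign the region (by its midpoint) to exactly one category.

    The nearest gene is the transcript whose TSS is closest to the midpoint;
    the signed distance is positive downstream of the TSS in the transcript's
    direction.
    """
    mid = region.midpoint
    transcripts = model.on_chrom(region.chrom)
    if not transcripts:
        if strict:
            raise ValueError(f"unknown chromosome {region.chrom}")
        logger.warning(
            "region on chromosome %s absent from gene model; intergenic",
            region.chrom,
        )
        return AnnotationRecord(region, "intergenic", None, None, None, pattern)

    best_cat = "intergenic"
    for t in transcripts:
        cat = _categorize_in_transcript(mid, t, promoter_window, tts_window)
        if cat is not None and _PRECEDENCE[cat] < _PRECEDENCE[best_cat]:
            best_cat = cat

    nearest = min(transcripts, key=lambda t: abs(mid - t.tss))
    signed = mid - nearest.tss
    if nearest.strand == "-":
        signed = -signed
    return AnnotationRecord(
        region=region,
        category=best_cat,
        gene_id=nearest.gene_id,
        gene_type=nearest.gene_type,
        distance_to_tss=int(signed),
        pattern=pattern,
    )


# Table-1 style display order and labels
_SUMMARY_CATEGORIES = (
    ("exon", "Exons"),
    ("intergenic", "Intergenic regions"),
    ("intron", "Introns"),
    ("TSS", "TSS"),
    ("TTS", "TTS"),
    ("5'UTR", "5'UTR"),
    ("3'UTR", "3'UTR"),
    ("non-coding", "Non-coding"),
)


def summarize_annotations(
    records: Sequence[AnnotationRecord],
) -> pd.DataFrame:
    """Table-1-style category x subtype accounting.

    One row per category plus one per gene type within each category.
    Columns carry counts and percentages for all regions and the hyper/hypo
    subtypes; category percentages are over each column's total record count,
    gene-type percentages are within the category.  Raw percentages are
    reported alongside integer and one-decimal roundings (the two precisions
    used in published tables).
    """
    if not records:
        return pd.DataFrame(
            columns=["row", "level"]
            + [f"{c}_{k}" for c in ("all", "hyper", "hypo")
               for k in ("n", "pct", "pct_int", "pct_1dp")]
        )
    subsets = {
        "all": list(records),
        "hyper": [r for r in records if r.pattern == "hyper"],
        "hypo": [r for r in records if r.pattern == "hypo"],
    }
    rows = []

    def pct_cells(n: int, denom: int) -> dict[str, float]:
        pct = 100.0 * n / denom if denom else 0.0
        return {
            "n": n,
            "pct": pct,
            "pct_int": round(pct),
            "pct_1dp": round(pct, 1),
        }

    header = {"row": "n", "level": "total"}
    for name, subset in subsets.items():
        header[f"{name}_n"] = len(subset)
        header[f"{name}_pct"] = 100.0 * len(subset) / max(len(records), 1)
        header[f"{name}_pct_int"] = round(header[f"{name}_pct"])
        header[f"{name}_pct_1dp"] = round(header[f"{name}_pct"], 1)
    rows.append(header)

    for cat, label in _SUMMARY_CATEGORIES:
        cat_records = {
            name: [r for r in subset if r.category == cat]
            for name, subset in subsets.items()
        }
        if not cat_records["all"]:
            continue
        row = {"row": label, "level": "category"}
        for name, subset in subsets.items():
            cells = pct_cells(len(cat_records[name]), len(subset))
            for k, v in cells.items():
                row[f"{name}_{k}"] = v
        rows.append(row)
        for gt in GENE_TYPES:
            gt_counts = {
                name: sum(1 for r in rs if r.gene_type == gt)
                for name, rs in cat_records.items()
            }
            if gt_counts["all"] == 0 and gt == "other":
                continue
            row = {"row": gt, "level": f"gene_type:{label}"}
            for name in subsets:
                cells = pct_cells(gt_counts[name], len(cat_records[name]))
                for k, v in cells.items():
                    row[f"{name}_{k}"] = v
            rows.append(row)
    return pd.DataFrame(rows)
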