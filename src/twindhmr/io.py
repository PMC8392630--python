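"""Readers and writers for the pipeline's plain-text artifacts.

BED is written 0-based half-open; count matrices are TSV with chrom/start/end
key columns followed by one column per sample; floats serialize with 10
significant digits in JSON artifacts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .windows import CandidateRegion, GenomicInterval, WindowCountMatrix

logger = logging.getLogger(__name__)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            try:
                out[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: invalid length {parts[1]!r}"
                ) from exc
    return out


def write_chrom_sizes(chrom_lengths: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(chrom_lengths):
            fh.write(f"{chrom}\t{chrom_lengths[chrom]}\n")


def read_bed_fragments(path: str | Path) -> pd.DataFrame:
    """BED3+ fragment intervals (0-based half-open)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: BED line needs >= 3 columns"
                )
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: invalid coordinates"
                ) from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_bed_fragments(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_regions_bed(
    regions: Sequence[CandidateRegion],
    path: str | Path,
    scores: Sequence[float] | None = None,
) -> None:
    """Candidate regions as BED6: name = pattern, score = -log10(min q)."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            score = 0.0 if scores is None else scores[i]
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"{r.pattern}\t{score:.10g}\t.\n"
            )


def read_regions_bed(
    path: str | Path, one_based: bool = False
) -> list[GenomicInterval]:
    """Region intervals from BED (or 1-based inclusive with ``one_based``)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: need >= 3 columns")
            start, end = int(parts[1]), int(parts[2])
            if one_based:
                start -= 1
            out.append(GenomicInterval(parts[0], start, end))
    return out


def write_count_matrix(matrix: WindowCountMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False)


def read_count_matrix(path: str | Path) -> WindowCountMatrix:
    df = pd.read_csv(path, sep="\t")
    return WindowCountMatrix.from_frame(df)


def _json_sanitize(obj):
    """Recursively coerce to JSON types; floats keep 10 significant digits."""
    if isinstance(obj, bool):
        return obj
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        return float(f"{float(obj):.10g}")
    if isinstance(obj, np.ndarray):
        return _json_sanitize(obj.tolist())
    if isinstance(obj, dict):
        return {str(k): _json_sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_sanitize(v) for v in obj]
    return obj


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_json_sanitize(obj), fh, indent=2, sort_keys=True,
                  default=str)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def read_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: run config must be a YAML mapping")
    return cfg


def write_yaml_config(cfg: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
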