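"""Window counting and noise filtering for 5hmC enrichment fragments.

Fragments (sonicated, affinity-captured DNA of ~200 bp) are binned into
fixed-width genomic windows tiling each chromosome.  A filtering cascade then
removes windows indistinguishable from background: per-sample Poisson
read-count cutoffs, median-of-ratios library-size normalization, a per-window
case/control negative-binomial signal test with a stratified
Benjamini-Hochberg rule over integer count levels, and finally joining of
same-pattern signal windows into candidate regions.

Coordinates are 0-based, half-open (BED convention) throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

Pattern = Literal["hyper", "hypo"]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def tile_windows(
    chrom_lengths: Mapping[str, int], window_size: int = 50
) -> pd.DataFrame:
    """Tile each chromosome with non-overlapping windows of ``window_size``.

    The last window of a chromosome is truncated at the chromosome end.
    Returns a DataFrame with columns chrom/start/end sorted by (chrom, start).
    """
    frames = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        starts = np.arange(0, length, window_size, dtype=np.int64)
        ends = np.minimum(starts + window_size, length)
        frames.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class WindowCountMatrix:
    """Integer fragment counts per genomic window per sample.

    ``windows`` holds chrom/start/end rows sorted by (chrom, start); ``counts``
    is a windows x samples integer matrix; ``size_factors``, when present, are
    positive per-sample scaling constants (median-of-ratios).
    """

    windows: pd.DataFrame
    sample_ids: list[str]
    counts: np.ndarray
    size_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.windows), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.windows)} windows x {len(self.sample_ids)} samples"
            )
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.size_factors is not None:
            self.size_factors = np.asarray(self.size_factors, dtype=float)
            if np.any(self.size_factors <= 0):
                raise ValueError("size factors must be positive")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def normalized(self) -> np.ndarray:
        """Counts divided by per-sample size factors (floats)."""
        if self.size_factors is None:
            raise ValueError("size factors not estimated")
        return self.counts / self.size_factors[np.newaxis, :]

    def interval(self, index: int) -> GenomicInterval:
        row = self.windows.iloc[index]
        return GenomicInterval(str(row.chrom), int(row.start), int(row.end))

    def subset_samples(self, sample_ids: Sequence[str]) -> "WindowCountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        sf = self.size_factors[idx] if self.size_factors is not None else None
        return WindowCountMatrix(
            self.windows, list(sample_ids), self.counts[:, idx], sf
        )

    def to_frame(self) -> pd.DataFrame:
        df = self.windows.reset_index(drop=True).copy()
        for j, s in enumerate(self.sample_ids):
            df[s] = self.counts[:, j]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "WindowCountMatrix":
        meta = ["chrom", "start", "end"]
        missing = [c for c in meta if c not in df.columns]
        if missing:
            raise ValueError(f"count matrix missing columns: {missing}")
        sample_ids = [c for c in df.columns if c not in meta]
        return cls(
            df[meta].reset_index(drop=True),
            sample_ids,
            df[sample_ids].to_numpy(dtype=np.int64),
        )


@dataclass(frozen=True)
class SignalWindow:
    """A window flagged as containing 5hmC signal."""

    index: int
    pattern: Pattern
    p_value: float
    mean_level: float


@dataclass(frozen=True)
class CandidateRegion:
    """A joined run of same-pattern signal windows ("noise-free region")."""

    interval: GenomicInterval
    pattern: Pattern
    member_windows: tuple[int, ...]


def bin_fragments(
    fragments: Mapping[str, pd.DataFrame],
    chrom_lengths: Mapping[str, int],
    window_size: int = 50,
    fragment_size: int = 200,
) -> WindowCountMatrix:
    """Bin per-sample fragment intervals into tiled window counts.

    Each fragment increments every window it overlaps by at least 1 bp.
    ``fragments`` maps sample id to a DataFrame with chrom/start/end columns
    (0-based half-open).  A record whose end equals its start + 1 smaller than
    ``fragment_size`` is treated as given; records lacking an ``end`` column
    are read starts extended to ``fragment_size`` on the + strand.
    """
    windows = tile_windows(chrom_lengths, window_size)
    chrom_offsets: dict[str, int] = {}
    chrom_nwin: dict[str, int] = {}
    offset = 0
    for chrom in sorted(chrom_lengths):
        nwin = math.ceil(chrom_lengths[chrom] / window_size)
        chrom_offsets[chrom] = offset
        chrom_nwin[chrom] = nwin
        offset += nwin
    total_windows = offset

    sample_ids = list(fragments)
    counts = np.zeros((total_windows, len(sample_ids)), dtype=np.int64)
    for j, sample in enumerate(sample_ids):
        df = fragments[sample]
        if len(df) == 0:
            continue
        if "end" not in df.columns:
            df = df.assign(end=df["start"] + fragment_size)
        unknown = set(df["chrom"].unique()) - set(chrom_lengths)
        if unknown:
            raise ValueError(
                f"fragments on unknown chromosomes: {sorted(unknown)}"
            )
        for chrom, sub in df.groupby("chrom", observed=True):
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            ends = np.minimum(ends, chrom_lengths[chrom])
            starts = np.maximum(starts, 0)
            first = starts // window_size
            last = (ends - 1) // window_size
            base = chrom_offsets[chrom]
            nwin = chrom_nwin[chrom]
            span = int((last - first).max()) + 1
            for k in range(span):
                idx = first + k
                mask = (idx <= last) & (idx < nwin)
                if mask.any():
                    counts[:, j] += np.bincount(
                        idx[mask] + base, minlength=total_windows
                    )
    return WindowCountMatrix(windows, sample_ids, counts)


def estimate_size_factors(matrix: WindowCountMatrix) -> np.ndarray:
    """Median-of-ratios size factors (the DESeq normalization).

    Reference windows are those with strictly positive counts in every sample;
    the factor for sample s is the median over reference windows of the ratio
    of its count to the across-sample geometric mean.
    """
    counts = matrix.counts
    reference = (counts > 0).all(axis=1)
    if not reference.any():
        raise ValueError(
            "no window has positive counts in all samples; pre-filter "
            "low-coverage windows before estimating size factors"
        )
    ref = counts[reference].astype(float)
    log_geo_mean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geo_mean[:, np.newaxis]
    factors = np.exp(np.median(ratios, axis=0))
    matrix.size_factors = factors
    return factors


def sample_cutoffs(
    matrix: WindowCountMatrix, cutoff_fdr: float = 0.05
) -> np.ndarray:
    """Per-sample integer read-count cutoffs from a Poisson background model.

    For sample s with genome-wide mean rate lambda_s, the cutoff is the
    smallest integer c >= 1 at which the expected number of background
    (Poisson) windows at count >= c, divided by the observed number of windows
    at count >= c, drops to ``cutoff_fdr`` or below.  A window survives the
    filter if it reaches the cutoff in at least one sample.
    """
    n_windows = matrix.n_windows
    cutoffs = np.ones(matrix.n_samples, dtype=np.int64)
    for j in range(matrix.n_samples):
        col = matrix.counts[:, j]
        total = int(col.sum())
        if total == 0:
            logger.warning(
                "sample %s has no counts; cutoff set to 1",
                matrix.sample_ids[j],
            )
            cutoffs[j] = 1
            continue
        lam = total / n_windows
        cmax = int(col.max())
        c = 1
        while c <= cmax + 1:
            expected = n_windows * stats.poisson.sf(c - 1, lam)
            observed = int((col >= c).sum())
            if expected / max(observed, 1) <= cutoff_fdr:
                break
            c += 1
        cutoffs[j] = c
    return cutoffs


def surviving_windows(
    matrix: WindowCountMatrix, cutoffs: np.ndarray
) -> np.ndarray:
    """Boolean mask of windows reaching the cutoff in at least one sample."""
    return (matrix.counts >= cutoffs[np.newaxis, :]).any(axis=1)


def _pooled_mom_dispersion(
    x_case: np.ndarray, x_ctrl: np.ndarray
) -> np.ndarray:
    """Per-window method-of-moments NB dispersion pooled across the groups."""
    n1, n0 = x_case.shape[1], x_ctrl.shape[1]
    m1 = x_case.mean(axis=1)
    m0 = x_ctrl.mean(axis=1)
    ssr = ((x_case - m1[:, None]) ** 2).sum(axis=1) + (
        (x_ctrl - m0[:, None]) ** 2
    ).sum(axis=1)
    s2 = ssr / max(n1 + n0 - 2, 1)
    m = (n1 * m1 + n0 * m0) / (n1 + n0)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - m) / np.square(m)
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    return np.clip(alpha, 0.0, None)


def filter_noise_windows(
    matrix: WindowCountMatrix,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    signal_fdr: float = 0.10,
    cutoff_fdr: float = 0.05,
    pseudocount: float = 0.5,
) -> list[SignalWindow]:
    """Flag windows whose normalized counts differ between cases and controls.

    Cutoff-surviving windows are tested with a two-group negative-binomial
    Wald test on the log normalized-mean difference (method-of-moments
    dispersion).  Windows are then stratified by their integer-rounded mean
    normalized count; Benjamini-Hochberg runs within each stratum, and the
    lowest count level at which any window attains q < ``signal_fdr`` sets
    the signal floor: signal windows are those at or above that level with
    q < ``signal_fdr``, labeled hyper or hypo by the sign of the case minus
    control difference.
    """
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise ValueError("need at least 2 samples per group")
    if matrix.size_factors is None:
        estimate_size_factors(matrix)

    cutoffs = sample_cutoffs(matrix, cutoff_fdr)
    survive = surviving_windows(matrix, cutoffs)
    idx = np.flatnonzero(survive)
    if idx.size == 0:
        return []

    norm = matrix.normalized()[idx]
    case_j = [matrix.sample_ids.index(s) for s in case_ids]
    ctrl_j = [matrix.sample_ids.index(s) for s in control_ids]
    x1 = norm[:, case_j]
    x0 = norm[:, ctrl_j]
    m1 = x1.mean(axis=1)
    m0 = x0.mean(axis=1)
    alpha = _pooled_mom_dispersion(x1, x0)

    # Wald statistic on the log difference of shifted group means; the
    # delta-method variance of log(mean) uses the NB variance mu + alpha*mu^2.
    v1 = (m1 + alpha * m1**2) / len(case_j) / np.square(m1 + pseudocount)
    v0 = (m0 + alpha * m0**2) / len(ctrl_j) / np.square(m0 + pseudocount)
    delta = np.log(m1 + pseudocount) - np.log(m0 + pseudocount)
    se = np.sqrt(v1 + v0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, delta / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    mean_level = (x1.sum(axis=1) + x0.sum(axis=1)) / (len(case_j) + len(ctrl_j))
    level = np.rint(mean_level).astype(np.int64)

    from .dhmr_stats import benjamini_hochberg

    q = np.ones_like(p)
    for lev in np.unique(level):
        mask = level == lev
        q[mask] = benjamini_hochberg(p[mask])

    qualifying_levels = np.unique(level[q < signal_fdr])
    if qualifying_levels.size == 0:
        return []
    level_floor = qualifying_levels.min()

    flagged = (level >= level_floor) & (q < signal_fdr)
    out: list[SignalWindow] = []
    for k in np.flatnonzero(flagged):
        pattern: Pattern = "hyper" if m1[k] > m0[k] else "hypo"
        out.append(
            SignalWindow(
                index=int(idx[k]),
                pattern=pattern,
                p_value=float(p[k]),
                mean_level=float(mean_level[k]),
            )
        )
    return out


def join_candidate_regions(
    signal: Iterable[SignalWindow],
    matrix: WindowCountMatrix,
    join_gap: int = 200,
    min_region_size: int = 150,
) -> list[CandidateRegion]:
    """Join same-chromosome, same-pattern signal windows into regions.

    Consecutive signal windows are merged when the gap from the previous
    window's end to the next window's start is <= ``join_gap`` (ties joined).
    Merged regions shorter than ``min_region_size`` bp are discarded.
    """
    items = []
    for sw in signal:
        iv = matrix.interval(sw.index)
        items.append((iv.chrom, iv.start, iv.end, sw.pattern, sw.index))
    items.sort(key=lambda t: (t[0], t[1], t[2]))

    regions: list[CandidateRegion] = []
    run: list[tuple[str, int, int, str, int]] = []

    def flush() -> None:
        if not run:
            return
        chrom = run[0][0]
        start = run[0][1]
        end = max(t[2] for t in run)
        if end - start >= min_region_size:
            regions.append(
                CandidateRegion(
                    interval=GenomicInterval(chrom, start, end),
                    pattern=run[0][3],  # type: ignore[arg-type]
                    member_windows=tuple(t[4] for t in run),
                )
            )

    for item in items:
        if run and (
            item[0] != run[-1][0]
            or item[3] != run[-1][3]
            or item[1] - max(t[2] for t in run) > join_gap
        ):
            flush()
            run = []
        run.append(item)
    flush()
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return regions


def aggregate_region_counts(
    matrix: WindowCountMatrix, regions: Sequence[CandidateRegion]
) -> np.ndarray:
    """Sum member-window counts per sample for each region."""
    out = np.zeros((len(regions), matrix.n_samples), dtype=np.int64)
    for i, region in enumerate(regions):
        for w in region.member_windows:
            if not 0 <= w < matrix.n_windows:
                raise ValueError(
                    f"region {i} references unknown window index {w}"
                )
        out[i] = matrix.counts[list(region.member_windows)].sum(axis=0)
    return out
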