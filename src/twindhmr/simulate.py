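"""Synthetic twin-cohort generator for 5hmC enrichment counts.

Emulates the data the pipeline expects: matched case/control co-twin pairs
(monozygotic and dizygotic), fragment counts per 50 bp window following a
negative-binomial log-link model with per-pair random effects and
library-size variation, leukocyte-composition and age covariates, and spiked
hyper-/hypo-hydroxymethylated regions with known log2 fold changes that serve
as ground truth for recovery tests.

The window-level model is

    log mu = log(baseline_mean) + pair_effect + libsize_offset
             + spike_effect (cases only) + covariate_effect

with counts drawn NB(mu, alpha), variance mu + alpha * mu^2.  When fragment
emission is enabled the NB draw is the number of fragments starting in the
window; fragment starts are placed uniformly within the window, and the
cohort's count matrix is the overlap-binned version of those fragments so
that binning the emitted fragments reproduces it exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dhmr_stats import LEUKOCYTE_FRACTIONS, TwinSample
from .windows import (
    GenomicInterval,
    WindowCountMatrix,
    bin_fragments,
    tile_windows,
)

logger = logging.getLogger(__name__)

# Typical adult peripheral-blood composition: granulocytes dominate and are
# the omitted remainder of the five modeled fractions.
DEFAULT_LEUKOCYTE_MEANS = {
    "cd8t": 0.08,
    "cd4t": 0.15,
    "nk": 0.05,
    "bcell": 0.05,
    "mono": 0.07,
}
DEFAULT_GRANULOCYTE_MEAN = 0.60


@dataclass(frozen=True)
class SpikeSpec:
    """A planted differentially hydroxymethylated region."""

    interval: GenomicInterval
    log2fc: float
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2fc):
            raise ValueError("log2fc must be finite")
        if not 0 < self.penetrance <= 1:
            raise ValueError("penetrance must lie in (0, 1]")


@dataclass
class CovariateModel:
    """Leukocyte-fraction and age generation parameters.

    Fractions come from a Dirichlet over the six blood subtypes (five modeled
    plus granulocytes) with the given means and ``concentration`` controlling
    between-sample variability.  Ages are uniform on ``age_range`` per sample.
    ``confounder`` optionally links one covariate to window log-means with
    the given coefficient (off by default; used to plant confounding).
    """

    leukocyte_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LEUKOCYTE_MEANS)
    )
    granulocyte_mean: float = DEFAULT_GRANULOCYTE_MEAN
    concentration: float = 200.0
    age_range: tuple[float, float] = (55.0, 65.0)
    confounder: str | None = None
    confounder_coef: float = 0.0


@dataclass
class SimulationConfig:
    """Parameters of one synthetic twin cohort."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chrS1": 3_000_000, "chrS2": 2_000_000}
    )
    n_pairs_mz: int = 19
    n_pairs_dz: int = 19
    window_size: int = 50
    fragment_size: int = 200
    baseline_mean: float = 5.0
    dispersion: float = 0.3
    pair_effect_sd: float = 0.15
    libsize_cv: float = 0.2
    spikes: list[SpikeSpec] = field(default_factory=list)
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    emit_fragments: bool = False

    def validate(self) -> None:
        if self.n_pairs_mz + self.n_pairs_dz <= 0:
            raise ValueError("cohort must contain at least one twin pair")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        for spike in self.spikes:
            iv = spike.interval
            if iv.chrom not in self.chrom_lengths:
                raise ValueError(f"spike on unknown chromosome {iv.chrom}")
            if iv.end > self.chrom_lengths[iv.chrom]:
                raise ValueError(
                    f"spike {iv.chrom}:{iv.start}-{iv.end} extends past "
                    "chromosome end"
                )
        for i, a in enumerate(self.spikes):
            for b in self.spikes[i + 1 :]:
                if a.interval.overlaps(b.interval):
                    raise ValueError(
                        f"overlapping spikes: {a.interval} and {b.interval}"
                    )


@dataclass
class SimulatedCohort:
    """A generated cohort with its ground truth."""

    counts: WindowCountMatrix
    samples: list[TwinSample]
    truth: pd.DataFrame
    fragments: dict[str, pd.DataFrame] | None = None
    config: SimulationConfig | None = None


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, alpha: float
) -> np.ndarray:
    if alpha <= 0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def _window_index(
    chrom_lengths: Mapping[str, int], window_size: int
) -> tuple[pd.DataFrame, dict[str, tuple[int, int]]]:
    windows = tile_windows(chrom_lengths, window_size)
    spans: dict[str, tuple[int, int]] = {}
    offset = 0
    for chrom in sorted(chrom_lengths):
        nwin = math.ceil(chrom_lengths[chrom] / window_size)
        spans[chrom] = (offset, offset + nwin)
        offset += nwin
    return windows, spans


def _spike_window_mask(
    config: SimulationConfig, spans: Mapping[str, tuple[int, int]], n_windows: int
) -> list[tuple[SpikeSpec, np.ndarray]]:
    masks = []
    for spike in config.spikes:
        iv = spike.interval
        lo, hi = spans[iv.chrom]
        first = lo + iv.start // config.window_size
        last = lo + (iv.end - 1) // config.window_size
        idx = np.arange(first, min(last + 1, hi))
        mask = np.zeros(n_windows, dtype=bool)
        mask[idx] = True
        masks.append((spike, mask))
    return masks


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort, deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    windows, spans = _window_index(config.chrom_lengths, config.window_size)
    n_windows = len(windows)

    # sample metadata
    samples: list[TwinSample] = []
    pair_specs = [("MZ", i) for i in range(config.n_pairs_mz)] + [
        ("DZ", i) for i in range(config.n_pairs_dz)
    ]
    cov = config.covariate_model
    dir_means = np.array(
        [cov.leukocyte_means[k] for k in LEUKOCYTE_FRACTIONS]
        + [cov.granulocyte_mean]
    )
    dir_means = dir_means / dir_means.sum()

    pair_effects: dict[str, float] = {}
    raw_samples: list[dict] = []
    for zyg, i in pair_specs:
        pair_id = f"{zyg}{i + 1:02d}"
        pair_effects[pair_id] = rng.normal(0.0, config.pair_effect_sd)
        age = rng.uniform(*cov.age_range)  # co-twins share their age
        for role in ("case", "control"):
            fracs = rng.dirichlet(dir_means * cov.concentration)
            raw_samples.append(
                dict(
                    sample_id=f"{pair_id}_{role}",
                    pair_id=pair_id,
                    zygosity=zyg,
                    role=role,
                    **dict(zip(LEUKOCYTE_FRACTIONS, fracs[:5])),
                    age=age,
                )
            )

    n_samples = len(raw_samples)
    lib_scale = np.exp(
        rng.normal(0.0, config.libsize_cv, size=n_samples)
    ) if config.libsize_cv > 0 else np.ones(n_samples)

    # per-pair spike carriage (penetrance)
    spike_masks = _spike_window_mask(config, spans, n_windows)
    pair_ids = sorted(pair_effects)
    carriage: dict[tuple[int, str], bool] = {}
    for k, (spike, _) in enumerate(spike_masks):
        for pid in pair_ids:
            carriage[(k, pid)] = bool(rng.random() < spike.penetrance)

    # window x sample log-mean and NB draw
    log_mu = np.full((n_windows, n_samples), np.log(config.baseline_mean))
    for j, s in enumerate(raw_samples):
        log_mu[:, j] += pair_effects[s["pair_id"]] + np.log(lib_scale[j])
        if cov.confounder is not None and cov.confounder_coef != 0.0:
            value = s[cov.confounder]
            log_mu[:, j] += cov.confounder_coef * value
        if s["role"] == "case":
            for k, (spike, mask) in enumerate(spike_masks):
                if carriage[(k, s["pair_id"])]:
                    log_mu[mask, j] += spike.log2fc * np.log(2.0)

    counts = _nb_draw(rng, np.exp(log_mu), config.dispersion).astype(np.int64)

    truth_rows = []
    for k, (spike, _) in enumerate(spike_masks):
        carriers = [pid for pid in pair_ids if carriage[(k, pid)]]
        truth_rows.append(
            dict(
                chrom=spike.interval.chrom,
                start=spike.interval.start,
                end=spike.interval.end,
                log2fc=spike.log2fc,
                penetrance=spike.penetrance,
                carrier_pairs=",".join(carriers),
            )
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "start", "end", "log2fc", "penetrance", "carrier_pairs"],
    )

    sample_ids = [s["sample_id"] for s in raw_samples]
    matrix = WindowCountMatrix(windows, sample_ids, counts)

    fragments = None
    if config.emit_fragments:
        fragments = emit_fragments_from_starts(matrix, config, rng)
        matrix = bin_fragments(
            fragments, config.chrom_lengths, config.window_size,
            config.fragment_size,
        )

    twin_samples = [TwinSample(**s) for s in raw_samples]
    return SimulatedCohort(
        counts=matrix,
        samples=twin_samples,
        truth=truth,
        fragments=fragments,
        config=config,
    )


def emit_fragments_from_starts(
    matrix: WindowCountMatrix,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, pd.DataFrame]:
    """Place one fragment per counted start uniformly within its window.

    Fragments extend ``fragment_size`` bp rightward and are clipped at the
    chromosome end (clips are counted in a warning).  Binning the result with
    the same window/fragment sizes reproduces the overlap-count matrix of the
    emitted fragments exactly.
    """
    chrom_arr = matrix.windows["chrom"].to_numpy()
    start_arr = matrix.windows["start"].to_numpy()
    end_arr = matrix.windows["end"].to_numpy()

    out: dict[str, pd.DataFrame] = {}
    n_clipped = 0
    for j, sample in enumerate(matrix.sample_ids):
        col = matrix.counts[:, j]
        nz = np.flatnonzero(col)
        reps = col[nz]
        w_start = np.repeat(start_arr[nz], reps)
        w_end = np.repeat(end_arr[nz], reps)
        chroms = np.repeat(chrom_arr[nz], reps)
        starts = w_start + rng.integers(0, w_end - w_start)
        ends = starts + config.fragment_size
        lengths = np.array(
            [config.chrom_lengths[c] for c in chroms], dtype=np.int64
        ) if len(chroms) else np.array([], dtype=np.int64)
        clipped = ends > lengths
        n_clipped += int(clipped.sum())
        ends = np.minimum(ends, lengths)
        df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(
            drop=True
        )
        out[sample] = df
    if n_clipped:
        logger.warning(
            "%d fragments clipped at chromosome ends during emission",
            n_clipped,
        )
    return out


def emit_fragments(cohort: SimulatedCohort) -> dict[str, pd.DataFrame]:
    """Return the cohort's emitted fragments (requires emission enabled)."""
    if cohort.fragments is None:
        raise ValueError(
            "cohort was generated without fragment emission; set "
            "emit_fragments=True in SimulationConfig"
        )
    return cohort.fragments


def default_spikes(
    config: SimulationConfig,
    n_hyper: int,
    n_hypo: int,
    log2fc: float = 2.0,
    region_size: int = 500,
    spacing: int = 20_000,
    start_offset: int = 10_000,
) -> list[SpikeSpec]:
    """Evenly spaced non-overlapping spike intervals on the first chromosome."""
    chrom = sorted(config.chrom_lengths)[0]
    length = config.chrom_lengths[chrom]
    spikes = []
    pos = start_offset
    for i in range(n_hyper + n_hypo):
        if pos + region_size > length:
            raise ValueError("chromosome too short for requested spikes")
        fc = log2fc if i < n_hyper else -log2fc
        spikes.append(
            SpikeSpec(GenomicInterval(chrom, pos, pos + region_size), fc)
        )
        pos += spacing
    return spikes


def synthesize_pair_samples(
    n_pairs: int,
    zygosity: str = "MZ",
    rng: np.random.Generator | None = None,
    covariate_model: CovariateModel | None = None,
    pair_prefix: str | None = None,
) -> list[TwinSample]:
    """Draw paired sample metadata only (no counts).

    Co-twins share their age; leukocyte fractions are Dirichlet per sample.
    Useful for region-level benchmarks that bypass window binning.
    """
    rng = np.random.default_rng() if rng is None else rng
    cov = covariate_model or CovariateModel()
    prefix = zygosity if pair_prefix is None else pair_prefix
    dir_means = np.array(
        [cov.leukocyte_means[k] for k in LEUKOCYTE_FRACTIONS]
        + [cov.granulocyte_mean]
    )
    dir_means = dir_means / dir_means.sum()
    out: list[TwinSample] = []
    for i in range(n_pairs):
        pair_id = f"{prefix}{i + 1:02d}"
        age = rng.uniform(*cov.age_range)
        for role in ("case", "control"):
            fracs = rng.dirichlet(dir_means * cov.concentration)
            out.append(
                TwinSample(
                    sample_id=f"{pair_id}_{role}",
                    pair_id=pair_id,
                    zygosity=zygosity,
                    role=role,
                    **dict(zip(LEUKOCYTE_FRACTIONS, fracs[:5])),
                    age=age,
                )
            )
    return out


def simulate_region_counts(
    samples: Sequence[TwinSample],
    n_regions: int,
    spikes: Mapping[int, float] | None = None,
    baseline_mean: float = 100.0,
    dispersion: float = 0.2,
    pair_effect_sd: float = 0.15,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Region-level NB count matrix (regions x samples) with planted effects.

    ``spikes`` maps region row indices to log2 fold changes applied to case
    samples.  Each region gets its own per-pair random effect; columns follow
    the order of ``samples``.
    """
    rng = np.random.default_rng() if rng is None else rng
    pair_ids = sorted({s.pair_id for s in samples})
    pair_col = {pid: k for k, pid in enumerate(pair_ids)}
    pair_eff = rng.normal(0.0, pair_effect_sd, size=(n_regions, len(pair_ids)))
    cols = np.array([pair_col[s.pair_id] for s in samples])
    mu = baseline_mean * np.exp(pair_eff[:, cols])
    case = np.array([s.role == "case" for s in samples])
    for idx, fc in (spikes or {}).items():
        mu[idx, case] *= 2.0 ** fc
    return _nb_draw(rng, mu, dispersion).astype(np.int64)


def samples_to_frame(samples: Sequence[TwinSample]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                sample_id=s.sample_id,
                pair_id=s.pair_id,
                zygosity=s.zygosity,
                role=s.role,
                cd8t=s.cd8t,
                cd4t=s.cd4t,
                nk=s.nk,
                bcell=s.bcell,
                mono=s.mono,
                age=s.age,
                size_factor=s.size_factor,
            )
            for s in samples
        ]
    )


def samples_from_frame(df: pd.DataFrame) -> list[TwinSample]:
    required = {
        "sample_id", "pair_id", "zygosity", "role",
        "cd8t", "cd4t", "nk", "bcell", "mono", "age",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    samples = []
    for _, row in df.iterrows():
        samples.append(
            TwinSample(
                sample_id=str(row.sample_id),
                pair_id=str(row.pair_id),
                zygosity=str(row.zygosity),
                role=str(row.role),
                cd8t=float(row.cd8t),
                cd4t=float(row.cd4t),
                nk=float(row.nk),
                bcell=float(row.bcell),
                mono=float(row.mono),
                age=float(row.age),
                size_factor=float(row.get("size_factor", 1.0)),
            )
        )
    return samples
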