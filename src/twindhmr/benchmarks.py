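"""Self-contained statistical benchmarks for the discovery pipeline.

Both benchmarks simulate region-level counts with known truth, run the same
inference code the pipeline uses, and report summary metrics.  They back the
acceptance checks and the reproduction section of the README, so they take a
single seed and are fully deterministic given it.

``calibration_benchmark``: null regions only; checks that ANODEV p-values are
uniform and that Benjamini-Hochberg selection at q <= 0.01 stays near the
nominal false discovery rate.

``recovery_benchmark``: spiked regions among nulls; runs phase-1 discovery on
a training cohort and phase-2 validation on a held-out cohort and reports
sensitivity, fold-change accuracy, sign correctness, and false positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dhmr_stats import (
    ModelSpec,
    anodev_group_test,
    benjamini_hochberg,
    build_design,
    discover_phase1,
    estimate_common_dispersion,
)
from .phases import validate_phase2
from .simulate import simulate_region_counts, synthesize_pair_samples
from .windows import GenomicInterval


def _regions(n: int, size: int = 500, spacing: int = 1000) -> list[GenomicInterval]:
    return [
        GenomicInterval("chrS1", i * spacing, i * spacing + size)
        for i in range(n)
    ]


@dataclass
class CalibrationResult:
    p_values: np.ndarray
    ks_p: float
    empirical_rate_at_nominal: float
    n_selected_bh: int
    n_regions: int


def calibration_benchmark(
    seed: int = 0,
    n_regions: int = 2000,
    n_pairs: int = 12,
    baseline_mean: float = 100.0,
    dispersion: float = 0.3,
    nominal: float = 0.01,
) -> CalibrationResult:
    """Null ANODEV calibration under the unadjusted paired model (model 1)."""
    rng = np.random.default_rng(seed)
    samples = synthesize_pair_samples(n_pairs, "MZ", rng)
    counts = simulate_region_counts(
        samples, n_regions, baseline_mean=baseline_mean,
        dispersion=dispersion, rng=rng,
    )
    model = ModelSpec.model(1)
    design, _ = build_design(samples, model, include_group=True)
    offsets = np.zeros(len(samples))
    alpha = estimate_common_dispersion(counts, design, offsets)
    p = np.empty(n_regions)
    for i in range(n_regions):
        res = anodev_group_test(counts[i], samples, model, alpha=alpha)
        p[i] = 1.0 if res["flagged"] else res["p_value"]
    ks_p = float(stats.kstest(p, "uniform").pvalue)
    q = benjamini_hochberg(p)
    return CalibrationResult(
        p_values=p,
        ks_p=ks_p,
        empirical_rate_at_nominal=float(np.mean(p <= nominal)),
        n_selected_bh=int(np.sum(q <= nominal)),
        n_regions=n_regions,
    )


@dataclass
class RecoveryResult:
    sensitivity: float
    mae_log2fc: float
    n_confirmed_true: int
    n_confirmed_false: int
    n_phase1_true: int
    all_signs_correct: bool
    n_spiked: int
    n_regions: int


def recovery_benchmark(
    seed: int = 0,
    n_regions: int = 500,
    n_spiked: int = 20,
    log2fc: float = 2.0,
    n_train_pairs: int = 12,
    n_valid_pairs: int = 7,
    baseline_mean: float = 100.0,
    dispersion: float = 0.2,
    phase1_q: float = 0.01,
    phase2_p: float = 0.01,
) -> RecoveryResult:
    """Spike-recovery of the full phase-1 + phase-2 pipeline.

    The first ``n_spiked`` regions are planted, half hyper (+``log2fc``) and
    half hypo (-``log2fc``); the remainder are null.  Training and validation
    cohorts are drawn from the same stream in that order.
    """
    rng = np.random.default_rng(seed)
    train = synthesize_pair_samples(n_train_pairs, "MZ", rng, pair_prefix="T")
    valid = synthesize_pair_samples(n_valid_pairs, "MZ", rng, pair_prefix="V")
    half = n_spiked // 2
    spikes = {i: (log2fc if i < half else -log2fc) for i in range(n_spiked)}
    counts_train = simulate_region_counts(
        train, n_regions, spikes, baseline_mean, dispersion, rng=rng
    )
    counts_valid = simulate_region_counts(
        valid, n_regions, spikes, baseline_mean, dispersion, rng=rng
    )
    records = discover_phase1(
        counts_train, _regions(n_regions), train, alpha_q=phase1_q
    )
    confirmed = validate_phase2(records, counts_valid, valid, p_max=phase2_p)
    true_conf = [r for r in confirmed if r.region_index < n_spiked]
    false_conf = [r for r in confirmed if r.region_index >= n_spiked]
    signs_ok = all(
        np.sign(r.log2fc["m3"]) == np.sign(spikes[r.region_index])
        for r in true_conf
    )
    mae = (
        float(
            np.mean(
                [
                    abs(r.log2fc["m3"] - spikes[r.region_index])
                    for r in true_conf
                ]
            )
        )
        if true_conf
        else float("nan")
    )
    return RecoveryResult(
        sensitivity=len(true_conf) / n_spiked,
        mae_log2fc=mae,
        n_confirmed_true=len(true_conf),
        n_confirmed_false=len(false_conf),
        n_phase1_true=sum(
            1 for r in records[:n_spiked] if r.phase1_selected
        ),
        all_signs_correct=bool(signs_ok),
        n_spiked=n_spiked,
        n_regions=n_regions,
    )
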