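"""Three-phase study orchestration: discovery, validation, generalization.

The monozygotic (MZ) pairs are randomly split at the pair level into a
training cohort (phase-1 discovery, default 12 pairs) and a validation cohort
(phase 2, the remaining pairs, default 7).  Phase 2 retests each phase-1
region on the held-out pairs under the fully adjusted covariate model,
keeping regions with nominal p <= 0.01 and a fold change of the same sign as
in training.  The dizygotic (DZ) pairs form the phase-3 generalization cohort
consumed by the classifier stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .dhmr_stats import (
    DhMRRecord,
    ModelSpec,
    TwinSample,
    anodev_group_test,
    check_pairing,
)
from .windows import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortSplit:
    """Pair-level assignment of twin pairs to the three phases."""

    training_pairs: tuple[str, ...]
    validation_pairs: tuple[str, ...]
    generalization_pairs: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.training_pairs) & set(self.validation_pairs):
            raise ValueError("training and validation pairs overlap")


def split_cohort(
    samples: Sequence[TwinSample], n_train: int = 12, seed: int = 0
) -> CohortSplit:
    """Randomly split MZ pairs into training/validation; DZ pairs generalize.

    The split is uniform over pairs (co-twins are never separated) and
    deterministic given the seed.
    """
    check_pairing(samples)
    mz_pairs = sorted({s.pair_id for s in samples if s.zygosity == "MZ"})
    dz_pairs = sorted({s.pair_id for s in samples if s.zygosity == "DZ"})
    if len(mz_pairs) < n_train + 1:
        raise ValueError(
            f"need at least {n_train + 1} MZ pairs for a {n_train}-pair "
            f"training split; got {len(mz_pairs)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(mz_pairs))
    training = tuple(sorted(mz_pairs[i] for i in order[:n_train]))
    validation = tuple(sorted(mz_pairs[i] for i in order[n_train:]))
    return CohortSplit(training, validation, tuple(dz_pairs), seed)


def subset_by_pairs(
    samples: Sequence[TwinSample], pair_ids: Sequence[str]
) -> list[TwinSample]:
    wanted = set(pair_ids)
    return [s for s in samples if s.pair_id in wanted]


def validate_phase2(
    phase1_records: Sequence[DhMRRecord],
    validation_matrix: np.ndarray,
    validation_samples: Sequence[TwinSample],
    p_max: float = 0.01,
    model: ModelSpec | None = None,
) -> list[DhMRRecord]:
    """Retest phase-1 selected regions on the validation cohort.

    Each record's region counts (rows of ``validation_matrix`` indexed by the
    record's ``region_index``) are tested under the fully adjusted covariate
    model (model 3); with the default 7 validation pairs (14 samples) a pair
    factor on top of the six model-3 covariates would saturate the
    likelihood, so the validation model omits it by default.  A Cox-Reid
    common dispersion is pooled across all rows of ``validation_matrix``.
    Records are confirmed when the validation p-value is <= ``p_max`` and the
    validation fold change has the training sign.
    """
    from .dhmr_stats import build_design, estimate_common_dispersion

    if model is None:
        model = ModelSpec.model(3, include_pair_factor=False)
    check_pairing(validation_samples)
    offsets = np.log(np.array([s.size_factor for s in validation_samples]))
    X_full, _ = build_design(validation_samples, model, include_group=True)
    alpha = estimate_common_dispersion(validation_matrix, X_full, offsets)
    confirmed: list[DhMRRecord] = []
    n_missing = 0
    for rec in phase1_records:
        if not rec.phase1_selected:
            continue
        if not 0 <= rec.region_index < validation_matrix.shape[0]:
            n_missing += 1
            continue
        res = anodev_group_test(
            validation_matrix[rec.region_index], validation_samples, model,
            alpha=alpha,
        )
        train_sign = np.sign(rec.log2fc[f"m{model.model_id}"])
        ok = (
            res["flagged"] == 0.0
            and res["p_value"] <= p_max
            and np.sign(res["log2fc"]) == train_sign
            and train_sign != 0
        )
        rec.p_values["validation"] = res["p_value"]
        rec.log2fc["validation"] = res["log2fc"]
        rec.phase2_confirmed = bool(ok)
        if ok:
            confirmed.append(rec)
    if n_missing:
        logger.warning(
            "%d phase-1 regions absent from the validation matrix", n_missing
        )
    return confirmed


def overlap_regions(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[tuple[int, int, int]]:
    """All (i, j, overlap_bp) pairs with >= 1 bp overlap (half-open).

    Sort-and-sweep over both lists; equivalent to the all-pairs check.
    """
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, iv in enumerate(b):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, j))
    for lst in by_chrom.values():
        lst.sort()
    out: list[tuple[int, int, int]] = []
    for i, iv in enumerate(a):
        for start, end, j in by_chrom.get(iv.chrom, []):
            if start >= iv.end:
                break
            ov = min(iv.end, end) - max(iv.start, start)
            if ov > 0:
                out.append((i, j, ov))
    out.sort()
    return out
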