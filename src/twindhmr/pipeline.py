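"""End-to-end three-phase DhMR pipeline.

Stages: (optionally) simulate a synthetic cohort or load counts and metadata,
estimate size factors, filter noise windows and join candidate regions on the
phase-1 training pairs, run the three-model analysis-of-deviance discovery,
validate on held-out MZ pairs, build the PCA transform and tanh classifier
for the DZ generalization cohort, and annotate confirmed regions.  Every
stage records its counts in a JSON-serializable run summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import io as tio
from .annotate import annotate_region, read_gene_model, summarize_annotations
from .classifier import (
    build_feature_matrix,
    decompose_boundary_transform,
    evaluate_classifier,
    fit_binary_linear_classifier,
    fit_pca,
    project_samples,
    select_separating_dimensions,
)
from .dhmr_stats import ModelSpec, discover_phase1, records_to_frame
from .phases import split_cohort, subset_by_pairs, validate_phase2
from .simulate import (
    SimulationConfig,
    samples_from_frame,
    samples_to_frame,
    simulate_cohort,
)
from .windows import (
    WindowCountMatrix,
    aggregate_region_counts,
    bin_fragments,
    estimate_size_factors,
    filter_noise_windows,
    join_candidate_regions,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters with their canonical defaults."""

    seed: int = 0
    outdir: str = "twindhmr_out"
    # inputs (either simulate block or counts+metadata paths)
    counts_path: str | None = None
    metadata_path: str | None = None
    fragments_dir: str | None = None
    chrom_sizes_path: str | None = None
    gene_model_path: str | None = None
    simulate: dict[str, Any] | None = None
    # stage parameters
    window_size: int = 50
    fragment_size: int = 200
    min_region_size: int = 150
    join_gap: int = 200
    cutoff_fdr: float = 0.05
    signal_fdr: float = 0.10
    phase1_q: float = 0.01
    phase2_p: float = 0.01
    n_train_pairs: int = 12
    n_restarts: int = 1000
    pca_max_rank: int = 10
    pca_dims_override: list[int] | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sim_config_from_dict(d: dict, seed: int) -> SimulationConfig:
    from .simulate import CovariateModel, SpikeSpec
    from .windows import GenomicInterval

    d = dict(d)
    spikes = [
        SpikeSpec(
            GenomicInterval(s["chrom"], s["start"], s["end"]),
            s["log2fc"],
            s.get("penetrance", 1.0),
        )
        for s in d.pop("spikes", [])
    ]
    cov = CovariateModel(**d.pop("covariate_model", {}))
    d.setdefault("seed", seed)
    return SimulationConfig(spikes=spikes, covariate_model=cov, **d)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return (and write) the run summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "seed": config.seed,
        "thresholds": {
            "window_size": config.window_size,
            "fragment_size": config.fragment_size,
            "min_region_size": config.min_region_size,
            "join_gap": config.join_gap,
            "cutoff_fdr": config.cutoff_fdr,
            "signal_fdr": config.signal_fdr,
            "phase1_q": config.phase1_q,
            "phase2_p": config.phase2_p,
            "n_restarts": config.n_restarts,
        },
        "stages": {},
    }

    # --- input stage -----------------------------------------------------
    if config.simulate is not None:
        sim_cfg = _sim_config_from_dict(config.simulate, config.seed)
        cohort = simulate_cohort(sim_cfg)
        matrix, samples = cohort.counts, cohort.samples
        cohort.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        summary["stages"]["simulate"] = {
            "n_windows": matrix.n_windows,
            "n_samples": matrix.n_samples,
            "n_spikes": len(cohort.truth),
        }
    elif config.counts_path and config.metadata_path:
        matrix = tio.read_count_matrix(config.counts_path)
        import pandas as pd

        samples = samples_from_frame(
            pd.read_csv(config.metadata_path, sep="\t")
        )
    else:
        raise ValueError(
            "config must provide either a simulate block or counts_path "
            "and metadata_path"
        )
    tio.write_count_matrix(matrix, outdir / "counts.tsv")
    samples_to_frame(samples).to_csv(
        outdir / "metadata.tsv", sep="\t", index=False
    )

    # --- normalization ----------------------------------------------------
    factors = estimate_size_factors(matrix)
    sf = dict(zip(matrix.sample_ids, factors))
    samples = [
        dataclasses.replace(s, size_factor=sf[s.sample_id]) for s in samples
    ]
    summary["stages"]["normalize"] = {
        "size_factor_min": float(factors.min()),
        "size_factor_max": float(factors.max()),
    }

    # --- split ------------------------------------------------------------
    split = split_cohort(samples, n_train=config.n_train_pairs,
                         seed=config.seed)
    train = subset_by_pairs(samples, split.training_pairs)
    valid = subset_by_pairs(samples, split.validation_pairs)
    dz = subset_by_pairs(samples, split.generalization_pairs)
    mz = train + valid
    summary["stages"]["split"] = {
        "training_pairs": list(split.training_pairs),
        "validation_pairs": list(split.validation_pairs),
        "generalization_pairs": list(split.generalization_pairs),
    }

    # --- window filtering and candidate regions (training cohort) ---------
    train_matrix = matrix.subset_samples([s.sample_id for s in train])
    train_matrix.size_factors = np.array([s.size_factor for s in train])
    signal = filter_noise_windows(
        train_matrix,
        case_ids=[s.sample_id for s in train if s.role == "case"],
        control_ids=[s.sample_id for s in train if s.role == "control"],
        signal_fdr=config.signal_fdr,
        cutoff_fdr=config.cutoff_fdr,
    )
    regions = join_candidate_regions(
        signal, train_matrix,
        join_gap=config.join_gap, min_region_size=config.min_region_size,
    )
    tio.write_regions_bed(regions, outdir / "candidate_regions.bed")
    summary["stages"]["filter"] = {
        "n_signal_windows": len(signal),
        "n_candidate_regions": len(regions),
    }

    if not regions:
        summary["stages"]["short_circuit"] = "no candidate regions"
        tio.write_json(summary, outdir / "run_summary.json")
        return summary

    # --- phase 1 discovery --------------------------------------------
    region_counts = aggregate_region_counts(matrix, regions)

    def cols(subset):
        return [matrix.sample_ids.index(s.sample_id) for s in subset]

    records = discover_phase1(
        region_counts[:, cols(train)], regions, train, alpha_q=config.phase1_q
    )
    records_to_frame(records).to_csv(
        outdir / "phase1_results.tsv", sep="\t", index=False
    )
    n_selected = sum(r.phase1_selected for r in records)
    summary["stages"]["phase1"] = {
        "n_tested": len(records),
        "n_selected": n_selected,
    }

    # --- phase 2 validation ----------------------------------------------
    confirmed = validate_phase2(
        records, region_counts[:, cols(valid)], valid, p_max=config.phase2_p
    )
    records_to_frame(records).to_csv(
        outdir / "phase2_results.tsv", sep="\t", index=False
    )
    summary["stages"]["phase2"] = {"n_confirmed": len(confirmed)}
    if not confirmed:
        summary["stages"]["short_circuit"] = "no confirmed DhMRs"
        tio.write_json(summary, outdir / "run_summary.json")
        return summary

    # --- phase 3: PCA transfer and classifier -----------------------------
    conf_idx = [r.region_index for r in confirmed]
    region_ids = [
        f"{r.interval.chrom}:{r.interval.start}-{r.interval.end}"
        for r in confirmed
    ]
    conf_counts = region_counts[conf_idx]

    mz_cols = cols(mz)
    feats_mz, center, scale, kept_ids = build_feature_matrix(
        conf_counts[:, mz_cols],
        np.array([s.size_factor for s in mz]),
        region_ids,
    )
    transform = fit_pca(feats_mz, kept_ids, center, scale)
    labels_mz = np.array([s.role == "case" for s in mz])
    dims = select_separating_dimensions(
        transform, feats_mz, labels_mz,
        max_rank=config.pca_max_rank,
        override=config.pca_dims_override,
    )
    tio.write_json(transform.to_dict(), outdir / "pca_transform.json")

    kept_rows = [region_ids.index(rid) for rid in kept_ids]
    dz_cols = cols(dz)
    classifier_json: dict[str, Any] = {"selected_dims": list(dims)}
    if dz:
        feats_dz, *_ = build_feature_matrix(
            conf_counts[np.ix_(kept_rows, dz_cols)],
            np.array([s.size_factor for s in dz]),
            kept_ids,
            center=center,
            scale=scale,
        )
        scores_dz = project_samples(transform, feats_dz)
        labels_dz = np.array([s.role == "case" for s in dz])
        clf = fit_binary_linear_classifier(
            scores_dz, labels_dz,
            n_restarts=config.n_restarts, seed=config.seed,
        )
        scores_mz = project_samples(transform, feats_mz)
        metrics = {
            "DZ": evaluate_classifier(clf, scores_dz, labels_dz).to_dict(),
            "MZ": evaluate_classifier(clf, scores_mz, labels_mz).to_dict(),
            "combined": evaluate_classifier(
                clf,
                np.vstack([scores_mz, scores_dz]),
                np.concatenate([labels_mz, labels_dz]),
            ).to_dict(),
        }
        decomposition = decompose_boundary_transform(clf)
        classifier_json.update(
            {
                "weights": {"w1": clf.w1, "w2": clf.w2, "b": clf.b},
                "boundary": {"slope": clf.slope, "intercept": clf.intercept},
                "selection": clf.selection,
                "metrics": metrics,
                "decomposition": decomposition,
            }
        )
        import pandas as pd

        pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in mz + dz],
                "cohort": ["MZ"] * len(mz) + ["DZ"] * len(dz),
                "role": [s.role for s in mz + dz],
                "score1": np.concatenate([scores_mz[:, 0], scores_dz[:, 0]]),
                "score2": np.concatenate([scores_mz[:, 1], scores_dz[:, 1]]),
            }
        ).to_csv(outdir / "scores.tsv", sep="\t", index=False)
        summary["stages"]["phase3"] = {
            "selected_dims": [f"PC{d + 1}" for d in dims],
            "auc_dz": metrics["DZ"]["auc"],
        }
    tio.write_json(classifier_json, outdir / "classifier.json")

    # --- annotation --------------------------------------------------------
    if config.gene_model_path:
        model = read_gene_model(config.gene_model_path)
        ann = [
            annotate_region(r.interval, model, pattern=r.pattern)
            for r in confirmed
        ]
        table = summarize_annotations(ann)
        table.to_csv(outdir / "annotation_summary.tsv", sep="\t", index=False)
        summary["stages"]["annotate"] = {"n_annotated": len(ann)}

    tio.write_json(summary, outdir / "run_summary.json")
    return summary


def summary_checksum(summary: dict) -> str:
    """Stable digest of a run summary for determinism audits."""
    blob = json.dumps(summary, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()
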