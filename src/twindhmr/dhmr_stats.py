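"""Region-level negative-binomial inference for DhMR discovery.

Each candidate region's summed counts across samples are modeled with an
NB2 generalized linear model (log link, log size factors as offsets).  The
case/control effect is tested by analysis of deviance: the likelihood-ratio
statistic between a full model containing the group term and a reduced model
without it, with the dispersion shared between the two fits, is referred to a
chi-square with one degree of freedom.  Three nested covariate models are
fitted: group only (model 1), group plus five leukocyte fractions (model 2),
and model 2 plus age (model 3).  The paired twin design enters all models as
a fixed pair factor.  Regions significant at Benjamini-Hochberg q <= 0.01 in
all three models with a consistent fold-change sign are the phase-1 DhMRs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .windows import GenomicInterval

logger = logging.getLogger(__name__)

LEUKOCYTE_FRACTIONS = ("cd8t", "cd4t", "nk", "bcell", "mono")

ALPHA_FLOOR = 1e-8


@dataclass(frozen=True)
class TwinSample:
    """One co-twin: pair membership, role, and covariates.

    Leukocyte fractions cover five of the six blood subtypes; granulocytes
    are the omitted remainder (avoiding the compositional collinearity).
    """

    sample_id: str
    pair_id: str
    zygosity: Literal["MZ", "DZ"]
    role: Literal["case", "control"]
    cd8t: float
    cd4t: float
    nk: float
    bcell: float
    mono: float
    age: float
    size_factor: float = 1.0

    def __post_init__(self) -> None:
        fractions = [self.cd8t, self.cd4t, self.nk, self.bcell, self.mono]
        if any(f < 0 or f > 1 for f in fractions):
            raise ValueError("leukocyte fractions must lie in [0, 1]")
        if sum(fractions) > 1 + 1e-9:
            raise ValueError("leukocyte fractions must sum to at most 1")
        if self.zygosity not in ("MZ", "DZ"):
            raise ValueError(f"invalid zygosity {self.zygosity!r}")
        if self.role not in ("case", "control"):
            raise ValueError(f"invalid role {self.role!r}")
        if self.size_factor <= 0:
            raise ValueError("size factor must be positive")


def check_pairing(samples: Sequence[TwinSample]) -> None:
    """Every pair must contain exactly one case and one control."""
    by_pair: dict[str, list[str]] = {}
    for s in samples:
        by_pair.setdefault(s.pair_id, []).append(s.role)
    for pair, roles in by_pair.items():
        if sorted(roles) != ["case", "control"]:
            raise ValueError(
                f"pair {pair} does not have exactly one case and one "
                f"control (roles: {roles})"
            )


@dataclass(frozen=True)
class ModelSpec:
    """One of the three nested covariate models."""

    model_id: int
    covariates: tuple[str, ...]
    include_pair_factor: bool = True

    @classmethod
    def model(cls, model_id: int, include_pair_factor: bool = True) -> "ModelSpec":
        if model_id == 1:
            covs: tuple[str, ...] = ()
        elif model_id == 2:
            covs = LEUKOCYTE_FRACTIONS
        elif model_id == 3:
            covs = LEUKOCYTE_FRACTIONS + ("age",)
        else:
            raise ValueError(f"unknown model id {model_id}")
        return cls(model_id, covs, include_pair_factor)


THREE_MODELS = tuple(ModelSpec.model(i) for i in (1, 2, 3))


@dataclass
class DhMRRecord:
    """A candidate/confirmed region with per-model and per-phase statistics."""

    interval: GenomicInterval
    pattern: Literal["hyper", "hypo"]
    log2fc: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    q_values: dict[str, float] = field(default_factory=dict)
    phase1_selected: bool = False
    phase2_confirmed: bool = False
    region_index: int = -1


@dataclass
class NBFit:
    """Result of one NB GLM fit."""

    coefficients: np.ndarray
    columns: list[str]
    log_likelihood: float
    deviance: float
    fitted: np.ndarray
    alpha: float
    converged: bool


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    mu = np.clip(mu, 1e-300, None)
    if alpha <= ALPHA_FLOOR:
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    r = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def _saturated_loglik(y: np.ndarray, alpha: float) -> float:
    mu = np.clip(y.astype(float), 1e-10, None)
    return _nb_loglik(y, mu, alpha)


def fit_nb_glm(
    y: np.ndarray,
    design: np.ndarray,
    offsets: np.ndarray | None = None,
    alpha: float = 0.0,
    columns: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    quiet: bool = False,
) -> NBFit:
    """Fit an NB2 GLM with log link and fixed dispersion by IRLS.

    ``alpha`` is the NB dispersion (variance = mu + alpha * mu**2); alpha = 0
    degenerates to Poisson.  Converges when the largest coefficient change
    falls below ``tol``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if columns is None:
        columns = [f"x{j}" for j in range(p)]
    columns = list(columns)
    offsets = np.zeros(n) if offsets is None else np.asarray(offsets, float)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")

    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the columns whose removal restores full rank
        bad = []
        keep: list[int] = []
        for j in range(p):
            trial = keep + [j]
            if np.linalg.matrix_rank(X[:, trial]) == len(trial):
                keep.append(j)
            else:
                bad.append(columns[j])
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )

    # start from a log-scale least-squares fit
    eta0 = np.log(y + 0.5) - offsets
    beta, *_ = np.linalg.lstsq(X, eta0, rcond=None)

    converged = False
    for it in range(max_iter):
        eta = X @ beta + offsets
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offsets) + (y - mu) / mu
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(
            X * sw[:, np.newaxis], z * sw, rcond=None
        )
        if it >= 30:  # damp late iterations to break IRLS oscillation
            beta_new = 0.5 * (beta_new + beta)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new

    mu = np.exp(np.clip(X @ beta + offsets, -30, 30))
    ll = _nb_loglik(y, mu, alpha)
    deviance = 2.0 * (_saturated_loglik(y, alpha) - ll)
    if not converged:
        logger.log(
            logging.DEBUG if quiet else logging.WARNING,
            "NB GLM did not converge in %d iterations", max_iter,
        )
    return NBFit(
        coefficients=beta,
        columns=columns,
        log_likelihood=ll,
        deviance=deviance,
        fitted=mu,
        alpha=alpha,
        converged=converged,
    )


def estimate_dispersion(
    y: np.ndarray,
    design: np.ndarray,
    offsets: np.ndarray | None = None,
) -> float:
    """Method-of-moments NB dispersion after removing fitted means.

    Fits a Poisson GLM, then matches the residual second moment:
    alpha = (sum((y - mu)^2 * n/(n-p)) - sum(mu)) / sum(mu^2), floored at
    1e-8.  The small-sample factor n/(n-p) compensates for the degrees of
    freedom absorbed by the design (pair factors in particular).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if n < 4:
        raise ValueError("need at least 4 samples to estimate dispersion")
    fit = fit_nb_glm(y, X, offsets, alpha=0.0)
    mu = fit.fitted
    dof_factor = n / max(n - p, 1)
    num = float(np.sum((y - mu) ** 2) * dof_factor - np.sum(mu))
    den = float(np.sum(mu**2))
    if den <= 0:
        return ALPHA_FLOOR
    return max(ALPHA_FLOOR, num / den)


def estimate_common_dispersion(
    region_matrix: np.ndarray,
    design: np.ndarray,
    offsets: np.ndarray | None = None,
    max_regions: int = 300,
    bounds: tuple[float, float] = (1e-4, 5.0),
) -> float:
    """Cox-Reid adjusted common NB dispersion shared across regions.

    Maximizes the sum over regions of the adjusted profile likelihood
    APL(alpha) = loglik(alpha; beta_hat) - 0.5 * log det(X' W X).  The
    adjustment removes the downward bias that per-region coefficient
    estimation (pair factors in particular) otherwise induces; pooling across
    regions makes the estimate precise enough that the analysis-of-deviance
    chi-square reference is calibrated.  At most ``max_regions`` regions
    (evenly spaced) enter the sum.
    """
    from scipy import optimize

    Y = np.asarray(region_matrix, dtype=float)
    X = np.asarray(design, dtype=float)
    n = X.shape[0]
    offsets = np.zeros(n) if offsets is None else np.asarray(offsets, float)
    if Y.ndim == 1:
        Y = Y[np.newaxis, :]
    if Y.shape[0] > max_regions:
        pick = np.linspace(0, Y.shape[0] - 1, max_regions).astype(int)
        Y = Y[pick]

    def apl(y: np.ndarray, alpha: float) -> float:
        fit = fit_nb_glm(y, X, offsets, alpha, quiet=True)
        mu = fit.fitted
        w = mu / (1.0 + alpha * mu)
        _, logdet = np.linalg.slogdet(X.T @ (X * w[:, np.newaxis]))
        return fit.log_likelihood - 0.5 * logdet

    def neg_total(log_alpha: float) -> float:
        a = float(np.exp(log_alpha))
        return -sum(apl(y, a) for y in Y)

    res = optimize.minimize_scalar(
        neg_total,
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-3},
    )
    return float(np.exp(res.x))


def build_design(
    samples: Sequence[TwinSample],
    model: ModelSpec,
    include_group: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept, pair dummies, covariates, case indicator.

    With the pair factor included, covariates that are constant within every
    pair (co-twins share their age, for instance) are exactly collinear with
    the pair dummies: the matching already adjusts for them, so they are
    dropped from the design with a warning instead of breaking the fit.
    """
    n = len(samples)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    if model.include_pair_factor:
        pair_ids = sorted({s.pair_id for s in samples})
        for pid in pair_ids[1:]:  # first pair is the reference level
            cols.append(
                np.array([1.0 if s.pair_id == pid else 0.0 for s in samples])
            )
            names.append(f"pair[{pid}]")
    for cov in model.covariates:
        values = np.array([getattr(s, cov) for s in samples], dtype=float)
        if model.include_pair_factor:
            by_pair: dict[str, list[float]] = {}
            for s, v in zip(samples, values):
                by_pair.setdefault(s.pair_id, []).append(v)
            if all(
                max(vs) - min(vs) < 1e-12 * max(1.0, abs(vs[0]))
                for vs in by_pair.values()
            ):
                warnings.warn(
                    f"covariate {cov} is constant within every pair; "
                    "absorbed by the pair factor and dropped from the design",
                    UserWarning,
                    stacklevel=2,
                )
                continue
        cols.append(values)
        names.append(cov)
    if include_group:
        cols.append(
            np.array([1.0 if s.role == "case" else 0.0 for s in samples])
        )
        names.append("group[case]")
    return np.column_stack(cols), names


def anodev_group_test(
    region_counts: np.ndarray,
    samples: Sequence[TwinSample],
    model: ModelSpec,
    pseudocount: float = 0.5,
    alpha: float | None = None,
    reference: Literal["f", "chisq"] | None = None,
) -> dict[str, float]:
    """Analysis-of-deviance test of the case/control effect for one region.

    Fits the full model (with the group term) and the reduced model (without)
    at a shared dispersion; the deviance difference is the test statistic.
    When ``alpha`` is supplied (normally a Cox-Reid common dispersion pooled
    across regions, see :func:`estimate_common_dispersion`) the statistic is
    referred to chi-square(1).  When ``alpha`` is None the dispersion is the
    per-region method-of-moments estimate, which with only n - p residual
    degrees of freedom is noisy; the statistic is then referred to a
    quasi-likelihood F(1, n - p), scaled by the full-model Pearson
    dispersion, which absorbs that estimation uncertainty (the plain
    chi-square reference would be anti-conservative).  ``reference``
    overrides the automatic choice.  Returns p_value, the deviance
    statistic, log2fc (from shifted normalized group means) and the fitted
    group coefficient.
    """
    y = np.asarray(region_counts, dtype=float)
    roles = np.array([s.role == "case" for s in samples])
    if roles.all() or not roles.any():
        raise ValueError("both case and control samples are required")
    offsets = np.log(np.array([s.size_factor for s in samples]))

    X_full, names_full = build_design(samples, model, include_group=True)
    X_red, _ = build_design(samples, model, include_group=False)

    norm = y / np.exp(offsets)
    m1 = norm[roles].mean()
    m0 = norm[~roles].mean()
    log2fc = float(np.log2((m1 + pseudocount) / (m0 + pseudocount)))

    if reference is None:
        reference = "chisq" if alpha is not None else "f"
    try:
        if alpha is None:
            alpha = estimate_dispersion(y, X_full, offsets)
        full = fit_nb_glm(y, X_full, offsets, alpha, columns=names_full)
        reduced = fit_nb_glm(y, X_red, offsets, alpha)
    except np.linalg.LinAlgError as exc:
        raise
    except ValueError:
        return {"p_value": 1.0, "deviance": 0.0, "log2fc": log2fc,
                "group_coefficient": 0.0, "flagged": 1.0}

    flagged = 0.0
    if not (full.converged and reduced.converged):
        flagged = 1.0
    dev = max(2.0 * (full.log_likelihood - reduced.log_likelihood), 0.0)
    n, p_full = X_full.shape
    if reference == "chisq":
        p = float(stats.chi2.sf(dev, df=1))
    else:
        mu = full.fitted
        pearson = float(np.sum((y - mu) ** 2 / (mu * (1.0 + alpha * mu))))
        df_res = max(n - p_full, 1)
        phi = max(pearson / df_res, ALPHA_FLOOR)
        p = float(stats.f.sf(dev / phi, 1, df_res))
    group_coef = float(full.coefficients[names_full.index("group[case]")])
    return {
        "p_value": p,
        "deviance": dev,
        "log2fc": log2fc,
        "group_coefficient": group_coef,
        "flagged": flagged,
    }


def benjamini_hochberg(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def discover_phase1(
    region_matrix: np.ndarray,
    regions: Sequence,
    samples: Sequence[TwinSample],
    alpha_q: float = 0.01,
    models: Sequence[ModelSpec] = THREE_MODELS,
) -> list[DhMRRecord]:
    """Phase-1 discovery on the training cohort.

    Estimates a Cox-Reid common dispersion per model (pooled across regions),
    tests every region under each covariate model, adjusts p-values per model
    across regions (Benjamini-Hochberg), and selects regions with q <=
    ``alpha_q`` in all models and an identical fold-change sign throughout.
    """
    check_pairing(samples)
    for model in models:
        if model.covariates and any(
            not hasattr(samples[0], c) for c in model.covariates
        ):
            raise ValueError(f"missing covariates for model {model.model_id}")

    offsets = np.log(np.array([s.size_factor for s in samples]))
    n_regions = region_matrix.shape[0]
    results: dict[int, list[dict[str, float]]] = {}
    for model in models:
        X_full, _ = build_design(samples, model, include_group=True)
        alpha = estimate_common_dispersion(region_matrix, X_full, offsets)
        rows = [
            anodev_group_test(region_matrix[i], samples, model, alpha=alpha)
            for i in range(n_regions)
        ]
        # regions with non-converged fits are untestable for selection
        p = np.array(
            [r["p_value"] if r["flagged"] == 0.0 else 1.0 for r in rows]
        )
        q = benjamini_hochberg(p)
        for i, r in enumerate(rows):
            r["q_value"] = float(q[i])
        results[model.model_id] = rows

    records: list[DhMRRecord] = []
    for i in range(n_regions):
        p_values = {}
        q_values = {}
        log2fc = {}
        signs = []
        qs = []
        for model in models:
            r = results[model.model_id][i]
            key = f"m{model.model_id}"
            p_values[key] = r["p_value"]
            q_values[key] = r["q_value"]
            log2fc[key] = r["log2fc"]
            signs.append(np.sign(r["log2fc"]))
            qs.append(r["q_value"])
        consistent = len(set(signs)) == 1 and signs[0] != 0
        selected = consistent and all(q <= alpha_q for q in qs)
        last = f"m{models[-1].model_id}"
        pattern = "hyper" if log2fc[last] > 0 else "hypo"
        region = regions[i]
        interval = getattr(region, "interval", region)
        records.append(
            DhMRRecord(
                interval=interval,
                pattern=pattern,
                log2fc=log2fc,
                p_values=p_values,
                q_values=q_values,
                phase1_selected=bool(selected),
                region_index=i,
            )
        )
    return records


def records_to_frame(records: Sequence[DhMRRecord]) -> pd.DataFrame:
    """Tabulate records (one row per region) for TSV export."""
    rows = []
    for rec in records:
        row = {
            "chrom": rec.interval.chrom,
            "start": rec.interval.start,
            "end": rec.interval.end,
            "pattern": rec.pattern,
        }
        for key in sorted(rec.log2fc):
            row[f"log2fc_{key}"] = rec.log2fc[key]
        for key in sorted(rec.p_values):
            row[f"p_{key}"] = rec.p_values[key]
        for key in sorted(rec.q_values):
            row[f"q_{key}"] = rec.q_values[key]
        row["phase1_selected"] = rec.phase1_selected
        row["phase2_confirmed"] = rec.phase2_confirmed
        rows.append(row)
    return pd.DataFrame(rows)
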