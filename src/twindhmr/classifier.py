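"""Phase-3 classification: PCA transfer and a single-unit tanh classifier.

Confirmed DhMR counts are turned into per-region z-scored log2 normalized
features; PCA on the fitting cohort yields a portable transformation matrix
(centering, scaling and loadings) whose two best case/control-separating
components define a 2-D score space.  Any cohort can be projected into that
space without refitting.  A single tanh unit trained by full-batch gradient
descent with random restarts defines a linear decision boundary; restarts are
resolved lexicographically by (sensitivity, AUC, specificity).  The boundary's
relation to a vertical reference line through the origin is decomposed into a
clockwise rotation plus a vertical translation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class PCATransform:
    """Portable PCA transformation: centering, scaling, loadings, dims.

    ``selected_dims`` are 0-based component indices; reporting uses 1-based
    PC labels (PC1, PC4, ...).
    """

    region_ids: list[str]
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # regions x components, orthonormal columns
    explained_variance: np.ndarray
    selected_dims: tuple[int, int] | None = None

    @property
    def selected_labels(self) -> tuple[str, str]:
        if self.selected_dims is None:
            raise ValueError("dimensions not selected")
        return tuple(f"PC{d + 1}" for d in self.selected_dims)  # type: ignore

    def to_dict(self) -> dict:
        return {
            "region_ids": self.region_ids,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "selected_dims": list(self.selected_dims)
            if self.selected_dims is not None
            else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCATransform":
        return cls(
            region_ids=list(d["region_ids"]),
            center=np.asarray(d["center"], float),
            scale=np.asarray(d["scale"], float),
            loadings=np.asarray(d["loadings"], float),
            explained_variance=np.asarray(d["explained_variance"], float),
            selected_dims=tuple(d["selected_dims"])
            if d.get("selected_dims") is not None
            else None,
        )


@dataclass
class LinearClassifier:
    """A 2-D linear decision boundary w1*s1 + w2*s2 + b = 0.

    Samples with tanh(w1*s1 + w2*s2 + b) > 0 are called cases.
    """

    w1: float
    w2: float
    b: float
    seed: int | None = None
    n_restarts: int = 1
    selection: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.w1 == 0 and self.w2 == 0:
            raise ValueError("weights must not both be zero")

    @property
    def slope(self) -> float:
        """Slope of the boundary line s2 = slope * s1 + intercept."""
        if self.w2 == 0:
            return math.inf
        return -self.w1 / self.w2

    @property
    def intercept(self) -> float:
        if self.w2 == 0:
            return math.nan
        return -self.b / self.w2

    def raw_output(self, scores: np.ndarray) -> np.ndarray:
        s = np.asarray(scores, float)
        return np.tanh(self.w1 * s[:, 0] + self.w2 * s[:, 1] + self.b)

    def predict(self, scores: np.ndarray) -> np.ndarray:
        return (self.raw_output(scores) > 0).astype(int)


@dataclass
class ClassifierMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auc: float
    tp: int
    fp: int
    tn: int
    fn: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def build_feature_matrix(
    region_counts: np.ndarray,
    size_factors: np.ndarray,
    region_ids: Sequence[str],
    center: np.ndarray | None = None,
    scale: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Samples x regions features: z-scored log2(normalized count + 1).

    When ``center``/``scale`` are given (projection of a held-out cohort) they
    are used verbatim; otherwise they are estimated from this cohort.  Regions
    with zero variance in the fitting cohort are dropped with a warning.
    Returns (features, center, scale, kept_region_ids).
    """
    region_counts = np.asarray(region_counts, float)
    norm = region_counts / size_factors[np.newaxis, :]
    logged = np.log2(norm + 1.0).T  # samples x regions
    ids = list(region_ids)
    if center is None:
        center = logged.mean(axis=0)
        scale = logged.std(axis=0, ddof=1)
        keep = scale > 0
        if not keep.all():
            dropped = [ids[i] for i in np.flatnonzero(~keep)]
            logger.warning(
                "dropping %d zero-variance regions: %s",
                len(dropped), dropped[:10],
            )
            logged = logged[:, keep]
            center = center[keep]
            scale = scale[keep]
            ids = [ids[i] for i in np.flatnonzero(keep)]
    else:
        scale = np.asarray(scale, float)
        center = np.asarray(center, float)
        if logged.shape[1] != center.size:
            raise ValueError(
                f"feature width {logged.shape[1]} does not match stored "
                f"center length {center.size}"
            )
    features = (logged - center) / scale
    return features, center, scale, ids


def fit_pca(
    features: np.ndarray, region_ids: Sequence[str],
    center: np.ndarray, scale: np.ndarray,
) -> PCATransform:
    """PCA of the (already centered/scaled) feature matrix via SVD.

    Components are eigenvectors of the sample covariance (divisor n-1),
    eigenvalues descending.  Sign convention: each loading column's
    largest-magnitude entry is positive.
    """
    X = np.asarray(features, float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for PCA")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 regions for PCA")
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("degenerate feature matrix (rank 0)")
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    explained = s**2 / (n - 1)
    loadings = vt.T
    # deterministic signs
    for k in range(loadings.shape[1]):
        col = loadings[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, k] = -col
    return PCATransform(
        region_ids=list(region_ids),
        center=np.asarray(center, float),
        scale=np.asarray(scale, float),
        loadings=loadings,
        explained_variance=explained,
    )


def select_separating_dimensions(
    transform: PCATransform,
    features: np.ndarray,
    labels: np.ndarray,
    n_dims: int = 2,
    max_rank: int = 10,
    override: Sequence[int] | None = None,
) -> tuple[int, ...]:
    """Pick the components that best separate cases from controls.

    A deterministic surrogate for a visual choice: among the first
    ``max_rank`` components, rank by the absolute standardized mean difference
    of case vs control scores; ties favor the lower component index.  An
    explicit ``override`` (0-based indices) bypasses the ranking.
    """
    if override is not None:
        dims = tuple(int(d) for d in override)
    else:
        labels = np.asarray(labels).astype(bool)
        if labels.all() or not labels.any():
            raise ValueError("both classes required to select dimensions")
        n_comp = min(max_rank, transform.loadings.shape[1])
        if n_dims > n_comp:
            raise ValueError(
                f"requested {n_dims} dimensions but only {n_comp} components"
            )
        scores = features @ transform.loadings[:, :n_comp]
        smd = np.empty(n_comp)
        for k in range(n_comp):
            a, b = scores[labels, k], scores[~labels, k]
            pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
            smd[k] = abs(a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
        # stable sort descending by score, ascending by index on ties
        order = np.lexsort((np.arange(n_comp), -smd))
        dims = tuple(int(d) for d in sorted(order[:n_dims]))
    transform.selected_dims = dims  # type: ignore[assignment]
    return dims


def project_samples(
    transform: PCATransform, features: np.ndarray
) -> np.ndarray:
    """Project (already centered/scaled) features onto the selected dims."""
    if transform.selected_dims is None:
        raise ValueError("dimensions not selected")
    features = np.asarray(features, float)
    if features.shape[1] != transform.loadings.shape[0]:
        raise ValueError(
            f"feature width {features.shape[1]} does not match transform "
            f"({transform.loadings.shape[0]} regions)"
        )
    return features @ transform.loadings[:, list(transform.selected_dims)]


def fit_binary_linear_classifier(
    scores: np.ndarray,
    labels: np.ndarray,
    n_restarts: int = 1000,
    seed: int = 0,
    learning_rate: float = 0.05,
    max_epochs: int = 5000,
    tol: float = 1e-9,
) -> LinearClassifier:
    """Train a single tanh unit on 2-D scores with random restarts.

    The unit computes tanh(w1*s1 + w2*s2 + b) against targets +/-1 (case =
    +1) under squared error, trained by full-batch gradient descent with a
    fixed learning rate.  Each restart draws initial parameters from
    U(-1, 1).  All restarts run simultaneously (vectorized); among them the
    classifier maximizing (sensitivity, AUC, specificity) lexicographically
    on the fitting data is selected.  Deterministic given the seed.
    """
    S = np.asarray(scores, float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes required to fit the classifier")
    t = np.where(y, 1.0, -1.0)
    n = S.shape[0]

    rng = np.random.default_rng(seed)
    params = rng.uniform(-1.0, 1.0, size=(n_restarts, 3))  # w1, w2, b
    X = np.column_stack([S, np.ones(n)])  # n x 3

    for _ in range(max_epochs):
        a = X @ params.T  # n x restarts
        o = np.tanh(a)
        # d/da of mean squared error
        g = 2.0 * (o - t[:, None]) * (1.0 - o**2) / n
        grad = g.T @ X  # restarts x 3
        step = learning_rate * grad
        params -= step
        if np.max(np.abs(step)) < tol:
            break

    o = np.tanh(X @ params.T)  # n x restarts
    pred = o > 0
    tp = (pred & y[:, None]).sum(axis=0)
    fn = (~pred & y[:, None]).sum(axis=0)
    tn = (~pred & ~y[:, None]).sum(axis=0)
    fp = (pred & ~y[:, None]).sum(axis=0)
    sens = tp / np.maximum(tp + fn, 1)
    spec = tn / np.maximum(tn + fp, 1)
    auc = np.array([_rank_auc(o[:, r], y) for r in range(n_restarts)])

    order = np.lexsort((np.arange(n_restarts), -spec, -auc, -sens))
    best = int(order[0])
    w1, w2, b = params[best]
    if w1 == 0 and w2 == 0:  # pathological restart; nudge
        w2 = 1e-12
    return LinearClassifier(
        w1=float(w1),
        w2=float(w2),
        b=float(b),
        seed=seed,
        n_restarts=n_restarts,
        selection={
            "sensitivity": float(sens[best]),
            "auc": float(auc[best]),
            "specificity": float(spec[best]),
            "restart_index": best,
        },
    )


def _rank_auc(outputs: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted 1/2."""
    y = np.asarray(labels).astype(bool)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        return math.nan
    ranks = stats.rankdata(outputs)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def evaluate_classifier(
    classifier: LinearClassifier,
    scores: np.ndarray,
    labels: np.ndarray,
) -> ClassifierMetrics:
    """Confusion-based metrics at the tanh sign threshold plus rank AUC."""
    y = np.asarray(labels).astype(bool)
    o = classifier.raw_output(scores)
    pred = o > 0
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    tn = int((~pred & ~y).sum())
    fn = int((~pred & y).sum())
    auc = _rank_auc(o, y)
    if math.isnan(auc):
        logger.warning("single-class labels: AUC undefined")
    return ClassifierMetrics(
        sensitivity=tp / (tp + fn) if tp + fn else math.nan,
        specificity=tn / (tn + fp) if tn + fp else math.nan,
        ppv=tp / (tp + fp) if tp + fp else math.nan,
        npv=tn / (tn + fn) if tn + fn else math.nan,
        auc=auc,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def decompose_boundary_transform(
    classifier: LinearClassifier,
) -> dict[str, float]:
    """Express the boundary as rotation + translation of a vertical reference.

    The reference is the vertical line through the origin (s1 = 0).  A
    clockwise rotation by theta takes it to a line of slope cot(theta);
    theta = atan2(1, m) recovers the rotation for a boundary of slope m, and
    the remaining vertical offset is the boundary intercept.  The round-trip
    (rotate, then translate) is checked to coincide with the target line.
    """
    if classifier.w2 == 0:
        logger.warning(
            "target boundary is vertical; rotation 0, translation along s1"
        )
        return {
            "rotation_deg_clockwise": 0.0,
            "vertical_translation": 0.0,
            "horizontal_translation": -classifier.b / classifier.w1,
            "residual": 0.0,
        }
    m = classifier.slope
    c = classifier.intercept
    theta = math.atan2(1.0, m)
    # round-trip check: rotate the unit vertical direction clockwise by theta
    # and verify it is parallel to (1, m); then translate by (0, c).
    dx = math.sin(theta)
    dy = math.cos(theta)
    residual = abs(dy - m * dx) / math.hypot(1.0, m)
    if residual > 1e-9:
        raise AssertionError(
            f"rotation round-trip failed: residual {residual:.3e}"
        )
    return {
        "rotation_deg_clockwise": math.degrees(theta),
        "vertical_translation": c,
        "residual": residual,
    }
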