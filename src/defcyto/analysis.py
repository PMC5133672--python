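"""Multiparameter statistics for biophysical feature tables.

Implements the statistical stack used downstream of feature extraction:
z-score standardization, expectation-maximization Gaussian-mixture (EMGM)
clustering initialized by k-means, a within/between clustering-error
statistic, greedy backward feature elimination (clustering- or SVM-scored),
SVM training with stratified 5-fold cross validation, ROC curves,
flow-cytometry-style gating (size / diagonal thresholds and a fitted
quantile ellipse), spike-in mixture-fraction prediction, spike-response
slope and limit of detection, pairwise-distance similarity matrices,
PCA/LDA projections, the D3/A stiffness summary, and the bead-based
deformability-to-elastic-modulus calibration curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.spatial.distance import cdist
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

SIZE_GATE_UM = 15.0          # size gate: initial diameter A < 15 um
DIAGONAL_GATE_D3 = 1.4       # diagonal gate: D3 > 1.4 and A < 15 um
DAY0_CONTAINMENT = 0.75      # reference ("day 0") gate contains 75% of its
                             # fitting population


# ---------------------------------------------------------------------------
# standardization


@dataclass
class StandardizedTable:
    """Z-scored feature matrix with the transform retained for reuse."""

    values: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    feature_names: list[str]
    dropped: list[str] = field(default_factory=list)

    def transform(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Apply the stored (training) center/scale to new data."""
        if isinstance(table, pd.DataFrame):
            x = table[self.feature_names].to_numpy(dtype=float)
        else:
            x = np.asarray(table, dtype=float)
        return (x - self.center) / self.scale


def standardize(table: pd.DataFrame, columns: Sequence[str] | None = None
                ) -> StandardizedTable:
    """Per-feature z-scoring; zero-variance columns are excluded with a warning."""
    if columns is None:
        columns = [c for c in table.columns
                   if pd.api.types.is_numeric_dtype(table[c])]
    x = table[list(columns)].to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardize")
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = [c for c, k in zip(columns, keep) if not k]
    if dropped:
        warnings.warn(f"zero-variance features excluded: {dropped}", stacklevel=2)
    cols = [c for c, k in zip(columns, keep) if k]
    return StandardizedTable(
        values=(x[:, keep] - mu[keep]) / sd[keep],
        center=mu[keep], scale=sd[keep], feature_names=cols, dropped=dropped,
    )


# ---------------------------------------------------------------------------
# EM for Gaussian mixtures


@dataclass
class ClusterSolution:
    """Fitted Gaussian mixture: parameters, responsibilities, hard labels."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    responsibilities: np.ndarray
    labels: np.ndarray
    log_likelihood_trace: np.ndarray
    converged: bool


def _gauss_logpdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    p = x.shape[1]
    L, low = cho_factor(cov, lower=True)
    dev = x - mean
    sol = cho_solve((L, low), dev.T)
    maha = np.sum(dev.T * sol, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (p * np.log(2 * np.pi) + logdet + maha)


def emgm(
    x: np.ndarray,
    k: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    ridge: float = 1e-6,
) -> ClusterSolution:
    """Gaussian-mixture clustering by expectation maximization.

    Initialization comes from seeded k-means hard assignments; EM then
    alternates E and M steps for a full-covariance mixture until the mean
    log-likelihood improves by less than ``tol``.  A small ridge is added
    to each covariance diagonal for numerical stability.
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k * (p + 1):
        raise ValueError(f"too few points (n={n}) for k={k}, p={p}")

    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
    resp = np.zeros((n, k))
    resp[np.arange(n), km.labels_] = 1.0

    ll_trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        # M step
        nk = resp.sum(axis=0) + 1e-300
        weights = nk / n
        means = (resp.T @ x) / nk[:, None]
        covs = np.empty((k, p, p))
        for c in range(k):
            dev = x - means[c]
            covs[c] = (resp[:, c][:, None] * dev).T @ dev / nk[c]
            covs[c].flat[:: p + 1] += ridge
        # E step
        log_prob = np.empty((n, k))
        for c in range(k):
            log_prob[:, c] = np.log(weights[c]) + _gauss_logpdf(x, means[c], covs[c])
        norm = logsumexp(log_prob, axis=1)
        resp = np.exp(log_prob - norm[:, None])
        ll = float(norm.sum())
        if ll_trace and abs(ll - ll_trace[-1]) < tol * n:
            ll_trace.append(ll)
            converged = True
            break
        ll_trace.append(ll)
    if not converged:
        warnings.warn("EMGM did not converge within max_iter", stacklevel=2)
    return ClusterSolution(
        k=k, weights=weights, means=means, covariances=covs,
        responsibilities=resp, labels=np.argmax(resp, axis=1),
        log_likelihood_trace=np.array(ll_trace), converged=converged,
    )


def clustering_error(x: np.ndarray, labels: np.ndarray) -> float:
    """Within-class over between-class variation for a two-class labelling.

    E = [sum_{i in C1} ||x_i - m_C1||^2 + sum_{j in C2} ||x_j - m_C2||^2]
        / (n * ||m_C1 - m_C2||^2).

    Scale invariant and intensive (independent of sample size); lower is
    better separated.  Returns ``inf`` when the class means coincide.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("clustering_error requires exactly 2 classes")
    x1, x2 = x[labels == classes[0]], x[labels == classes[1]]
    if len(x1) == 0 or len(x2) == 0:
        raise ValueError("both classes must be nonempty")
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    between = float(np.sum((m1 - m2) ** 2))
    if between == 0:
        return np.inf
    within = float(np.sum((x1 - m1) ** 2) + np.sum((x2 - m2) ** 2))
    return within / (len(x) * between)


# ---------------------------------------------------------------------------
# backward feature elimination


@dataclass
class FeatureRanking:
    """Backward-elimination result: removal order and metric trajectory.

    ``elimination_order`` lists features worst first; ``trajectory[i]`` is
    the metric value after ``i`` removals (index 0 = full feature set).
    ``surviving(m)`` returns the m features kept longest.
    """

    elimination_order: list[str]
    trajectory: list[float]
    mode: str

    def surviving(self, m: int) -> list[str]:
        return self.elimination_order[len(self.elimination_order) - m:]


def _clustering_metric(x: np.ndarray, y: np.ndarray, seed: int) -> float:
    sol = emgm(x, k=2, seed=seed)
    return clustering_error(x, sol.labels)


def _svm_cv_error(x: np.ndarray, y: np.ndarray, seed: int) -> float:
    bundle = train_svm(x, y, kernel="linear", seed=seed)
    return 1.0 - bundle.cv_accuracy


def backward_eliminate(
    table: pd.DataFrame | np.ndarray,
    labels: Sequence,
    metric: str = "clustering_error",
    floor: int = 1,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> FeatureRanking:
    """Greedy worst-first feature elimination.

    At each step every remaining feature is tentatively removed and the
    metric recomputed on the reduced set (clustering mode: re-run EMGM and
    score with the clustering error; SVM mode: refit with stratified
    5-fold CV and score with the misclassification rate).  The removal
    with the best (lowest) metric is committed; ties break toward the
    lowest feature index.  Proceeds down to ``floor`` features.
    """
    if isinstance(table, pd.DataFrame):
        feature_names = list(table.columns)
        x = table.to_numpy(dtype=float)
    else:
        x = np.asarray(table, dtype=float)
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(x.shape[1])]
        feature_names = list(feature_names)
    y = np.asarray(labels)
    p = x.shape[1]
    if p < 2:
        raise ValueError("need at least 2 features")
    if metric in ("clustering_error", "clustering"):
        score: Callable = _clustering_metric
        mode = "clustering"
    elif metric in ("svm_cv_error", "svm"):
        score = _svm_cv_error
        mode = "svm"
    else:
        raise ValueError(f"unknown metric {metric!r}")

    remaining = list(range(p))
    order: list[int] = []
    trajectory = [score(x[:, remaining], y, seed)]
    while len(remaining) > floor:
        best_metric, best_j = np.inf, None
        for j in remaining:  # ascending index => ties keep the lowest index
            sub = [i for i in remaining if i != j]
            try:
                m = score(x[:, sub], y, seed)
            except Exception as e:  # metric failure on this subset
                warnings.warn(f"metric failed without {feature_names[j]}: {e}",
                              stacklevel=2)
                continue
            if m < best_metric:
                best_metric, best_j = m, j
        if best_j is None:
            break
        remaining.remove(best_j)
        order.append(best_j)
        trajectory.append(best_metric)
    order += remaining  # features surviving to the floor, best last
    return FeatureRanking(
        elimination_order=[feature_names[i] for i in order],
        trajectory=trajectory, mode=mode,
    )


# ---------------------------------------------------------------------------
# SVM classification


@dataclass
class ClassifierBundle:
    """Trained classifier plus the preprocessing needed to reuse it."""

    center: np.ndarray
    scale: np.ndarray
    feature_names: list[str]
    kernel: str
    model: SVC
    class_names: list
    cv_accuracy: float
    seed: int
    gamma: float | None = None

    def _prepare(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(table, pd.DataFrame):
            x = table[self.feature_names].to_numpy(dtype=float)
        else:
            x = np.asarray(table, dtype=float)
        return (x - self.center) / self.scale

    def predict(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        return self.model.predict(self._prepare(table))

    def decision_function(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        return self.model.decision_function(self._prepare(table))


def _median_heuristic_gamma(x: np.ndarray, rng: np.random.Generator) -> float:
    m = min(len(x), 1000)
    idx = rng.choice(len(x), size=m, replace=False)
    d = cdist(x[idx], x[idx])
    med = np.median(d[np.triu_indices(m, k=1)])
    return 1.0 / (2.0 * med**2) if med > 0 else 1.0


def train_svm(
    table: pd.DataFrame | np.ndarray,
    labels: Sequence,
    kernel: str = "linear",
    folds: int = 5,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
    C: float = 1.0,
) -> ClassifierBundle:
    """Train an SVM with stratified seeded k-fold cross validation.

    Features are z-scored with training statistics; the Gaussian kernel
    width follows the median heuristic on pairwise distances.  CV accuracy
    is the pooled fraction of held-out points classified correctly; the
    returned model is refit on all data.  Multiclass is one-vs-one.
    """
    if isinstance(table, pd.DataFrame):
        feature_names = list(table.columns)
        x = table.to_numpy(dtype=float)
    else:
        x = np.asarray(table, dtype=float)
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(x.shape[1])]
        feature_names = list(feature_names)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < folds:
        raise ValueError(f"every class needs at least {folds} members")

    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd

    rng = np.random.default_rng(seed)
    if kernel == "gaussian":
        gamma = _median_heuristic_gamma(z, rng)
        make = lambda: SVC(kernel="rbf", gamma=gamma, C=C,
                           decision_function_shape="ovo")
    elif kernel == "linear":
        gamma = None
        make = lambda: SVC(kernel="linear", C=C, decision_function_shape="ovo")
    else:
        raise ValueError(f"unknown kernel {kernel!r}")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, test_idx in skf.split(z, y):
        clf = make().fit(z[train_idx], y[train_idx])
        correct += int(np.sum(clf.predict(z[test_idx]) == y[test_idx]))
    cv_accuracy = correct / len(y)

    model = make().fit(z, y)
    return ClassifierBundle(
        center=mu, scale=sd, feature_names=feature_names, kernel=kernel,
        model=model, class_names=list(classes), cv_accuracy=cv_accuracy,
        seed=seed, gamma=gamma,
    )


def roc(scores: Sequence[float], labels: Sequence) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve and AUC from decision scores.

    Sweeps every distinct score as a threshold (equal scores grouped at
    one threshold).  TPR = TP/(TP+FN), FPR = FP/(TN+FP); AUC by the
    trapezoid rule, equivalent to the tie-corrected Mann-Whitney statistic.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    tp = np.cumsum(y)
    fp = np.cumsum(~y)
    # group tied scores: keep the last index of each tie block
    distinct = np.r_[np.diff(s) != 0, True]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


# ---------------------------------------------------------------------------
# gating


@dataclass
class GateSpec:
    """A gate: a selected region in a low-dimensional parameter subspace."""

    kind: str                                  # size | diagonal | quantile
    size_threshold: float = SIZE_GATE_UM
    d3_threshold: float = DIAGONAL_GATE_D3
    features: tuple[str, str] = ("A", "D3")
    center: np.ndarray | None = None
    shape_matrix: np.ndarray | None = None     # covariance of the reference
    radius: float | None = None                # Mahalanobis radius
    containment: float | None = None
    box_bounds: np.ndarray | None = None       # fallback for singular covariance


def apply_gate(table: pd.DataFrame, gate: GateSpec) -> tuple[np.ndarray, float]:
    """Evaluate a gate on a feature table: boolean mask and gated fraction.

    Size gate: A < 15 um (strict).  Diagonal gate: D3 > 1.4 and A < 15 um
    (strict).  Quantile gate: Mahalanobis distance to the fitted center at
    most the fitted radius.
    """
    if gate.kind == "size":
        _require(table, ["A"])
        mask = table["A"].to_numpy(dtype=float) < gate.size_threshold
    elif gate.kind == "diagonal":
        _require(table, ["A", "D3"])
        mask = ((table["D3"].to_numpy(dtype=float) > gate.d3_threshold)
                & (table["A"].to_numpy(dtype=float) < gate.size_threshold))
    elif gate.kind == "quantile":
        _require(table, list(gate.features))
        x = table[list(gate.features)].to_numpy(dtype=float)
        if gate.box_bounds is not None:
            lo, hi = gate.box_bounds
            mask = np.all((x >= lo) & (x <= hi), axis=1)
        else:
            d = _mahalanobis(x, gate.center, gate.shape_matrix)
            mask = d <= gate.radius + 1e-12
    else:
        raise ValueError(f"unknown gate kind {gate.kind!r}")
    return mask, float(mask.mean())


def _require(table: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"missing required column(s): {missing}")


def _mahalanobis(x: np.ndarray, center: np.ndarray, cov: np.ndarray) -> np.ndarray:
    dev = x - center
    sol = np.linalg.solve(cov, dev.T)
    return np.sqrt(np.sum(dev.T * sol, axis=0))


def fit_quantile_gate(
    reference: pd.DataFrame,
    features: tuple[str, str] = ("A", "D3"),
    containment: float = DAY0_CONTAINMENT,
) -> GateSpec:
    """Fit a reference-population ("day 0"-style) quantile gate.

    The gate is the Mahalanobis ellipse centered at the reference feature
    means with the reference covariance as shape matrix; its radius is the
    empirical ``containment`` quantile of the reference Mahalanobis
    distances, so exactly ``ceil(containment * n)`` reference points fall
    inside or on the boundary.
    """
    if not 0 < containment <= 1:
        raise ValueError("containment must be in (0, 1]")
    _require(reference, list(features))
    x = reference[list(features)].to_numpy(dtype=float)
    n = len(x)
    if n < 20:
        raise ValueError("reference population too small (need n >= 20)")
    center = x.mean(axis=0)
    cov = np.cov(x.T, ddof=1)
    if np.linalg.matrix_rank(cov) < len(features):
        warnings.warn("singular reference covariance; using axis-aligned "
                      "quantile box", stacklevel=2)
        half = (1 - containment) / 2
        lo = np.quantile(x, half, axis=0)
        hi = np.quantile(x, 1 - half, axis=0)
        return GateSpec(kind="quantile", features=features,
                        containment=containment,
                        box_bounds=np.vstack([lo, hi]))
    d = np.sort(_mahalanobis(x, center, cov))
    radius = float(d[int(np.ceil(containment * n)) - 1])
    return GateSpec(kind="quantile", features=features, center=center,
                    shape_matrix=cov, radius=radius, containment=containment)


# ---------------------------------------------------------------------------
# mixture deconvolution, spike response, limit of detection


def predict_fractions(bundle: ClassifierBundle, table: pd.DataFrame | np.ndarray
                      ) -> dict:
    """Classify every row and report the per-class fraction (sums to 1)."""
    if len(table) == 0:
        raise ValueError("empty table")
    pred = bundle.predict(table)
    n = len(pred)
    return {c: float(np.sum(pred == c)) / n for c in bundle.class_names}


def spike_response(spiked: Sequence[float], predicted: Sequence[float]
                   ) -> tuple[float, float]:
    """OLS slope and intercept of predicted vs spiked fraction.

    A slope of 1 with intercept 0 is the ideal response; a shallower slope
    means the assay underreports changes in the spiked ratio.
    """
    s = np.asarray(spiked, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if len(np.unique(s)) < 3:
        raise ValueError("need at least 3 distinct spiked fractions")
    slope, intercept = np.polyfit(s, p, 1)
    return float(slope), float(intercept)


def limit_of_detection(slope: float, sd_max: float) -> float:
    """Limit of detection: inverse of the analytical sensitivity.

    Analytical sensitivity is the spike-response slope normalized by the
    maximum (across mixing ratios) replicate SD of the classified
    fraction; the LOD is its inverse, sd_max / slope, in fraction units.
    """
    if slope <= 0:
        raise ValueError("undefined LOD: slope must be positive")
    if sd_max < 0:
        raise ValueError("sd_max must be >= 0")
    return sd_max / slope


# ---------------------------------------------------------------------------
# unsupervised summaries and projections


def similarity_matrix(x: np.ndarray, labels: Sequence | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Euclidean distance matrix over rows (standardized data).

    When labels are given, rows are ordered by class and then original
    order, so subpopulations appear as blocks of small distances.
    Returns (distance matrix, row order used).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 rows")
    if labels is not None:
        order = np.argsort(np.asarray(labels), kind="stable")
    else:
        order = np.arange(len(x))
    d = cdist(x[order], x[order])
    return d, order


def pca_project(x: np.ndarray, n_components: int
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA scores, loadings and explained-variance ratios.

    Loadings are orthonormal columns; each component's sign is fixed so
    its largest-magnitude loading entry is positive.
    """
    from sklearn.decomposition import PCA

    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if n_components > p:
        raise ValueError("n_components cannot exceed the number of features")
    if n <= p:
        raise ValueError("need more rows than features")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(x)
    loadings = pca.components_.T.copy()
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return scores, loadings, pca.explained_variance_ratio_


def lda_project(
    x: np.ndarray, labels: Sequence, n_components: int | None = None,
    ridge: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear discriminant projection maximizing between/within scatter.

    Solves the generalized eigenproblem S_b v = lambda S_w v (with a small
    ridge on S_w); at most (number of classes - 1) discriminant directions
    exist.  Returns (projected scores, directions as columns).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    max_comp = len(classes) - 1
    if n_components is None:
        n_components = max_comp
    n_components = min(n_components, max_comp)
    p = x.shape[1]
    gm = x.mean(axis=0)
    sw = np.zeros((p, p))
    sb = np.zeros((p, p))
    for c in classes:
        xc = x[y == c]
        mc = xc.mean(axis=0)
        sw += (xc - mc).T @ (xc - mc)
        dm = (mc - gm)[:, None]
        sb += len(xc) * (dm @ dm.T)
    sw.flat[:: p + 1] += ridge
    vals, vecs = eigh(sb, sw)
    idx = np.argsort(vals)[::-1][:n_components]
    w = vecs[:, idx]
    w /= np.linalg.norm(w, axis=0)
    return x @ w, w


def deformability_size_ratio(table: pd.DataFrame) -> float:
    """Median of per-cell D3/A — a scalar summary of relative stiffness.

    Normalizing deformability by diameter compensates for size-dependent
    differences in the applied hydrodynamic stress.  Rows with
    nonpositive diameter are excluded with a warning.
    """
    _require(table, ["A", "D3"])
    a = table["A"].to_numpy(dtype=float)
    d3 = table["D3"].to_numpy(dtype=float)
    ok = a > 0
    if not ok.all():
        warnings.warn(f"excluded {int((~ok).sum())} rows with nonpositive A",
                      stacklevel=2)
    if not ok.any():
        raise ValueError("no rows with positive A")
    return float(np.median(d3[ok] / a[ok]))


# ---------------------------------------------------------------------------
# stiffness calibration


@dataclass
class CalibrationCurve:
    """Bead-derived standard curve mapping deformability to modulus (kPa).

    Log-linear model log10(E) = alpha + beta * D fitted on calibration
    beads of known (AFM-measured) elastic modulus.
    """

    alpha: float
    beta: float
    residual: float
    d_range: tuple[float, float]
    e_range: tuple[float, float]

    def map(self, d: np.ndarray | float) -> np.ndarray:
        """Deformability -> effective elastic modulus (kPa)."""
        d_arr = np.asarray(d, dtype=float)
        if np.any(d_arr < self.d_range[0]) or np.any(d_arr > self.d_range[1]):
            warnings.warn("deformability outside the calibrated range; "
                          "extrapolating", stacklevel=2)
        return 10.0 ** (self.alpha + self.beta * d_arr)

    def inverse(self, e: np.ndarray | float) -> np.ndarray:
        """Elastic modulus (kPa) -> deformability."""
        return (np.log10(np.asarray(e, dtype=float)) - self.alpha) / self.beta


def fit_stiffness_calibration(
    bead_deformability: Sequence[float], bead_modulus_kpa: Sequence[float]
) -> CalibrationCurve:
    """Least-squares fit of log10(modulus) on bead deformability.

    Calibration beads (e.g. agarose, moduli spanning roughly 0.2-40 kPa)
    anchor the deformability scale to an absolute elastic modulus.  A
    warning is issued when the fit explains less than half the variance.
    """
    d = np.asarray(bead_deformability, dtype=float)
    e = np.asarray(bead_modulus_kpa, dtype=float)
    if len(d) < 3:
        raise ValueError("need at least 3 calibration beads")
    if np.any(e <= 0):
        raise ValueError("bead moduli must be positive")
    loge = np.log10(e)
    beta, alpha = np.polyfit(d, loge, 1)
    pred = alpha + beta * d
    ss_res = float(np.sum((loge - pred) ** 2))
    ss_tot = float(np.sum((loge - loge.mean()) ** 2))
    if ss_tot > 0 and 1 - ss_res / ss_tot < 0.5:
        warnings.warn("poor calibration fit (R^2 < 0.5)", stacklevel=2)
    return CalibrationCurve(
        alpha=float(alpha), beta=float(beta), residual=ss_res,
        d_range=(float(d.min()), float(d.max())),
        e_range=(float(e.min()), float(e.max())),
    )
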