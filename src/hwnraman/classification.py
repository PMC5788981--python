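"""Dense-cancer vs non-diagnostic classification of Raman spectra.

The clinical contrast: a biopsy sample is worth collecting only if it holds
enough cancer cells for reliable molecular diagnosis, operationalized as a
cancer-cell fraction above 60%. Samples above the threshold are *dense
cancer* (the positive class); normal and infiltrated tissue are pooled into
the *non-diagnostic* class.

The classifier is a support vector machine on a p-value-screened subset of
spectral channels: each channel is scored by the two-sided p-value of its
point-biserial correlation with the binary label (equivalent to the pooled
two-sample t-test), and the k channels with the smallest p-values are kept
(k = 141 by default). Evaluation is leave-one-out cross-validation: each
spectrum is scored by an SVM trained on all the others. By default feature
selection and feature standardization are re-run inside every fold, which
avoids selection leakage; a global-selection mode (screen once on the full
data) is available for comparison and is recorded in provenance.

The ROC curve is built over thresholds at midpoints between distinct sorted
scores (plus infinite sentinels); its trapezoid-rule area equals the
Mann-Whitney concordance probability with ties counted one half. The
reported operating point minimizes the Euclidean distance to the ideal
corner (FPR 0, TPR 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.svm import SVC

__all__ = [
    "POSITIVE_LABEL",
    "NEGATIVE_LABEL",
    "SvmParams",
    "CVResult",
    "RocCurve",
    "PerformanceReport",
    "binarize",
    "feature_pvalues",
    "select_features",
    "train_and_score",
    "loocv",
    "roc_and_auc",
    "choose_operating_point",
    "performance_report",
    "evaluate",
]

POSITIVE_LABEL = "dense_cancer"
NEGATIVE_LABEL = "non_diagnostic"

DENSE_FRACTION_THRESHOLD = 0.60
DEFAULT_N_FEATURES = 141


@dataclass(frozen=True)
class SvmParams:
    """SVM and selection settings: linear kernel, C = 1, within-fold
    standardization, in-fold screening of ``n_features`` channels."""

    kernel: str = "linear"
    C: float = 1.0
    gamma: str | float = "scale"
    n_features: int = DEFAULT_N_FEATURES
    selection: str = "in-fold"  # or "global"
    standardize: bool = True


@dataclass(frozen=True)
class CVResult:
    scores: np.ndarray = field(repr=False)
    fold_ids: np.ndarray = field(repr=False)
    degenerate_folds: tuple[int, ...] = ()
    provenance: tuple[str, ...] = ()


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    thresholds: np.ndarray = field(repr=False)
    auc: float = 0.0


@dataclass(frozen=True)
class PerformanceReport:
    accuracy: float
    sensitivity: float
    specificity: float
    tp: int
    fn: int
    tn: int
    fp: int
    threshold: float
    auc: float


def binarize(labels_or_fractions) -> np.ndarray:
    """Map tissue labels or cancer fractions to the binary clinical classes.

    ``dense_cancer`` (fraction > 0.60) is positive; normal and infiltrated
    (fraction <= 0.60) collapse to ``non_diagnostic``.
    """
    items = list(labels_or_fractions)
    out = []
    for item in items:
        value = getattr(item, "value", item)
        if isinstance(value, str):
            if value == "dense_cancer":
                out.append(POSITIVE_LABEL)
            elif value in ("normal", "infiltrated", NEGATIVE_LABEL):
                out.append(NEGATIVE_LABEL)
            else:
                raise ValueError(f"unknown tissue label {value!r}")
        else:
            f = float(value)
            if not 0.0 <= f <= 1.0:
                raise ValueError("cancer fraction must lie in [0, 1]")
            out.append(POSITIVE_LABEL if f > DENSE_FRACTION_THRESHOLD else NEGATIVE_LABEL)
    return np.array(out, dtype=object)


def _as_indicator(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "bif":
        return y.astype(float)
    return (y == POSITIVE_LABEL).astype(float)


def feature_pvalues(X: np.ndarray, y) -> np.ndarray:
    """Two-sided p-value per channel of the point-biserial correlation with the
    binary label — algebraically the pooled two-sample t-test p-value.

    Constant channels get p = 1 by convention.
    """
    X = np.asarray(X, dtype=float)
    ind = _as_indicator(y)
    classes = np.unique(ind)
    if classes.size != 2:
        raise ValueError("both classes must be present")
    n = X.shape[0]
    if n < 3:  # pooled t needs n - 2 >= 1 degrees of freedom
        raise ValueError("need at least 3 samples for feature screening")
    a = X[ind == classes[0]]
    b = X[ind == classes[1]]
    na, nb = a.shape[0], b.shape[0]
    mean_diff = a.mean(axis=0) - b.mean(axis=0)
    ssa = ((a - a.mean(axis=0)) ** 2).sum(axis=0)
    ssb = ((b - b.mean(axis=0)) ** 2).sum(axis=0)
    dof = na + nb - 2
    pooled_var = (ssa + ssb) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_diff / np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(np.abs(t), dof)
    constant = (ssa + ssb) == 0
    # constant column: no variation around class means; if the class means
    # also agree the statistic is 0/0 -> p = 1; perfectly separated constant
    # columns get p = 0
    p = np.where(constant & (mean_diff == 0), 1.0, p)
    p = np.where(constant & (mean_diff != 0), 0.0, p)
    return p


def select_features(pvalues: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k smallest p-values, ties broken by lower column index."""
    pvalues = np.asarray(pvalues, dtype=float)
    if not 1 <= k <= pvalues.size:
        raise ValueError(f"k must lie in [1, {pvalues.size}], got {k}")
    order = np.argsort(pvalues, kind="stable")  # stable sort = index tie-break
    return np.sort(order[:k])


def _fit_svm(X_train, ind_train, params: SvmParams):
    # tight solver tolerance so decision scores are invariant to training-row
    # order well below any reporting precision
    clf = SVC(kernel=params.kernel, C=params.C, gamma=params.gamma, tol=1e-8)
    clf.fit(X_train, ind_train)
    return clf


def train_and_score(
    X_train: np.ndarray,
    y_train,
    X_test: np.ndarray,
    params: SvmParams | None = None,
) -> np.ndarray:
    """Fit the screened, standardized SVM on the training rows and return
    signed decision scores for the test rows (positive = dense-cancer side).

    Feature selection and standardization statistics are computed from
    ``X_train`` only and applied to ``X_test``.
    """
    params = params or SvmParams()
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    ind = _as_indicator(y_train)
    if np.unique(ind).size < 2:
        raise ValueError("training set must contain both classes")

    k = min(params.n_features, X_train.shape[1])
    cols = select_features(feature_pvalues(X_train, ind), k)
    Xtr, Xte = X_train[:, cols], X_test[:, cols]
    if params.standardize:
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (Xtr - mu) / sd
        Xte = (Xte - mu) / sd
    clf = _fit_svm(Xtr, ind, params)
    return clf.decision_function(Xte)


def loocv(X: np.ndarray, y, params: SvmParams | None = None) -> CVResult:
    """Leave-one-out cross-validation: score each spectrum with an SVM trained
    on all the others.

    With ``selection='in-fold'`` (default) channel screening is redone per
    fold on the training rows only; ``'global'`` screens once on the full
    data before cross-validating (optimistically biased on noise; provided
    for comparison). A degenerate single-class training fold falls back to
    the majority sign and is flagged.
    """
    params = params or SvmParams()
    X = np.asarray(X, dtype=float)
    ind = _as_indicator(y)
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 spectra")
    if np.unique(ind).size < 2:
        raise ValueError("both classes must be present")

    if params.selection == "global":
        cols = select_features(
            feature_pvalues(X, ind), min(params.n_features, X.shape[1])
        )
        X_eff = X[:, cols]
        fold_params = SvmParams(
            kernel=params.kernel, C=params.C, gamma=params.gamma,
            n_features=X_eff.shape[1], selection="global",
            standardize=params.standardize,
        )
    elif params.selection == "in-fold":
        X_eff = X
        fold_params = params
    else:
        raise ValueError(f"unknown selection mode {params.selection!r}")

    scores = np.empty(n)
    degenerate: list[int] = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_tr = ind[mask]
        if np.unique(y_tr).size < 2:
            majority = 1.0 if y_tr.mean() >= 0.5 else 0.0
            scores[i] = 1.0 if majority == 1.0 else -1.0
            degenerate.append(i)
            continue
        scores[i] = train_and_score(X_eff[mask], y_tr, X_eff[i], fold_params)[0]
    return CVResult(
        scores=scores,
        fold_ids=np.arange(n),
        degenerate_folds=tuple(degenerate),
        provenance=(f"selection={params.selection}", f"kernel={params.kernel}",
                    f"n_features={params.n_features}", f"C={params.C}"),
    )


def roc_and_auc(scores: np.ndarray, y) -> RocCurve:
    """ROC curve over midpoint thresholds and its trapezoid-rule AUC.

    Thresholds sit at midpoints between distinct sorted scores, with +/-inf
    sentinels, so every achievable (FPR, TPR) pair appears exactly once; the
    curve runs from (0, 0) to (1, 1). The trapezoid AUC equals the
    Mann-Whitney concordance probability with ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    ind = _as_indicator(y)
    n_pos = int(ind.sum())
    n_neg = int(ind.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([np.inf], mids[::-1], [-np.inf]))
    fpr = np.empty(thresholds.size)
    tpr = np.empty(thresholds.size)
    for j, th in enumerate(thresholds):
        pred = scores >= th
        tpr[j] = (pred & (ind == 1)).sum() / n_pos
        fpr[j] = (pred & (ind == 0)).sum() / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def choose_operating_point(roc: RocCurve) -> tuple[float, float, float]:
    """Operating point closest (Euclidean) to the ideal corner (FPR 0, TPR 1).

    Ties broken by higher TPR, then lower FPR. Returns
    ``(threshold, fpr, tpr)``.
    """
    if roc.fpr.size == 0:
        raise ValueError("empty ROC curve")
    dist = np.sqrt(roc.fpr**2 + (1.0 - roc.tpr) ** 2)
    # lexicographic: min distance, then max tpr, then min fpr
    order = np.lexsort((roc.fpr, -roc.tpr, dist))
    best = order[0]
    return float(roc.thresholds[best]), float(roc.fpr[best]), float(roc.tpr[best])


def performance_report(
    scores: np.ndarray, y, threshold: float, auc: float = np.nan
) -> PerformanceReport:
    """Confusion counts and accuracy/sensitivity/specificity at a threshold.

    Dense cancer is the positive class; a spectrum is called positive when
    its decision score is at or above the threshold.
    """
    scores = np.asarray(scores, dtype=float)
    ind = _as_indicator(y)
    pred = scores >= threshold
    tp = int((pred & (ind == 1)).sum())
    fn = int((~pred & (ind == 1)).sum())
    tn = int((~pred & (ind == 0)).sum())
    fp = int((pred & (ind == 0)).sum())
    n = tp + fn + tn + fp
    return PerformanceReport(
        accuracy=(tp + tn) / n,
        sensitivity=tp / (tp + fn) if tp + fn else np.nan,
        specificity=tn / (tn + fp) if tn + fp else np.nan,
        tp=tp, fn=fn, tn=tn, fp=fp,
        threshold=threshold, auc=float(auc),
    )


def evaluate(X: np.ndarray, y, params: SvmParams | None = None
             ) -> tuple[CVResult, RocCurve, PerformanceReport]:
    """LOOCV -> ROC/AUC -> corner-closest operating point -> report."""
    cv = loocv(X, y, params)
    roc = roc_and_auc(cv.scores, y)
    threshold, _, _ = choose_operating_point(roc)
    report = performance_report(cv.scores, y, threshold, auc=roc.auc)
    return cv, roc, report
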