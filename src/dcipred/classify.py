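"""Classifiers, ROC machinery, and the derivation/validation protocol.

Three scoring classifiers are exposed: partial least squares regression of the
binary label on the first latent components (PLS), and class-weighted linear
and RBF-kernel support vector machines (SVM-L, SVM-K) whose class weights are
inversely proportional to class frequency to absorb outcome imbalance.

The evaluation protocol mirrors the study design: an 80/20 stratified split
into derivation and validation; internal validation by repeated stratified
12.5% hold-outs of the derivation set (median AUC over the runs, every fitted
step — imputation, standardization, mRMR, classifier — refit on the 87.5%
training part of each run); and a single validation AUC with a Hanley-McNeil
95% confidence interval on the untouched 20%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats as sps
from sklearn.cross_decomposition import PLSRegression
from sklearn.svm import SVC

from .features import FeatureMatrix, impute_and_standardize
from .selection import mrmr_rank
from .timeseries import Cohort


@dataclass
class ModelSpec:
    """What to fit: classifier family, hyperparameters, optional mRMR step."""

    classifier: str = "PLS"            # PLS | SVM-L | SVM-K
    pls_components: int = 3
    svm_c: float = 1.0
    rbf_gamma: Optional[float] = None  # None -> median heuristic
    mrmr_k: Optional[int] = None       # None -> no selection step
    mrmr_criterion: str = "MID"
    name: str = ""

    def __post_init__(self) -> None:
        if self.classifier not in ("PLS", "SVM-L", "SVM-K"):
            raise ValueError("classifier must be PLS, SVM-L or SVM-K")
        if self.pls_components <= 0 or self.svm_c <= 0:
            raise ValueError("hyperparameters must be positive")


@dataclass
class EvalResult:
    auc: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    per_run_aucs: list = field(default_factory=list)
    n_pos: int = 0
    n_neg: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0,1]")


# ---------------------------------------------------------------------------
# fitting and scoring
# ---------------------------------------------------------------------------

class _FittedModel:
    """A fitted transform + optional mRMR column subset + scorer."""

    def __init__(self, spec, transform, columns, scorer):
        self.spec = spec
        self.transform = transform
        self.columns = columns
        self._scorer = scorer

    def score(self, F: FeatureMatrix) -> np.ndarray:
        Xt = self.transform.apply(F).values
        if self.columns is not None:
            Xt = Xt[:, self.columns]
        return self._scorer(Xt)


def _median_heuristic_gamma(X: np.ndarray) -> float:
    n = X.shape[0]
    idx = np.random.default_rng(0).choice(n, size=min(n, 200), replace=False)
    sub = X[idx]
    d2 = np.sum((sub[:, None, :] - sub[None, :, :]) ** 2, axis=-1)
    med = np.median(d2[np.triu_indices_from(d2, k=1)])
    return 1.0 / max(med, 1e-12)


def fit(spec: ModelSpec, F: FeatureMatrix, labels: np.ndarray,
        seed: int = 0) -> _FittedModel:
    """Fit imputation/standardization, optional mRMR, and the classifier.

    All statistics come from the rows of ``F`` only. PLS regresses the 0/1
    label on the first ``pls_components`` latent components and scores by the
    predicted response; SVMs score by the signed decision value with class
    weights proportional to inverse class frequency.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 examples of each class")
    Ft, _, tf = impute_and_standardize(F)
    X = Ft.values
    columns = None
    if spec.mrmr_k is not None:
        k = min(spec.mrmr_k, X.shape[1])
        columns = mrmr_rank(X, y, criterion=spec.mrmr_criterion, k=k)
        X = X[:, columns]
    if spec.classifier == "PLS":
        c = min(spec.pls_components, X.shape[1], X.shape[0] - 1)
        model = PLSRegression(n_components=c, scale=False)
        model.fit(X, y.astype(float))
        scorer = lambda Z: model.predict(Z).ravel()
    else:
        kernel = "linear" if spec.classifier == "SVM-L" else "rbf"
        gamma = (spec.rbf_gamma if spec.rbf_gamma is not None
                 else _median_heuristic_gamma(X)) if kernel == "rbf" else "scale"
        model = SVC(C=spec.svm_c, kernel=kernel, gamma=gamma,
                    class_weight="balanced", random_state=seed)
        model.fit(X, y)
        scorer = lambda Z: model.decision_function(Z)
    return _FittedModel(spec, tf, columns, scorer)


# ---------------------------------------------------------------------------
# ROC machinery
# ---------------------------------------------------------------------------

def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability a random positive outscores a random negative, ties 1/2.

    Computed from midranks (equivalent to the Mann-Whitney statistic).
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def hanley_se(a: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of an AUC."""
    q1 = a / (2.0 - a)
    q2 = 2.0 * a ** 2 / (1.0 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a ** 2)
           + (n_neg - 1) * (q2 - a ** 2)) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def auc_ci_hanley(a: float, n_pos: int, n_neg: int,
                  level: float = 0.95) -> tuple:
    """Normal-approximation CI from the Hanley-McNeil SE, clipped to [0,1]."""
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one case per class")
    se = hanley_se(a, n_pos, n_neg)
    z = sps.norm.ppf(0.5 + level / 2.0)
    return float(np.clip(a - z * se, 0.0, 1.0)), float(np.clip(a + z * se, 0.0, 1.0))


def compare_auc_correlated(scores_a: np.ndarray, scores_b: np.ndarray,
                           labels: np.ndarray, method: str = "hanley") -> tuple:
    """Two-sided comparison of two ROC areas measured on the same cases.

    ``method='hanley'``: z = (A1-A2)/sqrt(SE1^2+SE2^2-2 r SE1 SE2) with the
    score correlation r taken as the average of the within-positive and
    within-negative Pearson correlations (the published correlation table is
    approximated by this average, which it tracks closely).
    ``method='delong'``: DeLong's covariance of the paired placement values.
    """
    y = np.asarray(labels, dtype=int)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape or sa.shape != y.shape:
        raise ValueError("score vectors must cover identical cases")
    a1, a2 = auc(sa, y), auc(sb, y)
    if np.array_equal(sa, sb):
        return 0.0, 1.0
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if method == "hanley":
        se1 = hanley_se(a1, n_pos, n_neg)
        se2 = hanley_se(a2, n_pos, n_neg)

        def _safe_corr(u, v):
            if np.std(u) == 0 or np.std(v) == 0:
                return 0.0
            return float(np.corrcoef(u, v)[0, 1])

        r = 0.5 * (_safe_corr(sa[y == 1], sb[y == 1])
                   + _safe_corr(sa[y == 0], sb[y == 0]))
        var = se1 ** 2 + se2 ** 2 - 2.0 * r * se1 * se2
        if var <= 0:
            raise ValueError("degenerate variance in correlated AUC comparison")
        z = (a1 - a2) / np.sqrt(var)
    elif method == "delong":
        # placement values: V10 per positive, V01 per negative
        def _placements(s):
            pos, neg = s[y == 1], s[y == 0]
            v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n_neg
                            for p in pos])
            v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / n_pos
                            for q in neg])
            return v10, v01
        v10a, v01a = _placements(sa)
        v10b, v01b = _placements(sb)
        s10 = np.cov(np.stack([v10a, v10b]))
        s01 = np.cov(np.stack([v01a, v01b]))
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n_pos \
            + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n_neg
        if var <= 0:
            raise ValueError("degenerate variance in correlated AUC comparison")
        z = (a1 - a2) / np.sqrt(var)
    else:
        raise ValueError("method must be 'hanley' or 'delong'")
    p = float(2.0 * sps.norm.sf(abs(z)))
    return float(z), p


# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------

def _stratified_split_idx(y: np.ndarray, fraction: float,
                          rng: np.random.Generator) -> tuple:
    first, second = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if idx.size < 2:
            raise ValueError("each class needs at least 2 members")
        idx = rng.permutation(idx)
        # proportional to rounding, but never empty on either side
        n_first = min(max(int(round(fraction * idx.size)), 1), idx.size - 1)
        first.extend(idx[:n_first])
        second.extend(idx[n_first:])
    return np.sort(np.array(first, int)), np.sort(np.array(second, int))


def split_cohort(cohort: Cohort, fraction: float = 0.8, seed: int = 0) -> tuple:
    """Stratified (by DCI label) split into derivation and validation cohorts.

    Class proportions are preserved to within rounding; the split is
    disjoint, exhaustive, and deterministic per seed.
    """
    y = cohort.labels()
    rng = np.random.default_rng(seed)
    di, vi = _stratified_split_idx(y, fraction, rng)
    return (cohort.subset(di, provenance="derivation"),
            cohort.subset(vi, provenance="validation"))


def cv_median_auc(F: FeatureMatrix, labels: np.ndarray, spec: ModelSpec,
                  runs: int = 100, holdout: float = 0.125,
                  seed: int = 0) -> EvalResult:
    """Repeated stratified hold-out on the derivation feature matrix.

    Each run holds out ``holdout`` of the rows (stratified); imputation,
    standardization, mRMR and the classifier are all refit on the remaining
    rows only; the hold-out AUC is recorded. Reports the median AUC over the
    runs. A run whose hold-out lacks a class is re-drawn (up to 10 retries).
    """
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    aucs = []
    for run in range(runs):
        for attempt in range(10):
            hold_idx, train_idx = _stratified_split_idx(y, holdout, rng)
            if len(np.unique(y[hold_idx])) == 2 and \
                    min(np.bincount(y[train_idx], minlength=2)) >= 2:
                break
        else:
            raise ValueError("could not draw a two-class hold-out set")
        model = fit(spec, F.rows(train_idx), y[train_idx],
                    seed=int(rng.integers(0, 2 ** 31)))
        scores = model.score(F.rows(hold_idx))
        aucs.append(auc(scores, y[hold_idx]))
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    return EvalResult(float(np.median(aucs)), per_run_aucs=aucs,
                      n_pos=n_pos, n_neg=n_neg)


def evaluate_validation(train_F: FeatureMatrix, train_y: np.ndarray,
                        val_F: FeatureMatrix, val_y: np.ndarray,
                        spec: ModelSpec, seed: int = 0,
                        return_scores: bool = False):
    """Fit on the full derivation matrix, evaluate once on validation.

    No fitted step sees the validation rows. Returns the validation AUC with
    its Hanley 95% CI (and optionally the validation scores).
    """
    model = fit(spec, train_F, np.asarray(train_y, int), seed=seed)
    scores = model.score(val_F)
    vy = np.asarray(val_y, int)
    a = auc(scores, vy)
    lo, hi = auc_ci_hanley(a, int(vy.sum()), int((1 - vy).sum()))
    res = EvalResult(a, lo, hi, n_pos=int(vy.sum()), n_neg=int((1 - vy).sum()))
    if return_scores:
        return res, scores
    return res
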