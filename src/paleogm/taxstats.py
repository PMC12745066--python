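"""Inference layer for taxonomic attribution from PC scores.

Covers the statistical battery applied to the comparative samples:
pairwise permutation tests on the first three PC scores with Holm
adjustment, the Shapiro-Wilk normality gate choosing between linear and
quadratic discriminant analysis, PC-count selection inside the 70-90%
cumulative-variance window, leave-one-out cross-validated discriminant
accuracy, posterior probabilities for query specimens, Pearson
correlations of Neanderthal scores with geography, and ANOVA /
Kruskal-Wallis comparisons across Marine Isotope Stage groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.model_selection import LeaveOneOut, cross_val_predict
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05
N_PERMUTATIONS = 10_000
N_GATE_PCS = 3
VARIANCE_WINDOW = (0.70, 0.90)


class InsufficientDataError(ValueError):
    pass


class WindowEmptyError(ValueError):
    pass


class SingularCovarianceError(ValueError):
    pass


@dataclass
class PermutationReport:
    pairs: list
    observed_stat: np.ndarray
    p_raw: np.ndarray
    p_holm: np.ndarray
    n_permutations: int

    def to_frame(self):
        return pd.DataFrame(
            {
                "pair": [f"{a}-{b}" for a, b in self.pairs],
                "observed": self.observed_stat,
                "p_raw": self.p_raw,
                "p_holm": self.p_holm,
            }
        )


@dataclass
class ClassifierReport:
    model: str
    pcs_used: int
    cumulative_variance: float
    loo_accuracy: float
    per_group_accuracy: dict
    confusion: pd.DataFrame
    query_posteriors: pd.DataFrame = None


@dataclass
class GeoChronoReport:
    geography: pd.DataFrame = None
    chronology: pd.DataFrame = None


def holm_adjust(p_values):
    """Step-down Holm adjustment (never decreases a p-value; monotone)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="holm")[1]


def permutation_test_pairs(scores, labels, n_permutations=N_PERMUTATIONS,
                           rng=None):
    """Pairwise permutation tests on score vectors (first 3 PCs by
    convention).

    The statistic per pair is the Euclidean distance between group mean
    score vectors; group labels are permuted within the pooled pair and
    p = (#{permuted >= observed} + 1) / (N + 1), Holm-adjusted across
    pairs.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    rng = np.random.default_rng(rng)
    groups = [g for g in pd.unique(labels)]
    if len(groups) < 2:
        raise InsufficientDataError("need >= 2 groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise InsufficientDataError(f"group {g!r} has fewer than 2 members")

    pairs, observed, p_raw = [], [], []
    for a, b in combinations(groups, 2):
        xa = scores[labels == a]
        xb = scores[labels == b]
        na = xa.shape[0]
        pooled = np.vstack([xa, xb])
        m = pooled.shape[0]
        obs = float(np.linalg.norm(xa.mean(axis=0) - xb.mean(axis=0)))
        # vectorized label permutations: argsort of uniform draws
        order = np.argsort(rng.random((n_permutations, m)), axis=1)
        perm = pooled[order]  # (N, m, d)
        mean_a = perm[:, :na].mean(axis=1)
        mean_b = perm[:, na:].mean(axis=1)
        dist = np.linalg.norm(mean_a - mean_b, axis=1)
        p = (np.count_nonzero(dist >= obs - 1e-12) + 1) / (n_permutations + 1)
        pairs.append((a, b))
        observed.append(obs)
        p_raw.append(p)

    p_raw = np.asarray(p_raw)
    return PermutationReport(
        pairs=pairs,
        observed_stat=np.asarray(observed),
        p_raw=p_raw,
        p_holm=holm_adjust(p_raw),
        n_permutations=n_permutations,
    )


def normality_gate(scores, labels, n_pcs=N_GATE_PCS, alpha=ALPHA):
    """Shapiro-Wilk gate: QDA if any of the first ``n_pcs`` scores in any
    group rejects normality at ``alpha``, otherwise LDA."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    n_pcs = min(n_pcs, scores.shape[1])
    for g in pd.unique(labels):
        block = scores[labels == g, :n_pcs]
        if block.shape[0] < 3:
            raise InsufficientDataError(
                f"group {g!r} has n < 3; Shapiro-Wilk undefined"
            )
        for j in range(n_pcs):
            col = block[:, j]
            if np.ptp(col) < 1e-15:
                raise InsufficientDataError(
                    f"constant PC{j + 1} in group {g!r}; normality test "
                    "undefined"
                )
            if stats.shapiro(col).pvalue < alpha:
                return "QDA"
    return "LDA"


def _make_estimator(model, priors=None):
    if model == "LDA":
        return LinearDiscriminantAnalysis(priors=priors)
    if model == "QDA":
        return QuadraticDiscriminantAnalysis(priors=priors)
    raise ValueError(f"unknown model {model!r}")


def _check_da_preconditions(scores, labels, model, k):
    labels = np.asarray(labels)
    n = scores.shape[0]
    if model == "QDA":
        for g in pd.unique(labels):
            ng = (labels == g).sum()
            if ng <= k:
                raise InsufficientDataError(
                    f"QDA with {k} PCs needs per-group n > {k}; group {g!r} "
                    f"has n = {ng}"
                )
            cov = np.cov(scores[labels == g, :k], rowvar=False)
            if np.linalg.matrix_rank(np.atleast_2d(cov)) < k:
                raise SingularCovarianceError(
                    f"singular covariance in group {g!r} with {k} PCs"
                )
    else:
        if n <= k:
            raise InsufficientDataError(
                f"LDA with {k} PCs needs pooled n > {k}; n = {n}"
            )


def fit_da_loo(scores, labels, model, n_pcs=None, priors=None):
    """Leave-one-out cross-validated discriminant analysis.

    Each specimen is classified by a model fitted on the remaining n-1;
    returns a :class:`ClassifierReport` with overall and per-group LOO
    accuracy and the confusion matrix. ``priors=None`` uses priors
    proportional to training group sizes.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    k = scores.shape[1] if n_pcs is None else int(n_pcs)
    X = scores[:, :k]
    _check_da_preconditions(X, labels, model, k)
    est = _make_estimator(model, priors)
    try:
        pred = cross_val_predict(est, X, labels, cv=LeaveOneOut())
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            f"singular within-group covariance during LOO with {k} PCs: "
            f"{exc}"
        ) from exc
    groups = pd.unique(labels)
    confusion = pd.crosstab(
        pd.Series(labels, name="true"), pd.Series(pred, name="predicted")
    ).reindex(index=groups, columns=groups, fill_value=0)
    per_group = {
        g: float((pred[labels == g] == g).mean()) for g in groups
    }
    return ClassifierReport(
        model=model,
        pcs_used=k,
        cumulative_variance=np.nan,
        loo_accuracy=float((pred == labels).mean()),
        per_group_accuracy=per_group,
        confusion=confusion,
    )


def select_pc_count(variance_ratio, scores, labels, model, priors=None,
                    window=VARIANCE_WINDOW):
    """Minimum PC count achieving the highest LOO accuracy within the
    70-90% cumulative-variance window.

    The window contains every k whose cumulative variance lies in
    [window[0], window[1]]; if the cumulative variance jumps over the
    window, the smallest k reaching window[0] is used. For QDA the window
    is additionally truncated so every group keeps n > k.
    """
    variance_ratio = np.asarray(variance_ratio, dtype=float)
    labels = np.asarray(labels)
    cum = np.cumsum(variance_ratio)
    ks = [k for k in range(1, len(cum) + 1)
          if window[0] - 1e-12 <= cum[k - 1] <= window[1] + 1e-12]
    if not ks:
        above = np.nonzero(cum >= window[0] - 1e-12)[0]
        if above.size:
            ks = [int(above[0]) + 1]
    min_group_n = min((labels == g).sum() for g in pd.unique(labels))
    if model == "QDA":
        # LOO folds drop one group member, so keep k <= min n - 2
        ks = [k for k in ks if k <= min_group_n - 2]
    ks = [k for k in ks if k <= scores.shape[1]]
    if not ks:
        raise WindowEmptyError(
            f"no usable PC count: cumulative variance {np.round(cum, 3)}, "
            f"window {window}, smallest group n = {min_group_n}, model "
            f"{model}"
        )
    best_k, best_acc = None, -1.0
    for k in ks:
        try:
            acc = fit_da_loo(scores, labels, model, n_pcs=k,
                             priors=priors).loo_accuracy
        except SingularCovarianceError:
            continue  # infeasible k inside the window; try the next
        if acc > best_acc + 1e-12:
            best_k, best_acc = k, acc
    if best_k is None:
        raise WindowEmptyError(
            f"every candidate PC count in {ks} has a singular within-group "
            f"covariance for {model}"
        )
    return best_k


def classify_query(scores, labels, query_scores, model, n_pcs=None,
                   priors=None, query_names=None):
    """Posterior probabilities of group membership for query specimens
    under a discriminant model fitted on the full training data."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    query = np.atleast_2d(np.asarray(query_scores, dtype=float))
    k = scores.shape[1] if n_pcs is None else int(n_pcs)
    if query.shape[1] < k:
        raise ValueError(
            f"query has {query.shape[1]} scores; model uses {k} PCs"
        )
    _check_da_preconditions(scores[:, :k], labels, model, k)
    est = _make_estimator(model, priors).fit(scores[:, :k], labels)
    post = est.predict_proba(query[:, :k])
    return pd.DataFrame(post, columns=est.classes_, index=query_names)


class DiscriminantClassifier:
    """Normality-gated LDA/QDA with LOO cross-validation and PC selection.

    Parameters
    ----------
    model : {"auto", "LDA", "QDA"}, default "auto"
        "auto" applies the Shapiro-Wilk gate on the first 3 PCs per group.
    n_pcs : int or None
        None selects the minimum PC count with the highest LOO accuracy in
        the cumulative-variance ``window`` (requires ``variance_ratio`` at
        fit time).
    priors : array-like or None
        None = priors proportional to training group sizes.
    window : (float, float), default (0.70, 0.90)

    Attributes
    ----------
    model_, n_pcs_, loo_accuracy_, per_group_accuracy_, confusion_,
    cumulative_variance_, estimator_ (full-data fitted sklearn model)
    """

    def __init__(self, model="auto", n_pcs=None, priors=None,
                 window=VARIANCE_WINDOW):
        self.model = model
        self.n_pcs = n_pcs
        self.priors = priors
        self.window = window

    def get_params(self, deep=True):
        return {"model": self.model, "n_pcs": self.n_pcs,
                "priors": self.priors, "window": self.window}

    def set_params(self, **params):
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y, variance_ratio=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        model = self.model
        if model == "auto":
            model = normality_gate(X, y)
        if self.n_pcs is not None:
            k = int(self.n_pcs)
        elif variance_ratio is not None:
            k = select_pc_count(variance_ratio, X, y, model,
                                priors=self.priors, window=self.window)
        else:
            k = X.shape[1]
        report = fit_da_loo(X, y, model, n_pcs=k, priors=self.priors)
        self.model_ = model
        self.n_pcs_ = k
        self.loo_accuracy_ = report.loo_accuracy
        self.per_group_accuracy_ = report.per_group_accuracy
        self.confusion_ = report.confusion
        self.cumulative_variance_ = (
            float(np.cumsum(variance_ratio)[k - 1])
            if variance_ratio is not None else np.nan
        )
        self.estimator_ = _make_estimator(model, self.priors).fit(X[:, :k], y)
        self.classes_ = self.estimator_.classes_
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.estimator_.predict(X[:, : self.n_pcs_])

    def predict_proba(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.estimator_.predict_proba(X[:, : self.n_pcs_])

    def report(self, query_scores=None, query_names=None):
        post = None
        if query_scores is not None:
            query = np.atleast_2d(np.asarray(query_scores, dtype=float))
            post = pd.DataFrame(self.predict_proba(query),
                                columns=self.classes_, index=query_names)
        return ClassifierReport(
            model=self.model_,
            pcs_used=self.n_pcs_,
            cumulative_variance=self.cumulative_variance_,
            loo_accuracy=self.loo_accuracy_,
            per_group_accuracy=self.per_group_accuracy_,
            confusion=self.confusion_,
            query_posteriors=post,
        )


def geo_correlation(scores, latitudes, longitudes, n_pcs=N_GATE_PCS):
    """Pearson r and two-sided p per PC against latitude and longitude."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    lat = np.asarray(latitudes, dtype=float)
    lon = np.asarray(longitudes, dtype=float)
    n = scores.shape[0]
    if n < 4:
        raise InsufficientDataError("geographic correlation needs n >= 4")
    if not (np.all(np.isfinite(lat)) and np.all(np.isfinite(lon))):
        raise ValueError("non-finite coordinates")
    rows = []
    for name, coord in (("latitude", lat), ("longitude", lon)):
        if np.ptp(coord) < 1e-15:
            raise ValueError(f"zero-variance {name} vector")
        for j in range(min(n_pcs, scores.shape[1])):
            r, p = stats.pearsonr(scores[:, j], coord)
            rows.append({"coordinate": name, "pc": j + 1, "r": float(r),
                         "p": float(p)})
    return pd.DataFrame(rows)


def chrono_group_test(scores, mis_groups, n_pcs=N_GATE_PCS, alpha=ALPHA):
    """Per-PC comparison across the two MIS groups ("early" vs "classic").

    Shapiro-Wilk within each group gates the branch: one-way ANOVA when
    normality holds on that PC, Kruskal-Wallis otherwise.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    mis = np.asarray(mis_groups)
    groups = pd.unique(mis)
    if groups.size < 2:
        raise InsufficientDataError("need 2 MIS groups")
    for g in groups:
        if (mis == g).sum() < 3:
            raise InsufficientDataError(f"MIS group {g!r} has n < 3")
    rows = []
    for j in range(min(n_pcs, scores.shape[1])):
        samples = [scores[mis == g, j] for g in groups]
        normal = all(stats.shapiro(s).pvalue >= alpha for s in samples)
        if normal:
            stat, p = stats.f_oneway(*samples)
            branch = "anova"
        else:
            stat, p = stats.kruskal(*samples)
            branch = "kruskal-wallis"
        rows.append({"pc": j + 1, "branch": branch, "stat": float(stat),
                     "p": float(p)})
    return pd.DataFrame(rows)
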