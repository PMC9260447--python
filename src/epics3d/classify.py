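"""Open/closed state assignment and the interpretable classifier.

The statistical chain:

1. per-batch z-normalization of the metric table (removes batch effects,
   e.g. from differing voxel resolutions);
2. k-means with k=2, run independently per batch on the normalized
   features;
3. polarity-aware labeling: the cluster whose mean of the Mean-intensity
   metric indicates *more* chromatin material is the closed (B) state —
   lower raw mean under dark-is-signal, higher under bright-is-signal;
4. stratified 70/30 train-validation split;
5. L1-penalized (LASSO) logistic path with K-fold cross-validated
   deviance and the one-standard-error rule for the penalty;
6. an unpenalized logistic refit on the selected features in their
   original physical units, giving coefficients, z-values and variable
   importance (|z|, and relative to the maximum).

Class coding: B (closed) = 1, A (open) = 0, so coefficients are
log-odds of being closed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.proportion import proportion_confint

from .stack_io import BRIGHT_IS_SIGNAL, DARK_IS_SIGNAL

__all__ = [
    "OPEN", "CLOSED",
    "BatchZScorer", "TwoStateKMeans", "LassoLogisticModel",
    "StateAssignment", "LassoResult", "EvaluationResult", "StabilityReport",
    "batch_normalize", "cluster_domains", "assign_states", "stratified_split",
    "select_features_lasso", "fit_logistic", "odds_table", "coefficient_ratio",
    "evaluate", "bootstrap_stability", "match_two_cluster_labels",
]

OPEN = "A"
CLOSED = "B"
MEAN_INTENSITY_COLUMN = "mean_int"


def _check_matrix(X) -> pd.DataFrame:
    X = pd.DataFrame(X)
    if X.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    return X


# ---------------------------------------------------------------------------
# 1. batch normalization


class BatchZScorer(BaseEstimator, TransformerMixin):
    """Per-batch z-scoring of every feature (sample SD, n-1 denominator).

    Features with zero variance in *any* batch are dropped identically
    across batches (a z-score is undefined there), with a warning.

    Fitted attributes: ``means_`` and ``sds_`` (DataFrames indexed by
    batch), ``dropped_features_``, ``feature_names_``.
    """

    def fit(self, X, batch_ids):
        X = _check_matrix(X)
        batch_ids = np.asarray(batch_ids)
        groups = X.groupby(batch_ids)
        sizes = groups.size()
        if (sizes < 2).any():
            bad = sizes[sizes < 2].index.tolist()
            raise ValueError(f"each batch needs >= 2 domains; too small: {bad}")
        self.means_ = groups.mean()
        self.sds_ = groups.std(ddof=1)
        zero_var = (self.sds_ == 0).any(axis=0)
        self.dropped_features_ = list(self.sds_.columns[zero_var])
        if self.dropped_features_:
            warnings.warn(
                f"dropping zero-variance features (identically in all batches): "
                f"{self.dropped_features_}"
            )
        self.feature_names_ = [c for c in X.columns if c not in self.dropped_features_]
        return self

    def transform(self, X, batch_ids) -> pd.DataFrame:
        X = _check_matrix(X)[self.feature_names_ + self.dropped_features_]
        batch_ids = np.asarray(batch_ids)
        out = pd.DataFrame(index=X.index, columns=self.feature_names_, dtype=float)
        for b in np.unique(batch_ids):
            rows = batch_ids == b
            mu = self.means_.loc[b, self.feature_names_]
            sd = self.sds_.loc[b, self.feature_names_]
            out.loc[rows, :] = ((X.loc[rows, self.feature_names_] - mu) / sd).values
        return out

    def fit_transform(self, X, batch_ids=None, **kw):
        return self.fit(X, batch_ids).transform(X, batch_ids)


def batch_normalize(D, batch_ids):
    """z-score per feature per batch; returns ``(normalized, scaler)``."""
    scaler = BatchZScorer()
    return scaler.fit_transform(D, batch_ids), scaler


# ---------------------------------------------------------------------------
# 2-3. clustering and state assignment


class TwoStateKMeans(BaseEstimator):
    """k-means with k=2 run independently per batch.

    Clusters are renumbered by first occurrence within each batch (the
    cluster of the batch's first row is 1) so that labels are insensitive
    to k-means initialization; the polarity rules below then make the
    final A/B states initialization-invariant.

    Fitted attribute: ``labels_`` (values in {1, 2}).
    """

    def __init__(self, n_init=10, random_state=None):
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, batch_ids):
        X = _check_matrix(X)
        batch_ids = np.asarray(batch_ids)
        labels = np.zeros(len(X), dtype=int)
        rng = np.random.default_rng(self.random_state)
        for b in pd.unique(batch_ids):
            rows = np.flatnonzero(batch_ids == b)
            if len(rows) < 2:
                raise ValueError(f"batch {b!r} has fewer rows than clusters (2)")
            km = KMeans(
                n_clusters=2,
                n_init=self.n_init,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(X.iloc[rows].values)
            raw = km.labels_
            first = raw[0]
            labels[rows] = np.where(raw == first, 1, 2)
        self.labels_ = labels
        return self

    def fit_predict(self, X, batch_ids):
        return self.fit(X, batch_ids).labels_


def cluster_domains(normalized, batch_ids, seed=None) -> np.ndarray:
    """Per-batch 2-means cluster indices in {1, 2}, deterministic given seed."""
    return TwoStateKMeans(random_state=seed).fit_predict(normalized, batch_ids)


@dataclass
class StateAssignment:
    """Per-domain cluster index and open/closed state."""

    cluster: np.ndarray  # in {1, 2}
    state: np.ndarray  # "A" (open) or "B" (closed)
    cluster_means: dict  # batch -> (m1, m2): mean Mean-intensity per cluster

    @property
    def n_open(self) -> int:
        return int(np.sum(self.state == OPEN))

    @property
    def n_closed(self) -> int:
        return int(np.sum(self.state == CLOSED))


def assign_states(clusters, D, polarity, batch_ids=None) -> StateAssignment:
    """Turn cluster indices into open/closed states via the polarity rules.

    ``m1`` and ``m2`` are the means of the Mean-intensity metric over
    clusters 1 and 2, computed on the ORIGINAL (unnormalized) matrix,
    per batch.  Bright-is-signal: the higher-mean cluster is closed (B);
    equality sends cluster 1 to open (A).  Dark-is-signal: the lower-mean
    cluster is closed; equality sends cluster 1 to open.
    """
    D = _check_matrix(D)
    if MEAN_INTENSITY_COLUMN not in D.columns:
        raise ValueError(f"feature matrix lacks the {MEAN_INTENSITY_COLUMN!r} column")
    if polarity not in (DARK_IS_SIGNAL, BRIGHT_IS_SIGNAL):
        raise ValueError(f"unknown polarity {polarity!r}")
    clusters = np.asarray(clusters)
    if batch_ids is None:
        batch_ids = np.zeros(len(D), dtype=int)
    batch_ids = np.asarray(batch_ids)
    mean_int = D[MEAN_INTENSITY_COLUMN].to_numpy(dtype=float)

    state = np.empty(len(D), dtype=object)
    cluster_means = {}
    for b in pd.unique(batch_ids):
        rows = batch_ids == b
        m1 = float(np.mean(mean_int[rows & (clusters == 1)]))
        m2 = float(np.mean(mean_int[rows & (clusters == 2)]))
        cluster_means[b] = (m1, m2)
        if polarity == BRIGHT_IS_SIGNAL:
            cluster1_closed = m1 > m2
        else:  # dark: more material = lower raw intensity
            cluster1_closed = m1 < m2
        b_cluster = 1 if cluster1_closed else 2
        state[rows] = np.where(clusters[rows] == b_cluster, CLOSED, OPEN)
    return StateAssignment(cluster=clusters, state=state.astype(str), cluster_means=cluster_means)


# ---------------------------------------------------------------------------
# 4. split


def stratified_split(states, fraction=0.7, seed=None):
    """Seeded stratified split; returns (train_idx, val_idx) position arrays.

    Per-state proportions are preserved to within one domain.  A state with
    a single member goes to the training set.
    """
    if not (0 < fraction < 1):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    states = np.asarray(states)
    rng = np.random.default_rng(seed)
    train, val = [], []
    for s in np.unique(states):
        idx = np.flatnonzero(states == s)
        if len(idx) == 0:
            raise ValueError(f"state {s!r} has no members")
        rng.shuffle(idx)
        n_train = int(round(fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx))
        train.extend(idx[:n_train])
        val.extend(idx[n_train:])
    return np.sort(np.array(train, dtype=int)), np.sort(np.array(val, dtype=int))


# ---------------------------------------------------------------------------
# 5. LASSO path with CV and the one-standard-error rule


@dataclass
class LassoResult:
    lambda_path: np.ndarray  # decreasing
    cv_mean: np.ndarray  # mean held-out binomial deviance per lambda
    cv_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    chosen_lambda: float
    selected_features: list[str]
    coef_path: np.ndarray = field(repr=False, default=None)  # (n_lambda, p) original units
    n_nonzero_path: np.ndarray = None


def _deviance(y, p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.mean(-2 * (y * np.log(p) + (1 - y) * np.log(1 - p))))


def _l1_path_fits(Xs, y, lambdas):
    """L1 logistic fits over a decreasing lambda grid on standardized data.

    liblinear coordinate descent with a large ``intercept_scaling`` so the
    intercept is effectively unpenalized, matching the usual convention.
    """
    n = len(y)
    coefs = np.zeros((len(lambdas), Xs.shape[1]))
    icepts = np.zeros(len(lambdas))
    est = LogisticRegression(
        l1_ratio=1.0,
        solver="liblinear",
        intercept_scaling=1000.0,
        warm_start=True,
        max_iter=500,
        tol=1e-8,
        C=1.0,
    )
    with warnings.catch_warnings():
        # near the unpenalized end of the path, separated data legitimately
        # stops coordinate descent at the iteration cap
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        for i, lam in enumerate(lambdas):
            est.C = 1.0 / (n * lam) if lam > 0 else 1e10
            est.fit(Xs, y)
            coefs[i] = est.coef_[0]
            icepts[i] = est.intercept_[0]
    return coefs, icepts


def select_features_lasso(
    X,
    y,
    folds: int = 10,
    lambda_policy: str = "one_se",
    lambda_value: float | None = None,
    seed=None,
    n_lambda: int = 100,
) -> LassoResult:
    """Cross-validated LASSO logistic feature selection.

    The penalty grid has ``n_lambda`` log-spaced values from the smallest
    lambda that zeroes every coefficient down to 1e-4 of it.  Features are
    standardized internally for the penalty; reported coefficients are in
    original units.  ``lambda_policy='one_se'`` picks the largest lambda
    whose CV deviance is within one standard error of the minimum;
    ``'fixed'`` reuses a supplied value (e.g. carrying one dataset's choice
    over to another).  An empty selection at the one-SE lambda warns and
    falls back to ``lambda_min``.
    """
    X = _check_matrix(X)
    y = np.asarray(y)
    if set(np.unique(y)) - {0, 1}:
        y = (y == CLOSED).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both states")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    mu, sd = Xv.mean(axis=0), Xv.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xs = (Xv - mu) / sd
    n = len(y)

    lam_max = float(np.max(np.abs(Xs.T @ (y - y.mean()))) / n)
    lambdas = np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-4), n_lambda)

    minority = int(np.bincount(y).min())
    if minority < 2:
        raise ValueError("cross-validation needs >= 2 members of each state")
    if folds > minority:
        warnings.warn(
            f"reducing cv folds from {folds} to {minority} (minority state size)"
        )
        folds = minority
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=_as_int_seed(seed))
    fold_dev = np.zeros((folds, n_lambda))
    for k, (tr, te) in enumerate(skf.split(Xs, y)):
        coefs, icepts = _l1_path_fits(Xs[tr], y[tr], lambdas)
        logits = Xs[te] @ coefs.T + icepts
        probs = 1.0 / (1.0 + np.exp(-logits))
        for i in range(n_lambda):
            fold_dev[k, i] = _deviance(y[te], probs[:, i])
    cv_mean = fold_dev.mean(axis=0)
    cv_se = fold_dev.std(axis=0, ddof=1) / np.sqrt(folds)

    i_min = int(np.argmin(cv_mean))
    lambda_min = float(lambdas[i_min])
    within = np.flatnonzero(cv_mean[: i_min + 1] <= cv_mean[i_min] + cv_se[i_min])
    i_1se = int(within[0])  # grid is decreasing: first index = largest lambda
    lambda_1se = float(lambdas[i_1se])

    coefs_full, _ = _l1_path_fits(Xs, y, lambdas)
    coef_path = coefs_full / sd  # back to original units
    n_nonzero = (np.abs(coefs_full) > 1e-10).sum(axis=1)

    if lambda_policy == "one_se":
        chosen = lambda_1se
    elif lambda_policy == "fixed":
        if lambda_value is None:
            raise ValueError("fixed lambda policy requires lambda_value")
        chosen = float(lambda_value)
    else:
        raise ValueError(f"unknown lambda policy {lambda_policy!r}")

    def _selected_at(lam):
        if lam <= 0:
            c, _ = _l1_path_fits(Xs, y, np.array([0.0]))
            return [names[j] for j in np.flatnonzero(np.abs(c[0]) > 1e-10)]
        i = int(np.argmin(np.abs(np.log(lambdas) - np.log(lam))))
        if not np.isclose(lambdas[i], lam, rtol=1e-6):
            c, _ = _l1_path_fits(Xs, y, np.array([lam]))
            return [names[j] for j in np.flatnonzero(np.abs(c[0]) > 1e-10)]
        return [names[j] for j in np.flatnonzero(np.abs(coefs_full[i]) > 1e-10)]

    selected = _selected_at(chosen)
    if not selected:
        warnings.warn("no features selected at the chosen lambda; falling back to lambda_min")
        chosen = lambda_min
        selected = _selected_at(chosen)

    return LassoResult(
        lambda_path=lambdas,
        cv_mean=cv_mean,
        cv_se=cv_se,
        lambda_min=lambda_min,
        lambda_1se=lambda_1se,
        chosen_lambda=chosen,
        selected_features=selected,
        coef_path=coef_path,
        n_nonzero_path=n_nonzero,
    )


def _as_int_seed(seed):
    if seed is None:
        return None
    return int(np.random.default_rng(seed).integers(2**31 - 1))


# ---------------------------------------------------------------------------
# 6. final logistic model


class LassoLogisticModel(BaseEstimator, ClassifierMixin):
    """LASSO-selected, unpenalized-refit logistic classifier.

    ``fit(X, y)`` runs the cross-validated L1 path for feature selection
    and then refits an ordinary maximum-likelihood logistic regression on
    the selected features in their ORIGINAL physical units, so the
    coefficients read as log-odds (of being closed) per physical unit.

    Fitted attributes
    -----------------
    selected_features_ : list of str
    intercept_, coef_ : original-unit estimates (``coef_`` is a Series)
    z_values_ : Wald z per selected feature
    vi_, relative_vi_ : variable importance |z| and |z| / max |z|
    z_reliable_ : False when the refit hit separation / non-convergence
    lasso_ : the full :class:`LassoResult`
    """

    def __init__(self, cv_folds=10, lambda_policy="one_se", lambda_value=None, random_state=None):
        self.cv_folds = cv_folds
        self.lambda_policy = lambda_policy
        self.lambda_value = lambda_value
        self.random_state = random_state

    def fit(self, X, y):
        X = _check_matrix(X)
        y01 = np.asarray(y)
        if y01.dtype.kind in "UO":
            y01 = (y01 == CLOSED).astype(int)
        self.lasso_ = select_features_lasso(
            X,
            y01,
            folds=self.cv_folds,
            lambda_policy=self.lambda_policy,
            lambda_value=self.lambda_value,
            seed=self.random_state,
        )
        self.selected_features_ = self.lasso_.selected_features
        fit = fit_logistic(X[self.selected_features_], y01)
        (
            self.intercept_,
            self.coef_,
            self.std_errors_,
            self.z_values_,
            self.z_reliable_,
        ) = fit
        self.vi_ = self.z_values_.abs()
        vmax = self.vi_.max()
        self.relative_vi_ = self.vi_ / vmax if vmax > 0 else self.vi_ + 1.0
        self.classes_ = np.array([OPEN, CLOSED])
        return self

    def decision_function(self, X):
        X = _check_matrix(X)[self.selected_features_]
        return self.intercept_ + X.to_numpy(dtype=float) @ self.coef_.to_numpy()

    def predict_proba(self, X):
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return np.where(p > 0.5, CLOSED, OPEN)


def fit_logistic(X, y, maxiter: int = 100):
    """Unpenalized ML logistic fit (closed=1) with Wald z-values.

    Perfect separation is tolerated: the fit is iteration-capped, a
    warning is emitted and the z-values are flagged unreliable.
    Returns ``(intercept, coef Series, std-error Series, z Series, reliable)``.
    """
    X = _check_matrix(X)
    if X.shape[1] == 0:
        raise ValueError("at least one selected feature is required")
    y = np.asarray(y)
    if y.dtype.kind in "UO":
        y = (y == CLOSED).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both states are required to fit the model")
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    reliable = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=maxiter)
            params, bse = res.params, res.bse
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:  # singular Hessian under complete separation
            res, converged = None, False
            params = bse = None
    if res is None:
        # ridge-stabilized fallback: coefficients from a near-unpenalized
        # fit, standard errors from the regularized Fisher information
        est = LogisticRegression(C=1e8, max_iter=1000, tol=1e-8).fit(
            X.to_numpy(dtype=float), y
        )
        params = np.concatenate([est.intercept_, est.coef_[0]])
        p = 1 / (1 + np.exp(-np.clip(design @ params, -500, 500)))
        W = p * (1 - p)
        info = design.T * W @ design + 1e-8 * np.eye(design.shape[1])
        bse = np.sqrt(np.diag(np.linalg.pinv(info)))
    if not converged or any("separation" in str(w.message).lower() for w in caught):
        warnings.warn(
            "possible separation or non-convergence in the logistic refit; "
            "z-values are unreliable"
        )
        reliable = False
    names = list(X.columns)
    coef = pd.Series(np.asarray(params)[1:], index=names)
    se = pd.Series(np.asarray(bse)[1:], index=names)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = coef / se
    z = z.replace([np.inf, -np.inf], np.nan).fillna(0.0)
    return float(np.asarray(params)[0]), coef, se, z, reliable


def odds_table(model: LassoLogisticModel) -> pd.DataFrame:
    """Per-feature log-odds and odds (3 decimals), sorted by relative VI."""
    df = pd.DataFrame(
        {
            "feature": model.coef_.index,
            "log_odds": model.coef_.values,
            "odds": np.round(np.exp(model.coef_.values), 3),
            "z_value": model.z_values_.values,
            "vi": model.vi_.values,
            "relative_vi": model.relative_vi_.values,
        }
    )
    return df.sort_values("relative_vi", ascending=False).reset_index(drop=True)


def coefficient_ratio(beta_a: float, beta_b: float, decimals: int = 2) -> float:
    """Fold change between two models' coefficients for a shared feature."""
    return float(np.round(beta_a / beta_b, decimals))


# ---------------------------------------------------------------------------
# 7. evaluation


@dataclass
class EvaluationResult:
    accuracy: float
    ci_low: float
    ci_high: float
    n: int
    confusion: dict  # {(true, pred): count}


def evaluate(model, X, y_true) -> EvaluationResult:
    """Accuracy at the 0.5 cutoff with an exact (Clopper-Pearson) 95% CI."""
    y_true = np.asarray(y_true)
    if len(y_true) == 0:
        raise ValueError("cannot evaluate on empty data")
    if y_true.dtype.kind not in "UO":
        y_true = np.where(y_true == 1, CLOSED, OPEN)
    pred = model.predict(X)
    correct = int(np.sum(pred == y_true))
    n = len(y_true)
    lo, hi = proportion_confint(correct, n, alpha=0.05, method="beta")
    confusion = {
        (t, p): int(np.sum((y_true == t) & (pred == p)))
        for t in (OPEN, CLOSED)
        for p in (OPEN, CLOSED)
    }
    return EvaluationResult(correct / n, float(lo), float(hi), n, confusion)


# ---------------------------------------------------------------------------
# 8. bootstrap cluster stability


def match_two_cluster_labels(reference, candidate):
    """Relabel a 2-cluster candidate to best agree with the reference.

    Exhausts both pairings (k=2) and keeps the one maximizing agreement.
    """
    reference = np.asarray(reference)
    candidate = np.asarray(candidate)
    swapped = np.where(candidate == 1, 2, 1)
    if np.sum(candidate == reference) >= np.sum(swapped == reference):
        return candidate
    return swapped


def _jaccard(reference, candidate) -> float:
    """Mean per-cluster intersection-over-union after matching."""
    vals = []
    for c in (1, 2):
        a, b = reference == c, candidate == c
        union = np.sum(a | b)
        vals.append(np.sum(a & b) / union if union else 1.0)
    return float(np.mean(vals))


@dataclass
class StabilityReport:
    jaccard: np.ndarray
    accuracy: np.ndarray
    balanced_accuracy: np.ndarray

    @property
    def summary(self) -> dict:
        return {
            "mean_jaccard": float(self.jaccard.mean()),
            "mean_accuracy": float(self.accuracy.mean()),
            "mean_balanced_accuracy": float(self.balanced_accuracy.mean()),
        }


def bootstrap_stability(
    normalized,
    reference_clusters,
    batch_ids=None,
    n_bootstrap: int = 100,
    seed=None,
) -> StabilityReport:
    """Cluster-stability check by bootstrap reclustering.

    Each of ``n_bootstrap`` resamples (with replacement) is reclustered
    with per-batch 2-means; labels are matched to the reference partition
    per batch over the two possible pairings, then Jaccard index, accuracy
    and balanced accuracy are pooled over the resampled rows.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    X = _check_matrix(normalized)
    ref = np.asarray(reference_clusters)
    if batch_ids is None:
        batch_ids = np.zeros(len(X), dtype=int)
    batch_ids = np.asarray(batch_ids)
    rng = np.random.default_rng(seed)

    ji, acc, bacc = [], [], []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, len(X), size=len(X))
        Xb, refb, batchb = X.iloc[idx], ref[idx], batch_ids[idx]
        pred = np.zeros(len(idx), dtype=int)
        for b in pd.unique(batchb):
            rows = np.flatnonzero(batchb == b)
            if len(rows) < 2 or len(np.unique(Xb.iloc[rows].values, axis=0)) < 2:
                pred[rows] = refb[rows]  # degenerate resample: trivially stable
                continue
            km = KMeans(n_clusters=2, n_init=10, random_state=int(rng.integers(2**31 - 1)))
            raw = km.fit_predict(Xb.iloc[rows].values) + 1
            pred[rows] = match_two_cluster_labels(refb[rows], raw)
        ji.append(_jaccard(refb, pred))
        acc.append(float(np.mean(pred == refb)))
        bacc.append(float(balanced_accuracy_score(refb, pred)))
    return StabilityReport(np.array(ji), np.array(acc), np.array(bacc))
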