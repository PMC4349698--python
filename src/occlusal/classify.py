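"""Equal-prior linear discriminant classification of diet categories.

Classic pooled-covariance LDA (scikit-learn's eigen solver behind a thin
wrapper): each group is modelled as a Gaussian with its own mean and a
shared within-group covariance; specimens are assigned to the group with
the highest discriminant score.  Priors are equal by default so unequal
group sampling does not bias assignment — under three groups a random
classifier then scores 33.3%.  Accuracy is reported from leave-one-out
cross-validation (each specimen classified by a model fitted to the other
n-1), the honest analogue of the study's protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from occlusal.errors import InputError, NumericError


@dataclass
class LDAModel:
    """A fitted equal-prior linear discriminant rule."""

    group_labels: list[str]
    group_means: np.ndarray            # (k, p)
    pooled_cov: np.ndarray             # unbiased pooled within-group (p, p)
    priors: np.ndarray                 # (k,)
    feature_names: list[str]
    estimator: LinearDiscriminantAnalysis = field(repr=False, default=None)

    def predict(self, X) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))


@dataclass
class ClassificationReport:
    confusion: pd.DataFrame            # true x predicted counts
    rate_percent: float
    per_group_rates: pd.Series
    mode: str                          # "resubstitution" | "leave_one_out"
    n: int


@dataclass
class CanonicalScores:
    scores: np.ndarray                 # (n, n_functions)
    pct_variance: np.ndarray           # sums to 100


def _check_Xy(X, labels, feature_names=None):
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or len(labels) != X.shape[0]:
        raise InputError("X must be 2-D with one label per row")
    if np.isnan(X).any():
        raise InputError("X contains missing values")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    return X, labels, list(feature_names)


def fit_lda(X, labels, priors: str | np.ndarray = "equal",
            feature_names=None, ridge: float = 0.0) -> LDAModel:
    """Fit pooled-covariance LDA with equal (or given) priors.

    ``ridge`` adds eps * mean-diagonal to the pooled covariance for
    near-singular feature sets (off by default).  Ties in posterior break
    toward the earlier group in sorted label order.
    """
    X, labels, feature_names = _check_Xy(X, labels, feature_names)
    groups = sorted(pd.unique(labels))
    k, (n, p) = len(groups), X.shape
    if k < 2:
        raise InputError("need >= 2 groups")
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise InputError(f"groups with < 2 members: "
                         f"{counts[counts < 2].index.tolist()}")
    if n <= p + k:
        raise InputError(f"need n > p + k (n={n}, p={p}, k={k})")

    pr = np.full(k, 1.0 / k) if isinstance(priors, str) and priors == "equal" \
        else np.asarray(priors, dtype=float)
    if len(pr) != k or not np.isclose(pr.sum(), 1.0):
        raise InputError("priors must be one per group and sum to 1")

    means = np.vstack([X[labels == g].mean(axis=0) for g in groups])
    pooled = np.zeros((p, p))
    for g, m in zip(groups, means):
        d = X[labels == g] - m
        pooled += d.T @ d
    pooled /= (n - k)
    if ridge > 0:
        pooled = pooled + ridge * np.trace(pooled) / p * np.eye(p)
    else:
        cond = np.linalg.cond(pooled)
        if not np.isfinite(cond) or cond > 1e12:
            raise NumericError(
                f"pooled within-group covariance is near-singular (condition "
                f"number {cond:.3g}); remove collinear features or set ridge > 0")

    # ridge maps to the eigen solver's shrinkage toward the average eigenvalue
    est = LinearDiscriminantAnalysis(
        solver="eigen", priors=pr,
        shrinkage=None if ridge == 0 else min(ridge / (1.0 + ridge), 1.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinearity warnings already screened
        est.fit(X, labels)
    return LDAModel(group_labels=[str(g) for g in groups], group_means=means,
                    pooled_cov=pooled, priors=pr,
                    feature_names=feature_names, estimator=est)


def _report(true: np.ndarray, pred: np.ndarray, groups: list[str],
            mode: str) -> ClassificationReport:
    conf = pd.DataFrame(0, index=groups, columns=groups, dtype=int)
    for t, p in zip(true, pred):
        conf.loc[t, p] += 1
    n = len(true)
    rate = 100.0 * np.trace(conf.to_numpy()) / n
    per_group = pd.Series(
        {g: 100.0 * conf.loc[g, g] / conf.loc[g].sum() if conf.loc[g].sum()
         else np.nan for g in groups})
    return ClassificationReport(confusion=conf, rate_percent=float(rate),
                                per_group_rates=per_group, mode=mode, n=n)


def resubstitution_classify(X, labels, priors="equal",
                            ridge: float = 0.0) -> ClassificationReport:
    """Classify the training specimens with the model fitted to all of them."""
    X, labels, _ = _check_Xy(X, labels)
    model = fit_lda(X, labels, priors=priors, ridge=ridge)
    pred = model.predict(X)
    return _report(labels.astype(str), pred.astype(str),
                   model.group_labels, "resubstitution")


def loo_classify(X, labels, priors="equal", ridge: float = 0.0,
                 ids=None) -> ClassificationReport:
    """Leave-one-out classification: each row scored by a model fit to the rest."""
    X, labels, _ = _check_Xy(X, labels)
    n = X.shape[0]
    groups = sorted(pd.unique(labels))
    ids = list(ids) if ids is not None else list(range(n))
    pred = np.empty(n, dtype=object)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        sub_labels = labels[keep]
        counts = pd.Series(sub_labels).value_counts()
        if len(counts) < len(groups) or counts.min() < 2:
            raise InputError(
                f"leaving out specimen {ids[i]!r} empties a group "
                f"(or leaves it below the 2-member fitting minimum)")
        model = fit_lda(X[keep], sub_labels, priors=priors, ridge=ridge)
        pred[i] = model.predict(X[i:i + 1])[0]
    return _report(labels.astype(str), pred.astype(str),
                   [str(g) for g in groups], "leave_one_out")


def canonical_scores(model: LDAModel, X) -> CanonicalScores:
    """Canonical variates: projections onto the eigenvectors of
    pooled-within^-1 x between-group scatter, with percent of between-group
    variance per discriminant function."""
    if len(model.group_labels) < 2:
        raise InputError("no discriminant functions for a single group")
    X = np.asarray(X, dtype=float)
    scores = model.estimator.transform(X)
    ratio = model.estimator.explained_variance_ratio_
    n_fn = min(len(model.group_labels) - 1, len(model.feature_names))
    pct = 100.0 * np.asarray(ratio[:n_fn]) / np.sum(ratio[:n_fn])
    return CanonicalScores(scores=scores[:, :n_fn], pct_variance=pct)


def variable_subset_report(features: pd.DataFrame, labels,
                           subsets: dict[str, list[str]],
                           priors="equal", ridge: float = 0.0
                           ) -> dict[str, ClassificationReport]:
    """One LOO classification report per named feature subset.

    ``features`` is a specimen-by-feature frame; each subset names a column
    combination (the Table-5-style grid of single indices, index + length,
    and all-variable models).  Empty or unknown subsets are skipped with a
    warning.
    """
    out: dict[str, ClassificationReport] = {}
    for name, cols in subsets.items():
        if not cols:
            warnings.warn(f"subset {name!r} is empty: skipped", stacklevel=2)
            continue
        missing = [c for c in cols if c not in features.columns]
        if missing:
            raise InputError(f"subset {name!r} has unknown features: {missing}")
        sub = features[cols].dropna()
        out[name] = loo_classify(sub.to_numpy(),
                                 np.asarray(labels)[sub.index.to_numpy()]
                                 if isinstance(labels, np.ndarray)
                                 else pd.Series(labels).loc[sub.index].to_numpy(),
                                 priors=priors, ridge=ridge,
                                 ids=list(sub.index))
    return out
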