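"""Chromatin-feature models: cross-validated logistic prediction of called
elements and random-forest classification of top vs bottom regulatory pairs."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_score

from ._stats import bh_adjust, zscore

log = logging.getLogger(__name__)

BASE_FEATURES = ("H3K27ac", "H3K4me1", "H3K4me3", "ATAC")
HISTONE_PREFIXES = ("H3K",)


@dataclass
class ModelReport:
    """Coefficient table (Wald CI, Z p, BH FDR) for one logistic model."""

    coefficients: pd.DataFrame  # index: term; columns: coef, se, ci_lo, ci_hi, p, fdr
    converged: bool
    penalized: bool = False


def summarize_rpk(
    track: pd.DataFrame,
    regions: pd.DataFrame,
    is_histone: bool = False,
    min_width_histone: int = 1000,
) -> np.ndarray:
    """Reads-per-kilobase of a coverage track over regions.

    Track values are read counts per track interval; a region collects each
    interval's count pro-rated by fractional overlap, divided by the region
    width in kb. Histone-type features are summarized over regions resized
    to at least ``min_width_histone`` bp centered on the region midpoint.
    """
    if (regions["end"] <= regions["start"]).any():
        raise ValueError("zero-width region")
    t = track.sort_values("start")
    ts = t["start"].to_numpy(float)
    te = t["end"].to_numpy(float)
    tv = t["value"].to_numpy(float)
    tlen = te - ts
    out = np.zeros(len(regions))
    for i, rec in enumerate(regions.itertuples(index=False)):
        rs, re = int(rec.start), int(rec.end)
        if is_histone and re - rs < min_width_histone:
            mid = (rs + re) // 2
            rs, re = mid - min_width_histone // 2, mid + min_width_histone // 2
        lo = np.searchsorted(te, rs, side="right")
        hi = np.searchsorted(ts, re, side="left")
        if hi > lo:
            ov = np.minimum(te[lo:hi], re) - np.maximum(ts[lo:hi], rs)
            out[i] = float((tv[lo:hi] * ov / tlen[lo:hi]).sum())
        out[i] /= (re - rs) / 1000.0
    return out


def feature_matrix(
    tracks: dict[str, pd.DataFrame],
    bins: pd.DataFrame,
    min_width_histone: int = 1000,
) -> pd.DataFrame:
    """RPK per feature over ``bins``, z-scored per feature column.

    Bins outside a track get 0 coverage before z-scoring (logged).
    """
    cols = {}
    for name, track in tracks.items():
        is_hist = name.startswith(HISTONE_PREFIXES)
        rpk = summarize_rpk(track, bins, is_histone=is_hist, min_width_histone=min_width_histone)
        cols[name] = zscore(rpk)
    return pd.DataFrame(cols, index=bins.index)


def _wald_report(params, bse, names, alpha=0.05) -> pd.DataFrame:
    z = np.divide(params, bse, out=np.zeros_like(params), where=bse > 0)
    p = 2 * stats.norm.sf(np.abs(z))
    crit = stats.norm.ppf(1 - alpha / 2)
    # the intercept is not a feature: keep it out of the FDR pool
    p_for_fdr = np.where([n == "intercept" for n in names], np.nan, p)
    return pd.DataFrame(
        {
            "coef": params,
            "se": bse,
            "ci_lo": params - crit * bse,
            "ci_hi": params + crit * bse,
            "p": p,
            "fdr": bh_adjust(p_for_fdr),
        },
        index=names,
    )


def fit_care_logistic(features: pd.DataFrame, labels: np.ndarray) -> ModelReport:
    """ML logistic fit of label ~ features with per-coefficient Wald stats.

    Perfect separation triggers a flagged L2-penalized refit (penalty weight
    1e-4) whose standard errors come from the penalized Hessian.
    """
    y = np.asarray(labels, dtype=float)
    if features.shape[1] == 0:
        raise ValueError("no feature columns")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = sm.add_constant(features.to_numpy(), has_constant="add")
    names = ["intercept", *features.columns]
    penalized = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            ok = (
                np.all(np.isfinite(res.bse))
                and np.max(np.abs(res.params)) < 50
                and np.max(res.bse) < 100
            )
        except Exception:
            ok = False
        if not ok:
            penalized = True
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
                alpha=1e-4, L1_wt=0.0
            )
            # penalized fits lack bse; approximate from the unpenalized Hessian
            mu = 1 / (1 + np.exp(-np.clip(X @ res.params, -30, 30)))
            w = np.clip(mu * (1 - mu), 1e-8, None)
            cov = np.linalg.pinv((X * w[:, None]).T @ X + 1e-4 * np.eye(X.shape[1]))
            bse = np.sqrt(np.diag(cov))
            report = _wald_report(np.asarray(res.params), bse, names)
            return ModelReport(coefficients=report, converged=True, penalized=True)
    report = _wald_report(np.asarray(res.params), np.asarray(res.bse), names)
    return ModelReport(coefficients=report, converged=bool(res.converged), penalized=penalized)


def cv_auc(
    features: pd.DataFrame,
    labels: np.ndarray,
    folds: int = 5,
    repeats: int = 10,
    shuffle_baseline: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Held-out AUCs from repeated stratified K-fold CV, with an optional
    shuffled-label baseline (labels permuted once per repetition).

    Returns a long table (repeat, fold, category, auc) with
    ``folds * repeats`` models per category.
    """
    y = np.asarray(labels, dtype=int)
    X = features.to_numpy()
    counts = np.bincount(y)
    if counts.min() < folds:
        raise ValueError("a class is too small for stratified folds")
    rng = np.random.default_rng(seed)
    rows = []
    categories = ["true"] + (["shuffled"] if shuffle_baseline else [])
    for rep in range(repeats):
        rep_seed = int(rng.integers(2**31 - 1))
        for cat in categories:
            yy = y if cat == "true" else rng.permutation(y)
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
            for fold, (tr, te) in enumerate(skf.split(X, yy)):
                clf = LogisticRegression(max_iter=1000)
                clf.fit(X[tr], yy[tr])
                auc = roc_auc_score(yy[te], clf.predict_proba(X[te])[:, 1])
                rows.append((rep, fold, cat, auc))
    return pd.DataFrame(rows, columns=["repeat", "fold", "category", "auc"])


def tf_logistic(
    features: pd.DataFrame,
    tf_columns: list[str],
    labels: np.ndarray,
    base_features: tuple[str, ...] = BASE_FEATURES,
) -> pd.DataFrame:
    """One controlled logistic model per TF: label ~ TF + base features.

    Returns the TF coefficient rows with Wald stats; FDR is re-adjusted
    across TFs. Zero-variance TF columns report a 0 coefficient, flagged.
    """
    base = [c for c in base_features if c in features.columns]
    rows = []
    for tf in tf_columns:
        col = features[tf].to_numpy()
        if np.all(col == col[0]):
            rows.append((tf, 0.0, 0.0, 0.0, 0.0, 1.0, True))
            continue
        sub = features[[tf, *base]]
        rep = fit_care_logistic(sub, labels)
        r = rep.coefficients.loc[tf]
        rows.append((tf, r["coef"], r["se"], r["ci_lo"], r["ci_hi"], r["p"], rep.penalized))
    out = pd.DataFrame(
        rows, columns=["tf", "coef", "se", "ci_lo", "ci_hi", "p", "flagged"]
    ).set_index("tf")
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


def rf_pairs(
    pair_features: pd.DataFrame,
    ranking: np.ndarray,
    n_top: int = 50,
    n_bottom: int = 50,
    seed: int = 0,
    n_estimators: int = 500,
    cv_folds: int = 5,
) -> dict:
    """Random forest separating the top vs bottom ranked regulatory pairs.

    ``ranking`` orders rows best-first (e.g. ascending adjusted p). Labels 1
    for the first ``n_top`` pairs, 0 for the last ``n_bottom``. Returns OOB
    and CV accuracy, permutation importances, and a correlation-based
    feature dendrogram linkage.
    """
    n = len(pair_features)
    if n < n_top + n_bottom:
        raise ValueError(f"need at least {n_top + n_bottom} ranked pairs, got {n}")
    order = np.asarray(ranking)
    sel = np.concatenate([order[:n_top], order[-n_bottom:]])
    X = pair_features.iloc[sel].to_numpy()
    y = np.concatenate([np.ones(n_top, int), np.zeros(n_bottom, int)])

    clf = RandomForestClassifier(
        n_estimators=n_estimators, oob_score=True, random_state=seed, n_jobs=1
    )
    clf.fit(X, y)
    cv = cross_val_score(
        RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1),
        X, y, cv=StratifiedKFold(cv_folds, shuffle=True, random_state=seed),
        scoring="accuracy",
    )
    imp = permutation_importance(clf, X, y, n_repeats=10, random_state=seed, n_jobs=1)
    importances = pd.Series(
        imp.importances_mean, index=pair_features.columns, name="importance"
    ).sort_values(ascending=False)

    corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    dist = squareform(np.clip(1.0 - np.abs(corr), 0.0, None), checks=False)
    link = linkage(dist, method="average")
    return {
        "oob_accuracy": float(clf.oob_score_),
        "cv_accuracy": float(cv.mean()),
        "cv_scores": cv.tolist(),
        "importances": importances,
        "dendrogram_linkage": link,
        "gini_importances": pd.Series(clf.feature_importances_, index=pair_features.columns),
    }
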