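"""The statistical layer: regression to grade, bootstrap AUROC to CsPCa.

Per-patient scalar features (SCR variants, z-score, blob morphometrics, AI
likelihood) are related to outcomes two ways:

* ordinary least squares against the continuous ISUP grade — univariate
  (signed Pearson r, two-sided F-test p) and multivariate (multiple
  correlation R of fitted vs observed, overall F-test p, per-coefficient
  95% confidence intervals), with pairwise exclusion of missing values;
* logistic regression against the binary CsPCa label, refit over many
  (default 1000) seeded stratified random train/test splits; the test-set
  AUROC distribution is summarized by its 2.5th/97.5th percentiles as a 95%
  confidence interval.

OLS goes through statsmodels; the single-curve AUROC is the rank-sum
(concordance) statistic with ties counted one half, identical to the
trapezoidal area under the empirical ROC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

__all__ = [
    "FitResult",
    "AUROCResult",
    "DegenerateFitError",
    "CollinearityError",
    "ClassError",
    "univariate_fit",
    "multivariate_fit",
    "cross_correlation",
    "roc_auc",
    "logistic_auroc_ci",
    "analysis_report",
]


class DegenerateFitError(ValueError):
    """Raised for constant predictors or too few complete observations."""


class CollinearityError(ValueError):
    """Raised when requested predictors are linearly dependent."""


class ClassError(ValueError):
    """Raised when a binary outcome carries only one class."""


@dataclass(frozen=True)
class FitResult:
    """Linear-fit summary: coefficients, correlation, F-test p, CIs."""

    coefficients: np.ndarray  # slope(s), without intercept
    intercept: float
    R: float  # multiple correlation of fitted vs observed, in [0, 1]
    r_signed: Optional[float]  # signed Pearson r (univariate only)
    p_value: float  # two-sided overall F-test probability
    conf_int: np.ndarray  # (n_coef + 1, 2) rows: intercept first
    n_used: int


@dataclass(frozen=True)
class AUROCResult:
    """AUROC distribution over randomized train/test splits."""

    aurocs: np.ndarray
    mean: float
    ci_low: float  # 2.5th percentile
    ci_high: float  # 97.5th percentile
    n_iter: int
    split_fraction: float
    seed: int
    n_skipped: int = 0


def _complete_rows(*arrays) -> tuple[np.ndarray, ...]:
    arrays = [np.asarray(a, dtype=float) for a in arrays]
    ok = np.ones(arrays[0].shape[0], dtype=bool)
    for a in arrays:
        ok &= np.all(np.isfinite(np.atleast_2d(a.T).T), axis=1)
    return tuple(a[ok] for a in arrays)


def univariate_fit(x, y) -> FitResult:
    """OLS of outcome y on a single predictor x.

    Missing values are excluded pairwise.  Reports the signed Pearson r and
    the two-sided F-test p (equivalent to the slope t-test).
    """
    x, y = _complete_rows(x, y)
    if len(x) < 3:
        raise DegenerateFitError(f"need ≥ 3 complete pairs, got {len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateFitError("predictor is constant")
    return _ols(x[:, None], y, univariate=True)


def multivariate_fit(X, y) -> FitResult:
    """OLS of outcome y on several predictors (complete rows only)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2D predictor matrix")
    X, y = _complete_rows(X, y)
    n, k = X.shape
    if n <= k + 1:
        raise DegenerateFitError(f"{n} complete rows cannot support {k} predictors")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < k + 1:
        raise CollinearityError("predictors are linearly dependent")
    return _ols(X, y, univariate=False)


def _ols(X: np.ndarray, y: np.ndarray, univariate: bool) -> FitResult:
    design = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y, design).fit()
    fitted = fit.fittedvalues
    if np.ptp(fitted) == 0 or np.ptp(y) == 0:
        big_r = 0.0
    else:
        big_r = float(np.corrcoef(fitted, y)[0, 1])
    r_signed = None
    if univariate:
        r_signed = float(np.corrcoef(X[:, 0], y)[0, 1]) if np.ptp(y) > 0 else 0.0
    p = float(fit.f_pvalue)
    return FitResult(
        coefficients=np.asarray(fit.params[1:]),
        intercept=float(fit.params[0]),
        R=max(big_r, 0.0),
        r_signed=r_signed,
        p_value=p if np.isfinite(p) else 1e-300,
        conf_int=np.asarray(fit.conf_int(alpha=0.05)),
        n_used=len(y),
    )


def cross_correlation(x1, x2) -> float:
    """Signed Pearson correlation on complete pairs."""
    x1, x2 = _complete_rows(x1, x2)
    if len(x1) < 3:
        raise DegenerateFitError(f"need ≥ 3 complete pairs, got {len(x1)}")
    if np.ptp(x1) == 0 or np.ptp(x2) == 0:
        raise DegenerateFitError("constant input has undefined correlation")
    return float(sps.pearsonr(x1, x2).statistic)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve; rank-sum statistic with ties counted 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ClassError("both outcome classes must be present")
    return float(roc_auc_score(labels, scores))


def _fit_logistic(x_train: np.ndarray, y_train: np.ndarray) -> LogisticRegression:
    """Unpenalized ML logistic fit; tiny ridge fallback on separable data."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        try:
            model = LogisticRegression(C=np.inf, max_iter=500)
            model.fit(x_train, y_train)
        except Exception:
            model = LogisticRegression(C=1e6, max_iter=500)
            model.fit(x_train, y_train)
    return model


def logistic_auroc_ci(
    x,
    labels,
    n_iter: int = 1000,
    split_fraction: float = 0.3,
    seed: int = 0,
    max_retries: int = 10,
) -> AUROCResult:
    """AUROC confidence interval over randomized train/test splits.

    Each iteration draws a seeded stratified split (``split_fraction`` of
    patients held out for testing, default 30%), fits a logistic model to
    CsPCa on the training part by maximum likelihood, and scores the AUROC
    on the held-out part.  The 2.5th and 97.5th percentiles of the
    ``n_iter`` AUROCs delineate the 95% confidence interval.  Fully
    reproducible from ``seed``.
    """
    x, labels = _complete_rows(x, labels)
    labels = labels.astype(int)
    if n_iter < 1:
        raise ValueError("n_iter must be ≥ 1")
    if len(np.unique(labels)) < 2:
        raise ClassError("both outcome classes must be present")
    X = x[:, None] if x.ndim == 1 else x
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_iter)
    aurocs, skipped = [], 0
    for child in children:
        rng_ints = child.generate_state(max_retries)
        auroc = None
        for attempt in range(max_retries):
            state = int(rng_ints[attempt]) % (2**32 - 1)
            X_tr, X_te, y_tr, y_te = train_test_split(
                X,
                labels,
                test_size=split_fraction,
                stratify=labels,
                random_state=state,
            )
            if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
                continue
            model = _fit_logistic(X_tr, y_tr)
            auroc = roc_auc(model.predict_proba(X_te)[:, 1], y_te)
            break
        if auroc is None:
            skipped += 1
        else:
            aurocs.append(auroc)
    aurocs = np.asarray(aurocs)
    if aurocs.size == 0:
        raise ClassError("every split left a class empty; cohort too small")
    return AUROCResult(
        aurocs=aurocs,
        mean=float(aurocs.mean()),
        ci_low=float(np.percentile(aurocs, 2.5)),
        ci_high=float(np.percentile(aurocs, 97.5)),
        n_iter=n_iter,
        split_fraction=split_fraction,
        seed=seed,
        n_skipped=skipped,
    )


# --------------------------------------------------------------------------
# Report assembly


@dataclass(frozen=True)
class ModelSpec:
    """One requested model: a set of predictors against an outcome column."""

    predictors: tuple[str, ...]
    outcome: str = "isup"
    logistic_outcome: Optional[str] = "cspca"
    n_iter: int = 1000
    split_fraction: float = 0.3

    @staticmethod
    def from_dict(d: dict) -> "ModelSpec":
        preds = d["predictors"]
        if isinstance(preds, str):
            preds = [preds]
        return ModelSpec(
            predictors=tuple(preds),
            outcome=d.get("outcome", "isup"),
            logistic_outcome=d.get("logistic_outcome", "cspca"),
            n_iter=int(d.get("n_iter", 1000)),
            split_fraction=float(d.get("split_fraction", 0.3)),
        )


def analysis_report(
    features: pd.DataFrame,
    model_specs: Sequence[ModelSpec],
    seed: int = 0,
) -> pd.DataFrame:
    """Summary-table rows (R, p, AUROC CI, cross-correlations) per model.

    For single-predictor models the row carries the univariate signed r; for
    two-predictor models it carries both univariate R's, their
    cross-correlation, and the multivariate R — the shape of the published
    uni/multivariate summary tables.  Errors (collinearity, missing
    features) are surfaced per row rather than aborting the report.
    """
    rows = []
    for k, spec in enumerate(model_specs):
        row: dict = {
            "model": " + ".join(spec.predictors),
            "outcome": spec.outcome,
            "n_used": np.nan,
            "R": np.nan,
            "r_signed": np.nan,
            "R1": np.nan,
            "R2": np.nan,
            "cross_correlation": np.nan,
            "p_value": np.nan,
            "auroc_mean": np.nan,
            "auroc_ci_low": np.nan,
            "auroc_ci_high": np.nan,
            "error": "",
        }
        try:
            missing = [c for c in spec.predictors if c not in features.columns]
            if missing or spec.outcome not in features.columns:
                raise KeyError(f"feature column(s) absent: {missing or [spec.outcome]}")
            y = features[spec.outcome].to_numpy(dtype=float)
            if len(spec.predictors) == 1:
                x = features[spec.predictors[0]].to_numpy(dtype=float)
                fit = univariate_fit(x, y)
                row.update(R=fit.R, r_signed=fit.r_signed)
            else:
                X = features[list(spec.predictors)].to_numpy(dtype=float)
                fit = multivariate_fit(X, y)
                row.update(R=fit.R)
                if len(spec.predictors) == 2:
                    f1 = univariate_fit(X[:, 0], y)
                    f2 = univariate_fit(X[:, 1], y)
                    row.update(
                        R1=abs(f1.r_signed),
                        R2=abs(f2.r_signed),
                        cross_correlation=cross_correlation(X[:, 0], X[:, 1]),
                    )
            row.update(p_value=fit.p_value, n_used=fit.n_used)
            if spec.logistic_outcome and spec.logistic_outcome in features.columns:
                labels = features[spec.logistic_outcome].to_numpy(dtype=float)
                X = features[list(spec.predictors)].to_numpy(dtype=float)
                res = logistic_auroc_ci(
                    X,
                    labels,
                    n_iter=spec.n_iter,
                    split_fraction=spec.split_fraction,
                    seed=seed + k,
                )
                row.update(
                    auroc_mean=res.mean,
                    auroc_ci_low=res.ci_low,
                    auroc_ci_high=res.ci_high,
                )
        except (DegenerateFitError, CollinearityError, ClassError, KeyError) as exc:
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
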