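"""Two-stage diagnostic modelling: univariate logistic screen, L1-penalized
logistic feature selection with stratified 10-fold cross-validation, and a
final unpenalized multivariate logistic model with odds ratios, ROC/AUC
(DeLong confidence interval) and Hosmer-Lemeshow calibration.

The penalized solver is a glmnet-style cyclic coordinate descent on
standardized features: an outer iteratively-reweighted least-squares
quadratic approximation of the binomial log-likelihood, solved by inner
coordinate descent with soft thresholding, warm-started along a descending
log-spaced lambda path.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

from .stats import TestResult, benjamini_hochberg

_MIN_W = 1e-5


@dataclass
class AucResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


@dataclass
class LassoResult:
    selected: list[str]
    lambda_path: np.ndarray
    coef_path: np.ndarray  # (n_lambda, n_features) on the original scale
    cv_deviance: np.ndarray
    cv_deviance_se: np.ndarray
    lambda_min: float
    n_folds: int
    seed: int
    feature_ids: list[str]


@dataclass
class DiagnosticModel:
    feature_ids: list[str]
    intercept: float
    coefficients: dict[str, float]
    odds_ratios: dict[str, tuple[float, float, float]]  # OR, CI low, CI high
    p_values: dict[str, float]
    auc: AucResult | None = None
    c_index: float | None = None
    cv_folds: int = 10
    lambda_min: float | None = None
    seed: int | None = None

    def linear_predictor(self, matrix: pd.DataFrame) -> pd.Series:
        missing = [f for f in self.feature_ids if f not in matrix.index]
        if missing:
            raise ValueError(f"features missing from matrix: {missing}")
        x = matrix.loc[self.feature_ids].to_numpy(dtype=float).T
        beta = np.array([self.coefficients[f] for f in self.feature_ids])
        return pd.Series(self.intercept + x @ beta, index=matrix.columns)

    def predict_proba(self, matrix: pd.DataFrame) -> pd.Series:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(matrix)))

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, default=float)

    @classmethod
    def from_json(cls, path) -> "DiagnosticModel":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("auc"):
            d["auc"] = AucResult(**d["auc"])
        d["odds_ratios"] = {k: tuple(v) for k, v in d["odds_ratios"].items()}
        return cls(**d)


def _as_binary(groups) -> np.ndarray:
    g = pd.Series(np.asarray(groups))
    lvls = sorted(g.unique())
    if len(lvls) != 2:
        raise ValueError("binary outcome required")
    positive = "case" if "case" in lvls else lvls[-1]
    return (g == positive).to_numpy(dtype=float)


def univariate_logistic_screen(
    matrix: pd.DataFrame, groups, alpha: float = 0.05
) -> tuple[list[str], pd.DataFrame]:
    """Per-feature single-predictor logistic fits; keep Wald p < alpha.

    Perfectly separating features are flagged and kept with a warning.
    """
    y = _as_binary(groups)
    rows, kept = [], []
    for name, row in matrix.iterrows():
        x = row.to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"feature {name!r} is constant")
        design = sm.add_constant(x)
        separated = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, design).fit(disp=0, maxiter=100, tol=1e-8)
            beta, p = fit.params[1], fit.pvalues[1]
            # boundary fits show diverging coefficients or exploding Wald SEs
            if not np.isfinite(p) or abs(beta) > 50 or fit.bse[1] > 1e3:
                separated = True
        except Exception:
            separated = True
        if separated:
            warnings.warn(f"feature {name!r}: perfect separation; kept", stacklevel=2)
            beta, p = np.inf, 0.0
        rows.append((name, beta, p, separated))
        if p < alpha:
            kept.append(name)
    table = pd.DataFrame(rows, columns=["feature", "coef", "p_value", "separated"])
    table["adjusted_p"] = benjamini_hochberg(np.clip(table["p_value"], 0, 1))
    return kept, table.set_index("feature")


def soft_threshold(z: np.ndarray | float, lam: float):
    return np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)


def lasso_gaussian_cd(
    x: np.ndarray, y: np.ndarray, lam: float, tol: float = 1e-10, max_iter: int = 10000
) -> np.ndarray:
    """Gaussian-loss LASSO by cyclic coordinate descent.

    Minimizes (1/2n)||y - X b||^2 + lam ||b||_1 (no intercept, X as given).
    This is the inner-loop primitive of the logistic solver; on an
    orthonormal design (X'X/n = I) the solution is soft_threshold(X'y/n, lam).
    """
    n, p = x.shape
    b = np.zeros(p)
    col_ss = (x**2).sum(axis=0) / n
    r = y.copy()
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            if col_ss[j] == 0:
                continue
            zj = x[:, j] @ r / n + col_ss[j] * b[j]
            bj = soft_threshold(zj, lam) / col_ss[j]
            if bj != b[j]:
                r -= x[:, j] * (bj - b[j])
                max_delta = max(max_delta, abs(bj - b[j]))
                b[j] = bj
        if max_delta < tol:
            break
    return b


def _logistic_lasso_path(
    x: np.ndarray, y: np.ndarray, lambdas: np.ndarray, tol: float = 1e-6,
    max_outer: int = 25, max_inner: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the penalized logistic path on standardized x, warm-started.

    Outer IRLS quadratic approximation; inner cyclic coordinate descent with
    covariance updates (the p x p weighted Gram matrix is formed once per
    outer step, so each coordinate update costs O(p)).  Returns
    (intercepts, coefs) with coefs of shape (n_lambda, p), on the
    standardized scale.
    """
    n, p = x.shape
    b = np.zeros(p)
    b0 = np.log(y.mean() / (1 - y.mean())) if 0 < y.mean() < 1 else 0.0
    intercepts = np.empty(len(lambdas))
    coefs = np.empty((len(lambdas), p))
    for li, lam in enumerate(lambdas):
        for _ in range(max_outer):
            eta = np.clip(b0 + x @ b, -30.0, 30.0)
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.clip(mu * (1 - mu), _MIN_W, None)
            z = eta + (y - mu) / w
            wx = x * w[:, None]
            gram = wx.T @ x / n  # A = X'WX/n
            q = wx.T @ z / n
            c = x.T @ w / n
            sw = w.sum()
            wz = w @ z
            b_outer = b.copy()
            diag = np.diag(gram).copy()
            for _ in range(max_inner):
                max_delta = abs_d0 = 0.0
                new_b0 = (wz - n * (c @ b)) / sw
                abs_d0 = abs(new_b0 - b0)
                b0 = new_b0
                for j in range(p):
                    zj = q[j] - b0 * c[j] - gram[j] @ b + diag[j] * b[j]
                    bj = soft_threshold(zj, lam) / diag[j]
                    if bj != b[j]:
                        max_delta = max(max_delta, abs(bj - b[j]))
                        b[j] = bj
                if max(max_delta, abs_d0) < tol:
                    break
            if np.max(np.abs(b - b_outer)) < 10 * tol:
                break
        intercepts[li], coefs[li] = b0, b
    return intercepts, coefs


def _binomial_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-10, 1 - 1e-10)
    return float(-2.0 * np.mean(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def lambda_max(x_std: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every coefficient is zero: max|X'(y-ybar)|/n."""
    n = x_std.shape[0]
    return float(np.max(np.abs(x_std.T @ (y - y.mean()))) / n)


def lasso_logistic_cv(
    matrix: pd.DataFrame,
    groups,
    n_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_decades: float = 4.0,
) -> LassoResult:
    """L1-penalized logistic feature selection with stratified CV.

    Features (matrix rows) are standardized inside the solver; the lambda
    grid is log-spaced from lambda_max down ``lambda_decades`` decades; folds
    are stratified by class; selection at the lambda minimizing mean CV
    binomial deviance; returned coefficients are on the original scale.
    """
    y = _as_binary(groups)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if min(n_pos, n_neg) < n_folds:
        raise ValueError(f"need at least {n_folds} samples per class for {n_folds}-fold CV")
    feats = list(matrix.index)
    x_raw = matrix.to_numpy(dtype=float).T
    mean, sd = x_raw.mean(axis=0), x_raw.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant feature(s) cannot be standardized")
    x = (x_raw - mean) / sd

    lmax = lambda_max(x, y)
    lambdas = np.logspace(np.log10(lmax), np.log10(lmax) - lambda_decades, n_lambda)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    dev = np.zeros((n_folds, n_lambda))
    for fi, (tr, te) in enumerate(skf.split(x, y)):
        b0s, bs = _logistic_lasso_path(x[tr], y[tr], lambdas)
        for li in range(n_lambda):
            dev[fi, li] = _binomial_deviance(y[te], b0s[li] + x[te] @ bs[li])
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
    li_min = int(np.argmin(mean_dev))
    lam_min = float(lambdas[li_min])

    b0s, bs = _logistic_lasso_path(x, y, lambdas)
    coef_path = bs / sd  # back to the original scale
    selected = [feats[j] for j in range(len(feats)) if bs[li_min, j] != 0.0]
    return LassoResult(
        selected=selected,
        lambda_path=lambdas,
        coef_path=coef_path,
        cv_deviance=mean_dev,
        cv_deviance_se=se_dev,
        lambda_min=lam_min,
        n_folds=n_folds,
        seed=seed,
        feature_ids=feats,
    )


def fit_multivariate_logistic(
    matrix: pd.DataFrame, groups, features: list[str]
) -> DiagnosticModel:
    """Unpenalized multivariate logistic fit with Wald odds-ratio CIs."""
    if not features:
        raise ValueError("no features supplied")
    missing = [f for f in features if f not in matrix.index]
    if missing:
        raise ValueError(f"features missing from matrix: {missing}")
    y = _as_binary(groups)
    n = len(y)
    if n <= len(features) + 1:
        raise ValueError("need more samples than features + 1")
    x = matrix.loc[features].to_numpy(dtype=float).T
    design = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=100)
    except Exception as exc:
        raise RuntimeError(
            "logistic fit did not converge after 100 iterations; reduce features"
        ) from exc
    if not (np.all(np.isfinite(fit.params)) and np.all(np.isfinite(fit.bse))):
        raise RuntimeError("logistic fit did not converge; reduce features")
    if np.max(np.abs(fit.params)) > 50:
        warnings.warn(
            "quasi-complete separation: coefficients are at the boundary and "
            "Wald intervals are unreliable",
            stacklevel=2,
        )
    beta = fit.params
    se = fit.bse
    ors = {
        f: (float(np.exp(beta[i + 1])),
            float(np.exp(beta[i + 1] - 1.96 * se[i + 1])),
            float(np.exp(beta[i + 1] + 1.96 * se[i + 1])))
        for i, f in enumerate(features)
    }
    model = DiagnosticModel(
        feature_ids=list(features),
        intercept=float(beta[0]),
        coefficients={f: float(beta[i + 1]) for i, f in enumerate(features)},
        odds_ratios=ors,
        p_values={f: float(fit.pvalues[i + 1]) for i, f in enumerate(features)},
    )
    scores = model.linear_predictor(matrix)
    model.auc = roc_auc(scores.to_numpy(), y)
    model.c_index = model.auc.auc  # identical for a binary outcome
    return model


def _midrank(v: np.ndarray) -> np.ndarray:
    return sps.rankdata(v, method="average")


def roc_auc(scores, labels) -> AucResult:
    """AUC by the Mann-Whitney midrank formula with a DeLong 95% CI."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    pos, neg = scores[y == 1], scores[y != 1]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_r = _midrank(np.concatenate([pos, neg]))
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong structural components
    v10 = (all_r[:m] - _midrank(pos)) / n
    v01 = 1.0 - (all_r[m:] - _midrank(neg)) / m
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    return AucResult(
        auc=float(auc),
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        n_pos=m,
        n_neg=n,
    )


def hosmer_lemeshow(probabilities, labels, g: int = 10) -> TestResult:
    """Hosmer-Lemeshow goodness-of-fit over g deciles of predicted risk."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(p) < 2 * g:
        raise ValueError("need n >= 2g observations")
    if g < 3:
        raise ValueError("need g >= 3 groups for a positive-df chi-square")
    order = np.argsort(p, kind="stable")
    groups = np.array_split(order, g)
    obs, exp, sizes = [], [], []
    for idx in groups:
        obs.append(y[idx].sum())
        exp.append(p[idx].sum())
        sizes.append(len(idx))
    # merge groups with zero expected count into their right neighbor
    i = 0
    while i < len(exp) and len(exp) > 1:
        if exp[i] == 0:
            j = i + 1 if i + 1 < len(exp) else i - 1
            warnings.warn("merged a zero-expected risk group with its neighbor", stacklevel=2)
            exp[j] += exp[i]
            obs[j] += obs[i]
            sizes[j] += sizes[i]
            del exp[i], obs[i], sizes[i]
        else:
            i += 1
    g_eff = len(exp)
    if g_eff < 3:
        raise ValueError("too few usable risk groups after merging")
    chi2 = 0.0
    for o, e, ng in zip(obs, exp, sizes):
        denom = e * (1.0 - e / ng)
        if denom > 0:
            chi2 += (o - e) ** 2 / denom
        elif o != e:
            chi2 = np.inf
    df = g_eff - 2
    return TestResult(statistic=float(chi2), p_value=float(sps.chi2.sf(chi2, df)))


def validate_external(model: DiagnosticModel, matrix: pd.DataFrame, groups) -> AucResult:
    """Apply frozen coefficients to an external cohort; no refitting."""
    y = _as_binary(groups)
    scores = model.linear_predictor(matrix)
    return roc_auc(scores.to_numpy(), y)
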