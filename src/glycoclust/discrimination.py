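"""T1D-status discrimination: nested logistic models, LRT, ROC/AUC,
GLM partial R2, permutation q-values, and glycan saturation.

All discrimination models contrast progressors against controls
(non-progressors excluded). The full model adds every cluster FPC to the
clinical covariates; the partial model adds only the clusters flagged by the
cluster association models. Model-fit AUCs are in-sample (apparent) and
therefore optimistic; the saturation analysis defaults to out-of-fold AUC,
since an apparent AUC inflates mechanically as random features are added.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

import statsmodels.api as sm

from glycoclust.data_io import AcaMatrix, ClinicalTable, ValidationError
from glycoclust.association import build_design
from glycoclust.profiles import ClusterScoreMatrix

CLINICAL_TERMS = ("sex_M", "fdr_yes", "hla_H", "draw_age")
DEFAULT_GRID = tuple([1] + list(range(10, 201, 10)))


@dataclass
class StatusModelFit:
    """A fitted logistic (or Gaussian-limit) status model."""

    tag: str  # null | partial | full | saturation | custom
    params: pd.Series
    deviance: float
    llf: float
    fitted: pd.Series
    auc: float
    y: pd.Series
    design: pd.DataFrame
    family: str = "binomial"

    @property
    def terms(self) -> list[str]:
        return list(self.design.columns)

    @property
    def df_model(self) -> int:
        return len(self.design.columns)


@dataclass
class PermutationResult:
    observed_auc: float
    null_aucs: np.ndarray
    q_value: float  # add-one convention (1 + #{null >= obs}) / (1 + n_perm)
    q_raw: float  # 1 - empirical percentile of the observed AUC
    seed: int

    @property
    def n_perm(self) -> int:
        return len(self.null_aucs)


# ---------------------------------------------------------------------------
# Core fitting


def _glm_family(family: str):
    if family == "binomial":
        return sm.families.Binomial()
    if family == "gaussian":
        return sm.families.Gaussian()
    raise ValidationError(f"unsupported family {family!r}")


def fit_glm(y: pd.Series, design: pd.DataFrame, tag: str = "custom",
            family: str = "binomial") -> StatusModelFit:
    """Fit a GLM (IRLS) and package coefficients, deviance and apparent AUC."""
    model = sm.GLM(y.to_numpy(dtype=float), design.to_numpy(dtype=float),
                   family=_glm_family(family))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100)
    fitted = pd.Series(res.fittedvalues, index=design.index)
    if family == "binomial" and y.nunique() == 2:
        _, auc = roc_auc(y, fitted)
    else:
        auc = np.nan
    if family == "binomial" and np.abs(res.params).max() > 50:
        warnings.warn(f"possible perfect separation in {tag} model; "
                      "coefficients capped by iteration limit")
    return StatusModelFit(
        tag=tag,
        params=pd.Series(res.params, index=design.columns),
        deviance=float(res.deviance),
        llf=float(res.llf),
        fitted=fitted,
        auc=float(auc) if np.isfinite(auc) else auc,
        y=y.astype(float),
        design=design,
        family=family,
    )


def _status_subset(clinical: ClinicalTable, sample_ids) -> tuple[pd.Series, pd.DataFrame]:
    """Progressors-vs-controls outcome and clinical design restricted to them."""
    design_all = build_design(clinical, sample_ids)
    groups = clinical.table.loc[design_all.index, "group"]
    keep = groups.isin(["progressor", "control"])
    design = design_all.loc[keep, ["const", *CLINICAL_TERMS]]
    y = (groups[keep] == "progressor").astype(float)
    if y.nunique() < 2:
        raise ValidationError("both progressors and controls are required")
    return y, design


def fit_status_model(
    clinical: ClinicalTable,
    scores: ClusterScoreMatrix,
    spec: str = "full",
    significant: list[int] | None = None,
) -> StatusModelFit:
    """Fit the null / partial / full discrimination model.

    null: clinical covariates only; full: clinical + all cluster FPCs;
    partial: clinical + the FPCs of ``significant`` clusters (as flagged by the
    cluster association models).
    """
    if spec not in ("null", "partial", "full"):
        raise ValidationError(f"unknown model spec {spec!r}")
    y, design = _status_subset(clinical, scores.sample_ids)
    if spec == "partial":
        if not significant:
            raise ValidationError("partial model needs a list of significant clusters")
        cols = [f"cluster_{c}" for c in significant]
        missing = [c for c in cols if c not in scores.scores.columns]
        if missing:
            raise ValidationError(f"clusters not in score matrix: {missing}")
    elif spec == "full":
        cols = list(scores.scores.columns)
    else:
        cols = []
    if cols:
        design = design.join(scores.scores.loc[design.index, cols])
    if design.isna().any().any():
        raise ValidationError("missing covariate or score values")
    return fit_glm(y, design, tag=spec)


def lrt(full: StatusModelFit, null: StatusModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested GLMs via the deviance difference."""
    if not set(null.terms).issubset(full.terms):
        raise ValidationError("null model is not nested in the full model")
    stat = null.deviance - full.deviance
    df = full.df_model - null.df_model
    if df == 0:
        return max(stat, 0.0), 0, 1.0
    p = float(stats.chi2.sf(max(stat, 0.0), df))
    return float(max(stat, 0.0)), int(df), p


# ---------------------------------------------------------------------------
# ROC / AUC


def roc_auc(labels, scores) -> tuple[pd.DataFrame, float]:
    """ROC curve over all thresholds and the Mann-Whitney (tie-corrected) AUC."""
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present")
    fpr, tpr, thresh = roc_curve(y, s)
    n1 = int((y == 1).sum())
    n0 = len(y) - n1
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresh})
    return curve, float(auc)


def _fast_auc(y: np.ndarray, s: np.ndarray) -> float:
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


# ---------------------------------------------------------------------------
# Variance-function R2 and partial R2


def glm_rsq(y: np.ndarray, mu: np.ndarray, mu0: np.ndarray, family: str) -> float:
    """Sum-of-squares coefficient of determination for a GLM on the response
    scale (Efron's R2): 1 - Sum (y-mu)^2 / Sum (y-mu0)^2 with mu0 the
    intercept-only fit.

    This is the member of the GLM R2 family that reduces exactly to the
    classical R2 for the Gaussian family, which keeps nested partial-R2
    decompositions interpretable across families. (A Pearson-residual-weighted
    variant is degenerate for binomial responses: its weighted residual sum
    stays near n for any correctly specified model, so explained-variance
    differences vanish asymptotically.)"""
    if family not in ("binomial", "gaussian"):
        raise ValidationError(f"unsupported family {family!r}")
    sse = float(((y - mu) ** 2).sum())
    sst = float(((y - mu0) ** 2).sum())
    return 1.0 - sse / sst


def partial_r2(full: StatusModelFit, term_groups: dict[str, list[str]]) -> pd.DataFrame:
    """Partial R2 of term groups: (R2_full - R2_reduced) / (1 - R2_reduced),
    with R2 the response-scale sum-of-squares GLM coefficient of determination.

    ``term_groups`` maps a group name to the design columns dropped together,
    e.g. all cluster FPCs, or the genetic components (sex + FDR + HLA risk).
    """
    y = full.y.to_numpy()
    design = full.design
    for name, cols in term_groups.items():
        missing = [c for c in cols if c not in design.columns]
        if missing:
            raise ValidationError(f"group {name!r} has terms not in the model: {missing}")
    mu0 = fit_glm(full.y, design[["const"]], tag="intercept", family=full.family).fitted.to_numpy()
    mu_full = full.fitted.to_numpy()
    r2_full = glm_rsq(y, mu_full, mu0, full.family)
    rows = []
    for name, cols in term_groups.items():
        reduced_cols = [c for c in design.columns if c not in set(cols)]
        red = fit_glm(full.y, design[reduced_cols], tag="reduced", family=full.family)
        r2_red = glm_rsq(y, red.fitted.to_numpy(), mu0, full.family)
        rows.append((name, (r2_full - r2_red) / (1.0 - r2_red), r2_red))
    out = pd.DataFrame(rows, columns=["group", "partial_r2", "r2_reduced"])
    out.attrs["r2_full"] = r2_full
    return out


def default_term_groups(full: StatusModelFit) -> dict[str, list[str]]:
    """Per-term groups plus the aggregates used for variance decomposition:
    all cluster FPCs together, and the genetic components (sex, FDR, HLA)."""
    groups: dict[str, list[str]] = {}
    cluster_cols = [c for c in full.terms if c.startswith("cluster_")]
    for t in full.terms:
        if t == "const":
            continue
        groups[t] = [t]
    if cluster_cols:
        groups["all_clusters"] = cluster_cols
    groups["genetic_components"] = [t for t in ("sex_M", "fdr_yes", "hla_H") if t in full.terms]
    return groups


# ---------------------------------------------------------------------------
# Fast IRLS used inside permutation loops


def _irls_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 50,
                   tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton-Raphson / IRLS logistic fit; returns (beta, fitted, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        xw = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ xw, xw.T @ z)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(X.T @ xw, xw.T @ z, rcond=None)[0]
        if not np.all(np.isfinite(beta_new)):
            return beta, 1.0 / (1.0 + np.exp(-(X @ beta))), False
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    return beta, mu, converged


# ---------------------------------------------------------------------------
# Permutation q-value


def permutation_q(
    clinical: ClinicalTable,
    scores: ClusterScoreMatrix,
    model_spec: str = "full",
    n_perm: int = 10_000,
    seed: int = 0,
    significant: list[int] | None = None,
) -> PermutationResult:
    """Permutation q-value for a discrimination model's apparent AUC.

    Outcome labels are shuffled (covariate rows, including the FPC columns,
    stay fixed), the model is refit per iteration, and the in-sample AUC is
    recorded to form the null distribution. The primary q uses the add-one
    convention q = (1 + #{null >= observed}) / (1 + n_perm), which avoids
    reporting exactly zero; the raw 1 - percentile version is also returned.
    """
    fit = fit_status_model(clinical, scores, spec=model_spec, significant=significant)
    X = fit.design.to_numpy(dtype=float)
    y = fit.y.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    null_aucs = np.empty(n_perm)
    failures = 0
    for i in range(n_perm):
        yp = rng.permutation(y)
        _, mu, converged = _irls_logistic(X, yp)
        if not converged and not np.all(np.isfinite(mu)):
            failures += 1
            null_aucs[i] = np.nan
            continue
        null_aucs[i] = _fast_auc(yp, mu)
    if failures > 0.01 * n_perm:
        raise ValidationError(
            f"{failures}/{n_perm} permutation fits failed; check the design"
        )
    valid = null_aucs[np.isfinite(null_aucs)]
    q = (1.0 + float((valid >= fit.auc).sum())) / (1.0 + len(valid))
    q_raw = float((valid >= fit.auc).mean())
    return PermutationResult(
        observed_auc=fit.auc, null_aucs=valid, q_value=q, q_raw=q_raw, seed=seed
    )


# ---------------------------------------------------------------------------
# Saturation analysis


def saturation(
    matrix: AcaMatrix,
    clinical: ClinicalTable,
    grid: tuple[int, ...] = DEFAULT_GRID,
    n_iter: int = 1000,
    seed: int = 0,
    lambda_policy: str | float = "cv",
    n_lambdas: int = 50,
    cv_folds: int = 5,
    auc_mode: str = "oof",
) -> pd.DataFrame:
    """Ridge-logistic AUC as a function of the number of random glycans.

    For each m in ``grid`` and each iteration, m glycans are sampled uniformly
    without replacement and an L2-penalized logistic model of status on the
    clinical covariates plus those glycans (columns standardized, as glmnet
    does) is fitted. ``lambda_policy`` is either "cv" (penalty chosen per fit
    by ``cv_folds``-fold cross-validated log-loss over ``n_lambdas`` log-spaced
    values) or a fixed positive penalty.

    ``auc_mode`` selects how the AUC per iteration is measured:

    - "oof" (default): pooled out-of-fold AUC from a stratified K-fold split,
      the quantity cv.glmnet-style workflows report. Under pure-noise glycans
      this stays at the clinical-only level instead of inflating with m.
    - "apparent": in-sample AUC of the fit on all rows. Optimistic; with many
      random features it rises mechanically, so use it only for like-for-like
      comparison with apparent-AUC model fits.

    m = 0 is allowed: the clinical-only unpenalized fit (its apparent AUC in
    "apparent" mode, pooled out-of-fold AUC in "oof" mode).

    Returns a frame with columns m, mean_auc, ci_low, ci_high, n_iter
    (percentile 95% interval of the per-iteration AUC sample).
    """
    if max(grid) > matrix.shape[1]:
        raise ValidationError(
            f"grid maximum {max(grid)} exceeds available glycans ({matrix.shape[1]})"
        )
    if auc_mode not in ("oof", "apparent"):
        raise ValidationError(f"unknown auc_mode {auc_mode!r}")
    y, design = _status_subset(clinical, matrix.sample_ids)
    base = design.drop(columns=["const"])
    Xc = base.to_numpy(dtype=float)
    Xc = (Xc - Xc.mean(axis=0)) / np.where(Xc.std(axis=0) == 0, 1.0, Xc.std(axis=0))
    values = matrix.values.loc[design.index].to_numpy(dtype=float)
    sd = values.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (values - values.mean(axis=0)) / sd
    yv = y.to_numpy(dtype=float)
    n_glycans = Z.shape[1]
    rng = np.random.default_rng(seed)

    if lambda_policy == "cv":
        def make_model():
            return LogisticRegressionCV(
                Cs=np.logspace(-4, 4, n_lambdas),
                cv=cv_folds,
                penalty="l2",
                scoring="neg_log_loss",
                max_iter=500,
                random_state=0,
            )
    else:
        lam = float(lambda_policy)
        if lam <= 0:
            raise ValidationError("fixed ridge penalty must be positive")

        def make_model():
            return LogisticRegression(C=1.0 / lam, penalty="l2", max_iter=500)

    def one_auc(X: np.ndarray, fold_seed: int, penalized: bool = True) -> float:
        if auc_mode == "apparent":
            if penalized:
                model = make_model()
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(X, yv)
                probs = model.predict_proba(X)[:, 1]
            else:
                probs = _irls_logistic(np.hstack([np.ones((len(yv), 1)), X]), yv)[1]
            return _fast_auc(yv, probs)
        splitter = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=fold_seed)
        oof = np.empty(len(yv))
        for train, test in splitter.split(X, yv):
            if penalized:
                model = make_model()
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(X[train], yv[train])
                oof[test] = model.predict_proba(X[test])[:, 1]
            else:
                Xt = np.hstack([np.ones((len(train), 1)), X[train]])
                beta, _, _ = _irls_logistic(Xt, yv[train])
                eta = np.hstack([np.ones((len(test), 1)), X[test]]) @ beta
                oof[test] = 1.0 / (1.0 + np.exp(-eta))
        return _fast_auc(yv, oof)

    rows = []
    for m in grid:
        if m == 0:
            auc0 = one_auc(Xc, int(rng.integers(2**31)), penalized=False)
            rows.append((0, auc0, auc0, auc0, 1))
            continue
        aucs = np.empty(n_iter)
        for it in range(n_iter):
            cols = rng.choice(n_glycans, size=m, replace=False)
            X = np.hstack([Xc, Z[:, cols]])
            aucs[it] = one_auc(X, int(rng.integers(2**31)))
        rows.append(
            (
                int(m),
                float(aucs.mean()),
                float(np.percentile(aucs, 2.5)),
                float(np.percentile(aucs, 97.5)),
                n_iter,
            )
        )
    out = pd.DataFrame(rows, columns=["m", "mean_auc", "ci_low", "ci_high", "n_iter"])
    out.attrs["seed"] = seed
    out.attrs["lambda_policy"] = lambda_policy
    out.attrs["auc_mode"] = auc_mode
    return out
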