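"""Linear association models for cluster scores, single glycans and genotype.

The shared design is: response ~ progressor + non_progressor (control as the
reference level of a three-level disease status) + sex + first-degree-relative
status + HLA risk + age at blood draw. Samples with unknown HLA risk are
excluded listwise. All p-values are two-sided; p < 0.05 flags significance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from glycoclust.data_io import AcaMatrix, ClinicalTable, ValidationError
from glycoclust.profiles import ClusterScoreMatrix

DESIGN_TERMS = ("progressor", "non_progressor", "sex_M", "fdr_yes", "hla_H", "draw_age")


def build_design(clinical: ClinicalTable, sample_ids=None) -> pd.DataFrame:
    """Dummy-coded covariate design with control/F/no/L as reference levels.

    Rows with hla_risk == "unknown" are dropped. Includes a constant column.
    """
    df = clinical.table
    if sample_ids is not None:
        df = df.loc[[s for s in sample_ids if s in df.index]]
    df = df[df["hla_risk"] != "unknown"]
    design = pd.DataFrame(index=df.index)
    design["const"] = 1.0
    design["progressor"] = (df["group"] == "progressor").astype(float)
    design["non_progressor"] = (df["group"] == "non_progressor").astype(float)
    design["sex_M"] = (df["sex"] == "M").astype(float)
    design["fdr_yes"] = (df["fdr"] == "yes").astype(float)
    design["hla_H"] = (df["hla_risk"] == "H").astype(float)
    design["draw_age"] = df["draw_age"].astype(float)
    return design


def _check_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank growth
        collinear = []
        cols: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, cols + [j]]
            if np.linalg.matrix_rank(trial) == len(cols):
                collinear.append(design.columns[j])
            else:
                cols.append(j)
        raise ValidationError(f"rank-deficient design; collinear terms: {collinear}")


def _ols_rows(y: pd.Series, design: pd.DataFrame, response_id: str) -> list[tuple]:
    fit = sm.OLS(y.to_numpy(dtype=float), design.to_numpy(dtype=float)).fit()
    ci = fit.conf_int(alpha=0.05)
    rows = []
    for j, term in enumerate(design.columns):
        name = "intercept" if term == "const" else term
        rows.append(
            (
                response_id,
                name,
                float(fit.params[j]),
                float(ci[j, 0]),
                float(ci[j, 1]),
                float(fit.pvalues[j]),
                int(fit.nobs),
            )
        )
    return rows


def fit_cluster_models(
    scores: ClusterScoreMatrix, clinical: ClinicalTable
) -> pd.DataFrame:
    """OLS of each cluster FPC on disease status and clinical covariates.

    One row per (cluster, term): estimate, Wald 95% CI, two-sided p, n, and a
    significance flag at p < 0.05.
    """
    design = build_design(clinical, scores.sample_ids)
    if design.empty or len(design) < len(design.columns) + 1:
        raise ValidationError("too few complete samples for the model")
    _check_rank(design)
    rows: list[tuple] = []
    for col in scores.scores.columns:
        y = scores.scores.loc[design.index, col]
        rows.extend(_ols_rows(y, design, col))
    out = pd.DataFrame(
        rows, columns=["response", "term", "estimate", "ci_low", "ci_high", "p_value", "n"]
    )
    out["significant"] = out["p_value"] < 0.05
    return out


def significant_clusters(cluster_models: pd.DataFrame) -> list[int]:
    """Cluster labels whose progressor or non-progressor contrast has p < 0.05."""
    mask = cluster_models["term"].isin(["progressor", "non_progressor"]) & (
        cluster_models["p_value"] < 0.05
    )
    labels = sorted(
        {int(r.split("_")[1]) for r in cluster_models.loc[mask, "response"]}
    )
    return labels


def per_glycan_association(
    matrix: AcaMatrix, clinical: ClinicalTable, log1p: bool = False
) -> pd.DataFrame:
    """Univariate-per-glycan linear models with the shared covariate design.

    Emits, for each glycan and each disease contrast, the estimate (direction),
    two-sided p, -log10 p (radar-chart value; the p = 0.05 ring sits at
    -log10(0.05) ~ 1.301), and a significance mask.
    """
    design = build_design(clinical, matrix.sample_ids)
    if design.empty:
        raise ValidationError("no complete samples shared with the matrix")
    _check_rank(design)
    values = matrix.values.loc[design.index]
    if log1p:
        values = np.log1p(values)
    X = design.to_numpy(dtype=float)
    Y = values.to_numpy(dtype=float)
    # one multi-response OLS solve; per-column inference
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y
    resid = Y - X @ B
    dof = X.shape[0] - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    tvals = B / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    terms = list(design.columns)
    rows = []
    for contrast in ("progressor", "non_progressor"):
        j = terms.index(contrast)
        for g_idx, glycan in enumerate(values.columns):
            p = float(pvals[j, g_idx])
            est = float(B[j, g_idx])
            rows.append(
                (
                    glycan,
                    contrast,
                    est,
                    p,
                    float(-np.log10(max(p, np.finfo(float).tiny))),
                    "up" if est > 0 else "down",
                    p < 0.05,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["glycan", "contrast", "estimate", "p_value", "neg_log10_p", "direction", "significant"],
    )


def genotype_comparison(levels: pd.Series, genotypes: pd.Series) -> pd.DataFrame:
    """One-way ANOVA + Tukey HSD pairwise contrasts across G/G, G/A, A/A,
    followed by BH adjustment across the three contrasts.

    ``levels`` are per-sample antibody levels; both series are aligned on
    sample id. Returns one row per pairwise contrast with the mean difference,
    Tukey-adjusted p (studentized-range distribution) and BH-adjusted p, plus
    per-group means and five-number summaries as a frame attribute
    ``.attrs["group_summaries"]``.
    """
    common = levels.index.intersection(genotypes.index)
    lv = levels.loc[common].astype(float)
    gt = genotypes.loc[common].astype(str)
    groups = sorted(gt.unique())
    if len(groups) < 2:
        raise ValidationError("need at least two genotype groups")
    arrays = [lv[gt == g].to_numpy() for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValidationError("empty genotype group")
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    rows = []
    if lv.nunique() == 1:
        # degenerate: identical values everywhere -> no differences to test
        f_stat, anova_p = 0.0, 1.0
        rows = [(a, b, 0.0, 1.0) for a, b in pairs]
    else:
        f_stat, anova_p = stats.f_oneway(*arrays)
        tk = pairwise_tukeyhsd(lv.to_numpy(), gt.to_numpy())
        # statsmodels orders contrasts over sorted group labels with i < j
        for (a, b), diff, p in zip(pairs, tk.meandiffs, tk.pvalues):
            rows.append((a, b, float(diff), float(p)))
    out = pd.DataFrame(rows, columns=["group_1", "group_2", "mean_diff", "tukey_p"])
    out["bh_p"] = multipletests(out["tukey_p"], method="fdr_bh")[1]
    out.attrs["anova_f"] = float(f_stat)
    out.attrs["anova_p"] = float(anova_p)
    summaries = {}
    for g, arr in zip(groups, arrays):
        summaries[g] = {
            "n": int(len(arr)),
            "mean": float(arr.mean()),
            "min": float(arr.min()),
            "q1": float(np.percentile(arr, 25)),
            "median": float(np.median(arr)),
            "q3": float(np.percentile(arr, 75)),
            "max": float(arr.max()),
        }
    out.attrs["group_summaries"] = summaries
    return out
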