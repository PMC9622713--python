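"""Community annotation and per-sample cluster summaries.

Enrichment: each (cluster, functional class) pair is a 2x2 table tested with
a one-sided Fisher's exact test (enrichment direction), BH-adjusted across all
pairs. Cluster level per sample is the first principal component (FPC) of the
cluster's z-scored glycan columns, sign-oriented so that a higher score means
higher average antibody level in the cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from glycoclust.data_io import AcaMatrix, GlycanPanel, ValidationError
from glycoclust.network import CommunityPartition


@dataclass
class ClusterScoreMatrix:
    """Per-sample FPC score for each cluster, plus loadings and diagnostics."""

    scores: pd.DataFrame  # samples x clusters, columns "cluster_<label>"
    loadings: dict[int, pd.Series]  # cluster -> glycan loading (unit norm)
    explained_variance: dict[int, float]
    orientation: dict[int, int]  # +1 / -1 sign applied per cluster

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def cluster_labels(self) -> list[int]:
        return [int(c.split("_")[1]) for c in self.scores.columns]


def class_enrichment(
    partition: CommunityPartition, panel: GlycanPanel
) -> pd.DataFrame:
    """Fisher-exact functional-class enrichment per cluster.

    Returns a table with one row per (cluster, class): the overlap count, odds
    ratio, one-sided (greater) p-value, two-sided p-value, and BH-adjusted
    one-sided p across all pairs.
    """
    classes = panel.table["functional_class"]
    missing = [g for g in partition.assignment if g not in classes.index]
    if missing:
        raise ValidationError(f"glycans without a class: {missing}")
    glycans = list(partition.assignment)
    n_total = len(glycans)
    cls = classes.loc[glycans]
    rows = []
    for label in partition.labels():
        in_cluster = {g for g in glycans if partition.assignment[g] == label}
        for c in sorted(cls.unique()):
            in_class = set(cls.index[cls == c])
            a = len(in_cluster & in_class)
            b = len(in_cluster) - a
            c_ = len(in_class) - a
            d = n_total - a - b - c_
            table = [[a, b], [c_, d]]
            odds, p_greater = stats.fisher_exact(table, alternative="greater")
            _, p_two = stats.fisher_exact(table, alternative="two-sided")
            rows.append((label, c, a, odds, p_greater, p_two))
    out = pd.DataFrame(
        rows,
        columns=["cluster", "functional_class", "count", "odds_ratio", "p_value", "p_two_sided"],
    )
    out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def cluster_fpc(matrix: AcaMatrix, partition: CommunityPartition) -> ClusterScoreMatrix:
    """First-principal-component score of each cluster per sample.

    Columns are z-scored before PCA (MFI scales differ by orders of magnitude
    across glycans, so covariance PCA would be dominated by bright glycans).
    The FPC sign is oriented so the score correlates positively with the
    per-sample mean of the cluster's z-scored glycans; singleton clusters fall
    back to the z-scored glycan itself with a warning.
    """
    values = matrix.values
    scores = {}
    loadings: dict[int, pd.Series] = {}
    evar: dict[int, float] = {}
    orientation: dict[int, int] = {}
    for label in partition.labels():
        members = [g for g in partition.members(label) if g in values.columns]
        if not members:
            raise ValidationError(f"cluster {label} has no glycans in the matrix")
        sub = values[members].to_numpy(dtype=float)
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [m for m, s in zip(members, sd) if s == 0]
            raise ValidationError(f"constant glycan column(s) in cluster {label}: {bad}")
        z = (sub - mean) / sd
        if len(members) == 1:
            warnings.warn(f"cluster {label} is a singleton; using its z-scored glycan")
            score = z[:, 0]
            load = pd.Series([1.0], index=members)
            ev, sign = 1.0, 1
        else:
            u, s, vt = np.linalg.svd(z, full_matrices=False)
            score = u[:, 0] * s[0]
            load = pd.Series(vt[0], index=members)
            ev = float(s[0] ** 2 / (s**2).sum())
            ref = z.mean(axis=1)
            r = np.corrcoef(score, ref)[0, 1] if np.std(score) > 0 else 0.0
            sign = -1 if r < 0 else 1
            score = sign * score
            load = sign * load
        scores[f"cluster_{label}"] = score
        loadings[label] = load
        evar[label] = ev
        orientation[label] = sign if len(members) > 1 else 1
    frame = pd.DataFrame(scores, index=values.index)
    return ClusterScoreMatrix(
        scores=frame, loadings=loadings, explained_variance=evar, orientation=orientation
    )


def cluster_correlation(scores: ClusterScoreMatrix) -> pd.DataFrame:
    """Spearman correlation between cluster FPCs, ordered by average-linkage
    hierarchical clustering on 1 - |rho|."""
    frame = scores.scores
    if frame.shape[1] < 2:
        raise ValidationError("need at least two clusters")
    constant = [c for c in frame.columns if frame[c].nunique() == 1]
    if constant:
        warnings.warn(f"constant score column(s), correlations undefined: {constant}")
    rho, _ = stats.spearmanr(frame.to_numpy())
    rho = np.atleast_2d(rho)
    corr = pd.DataFrame(rho, index=frame.columns, columns=frame.columns)
    dist = 1.0 - corr.abs().to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.nan_to_num(dist, nan=1.0)
    link = average(squareform(dist, checks=False))
    order = leaves_list(link)
    cols = [frame.columns[i] for i in order]
    return corr.loc[cols, cols]
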