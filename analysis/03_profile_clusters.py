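"""Annotate communities by functional-class enrichment and score samples.

Computes the Fisher-exact class enrichment of every (cluster, class) pair with
BH adjustment, the per-sample first-principal-component (FPC) level of each
cluster in the clinically balanced cohort, and the Spearman correlation
structure among cluster scores.
"""

import argparse
from pathlib import Path

import pandas as pd

from glycoclust.data_io import read_aca, read_panel
from glycoclust.network import CommunityPartition
from glycoclust.profiles import class_enrichment, cluster_correlation, cluster_fpc


def load_partition(path) -> CommunityPartition:
    assign = pd.read_csv(path, dtype={"glycan_id": str}).set_index("glycan_id")["cluster"]
    return CommunityPartition(
        assignment=assign.to_dict(), modularity=float("nan"), seed=0, resolution=1.0
    )


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dir", type=str, default="results/analysis")
    args = ap.parse_args()
    out = Path(args.dir)

    panel = read_panel(out / "panel.csv")
    aca_b = read_aca(out / "aca_cohort_b.csv", panel, cohort="B")
    partition = load_partition(out / "partition.csv")

    enrichment = class_enrichment(partition, panel)
    enrichment.to_csv(out / "enrichment.csv", index=False)
    top = (
        enrichment[enrichment.p_adjusted < 0.05]
        .sort_values("p_adjusted")
        .groupby("cluster")
        .head(2)
    )
    print(f"{(enrichment.p_adjusted < 0.05).sum()} enriched (cluster, class) pairs at BH 0.05")
    print(top[["cluster", "functional_class", "count", "p_adjusted"]].to_string(index=False))

    scores = cluster_fpc(aca_b, partition)
    scores.scores.to_csv(out / "cluster_scores.csv", index_label="sample_id")
    ev = pd.Series(scores.explained_variance).round(3)
    print(f"FPC explained-variance fraction per cluster:\n{ev.to_string()}")

    corr = cluster_correlation(scores)
    corr.to_csv(out / "cluster_correlation.csv")
    print("cluster FPC Spearman correlations written (hierarchically ordered)")


if __name__ == "__main__":
    main()
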