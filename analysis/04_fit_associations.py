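"""Fit the association models: cluster FPCs, single glycans, genotype.

Model 1 per cluster: FPC ~ progressor + non-progressor + sex + FDR status +
HLA risk + draw age (control as reference). Per-glycan univariate models share
the design and report -log10 p radar values for the disease contrasts. The
genotype comparison runs Tukey HSD + BH across G/G vs G/A vs A/A on the
genotype-dosed glycan's log level.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from glycoclust.association import (
    fit_cluster_models,
    genotype_comparison,
    per_glycan_association,
    significant_clusters,
)
from glycoclust.data_io import read_aca, read_clinical, read_panel
from glycoclust.profiles import ClusterScoreMatrix


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dir", type=str, default="results/analysis")
    ap.add_argument("--genotype-glycan", type=str, default="G098")
    args = ap.parse_args()
    out = Path(args.dir)

    panel = read_panel(out / "panel.csv")
    aca_a = read_aca(out / "aca_cohort_a.csv", panel, cohort="A")
    aca_b = read_aca(out / "aca_cohort_b.csv", panel, cohort="B")
    clinical = read_clinical(out / "clinical.csv")
    frame = pd.read_csv(out / "cluster_scores.csv").set_index("sample_id")
    scores = ClusterScoreMatrix(
        scores=frame, loadings={}, explained_variance={}, orientation={}
    )

    cluster_models = fit_cluster_models(scores, clinical)
    cluster_models.to_csv(out / "cluster_associations.csv", index=False)
    sig = significant_clusters(cluster_models)
    print(f"clusters associated with disease status (p < 0.05): {sig}")
    hits = cluster_models[
        cluster_models.term.isin(["progressor", "non_progressor"]) & cluster_models.significant
    ]
    print(hits[["response", "term", "estimate", "ci_low", "ci_high", "p_value"]].round(4).to_string(index=False))

    glycan_assoc = per_glycan_association(aca_b, clinical)
    glycan_assoc.to_csv(out / "per_glycan_associations.csv", index=False)
    n_sig = glycan_assoc.groupby("contrast")["significant"].sum()
    print(f"significant glycans per contrast:\n{n_sig.to_string()}")

    geno_path = out / "genotypes.csv"
    if geno_path.exists():
        genotypes = pd.read_csv(geno_path, dtype=str).set_index("sample_id")["genotype"]
        levels = np.log(pd.concat([aca_a.values, aca_b.values])[args.genotype_glycan])
        cmp_ = genotype_comparison(levels, genotypes)
        cmp_.to_csv(out / "genotype_comparison.csv", index=False)
        print(f"genotype comparison on {args.genotype_glycan} (log level):")
        print(cmp_.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
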