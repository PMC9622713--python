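"""End-to-end orchestration: synth/ingest -> network -> clusters -> models.

A run is a pure function of (inputs, config, seeds): every stage writes its
artifact under the output directory and a manifest records seeds, package
version and SHA-256 checksums, so re-running the same config reproduces the
checksums byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import glycoclust
from glycoclust.data_io import (
    ValidationError,
    read_aca,
    read_clinical,
    read_panel,
    write_aca,
    write_clinical,
    write_panel,
)
from glycoclust.synthetic import generate_cohorts, generate_panel, spec_from_dict
from glycoclust.network import fuzzy_knn_graph, louvain, merge_graphs
from glycoclust.profiles import class_enrichment, cluster_fpc
from glycoclust.association import (
    fit_cluster_models,
    genotype_comparison,
    per_glycan_association,
    significant_clusters,
)
from glycoclust.discrimination import (
    default_term_groups,
    fit_status_model,
    lrt,
    partial_r2,
    permutation_q,
    saturation,
)

log = logging.getLogger("glycoclust")

ARTIFACTS = (
    "panel.csv",
    "aca_cohort_a.csv",
    "aca_cohort_b.csv",
    "clinical.csv",
    "genotypes.csv",
    "truth.json",
    "graph_edges.csv",
    "partition.csv",
    "enrichment.csv",
    "cluster_scores.csv",
    "model_report.json",
)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-loadable)."""

    out_dir: str = "glycoclust_run"
    seed: int = 0
    synth: dict | None = field(default_factory=dict)  # None -> load from inputs
    inputs: dict | None = None  # panel / aca_a / aca_b / clinical / genotypes paths
    k: int = 5
    resolution: float = 1.0
    log1p: bool = False
    n_perm: int = 1000
    saturation_grid: tuple[int, ...] = tuple([1] + list(range(10, 201, 10)))
    saturation_n_iter: int = 50
    lambda_policy: str | float = 1.0
    genotype_glycan: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        if "saturation_grid" in raw:
            raw["saturation_grid"] = tuple(raw["saturation_grid"])
        return cls(**raw)

    def validate(self) -> None:
        if self.synth is None and not self.inputs:
            raise ValidationError("either synth spec or input paths must be given")
        if self.inputs:
            for key, p in self.inputs.items():
                if p and not Path(p).exists():
                    raise ValidationError(f"input path for {key!r} does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and return the run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    report: dict = {"config": _jsonify(asdict(config)), "stages": {}}

    def stage(name):
        log.info("stage %s (t=%.1fs)", name, time.time() - t0)
        report["stages"][name] = round(time.time() - t0, 3)

    # --- data -------------------------------------------------------------
    truth = None
    if config.synth is not None:
        stage("synth")
        spec_dict = dict(config.synth)
        spec_dict.setdefault("seed", config.seed)
        spec = spec_from_dict(spec_dict)
        panel = generate_panel(spec)
        aca_a, aca_b, clinical, genotypes, truth = generate_cohorts(spec, panel)
        if config.genotype_glycan is None:
            config.genotype_glycan = panel.glycan_ids[spec.genotype_feature[0]]
    else:
        stage("ingest")
        paths = config.inputs
        panel = read_panel(paths["panel"])
        aca_a = read_aca(paths["aca_a"], panel, cohort="A")
        aca_b = read_aca(paths["aca_b"], panel, cohort="B")
        clinical = read_clinical(paths["clinical"])
        genotypes = (
            pd.read_csv(paths["genotypes"], dtype=str).set_index("sample_id")["genotype"]
            if paths.get("genotypes")
            else None
        )

    write_panel(panel, out / "panel.csv")
    write_aca(aca_a, out / "aca_cohort_a.csv")
    write_aca(aca_b, out / "aca_cohort_b.csv")
    write_clinical(clinical, out / "clinical.csv")
    if genotypes is not None:
        genotypes.rename("genotype").to_csv(out / "genotypes.csv", index_label="sample_id")
    if truth is not None:
        truth.to_json(out / "truth.json")
    else:
        (out / "truth.json").write_text(json.dumps({"synthetic": False}))

    # --- network ----------------------------------------------------------
    stage("network")
    g_a = fuzzy_knn_graph(aca_a, k=config.k, log1p=config.log1p, provenance="cohort-A only")
    g_b = fuzzy_knn_graph(aca_b, k=config.k, log1p=config.log1p, provenance="cohort-B only")
    merged = merge_graphs(g_a, g_b)
    partition = louvain(merged, seed=config.seed, resolution=config.resolution)
    merged.to_edge_frame().to_csv(out / "graph_edges.csv", index=False)
    pd.Series(partition.assignment, name="cluster").rename_axis("glycan_id").to_csv(
        out / "partition.csv"
    )
    report["n_communities"] = partition.n_communities
    report["modularity"] = partition.modularity

    # --- cluster profiles -------------------------------------------------
    stage("profiles")
    enrichment = class_enrichment(partition, panel)
    enrichment.to_csv(out / "enrichment.csv", index=False)
    # the clinically balanced cohort (B) feeds the association and
    # discrimination models; clustering used both cohorts
    scores = cluster_fpc(aca_b, partition)
    scores.scores.to_csv(out / "cluster_scores.csv", index_label="sample_id")

    # --- association ------------------------------------------------------
    stage("association")
    cluster_models = fit_cluster_models(scores, clinical)
    sig = significant_clusters(cluster_models)
    glycan_assoc = per_glycan_association(aca_b, clinical, log1p=config.log1p)
    geno_cmp = None
    if genotypes is not None and config.genotype_glycan is not None:
        levels = pd.concat([aca_a.values, aca_b.values])[config.genotype_glycan]
        geno_cmp = genotype_comparison(levels, genotypes)

    # --- discrimination ---------------------------------------------------
    stage("discrimination")
    fit_null = fit_status_model(clinical, scores, spec="null")
    fit_full = fit_status_model(clinical, scores, spec="full")
    lrt_stat, lrt_df, lrt_p = lrt(fit_full, fit_null)
    fit_partial = (
        fit_status_model(clinical, scores, spec="partial", significant=sig) if sig else None
    )
    perm = permutation_q(
        clinical, scores, model_spec="full", n_perm=config.n_perm, seed=config.seed
    )
    pr2 = partial_r2(fit_full, default_term_groups(fit_full))
    sat = saturation(
        aca_b,
        clinical,
        grid=config.saturation_grid,
        n_iter=config.saturation_n_iter,
        seed=config.seed,
        lambda_policy=config.lambda_policy,
    )

    model_report = {
        "cluster_models": cluster_models,
        "significant_clusters": sig,
        "per_glycan_association": glycan_assoc,
        "genotype_comparison": geno_cmp,
        "discrimination": {
            "auc_null": fit_null.auc,
            "auc_full": fit_full.auc,
            "auc_partial": fit_partial.auc if fit_partial is not None else None,
            "lrt": {"statistic": lrt_stat, "df": lrt_df, "p_value": lrt_p},
            "permutation": {
                "observed_auc": perm.observed_auc,
                "q_value": perm.q_value,
                "q_raw": perm.q_raw,
                "n_perm": perm.n_perm,
            },
            "partial_r2": pr2,
            "r2_full": pr2.attrs["r2_full"],
            "saturation": sat,
        },
    }
    with open(out / "model_report.json", "w") as fh:
        json.dump(_jsonify(model_report), fh, indent=1, sort_keys=True)

    # --- manifest ---------------------------------------------------------
    stage("manifest")
    manifest = {
        "version": glycoclust.__version__,
        "seed": config.seed,
        "artifacts": {name: _sha256(out / name) for name in ARTIFACTS if (out / name).exists()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    report["manifest"] = manifest
    report["model_report"] = _jsonify(model_report)
    log.info("pipeline finished in %.1fs", time.time() - t0)
    return report
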