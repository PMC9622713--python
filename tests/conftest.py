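import numpy as np
import pandas as pd
import pytest

from glycoclust.data_io import AcaMatrix, ClinicalTable
from glycoclust.network import fuzzy_knn_graph, louvain, merge_graphs
from glycoclust.profiles import ClusterScoreMatrix, cluster_fpc
from glycoclust.synthetic import SynthSpec, generate_cohorts, generate_panel


@pytest.fixture(scope="session")
def default_spec():
    return SynthSpec(seed=1)


@pytest.fixture(scope="session")
def default_data(default_spec):
    """Full-size synthetic study: panel, both cohorts, clinical, genotypes, truth."""
    panel = generate_panel(default_spec)
    aca_a, aca_b, clinical, genotypes, truth = generate_cohorts(default_spec, panel)
    return {
        "spec": default_spec,
        "panel": panel,
        "aca_a": aca_a,
        "aca_b": aca_b,
        "clinical": clinical,
        "genotypes": genotypes,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def default_partition(default_data):
    merged = merge_graphs(
        fuzzy_knn_graph(default_data["aca_a"], provenance="cohort-A only"),
        fuzzy_knn_graph(default_data["aca_b"], provenance="cohort-B only"),
    )
    return merged, louvain(merged, seed=1)


@pytest.fixture(scope="session")
def default_scores(default_data, default_partition):
    _, partition = default_partition
    return cluster_fpc(default_data["aca_b"], partition)


def truth_score_matrix(truth, cohort: str = "B") -> ClusterScoreMatrix:
    """Score matrix built from the generator's latent block scores (bypasses
    the network); used when a test needs label-independent regressors fast."""
    frame = truth.block_scores[cohort].copy()
    frame.columns = [f"cluster_{i + 1}" for i in range(frame.shape[1])]
    n = frame.shape[1]
    return ClusterScoreMatrix(
        scores=frame,
        loadings={i + 1: pd.Series(dtype=float) for i in range(n)},
        explained_variance={i + 1: 1.0 for i in range(n)},
        orientation={i + 1: 1 for i in range(n)},
    )


def small_matrix(rng: np.random.Generator, n_samples=30, n_glycans=12, cohort="A") -> AcaMatrix:
    values = pd.DataFrame(
        np.exp(rng.normal(5.0, 0.8, size=(n_samples, n_glycans))),
        index=pd.Index([f"{cohort}{i:03d}" for i in range(n_samples)], name="sample_id"),
        columns=[f"G{j + 1:03d}" for j in range(n_glycans)],
    )
    return AcaMatrix(cohort=cohort, values=values)


def toy_clinical(rng: np.random.Generator, n=80, cohort="B") -> ClinicalTable:
    idx = pd.Index([f"{cohort}{i:03d}" for i in range(n)], name="sample_id")
    return ClinicalTable(
        pd.DataFrame(
            {
                "cohort": cohort,
                "group": rng.choice(
                    ["control", "progressor", "non_progressor"], size=n, p=[0.35, 0.4, 0.25]
                ),
                "sex": rng.choice(["F", "M"], size=n),
                "draw_age": rng.uniform(2, 20, size=n),
                "fdr": rng.choice(["yes", "no"], size=n),
                "hla_risk": rng.choice(["H", "L"], size=n),
            },
            index=idx,
        )
    )
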