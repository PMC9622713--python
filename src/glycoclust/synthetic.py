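"""Two-cohort synthetic ACA serology generator with planted structure.

The generator emulates the study design the pipeline targets: a large
case-control cohort (~576 samples) and a smaller clinically balanced cohort
(~112 samples) profiled on a shared panel of ~202 glycans organized in latent
correlated blocks; right-skewed nonnegative MFI; a handful of blocks whose
latent scores shift the log-odds of progressing to T1D; one bimodal "exposure"
glycan with a small upper mode; and one glycan with an additive genotype effect
(A/A > G/A > G/G).

Model: per sample, each planted block b has a latent factor f_b ~ N(0,1);
the log-MFI of glycan g in block b is

    log MFI_g = mu_g + noise_sd * (sqrt(rho) * f_b + sqrt(1 - rho) * eps_g)

with eps_g ~ N(0,1) i.i.d., so the within-block pairwise correlation of log-MFI
is exactly ``within_block_corr`` = rho and the total log-scale spread is
``noise_sd``. MFI = exp(log MFI) is log-normal: right-skewed and nonnegative,
which is how fluorescence intensities behave. Disease status is drawn from a
logistic model on the standardized block scores; clinical covariates are
independent of the blocks by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from glycoclust.data_io import AcaMatrix, ClinicalTable, GlycanPanel, ValidationError

# 22 functional classes mirroring the composition of a natural-glycan array
FUNCTIONAL_CLASSES = (
    "monosaccharides",
    "disaccharides",
    "trisaccharides",
    "blood group A antigens",
    "blood group B antigens",
    "blood group H antigens",
    "blood group analogues",
    "Lewis antigens",
    "lacto-series",
    "ganglio-series",
    "ganglio-series analogues",
    "globo-series",
    "isoglobo-series",
    "glycolipids",
    "O-linked glycans",
    "aminoglycosides",
    "maltodextrins",
    "chitin derivatives",
    "glucuronylated oligosaccharides",
    "stage-specific embryonic antigens",
    "plant oligosaccharides",
    "Forssman antigens",
)

_SUGARS = ("Gal", "Glc", "GalNAc", "GlcNAc", "Man", "Fuc", "Neu5Ac", "Neu5Gc", "Rha")
_LINKS = ("a1-2", "a1-3", "b1-3", "b1-4", "b1-6", "a2-3", "a2-6")


@dataclass
class SynthSpec:
    """Parameters of the synthetic two-cohort study.

    ``effect_clusters`` maps 1-based planted-block labels to log-odds
    coefficients per unit standardized block score. ``bimodal_feature`` is
    (0-based glycan index, upper-mode fraction, mode separation in log-MFI
    units); ``genotype_feature`` is (0-based glycan index, additive log-MFI
    shift per A allele of a biallelic G/A variant).
    """

    n_glycans: int = 202
    n_clusters_planted: int = 11
    cohort_sizes: tuple[int, int] = (576, 112)
    within_block_corr: float = 0.75
    noise_sd: float = 0.4
    effect_clusters: tuple[tuple[int, float], ...] = (
        (1, -1.0),
        (2, 1.0),
        (5, 1.0),
        (7, 1.0),
        (8, -1.0),
    )
    prevalence: float = 0.42
    nonprogressor_frac: float = 0.538
    bimodal_feature: tuple[int, float, float] = (97, 0.053, 2.5)
    genotype_feature: tuple[int, float] = (97, 0.5)
    class_alignment: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_glycans < 1:
            raise ValidationError("n_glycans must be >= 1")
        if not (1 <= self.n_clusters_planted <= self.n_glycans):
            raise ValidationError("n_clusters_planted must be in [1, n_glycans]")
        if any(n <= 0 for n in self.cohort_sizes):
            raise ValidationError("cohort_sizes must be positive")
        if not (0.0 <= self.within_block_corr < 1.0):
            raise ValidationError("within_block_corr must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if not (0.0 < self.prevalence < 1.0):
            raise ValidationError("prevalence must be in (0, 1)")
        if not (0.0 <= self.nonprogressor_frac <= 1.0):
            raise ValidationError("nonprogressor_frac must be in [0, 1]")
        if not (0.0 < self.bimodal_feature[1] < 1.0):
            raise ValidationError("bimodal_feature upper-mode fraction must be in (0, 1)")
        if not (0 <= self.bimodal_feature[0] < self.n_glycans):
            raise ValidationError("bimodal_feature glycan index out of range")
        if not (0 <= self.genotype_feature[0] < self.n_glycans):
            raise ValidationError("genotype_feature glycan index out of range")
        if not (0.0 <= self.class_alignment <= 1.0):
            raise ValidationError("class_alignment must be in [0, 1]")
        for c, _ in self.effect_clusters:
            if not (1 <= c <= self.n_clusters_planted):
                raise ValidationError(
                    f"effect_clusters references nonexistent block {c}"
                )


@dataclass
class SynthTruth:
    """Ground truth emitted alongside generated data; recovery tests compare
    against this object, never against hard-coded numbers."""

    partition: dict[str, int]  # glycan_id -> 1-based planted block
    block_scores: dict[str, pd.DataFrame]  # cohort -> samples x blocks latent scores
    coefficients: dict[int, float]  # block -> log-odds coefficient
    intercept: float
    genotype: pd.Series  # sample_id -> "G/G" | "G/A" | "A/A"
    bimodal_upper: pd.Series  # sample_id -> 0/1 upper-mode indicator

    def to_json(self, path) -> None:
        payload = {
            "partition": self.partition,
            "coefficients": {str(k): v for k, v in self.coefficients.items()},
            "intercept": self.intercept,
            "genotype": self.genotype.to_dict(),
            "bimodal_upper": {k: int(v) for k, v in self.bimodal_upper.items()},
            "block_scores": {c: df.to_dict(orient="index") for c, df in self.block_scores.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def block_partition(n_glycans: int, n_blocks: int) -> np.ndarray:
    """Deterministic near-equal contiguous partition; returns 1-based labels."""
    sizes = np.full(n_blocks, n_glycans // n_blocks)
    sizes[: n_glycans % n_blocks] += 1
    return np.repeat(np.arange(1, n_blocks + 1), sizes)


def _glycan_ids(n: int) -> list[str]:
    return [f"G{i + 1:03d}" for i in range(n)]


def _random_structure(rng: np.random.Generator) -> str:
    k = int(rng.integers(1, 5))
    parts = [str(rng.choice(_SUGARS))]
    for _ in range(k - 1):
        parts.append(f"({rng.choice(_LINKS)}){rng.choice(_SUGARS)}")
    return "".join(parts)


def generate_panel(spec: SynthSpec) -> GlycanPanel:
    """Generate the glycan panel with block-aligned functional classes.

    Each planted block gets two "home" classes from the 22-class vocabulary;
    a glycan adopts one of its block's home classes with probability
    ``class_alignment`` (alternating between the two so both appear), and a
    uniformly random other class otherwise. With 11 blocks this covers all 22
    classes while keeping class membership informative about block identity.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 11])
    labels = block_partition(spec.n_glycans, spec.n_clusters_planted)
    ids = _glycan_ids(spec.n_glycans)
    n_classes = len(FUNCTIONAL_CLASSES)

    home: dict[int, tuple[str, str]] = {}
    for b in range(1, spec.n_clusters_planted + 1):
        c0 = FUNCTIONAL_CLASSES[(2 * (b - 1)) % n_classes]
        c1 = FUNCTIONAL_CLASSES[(2 * (b - 1) + 1) % n_classes]
        home[b] = (c0, c1)

    classes = []
    aligned_counter: dict[int, int] = {b: 0 for b in home}
    for g, b in enumerate(labels):
        if rng.random() < spec.class_alignment:
            pair = home[int(b)]
            classes.append(pair[aligned_counter[int(b)] % 2])
            aligned_counter[int(b)] += 1
        else:
            others = [c for c in FUNCTIONAL_CLASSES if c not in home[int(b)]]
            classes.append(str(rng.choice(others)))

    table = pd.DataFrame(
        {
            "display_number": np.arange(1, spec.n_glycans + 1),
            "structure": [_random_structure(rng) for _ in ids],
            "functional_class": classes,
        },
        index=pd.Index(ids, name="glycan_id"),
    )
    return GlycanPanel(table)


def _solve_intercept(eta_lin: np.ndarray, prevalence: float) -> float:
    """Bisection for alpha so that mean sigmoid(alpha + eta_lin) = prevalence."""
    lo, hi = -20.0, 20.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if np.mean(1.0 / (1.0 + np.exp(-(mid + eta_lin)))) < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohorts(
    spec: SynthSpec, panel: GlycanPanel
) -> tuple[AcaMatrix, AcaMatrix, ClinicalTable, pd.Series, SynthTruth]:
    """Generate both cohorts, clinical covariates, genotypes and ground truth.

    Returns (cohort A matrix, cohort B matrix, clinical table covering both,
    genotype series, truth). Cohorts share the planted partition and per-glycan
    baselines but draw independent samples and noise.
    """
    spec.validate()
    if len(panel) != spec.n_glycans:
        raise ValidationError("panel size does not match spec.n_glycans")
    rng = np.random.default_rng([spec.seed, 29])
    labels = block_partition(spec.n_glycans, spec.n_clusters_planted)
    ids = panel.glycan_ids
    rho = spec.within_block_corr

    mu = rng.normal(6.0, 1.0, size=spec.n_glycans)  # shared per-glycan baseline
    bg_idx, bg_frac, bg_sep = spec.bimodal_feature
    gt_idx, gt_eff = spec.genotype_feature
    betas = dict(spec.effect_clusters)

    matrices: list[AcaMatrix] = []
    clin_frames: list[pd.DataFrame] = []
    geno_parts: list[pd.Series] = []
    bimodal_parts: list[pd.Series] = []
    scores: dict[str, pd.DataFrame] = {}
    intercept = np.nan

    for cohort, n in zip(("A", "B"), spec.cohort_sizes):
        sample_ids = [f"{cohort}{i + 1:04d}" for i in range(n)]
        f = rng.normal(size=(n, spec.n_clusters_planted))
        eps = rng.normal(size=(n, spec.n_glycans))
        log_mfi = (
            mu[None, :]
            + spec.noise_sd
            * (np.sqrt(rho) * f[:, labels - 1] + np.sqrt(1.0 - rho) * eps)
        )

        upper = (rng.random(n) < bg_frac).astype(int)
        log_mfi[:, bg_idx] += upper * bg_sep

        geno_counts = rng.binomial(2, 0.49, size=n)  # A-allele count, HWE
        log_mfi[:, gt_idx] += geno_counts * gt_eff
        geno = pd.Series(
            np.array(["G/G", "G/A", "A/A"])[geno_counts], index=sample_ids
        )

        eta_lin = np.zeros(n)
        for c, b in betas.items():
            eta_lin += b * f[:, c - 1]
        alpha = _solve_intercept(eta_lin, spec.prevalence)
        if cohort == "B":
            intercept = alpha
        p = 1.0 / (1.0 + np.exp(-(alpha + eta_lin)))
        prog = rng.random(n) < p
        nonprog = (~prog) & (rng.random(n) < spec.nonprogressor_frac)
        group = np.where(prog, "progressor", np.where(nonprog, "non_progressor", "control"))

        clin = pd.DataFrame(
            {
                "cohort": cohort,
                "group": group,
                "sex": np.where(rng.random(n) < 0.5, "F", "M"),
                "draw_age": rng.uniform(2.0, 20.0, size=n),
                "fdr": np.where(rng.random(n) < 0.55, "yes", "no"),
                "hla_risk": np.where(rng.random(n) < 0.70, "H", "L"),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )

        matrices.append(
            AcaMatrix(
                cohort=cohort,
                values=pd.DataFrame(np.exp(log_mfi), index=sample_ids, columns=ids),
            )
        )
        clin_frames.append(clin)
        geno_parts.append(geno)
        bimodal_parts.append(pd.Series(upper, index=sample_ids))
        scores[cohort] = pd.DataFrame(
            f,
            index=sample_ids,
            columns=[f"block_{b}" for b in range(1, spec.n_clusters_planted + 1)],
        )

    truth = SynthTruth(
        partition={g: int(b) for g, b in zip(ids, labels)},
        block_scores=scores,
        coefficients=betas,
        intercept=float(intercept),
        genotype=pd.concat(geno_parts),
        bimodal_upper=pd.concat(bimodal_parts),
    )
    clinical = ClinicalTable(pd.concat(clin_frames))
    return matrices[0], matrices[1], clinical, truth.genotype, truth


def spec_from_dict(d: dict) -> SynthSpec:
    """Build a SynthSpec from a plain dict (e.g. parsed YAML), with validation."""
    kwargs = dict(d)
    for key in ("cohort_sizes", "bimodal_feature", "genotype_feature"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    if "effect_clusters" in kwargs and kwargs["effect_clusters"] is not None:
        kwargs["effect_clusters"] = tuple(
            (int(c), float(b)) for c, b in kwargs["effect_clusters"]
        )
    unknown = set(kwargs) - set(SynthSpec.__dataclass_fields__)
    if unknown:
        raise ValidationError(f"unknown SynthSpec fields: {sorted(unknown)}")
    spec = SynthSpec(**kwargs)
    spec.validate()
    return spec
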