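"""Core data containers, CSV ingestion, background subtraction, cohort descriptives.

Conventions used throughout the package: samples are rows, glycans are columns;
MFI values are nonnegative reals on an arbitrary fluorescence scale; every matrix
carries a cohort tag so provenance survives graph merging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

GROUP_LEVELS = ("control", "progressor", "non_progressor")
SEX_LEVELS = ("F", "M")
HLA_LEVELS = ("H", "L", "unknown")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class GlycanPanel:
    """The glycan node set: identities, structures and functional classes.

    ``table`` is indexed by ``glycan_id`` with columns ``display_number``
    (the printed "#" label), ``structure`` (IUPAC-condensed free text) and
    ``functional_class`` (closed vocabulary, e.g. 22 classes for the full array).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"display_number", "structure", "functional_class"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"panel missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            dupes = self.table.index[self.table.index.duplicated()].tolist()
            raise ValidationError(f"duplicate glycan ids: {dupes}")
        if self.table["functional_class"].isna().any() or (
            self.table["functional_class"].astype(str) == ""
        ).any():
            raise ValidationError("every glycan needs a non-empty functional_class")

    @property
    def glycan_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def classes(self) -> list[str]:
        return sorted(self.table["functional_class"].unique())

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class AcaMatrix:
    """Background-subtracted MFI, samples x glycans, with a cohort tag."""

    cohort: str
    values: pd.DataFrame  # index = sample_id, columns = glycan_id

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate glycan ids: {dupes}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValidationError("MFI values must be finite")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def glycan_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates.

    Columns: ``cohort``, ``group`` (control / progressor / non_progressor),
    ``sex`` (F/M), ``draw_age`` (years, > 0), ``fdr`` (first-degree relative with
    T1D, yes/no), ``hla_risk`` (H / L / unknown). Indexed by sample id.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"cohort", "group", "sex", "draw_age", "fdr", "hla_risk"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"clinical table missing columns: {sorted(missing)}")
        bad = set(self.table["group"]) - set(GROUP_LEVELS)
        if bad:
            raise ValidationError(f"unknown group levels: {sorted(bad)}")
        bad = set(self.table["sex"]) - set(SEX_LEVELS)
        if bad:
            raise ValidationError(f"unknown sex levels: {sorted(bad)}")
        bad = set(self.table["hla_risk"]) - set(HLA_LEVELS)
        if bad:
            raise ValidationError(f"unknown hla_risk levels: {sorted(bad)}")
        if (self.table["draw_age"] <= 0).any():
            raise ValidationError("draw_age must be > 0")
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate sample ids in clinical table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class DescriptiveReport:
    """Per-variable descriptive test results stratified by group."""

    rows: pd.DataFrame  # variable, test, statistic, p_value
    counts: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = ["Descriptive cohort comparison (stratified by group)"]
        for _, r in self.rows.iterrows():
            lines.append(
                f"  {r['variable']:<10s} {r['test']:<28s} "
                f"stat={r['statistic']:.3f}  p={r['p_value']:.3g}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# CSV ingestion / serialization


def read_panel(path) -> GlycanPanel:
    df = pd.read_csv(path, dtype={"glycan_id": str}).set_index("glycan_id")
    return GlycanPanel(df)


def write_panel(panel: GlycanPanel, path) -> None:
    panel.table.to_csv(path, index_label="glycan_id")


def read_aca(path, panel: GlycanPanel | None = None, cohort: str | None = None) -> AcaMatrix:
    """Read a samples x glycans MFI CSV (first column ``sample_id``).

    If ``panel`` is given every column must be a known glycan id; offenders are
    listed in the error. Non-numeric cells are reported with row and column.
    """
    df = pd.read_csv(path, dtype={"sample_id": str}).set_index("sample_id")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            bad_rows = df.index[coerced.isna() & ~df[col].isna()].tolist()
            raise ValidationError(f"non-numeric cell(s) in column {col!r}, rows {bad_rows}")
        df[col] = coerced
    if df.isna().any().any():
        raise ValidationError("missing MFI values are not allowed")
    if panel is not None:
        unknown = sorted(set(df.columns) - set(panel.glycan_ids))
        if unknown:
            raise ValidationError(f"glycans absent from panel: {unknown}")
    return AcaMatrix(cohort=cohort or "unknown", values=df.astype(float))


def write_aca(matrix: AcaMatrix, path) -> None:
    matrix.values.to_csv(path, index_label="sample_id")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, dtype={"sample_id": str}).set_index("sample_id")
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.table.to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# Background subtraction


def subtract_background(
    raw: AcaMatrix, background_columns: list[str], floor: bool = True
) -> AcaMatrix:
    """Subtract the per-sample mean of the no-glycan bead columns.

    The background columns are removed from the output. Post-subtraction
    negatives are floored at 0 unless ``floor=False`` (flooring keeps downstream
    log transforms defined).
    """
    present = [c for c in background_columns if c in raw.values.columns]
    if not present:
        raise ValidationError(
            f"no background column found among {background_columns!r}"
        )
    bg = raw.values[present].mean(axis=1)
    keep = [c for c in raw.values.columns if c not in set(present)]
    out = raw.values[keep].sub(bg, axis=0)
    if floor:
        out = out.clip(lower=0.0)
    return AcaMatrix(cohort=raw.cohort, values=out)


# ---------------------------------------------------------------------------
# Descriptive statistics (cohort tables)

_CATEGORICAL = ("sex", "fdr", "hla_risk")
_CONTINUOUS = ("draw_age",)


def chi_squared_test(counts: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared on an r x c count table, no continuity correction."""
    counts = np.asarray(counts, dtype=float)
    stat, p, _, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), float(p)


def descriptive_table(
    clinical: ClinicalTable, stratify_by: str = "group"
) -> DescriptiveReport:
    """Compare clinical variables across strata.

    Categorical variables use Pearson chi-squared (no continuity correction) on
    the r x c table; continuous variables use Kruskal-Wallis with tie
    correction. Two-sided p-values throughout. A constant variable yields p = 1
    with a warning.
    """
    df = clinical.table
    strata = df[stratify_by]
    levels = [lv for lv in pd.unique(strata)]
    if len(levels) < 2:
        raise ValidationError("need at least two strata")
    for lv in levels:
        if (strata == lv).sum() == 0:
            raise ValidationError(f"stratum {lv!r} is empty")

    rows = []
    counts: dict[str, pd.DataFrame] = {}
    for var in _CATEGORICAL:
        tab = pd.crosstab(df[var], strata)
        counts[var] = tab
        if tab.shape[0] < 2:
            warnings.warn(f"variable {var!r} is constant; p set to 1")
            rows.append((var, "chi_squared", 0.0, 1.0))
            continue
        stat, p = chi_squared_test(tab.to_numpy())
        rows.append((var, "chi_squared", stat, p))
    for var in _CONTINUOUS:
        groups = [df.loc[strata == lv, var].to_numpy() for lv in levels]
        if df[var].nunique() < 2:
            warnings.warn(f"variable {var!r} is constant; p set to 1")
            rows.append((var, "kruskal_wallis", 0.0, 1.0))
            continue
        stat, p = stats.kruskal(*groups)
        rows.append((var, "kruskal_wallis", float(stat), float(p)))

    report = pd.DataFrame(rows, columns=["variable", "test", "statistic", "p_value"])
    return DescriptiveReport(rows=report, counts=counts)
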