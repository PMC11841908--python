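"""Cleanup, mean imputation, reliability, and descriptive statistics.

Mirrors the preprocessing stage of a trust-level survey analysis: fill
missing cells by column-mean imputation, check each section's internal
consistency with Cronbach's alpha, and summarize the section scores with
descriptive and Pearson-correlation tables.  The sample-variance convention
is n-1 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .synth import SurveyDataset

# Published adequacy band for survey internal consistency.
ALPHA_ACCEPTABLE = (0.50, 0.95)


@dataclass
class ReliabilityReport:
    """Per-section Cronbach alpha with the adequacy flag."""

    table: pd.DataFrame  # columns: section, n_items, alpha, acceptable

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class DescriptiveSummary:
    """Per-column mean/median/SD/min/max/n."""

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def impute_mean(dataset: SurveyDataset) -> SurveyDataset:
    """Replace each missing cell by its column's observed mean."""
    values = dataset.values
    if values.isna().all(axis=0).any():
        bad = values.columns[values.isna().all(axis=0)].tolist()
        raise ValueError(f"fully-missing columns cannot be imputed: {bad}")
    return replace(dataset, values=values.fillna(values.mean(axis=0)))


def remove_outliers(dataset: SurveyDataset, z_max: float = 4.0) -> SurveyDataset:
    """Optional row filter: drop rows with any |z-score| above ``z_max``.

    Off by default in the pipeline; at trust-level aggregation scores are
    tightly clustered and the default analysis keeps all rows.
    """
    values = dataset.values
    z = (values - values.mean(axis=0)) / values.std(axis=0, ddof=1)
    keep = ~(z.abs() > z_max).any(axis=1)
    return replace(dataset, values=values.loc[keep].reset_index(drop=True))


def cronbach_alpha(items: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha: m/(m-1) * (1 - sum var(item_i) / var(row sums))."""
    x = np.asarray(items, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need an n x m matrix with m >= 2")
    if np.isnan(x).any():
        raise ValueError("missing cells must be imputed before reliability")
    m = x.shape[1]
    total_var = np.var(x.sum(axis=1), ddof=1)
    if total_var == 0:
        raise ValueError("zero total variance")
    item_vars = np.var(x, axis=0, ddof=1)
    return float(m / (m - 1) * (1.0 - item_vars.sum() / total_var))


def reliability(item_data: SurveyDataset) -> ReliabilityReport:
    """Per-section Cronbach alpha over an item-level dataset."""
    if item_data.level != "item":
        raise ValueError("reliability needs item-level data")
    rows = []
    sections = sorted(set(item_data.section_of.values()))
    for sec in sections:
        cols = [c for c in item_data.columns if item_data.section_of[c] == sec]
        a = cronbach_alpha(item_data.values[cols])
        rows.append(
            {
                "section": sec,
                "n_items": len(cols),
                "alpha": a,
                "acceptable": ALPHA_ACCEPTABLE[0] <= a <= ALPHA_ACCEPTABLE[1],
            }
        )
    return ReliabilityReport(table=pd.DataFrame(rows))


def describe(dataset: SurveyDataset) -> DescriptiveSummary:
    values = dataset.values
    if len(values) == 0:
        raise ValueError("empty dataset")
    if values.isna().any().any():
        raise ValueError("impute missing cells before describing")
    table = pd.DataFrame(
        {
            "column": values.columns,
            "mean": values.mean(axis=0).to_numpy(),
            "median": values.median(axis=0).to_numpy(),
            "sd": values.std(axis=0, ddof=1).to_numpy(),
            "min": values.min(axis=0).to_numpy(),
            "max": values.max(axis=0).to_numpy(),
            "n": len(values),
        }
    )
    return DescriptiveSummary(table=table)


def correlations(dataset: SurveyDataset) -> pd.DataFrame:
    """Pearson correlation matrix of the dataset's columns."""
    values = dataset.values
    if len(values) < 2:
        raise ValueError("need at least two rows")
    if values.isna().any().any():
        raise ValueError("impute missing cells before correlating")
    if (values.std(axis=0, ddof=1) == 0).any():
        raise ValueError("zero-variance column")
    return values.corr(method="pearson")
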