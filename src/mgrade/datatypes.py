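"""Core typed containers shared by every pipeline stage.

The pipeline works on three kinds of tabular objects: a genes-by-samples
expression matrix (log2 intensities for microarray-like data, log-CPM or raw
counts for RNA-seq), a per-sample clinical table with histological grade and
overall-survival follow-up, and a per-cancer configuration holding the
differential-expression filters and gradient-boosting hyperparameters.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Platform",
    "ExpressionMatrix",
    "ClinicalTable",
    "GRADE_VALUES",
    "STAGE_VALUES",
    "DEThresholds",
    "GBMParams",
    "CancerConfig",
    "config_for",
]


class Platform(str, enum.Enum):
    """Expression profiling platform; controls DE floors and the counts path."""

    RNASEQ = "rnaseq"
    MICROARRAY = "microarray"


GRADE_VALUES = ("G1", "G2", "G3", "G4", "missing")
STAGE_VALUES = ("I", "II", "III", "IV", "missing")


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with ID bookkeeping.

    ``values`` is a pandas DataFrame indexed by gene ID with sample IDs as
    columns. Missing measurements are NaN and stay NaN — downstream ranking
    omits them rather than imputing.
    """

    values: pd.DataFrame
    platform: Platform = Platform.MICROARRAY
    batch: pd.Series | None = None  # per-sample batch label, indexed by sample

    def __post_init__(self) -> None:
        self.platform = Platform(self.platform)
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate gene ID: {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        if not all(np.issubdtype(dt, np.number) for dt in self.values.dtypes):
            raise ValueError("expression values must be numeric")
        if self.batch is not None:
            self.batch = self.batch.reindex(cols)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        batch = self.batch.loc[list(sample_ids)] if self.batch is not None else None
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], self.platform, batch)

    def sample_vector(self, sample_id: str) -> pd.Series:
        """Per-gene values for one sample (a single-sample workflow entry point)."""
        return self.values[sample_id]


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations, one row per sample.

    ``data`` is indexed by sample_id with columns: grade (G1..G4 or
    "missing"), os_time (days), os_event (0/1), stage, cohort,
    lymph_node_status (optional, may be all-missing).
    """

    data: pd.DataFrame

    REQUIRED = ("grade", "os_time", "os_event", "stage", "cohort", "lymph_node_status")

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        t = df["os_time"].astype(float)
        ev = df["os_event"]
        bad = t.notna() & (t < 0)
        if bad.any():
            raise ValueError(f"negative os_time for sample {df.index[bad][0]!r}")
        has_event = ev.notna()
        if (has_event & ~np.isfinite(t.fillna(np.inf) * 0 + t)).any():
            raise ValueError("os_time must be finite when os_event is present")
        bad_grade = ~df["grade"].isin(GRADE_VALUES)
        if bad_grade.any():
            raise ValueError(f"unnormalized grade value {df.loc[bad_grade, 'grade'].iloc[0]!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, sample_ids) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)].copy())

    @property
    def grade(self) -> pd.Series:
        return self.data["grade"]

    @property
    def os_time(self) -> pd.Series:
        return self.data["os_time"].astype(float)

    @property
    def os_event(self) -> pd.Series:
        return self.data["os_event"].astype(int)


@dataclass(frozen=True)
class DEThresholds:
    """Differential-expression gene filters.

    ``logfc_up``/``logfc_down`` bound the log2 fold change (high minus low);
    expression floors are platform specific: minimum log-CPM for RNA-seq and
    minimum average log2 intensity for microarray.
    """

    q_max: float = 0.05
    logfc_up: float = 1.0
    logfc_down: float = -1.0
    floor_rnaseq: float = 2.0  # minimum logCPM
    floor_microarray: float = 3.0  # minimum average log2 intensity


@dataclass(frozen=True)
class GBMParams:
    n_estimators: int = 500
    reg_alpha: float = 0.0
    reg_lambda: float = 0.6
    max_depth: int = -1

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class CancerConfig:
    """Per-cancer-type settings for labeling, training and elimination."""

    cancer_type: str = "custom"
    de: DEThresholds = field(default_factory=DEThresholds)
    gbm: GBMParams = field(default_factory=GBMParams)
    elimination_stop: int = 20
    cv_folds: int = 5
    test_fraction: float = 0.2
    high_label: str = "mG3"
    low_label: str = "mG1"
    mutation_top_k: int = 15

    def __post_init__(self) -> None:
        if self.elimination_stop < 1:
            raise ValueError("elimination_stop must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")


_CONFIGS = {
    # Hyperparameters follow the published per-cancer optima; DE floors are the
    # platform-specific expression minima for each cancer's array data.
    "BRCA": CancerConfig(
        cancer_type="BRCA",
        de=DEThresholds(0.05, 1.0, -1.0, floor_rnaseq=2.0, floor_microarray=3.0),
        gbm=GBMParams(n_estimators=500, reg_alpha=0.3, reg_lambda=0.6, max_depth=-1),
        high_label="mG3",
        mutation_top_k=15,
    ),
    "LUAD": CancerConfig(
        cancer_type="LUAD",
        de=DEThresholds(0.05, 1.5, -1.2, floor_rnaseq=2.0, floor_microarray=3.0),
        gbm=GBMParams(n_estimators=500, reg_alpha=0.0, reg_lambda=0.6, max_depth=-1),
        high_label="mG3",
        mutation_top_k=15,
    ),
    "ccRCC": CancerConfig(
        cancer_type="ccRCC",
        de=DEThresholds(0.05, 1.0, -1.0, floor_rnaseq=2.0, floor_microarray=7.0),
        gbm=GBMParams(n_estimators=200, reg_alpha=0.0, reg_lambda=0.6, max_depth=-1),
        high_label="mG4",
        mutation_top_k=5,
    ),
    # Fixture-scale default for cohorts that are not one of the three published
    # cancer types; smaller ensemble keeps synthetic runs fast.
    "custom": CancerConfig(
        cancer_type="custom",
        de=DEThresholds(),
        gbm=GBMParams(n_estimators=200, reg_alpha=0.0, reg_lambda=0.6, max_depth=-1),
        high_label="mG3",
        mutation_top_k=15,
    ),
}


def config_for(cancer_type: str) -> CancerConfig:
    """Return the default :class:`CancerConfig` for a cancer type."""
    try:
        return _CONFIGS[cancer_type]
    except KeyError:
        raise KeyError(
            f"unknown cancer type {cancer_type!r}; known: {sorted(_CONFIGS)}"
        ) from None
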