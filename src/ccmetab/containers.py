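"""Core data containers shared by every stage of the pipeline.

The two central objects are :class:`AbundanceMatrix` (samples x metabolites,
non-negative, missing values allowed, with a per-sample run-day label) and
:class:`StudyDesign` (the strain x diet experimental frame).  Both are thin,
validated wrappers around :class:`pandas.DataFrame` so that downstream code
can rely on aligned indices without re-checking them at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

DIETS = ("VDS", "VDD")

#: Processing stages an abundance matrix moves through, in pipeline order.
#: "corrected" marks a strain-residualized matrix, which may hold negatives.
STAGES = ("raw", "normalized", "rescaled", "imputed", "corrected")


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


@dataclass
class AbundanceMatrix:
    """Samples x metabolites abundance table with run-day labels.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, columns are metabolite ids.  Missing
        measurements (below the limit of detection) are ``NaN``.  Present
        values must be non-negative.
    run_day
        Series mapping every sample id to its instrument batch (run day).
    stage
        Provenance flag, one of :data:`STAGES`.
    imputed
        Optional boolean mask, same shape as ``values``, marking cells that
        were filled by minimum-value imputation.
    """

    values: pd.DataFrame
    run_day: pd.Series
    stage: str = "raw"
    imputed: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate metabolite ids: {dups}")
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        missing_days = self.values.index.difference(self.run_day.index)
        if len(missing_days):
            raise ValidationError(
                f"run_day undefined for samples: {missing_days.tolist()}"
            )
        self.run_day = self.run_day.loc[self.values.index]
        if self.stage != "corrected":
            vals = self.values.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValidationError("abundances must be non-negative where present")

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def with_values(
        self, values: pd.DataFrame, stage: str, imputed: Optional[pd.DataFrame] = None
    ) -> "AbundanceMatrix":
        """Return a copy carrying new values and an updated provenance flag."""
        return AbundanceMatrix(
            values=values,
            run_day=self.run_day,
            stage=stage,
            imputed=self.imputed if imputed is None else imputed,
        )


@dataclass
class StudyDesign:
    """Per-sample experimental factors: strain, diet, and optional covariates.

    ``table`` is indexed by sample id and must contain ``strain`` and ``diet``
    columns; ``run_day``, ``vitd_25ohd`` (plasma 25-hydroxyvitamin D, ng/mL)
    and ``litter_size`` are optional.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids in design: {dups}")
        for col in ("strain", "diet"):
            if col not in self.table.columns:
                raise ValidationError(f"design table lacks required column {col!r}")
        bad = set(self.table["diet"].unique()) - set(DIETS)
        if bad:
            raise ValidationError(f"unknown diet labels: {sorted(bad)}; expected {DIETS}")
        if self.table.empty:
            raise ValidationError("design table is empty")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def strains(self) -> list:
        return sorted(self.table["strain"].unique().tolist())

    @property
    def diets(self) -> list:
        return [d for d in DIETS if d in set(self.table["diet"])]

    def strain_of(self) -> pd.Series:
        return self.table["strain"]

    def diet_of(self) -> pd.Series:
        return self.table["diet"]

    def subset(self, sample_ids: Sequence) -> "StudyDesign":
        return StudyDesign(self.table.loc[list(sample_ids)].copy())

    def check_matches(self, matrix: AbundanceMatrix) -> None:
        """Raise unless matrix and design describe exactly the same samples."""
        only_m = matrix.sample_ids.difference(self.table.index)
        only_d = self.table.index.difference(matrix.sample_ids)
        if len(only_m) or len(only_d):
            raise ValidationError(
                "matrix/design sample mismatch: "
                f"only in matrix {only_m.tolist()}, only in design {only_d.tolist()}"
            )
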