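"""Platform-standard preprocessing: run-day median normalization, per-compound
rescaling to unit median, and minimum-observed-value imputation.

Pipeline order is normalize -> rescale -> impute.  Normalization divides each
metabolite's values within a run day by that (metabolite, day) median, which
removes per-day multiplicative batch factors exactly; rescaling then sets
each compound's overall median to 1 so compounds with wide numerical ranges
do not dominate multivariate models; finally, missing (below-LOD) cells are
filled with the metabolite's minimum observed value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, ValidationError


def normalize_run_day(m: AbundanceMatrix) -> AbundanceMatrix:
    """Divide each metabolite's values by its within-run-day median.

    Missing entries stay missing.  A (metabolite, day) block that is entirely
    missing, or whose median is zero, raises a :class:`ValidationError`
    naming the block.
    """
    values = m.values.copy()
    for day, idx in values.groupby(m.run_day).groups.items():
        block = values.loc[idx]
        med = block.median(axis=0, skipna=True)
        empty = med.index[med.isna()]
        if len(empty):
            raise ValidationError(
                f"run day {day!r}: no observed values for metabolites "
                f"{empty.tolist()[:5]}"
            )
        zero = med.index[med == 0]
        if len(zero):
            raise ValidationError(
                f"run day {day!r}: zero within-day median for metabolites "
                f"{zero.tolist()[:5]}"
            )
        values.loc[idx] = block / med
    return m.with_values(values, stage="normalized")


def rescale_to_unit_median(m: AbundanceMatrix) -> AbundanceMatrix:
    """Rescale each metabolite so its overall median of observed values is 1."""
    med = m.values.median(axis=0, skipna=True)
    empty = med.index[med.isna()]
    if len(empty):
        raise ValidationError(f"all-missing metabolites: {empty.tolist()[:5]}")
    zero = med.index[med == 0]
    if len(zero):
        raise ValidationError(f"zero overall median for metabolites: {zero.tolist()[:5]}")
    return m.with_values(m.values / med, stage="rescaled")


def impute_minimum(m: AbundanceMatrix) -> AbundanceMatrix:
    """Fill every missing cell with the metabolite's minimum observed value."""
    col_min = m.values.min(axis=0, skipna=True)
    empty = col_min.index[col_min.isna()]
    if len(empty):
        raise ValidationError(f"all-missing metabolites: {empty.tolist()[:5]}")
    mask = m.values.isna()
    values = m.values.fillna(col_min)
    return m.with_values(values, stage="imputed", imputed=mask)


def preprocess(m: AbundanceMatrix) -> AbundanceMatrix:
    """Full preprocessing chain: normalize -> rescale -> impute."""
    return impute_minimum(rescale_to_unit_median(normalize_run_day(m)))
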