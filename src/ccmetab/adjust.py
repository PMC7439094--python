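"""Per-metabolite strain residualization.

For each metabolite an ordinary least squares model ``metabolite ~ diet +
strain`` is fit with treatment (reference-level) coding — diet reference
``VDS``, strain reference the declared baseline strain — and the fitted
strain coefficients are subtracted from the corresponding samples' values.
Baseline-strain samples are left untouched.  The diet effect is deliberately
not removed: the corrected matrix feeds the diet OPLS-DA, and strain-specific
diet responses remain in the residuals for it to find.

All metabolites share one design matrix, so the fits are performed as a
single least-squares solve over the whole matrix; this is algebraically
identical to looping ``lm()`` over metabolites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, StudyDesign, ValidationError


@dataclass
class AdjustmentModel:
    """Fitted strain-adjustment state.

    ``coefficients`` rows are ``intercept``, ``diet[T.VDD]`` and one
    ``strain[T.<name>]`` per non-baseline strain; columns are metabolites.
    """

    baseline_strain: str
    coefficients: pd.DataFrame
    corrected: AbundanceMatrix
    rank_deficient: bool = False


def _design_matrix(d: StudyDesign, baseline: str):
    strains = [s for s in d.strains if s != baseline]
    diet = (d.table["diet"] == "VDD").to_numpy(dtype=float)
    cols = [np.ones(len(d.table)), diet]
    names = ["intercept", "diet[T.VDD]"]
    for s in strains:
        cols.append((d.table["strain"] == s).to_numpy(dtype=float))
        names.append(f"strain[T.{s}]")
    return np.column_stack(cols), names, strains


def fit_and_correct(
    m: AbundanceMatrix, d: StudyDesign, baseline: str = "CC011"
) -> AdjustmentModel:
    """Fit ``metabolite ~ diet + strain`` and subtract strain coefficients.

    Parameters
    ----------
    m
        Fully imputed abundance matrix (no missing values).
    d
        Study design; must contain both diets and at least two strains.
    baseline
        Reference strain whose samples are returned unchanged.
    """
    d.check_matches(m)
    if m.n_missing:
        raise ValidationError("matrix must be fully imputed before adjustment")
    if baseline not in d.strains:
        raise ValidationError(f"unknown baseline strain {baseline!r}")
    # a cohort consisting solely of the baseline strain needs no correction,
    # so it is accepted; any other single-strain design is a user error
    if len(d.strains) < 2 and d.strains != [baseline]:
        raise ValidationError("need >= 2 strains to adjust for strain")
    if len(d.diets) < 2:
        raise ValidationError("both diets must be present")

    design = d.subset(m.sample_ids)
    X, names, strains = _design_matrix(design, baseline)
    Y = m.values.to_numpy(dtype=float)

    rank = np.linalg.matrix_rank(X)
    deficient = rank < X.shape[1]
    if deficient:
        warnings.warn(
            "rank-deficient strain/diet design; coefficients are a minimum-norm "
            "solution", UserWarning, stacklevel=2,
        )

    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    coef = pd.DataFrame(B, index=names, columns=m.metabolite_ids)

    strain_cols = X[:, 2:]  # indicator columns for non-baseline strains
    corrected_vals = Y - strain_cols @ B[2:, :]
    corrected = pd.DataFrame(corrected_vals, index=m.sample_ids,
                             columns=m.metabolite_ids)
    # baseline-strain samples carry no strain indicator, hence are bit-unchanged
    corrected_m = AbundanceMatrix(
        values=corrected,
        run_day=m.run_day,
        stage="corrected",  # residualized values may legitimately go negative
        imputed=m.imputed,
    )
    return AdjustmentModel(
        baseline_strain=baseline,
        coefficients=coef,
        corrected=corrected_m,
        rank_deficient=deficient,
    )
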