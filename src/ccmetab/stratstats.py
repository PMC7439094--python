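"""Strain-stratified and population-level univariate statistics.

Covers the classical test battery around strain x diet group comparisons:

* fold changes (ratio of VDD to VDS group means), population-level and
  per-strain;
* the percentage-reduction summary ``(VDD_sample - VDS_mean) / VDS_mean``
  used for plasma 25(OH)D;
* an assumption-gated test chooser (Shapiro-Wilk normality, Bartlett
  variance homogeneity) dispatching to pooled t / Welch t / ANOVA /
  Welch ANOVA / Wilcoxon rank-sum / Kruskal-Wallis;
* the Brown-Mood median test with an exact 2x2 branch at small expected
  counts;
* Tukey-Kramer HSD pairwise comparisons with a compact letter display;
* the combined VIP >= 1.5 and >= 1.5-fold robust-change filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceMatrix, StudyDesign, ValidationError


# ---------------------------------------------------------------------------
# Fold changes and percentage reduction
# ---------------------------------------------------------------------------

def fold_change(m: AbundanceMatrix, d: StudyDesign,
                by_strain: bool = False) -> pd.DataFrame:
    """Ratio of arithmetic VDD to VDS group means per metabolite.

    With ``by_strain`` the ratio is computed within each strain and the
    result has a (strain, metabolite) MultiIndex-free long format: one row
    per strain, columns are metabolites.  A non-positive VDS mean yields
    ``NaN`` (flagged, never silently dropped).
    """
    d.check_matches(m)
    vals = m.values

    def _fc(sub_ids: pd.Index) -> pd.Series:
        sub = d.table.loc[sub_ids]
        vds = vals.loc[sub.index[sub["diet"] == "VDS"]].mean(axis=0, skipna=True)
        vdd = vals.loc[sub.index[sub["diet"] == "VDD"]].mean(axis=0, skipna=True)
        if (sub["diet"] == "VDS").sum() == 0 or (sub["diet"] == "VDD").sum() == 0:
            raise ValidationError("each referenced group needs >= 1 sample")
        fc = vdd / vds
        fc[vds <= 0] = np.nan
        return fc

    if not by_strain:
        return _fc(d.sample_ids).to_frame("fold_change").T
    rows = {}
    for strain in d.strains:
        ids = d.table.index[d.table["strain"] == strain]
        rows[strain] = _fc(ids)
    return pd.DataFrame(rows).T.rename_axis("strain")


@dataclass
class PctReduction:
    """Per-sample and per-strain percentage change of VDD relative to the
    within-strain VDS mean, in percent (negative = reduction)."""

    per_sample: pd.Series
    per_strain: pd.DataFrame  # columns: mean, sem, n


def pct_reduction_25ohd(values: pd.Series, d: StudyDesign) -> PctReduction:
    """Percentage reduction ``100 * (VDD_sample - VDS_mean) / VDS_mean``.

    ``values`` holds one measurement per sample (e.g. plasma 25(OH)D in
    ng/mL); the VDS mean is computed within the sample's strain.  Defined
    only for VDD samples.
    """
    missing = d.sample_ids.difference(values.index)
    if len(missing):
        raise ValidationError(f"values missing for samples: {missing.tolist()[:5]}")
    per_sample = {}
    for strain in d.strains:
        sub = d.table[d.table["strain"] == strain]
        vds_ids = sub.index[sub["diet"] == "VDS"]
        vdd_ids = sub.index[sub["diet"] == "VDD"]
        if len(vds_ids) == 0:
            raise ValidationError(f"strain {strain!r} has no VDS stratum")
        vds_mean = float(values.loc[vds_ids].mean())
        for sid in vdd_ids:
            per_sample[sid] = 100.0 * (float(values.loc[sid]) - vds_mean) / vds_mean
    per_sample = pd.Series(per_sample, name="pct_reduction")
    strain_of = d.table.loc[per_sample.index, "strain"]
    grp = per_sample.groupby(strain_of)
    per_strain = pd.DataFrame({
        "mean": grp.mean(),
        "sem": grp.sem(ddof=1),
        "n": grp.size(),
    })
    return PctReduction(per_sample=per_sample, per_strain=per_strain)


# ---------------------------------------------------------------------------
# Assumption-gated hypothesis tests
# ---------------------------------------------------------------------------

@dataclass
class GatedTestResult:
    test: str
    p: float
    normal: Optional[bool]
    equal_variance: Optional[bool]
    warnings: List[str] = field(default_factory=list)


def _welch_anova(groups: Sequence[np.ndarray]) -> float:
    import pingouin as pg
    values = np.concatenate(groups)
    labels = np.concatenate([[i] * len(g) for i, g in enumerate(groups)])
    df = pd.DataFrame({"y": values, "g": labels})
    res = pg.welch_anova(data=df, dv="y", between="g")
    col = "p_unc" if "p_unc" in res.columns else "p-unc"
    return float(res[col].iloc[0])


def gated_test(groups: Sequence[Sequence[float]], alpha: float = 0.05
               ) -> GatedTestResult:
    """Choose and run the appropriate two-or-more-group location test.

    Decision tree: per-group Shapiro-Wilk at ``alpha``; any failure sends
    the data to the nonparametric branch (Wilcoxon rank-sum for 2 groups,
    Kruskal-Wallis for more).  If normality holds, Bartlett's test gates
    between the pooled and the Welch variants of t / ANOVA.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    notes: List[str] = []
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        notes.append("all observations identical; no evidence either way")
        warnings.warn(notes[-1], UserWarning, stacklevel=2)
        return GatedTestResult("degenerate", 1.0, None, None, notes)
    if min(len(g) for g in groups) < 2:
        notes.append("group with < 2 observations; nonparametric fallback")
        warnings.warn(notes[-1], UserWarning, stacklevel=2)
        p = _nonparametric(groups)
        name = "wilcoxon" if len(groups) == 2 else "kruskal-wallis"
        return GatedTestResult(name, p, None, None, notes)

    normal = True
    for g in groups:
        if len(g) < 3 or np.all(g == g[0]):
            # normality untestable on < 3 points; constant group -> non-normal
            if np.all(g == g[0]):
                normal = False
            continue
        if stats.shapiro(g).pvalue < alpha:
            normal = False
            break
    if not normal:
        p = _nonparametric(groups)
        name = "wilcoxon" if len(groups) == 2 else "kruskal-wallis"
        return GatedTestResult(name, p, False, None, notes)

    equal_var = bool(stats.bartlett(*groups).pvalue >= alpha)
    if len(groups) == 2:
        p = float(stats.ttest_ind(groups[0], groups[1], equal_var=equal_var).pvalue)
        name = "t" if equal_var else "welch-t"
    else:
        if equal_var:
            p = float(stats.f_oneway(*groups).pvalue)
            name = "anova"
        else:
            p = _welch_anova(groups)
            name = "welch-anova"
    return GatedTestResult(name, p, True, equal_var, notes)


def _nonparametric(groups: Sequence[np.ndarray]) -> float:
    if len(groups) == 2:
        return float(stats.mannwhitneyu(groups[0], groups[1],
                                        alternative="two-sided").pvalue)
    return float(stats.kruskal(*groups).pvalue)


def median_test(groups: Sequence[Sequence[float]]) -> float:
    """Brown-Mood median test.

    Observations are classified as above vs at-or-below the grand median;
    the resulting contingency table is tested by chi-square (Yates-corrected
    on 2x2, matching the common convention) or, for two groups with any
    expected count < 5, by the exact two-sided Fisher test.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return 1.0
    grand = np.median(flat)
    table = np.array([[(g > grand).sum(), (g <= grand).sum()] for g in groups]).T
    if (table.sum(axis=0) == 0).any():
        return 1.0
    expected = stats.contingency.expected_freq(table)
    if len(groups) == 2 and (expected < 5).any():
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    correction = len(groups) == 2
    chi2 = stats.chi2_contingency(table, correction=correction)
    return float(chi2.pvalue)


# ---------------------------------------------------------------------------
# Tukey-Kramer HSD and compact letter display
# ---------------------------------------------------------------------------

@dataclass
class TukeyResult:
    labels: List[str]
    pairwise_p: pd.DataFrame
    letters: Dict[str, str]
    alpha: float


def _compact_letters(labels: Sequence[str], means: np.ndarray,
                     sig_pairs: set, ) -> Dict[str, str]:
    """Insert-and-absorb compact letter display.

    Start from one column holding every group; for each significantly
    different pair split every column containing both; then drop columns
    that are subsets of others.  Groups sharing a letter are not
    significantly different.
    """
    columns: List[set] = [set(range(len(labels)))]
    for (i, j) in sorted(sig_pairs):
        for col in [c for c in columns if i in c and j in c]:
            columns.remove(col)
            columns.extend([col - {i}, col - {j}])
        # absorb: remove columns contained in another
        columns = [c for c in columns
                   if not any(c < other for other in columns)]
    # deduplicate and order by the smallest group mean in each column
    uniq: List[set] = []
    for c in columns:
        if c not in uniq:
            uniq.append(c)
    uniq.sort(key=lambda c: min(means[i] for i in c) if c else np.inf)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lab: "" for lab in labels}
    for k, col in enumerate(uniq):
        for i in sorted(col):
            letters[labels[i]] += alphabet[k % len(alphabet)]
    return letters


def tukey_kramer(groups: Sequence[Sequence[float]],
                 labels: Optional[Sequence[str]] = None,
                 alpha: float = 0.05) -> TukeyResult:
    """Tukey-Kramer HSD pairwise comparisons with letter display.

    Uses the studentized-range distribution with Kramer's unequal-n
    correction (which reduces to plain Tukey HSD for balanced groups).
    Requires >= 3 groups; use the two-sample tests for pairs.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValidationError("Tukey-Kramer needs >= 3 groups; "
                              "use a two-group test for pairs")
    if min(len(g) for g in groups) < 2:
        raise ValidationError("every group needs >= 2 observations")
    if labels is None:
        labels = [f"g{i + 1}" for i in range(len(groups))]
    labels = list(labels)
    res = stats.tukey_hsd(*groups)
    pmat = pd.DataFrame(res.pvalue, index=labels, columns=labels)
    means = np.array([g.mean() for g in groups])
    sig = {(i, j)
           for i in range(len(groups)) for j in range(i + 1, len(groups))
           if res.pvalue[i, j] < alpha}
    letters = _compact_letters(labels, means, sig)
    return TukeyResult(labels=labels, pairwise_p=pmat, letters=letters,
                       alpha=alpha)


# ---------------------------------------------------------------------------
# Robust-change filter and the combined response table
# ---------------------------------------------------------------------------

def robust_change_filter(vip_table: pd.DataFrame, response_table: pd.DataFrame,
                         vip_min: float = 1.5, fc_min: float = 1.5,
                         vip_column: str = "rmsVIP") -> pd.DataFrame:
    """Select VIP >= ``vip_min`` metabolites; flag the >= ``fc_min``-fold subset.

    The fold-change threshold is applied symmetrically: a metabolite passes
    if ``max(FC, 1/FC) >= fc_min``, so decreases count the same as
    increases.  Both inputs must be indexed by the same metabolite ids.
    """
    if set(vip_table.index) != set(response_table.index):
        only_v = sorted(set(vip_table.index) - set(response_table.index))[:5]
        only_r = sorted(set(response_table.index) - set(vip_table.index))[:5]
        raise ValidationError(
            f"mismatched metabolite ids: vip-only {only_v}, response-only {only_r}"
        )
    fc = response_table.loc[vip_table.index, "fold_change"].astype(float)
    sym = np.maximum(fc, 1.0 / fc)
    out = pd.DataFrame({
        "vip": vip_table[vip_column].astype(float),
        "fold_change": fc,
        "selected": vip_table[vip_column] >= vip_min,
    })
    out["robust"] = out["selected"] & (sym >= fc_min)
    return out


def strain_response_table(
    m: AbundanceMatrix,
    d: StudyDesign,
    vip_table: Optional[pd.DataFrame] = None,
    diet_test: str = "gated",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-metabolite summary: fold changes, diet test, strain effect, letters.

    The strain effect is tested on per-VDD-sample relative responses
    (``VDD_sample / within-strain VDS mean``), mirroring the fold-change
    bars: the gated ANOVA family compares these responses across strains,
    and Tukey-Kramer letters mark strains with distinct responses.

    ``diet_test`` is ``gated`` (assumption-gated battery), ``wilcoxon`` or
    ``median``.  BH-adjusted q-values are appended as a labeled extension.
    """
    from statsmodels.stats.multitest import multipletests

    d.check_matches(m)
    pop_fc = fold_change(m, d, by_strain=False).loc["fold_change"]
    strain_fc = fold_change(m, d, by_strain=True)

    diet_p = {}
    strain_p = {}
    letters: Dict[str, Dict[str, str]] = {}
    vals = m.values
    vdd_ids = d.table.index[d.table["diet"] == "VDD"]
    vds_mean_by_strain = {
        s: vals.loc[d.table.index[(d.table["strain"] == s)
                                  & (d.table["diet"] == "VDS")]].mean(axis=0)
        for s in d.strains
    }
    for met in m.metabolite_ids:
        col = vals[met]
        g_vds = col[d.table["diet"] == "VDS"].dropna().to_numpy()
        g_vdd = col[d.table["diet"] == "VDD"].dropna().to_numpy()
        if diet_test == "gated":
            diet_p[met] = gated_test([g_vds, g_vdd], alpha=alpha).p
        elif diet_test == "wilcoxon":
            diet_p[met] = _nonparametric([g_vds, g_vdd])
        elif diet_test == "median":
            diet_p[met] = median_test([g_vds, g_vdd])
        else:
            raise ValidationError(f"unknown diet_test {diet_test!r}")

        resp_groups, resp_labels = [], []
        for s in d.strains:
            ids = [i for i in vdd_ids if d.table.loc[i, "strain"] == s]
            denom = vds_mean_by_strain[s][met]
            g = (col.loc[ids] / denom).dropna().to_numpy()
            if len(g) >= 2 and np.isfinite(denom) and denom > 0:
                resp_groups.append(g)
                resp_labels.append(s)
        if len(resp_groups) >= 3:
            strain_p[met] = gated_test(resp_groups, alpha=alpha).p
            try:
                letters[met] = tukey_kramer(resp_groups, resp_labels,
                                            alpha=alpha).letters
            except ValidationError:
                letters[met] = {}
        else:
            strain_p[met] = np.nan
            letters[met] = {}

    table = pd.DataFrame({
        "fold_change": pop_fc,
        "diet_p": pd.Series(diet_p),
        "strain_effect_p": pd.Series(strain_p),
    })
    ok = table["diet_p"].notna()
    q = np.full(len(table), np.nan)
    if ok.any():
        q[ok.to_numpy()] = multipletests(table.loc[ok, "diet_p"], method="fdr_bh")[1]
    table["diet_q_bh"] = q  # BH adjustment: an extension beyond raw p-values
    for s in d.strains:
        table[f"fc_{s}"] = strain_fc.loc[s]
        table[f"letter_{s}"] = [letters[met].get(s, "") for met in table.index]
    if vip_table is not None:
        table = table.join(vip_table[["VIP_pred", "VIP_ortho", "rmsVIP"]])
    return table
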