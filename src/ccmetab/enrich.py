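"""Over-representation analysis of selected metabolites against named sets.

A stand-in for pathway-database enrichment: each user-supplied metabolite
set is intersected with the analysis universe (all metabolites present
after preprocessing) and tested with the one-sided hypergeometric
upper-tail probability of observing at least the seen overlap between the
set and the selected list.  Benjamini-Hochberg FDR is applied across the
tested sets.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Sequence

from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import ValidationError


def _hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(overlap >= k) drawing n of N with K marked, by integer arithmetic.

    The numerator and denominator are exact integers, so the float result
    is correctly rounded — closed-form extremes like 1/C(10,5) come out
    bit-exact, which a floating-point survival function does not guarantee.
    """
    if k <= 0:
        return 1.0
    num = sum(comb(K, j) * comb(N - K, n - j)
              for j in range(k, min(K, n) + 1))
    return num / comb(N, n)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values (monotonicity enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora(
    selected: Iterable[str],
    sets: Dict[str, Sequence[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
    min_set_size: int = 2,
) -> pd.DataFrame:
    """Hypergeometric over-representation analysis.

    Parameters
    ----------
    selected
        Metabolite ids chosen by the upstream filter (e.g. VIP >= 1.5).
        Must be a subset of ``universe``.
    sets
        Mapping of set name to member ids (GMT-style).  Members are
        intersected with the universe before testing; sets smaller than
        ``min_set_size`` after intersection are skipped with a note.
    universe
        All metabolites eligible for selection.

    Returns a table with N (universe), K (set), n (selected), k (overlap),
    the upper-tail hypergeometric p, BH q, and a significance flag.
    """
    universe = list(dict.fromkeys(universe))
    selected = list(dict.fromkeys(selected))
    if not universe:
        raise ValidationError("empty universe")
    if not selected:
        raise ValidationError("empty selection")
    uni = set(universe)
    stray = [s for s in selected if s not in uni]
    if stray:
        raise ValidationError(f"selected ids outside universe: {stray[:5]}")
    N, n = len(uni), len(selected)
    sel = set(selected)
    rows = []
    skipped = []
    for name, members in sets.items():
        mem = set(members) & uni
        K = len(mem)
        if K < min_set_size:
            skipped.append(name)
            continue
        k = len(mem & sel)
        p = _hypergeom_upper_tail(k, N, K, n)
        rows.append((name, N, K, n, k, p))
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} set(s) below size {min_set_size} after "
            f"universe intersection: {skipped[:5]}", UserWarning, stacklevel=2,
        )
    out = pd.DataFrame(
        rows, columns=["set", "N", "K", "n", "k", "p"]
    ).set_index("set")
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
        out["significant"] = out["q"] < alpha
        out = out.sort_values("p")
    return out
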