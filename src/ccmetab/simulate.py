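"""Synthetic study generator for the strain x diet liver metabolomics design.

Emulates an 8-strain Collaborative Cross dam cohort (two diets, vitamin D
sufficient ``VDS`` vs deficient ``VDD``, 72 dams in groups of 3-6) profiled on
an untargeted metabolomics platform: log-normal abundances with strain main
effects, diet effects on a subset of metabolites, strain-specific diet
responses ("responder" strains), multiplicative run-day batch factors, and
below-LOD censoring of the lowest raw values.  Every random component is
driven by an independent substream spawned from a single seed, so identical
``(config, seed)`` pairs give bit-identical output.

The generative model on the natural-log scale is

    log x_ij = b_j + s(strain_i, j) + 1[diet_i = VDD] * d_j(strain_i) * ln 2
               + log f(day_i, j) + e_ij,     e_ij ~ N(0, sigma^2)

with ``d_j(strain)`` the diet effect in log2 units (population effect, or the
responder-spec total for declared responder strains), ``f`` the per-(day,
metabolite) batch multiplier, and ``sigma = sqrt(ln(1 + cv^2))`` so that the
residual coefficient of variation on the raw scale equals ``noise_cv``.
After exponentiation, the lowest ``lod_quantile`` fraction of each
metabolite's raw values is censored to missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, StudyDesign, ValidationError

DEFAULT_STRAINS = (
    "CC001", "CC004", "CC011", "CC017", "CC032", "CC041", "CC042", "CC051",
)

#: Default responder strains: one strain with a ~4.5-fold lipid response and
#: one with a ~9-fold response on a second metabolite family.
DEFAULT_RESPONDER_SPECS = (
    ("CC017", "fatty_acids", math.log2(4.5), 13),
    ("CC032", "glycerophospholipids", math.log2(9.0), 15),
)


class ConfigurationError(ValidationError):
    """Raised when a synthetic-study configuration is internally inconsistent."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic strain x diet metabolomics study.

    Defaults reproduce the study scale: 8 strains x 2 diets, 72 dams in
    groups of 3-6, 654 metabolites of which 78 respond to diet, ~30% carrying
    strain main effects, 4 instrument run days, and 2% below-LOD censoring.
    """

    strains: Sequence[str] = DEFAULT_STRAINS
    n_total: int = 72
    n_per_group: Optional[Mapping[Tuple[str, str], int]] = None
    group_size_range: Tuple[int, int] = (3, 6)
    n_metabolites: int = 654
    n_diet_responsive: int = 78
    diet_log2fc_range: Tuple[float, float] = (0.5, 1.5)
    frac_diet_increase: float = 0.8
    frac_strain_affected: float = 0.3
    strain_effect_sd: float = 0.5
    responder_specs: Sequence[Tuple[str, str, float, int]] = DEFAULT_RESPONDER_SPECS
    strain_shift_specs: Sequence[Tuple[str, Sequence[str], float]] = ()
    n_run_days: int = 4
    batch_sd: float = 0.1
    noise_cv: float = 0.3
    lod_quantile: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_diet_responsive > self.n_metabolites:
            raise ConfigurationError("n_diet_responsive exceeds n_metabolites")
        if not (0 <= self.lod_quantile < 1):
            raise ConfigurationError("lod_quantile must lie in [0, 1)")
        strains = set(self.strains)
        for strain, label, _, n_members in self.responder_specs:
            if strain not in strains:
                raise ConfigurationError(f"responder strain {strain!r} not in strains")
            if n_members < 1:
                raise ConfigurationError(f"responder set {label!r} has no members")
        if sum(s[3] for s in self.responder_specs) > self.n_diet_responsive:
            raise ConfigurationError(
                "responder-set members exceed n_diet_responsive"
            )
        for strain, _, _ in self.strain_shift_specs:
            if strain not in strains:
                raise ConfigurationError(f"shift-spec strain {strain!r} not in strains")
        lo, hi = self.group_size_range
        if lo < 2:
            raise ConfigurationError("group sizes must be >= 2")
        if self.n_per_group is not None:
            if min(self.n_per_group.values()) < 2:
                raise ConfigurationError("group sizes must be >= 2")
        else:
            n_groups = 2 * len(self.strains)
            if not (n_groups * lo <= self.n_total <= n_groups * hi):
                raise ConfigurationError(
                    f"n_total={self.n_total} unreachable with group sizes in "
                    f"[{lo}, {hi}] over {n_groups} groups"
                )
        if self.noise_cv < 0 or self.batch_sd < 0:
            raise ConfigurationError("noise_cv and batch_sd must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground-truth record of every injected effect, for recovery testing.

    Diet effects are stored in log2 units; strain main-effect shifts and
    responder interactions are also recorded (interaction = responder total
    minus the population diet effect, log2).  Units are documented per field.
    """

    diet_responsive_ids: List[str]
    diet_log2fc: pd.Series  # per metabolite, log2; zero for non-responsive
    interaction_log2: Dict[Tuple[str, str], float]  # (strain, metabolite) -> log2
    responder_sets: Dict[str, List[str]]  # set label -> metabolite ids
    responder_strain_of_set: Dict[str, str]
    strain_effect_map: pd.DataFrame  # strains x metabolites, natural-log shifts
    day_factors: pd.DataFrame  # run days x metabolites, multiplicative
    lod_censored: List[Tuple[str, str]]  # (sample_id, metabolite_id)

    def total_log2fc(self, strain: str) -> pd.Series:
        """Diet log2 fold change experienced by a given strain."""
        out = self.diet_log2fc.copy()
        for (s, met), extra in self.interaction_log2.items():
            if s == strain:
                out[met] += extra
        return out


def _draw_group_sizes(config: SyntheticConfig, rng: np.random.Generator
                      ) -> Dict[Tuple[str, str], int]:
    if config.n_per_group is not None:
        return dict(config.n_per_group)
    lo, hi = config.group_size_range
    groups = [(s, d) for s in config.strains for d in ("VDS", "VDD")]
    sizes = rng.integers(lo, hi + 1, size=len(groups))
    # nudge random groups up/down (within bounds) until the total matches
    while sizes.sum() != config.n_total:
        i = rng.integers(len(groups))
        if sizes.sum() < config.n_total and sizes[i] < hi:
            sizes[i] += 1
        elif sizes.sum() > config.n_total and sizes[i] > lo:
            sizes[i] -= 1
    return {g: int(n) for g, n in zip(groups, sizes)}


def simulate_study(config: SyntheticConfig
                   ) -> Tuple[AbundanceMatrix, StudyDesign, SyntheticTruth]:
    """Generate one synthetic study: abundances, design, and ground truth.

    Deterministic given ``config`` (which includes the seed).  Samples are
    assigned to run days round-robin so every day contains every strain x
    diet group and the per-day median normalization stays estimable.
    """
    ss = np.random.SeedSequence(config.seed)
    (ss_sizes, ss_base, ss_strain, ss_diet, ss_day, ss_noise) = ss.spawn(6)

    sizes = _draw_group_sizes(config, np.random.default_rng(ss_sizes))
    for g, n in sizes.items():
        if n < 2:
            raise ConfigurationError(f"group {g} has size {n} < 2")

    # ---- design frame --------------------------------------------------------
    rows = []
    for strain in config.strains:
        for diet in ("VDS", "VDD"):
            for k in range(sizes[(strain, diet)]):
                rows.append((f"{strain}_{diet}_{k + 1}", strain, diet))
    sample_ids = [r[0] for r in rows]
    n = len(sample_ids)
    design = pd.DataFrame(
        {"strain": [r[1] for r in rows], "diet": [r[2] for r in rows]},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    # Round-robin day assignment over diet-paired samples: the two diet arms
    # of each strain are paired off and both members of a pair share a run
    # day, so every day contains every group and run day is unconfounded
    # with diet (as in a randomized, diet-blocked acquisition order).
    # Unpaired leftovers from unequal group sizes continue the rotation.
    day_of = {}
    counter = 0
    for strain in config.strains:
        vds = [f"{strain}_VDS_{k + 1}" for k in range(sizes[(strain, "VDS")])]
        vdd = [f"{strain}_VDD_{k + 1}" for k in range(sizes[(strain, "VDD")])]
        n_pair = min(len(vds), len(vdd))
        for k in range(n_pair):
            day = f"day{1 + counter % config.n_run_days}"
            day_of[vds[k]] = day_of[vdd[k]] = day
            counter += 1
        for sid in vds[n_pair:] + vdd[n_pair:]:
            day_of[sid] = f"day{1 + counter % config.n_run_days}"
            counter += 1
    design["run_day"] = [day_of[sid] for sid in sample_ids]

    p = config.n_metabolites
    met_ids = [f"met{j + 1:04d}" for j in range(p)]

    # ---- baselines and strain main effects ----------------------------------
    baseline = np.random.default_rng(ss_base).normal(0.0, 1.0, size=p)

    rng_strain = np.random.default_rng(ss_strain)
    n_affected = int(round(config.frac_strain_affected * p))
    affected = rng_strain.choice(p, size=n_affected, replace=False)
    strain_fx = np.zeros((len(config.strains), p))
    strain_fx[:, affected] = rng_strain.normal(
        0.0, config.strain_effect_sd, size=(len(config.strains), n_affected)
    )
    for strain, ids, shift in config.strain_shift_specs:
        si = list(config.strains).index(strain)
        cols = [met_ids.index(m) for m in ids]
        strain_fx[si, cols] += shift
    strain_effect_map = pd.DataFrame(
        strain_fx, index=list(config.strains), columns=met_ids
    )

    # ---- diet effects and responder interactions ----------------------------
    rng_diet = np.random.default_rng(ss_diet)
    responsive_idx = rng_diet.choice(p, size=config.n_diet_responsive, replace=False)
    lo, hi = config.diet_log2fc_range
    mags = rng_diet.uniform(lo, hi, size=config.n_diet_responsive)
    signs = np.where(
        rng_diet.random(config.n_diet_responsive) < config.frac_diet_increase, 1.0, -1.0
    )
    diet_log2 = np.zeros(p)
    diet_log2[responsive_idx] = mags * signs
    diet_log2fc = pd.Series(diet_log2, index=met_ids)

    responder_sets: Dict[str, List[str]] = {}
    responder_strain_of_set: Dict[str, str] = {}
    interaction_log2: Dict[Tuple[str, str], float] = {}
    pool = list(responsive_idx)
    for strain, label, log2_total, n_members in config.responder_specs:
        members_idx = [pool.pop(int(rng_diet.integers(len(pool))))
                       for _ in range(n_members)]
        members = [met_ids[j] for j in members_idx]
        responder_sets[label] = members
        responder_strain_of_set[label] = strain
        for m in members:
            # interaction tops the population effect up to the spec'd total
            interaction_log2[(strain, m)] = log2_total - diet_log2fc[m]

    # ---- day factors and noise ----------------------------------------------
    day_labels = [f"day{d + 1}" for d in range(config.n_run_days)]
    day_fx = np.exp(
        np.random.default_rng(ss_day).normal(
            0.0, config.batch_sd, size=(config.n_run_days, p)
        )
    )
    day_factors = pd.DataFrame(day_fx, index=day_labels, columns=met_ids)

    sigma = math.sqrt(math.log1p(config.noise_cv ** 2))
    noise = np.random.default_rng(ss_noise).normal(0.0, sigma, size=(n, p))

    # ---- assemble log abundances --------------------------------------------
    strain_row = design["strain"].map(
        {s: i for i, s in enumerate(config.strains)}
    ).to_numpy()
    is_vdd = (design["diet"] == "VDD").to_numpy(dtype=float)
    day_row = design["run_day"].map(
        {d: i for i, d in enumerate(day_labels)}
    ).to_numpy()

    diet_total_log2 = np.tile(diet_log2, (n, 1))
    for (strain, met), extra in interaction_log2.items():
        mask = design["strain"].to_numpy() == strain
        diet_total_log2[mask, met_ids.index(met)] += extra

    log_x = (
        baseline[None, :]
        + strain_fx[strain_row, :]
        + is_vdd[:, None] * diet_total_log2 * math.log(2.0)
        + np.log(day_fx)[day_row, :]
        + noise
    )
    values = np.exp(log_x)

    # ---- below-LOD censoring -------------------------------------------------
    censored: List[Tuple[str, str]] = []
    k_cens = int(math.floor(config.lod_quantile * n))
    if k_cens > 0:
        order = np.argsort(values, axis=0, kind="stable")
        for j in range(p):
            for i in order[:k_cens, j]:
                censored.append((sample_ids[i], met_ids[j]))
                values[i, j] = np.nan

    matrix = AbundanceMatrix(
        values=pd.DataFrame(values, index=design.index, columns=met_ids),
        run_day=design["run_day"],
        stage="raw",
    )
    truth = SyntheticTruth(
        diet_responsive_ids=[met_ids[j] for j in sorted(responsive_idx)],
        diet_log2fc=diet_log2fc,
        interaction_log2=interaction_log2,
        responder_sets=responder_sets,
        responder_strain_of_set=responder_strain_of_set,
        strain_effect_map=strain_effect_map,
        day_factors=day_factors,
        lod_censored=censored,
    )
    return matrix, StudyDesign(design), truth


# ---------------------------------------------------------------------------
# Plasma 25(OH)D
# ---------------------------------------------------------------------------

#: Printed anchors: CC011 15.9 ng/mL VDS and -34% depletion; CC017 7.4 ng/mL
#: and ~57% depletion; CC032 the highest VDS mean with ~66% depletion.  The
#: remaining five strains are synthetic interpolations of that range.
DEFAULT_VDS_MEANS = {
    "CC001": 12.0, "CC004": 10.5, "CC011": 15.9, "CC017": 7.4,
    "CC032": 16.5, "CC041": 11.0, "CC042": 13.0, "CC051": 9.5,
}
DEFAULT_DEPLETION = {
    "CC001": 0.55, "CC004": 0.50, "CC011": 0.34, "CC017": 0.57,
    "CC032": 0.66, "CC041": 0.60, "CC042": 0.52, "CC051": 0.48,
}


def simulate_25ohd(
    design: StudyDesign,
    strain_means_vds: Optional[Mapping[str, float]] = None,
    depletion_frac: Optional[Mapping[str, float]] = None,
    cv: float = 0.2,
    seed: int = 0,
) -> pd.Series:
    """Per-sample plasma 25-hydroxyvitamin D concentrations (ng/mL).

    VDS samples are drawn around the strain's sufficient-diet mean, VDD
    samples around ``mean * (1 - depletion_frac)``.  Values are strictly
    positive: multiplicative log-normal noise with the stated coefficient of
    variation, mean-corrected so sample means recover the inputs.
    """
    means = dict(DEFAULT_VDS_MEANS if strain_means_vds is None else strain_means_vds)
    depl = dict(DEFAULT_DEPLETION if depletion_frac is None else depletion_frac)
    for s, m in means.items():
        if m < 0:
            raise ValidationError(f"negative 25(OH)D mean for strain {s}")
    for s, f in depl.items():
        if not (0.0 <= f <= 1.0):
            raise ValidationError(f"depletion_frac for {s} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(cv ** 2))
    out = []
    for sid, row in design.table.iterrows():
        mu = means[row["strain"]]
        if row["diet"] == "VDD":
            mu = mu * (1.0 - depl[row["strain"]])
        # E[exp(N(-s^2/2, s^2))] = 1, so the sample mean targets mu exactly
        out.append(mu * math.exp(rng.normal(-sigma ** 2 / 2.0, sigma)) if cv > 0
                   else mu)
    return pd.Series(out, index=design.sample_ids, name="vitd_25ohd")


# ---------------------------------------------------------------------------
# Pathway sets
# ---------------------------------------------------------------------------

def make_pathway_sets(
    metabolite_ids: Sequence[str],
    set_sizes: Sequence[int],
    overlap_with_truth: float,
    seed: int = 0,
    truth_ids: Sequence[str] = (),
) -> Dict[str, List[str]]:
    """Build GMT-style named metabolite sets for enrichment testing.

    The first set, named ``responsive_set``, contains
    ``floor(overlap_with_truth * len(truth_ids))`` ground-truth responsive
    metabolites topped up with random non-truth members — a positive control
    for over-representation analysis.  Remaining sets are random draws.
    """
    if not (0.0 <= overlap_with_truth <= 1.0):
        raise ValidationError("overlap_with_truth must lie in [0, 1]")
    universe = list(metabolite_ids)
    for size in set_sizes:
        if size > len(universe):
            raise ValidationError(f"set size {size} exceeds universe {len(universe)}")
    rng = np.random.default_rng(seed)
    truth = [m for m in truth_ids if m in set(universe)]
    sets: Dict[str, List[str]] = {}
    for i, size in enumerate(set_sizes):
        if i == 0:
            k = int(math.floor(overlap_with_truth * len(truth)))
            k = min(k, size)
            members = list(rng.choice(truth, size=k, replace=False)) if k else []
            non_truth = [m for m in universe if m not in set(truth)]
            fill = size - k
            if fill > len(non_truth):
                raise ValidationError("not enough non-truth metabolites to fill set")
            members += list(rng.choice(non_truth, size=fill, replace=False))
            sets["responsive_set"] = sorted(members)
        else:
            sets[f"random_set_{i}"] = sorted(
                rng.choice(universe, size=size, replace=False)
            )
    return sets
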