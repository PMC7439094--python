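import math

import numpy as np
import pandas as pd
import pytest

import ccmetab as cm


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: 4 strains, 40 dams, 120 metabolites."""
    return cm.SyntheticConfig(
        strains=("CC001", "CC011", "CC017", "CC032"),
        n_total=40,
        n_metabolites=120,
        n_diet_responsive=20,
        responder_specs=(("CC017", "fatty_acids", math.log2(4.5), 5),),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return cm.simulate_study(small_config)


@pytest.fixture(scope="session")
def preprocessed_small(small_study):
    matrix, design, truth = small_study
    return cm.preprocess(matrix), design, truth


def zero_effect_config(**overrides):
    """Pure-noise configuration (no strain, diet, or responder effects)."""
    base = dict(
        strains=("CC001", "CC011", "CC017", "CC032"),
        n_total=40,
        n_metabolites=120,
        n_diet_responsive=0,
        frac_strain_affected=0.0,
        responder_specs=(),
        seed=0,
    )
    base.update(overrides)
    return cm.SyntheticConfig(**base)


def toy_design(strains, diets, run_day="day1"):
    """Build a design + matching index from parallel strain/diet lists."""
    ids = [f"s{i}" for i in range(len(strains))]
    table = pd.DataFrame({"strain": strains, "diet": diets,
                          "run_day": run_day},
                         index=pd.Index(ids, name="sample_id"))
    return cm.StudyDesign(table)


def toy_matrix(values, design, metabolites=None):
    values = np.asarray(values, dtype=float)
    cols = metabolites or [f"m{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=design.sample_ids, columns=cols)
    return cm.AbundanceMatrix(values=df, run_day=design.table["run_day"])
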