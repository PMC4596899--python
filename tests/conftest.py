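import warnings

import numpy as np
import pandas as pd
import pytest

import mrscore as m


@pytest.fixture(scope="session")
def desk_data():
    """Default desk-scale consortium, shared across read-only tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return m.simulate_consortium(m.SimulationSpec(seed=7))


@pytest.fixture(scope="session")
def height_score(desk_data):
    w = desk_data.weights_for("height")
    panel = m.harmonize(desk_data.panel, w)
    return m.standardize(m.build_score(panel, w))


@pytest.fixture
def tiny_weights():
    return m.WeightTable(
        [
            m.VariantWeight("rs1", "A", "G", 0.10),
            m.VariantWeight("rs2", "C", "T", 0.05),
        ]
    )


@pytest.fixture
def tiny_panel():
    df = pd.DataFrame(
        {"rs1": [1.5, 0.0, 2.0], "rs2": [0.5, 1.0, 0.25]},
        index=["s1", "s2", "s3"],
    )
    return m.DosagePanel(df, {"rs1": "A", "rs2": "C"}, {"rs1": "G", "rs2": "T"})


def null_simulation_spec(seed, n_studies=22, n_cases=40, n_controls=40, n_variants=12):
    """Consortium spec with every genetic effect on disease and death zeroed."""
    return m.SimulationSpec(
        n_studies=n_studies,
        n_cases_per_study=n_cases,
        n_controls_per_study=n_controls,
        n_variants={"height": n_variants},
        target_r2={"height": 0.06},
        disease_logor={"height": 0.0},
        grade_high_logor={"height": 0.0},
        stage_advanced_logor={"height": 0.0},
        hr_disease_death={"height": {"low": 0.0, "high": 0.0}},
        hr_other_death={"height": {"low": 0.0, "high": 0.0}},
        seed=seed,
    )


def standardized_score(data, phenotype="height"):
    w = data.weights_for(phenotype)
    return m.standardize(m.build_score(m.harmonize(data.panel, w), w))
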