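"""Shared fixtures: a small synthetic cohort and the hand-enumerable codon toy."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ipmg import preprocess
from ipmg.cohort import CohortSpec, generate_cohort, generate_codon_fixture


def small_spec(seed: int = 11, **overrides) -> CohortSpec:
    """A reduced cohort for unit tests (fast to generate and screen)."""
    kwargs = dict(
        n_cancer_types=4, samples_per_type=40, n_genes=300, n_pathways=20,
        genes_per_pathway=15, n_immune_genes=20, n_hypermutated_genes=10,
        n_low_genes=3, n_snps=40, seed=seed,
    )
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_spec())


@pytest.fixture(scope="session")
def small_norm(small_cohort):
    m = preprocess.impute_by_cancer_type(small_cohort.expression, small_cohort.clinical)
    m = preprocess.filter_low_expression(m)
    return preprocess.log2_quantile_normalize(m)


@pytest.fixture(scope="session")
def codon_fixture():
    cds, muts = generate_codon_fixture()
    clin = pd.DataFrame({
        "sample_id": ["X1", "X2", "X3", "X4"],
        "cancer_type": ["TX"] * 4,
        "treatment_class": ["immunotherapy"] * 4,
        "time_days": [400.0, 300.0, 200.0, 100.0],
        "event": [1, 0, 1, 1],
    })
    return cds, muts, clin


# -- shared cache of default-scale cohorts for the acceptance suite ----------

_DEFAULT_CACHE: dict[int, tuple] = {}


def default_cohort(seed: int):
    """Default-scale cohort + normalized expression, cached across tests."""
    if seed not in _DEFAULT_CACHE:
        data = generate_cohort(CohortSpec(seed=seed))
        m = preprocess.impute_by_cancer_type(data.expression, data.clinical)
        m = preprocess.filter_low_expression(m)
        norm = preprocess.log2_quantile_normalize(m)
        _DEFAULT_CACHE[seed] = (data, norm)
        while len(_DEFAULT_CACHE) > 4:  # bound memory
            _DEFAULT_CACHE.pop(next(iter(_DEFAULT_CACHE)))
    return _DEFAULT_CACHE[seed]
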