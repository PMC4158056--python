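"""Shared fixtures: small planted scenarios generated at test time."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rhodonet import ExprMatrix, ModulePartition, OrthologMap

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")
from rhodonet.preprocess import robust_z
from rhodonet.synthdata import SynthSpec, gen_two_species


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Degenerate-row warnings are part of several contracts under test;
    keep the output readable without hiding unexpected warnings."""
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        yield


def small_two_species(seed: int = 1, preserved=(True, True, True, False, False),
                      rho: float = 0.9, n_genes: int = 400,
                      module_size: int = 40):
    """5-module two-species scenario with 50% background."""
    spec = SynthSpec(
        n_genes_A=n_genes,
        n_conditions_A=30,
        n_conditions_B=30,
        module_sizes=[module_size] * len(preserved),
        preserved_flags=list(preserved),
        within_module_cor=rho,
        background_fraction=1 - module_size * len(preserved) / n_genes,
        ortholog_fraction=1.0,
        seed=seed,
    )
    return spec, *gen_two_species(spec)


@pytest.fixture(scope="session")
def planted_scenario():
    """Reference planted dataset: 5 x 40-gene modules, rho=0.9, 200
    background genes, 30 conditions; plus the robust-z matrices."""
    spec, exprA, exprB, mapping, truth = small_two_species(seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        zA, _ = robust_z(exprA)
        zB, _ = robust_z(exprB)
    return {
        "spec": spec,
        "exprA": exprA,
        "exprB": exprB,
        "zA": zA,
        "zB": zB,
        "mapping": mapping,
        "truth": truth,
        "partition": ModulePartition(truth.labels_series()),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def expr_from_array(X, prefix="g", cprefix="c", standardization="robust_z"):
    X = np.asarray(X, dtype=float)
    return ExprMatrix(
        pd.DataFrame(
            X,
            index=[f"{prefix}{i:04d}" for i in range(X.shape[0])],
            columns=[f"{cprefix}{j:03d}" for j in range(X.shape[1])],
        ),
        standardization=standardization,
    )
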