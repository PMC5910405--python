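"""Shared fixtures: packaged pathway/kinetics and synthetic populations.

The expensive session fixtures (239-line populations and their fits) are
shared between the recovery and cross-validation tests.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pytest

from monolignol import (
    GeneratorSpec,
    fit_full,
    generate_population,
    load_default_kinetics,
    load_default_pathway,
)
from monolignol.pathway import (
    ComplexSpec,
    KineticParameterSet,
    PathwayDefinition,
    build_pathway,
)


@pytest.fixture(scope="session")
def pathway() -> PathwayDefinition:
    return load_default_pathway()


@pytest.fixture(scope="session")
def kinetics() -> KineticParameterSet:
    return load_default_kinetics()


@pytest.fixture(scope="session")
def wt_proteins(pathway):
    _, _, prot = GeneratorSpec().structural(pathway)
    return prot


def toy_chain_doc(kcat1=4.0, km1=10.0, kcat2=9.0, km2=25.0):
    """Two-step linear chain (source -> M -> sink) with known closed form.

    At steady state the intermediate M satisfies
    kcat1*E1*S/(km1+S) = kcat2*E2*M/(km2+M).
    """
    doc = {
        "metabolites": [
            {"id": 1, "name": "substrate", "role": "source"},
            {"id": 2, "name": "intermediate", "role": "internal"},
            {"id": 20, "name": "sink-a", "role": "sink"},
            {"id": 22, "name": "product", "role": "sink"},
            {"id": 24, "name": "sink-b", "role": "sink"},
        ],
        "reactions": [
            {"id": 1, "substrate": 1, "product": 2, "enzymes": ["E1"],
             "family": "F1", "active": True},
            {"id": 2, "substrate": 2, "product": 22, "enzymes": ["E2"],
             "family": "F2", "active": True},
        ],
        "inhibitions": [],
        "gene_families": {"E1": "F1", "E2": "F2"},
    }
    params = KineticParameterSet(
        reaction_params={(1, "E1"): (kcat1, km1), (2, "E2"): (kcat2, km2)},
        inhibition_params={},
    )
    return build_pathway(doc), params


@pytest.fixture()
def toy_chain():
    return toy_chain_doc()


def _generate(n_lines: int, seed: int, **overrides):
    spec = dataclasses.replace(GeneratorSpec(), n_lines=n_lines, **overrides)
    pathway = load_default_pathway()
    kinetics = load_default_kinetics()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_population(pathway, kinetics, spec, seed=seed), pathway, kinetics


@pytest.fixture(scope="session")
def small_noisefree():
    """40-line noise-free population plus its full fit."""
    ds, pathway, kinetics = _generate(
        40, seed=7, protein_noise_cv=0.0, trait_noise_cv=0.0
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pipe = fit_full(
            ds.transcripts, ds.proteins, ds.traits, pathway, kinetics,
            target_sg=ds.ground_truth.target_sg, max_terms=3,
        )
    return ds, pipe


@pytest.fixture(scope="session")
def study_noisefree():
    """Noise-free population at the study size (239 lines)."""
    ds, pathway, kinetics = _generate(
        239, seed=1, protein_noise_cv=0.0, trait_noise_cv=0.0
    )
    return ds, pathway, kinetics


@pytest.fixture(scope="session")
def study_noisy():
    """239-line population at the default noise levels (20% protein CV,
    10% trait noise-to-signal)."""
    ds, pathway, kinetics = _generate(239, seed=1)
    return ds, pathway, kinetics
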