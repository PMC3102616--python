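"""Shared fixtures: small synthetic datasets and one cached posterior fit."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import emaxdr as e

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_data():
    """One synthetic study-level dataset at the default 11-study design."""
    return e.generate_study_level(e.StudyLevelTruth(), seed=11)


@pytest.fixture(scope="session")
def study_results(study_data):
    """A fitted study-level posterior (moderate chain lengths), reused by
    every test that only needs *some* valid posterior."""
    model = e.StudyLevelEmaxModel(study_data)
    return model.fit(e.McmcConfig(n_chains=2, n_warmup=800, n_draws=800,
                                  seed=42))


@pytest.fixture(scope="session")
def base_patient_truth():
    """Patient-level truth with no covariate links (pure base model)."""
    spec = replace(e.PatientLevelTruth().spec, links=())
    return replace(e.PatientLevelTruth(), spec=spec)


@pytest.fixture(scope="session")
def small_patient_data(base_patient_truth):
    """A small (n=240) patient-level dataset from the base-model truth."""
    truth = replace(base_patient_truth, n_patients=240)
    return e.generate_patient_level(truth, seed=21)


def degenerate_posterior(emax=176.0, ed50=26.0, n=64, **extra):
    """A posterior whose draws are all the same point (two chains)."""
    params = dict(emax=emax, ed50=ed50, omega_study=0.0, omega_visit=0.0,
                  mu_for=0.0, mu_sal=0.0, omega_sal_visit=0.0, mu_tio=0.0)
    params.update(extra)
    names = list(params)
    arr = np.tile(np.array([params[k] for k in names]), (2, n // 2, 1))
    samples = e.PosteriorSamples(arr, names, None, np.zeros(2),
                                 point_mask=[True] * len(names))
    return e.StudyLevelEmaxResults(None, samples)


@pytest.fixture
def table2_posterior():
    """Degenerate posterior at the study-level medians (Emax 176, ED50 26)."""
    return degenerate_posterior()
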