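import numpy as np
import pandas as pd
import pytest

from vitropop import plate_qc as qc
from vitropop.hill import FitConfig, fit_population
from vitropop.synthetic import (PlateLayoutSpec, PopulationSpec,
                                simulate_plates, simulate_population)


def make_screen(n_individuals=8, seed=11, error_scale=0.05, **pop_kwargs):
    """Simulate one substance's screen and return (truth, dose_response)."""
    spec = PopulationSpec(n_individuals=n_individuals, seed=seed,
                          error_scale=error_scale, **pop_kwargs)
    params = simulate_population(spec)
    plates = simulate_plates(params, PlateLayoutSpec(),
                             error_scale=spec.error_scale,
                             error_df=spec.error_df, seed=seed + 1)
    norm = qc.normalize_plates(plates)
    dose = qc.to_dose_response(qc.filter_qc(norm, qc.qc_plates(norm)))
    return params, dose


@pytest.fixture(scope="session")
def small_fit():
    """A converged hierarchical fit on a small synthetic screen, shared
    across tests that only need *a* valid posterior."""
    params, dose = make_screen(n_individuals=8, seed=11)
    post = fit_population(
        dose, FitConfig(initial_iterations=2000, max_iterations=8000, seed=7))
    return params, post


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
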