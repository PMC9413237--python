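"""Shared builders for small synthetic screens used across test modules."""

from vitropop import plate_qc as qc
from vitropop.synthetic import (PlateLayoutSpec, PopulationSpec,
                                simulate_plates, simulate_population)


def noisy_screen_normalized(n_individuals=6, seed=21, error_scale=0.05):
    spec = PopulationSpec(n_individuals=n_individuals, seed=seed,
                          error_scale=error_scale)
    params = simulate_population(spec)
    plates = simulate_plates(params, PlateLayoutSpec(),
                             error_scale=error_scale, seed=seed + 1)
    return qc.normalize_plates(plates)
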