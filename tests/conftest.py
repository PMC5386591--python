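"""Shared fixtures: one small synthetic experiment carried through the
pipeline stages, reused across test modules."""

from __future__ import annotations

import warnings

import pytest

from morphomap import hits, profiling, selection, simulate


@pytest.fixture(scope="session")
def small_config() -> simulate.SimulationConfig:
    """A dense 24-well plate design, 5 replicates, 20 features, planted
    groups with strong effects and a constant feature."""
    return simulate.SimulationConfig(
        n_treatments=18,
        n_negative_control_wells=6,
        plate_rows=4,
        plate_cols=6,
        n_features=20,
        cells_per_well_mean=100,
        seed=1,
        effect_magnitude=2.0,
        fraction_null=0.2,
        n_groups=4,
        within_group_noise=0.15,
        n_constant_features=1,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate.simulate_experiment(small_config)


@pytest.fixture(scope="session")
def polished_profiles(small_experiment):
    cells, _ = small_experiment
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normalized = profiling.normalize_cells(cells)
        raw = profiling.zscore_cell_count(profiling.aggregate_well(normalized))
        return profiling.median_polish(raw, max_iter=300)


@pytest.fixture(scope="session")
def normalized_cells(small_experiment):
    cells, _ = small_experiment
    return profiling.normalize_cells(cells)


@pytest.fixture(scope="session")
def reduced_centered(polished_profiles):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filtered = selection.filter_features(polished_profiles)
        sel = selection.select_features(filtered)
        reduced = selection.pca_reduce(sel.profiles)
        return hits.center_to_controls(reduced.profiles), sel


@pytest.fixture(scope="session")
def hit_result(reduced_centered):
    centered, _ = reduced_centered
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return hits.call_hits(centered, seed=99)
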