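import numpy as np
import pytest

import viperarisk as v


@pytest.fixture(scope="session")
def small_stack():
    return v.make_climate_stack(1, n_layers=6, n_rows=50, n_cols=50,
                                autocorr_range_cells=6, collinear_pairs=2)


@pytest.fixture(scope="session")
def sharp_species():
    """Strongly climate-determined virtual species (near-binary suitability)."""
    return v.VirtualSpeciesSpec({"bio1": (24.0, -48.0)}, prevalence_target=0.15)


@pytest.fixture(scope="session")
def small_suitability(small_stack, sharp_species):
    return v.true_suitability(small_stack, sharp_species)


@pytest.fixture(scope="session")
def small_table(small_stack, small_suitability):
    """Weighted presence/pseudo-absence table on the small synthetic stack."""
    occs = v.sample_occurrences(small_suitability, 150, seed=11)
    absences = v.sample_pseudo_absences(small_stack, 800, seed=12)
    return v.build_training_table(small_stack, occs.lonlat, absences)


def binary_map(values, **kw):
    """Convenience: boolean array -> BinaryRangeMap on a default geometry."""
    values = np.asarray(values, dtype=bool)
    geom = v.RasterGrid(np.zeros(values.shape))
    return v.BinaryRangeMap(values, geom, **kw)


@pytest.fixture
def make_binary():
    return binary_map
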