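"""Shared fixtures: a small synthetic world reused across test modules."""

import numpy as np
import pytest

import sdmpipe as sp
from sdmpipe.models import PresenceBackgroundTable
from sdmpipe.predictors import vif_filter

LAYERS = ["vpd", "light", "sand", "silt", "clay", "elevation"]


@pytest.fixture(scope="session")
def spec():
    return sp.GridSpec(origin_lon=100.0, origin_lat=10.0, cell_size=0.04,
                       n_rows=40, n_cols=40)


@pytest.fixture(scope="session")
def ocean_mask(spec):
    return sp.generate_ocean_mask(spec, ocean_fraction=0.15, seed=7)


@pytest.fixture(scope="session")
def stack(spec, ocean_mask):
    return sp.generate_environment(
        spec, LAYERS, corr_range_cells=5.0, seed=7, nodata_mask=ocean_mask
    )


@pytest.fixture(scope="session")
def virtual_species():
    return sp.VirtualSpeciesDefinition(
        "virtual A", {"vpd": sp.GaussianResponse(optimum=1.25, breadth=0.15, weight=1.0)}
    )


@pytest.fixture(scope="session")
def suitability(stack, virtual_species):
    return sp.true_suitability(stack, virtual_species)


@pytest.fixture(scope="session")
def presences(suitability):
    return sp.sample_presences(suitability, n=40, seed=21, species="virtual A")


@pytest.fixture(scope="session")
def table(spec, stack, presences, ocean_mask):
    """Screened presence-background modelling table (one background set)."""
    sets = sp.sample_pseudo_absences(
        spec, presences, ratio=10, n_sets=1, buffer_km=1.0, seed=33,
        nodata_mask=ocean_mask,
    )
    p = sp.extract_at_points(
        stack, presences.data["lon"].to_numpy(), presences.data["lat"].to_numpy()
    )
    b = sp.extract_at_points(stack, sets[0].lon, sets[0].lat)
    full = PresenceBackgroundTable.from_parts(p, b, set_id=1)
    screened, _ = vif_filter(full.features, threshold=5.0)
    return PresenceBackgroundTable(
        screened, full.labels, full.lon, full.lat, set_id=1
    )


@pytest.fixture(scope="session")
def fitted_families(table):
    """All four families fitted once on the shared table."""
    return {
        fam: sp.fit(fam, table, seed=5)
        for fam in ("linear_logistic", "smooth_additive_logistic",
                    "elastic_net_logistic", "randomized_tree_ensemble")
    }
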