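"""Virtual-world generators: fields, niches, presence draws, land cover."""

import numpy as np
import pytest
from scipy import stats

import sdmpipe as sp
from sdmpipe.grids import GridSpec, SuitabilityMap
from sdmpipe.synth import gaussian_response, generate_landcover


@pytest.fixture()
def flat_spec():
    return GridSpec(100.0, 2.0, 0.04, 30, 30)


class TestGenerateEnvironment:
    def test_zero_range_gives_white_noise(self, flat_spec):
        stack = sp.generate_environment(flat_spec, ["vpd"], corr_range_cells=0.0, seed=1)
        z = stack["vpd"]
        # lag-1 autocorrelation along rows ~ 0 for white noise
        a, b = z[:, :-1].ravel(), z[:, 1:].ravel()
        r = np.corrcoef(a, b)[0, 1]
        assert abs(r) < 0.1

    def test_smoothing_induces_positive_lag1_autocorrelation(self, flat_spec):
        stack = sp.generate_environment(flat_spec, ["vpd"], corr_range_cells=4.0, seed=1)
        z = stack["vpd"]
        r = np.corrcoef(z[:, :-1].ravel(), z[:, 1:].ravel())[0, 1]
        assert r > 0.8

    def test_collinear_duplicate_is_exact(self, flat_spec):
        stack = sp.generate_environment(
            flat_spec,
            ["vpd"],
            corr_range_cells=2.0,
            collinear_spec=[("vpd_copy", {"vpd": 1.0}, 0.0)],
            seed=3,
        )
        assert np.array_equal(stack["vpd"], stack["vpd_copy"])

    def test_collinear_combination_with_noise(self, flat_spec):
        stack = sp.generate_environment(
            flat_spec,
            ["vpd", "light"],
            corr_range_cells=2.0,
            collinear_spec=[("mix", {"vpd": 2.0, "light": -1.0}, 0.5)],
            seed=3,
        )
        resid = stack["mix"] - (2.0 * stack["vpd"] - stack["light"])
        assert abs(resid.mean()) < 0.1
        assert resid.std() == pytest.approx(0.5, abs=0.1)

    def test_collinear_unknown_source_raises_with_name(self, flat_spec):
        with pytest.raises(ValueError, match="ghost"):
            sp.generate_environment(
                flat_spec, ["vpd"], collinear_spec=[("bad", {"ghost": 1.0}, 0.0)],
                seed=0,
            )

    def test_soil_triplet_sums_to_100(self, flat_spec):
        stack = sp.generate_environment(
            flat_spec, ["sand", "silt", "clay"], corr_range_cells=3.0, seed=5
        )
        total = stack["sand"] + stack["silt"] + stack["clay"]
        assert np.max(np.abs(total - 100.0)) < 1e-6
        for n in ("sand", "silt", "clay"):
            assert stack[n].min() >= 0 and stack[n].max() <= 100

    def test_deterministic_given_seed(self, flat_spec):
        a = sp.generate_environment(flat_spec, ["vpd", "light"], 3.0, seed=9)
        b = sp.generate_environment(flat_spec, ["vpd", "light"], 3.0, seed=9)
        for n in a.layer_names:
            assert np.array_equal(a[n], b[n])


class TestVirtualSpecies:
    def test_gaussian_response_closed_form(self):
        # one breadth from the optimum: exp(-1/2) of the maximum
        assert gaussian_response(1.0, 0.0, 1.0) == pytest.approx(np.exp(-0.5))
        assert gaussian_response(0.0, 0.0, 1.0) == 1.0

    def test_irrelevant_predictor_invariance(self, flat_spec):
        stack = sp.generate_environment(flat_spec, ["vpd", "light"], 3.0, seed=2)
        vs = sp.VirtualSpeciesDefinition(
            "v", {"vpd": sp.GaussianResponse(0.9, 0.2, 1.0)}
        )
        s1 = sp.true_suitability(stack, vs)
        shuffled = dict(stack.layers)
        rng = np.random.default_rng(0)
        shuffled["light"] = rng.permutation(shuffled["light"].ravel()).reshape(
            stack.spec.shape
        )
        s2 = sp.true_suitability(
            sp.EnvironmentalStack(stack.spec, shuffled), vs
        )
        assert np.array_equal(s1.values, s2.values)

    def test_optimum_cell_attains_link_maximum(self):
        vs = sp.VirtualSpeciesDefinition(
            "v",
            {
                "a": sp.GaussianResponse(2.0, 0.5, 1.0),
                "b": sp.GaussianResponse(-1.0, 1.0, 2.0),
            },
        )
        at_opt = vs.suitability({"a": np.array([2.0]), "b": np.array([-1.0])})
        assert at_opt[0] == pytest.approx(1.0)  # rescaled logistic maximum
        elsewhere = vs.suitability({"a": np.array([5.0]), "b": np.array([3.0])})
        assert elsewhere[0] < at_opt[0]

    def test_missing_predictor_raises_with_name(self, flat_spec):
        stack = sp.generate_environment(flat_spec, ["vpd"], 2.0, seed=2)
        vs = sp.VirtualSpeciesDefinition("v", {"light": sp.GaussianResponse(15, 2)})
        with pytest.raises(KeyError, match="light"):
            sp.true_suitability(stack, vs)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            sp.VirtualSpeciesDefinition("v", {"a": sp.GaussianResponse(0, 1, 0.0)})


class TestSamplePresences:
    def test_uniform_support(self, flat_spec):
        suit = SuitabilityMap(flat_spec, np.full(flat_spec.shape, 0.5))
        occ = sp.sample_presences(suit, 100, seed=1)
        assert len(occ) == 100
        lon = occ.data["lon"].to_numpy()
        lat = occ.data["lat"].to_numpy()
        assert flat_spec.contains(lon, lat).all()
        cells = set(zip(*flat_spec.cell_of(lon, lat)))
        assert len(cells) == 100  # without replacement: all distinct

    def test_degenerate_support_selects_the_cell(self, flat_spec):
        values = np.zeros(flat_spec.shape)
        values[7, 11] = 1.0
        occ = sp.sample_presences(SuitabilityMap(flat_spec, values), 1, seed=4)
        row, col = flat_spec.cell_of(occ.data["lon"][0], occ.data["lat"][0])
        assert (row, col) == (7, 11)

    def test_oversampling_raises(self, flat_spec):
        values = np.zeros(flat_spec.shape)
        values[0, :3] = 1.0
        with pytest.raises(ValueError):
            sp.sample_presences(SuitabilityMap(flat_spec, values), 4, seed=0)

    def test_sampling_prefers_suitable_cells(self):
        # over many seeds the mean suitability at sampled cells exceeds the
        # grid mean (Monte-Carlo oracle)
        spec = GridSpec(0.0, 5.0, 0.1, 12, 12)
        rng = np.random.default_rng(99)
        values = rng.uniform(0.05, 1.0, size=spec.shape)
        suit = SuitabilityMap(spec, values)
        grid_mean = values.mean()
        means = []
        for seed in range(500):
            occ = sp.sample_presences(suit, 10, seed=seed)
            means.append(suit.at_points(occ.data["lon"], occ.data["lat"]).mean())
        assert np.mean(means) > grid_mean

    def test_selection_frequency_matches_suitability(self):
        # chi-square goodness of fit on a 10-cell toy grid, 10,000 draws
        spec = GridSpec(0.0, 1.0, 0.1, 1, 10)
        values = np.array([[0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5]])
        suit = SuitabilityMap(spec, values)
        counts = np.zeros(10)
        for seed in range(10_000):
            occ = sp.sample_presences(suit, 1, seed=seed)
            _, col = spec.cell_of(occ.data["lon"][0], occ.data["lat"][0])
            counts[col] += 1
        expected = 10_000 * values.ravel() / values.sum()
        _, p = stats.chisquare(counts, expected)
        assert p > 0.01


class TestGenerateLandcover:
    def test_extreme_fractions(self, flat_spec):
        lc0 = generate_landcover(flat_spec, 0.0, seed=1)
        cats0 = lc0.category_grid()
        assert (cats0 == "natural").all()
        lc1 = generate_landcover(flat_spec, 1.0, seed=1)
        assert (lc1.category_grid() == "anthropogenic").all()

    def test_half_fraction_realized_on_large_grid(self):
        spec = GridSpec(0.0, 10.0, 0.04, 200, 200)
        lc = generate_landcover(spec, 0.5, cluster_cells=5.0, seed=3)
        share = (lc.category_grid() == "anthropogenic").mean()
        assert 0.45 <= share <= 0.55

    def test_clustering(self, flat_spec):
        lc = generate_landcover(flat_spec, 0.5, cluster_cells=5.0, seed=3)
        anthro = (lc.category_grid() == "anthropogenic").astype(float)
        r = np.corrcoef(anthro[:, :-1].ravel(), anthro[:, 1:].ravel())[0, 1]
        assert r > 0.5  # spatially clustered, not salt-and-pepper

    def test_every_code_is_mapped(self, flat_spec):
        lc = generate_landcover(flat_spec, 0.3, other_fraction=0.1, seed=2)
        present = np.unique(lc.codes[lc.codes >= 0])
        assert set(present.tolist()) <= set(lc.mapping)
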