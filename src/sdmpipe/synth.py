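"""Virtual-species world generator.

Builds the inputs the analysis assumes — smooth spatially autocorrelated
predictor fields (with an optional compositional sand/silt/clay triplet and
engineered collinear layers), a virtual species whose suitability is a known
Gaussian-niche function of chosen predictors, presence samples drawn
proportionally to suitability, and a clustered categorical land-cover grid —
so every downstream stage can be verified against ground truth without any
external downloads.

Spatial autocorrelation is controlled by low-pass filtering white Gaussian
noise with an isotropic Gaussian kernel whose standard deviation is the
requested correlation range in cells. All generators are deterministic given
(seed, arguments).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import EnvironmentalStack, GridSpec, LandCoverGrid, SuitabilityMap
from .occurrences import OccurrenceSet

__all__ = [
    "GaussianResponse",
    "VirtualSpeciesDefinition",
    "gaussian_response",
    "generate_environment",
    "true_suitability",
    "sample_presences",
    "generate_landcover",
    "generate_ocean_mask",
    "DEFAULT_LANDCOVER_MAPPING",
]

# plausible unit scales per predictor name: (mean, sd, clip_lo, clip_hi)
UNIT_SCALES: dict[str, tuple[float, float, float | None, float | None]] = {
    "vpd": (0.9, 0.35, 0.05, None),          # kPa
    "light": (16.0, 3.0, 0.1, None),          # MJ m-2 day-1
    "evapotranspiration": (110.0, 35.0, 0.0, None),  # mm
    "bulk_density": (1.30, 0.15, 0.5, 2.2),   # g cm-3
    "nitrogen": (2.5, 1.0, 0.05, None),       # g kg-1
    "elevation": (350.0, 300.0, 0.0, None),   # m
}
SOIL_TRIPLET = ("sand", "silt", "clay")      # percentages closed to 100


def _smooth_field(rng: np.random.Generator, shape, corr_range_cells: float) -> np.ndarray:
    """Standardised Gaussian random field with the stated correlation range."""
    z = rng.standard_normal(shape)
    if corr_range_cells > 0:
        z = gaussian_filter(z, sigma=corr_range_cells, mode="reflect")
    sd = z.std()
    if sd > 0:
        z = (z - z.mean()) / sd
    return z


def _to_units(z: np.ndarray, name: str) -> np.ndarray:
    mean, sd, lo, hi = UNIT_SCALES.get(name, (0.0, 1.0, None, None))
    out = mean + sd * z
    if lo is not None or hi is not None:
        out = np.clip(out, lo, hi)
    return out


def generate_environment(
    spec: GridSpec,
    layer_names: list[str],
    corr_range_cells: float = 6.0,
    collinear_spec: list[tuple[str, dict[str, float], float]] | None = None,
    seed: int = 0,
    nodata_mask: np.ndarray | None = None,
) -> EnvironmentalStack:
    """Generate a stack of smooth predictor layers in plausible units.

    Parameters
    ----------
    layer_names : list of str
        Base layers to generate. If all of ``sand``, ``silt``, ``clay`` are
        requested the triplet is produced compositionally (per-cell sum
        exactly 100).
    corr_range_cells : float
        Gaussian smoothing sd in cells (0 = white noise).
    collinear_spec : list of (target, sources, noise_sd)
        Extra layers engineered as a linear combination of already-generated
        layers plus N(0, noise_sd) noise; ``sources`` maps layer name to its
        coefficient.
    nodata_mask : bool array, optional
        True cells become nodata (NaN) in every layer.
    """
    if not layer_names:
        raise ValueError("layer_names must be nonempty")
    if corr_range_cells < 0:
        raise ValueError("corr_range_cells must be >= 0")
    rng = np.random.default_rng(seed)
    layers: dict[str, np.ndarray] = {}

    triplet_requested = all(n in layer_names for n in SOIL_TRIPLET)
    if triplet_requested:
        # three positive fields closed per cell to a 100% composition
        raw = {
            n: np.exp(0.8 * _smooth_field(rng, spec.shape, corr_range_cells))
            for n in SOIL_TRIPLET
        }
        total = sum(raw.values())
        for n in SOIL_TRIPLET:
            layers[n] = 100.0 * raw[n] / total

    for name in layer_names:
        if name in layers:
            continue
        z = _smooth_field(rng, spec.shape, corr_range_cells)
        if name in SOIL_TRIPLET:  # lone percentage layer, no closure partner
            layers[name] = np.clip(40.0 + 12.0 * z, 0.0, 100.0)
        else:
            layers[name] = _to_units(z, name)

    for target, sources, noise_sd in collinear_spec or []:
        missing = [s for s in sources if s not in layers]
        if missing:
            raise ValueError(
                f"collinear layer {target!r} references ungenerated source(s) {missing}"
            )
        combo = sum(coef * layers[src] for src, coef in sources.items())
        if noise_sd > 0:
            combo = combo + rng.normal(0.0, noise_sd, size=spec.shape)
        layers[target] = combo

    if nodata_mask is not None:
        nodata_mask = np.asarray(nodata_mask, dtype=bool)
        for name in layers:
            layers[name] = np.where(nodata_mask, np.nan, layers[name])
    return EnvironmentalStack(spec, layers)


def generate_ocean_mask(
    spec: GridSpec, ocean_fraction: float = 0.2, cluster_cells: float = 8.0, seed: int = 0
) -> np.ndarray:
    """Clustered boolean mask (True = ocean/nodata) covering a target share."""
    if not 0.0 <= ocean_fraction <= 1.0:
        raise ValueError("ocean_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    z = _smooth_field(rng, spec.shape, cluster_cells)
    k = int(round(ocean_fraction * z.size))
    mask = np.zeros(spec.shape, dtype=bool)
    if k > 0:
        flat = z.ravel()
        idx = np.argsort(flat, kind="stable")[:k]
        mask.ravel()[idx] = True
    return mask


# -- virtual species ---------------------------------------------------------

@dataclass(frozen=True)
class GaussianResponse:
    """Bell-shaped response to one predictor: exp(-((x-opt)/breadth)^2 / 2)."""

    optimum: float
    breadth: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.breadth <= 0:
            raise ValueError("breadth must be > 0")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


def gaussian_response(x, optimum: float, breadth: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.exp(-0.5 * ((x - optimum) / breadth) ** 2)


@dataclass(frozen=True)
class VirtualSpeciesDefinition:
    """Known niche: per-predictor Gaussian responses combined by a link.

    The default ``logistic`` link maps the weight-normalised sum of
    responses r in [0, 1] through a logistic rescaled so r = 0 -> 0 and
    r = 1 -> 1 (its maximum); the ``identity`` link returns r itself.
    """

    name: str
    responses: dict[str, GaussianResponse]
    link: str = "logistic"
    steepness: float = 6.0
    midpoint: float = 0.5

    def __post_init__(self) -> None:
        if not self.responses:
            raise ValueError("a virtual species needs at least one response")
        if all(r.weight == 0 for r in self.responses.values()):
            raise ValueError("at least one response weight must be > 0")
        if self.link not in ("logistic", "identity"):
            raise ValueError(f"unknown link {self.link!r}")

    def suitability(self, features: dict[str, np.ndarray] | pd.DataFrame) -> np.ndarray:
        total_w = sum(r.weight for r in self.responses.values())
        raw = None
        for name, resp in self.responses.items():
            if name not in features:
                raise KeyError(f"predictor {name!r} required by {self.name!r} is missing")
            g = resp.weight / total_w * gaussian_response(
                np.asarray(features[name], dtype=float), resp.optimum, resp.breadth
            )
            raw = g if raw is None else raw + g
        if self.link == "identity":
            return raw

        def sigmoid(v):
            return 1.0 / (1.0 + np.exp(-self.steepness * (v - self.midpoint)))

        lo, hi = sigmoid(0.0), sigmoid(1.0)
        return (sigmoid(raw) - lo) / (hi - lo)


def true_suitability(stack: EnvironmentalStack, vs: VirtualSpeciesDefinition) -> SuitabilityMap:
    """Evaluate the virtual species' known suitability over a stack."""
    missing = [n for n in vs.responses if n not in stack]
    if missing:
        raise KeyError(f"stack lacks predictor(s) {missing} required by {vs.name!r}")
    values = vs.suitability({n: stack[n] for n in vs.responses})
    return SuitabilityMap(stack.spec, values)


def sample_presences(
    suit: SuitabilityMap,
    n: int,
    seed: int = 0,
    bias: np.ndarray | None = None,
    species: str = "virtual species",
    year: int = 2020,
    jitter: bool = False,
) -> OccurrenceSet:
    """Draw ``n`` distinct presence cells with probability ∝ suitability × bias.

    Records are placed at cell centers (uniform within-cell jitter behind the
    ``jitter`` flag, off by default so thinning stays deterministic).
    """
    values = suit.values
    weights = np.where(np.isnan(values), 0.0, values)
    if bias is not None:
        bias = np.asarray(bias, dtype=float)
        if bias.shape != values.shape:
            raise ValueError("bias grid does not conform to the suitability map")
        weights = weights * np.where(np.isnan(bias), 0.0, bias)
    flat = weights.ravel()
    eligible = int((flat > 0).sum())
    if n > eligible:
        raise ValueError(
            f"requested {n} presences but only {eligible} cells have positive weight"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(flat.size, size=n, replace=False, p=flat / flat.sum())
    row, col = np.unravel_index(idx, values.shape)
    lon, lat = suit.spec.cell_center(row, col)
    if jitter:
        half = suit.spec.cell_size / 2.0
        lon = lon + rng.uniform(-half, half, size=n)
        lat = lat + rng.uniform(-half, half, size=n)
    df = pd.DataFrame(
        {
            "species": species,
            "lon": lon,
            "lat": lat,
            "year": year,
            "basis": "human observation",
            "source": "synthetic",
        }
    )
    occ = OccurrenceSet(species, df)
    occ.log("sample_presences", n, n, seed=seed)
    return occ


# -- land cover --------------------------------------------------------------

DEFAULT_LANDCOVER_MAPPING: dict[int, str] = {
    10: "anthropogenic",  # cropland
    80: "anthropogenic",  # impervious surface
    50: "natural",        # tree cover
    60: "natural",        # shrubland
    90: "other",          # water / wetland
}


def generate_landcover(
    spec: GridSpec,
    anthropogenic_fraction: float,
    cluster_cells: float = 5.0,
    seed: int = 0,
    other_fraction: float = 0.0,
    nodata_mask: np.ndarray | None = None,
) -> LandCoverGrid:
    """Clustered categorical land-cover grid hitting a target anthropogenic share.

    Category regions come from rank-thresholding a smooth random field, so
    the realised share equals the target up to grid discreteness; cells
    within a category are split between that category's codes at random.
    """
    if not 0.0 <= anthropogenic_fraction <= 1.0:
        raise ValueError("anthropogenic_fraction must be in [0, 1]")
    if not 0.0 <= anthropogenic_fraction + other_fraction <= 1.0:
        raise ValueError("anthropogenic_fraction + other_fraction must be <= 1")
    rng = np.random.default_rng(seed)
    z = _smooth_field(rng, spec.shape, cluster_cells)
    land = np.ones(spec.shape, dtype=bool)
    if nodata_mask is not None:
        land = ~np.asarray(nodata_mask, dtype=bool)
    flat_idx = np.flatnonzero(land.ravel())
    order = flat_idx[np.argsort(z.ravel()[flat_idx], kind="stable")[::-1]]
    n_land = order.size
    n_anthro = int(round(anthropogenic_fraction * n_land))
    n_other = int(round(other_fraction * n_land))

    codes = np.full(spec.shape, -1, dtype=int)
    flat = codes.ravel()
    by_cat = {
        "anthropogenic": order[:n_anthro],
        "other": order[n_anthro : n_anthro + n_other],
        "natural": order[n_anthro + n_other :],
    }
    for cat, cells in by_cat.items():
        cat_codes = [c for c, k in DEFAULT_LANDCOVER_MAPPING.items() if k == cat]
        flat[cells] = rng.choice(cat_codes, size=cells.size)
    codes = flat.reshape(spec.shape)
    return LandCoverGrid(spec, codes, dict(DEFAULT_LANDCOVER_MAPPING))
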