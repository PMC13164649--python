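"""Habitat classification, latitude-corrected areas, anthropogenic pressure,
and environmental characterisation at species locations.

Suitability maps are reclassified into three classes — unsuitable (below
the 10th-percentile training-presence threshold), marginal ([p10, 0.40])
and core (> 0.40). Cell areas use the exact spherical band formula on a
sphere of radius 6371.0088 km, so per-class areas are latitude-corrected.
Anthropogenic pressure is the share of each habitat class covered by
anthropogenic land cover, computed by area. Environmental characterisation
compares predictor values extracted at species locations by one-way ANOVA
with Tukey HSD (or Kruskal-Wallis with Dunn tests), summarised as a compact
letter display.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grids import EARTH_RADIUS_KM, EnvironmentalStack, GridSpec, LandCoverGrid, SuitabilityMap
from .occurrences import OccurrenceSet
from .predictors import extract_at_points

__all__ = [
    "HabitatClassMap",
    "AreaSummary",
    "presence_threshold",
    "classify_habitat",
    "cell_area_km2",
    "class_area_summary",
    "pressure_summary",
    "env_characterization",
    "compact_letter_display",
]

CLASS_CODES = {"unsuitable": 0, "marginal": 1, "core": 2}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}
NODATA_CODE = -1


def presence_threshold(suitability_at_presences, pct: float = 10.0) -> float:
    """Empirical pct-th percentile of suitability at training presences.

    Linear interpolation between order statistics; pct = 0 gives the
    minimum.
    """
    values = np.asarray(suitability_at_presences, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("no presence suitability values supplied")
    return float(np.percentile(values, pct))


@dataclass
class HabitatClassMap:
    """Three-class habitat map (0 unsuitable, 1 marginal, 2 core, -1 nodata)."""

    spec: GridSpec
    classes: np.ndarray
    p10: float
    core_cut: float = 0.40

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=int)
        if self.classes.shape != self.spec.shape:
            raise ValueError("class grid does not conform to GridSpec")

    def mask(self, name: str) -> np.ndarray:
        return self.classes == CLASS_CODES[name]


def classify_habitat(
    suit: SuitabilityMap, p10: float, core_cut: float = 0.40
) -> HabitatClassMap:
    """Threshold a suitability map into unsuitable / marginal / core.

    Boundary conventions: marginal is the closed interval [p10, core_cut];
    core is strictly above core_cut. ``p10 > core_cut`` is degenerate and
    rejected.
    """
    if p10 > core_cut:
        raise ValueError(
            f"p10 threshold ({p10}) exceeds the core cut ({core_cut}); "
            "degenerate classification"
        )
    v = suit.values
    classes = np.full(v.shape, NODATA_CODE, dtype=int)
    ok = ~np.isnan(v)
    classes[ok & (v < p10)] = CLASS_CODES["unsuitable"]
    classes[ok & (v >= p10) & (v <= core_cut)] = CLASS_CODES["marginal"]
    classes[ok & (v > core_cut)] = CLASS_CODES["core"]
    return HabitatClassMap(suit.spec, classes, p10=p10, core_cut=core_cut)


def cell_area_km2(lat_center, cell_size: float) -> np.ndarray:
    """Exact spherical band area of a cell_size x cell_size cell, km².

    A = (pi/180) R² Δλ (sin(φ+h) − sin(φ−h)) with h = Δφ/2 and
    R = 6371.0088 km; reduces to the cosine scaling R²ΔλΔφcos(φ) for small
    cells.
    """
    lat = np.asarray(lat_center, dtype=float)
    h = cell_size / 2.0
    if np.any(np.abs(lat) + h > 90.0 + 1e-12):
        raise ValueError("cell extends beyond the pole")
    band = np.sin(np.radians(lat + h)) - np.sin(np.radians(lat - h))
    return (math.pi / 180.0) * EARTH_RADIUS_KM**2 * cell_size * band


def _area_grid(spec: GridSpec) -> np.ndarray:
    per_row = cell_area_km2(spec.lat_centers(), spec.cell_size)
    return np.repeat(per_row[:, None], spec.n_cols, axis=1)


@dataclass
class AreaSummary:
    """Per-habitat-class area in km² and as a fraction of classified land."""

    areas_km2: dict[str, float]

    @property
    def total_km2(self) -> float:
        return float(sum(self.areas_km2.values()))

    @property
    def fractions(self) -> dict[str, float]:
        total = self.total_km2
        return {k: (v / total if total > 0 else 0.0) for k, v in self.areas_km2.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": list(self.areas_km2),
                "area_km2": list(self.areas_km2.values()),
                "fraction": list(self.fractions.values()),
            }
        )


def class_area_summary(classes: HabitatClassMap) -> AreaSummary:
    """Latitude-corrected area of each habitat class."""
    area = _area_grid(classes.spec)
    return AreaSummary(
        {
            name: float(area[classes.classes == code].sum())
            for name, code in CLASS_CODES.items()
        }
    )


def pressure_summary(classes: HabitatClassMap, lc: LandCoverGrid) -> pd.DataFrame:
    """Per-habitat-class land-cover category shares, by area (percent).

    Land-cover codes are aggregated to anthropogenic/natural/other via the
    grid's mapping. The land-cover grid may be on the same grid or finer:
    each land-cover cell contributes its own latitude-corrected area to the
    habitat-class cell containing its center. Rows sum to 100.
    """
    cat_grid = lc.category_grid()
    lc_area = _area_grid(lc.spec)
    lc_rows, lc_cols = np.nonzero(lc.codes >= 0)
    lon, lat = lc.spec.cell_center(lc_rows, lc_cols)
    inside = classes.spec.contains(lon, lat)
    lc_rows, lc_cols = lc_rows[inside], lc_cols[inside]
    lon, lat = lon[inside], lat[inside]
    crow, ccol = classes.spec.cell_of(lon, lat)
    cls = classes.classes[crow, ccol]

    categories = LandCoverGrid.VALID_CATEGORIES
    out = pd.DataFrame(
        0.0, index=list(CLASS_CODES), columns=[f"{c}_pct" for c in categories]
    )
    areas = lc_area[lc_rows, lc_cols]
    cats = cat_grid[lc_rows, lc_cols]
    for name, code in CLASS_CODES.items():
        in_class = cls == code
        total = areas[in_class].sum()
        if total <= 0:
            out.loc[name] = np.nan
            continue
        for cat in categories:
            share = areas[in_class & (cats == cat)].sum() / total
            out.loc[name, f"{cat}_pct"] = 100.0 * share
    return out


# -- environmental characterisation ------------------------------------------

def compact_letter_display(
    groups: list[str], significant: set[tuple[str, str]]
) -> dict[str, str]:
    """Assign letters so that groups sharing a letter are pairwise
    non-significant (insert-and-absorb algorithm)."""
    letters: list[set[str]] = [set(groups)]
    for a, b in significant:
        for s in [s for s in letters if a in s and b in s]:
            letters.remove(s)
            letters.extend([s - {a}, s - {b}])
        # absorb sets contained in another
        letters = [
            s
            for s in letters
            if s and not any(s < t for t in letters if t is not s)
        ]
        # drop duplicates
        uniq: list[set[str]] = []
        for s in letters:
            if s not in uniq:
                uniq.append(s)
        letters = uniq
    order = {g: i for i, g in enumerate(groups)}
    letters.sort(key=lambda s: min(order[g] for g in s))
    labels = {g: "" for g in groups}
    for i, s in enumerate(letters):
        ch = chr(ord("a") + i)
        for g in s:
            labels[g] += ch
    return {g: "".join(sorted(v)) for g, v in labels.items()}


def _pairwise_significant(
    values: np.ndarray, groups: np.ndarray, alpha: float, test: str
) -> tuple[set[tuple[str, str]], float]:
    names = sorted(set(groups))
    samples = [values[groups == g] for g in names]
    if test == "anova":
        _, p_global = stats.f_oneway(*samples)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        res = pairwise_tukeyhsd(values, groups, alpha=alpha)
        sig = set()
        for (g1, g2), reject in zip(
            itertools.combinations(res.groupsunique, 2), res.reject
        ):
            if reject:
                sig.add((str(g1), str(g2)))
    elif test == "kruskal":
        _, p_global = stats.kruskal(*samples)
        # Dunn's test: pairwise z on mean ranks, Holm-adjusted
        ranks = stats.rankdata(values)
        n = values.size
        ties, counts = np.unique(values, return_counts=True)
        tie_corr = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
        pairs = list(itertools.combinations(names, 2))
        pvals = []
        for g1, g2 in pairs:
            r1, r2 = ranks[groups == g1], ranks[groups == g2]
            se = math.sqrt(
                (n * (n + 1) / 12.0) * tie_corr * (1 / r1.size + 1 / r2.size)
            )
            z = (r1.mean() - r2.mean()) / se
            pvals.append(2 * stats.norm.sf(abs(z)))
        # Holm step-down
        order = np.argsort(pvals)
        m = len(pvals)
        sig = set()
        running_max = 0.0
        for rank_i, idx in enumerate(order):
            p_adj = min(1.0, (m - rank_i) * pvals[idx])
            running_max = max(running_max, p_adj)
            if running_max < alpha:
                sig.add(pairs[idx])
    else:
        raise ValueError(f"unknown test {test!r}")
    return sig, float(p_global)


def env_characterization(
    stack: EnvironmentalStack,
    occ_by_species: dict[str, OccurrenceSet],
    alpha: float = 0.05,
    test: str = "anova",
) -> dict[str, pd.DataFrame]:
    """Compare predictor values at species locations across species.

    Extracts every stack layer at each species' occurrences, runs a global
    test per variable (one-way ANOVA + Tukey HSD by default,
    Kruskal-Wallis + Dunn with ``test='kruskal'``), and returns per
    variable a per-species summary: n, median, quartiles, 1.5 x IQR outlier
    count and the compact-letter-display group letter. Species with fewer
    than two usable records are excluded with a warning.
    """
    frames = []
    for species, occ in occ_by_species.items():
        ft = extract_at_points(
            stack, occ.data["lon"].to_numpy(float), occ.data["lat"].to_numpy(float)
        )
        if len(ft) < 2:
            warnings.warn(
                f"species {species!r} has <2 usable records; excluded", stacklevel=2
            )
            continue
        df = ft.features.copy()
        df["species"] = species
        frames.append(df)
    if len(frames) < 2:
        raise ValueError("need at least two species with >= 2 records each")
    data = pd.concat(frames, ignore_index=True)
    species_order = sorted(data["species"].unique())

    out: dict[str, pd.DataFrame] = {}
    for var in stack.layer_names:
        values = data[var].to_numpy(float)
        groups = data["species"].to_numpy()
        sig, p_global = _pairwise_significant(values, groups, alpha, test)
        letters = compact_letter_display(species_order, sig)
        rows = []
        for sp in species_order:
            v = values[groups == sp]
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            iqr = q3 - q1
            outliers = int(((v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)).sum())
            rows.append(
                {
                    "species": sp,
                    "n": v.size,
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "n_outliers": outliers,
                    "letter": letters[sp],
                    "p_global": p_global,
                }
            )
        out[var] = pd.DataFrame(rows)
    return out
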