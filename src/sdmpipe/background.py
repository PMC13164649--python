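"""Spatially constrained pseudo-absence (background) sampling.

Background points characterise the available environment in a
presence-background design. Sets are drawn uniformly at random, without
replacement, from cells that (i) are land (non-nodata), (ii) contain no
presence record, and (iii) have centers farther than a buffer distance
(great-circle, km) from every presence. No environmental stratification or
bias correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import GridSpec, haversine_km
from .occurrences import OccurrenceSet

__all__ = ["PseudoAbsenceSet", "eligible_cells", "sample_pseudo_absences"]


@dataclass
class PseudoAbsenceSet:
    """One background draw: cell-center points plus bookkeeping."""

    set_id: int
    lon: np.ndarray
    lat: np.ndarray
    seed: int

    def __len__(self) -> int:
        return self.lon.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"set_id": self.set_id, "lon": self.lon, "lat": self.lat})


def eligible_cells(
    spec: GridSpec,
    presences: OccurrenceSet,
    buffer_km: float = 1.0,
    nodata_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of cells eligible to receive a pseudo-absence."""
    ok = np.ones(spec.shape, dtype=bool)
    if nodata_mask is not None:
        ok &= ~np.asarray(nodata_mask, dtype=bool)
    p_lon = presences.data["lon"].to_numpy(float)
    p_lat = presences.data["lat"].to_numpy(float)
    in_grid = spec.contains(p_lon, p_lat)
    prow, pcol = spec.cell_of(p_lon[in_grid], p_lat[in_grid])
    ok[prow, pcol] = False

    rows, cols = np.nonzero(ok)
    lon, lat = spec.cell_center(rows, cols)
    if buffer_km > 0 and p_lon.size:
        # min distance from each candidate center to any presence
        d = haversine_km(
            lon[:, None], lat[:, None], p_lon[None, :], p_lat[None, :]
        ).min(axis=1)
        keep = d > buffer_km
        rows, cols = rows[keep], cols[keep]
    return rows, cols


def sample_pseudo_absences(
    spec: GridSpec,
    presences: OccurrenceSet,
    ratio: int = 10,
    n_sets: int = 10,
    buffer_km: float = 1.0,
    seed: int = 0,
    nodata_mask: np.ndarray | None = None,
) -> list[PseudoAbsenceSet]:
    """Draw ``n_sets`` background sets of ``ratio`` x n_presences points each.

    Each set is an independent uniform draw without replacement from the
    eligible cells; identical duplicate sets are redrawn so the sets differ.
    Raises when the eligible pool cannot supply one set.
    """
    n_points = ratio * len(presences)
    rows, cols = eligible_cells(spec, presences, buffer_km, nodata_mask)
    if rows.size < n_points:
        raise ValueError(
            f"need {n_points} eligible cells per set but only {rows.size} remain "
            f"after the nodata/presence/{buffer_km} km-buffer constraints"
        )
    lon, lat = spec.cell_center(rows, cols)
    rng = np.random.default_rng(seed)
    sets: list[PseudoAbsenceSet] = []
    seen: set[tuple] = set()
    for set_id in range(1, n_sets + 1):
        for _ in range(100):
            idx = rng.choice(rows.size, size=n_points, replace=False)
            key = tuple(np.sort(idx))
            if key not in seen or rows.size == n_points:
                break
        seen.add(key)
        sets.append(
            PseudoAbsenceSet(set_id=set_id, lon=lon[idx], lat=lat[idx], seed=seed)
        )
    return sets
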