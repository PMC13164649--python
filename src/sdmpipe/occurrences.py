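"""Occurrence-record cleaning, spatial validation, thinning and merging.

Records follow a DarwinCore-flavoured schema (species, decimalLongitude,
decimalLatitude, eventDate year, basisOfRecord, source). The cleaning
protocol drops fossils, pre-cutoff records, coordinate-less rows and exact
duplicates; spatial validation keeps points inside the study extent (land
cells only when a mask is supplied); thinning retains a single record per
grid cell of the modelling grid so pixel-level clustering cannot inflate
evaluation metrics.

Every stage appends to a provenance log (stage, n_in, n_out, detail) so the
record counts of a run can be audited after the fact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import GridSpec

__all__ = [
    "OccurrenceSet",
    "clean_records",
    "filter_extent",
    "thin_to_grid",
    "merge_sources",
    "read_occurrence_csv",
    "write_occurrence_csv",
]

COLUMNS = ["species", "lon", "lat", "year", "basis", "source"]

CSV_COLUMNS = {
    "species": "species",
    "lon": "decimalLongitude",
    "lat": "decimalLatitude",
    "year": "eventDate",
    "basis": "basisOfRecord",
    "source": "source",
}


@dataclass
class OccurrenceSet:
    """Ordered occurrence records for one species plus a provenance log."""

    species: str
    data: pd.DataFrame
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in COLUMNS:
            if col not in df.columns:
                df[col] = np.nan if col in ("lon", "lat", "year") else ""
        df = df[COLUMNS].reset_index(drop=True)
        df["species"] = df["species"].replace("", self.species).fillna(self.species)
        bad = df["species"] != self.species
        if bad.any():
            raise ValueError(
                f"records for species {sorted(df.loc[bad, 'species'].unique())} "
                f"in a set declared for {self.species!r}"
            )
        lon = pd.to_numeric(df["lon"], errors="coerce")
        lat = pd.to_numeric(df["lat"], errors="coerce")
        has_coords = lon.notna() & lat.notna()
        out_of_range = has_coords & (
            (lon < -180) | (lon > 180) | (lat < -90) | (lat > 90)
        )
        if out_of_range.any():
            rows = list(df.index[out_of_range])
            raise ValueError(f"coordinates out of range at rows {rows}")
        df["lon"], df["lat"] = lon, lat
        df["year"] = pd.to_numeric(df["year"], errors="coerce")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    def log(self, stage: str, n_in: int, n_out: int, **detail) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {stage!r} increased the record count")
        self.provenance.append(
            {"stage": stage, "n_in": int(n_in), "n_out": int(n_out), **detail}
        )

    def _derive(self, df: pd.DataFrame, stage: str, **detail) -> "OccurrenceSet":
        out = OccurrenceSet(self.species, df.reset_index(drop=True), list(self.provenance))
        out.log(stage, len(self.data), len(df), **detail)
        return out

    def write_provenance(self, path) -> None:
        Path(path).write_text(json.dumps(self.provenance, indent=2) + "\n")


def clean_records(raw: OccurrenceSet, min_year: int = 1800) -> OccurrenceSet:
    """Drop coordinate-less, fossil, pre-``min_year`` and duplicate records.

    Records with an unknown collection year are retained (the year filter
    only removes records positively dated before the cutoff). Exact
    duplicates share (lon, lat, year, basis); the first is kept.
    """
    df = raw.data
    keep = df["lon"].notna() & df["lat"].notna()
    n_coordless = int((~keep).sum())
    basis = df["basis"].astype(str).str.lower()
    is_fossil = basis.str.contains("fossil")
    keep &= ~is_fossil
    old = df["year"].notna() & (df["year"] < min_year)
    keep &= ~old
    df = df[keep]
    before_dedup = len(df)
    df = df.drop_duplicates(subset=["lon", "lat", "year", "basis"], keep="first")
    return raw._derive(
        df,
        "clean",
        min_year=min_year,
        n_missing_coords=n_coordless,
        n_fossil=int(is_fossil.sum()),
        n_pre_cutoff=int(old.sum()),
        n_duplicates=before_dedup - len(df),
    )


def filter_extent(occ: OccurrenceSet, extent, mask: np.ndarray | None = None) -> OccurrenceSet:
    """Keep records whose point lies inside the study extent.

    ``extent`` is a :class:`GridSpec` (optionally with a boolean nodata
    ``mask``, True = excluded cell) or a shapely polygon. Boundary points
    are retained (closed extent).
    """
    df = occ.data
    lon = df["lon"].to_numpy(float)
    lat = df["lat"].to_numpy(float)
    if isinstance(extent, GridSpec):
        inside = extent.contains(lon, lat)
        if mask is not None:
            row, col = extent.cell_of(lon, lat)
            ok = np.zeros(len(df), dtype=bool)
            ok[inside] = ~mask[row[inside], col[inside]]
            inside = ok
    else:
        import shapely

        pts = shapely.points(lon, lat)
        inside = shapely.covers(extent, pts)
    return occ._derive(df[inside], "filter_extent", n_outside=int((~inside).sum()))


def thin_to_grid(occ: OccurrenceSet, spec: GridSpec) -> OccurrenceSet:
    """Retain at most one record per grid cell.

    Within a cell the earliest-year record wins; unknown years sort last;
    remaining ties resolve to the first record in stable input order.
    """
    df = occ.data
    if df["lon"].isna().any() or df["lat"].isna().any():
        raise ValueError("thinning requires coordinates on every record")
    row, col = spec.cell_of(df["lon"].to_numpy(float), df["lat"].to_numpy(float))
    work = df.assign(
        _cell=np.asarray(row) * spec.n_cols + np.asarray(col),
        _year_key=df["year"].fillna(np.inf),
        _order=np.arange(len(df)),
    )
    work = work.sort_values(["_cell", "_year_key", "_order"], kind="stable")
    work = work.drop_duplicates(subset="_cell", keep="first")
    work = work.sort_values("_order")
    return occ._derive(
        work[COLUMNS], "thin_to_grid", cell_size=spec.cell_size,
        n_removed=len(df) - len(work),
    )


def merge_sources(sets: list[OccurrenceSet], spec: GridSpec) -> OccurrenceSet:
    """Union several occurrence sets for one species, then thin to the grid."""
    if not sets:
        raise ValueError("merge_sources needs at least one set")
    species = {s.species for s in sets}
    if len(species) > 1:
        raise ValueError(f"cannot merge sets for different species: {sorted(species)}")
    frames = [s.data for s in sets]
    merged = pd.concat(frames, ignore_index=True)
    per_source = {
        f"n_set_{i}": len(s) for i, s in enumerate(sets)
    }
    union = OccurrenceSet(sets[0].species, merged)
    union.provenance = [p for s in sets for p in s.provenance]
    union.log("merge_sources", len(merged), len(merged), **per_source)
    return thin_to_grid(union, spec)


def write_occurrence_csv(occ: OccurrenceSet, path) -> None:
    out = occ.data.rename(columns=CSV_COLUMNS)
    out.to_csv(path, index=False)


def read_occurrence_csv(path, species: str | None = None) -> OccurrenceSet:
    """Read a DarwinCore-style occurrence CSV; validates coordinate ranges."""
    df = pd.read_csv(path)
    inverse = {v: k for k, v in CSV_COLUMNS.items()}
    df = df.rename(columns=inverse)
    if species is not None:
        df = df[df["species"] == species]
    else:
        uniq = df["species"].dropna().unique()
        if len(uniq) != 1:
            raise ValueError(
                f"CSV holds species {sorted(uniq)}; pass `species` to select one"
            )
        species = uniq[0]
    try:
        return OccurrenceSet(species, df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
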