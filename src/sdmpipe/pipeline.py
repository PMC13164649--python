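"""End-to-end per-species workflow orchestration.

Stages: simulate/load inputs → clean/thin occurrences → pseudo-absence
sampling → feature extraction and VIF screening → replicated fit/evaluate
per family and background set (+ spatial block CV and null-model test) →
TSS-weighted ensemble and permutation importance → habitat classification,
latitude-corrected areas and land-cover pressure → (multi-species)
environmental characterisation and genus composite.

Every stochastic stage derives its seed deterministically from the master
seed, so a run is bit-identical given the same configuration and seed; the
run manifest records the configuration snapshot, per-stage seeds, row/cell
counts and output checksums (no timestamps, so manifests of identical runs
compare equal byte-for-byte).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .background import sample_pseudo_absences
from .ensemble import (
    ensemble_predict,
    fit_ensemble,
    composite_mean,
    percentile_bins,
    permutation_importance,
    tss_weights,
)
from .evaluation import (
    assign_spatial_blocks,
    auc,
    null_model_test,
    replicate_evaluate,
    spatial_cv,
)
from .grids import (
    EnvironmentalStack,
    GridSpec,
    LandCoverGrid,
    SuitabilityMap,
    read_ascii_grid,
    write_ascii_grid,
)
from .habitat import (
    class_area_summary,
    classify_habitat,
    env_characterization,
    presence_threshold,
    pressure_summary,
)
from .models import FAMILIES, PresenceBackgroundTable, canonical_family, fit, predict_prob, save_model
from .occurrences import (
    OccurrenceSet,
    clean_records,
    filter_extent,
    read_occurrence_csv,
    thin_to_grid,
    write_occurrence_csv,
)
from .predictors import extract_at_points, vif_filter
from .synth import (
    GaussianResponse,
    VirtualSpeciesDefinition,
    generate_environment,
    generate_landcover,
    generate_ocean_mask,
    sample_presences,
    true_suitability,
)

__all__ = ["PipelineConfig", "SyntheticConfig", "SpeciesConfig", "run_pipeline", "load_config"]

log = logging.getLogger("sdmpipe")


# -- configuration ------------------------------------------------------------

def _from_dict(cls, data: dict, context: str):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {context}")
    return cls(**data)


@dataclass
class SpeciesConfig:
    """One virtual species: its known niche and presence sample size."""

    name: str
    n_presences: int = 50
    # layer -> {optimum, breadth, weight}
    responses: dict = field(default_factory=dict)

    def definition(self) -> VirtualSpeciesDefinition:
        return VirtualSpeciesDefinition(
            name=self.name,
            responses={
                layer: GaussianResponse(**params)
                for layer, params in self.responses.items()
            },
        )


@dataclass
class SyntheticConfig:
    """Synthetic world: grid, predictor fields, land mask, species, land cover."""

    n_rows: int = 60
    n_cols: int = 60
    origin_lon: float = 98.0
    origin_lat: float = 8.0
    cell_size: float = 0.04
    layers: list = field(
        default_factory=lambda: [
            "vpd",
            "light",
            "evapotranspiration",
            "bulk_density",
            "sand",
            "silt",
            "clay",
            "nitrogen",
            "elevation",
        ]
    )
    corr_range_cells: float = 6.0
    ocean_fraction: float = 0.15
    landcover_anthropogenic: float = 0.30
    landcover_other: float = 0.05
    landcover_cluster: float = 5.0
    species: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.species = [
            s if isinstance(s, SpeciesConfig) else _from_dict(SpeciesConfig, s, "species")
            for s in self.species
        ]

    def grid_spec(self) -> GridSpec:
        return GridSpec(
            origin_lon=self.origin_lon,
            origin_lat=self.origin_lat,
            cell_size=self.cell_size,
            n_rows=self.n_rows,
            n_cols=self.n_cols,
        )


@dataclass
class InputPaths:
    """External inputs: occurrence CSV plus raster directory and land cover."""

    occurrences_csv: str = ""
    raster_dir: str = ""
    landcover_asc: str = ""
    landcover_mapping_csv: str = ""


@dataclass
class PipelineConfig:
    """Every tunable of the workflow plus the master seed."""

    seed: int = 0
    synthetic: SyntheticConfig | None = None
    inputs: InputPaths | None = None
    vif_threshold: float = 5.0
    pa_ratio: int = 10
    pa_sets: int = 10
    buffer_km: float = 1.0
    test_fraction: float = 0.30
    n_reps: int = 10
    schemes: list = field(default_factory=lambda: ["subsample", "bootstrap"])
    block_km: float = 200.0
    k: int = 5
    n_null: int = 99
    null_families: list = field(default_factory=lambda: ["linear_logistic"])
    p10_pct: float = 10.0
    core_cut: float = 0.40
    families: list = field(default_factory=lambda: list(FAMILIES))
    spatial_cv_family: str = "randomized_tree_ensemble"
    min_year: int = 1800
    n_bins: int = 6

    def __post_init__(self) -> None:
        if isinstance(self.synthetic, dict):
            self.synthetic = _from_dict(SyntheticConfig, self.synthetic, "synthetic")
        if isinstance(self.inputs, dict):
            self.inputs = _from_dict(InputPaths, self.inputs, "inputs")
        if self.synthetic is None and self.inputs is None:
            raise ValueError("config needs either a `synthetic` or an `inputs` block")
        checks = [
            (self.vif_threshold > 1, "vif_threshold must be > 1"),
            (self.pa_ratio >= 1, "pa_ratio must be >= 1"),
            (self.pa_sets >= 1, "pa_sets must be >= 1"),
            (self.buffer_km >= 0, "buffer_km must be >= 0"),
            (0 < self.test_fraction < 1, "test_fraction must be in (0, 1)"),
            (self.n_reps >= 1, "n_reps must be >= 1"),
            (self.block_km > 0, "block_km must be > 0"),
            (self.k >= 2, "k must be >= 2"),
            (self.n_null >= 19, "n_null must be >= 19"),
            (0 <= self.p10_pct <= 100, "p10_pct must be in [0, 100]"),
            (0 < self.core_cut < 1, "core_cut must be in (0, 1)"),
            (len(self.families) >= 1, "at least one model family required"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)
        self.families = [canonical_family(f) for f in self.families]
        self.null_families = [canonical_family(f) for f in self.null_families]
        self.spatial_cv_family = canonical_family(self.spatial_cv_family)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_dict(PipelineConfig, data, str(path))


# -- helpers ------------------------------------------------------------------

def _slug(name: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in name).strip("_").lower()


def _stage_seed(master: int, stage: str, index: int = 0) -> int:
    digest = hashlib.sha256(f"{master}:{stage}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# -- runner -------------------------------------------------------------------

class PipelineRunner:
    """Executes the workflow stage by stage into an output directory."""

    def __init__(self, config: PipelineConfig, outdir):
        self.cfg = config
        self.out = Path(outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "software": {"package": "sdmpipe", "version": __version__},
            "config": config.to_dict(),
            "seeds": {},
            "counts": {},
            "results": {},
            "outputs": {},
        }
        self.stack: EnvironmentalStack | None = None
        self.landcover: LandCoverGrid | None = None
        self.raw_occurrences: dict[str, OccurrenceSet] = {}
        self.occurrences: dict[str, OccurrenceSet] = {}
        self.retained: list[str] | None = None
        self.tables: dict[str, list[PresenceBackgroundTable]] = {}
        self.records: dict[str, pd.DataFrame] = {}
        self.models: dict[str, dict] = {}
        self.weights: dict[str, object] = {}
        self.ensemble_maps: dict[str, SuitabilityMap] = {}
        self.class_maps: dict[str, object] = {}

    # ---- stage: simulate / load ------------------------------------------
    def stage_simulate(self) -> None:
        cfg = self.cfg
        if cfg.synthetic is None:
            return self._stage_load_inputs()
        syn = cfg.synthetic
        spec = syn.grid_spec()
        seed_env = _stage_seed(cfg.seed, "environment")
        seed_mask = _stage_seed(cfg.seed, "ocean_mask")
        seed_lc = _stage_seed(cfg.seed, "landcover")
        self.manifest["seeds"]["environment"] = seed_env
        mask = generate_ocean_mask(spec, syn.ocean_fraction, seed=seed_mask)
        self.stack = generate_environment(
            spec,
            syn.layers,
            corr_range_cells=syn.corr_range_cells,
            seed=seed_env,
            nodata_mask=mask,
        )
        self.landcover = generate_landcover(
            spec,
            syn.landcover_anthropogenic,
            cluster_cells=syn.landcover_cluster,
            seed=seed_lc,
            other_fraction=syn.landcover_other,
            nodata_mask=mask,
        )
        env_dir = self.out / "env"
        self.stack.write_dir(env_dir)
        write_ascii_grid(self.out / "landcover.asc", self.landcover.codes.astype(float), spec)
        pd.DataFrame(
            {"code": list(self.landcover.mapping), "category": list(self.landcover.mapping.values())}
        ).to_csv(self.out / "landcover_mapping.csv", index=False)

        if not syn.species:
            raise PipelineError("simulate", "synthetic config lists no species")
        for i, sp in enumerate(syn.species):
            vs = sp.definition()
            suit = true_suitability(self.stack, vs)
            seed_sp = _stage_seed(cfg.seed, "presences", i)
            self.manifest["seeds"][f"presences:{sp.name}"] = seed_sp
            occ = sample_presences(suit, sp.n_presences, seed=seed_sp, species=sp.name)
            self.raw_occurrences[sp.name] = occ
            suit.write(self.out / f"true_suitability_{_slug(sp.name)}.asc")
        all_occ = pd.concat(
            [o.data for o in self.raw_occurrences.values()], ignore_index=True
        )
        from .occurrences import CSV_COLUMNS

        all_occ.rename(columns=CSV_COLUMNS).to_csv(
            self.out / "occurrences_raw.csv", index=False
        )
        self.manifest["counts"]["n_raw_occurrences"] = int(len(all_occ))
        log.info("simulate: %d species, %d occurrences, grid %dx%d",
                 len(self.raw_occurrences), len(all_occ), spec.n_rows, spec.n_cols)

    def _stage_load_inputs(self) -> None:
        paths = self.cfg.inputs
        self.stack = EnvironmentalStack.read_dir(paths.raster_dir)
        codes, lc_spec = read_ascii_grid(paths.landcover_asc)
        mapping_df = pd.read_csv(paths.landcover_mapping_csv)
        mapping = dict(zip(mapping_df["code"].astype(int), mapping_df["category"]))
        codes = np.where(np.isnan(codes), -1, codes).astype(int)
        self.landcover = LandCoverGrid(lc_spec, codes, mapping)
        df = pd.read_csv(paths.occurrences_csv)
        for species in sorted(df["species"].dropna().unique()):
            self.raw_occurrences[species] = read_occurrence_csv(
                paths.occurrences_csv, species=species
            )
        self.manifest["counts"]["n_raw_occurrences"] = int(
            sum(len(o) for o in self.raw_occurrences.values())
        )

    # ---- stage: clean ----------------------------------------------------
    def stage_clean(self) -> None:
        if self.stack is None:
            raise PipelineError("clean", "no inputs loaded; run simulate first")
        spec = self.stack.spec
        mask = self.stack.nodata_mask
        for species, occ in self.raw_occurrences.items():
            cleaned = clean_records(occ, min_year=self.cfg.min_year)
            inside = filter_extent(cleaned, spec, mask=mask)
            thinned = thin_to_grid(inside, spec)
            if len(thinned) < 2:
                raise PipelineError(
                    "clean", f"species {species!r} has {len(thinned)} records after cleaning"
                )
            self.occurrences[species] = thinned
            slug = _slug(species)
            write_occurrence_csv(thinned, self.out / f"occurrences_{slug}.csv")
            thinned.write_provenance(self.out / f"provenance_{slug}.json")
            self.manifest["counts"][f"n_occurrences:{species}"] = len(thinned)
            log.info("clean: %s %d -> %d records", species, len(occ), len(thinned))

    # ---- stage: fit (background, VIF, tables, full models) ---------------
    def stage_fit(self) -> None:
        cfg = self.cfg
        if not self.occurrences:
            raise PipelineError("fit", "no cleaned occurrences; run clean first")
        spec = self.stack.spec
        mask = self.stack.nodata_mask

        # pseudo-absences per species
        backgrounds: dict[str, list] = {}
        for i, (species, occ) in enumerate(self.occurrences.items()):
            seed = _stage_seed(cfg.seed, "background", i)
            self.manifest["seeds"][f"background:{species}"] = seed
            sets = sample_pseudo_absences(
                spec,
                occ,
                ratio=cfg.pa_ratio,
                n_sets=cfg.pa_sets,
                buffer_km=cfg.buffer_km,
                seed=seed,
                nodata_mask=mask,
            )
            backgrounds[species] = sets
            pd.concat([s.to_frame() for s in sets], ignore_index=True).to_csv(
                self.out / f"background_{_slug(species)}.csv", index=False
            )
            self.manifest["counts"][f"n_pseudo_absences_per_set:{species}"] = len(sets[0])

        # VIF screening on the pooled presence + first-set background rows
        frames = []
        for species, occ in self.occurrences.items():
            p = extract_at_points(
                self.stack, occ.data["lon"].to_numpy(float), occ.data["lat"].to_numpy(float)
            )
            b = extract_at_points(
                self.stack, backgrounds[species][0].lon, backgrounds[species][0].lat
            )
            frames.extend([p.features, b.features])
        pooled = pd.concat(frames, ignore_index=True)
        retained_tbl, report = vif_filter(pooled, threshold=cfg.vif_threshold)
        self.retained = list(retained_tbl.columns)
        report.to_frame().to_csv(self.out / "vif_report.csv", index=False)
        self.manifest["results"]["retained_predictors"] = self.retained
        self.manifest["results"]["vif_removed"] = list(report.removed)
        log.info("fit: VIF retained %d/%d predictors", len(self.retained), pooled.shape[1])

        # modelling tables (presence + each background set) and full models
        screened = self.stack.subset(self.retained)
        for i, (species, occ) in enumerate(self.occurrences.items()):
            tables = []
            p = extract_at_points(
                screened, occ.data["lon"].to_numpy(float), occ.data["lat"].to_numpy(float)
            )
            for s in backgrounds[species]:
                b = extract_at_points(screened, s.lon, s.lat)
                tables.append(PresenceBackgroundTable.from_parts(p, b, set_id=s.set_id))
            self.tables[species] = tables
            models = {}
            for fam in cfg.families:
                seed = _stage_seed(cfg.seed, f"fit:{fam}", i)
                models[fam] = fit(fam, tables[0], seed=seed)
                save_model(models[fam], self.out / f"model_{_slug(species)}_{fam}.joblib")
            self.models[species] = models

    # ---- stage: evaluate --------------------------------------------------
    def stage_evaluate(self) -> None:
        cfg = self.cfg
        if not self.tables:
            raise PipelineError("evaluate", "no modelling tables; run fit first")
        for i, (species, tables) in enumerate(self.tables.items()):
            rows = []
            for fam in cfg.families:
                for scheme in cfg.schemes:
                    for table in tables:
                        seed = _stage_seed(
                            cfg.seed, f"eval:{fam}:{scheme}:{table.set_id}", i
                        )
                        recs = replicate_evaluate(
                            fam,
                            table,
                            scheme=scheme,
                            n_reps=cfg.n_reps,
                            test_fraction=cfg.test_fraction,
                            seed=seed,
                        )
                        rows.extend(r.to_dict() for r in recs)
            df = pd.DataFrame(rows)
            self.records[species] = df
            df.to_csv(self.out / f"evaluation_{_slug(species)}.csv", index=False)
            summary = df.groupby("family")[["auc", "cor", "tss", "deviance"]].mean()
            log.info("evaluate: %s\n%s", species, summary.round(3))

            # spatial block CV on the first table
            table = tables[0]
            seed = _stage_seed(cfg.seed, "spatial_cv", i)
            try:
                folds = assign_spatial_blocks(
                    table.lon, table.lat, table.labels,
                    block_km=cfg.block_km, k=cfg.k, seed=seed,
                )
                per_fold, mean_auc = spatial_cv(
                    cfg.spatial_cv_family, table, folds, seed=seed
                )
                pd.DataFrame(per_fold, columns=["fold", "auc"]).to_csv(
                    self.out / f"spatial_cv_{_slug(species)}.csv", index=False
                )
                random_auc = float(
                    df[df["family"] == cfg.spatial_cv_family]["auc"].mean()
                )
                self.manifest["results"][f"spatial_cv_auc:{species}"] = mean_auc
                self.manifest["results"][f"spatial_cv_drop:{species}"] = (
                    random_auc - mean_auc
                )
            except (ValueError, RuntimeError) as exc:
                log.warning("spatial CV skipped for %s: %s", species, exc)
                self.manifest["results"][f"spatial_cv_auc:{species}"] = None

            # null-model significance
            seed = _stage_seed(cfg.seed, "null", i)
            null = self._null_test(species, seed)
            self.manifest["results"][f"null_observed_auc:{species}"] = null.observed_auc
            self.manifest["results"][f"null_critical_auc:{species}"] = null.critical_value
            self.manifest["results"][f"null_significant:{species}"] = null.significant
            (self.out / f"null_{_slug(species)}.json").write_text(
                json.dumps(
                    {
                        "observed_auc": null.observed_auc,
                        "critical_value": null.critical_value,
                        "significant": null.significant,
                        "null_aucs": null.null_aucs.tolist(),
                    },
                    indent=2,
                )
                + "\n"
            )

    def _null_statistic(self, lon, lat, seed: int) -> float:
        """Full-table training AUC of the null families on given presences."""
        cfg = self.cfg
        spec = self.stack.spec
        mask = self.stack.nodata_mask
        occ_df = pd.DataFrame(
            {"species": "null", "lon": lon, "lat": lat, "year": 2020,
             "basis": "human observation", "source": "synthetic"}
        )
        occ = OccurrenceSet("null", occ_df)
        sets = sample_pseudo_absences(
            spec, occ, ratio=cfg.pa_ratio, n_sets=1,
            buffer_km=cfg.buffer_km, seed=seed, nodata_mask=mask,
        )
        screened = self.stack.subset(self.retained)
        p = extract_at_points(screened, lon, lat)
        b = extract_at_points(screened, sets[0].lon, sets[0].lat)
        table = PresenceBackgroundTable.from_parts(p, b)
        aucs = []
        for fam in cfg.null_families:
            model = fit(fam, table, seed=seed)
            scores = model.predict_proba(table.features)[:, 1]
            aucs.append(auc(scores, table.labels))
        return float(np.mean(aucs))

    def _null_test(self, species: str, seed: int):
        cfg = self.cfg
        occ = self.occurrences[species]
        observed = self._null_statistic(
            occ.data["lon"].to_numpy(float), occ.data["lat"].to_numpy(float),
            _stage_seed(cfg.seed, "null_observed", 0),
        )
        return null_model_test(
            self.stack.spec,
            len(occ),
            self._null_statistic,
            observed_auc=observed,
            n_null=cfg.n_null,
            seed=seed,
            nodata_mask=self.stack.nodata_mask,
        )

    # ---- stage: ensemble ---------------------------------------------------
    def stage_ensemble(self) -> None:
        cfg = self.cfg
        if not self.records:
            raise PipelineError("ensemble", "no evaluation records; run evaluate first")
        screened = self.stack.subset(self.retained)
        for i, species in enumerate(self.occurrences):
            df = self.records[species]
            mean_tss = df.groupby("family")["tss"].mean().to_dict()
            weights = tss_weights(mean_tss)
            self.weights[species] = weights
            weights.to_frame().to_csv(
                self.out / f"weights_{_slug(species)}.csv", index=False
            )
            maps = {
                fam: predict_prob(model, screened)
                for fam, model in self.models[species].items()
            }
            ens = ensemble_predict(maps, weights)
            self.ensemble_maps[species] = ens
            ens.write(self.out / f"ensemble_{_slug(species)}.asc")
            self.manifest["results"][f"ensemble_weights:{species}"] = weights.weights

            seed = _stage_seed(cfg.seed, "importance", i)
            imp = permutation_importance(
                self.models[species], weights, self.tables[species][0],
                n_perm=5, seed=seed,
            )
            merged = imp.per_family.copy()
            merged["ensemble_raw"] = imp.aggregated["importance_raw"]
            merged["ensemble"] = imp.aggregated["importance"]
            merged.index.name = "variable"
            merged.to_csv(self.out / f"importance_{_slug(species)}.csv")
            top = imp.ranked().index[0]
            self.manifest["results"][f"top_variable:{species}"] = str(top)
            log.info("ensemble: %s weights=%s top=%s", species,
                     {k: round(v, 3) for k, v in weights.weights.items()}, top)

    # ---- stage: classify ---------------------------------------------------
    def stage_classify(self) -> None:
        cfg = self.cfg
        if not self.ensemble_maps:
            raise PipelineError("classify", "no ensemble maps; run ensemble first")
        for species, ens in self.ensemble_maps.items():
            occ = self.occurrences[species]
            at_presence = ens.at_points(
                occ.data["lon"].to_numpy(float), occ.data["lat"].to_numpy(float)
            )
            p10 = presence_threshold(at_presence, pct=cfg.p10_pct)
            p10 = min(p10, cfg.core_cut)  # guard: tiny samples can push p10 high
            cmap = classify_habitat(ens, p10=p10, core_cut=cfg.core_cut)
            self.class_maps[species] = cmap
            write_ascii_grid(
                self.out / f"habitat_{_slug(species)}.asc",
                np.where(cmap.classes < 0, np.nan, cmap.classes.astype(float)),
                cmap.spec,
            )
            areas = class_area_summary(cmap)
            areas.to_frame().to_csv(
                self.out / f"areas_{_slug(species)}.csv", index=False
            )
            self.manifest["results"][f"p10_threshold:{species}"] = p10
            self.manifest["results"][f"areas_km2:{species}"] = areas.areas_km2
            log.info("classify: %s p10=%.3f core=%.0f km2",
                     species, p10, areas.areas_km2["core"])

    # ---- stage: pressure ----------------------------------------------------
    def stage_pressure(self) -> None:
        if not self.class_maps:
            raise PipelineError("pressure", "no habitat class maps; run classify first")
        for species, cmap in self.class_maps.items():
            table = pressure_summary(cmap, self.landcover)
            table.index.name = "habitat_class"
            table.to_csv(self.out / f"pressure_{_slug(species)}.csv")
            core = table.loc["core"]
            self.manifest["results"][f"core_anthropogenic_pct:{species}"] = (
                None if np.isnan(core["anthropogenic_pct"]) else float(core["anthropogenic_pct"])
            )

    # ---- stage: characterize / composite ------------------------------------
    def stage_characterize(self) -> None:
        if len(self.occurrences) >= 2:
            summaries = env_characterization(
                self.stack.subset(self.retained) if self.retained else self.stack,
                self.occurrences,
            )
            combined = pd.concat(
                [df.assign(variable=var) for var, df in summaries.items()],
                ignore_index=True,
            )
            combined.to_csv(self.out / "characterization.csv", index=False)
        if len(self.ensemble_maps) >= 2:
            comp = composite_mean(list(self.ensemble_maps.values()))
            comp.write(self.out / "composite.asc")
            bins = percentile_bins(comp, n_bins=self.cfg.n_bins)
            write_ascii_grid(
                self.out / "composite_bins.asc",
                np.where(bins < 0, np.nan, bins.astype(float)),
                comp.spec,
            )

    # ---- manifest ------------------------------------------------------------
    def write_manifest(self) -> Path:
        outputs = {}
        for path in sorted(self.out.rglob("*")):
            if path.is_file() and path.name != "manifest.json":
                outputs[str(path.relative_to(self.out))] = _sha256(path)
        self.manifest["outputs"] = outputs
        path = self.out / "manifest.json"
        path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")
        return path

    def run_all(self) -> dict:
        for stage in (
            self.stage_simulate,
            self.stage_clean,
            self.stage_fit,
            self.stage_evaluate,
            self.stage_ensemble,
            self.stage_classify,
            self.stage_pressure,
            self.stage_characterize,
        ):
            name = stage.__name__.replace("stage_", "")
            log.info("=== stage %s ===", name)
            try:
                stage()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        self.write_manifest()
        return self.manifest


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full workflow; returns the manifest dict."""
    return PipelineRunner(config, outdir).run_all()
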