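# Desk-scale synthetic study: one virtual species on a 40x40 grid.
seed: 11
synthetic:
  n_rows: 40
  n_cols: 40
  origin_lon: 100.0
  origin_lat: 10.0
  cell_size: 0.04
  corr_range_cells: 5.0
  ocean_fraction: 0.15
  landcover_anthropogenic: 0.30
  landcover_other: 0.05
  layers: [vpd, light, sand, silt, clay, elevation]
  species:
    - name: virtual A
      n_presences: 30
      responses:
        vpd: {optimum: 1.25, breadth: 0.15, weight: 1.0}
pa_sets: 2
n_reps: 3
schemes: [subsample]
n_null: 19
block_km: 50.0
k: 4
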