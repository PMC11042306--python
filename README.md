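# colonnade

Quantitative analysis of columnar connectomes: the pipeline that turns raw
synapse/neuron/connection tables from an insect optic lobe into a cell-type
inventory with spatial-coverage and connectivity statistics.

The fly visual system is built from repeating retinotopic **columns** — one
per ommatidial lens, addressed by hexagonal coordinates — crossed by
**layers** at characteristic depths. `colonnade` implements the analysis
stages that exploit this architecture:

- **Pins** — curved column centerlines fitted through per-column synapse
  clouds (PCA axis, lateral-outlier removal at `f_lat·σ_lat`, boundary-anchored
  endpoints, rank-ordered moving average, gap-bounded shortest sublist,
  PCHIP resampling to `N_samp` points), plus neighbor-median regularization
  and fill-in of missing columns. Every synapse gets a column and a depth
  ∈ [0, 1] from its nearest pin point.
- **Layers** — 1D synapse-depth distributions per cell type and peak-cutoff
  boundaries: the threshold `syn_thre` leaves a fraction `frac_peaks` of the
  distribution's mass above it, and layer boundaries sit at peak cutoffs at
  least 3 depth bins apart.
- **Coordinate assignment** — the paired-connection mode rule (each synapse in
  a listed type-pair connection votes for its nearest column axis) and
  cross-region extension by maximum-weight bipartite matching on the
  row-normalized connectivity matrix `C̃ᵢⱼ = Cᵢⱼ / Σₖ Cᵢₖ`, with pairs more
  than 8 µm apart rejected.
- **Cell typing** — per-neuron connectivity features (summed input/output
  weights to every named type-instance), hierarchical clustering with cosine
  distance and Ward linkage (as Ward on L2-normalized rows), confusion
  matrices with the five-way 80%/10% cell taxonomy, entropy-based
  completeness/homogeneity, top-k partner distinguishability, and the
  OLIN/OLCN/VPN/VCN group rules (>98% / >10% synapse-location thresholds).
- **Morphology** — 244-dimensional per-neuron vectors (pre/post synapse and
  innervated-column counts across 61 depth bins) clustered under the
  Euclidean metric.
- **Coverage** — the trimming procedure (median cumulative-fraction curve,
  kneedle knee at sensitivity S=1, 0.775/0.995 mass fallback) and per-type
  statistics: trimmed median cell size, coverage factor, columnar
  completeness, convex-hull area in column units.
- **Transmitters** — per-presynapse probabilities over seven transmitters
  aggregated to neuron (≥50 presynapses) and type (≥100) consensus calls at
  confidence ≥0.5, with the aminergic no-support override and fanout.
- **Inter-region flow** — the product rule (output count × input fraction)
  summed over neuron groups, with cumulative-sum binning.

A fully seeded synthetic generator (`colonnade.synthetic`) plants a
hexagonal lattice with curved centerlines, columnar cell types with depth
profiles, overlapping mosaics, block-structured connectivity and dominant
transmitters, so every stage is testable against known ground truth with no
database access.

## Worked example

```bash
colonnade run --out demo --seed 1
```

generates a radius-3 lattice (37 columns) with 6 planted columnar types
(~6.6k synapses), builds pins, assigns synapses to columns and depths,
clusters the cells by connectivity, and writes coverage, transmitter and
flow tables. On this dataset it prints/writes:

- `scores.json`: `{"completeness": 1.0, "homogeneity": 1.0, "k": 6}` — the 6
  planted types are recovered one-to-one by connectivity clustering alone.
- `coverage.csv` (first row): `Pt00, cell_size=1.0, coverage_factor=1.0,
  completeness=1.0, convex_area=27.0, n_cells=37` — after trimming, each
  columnar cell occupies exactly its home column, one cell per column, the
  type tiles all 37 columns, and its hull covers 27 column units.
- `nt.csv` (first row): `Pt00, acetylcholine, confidence=1.0,
  n_presynapses=519` — the pooled type-level consensus recovers the planted
  transmitter.

In library form:

```python
from colonnade import SyntheticConfig, simulate_dataset, PinParams
from colonnade.pins import build_region_pins, assign_to_columns

ds, truth = simulate_dataset(SyntheticConfig(lattice_radius=3, seed=1))
pins = build_region_pins(ds, truth.true_column, PinParams.medulla(n_avg=8, n_pc=50))
assign = assign_to_columns(ds, pins)   # synapse -> (column, depth)
```

## Data format

CSV tables: `synapses.csv` (id, neuron, pre/post kind, x/y/z in nm, region,
partner id, seven transmitter probabilities), `neurons.csv` (id, type,
instance, group, status), `connections.csv` (pre, post, weight, region),
`regions.csv` (region, top/bottom boundary z). See
`colonnade.data_model.read_dataset` for the validation rules. An adapter
from a neuPrint export dump to this schema is a documented extension point,
not a dependency.
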