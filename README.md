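# divprior

Spatial biodiversity prioritization on occurrence grids: from raw species
occurrence records and a phylogeny to per-cell diversity surfaces,
multi-threshold hotspots, conservation-effectiveness and gap reports
against reserve layers, ethnic-use matrix analytics, and ensemble-SDM
post-processing for climate-change range assessment. A synthetic-data
generator produces every input with known ground truth, so the whole
pipeline is testable end to end without external data.

## What it computes

| Stage | Module | Highlights |
| --- | --- | --- |
| Data generation | `divprior.synthetic` | contiguous land masks, spreading-dye species ranges with a richness gradient, planted dirty records, Yule phylogenies, block-structured use matrices, calibrated reserve layers, climate rasters with an engineered collinear pair |
| Record handling | `divprior.occurrences` | five ordered cleaning filters (missing coordinates, lat == lon, zero/integer coordinates, in-sea, outside native range), per-cell thinning, gridding into a binary presence matrix |
| Grids | `divprior.grid` | equal-area square-cell grids (Albers conic or cylindrical equal-area), stable row-major ids, half-open cells with a lower-id edge tie-break |
| Diversity surfaces | `divprior.diversity` | SR, weighted endemism, greedy complementarity (set cover) with a rank surface, Faith PD, phylogenetic endemism, the composite PA = PD/PD_max + PE/PE_max, Pearson pattern correlations |
| Hotspots | `divprior.hotspots` | top-q% selection per metric, rank-sum overlay to the final set, Class I/II/III tiers, species coverage by category |
| Conservation | `divprior.conservation` | reserve overlay (any positive-area intersection), grid- and species-level effectiveness, gap cells and gap species per scope (NNR / PNR / union) |
| Ethnobotany | `divprior.ethnobotany` | composition and uniqueness tables, use-frequency spectra, A/C sequence coding with FASTA/NEXUS export, p-distances, NJ / average-linkage group trees |
| SDM | `divprior.sdm` | collinearity screening (|r| > 0.85), pseudo-absence sampling, stratified 70/30 splits, TSS/AUC evaluation, TSS-weighted ensembles (TSS >= 0.5, AUC >= 0.7), max-TSS binarization, stacked richness, range-change assessment; pluggable learners with a built-in percentile-envelope reference |

## CLI

```bash
divprior simulate  --out worlds/demo --seed 1          # synthetic world
divprior clean     --occurrences occ.csv --grid grid.json --out cleaned.csv
divprior rasterize --occurrences cleaned.csv --grid grid.json --out presence.csv
divprior thin      --occurrences cleaned.csv --grid grid.json --seed 1 --out thin.csv
divprior metrics   --presence presence.csv --grid grid.json \
                   --tree tree.nwk --which sr,we,sc,pd,pe,pa --out-dir metrics/
divprior hotspots  --presence presence.csv --grid grid.json --tree tree.nwk \
                   --q 0.05,0.10,0.17,0.30 --out-dir hotspots/
divprior protect   --grid grid.json --reserves reserves.geojson \
                   --hotspot-table hotspots/hotspots_q0.05.csv \
                   --presence presence.csv --traits traits.csv --scope both
divprior ethno compose|freq|encode|tree --use-matrix use.csv
divprior sdm screen|stack|change ...
```

All artifacts are plain text: grids as JSON, vector layers as GeoJSON,
rasters as ESRI ASCII grids, tables as CSV, trees as Newick.

## Library example

```python
import divprior as dp

world = dp.make_world(seed=1)
cleaned, report = dp.clean_records(
    world.occurrences, world.land_polygon(), world.native_ranges()
)
pm, _ = dp.rasterize_presence(cleaned, world.grid)
tree = dp.load_tree(world.phylogeny)

surfaces = {
    "SR": dp.species_richness(pm),
    "SC_rank": dp.complementarity(pm).sc_rank,
    "WE": dp.weighted_endemism(pm),
    "PA": dp.pa_index(
        dp.phylogenetic_diversity(pm, tree),
        dp.phylogenetic_endemism(pm, tree),
    ),
}
hotspots = dp.combine_rank_sum(surfaces, q=0.05, sr_surface=surfaces["SR"])
status = dp.protection_status(world.grid, world.reserves)
report = dp.effectiveness_report(
    hotspots.final_cells, status, pm, world.species_table, scope="NNR-PNR"
)
print(report.summary())
```
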