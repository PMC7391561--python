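# refugeo

Population-genetic and spatial-regression tools for asking why a sexual
cytotype occurs where it does when it shares its range with apomictic
(asexually seed-producing) relatives.  The package implements a complete
analysis chain for sexual–apomictic plant complexes in formerly glaciated
mountain regions:

1. **Per-population genetic indices** from plastid sequences and dominant
   AFLP markers — haplotype diversity *h*, nucleotide diversity *π*, gene
   diversity, and rarity (frequency-down-weighted marker values, DW) —
   plus Jost's *D*<sub>est</sub> differentiation and a permutation Mantel
   test of isolation by distance.
2. **Grid-correlation inference of the colonization source**: the study
   area is divided into a regular lon/lat grid; for each cell, the
   Spearman correlation between centroid-to-population distance and each
   genetic index is computed.  Under serial founder effects diversity and
   rarity decline away from the source, so source-like cells show strongly
   negative correlations.  Cells are ranked per index, rankings averaged,
   and the Spearman correlation of the combined rank with latitude gives
   the colonization direction (positive ρ ⇒ southern source).
3. **Least-accumulative-cost distance** from the inferred ice-margin
   source line over an elevation raster, with classic GIS cost-distance
   semantics: 8-connected moves costing the mean of the two cells'
   impedance times the planimetric move length (×√2 on diagonals), solved
   exactly with Dijkstra's algorithm.
4. **Binomial GLM machinery**: single-predictor logistic screens with
   Bonferroni correction, explained deviance
   *D*² = (dev₀ − dev)/dev₀ and its adjusted form
   adj *D*² = 1 − [(n−1)/(n−p)](1 − *D*²), and three-matrix variation
   partitioning (ecology / colonization history / apomict occurrence)
   into unique and shared fractions of adj *D*².
5. **Synthetic-data generators** for every stage: a stepping-stone serial
   founder simulation, a logistic cytotype-occurrence generator, and
   synthetic relief rasters — so the entire chain is testable without any
   external download.

Intended users: population geneticists and biogeographers working with
dominant-marker datasets (AFLPs) and presence/absence cytotype surveys
who want a scripted, reproducible version of this analysis style.

## Worked example

Simulate a serial-founder colonization from the southern edge of an
Alpine-scale transect (68 populations × 4 individuals, 370 AFLP loci),
compute the four genetic indices and run the refugium inference:

```python
from refugeo.simulate import FounderSimConfig, simulate_serial_founder
from refugeo import popgen, refugium

table, aflp, haps, _ = simulate_serial_founder(FounderSimConfig(seed=42))
idx = popgen.genetic_index_table(aflp, haps)
print(idx.head().round(4).to_string(index=False))

grid = refugium.build_grid(9.4, 44.7, 13.9, 48.1, 0.1)   # 34 x 45 cells
ranks = [
    refugium.rank_cells(
        refugium.correlation_surface(grid, table, idx[c].to_numpy(), index_name=c)
    )
    for c in ("hap_div", "nuc_div", "gene_div", "rarity")
]
res = refugium.direction_test(refugium.combine_ranks(ranks))
print(f"rho={res.rho:.3f} p={res.p:.2e} source={res.inferred_source}")
```

Output:

```
pop_id  n  hap_div  nuc_div  gene_div  rarity
  P001  4      0.0     0.00    0.0694  1.1771
  P002  4      0.0     0.00    0.0158  1.1481
  P003  4      0.0     0.00    0.1230  1.2071
  P004  4      1.0     0.01    0.2865  2.0206
  P005  4      0.0     0.00    0.0036  0.9650
rho=0.968 p=0.00e+00 source=south
```

Populations near the source edge retain diversity (e.g. `P004`), distant
ones have lost it to repeated founder events; the combined cell ranking
correlates strongly and positively with latitude, so the southern margin
is (correctly) inferred as the colonization source.

The same stages are available from the shell:

```bash
refugeo simulate founder --seed 42 --out-dir sim/
refugeo indices --aflp sim/aflp.csv --fasta sim/cp.fasta --pops sim/pops.csv --out indices.csv
refugeo refugium --indices indices.csv --pops sim/pops.csv --out-prefix ref/
refugeo costdist --dem dem.asc --source margin.geojson --pops sim/pops.csv \
    --out surface.asc --out-pops pops_cd.csv
refugeo varpart --pops pops_cd.csv --out fractions.json
refugeo run --config pipeline.yaml      # everything, with a run manifest
```

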