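# divfacets

Taxonomic, functional and phylogenetic alpha/beta/gamma diversity of
habitat-structured species communities, with a continental grid-cell
complementarity analysis and a synthetic-data generator for testing.

What it computes:

- **Trait space** — Gower distances on mixed continuous/ordinal/categorical
  traits, embedded by non-metric multidimensional scaling (own PAVA +
  SMACOF implementation, Kruskal stress-1) into one shared k-D space.
- **Alpha diversity** per site — species richness, convex-hull functional
  richness (FRic) in trait space, rooted Faith's PD; plus a tip-graft rule
  for species missing from the tree.
- **Beta diversity** — pairwise Sørensen dissimilarity in taxonomic
  (set-based), functional (hull-intersection volume) and phylogenetic
  (PhyloSor, shared rooted branch length) form.
- **Regional comparisons** — pooled and subsampled gamma diversity,
  sample-based species-accumulation curves (exact or permutation),
  elevation filtering, Welch t contrasts with medians/IQRs, OLS facet
  correlations.
- **Grid complementarity** — per-cell richness/PD, weighted species and
  phylogenetic endemism, richness-corrected complementarity (we/S, pe/PD),
  a cell-replacement counterfactual, and max-scaling for mapping.
- **Synthetic data** — Yule trees, Brownian/Mk trait evolution,
  habitat-structured communities with a tunable homogenization level, and
  continental grids with an endemism hotspot.

## CLI

```sh
divfacets simulate --out-dir data/                 # synthetic dataset
divfacets traitspace --traits data/traits.csv --schema data/traits.schema.yaml --out space.csv
divfacets alpha --community data/community.csv --space space.csv --tree data/tree.nwk --out alpha.csv
divfacets beta --community data/community.csv --facet taxonomic --tree data/tree.nwk --out beta.csv
divfacets gamma --community data/community.csv --draws 1000 --group-sizes forest=7,savannah=8 --out gamma.csv
divfacets compare --alpha alpha.csv --beta beta.csv --out contrasts.csv
divfacets accumulate --community data/community.csv --mode exact --out curve.csv
divfacets complement --grid data/grid.csv --tree data/tree.nwk --out cells.csv
divfacets run --config run.yaml                    # full pipeline, manifest + CSVs
```

File formats are plain CSV (incidence matrices with `site_id`/`cell_id`
leading columns), standard Newick with branch lengths, and a YAML sidecar
declaring trait kinds. See `divfacets <cmd> --help` for options.

## Layout

```
src/divfacets/
  io.py               data model + CSV/Newick readers/writers + validation
  traitspace.py       Gower distance, PAVA, stress-1, NMDS
  alpha.py            richness, FRic, Faith's PD, tip grafting
  beta.py             Sørensen facets, hull-intersection volume
  regional.py         subsampled gamma, accumulation, contrasts
  complementarity.py  weighted endemism, complementarity, cell replacement
  simulate.py         synthetic trees/traits/communities/grids
  pipeline.py, cli.py orchestration and the divfacets command
tests/                unit + property + acceptance suites
scripts/acceptance.py acceptance report entry point
```
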