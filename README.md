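# netcurv

Graph Ricci curvature analysis of resting-state functional connectivity
networks: from per-subject correlation matrices through MST + sparsity
graph construction, Forman–Ricci and Ollivier–Ricci curvature and
standard graph measures, to multi-density group statistics,
clinical-score partial correlation, and surrogate-null term-enrichment
decoding. A synthetic-cohort generator with planted group effects makes
the whole pipeline testable end to end without any imaging data.

## Layout

| module | contents |
| --- | --- |
| `netcurv.synthetic` | two-group synthetic cohorts (block-structured FC matrices, covariates, clinical scores, term tables) |
| `netcurv.connectivity` | Pearson FC matrices, atlas tables, file I/O and validation |
| `netcurv.graphs` | density grid, maximum spanning tree (Kruskal), nested binarized graph series |
| `netcurv.curvature` | Forman–Ricci (classical/augmented) and Ollivier–Ricci edge curvature (exact transportation LP), node curvature |
| `netcurv.measures` | clustering, modularity, path length, betweenness, global/local efficiency |
| `netcurv.stats` | per-density t-tests, nodal AUC comparison, BH-FDR, partial correlation, ROI overlap |
| `netcurv.decoding` | surrogate-null term-frequency enrichment (z-scores vs random ROI sets) |
| `netcurv.pipeline` | cohort-level orchestration into measure tensors |
| `netcurv.cli` | `netcurv` command-line interface |

## CLI

All subcommands read one YAML run-config (see `netcurv.config.DEFAULTS`
for every key) and share an output directory; each run writes the fully
resolved configuration to `<out_dir>/resolved_config.yaml`.

```sh
netcurv simulate     --config run.yaml   # synthetic cohort: FC CSVs, subjects, atlas, terms
netcurv build-graphs --config run.yaml   # per-density edge lists + manifest
netcurv curvature    --config run.yaml   # per-edge / per-node curvature tables
netcurv measures     --config run.yaml   # global measures + nodal AUCs
netcurv compare      --config run.yaml   # group t-tests with BH-FDR, JSON summary
netcurv correlate    --config run.yaml   # partial correlation with age/gender covariates
netcurv decode       --config run.yaml   # surrogate-null term enrichment per RSN
netcurv report       --config run.yaml   # print the comparison summary
```

Example `run.yaml`:

```yaml
seed: 1
out_dir: myrun
cohort: {n_rois: 40, n_subjects_per_group: 20, n_blocks: 4, group_effect: 0.15, noise_sd: 0.05}
grid: {start: 0.05, stop: 0.5, step: 0.05}
```

## Notes

- The default density grid requires roughly ≥ 100 nodes so that the
  sparsest graph's edge budget covers the spanning tree; smaller graphs
  need a higher start density (the error message names the minimum).
- The packaged 200-ROI atlas table (`netcurv/data/schaefer200_7net.tsv`)
  carries the standard 7 network labels and Schaefer-style ROI names with
  synthetic centroid coordinates; supply your own TSV for real analyses.
- Ollivier–Ricci curvature solves an exact dense transportation LP per
  edge (scipy HiGHS); Forman–Ricci is combinatorial and fast, with the
  triangle-augmented variant as default.
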