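# cortexscreen

Screen 3D gene-expression volumes for genes that mark cortical-area borders.

The pipeline mirrors a projection-plus-classification screen over a voxel
atlas: per-gene expression volumes co-registered to an annotation volume are
masked to cortex, collapsed to 2D surface maps (a horizontal *top* view and
an unfurled *flat map*) by maximum-intensity projection along surface
normals, and then, for each cortical area, a Gini-criterion random forest is
trained to classify pixels of a dilated border neighborhood as inside or
outside the area. Genes are ranked by normalized Gini variable importance;
the top-ranked genes are candidate border markers, annotated with automated
hemisphere-asymmetry and within-area-gradient flags.

Because screen-scale atlas data cannot ship with the package, a first-class
synthetic generator (`cortexscreen.synthetic`) produces shell-shaped
annotations and gene volumes with planted border markers, expression
gradients, per-section multiplicative banding and zeroed (missing) coronal
sections — enough statistical structure to exercise and validate every
stage, including parameter-recovery of the planted markers.

## Layout

| module                    | role |
| ------------------------- | ---- |
| `cortexscreen.synthetic`  | synthetic annotations, gene volumes, studies with ground truth |
| `cortexscreen.atlas`      | volume/tree data model, NRRD I/O, cortex & area mask extraction |
| `cortexscreen.projection` | surface mapping, max-intensity top/flat-map projection, area-mask projection |
| `cortexscreen.classifier` | dilated neighborhoods, pixel datasets, random forest, confusion matrix, importances |
| `cortexscreen.screen`     | per-area orchestration, size filter, candidate flags, accuracy-vs-size report |
| `cortexscreen.cli`        | `cortexscreen generate / project / screen / report` subcommands |

## CLI walkthrough

```sh
# 1. write a study spec (see SyntheticSpec.to_dict for the schema)
python - <<'EOF'
import yaml
from cortexscreen.synthetic import SyntheticSpec, marker_panel
spec = SyntheticSpec(gene_specs=marker_panel(n_areas=4, n_genes=50, noise_sd=0.05))
yaml.safe_dump(spec.to_dict(), open("spec.yaml", "w"))
EOF

# 2. generate volumes, annotation, structure tree and ground truth
cortexscreen generate --config spec.yaml --out data/

# 3. project all genes and area masks (mapping is built once and cached)
cortexscreen project --data data/ --out proj/ --kind top --kind flatmap

# 4. run the per-area marker screen
cortexscreen screen --projections proj/ --out screen/ --kind top

# 5. accuracy-versus-area-size table
cortexscreen report --reports screen/reports.json --out accuracy_vs_size.csv
```

Each stage writes a `provenance.json` (config hash, seeds, versions) next to
its outputs. Screen results land in `candidates.csv` (one row per area ×
candidate gene, with importance, rank, accuracy and flag scores) and
`reports.json`.

## Notes

- All lattices use 0-based (anterior-posterior, dorsal-ventral,
  medial-lateral) axis order; coronal sections are constant-AP planes.
- Invalid projection pixels (no cortex beneath) are NaN, distinct from a
  measured 0 (which can mean missing data).
- Missing data is fed to the classifier as-is — no imputation or smoothing;
  tolerance to it is a property of the forest, verified by the recovery
  tests.
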