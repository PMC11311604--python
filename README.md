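# punctacount

Per-cell quantification of autophagosome puncta in three-channel
fluorescence micrographs of cultured microglia, with immunoblot
densitometry and group statistics.

Autophagy activity in cells is commonly read out by counting discrete
fluorescent puncta — autophagosomes labelled by markers such as p62/SQSTM1 —
inside each cell. Doing this reproducibly requires more than spot
detection: cells must be segmented and validated (one nucleus per cell,
genuine marker staining, debris excluded), adherent cells split, the spot
size window derived from physics rather than tuned by eye, and the
resulting zero-inflated, overdispersed counts compared across treatment
groups with appropriate nonparametric statistics. `punctacount` implements
that entire chain as a tested Python library with a thin CLI, plus a
synthetic-scene generator with exact ground truth so every stage can be
validated without any microscope.

## The measurement model

Channels follow the common staining convention: red = cytoplasmic cell
marker (Iba1 for microglia), green = punctum marker (p62/SQSTM1),
blue = nuclear stain (DAPI).

**Size gate.** At scale *s* (px/μm) and an expected punctum diameter range
[d₋, d₊] (0.5–1.5 μm for mammalian autophagosomes), radii r = d/2 convert
to pixels and areas follow A = πr². At the default s = 5.62 px/μm this
gives radii 1.405–4.215 px and areas 6.202–55.814 px², rounded to the
inclusive integer gate **6–56 px²**. Only connected components inside the
gate count as candidate puncta.

**Background.** Puncta are isolated from diffuse cytosolic signal by
rolling-ball subtraction — grayscale opening with a ball of radius equal to
the largest punctum radius (4.215 px) — followed by a per-image recursive
Otsu threshold, hole filling and distance-transform watershed at a
temporarily up-scaled resolution.

**Cell validation.** A segmented marker region is a cell only if it
contains exactly one nucleus (multi-nucleus regions are watershed-split on
nucleus markers) and shows adequate mean marker intensity; anucleate
debris and marker-negative free nuclei are excluded. Each punctum is
assigned to the cell containing its centroid; orphans are dropped.

**Statistics.** Per-cell counts are compared with Kruskal–Wallis H
(tie-corrected) and Dunn's post-hoc z tests under Bonferroni adjustment;
approximately normal data (densitometry, cells per field) use one-way ANOVA
with Tukey's HSD; a Shapiro–Wilk screen flags which track applies. Blot
band intensities are integrated as optical density, normalized to an
internal standard (GAPDH) per lane and expressed as percent of control.

## Worked example

```python
from punctacount import (SceneSpec, generate_scene, RunConfig,
                         analyze_field, truth_compare)

spec = SceneSpec(n_cells=6, seed=42)          # one synthetic field
image, truth = generate_scene(spec)           # 600×600 RGB + ground truth
result = analyze_field(image, RunConfig(), field_id="demo")
print(result.table.to_string(index=False))
print(truth_compare(result.cells, result.puncta, truth))
```

prints

```
 cell_id field_id group   baf  count
       1     demo       False      9
       2     demo       False      1
       3     demo       False      3
       4     demo       False      8
       5     demo       False      3
       6     demo       False      3
{'cell_count_error': 0.0, 'count_mae': 0.0, 'precision': 1.0, 'recall': 1.0}
```

All six cells are recovered, each punctum count matches the generator's
truth exactly (`count_mae` 0), and every detected punctum lies within one
punctum radius of a true one (precision = recall = 1).

The same derivation is available from the shell:

```
$ punctacount calibrate
scale: 5.62 px/um
radius bounds: 1.405 - 4.215 px
area bounds: 6.202 - 55.814 px^2
integer gate: 6 - 56 px^2
rolling-ball radius: 4.215 px
```

Other subcommands: `simulate` (write a synthetic eight-group study as
TIFFs + truth tables), `segment`, `count-puncta`, `densitometry`, `stats`
and `run` (full batch over a manifest-described directory, producing tidy
CSVs, label maps and QC overlays).

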