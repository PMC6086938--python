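# codextk

Single-cell analysis of highly multiplexed (CODEX-style) fluorescence
tissue images: crowded-tissue segmentation, positional spillover
compensation, cleanup gating, and the downstream spatial statistics —
Delaunay cell–cell interaction odds ratios and i-niche (first-tier
neighborhood) clustering — together with a synthetic tissue-phantom
generator that provides full ground truth for every stage.

It is written for computational biologists processing multicycle
antibody-imaging data of dense tissue (lymphoid organs in particular),
where three problems dominate:

1. **Segmentation in crowded fields.** Cells are so tightly packed that
   nuclear staining alone cannot separate neighbours.  The segmenter builds
   a contrast image as (inverted membrane) × (nuclear) — the ubiquitous
   membrane marker forms ridges exactly where adjacent nuclei meet — then
   low-pass filters it in the Fourier domain and applies a seeded watershed
   on the gradient magnitude.
2. **Positional spillover.** Adjacent cells share membrane boundary, so a
   fraction of each cell's signal blends into its neighbours.  With
   `b_ij` the shared boundary face count and `B_j` the total boundary of
   cell *j*, the observed intensities follow `observed = S · true` with

       S[i,j] = c · b_ij / B_j   (i ≠ j),   S[j,j] = 1 − c · Σ_i b_ij / B_j

   a column-stochastic, strictly diagonally dominant (hence invertible for
   c < 0.5) sparse banded matrix.  Compensation multiplies by `S⁻¹`.
3. **Spatial statistics.** On the pruned 2-D Delaunay graph of cell
   centers, the specificity of contact between cell types A and B is the
   log odds ratio `ln(observed_AB / expected_AB)` with `observed_AB =
   N_AB / E` (the mean of a Beta(N_AB, E − N_AB) distribution) and the
   expected frequency from the types' incident-edge frequencies;
   significance comes from the lower tail of Binomial(E, expected) with
   Benjamini–Hochberg correction (q < 0.05 avoidance, q > 0.95
   attraction).  The *i-niche* of an index cell is its ring of first-tier
   Delaunay neighbours summarised as a type-fraction vector; K-means over
   these vectors yields recurring micro-neighbourhoods, and a nested
   F-test (marker ~ type vs marker ~ type + niche) quantifies how much a
   cell's surface phenotype depends on its neighbours.

## Worked example

The whole pipeline runs on a built-in 200-cell dense phantom:

```
$ codex run --out-dir work --preset dense --k 8
segmented 177 cells
gating: {'input': 177, 'removed_gate1_density_homogeneity': 4,
         'removed_gate2_blank': 0, 'removed_gate3_size': 0, 'kept': 173}
pipeline complete -> work
```

Reading the output: the watershed resolved 177 objects out of 200 planted
cells (dense tissue merges a few neighbour pairs; the benchmark on this
fixture scores ~100% of nuclei found and ~94% singlets), the cleanup gates
removed 4 objects whose nuclear-stain density fell outside the reference
window, and the remaining 173 cells were compensated, typed, and analysed.
`work/` then holds the stack (`stack.tif`), the labelled mask
(`mask.tif`), raw/compensated/gated cell tables (CSV), the sparse spill
matrix (`spill_matrix.csv`), interaction statistics
(`interactions.csv`: type pair, count, log odds, p, q), niche assignments
and centroids, and an FCS 3.0 export (`cells.fcs`) readable by cytometry
software.

The same stages are available as library functions:

```python
from codextk import phantoms, segmentation, compensation, interactions

truth = phantoms.make_cell_map(phantoms.standard_dense_spec())
stack = phantoms.render_image_stack(truth)
mask  = segmentation.segment_stack(stack)
cells = segmentation.quantify_cells(mask, stack)
spill = compensation.contact_fractions(mask, c=0.3)
cells = compensation.compensate(cells, spill)
graph = interactions.delaunay_graph(cells[["x", "y"]].to_numpy())
```

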