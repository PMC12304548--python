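# costack

Integration and cross-modal analysis of **spatial transcriptomics (ST)**
and **spatial proteomics (SP)** acquired from the **same tissue section**,
with histology (H&E) as the common coordinate frame.

When both modalities come from one physical section, every cell has both a
transcript readout and a protein readout — but the two instruments observe
the tissue in different coordinate frames, with different acquisition
windows, and with segmentations that disagree systematically (nuclear
expansion over-grows cells; membrane-marker segmentation under-grows
them). `costack` provides the full analysis chain for this setting:

1. **Registration** — thin-plate-spline (TPS) warps fitted from landmark
   pairs map each modality frame onto the H&E frame. The TPS minimises
   bending energy `∬ (f_xx² + 2 f_xy² + f_yy²)` among interpolants, with
   optional smoothing λ; the fitted map is affine + Σᵢ wᵢ U(‖x − cᵢ‖),
   U(r) = r² log r.
2. **Integration** — transcript spots are assigned to the cell mask pixel
   under their coordinate; per-cell mean channel intensities are averaged
   over each cell's pixels; analysis is restricted to the region covered
   by all modalities; cells without transcripts are excluded.
3. **Segmentation comparison** — cells from the two segmentations are
   matched by nearest centroid distance (mutual nearest neighbours) and
   compared morphologically (Δarea) and molecularly (per-gene Spearman
   across segmentations, dropout per segmentation).
4. **Correlation** — per gene–protein pair, Spearman's ρ between per-cell
   transcript count and mean immunofluorescence intensity; dropout (the
   fraction of cells in which a gene is undetected) is reported alongside,
   and the dropout-vs-ρ trend summarised. Regional differences
   (tumour vs non-tumour) are tested with Fisher's Z on atanh(ρ) using
   the rank-correlation variance 1.06/(n−3).
5. **Cell typing** — the SP arm by threshold-rescaled hierarchical gating
   (gate ↦ 0.5 after piecewise-linear rescaling to [0, 1]); the ST arm by
   k-nearest-neighbour label transfer in a reference embedding. Labels are
   harmonized to a shared coarse vocabulary and compared per class with
   the Jaccard index |A ∩ B| / |A ∪ B| over matched cells.
6. **Clustering** — total-count normalization + log1p, cosine kNN graph
   (k = 15), seeded Louvain.

Because raw same-section datasets of this kind are generally not publicly
available, the package ships a first-class **synthetic-data generator**
(`costack.simulate`) with known ground truth: non-overlapping cell
polygons, negative-binomial transcript counts with gene-specific dropout,
protein intensities coupled to their paired transcripts through a
Gaussian copula at a configurable rank correlation, two discrepant
segmentations, tumour/non-tumour regions, and a smooth invertible
deformation between modality frames with known landmarks. Every stage of
the pipeline is tested end-to-end against this generator.

## Worked example

```bash
costack init-config cfg.yaml --seed 1      # default study conditions
costack run-all --config cfg.yaml --outdir out/
```

which prints (abridged):

```
dropout_trend_stat_sp: -0.9999999999999999
genewise_seg_rho_median: 0.8871761527804867
jaccard_mean: 0.42446151804327276
matched_delta_area_positive_fraction: 1.0
n_cells: 450
n_clusters: 5
n_matched: 449
pair_rho_mean_sp: 0.4757904989790454
registration_heldout_mean_px_st: 0.4576274030482284
```

Reading: held-out landmarks land within half a pixel after TPS
registration; all 449 matched nuclear-expansion cells are larger than
their membrane-based counterparts (the over-expansion/under-segmentation
signature); transcript–protein rank correlation averages ≈0.48 against
copula targets of 0.3–0.8 (attenuation by count discreteness and
dropout); the dropout-vs-correlation trend is strongly negative; Louvain
finds 5 clusters for the 5 simulated cell types; and cross-modality cell
typing reaches a mean per-class Jaccard of ≈0.42 on matched cells.

All outputs are plain CSV/TIFF/GeoJSON/JSON in `out/`; `summary.json`
records the seed and config hash. Two runs with the same seed are
byte-identical.

The same stages are available as library functions
(`costack.register.fit_spline_transform`, `costack.integrate
.assign_transcripts`, `costack.correlate.differential_correlation`, ...)
and as individual CLI subcommands (`simulate`, `register`, `segment`,
`integrate`, `compare-seg`, `correlate`, `annotate`, `cluster`).

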