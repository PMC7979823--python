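# melchist

Analysis pipeline for **multi-epitope ligand cartography (MELC)** — cyclic
stain/image/bleach multiplexed immunofluorescence on a single tissue
section. From the raw per-cycle z-stacks it produces registered, corrected
marker images, random-forest probability maps, single-cell segmentations,
flow-cytometry-style gated phenotypes (including rare
Lin⁻CD45⁺CD127⁺ innate lymphoid cells, ILCs), 10 µm spatial niches,
tissue-compartment assignments, and arcsinh/PCA/t-SNE phenotype clusters.

It is written for immunologists and image analysts who want a scriptable,
fully reproducible version of the classic Ilastik + CellProfiler MELC
workflow, and it ships a synthetic-acquisition generator with complete
ground truth so that every stage of the pipeline is testable without
gigabytes of real microscope data.

## The pipeline

Each MELC cycle stains up to three antibodies, acquires a fluorescence
z-stack per channel (±z planes around focus), photo-bleaches, and acquires
a matching post-bleach stack. The analysis chain is:

1. **Registration** — each cycle is aligned to the run reference by
   normalized cross-correlation over integer shifts; ties break by smallest
   |Δr|+|Δc|, then lexicographically.
2. **Background subtraction** — the bleach stack of the previous cycle in
   the same channel (or the pre-run blank, or a secondary-antibody-only
   image) is subtracted, clamped at zero:
   `I' = max(I_fluo − I_bleach_prev, 0)`. This removes tissue
   autofluorescence and residual signal from the previous stain.
3. **Illumination correction** — a smoothing cubic-spline surface through
   per-block minimum intensities of the same cycle's bleach image estimates
   the multiplicative shading field (normalized to mean 1); images are
   divided by it.
4. **Extended depth of field** — per pixel, the z-plane with the highest
   local intensity variance wins (median-filtered selection map), giving
   one all-in-focus 2D image per marker.
5. **Normalization** — rolling-ball background subtraction, edge cropping
   by the maximum observed shift, and a linear stretch to the full 16-bit
   range.
6. **Pixel classification** — a random forest on multi-scale features
   (Gaussian, gradient magnitude, Laplacian of Gaussian, structure-tensor
   eigenvalues at σ ∈ {0.7, 1.0, 1.6, 3.5, 5}) of the DAPI image and the
   sum-of-membranes composite yields nuclei/membrane/ECM probability maps
   (summing to 1 per pixel). A model trained on ~6 % of one image
   transfers to further runs without retraining.
7. **Segmentation** — nuclei as primary objects (threshold 0.5 +
   distance-transform watershed declumping + size filter), cells as
   secondary objects (seeded watershed on the membrane map, capped at
   12 px beyond the nucleus). Exactly one cell per nucleus, same label.
8. **Quantification & gating** — per-cell mean fluorescence intensity
   (MFI, 0–1 scale; nuclear markers measured on the nucleus mask), Otsu
   default thresholds (manual overrides supported), and priority-ordered
   gating rules: B (CD45⁺CD19⁺), T helper (CD45⁺CD3⁺CD4⁺), cytotoxic T
   (CD45⁺CD3⁺CD8⁺), plasma (CD138⁺), myeloid, endothelial (CD31⁺),
   ILC (Lin⁻CD45⁺CD127⁺), else "others".
9. **Spatial analysis** — 10 µm-radius niches around seed cells (= 31 px at
   0.325 µm/px) with composition vs whole-tissue enrichment, minimum
   distances to vessel/fiber masks, and smooth-score tissue compartments
   (follicle, T zone, connective septum) with a 10 µm follicle border band.
10. **Clustering** — `asinh(MFI / 0.2)` transform, PCA (52 components for
    tonsil panels, 48 for colon, capped at the data dimensionality), t-SNE
    (perplexity 30, 1000 iterations, fixed seed), k-means with silhouette
    model selection, a cluster × marker mean-relative-expression heat-map,
    and the cluster-vs-gate agreement (e.g. the fraction of the ILC-rich
    cluster that is gated ILC).

## Worked example

```python
from melchist import default_tonsil_like_spec, simulate_run
from melchist.pipeline import RunConfig, run_all

spec = default_tonsil_like_spec(seed=11)          # 512x512, 150 cells, 12 markers
run, truth = simulate_run(spec)
res = run_all(run, "out/", RunConfig(seed=5), truth_class_image=truth.class_image)
print({t: v["count"] for t, v in res["counts"].items()})
print(res["clusters"])
```

prints:

```
{'B': 42, 'T_helper': 30, 'others': 18, 'T_cytotoxic': 18, 'myeloid': 15,
 'plasma': 12, 'endothelial': 12, 'ILC': 3}
{'focus_cluster': 9, 'n_clusters': 10, 'agreement': 1.0}
```

i.e. despite stage shifts, uneven illumination, bleach residual and noise,
the pipeline found all 150 simulated cells, gated every one into its true
type (the 3 rare ILCs included), and the t-SNE/k-means cluster that holds
the gated ILCs is 100 % ILC. `out/` contains the corrected marker
TIFFs, probability maps, label images, `cells.csv`, `niches.json`,
`clusters.csv`, `heatmap.csv` and `provenance.json`.

The same stages are available from the shell:

```bash
melchist simulate --out rundir/ --seed 1
melchist run-all rundir/ --out results/ --seed 1
melchist preprocess rundir/ --out corrected/
melchist gate cells.csv --out gated.csv
```

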