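# cytoplex

Quantification toolkit for multiplex immunofluorescence images of brain
tissue, with a ground-truthed synthetic-data generator so that every stage
is testable end to end without any raw microscopy data.

The pipeline covers:

- **`cytoplex.synthetic`** — simulators for multichannel tissue scenes
  (DAPI nuclei, cell-type marker channels, a perinuclear target channel,
  diffuse neuropil signal, control background, autofluorescent puncta) and
  for cluster × gene mean-expression matrices, both returning full ground
  truth.
- **`cytoplex.nuclei`** — DAPI nuclei counting: difference-of-Gaussians
  filter, triangle-algorithm threshold, watershed separation of touching
  nuclei, inclusive 10–250 px particle-size filter.
- **`cytoplex.regional`** — background-corrected intensity-per-cell scores
  per ROI ((mean − control mean) × area ÷ nuclei) and quartile-level
  classification (low / moderately low / moderately high / high).
- **`cytoplex.coloc`** — background-subtracted Manders split coefficients
  (M1/M2), 3-class binary overlays, and proximal/medial/distal distance
  bands from a reference layer.
- **`cytoplex.discs`** — per-cell multiplex quantification: cell detection
  (median → Gaussian → opening-by-reconstruction background subtraction →
  threshold → shape watershed → area filter), 2 μm nucleus expansion into
  non-overlapping "discs", seeded feed-forward pixel classifiers over a
  multiscale feature bank (Gaussian, LoG, gradient magnitude, Hessian
  determinant, weighted std, optional local normalization), centroid-based
  marker classification, per-ROI diffuse-signal correction by the median of
  a classified low-target area, upper-quartile normalization, region/marker
  exclusion rules, and subject × region × marker summaries.  An alternative
  detection mode segments intensely-somatic markers (IBA1-like) directly,
  without expansion, to avoid contamination from overlapping neighbours.
- **`cytoplex.stats`** — one-way and blocked two-way fixed-effects ANOVA
  (Type II or I sums of squares) with Tukey–Kramer post hoc tests, plus
  Shapiro–Wilk, Levene (center = mean) and Mauchly sphericity diagnostics.
- **`cytoplex.xpr`** — cluster-level expression aggregation: population
  filtering, canonical-marker class assignment with explicit overrides,
  per-class mean/SEM/rank summaries, and cross-dataset rank concordance.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end property criteria
(parameter recovery on simulated scenes, oracle equivalence, null
calibration); the rest are per-module unit and property tests.

## CLI

All functionality is exposed through one entry point:

```sh
cytoplex simulate --config scene.json --seed 1 --out scene_dir/
cytoplex count-nuclei --image scene_dir/scene.ome.tiff --out counts.csv
cytoplex regional --stained stained.ome.tiff --control control.tiff \
    --rois rois.geojson --counts counts.csv --out regional.csv
cytoplex coloc --image img.ome.tiff --ch-a TARGET --ch-b MAP2 \
    --rois rois.geojson --out coloc.csv
cytoplex stats --table summary.csv --design twoway-blocked \
    --factors marker,region --block subject --out anova.json
cytoplex xpr --matrix clusters.csv --rulebook rules.json --gene Igf2r \
    --out classes.csv
```

Images are (OME-)TIFF with channel names in metadata; ROIs are GeoJSON
polygons in micrometre coordinates (a feature property `exclusion_of`
marks exclusion sub-regions); tables are CSV.

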