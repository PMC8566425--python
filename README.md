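# mammilieu

Quantification of immune-cell milieus in normal breast tissue from
multiplex brightfield immunohistochemistry (IHC), with the orthogonal
flow-cytometry and transcriptional arms that accompany such studies.

Normal human mammary gland hosts T cells, B cells and macrophages whose
densities depend on how close they sit to the epithelium and change with
age. Quantifying this *in situ* requires (1) segmenting scanned sections
into tissue compartments — epithelium-enriched regions (EER) vs fat/stroma
(FSR), and within EER the peri-epithelium (PE) vs intralobular stroma
(ILS) — and (2) detecting and classifying chromogen-stained immune cells
so that densities can be expressed as cells/mm² per compartment. Because
cohort-level results from human tissue are not reproducible from published
numbers alone, this package ships a first-class synthetic-data layer:
scenes, cohorts, cytometry events and expression matrices are generated
with known ground truth, and the pipeline is validated by
parameter recovery against what was planted.

Intended users: computational pathology and cancer-biology researchers who
want a tested, reusable reference implementation of this quantification
workflow, or a ground-truthed sandbox to benchmark alternatives.

## What is implemented

- **`mammilieu.simulate`** — seeded generators: brightfield scenes rendered
  by Beer–Lambert composition of stain optical densities (0.465 µm/pixel;
  triple CD3/CD20/CD68 and double CD68/CD163 panels, nucleus-free CD68
  "speckles", sub-15-µm debris), donor cohorts with a linear
  density-vs-age truth model, flow-cytometry event mixtures, and
  probe-level expression matrices with planted signature shifts.
- **`mammilieu.stains`** — color deconvolution: `OD = M·c` with unit stain
  vectors; per-marker passes unmix each chromogen against hematoxylin plus
  an orthogonal residual.
- **`mammilieu.segmentation`** — two-stage encoder–decoder semantic
  segmentation (EER/FSR, then PE/ILS inside EER), trained with
  augmentation until held-out pixel error < 10%; a numpy implementation
  with manual backpropagation, plus an oracle mode that returns generator
  truth.
- **`mammilieu.detection`** — mean-filter smoothing, blob segmentation at a
  33 µm characteristic scale with watershed splitting, removal of objects
  < 15 µm equivalent diameter, positivity at per-object mean intensity
  < 50 (0 = strongest stain), CD68 nucleus-association, and panel
  classification rules (multi-positive → unclassified in the triple panel;
  CD163⁺ → M2 in the double panel).
- **`mammilieu.density`** — cells/mm² per donor × class × compartment,
  pooling counts and areas before dividing.
- **`mammilieu.stats`** — age regressions (OLS, Pearson r), one-way ANOVA
  with Tukey HSD, paired (PE vs ILS) and unpaired (risk, menopause)
  t-tests, Tukey boxplot summaries, significance symbols.
- **`mammilieu.gating`** — 7-AAD viability exclusion (≥ 10,000 viable
  events required), CD45 gating, subset percentages with ambiguity bands,
  blood–tissue Pearson correlation.
- **`mammilieu.signatures`** — probe collapse by maximal mean, per-gene
  z-scaling, signature scores as mean of member genes, Wilcoxon rank-sum
  young (≤ 35 y) vs older (≥ 50 y) with Holm–Bonferroni correction.
- **`mammilieu.pipeline` / `mammilieu.cli`** — orchestrated, seeded runs
  with a JSON manifest; `mammilieu generate|segment|detect|quantify|stats|
  flow|signatures|run`.

## Worked example

```python
from mammilieu.simulate.scene import SceneSpec, generate_scene
from mammilieu.detection import DetectionParams, detect_scene, assign_compartment
from mammilieu.density import compute_density
from mammilieu.segmentation import oracle_segmenter

spec = SceneSpec(
    image_size_px=(1200, 1200), eer_fraction=0.8, pe_fraction_of_eer=0.15,
    planted_density={("Mac", "ILS"): 101.0},  # cells/mm^2
    cd68_speckle_fraction=0.2, seed=3,
)
rgb, truth = generate_scene(spec)
cells = assign_compartment(
    detect_scene(rgb, DetectionParams(), panel="triple"),
    oracle_segmenter(truth),
)
for r in compute_density(cells, truth.compartment_mask, "donor0"):
    if r.cell_class == "Mac":
        print(f"{r.compartment:9s} n={r.count:3d} area={r.area_mm2:.3f} mm^2 "
              f"density={r.density:.1f} cells/mm^2")
```

prints

```
PE        n=  0 area=0.042 mm^2 density=0.0
ILS       n= 26 area=0.207 mm^2 density=125.4
EER_total n= 26 area=0.249 mm^2 density=104.4
```

All 26 nucleated macrophages planted in the intralobular stroma are
recovered (the 7 nucleus-free speckles are excluded by the
nucleus-association rule); the realized density of 125.4 cells/mm²
reflects Poisson count noise at this small area and converges to the
planted 101 cells/mm² as area grows.

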