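# lincquant

Quantitative analysis of LINC-complex filaments at meiotic telomere
attachment sites segmented from electron tomograms.

## The problem

During meiotic prophase I, telomeres attach to the nuclear envelope and
are actively moved by cytoplasmic dynein–dynactin motors walking on
microtubules.  The force is transmitted into the nucleus by LINC
(Linker of Nucleoskeleton and Cytoskeleton) complexes — trimeric
SUN1/2–KASH5 bridges that appear in electron tomograms as ~90 nm
filaments clustering over the two attachment plates of each synapsed
telomere pair.  Manual segmentation of such tomograms yields labelled 3D
point models (IMOD `model2point` text exports): membranes, synaptonemal
complex elements, attachment plates, and one open contour per traced
filament.

`lincquant` turns those point models into the quantities that describe
LINC-complex organisation and the forces it can sustain:

- **per-filament geometry** — polyline arc length *L*, end-to-end
  (linear) distance *d*, and the stretch factor *s = d / L* ∈ (0, 1]
  (1 = straight, smaller = more rippled); the filament **origin** is the
  vertex with the minimum Euclidean distance to the lateral-element
  point set, i.e. its anchor at the inner nuclear membrane;
- **nearest-neighbour statistics** — distances between filament origins
  and between entire filaments, which follow a shifted exponential with
  a hard packing minimum (the "global minimum distance");
- **plane fits** — a PCA plane through the origins of each attachment
  plate; its long in-plane extent is the stretch of membrane (and hence
  microtubule) over which the filaments concentrate;
- **microtubule proximity** — per-filament distance to the microtubule
  axis, close/far contrasts of linear distance across a cutoff grid
  (Wilcoxon rank-sum), and stretch-factor cohort comparisons;
- **the force model** — dynein–dynactin complexes (~43 nm footprint,
  ~5 pN per dynein, 1 or 2 dyneins per dynactin) packed at maximum
  density on the engaged microtubule length per plate:
  `complexes = plates × ⌈extent / 43 nm⌉`, `force = complexes × dyneins ×
  5 pN`, plus nucleus-wide filament/SUN/KASH totals from the mean
  per-site count.

Because the original tomograms are not publicly deposited, the package
ships a seeded **synthetic generator** that emulates the reported
statistical structure (two plate clusters, counts near the observed
per-site table, lengths ≈ 91 ± 18 nm, ≥ 5 nm origin spacing, ≥ 2 nm
inter-filament clearance, rippled polylines, optional microtubule with a
near-axis straightening effect) and emits exact ground truth, so every
pipeline stage is testable end to end.

## Worked example

Quantify a synthetic 11-site cohort whose per-site counts are forced to
the observed table (six sites without and five with a microtubule):

```python
from lincquant import (SyntheticConfig, TABLE1_FILAMENT_COUNTS,
                       TABLE1_HAS_MICROTUBULE, generate_cohort,
                       quantify_sites, compare_cohorts)

cfg = SyntheticConfig(n_sites=11, filament_counts=TABLE1_FILAMENT_COUNTS, seed=42)
cohort = generate_cohort(cfg, mt_pattern=TABLE1_HAS_MICROTUBULE)
metrics, summaries = quantify_sites(cohort.models)
report = compare_cohorts(metrics, summaries)
```

With this seed the report contains:

- 11 sites, **832** filaments in total, **75.6** per site on average;
- recovered filament lengths **91.4 ± 18.0 nm** (generator target 91 ± 18);
- minimum origin nearest-neighbour distance **5.0 nm** and minimum
  whole-filament distance **2.0 nm** — the generator's packing floors,
  recovered by the distance stage;
- mean plane-fit long extent **143.4 nm** (the min–max range of ~38
  origins on a 150 nm plate slightly undershoots the plate length);
- per-site count comparison, without- vs with-microtubule (n = 6 vs 5):
  KS *D* = 0.267, exact *p* = 0.965 (corrected-asymptotic convention:
  0.970) — no count difference between moving and stationary sites;
- stretch factor higher with a microtubule (difference 0.017, rank-sum
  *p* ≈ 3 × 10⁻²³), reflecting the generator's near-axis straightening;
- force model at the measured extent: **8** dynein–dynactin complexes
  per site, **40 pN** (single dynein per dynactin; 80 pN with two),
  **≈3000** filaments and **≈9100** SUN monomers per nucleus.

The same pipeline runs from the shell:

```sh
lincquant simulate --seed 42 --n-sites 11 --out sim/
lincquant quantify --config sim/cohort.yaml --out quant/
lincquant compare  --config sim/cohort.yaml --out cmp/
lincquant force    --dyneins-per-dynactin 2
```

`quantify` writes `filament_metrics.csv` (one row per filament) and
`site_summaries.json`; `compare` adds `cohort_report.json` and
`cutoff_scan.csv`.  Real segmentations are analysed the same way: point
a cohort YAML (`sites:` with `path`, `pixel_size_nm`, `labels`,
`has_microtubule`) at `model2point` text exports.

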