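# punctakit

Quantitative analysis of intranuclear protein-aggregate puncta in
fluorescence microscopy.

`punctakit` is aimed at cell biologists and image analysts comparing
nuclear aggregates formed by benign versus pathogenic protein variants —
the motivating case is PABPN1, whose alanine-expanded form causes
oculopharyngeal muscular dystrophy (OPMD) and forms nuclear aggregates
that differ from the wild-type protein's in number, size, shape,
mobility and mRNA sequestration. The package turns the interactive
macro-and-plugin workflow usually used for such comparisons into a
reusable, tested Python pipeline, and ships a synthetic-scene generator
with full ground truth so every stage is verifiable without proprietary
image data.

## What it computes

Per nucleus (segmented from the counterstain channel, with a perinuclear
ring as cytoplasmic proxy):

* **Puncta morphometrics** — constant-threshold puncta masks (Gaussian
  blur → despeckle → threshold → connected components → strict
  area > 0.01 µm² filter), then per punctum the area *A* (µm²), perimeter
  *P*, circularity 4π·A/P² (clamped at 1), and MFI on the raw pixels;
  per nucleus the counts, means, and intranuclear SDs, plus an OLS fit of
  log₂(circularity) on log₂(area) with the F-test of zero slope.
* **Dual-threshold aggregation index** — with a low (bulk) and high
  (aggregate) threshold on the same image,
  `aggregation_index = Σ I(high mask) / Σ I(low mask) ∈ [0, 1]`.
* **Overlap dynamics** — three time-lapse frames binarized with the same
  threshold; `ratio = |M₁∩M₂∩M₃| / |M₁∪M₂∪M₃|` (the "white over colored"
  area of an RGB overlay). 1 = immobile puncta, → 0 = fast puncta.
* **mRNA colocalization** — Manders M1/M2 over background-subtracted
  intensities, Pearson correlation over nucleus pixels, overlap area, and
  the compartment ratio log₂(nuclear MFI / perinuclear MFI).
* **Nuclear texture** — gray-level co-occurrence matrix (GLCM) inside the
  nucleus mask with per-ROI quantization; entropy −Σ p·ln p and inverse
  difference moment Σ pᵢⱼ/(1+(i−j)²).
* **Group statistics** — Student t-test / one-way ANOVA on per-nucleus
  (or per-scene) metrics across conditions.

A rule-based classifier labels each nucleus `punctate` or `bouquet`
(large + irregular or multi-lobed aggregates), an image-level analog of
manual aggregate-morphology scoring.

## Worked example

Generate two small batches of synthetic scenes from the documented
phenotype presets (`ala10`: few/small/round/slow puncta, low mRNA
co-sequestration; `ala16`: many/large/irregular/fast, high
co-sequestration), run the full pipeline, and compare groups:

```python
from punctakit import (AnalysisConfig, compare_groups, generate_mrna_channel,
                       generate_timelapse, preset, run_pipeline)

config = AnalysisConfig()
config.dynamics_times_s = (0.0, 2.0, 4.0)

scenes = []
for group in ("ala10", "ala16"):
    for seed in range(3):
        params = preset(group, seed=seed)
        scene, truth = generate_timelapse(params, n_frames=3, frame_interval_s=2.0)
        scene, truth = generate_mrna_channel(scene, truth, params)
        scene.name = f"{group}_{seed}"
        scenes.append((scene, group))

bundle = run_pipeline(config, scenes, out_dir="results/demo")

for table, metric in [
    (bundle.nuclei, "puncta_count"),
    (bundle.nuclei, "mean_area"),
    (bundle.nuclei, "mean_circularity"),
    (bundle.nuclei, "aggregation_index"),
    (bundle.dynamics, "white_to_colored_ratio"),
    (bundle.coloc, "m2"),
]:
    res = compare_groups(table, metric, test="t_test")
    print(f"{metric:24s} ala10={res.means[0]:.3f}  ala16={res.means[1]:.3f}  p={res.p_value:.2e}")
```

Output:

```
puncta_count             ala10=4.111  ala16=6.333  p=5.49e-02
mean_area                ala10=0.544  ala16=1.677  p=1.89e-05
mean_circularity         ala10=0.989  ala16=0.920  p=6.88e-03
aggregation_index        ala10=0.000  ala16=0.591  p=7.70e-11
white_to_colored_ratio   ala10=0.417  ala16=0.255  p=1.51e-03
m2                       ala10=0.349  ala16=0.746  p=2.22e-18
```

Reading the numbers: the pathogenic-like preset shows more puncta per
nucleus, ~3× larger mean punctum area, lower circularity, most of its
signal above the high (aggregate) threshold (index 0.59 vs 0.00), lower
frame-to-frame overlap (faster puncta), and a twice-higher fraction of
nuclear mRNA inside aggregate masks — each in the direction expected for
a pathogenic aggregation phenotype. With only 3 scenes per group the
count difference is not yet significant; 10 scenes per group push all
six comparisons below p = 0.01. Tidy CSVs (`puncta`, `nuclei`,
`dynamics`, `coloc`, `texture`) and a run manifest land in
`results/demo/`.

The same pipeline runs from the shell:

```sh
punctakit simulate --phenotype ala16 --seed 0 --frames 3 --out scenes/a16
punctakit measure scenes/a16/ala16_seed0.tif --out results/
punctakit dynamics scenes/a16/ala16_seed0.tif --times 0,2,4 --out results/
```

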