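# nbceus

Quantification of nanobubble contrast-enhanced ultrasound (CEUS) cine
loops for kidney inflammation imaging: pixel-wise time–intensity-curve
(TIC) parametric mapping, echo decorrelation-time (DT) mapping,
Haralick texture of the parametric maps, and the group/correlation
statistics to compare injured and control kidneys — plus a seeded
synthetic cine simulator that makes every stage verifiable without
animal data.

**Who it is for.** Researchers analysing dynamic contrast ultrasound
of small-animal kidneys (or similar organs) who need reproducible,
scriptable implementations of the standard perfusion/retention
read-outs, and a ground-truth simulator to validate them.

## The quantities computed

For each pixel (or the whole organ) the TIC is reduced to

* **TTP** — time-to-peak; **PI** — peak intensity;
* **AUC = AUrC + AUfC** — total area under the curve, split exactly at
  the peak into the rising (inflow) and falling (washout + retention)
  limbs.

For each acquisition window, the **decorrelation time** of a pixel is
the lag τ at which the autocorrelation of its z-scored signal first
falls to 0.5 (linearly interpolated). Freely circulating agent
decorrelates within a frame or two; extravasated, stationary agent
keeps r(k) high for tens of seconds. For an AR(1) fluctuation with
coefficient ρ, DT = ln(0.5)/ln(ρ)·Δt analytically, which anchors the
tests. DT maps are summarized by mean DT, spatial DT variance
(patchiness) and the number of pixels with DT > 10 s.

Texture of a parametric map comes from a mask-aware gray-level
co-occurrence matrix (32 levels, four distance-1 directions,
symmetric): contrast Σp(i,j)(i−j)², energy Σp², homogeneity
Σp/(1+|i−j|), correlation Σ(i−μᵢ)(j−μⱼ)p/(σᵢσⱼ).

Groups are compared with Welch's t-test and **Glass's Δ** =
(mean_injury − mean_control)/SD_control; imaging metrics are
correlated with histology read-outs via Pearson r on log10 scales,
with per-animal averages over the early (Aq 1–3) and late (Aq 4–6)
phases.

## Worked example

```python
from nbceus.pipeline import DT_METRICS, cohort_dt_table
from nbceus.stats import compare_groups, phase_average
from nbceus.synthetic import generate_cohort

cohort = generate_cohort(4, 6, seed=2024)          # 4 control + 6 injury
dt = cohort_dt_table(cohort)                       # per-acquisition DT metrics
phases = phase_average(dt[dt["metric"].isin(DT_METRICS)])
print(compare_groups(phases))
```

prints (abridged; from `examples/05_group_statistics.py`):

```
  early mean_dt_s          sham     0.84  iri     0.83  p=0.5701  delta=  -0.5
  late  mean_dt_s          sham     0.62  iri     2.81  p=0.0014  delta=  26.7
  early n_above_threshold  sham     0.08  iri     0.11  p=0.8065  delta=   0.2
  late  n_above_threshold  sham    22.33  iri   261.72  p=0.0021  delta=  33.5
```

Early-phase DT metrics overlap between groups (p ≫ 0.05), while
late-phase retention separates them with very large effects — the
injury signature the pipeline is built to detect. The late-phase
metrics correlate with the synthetic histology read-outs at r ≈ 0.7–0.9
on the log-log scale (the generator's latent coupling is 0.8).

The `examples/` directory holds one short script per capability:
simulation, parametric maps, DT maps, texture, statistics. Each builds
a small input, runs the method and prints annotated numbers.

## Command line

The same stages are available as a thin CLI for file-based workflows
(multi-page TIFF cine stacks, single-page TIFF masks, CSV tables):

```bash
nbceus simulate --n-sham 4 --n-iri 6 --seed 1 --out data/
nbceus parametric --cine data/cine/iri-01_aq*.tif \
    --mask data/masks/iri-01_mask.tif --schedule data/schedule.json --out maps/
nbceus dtmap --cine data/cine/iri-01_aq*.tif \
    --mask data/masks/iri-01_mask.tif --schedule data/schedule.json --out dt/
nbceus run --seed 1 --out run1/      # full synthetic pipeline end to end
```

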