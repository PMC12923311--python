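"""Haralick texture of parametric maps via the co-occurrence matrix.

Quantizes each map to 32 gray levels inside the kidney mask, accumulates
a symmetric GLCM over the four distance-1 directions, and derives
contrast (local differences), energy (uniformity), correlation (spatial
organisation) and homogeneity (smoothness).  Patchy injury raises
contrast and lowers energy relative to the uniform control kidney.
"""

from nbceus.synthetic import generate_cohort
from nbceus.texture import map_texture
from nbceus.tic import parametric_maps

cohort = generate_cohort(1, 1, seed=8)

print(f"{'animal':10s} {'map':6s} {'contrast':>9s} {'energy':>7s} {'corr':>6s} {'homog':>6s}")
for series, truth in cohort:
    maps = parametric_maps(series)
    for name in ("ttp_s", "aufc"):
        tv = map_texture(maps[name], series.mask, levels=32)
        print(f"{truth.animal_id:10s} {name:6s} {tv.contrast:9.2f} "
              f"{tv.energy:7.3f} {tv.correlation:6.2f} {tv.homogeneity:6.3f}")

print("\nhigher contrast / lower energy for the injury animal reflects the")
print("spatially heterogeneous (patchy) perfusion and retention pattern.")
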