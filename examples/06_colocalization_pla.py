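"""Granule colocalization (Costes-threshold Pearson) and PLA focus density.

Synthetic two-channel granule images with a known colocalized fraction show
how the Pearson coefficient over Costes-thresholded pixels tracks true
colocalization; thresholded connected components quantify proximity-ligation
foci per um^2.
"""

import numpy as np

from spckinetics import imaging

print("coloc_fraction   Pearson(all)   Pearson(above Costes thresholds)")
for frac in (0.0, 0.5, 1.0):
    rs_all, rs_above = [], []
    for seed in range(5):
        pair = imaging.generate_granule_image(
            40, frac, shape=(128, 128), noise_sd=0.05, seed=seed
        )
        res = imaging.costes_threshold(pair)
        rs_all.append(res.pearson_all)
        rs_above.append(res.pearson_above)
    print(f"    {frac:.1f}          {np.mean(rs_all):+.3f}          "
          f"{np.nanmean(rs_above):+.3f}")

# PLA: known focus density round trip
rng = np.random.default_rng(1)
shape, px = (256, 256), 0.5  # 128 x 128 um field
n = 40
img = np.zeros(shape)
for y, x in zip(rng.uniform(3, shape[0] - 3, n), rng.uniform(3, shape[1] - 3, n)):
    img[int(y) - 1 : int(y) + 2, int(x) - 1 : int(x) + 2] = 1.0
foci = imaging.detect_foci(img, threshold_method=0.5)
res = imaging.pla_density(foci, np.ones(shape, bool), pixel_size=px)
print(f"\nPLA: {res.n_foci} foci over {res.mask_area_um2:.0f} um^2 -> "
      f"{res.density_per_um2:.4f} /um^2 (placed {n / res.mask_area_um2:.4f})")
print(
    "\nPearson over Costes-thresholded pixels rises with the true colocalized\n"
    "granule fraction; PLA density recovers the placed focus density."
)
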