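# condquant

Quantification toolkit for biomolecular-condensate imaging assays and pooled
CRISPR screens, built for studies of liquid–liquid phase separation in cells
— e.g. transcription-factor oncofusion condensates in translocation renal
cell carcinoma.  It implements, as tested reusable code, four bespoke
readouts that are usually done ad hoc in ImageJ or spreadsheets:

1. **LacO-array recruitment statistic.**  A GFP-fused bait tethered at a
   genomic LacO repeat array forms one bright nuclear punctum; recruitment of
   an mCherry-fused prey is scored by the enrichment ratio

   *I*<sub>peak</sub> / *I*<sub>periphery</sub>,

   where the mCherry slice is smoothed with a 5×5 all-ones kernel (J5),
   *I*<sub>peak</sub> is the mean of the four pixels edge-adjacent to the
   smoothed peak inside the punctum, and *I*<sub>periphery</sub> is the mean
   of the two radial-profile values just outside the punctum radius.  The
   radius is estimated from the GFP radial profile as the first distance at
   which the outward intensity derivative stops decreasing.  A ratio > 1
   calls the pair interacting.
2. **Droplet readouts.**  Otsu + 8-connected segmentation of droplet images,
   per-droplet areas, droplet-positive cell fractions, line profiles, and
   object-level co-condensation efficiency (fraction of reference-channel
   droplets carrying partner-channel signal).
3. **FRAP kinetics.**  Percent recovery (I − I<sub>min</sub>)/(I<sub>0</sub> −
   I<sub>min</sub>) × 100 after background subtraction, fit with
   R(t) = 100·M·(1 − e<sup>−kt</sup>) to report the mobile fraction M and
   half-time t<sub>½</sub> = ln2/k.
4. **Pooled-screen scoring.**  Guide counts normalized to
   (count/total) × 100,000, per-sgRNA log₂(T<sub>late</sub>/T₀), gene-level
   medians, and a shared vs. cell-line-specific partition of depleted
   candidates.  A small utility computes xenograft tumor volume
   (length × width² × 0.52).

Every stage is paired with a seeded synthetic-data generator
(`condquant.synthetic`) producing scenes, droplet fields, FRAP traces and
negative-binomial count matrices with known ground truth, so the whole
pipeline is validated end to end against simulations and brute-force oracles.

## Worked example

```python
from condquant import synthetic as syn, laco, frap

spec = syn.PunctumSpec(center_xy=(32.0, 32.0), z_index=4, sigma_px=3.0,
                       amplitude_gfp=100.0, amplitude_mch=50.0,
                       noise_sd=2.0, seed=7)
scene = syn.make_laco_scene(spec)          # two-channel 9x64x64 z-stack
m = laco.measure_enrichment(scene, r_max=20)
print(m.slice_index, m.center, m.radius_px, round(m.ratio, 2), m.interacting)
# 4 (32, 32) 10 4.82 True

fit = frap.analyze_trace(syn.make_frap_trace(syn.FrapSpec(noise_sd=2.0, seed=7)))
print(round(fit.mobile_fraction, 3), round(fit.rate_k, 4), round(fit.t_half, 2))
# 0.613 0.098 7.07
```

The enrichment measurement found the punctum on slice 4 at pixel (32, 32)
with a 10 px radius and a 4.8-fold mCherry enrichment over the periphery —
an interacting pair (the scene was simulated with amplitude_mch = 50 over a
background of 10).  The FRAP fit recovered the simulated mobile fraction
0.6 and rate 0.1 s⁻¹ to within a few percent from a trace with 2% noise.

The same stages are available from a shell:

```bash
condquant simulate laco --seed 7 --out-dir scenes/
condquant laco --gfp scenes/scene_000_gfp.tif --mch scenes/scene_000_mch.tif \
    --r-max 20 --out laco.csv
condquant frap --in trace.csv --bleach-index 5 --out fit.csv
condquant screen score --counts counts.tsv --samples samples.csv --out-dir scored/
condquant tumor-volume --length 10 --width 8   # 332.8
```

All randomness flows from `--seed`; re-running any stage with the same seed
and config produces byte-identical outputs.

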