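# periquant

Histomorphometry of periimplant bone regeneration, as a tested Python
package. `periquant` quantifies how much new bone forms around a titanium
implant placed in a trephine bone defect, working from calibrated 2-D
colour images of stained cross-sections, plus the surrounding analytics a
study of implant-surface coatings needs: immunofluorescence area
quantification (CD31 as an angiogenesis readout), growth-factor
loading/release arithmetic for coated implants, and the nonparametric
paired statistics used for inference across a small animal cohort.

Because real histology images of such studies are rarely deposited, the
package ships a **synthetic phantom generator** that renders
Alizarin-Red-like stained cross-sections and two-channel fluorescence
fields with *exact, pixel-level ground truth* — every estimator in the
package is validated against phantoms whose true masks and metric values
are known by construction.

## What it computes

All measurements start from a calibrated image (physical pixel area
*a* in μm²/pixel; the study default is *a* = 17.43, i.e. a pitch of
√*a* ≈ 4.17 μm) and aligned binary masks for the implant *I*, the
trephine-defect ROI *D*, and stained bone *B*:

- **Bone formation** BF = |B ∩ D| · *a* · 10⁻⁶ mm², and **bone density**
  BD = 100 · |B ∩ D| / |D| % (pixel counting in the defect ROI).
- **Bone–implant contact** BIC: the implant mask is enlarged by one pixel
  (8-connectivity), limited to the defect, giving the surface ring
  S = (I ⊕ 3×3) \ I ∩ D; BIC = 100 · |S ∩ B| / |S| %. This mask-dilation
  statistic is verified against a brute-force adjacency enumeration.
- **Periimplant layers**: the exact Euclidean distance transform (in μm)
  labels three concentric 100 μm bands — immediate, intermediate, remote —
  inside the defect; bone area is reported per band. The bands partition
  the 300 μm zone exactly (half-open distance bins).
- **CD31-positive area** = positive-pixel count · *a* μm², from an
  intensity threshold (Otsu by default) on the target fluorescence channel.
- **Per-disc aggregation**: mean ± sample SD over a disc's 3–4 sections.
- **Inference**: Wilcoxon signed-rank (asymptotic z without continuity
  correction, and exact 2ⁿ sign-assignment enumeration), Friedman test with
  tie correction, Bonferroni α-splitting, and z-approximation sample sizes.
- **Release analytics**: loading by supernatant depletion
  ((V·c − residual)/area), cumulative release curves, released fractions,
  with the study's loading/release tables packaged as fixtures.

## Worked example

```python
import numpy as np
from periquant import (PhantomSpec, generate_histology_phantom,
                       segment_implant, segment_bone, build_mask_set,
                       section_metrics)

spec = PhantomSpec(contact_fraction=0.62,
                   bone_fraction_per_layer=(0.70, 0.55, 0.45, 0.40),
                   seed=42)
image, truth = generate_histology_phantom(spec)

implant = segment_implant(image)
bone = segment_bone(image, implant_mask=implant)
masks = build_mask_set(implant, bone, image.pixel_area, spec.defect_width_mm)
sm = section_metrics(masks, image.pixel_area, "demo")
print(f"bone area {sm.bone_area_mm2:.3f} mm^2, density "
      f"{sm.bone_density_pct:.1f} %, BIC {sm.bic_pct:.1f} %")
```

prints

```
bone area 2.894 mm^2, density 48.1 %, BIC 62.0 %
```

— the measured BIC of 62.0 % matches the planted contact fraction of 0.62
exactly (truth: 2.894 mm², 48.1 %, 62.0 %), because at this noise level the
colour segmentation recovers the planted bone mask pixel-perfectly.

A paired cohort with a strong planted effect reproduces the hallmark
small-cohort p-value: with n = 6 units and all six within-unit differences
of one sign, the asymptotic signed-rank test gives p = 0.028 — the floor
attainable at that sample size (the exact-enumeration floor is
2/64 = 0.031):

```python
from periquant import generate_paired_cohort, wilcoxon_signed_rank
data = generate_paired_cohort(6, 2, effect_sizes=np.array([0.0, 8.0]),
                              noise_sd=2.0, seed=7)
print(wilcoxon_signed_rank(data[:, 1], data[:, 0]).p_two_sided)  # 0.028
```

The packaged release tables summarise to released fractions per condition
(`periquant release` on the command line); the four collagen/heparin-PEM
growth-factor conditions span 27.7–39.1 %.

There is also a CLI: `periquant phantom histology|fluorescence`,
`periquant segment`, `periquant measure`, `periquant stats`,
`periquant release`, and `periquant run` for a full phantom-cohort
pipeline writing per-section/per-disc CSVs, pairwise p-value matrices and
a reproducibility manifest.

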