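# gnladc

Gradient-nonlinearity (GNL) b-value bias modelling and on-scanner-style
correction (GNC) of apparent diffusion coefficient (ADC) maps for
multi-station bone-marrow diffusion MRI, together with a synthetic phantom
and virtual-cohort generator so the whole analysis runs end to end without
any scan data.

## Who this is for

Quantitative-MRI researchers who measure bone-marrow ADC over large fields
of view (lumbar spine plus pelvis/femur, two couch stations) and need to
separate *biological* ADC heterogeneity across bone sites from the
*technical* spatial bias that gradient nonlinearity imprints on the applied
diffusion weighting — and who need to know how much of their test-retest
variability is simply repositioning moving anatomy through that bias field.

## The model

Each gradient coil field is expanded in real solid harmonics (Schmidt
semi-normalized, reference radius R0) and normalized by the nominal
gradient, so the GNL tensor

    L_ab(r) = ∂f_a / ∂x_b ,   L(0) = I

maps nominal to actual gradient vectors.  For a diffusion direction u_k the
actual b-value is scaled by c_k = u_kᵀ(LᵀL)u_k, and for a trace (three
orthogonal directions) acquisition by the triad-independent

    c̄(r) = tr(LᵀL) / 3 .

b-maps store c̄ as integers scaled to 1E4 at the isocenter; the percent
bias map is 100·((v/1E4) − 1).  Because bone marrow is modelled isotropic,
the measured trace ADC is c̄·ADC_true and the correction is the voxelwise
division ADC_GNC = ADC / c̄.  Two-point mono-exponential fitting
(ADC = ln(S0/S_b)/b, reported in μm²/ms), ROI histogram statistics with an
ADC > 0.01 μm²/ms floor, site groupings (trochanter / ilium /
mid-vertebrae L2-L4 / edge-vertebrae T11-L1, L5, S1), heterogeneity CV, and
Bland-Altman limits of agreement (1.96·SD of test-retest differences)
complete the pipeline.

The true spherical-harmonic coefficients of clinical scanners are
proprietary; the package ships a documented representative coil model (odd
orders 3 and 5 per coil) whose trace bias spans about −10% at 200 mm S-I to
+8.5% at 200 mm R-L — the regime typical of torso-size fields of view.

## Worked example: phantom validation

```python
import numpy as np
from gnladc import (PhantomSpec, apply_gnc, bias_percent, default_model,
                    fit_adc, fractional_adc_bias, generate_phantom, make_bmap)

model = default_model()
phantom = generate_phantom(PhantomSpec.spag_room_temperature(), model)
adc = fit_adc(phantom.dwi)                       # uncorrected two-point ADC
bmap = make_bmap(model, phantom.dwi.s0)          # 1E4-scaled c-bar map
adc_gnc = apply_gnc(adc, bmap)                   # GNL-corrected ADC

beta = bias_percent(bmap).data[phantom.mask]
print(f"b-value bias over phantom FOV : {beta.min():+.1f}% .. {beta.max():+.1f}%")
u = adc.volume.data[phantom.mask]; c = adc_gnc.volume.data[phantom.mask]
print(f"uncorrected ADC               : {u.min():.3f} .. {u.max():.3f} um^2/ms")
print(f"corrected ADC                 : {c.min():.3f} .. {c.max():.3f} um^2/ms (truth 2.130)")
fb, fbmask = fractional_adc_bias(adc, adc_gnc)
err = np.abs(fb.data[phantom.mask & fbmask] - bias_percent(bmap).data[phantom.mask & fbmask])
print(f"max |measured - model bias|   : {err.max():.2e} %")
```

prints

```
b-value bias over phantom FOV : -8.7% .. +1.4%
uncorrected ADC               : 1.944 .. 2.161 um^2/ms
corrected ADC                 : 2.130 .. 2.130 um^2/ms (truth 2.130)
max |measured - model bias|   : 1.07e-14 %
```

The uniform gel phantom (true diffusivity 2.13 μm²/ms) picks up a −8.7% to
+1.4% spread in apparent ADC purely from the nonlinear gradients; dividing
by the b-map restores a flat map at the true value, and the *measured*
fractional ADC bias 100·(ADC − ADC_GNC)/ADC_GNC reproduces the model bias
map voxel for voxel.

A virtual cohort works the same way at larger scale:

```python
from gnladc import CohortSpec, build_cohort_table, generate_cohort, summarize_groups
cohort = generate_cohort(CohortSpec(n_subjects=20, seed=7), model)
table = build_cohort_table(cohort, model)        # subject x timepoint x site
print(summarize_groups(table))
```

There is also a CLI (`gnladc simulate-phantom / simulate-cohort / bmap /
correct / analyze / report`) that writes MHD volumes, tidy CSV tables, and
Bland-Altman / box-plot figures.

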