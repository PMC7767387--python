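# lodgemap

Mapping typhoon-lodged rice from dual-polarimetric SAR and multispectral
optical imagery.

Rice lodging — the permanent displacement of stems from vertical after wind
and heavy rain — changes both the radar backscatter of the canopy (less
attenuation in VV, stronger volume scattering in VH) and its reflectance
(brighter across VIS–NIR–SWIR as chlorophyll and canopy structure degrade).
`lodgemap` implements a complete pipeline that exploits these signals:

1. **SAR feature extraction** from per-pixel dual-pol covariance matrices
   `C2 = [[C11, C12], [C12*, C22]]`: backscatter σ⁰(VV), σ⁰(VH) in dB, their
   dB-domain combinations VV + VH, VV − VH, VH/VV, and the eigenvalue
   family — mean alpha angle ᾱ = Σᵢ Pᵢ αᵢ, entropy H = −Σᵢ Pᵢ log₂ Pᵢ,
   anisotropy A = (λ₁−λ₂)/(λ₁+λ₂), span Tr(C2), and Shannon entropy
   SE = 2 ln(πe·Tr(C2)/2) + ln(4·det(C2)/Tr(C2)²) — plus a 3×3
   local-statistics Lee speckle filter.
2. **OSPL screening** of "optimal sensitive parameters for lodging".  With
   LB/LA (HB/HA) the lodged (healthy) plot means before/after the event, a
   parameter is kept when it passes three steps:
   - sensitivity  γ = |LBav−LAav|/|LBav+LAav| − 1.5·|HBav−HAav|/|HBav+HAav| > 0,
   - consistency  β ≥ 9, where β is the majority-sign count of the per-plot
     differences εᵢ = LAᵢ − LBᵢ over the ten lodged plots,
   - separability: after the event, the higher-mean class's lower quartile
     must exceed the lower-mean class's maximum and the lower-mean class's
     upper quartile must fall below the higher-mean class's minimum.
   Survivors split into OSF (SAR features) and OSI (optical indices).
3. **Classification**: a Gaussian maximum-likelihood classifier derives the
   rice mask from the optical bands; a 100-tree Random Forest
   (2 candidate features per split, node-impurity stop at Gini 0.2) maps
   lodged vs. healthy rice under three feature cases — OSF, OSI, OSF–OSI.
4. **Evaluation**: confusion matrix with producer's/user's accuracy, overall
   accuracy and Cohen's kappa.

Because the original satellite scenes are not redistributable, the package
ships a synthetic-scene generator that reproduces the class-conditional
before/after statistics of the reference lodging campaign (gamma-distributed
speckle on SAR intensities, Gaussian noise on reflectance, labelled sample
plots and train/validation pixel sets), so the whole pipeline runs
end-to-end with no downloads.

## Worked example

```python
from lodgemap.screening import gamma_sensitivity
from lodgemap.reference import REFERENCE_PLOT_MEANS

s = REFERENCE_PLOT_MEANS["VV"]       # plot-mean σ⁰(VV), dB
print(round(gamma_sensitivity(s.lodged_before, s.lodged_after,
                              s.healthy_before, s.healthy_after), 3))
# 0.011  -> positive: VV backscatter is sensitive to lodging
```

Running the full pipeline on a synthetic 256×256 scene:

```bash
python analysis/03_classify_and_evaluate.py --seed 0
```

prints, for the fused SAR+optical case (rows = classification, columns =
ground truth, lodged = 0, healthy = 1):

```
=== case OSF_OSI (13 features) ===
GT           0    1  UA (%)
CC
0          428   10    98.0
1           52  937    95.0
PA (%)      89   99     NaN
OA (%)    96.0  NaN     NaN
Kappa   0.9005  NaN     NaN
```

i.e. 428 of 480 truly lodged validation pixels are mapped as lodged
(producer's accuracy 89%), 98% of pixels mapped lodged are correct (user's
accuracy), overall accuracy 96% and kappa 0.90.  The SAR-only case reaches
85% OA and the optical-only case 97% on the same scene; the numbered
scripts under `analysis/` walk through screening (`01`, `02`),
classification (`03`) and the ten-seed fusion-ranking experiment (`04`),
writing their tables under `results/`.

A CLI mirrors the pipeline stage by stage:

```bash
lodgemap run-all --seed 0 --out out/
lodgemap simulate --seed 0 --out out/scene        # or stage by stage
lodgemap features --scene out/scene --out out/features
```

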