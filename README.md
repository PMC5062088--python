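# echoqdi

Quantitative ultrasound tissue characterization for grading nonalcoholic
fatty liver disease (NAFLD) from raw radiofrequency (RF) frames, with a
point-scatterer phantom simulator so the whole pipeline can be developed and
validated without clinical data.

Fatty infiltration changes three acoustic properties of liver parenchyma at
once: B-mode texture/echogenicity, the statistics of the backscattered
envelope, and frequency-dependent attenuation. `echoqdi` measures one index
for each and fuses them into a single ordinal score:

1. **Texture.** The 8-bit B-mode image (Hilbert envelope, 40 dB log
   compression) is scanned with a 3 × 3 mm² window; per window a gray-level
   co-occurrence matrix `p(i, j)` (d = 1, θ ∈ {0°, 45°, 90°, 135°},
   symmetric, 256 levels) yields three Haralick features,
   autocorrelation `AC = Σᵢⱼ i·j·p(i,j)`, sum average
   `SA = Σₖ k·p_{x+y}(k)` and sum variance `SV = Σₖ (k−SA)²·p_{x+y}(k)`.
   ROI-averaged (AC, SA, SV) triplets are projected onto the leading Fisher
   discriminant → the **LDA-texture index**.
2. **Backscattering.** The envelope SNR, `E(R)/√(E(R²)−E(R)²)`, equals
   `√(π/(4−π)) ≈ 1.91` for fully developed (Rayleigh) speckle; sparse
   scatterers push it below, clustered/heterogeneous media above. A sliding
   3 × 3 mm² window maps the local **SNR**.
3. **Attenuation.** For a Gaussian pulse with power-spectrum variance σ²,
   linear-in-frequency attenuation β (dB·cm⁻¹·MHz⁻¹) shifts the echo center
   frequency down linearly with depth: `f_c(z) = f_o − 4σ²β_np·z` (round-trip
   path, β_np = β/8.686). Center frequencies are located as FWHM midpoints of
   block power spectra; the least-squares **CFDS slope** of `f_o − f_c(z)`
   versus depth is proportional to β.

Each feature is coded 0/1/2 by tertiles fitted on a training cohort and the
codes are summed into the **quantitative diagnostic index (QDI, 0–6)**.
Cohort-level utilities provide Mann–Whitney AUC with bootstrap CIs,
multinomial-logistic odds ratios (mild disease as reference), Pearson
correlations, and ANOVA with a linear trend test.

## Worked example

Simulate a severe-NAFLD phantom (dense, strongly attenuating scatterers) and
measure all three feature families:

```sh
$ echoqdi simulate --class-label severe --seed 7 --out frame.h5
wrote frame.h5 (severe, seed 7)
$ echoqdi texture frame.h5
{"ac": 4.74129020994729, "sa": 3.181642649232183, "sv": 17.446055777617055}
$ echoqdi snr frame.h5
{"snr": 1.9638179280895338}
$ echoqdi cfds frame.h5 --depth 2:7
{"cfds_slope": 0.08801508622477085, "beta_db": 1.1474777603323996, "r2": 0.913951607899847}
```

Reading the numbers: the ROI texture features are low because the severe
phantom's strong attenuation (β = 1.1 dB·cm⁻¹·MHz⁻¹) darkens the 5 cm-deep
ROI under max-normalized 40 dB compression; the ROI envelope SNR sits at the
Rayleigh value (the phantom has ~20 scatterers per resolution cell, i.e.
fully developed speckle); and the CFDS slope of 0.088 MHz/cm converts to a
recovered attenuation of 1.15 dB·cm⁻¹·MHz⁻¹, within 5% of the simulated
truth, with r² ≈ 0.91 for the linearity of the downshift.

The full chain (simulate a labelled cohort → extract features → fit LDA and
tertiles on the training split → score → evaluate) runs from a single config:

```sh
echoqdi pipeline --config run.toml
```

writing `features.csv`, `model.json` and `report.json` (per-class feature
means, trend tests, AUCs, odds ratios), deterministically for a fixed seed.

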