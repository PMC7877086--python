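# ecvtask

ECG-less, free-breathing myocardial T1 and extracellular-volume (ECV) mapping
on a digital rat-heart phantom, using a motion-resolved low-rank tensor
reconstruction of a continuous IR-FLASH acquisition.

The package implements the full chain:

1. **`ecvtask.sequence`** — closed-form IR-prepared FLASH signal model
   (inversion → N low-flip readouts per recovery period, periodic steady
   state), a joint pre/post-contrast curve dictionary over
   (T1_pre > T1_post, flip angle, inversion efficiency), and its SVD
   temporal basis `U_T1`.
2. **`ecvtask.phantom`** — beating (≈300 bpm) / breathing (≈60 cpm) 2D
   short-axis phantom and k-space simulator: one fully-sampled
   frequency-encode line per TR, even readouts on the k-space center line
   (training data), odd readouts at Gaussian-density random ky (imaging
   data), two scans (pre/post Gd), complex Gaussian noise, full per-readout
   ground truth for scoring.
3. **`ecvtask.realtime`** — SVD real-time temporal basis from the training
   lines, direct per-ky-row least-squares real-time spatial basis, and
   modified-k-means motion binning (per-readout-index ensemble references
   cancel the T1-recovery contrast; band-split + rate-regularized phases;
   k-means into 5 respiratory × 10 cardiac bins shared by both scans).
4. **`ecvtask.tensor`** — 4-way training tensor (k × cardiac × respiratory ×
   832 inversion times), Bloch-constrained low-rank tensor completion,
   HOSVD factors, `Phi = C_(1)(U_c ⊗ U_r ⊗ U_T1)^T`, and wavelet-regularized
   (FISTA) / Tikhonov-damped spatial-basis recovery with an in-package
   orthogonal db4 DWT.
5. **`ecvtask.mapping`** — joint 5-parameter pixel-wise T1 fitting
   (T1_pre, T1_post, shared M0, α, B), M0-thresholded blood selection,
   α = 0 (inflow) blood fitting, ECV = (1−HCT)·ΔR1_myo/ΔR1_blood·100,
   affine-R1-calibration invariance, and reporting statistics (Welch,
   Pearson, Bland–Altman, ICC(2,1), within-subject CoV).
6. **`ecvtask.io` / `ecvtask.cli`** — HDF5 raw-data layout, NIfTI-1 maps,
   YAML configs, presets, and the `ecvtask` command line.

## Command line

```sh
ecvtask simulate --preset fast-test --seed 7 -o raw.h5
ecvtask bin      --preset fast-test raw.h5 -o bins.h5
ecvtask recon    --preset fast-test raw.h5 bins.h5 -o recon.h5
ecvtask fit      --preset fast-test raw.h5 bins.h5 recon.h5 --hct 0.42 -o maps/
ecvtask report   group_a.txt group_b.txt -o stats.json
ecvtask e2e      --preset fast-test --seed 7 -o out/
```

Presets: `protocol` (128×128, FOV 40 mm, TR 7 ms, flip 5°, 85 IR
blocks of N = 416 readouts, 10 cardiac × 5 respiratory bins),
`fast-test` (matrix 64, 48 IR blocks, same timing), `tiny` (smoke tests).
`e2e` runs simulate → bin → recon → fit → ECV and prints a summary JSON
with ground-truth recovery scores.

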