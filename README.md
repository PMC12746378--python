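# subtherm

Subvoxel susceptibility-artifact correction for PRFS MR thermometry, with
CEM43 dosimetry and lesion-overlap evaluation.

## The problem

Real-time MR thermometry during thermal ablation (e.g. microwave liver
ablation) maps temperature change from the proton resonance frequency shift
(PRFS):

    dT = dPhi / (alpha * B0 * gamma * TE),        alpha ~ -0.0094 ppm/degC.

When tissue boils, gas bubbles near the ablation probe perturb the magnetic
susceptibility and imprint a dipole-shaped phase pattern on the images. Read
through the PRFS relation, this appears as temperature errors of tens of
degrees — negative lobes aligned with B0, positive equatorial lobes — which
wreck the cumulative thermal dose (CEM43) and hence the predicted lesion.

## The method

The susceptibility change adds a term to the measured relative difference
field (RDF, ppm): `RDF_meas = alpha*dT_true + d (*) chi`, where `d` is the
unit dipole kernel

    d(x) = (1/4pi) * (3 (x.n)^2 - |x|^2) / |x|^5,     d(0) = 0,

and `n` the B0 direction. `subtherm` estimates a *subvoxel* susceptibility
distribution `chi` (the acquisition lattice refined by a factor 2, slice
pitch including the inter-slice gap) that reproduces the stable component of
the artifact, then subtracts the forward-simulated artifact from every
corrupted dynamic:

1. **Prior** — mean of five dynamics after bubble stabilization minus the
   mean of five dynamics before onset, converted to RDF.
2. **Masks** — a bubble mask `M_b` inside the probe signal void (candidate
   sources) and a disjoint ROI mask `M_ROI` (probe line dilated in-plane by
   nine voxels, minus `M_b`) selecting the data voxels.
3. **Weights** — per-voxel inverse RDF noise, from the magnitude SNR.
4. **Bounded least squares** — minimize `||A chi - b||_2` with
   `chi in [0, 10] ppm`, where `A = M_ROI . W . P . D_A . D_s` composes
   dipole convolution on the subvoxel grid, block-averaging back to voxel
   resolution, weighting, and ROI cropping. The correction runs per data
   slice with candidate sources in the central and adjacent slice slabs (an
   `all_slices` mode solves a single stack-wide problem instead).
5. **Dosimetry** — 0.04 Hz first-order Butterworth temporal filtering, then
   Sapareto CEM43 from a 37 degC baseline with the 240-equivalent-minute
   lesion threshold; Dice / total-overlap / false-negative-rate and
   principal-axis geometry against a reference lesion mask.

A synthetic module generates the reference numerical phantom and full
dynamic acquisitions (heating field, sudden bubble event, probe signal
void, complex noise) with stored ground truth, so every stage is testable
without scanner data. A supplementary detector locates the artifact onset
by counting voxels in the negative temperature lobes along B0.

## Worked example

Three inversion layouts are compared on the numerical phantom
(2.3 x 2.3 x 4.5 mm voxels, 1.15 x 1.15 x 2.25 mm subvoxels, random bubble
susceptibility in the two central and four adjacent subslices): Method 1
(voxel grid, central slice), Method 2 (subvoxel grid, central subslices),
Method 3 (subvoxel grid, central + adjacent subslices).

```python
import numpy as np
from subtherm import (AcquisitionParams, PhantomSpec, make_phantom,
                      run_method, evaluate_artifact_error)

params = AcquisitionParams(b0=1.5, te=0.015)   # 1.5 T protocol
spec = PhantomSpec(seed=1)                     # 128x128x7 phantom
chi_true, artifact = make_phantom(spec, params)
print(f"peak |artifact| = {np.abs(artifact.values).max():.1f} degC, "
      f"max chi = {chi_true.values.max():.2f} ppm")
for method in (1, 2, 3):
    est = run_method(method, artifact, spec, params)
    err = evaluate_artifact_error(artifact, est, spec)
    print(f"Method {method}: RMSE = {err['rmse_c']:.2f} degC, "
          f"mean|err| = {err['mean_abs_c']:.2f} +- {err['sd_abs_c']:.2f} degC")
```

prints

```
peak |artifact| = 35.0 degC, max chi = 1.36 ppm
Method 1: RMSE = 3.06 degC, mean|err| = 2.72 +- 1.39 degC
Method 2: RMSE = 1.43 degC, mean|err| = 1.15 +- 0.85 degC
Method 3: RMSE = 0.00 degC, mean|err| = 0.00 +- 0.00 degC
```

The errors are evaluated over a 10 x 10 voxel window covering the artifact
on the central slice, excluding the two lines that contain the sources.
Subvoxel resolution (Method 2) and adjacent-slice sources (Method 3) each
tighten the reconstruction; Method 3, whose support matches the phantom,
fits the noiseless central-slice data essentially exactly.

## Command line

```sh
subtherm simulate --seed 7 --out-dir fixtures/          # synthetic bundle
subtherm detect   --input T.nii.gz --roi roi.nii.gz --probe-line line.nii.gz
subtherm correct  --input T.nii.gz --magnitude M.nii.gz \
                  --probe-line line.nii.gz --onset 40 --out corrected.nii.gz
subtherm dose     --input corrected.nii.gz --dt 5.0 --out dose.nii.gz
subtherm evaluate --source lesion_td.nii.gz --target lesion_t1w.nii.gz \
                  --report report.json
subtherm run      --input T.nii.gz --magnitude M.nii.gz \
                  --probe-line line.nii.gz --out-dir out/   # full pipeline
```

All maps are NIfTI (time as the 4th dimension); configuration is a YAML
file validated against a strict schema (`subtherm.PipelineConfig`).

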