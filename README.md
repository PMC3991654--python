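# acmap

Spatially normalized **anatomical connectivity mapping** (ACM) from
diffusion MRI, end to end:

1. **multitensor** — per-voxel 1–2 tensor fitting (log-linear init +
   Levenberg–Marquardt with Cholesky-PSD parameterization), F-test model
   order selection, FA/MD maps.
2. **normalization** — application of deformation fields to tensor fields
   with preservation-of-principal-direction (PPD) reorientation, Jacobian
   determinant maps, ICV-scaled atrophy covariates, analytic field
   constructors for download-free testing.
3. **pico** — Bingham fiber-orientation uncertainty: moment-matched
   fitting, exact ACG-envelope sampling, Monte-Carlo calibration of
   concentrations vs tensor shape and SNR (default SNR 16).
4. **tractography** — probabilistic streamline propagation (1/10-voxel
   steps, probabilistic-nearest fODF interpolation, intra-voxel 180°
   doubling-back guard), batch-vectorized; `.trk`/TSV streamline I/O.
5. **acm** — exhaustive per-voxel seeding with streamline-visit counting
   plus the CV/SNR precision analysis over repeated estimations.
6. **groupstats** — 4 mm FWHM smoothing, voxel-wise GLMs
   (group/age/gender/atrophy), unequal-variance contrasts, permutation
   maxT small-volume FWE correction (Freedman–Lane), ROI medians,
   disability correlations with Bonferroni adjustment, lesion frequency
   maps, Dice overlap.
7. **phantoms** — synthetic tube/crossing/arc DWI phantoms with Rician
   noise and three-group patient-like cohorts (focal anisotropy-reducing
   lesions, disability scores coupled to tract damage).
8. **pipeline / cli** — config-driven runs with reproducibility manifests.

## CLI

```bash
acmap phantom --kind crossing --dims 24,16,16 --snr 16 --seed 1 --out-dir work/
acmap fit-tensors --dwi dwi.nii --bval s.bval --bvec s.bvec --mask mask.nii --out tensors.nii
acmap warp-tensors --field tensors.nii --def warp.nii --mask atlas_mask.nii --out atlas_tensors.nii
acmap calibrate --snr 16 --trials 1000 --seed 0 --out calib.json
acmap build-fodf --tensors atlas_tensors.nii --calib calib.json --out fodf.nii
acmap acm --fodf fodf.nii --mask atlas_mask.nii --n 500 --seed 42 --out acm.nii
acmap acm-precision --fodf fodf.nii --mask atlas_mask.nii --n-list 10,50,100,150,300,500,700 --repeats 5 --out precision.tsv
acmap glm --design design.tsv --contrast "RR=1,SP=-1" --roi roi.nii --perms 5000 --seed 7 --out-prefix rr_vs_sp
acmap dice --a sig.nii --b lesions.nii
acmap run --config pipeline.yaml
```

Volumes are NIfTI-1; gradients are FSL-style bval/bvec; design tables are
TSV; deformation fields are 4D NIfTI displacement volumes (mm, atlas→
subject pull-back convention).

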