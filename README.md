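# breathsync

Breathing synchronization of lung-perfusion SPECT to deep-inspiration CT,
with histogram-based SPECT lung volumetry and a phantom validation suite.

## The problem

Perfusion SPECT of the lung (^99m^Tc-MAA) is acquired over minutes of free
breathing; the chest CT it is fused with — for example when reading
Q-SPECT/CT for pulmonary embolism — is a deep-inspiration breath hold.
Averaged over the breathing cycle the diaphragm sits higher than on CT, so
the caudal lung on SPECT appears compressed cranially: fused images
disagree at the lung bases, and SPECT-derived lung volumes underestimate
the CT volume. This package corrects the mismatch using only four planar
images that can be added to a routine protocol (anterior + posterior views
at deep intake and at free breathing), with no gating hardware.

## The method

The correction is a two-parameter caudal scaling along the
superior→inferior axis: a baseline row `X` above which nothing moves, and
a magnification `Y` applied below it,

    r' = X + (r − X)·Y    (r ≥ X).

Per breathing phase the anterior and (left–right mirrored) posterior
planars are summed; the deep-intake sum is rigidly aligned (translation +
rotation, mean-squared-error cost) to the SPECT coronal sum projection and
the free-breathing sum is moved with the same transform. `(X, Y)` is then
found by exhaustive grid search (integer `X` over a caudal band, `Y` in
[0.8, 1.6] step 0.01) maximizing the normalized mutual information
NMI = (H(A)+H(B))/H(A,B) between the deep-intake image and the scaled
free-breathing image. The winning row remap is applied identically to
every line of the SPECT volume. Lung volumetry thresholds the volume at a
cutoff fraction (5–20%) of its maximum count; volume = supra-threshold
voxels × voxel volume.

Because no clinical dataset ships with the package, validation runs on
synthetic phantoms: paired breathing states of an ellipsoidal two-lung
activity distribution on a 128³ grid, related by a known `(X*, Y*)`,
blurred to SPECT resolution, optionally Poisson-noised, with a matching
CT and analytic truth volumes. See `docs/methods.md` for the model,
assumptions, and what the phantoms do and do not emulate.

## Worked example

Simulate a default phantom (true X = 45, Y = 1.2, true deep-inspiration
lung volume 3769.9 ml, free-breathing 3267.6 ml), synchronize the
free-breathing SPECT, and measure volumes:

```sh
breathsync simulate --seed 4 --out-dir case
breathsync sync --spect case/spect_free.nii \
    --planar-ant-deep  case/planar_deep_intake_anterior.nii \
    --planar-post-deep case/planar_deep_intake_posterior.nii \
    --planar-ant-free  case/planar_free_breathing_anterior.nii \
    --planar-post-free case/planar_free_breathing_posterior.nii \
    --out synced.nii --trace trace.csv
# INFO sync: X=42 Y=1.19 NMI=1.9066 (bins=64)
breathsync volume --spect case/spect_free.nii --sweep 0.05,0.10,0.15,0.20 --out vols_free.csv
breathsync volume --spect synced.nii         --sweep 0.05,0.10,0.15,0.20 --out vols_synced.csv
```

The estimated magnification 1.19 is one grid step from the generating 1.20;
the baseline 42 differs from the generating 45 by exactly the axial shift
the rigid alignment introduced (the baseline is defined in the aligned
frame — see `docs/methods.md`). Volumes at the 10% cutoff:

| volume                | 10% cutoff (ml) |
| --------------------- | --------------- |
| true deep-inspiration | 3769.9          |
| free-breathing SPECT  | 2912.4          |
| synchronized SPECT    | 3391.9          |

The free-breathing volume underestimates the truth by ~23%; after
synchronization the deficit shrinks to ~10%. Across the sweep
(`vols_synced.csv`) the 5% cutoff over- and the 20% cutoff under-estimates:
3962.0 / 3391.9 / 3002.2 / 2674.4 ml at 5/10/15/20%. Every run writes a
JSON manifest (config, input hashes, version, seed) next to its outputs.

`breathsync evaluate --cohort cohort.csv --out report.json` summarizes a
per-case volume table (mean ± SD per method) and tests each SPECT method
against CT with Dunnett's many-to-one comparison.

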