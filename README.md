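# olfparc

Connectivity-based parcellation of primary olfactory cortex and
whole-brain olfactory network mapping.

The human olfactory bulb projects directly to several cortical targets —
anterior olfactory nucleus (AON), olfactory tubercle (TUB), frontal and
temporal piriform cortex (PirF, PirT).  Whether these subregions form
distinct large-scale processing networks can be tested from resting-state
fMRI alone: if each subregion has its own whole-brain functional
connectivity profile, clustering seed voxels by those profiles should
recover the anatomical subdivisions.  `olfparc` implements that analysis
end to end for researchers in functional connectomics, plus a synthetic
multi-subject BOLD generator with planted ground truth so every stage is
testable without scanner data.

## What it computes

Given multi-subject 4D volumes on a common grid, a seed-region mask and a
brain mask:

1. **Cleaning** — grand-mean intensity normalization, polynomial
   detrending, nuisance (motion/WM/CSF) regression, FFT band-pass
   (0.008–0.1 Hz), Gaussian smoothing (σ = 3 mm).
2. **Connectivity** — per subject, Pearson r between every seed voxel and
   every brain voxel outside the seed; Fisher-z group averaging
   r̄ = tanh(mean(atanh r)); leave-one-out inter-subject stability with a
   dimension-aware significance threshold on r.
3. **Parcellation** — k-means on connectivity rows under the correlation
   distance d(x, c) = 1 − r(x, c) (standardized rows, k-means++ seeding,
   deterministic restarts), default k = 4, with a k = 3…6 sweep.
4. **Validation** — cluster × atlas-region overlap proportions, permutation
   z-scores (labels shuffled across ROI voxels, Gaussian fit to the null),
   Benjamini–Hochberg FDR, and optimal cluster→region assignment.
5. **Group networks** — per-cluster seed maps (Fisher z), one-sample
   sign-flipping permutation tests with TFCE enhancement
   (E = 0.5, H = 2) and max-statistic FWE control; unique/common network
   decomposition across seeds; atlas volume tables; lateralization index
   LI = (Z_L − Z_R)/(Z_L + Z_R) with a two-sided group test.

See `docs/methods.md` for the models, defaults, and validation design.

## Worked example

Run the full pipeline on the built-in synthetic study (10 subjects,
24×24×16 grid of 2 mm voxels, T = 300 at TR = 2 s, four 27-voxel planted
parcels with subdivision-specific and shared target networks, ρ = 0.5):

```python
import olfparc

cfg = olfparc.PipelineConfig(output_dir="run", simulate=True, rng_seed=0,
                             n_perm_group=1000, alpha=0.01)
report = olfparc.run_pipeline(cfg)
print(report["stages"]["parcellation"]["ari"])
print(report["stages"]["parcellation"]["min_matched_z"])
print(report["stages"]["connectivity"]["stability_mean"])
```

prints (a few minutes on one CPU):

```
1.0
10.28518...
0.79089...
```

The adjusted Rand index of 1.0 means the correlation-distance k-means
recovered the four planted parcels exactly from the group connectivity
matrix; the minimum permutation z of ≈ 10.3 across the matched
cluster→region pairs says every cluster sits in its anatomical region far
beyond what label shuffling produces (each cluster has exactly one region
at FDR q < 0.001); and the mean leave-one-out stability of ≈ 0.79 shows
individual connectivity profiles are highly consistent across these
synthetic subjects, justifying the Fisher-z group average.  Outputs (label
volumes, stability map, overlap tables, significance and unique/common
masks, provenance with parameters and checksums) are written under
`run/`.

The same stages are available as a CLI for file-based workflows:

```bash
olfparc simulate --out sim --subjects 10 --seed 0
olfparc run --out run --seed 0
```

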