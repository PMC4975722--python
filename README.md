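# smtdwi

Per-axon diffusion microstructure from multi-shell diffusion MRI via the
**spherical mean technique (SMT)**.

Brain white matter is full of crossing and dispersing axon bundles, so
voxel-scale diffusion measures (tensor FA, axial/radial diffusivity)
conflate the microscopic diffusion process with the fiber orientation
distribution. SMT removes that confound. For each diffusion weighting
`b`, the direction-averaged (powder-averaged) signal

    ē_b = (1 / 4π) ∫_{S²} e_b(g) dg

is *invariant* to the intravoxel fiber orientation distribution: it
depends only on the impulse response of a single axon segment. Modelling
that response as an axially symmetric microscopic tensor with
diffusivities λ∥ (parallel) and λ⊥ (perpendicular, in μm²/ms), the powder
average has the closed form

    ē_b(λ∥, λ⊥) = exp(−b λ⊥) · √π · erf(√(b(λ∥ − λ⊥))) / (2 √(b(λ∥ − λ⊥)))
                = exp(−b λ⊥) · ₁F₁(1/2; 3/2; −b(λ∥ − λ⊥)).

Fitting this to the per-shell sample means of the (Rician-bias-adjusted,
b0-normalized) signal under the physical constraint
`0 ≤ λ⊥ ≤ λ∥ ≤ λ_free` (λ_free = 3.05 μm²/ms, free water at 37 °C)
recovers the per-axon diffusivities and the derived per-axon metrics

    MD = (λ∥ + 2λ⊥)/3,   FA = √(3/2) √(((λ∥−MD)² + 2(λ⊥−MD)²) / (λ∥² + 2λ⊥²)),
    anisotropy index λ∥/λ⊥,

regardless of how the axons are oriented. The package is aimed at
researchers analyzing multi-shell (≥ 2 nonzero b-values) diffusion MRI —
in vivo or simulated — who want orientation-invariant microstructure maps.

The package also contains the validation machinery: a Dirichlet-process
mixture of bipolar Watson densities for drawing realistic random fiber
orientation distributions, spherical-convolution signal synthesis, a
Rician noise model with maximum-likelihood noise-level estimation, and a
Monte-Carlo benchmark harness.

## Worked example

```python
import numpy as np
import smtdwi as smt

truth = smt.MicroParams(lam_par=2.5, lam_perp=0.1)   # μm²/ms

# Closed-form powder averages at b = 1000 / 2500 s/mm² (= 1.0 / 2.5 ms/μm²)
print(round(smt.spherical_mean_model(1.0, truth), 3))   # 0.503
print(round(smt.spherical_mean_model(2.5, truth), 3))   # 0.282

# Two-shell protocol: 76 + 75 uniform directions, 10 b=0 images
scheme = smt.generate_uniform_scheme([76, 75], [1.0, 2.5], n_b0=10, rng_seed=0)

# A random fiber orientation distribution (dispersed, crossing) ...
fod = smt.sample_dpm_fod(smt.DPMHyper(), rng_seed=7)
signal = smt.synthesize_signal(fod, scheme, truth)

# ... yet the shell means don't care about the orientations:
part = smt.group_shells(scheme)
sm = smt.compute_shell_means(signal, part)
print(np.round(sm.means, 3))                            # [0.503 0.282]

fit = smt.fit_smt(sm)
print(round(fit.params.lam_par, 3), round(fit.params.lam_perp, 3))  # 2.502 0.1
print(round(fit.fa, 3), round(fit.md, 3), round(fit.ratio, 1))      # 0.959 0.9 25.1
```

The estimate matches the ground truth to the 76-direction sampling error
although the fitter never saw the orientation distribution — that is the
point of the technique. With
Rician noise at SNR 17.5 (the protocol's white-matter noise regime) the
median estimates over 500 Monte-Carlo trials stay within a few percent:

```sh
smt benchmark --snr 17.5 --dirs 76 --trials 500 --seed 1 --out bench.csv
```

## Command line

```sh
smt simulate --n-voxels 1000 --shells 1000,2500 --dirs 76,75 --n-b0 10 \
             --snr 17.5 --seed 1 --out sim/vox          # synthetic dataset
smt fit --dwi dwi.nii.gz --bvals dwi.bval --bvecs dwi.bvec \
        --mask mask.nii.gz --estimate-sigma --out-prefix out/smt
smt mean --dwi dwi.nii.gz --bvals dwi.bval --bvecs dwi.bvec \
         --sigma 0.057 --out-prefix out/powder
```

`smt fit` writes λ∥, λ⊥, per-axon MD/FA/ratio and per-shell mean maps
(NIfTI, float32, native grid) plus a JSON fit report.

## Documentation

See `docs/methods.md` for the model, the simulation framework, numerical
choices, and known limitations.
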