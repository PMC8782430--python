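# texkem

Texture-feature-guided kernelized EM reconstruction for dynamic PET, with a
digital-phantom simulator and quantitative image-quality evaluation.

## The problem

Dynamic PET splits a scan into many short frames to follow tracer kinetics, so
each frame is photon-starved and classical maximum-likelihood EM (MLEM)
reconstructions are noisy. Kernelized EM (KEM) regularizes this by
representing the image as **x = Kα**, where the kernel matrix K links pixels
whose *prior-image features* are similar, and iterating EM on the coefficient
image α:

```
α ⁿ⁺¹ = α ⁿ / (Kᵀ Pᵀ 1_M) · Kᵀ Pᵀ ( y / (P K α ⁿ + r) ),     x̂ = K α̂
```

with P the (attenuated) projection operator, y the measured sinogram, r the
expected background, and 1_M the all-ones sinogram. K = I reduces the update
to plain MLEM.

The priors come from the data themselves: the 24 dynamic sinograms are summed
into three 20-minute composite frames, each reconstructed with 100 MLEM
iterations. This package builds the kernel from a 9-component feature vector
per pixel — the three prior intensities plus two *texture descriptors* of
each prior:

* **IDM**, the inverse difference moment of the gray level–gradient
  cooccurrence matrix (GGCM): `Σᵢⱼ P(i,j)/(1+(i−j)²)`, high for homogeneous
  neighborhoods;
* **LRLGE**, the long-run low gray-level emphasis of the gray-level run
  length matrix (GLRLM): `(1/n_r) Σᵢⱼ p(i,j)·j²/i²`, averaged over the four
  scan directions.

Similarity is the Gaussian kernel `κ(f_j, f_l) = exp(−‖f_j−f_l‖²/2σ²)` over
each pixel's 50 nearest feature neighbors in a 9×9 spatial window, with rows
normalized to unit sum. Intensity-only (`kem`) and intensity+GLCM-correlation
(`kem_glcm`) kernels are provided as comparators.

## What is in the box

| module | contents |
| --- | --- |
| `texkem.phantom` | 217×217 brain-like phantom, regional time–activity curves, 24-frame schedule, Poisson acquisition with 20% uniform background, composite-frame rebinning |
| `texkem.projector` | 2D parallel-beam system model (249×210 sinogram), exact matched adjoint pair, Beer–Lambert attenuation |
| `texkem.texture` | GGCM/IDM, GLRLM/LRLGE, GLCM correlation; numba-compiled sliding-window feature maps |
| `texkem.kernel` | feature fields, windowed kNN, sparse Gaussian kernel K |
| `texkem.recon` | MLEM and KEM with likelihood traces |
| `texkem.metrics` | SNR, NMSE, global SSIM, ROI SD, CRC, line profiles |
| `texkem.pipeline` / `texkem` CLI | one-config end-to-end experiments |

## Worked example

A reduced study (128-pixel grid, one noise realization, 50 EM iterations,
frames 12 and 24 of the hour-long schedule):

```python
from texkem.phantom import AcquisitionSettings
from texkem.pipeline import ExperimentConfig, KernelSettings, run_experiment
from texkem.recon import ReconSettings

config = ExperimentConfig(
    grid_size=128,
    acquisition=AcquisitionSettings(realizations=1),
    kernel=KernelSettings(k=50),
    recon=ReconSettings(iterations=50),
    methods=("mlem", "kem_dual"),
    frames=(12, 24),
    seed=0,
)
result = run_experiment(config, outdir="experiment_out")
for row in result.metrics_rows:
    print(f"frame {row['frame']:2d}  {row['method']:8s}"
          f"  SNR {row['snr']:6.2f} dB  NMSE {row['nmse']:.4f}"
          f"  SSIM {row['ssim']:.4f}  CRC {row['crc']:.3f}")
```

prints

```
frame 12  mlem      SNR   9.80 dB  NMSE 0.1047  SSIM 0.9139  CRC 0.764
frame 24  mlem      SNR  14.45 dB  NMSE 0.0359  SSIM 0.9688  CRC 0.862
frame 12  kem_dual  SNR  17.81 dB  NMSE 0.0165  SSIM 0.9865  CRC 0.816
frame 24  kem_dual  SNR  19.63 dB  NMSE 0.0109  SSIM 0.9905  CRC 0.883
```

The dual-texture kernel raises SNR by ~5–8 dB over MLEM and cuts NMSE by
5–6×; frame 12 (a low-count 60 s frame) benefits far more than the
high-count final frame. CRC < 1 means part of the small tumor's contrast is
lost to regularization — the usual noise/contrast trade-off.

The same pipeline is scriptable from the shell:

```sh
texkem run --out experiment_out            # full default study (217², 10 realizations)
texkem simulate --out sim_out              # phantom + noisy sinograms only
texkem features --image prior.npz --descriptor idm --out idm.npz
texkem recon --frames sim_out/noisy_r0.npz --method mlem --iters 100 --out rec.npz
```

Sinograms use axis order (radial bin, angle); angle zero corresponds to rays
parallel to the image y-axis. NPZ is the canonical container; NIfTI export is
available through `texkem.io.export_nifti`.

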