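# fluorofill

Two-stage edge-guided GAN inpainting of **saturation artifacts** in
fluorescence microscope images.

Overexposure, excess fluorescent dye or uneven illumination clip parts of a
micrograph at the sensor maximum (gray level 255 in 8-bit): contiguous
white clusters in which cell shape, inter-cell context, texture and
intensity information are destroyed.  Such images are usually discarded
from quantitative phenotypic analyses.  `fluorofill` restores them instead,
for anyone doing cell-image profiling who would rather repair a clipped
image than lose the sample.

## Method

Restoration runs in two adversarially trained stages:

1. **Edge stage** — a generator G1 receives the masked grayscale image, the
   mask M, and the masked Canny edge map, and predicts the missing edges
   Ẑ_pred.  It trains against a 70×70 PatchGAN discriminator D1 with

       min_G1 max_D1  λ_adv1 · L_adv1 + λ_FM · L_FM ,   λ_adv1 = 1, λ_FM = 10,

   where L_FM = Σᵢ (1/Nᵢ)‖D1ⁱ(E) − D1ⁱ(Ẑ_pred)‖₁ matches the
   discriminator's intermediate activations.
2. **Content stage** — the composite edge map
   Ẑ_comp = E ⊙ (1−M) + Ẑ_pred ⊙ M and the masked image feed a second
   generator G2, trained with

       min_G2 max_D2  λ_l1·L_l1 + λ_adv2·L_adv2 + λ_p·L_perc + λ_s·L_style .

   The final output is composited as I ⊙ (1−M) + G2(·) ⊙ M, so pixels
   outside the mask are bit-identical to the input.

Both generators carry a **contextual attention** branch: each masked
feature patch is synthesized as a softmax-weighted average of the
background patches most cosine-similar to it (S = ⟨f/‖f‖, b/‖b‖⟩), which
keeps restored texture consistent with the surrounding cells.  The edge
stage trains **progressively** — first at low resolution, then, the
networks being fully convolutional, the same weights continue at double
resolution.

The package also implements the surrounding protocol: histogram-based
dataset screening (artifact-affected if raw mean > 20, std > 20 and
saturated pixels present; clean-and-edge-rich if no saturated pixel and
discrete entropy > 5 bits), automatic artifact-mask detection for
unannotated images, paired PSNR / SSIM / FID evaluation, and a synthetic
fluorescence-scene generator so everything is testable without any
external dataset.  See `docs/methods.md` for details and design choices.

## Worked example

Train both stages on synthetic scenes and restore held-out clipped images
(desk-scale sizes; ~10 min on one CPU):

```python
from fluorofill.experiment import run_smoke_experiment

metrics = run_smoke_experiment(seed=1)   # 200 scenes, 1k+1k+2k steps
print(f"mask group:        PSNR {metrics['mask_psnr_db']:.2f} dB, "
      f"SSIM {metrics['mask_ssim']:.3f}, FID {metrics['mask_fid']:.3f}")
print(f"restoration group: PSNR {metrics['restored_psnr_db']:.2f} dB, "
      f"SSIM {metrics['restored_ssim']:.3f}, FID {metrics['restored_fid']:.4f}")
```

which prints:

```
mask group:        PSNR 10.78 dB, SSIM 0.712, FID 0.357
restoration group: PSNR 19.49 dB, SSIM 0.790, FID 0.0058
```

The *mask group* compares 20 held-out originals with their artifact-clipped
versions (how much information the artifact destroys); the *restoration
group* compares the same originals with the restored outputs.  Restoration
raises mean PSNR by ~8.7 dB, raises SSIM, and drops FID by two orders of
magnitude — the restored images are far closer to the originals than the
clipped ones, which is the property the method exists to deliver.  The run
also reports that all 200 training scenes pass the clean-edge-rich screen
and that automatic artifact-mask detection overlaps the true masks with
Jaccard ≈ 0.99.

The same pipeline is scriptable from the shell:

```bash
fluorofill synth --n 16 --size 128 --artifact-fraction 0.2 --seed 3 --out fixtures/
fluorofill screen --in fixtures/ --out report.csv
fluorofill train-edge --data clean/ --out edge.npz
fluorofill train-content --data clean/ --edge-checkpoint edge.npz --out content.npz
fluorofill restore --image img.png --auto-mask \
    --edge-checkpoint edge.npz --content-checkpoint content.npz --out restored.png
fluorofill evaluate --originals orig/ --masked masked/ --restored restored/
```

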