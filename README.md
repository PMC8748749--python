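# rrlsrn — residual-learning super-resolution for 2D brain MRI slices

`rrlsrn` reconstructs a high-resolution (HR) brain MRI slice from a
low-resolution (LR) one at a ×2 scale factor.  Fast fetal MRI sequences
(e.g. SSFSE) freeze motion by acquiring quick, low-resolution 2D slices;
recovering the lost spatial detail afterwards is a super-resolution
problem.  The package implements a compact residual-learning
convolutional network together with everything needed to study it
end-to-end on one workstation: the bicubic degradation model that builds
LR/HR training pairs, the Charbonnier + Gradient Difference training
loss, classical baselines (cubic spline, non-local-means up-sampling),
PSNR/SSIM evaluation with mean/SD/95%-CI reports, and a synthetic brain
phantom generator so no external data is required.

## The model

With `y` the HR slice, `κ` bicubic ×2 decimation and `u` bicubic
up-sampling, the LR observation is `x = κ(y)` and the target decomposes
as

    y = u(x) + r,        r = y − u(x)

The network predicts `y` as the sum of two branches applied to `x`:

* a **residual branch** — 13 convolutions (3×3×64, zero-padded,
  leaky-ReLU slope 0.2) followed by a 4×4 stride-2 transposed
  convolution producing `r̂`;
* an **image branch** — a single 4×4 stride-2 transposed convolution,
  a learned up-sampler playing the role of `u`.

Training minimizes the robust Charbonnier penalty
`mean √((ŷ−y)² + ε²)` (ε = 1e-3) plus a weighted Gradient Difference
Loss `Σ (|∇y| − |∇ŷ|)²` over neighbor pairs, which keeps edges sharp.
Quality is reported as PSNR (`10·log10(1/MSE)` dB on [0,1] data) and
SSIM, summarized per method as mean, SD, and Student-t 95% CI.

See `docs/methods.md` for the full model description, the training
recipe, and what the phantom experiments do and do not demonstrate.

## Worked example

Train on 15 synthetic phantoms and compare against bicubic on 5 held-out
ones (a few minutes on one CPU core):

```python
import numpy as np
import rrlsrn as rr

images = rr.generate_dataset(20, rr.PhantomSpec(), seed=42)
train_imgs, test_imgs = images[:15], images[15:]

cfg = rr.desk_train_config(seed=0, epochs=30)
model, history = rr.train(train_imgs, cfg)

test_pairs = [rr.make_pair(im) for im in test_imgs]
psnr_model = np.mean([rr.psnr(rr.predict_slice(model, p.lr), p.hr)
                      for p in test_pairs])
psnr_bicubic = np.mean([rr.psnr(np.clip(p.upsampled, 0, 1), p.hr)
                        for p in test_pairs])
print(f"loss {history.loss[0]:.4f} -> {history.loss[-1]:.4f}")
print(f"PSNR: model {psnr_model:.2f} dB vs bicubic {psnr_bicubic:.2f} dB")
```

Output:

```
loss 0.2386 -> 0.0190
PSNR: model 35.79 dB vs bicubic 27.19 dB
```

The training loss falls by an order of magnitude and the trained
network recovers more than 8 dB of PSNR over plain bicubic
interpolation: the residual branch has learned the edge detail that
interpolation loses.  (Exact numbers vary by a few tenths of a dB with
the seeds.)

There is also a CLI covering the same workflow:

```bash
rrlsrn phantom --n 20 --size 128 --seed 1 --out-dir data/
rrlsrn degrade data/*.png --out-dir pairs/
rrlsrn train data/*.png --config train.yaml --out-dir run/
rrlsrn sr pairs/lr/*.png --model run/model.npz --out-dir sr/
rrlsrn eval data/*.png --model run/model.npz --out-dir report/
rrlsrn ablate data/*.png --seeds 0,1,2 --out-dir ablation/
```

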