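# grdrn

Joint **g**roupwise **r**egistration and **d**ynamic **r**econstruction
**n**etwork for highly undersampled dynamic MRI, exercised end-to-end on
synthetic cine phantoms with known ground-truth motion.

## The problem

Dynamic MRI (e.g. cardiac cine) trades acquisition time against image
quality: at acceleration factors of 8-16x only a fraction of the k-space
phase-encode lines are measured per frame, and the zero-filled inverse FFT
is heavily aliased.  The frames of a dynamic sequence are highly
correlated, but the anatomy moves between frames, so naive temporal
pooling blurs moving structures.  This package implements an unrolled,
end-to-end trainable reconstruction in which every iteration

1. registers the whole intermediate sequence **groupwise** to an implicit
   template with a diffeomorphic registration network (stationary velocity
   fields, integrated by scaling and squaring, so forward and inverse
   transforms come for free),
2. generates a **motion-augmented** sequence by warping the template back
   to every frame and enforcing **data consistency** (DC) with the
   acquired k-space lines, and
3. removes residual aliasing with a 3D residual network followed by a
   final DC layer.

## The model

Given frames `X = {X_1..X_N}`, the registration network predicts
stationary velocity fields `v = F_theta(|X|)` which are centered so they
sum to zero; transforms `T_n` and inverses `T_n^-1` are the unit-time
flows of `+v_n` and `-v_n`.  The implicit template is the average of the
forward-warped frames,

    Xbar = (1/N) sum_n T_n o X_n,

and the registration loss is

    L_reg = (1/N) sum_n ||Xbar - T_n o X_n||^2
          + (1/N) sum_n ||X_n - T_n^-1 o Xbar||^2
          + alpha (1/N) sum_n ||grad v_n||^2 .

Iteration k generates `G_n = DC(T_n^-1 o Xbar)`, dealiases
`Z^k = H_phi(G^{k-1}, G^0, X^{k-1}) + X^{k-1}`, and sets
`X^k = DC(Z^k)`.  Both networks share parameters across the K unrolled
iterations and are trained jointly with

    sum_k exp(k - K) * ( ||X_gt - X^k||^2 + lambda * L_reg^k ),

with the registration loss always evaluated against the fully sampled
ground truth.  Defaults: `K = 4`, `alpha = 0.05`, `lambda = 1`, channel
widths `[32, 64, 128, 256, 128, 64, 32]`, Adam at 1e-4 halved every 20
epochs (desk-scale runs use smaller networks and a larger rate; see
`docs/methods.md`).  Ablations: pairwise registration to the first frame
(`mode="pairwise"`) and the motion-free cascade (`motion_mode="none"`).

Acquisition is simulated with Cartesian Gaussian-density undersampling:
per frame, `round(n_pe / R)` phase-encode lines drawn without replacement
with probability proportional to a zero-mean Gaussian over the offset from
the k-space center, the 5 central lines always included.

The networks run on a small reverse-mode autodiff engine written for this
package (`grdrn.autodiff`), with gradient correctness pinned to central
finite differences in the test suite.

## Worked example

```python
import numpy as np
from grdrn import kspace, metrics
from grdrn.phantom import PhantomConfig, generate_sequence
from grdrn.registration import RegistrationConfig
from grdrn.reconstruction import ReconConfig
from grdrn.training import TrainConfig, train, validate_psnr

seqs = [generate_sequence(PhantomConfig(noise_sd=0.01, seed=s))[0]
        for s in range(12)]
train_seqs, test_seqs = seqs[:10], seqs[10:]

tc = TrainConfig(accelerations=(8,), epochs=5, learning_rate=1e-3, seed=0)
rc = ReconConfig(channels=(8, 16, 32, 16, 8), iterations=2)
gc = RegistrationConfig(n_frames=8, channels=(8, 16, 32, 16, 8))
result = train(train_seqs, tc, rc, gc, verbose=True)

psnr = validate_psnr(result.reg_net, result.recon_net, rc, test_seqs, 8)
print(f"held-out PSNR at 8x: {psnr:.2f} dB")
```

Typical output (seeds as above, one CPU, a few minutes):

```
epoch   1  loss 0.03135
epoch   2  loss 0.02200
epoch   3  loss 0.01354
epoch   4  loss 0.01145
epoch   5  loss 0.00966
held-out PSNR at 8x: 26.59 dB
```

The loss is the weighted sum of per-iteration reconstruction MSE and
registration loss; the held-out PSNR compares the final-iteration
magnitude reconstruction against the noise-free rendering of the phantom
(zero-filling alone reaches about 21 dB under the same masks).

There is also a CLI covering the full workflow:

```bash
grdrn simulate --out data --n-train 50 --n-val 3 --n-test 20 --seed 1
grdrn train --data data --out run --epochs 10 --accel 8 \
      --channels 8 16 32 16 8 --iterations 2 --learning-rate 1e-3 --seed 1
grdrn reconstruct --input data/test.h5 --checkpoint run/checkpoint.npz \
      --accel 8 --out run/recon.h5
grdrn evaluate --pred run/recon.h5 --gt data/test.h5 --out run/metrics.csv
```

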