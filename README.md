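# spfseg

Self-initialized active-contour segmentation for single-channel 2-D
images with intensity inhomogeneity — e.g. microscopy frames where
uneven illumination makes one cell's interior span the background's
intensity range.

The method evolves a level-set contour under a hybrid energy that
couples a **global** two-phase fit (region means `c1`, `c2`) with a
**local, bias-corrected** fit (a smooth multiplicative bias field `b(x)`
and local means `m1`, `m2`, from Gaussian-windowed clustering of the
formation model `I = b·J + n`), regularized by signed-pressure-force
(SPF) length and area terms:

    ∂φ/∂t = δ_ε(φ)(I − I_bLFI)(c1 − c2) + δ_ε(φ)(I − I_GFI)(m1 − m2)
          + μ_eff div( spf·∇φ/|∇φ| ) δ_ε(φ) + ν_eff spf δ_ε(φ)

with `I_GFI = c1 M1 + c2 M2`, `I_bLFI = b(m1 M1 + m2 M2)`,
`spf = (I − I_GFI)/max|I − I_GFI| ∈ [−1, 1]`, and weights that
self-adjust to the image contrast (`μ_eff = μ|c1 − c2|`,
`ν_eff = ν(c1 − c2)`). No manual initialization is needed: seeds are
found automatically from converging configurations of the image
gradient field via windowed circular projections, and the final mask is
insensitive to where the contour starts. `docs/methods.md` has the full
model description.

The package also ships the evaluation metrics (pixel accuracy, Dice,
Jaccard/JSI, boundary-F1) and a phantom generator producing ground-truth
masks and bias fields, so the whole pipeline is testable end to end
without any external data.

## Worked example

Segment a 128×128 disk phantom corrupted by a strong (amplitude 0.5)
linear illumination ramp — the foreground on the dark side of the ramp
is darker than the background on the bright side, so a plain global
model cannot separate them:

```python
import numpy as np
from spfseg import PhantomSpec, generate, segment
from spfseg.metrics import evaluate_masks

ph = generate(PhantomSpec(bias="linear_ramp", bias_amplitude=0.5))
res = segment(ph.image)                 # auto-seeded
print(res.iterations_used, res.converged)
print(evaluate_masks(res.mask, ph.truth_mask).to_text())
print("bias corr %.3f" % np.corrcoef(res.bias_final.ravel(),
                                     ph.truth_bias.ravel())[0, 1])
```

prints

```
343 True
accuracy = 0.995728
dice = 0.989274
jaccard = 0.978775
bf_score = 1.000000
bias corr 0.995
```

i.e. the contour converged in 343 iterations to a mask overlapping the
ground truth at Dice 0.989 with every boundary pixel within 2 px of the
true boundary, and the estimated illumination field matches the true
ramp at correlation 0.995 (the bias is identifiable up to scale, hence
correlation rather than RMSE).

The same pipeline from the shell:

```
spfseg phantom --bias linear_ramp --amplitude 0.5 --output-dir out
spfseg segment out/phantom.png --output-dir out \
       --eval-against out/phantom_truth.png --save-bias
spfseg evaluate out/phantom_mask.png out/phantom_truth.png
```

`segment` writes the mask PNG, optionally the estimated bias as 32-bit
TIFF, and a JSON run report (parameters, iterations, metrics).

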