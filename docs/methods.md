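# Methods

## Model

`spfseg` segments a single-channel 2-D image `I` into two phases with a
level-set function `phi`; the contour is the zero level set and the
*inside* of the contour is `phi > 0` throughout the package. The image is
modelled as

    I(x) = b(x) J(x) + n(x)

where `J` is a piecewise-constant true image, `b` a smooth, strictly
positive multiplicative bias field (uneven illumination, vignetting) and
`n` additive noise. Two fits are maintained:

* **Global fit** — scalar region means `c1 = Σ I·H_ε(φ) / Σ H_ε(φ)` and
  `c2` (complement), with the arctan-regularized Heaviside
  `H_ε(φ) = ½(1 + (2/π) arctan(φ/ε))` and its derivative, the Cauchy
  impulse `δ_ε(φ) = ε / (π(φ² + ε²))`. The global fitted image is
  `I_GFI = c1 M1 + c2 M2` with memberships `M1 = H_ε(φ)`, `M2 = 1 − M1`.

* **Local, bias-corrected fit** — windowed K-means-style clustering under
  a truncated Gaussian kernel `K_σ` gives closed-form alternating
  updates for the bias field and scalar local means:

      b   = K_σ ∗ (I (m1 M1 + m2 M2)) / K_σ ∗ (m1² M1 + m2² M2)
      m_i = Σ I · (K_σ ∗ b) · M_i  /  Σ (K_σ ∗ b²) · M_i

  and the bias-corrected local fitted image
  `I_bLFI = b (m1 M1 + m2 M2)`. The `m_i` update is the exact
  stationary point of the windowed energy with `b` fixed; smoothing the
  *product* `I·b` instead of `b` alone would leak intensities across the
  region boundary and bias the means (for `b ≡ 1` the exact form reduces
  to plain region means, which we assert in tests).

* **Signed pressure force** — `spf = (I − I_GFI) / max|I − I_GFI|`,
  a max-normalized residual in [−1, 1]; if the residual vanishes
  identically the zero field is returned so the flow is well defined at
  exact convergence.

The contour evolves by the explicit Euler step

    φ ← φ + dt · δ_ε(φ) · [ (I − I_bLFI)(c1 − c2)
                          + (I − I_GFI)(m1 − m2)
                          + μ|c1 − c2| · div( spf · ∇φ/|∇φ| )
                          + ν (c1 − c2) · spf ]

followed by a Gaussian smoothing of `phi` (width `phi_smooth_sigma`) and
clamping to `[−p, p]`. The first two terms are the gradient-descent flow
of the product-form local–global fitting energy; the third is the
SPF-weighted length (curvature) force; the fourth the SPF balloon force.

### Self-adjusting regularization weights

The raw length/area weights would need retuning per image-contrast
range. Both are therefore scaled by the instantaneous global contrast:
`μ_eff = μ·|c1 − c2|` and `ν_eff = ν·(c1 − c2)`. The *sign* carried by
the balloon weight makes the pressure force corrective under either
orientation of the contour: when the inside is the brighter phase
(`c1 > c2`), positive SPF (pixels brighter than the global fit) inflates
the contour; when the inside latches onto the darker phase the force
flips with the contrast. With this rule the user-facing defaults
`μ = ν = 1` work unchanged across contrast ranges and polarities.

### Scale fixing and the reported bias field

The decomposition `I ≈ b·(m1 M1 + m2 M2)` is invariant under
`b → b/s`, `m_i → s·m_i`; freely alternating the two closed-form updates
drifts along this ray (numerically `b → 0`, `m_i → ∞`, which also
inflates the `(m1 − m2)` force). The scale is pinned by normalizing
`b` to unit mean after every update.

A second, subtler identifiability issue affects the *reported* bias
estimate. Because `b` is only constrained at the kernel scale `σ`, it can
absorb almost any error in the `m1/m2` ratio outside a boundary band of
width `~σ`; and with soft memberships the much larger background leaks
mass into `M1` (≈25 % at the defaults for a disk occupying a fifth of the
frame), dragging the fitted ratio toward 1. The segmentation is
insensitive to this (only differences and residuals enter the force),
but the in-loop `b` then correlates poorly with the true illumination
field. The `bias_final` returned by `segment` is therefore a one-shot
refit at convergence: crisp memberships from the final mask, plain
region means, one windowed-moment update, unit-mean normalization. On
linear-ramp phantoms of amplitude 0.5 this estimate correlates with the
ground-truth field at r ≈ 0.995 (the in-loop estimate: ≈ 0.48).

## Automatic seeding (circular projections)

The initial contour is derived from the image. The vector field
`V = ∇(G_σp ∗ I)` points toward brighter intensities. For a window of
side `z` centred at a pixel, `circular_projection` accumulates squared
projections of the windowed vectors onto direction vectors
`(cos θ, sin θ)`, `θ` uniform on `[0, π)`, split by projection sign into
`(P⁺, P⁻)`. Seed selection uses the radial specialization: each window
neighbour's vector is projected onto the outward radial unit vector of
its offset; negative projections (vectors pointing at the centre) score
the *converging* configuration `C`, positive ones the *diverging* `D`.
The raw magnitudes of `C` and `D` are nearly mirror-symmetric across an
object boundary, but the signed score `C − D` changes sign there —
positive just inside a bright object, negative just outside — so
thresholding its top quantile (`top_fraction`, default 2 %) confines
seed evidence to object interiors. Polarity (bright-on-dark vs
dark-on-bright) is auto-detected by keeping whichever sign of the score
has the stronger peak. Connected components of the thresholded score are
reduced to centroids and dilated to disks of radius `window_z` to form
the seed region. On randomized disk phantoms (position, size, polarity)
the selected seeds fall inside the true object in ≥ 95 % of runs.

The level set is initialized binary from the seed region: `+p` strictly
inside, `0` on the seed boundary (seed pixels 4-adjacent to non-seed),
`−p` outside.

## Parameters

| name | default | units | role |
|------|---------|-------|------|
| `epsilon` | 0.5 | φ-units | Heaviside/Dirac width |
| `p` | 2.0 | φ-units | binary init height and clamp bound |
| `sigma` | 3.0 | px | local window scale (kernel radius `ceil(2σ)`) |
| `mu`, `nu` | 1.0 | — | length/area weights before contrast scaling |
| `dt` | 1.0 | — | Euler step |
| `phi_smooth_sigma` | 0.5 | px | per-iteration Gaussian smoothing of φ |
| `max_iter` | 2000 | — | iteration cap |
| `tol`, `window`, `min_iter` | 1e-4, 10, 100 | — | stopping rule (below) |
| `window_z`, `n_theta` | 9, 16 | px, — | seeding window and directions |
| `presmooth_sigma`, `top_fraction` | 2.0, 0.02 | px, — | seeding smoothing/threshold |

The pair `(p, epsilon)` controls membership crispness at the clamp:
`H(±p)` must be close to 0/1 or the region means are diluted by the
opposite phase and the fitted images can never match the data (with
`p/ε = 4`, `H(±p) ≈ 0.92/0.08`). The clamp itself keeps the Dirac factor
— and hence the front speed — bounded away from zero everywhere;
without reinitialization φ would saturate and the evolution stall.
`phi_smooth_sigma` is the only curvature regularizer (no signed-distance
reinitialization); it also provides the noise robustness: isolated
noise-flipped pixels cannot sustain their own region against the
per-iteration smoothing.

**Stopping rule.** The run stops when the fraction of pixels changing
mask label stays below `tol` for `window` consecutive iterations — but
only after `min_iter` iterations *and* once the cumulative mask change
exceeds 2 % of the frame (or the update has vanished outright, as on a
constant image). The guards exist because the early "charge-up" phase —
φ drifting toward zero before any pixel crosses it — is
indistinguishable from convergence to a purely mask-based criterion,
especially when the seed starts far from the object and the two-phase
contrast must bootstrap from near zero.

## Phantom generator

Phantoms realize the formation model directly: a two-level true image
(disk, two disks, square, or four rounded parallel bars with 2-px gaps),
times a bias field (unit, linear column ramp `1−a … 1+a`, or
peak-normalized Gaussian bump `1 + a·G`), plus noise (additive Gaussian
of variance `level`, or salt-&-pepper replacing a `level` fraction of
pixels by 0/1 equiprobably), clipped to [0, 1]. Default levels
fg = 0.65 / bg = 0.25 keep `b·J` inside [0, 1] for amplitudes up to 0.5,
so the multiplicative model survives the final clip unmodified.
Generation is bit-deterministic in `(spec, rng_seed)`.

What the phantoms do *not* emulate: optics (PSF blur, defocus), shot
noise, textured foregrounds, touching objects of different mean
intensity, and 3-D structure. Passing the phantom suite shows the model
recovers piecewise-constant objects under smooth multiplicative bias
and moderate pixel noise; it does not certify performance on real
micrographs, where deviations from the two-phase piecewise-constant
assumption dominate.

## Numerical choices

* Finite differences: central in the interior, one-sided at borders;
  all convolutions use replicate padding; `|∇φ|` is regularized by
  `η = 1e-8` before division.
* The truncated Gaussian kernel is renormalized to unit sum and applied
  as two 1-D passes (exactly equal to the dense stencil).
* Degenerate inputs: a vanishing region mass or fit denominator raises
  a `DegenerateRegionError` naming the side; a constant image raises a
  seeding error in auto-seed mode (no gradient structure to seed from).
* Foreground orientation of the final mask is deterministic: the phase
  whose mean deviates most from the global image mean is labelled
  foreground, which makes the result invariant under `I → 1 − I`.

## Known limitations

* Strictly two-phase; multiple objects are segmented jointly, not
  instance-labelled.
* Seeds with very small area placed entirely in flat background can be
  eroded away by the φ-smoothing before two-phase competition builds
  contrast (the balloon and data forces are both ∝ the near-zero
  contrast there). Seeding configurations with adequate mass — or any
  seed touching the object — converge to the same mask; runs from a
  pure-background 25×25 corner seed do too, just much more slowly.
* Bias fields are recovered up to scale only, and only at smoothness
  scales ≳ the kernel width.
* The product-form energy admits degenerate splits (e.g. a dark corner
  vs everything else) as local minima under extreme initializations
  combined with premature stopping; the activity guard in the stopping
  rule is the mitigation.
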