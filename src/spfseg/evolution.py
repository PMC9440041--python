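"""Level-set evolution: initialization, PDE update, and the driver.

Sign convention (used consistently across the package): the *inside* of
the contour is ``phi > 0``, so ``c1``/``m1`` are inside means.  The
binary initialization therefore places ``+p`` inside the seed region,
``0`` on its boundary and ``-p`` outside.

Each iteration recomputes, in order, the global means, the bias field,
the bias-corrected local means, the fitted images and the signed pressure
force, then takes one explicit Euler step of the gradient-descent flow

``phi_t = delta(phi) [ (I - I_bLFI)(c1 - c2) + (I - I_GFI)(m1 - m2) ]
        + mu_eff  div( spf grad(phi)/|grad(phi)| ) delta(phi)
        + nu_eff  spf delta(phi)``

followed by a light Gaussian smoothing of ``phi`` (the only regularizer;
no signed-distance reinitialization is performed).  The length and area
weights self-adjust to the image: ``mu_eff = mu |c1 - c2|`` and
``nu_eff = nu (c1 - c2)``, i.e. both scale with the current global
contrast, and the balloon force carries the contrast's sign so that it
always inflates the contour over pixels brighter than the global fit
when the inside is the brighter phase, and symmetrically otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from spfseg import fitting
from spfseg.field_math import (
    curvature_divergence,
    dirac,
    gaussian_kernel,
    SmoothingParams,
)
from spfseg.fitting import (
    FittedImages,
    GlobalMeans,
    LocalMeans,
    memberships,
)

__all__ = [
    "SeedingError",
    "EvolutionParams",
    "EvolutionState",
    "SegmentationResult",
    "initialize_phi",
    "refit_bias",
    "evolve_step",
    "has_converged",
    "segment",
]

logger = logging.getLogger(__name__)

#: |grad(phi)| regularizer in the curvature term.
_ETA = 1e-8


class SeedingError(ValueError):
    """Seed region is empty, full, or could not be derived from the image."""


@dataclass(frozen=True)
class EvolutionParams:
    """Tunable parameters of the contour evolution.

    mu, nu
        Length- and area-term weights; both are rescaled internally by the
        global contrast ``|c1 - c2|`` each iteration, so the defaults of
        1.0 work across images of different dynamic range.
    dt
        Explicit Euler time step.
    p
        Height of the binary level-set initialization.
    epsilon, sigma
        Heaviside/Dirac width and Gaussian window scale (pixels).
    phi_smooth_sigma
        Width of the per-iteration Gaussian smoothing of ``phi``
        (0 disables it).
    max_iter, tol, window, min_iter, activity_min
        Iteration cap and convergence rule: stop when the fraction of
        pixels changing mask label stays below ``tol`` for ``window``
        consecutive iterations, but never before ``min_iter`` iterations
        and only once the cumulative mask change exceeds
        ``activity_min`` (or the update force has vanished outright).
        The guards avoid stopping during a quiet "charge-up" phase, when
        ``phi`` drifts toward zero without any pixel having crossed it
        yet — common when the seed starts far from the object.
    spf_mode
        "plain" uses the max-normalized global residual; "membership"
        selects the ablation variant with membership-reweighted fitting.
    """

    mu: float = 1.0
    nu: float = 1.0
    dt: float = 1.0
    p: float = 2.0
    epsilon: float = 0.5
    sigma: float = 3.0
    phi_smooth_sigma: float = 0.5
    max_iter: int = 2000
    tol: float = 1e-4
    window: int = 10
    min_iter: int = 100
    activity_min: float = 0.02
    spf_mode: str = "plain"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.p <= 0:
            raise ValueError(f"p must be positive, got {self.p}")
        if self.mu < 0:
            raise ValueError(f"mu must be non-negative, got {self.mu}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.tol <= 0:
            raise ValueError(f"tol must be positive, got {self.tol}")
        if self.phi_smooth_sigma < 0:
            raise ValueError("phi_smooth_sigma must be non-negative")
        if self.min_iter < 0:
            raise ValueError("min_iter must be non-negative")
        if self.spf_mode not in ("plain", "membership"):
            raise ValueError(f"unknown spf_mode {self.spf_mode!r}")
        # Validates epsilon/sigma positivity and derives the kernel radius.
        self.smoothing()

    def smoothing(self) -> SmoothingParams:
        return SmoothingParams(epsilon=self.epsilon, sigma=self.sigma)


@dataclass
class EvolutionState:
    """Mutable per-iteration state carried through the evolution."""

    phi: np.ndarray
    bias: np.ndarray
    means_g: GlobalMeans
    means_l: LocalMeans
    fitted: FittedImages | None = None
    iteration: int = 0
    converged: bool = False
    history: list[float] = field(default_factory=list)
    last_update_max: float = float("inf")


@dataclass(frozen=True)
class SegmentationResult:
    mask: np.ndarray  # binary, foreground = True
    phi_final: np.ndarray
    bias_final: np.ndarray
    iterations_used: int
    converged: bool
    history: tuple[float, ...] = ()


def initialize_phi(
    shape: tuple[int, int], seed_region: np.ndarray, p: float
) -> np.ndarray:
    """Binary level-set initialization from a seed mask.

    ``+p`` strictly inside the seed region, ``0`` on its boundary (seed
    pixels 4-adjacent to a non-seed pixel), ``-p`` outside.
    """
    if p <= 0:
        raise ValueError(f"p must be positive, got {p}")
    seed = np.asarray(seed_region, dtype=bool)
    if seed.shape != tuple(shape):
        raise ValueError(f"seed shape {seed.shape} != grid shape {shape}")
    n_seed = int(seed.sum())
    if n_seed == 0:
        raise SeedingError("seed region is empty")
    if n_seed == seed.size:
        raise SeedingError("seed region covers the full grid")
    four = ndimage.generate_binary_structure(2, 1)
    interior = ndimage.binary_erosion(seed, structure=four, border_value=1)
    boundary = seed & ~interior
    phi = np.where(seed, p, -p).astype(float)
    phi[boundary] = 0.0
    return phi


def _spf_field(
    image: np.ndarray,
    means_g: GlobalMeans,
    fitted: FittedImages,
    member: fitting.MembershipPair,
    mode: str,
) -> np.ndarray:
    if mode == "membership":
        return fitting.spf_with_membership(image, means_g, member)
    return fitting.spf(image, fitted.I_GFI)


def evolve_step(
    image: np.ndarray, state: EvolutionState, params: EvolutionParams
) -> EvolutionState:
    """One explicit update of ``phi`` with all fits recomputed first."""
    sm = params.smoothing()
    kernel = gaussian_kernel(sm.sigma, sm.kernel_radius)

    member = memberships(state.phi, params.epsilon)
    means_g = fitting.global_means(image, state.phi, params.epsilon)
    bias = fitting.bias_field(image, member, state.means_l, kernel)
    # The product b*(m1,m2) is identifiable but the common scale is not:
    # alternating the two closed-form updates lets b drift toward 0 and
    # the means toward infinity.  Pinning <b> = 1 removes the ambiguity.
    bias = bias / bias.mean()
    means_l = fitting.local_means(image, bias, member, kernel)
    fitted = fitting.fitted_images(means_g, means_l, bias, member)
    spf = _spf_field(image, means_g, fitted, member, params.spf_mode)

    delta = dirac(state.phi, params.epsilon)
    contrast = means_g.c1 - means_g.c2
    force = (
        (image - fitted.I_bLFI) * (means_g.c1 - means_g.c2)
        + (image - fitted.I_GFI) * (means_l.m1 - means_l.m2)
        + params.mu * abs(contrast) * curvature_divergence(state.phi, spf, _ETA)
        + params.nu * contrast * spf
    )
    phi = state.phi + params.dt * delta * force
    if params.phi_smooth_sigma > 0:
        phi = ndimage.gaussian_filter(phi, params.phi_smooth_sigma, mode="nearest")
    # Keep phi near-binary: without signed-distance reinitialization the
    # field would otherwise saturate and the Dirac response (and hence the
    # front speed) would collapse far from the contour.
    np.clip(phi, -params.p, params.p, out=phi)

    update_max = float(np.abs(phi - state.phi).max())
    changed = float(np.mean((phi > 0) != (state.phi > 0)))
    history = state.history + [changed]
    logger.debug(
        "iter=%d c1=%.4f c2=%.4f m1=%.4f m2=%.4f mask_change=%.2e",
        state.iteration + 1,
        means_g.c1,
        means_g.c2,
        means_l.m1,
        means_l.m2,
        changed,
    )
    return EvolutionState(
        phi=phi,
        bias=bias,
        means_g=means_g,
        means_l=means_l,
        fitted=fitted,
        iteration=state.iteration + 1,
        converged=state.converged,
        history=history,
        last_update_max=update_max,
    )


def has_converged(history: list[float], tol: float, window: int) -> bool:
    """True iff the mask-change fraction stayed below ``tol`` for the last
    ``window`` consecutive iterations."""
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if len(history) < window:
        return False
    return all(h < tol for h in history[-window:])


def refit_bias(image: np.ndarray, mask: np.ndarray, sigma: float) -> np.ndarray:
    """Closed-form bias estimate given a final segmentation.

    Uses crisp memberships and the plain region means of the mask, then a
    single windowed-moment update, normalized to unit mean.  The
    scalar-means decomposition ``I = b J`` is only weakly identifiable
    when memberships are soft or the fit is iterated freely (the bias can
    absorb membership leakage), so the one-shot crisp estimate is the
    best-conditioned bias to report.
    """
    if not mask.any() or mask.all():
        return np.ones_like(image)
    sm = SmoothingParams(sigma=sigma)
    kernel = gaussian_kernel(sm.sigma, sm.kernel_radius)
    member = fitting.MembershipPair(
        M1=mask.astype(float), M2=(~mask).astype(float)
    )
    ml = LocalMeans(m1=float(image[mask].mean()), m2=float(image[~mask].mean()))
    bias = fitting.bias_field(image, member, ml, kernel)
    return bias / bias.mean()


def _orient_foreground(mask: np.ndarray, image: np.ndarray) -> np.ndarray:
    """Label as foreground the phase whose mean deviates most from the
    global image mean (deterministic inside/outside disambiguation)."""
    n_in = int(mask.sum())
    if n_in == 0 or n_in == mask.size:
        return mask
    g = float(image.mean())
    dev_in = abs(float(image[mask].mean()) - g)
    dev_out = abs(float(image[~mask].mean()) - g)
    return mask if dev_in >= dev_out else ~mask


def segment(
    image: np.ndarray,
    params: EvolutionParams | None = None,
    seed_region: np.ndarray | None = None,
) -> SegmentationResult:
    """Segment a single-channel image into foreground/background.

    If ``seed_region`` is omitted, seeds are derived automatically from
    converging configurations of the image gradient field (circular
    projections).  Runs the evolution until the mask settles or
    ``max_iter`` is reached.

    Parameters
    ----------
    image
        2-D float array, finite, nominally scaled to [0, 1].
    params
        Evolution parameters; defaults are suitable for [0, 1] images.
    seed_region
        Optional boolean initial-contour interior; any non-empty,
        non-full region works (the result is initialization-insensitive).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    params = params or EvolutionParams()

    if seed_region is None:
        from spfseg.seeding import CPParams, select_seeds

        seed_region = select_seeds(image, CPParams()).region

    phi = initialize_phi(image.shape, seed_region, params.p)
    state = EvolutionState(
        phi=phi,
        bias=np.ones_like(image),
        means_g=fitting.global_means(image, phi, params.epsilon),
        means_l=LocalMeans(m1=0.0, m2=0.0),
        iteration=0,
    )
    # Bootstrap the local means from the plain region means.
    state.means_l = LocalMeans(m1=state.means_g.c1, m2=state.means_g.c2)

    for _ in range(params.max_iter):
        state = evolve_step(image, state, params)
        armed = (
            sum(state.history) >= params.activity_min
            or state.last_update_max < 1e-6
        )
        if (
            armed
            and state.iteration >= params.min_iter
            and has_converged(state.history, params.tol, params.window)
        ):
            state.converged = True
            break

    mask = _orient_foreground(state.phi > 0, image)
    # Keep phi's sign aligned with the reported mask.
    phi_final = state.phi if np.array_equal(mask, state.phi > 0) else -state.phi
    return SegmentationResult(
        mask=mask,
        phi_final=phi_final,
        bias_final=refit_bias(image, mask, params.sigma),
        iterations_used=state.iteration,
        converged=state.converged,
        history=tuple(state.history),
    )
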