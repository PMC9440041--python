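"""Numerical substrate: smooth step/impulse functions and stencils.

All level-set machinery rests on four primitives: the arctan-regularized
Heaviside step ``H_eps`` and its derivative, the Cauchy-kernel Dirac
impulse ``delta_eps``; a truncated, unit-sum Gaussian kernel used for
local averaging; and finite-difference gradient/divergence stencils with
replicate boundary handling.

Conventions shared by every module: fields are 2-D ``float64`` arrays in
row-major order, origin at the top-left, unit pixel spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Grid2D",
    "SmoothingParams",
    "heaviside",
    "dirac",
    "gaussian_kernel",
    "convolve",
    "gradient",
    "divergence",
    "curvature_divergence",
]


@dataclass(frozen=True)
class Grid2D:
    """Image domain: a ``height x width`` pixel lattice with unit spacing."""

    height: int
    width: int
    spacing: float = 1.0

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError(
                f"grid must be at least 8x8, got {self.height}x{self.width}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @classmethod
    def of(cls, arr: np.ndarray) -> "Grid2D":
        if arr.ndim != 2:
            raise ValueError(f"expected a 2-D field, got shape {arr.shape}")
        return cls(arr.shape[0], arr.shape[1])


@dataclass(frozen=True)
class SmoothingParams:
    """Widths of the regularized step and the local-averaging kernel.

    ``epsilon`` sets the transition width of the Heaviside/Dirac pair (in
    level-set units); ``sigma`` is the Gaussian scale in pixels over which
    local means and the bias field are fitted; ``kernel_radius`` truncates
    the kernel (must cover at least two sigma).
    """

    epsilon: float = 1.0
    sigma: float = 3.0
    kernel_radius: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.kernel_radius < 0:
            object.__setattr__(self, "kernel_radius", math.ceil(2 * self.sigma))
        if self.kernel_radius < math.ceil(2 * self.sigma):
            raise ValueError(
                f"kernel_radius {self.kernel_radius} < ceil(2*sigma) "
                f"= {math.ceil(2 * self.sigma)}"
            )


def heaviside(phi: np.ndarray | float, epsilon: float) -> np.ndarray:
    """Arctan-regularized Heaviside step.

    ``H(phi) = 1/2 (1 + (2/pi) arctan(phi/epsilon))``; strictly increasing
    in ``phi`` with ``H(phi) + H(-phi) = 1`` exactly.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    phi = np.asarray(phi, dtype=float)
    return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(phi / epsilon))


def dirac(phi: np.ndarray | float, epsilon: float) -> np.ndarray:
    """Cauchy-kernel Dirac impulse, the derivative of :func:`heaviside`.

    ``delta(phi) = epsilon / (pi (phi^2 + epsilon^2))``; even in ``phi``,
    peaked at 0 with height ``1/(pi epsilon)`` and unit integral.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    phi = np.asarray(phi, dtype=float)
    return epsilon / (np.pi * (phi * phi + epsilon * epsilon))


def gaussian_kernel(sigma: float, radius: int) -> np.ndarray:
    """Truncated isotropic Gaussian on ``(2 radius + 1)^2`` taps, unit sum."""
    if radius < 1:
        raise ValueError(f"kernel radius must be >= 1, got {radius}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    x = np.arange(-radius, radius + 1, dtype=float)
    g1 = np.exp(-0.5 * (x / sigma) ** 2)
    k = np.outer(g1, g1)
    return k / k.sum()


def convolve(fld: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Correlate ``fld`` with a symmetric kernel, replicate padding.

    Separable kernels (rank-1, e.g. the truncated Gaussian) are split into
    two 1-D passes; the result is identical to the dense stencil.
    """
    fld = np.asarray(fld, dtype=float)
    # Truncated Gaussians are outer products of their middle row/column;
    # exploit that for two 1-D passes, fall back to the dense stencil.
    r = kernel.shape[0] // 2
    row = kernel[r, :]
    col = kernel[:, r]
    sep = np.outer(col, row)
    if (
        kernel.shape[0] == kernel.shape[1]
        and sep.sum() > 0
        and np.allclose(sep / sep.sum(), kernel / kernel.sum(), atol=1e-13)
    ):
        out = ndimage.correlate1d(fld, col / col.sum(), axis=0, mode="nearest")
        out = ndimage.correlate1d(out, row / row.sum(), axis=1, mode="nearest")
        return out * kernel.sum()
    return ndimage.correlate(fld, kernel, mode="nearest")


def gradient(fld: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient ``(d/drow, d/dcol)``, one-sided at borders."""
    fld = np.asarray(fld, dtype=float)
    gr, gc = np.gradient(fld)
    return gr, gc


def divergence(vr: np.ndarray, vc: np.ndarray) -> np.ndarray:
    """Divergence of a vector field by the adjoint central-difference stencil."""
    return np.gradient(vr, axis=0) + np.gradient(vc, axis=1)


def curvature_divergence(
    phi: np.ndarray, weight: np.ndarray | float, eta: float = 1e-8
) -> np.ndarray:
    """``div(weight * grad(phi) / (|grad(phi)| + eta))``.

    With ``weight = 1`` this is the mean curvature of the level lines of
    ``phi`` (e.g. ``1/R`` on circles of radius ``R``); a spatially varying
    weight yields the SPF-modulated length force.
    """
    if eta <= 0:
        raise ValueError(f"eta must be positive, got {eta}")
    gr, gc = gradient(phi)
    mag = np.sqrt(gr * gr + gc * gc) + eta
    w = np.asarray(weight, dtype=float)
    return divergence(w * gr / mag, w * gc / mag)
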