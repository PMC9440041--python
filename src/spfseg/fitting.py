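"""Data-fitting quantities of the hybrid local-global energy.

The image is modelled as ``I(x) = b(x) J(x) + n(x)``: a piecewise-constant
true image ``J`` corrupted by a smooth multiplicative bias field ``b`` and
additive noise.  Two fits are maintained simultaneously:

* a *global* two-phase fit with scalar region means ``c1`` (inside,
  ``phi > 0``) and ``c2`` (outside), as in classical region-based active
  contours;
* a *local*, bias-corrected fit with scalar means ``m1``, ``m2`` and the
  bias field ``b(x)`` estimated from Gaussian-windowed clustering.

From these, the fitted images ``I_GFI = c1 M1 + c2 M2`` and
``I_bLFI = b (m1 M1 + m2 M2)`` and the signed pressure force
``spf = (I - I_GFI) / max|I - I_GFI|`` are derived.  ``M1 = H_eps(phi)``
and ``M2 = 1 - M1`` are the soft region memberships.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from spfseg.field_math import convolve, heaviside

__all__ = [
    "DegenerateRegionError",
    "GlobalMeans",
    "LocalMeans",
    "MembershipPair",
    "FittedImages",
    "memberships",
    "global_means",
    "bias_field",
    "local_means",
    "fitted_images",
    "spf",
    "spf_with_membership",
]

#: Region masses / fit denominators below this are treated as degenerate.
_MASS_FLOOR = 1e-6
#: Residual images with max-abs below this yield a zero SPF field.
_SPF_FLOOR = 1e-12


class DegenerateRegionError(ValueError):
    """One of the two regions has (numerically) vanished."""


@dataclass(frozen=True)
class GlobalMeans:
    c1: float  # mean intensity inside the contour (phi > 0)
    c2: float  # mean intensity outside


@dataclass(frozen=True)
class LocalMeans:
    m1: float
    m2: float


@dataclass(frozen=True)
class MembershipPair:
    """Soft region indicators ``M1 = H_eps(phi)``, ``M2 = 1 - M1``."""

    M1: np.ndarray
    M2: np.ndarray


@dataclass(frozen=True)
class FittedImages:
    I_GFI: np.ndarray  # global fitted image  c1*M1 + c2*M2
    I_bLFI: np.ndarray  # bias-corrected local fitted image  b*(m1*M1 + m2*M2)


def memberships(phi: np.ndarray, epsilon: float) -> MembershipPair:
    """Build the membership pair from the level-set field."""
    m1 = heaviside(phi, epsilon)
    return MembershipPair(M1=m1, M2=1.0 - m1)


def global_means(
    image: np.ndarray, phi: np.ndarray, epsilon: float
) -> GlobalMeans:
    """Heaviside-weighted region means over the whole domain.

    ``c1 = sum(I H) / sum(H)`` and ``c2 = sum(I (1-H)) / sum(1-H)``.
    """
    h = heaviside(phi, epsilon)
    mass1 = float(h.sum())
    mass2 = float((1.0 - h).sum())
    if mass1 <= _MASS_FLOOR:
        raise DegenerateRegionError("inside region has vanishing mass")
    if mass2 <= _MASS_FLOOR:
        raise DegenerateRegionError("outside region has vanishing mass")
    c1 = float((image * h).sum() / mass1)
    c2 = float((image * (1.0 - h)).sum() / mass2)
    return GlobalMeans(c1=c1, c2=c2)


def bias_field(
    image: np.ndarray,
    membership: MembershipPair,
    means: LocalMeans,
    kernel: np.ndarray,
) -> np.ndarray:
    """Estimate the multiplicative bias field.

    Pointwise ratio of two Gaussian-windowed moments,

    ``b = K * (I (m1 M1 + m2 M2)) / K * (m1^2 M1 + m2^2 M2)``,

    the closed-form minimizer of the windowed clustering energy with the
    means held fixed.  Smooth at the kernel scale by construction.
    """
    num = convolve(image * (means.m1 * membership.M1 + means.m2 * membership.M2), kernel)
    den = convolve(
        means.m1**2 * membership.M1 + means.m2**2 * membership.M2, kernel
    )
    if np.any(den <= _MASS_FLOOR):
        raise DegenerateRegionError("bias-field denominator vanishes")
    return num / den


def local_means(
    image: np.ndarray,
    bias: np.ndarray,
    membership: MembershipPair,
    kernel: np.ndarray,
) -> LocalMeans:
    """Bias-corrected scalar region means.

    ``m_i = sum_x I(x) [K*b](x) M_i(x) / sum_x [K*(b^2)](x) M_i(x)`` — the
    exact minimizer of the windowed clustering energy with the bias held
    fixed (only the bias moments are kernel-smoothed; smoothing the
    product ``I b`` instead would leak intensities across the region
    boundary and bias the means).  With ``b = 1`` this reduces exactly to
    the plain region means.
    """
    kb = convolve(bias, kernel)
    kb2 = convolve(bias * bias, kernel)
    out = []
    for mi, side in ((membership.M1, "inside"), (membership.M2, "outside")):
        den = float((kb2 * mi).sum())
        if den <= _MASS_FLOOR:
            raise DegenerateRegionError(f"{side} local-mean denominator vanishes")
        out.append(float((image * kb * mi).sum() / den))
    return LocalMeans(m1=out[0], m2=out[1])


def fitted_images(
    means_g: GlobalMeans,
    means_l: LocalMeans,
    bias: np.ndarray,
    membership: MembershipPair,
) -> FittedImages:
    """Compose the global and bias-corrected local fitted images."""
    gfi = means_g.c1 * membership.M1 + means_g.c2 * membership.M2
    blfi = bias * (means_l.m1 * membership.M1 + means_l.m2 * membership.M2)
    return FittedImages(I_GFI=gfi, I_bLFI=blfi)


def spf(image: np.ndarray, gfi: np.ndarray) -> np.ndarray:
    """Signed pressure force: max-normalized global residual in [-1, 1].

    Positive where the image is brighter than the global fit and negative
    where darker, so it inflates the contour inside the object and deflates
    it outside.  A (numerically) zero residual image returns the zero
    field, which keeps the evolution well defined at exact convergence.
    """
    resid = image - gfi
    peak = float(np.abs(resid).max())
    if peak < _SPF_FLOOR:
        return np.zeros_like(resid)
    return resid / peak


def spf_with_membership(
    image: np.ndarray, means_g: GlobalMeans, membership: MembershipPair
) -> np.ndarray:
    """Ablation-mode SPF with membership-reweighted fitted image.

    The fitted image inside the normalization is weighted by the squared
    memberships, ``(c1 M1^2 + c2 M2^2) / (M1^2 + M2^2)``, which coincides
    with the plain global fitted image for crisp memberships but leans
    toward the more confident region when they are soft.
    """
    m1sq = membership.M1**2
    m2sq = membership.M2**2
    gfi_w = (means_g.c1 * m1sq + means_g.c2 * m2sq) / (m1sq + m2sq)
    return spf(image, gfi_w)
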