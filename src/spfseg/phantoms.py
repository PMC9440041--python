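"""Synthetic phantoms with known masks and bias fields.

Images are built by the multiplicative formation model
``I(x) = clip( b(x) J(x) + n(x) )``: a two-level true image ``J``
(foreground/background shapes), a smooth multiplicative bias field ``b``
emulating uneven illumination, and additive Gaussian or salt-&-pepper
impulse noise.  Every phantom carries its ground-truth mask and bias
field, so segmentation and bias recovery can be validated in closed loop.

Generation is fully deterministic given the spec (including its
``rng_seed``).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
import json

import numpy as np

__all__ = ["PhantomSpec", "Phantom", "make_true_image", "make_bias", "add_noise", "generate"]

SHAPES = ("disk", "two_disks", "fingers_like", "square")
BIAS_KINDS = ("none", "linear_ramp", "gaussian_blob")
NOISE_KINDS = ("none", "gaussian", "salt_pepper")


class PhantomSpecError(ValueError):
    """Invalid or degenerate phantom specification."""


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom.

    ``bias_amplitude`` is the peak relative deviation of ``b`` from 1
    (must stay below 1 so ``b`` remains positive); ``noise_level`` is the
    Gaussian noise variance or the salt-&-pepper corruption density.
    ``center`` and ``radius`` optionally override the default geometry
    (fractions of the grid for ``center``, pixels for ``radius``).
    """

    shape: str = "disk"
    height: int = 128
    width: int = 128
    # Defaults keep b*J inside [0,1] for bias amplitudes up to 0.5, so the
    # multiplicative formation model survives the final clip unmodified.
    fg_level: float = 0.65
    bg_level: float = 0.25
    bias: str = "none"
    bias_amplitude: float = 0.0
    noise: str = "none"
    noise_level: float = 0.0
    rng_seed: int = 0
    center: tuple[float, float] | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise PhantomSpecError(f"unknown shape {self.shape!r}")
        if self.bias not in BIAS_KINDS:
            raise PhantomSpecError(f"unknown bias kind {self.bias!r}")
        if self.noise not in NOISE_KINDS:
            raise PhantomSpecError(f"unknown noise kind {self.noise!r}")
        if self.fg_level == self.bg_level:
            raise PhantomSpecError("fg_level and bg_level must differ")
        for lvl in (self.fg_level, self.bg_level):
            if not (0.0 <= lvl <= 1.0):
                raise PhantomSpecError(f"intensity level {lvl} outside [0, 1]")
        if self.bias_amplitude < 0:
            raise PhantomSpecError("bias_amplitude must be >= 0")
        if self.bias != "none" and self.bias_amplitude >= 1:
            raise PhantomSpecError(
                "bias_amplitude must be < 1 to keep the bias field positive"
            )
        if self.noise_level < 0:
            raise PhantomSpecError("noise_level must be >= 0")
        if self.height < 8 or self.width < 8:
            raise PhantomSpecError("phantom grid must be at least 8x8")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        if d.get("center") is not None:
            d["center"] = tuple(d["center"])
        return cls(**d)


@dataclass(frozen=True)
class Phantom:
    image: np.ndarray
    truth_mask: np.ndarray
    truth_bias: np.ndarray
    spec: PhantomSpec


def _disk_mask(
    h: int, w: int, center: tuple[float, float], radius: float
) -> np.ndarray:
    rr, cc = np.ogrid[:h, :w]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def make_true_image(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Two-level true image ``J`` and its exact foreground mask."""
    h, w = spec.height, spec.width
    cy, cx = spec.center if spec.center else (0.5, 0.5)
    center = (cy * (h - 1), cx * (w - 1))
    radius = spec.radius if spec.radius is not None else 0.25 * min(h, w)

    if spec.shape == "disk":
        mask = _disk_mask(h, w, center, radius)
    elif spec.shape == "two_disks":
        r = min(radius, 0.18 * min(h, w))
        mask = _disk_mask(h, w, (0.30 * (h - 1), 0.28 * (w - 1)), r) | _disk_mask(
            h, w, (0.68 * (h - 1), 0.72 * (w - 1)), r
        )
    elif spec.shape == "square":
        half = int(round(radius))
        r0, c0 = int(round(center[0])), int(round(center[1]))
        mask = np.zeros((h, w), dtype=bool)
        mask[max(0, r0 - half) : r0 + half + 1, max(0, c0 - half) : c0 + half + 1] = True
    elif spec.shape == "fingers_like":
        # Four parallel rounded bars with 2-px gaps: adjacent boundaries
        # challenge the contour's ability to keep objects separate.
        mask = np.zeros((h, w), dtype=bool)
        bar_w = max(3, w // 12)
        gap = 2
        top, bottom = int(0.15 * h), int(0.80 * h)
        total = 4 * bar_w + 3 * gap
        left = (w - total) // 2
        for i in range(4):
            c0 = left + i * (bar_w + gap)
            mask[top:bottom, c0 : c0 + bar_w] = True
            # round the bar tips with half-disk caps
            cmid = c0 + bar_w / 2 - 0.5
            mask |= _disk_mask(h, w, (top, cmid), bar_w / 2)
            mask |= _disk_mask(h, w, (bottom - 1, cmid), bar_w / 2)
    else:  # pragma: no cover - guarded by the spec validator
        raise PhantomSpecError(f"unknown shape {spec.shape!r}")

    if not mask.any() or mask.all():
        raise PhantomSpecError("shape rasterizes to a degenerate (empty/full) mask")
    J = np.where(mask, spec.fg_level, spec.bg_level).astype(float)
    return J, mask


def make_bias(spec: PhantomSpec) -> np.ndarray:
    """Smooth positive multiplicative bias field ``b`` with mean near 1."""
    h, w = spec.height, spec.width
    a = spec.bias_amplitude
    if spec.bias == "none" or a == 0.0:
        return np.ones((h, w), dtype=float)
    if spec.bias == "linear_ramp":
        ramp = np.linspace(1.0 - a, 1.0 + a, w)
        return np.tile(ramp, (h, 1))
    # gaussian_blob: peak-normalized bump at a reproducibly random position
    rng = np.random.default_rng(spec.rng_seed + 1)
    cy = rng.uniform(0.25, 0.75) * (h - 1)
    cx = rng.uniform(0.25, 0.75) * (w - 1)
    rr, cc = np.ogrid[:h, :w]
    s = 0.35 * min(h, w)
    g = np.exp(-((rr - cy) ** 2 + (cc - cx) ** 2) / (2 * s * s))
    return 1.0 + a * g / g.max()


def add_noise(
    image: np.ndarray, noise: str, level: float, rng_seed: int
) -> np.ndarray:
    """Additive Gaussian (variance ``level``) or salt-&-pepper (density
    ``level``) corruption, clipped to [0, 1]; deterministic in ``rng_seed``."""
    if noise not in NOISE_KINDS:
        raise PhantomSpecError(f"unknown noise kind {noise!r}")
    if level < 0:
        raise PhantomSpecError("noise level must be >= 0")
    image = np.asarray(image, dtype=float)
    if noise == "none" or level == 0.0:
        return image.copy()
    rng = np.random.default_rng(rng_seed + 2)
    if noise == "gaussian":
        out = image + rng.normal(0.0, np.sqrt(level), size=image.shape)
        return np.clip(out, 0.0, 1.0)
    # salt_pepper: each pixel independently corrupted with probability
    # `level`, set to 0 or 1 equiprobably.
    out = image.copy()
    corrupt = rng.random(image.shape) < level
    out[corrupt] = rng.choice([0.0, 1.0], size=int(corrupt.sum()))
    return out


def generate(spec: PhantomSpec) -> Phantom:
    """Compose true image, bias and noise into a reproducible phantom."""
    J, mask = make_true_image(spec)
    b = make_bias(spec)
    image = add_noise(np.clip(b * J, 0.0, 1.0), spec.noise, spec.noise_level, spec.rng_seed)
    return Phantom(image=image, truth_mask=mask, truth_bias=b, spec=spec)
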