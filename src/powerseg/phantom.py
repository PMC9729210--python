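"""Seeded synthetic phantoms with ground truth for end-to-end validation.

Generates piecewise-constant multi-object scenes (disks, rectangles, rings)
over a uniform background, with optional corruption by

* **speckle** noise ``u·(1+n)`` with ``n`` zero-mean uniform of a given
  variance (the multiplicative noise typical of ultrasound/coherent
  imaging),
* additive **Gaussian** noise of a given variance,
* **salt-and-pepper** outliers (a given fraction of pixels forced to 0 or 1),
* a smooth multiplicative intensity-inhomogeneity **bias field**.

The ground-truth mask is the union of the objects and is fixed before any
corruption.  Everything is a pure function of the spec and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "add_noise",
    "add_bias_field",
    "realize",
    "three_object_spec",
]

NOISE_MODELS = ("none", "speckle", "gaussian", "salt_pepper")


@dataclass(frozen=True)
class PhantomSpec:
    """Description of a synthetic scene.

    ``objects`` is a sequence of ``(kind, geometry, intensity)`` with
    ``kind`` one of ``disk`` (geometry ``(row, col, radius)``), ``rectangle``
    (``(row0, col0, height, width)``) or ``ring`` (``(row, col, r_outer,
    r_inner)``); all geometry in pixels, intensities in [0, 1].  Every object
    intensity must differ from the background by at least ``min_contrast``.
    ``noise`` is ``(model, level)`` and ``bias`` is ``(strength, scale)``.
    """

    shape: tuple[int, int] = (128, 128)
    objects: Sequence[tuple] = field(default_factory=tuple)
    background: float = 0.2
    noise: tuple[str, float] = ("none", 0.0)
    bias: tuple[float, float] = (0.0, 16.0)
    seed: int = 0
    min_contrast: float = 0.2


def _rasterize(kind: str, geom, shape) -> np.ndarray:
    n, m = shape
    rr, cc = np.mgrid[0:n, 0:m]
    if kind == "disk":
        r0, c0, rad = geom
        if not (rad > 0 and rad <= r0 <= n - 1 - rad and rad <= c0 <= m - 1 - rad):
            raise ValueError(f"disk {geom} out of bounds for shape {shape}")
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
    if kind == "rectangle":
        r0, c0, h, w = geom
        if not (h > 0 and w > 0 and 0 <= r0 and 0 <= c0 and r0 + h <= n and c0 + w <= m):
            raise ValueError(f"rectangle {geom} out of bounds for shape {shape}")
        box = np.zeros(shape, bool)
        box[int(r0):int(r0 + h), int(c0):int(c0 + w)] = True
        return box
    if kind == "ring":
        r0, c0, r_out, r_in = geom
        if not (0 < r_in < r_out and r_out <= r0 <= n - 1 - r_out
                and r_out <= c0 <= m - 1 - r_out):
            raise ValueError(f"ring {geom} out of bounds for shape {shape}")
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        return (d2 <= r_out**2) & (d2 > r_in**2)
    raise ValueError(f"unknown object kind {kind!r}")


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Clean piecewise-constant image and its ground-truth foreground mask.

    Later objects overwrite earlier ones; the mask is the union of all
    objects.  Deterministic given the spec.
    """
    if not 0 <= spec.background <= 1:
        raise ValueError("background intensity must lie in [0, 1]")
    image = np.full(spec.shape, float(spec.background))
    mask = np.zeros(spec.shape, bool)
    for kind, geom, intensity in spec.objects:
        if not 0 <= intensity <= 1:
            raise ValueError("object intensities must lie in [0, 1]")
        if abs(intensity - spec.background) < spec.min_contrast:
            raise ValueError(
                f"object intensity {intensity} too close to background "
                f"{spec.background} (min contrast {spec.min_contrast})")
        obj = _rasterize(kind, geom, spec.shape)
        image[obj] = intensity
        mask |= obj
    return image, mask


def add_noise(image, model: str, level: float, seed: int = 0) -> np.ndarray:
    """Corrupt an image with seeded noise, clipping the result to [0, 1].

    ``speckle``: multiplicative ``u·(1+n)``, n uniform zero-mean with
    variance ``level``.  ``gaussian``: additive, variance ``level``.
    ``salt_pepper``: a fraction ``level`` of pixels forced to 0 or 1 with
    equal probability.  ``level = 0`` (or model ``none``) is the identity.
    """
    u = np.asarray(image, dtype=float)
    if level < 0:
        raise ValueError("noise level must be non-negative")
    if model not in NOISE_MODELS:
        raise ValueError(f"unknown noise model {model!r}")
    if model == "none" or level == 0:
        return u.copy()
    rng = np.random.default_rng(seed)
    if model == "speckle":
        half_width = np.sqrt(3.0 * level)  # Var(U[-a,a]) = a^2/3
        n = rng.uniform(-half_width, half_width, size=u.shape)
        out = u * (1.0 + n)
    elif model == "gaussian":
        out = u + rng.normal(0.0, np.sqrt(level), size=u.shape)
    else:  # salt_pepper
        if level > 1:
            raise ValueError("salt_pepper level is a pixel fraction in [0, 1]")
        out = u.copy()
        hit = rng.random(u.shape) < level
        out[hit] = rng.integers(0, 2, size=int(hit.sum())).astype(float)
    return np.clip(out, 0.0, 1.0)


def add_bias_field(image, strength: float, scale: float, seed: int = 0) -> np.ndarray:
    """Multiply by a smooth positive field ``1 + strength·g``, ``g ∈ [−1, 1]``.

    ``g`` is seeded white noise smoothed with a Gaussian of width ``scale``
    pixels and normalized to max |g| = 1, emulating slowly varying
    illumination/gain inhomogeneity.  Output clipped to [0, 1];
    ``strength = 0`` is the identity.
    """
    u = np.asarray(image, dtype=float)
    if strength < 0 or scale <= 0:
        raise ValueError("strength must be >= 0 and scale > 0")
    if strength == 0:
        return u.copy()
    rng = np.random.default_rng(seed)
    g = gaussian_filter(rng.standard_normal(u.shape), scale, mode="reflect")
    g /= np.max(np.abs(g))
    return np.clip(u * (1.0 + strength * g), 0.0, 1.0)


def realize(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a spec end to end: rasterize, apply bias field, then noise.

    Returns the corrupted image and the (uncorrupted) ground-truth mask.
    """
    image, mask = make_phantom(spec)
    strength, scale = spec.bias
    if strength > 0:
        image = add_bias_field(image, strength, scale, seed=spec.seed + 1)
    model, level = spec.noise
    image = add_noise(image, model, level, seed=spec.seed)
    return image, mask


def three_object_spec(
    shape: tuple[int, int] = (128, 128),
    noise: tuple[str, float] = ("speckle", 0.2),
    seed: int = 0,
    bias: tuple[float, float] = (0.0, 16.0),
) -> PhantomSpec:
    """The standard noisy test scene: disk + rectangle + ring on a 0.2 background.

    Three foreground components of distinct intensities (0.85, 0.7, 0.9)
    emulate a multi-object scene; the default corruption is speckle noise of
    variance 0.2.
    """
    n, m = shape
    sr, sc = n / 128.0, m / 128.0  # keep proportions on other grid sizes
    objects = (
        ("disk", (int(38 * sr), int(36 * sc), int(round(20 * min(sr, sc)))), 0.85),
        ("rectangle", (int(72 * sr), int(66 * sc), int(40 * sr), int(44 * sc)), 0.7),
        ("ring", (int(40 * sr), int(92 * sc), int(round(16 * min(sr, sc))),
                  int(round(7 * min(sr, sc)))), 0.9),
    )
    return PhantomSpec(shape=shape, objects=objects, background=0.2,
                       noise=noise, bias=bias, seed=seed)
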