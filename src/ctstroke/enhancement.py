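"""Cubic tone-curve contrast enhancement.

A single cubic y = a x^3 + b x^2 + c x is fitted per image on the display
scale [0, 255].  Four constraints pin the curve: it passes through (0, 0)
and (255, 255), and its inflection point sits at abscissa A with zero slope
(f'(A) = f''(A) = 0), so the curve is the monotone "S" that flattens around
A and steepens elsewhere.  A is placed at 70% of the image's intensity
range, which pushes the flat (contrast-compressing) part into the bright
tissue band and stretches the darker structures apart.

Closed forms: a = 1 / (255^2 - 3*255*A + 3 A^2), b = -3 a A,
c = 1 - a*255^2 - b*255.  The denominator of a is positive for every real A
(negative discriminant), so a > 0 and f'(x) = 3a (x - A)^2 >= 0: the map
never reorders pixel values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, ParameterError

FULL_SCALE = 255.0
DEFAULT_INFLECTION_FACTOR = 0.7

_TOL = 1e-9


@dataclass(frozen=True)
class CubicCurve:
    """Monotone cubic tone curve y = a x^3 + b x^2 + c x with inflection at A."""

    a: float
    b: float
    c: float
    inflection: float

    def __post_init__(self):
        if self.a <= 0:
            raise ParameterError("cubic coefficient a must be positive")
        if abs(self(FULL_SCALE) - FULL_SCALE) > 1e-6:
            raise ParameterError("curve must map 255 to 255")
        if abs(self.derivative(self.inflection)) > 1e-6:
            raise ParameterError("curve slope at the inflection must vanish")
        if abs(6 * self.a * self.inflection + 2 * self.b) > 1e-6:
            raise ParameterError("curvature at the inflection must vanish")

    def __call__(self, x):
        x = np.asarray(x, dtype=np.float64)
        out = ((self.a * x + self.b) * x + self.c) * x
        return out if out.ndim else float(out)

    def derivative(self, x):
        x = np.asarray(x, dtype=np.float64)
        out = (3 * self.a * x + 2 * self.b) * x + self.c
        return out if out.ndim else float(out)


def compute_inflection(img: np.ndarray,
                       factor: float = DEFAULT_INFLECTION_FACTOR) -> float:
    """Inflection abscissa A = min + factor * (max - min) of the image."""
    img = np.asarray(img)
    if img.size == 0:
        raise InputError("cannot compute the inflection of an empty image")
    lo = float(img.min())
    hi = float(img.max())
    return lo + factor * (hi - lo)


def fit_cubic(A: float) -> CubicCurve:
    """Fit the four-constraint cubic with inflection abscissa ``A``.

    Raises
    ------
    ParameterError
        if A lies outside the open interval (0, 255).
    """
    if not (0.0 < A < FULL_SCALE):
        raise ParameterError(f"inflection abscissa must be in (0, 255), got {A}")
    denom = FULL_SCALE ** 2 - 3 * FULL_SCALE * A + 3 * A * A
    a = 1.0 / denom
    b = -3.0 * a * A
    c = 1.0 - a * FULL_SCALE ** 2 - b * FULL_SCALE
    return CubicCurve(a=a, b=b, c=c, inflection=A)


def apply_curve(img: np.ndarray, curve: CubicCurve) -> np.ndarray:
    """Apply the tone curve pointwise, clamped to [0, 255].

    Output stays real-valued; quantisation is deferred to final rendering so
    later brightness comparisons are not polluted by rounding.
    """
    img = np.asarray(img, dtype=np.float64)
    return np.clip(curve(img), 0.0, FULL_SCALE)


def enhance(img: np.ndarray,
            factor: float = DEFAULT_INFLECTION_FACTOR) -> tuple[np.ndarray, CubicCurve]:
    """Convenience wrapper: fit the image's curve and apply it.

    A constant image has zero range, putting A on the domain boundary where
    the cubic degenerates; it is returned unchanged with the identity-like
    midpoint curve.
    """
    A = compute_inflection(img, factor)
    if not (0.0 < A < FULL_SCALE):
        A = FULL_SCALE / 2.0
    curve = fit_cubic(A)
    return apply_curve(img, curve), curve
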