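"""Angle arithmetic and circular densities on the 360-degree response circle.

Conventions
-----------
* Locations live on a circle measured in **degrees**; canonical range ``[0, 360)``.
* Signed errors (differences between two locations) live in ``[-180, 180)``,
  closed at -180, so every antipodal difference has a single representative.
* Clockwise displacements are **negative** degrees.
* Densities are returned **per degree**, so a uniform response distribution has
  density ``1/360`` everywhere.  Internally the von Mises density is evaluated
  in radians (exponentially scaled Bessel functions for numerical stability)
  and converted once through the Jacobian ``pi/180``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import i0e

__all__ = [
    "wrap_signed",
    "wrap_circle",
    "circ_dist",
    "abs_error",
    "circ_mean",
    "vonmises_pdf",
    "vonmises_logpdf",
]

#: concentrations above this would overflow exp(kappa) pathways; rejected outright
KAPPA_OVERFLOW = 700.0

_DEG2RAD = np.pi / 180.0


def _as_finite_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {x!r}")
    return arr


def _maybe_scalar(arr: np.ndarray, like) -> np.ndarray | float:
    if np.isscalar(like) or (isinstance(like, np.ndarray) and like.ndim == 0):
        return float(arr)
    return arr


def wrap_signed(angle):
    """Wrap an angle in degrees to the signed canonical range ``[-180, 180)``."""
    arr = _as_finite_array(angle, "angle")
    wrapped = (arr + 180.0) % 360.0 - 180.0
    # a tiny negative modulo input can round up to exactly 360, i.e. +180 here
    wrapped = np.where(wrapped >= 180.0, -180.0, wrapped)
    return _maybe_scalar(wrapped, angle)


def wrap_circle(angle):
    """Wrap an angle in degrees to the canonical location range ``[0, 360)``."""
    arr = _as_finite_array(angle, "angle")
    wrapped = arr % 360.0
    # a tiny negative input can round up to exactly 360.0 under %
    wrapped = np.where(wrapped >= 360.0, 0.0, wrapped)
    return _maybe_scalar(wrapped, angle)


def circ_dist(a, b):
    """Signed circular difference ``a - b`` in degrees, in ``[-180, 180)``.

    Antisymmetric up to the closed -180 boundary:
    ``circ_dist(a, b) == -circ_dist(b, a)`` except when the difference is
    exactly 180 degrees, where both return -180.
    """
    arr_a = _as_finite_array(a, "a")
    arr_b = _as_finite_array(b, "b")
    out = (arr_a - arr_b + 180.0) % 360.0 - 180.0
    out = np.where(out >= 180.0, -180.0, out)
    if np.isscalar(a) and np.isscalar(b):
        return float(out)
    return out


def abs_error(target, response):
    """Absolute circular error between target and response, in ``[0, 180]``.

    This is the trial-level accuracy measure of the continuous-report task:
    the absolute difference between the studied location and the recreated
    location, with larger values meaning a less accurate response.
    """
    out = np.abs(circ_dist(response, target))
    if np.isscalar(target) and np.isscalar(response):
        return float(out)
    return out


def circ_mean(angles, tol: float = 1e-8):
    """Circular mean direction of a set of angles, in degrees ``[0, 360)``.

    The mean is the direction of the vector resultant.  When the mean
    resultant length falls below ``tol`` (e.g. an antipodal pair) the mean
    direction is undefined and a ``ValueError`` is raised.
    """
    arr = _as_finite_array(angles, "angles")
    if arr.size == 0:
        raise ValueError("circ_mean of an empty set is undefined")
    rad = arr * _DEG2RAD
    c = np.cos(rad).mean()
    s = np.sin(rad).mean()
    if np.hypot(c, s) < tol:
        raise ValueError(
            f"circular mean undefined: mean resultant length {np.hypot(c, s):.3g} < {tol:g}"
        )
    return float(wrap_circle(np.degrees(np.arctan2(s, c))))


def _check_kappa(kappa: float) -> float:
    kappa = float(kappa)
    if not np.isfinite(kappa) or kappa < 0.0:
        raise ValueError(f"kappa must be finite and >= 0, got {kappa!r}")
    if kappa > KAPPA_OVERFLOW:
        raise ValueError(f"kappa={kappa} exceeds overflow guard {KAPPA_OVERFLOW}")
    return kappa


def vonmises_logpdf(x, mu, kappa):
    """Log von Mises density per degree at ``x`` for centre ``mu``.

    Uses ``log f = kappa*(cos d - 1) - log(2*pi*i0e(kappa)) + log(pi/180)``
    with ``d = circ_dist(x, mu)`` in radians; ``i0e`` keeps the expression
    stable for large concentrations.
    """
    kappa = _check_kappa(kappa)
    d = np.asarray(circ_dist(x, mu), dtype=float) * _DEG2RAD
    out = kappa * (np.cos(d) - 1.0) - np.log(2.0 * np.pi * i0e(kappa)) + np.log(_DEG2RAD)
    if np.isscalar(x) and np.isscalar(mu):
        return float(out)
    return out


def vonmises_pdf(x, mu, kappa):
    """Von Mises density per degree at ``x`` for centre ``mu``, concentration ``kappa``.

    At ``kappa == 0`` this is exactly the uniform density ``1/360``; the
    density integrates to 1 over any full 360-degree interval.
    """
    kappa = _check_kappa(kappa)
    if kappa == 0.0:
        d = np.asarray(circ_dist(x, mu), dtype=float)  # validates inputs
        out = np.full_like(d, 1.0 / 360.0)
    else:
        d = np.asarray(circ_dist(x, mu), dtype=float) * _DEG2RAD
        out = np.exp(kappa * (np.cos(d) - 1.0)) / (2.0 * np.pi * i0e(kappa)) * _DEG2RAD
    if np.isscalar(x) and np.isscalar(mu):
        return float(out)
    return out
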