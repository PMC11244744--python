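"""Hyperbolic curve families for the CSF-Aβ42 vs amyloid-PET relationship.

The imbalance model represents the joint distribution of CSF-Aβ42 (ordinate,
pg/mL or z-units) and global amyloid-PET burden (abscissa, Centiloid) by a
three-parameter, strictly decreasing hyperbola-like curve.  Three algebraic
families are supported; all downstream geometry (projection, scoring) is
form-generic:

``reciprocal``  y = a + b / (x - c)        (rectangular hyperbola)
``rational``    y = a + b * x / (x - c)    (saturating rational; default)
``log10``       y = a + b * log10(x - c)

The ``rational`` family is the default because published three-parameter fits
of Centiloid against CSF-Aβ42 of magnitude (a ≈ 3.7e3 pg/mL, b ≈ -2.9e3,
c ≈ -0.3 CL) are strictly decreasing under this family (the level at CL = 0
is ``a`` and the high-burden asymptote is ``a + b``), whereas the
rectangular family with parameters of that magnitude would be increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "CURVE_FORMS",
    "HyperbolaParams",
    "evaluate_curve",
    "curve_derivative",
    "pole_location",
    "is_strictly_decreasing",
    "CurveDomainError",
]

CURVE_FORMS = ("rational", "reciprocal", "log10")

#: grid resolution used for monotonicity screening
_MONO_GRID = 512


class CurveDomainError(ValueError):
    """Raised when the curve is evaluated at or beyond a pole / branch edge."""


@dataclass(frozen=True)
class HyperbolaParams:
    """Parameters of one decreasing hyperbolic curve.

    Parameters
    ----------
    form : str
        Curve family, one of :data:`CURVE_FORMS`.
    a : float
        Level parameter (y-units).
    b : float
        Scale parameter (units depend on the family).
    c : float
        Horizontal shift (x-units); the pole / branch point of the family.
    domain : tuple of float
        Closed x-interval on which the curve is used.  Must not contain the
        pole.
    """

    form: str
    a: float
    b: float
    c: float
    domain: tuple[float, float] = field(default=(0.0, 100.0))

    def __post_init__(self) -> None:
        if self.form not in CURVE_FORMS:
            raise ValueError(
                f"unknown curve form {self.form!r}; expected one of {CURVE_FORMS}"
            )
        lo, hi = self.domain
        if not (np.isfinite(lo) and np.isfinite(hi)) or not lo < hi:
            raise ValueError(f"invalid domain {self.domain!r}")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "a": float(self.a),
            "b": float(self.b),
            "c": float(self.c),
            "domain": [float(self.domain[0]), float(self.domain[1])],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HyperbolaParams":
        return cls(
            form=d["form"],
            a=float(d["a"]),
            b=float(d["b"]),
            c=float(d["c"]),
            domain=(float(d["domain"][0]), float(d["domain"][1])),
        )


def pole_location(form: str, c: float) -> float | None:
    """x-coordinate at which the family is singular (None if finite there).

    All three families are singular (or branch-limited) at x = c: the two
    hyperbolic families have a pole, the log family a vertical branch edge
    and no values for x <= c.
    """
    return c


def _raw_evaluate(form: str, a: float, b: float, c: float, x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        if form == "reciprocal":
            return a + b / (x - c)
        if form == "rational":
            return a + b * x / (x - c)
        if form == "log10":
            return a + b * np.log10(x - c)
    raise ValueError(f"unknown curve form {form!r}")


def _raw_derivative(form: str, a: float, b: float, c: float, x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        if form == "reciprocal":
            return -b / (x - c) ** 2
        if form == "rational":
            return -b * c / (x - c) ** 2
        if form == "log10":
            return b / ((x - c) * np.log(10.0))
    raise ValueError(f"unknown curve form {form!r}")


def _raw_second_derivative(
    form: str, a: float, b: float, c: float, x: np.ndarray
) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        if form == "reciprocal":
            return 2.0 * b / (x - c) ** 3
        if form == "rational":
            return 2.0 * b * c / (x - c) ** 3
        if form == "log10":
            return -b / ((x - c) ** 2 * np.log(10.0))
    raise ValueError(f"unknown curve form {form!r}")


def evaluate_curve(params: HyperbolaParams, x, *, check_domain: bool = True):
    """Predicted CSF level at amyloid-PET burden ``x``.

    Raises :class:`CurveDomainError` if any ``x`` sits at/beyond the pole of
    the family (or outside the stated domain when ``check_domain``).
    """
    x_arr = np.asarray(x, dtype=float)
    scalar = x_arr.ndim == 0
    x_arr = np.atleast_1d(x_arr)
    if check_domain:
        lo, hi = params.domain
        bad = (x_arr < lo) | (x_arr > hi) | ~np.isfinite(x_arr)
        if bad.any():
            offending = x_arr[bad][0]
            raise CurveDomainError(
                f"x = {offending!r} outside curve domain [{lo}, {hi}] "
                f"for form {params.form!r}"
            )
    y = _raw_evaluate(params.form, params.a, params.b, params.c, x_arr)
    if check_domain and not np.all(np.isfinite(y)):
        offending = x_arr[~np.isfinite(y)][0]
        raise CurveDomainError(
            f"curve form {params.form!r} is singular at x = {offending!r} (pole at c = {params.c})"
        )
    return float(y[0]) if scalar else y


def curve_derivative(params: HyperbolaParams, x):
    """dy/dx of the curve at ``x`` (no domain check; used by geometry)."""
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    d = _raw_derivative(params.form, params.a, params.b, params.c, x_arr)
    return float(d[0]) if np.asarray(x).ndim == 0 else d


def is_strictly_decreasing(
    params: HyperbolaParams, n_grid: int = _MONO_GRID
) -> bool:
    """True when the curve is finite and strictly decreasing over its domain."""
    lo, hi = params.domain
    pole = pole_location(params.form, params.c)
    if pole is not None and lo <= pole <= hi:
        return False
    if params.form == "log10" and lo <= params.c:
        return False
    grid = np.linspace(lo, hi, n_grid)
    y = _raw_evaluate(params.form, params.a, params.b, params.c, grid)
    if not np.all(np.isfinite(y)):
        return False
    return bool(np.all(np.diff(y) < 0))


def monotonicity_violation(params: HyperbolaParams, n_grid: int = _MONO_GRID) -> float:
    """Nonnegative magnitude of the violation of the decreasing constraint.

    Zero for a valid curve.  Used as a smooth-ish penalty by the fitter so the
    search can traverse infeasible regions: poles inside the domain contribute
    proportionally to how deep the pole sits in the domain; non-monotone
    stretches contribute the summed positive increments of y.
    """
    lo, hi = params.domain
    width = hi - lo
    pole = pole_location(params.form, params.c)
    viol = 0.0
    if pole is not None and lo <= pole <= hi:
        # depth of incursion, normalized by domain width
        viol += 1.0 + min(pole - lo, hi - pole) / width
        return viol
    if params.form == "log10" and lo <= params.c:
        viol += 1.0 + (params.c - lo) / width
        return viol
    grid = np.linspace(lo, hi, n_grid)
    y = _raw_evaluate(params.form, params.a, params.b, params.c, grid)
    if not np.all(np.isfinite(y)):
        return 2.0
    dy = np.diff(y)
    scale = max(np.abs(y).max(), 1.0)
    viol += float(np.clip(dy, 0.0, None).sum() / scale)
    return viol


def auto_domain(
    form: str, c: float, x: Iterable[float], pad: float = 5.0
) -> tuple[float, float]:
    """Default curve domain: data range padded by ``pad``, clamped off the pole.

    The domain is [min(x) - pad, max(x) + pad]; if the family's pole at
    ``c`` would fall inside, the nearer edge is pulled to a small safety
    margin away from it.
    """
    x_arr = np.asarray(list(x), dtype=float)
    lo = float(np.min(x_arr)) - pad
    hi = float(np.max(x_arr)) + pad
    # the margin is kept tiny: the near-pole cliff is a legitimate part of
    # the curve and carries the projections of low-burden subjects
    margin = max(1e-6 * (hi - lo), 1e-12)
    if lo <= c <= hi:
        # pole inside: keep the side holding the data
        mid = float(np.median(x_arr))
        if mid >= c:
            lo = c + margin
        else:
            hi = c - margin
    if form == "log10" and lo <= c:
        lo = c + margin
    if not lo < hi:
        raise ValueError("degenerate auto domain; supply an explicit domain")
    return (lo, hi)
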