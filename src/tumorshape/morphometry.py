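"""Tumor-volume estimators and the spheroid-ellipsoid discrepancy (SED).

A tumor is described by its three pathologic diameters ``a >= b >= c`` (cm).
Four volume estimators are in use clinically, all of the ellipsoid family
``V = 4/3 * pi * r1 * r2 * r3`` with semi-axes taken from the diameters:

======== =======================================
spheroid ``4/3 pi (a/2)^3``       (a only; STV)
oblate   ``4/3 pi (a/2)^2 (b/2)``
prolate  ``4/3 pi (a/2) (c/2)^2``
ellipsoid``4/3 pi (a/2)(b/2)(c/2)`` (all three; ETV)
======== =======================================

The spheroid estimator is the volume implied by the traditional
longest-diameter staging convention; the ellipsoid estimator uses all three
diameters.  Their proportional gap

    SED = (STV - ETV) / STV = 1 - b*c / a**2

is a dimensionless eccentricity statistic: 0 for a perfect sphere
(a = b = c), approaching 1 as the tumor flattens or elongates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

__all__ = [
    "TumorDimensions",
    "VolumeSet",
    "SedResult",
    "DimensionError",
    "normalize_dimensions",
    "volume_set",
    "sed",
    "relative_diameters",
    "is_suspect_thin",
    "sed_from_sorted",
]

#: Pathology rulers resolve ~0.1 cm; a smallest diameter below this default
#: is flagged as suspect rather than rejected.
DEFAULT_MIN_THICKNESS_CM = 0.05


class DimensionError(ValueError):
    """A tumor diameter violates the domain preconditions."""


@dataclass(frozen=True)
class TumorDimensions:
    """Ordered triple of pathologic diameters in cm, ``a >= b >= c > 0``."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise DimensionError(f"diameter {name!r} is not finite: {v!r}")
            if v <= 0:
                raise DimensionError(f"diameter {name!r} must be > 0, got {v!r}")
        if not (self.a >= self.b >= self.c):
            raise DimensionError(
                f"diameters must satisfy a >= b >= c, got ({self.a}, {self.b}, {self.c}); "
                "use normalize_dimensions() for unordered input"
            )

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.a, self.b, self.c)


@dataclass(frozen=True)
class VolumeSet:
    """The four volume estimators (cm^3) for one tumor.

    For any valid triple the ordering ``spheroid >= oblate >= ellipsoid >=
    prolate > 0`` holds, with equalities exactly where the corresponding
    diameters coincide.
    """

    spheroid: float
    oblate: float
    prolate: float
    ellipsoid: float


@dataclass(frozen=True)
class SedResult:
    """SED with the two volumes it is derived from."""

    sed: float
    stv: float
    etv: float


def normalize_dimensions(d1: float, d2: float, d3: float) -> TumorDimensions:
    """Sort three measured diameters (cm) into the ``a >= b >= c`` convention.

    Pathology reports may list the diameters in any order; the volume formulas
    are asymmetric in a, b, c, so sorting is mandatory before any computation.

    Raises
    ------
    DimensionError
        If any value is non-positive or non-finite; the message names the
        offending input position (d1/d2/d3).
    """
    for name, v in (("d1", d1), ("d2", d2), ("d3", d3)):
        try:
            fv = float(v)
        except (TypeError, ValueError) as exc:
            raise DimensionError(f"diameter {name!r} is not numeric: {v!r}") from exc
        if not math.isfinite(fv):
            raise DimensionError(f"diameter {name!r} is not finite: {v!r}")
        if fv <= 0:
            raise DimensionError(f"diameter {name!r} must be > 0, got {v!r}")
    a, b, c = sorted((float(d1), float(d2), float(d3)), reverse=True)
    return TumorDimensions(a=a, b=b, c=c)


def volume_set(dims: TumorDimensions) -> VolumeSet:
    """Compute the four volume estimators (cm^3) from sorted diameters."""
    ra, rb, rc = dims.a / 2.0, dims.b / 2.0, dims.c / 2.0
    base = (4.0 / 3.0 * math.pi) * ra
    # shared-prefix factorization: monotone float multiplication then makes
    # spheroid >= oblate >= ellipsoid >= prolate exact, not just approximate
    return VolumeSet(
        spheroid=(base * ra) * ra,
        oblate=(base * ra) * rb,
        ellipsoid=(base * rb) * rc,
        prolate=(base * rc) * rc,
    )


def sed(dims: TumorDimensions) -> SedResult:
    """Spheroid-ellipsoid discrepancy: ``(STV - ETV)/STV = 1 - b*c/a**2``.

    Always in [0, 1); equals 0 exactly when a = b = c.
    """
    vols = volume_set(dims)
    value = (vols.spheroid - vols.ellipsoid) / vols.spheroid
    # clamp the tiny negative that floating cancellation can produce at a=b=c
    if -1e-12 < value < 0.0:
        value = 0.0
    return SedResult(sed=value, stv=vols.spheroid, etv=vols.ellipsoid)


def relative_diameters(dims: TumorDimensions) -> Tuple[float, float]:
    """Relative lengths (b/a, c/a) of the two shorter diameters, each in (0, 1]."""
    return (dims.b / dims.a, dims.c / dims.a)


def is_suspect_thin(dims: TumorDimensions, min_c: float = DEFAULT_MIN_THICKNESS_CM) -> bool:
    """Flag near-degenerate flat tumors (smallest diameter below ``min_c`` cm).

    Such records are kept in the analysis but flagged: pathology granularity
    is about 0.1 cm, so thinner values usually indicate transcription errors.
    """
    return dims.c < min_c


def sed_from_sorted(a, b, c):
    """Vectorised SED for arrays already sorted as a >= b >= c (cohort-scale path)."""
    import numpy as np

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    return 1.0 - (b * c) / (a * a)
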