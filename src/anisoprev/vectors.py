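"""Sphero-cylindrical <-> power-vector conversion and axis-safe averaging.

A refraction reading (sphere *S*, cylinder *C*, axis *alpha*) lives on a
half-turn manifold: axes 0 and 180 degrees describe the same cylinder.
Arithmetic on the raw triplet is therefore unsafe -- averaging axes 10 and
170 degrees as 90 is wrong.  The standard fix is Thibos' power-vector
decomposition

    SE  = S + C/2
    J0  = -(C/2) * cos(2*alpha)
    J45 = -(C/2) * sin(2*alpha)

where the double angle makes the representation single-valued.  SE is the
spherical equivalent, J0 the with/against-the-rule Jackson crossed-cylinder
component and J45 the oblique component, all in diopters.  In this space
every component is an ordinary Cartesian coordinate, so replicate readings
are averaged component-wise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "SpheroCylinder",
    "PowerVector",
    "InvalidMeasurementError",
    "InsufficientReplicatesError",
    "to_power_vector",
    "from_power_vector",
    "mean_refraction",
]


class InvalidMeasurementError(ValueError):
    """A refraction component is non-finite or otherwise unusable."""


class InsufficientReplicatesError(ValueError):
    """Fewer replicate readings than the protocol requires."""


@dataclass(frozen=True)
class SpheroCylinder:
    """One sphere/cylinder/axis reading in diopters, negative-cylinder form.

    Construction normalizes the reading:

    * positive-cylinder input is transposed to negative form
      ``(S + C, -C, axis + 90)``;
    * the axis is reduced modulo 180 into ``[0, 180)``;
    * a zero cylinder stores axis 0 (the axis is then meaningless).

    Parameters
    ----------
    sphere : float
        Spherical power S, diopters.
    cylinder : float
        Cylindrical power C, diopters.  Any sign on input; stored <= 0.
    axis : float
        Cylinder axis alpha, degrees.  Any value on input; stored in
        ``[0, 180)``.
    """

    sphere: float
    cylinder: float
    axis: float

    def __post_init__(self) -> None:
        s, c, a = float(self.sphere), float(self.cylinder), float(self.axis)
        if not (math.isfinite(s) and math.isfinite(c) and math.isfinite(a)):
            raise InvalidMeasurementError(
                f"non-finite refraction components: S={s}, C={c}, axis={a}"
            )
        if c > 0:  # transpose to negative-cylinder form
            s, c, a = s + c, -c, a + 90.0
        a %= 180.0
        if c == 0:
            a = 0.0
        object.__setattr__(self, "sphere", s)
        object.__setattr__(self, "cylinder", c)
        object.__setattr__(self, "axis", a)


@dataclass(frozen=True)
class PowerVector:
    """(SE, J0, J45) power-vector refraction, diopters."""

    se: float
    j0: float
    j45: float

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.se, self.j0, self.j45))):
            raise InvalidMeasurementError(
                f"non-finite power vector: ({self.se}, {self.j0}, {self.j45})"
            )

    @property
    def cylinder(self) -> float:
        """Implied (negative-form) cylinder power, ``-2 * sqrt(J0^2 + J45^2)``."""
        return -2.0 * math.hypot(self.j0, self.j45)


def to_power_vector(reading: SpheroCylinder) -> PowerVector:
    """Convert a normalized sphero-cylindrical reading to (SE, J0, J45)."""
    half_c = reading.cylinder / 2.0
    two_alpha = math.radians(2.0 * reading.axis)
    return PowerVector(
        se=reading.sphere + half_c,
        j0=-half_c * math.cos(two_alpha),
        j45=-half_c * math.sin(two_alpha),
    )


def from_power_vector(pv: PowerVector) -> SpheroCylinder:
    """Invert :func:`to_power_vector`.

    ``C = -2 * sqrt(J0^2 + J45^2)``, ``S = SE - C/2`` and
    ``alpha = atan2(J45, J0) / 2`` mapped into ``[0, 180)``; a zero
    cylinder reports axis 0.  (With C <= 0 the forward map scales
    ``(cos 2a, sin 2a)`` by the positive factor ``-C/2``, so the
    double angle is recovered directly from ``(J0, J45)``.)
    """
    c = -2.0 * math.hypot(pv.j0, pv.j45)
    if c == 0:
        return SpheroCylinder(sphere=pv.se, cylinder=0.0, axis=0.0)
    alpha = math.degrees(math.atan2(pv.j45, pv.j0)) / 2.0
    return SpheroCylinder(sphere=pv.se - c / 2.0, cylinder=c, axis=alpha % 180.0)


def mean_refraction(
    readings: Sequence[SpheroCylinder] | Iterable[SpheroCylinder],
    min_count: int = 3,
) -> PowerVector:
    """Average replicate readings of one eye in power-vector space.

    The mean is component-wise over (SE, J0, J45); raw axes are never
    averaged.  Raises :class:`InsufficientReplicatesError` when fewer than
    ``min_count`` readings are supplied.
    """
    pvs = [to_power_vector(r) for r in readings]
    if len(pvs) < min_count:
        raise InsufficientReplicatesError(
            f"got {len(pvs)} readings, protocol requires {min_count}"
        )
    n = len(pvs)
    return PowerVector(
        se=sum(p.se for p in pvs) / n,
        j0=sum(p.j0 for p in pvs) / n,
        j45=sum(p.j45 for p in pvs) / n,
    )
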