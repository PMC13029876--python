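"""Statics of the double-ring triangular load-cell interface.

Three compression load cells sit on a circle of radius ``R`` between two
parallel fixator rings.  An axial distraction load whose centre of resistance
is offset from the ring centre by an eccentricity ``e`` produces a bending
moment ``M = F·e``; the three-point support is statically determinate, so the
individual cell forces follow from one force and two moment equations.  The
sum of the three readings recovers the total axial force regardless of where
the load acts, and the differential readings recover the load centroid.

Sign convention: the distraction axis is z, compression is positive, sensor 1
sits on the +x axis and the sensors are numbered counter-clockwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError

__all__ = [
    "SensorArrayGeometry",
    "AxialLoadCase",
    "SensorTriplet",
    "distribute_load",
    "recover_axial_force",
    "recover_load_centroid",
]

#: Default ring radius (m); plausible for an ovine ring fixator. Free config.
DEFAULT_RING_RADIUS = 0.05

_DEFAULT_ANGLES = (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)


@dataclass(frozen=True)
class SensorArrayGeometry:
    """Positions of the three load cells on the sensor circle.

    Parameters
    ----------
    ring_radius : float
        Radius of the circle the cells sit on (m), > 0.
    sensor_angles : tuple of float
        Angular positions (rad) of the three cells, counter-clockwise from
        the +x axis.  Default is the equidistant 120° layout.
    """

    ring_radius: float = DEFAULT_RING_RADIUS
    sensor_angles: tuple[float, float, float] = _DEFAULT_ANGLES
    axis_convention: str = "z-compression-positive"

    def __post_init__(self) -> None:
        if not self.ring_radius > 0:
            raise GeometryError(f"ring_radius must be > 0, got {self.ring_radius}")
        if len(self.sensor_angles) != 3:
            raise GeometryError("exactly three sensor angles are required")

    @property
    def positions(self) -> np.ndarray:
        """(3, 2) in-plane sensor positions (m)."""
        ang = np.asarray(self.sensor_angles, dtype=float)
        return self.ring_radius * np.column_stack([np.cos(ang), np.sin(ang)])

    @property
    def is_equidistant(self) -> bool:
        """True when the layout is (a rotation of) the 120° pattern."""
        d = np.diff(np.sort(np.mod(self.sensor_angles, 2 * np.pi)))
        return bool(np.allclose(d, 2 * np.pi / 3, atol=1e-12))


@dataclass(frozen=True)
class AxialLoadCase:
    """An eccentric axial load on the sensor plane.

    ``axial_force`` is the total compressive force (N, >= 0) and
    ``eccentricity`` the in-plane offset (m) of the load centroid from the
    ring centre.  The implied bending moment is ``M = F · e``.
    """

    axial_force: float
    eccentricity: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not np.isfinite(self.axial_force) or self.axial_force < 0:
            raise ValueError(f"axial_force must be finite and >= 0, got {self.axial_force}")
        if len(self.eccentricity) != 2 or not np.all(np.isfinite(self.eccentricity)):
            raise ValueError("eccentricity must be a finite 2-vector")

    @property
    def moment(self) -> np.ndarray:
        """In-plane moment vector F·e (N·m)."""
        return self.axial_force * np.asarray(self.eccentricity, dtype=float)


@dataclass(frozen=True)
class SensorTriplet:
    """One reading per load cell (N, compression positive)."""

    f1: float
    f2: float
    f3: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.f1, self.f2, self.f3])):
            raise ValueError("sensor readings must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.f1, self.f2, self.f3], dtype=float)


def _equilibrium_matrix(geom: SensorArrayGeometry) -> np.ndarray:
    p = geom.positions
    return np.vstack([np.ones(3), p[:, 0], p[:, 1]])


def distribute_load(load: AxialLoadCase, geom: SensorArrayGeometry | None = None) -> SensorTriplet:
    """Distribute an eccentric axial load onto the three cells.

    Solves the statically determinate 3×3 system: force balance
    ``ΣFi = F`` plus the two in-plane moment balances ``ΣFi·pi = F·e``.

    Raises
    ------
    GeometryError
        If the sensors are collinear (singular statics) or the load centroid
        lies on/outside the sensor circle (``|e| >= R``), where a no-tension
        solution is not guaranteed.
    """
    geom = geom or SensorArrayGeometry()
    e = np.asarray(load.eccentricity, dtype=float)
    if np.hypot(*e) >= geom.ring_radius:
        raise GeometryError(
            f"load centroid |e|={np.hypot(*e):.4g} m lies outside the sensor "
            f"circle R={geom.ring_radius:.4g} m"
        )
    a = _equilibrium_matrix(geom)
    if abs(np.linalg.det(a)) < 1e-12 * geom.ring_radius**2:
        raise GeometryError("sensor positions are collinear; statics are singular")
    rhs = np.array([load.axial_force, *load.moment])
    forces = np.linalg.solve(a, rhs)
    if np.any(forces < -1e-9 * max(load.axial_force, 1.0)):
        warnings.warn(
            "distribution implies tension at a compression-only cell",
            stacklevel=2,
        )
    return SensorTriplet(*forces)


def distribute_load_closed_form(
    load: AxialLoadCase, geom: SensorArrayGeometry | None = None
) -> SensorTriplet:
    """Closed-form distribution for the equidistant 120° layout.

    ``Fi = F(1/3 + 2(e·pi)/(3R²))``; only valid when the layout is
    equidistant (``Σpi = 0``).  Serves as an independent cross-check of
    :func:`distribute_load`.
    """
    geom = geom or SensorArrayGeometry()
    if not geom.is_equidistant:
        raise GeometryError("closed form requires the equidistant 120° layout")
    e = np.asarray(load.eccentricity, dtype=float)
    p = geom.positions
    forces = load.axial_force * (1.0 / 3.0 + 2.0 * (p @ e) / (3.0 * geom.ring_radius**2))
    return SensorTriplet(*forces)


def recover_axial_force(readings: SensorTriplet) -> float:
    """Total axial force: the plain sum F1+F2+F3, invariant to any moment."""
    return float(readings.as_array().sum())


def recover_load_centroid(
    readings: SensorTriplet,
    geom: SensorArrayGeometry | None = None,
    *,
    total_force_tol: float = 1e-9,
) -> np.ndarray:
    """Recover the load centroid ``e = (ΣFi·pi) / ΣFi`` from the readings.

    A pure moment imbalance shows up as a differential reading between the
    cells; the force-weighted mean of the sensor positions is the point where
    the resultant acts.

    Raises
    ------
    ValueError
        If the total force is below ``total_force_tol`` (centroid undefined).
    """
    geom = geom or SensorArrayGeometry()
    f = readings.as_array()
    total = f.sum()
    if abs(total) <= total_force_tol:
        raise ValueError("total force ~ 0; load centroid is undefined")
    return (f @ geom.positions) / total
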