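"""Embedding-vessel geometry and the axial colony-position distribution.

A viable cell mixed uniformly into a gel-filled vessel founds a colony at a
uniformly random point of the gel volume.  Projected onto the vessel axis,
the colony position ``x`` (measured from the apex/tip toward the base, in mm)
is therefore distributed proportionally to the cross-sectional area at ``x``:

* circular cone / square pyramid:  ``pdf(x) = 3 x^2 / h^3``  (area ∝ x²)
* wedge (one linear taper):        ``pdf(x) = 2 x / h^2``
* cylinder (no taper):             ``pdf(x) = 1 / h``

The cone's cubic CDF ``(x/h)^3`` is what gives the assay its dynamic range:
most colonies sit near the base, and the position of the first few colonies
from the tip encodes the density.

Lengths are millimetres and volumes microlitres throughout (1 µL = 1 mm³).
Axial length and volume are independent fields: a real pipette tip is not an
exact cone, and the estimator only needs ``h`` for geometry and ``V`` for
concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConeGeometry",
    "GEOMETRY_PROFILES",
    "axial_pdf",
    "axial_cdf",
    "axial_inverse_cdf",
]

#: shapes whose axial density is the cubic cone law (cross-section ∝ x²)
_CONELIKE = {"circular_cone", "square_pyramid"}
_SHAPES = _CONELIKE | {"cylinder", "wedge"}


@dataclass(frozen=True)
class ConeGeometry:
    """An axially symmetric embedding vessel.

    Parameters
    ----------
    shape
        One of ``circular_cone``, ``square_pyramid``, ``cylinder``, ``wedge``.
        Cone and square pyramid share the same axial density.
    axial_length_mm
        Length ``h`` of the vessel axis, apex to base (mm).
    volume_uL
        Total gel volume ``V`` (µL).  Independent of ``h``; only the density
        calculation uses it.
    """

    shape: str = "circular_cone"
    axial_length_mm: float = 36.0
    volume_uL: float = 150.0

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(
                f"unknown shape {self.shape!r}; expected one of {sorted(_SHAPES)}"
            )
        if not self.axial_length_mm > 0:
            raise ValueError("axial_length_mm must be positive")
        if not self.volume_uL > 0:
            raise ValueError("volume_uL must be positive")

    # -- convenience -------------------------------------------------------
    @property
    def volume_mL(self) -> float:
        return self.volume_uL / 1000.0

    @property
    def h(self) -> float:
        return self.axial_length_mm

    def pdf(self, x):
        return axial_pdf(self, x)

    def cdf(self, x):
        return axial_cdf(self, x)

    def inverse_cdf(self, u):
        return axial_inverse_cdf(self, u)


#: named geometry profiles usable from config files and the CLI.
#: "p200" is the standard 200 µL pipette tip loaded with 150 µL of gel.
GEOMETRY_PROFILES: dict[str, ConeGeometry] = {
    "p200": ConeGeometry("circular_cone", 36.0, 150.0),
    "p1000": ConeGeometry("circular_cone", 60.0, 750.0),
}


def _check_domain(value, lo: float, hi: float, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < lo) or np.any(arr > hi):
        raise ValueError(f"{name} outside [{lo:g}, {hi:g}]")
    return arr


def axial_pdf(geom: ConeGeometry, x):
    """Probability density of a colony's axial position at ``x`` mm from the tip.

    Raises ``ValueError`` if any ``x`` lies outside ``[0, h]``.
    """
    h = geom.axial_length_mm
    xa = _check_domain(x, 0.0, h, "x")
    if geom.shape in _CONELIKE:
        out = 3.0 * xa**2 / h**3
    elif geom.shape == "wedge":
        out = 2.0 * xa / h**2
    else:  # cylinder
        out = np.full_like(xa, 1.0 / h)
    return out if out.ndim else float(out)


def axial_cdf(geom: ConeGeometry, x):
    """Cumulative probability that a colony lies within ``x`` mm of the tip."""
    h = geom.axial_length_mm
    xa = _check_domain(x, 0.0, h, "x")
    if geom.shape in _CONELIKE:
        out = (xa / h) ** 3
    elif geom.shape == "wedge":
        out = (xa / h) ** 2
    else:
        out = xa / h
    return out if out.ndim else float(out)


def axial_inverse_cdf(geom: ConeGeometry, u):
    """Axial position below which a fraction ``u`` of colonies is expected.

    Closed form for every supported shape; for the cone ``x = h u^(1/3)``.
    Used for inverse-transform sampling of colony positions.
    """
    h = geom.axial_length_mm
    ua = _check_domain(u, 0.0, 1.0, "u")
    if geom.shape in _CONELIKE:
        out = h * ua ** (1.0 / 3.0)
    elif geom.shape == "wedge":
        out = h * np.sqrt(ua)
    else:
        out = h * ua
    return out if out.ndim else float(out)
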