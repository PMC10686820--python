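"""Printable camera-free rulers: where to expect the K-th colony.

Inverting the cone's cumulative axial distribution turns the estimator into
a physical ruler.  A sample at concentration ``c`` (before the embedding
dilution ``D``) seeds an expected ``m = (c/D)·V`` colonies into the gel, of
which ``m·(x/h)³`` are expected within ``x`` of the tip.  The expected
position of the K-th colony is therefore

    x_K = h · (K / m)^(1/3)        (defined when m >= K)

Printing ticks at ``x_K`` for a grid of concentrations, at 1:1 physical
scale, lets a user read a tip's concentration by aligning it against paper:
the tick nearest the observed K-th colony is the estimate.

An alternative annotation, the *median* position of the K-th colony under
Poisson counting (solve ``P(N([0,x]) >= K) = 1/2``), is available via
``method="median_order_statistic"``; it differs from the expected-count
inversion by O(1/m).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .geometry import ConeGeometry

__all__ = ["RulerSpec", "kth_colony_position", "render_ruler", "min_annotatable_concentration"]


def min_annotatable_concentration(
    geom: ConeGeometry, dilution_factor: float = 100.0, k: int = 10
) -> float:
    """Smallest sample concentration whose K-th colony is expected to exist."""
    return k * dilution_factor / geom.volume_mL


def kth_colony_position(
    geom: ConeGeometry,
    sample_concentration: float,
    dilution_factor: float = 100.0,
    k: int = 10,
    method: str = "expected_count",
) -> float:
    """Axial position (mm from the tip) where the K-th colony is expected.

    Parameters
    ----------
    sample_concentration
        CFU/mL of the original sample, before the embedding dilution.
    method
        ``"expected_count"`` (default): the x where the expected number of
        colonies nearer the tip equals K — the closed form ``h·(K/m)^(1/3)``.
        ``"median_order_statistic"``: the median position of the K-th colony
        under Poisson counting.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if sample_concentration <= 0:
        raise ValueError("concentration must be positive")
    m = (sample_concentration / dilution_factor) * geom.volume_mL
    if m < k:
        raise ValueError(
            f"concentration too low: expected total colonies m={m:.3g} < k={k}; "
            f"minimum annotatable concentration is "
            f"{min_annotatable_concentration(geom, dilution_factor, k):.3g} CFU/mL"
        )
    h = geom.axial_length_mm
    if method == "expected_count":
        return float(h * (k / m) ** (1.0 / 3.0))
    if method == "median_order_statistic":
        # median of the K-th arrival: P(Poisson(m·cdf(x)) >= k) = 1/2.
        def half(x):
            return stats.poisson.sf(k - 1, m * geom.cdf(x)) - 0.5

        if half(h) < 0:  # K-th colony more likely than not absent even at the base
            raise ValueError("concentration too low for a median K-th colony position")
        return float(optimize.brentq(half, 0.0, h, xtol=1e-10))
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class RulerSpec:
    """Layout of a printable ruler.

    ``concentrations`` are sample-scale CFU/mL values to annotate (sorted
    ascending); ``page_mm`` is (width, height) of the output page; the axis
    is drawn at 1:1 physical scale so the printout can be held against a tip.
    """

    geom: ConeGeometry = field(default_factory=ConeGeometry)
    k: int = 10
    concentrations: tuple[float, ...] = (1e5, 1e6, 1e7, 1e8, 1e9)
    dilution_factor: float = 100.0
    page_mm: tuple[float, float] = (80.0, 60.0)
    method: str = "expected_count"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        conc = tuple(sorted(float(c) for c in self.concentrations))
        if any(c <= 0 for c in conc):
            raise ValueError("concentrations must be positive")
        object.__setattr__(self, "concentrations", conc)


def _ticks(spec: RulerSpec) -> list[tuple[float, float]]:
    """(concentration, x_mm) pairs, dropping unannotatable concentrations."""
    out, dropped = [], []
    for c in spec.concentrations:
        try:
            x = kth_colony_position(spec.geom, c, spec.dilution_factor, spec.k, spec.method)
        except ValueError:
            dropped.append(c)
            continue
        out.append((c, x))
    if dropped:
        warnings.warn(
            f"{len(dropped)} concentration(s) below the annotatable minimum "
            f"({min_annotatable_concentration(spec.geom, spec.dilution_factor, spec.k):.3g} "
            f"CFU/mL) dropped: {[f'{c:.0e}' for c in dropped]}",
            stacklevel=3,
        )
    return out


def render_ruler(spec: RulerSpec, path=None) -> str:
    """Render the ruler as an SVG document in physical millimetre units.

    The SVG user unit is 1 mm (width/height carry explicit ``mm`` units), so
    printing at 100% scale reproduces tick positions exactly.  The axis runs
    horizontally from an apex-alignment origin (circle marker at x=0); each
    tick marks the expected K-th colony position for one concentration.

    Returns the SVG text; also writes it to ``path`` when given.
    """
    w, hgt = spec.page_mm
    h = spec.geom.axial_length_mm
    if w < h + 10:
        raise ValueError(
            f"page width {w:g} mm too small for a 1:1 axis of {h:g} mm plus margins"
        )
    x0, y0 = 5.0, hgt / 2.0  # apex origin on the page
    ticks = _ticks(spec)
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w:g}mm" height="{hgt:g}mm" '
        f'viewBox="0 0 {w:g} {hgt:g}">',
        f'<title>K={spec.k} colony ruler, {spec.geom.shape} h={h:g} mm '
        f"V={spec.geom.volume_uL:g} uL, dilution 1:{spec.dilution_factor:g}</title>",
        # apex alignment origin + main axis at 1:1 scale
        f'<circle cx="{x0}" cy="{y0}" r="1" fill="none" stroke="black" stroke-width="0.2"/>',
        f'<line x1="{x0}" y1="{y0}" x2="{x0 + h}" y2="{y0}" stroke="black" stroke-width="0.3"/>',
        f'<text x="{x0}" y="{y0 + 8}" font-size="2.5">tip apex</text>',
    ]
    for c, x in ticks:
        px = x0 + x
        parts.append(
            f'<line x1="{px:.4f}" y1="{y0 - 4}" x2="{px:.4f}" y2="{y0 + 4}" '
            'stroke="black" stroke-width="0.25"/>'
        )
        parts.append(
            f'<text x="{px:.4f}" y="{y0 - 5.5}" font-size="2.5" text-anchor="middle" '
            f'transform="rotate(-60 {px:.4f} {y0 - 5.5})">{c:.0e}</text>'
        )
    parts.append(
        f'<text x="{x0 + h / 2}" y="{hgt - 4}" font-size="3" text-anchor="middle">'
        f"expected colony #{spec.k} from tip (CFU/mL of sample)</text>"
    )
    parts.append("</svg>")
    svg = "\n".join(parts)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(svg)
    return svg
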