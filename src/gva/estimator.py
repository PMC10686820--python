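"""CFU-concentration estimation from colony axial positions.

The estimator divides a colony count by the expected probability mass of the
axial interval that contains it:

    CFU/mL (gel) = N / ( V · [CDF(x2) − CDF(x1)] )

where ``(x1, x2)`` are the positions of the first and last colony used
(counted from the tip), ``N`` counts colonies with ``x1 <= x < x2``
(half-open, so with ``k`` colonies ``N = k − 1`` in the absence of ties) and
``V`` is the gel volume in mL.  Multiplying by the embedding dilution factor
converts the gel concentration to the original-sample concentration.

Counting modes
--------------
``interval``      first-to-last interval ``[x1, x2)`` — the printed equation.
``tip_anchored``  interval ``[0, x_k)`` anchored at the apex; slightly less
                  biased (the apex is a known point of the process).
``full_volume``   whole vessel, ``N = total count``; reduces to N/V and is
                  the exact-count oracle the other modes are checked against.

The estimate depends on axial positions only; radial coordinates carried by a
:class:`ColonySet` are ignored by design.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .geometry import ConeGeometry, axial_cdf

__all__ = [
    "ColonySet",
    "CfuEstimate",
    "estimate_cfu",
    "convergence_trace",
    "factor_off",
    "limit_of_detection",
]

MODES = ("interval", "tip_anchored", "full_volume")
DEFAULT_K = 10  # headline operating point: positions of the first 10 colonies


@dataclass(frozen=True)
class ColonySet:
    """Observed (or simulated) colonies of a single embedded tip.

    ``positions_mm`` are axial distances from the tip apex, sorted ascending.
    ``dilution_factor`` is sample-concentration / gel-concentration (the
    standard embedding protocol dilutes the sample 1:100 into the gel).
    ``y_mm``/``z_mm`` are optional radial coordinates; they are carried for
    rendering but never influence an estimate.
    """

    tip_id: str
    positions_mm: np.ndarray
    geom: ConeGeometry = field(default_factory=ConeGeometry)
    dilution_factor: float = 100.0
    gel_volume_uL: float | None = None
    y_mm: np.ndarray | None = None
    z_mm: np.ndarray | None = None

    def __post_init__(self) -> None:
        pos = np.atleast_1d(np.asarray(self.positions_mm, dtype=float))
        h = self.geom.axial_length_mm
        if pos.size and (pos.min() < 0 or pos.max() > h):
            raise ValueError(f"colony positions outside [0, {h:g}] mm")
        if pos.size and np.any(np.diff(pos) < 0):
            pos = np.sort(pos, kind="stable")
        object.__setattr__(self, "positions_mm", pos)
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")

    @property
    def n_colonies(self) -> int:
        return int(self.positions_mm.size)

    @property
    def volume_uL(self) -> float:
        return self.gel_volume_uL if self.gel_volume_uL is not None else self.geom.volume_uL

    @property
    def volume_mL(self) -> float:
        return self.volume_uL / 1000.0

    def replace(self, **changes) -> "ColonySet":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class CfuEstimate:
    """Result of a single-tip CFU estimate."""

    tip_id: str
    cfu_per_ml_sample: float | None
    cfu_per_ml_gel: float | None
    n_counted: int
    interval_mm: tuple[float, float] | None
    below_lod: bool = False
    #: upper bound (the detection limit) when no colony was observed
    upper_bound_cfu_per_ml: float | None = None
    mode: str = "interval"
    k_used: int | None = None
    convergence_trace: tuple[tuple[int, float], ...] | None = None


def factor_off(calculated, actual):
    """Multiplicative error metric ``|calculated − actual| / actual + 1``.

    Always >= 1, equal to 1 iff the estimate is exact; symmetric in spirit to
    a fold-change and well behaved over many orders of magnitude of CFU/mL.
    Vectorised over either argument.
    """
    act = np.asarray(actual, dtype=float)
    if np.any(act <= 0):
        raise ValueError("actual concentration must be positive")
    out = np.abs(np.asarray(calculated, dtype=float) - act) / act + 1.0
    return out if out.ndim else float(out)


def limit_of_detection(
    geom: ConeGeometry,
    dilution_factor: float = 100.0,
    gel_volume_uL: float | None = None,
) -> float:
    """Smallest detectable sample concentration: one colony in the gel volume.

    For the standard 150 µL embedding at 1:100 dilution this is
    ``1 / 0.15 mL × 100 ≈ 667 CFU/mL``.  Returned unrounded; round for display.
    """
    v_mL = (gel_volume_uL if gel_volume_uL is not None else geom.volume_uL) / 1000.0
    if v_mL <= 0:
        raise ValueError("gel volume must be positive")
    return dilution_factor / v_mL


def _below_lod(colonies: ColonySet, mode: str) -> CfuEstimate:
    return CfuEstimate(
        tip_id=colonies.tip_id,
        cfu_per_ml_sample=None,
        cfu_per_ml_gel=None,
        n_counted=0,
        interval_mm=None,
        below_lod=True,
        upper_bound_cfu_per_ml=limit_of_detection(
            colonies.geom, colonies.dilution_factor, colonies.gel_volume_uL
        ),
        mode=mode,
    )


def _gel_estimate(positions: np.ndarray, colonies: ColonySet, mode: str) -> tuple[float, int, tuple[float, float]]:
    """Gel-scale concentration from the selected (sorted) positions."""
    geom, v_mL = colonies.geom, colonies.volume_mL
    if mode == "full_volume":
        x1, x2 = 0.0, geom.axial_length_mm
        n = positions.size
        mass = 1.0
    else:
        if mode == "interval":
            x1, x2 = float(positions[0]), float(positions[-1])
        else:  # tip_anchored
            x1, x2 = 0.0, float(positions[-1])
        if x2 <= x1:
            raise ValueError(
                "degenerate counting interval: first and last colony coincide "
                f"(x1 = x2 = {x1:g} mm); use mode='full_volume'"
            )
        # half-open [x1, x2): ties at the far end are excluded
        n = int(np.sum((positions >= x1) & (positions < x2)))
        mass = axial_cdf(geom, x2) - axial_cdf(geom, x1)
    return n / (v_mL * mass), n, (x1, x2)


def estimate_cfu(
    colonies: ColonySet,
    k: int | str = DEFAULT_K,
    mode: str = "interval",
    with_trace: bool = False,
) -> CfuEstimate:
    """Estimate the sample CFU/mL from the first ``k`` colonies of a tip.

    Parameters
    ----------
    colonies
        Observed tip.  An empty set yields a ``below_lod`` result carrying the
        detection limit as an upper bound.
    k
        Number of colonies (counted from the tip) to use, or ``"all"``.
        Tips with fewer than ``k`` colonies use all of them.
    mode
        Counting convention, see module docstring.
    with_trace
        Attach the estimate-vs-k convergence trace to the result.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    pos = colonies.positions_mm
    if pos.size == 0:
        return _below_lod(colonies, mode)
    if k == "all":
        k_used = pos.size
    else:
        k_used = int(k)
        if k_used < 1:
            raise ValueError("k must be >= 1 or 'all'")
        k_used = min(k_used, pos.size)
    sel = pos[:k_used]
    if mode != "full_volume" and sel.size < 2:
        raise ValueError(
            "interval modes need at least 2 colonies; "
            "use mode='full_volume' for a single-colony whole-vessel count"
        )
    gel, n, interval = _gel_estimate(sel, colonies, mode)
    trace = tuple(convergence_trace(colonies, k_max=k_used, mode=mode)) if with_trace else None
    return CfuEstimate(
        tip_id=colonies.tip_id,
        cfu_per_ml_sample=gel * colonies.dilution_factor,
        cfu_per_ml_gel=gel,
        n_counted=n,
        interval_mm=interval,
        below_lod=False,
        mode=mode,
        k_used=k_used,
        convergence_trace=trace,
    )


def convergence_trace(
    colonies: ColonySet, k_max: int | None = None, mode: str = "interval"
) -> list[tuple[int, float]]:
    """Sample-scale estimate as a function of the number of colonies included.

    Returns ``[(k, CFU/mL), ...]`` for ``k = 2 .. min(k_max, n)``; an empty
    list for tips with fewer than two colonies.  The last entry agrees with
    ``estimate_cfu(k=n)`` by construction.
    """
    pos = colonies.positions_mm
    if pos.size < 2:
        return []
    n = pos.size if k_max is None else min(int(k_max), pos.size)
    out: list[tuple[int, float]] = []
    for k in range(2, n + 1):
        try:
            gel, _, _ = _gel_estimate(pos[:k], colonies, mode)
        except ValueError:  # tied positions make a zero-mass interval at this k
            continue
        out.append((k, gel * colonies.dilution_factor))
    return out
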