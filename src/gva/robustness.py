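"""Error and noise analyses: missed colonies, apex misplacement, replicate CV.

Real measurements deviate from the ideal in two main ways: the analyst
misses colonies (occlusion, faint staining), and the apex pixel used as the
position origin is off by some distance.  Both perturbations are applied to
*the same* simulated colony sets (paired design) so their effect on the
estimate is isolated from sampling noise.

Technical noise between replicate tips is summarised by the coefficient of
variation (sd/mean) of the replicate estimates, computed on the linear
CFU/mL scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimator import ColonySet, estimate_cfu, factor_off
from .geometry import ConeGeometry
from .simulator import replicate_rngs, sample_first_positions, _sub_seed

__all__ = [
    "PerturbationSpec",
    "drop_colonies",
    "offset_tip",
    "replicate_cv",
    "error_sweep",
]

REMOVAL_POLICIES = ("uniform_random", "nearest_tip_first", "farthest_first")


@dataclass(frozen=True)
class PerturbationSpec:
    """A perturbation to apply to a counted colony set.

    ``n_missing`` colonies are removed according to ``removal_policy``
    (uniform_random is the default; nearest_tip_first moves x1 and is the
    worst case).  ``tip_offset_mm`` displaces the assumed apex: positive
    means the apex was placed too far from the colonies, so every axial
    position increases.
    """

    n_missing: int = 0
    removal_policy: str = "uniform_random"
    tip_offset_mm: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_missing < 0:
            raise ValueError("n_missing must be >= 0")
        if self.removal_policy not in REMOVAL_POLICIES:
            raise ValueError(
                f"unknown removal_policy {self.removal_policy!r}; "
                f"expected one of {REMOVAL_POLICIES}"
            )


def drop_colonies(
    colonies: ColonySet,
    spec: PerturbationSpec,
    rng: np.random.Generator | None = None,
) -> ColonySet:
    """Remove ``spec.n_missing`` colonies from the counted set.

    At least two colonies must remain (the interval estimator needs a first
    and a last).  The surviving positions stay sorted.
    """
    n = colonies.n_colonies
    remaining = n - spec.n_missing
    if spec.n_missing == 0:
        return colonies
    if remaining < 2:
        raise ValueError(
            f"cannot drop {spec.n_missing} of {n} colonies: "
            "at least 2 must remain for interval estimation"
        )
    if spec.removal_policy == "nearest_tip_first":
        keep = np.arange(spec.n_missing, n)
    elif spec.removal_policy == "farthest_first":
        keep = np.arange(0, remaining)
    else:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        keep = np.sort(rng.choice(n, size=remaining, replace=False))
    return colonies.replace(
        positions_mm=colonies.positions_mm[keep],
        y_mm=None if colonies.y_mm is None else colonies.y_mm[keep],
        z_mm=None if colonies.z_mm is None else colonies.z_mm[keep],
    )


def offset_tip(colonies: ColonySet, tip_offset_mm: float) -> ColonySet:
    """Shift every axial position by a signed apex-placement error.

    Positive offset: the assumed apex is farther from the colonies than the
    true apex, so all positions grow.  Shifted positions are clipped to
    ``[0, h]``; the geometry itself is unchanged.
    """
    h = colonies.geom.axial_length_mm
    if abs(tip_offset_mm) >= h:
        raise ValueError(f"|tip offset| must be < axial length ({h:g} mm)")
    if tip_offset_mm == 0.0:
        return colonies
    shifted = np.clip(colonies.positions_mm + tip_offset_mm, 0.0, h)
    return colonies.replace(positions_mm=shifted)


def replicate_cv(estimates) -> float:
    """Coefficient of variation (sample sd / mean) of replicate estimates."""
    x = np.asarray(estimates, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs at least 2 replicate estimates")
    if np.any(x <= 0):
        raise ValueError("replicate estimates must be positive")
    return float(np.std(x, ddof=1) / np.mean(x))


def error_sweep(
    densities,
    missing_grid=(0,),
    offset_grid=(0.0,),
    n_reps: int = 1000,
    seed: int = 0,
    geom: ConeGeometry | None = None,
    n_counted: int = 15,
    k: int = 10,
    mode: str = "interval",
    removal_policy: str = "uniform_random",
) -> pd.DataFrame:
    """Paired sweep of missed-colony and apex-offset perturbations.

    For each density, ``n_reps`` cones are simulated once; every
    (n_missing, offset) combination re-estimates the *same* cones.  Missing
    colonies are removed from the first ``n_counted`` colonies; the estimate
    then uses up to ``k`` of the survivors.  Cones with fewer than
    ``max(n_counted, k)`` colonies, or with fewer than 2 survivors, are
    excluded from the affected cell and counted in ``n_tips``.

    Returns columns ``density, n_missing, offset_mm, mean_factor_off,
    sd_factor_off, n_tips``.
    """
    if len(missing_grid) == 0 or len(offset_grid) == 0:
        raise ValueError("perturbation grids must be nonempty")
    geom = geom or ConeGeometry()
    m_draw = max(n_counted, k)
    rows = []
    for d_idx, density in enumerate(densities):
        rngs = replicate_rngs(_sub_seed(seed, d_idx), n_reps)
        reps = [sample_first_positions(density, geom, m_draw, rng) for rng in rngs]
        # a second, independent stream per replicate for the removal draws
        perturb_rngs = replicate_rngs(_sub_seed(seed, 10_000 + d_idx), n_reps)
        for n_missing in missing_grid:
            for offset in offset_grid:
                fo = []
                for pos, prng in zip(reps, perturb_rngs):
                    if pos.size < n_missing + 2:
                        continue
                    cs = ColonySet("sim", pos[:n_counted], geom, dilution_factor=1.0)
                    if n_missing:
                        cs = drop_colonies(
                            cs,
                            PerturbationSpec(n_missing=n_missing, removal_policy=removal_policy),
                            rng=prng,
                        )
                    if offset:
                        cs = offset_tip(cs, offset)
                    est = estimate_cfu(cs, k=k, mode=mode)
                    fo.append(factor_off(est.cfu_per_ml_gel, density))
                fo = np.asarray(fo)
                rows.append(
                    {
                        "density": density,
                        "n_missing": n_missing,
                        "offset_mm": offset,
                        "mean_factor_off": fo.mean() if fo.size else np.nan,
                        "sd_factor_off": fo.std(ddof=1) if fo.size > 1 else np.nan,
                        "n_tips": fo.size,
                    }
                )
    return pd.DataFrame(rows)
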