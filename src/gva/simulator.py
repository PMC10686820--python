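"""Synthetic colony configurations and in-silico validation experiments.

Colonies in a uniformly seeded gel form an inhomogeneous Poisson point
process along the vessel axis: the total count is Poisson with mean
``density × V`` and, given the count, positions are i.i.d. with the vessel's
axial density (cone: ``3x²/h³``), sampled by inverse transform
``x = h · u^(1/3)``.

Two samplers are provided:

* :func:`sample_colonies` — the full configuration, including radial
  coordinates (uniform over the cross-sectional disc) for image rendering.
* :func:`sample_first_positions` — only the ``m`` colonies nearest the tip,
  generated as the first arrivals of the equivalent unit-rate Poisson process
  on the CDF scale (cumulative exponential gaps).  Exact in law and O(m)
  regardless of density, which keeps million-colony cones affordable in the
  Monte-Carlo studies.

The experiment drivers (:func:`convergence_experiment`,
:func:`dilution_series_experiment`) reproduce the standard validation
studies: error versus number of colonies counted, and log–log linearity of a
simulated dilution series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimator import ColonySet, estimate_cfu, factor_off
from .geometry import ConeGeometry, axial_inverse_cdf

__all__ = [
    "SimulationConfig",
    "replicate_rngs",
    "sample_colonies",
    "sample_first_positions",
    "convergence_experiment",
    "dilution_series_experiment",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for a batch of simulated cones.

    ``density_cfu_per_ml`` is the true in-gel colony density; estimates are
    compared with it on the gel scale, so ``dilution_factor`` defaults to 1
    and only matters when reporting on the original-sample scale.
    """

    density_cfu_per_ml: float
    geom: ConeGeometry = field(default_factory=ConeGeometry)
    n_reps: int = 1
    seed: int = 0
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.density_cfu_per_ml < 0:
            raise ValueError("density must be nonnegative")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def replicate_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent, reproducible RNG substreams, one per replicate cone.

    Derived by spawning from a single seed sequence so that paired
    perturbation experiments can replay identical colony sets.
    """
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def sample_colonies(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    tip_id: str = "sim",
    with_radial: bool = True,
    base_radius_mm: float | None = None,
) -> ColonySet:
    """Draw one simulated cone's colonies.

    Radial coordinates are uniform over the cross-sectional disc at each
    colony's axial position (disc radius grows linearly from the apex); they
    are carried for rendering only.  ``base_radius_mm`` defaults to the
    ideal-cone radius implied by the geometry's volume and length.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    geom = config.geom
    mean_n = config.density_cfu_per_ml * geom.volume_mL
    n = int(rng.poisson(mean_n))
    x = np.sort(axial_inverse_cdf(geom, rng.uniform(size=n))) if n else np.empty(0)
    y = z = None
    if with_radial and n:
        if base_radius_mm is None:
            # radius of the exact cone with this volume and axial length
            base_radius_mm = float(np.sqrt(3.0 * geom.volume_uL / (np.pi * geom.axial_length_mm)))
        r = base_radius_mm * (x / geom.axial_length_mm) * np.sqrt(rng.uniform(size=n))
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
        y, z = r * np.cos(theta), r * np.sin(theta)
    return ColonySet(
        tip_id=tip_id,
        positions_mm=x,
        geom=geom,
        dilution_factor=config.dilution_factor,
        y_mm=y,
        z_mm=z,
    )


def sample_first_positions(
    density_cfu_per_ml: float,
    geom: ConeGeometry,
    m: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Axial positions of the (up to) ``m`` colonies nearest the tip.

    On the CDF scale the colonies are a Poisson process of rate
    ``density × V`` on [0, 1]; its first ``m`` arrival times are cumulative
    exponential gaps, truncated at 1.  Returns fewer than ``m`` positions when
    the whole cone holds fewer colonies.
    """
    lam = density_cfu_per_ml * geom.volume_mL
    if lam <= 0:
        return np.empty(0)
    u = np.cumsum(rng.exponential(1.0 / lam, size=m))
    u = u[u <= 1.0]
    return axial_inverse_cdf(geom, u)


def convergence_experiment(
    densities,
    k_max: int = 10,
    n_reps: int = 1000,
    seed: int = 0,
    geom: ConeGeometry | None = None,
    mode: str = "interval",
) -> pd.DataFrame:
    """Estimation error versus number of colonies counted, per density.

    For each density, ``n_reps`` cones are simulated and the estimate from
    the first ``k`` colonies (k = 2..k_max) is compared with the truth via
    the factor-off metric.  Replicates with fewer than ``k`` colonies are
    excluded from that ``k``'s summary (a cone cannot contribute at a count
    it never reached); the retained fraction is reported.

    Returns a tidy frame with columns ``density, k, n_used, mean_factor_off,
    sd_factor_off, frac_within_2``; summaries where no replicate reached
    ``k`` carry NaNs.
    """
    geom = geom or ConeGeometry()
    rows = []
    for d_idx, density in enumerate(densities):
        rngs = replicate_rngs(_sub_seed(seed, d_idx), n_reps)
        # one colony set per replicate, reused across all k (paired design)
        reps = [sample_first_positions(density, geom, k_max, rng) for rng in rngs]
        for k in range(2, k_max + 1):
            fo = []
            for pos in reps:
                if pos.size < k:
                    continue
                cs = ColonySet("sim", pos[:k], geom, dilution_factor=1.0)
                est = estimate_cfu(cs, k=k, mode=mode)
                fo.append(factor_off(est.cfu_per_ml_gel, density))
            fo = np.asarray(fo)
            rows.append(
                {
                    "density": density,
                    "k": k,
                    "n_used": fo.size,
                    "mean_factor_off": fo.mean() if fo.size else np.nan,
                    "sd_factor_off": fo.std(ddof=1) if fo.size > 1 else np.nan,
                    "frac_within_2": float(np.mean(fo < 2.0)) if fo.size else np.nan,
                }
            )
    return pd.DataFrame(rows)


def dilution_series_experiment(
    base_density: float,
    fold: float = 4.0,
    n_steps: int = 8,
    n_reps: int = 4,
    seed: int = 0,
    geom: ConeGeometry | None = None,
    k: int | str = 10,
    mode: str = "interval",
):
    """Simulated dilution series and its log–log linearity.

    Simulates ``n_reps`` cones at each density ``base_density / fold**i``,
    estimates each (first ``k`` colonies, or all if a cone holds fewer),
    averages replicate estimates after taking log10, and regresses mean
    log-estimate on log true density.  A slope of 1 means the estimate
    scales linearly with dilution.

    Returns ``(per_step_table, fit)`` where ``fit`` is the scipy linregress
    result (``fit.slope``, ``fit.rvalue**2`` ...).
    """
    if n_steps < 2:
        raise ValueError("need at least 2 dilution steps for a regression")
    if fold <= 1.0:
        raise ValueError("dilution fold must be > 1 (fold=1 gives a degenerate regressor)")
    geom = geom or ConeGeometry()
    k_draw = 1000 if k == "all" else max(int(k), 2)
    rows = []
    for i in range(n_steps):
        density = base_density / fold**i
        logs = []
        for rng in replicate_rngs(_sub_seed(seed, i), n_reps):
            pos = sample_first_positions(density, geom, k_draw, rng)
            if pos.size < 2:
                continue
            cs = ColonySet("sim", pos, geom, dilution_factor=1.0)
            est = estimate_cfu(cs, k=k, mode=mode)
            logs.append(np.log10(est.cfu_per_ml_gel))
        if not logs:
            warnings.warn(
                f"dilution step {i} ({density:g} CFU/mL): every cone below the "
                "detection limit; step dropped",
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "step": i,
                "true_density": density,
                "n_reps_used": len(logs),
                "mean_log10_estimate": float(np.mean(logs)),
            }
        )
    table = pd.DataFrame(rows)
    if len(table) < 2:
        raise ValueError("fewer than 2 usable dilution steps; regression undefined")
    fit = stats.linregress(np.log10(table["true_density"]), table["mean_log10_estimate"])
    return table, fit


def _sub_seed(seed: int, index: int) -> int:
    """Deterministic per-condition child seed (kept within 32 bits)."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))
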