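"""Consumables and throughput accounting for viability-assay campaigns.

Compares what a screen of ``n`` viability measurements consumes under three
methods: the classical drop assay (serial dilution, 15 tips per sample,
colonies counted on shared agar plates), a spiral plater (one Petri dish
per sample, no tips), and the geometric assay (one tip per sample, no
dishes).  Rates default to standard protocol values and are overridable;
monetary costs are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ConsumablesModel", "ConsumablesEstimate", "consumables_estimate", "savings_ratio"]

METHODS = ("drop_cfu", "spiral_plater", "gva")


@dataclass(frozen=True)
class ConsumablesModel:
    """Per-sample consumption rates.

    ``drop_dishes_per_sample`` has no standard value (drop-assay plates are
    amortised across samples in a protocol-dependent way); leave it None to
    omit dish/agar accounting for the drop assay.
    """

    tips_per_sample: dict | None = None
    tips_per_box: int = 96
    agar_mL_per_dish: float = 25.0  # 1.5 % agar plates
    agar_fraction_dish: float = 0.015
    gel_uL_per_gva_sample: float = 200.0  # 0.5 % agarose embeddings
    agar_fraction_gel: float = 0.005
    drop_dishes_per_sample: float | None = None

    def tips(self, method: str) -> float:
        rates = self.tips_per_sample or {"drop_cfu": 15, "spiral_plater": 0, "gva": 1}
        return rates[method]

    def dishes(self, method: str) -> float | None:
        if method == "spiral_plater":
            return 1.0
        if method == "gva":
            return 0.0
        return self.drop_dishes_per_sample


@dataclass(frozen=True)
class ConsumablesEstimate:
    method: str
    n_samples: int
    tips: int
    tip_boxes: int
    petri_dishes: int | None
    agar_g: float | None


def consumables_estimate(
    n_samples: int, method: str, model: ConsumablesModel | None = None
) -> ConsumablesEstimate:
    """Consumption totals for ``n_samples`` measurements with one method.

    Box and dish counts are ceilings of exact quotients.  Agar mass is the
    dissolved agar(ose) powder: dish volume × 1.5 % for plate-based methods,
    embedding gel volume × 0.5 % for the geometric assay.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    model = model or ConsumablesModel()
    tips = int(n_samples * model.tips(method))
    tip_boxes = math.ceil(tips / model.tips_per_box) if tips else 0
    dish_rate = model.dishes(method)
    dishes = None if dish_rate is None else math.ceil(n_samples * dish_rate)
    if method == "gva":
        agar = n_samples * model.gel_uL_per_gva_sample / 1000.0 * model.agar_fraction_gel
    elif dishes is None:
        agar = None
    else:
        agar = dishes * model.agar_mL_per_dish * model.agar_fraction_dish
    return ConsumablesEstimate(method, n_samples, tips, tip_boxes, dishes, agar)


def savings_ratio(
    method_a: str,
    method_b: str,
    resource: str = "tips",
    model: ConsumablesModel | None = None,
) -> float:
    """Per-sample consumption ratio ``method_a / method_b`` for one resource.

    ``resource`` is ``"tips"`` or ``"dishes"``.  A zero or undefined
    denominator raises (e.g. dish savings over the dish-free geometric
    assay are unbounded).
    """
    model = model or ConsumablesModel()
    if resource == "tips":
        a, b = model.tips(method_a), model.tips(method_b)
    elif resource == "dishes":
        a, b = model.dishes(method_a), model.dishes(method_b)
    else:
        raise ValueError("resource must be 'tips' or 'dishes'")
    if a is None or b is None:
        raise ValueError(f"{resource} rate undefined for one of the methods")
    if b == 0:
        raise ValueError(f"{method_b} consumes no {resource}; ratio undefined")
    return a / b
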