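"""D study: projecting reliability under alternative facet configurations.

Given G-study variance components, a D-study plan assigns a projected
number of levels to every non-object facet and asks what the
generalizability (relative-error) or dependability (absolute-error)
coefficient would be under that configuration:

    coefficient = sigma2_object / (sigma2_object + sigma2_error)

Relative error sums the components of effects that contain the object of
measurement (excluding the pure object effect); absolute error additionally
includes every facet main effect and facet interaction.  Each component is
divided by the product of the plan sizes of the effect's facets other than
the object facet itself — so for a nested object (persons within sites) the
site index is averaged over like any other facet of the procedure, which
matches a setting where test takers are randomly assigned to sites.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .design import Design, Effect
from .errors import ConfigError, UndefinedCoefficientError
from .gstudy import VarianceComponents

ERROR_TYPES = ("relative", "absolute")


@dataclass(frozen=True)
class DStudyPlan:
    """Projected sizes for every non-object facet of a design."""

    sizes: dict[str, int]
    label: str = ""

    def __post_init__(self):
        for name, n in self.sizes.items():
            if int(n) != n:
                raise ConfigError(f"plan size for {name!r} must be an integer, got {n}")
            if n < 1:
                raise ConfigError(f"plan size for {name!r} must be ≥ 1, got {n}")
        object.__setattr__(self, "sizes", {k: int(v) for k, v in self.sizes.items()})

    def size(self, facet: str) -> int:
        if facet not in self.sizes:
            raise ConfigError(f"plan {self.label!r} lacks a size for facet {facet!r}")
        return self.sizes[facet]


@dataclass(frozen=True)
class CoefficientResult:
    """A projected coefficient with its error decomposition."""

    coefficient: float
    error_type: str
    error_variance: float
    object_variance: float
    plan: DStudyPlan

    @property
    def rounded(self) -> float:
        """Display value (4 decimals); never used in computation."""
        return round(self.coefficient, 4)


def _check_plan(design: Design, plan: DStudyPlan) -> None:
    obj = design.object_facet.name
    for f in design.facet_names:
        if f != obj:
            plan.size(f)  # raises ConfigError if missing / invalid


def _divisor(effect: Effect, plan: DStudyPlan, object_name: str) -> int:
    return math.prod(plan.size(g) for g in effect.facets if g != object_name)


def error_variance(
    vc: VarianceComponents, plan: DStudyPlan, error_type: str = "relative"
) -> float:
    """Projected error variance for a plan.

    Relative error: components of effects containing the object of
    measurement, excluding the object effect itself.  Absolute error adds
    the components of every effect not containing the object.  Each term is
    divided by the product of the plan sizes of the effect's non-object
    facets.
    """
    if error_type not in ERROR_TYPES:
        raise ConfigError(f"error_type must be one of {ERROR_TYPES}, got {error_type!r}")
    design = vc.design
    _check_plan(design, plan)
    obj = design.object_facet.name
    object_effect = design.object_effect
    total = 0.0
    for eff in design.effects:
        if eff.facets == object_effect.facets:
            continue
        contains_object = obj in eff.facets
        if error_type == "relative" and not contains_object:
            continue
        total += vc.sigma2(eff.name) / _divisor(eff, plan, obj)
    return total


def g_coefficient(
    vc: VarianceComponents, plan: DStudyPlan, error_type: str = "relative"
) -> CoefficientResult:
    """Generalizability (relative) or dependability (absolute) coefficient.

    The object variance is the component of the pure object effect
    (``sigma2_p``, or ``sigma2_p:s`` for a nested object).  Raises
    :class:`UndefinedCoefficientError` when object and error variance are
    both zero.
    """
    ev = error_variance(vc, plan, error_type)
    ov = vc.sigma2(vc.design.object_effect.name)
    if ov == 0.0 and ev == 0.0:
        raise UndefinedCoefficientError(
            "object variance and error variance are both zero; the "
            "coefficient is undefined (0/0)"
        )
    return CoefficientResult(
        coefficient=ov / (ov + ev),
        error_type=error_type,
        error_variance=ev,
        object_variance=ov,
        plan=plan,
    )


def dstudy_grid(
    vc: VarianceComponents,
    plans: list[DStudyPlan],
    error_type: str = "relative",
) -> list[CoefficientResult]:
    """One :class:`CoefficientResult` per plan, order-preserving."""
    if not plans:
        raise ConfigError("dstudy_grid requires at least one plan")
    return [g_coefficient(vc, plan, error_type) for plan in plans]


def grid_frame(results: list[CoefficientResult]) -> pd.DataFrame:
    """Delimited-table view of a D-study sweep (one row per plan)."""
    rows = []
    for r in results:
        row = {"plan": r.plan.label}
        row.update({f"n_{k}": v for k, v in r.plan.sizes.items()})
        row["error_type"] = r.error_type
        row["error_variance"] = r.error_variance
        row["coefficient"] = r.coefficient
        row["coefficient_4dp"] = r.rounded
        rows.append(row)
    return pd.DataFrame(rows)
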