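"""Cost-effectiveness analysis for assessment plans.

Couples D-study reliability projections with a facet-linear cost model:
plan cost is the sum of per-facet unit costs times facet sizes plus a
fixed term; the incremental cost-effectiveness ratio (ICER) between two
plans is ΔC/ΔE (money per 1.0 of coefficient, rescalable to money per
0.01); and a Monte-Carlo cost-effectiveness acceptability curve (CEAC)
gives, for each willingness-to-pay value λ, the probability that the
intervention's incremental net benefit λ·ΔE − ΔC is positive under the
configured uncertainty distributions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.stats import truncnorm

from .design import degrees_of_freedom
from .dstudy import DStudyPlan, g_coefficient
from .errors import ConfigError, DominanceError
from .gstudy import VarianceComponents, ems_matrix, estimate_components


# ---------------------------------------------------------------------------
# costs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CostSchedule:
    """Per-facet unit costs (money per level) plus a fixed cost."""

    unit_costs: dict[str, float]
    fixed_cost: float = 0.0
    currency_label: str = "£"

    def __post_init__(self):
        if not self.currency_label:
            raise ConfigError("currency label must be nonempty")
        for name, c in self.unit_costs.items():
            if c < 0:
                raise ConfigError(f"unit cost for {name!r} must be ≥ 0, got {c}")


def total_cost(schedule: CostSchedule, plan: DStudyPlan) -> float:
    """Linear cost of a plan: sum of unit_cost × size plus the fixed cost."""
    missing = [f for f in plan.sizes if f not in schedule.unit_costs]
    if missing:
        raise ConfigError(f"cost schedule lacks unit costs for facets {missing}")
    return (
        sum(schedule.unit_costs[f] * n for f, n in plan.sizes.items())
        + schedule.fixed_cost
    )


@dataclass(frozen=True)
class PlanEconomics:
    """A plan with its total cost and effectiveness (a coefficient in [0,1])."""

    plan: DStudyPlan
    total_cost: float
    effectiveness: float

    @classmethod
    def from_schedule(
        cls, plan: DStudyPlan, schedule: CostSchedule, effectiveness: float
    ) -> "PlanEconomics":
        return cls(plan=plan, total_cost=total_cost(schedule, plan),
                   effectiveness=effectiveness)


# ---------------------------------------------------------------------------
# ICER
# ---------------------------------------------------------------------------

def icer(intervention: PlanEconomics, base: PlanEconomics) -> float:
    """Incremental cost-effectiveness ratio ΔC/ΔE (money per 1.0 coefficient).

    Signs are preserved: a cost-saving, less-effective intervention has a
    negative numerator and denominator, hence a positive ICER.  Equal
    effectiveness raises :class:`DominanceError`.
    """
    delta_e = intervention.effectiveness - base.effectiveness
    if delta_e == 0.0:
        raise DominanceError(
            "effectiveness values are equal; the ICER is undefined — "
            "compare the plans' costs directly"
        )
    return (intervention.total_cost - base.total_cost) / delta_e


def rescale_icer(icer_value: float, unit: float = 0.01) -> float:
    """Express an ICER per ``unit`` of coefficient change (default 0.01)."""
    if unit <= 0:
        raise ConfigError(f"rescale unit must be > 0, got {unit}")
    return icer_value * unit


def display_round(amount: float) -> int:
    """Nearest-integer currency rounding, halves away from zero.

    Values are snapped to 9 decimals first so that binary-float noise from
    upstream arithmetic (e.g. a true .5 represented as .499999999999x) does
    not flip the rounding direction.  Display only; computation never uses
    rounded values.
    """
    snapped = round(amount, 9)
    return int(math.floor(abs(snapped) + 0.5)) * (1 if snapped >= 0 else -1)


# ---------------------------------------------------------------------------
# uncertainty distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeltaDistribution:
    """Sampling distribution for an incremental quantity (ΔC or ΔE).

    kinds:
      ``degenerate``  — point mass at ``mean``;
      ``normal``      — Normal(mean, sd), optionally truncated to ``bounds``;
      ``lognormal``   — lognormal on the magnitude with the sign of ``mean``,
                        moment-matched to (|mean|, sd); suited to costs.

    ``sd`` may be given directly or via a coefficient of variation ``cv``
    (sd = cv·|mean|).
    """

    kind: str
    mean: float
    sd: float | None = None
    cv: float | None = None
    bounds: tuple[float, float] | None = None

    def __post_init__(self):
        if self.kind not in ("degenerate", "normal", "lognormal"):
            raise ConfigError(f"unknown distribution kind {self.kind!r}")
        if self.kind != "degenerate" and self.sd is None and self.cv is None:
            raise ConfigError(f"{self.kind} distribution needs sd or cv")
        if self.sd is not None and self.sd < 0:
            raise ConfigError("sd must be ≥ 0")

    @property
    def scale(self) -> float:
        if self.sd is not None:
            return self.sd
        return abs(self.mean) * float(self.cv)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "degenerate" or self.scale == 0.0:
            return np.full(n, self.mean)
        if self.kind == "normal":
            if self.bounds is None:
                return rng.normal(self.mean, self.scale, size=n)
            lo, hi = self.bounds
            a, b = (lo - self.mean) / self.scale, (hi - self.mean) / self.scale
            return truncnorm.rvs(a, b, loc=self.mean, scale=self.scale,
                                 size=n, random_state=rng)
        # lognormal on the magnitude, sign carried from the mean
        m, s = abs(self.mean), self.scale
        if m == 0.0:
            raise ConfigError("lognormal distribution needs a nonzero mean")
        sigma2 = math.log1p((s / m) ** 2)
        mu = math.log(m) - sigma2 / 2.0
        draws = rng.lognormal(mu, math.sqrt(sigma2), size=n)
        return draws if self.mean > 0 else -draws


# ---------------------------------------------------------------------------
# CEAC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CEAResult:
    """Comparator pair economics, ICER, and the Monte-Carlo CEAC."""

    comparator: PlanEconomics | None
    intervention: PlanEconomics | None
    delta_cost: float
    delta_effectiveness: float
    icer: float
    icer_rescaled: float
    rescale_unit: float
    wtp_grid: np.ndarray
    ceac: np.ndarray
    n_draws: int
    seed: int

    @property
    def icer_display(self) -> int:
        return display_round(self.icer_rescaled)

    def curve_frame(self) -> pd.DataFrame:
        """Two-column table (wtp per rescale_unit, probability)."""
        return pd.DataFrame({"wtp": self.wtp_grid, "probability": self.ceac})


def default_wtp_grid(icer_rescaled: float, num: int = 100) -> np.ndarray:
    """0 to 3× the rescaled ICER in ``num`` steps (brackets the threshold)."""
    return np.linspace(0.0, 3.0 * abs(icer_rescaled), num)


def ceac(
    delta_cost_dist: DeltaDistribution,
    delta_effect_dist: DeltaDistribution,
    wtp_grid,
    n_draws: int,
    seed: int,
    rescale_unit: float = 0.01,
    intervention: PlanEconomics | None = None,
    comparator: PlanEconomics | None = None,
) -> CEAResult:
    """Monte-Carlo cost-effectiveness acceptability curve.

    Draws (ΔC_i, ΔE_i) independently from the configured distributions with
    the fixed seed.  For each willingness-to-pay λ on the grid (expressed
    per ``rescale_unit`` of coefficient; converted internally to per-1.0
    units) the curve reports the fraction of draws with incremental net
    benefit λ·ΔE_i − ΔC_i strictly positive (ties count as not
    cost-effective).
    """
    if n_draws < 1:
        raise ConfigError(f"n_draws must be ≥ 1, got {n_draws}")
    wtp = np.asarray(wtp_grid, dtype=float)
    if wtp.size == 0:
        raise ConfigError("WTP grid must be nonempty")
    if rescale_unit <= 0:
        raise ConfigError("rescale unit must be > 0")

    if intervention is not None and comparator is not None:
        delta_c = intervention.total_cost - comparator.total_cost
        delta_e = intervention.effectiveness - comparator.effectiveness
    else:
        delta_c = delta_cost_dist.mean
        delta_e = delta_effect_dist.mean
    if delta_e == 0.0:
        raise DominanceError("ΔE is zero; the ICER and CEAC threshold are undefined")
    icer_value = delta_c / delta_e

    rng = np.random.default_rng(seed)
    dc = delta_cost_dist.sample(rng, n_draws)
    de = delta_effect_dist.sample(rng, n_draws)
    lam_full = wtp[:, None] / rescale_unit  # money per 1.0 coefficient
    inb = lam_full * de[None, :] - dc[None, :]
    probs = np.mean(inb > 0.0, axis=1)

    return CEAResult(
        comparator=comparator,
        intervention=intervention,
        delta_cost=delta_c,
        delta_effectiveness=delta_e,
        icer=icer_value,
        icer_rescaled=rescale_icer(icer_value, rescale_unit),
        rescale_unit=rescale_unit,
        wtp_grid=wtp,
        ceac=probs,
        n_draws=n_draws,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# coefficient uncertainty
# ---------------------------------------------------------------------------

def effectiveness_uncertainty(
    vc: VarianceComponents,
    plan: DStudyPlan,
    method: str = "parametric-bootstrap",
    error_type: str = "relative",
    n_replicates: int = 1000,
    seed: int | None = None,
    scores: pd.DataFrame | None = None,
    value: float | None = None,
) -> float:
    """Standard error of a projected coefficient.

    ``parametric-bootstrap``: resample each mean square as MS·χ²_df/df,
    re-solve the EMS system (truncating negatives at zero), recompute the
    coefficient under ``plan``, and return the standard deviation across
    replicates.  ``jackknife``: delete-one over object-of-measurement
    levels (for nested objects, the i-th person label is removed within
    every parent group to preserve balance); requires ``scores``.
    ``user-supplied``: returns ``value`` unchanged.
    """
    if method == "user-supplied":
        if value is None:
            raise ConfigError("user-supplied method requires a value")
        return float(value)

    if method == "parametric-bootstrap":
        if not vc.has_mean_squares or vc.sizes is None:
            raise ConfigError(
                "parametric bootstrap needs G-study mean squares and df "
                "(components from estimate_components, not assumed values)"
            )
        if n_replicates < 2:
            raise ConfigError("parametric bootstrap needs ≥ 2 replicates")
        rng = np.random.default_rng(seed)
        design = vc.design
        ms = np.array([r.mean_square for r in vc.records])
        dfs = np.array([r.df for r in vc.records], dtype=float)
        c = ems_matrix(design, vc.sizes).to_numpy()
        chi = rng.chisquare(dfs, size=(n_replicates, len(ms)))
        ms_star = ms * chi / dfs
        raw = solve_triangular(c, ms_star.T, lower=False)  # (k, R)
        comps = np.clip(raw, 0.0, None)

        obj = design.object_facet.name
        obj_idx = [i for i, e in enumerate(design.effects)
                   if e.facets == design.object_effect.facets][0]
        weights = np.zeros(len(design.effects))
        for i, eff in enumerate(design.effects):
            if i == obj_idx:
                continue
            in_error = (obj in eff.facets) or (error_type == "absolute")
            if in_error:
                weights[i] = 1.0 / math.prod(
                    plan.size(g) for g in eff.facets if g != obj
                )
        ov = comps[obj_idx]
        ev = weights @ comps
        denom = ov + ev
        with np.errstate(invalid="ignore", divide="ignore"):
            coefs = np.where(denom > 0, ov / np.where(denom > 0, denom, 1.0), np.nan)
        coefs = coefs[np.isfinite(coefs)]
        if coefs.size < 2:
            return 0.0
        return float(np.std(coefs, ddof=1))

    if method == "jackknife":
        if scores is None:
            raise ConfigError("jackknife requires the original score table")
        design = vc.design
        obj = design.object_facet.name
        parents = list(design.object_facet.nested_within)
        work = scores.copy()
        if parents:
            work["_rank"] = work.groupby(parents)[obj].transform(
                lambda s: s.rank(method="dense").astype(int) - 1
            )
        else:
            labels = {v: i for i, v in enumerate(sorted(work[obj].unique()))}
            work["_rank"] = work[obj].map(labels)
        n = int(work["_rank"].max()) + 1
        if n < 2:
            raise ConfigError("jackknife needs ≥ 2 object-of-measurement levels")
        thetas = []
        for i in range(n):
            sub = work[work["_rank"] != i].drop(columns="_rank")
            vc_i = estimate_components(sub, design)
            thetas.append(g_coefficient(vc_i, plan, error_type).coefficient)
        thetas = np.asarray(thetas)
        return float(math.sqrt((n - 1) / n * np.sum((thetas - thetas.mean()) ** 2)))

    raise ConfigError(f"unknown uncertainty method {method!r}")
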