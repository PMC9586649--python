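"""The four-step run: G study → costs → D study + ICER → Monte-Carlo CEAC.

A single YAML configuration drives the whole flow so the audit trail of a
cost-effectiveness run lives in one file.  Validation happens before any
computation; outputs are written only once every step has succeeded, so a
failed run leaves no partial files.  Re-running an unchanged configuration
reproduces every machine-readable output byte for byte.
"""
from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cea import (
    CEAResult,
    CostSchedule,
    DeltaDistribution,
    PlanEconomics,
    ceac,
    default_wtp_grid,
    display_round,
    effectiveness_uncertainty,
    icer,
    rescale_icer,
    total_cost,
)
from .design import Design, parse_design
from .dstudy import DStudyPlan, dstudy_grid, grid_frame
from .errors import ConfigError, PipelineError
from .gstudy import VarianceComponents, estimate_components
from .io import read_scores, sha256_of, write_json, write_table
from .simulate import SimulationSpec, simulate_scores


@dataclass(frozen=True)
class RunConfig:
    """A validated run configuration (see :func:`load_config`)."""

    design: Design
    error_type: str
    scores_path: Path | None
    simulation: SimulationSpec | None
    assumed_components: dict[str, float] | None
    plans: list[DStudyPlan]
    schedule: CostSchedule
    cea_base: str
    cea_intervention: str
    effectiveness_override: dict[str, float]
    cost_override: dict[str, float]
    rescale_unit: float
    dist_cost: dict
    dist_effect: dict
    wtp_grid: np.ndarray | None
    n_draws: int
    cea_seed: int
    source_path: Path | None = None


def demo_config_path() -> Path:
    """Path of the packaged demonstration configuration (synthetic data)."""
    return Path(importlib.resources.files("precog") / "data" / "demo_config.yaml")


def load_config(path) -> RunConfig:
    """Load and fully validate a YAML run configuration.

    Every error class (missing seed, unknown plan reference, bad
    distribution, absent score file, ...) is caught here, before any
    computation begins.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    return _validate(raw, base_dir=path.parent, source=path)


def config_from_dict(raw: dict, base_dir=".") -> RunConfig:
    return _validate(dict(raw), base_dir=Path(base_dir), source=None)


def _validate(raw: dict, base_dir: Path, source: Path | None) -> RunConfig:
    if "design" not in raw:
        raise ConfigError("config lacks a 'design' formula")
    design = parse_design(str(raw["design"]))

    error_type = str(raw.get("error_type", "relative"))
    if error_type not in ("relative", "absolute"):
        raise ConfigError(f"error_type must be relative|absolute, got {error_type!r}")

    scores_path = None
    simulation = None
    assumed = None
    sources = [k for k in ("scores", "simulation", "components") if k in raw]
    if len(sources) != 1:
        raise ConfigError(
            "config must provide exactly one of scores:, simulation:, components:"
        )
    if "scores" in raw:
        scores_path = (base_dir / str(raw["scores"])).resolve()
        if not scores_path.exists():
            raise ConfigError(f"score table not found: {scores_path}")
    elif "simulation" in raw:
        sim = raw["simulation"]
        if "seed" not in sim:
            raise ConfigError("simulation block requires an explicit seed")
        simulation = SimulationSpec(
            design=design,
            sizes={str(k): int(v) for k, v in sim.get("sizes", {}).items()},
            true_components={str(k): float(v)
                             for k, v in sim.get("components", {}).items()},
            grand_mean=float(sim.get("grand_mean", 0.0)),
            seed=int(sim["seed"]),
        )
        simulation.validate()
    else:
        assumed = {str(k): float(v) for k, v in raw["components"].items()}
        VarianceComponents.assumed(design, assumed)  # validates

    plans_raw = raw.get("plans") or []
    if not plans_raw:
        raise ConfigError("config requires at least one plan")
    plans = []
    labels = set()
    for p in plans_raw:
        label = str(p.get("label", ""))
        if not label or label in labels:
            raise ConfigError(f"plans need unique nonempty labels (offender: {label!r})")
        labels.add(label)
        plans.append(DStudyPlan(sizes={str(k): int(v)
                                       for k, v in p["sizes"].items()}, label=label))
    obj = design.object_facet.name
    for plan in plans:
        for f in design.facet_names:
            if f != obj:
                plan.size(f)

    cs = raw.get("cost_schedule")
    if not cs:
        raise ConfigError("config lacks a cost_schedule")
    schedule = CostSchedule(
        unit_costs={str(k): float(v) for k, v in cs.get("unit_costs", {}).items()},
        fixed_cost=float(cs.get("fixed_cost", 0.0)),
        currency_label=str(cs.get("currency", "£")),
    )
    for plan in plans:
        total_cost(schedule, plan)  # raises if a facet is missing

    cea_block = raw.get("cea")
    if not cea_block:
        raise ConfigError("config lacks a cea block")
    for key in ("base", "intervention"):
        if str(cea_block.get(key, "")) not in labels:
            raise ConfigError(f"cea.{key} must name one of the plans")
    if "seed" not in cea_block:
        raise ConfigError("cea block requires an explicit seed (no clock seeding)")
    n_draws = int(cea_block.get("n_draws", 10000))
    if n_draws < 1:
        raise ConfigError("cea.n_draws must be ≥ 1")

    unc = cea_block.get("uncertainty", {})
    dist_cost = dict(unc.get("delta_cost", {"kind": "degenerate"}))
    dist_effect = dict(unc.get("delta_effectiveness", {"kind": "degenerate"}))
    for d in (dist_cost, dist_effect):
        if d.get("kind", "degenerate") not in ("degenerate", "normal", "lognormal"):
            raise ConfigError(f"unknown distribution kind {d.get('kind')!r}")

    wtp = None
    if "wtp_grid" in cea_block:
        g = cea_block["wtp_grid"]
        if isinstance(g, dict):
            wtp = np.linspace(float(g["start"]), float(g["stop"]), int(g["num"]))
        else:
            wtp = np.asarray([float(v) for v in g])
        if wtp.size == 0:
            raise ConfigError("cea.wtp_grid must be nonempty")

    return RunConfig(
        design=design,
        error_type=error_type,
        scores_path=scores_path,
        simulation=simulation,
        assumed_components=assumed,
        plans=plans,
        schedule=schedule,
        cea_base=str(cea_block["base"]),
        cea_intervention=str(cea_block["intervention"]),
        effectiveness_override={str(k): float(v)
                                for k, v in
                                (cea_block.get("effectiveness") or {}).items()},
        cost_override={str(k): float(v)
                       for k, v in (cea_block.get("costs") or {}).items()},
        rescale_unit=float(cea_block.get("rescale_unit", 0.01)),
        dist_cost=dist_cost,
        dist_effect=dist_effect,
        wtp_grid=wtp,
        n_draws=n_draws,
        cea_seed=int(cea_block["seed"]),
        source_path=source,
    )


def _step(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"step {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig, output_dir) -> dict:
    """Execute the four steps and write reports to ``output_dir``.

    Outputs: ``variance_components.csv``, ``dstudy.csv``, ``ceac.csv``,
    ``summary.json``.  Files are written only after all steps succeed.
    Returns the summary as a dict.
    """
    output_dir = Path(output_dir)

    # -- step 1: G study (or assumed components) ------------------------
    with _step("gstudy"):
        if config.simulation is not None:
            scores = simulate_scores(config.simulation)
            vc = estimate_components(scores, config.design)
            data_provenance = {"simulation_seed": config.simulation.seed}
        elif config.scores_path is not None:
            scores = read_scores(config.scores_path, config.design)
            vc = estimate_components(scores, config.design)
            data_provenance = {"scores_sha256": sha256_of(config.scores_path)}
        else:
            scores = None
            vc = VarianceComponents.assumed(config.design, config.assumed_components)
            data_provenance = {"components": "assumed"}
        vc_frame = vc.to_frame()

    # -- step 2: cost aggregation ---------------------------------------
    with _step("costs"):
        costs = {}
        for plan in config.plans:
            if plan.label in config.cost_override:
                costs[plan.label] = config.cost_override[plan.label]
            else:
                costs[plan.label] = total_cost(config.schedule, plan)

    # -- step 3: D study + ICER -----------------------------------------
    with _step("dstudy"):
        results = dstudy_grid(vc, config.plans, config.error_type)
        dframe = grid_frame(results)
        effectiveness = {
            r.plan.label: config.effectiveness_override.get(
                r.plan.label, r.coefficient
            )
            for r in results
        }
        base = PlanEconomics(
            plan=next(p for p in config.plans if p.label == config.cea_base),
            total_cost=costs[config.cea_base],
            effectiveness=effectiveness[config.cea_base],
        )
        intervention = PlanEconomics(
            plan=next(p for p in config.plans if p.label == config.cea_intervention),
            total_cost=costs[config.cea_intervention],
            effectiveness=effectiveness[config.cea_intervention],
        )
        icer_value = icer(intervention, base)
        icer_scaled = rescale_icer(icer_value, config.rescale_unit)

    # -- step 4: Monte-Carlo CEAC ---------------------------------------
    with _step("ceac"):
        delta_c = intervention.total_cost - base.total_cost
        delta_e = intervention.effectiveness - base.effectiveness
        dist_c = _build_dist(config.dist_cost, mean=delta_c)
        dist_e = _build_dist(
            config.dist_effect, mean=delta_e, bounds=(-1.0, 1.0),
            auto_sd=lambda: _auto_delta_sd(vc, config),
        )
        wtp = (config.wtp_grid if config.wtp_grid is not None
               else default_wtp_grid(icer_scaled))
        cea_result = ceac(
            dist_c, dist_e, wtp, config.n_draws, config.cea_seed,
            rescale_unit=config.rescale_unit,
            intervention=intervention, comparator=base,
        )

    # -- reports ---------------------------------------------------------
    summary = {
        "package_version": __version__,
        "design": config.design.formula_text,
        "error_type": config.error_type,
        "provenance": {
            **data_provenance,
            "cea_seed": config.cea_seed,
            "config_sha256": (sha256_of(config.source_path)
                              if config.source_path else None),
        },
        "plans": {
            p.label: {
                "sizes": p.sizes,
                "total_cost": costs[p.label],
                "effectiveness": effectiveness[p.label],
            }
            for p in config.plans
        },
        "cea": {
            "base": config.cea_base,
            "intervention": config.cea_intervention,
            "delta_cost": cea_result.delta_cost,
            "delta_effectiveness": cea_result.delta_effectiveness,
            "icer_per_unit": cea_result.icer,
            "rescale_unit": config.rescale_unit,
            "icer_rescaled": cea_result.icer_rescaled,
            "icer_display": cea_result.icer_display,
            "currency": config.schedule.currency_label,
            "n_draws": config.n_draws,
        },
    }

    write_table(vc_frame, output_dir / "variance_components.csv")
    write_table(dframe, output_dir / "dstudy.csv")
    write_table(cea_result.curve_frame(), output_dir / "ceac.csv")
    write_json(summary, output_dir / "summary.json")
    return summary


def _build_dist(spec: dict, mean: float, bounds=None, auto_sd=None) -> DeltaDistribution:
    kind = spec.get("kind", "degenerate")
    sd = spec.get("sd")
    cv = spec.get("cv")
    if sd == "auto":
        if auto_sd is None:
            raise ConfigError("sd: auto is only available for delta_effectiveness")
        sd = auto_sd()
    return DeltaDistribution(
        kind=kind,
        mean=mean,
        sd=None if sd is None else float(sd),
        cv=None if cv is None else float(cv),
        bounds=bounds if kind == "normal" else None,
    )


def _auto_delta_sd(vc: VarianceComponents, config: RunConfig) -> float:
    """SE of ΔE via per-plan parametric bootstrap, combined in quadrature."""
    if not vc.has_mean_squares:
        raise ConfigError(
            "sd: auto requires G-study mean squares (scores or simulation input)"
        )
    by_label = {p.label: p for p in config.plans}
    ses = []
    for i, label in enumerate((config.cea_base, config.cea_intervention)):
        ses.append(
            effectiveness_uncertainty(
                vc,
                by_label[label],
                method="parametric-bootstrap",
                error_type=config.error_type,
                n_replicates=1000,
                seed=config.cea_seed + 1 + i,
            )
        )
    return float(math.hypot(*ses))
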