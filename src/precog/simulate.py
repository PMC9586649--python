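"""Balanced rating-data simulator with known true variance components.

Scores are generated from the random-effects decomposition the G study
assumes: one independent zero-mean normal draw per effect per level
combination, with variance equal to that effect's true component, summed
onto the grand mean.  The simulator exists for parameter-recovery
experiments, expected-mean-square oracles, and end-to-end demonstrations —
no external data are required anywhere in the package.

Only normal effect draws are shipped; the ANOVA estimators are
moment-based, so recovery checks remain informative even though real
rating scales are bounded and often ordinal (see the methods note).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import Design
from .errors import ConfigError
from .gstudy import SCORE_COLUMN, VarianceComponents, estimate_components


@dataclass(frozen=True)
class SimulationSpec:
    """A generative model: design, facet sizes, true components, seed."""

    design: Design
    sizes: dict[str, int]
    true_components: VarianceComponents | dict[str, float]
    grand_mean: float = 0.0
    seed: int = 0

    def components(self) -> VarianceComponents:
        if isinstance(self.true_components, VarianceComponents):
            return self.true_components
        return VarianceComponents.assumed(self.design, dict(self.true_components))

    def validate(self) -> None:
        missing = [f for f in self.design.facet_names if f not in self.sizes]
        if missing:
            raise ConfigError(f"simulation spec lacks sizes for facets {missing}")
        for f, n in self.sizes.items():
            if n < 1:
                raise ConfigError(f"size for facet {f!r} must be ≥ 1, got {n}")
        self.components()  # validates names and non-negativity


def simulate_scores(spec: SimulationSpec) -> pd.DataFrame:
    """Generate one balanced score table from the spec.

    Rows enumerate the full factorial of facet levels (nested facets reuse
    labels 0..n-1 within each parent combination; the parent columns
    disambiguate).  Identical seeds give identical tables.
    """
    spec.validate()
    design = spec.design
    vc = spec.components()
    rng = np.random.default_rng(spec.seed)
    names = list(design.facet_names)
    dims = [spec.sizes[f] for f in names]

    index = pd.MultiIndex.from_product(
        [np.arange(n) for n in dims], names=names
    ).to_frame(index=False)
    scores = np.full(len(index), float(spec.grand_mean))

    order = {name: i for i, name in enumerate(names)}
    level_arrays = {name: index[name].to_numpy() for name in names}
    for eff in design.effects:
        sd = np.sqrt(vc.sigma2(eff.name))
        cols = sorted(eff.facets, key=order.__getitem__)
        shape = tuple(spec.sizes[c] for c in cols)
        draws = rng.normal(0.0, 1.0, size=int(np.prod(shape))) * sd
        codes = np.ravel_multi_index(
            tuple(level_arrays[c] for c in cols), dims=shape
        )
        scores = scores + draws[codes]

    index[SCORE_COLUMN] = scores
    return index


def recovery_experiment(spec: SimulationSpec, n_replicates: int) -> pd.DataFrame:
    """Simulate → estimate repeatedly; report per-effect bias and RMSE.

    Replicate seeds are spawned deterministically from ``spec.seed``, so
    the whole experiment is reproducible.
    """
    if n_replicates < 2:
        raise ConfigError("recovery experiment needs ≥ 2 replicates")
    spec.validate()
    truth = spec.components()
    master = np.random.default_rng(spec.seed)
    seeds = master.integers(0, 2**31 - 1, size=n_replicates)

    names = [e.name for e in spec.design.effects]
    estimates = np.empty((n_replicates, len(names)))
    for r, s in enumerate(seeds):
        rep = SimulationSpec(
            design=spec.design,
            sizes=spec.sizes,
            true_components=truth,
            grand_mean=spec.grand_mean,
            seed=int(s),
        )
        vc_hat = estimate_components(simulate_scores(rep), spec.design)
        estimates[r] = [vc_hat.sigma2(n) for n in names]

    true_vals = np.array([truth.sigma2(n) for n in names])
    mean_est = estimates.mean(axis=0)
    bias = mean_est - true_vals
    rmse = np.sqrt(np.mean((estimates - true_vals) ** 2, axis=0))
    return pd.DataFrame(
        {
            "effect": names,
            "true": true_vals,
            "mean_estimate": mean_est,
            "bias": bias,
            "rmse": rmse,
        }
    )
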