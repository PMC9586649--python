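"""Independent test oracles: tensor-algebra ANOVA for balanced designs.

These helpers never call the package's sums-of-squares or EMS code paths.
Balanced data are held as a dense array with one axis per facet (replicates
on axis 0); effect estimates are built directly from their definitions —
the mean over the effect's cells minus all contained effect estimates and
the grand mean — and sums of squares follow by squaring and summing over
the full grid.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd


def simulate_tensor(design, sizes, sigma2, n_reps, rng, grand_mean=0.0):
    """Draw score tensors (n_reps, *dims) from the random-effects model."""
    names = list(design.facet_names)
    dims = [sizes[n] for n in names]
    out = np.full([n_reps] + dims, float(grand_mean))
    for eff in design.effects:
        sd = math.sqrt(sigma2.get(eff.name, 0.0))
        shape = [n_reps] + [sizes[n] if n in eff.facets else 1 for n in names]
        out += rng.normal(0.0, 1.0, size=shape) * sd
    return out


def ss_from_effect_means(design, sizes, tensor):
    """Per-effect SS from effect-mean definitions; returns name -> (R,) array."""
    names = list(design.facet_names)
    dims = [sizes[n] for n in names]
    n_total = math.prod(dims)
    grid_axes = tuple(range(1, tensor.ndim))
    grand = tensor.mean(axis=grid_axes, keepdims=True)

    terms = {}
    for eff in design.effects:  # increasing index-set order
        absent = tuple(i + 1 for i, n in enumerate(names) if n not in eff.facets)
        t = tensor.mean(axis=absent, keepdims=True) - grand
        for b in design.effects:
            if b.facets < eff.facets:
                t = t - terms[b.name]
        terms[eff.name] = t

    ss = {}
    for eff in design.effects:
        t = terms[eff.name]
        obs_per_cell = n_total / math.prod(sizes[n] for n in eff.facets)
        ss[eff.name] = (t ** 2).sum(axis=grid_axes) * obs_per_cell
    return ss


def tensor_to_frame(design, sizes, grid):
    """One replicate's tensor as a long-format score table."""
    names = list(design.facet_names)
    index = pd.MultiIndex.from_product(
        [np.arange(sizes[n]) for n in names], names=names
    ).to_frame(index=False)
    index["score"] = np.asarray(grid).reshape(-1)
    return index


def monte_carlo_mean_squares(design, sizes, sigma2, n_reps, rng):
    """MC mean and standard error of each effect's mean square."""
    from precog.design import degrees_of_freedom

    tensor = simulate_tensor(design, sizes, sigma2, n_reps, rng)
    ss = ss_from_effect_means(design, sizes, tensor)
    out = {}
    for eff in design.effects:
        ms = ss[eff.name] / degrees_of_freedom(eff, sizes)
        out[eff.name] = (ms.mean(), ms.std(ddof=1) / math.sqrt(n_reps))
    return out


def relative_g_closed_form(sigma_p, sigma_pt, sigma_pr, sigma_ptr, n_t, n_r):
    """Direct evaluation of the two-facet crossed relative-error coefficient."""
    err = sigma_pt / n_t + sigma_pr / n_r + sigma_ptr / (n_t * n_r)
    return sigma_p / (sigma_p + err)
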