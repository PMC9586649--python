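"""G study: variance-component estimation from balanced rating data.

The estimator is the classical ANOVA (expected-mean-squares) method for
balanced random-effects designs: sums of squares by the T-term method,
mean squares, and a triangular expected-mean-square system solved exactly.
Negative raw estimates are truncated to zero *after* solving the full
system; the raw values are retained for diagnostics and sensitivity work.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .design import Design, Effect, degrees_of_freedom
from .errors import DataError, InternalError

SCORE_COLUMN = "score"


@dataclass(frozen=True)
class ComponentRecord:
    """One effect's estimated (or assumed) variance component."""

    effect: str
    sigma2: float
    raw_estimate: float
    truncated: bool
    mean_square: float | None = None
    df: int | None = None


@dataclass(frozen=True)
class VarianceComponents:
    """Per-effect variance components tied to a design.

    Holds either G-study estimates (with mean squares and degrees of
    freedom, needed for downstream uncertainty work) or assumed true values
    (``assumed`` constructor; ``mean_square``/``df`` are then ``None``).
    """

    design: Design
    records: tuple[ComponentRecord, ...]
    sizes: dict[str, int] | None = None

    @classmethod
    def assumed(cls, design: Design, sigma2s: dict[str, float]) -> "VarianceComponents":
        known = {e.name for e in design.effects}
        unknown = set(sigma2s) - known
        if unknown:
            raise KeyError(
                f"components named for effects not in the design: {sorted(unknown)}"
            )
        recs = []
        for e in design.effects:
            v = float(sigma2s.get(e.name, 0.0))
            if v < 0:
                raise ValueError(f"negative variance component for {e.name!r}")
            recs.append(ComponentRecord(e.name, v, v, False))
        return cls(design=design, records=tuple(recs))

    def __getitem__(self, effect_name: str) -> ComponentRecord:
        for r in self.records:
            if r.effect == effect_name:
                return r
        raise KeyError(effect_name)

    def sigma2(self, effect_name: str) -> float:
        return self[effect_name].sigma2

    @property
    def has_mean_squares(self) -> bool:
        return all(r.mean_square is not None and r.df is not None for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        """Structured report: effect, df, MS, raw, truncated, sigma2, % of total."""
        total = sum(r.sigma2 for r in self.records)
        rows = []
        for r in self.records:
            rows.append(
                {
                    "effect": r.effect,
                    "df": r.df,
                    "mean_square": r.mean_square,
                    "raw_estimate": r.raw_estimate,
                    "truncated": r.truncated,
                    "sigma2": r.sigma2,
                    "percent_total": 100.0 * r.sigma2 / total if total > 0 else 0.0,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# balance validation and size inference
# ---------------------------------------------------------------------------

def infer_sizes(scores: pd.DataFrame, design: Design) -> dict[str, int]:
    """Facet sizes implied by a balanced table (nested sizes are per parent)."""
    sizes: dict[str, int] = {}
    for f in design.facets:
        if f.nested_within:
            per_parent = scores.groupby(list(f.nested_within), sort=True)[f.name].nunique()
            if per_parent.nunique() != 1:
                raise DataError(
                    f"facet {f.name!r} has unequal level counts across "
                    f"{'×'.join(f.nested_within)} combinations"
                )
            sizes[f.name] = int(per_parent.iloc[0])
        else:
            sizes[f.name] = int(scores[f.name].nunique())
    return sizes


def validate_scores(scores: pd.DataFrame, design: Design) -> dict[str, int]:
    """Check the balanced-design contract; return inferred facet sizes.

    Exactly one row per admissible index combination, no missing scores.
    Raises :class:`DataError` naming the first offending cell.
    """
    cols = list(design.facet_names)
    missing_cols = [c for c in cols + [SCORE_COLUMN] if c not in scores.columns]
    if missing_cols:
        raise DataError(f"score table lacks columns {missing_cols}")
    if len(scores) == 0:
        raise DataError("no data: score table is empty")
    if scores[SCORE_COLUMN].isna().any():
        first = int(scores.index[scores[SCORE_COLUMN].isna()][0])
        raise DataError(f"missing score at row {first}")

    sizes = infer_sizes(scores, design)
    counts = scores.groupby(cols, sort=True).size()
    bad = counts[counts != 1]
    if len(bad) > 0:
        cell = dict(zip(cols, np.atleast_1d(bad.index[0])))
        raise DataError(f"unbalanced table: index combination {cell} appears "
                        f"{int(bad.iloc[0])} times")
    expected = math.prod(sizes.values())
    if len(counts) != expected:
        # find an incomplete cell: some combination of facet levels is absent
        raise DataError(
            f"unbalanced table: {len(counts)} distinct index combinations, "
            f"expected {expected} from facet sizes {sizes}"
        )
    return sizes


# ---------------------------------------------------------------------------
# sums of squares (T-term method)
# ---------------------------------------------------------------------------

def sums_of_squares(scores: pd.DataFrame, design: Design) -> pd.Series:
    """Per-effect sums of squares for a balanced table.

    Uses the T-term identity ``T(alpha) = T(mu) + sum of SS(beta) over
    effects beta contained in alpha``, where ``T(alpha)`` is the sum over
    alpha's cells of (cell count)·(cell mean)².  Effects are processed in
    increasing index-set order so each SS is obtained by subtraction.
    """
    validate_scores(scores, design)
    x = scores[SCORE_COLUMN].to_numpy(dtype=float)
    n_total = len(x)
    grand = x.mean()
    t_mu = n_total * grand * grand

    order = {name: i for i, name in enumerate(design.facet_names)}
    ss: dict[str, float] = {}
    for eff in design.effects:  # already sorted by |facets|
        cols = sorted(eff.facets, key=order.__getitem__)
        grp = scores.groupby(cols, sort=False)[SCORE_COLUMN]
        means = grp.mean().to_numpy()
        counts = grp.size().to_numpy()
        t_eff = float(np.sum(counts * means * means))
        inner = sum(ss[b.name] for b in design.effects
                    if b.facets < eff.facets)
        ss[eff.name] = t_eff - t_mu - inner
    return pd.Series(ss, name="SS")


# ---------------------------------------------------------------------------
# expected mean squares
# ---------------------------------------------------------------------------

def ems_matrix(design: Design, sizes: dict[str, int]) -> pd.DataFrame:
    """EMS coefficient matrix C with E[MS] = C @ sigma2.

    Row alpha, column beta: the coefficient of component beta in the
    expected mean square of effect alpha — the product of sizes of facets
    absent from beta when beta contains alpha, else zero.  With effects in
    increasing index-set order the matrix is upper triangular with positive
    diagonal, hence invertible.
    """
    names = [e.name for e in design.effects]
    k = len(names)
    c = np.zeros((k, k))
    all_names = set(design.facet_names)
    for j, beta in enumerate(design.effects):
        absent = all_names - beta.facets
        coef = math.prod(sizes[g] for g in absent)
        for i, alpha in enumerate(design.effects):
            if alpha.facets <= beta.facets:
                c[i, j] = coef
    return pd.DataFrame(c, index=names, columns=names)


def solve_components(mean_squares: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Solve the triangular EMS system for raw (untruncated) components."""
    if np.any(np.abs(np.diag(c)) < 1e-12):
        raise InternalError("singular EMS system: confounded effects not merged")
    return solve_triangular(c, mean_squares, lower=False)


def estimate_components(scores: pd.DataFrame, design: Design) -> VarianceComponents:
    """The G study: ANOVA variance-component estimates from balanced data.

    Mean squares are SS/df; the raw components solve the EMS system
    exactly (back-substitution in decreasing effect order); negative raw
    estimates are truncated to zero with a flag.
    """
    sizes = validate_scores(scores, design)
    ss = sums_of_squares(scores, design)
    dfs = {}
    for eff in design.effects:
        df = degrees_of_freedom(eff, sizes)
        if df == 0:
            small = sorted(n for n in eff.primary if sizes[n] < 2)
            which = small[0] if small else eff.name
            raise DataError(
                f"need ≥ 2 levels of {which!r} to estimate effect {eff.name!r}"
            )
        dfs[eff.name] = df
    ms = np.array([ss[e.name] / dfs[e.name] for e in design.effects])
    c = ems_matrix(design, sizes).to_numpy()
    raw = solve_components(ms, c)
    records = []
    for e, r, m in zip(design.effects, raw, ms):
        records.append(
            ComponentRecord(
                effect=e.name,
                sigma2=float(max(r, 0.0)),
                raw_estimate=float(r),
                truncated=bool(r < 0),
                mean_square=float(m),
                df=dfs[e.name],
            )
        )
    return VarianceComponents(design=design, records=tuple(records), sizes=sizes)
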