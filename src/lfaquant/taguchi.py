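"""Dynamic-characteristic Taguchi analysis for two-level screening designs.

The quality characteristic is the dynamic signal-to-noise ratio

    S/N = -10 * log10(Sd^2 / beta^2)   [dB]

where ``beta`` is the zero-point-proportional slope between measured and
reference signals and ``Sd`` the residual standard deviation about that
line.  Larger S/N means a more proportional, less noisy instrument response.
On top of the per-run statistic the module provides the classical screening
workflow: response table (level means, effects, ranks), ANOVA with an
error pool built from unassigned columns, factor screening at a confidence
threshold, baseline-preserving optimal-level selection with an additive
S/N prediction, and 2x2 interaction cell means.

``TaguchiModel`` / ``TaguchiResults`` wrap the workflow statsmodels-style;
the module-level functions are the individual steps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import FactorAssignment, OrthogonalArray, column_labels, error_columns
from .exceptions import (
    ConfoundedInteractionWarning,
    DegenerateDataError,
    InputError,
)

__all__ = [
    "fit_dynamic",
    "sn_dynamic",
    "RunResponse",
    "run_response",
    "ResponseTable",
    "response_table",
    "best_levels",
    "AnovaTable",
    "anova",
    "significant_factors",
    "OptimalSelection",
    "select_optimal",
    "InteractionSummary",
    "interaction_cells",
    "TaguchiModel",
    "TaguchiResults",
]


# ---------------------------------------------------------------------------
# per-run statistic


def fit_dynamic(
    standard_signals,
    measured_signals,
    *,
    through_origin: bool = True,
) -> tuple[float, float]:
    """Fit measured vs. reference signals; return ``(beta, sd)``.

    Default is the zero-point-proportional (through-origin) form standard for
    dynamic characteristics: ``beta = sum(M*y) / sum(M^2)`` and ``sd`` the
    residual standard deviation with ``n - 1`` divisor.  ``through_origin=False``
    fits an intercept (ordinary least squares, ``n - 2`` divisor).
    """
    M = np.asarray(standard_signals, dtype=float)
    y = np.asarray(measured_signals, dtype=float)
    if M.ndim != 1 or y.ndim != 1 or M.shape != y.shape:
        raise InputError("standard and measured signals must be 1-D of equal length")
    n = M.size
    if n < 2:
        raise InputError("at least two signal pairs are required")
    if through_origin:
        denom = float(M @ M)
        if denom == 0.0:
            raise DegenerateDataError("all reference signals are zero; slope undefined")
        beta = float(M @ y) / denom
        resid = y - beta * M
        sd = math.sqrt(float(resid @ resid) / (n - 1))
        # exact proportionality up to float rounding is a perfect fit
        if sd < 1e-12 * math.sqrt(float(y @ y) / (n - 1)):
            sd = 0.0
    else:
        if n < 3:
            raise InputError("intercept fit requires at least three signal pairs")
        if np.ptp(M) == 0.0:
            raise DegenerateDataError("constant reference signals; slope undefined")
        beta, intercept = np.polyfit(M, y, 1)
        resid = y - (beta * M + intercept)
        sd = math.sqrt(float(resid @ resid) / (n - 2))
        beta = float(beta)
    return beta, sd


def sn_dynamic(beta: float, sd: float) -> float:
    """Dynamic S/N in dB, ``-10*log10(sd^2/beta^2) = 20*log10(|beta|/sd)``.

    A perfect fit (``sd == 0``) returns ``math.inf``, the distinguished
    unbounded-S/N outcome.  ``beta == 0`` is an error: no signal response.
    """
    if beta == 0:
        raise DegenerateDataError("slope is zero; dynamic S/N undefined")
    if sd < 0:
        raise InputError("residual spread must be non-negative")
    if sd == 0:
        return math.inf
    return -10.0 * math.log10(sd**2 / beta**2)


@dataclass(frozen=True)
class RunResponse:
    """One run's paired signals with its fitted slope, spread and S/N."""

    run_index: int
    standard_signals: np.ndarray
    measured_signals: np.ndarray
    beta: float
    sd: float
    sn_db: float


def run_response(
    run_index, standard_signals, measured_signals, *, scale: float = 1.0, **kw
) -> RunResponse:
    """Fit one run's signal pair and attach its S/N.

    ``scale`` divides both signal vectors before fitting (e.g. 255 to work
    on the normalized 0-1 grayscale convention, under which a near-ideal
    8-bit reader has beta ~ 1, Sd ~ 0.005 and S/N in the 40-50 dB range).
    Joint scaling leaves beta and all level effects unchanged and shifts
    every run's S/N by the same constant, so screening conclusions do not
    depend on it -- only the absolute dB values do.
    """
    M = np.asarray(standard_signals, dtype=float)
    y = np.asarray(measured_signals, dtype=float)
    if scale <= 0:
        raise InputError("scale must be positive")
    beta, sd = fit_dynamic(M / scale, y / scale, **kw)
    return RunResponse(
        run_index=int(run_index),
        standard_signals=M,
        measured_signals=y,
        beta=beta,
        sd=sd,
        sn_db=sn_dynamic(beta, sd),
    )


# ---------------------------------------------------------------------------
# response table


@dataclass(frozen=True)
class ResponseTable:
    """Per-column level means of S/N with effects, ranges and ranks.

    ``table`` is indexed by column label with columns
    ``level1_mean, level2_mean, effect, range, rank``; ``effect`` is
    level-2 mean minus level-1 mean, ``rank`` orders columns by descending
    range (ties broken by column order).
    """

    grand_mean: float
    table: pd.DataFrame

    @property
    def labels(self) -> list[str]:
        return list(self.table.index)

    def level_mean(self, label: str, level: int) -> float:
        return float(self.table.loc[label, f"level{level}_mean"])


def _check_run_sn(array: OrthogonalArray, run_sn) -> np.ndarray:
    sn = np.asarray(run_sn, dtype=float)
    if sn.ndim != 1 or sn.size != array.n_runs:
        raise InputError(
            f"run_sn must have one value per run ({array.n_runs}), got {sn.size}"
        )
    return sn


def response_table(
    array: OrthogonalArray, run_sn, labels: list[str] | None = None
) -> ResponseTable:
    """Tabulate level means, effects (level2 - level1), ranges and ranks."""
    sn = _check_run_sn(array, run_sn)
    labels = labels or column_labels(array, None)
    if len(labels) != array.n_columns:
        raise InputError("one label per array column is required")
    m1 = np.array([sn[array.column(j) == 1].mean() for j in range(array.n_columns)])
    m2 = np.array([sn[array.column(j) == 2].mean() for j in range(array.n_columns)])
    effect = m2 - m1
    rng = np.abs(effect)
    order = np.argsort(-rng, kind="stable")  # stable: ties keep column order
    rank = np.empty(array.n_columns, dtype=int)
    rank[order] = np.arange(1, array.n_columns + 1)
    table = pd.DataFrame(
        {
            "level1_mean": m1,
            "level2_mean": m2,
            "effect": effect,
            "range": rng,
            "rank": rank,
        },
        index=pd.Index(labels, name="factor"),
    )
    return ResponseTable(grand_mean=float(sn.mean()), table=table)


def best_levels(table: ResponseTable) -> dict[str, int]:
    """Per column, the level with the larger mean S/N (ties -> level 1)."""
    out = {}
    for label, row in table.table.iterrows():
        out[label] = 2 if row["level2_mean"] > row["level1_mean"] else 1
    return out


# ---------------------------------------------------------------------------
# ANOVA


@dataclass(frozen=True)
class AnovaTable:
    """One-dof-per-column ANOVA of run S/N with a pooled error term.

    ``table`` is indexed by factor id with columns
    ``sum_sq, dof, mean_sq, f_ratio, confidence, pooled``; ``confidence`` is
    100*(1 - upper-tail F probability) and reported only for non-pooled
    factors.
    """

    table: pd.DataFrame
    error_ss: float
    error_dof: int
    total_ss: float
    total_dof: int

    @property
    def error_ms(self) -> float:
        return self.error_ss / self.error_dof if self.error_dof else math.nan


def _pooled_factor_ids(
    pooling,
    assignment: list[FactorAssignment],
    ss: np.ndarray,
    ranges: np.ndarray,
    err_cols: list[int],
) -> set[str]:
    """Resolve the pooling rule into a set of pooled factor ids."""
    if pooling is None or pooling == "none":
        return set()
    if (
        isinstance(pooling, tuple)
        and len(pooling) == 2
        and pooling[0] == "range-below"
    ):
        # prescreen-then-confirm: factors whose effect range falls below a
        # dB cut are treated as noise and pooled before the F test
        cut = float(pooling[1])
        return {f.factor_id for f in assignment if ranges[f.column] < cut}
    if pooling == "below-error":
        if not err_cols:
            return set()
        # pool factors whose column SS falls below the largest unassigned
        # (error) column SS -- those columns behave like noise
        threshold = max(ss[j] for j in err_cols)
        return {f.factor_id for f in assignment if ss[f.column] < threshold}
    if pooling == "half":
        # classical heuristic: pool smallest-SS factors until the error pool
        # holds about half the total degrees of freedom
        n_columns = ss.size
        target = n_columns // 2
        ordered = sorted(assignment, key=lambda f: ss[f.column])
        pooled: set[str] = set()
        for f in ordered:
            if len(err_cols) + len(pooled) >= target:
                break
            pooled.add(f.factor_id)
        return pooled
    if isinstance(pooling, (list, tuple, set, frozenset)):
        known = {f.factor_id for f in assignment}
        unknown = set(pooling) - known
        if unknown:
            raise InputError(f"cannot pool unknown factors: {sorted(unknown)}")
        return set(pooling)
    raise InputError(f"unknown pooling rule {pooling!r}")


def anova(
    array: OrthogonalArray,
    run_sn,
    assignment: list[FactorAssignment],
    pooling="below-error",
) -> AnovaTable:
    """Screen factors by F-test against an error pool.

    Each two-level column carries 1 dof with ``SS = (n_runs/4) * effect^2``.
    Unassigned columns always enter the error pool; the ``pooling`` rule may
    add assigned factors: "none", "below-error" [default], "half",
    ``("range-below", x_db)``, or an explicit iterable of factor ids.
    """
    sn = _check_run_sn(array, run_sn)
    n = array.n_runs
    m1 = np.array([sn[array.column(j) == 1].mean() for j in range(array.n_columns)])
    m2 = np.array([sn[array.column(j) == 2].mean() for j in range(array.n_columns)])
    ss = (n / 4.0) * (m2 - m1) ** 2
    err_cols = error_columns(array, assignment)
    pooled_ids = _pooled_factor_ids(pooling, assignment, ss, np.abs(m2 - m1), err_cols)

    error_ss = float(sum(ss[j] for j in err_cols))
    error_dof = len(err_cols)
    for f in assignment:
        if f.factor_id in pooled_ids:
            error_ss += float(ss[f.column])
            error_dof += 1
    if error_dof == 0:
        raise InputError(
            "no error degrees of freedom: leave a column unassigned or pool "
            "factors (pooling='half' or an explicit list)"
        )

    error_ms = error_ss / error_dof
    rows = []
    for f in assignment:
        pooled = f.factor_id in pooled_ids
        row = {
            "sum_sq": float(ss[f.column]),
            "dof": 1,
            "mean_sq": float(ss[f.column]),
            "f_ratio": math.nan,
            "confidence": math.nan,
            "pooled": pooled,
        }
        if not pooled:
            if error_ms == 0.0:
                row["f_ratio"] = math.inf
                row["confidence"] = 100.0
            else:
                fr = row["mean_sq"] / error_ms
                row["f_ratio"] = fr
                row["confidence"] = 100.0 * float(stats.f.cdf(fr, 1, error_dof))
        rows.append(row)
    table = pd.DataFrame(
        rows, index=pd.Index([f.factor_id for f in assignment], name="factor")
    )
    total_ss = float(((sn - sn.mean()) ** 2).sum())
    return AnovaTable(
        table=table,
        error_ss=error_ss,
        error_dof=error_dof,
        total_ss=total_ss,
        total_dof=n - 1,
    )


def significant_factors(anova_table: AnovaTable, threshold: float = 95.0) -> list[str]:
    """Non-pooled factors with confidence strictly above ``threshold`` (%),
    ordered by descending F ratio."""
    tab = anova_table.table
    keep = tab[(~tab["pooled"]) & (tab["confidence"] > threshold)]
    return list(keep.sort_values("f_ratio", ascending=False).index)


# ---------------------------------------------------------------------------
# optimal-level selection


@dataclass(frozen=True)
class OptimalSelection:
    """Baseline-preserving optimal levels with an additive S/N prediction."""

    baseline_levels: dict[str, int]
    significant_factors: list[str]
    chosen_levels: dict[str, int]
    predicted_sn: float


def select_optimal(
    table: ResponseTable,
    significant: list[str],
    baseline: dict[str, int],
) -> OptimalSelection:
    """Move only the significant factors to their best level.

    Non-significant factors keep their baseline setting (cheapest robust
    practice); the predicted S/N is the additive-model value
    ``grand_mean + sum over significant factors (chosen-level mean - grand_mean)``.
    """
    best = best_levels(table)
    unknown = [f for f in significant if f not in baseline or f not in best]
    if unknown:
        raise InputError(f"unknown significant factors: {unknown}")
    chosen = dict(baseline)
    predicted = table.grand_mean
    for f in significant:
        chosen[f] = best[f]
        predicted += table.level_mean(f, best[f]) - table.grand_mean
    return OptimalSelection(
        baseline_levels=dict(baseline),
        significant_factors=list(significant),
        chosen_levels=chosen,
        predicted_sn=predicted,
    )


# ---------------------------------------------------------------------------
# interactions


@dataclass(frozen=True)
class InteractionSummary:
    """2x2 interaction cell means for a pair of columns.

    ``cell_means[i, j]`` is the mean S/N with the first factor at level i+1
    and the second at level j+1.  ``nonparallelism`` is
    ``|(m22 - m21) - (m12 - m11)|``; zero means parallel effect profiles
    (no interaction).  ``confounded`` flags non-regular designs (L12) where
    two-factor interactions smear across all columns, so cell means are
    screening evidence only.
    """

    factor_pair: tuple[str, str]
    cell_means: np.ndarray
    nonparallelism: float
    best_cell: tuple[int, int]
    confounded: bool = False


def interaction_cells(
    array: OrthogonalArray,
    run_sn,
    col_a: int,
    col_b: int,
    labels: list[str] | None = None,
) -> InteractionSummary:
    """Mean S/N in each of the four level combinations of two columns."""
    sn = _check_run_sn(array, run_sn)
    if col_a == col_b:
        raise InputError("interaction requires two distinct columns")
    for c in (col_a, col_b):
        if not 0 <= c < array.n_columns:
            raise InputError(f"column index {c} outside 0..{array.n_columns - 1}")
    labels = labels or column_labels(array, None)
    a, b = array.column(col_a), array.column(col_b)
    means = np.empty((2, 2))
    for i, la in enumerate((1, 2)):
        for j, lb in enumerate((1, 2)):
            means[i, j] = sn[(a == la) & (b == lb)].mean()
    nonpar = abs((means[1, 1] - means[1, 0]) - (means[0, 1] - means[0, 0]))
    best = (1, 1)
    for i in (0, 1):
        for j in (0, 1):
            if means[i, j] > means[best[0] - 1, best[1] - 1]:
                best = (i + 1, j + 1)
    confounded = array.name == "L12"
    if confounded:
        warnings.warn(
            "L12 is a Plackett-Burman design: two-factor interactions are "
            "partially confounded with every column, treat these cell means "
            "as screening evidence and confirm with a 2x2 full factorial",
            ConfoundedInteractionWarning,
            stacklevel=2,
        )
    return InteractionSummary(
        factor_pair=(labels[col_a], labels[col_b]),
        cell_means=means,
        nonparallelism=float(nonpar),
        best_cell=best,
        confounded=confounded,
    )


# ---------------------------------------------------------------------------
# model / results wrappers


class TaguchiModel:
    """Dynamic-S/N screening experiment on a two-level orthogonal array.

    Parameters
    ----------
    array : OrthogonalArray
        The design the runs followed.
    run_sn : array-like
        One dynamic S/N value (dB) per run; build them from raw signal pairs
        with :meth:`from_measurements`.
    factors : list of FactorAssignment, optional
        Factor-to-column mapping; unassigned columns become error columns.
    """

    def __init__(self, array: OrthogonalArray, run_sn, factors=None):
        self.array = array
        self.run_sn = _check_run_sn(array, run_sn)
        self.factors = list(factors) if factors is not None else None
        self.labels = column_labels(array, self.factors)
        self.runs: list[RunResponse] | None = None

    @classmethod
    def from_measurements(
        cls,
        array: OrthogonalArray,
        standard_signals,
        measured_signals,
        factors=None,
        *,
        through_origin: bool = True,
        scale: float = 1.0,
    ) -> "TaguchiModel":
        """Build the per-run S/N from reference/measured signal pairs.

        ``measured_signals`` is an (n_runs, n_signals) matrix;
        ``standard_signals`` either one shared reference vector or a matrix
        of the same shape.  ``scale=255`` fits on the normalized grayscale
        convention (see :func:`run_response`).
        """
        y = np.asarray(measured_signals, dtype=float)
        if y.ndim != 2 or y.shape[0] != array.n_runs:
            raise InputError("measured_signals must be a (n_runs, k) matrix")
        M = np.asarray(standard_signals, dtype=float)
        if M.ndim == 1:
            M = np.broadcast_to(M, y.shape)
        if M.shape != y.shape:
            raise InputError("standard_signals shape incompatible with measurements")
        runs = [
            run_response(i + 1, M[i], y[i], through_origin=through_origin, scale=scale)
            for i in range(array.n_runs)
        ]
        model = cls(array, [r.sn_db for r in runs], factors)
        model.runs = runs
        return model

    def fit(self, pooling="below-error", threshold: float = 95.0) -> "TaguchiResults":
        table = response_table(self.array, self.run_sn, self.labels)
        anova_table = None
        significant: list[str] = []
        if self.factors is not None:
            anova_table = anova(self.array, self.run_sn, self.factors, pooling)
            significant = significant_factors(anova_table, threshold)
        return TaguchiResults(self, table, anova_table, significant, threshold)


class TaguchiResults:
    """Fitted screening analysis: response table, ANOVA, optimal levels."""

    def __init__(self, model, response, anova_table, significant, threshold):
        self.model = model
        self.response = response
        self.anova = anova_table
        self.significant = significant
        self.threshold = threshold

    @property
    def grand_mean(self) -> float:
        return self.response.grand_mean

    def best_levels(self) -> dict[str, int]:
        return best_levels(self.response)

    def select_optimal(self, baseline: dict[str, int] | None = None) -> OptimalSelection:
        """Optimal levels keeping non-significant factors at baseline
        (default baseline: every factor at level 1)."""
        if baseline is None:
            ids = (
                [f.factor_id for f in self.model.factors]
                if self.model.factors is not None
                else self.response.labels
            )
            baseline = {fid: 1 for fid in ids}
        return select_optimal(self.response, self.significant, baseline)

    def interaction(self, factor_a: str, factor_b: str) -> InteractionSummary:
        idx = {lab: j for j, lab in enumerate(self.model.labels)}
        for f in (factor_a, factor_b):
            if f not in idx:
                raise InputError(f"unknown factor {f!r}")
        return interaction_cells(
            self.model.array,
            self.model.run_sn,
            idx[factor_a],
            idx[factor_b],
            self.model.labels,
        )

    def plot_response(self, ax=None):
        """Main-effects (response) graph: level means per factor."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(1.0 * len(self.response.labels) + 2, 3.5))
        x = 0
        ticks, ticklabels = [], []
        for label, row in self.response.table.iterrows():
            ax.plot([x, x + 1], [row["level1_mean"], row["level2_mean"]], "o-")
            ticks += [x, x + 1]
            ticklabels += [f"{label}1", f"{label}2"]
            x += 2.5
        ax.axhline(self.grand_mean, color="gray", lw=0.8, ls="--")
        ax.set_xticks(ticks, ticklabels, fontsize=8)
        ax.set_ylabel("mean S/N (dB)")
        return ax

    def summary(self) -> str:
        lines = [
            "Dynamic-S/N Taguchi screening",
            f"  design: {self.model.array.name} "
            f"({self.model.array.n_runs} runs x {self.model.array.n_columns} columns)",
            f"  grand mean S/N: {self.grand_mean:.4f} dB",
            "",
            "Response table (dB):",
            self.response.table.round(4).to_string(),
        ]
        if self.anova is not None:
            lines += [
                "",
                f"ANOVA (error: SS={self.anova.error_ss:.4f}, dof={self.anova.error_dof}):",
                self.anova.table.round(4).to_string(),
                "",
                f"significant at >{self.threshold:g}% confidence: "
                + (", ".join(self.significant) if self.significant else "none"),
            ]
        return "\n".join(lines)
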