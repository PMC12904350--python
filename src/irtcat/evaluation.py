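"""Evaluation battery for CAT simulation output.

Covers the standard comparisons used to judge an adaptive short form against
full-length scoring: test-length and final-estimate summaries per scenario,
theta-recovery RMSE, the correlation between interim CAT thetas and
full-length thetas as a function of test length, diagnostics on sessions
terminated by the item cap (secondary stopping rule), the
standard-error-reduction-per-additional-item analysis, and scoring of a
fixed (static) short form for comparison.

Conventions, fixed so outputs are bit-reproducible: Pearson correlations;
population (n-denominator) standard deviations in summaries;
linear-interpolation percentiles for medians and IQRs; carry-forward of the
final theta for respondents who terminated before step k in the
correlation-by-length curve (mirroring how a deployed CAT capped at k items
would score them).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import STOP_MAX, STOP_SE, CATConfig, CATResult
from .estimation import init_posterior, update_posterior
from .exceptions import DataError
from .irt import ItemBank

__all__ = [
    "ScenarioSummary",
    "EvaluationReport",
    "rmse",
    "correlation_by_length",
    "correlation_curve",
    "length_summary",
    "theta_se_summary",
    "scenario_summary",
    "secondary_rule_diagnostics",
    "se_reduction_analysis",
    "compare_static_short_form",
]


@dataclass(frozen=True)
class ScenarioSummary:
    """Length / final-estimate / recovery aggregates for one scenario cell."""

    label: str
    se_threshold: float
    max_items: int
    n_respondents: int
    length_mean: float
    length_sd: float
    length_min: int
    length_max: int
    length_median: float
    length_q1: float
    length_q3: float
    theta_mean: float
    theta_sd: float
    theta_min: float
    theta_max: float
    se_mean: float
    se_sd: float
    se_min: float
    se_max: float
    rmse_vs_full_length: float

    def to_row(self) -> dict:
        return {
            "scenario": self.label,
            "se_threshold": self.se_threshold,
            "max_items": self.max_items,
            "n": self.n_respondents,
            "length_mean": self.length_mean,
            "length_sd": self.length_sd,
            "length_min": self.length_min,
            "length_max": self.length_max,
            "length_median": self.length_median,
            "length_q1": self.length_q1,
            "length_q3": self.length_q3,
            "theta_mean": self.theta_mean,
            "theta_sd": self.theta_sd,
            "theta_min": self.theta_min,
            "theta_max": self.theta_max,
            "se_mean": self.se_mean,
            "se_sd": self.se_sd,
            "se_min": self.se_min,
            "se_max": self.se_max,
            "rmse_vs_full_length": self.rmse_vs_full_length,
        }

    def __str__(self) -> str:
        return (
            f"Scenario {self.label} (SE<={self.se_threshold}, cap {self.max_items}, "
            f"n={self.n_respondents})\n"
            f"  items: mean {self.length_mean:.2f} (SD {self.length_sd:.2f}; "
            f"{self.length_min} to {self.length_max}), median {self.length_median:g} "
            f"(IQR {self.length_q1:g}-{self.length_q3:g})\n"
            f"  theta: mean {self.theta_mean:.2f} (SD {self.theta_sd:.2f}; "
            f"{self.theta_min:.2f} to {self.theta_max:.2f})\n"
            f"  SE:    mean {self.se_mean:.2f} (SD {self.se_sd:.2f}; "
            f"{self.se_min:.2f} to {self.se_max:.2f})\n"
            f"  RMSE vs full-length theta: {self.rmse_vs_full_length:.3f}"
        )


@dataclass(frozen=True)
class EvaluationReport:
    """Secondary-rule and per-step diagnostics for one scenario."""

    correlation_by_length: pd.DataFrame  # columns: k, r
    termination_counts: dict  # stop_reason -> count
    capped_tail: dict  # diagnostics of max_items cases
    se_reduction: pd.DataFrame  # columns: step, n_continuing, prop_reduction_gt_delta


def rmse(estimates, reference) -> float:
    """Root mean squared error between paired theta vectors."""
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape or est.size == 0:
        raise DataError("rmse needs equal-length, nonempty vectors")
    return float(np.sqrt(np.mean((est - ref) ** 2)))


def _theta_at_step(result: CATResult, k: int) -> float:
    """Interim theta at step k, carrying the final theta forward if the
    session ended earlier."""
    idx = min(k, result.n_items) - 1
    return result.interim_thetas[idx]


def correlation_by_length(results, full_thetas, k: int) -> float:
    """Pearson r between step-k CAT thetas and full-length thetas.

    Respondents who terminated before step ``k`` contribute their final theta
    (carry-forward).
    """
    if k < 1:
        raise DataError("k must be >= 1")
    cat = np.array([_theta_at_step(r, k) for r in results])
    full = np.asarray(full_thetas, dtype=float)
    if cat.shape != full.shape:
        raise DataError("results and full_thetas must align")
    if np.std(cat) == 0 or np.std(full) == 0:
        raise DataError("correlation undefined: zero variance")
    return float(np.corrcoef(cat, full)[0, 1])


def correlation_curve(results, full_thetas, max_k: int | None = None) -> pd.DataFrame:
    """r-versus-length curve, steps 1..max_k (default: longest session)."""
    if max_k is None:
        max_k = max(r.n_items for r in results)
    rows = [
        {"k": k, "r": correlation_by_length(results, full_thetas, k)}
        for k in range(1, max_k + 1)
    ]
    return pd.DataFrame(rows)


def _quartiles(x: np.ndarray):
    return (
        float(np.percentile(x, 25)),
        float(np.median(x)),
        float(np.percentile(x, 75)),
    )


def length_summary(results) -> dict:
    """Mean/SD/range/median/IQR of the administered item counts."""
    if not results:
        raise DataError("no results to summarise")
    n = np.array([r.n_items for r in results], dtype=float)
    q1, med, q3 = _quartiles(n)
    return {
        "mean": float(n.mean()),
        "sd": float(n.std()),  # population denominator
        "min": int(n.min()),
        "max": int(n.max()),
        "median": med,
        "q1": q1,
        "q3": q3,
    }


def theta_se_summary(results) -> dict:
    """Mean/SD/range of final thetas and final SEs."""
    th = np.array([r.final_theta for r in results])
    se = np.array([r.final_se for r in results])
    return {
        "theta_mean": float(th.mean()),
        "theta_sd": float(th.std()),
        "theta_min": float(th.min()),
        "theta_max": float(th.max()),
        "se_mean": float(se.mean()),
        "se_sd": float(se.std()),
        "se_min": float(se.min()),
        "se_max": float(se.max()),
    }


def scenario_summary(results, full_thetas, config: CATConfig, label: str | None = None) -> ScenarioSummary:
    """Assemble the one-row scenario aggregate from raw results."""
    ls = length_summary(results)
    ts = theta_se_summary(results)
    final = [r.final_theta for r in results]
    if label is None:
        label = f"SE{config.se_threshold:g}_max{config.max_items}"
    return ScenarioSummary(
        label=label,
        se_threshold=config.se_threshold,
        max_items=config.max_items,
        n_respondents=len(results),
        length_mean=ls["mean"],
        length_sd=ls["sd"],
        length_min=ls["min"],
        length_max=ls["max"],
        length_median=ls["median"],
        length_q1=ls["q1"],
        length_q3=ls["q3"],
        theta_mean=ts["theta_mean"],
        theta_sd=ts["theta_sd"],
        theta_min=ts["theta_min"],
        theta_max=ts["theta_max"],
        se_mean=ts["se_mean"],
        se_sd=ts["se_sd"],
        se_min=ts["se_min"],
        se_max=ts["se_max"],
        rmse_vs_full_length=rmse(final, full_thetas),
    )


def secondary_rule_diagnostics(results) -> dict:
    """Who hit the item cap, and where they sit on the theta scale.

    Sessions stopped by the cap (rather than the SE rule) concentrate in the
    tails of the theta distribution, where the bank carries less information.
    """
    if not results:
        raise DataError("no results to summarise")
    counts = {
        STOP_SE: sum(r.stop_reason == STOP_SE for r in results),
        STOP_MAX: sum(r.stop_reason == STOP_MAX for r in results),
    }
    capped = [r for r in results if r.stop_reason == STOP_MAX]
    out = {"counts": counts, "n_capped": len(capped)}
    if capped:
        th = np.array([r.final_theta for r in capped])
        se = np.array([r.final_se for r in capped])
        out.update(
            prop_theta_below_minus1=float(np.mean(th < -1.0)),
            prop_theta_above_plus1=float(np.mean(th > 1.0)),
            capped_se_mean=float(se.mean()),
            capped_se_min=float(se.min()),
            capped_se_max=float(se.max()),
        )
    else:
        out.update(
            prop_theta_below_minus1=None,
            prop_theta_above_plus1=None,
            capped_se_mean=None,
            capped_se_min=None,
            capped_se_max=None,
        )
    return out


def se_reduction_analysis(results, delta: float = 0.01) -> pd.DataFrame:
    """Among respondents who took item k+1, the share whose SE dropped by
    more than ``delta`` between steps k and k+1.

    Steps where nobody continued are omitted rather than reported as zero.
    Columns: ``step`` (k), ``n_continuing``, ``prop_reduction_gt_delta``.
    """
    max_len = max(r.n_items for r in results)
    rows = []
    for k in range(1, max_len):
        cont = [r for r in results if r.n_items >= k + 1]
        if not cont:
            continue
        drops = np.array([r.interim_ses[k - 1] - r.interim_ses[k] for r in cont])
        rows.append(
            {
                "step": k,
                "n_continuing": len(cont),
                "prop_reduction_gt_delta": float(np.mean(drops > delta)),
            }
        )
    return pd.DataFrame(rows, columns=["step", "n_continuing", "prop_reduction_gt_delta"])


def compare_static_short_form(matrix, bank: ItemBank, subset_item_ids, config: CATConfig):
    """Score every respondent on a fixed item subset; correlate with
    full-length thetas.

    Returns ``(short_form_thetas, r)`` where ``r`` is the Pearson correlation
    between the static short-form thetas and full-length thetas computed from
    the same response matrix.
    """
    from .engine import full_length_score  # local import to avoid cycle noise

    subset = list(subset_item_ids)
    unknown = [i for i in subset if i not in bank]
    if unknown:
        raise DataError(f"unknown item_ids in subset: {unknown}")
    grid = config.make_grid()
    items = [bank[i] for i in subset]
    short_thetas = np.empty(matrix.n_respondents)
    full_thetas = np.empty(matrix.n_respondents)
    for i in range(matrix.n_respondents):
        row = matrix.row(i)
        state = init_posterior(grid)
        for item in items:
            state = update_posterior(state, item, int(row[item.item_id]))
        short_thetas[i] = float(np.dot(state.grid.points, state.weights))
        full_thetas[i] = full_length_score(row, bank, config)[0]
    r = float(np.corrcoef(short_thetas, full_thetas)[0, 1])
    return short_thetas, r
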