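"""Cohort-level CAT simulation and synthetic data generation.

Two simulation modes are supported:

* **post-hoc** — the mode used to evaluate adaptive short forms of an
  already-fielded instrument: every respondent has a complete recorded 0/1
  response vector, and the adaptive session replays those recorded responses
  in whatever order the selection rule asks for them.  Post-hoc simulation
  is entirely deterministic (no random number generator is involved).
* **generative** — responses are drawn on the fly as Bernoulli(P(theta_i))
  from known true thetas; useful for parameter-recovery experiments.

The synthetic generator emulates a calibration study of 1000 respondents
answering a 22-item multiple-choice bank (4 options per item, hence lower
asymptotes near the chance level): thetas ~ Normal(0, 1), discriminations
log-normal around 1.2 truncated to a realistic positive range, difficulties
standard-normal truncated to [-3, 3], and guessing parameters Beta(5, 20)
(mean 0.2 — empirical 3PL calibrations of 4-option items typically land a
little below the nominal 0.25 chance rate).

The cohort-level interface follows the model/results idiom: build a
:class:`CATSimulation` from a response matrix, bank and configuration, call
``fit()`` and inspect the returned :class:`CATSimulationResults` (estimates,
uncertainties, diagnostics, ``summary()``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import (
    CATConfig,
    CATResult,
    _SessionTables,
    _run_cat_fast,
    full_length_score,
)
from .evaluation import (
    EvaluationReport,
    ScenarioSummary,
    correlation_by_length,
    correlation_curve,
    rmse,
    scenario_summary,
    se_reduction_analysis,
    secondary_rule_diagnostics,
)
from .exceptions import ConfigurationError, DataError
from .irt import Item, ItemBank

__all__ = [
    "ResponseMatrix",
    "SyntheticSpec",
    "generate_item_bank",
    "generate_thetas",
    "generate_response_matrix",
    "CATSimulation",
    "CATSimulationResults",
    "run_posthoc_simulation",
    "run_scenario_grid",
]


class ResponseMatrix:
    """A complete respondents × items 0/1 matrix tied to a bank's item_ids."""

    def __init__(self, respondent_ids, item_ids, values):
        values = np.asarray(values)
        respondent_ids = [str(r) for r in respondent_ids]
        item_ids = [str(i) for i in item_ids]
        if values.shape != (len(respondent_ids), len(item_ids)):
            raise DataError(
                f"values shape {values.shape} does not match "
                f"{len(respondent_ids)} respondents x {len(item_ids)} items"
            )
        if len(set(respondent_ids)) != len(respondent_ids):
            raise DataError("respondent_ids must be unique")
        if not np.isin(values, (0, 1)).all():
            raise DataError("response matrix entries must all be 0 or 1 (no missing data)")
        self.respondent_ids = respondent_ids
        self.item_ids = item_ids
        self.values = values.astype(np.int8)
        self._col = {i: k for k, i in enumerate(item_ids)}

    @property
    def n_respondents(self) -> int:
        return len(self.respondent_ids)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def row(self, i: int) -> dict:
        """Responses of respondent ``i`` as an item_id -> 0/1 mapping."""
        vals = self.values[i]
        return {item_id: int(vals[k]) for item_id, k in self._col.items()}

    def check_bank(self, bank: ItemBank) -> None:
        if set(self.item_ids) != set(bank.item_ids):
            extra = sorted(set(self.item_ids) - set(bank.item_ids))
            missing = sorted(set(bank.item_ids) - set(self.item_ids))
            raise DataError(
                f"matrix/bank item mismatch (matrix-only: {extra[:5]}, bank-only: {missing[:5]})"
            )

    def reordered(self, item_ids) -> np.ndarray:
        """Values with columns permuted to the given item order."""
        cols = [self._col[i] for i in item_ids]
        return self.values[:, cols]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.item_ids)
        frame.insert(0, "respondent_id", self.respondent_ids)
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ResponseMatrix":
        if "respondent_id" not in frame.columns:
            raise DataError("response matrix table must have a 'respondent_id' first column")
        item_cols = [c for c in frame.columns if c != "respondent_id"]
        if frame[item_cols].isna().any().any():
            raise DataError("response matrix contains missing entries")
        return cls(frame["respondent_id"].tolist(), item_cols, frame[item_cols].to_numpy())

    def __repr__(self) -> str:
        return f"ResponseMatrix({self.n_respondents} respondents x {self.n_items} items)"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic calibration cohort.

    Defaults mirror the scale of a typical instrument-calibration study:
    1000 respondents, 22 four-option multiple-choice items.
    """

    n_respondents: int = 1000
    n_items: int = 22
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    a_log_mean: float = float(np.log(1.2))
    a_log_sd: float = 0.35
    a_min: float = 0.5
    a_max: float = 3.0
    b_mean: float = 0.0
    b_sd: float = 1.0
    b_min: float = -3.0
    b_max: float = 3.0
    c_shape1: float = 5.0
    c_shape2: float = 20.0
    seed: int = 42

    def __post_init__(self):
        if self.n_respondents < 1 or self.n_items < 1:
            raise ConfigurationError("n_respondents and n_items must be >= 1")
        if self.theta_sd <= 0 or self.a_log_sd <= 0 or self.b_sd <= 0:
            raise ConfigurationError("scale parameters must be positive")
        if not (0 < self.a_min < self.a_max) or not (self.b_min < self.b_max):
            raise ConfigurationError("truncation bounds out of order")
        if self.c_shape1 <= 0 or self.c_shape2 <= 0:
            raise ConfigurationError("beta shapes must be positive")


def _truncated_draw(rng, sampler, low, high, n):
    """Rejection-sample ``n`` values from ``sampler`` restricted to [low, high]."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = sampler(rng, n - filled)
        keep = draw[(draw >= low) & (draw <= high)]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def generate_item_bank(spec: SyntheticSpec = SyntheticSpec()) -> ItemBank:
    """Draw a reproducible synthetic 3PL item bank per the spec."""
    rng = np.random.default_rng(spec.seed)
    a = _truncated_draw(
        rng,
        lambda r, n: r.lognormal(spec.a_log_mean, spec.a_log_sd, n),
        spec.a_min,
        spec.a_max,
        spec.n_items,
    )
    b = _truncated_draw(
        rng,
        lambda r, n: r.normal(spec.b_mean, spec.b_sd, n),
        spec.b_min,
        spec.b_max,
        spec.n_items,
    )
    c = rng.beta(spec.c_shape1, spec.c_shape2, spec.n_items)
    width = max(len(str(spec.n_items)), 2)
    items = [
        Item(
            item_id=f"item{j + 1:0{width}d}",
            a=float(a[j]),
            b=float(b[j]),
            c=float(c[j]),
            content_domain="synthetic",
        )
        for j in range(spec.n_items)
    ]
    return ItemBank(items, metadata=f"synthetic bank, seed={spec.seed}")


def generate_thetas(n: int, mean: float = 0.0, sd: float = 1.0, seed: int = 0) -> np.ndarray:
    """Draw ``n`` latent trait values from Normal(mean, sd)."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if sd <= 0:
        raise ConfigurationError("sd must be positive")
    rng = np.random.default_rng(seed)
    return rng.normal(mean, sd, n)


def generate_response_matrix(thetas, bank: ItemBank, seed: int = 0) -> ResponseMatrix:
    """Draw a complete Bernoulli 0/1 matrix from the 3PL model."""
    thetas = np.asarray(thetas, dtype=float)
    rng = np.random.default_rng(seed)
    p = bank.prob_matrix(thetas).T  # respondents x items
    values = (rng.random(p.shape) < p).astype(np.int8)
    ids = [f"r{i + 1:04d}" for i in range(thetas.size)]
    return ResponseMatrix(ids, bank.item_ids, values)


class CATSimulation:
    """Post-hoc CAT simulation over a complete response matrix.

    Parameters
    ----------
    matrix : ResponseMatrix
        Complete recorded responses; columns must match the bank's item_ids.
    bank : ItemBank
        The calibrated 3PL item pool.
    config : CATConfig, optional
        Grid, prior, selection policy and stopping rules; default is
        SE threshold 0.50 with a 15-item cap.
    true_thetas : array-like, optional
        Known generating thetas (available for synthetic cohorts); carried
        through to the results for recovery analyses.

    Examples
    --------
    >>> model = CATSimulation.from_synthetic(SyntheticSpec(seed=7))
    >>> res = model.fit()
    >>> print(res.summary())                        # doctest: +SKIP
    """

    def __init__(self, matrix: ResponseMatrix, bank: ItemBank, config: CATConfig | None = None,
                 true_thetas=None):
        matrix.check_bank(bank)
        self.matrix = matrix
        self.bank = bank
        if config is None:
            # default cap: 15 items, or the whole bank when it is smaller
            config = CATConfig(max_items=min(CATConfig().max_items, len(bank)))
        self.config = config
        if self.config.max_items > len(bank):
            raise ConfigurationError(
                f"max_items ({self.config.max_items}) exceeds bank size ({len(bank)})"
            )
        self.true_thetas = None if true_thetas is None else np.asarray(true_thetas, dtype=float)
        self._full_cache: tuple[np.ndarray, np.ndarray] | None = None

    @classmethod
    def from_synthetic(cls, spec: SyntheticSpec = SyntheticSpec(),
                       config: CATConfig | None = None) -> "CATSimulation":
        """Build a model on a freshly drawn synthetic cohort.

        Three independent streams (bank, thetas, responses) are derived from
        ``spec.seed`` so the cohort is reproducible from the single seed.
        """
        bank = generate_item_bank(spec)
        child = np.random.SeedSequence(spec.seed).spawn(2)
        theta_seed, resp_seed = (int(s.generate_state(1)[0] % (2**31)) for s in child)
        thetas = generate_thetas(spec.n_respondents, spec.theta_mean, spec.theta_sd, theta_seed)
        matrix = generate_response_matrix(thetas, bank, resp_seed)
        return cls(matrix, bank, config=config, true_thetas=thetas)

    def full_length(self) -> tuple[np.ndarray, np.ndarray]:
        """Full-length (all-items) EAP thetas and SEs, cached across fits."""
        if self._full_cache is None:
            thetas = np.empty(self.matrix.n_respondents)
            ses = np.empty(self.matrix.n_respondents)
            for i in range(self.matrix.n_respondents):
                thetas[i], ses[i] = full_length_score(self.matrix.row(i), self.bank, self.config)
            self._full_cache = (thetas, ses)
        return self._full_cache

    def fit(self, se_threshold: float | None = None, max_items: int | None = None) -> "CATSimulationResults":
        """Run the adaptive session for every respondent.

        ``se_threshold`` / ``max_items`` override the model's stopping rules
        for this fit only (the grid, prior and selection policy are fixed at
        construction).
        """
        config = self.config.with_stopping(se_threshold, max_items)
        if config.max_items > len(self.bank):
            raise ConfigurationError(
                f"max_items ({config.max_items}) exceeds bank size ({len(self.bank)})"
            )
        tables = _SessionTables(self.bank, config.make_grid())
        results = []
        for i, rid in enumerate(self.matrix.respondent_ids):
            row = self.matrix.row(i)
            results.append(_run_cat_fast(rid, row.__getitem__, tables, config))
        full_thetas, full_ses = self.full_length()
        return CATSimulationResults(self, config, results, full_thetas, full_ses)

    def fit_grid(self, se_thresholds, max_items_list) -> dict:
        """Fit every (threshold, cap) cell of a crossed stopping-rule design.

        Returns an ordered dict keyed by ``(se_threshold, max_items)``.
        """
        out = {}
        for thr in se_thresholds:
            for cap in max_items_list:
                out[(thr, cap)] = self.fit(se_threshold=thr, max_items=cap)
        return out


class CATSimulationResults:
    """Per-respondent adaptive sessions plus full-length reference scores.

    Attributes
    ----------
    results : list of CATResult
    full_thetas, full_ses : ndarray
        Full-length EAP scores used as the recovery reference.
    """

    def __init__(self, model: CATSimulation, config: CATConfig, results, full_thetas, full_ses):
        self.model = model
        self.config = config
        self.results: list[CATResult] = list(results)
        self.full_thetas = np.asarray(full_thetas, dtype=float)
        self.full_ses = np.asarray(full_ses, dtype=float)

    # --- basic accessors ---

    @property
    def thetas(self) -> np.ndarray:
        """Final CAT theta estimates, one per respondent."""
        return np.array([r.final_theta for r in self.results])

    @property
    def ses(self) -> np.ndarray:
        """Final CAT standard errors (posterior SDs)."""
        return np.array([r.final_se for r in self.results])

    @property
    def n_items(self) -> np.ndarray:
        """Administered item counts."""
        return np.array([r.n_items for r in self.results])

    @property
    def label(self) -> str:
        return f"SE{self.config.se_threshold:g}_max{self.config.max_items}"

    # --- evaluation battery ---

    def rmse_vs_full_length(self) -> float:
        return rmse(self.thetas, self.full_thetas)

    def correlation_by_length(self, k: int) -> float:
        return correlation_by_length(self.results, self.full_thetas, k)

    def correlation_curve(self, max_k: int | None = None) -> pd.DataFrame:
        return correlation_curve(self.results, self.full_thetas, max_k)

    def secondary_rule_diagnostics(self) -> dict:
        return secondary_rule_diagnostics(self.results)

    def se_reduction(self, delta: float = 0.01) -> pd.DataFrame:
        return se_reduction_analysis(self.results, delta)

    def summary(self) -> ScenarioSummary:
        """Table-style aggregate: length, final theta/SE, recovery RMSE."""
        return scenario_summary(self.results, self.full_thetas, self.config, label=self.label)

    def report(self, delta: float = 0.01) -> EvaluationReport:
        d = self.secondary_rule_diagnostics()
        return EvaluationReport(
            correlation_by_length=self.correlation_curve(),
            termination_counts=d["counts"],
            capped_tail={k: v for k, v in d.items() if k != "counts"},
            se_reduction=self.se_reduction(delta),
        )

    # --- tabular output ---

    def to_frame(self) -> pd.DataFrame:
        """One row per respondent: length, final estimates, stop reason."""
        return pd.DataFrame(
            {
                "respondent_id": [r.respondent_id for r in self.results],
                "n_items": self.n_items,
                "final_theta": self.thetas,
                "final_se": self.ses,
                "stop_reason": [r.stop_reason for r in self.results],
                "full_length_theta": self.full_thetas,
                "full_length_se": self.full_ses,
                "administered": ["|".join(r.administered) for r in self.results],
            }
        )

    def interim_frame(self) -> pd.DataFrame:
        """Long-format per-step trace (respondent, step, item, response, theta, se)."""
        rows = []
        for r in self.results:
            for step in range(r.n_items):
                rows.append(
                    {
                        "respondent_id": r.respondent_id,
                        "step": step + 1,
                        "item_id": r.administered[step],
                        "response": r.responses[step],
                        "theta": r.interim_thetas[step],
                        "se": r.interim_ses[step],
                    }
                )
        return pd.DataFrame(rows)

    # --- plotting (thin wrappers; see irtcat.plotting) ---

    def plot_correlation_curve(self, ax=None, **kwargs):
        from . import plotting

        return plotting.plot_correlation_curve(self, ax=ax, **kwargs)

    def plot_se_by_length(self, ax=None, **kwargs):
        from . import plotting

        return plotting.plot_se_by_length(self, ax=ax, **kwargs)

    def plot_se_reduction(self, ax=None, **kwargs):
        from . import plotting

        return plotting.plot_se_reduction(self, ax=ax, **kwargs)

    def plot_theta_hist(self, ax=None, **kwargs):
        from . import plotting

        return plotting.plot_theta_hist(self, ax=ax, **kwargs)

    def __repr__(self) -> str:
        return (
            f"<CATSimulationResults {self.label}: n={len(self.results)}, "
            f"median length {np.median(self.n_items):g}>"
        )


def run_posthoc_simulation(matrix: ResponseMatrix, bank: ItemBank, config: CATConfig):
    """Functional form of the post-hoc simulation.

    Returns ``(results, full_thetas, full_ses)``; equivalent to
    ``CATSimulation(matrix, bank, config).fit()``.
    """
    res = CATSimulation(matrix, bank, config).fit()
    return res.results, res.full_thetas, res.full_ses


def run_scenario_grid(matrix: ResponseMatrix, bank: ItemBank, se_thresholds, max_items_list,
                      config: CATConfig | None = None) -> pd.DataFrame:
    """Summaries for every cell of a crossed stopping-rule design.

    Returns a DataFrame with one row per (threshold, cap) cell.
    """
    model = CATSimulation(matrix, bank, config=config or CATConfig())
    fits = model.fit_grid(se_thresholds, max_items_list)
    return pd.DataFrame([res.summary().to_row() for res in fits.values()])
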