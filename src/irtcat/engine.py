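"""The adaptive administration loop and full-length scoring.

One CAT session is: select the next item, fetch the response, update the
posterior, record the interim EAP/SE, then test the stopping rules.  Two
rules are in force: the primary rule terminates once the standard error
(posterior SD) drops to the configured threshold; the secondary rule caps
the number of items administered.  Stopping is evaluated only after a
response has been absorbed, so at least one item is always given; when both
rules fire on the same item the primary (SE) rule is recorded as the reason.

Full-length scoring absorbs every response in the bank and is the reference
against which adaptive precision is judged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .estimation import (
    QuadratureGrid,
    init_posterior,
    make_grid,
    update_posterior,
)
from .exceptions import ConfigurationError, DataError
from .irt import ItemBank
from .selection import SelectionPolicy, select_next_item

__all__ = ["CATConfig", "CATResult", "should_stop", "run_cat", "full_length_score"]

STOP_SE = "se_reached"
STOP_MAX = "max_items"


@dataclass(frozen=True)
class CATConfig:
    """One simulation scenario.

    Defaults reflect a typical configuration for a 22-item dichotomous bank:
    SE threshold 0.50, cap of 15 items, standard-normal prior discretised on
    49 points over [-4, 4].
    """

    se_threshold: float = 0.50
    max_items: int = 15
    min_items: int = 1
    theta_min: float = -4.0
    theta_max: float = 4.0
    prior_mean: float = 0.0
    prior_sd: float = 1.0
    n_grid_points: int = 49
    policy: SelectionPolicy = field(default_factory=SelectionPolicy)

    def __post_init__(self):
        if not np.isfinite(self.se_threshold) or self.se_threshold < 0:
            raise ConfigurationError(f"se_threshold must be >= 0, got {self.se_threshold}")
        if not (1 <= self.min_items <= self.max_items):
            raise ConfigurationError(
                f"need 1 <= min_items <= max_items, got {self.min_items}, {self.max_items}"
            )

    def make_grid(self) -> QuadratureGrid:
        return make_grid(
            self.theta_min, self.theta_max, self.n_grid_points, self.prior_mean, self.prior_sd
        )

    def with_stopping(self, se_threshold=None, max_items=None) -> "CATConfig":
        """A copy with the stopping rules replaced (grid/prior untouched)."""
        kwargs = {}
        if se_threshold is not None:
            kwargs["se_threshold"] = se_threshold
        if max_items is not None:
            kwargs["max_items"] = max_items
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CATResult:
    """One respondent's adaptive session."""

    respondent_id: str
    administered: tuple  # item_ids in administration order
    responses: tuple  # 0/1, parallel to administered
    interim_thetas: tuple  # EAP after each item
    interim_ses: tuple  # posterior SD after each item
    final_theta: float
    final_se: float
    stop_reason: str

    def __post_init__(self):
        n = len(self.administered)
        if not (len(self.responses) == len(self.interim_thetas) == len(self.interim_ses) == n):
            raise DataError("administered/responses/interim traces must have equal length")
        if self.stop_reason not in (STOP_SE, STOP_MAX):
            raise DataError(f"unknown stop_reason {self.stop_reason!r}")

    @property
    def n_items(self) -> int:
        return len(self.administered)


def should_stop(current_se: float, n_administered: int, config: CATConfig):
    """Evaluate the dual stopping rules after ``n_administered`` responses.

    Returns ``(stop, reason)`` with reason ``"se_reached"`` or ``"max_items"``
    (or None when the session continues).  The SE rule takes precedence when
    both hold.
    """
    if n_administered < config.min_items:
        return False, None
    if current_se <= config.se_threshold:
        return True, STOP_SE
    if n_administered >= config.max_items:
        return True, STOP_MAX
    return False, None


class _SessionTables:
    """Precomputed per-(bank, grid) arrays shared across respondents.

    ``p[j, k]`` is the correct-response probability of item j at grid point k
    and ``info`` the matching Fisher information; both are what the update and
    MPWI steps need, so a cohort simulation computes them once.
    """

    def __init__(self, bank: ItemBank, grid: QuadratureGrid):
        self.bank = bank
        self.grid = grid
        self.p = bank.prob_matrix(grid.points)
        self.info = bank.information_matrix(grid.points)
        self.info_at = {}

    def first_scores(self, policy: SelectionPolicy) -> np.ndarray:
        if policy.first_item_rule == "max_info_at_theta0":
            t0 = policy.first_item_theta
            if t0 not in self.info_at:
                self.info_at[t0] = self.bank.information_matrix(np.array([t0]))[:, 0]
            return self.info_at[t0]
        return self.info @ self.grid.prior_weights


def _run_cat_fast(respondent_id, response_oracle, tables: _SessionTables, config: CATConfig) -> CATResult:
    """Vectorised inner loop; semantics identical to the public operations."""
    bank, grid = tables.bank, tables.grid
    points = grid.points
    weights = grid.prior_weights.copy()
    remaining = np.ones(len(bank), dtype=bool)

    administered, responses, thetas, ses = [], [], [], []
    stop_reason = None
    policy = config.policy
    while True:
        if not administered and policy.method == "mpwi":
            scores = tables.first_scores(policy)
        elif policy.method == "max_info_at_point":
            point = np.array([float(points @ weights)])
            scores = bank.information_matrix(point)[:, 0]
        else:
            scores = tables.info @ weights
        # argmax over remaining items; np.argmax takes the first (lowest-index) tie
        masked = np.where(remaining, scores, -np.inf)
        j = int(np.argmax(masked))
        item_id = bank[j].item_id
        resp = response_oracle(item_id)
        if resp not in (0, 1):
            raise DataError(f"oracle returned {resp!r} for item {item_id!r}; responses must be 0/1")
        lik = tables.p[j] if resp == 1 else 1.0 - tables.p[j]
        weights = weights * lik
        weights = weights / weights.sum()

        remaining[j] = False
        administered.append(item_id)
        responses.append(int(resp))
        mean = float(points @ weights)
        var = float(weights @ (points - mean) ** 2)
        se = float(np.sqrt(max(var, 0.0)))
        thetas.append(mean)
        ses.append(se)

        stop, reason = should_stop(se, len(administered), config)
        if stop:
            stop_reason = reason
            break
        if not remaining.any():
            # bank exhausted before either rule fired (only possible when
            # max_items exceeds the bank size); report the cap rule
            stop_reason = STOP_MAX
            break

    return CATResult(
        respondent_id=str(respondent_id),
        administered=tuple(administered),
        responses=tuple(responses),
        interim_thetas=tuple(thetas),
        interim_ses=tuple(ses),
        final_theta=thetas[-1],
        final_se=ses[-1],
        stop_reason=stop_reason,
    )


def run_cat(respondent_id, response_oracle, bank: ItemBank, config: CATConfig) -> CATResult:
    """Administer one adaptive session.

    Parameters
    ----------
    response_oracle : callable
        ``item_id -> 0/1``.  In post-hoc simulation this looks up the
        respondent's recorded response; in generative mode it draws a
        Bernoulli response from the true theta.
    """
    if config.max_items > len(bank):
        raise ConfigurationError(
            f"max_items ({config.max_items}) exceeds bank size ({len(bank)})"
        )
    tables = _SessionTables(bank, config.make_grid())
    return _run_cat_fast(respondent_id, response_oracle, tables, config)


def full_length_score(responses, bank: ItemBank, config: CATConfig):
    """EAP theta and posterior-SD SE after absorbing every bank item.

    ``responses`` maps item_id to 0/1 (a mapping, or a sequence in bank
    order).  The result is independent of item order up to floating-point
    rounding.
    """
    if not hasattr(responses, "keys"):
        if len(responses) != len(bank):
            raise DataError(
                f"expected {len(bank)} responses, got {len(responses)}"
            )
        responses = dict(zip(bank.item_ids, responses))
    missing = [i for i in bank.item_ids if i not in responses]
    if missing:
        raise DataError(f"responses missing for items: {missing[:5]}")
    state = init_posterior(config.make_grid())
    for item in bank:
        r = int(responses[item.item_id])
        if r not in (0, 1):
            raise DataError(f"response for {item.item_id!r} must be 0/1, got {r!r}")
        state = update_posterior(state, item, r)
    mean = float(np.dot(state.grid.points, state.weights))
    var = float(np.dot(state.weights, (state.grid.points - mean) ** 2))
    return mean, float(np.sqrt(max(var, 0.0)))
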