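"""Adaptive item selection by maximum posterior weighted information (MPWI).

MPWI scores each candidate item by its Fisher information integrated against
the current theta posterior, and administers the highest-scoring
unadministered item.  Ties are broken deterministically by lowest bank index.

The first item (no responses yet) is chosen either by maximum Fisher
information at theta = 0.0 — the conventional "first item at the prior mean"
rule — or by MPWI under the prior; with a symmetric prior the two typically
agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimation import PosteriorState
from .exceptions import ConfigurationError
from .irt import Item, ItemBank, item_information

__all__ = [
    "SelectionPolicy",
    "posterior_weighted_information",
    "select_next_item",
    "top_information_subset",
]

_METHODS = ("mpwi", "max_info_at_point")
_FIRST_ITEM_RULES = ("max_info_at_theta0", "mpwi_under_prior")


@dataclass(frozen=True)
class SelectionPolicy:
    """How the next item is picked.

    method : ``"mpwi"`` (default) scores candidates by posterior-weighted
        information; ``"max_info_at_point"`` scores by Fisher information at
        the current EAP estimate.
    first_item_rule : rule used while the posterior is still the bare prior —
        ``"max_info_at_theta0"`` (default, information at theta 0.0) or
        ``"mpwi_under_prior"``.
    first_item_theta : location for the default first-item rule.
    """

    method: str = "mpwi"
    first_item_rule: str = "max_info_at_theta0"
    first_item_theta: float = 0.0

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ConfigurationError(f"method must be one of {_METHODS}, got {self.method!r}")
        if self.first_item_rule not in _FIRST_ITEM_RULES:
            raise ConfigurationError(
                f"first_item_rule must be one of {_FIRST_ITEM_RULES}, got {self.first_item_rule!r}"
            )


def posterior_weighted_information(state: PosteriorState, item: Item) -> float:
    """Fisher information of ``item`` averaged over the posterior grid."""
    info = item_information(item, state.grid.points)
    return float(np.dot(info, state.weights))


def _candidate_scores(
    state: PosteriorState,
    bank: ItemBank,
    policy: SelectionPolicy,
    info_matrix: np.ndarray | None = None,
) -> np.ndarray:
    """Score every bank item (administered or not) under the policy."""
    if policy.method == "max_info_at_point":
        point = float(np.dot(state.grid.points, state.weights))
        return np.array([item_information(it, point) for it in bank])
    if state.n_updates == 0 and policy.first_item_rule == "max_info_at_theta0":
        theta0 = np.array([policy.first_item_theta])
        return bank.information_matrix(theta0)[:, 0]
    if info_matrix is None:
        info_matrix = bank.information_matrix(state.grid.points)
    return info_matrix @ state.weights


def select_next_item(
    state: PosteriorState,
    bank: ItemBank,
    administered,
    policy: SelectionPolicy = SelectionPolicy(),
    info_matrix: np.ndarray | None = None,
) -> str:
    """Return the item_id of the best unadministered item.

    Parameters
    ----------
    administered : collection of item_ids already given (excluded).
    info_matrix : optional precomputed ``bank.information_matrix(grid.points)``;
        passing it avoids recomputation inside the administration loop.

    Ties are broken by lowest bank index, so results are fully deterministic.
    """
    administered = set(administered)
    candidates = [k for k, it in enumerate(bank) if it.item_id not in administered]
    if not candidates:
        raise ConfigurationError("no unadministered items remain")
    scores = _candidate_scores(state, bank, policy, info_matrix=info_matrix)
    best = max(candidates, key=lambda k: (scores[k], -k))
    return bank[best].item_id


def top_information_subset(bank: ItemBank, k: int, theta: float = 0.0) -> list[str]:
    """The ``k`` items with the highest Fisher information at ``theta``.

    A convenience for building fixed (static) short forms against which the
    adaptive test is compared; ties again resolve to the lowest bank index.
    """
    if not (1 <= k <= len(bank)):
        raise ConfigurationError(f"k must be in [1, {len(bank)}], got {k}")
    info = bank.information_matrix(np.array([theta]))[:, 0]
    order = sorted(range(len(bank)), key=lambda j: (-info[j], j))
    chosen = sorted(order[:k])
    return [bank[j].item_id for j in chosen]
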