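"""Three-parameter logistic (3PL) item response model.

The 3PL model gives the probability that a respondent with latent trait
``theta`` answers a dichotomous item correctly:

    P(theta) = c + (1 - c) / (1 + exp(-a (theta - b)))

where ``a`` is the discrimination (slope), ``b`` the difficulty (location on
the theta scale) and ``c`` the lower asymptote (pseudo-guessing probability;
multiple-choice items with 4 options have ``c`` near 0.25).  The Fisher
information of an item at ``theta`` is

    I(theta) = a^2 * (Q / P) * ((P - c) / (1 - c))^2,   Q = 1 - P

which reduces to the familiar ``a^2 P Q`` when ``c = 0``.

All scalar operations also accept numpy arrays of theta values and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import DataError, ParameterError

__all__ = [
    "Item",
    "ItemBank",
    "prob_correct",
    "item_information",
    "response_likelihood",
]


@dataclass(frozen=True)
class Item:
    """A single dichotomous item with 3PL parameters.

    Parameters
    ----------
    item_id : str
        Short unique identifier within a bank.
    a : float
        Discrimination, logit units per theta unit; must be positive.
    b : float
        Difficulty on the theta scale; must be finite.
    c : float
        Lower asymptote (guessing probability), in ``[0, 1)``.
    content_domain : str
        Free-text content label (e.g. ``"relaxation"``); informational only,
        the engine does not balance content.
    """

    item_id: str
    a: float
    b: float
    c: float = 0.0
    content_domain: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.item_id, str) or not self.item_id:
            raise ParameterError("item_id must be a nonempty string")
        if not np.isfinite(self.a) or self.a <= 0:
            raise ParameterError(f"item {self.item_id!r}: discrimination a must be > 0, got {self.a}")
        if not np.isfinite(self.b):
            raise ParameterError(f"item {self.item_id!r}: difficulty b must be finite, got {self.b}")
        if not np.isfinite(self.c) or not (0.0 <= self.c < 1.0):
            raise ParameterError(f"item {self.item_id!r}: asymptote c must satisfy 0 <= c < 1, got {self.c}")


class ItemBank:
    """An ordered, index-addressable collection of :class:`Item`.

    Item order is stable; ties in item selection are broken by bank index, so
    the order in which items are supplied matters for reproducibility.
    """

    def __init__(self, items, metadata: str = ""):
        items = list(items)
        if not items:
            raise ParameterError("an item bank needs at least one item")
        ids = [it.item_id for it in items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ParameterError(f"duplicate item_ids in bank: {dupes}")
        self.items: list[Item] = items
        self.metadata = metadata
        self._index = {it.item_id: k for k, it in enumerate(items)}

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, key):
        if isinstance(key, str):
            return self.items[self._index[key]]
        return self.items[key]

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._index

    def index_of(self, item_id: str) -> int:
        try:
            return self._index[item_id]
        except KeyError:
            raise DataError(f"unknown item_id {item_id!r}") from None

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    # --- parameter arrays (used by the vectorised engine paths) ---

    @property
    def a(self) -> np.ndarray:
        return np.array([it.a for it in self.items])

    @property
    def b(self) -> np.ndarray:
        return np.array([it.b for it in self.items])

    @property
    def c(self) -> np.ndarray:
        return np.array([it.c for it in self.items])

    def prob_matrix(self, thetas: np.ndarray) -> np.ndarray:
        """Correct-response probabilities, shape ``(n_items, len(thetas))``."""
        thetas = np.asarray(thetas, dtype=float)
        a, b, c = self.a[:, None], self.b[:, None], self.c[:, None]
        return c + (1.0 - c) * expit(a * (thetas[None, :] - b))

    def information_matrix(self, thetas: np.ndarray) -> np.ndarray:
        """Fisher information, shape ``(n_items, len(thetas))``."""
        p = self.prob_matrix(thetas)
        a, c = self.a[:, None], self.c[:, None]
        q = 1.0 - p
        return a**2 * (q / p) * ((p - c) / (1.0 - c)) ** 2

    # --- frame / file round-trips ---

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id": self.item_ids,
                "a": self.a,
                "b": self.b,
                "c": self.c,
                "content_domain": [it.content_domain for it in self.items],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, metadata: str = "") -> "ItemBank":
        required = {"item_id", "a", "b", "c"}
        missing = required - set(frame.columns)
        if missing:
            raise DataError(f"item bank table missing columns: {sorted(missing)}")
        items = [
            Item(
                item_id=str(row.item_id),
                a=float(row.a),
                b=float(row.b),
                c=float(row.c),
                content_domain=str(getattr(row, "content_domain", "") or ""),
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(items, metadata=metadata)

    def __repr__(self) -> str:
        return f"ItemBank(n_items={len(self)})"


def _check_theta(theta) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ParameterError("theta must be finite")
    return theta


def prob_correct(item: Item, theta):
    """3PL probability of a correct response.

    Numerically stable for large ``|a (theta - b)|`` via ``scipy.special.expit``.
    Returns a scalar for scalar theta, an array for array theta.
    """
    theta = _check_theta(theta)
    p = item.c + (1.0 - item.c) * expit(item.a * (theta - item.b))
    return float(p) if np.ndim(p) == 0 else p


def item_information(item: Item, theta):
    """Fisher information of a 3PL item at ``theta`` (nonnegative)."""
    theta = _check_theta(theta)
    p = item.c + (1.0 - item.c) * expit(item.a * (theta - item.b))
    q = 1.0 - p
    info = item.a**2 * (q / p) * ((p - item.c) / (1.0 - item.c)) ** 2
    return float(info) if np.ndim(info) == 0 else info


def response_likelihood(item: Item, response: int, theta):
    """Bernoulli likelihood of an observed 0/1 response under the 3PL model."""
    if response not in (0, 1):
        raise DataError(f"response must be 0 or 1, got {response!r}")
    p = prob_correct(item, theta)
    return p if response == 1 else 1.0 - p
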