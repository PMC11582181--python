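"""Measurement models: graded-response (ordinal) and linear-Gaussian items.

A graded-response (GR) item maps a single latent state onto J ordered
categories through cumulative logistic exceedance curves,

    P(y_i > j | x) = 1 / (1 + exp[-alpha_i (x_{delta_i} - beta_ij)]),

with discrimination ``alpha_i > 0``, strictly increasing thresholds
``beta_i1 < ... < beta_i,J-1`` and selector ``delta_i`` assigning the item to
exactly one state (simple structure — items never cross-load).  Category
probabilities telescope:

    P(y_i = j | x) = P(y_i > j-1 | x) - P(y_i > j | x),   P(y_i > 0 | x) = 1.

The linear comparator treats integer-coded categories as continuous:
``y_i = center_i + loading_i * x_{delta_i} + e_i`` with ``e_i ~ N(0, psi_i)``.
The dynamic model has no measurement intercept, but integer-coded data have a
nonzero mean while the states are mean-zero, so the linear kind carries a
per-item ``center`` offset (in practice the item sample mean, subtracted
before fitting); this is deliberate and logged by the fitting code.

Categories are coded 1..J internally.  Missing responses (encoded as 0 for
ordinal tables, NaN for linear ones) are simply omitted from the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, DimensionError, ParameterError

__all__ = [
    "GRMItem",
    "LinearItem",
    "MeasurementModel",
    "exceedance_probs",
    "category_probs",
    "ordinal_loglik",
    "linear_loglik",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class GRMItem:
    """A graded-response item.

    state_index is 1-based (the selector delta_i maps the item to one state).
    """

    item_id: str
    state_index: int
    alpha: float
    beta: np.ndarray

    def __post_init__(self):
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if beta.ndim != 1 or beta.size < 1:
            raise ParameterError(f"item {self.item_id}: beta must be a 1-d vector")
        if np.any(np.diff(beta) <= 0):
            raise ParameterError(
                f"item {self.item_id}: thresholds must be strictly increasing, got {beta.tolist()}"
            )
        if not self.alpha > 0:
            raise ParameterError(f"item {self.item_id}: alpha must be positive")
        if self.state_index < 1:
            raise ParameterError(f"item {self.item_id}: state_index is 1-based")
        object.__setattr__(self, "beta", beta)

    @property
    def n_categories(self) -> int:
        return self.beta.size + 1


@dataclass(frozen=True)
class LinearItem:
    """A linear-Gaussian item: loading on one state plus iid normal error."""

    item_id: str
    state_index: int
    loading: float
    error_var: float

    def __post_init__(self):
        if not self.error_var > 0:
            raise ParameterError(f"item {self.item_id}: error_var must be positive")
        if self.state_index < 1:
            raise ParameterError(f"item {self.item_id}: state_index is 1-based")


@dataclass(frozen=True)
class MeasurementModel:
    """An ordered collection of items of one kind ('grm' or 'linear')."""

    kind: str
    items: tuple
    center: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.kind not in ("grm", "linear"):
            raise ParameterError(f"unknown measurement kind {self.kind!r}")
        items = tuple(self.items)
        ids = [it.item_id for it in items]
        if len(set(ids)) != len(ids):
            raise ParameterError("item_ids must be unique")
        want = GRMItem if self.kind == "grm" else LinearItem
        for it in items:
            if not isinstance(it, want):
                raise ParameterError(f"item {it.item_id} is not a {want.__name__}")
        center = self.center
        if center is None:
            center = np.zeros(len(items))
        center = np.asarray(center, dtype=float)
        if center.shape != (len(items),):
            raise DimensionError("center must have one entry per item")
        object.__setattr__(self, "items", items)
        object.__setattr__(self, "center", center)

    @property
    def q(self) -> int:
        return len(self.items)

    @property
    def p(self) -> int:
        return max(it.state_index for it in self.items)

    @property
    def item_ids(self):
        return [it.item_id for it in self.items]

    def state_indices(self) -> np.ndarray:
        """0-based selector vector delta (length q)."""
        return np.array([it.state_index - 1 for it in self.items], dtype=np.int64)


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


def exceedance_probs(item: GRMItem, x: float) -> np.ndarray:
    """P(y > j | x) for j = 1..J-1: strictly decreasing in j, increasing in x."""
    return _logistic(item.alpha * (float(x) - item.beta))


def category_probs(item: GRMItem, x: float) -> np.ndarray:
    """Category probabilities P(y = j | x), j = 1..J; sums to 1."""
    exc = exceedance_probs(item, x)
    upper = np.concatenate(([1.0], exc))
    lower = np.concatenate((exc, [0.0]))
    return upper - lower


def ordinal_loglik(y_t, x_t, model: MeasurementModel) -> float:
    """Log-likelihood of one timepoint's ordinal responses given the states.

    Parameters
    ----------
    y_t : length-q integer vector
        Categories in 1..J_i; 0 (or negative) marks a missing response,
        which contributes nothing.
    x_t : length-p state vector.
    """
    if model.kind != "grm":
        raise ParameterError("ordinal_loglik requires a grm measurement model")
    y_t = np.asarray(y_t)
    x_t = np.atleast_1d(np.asarray(x_t, dtype=float))
    if y_t.shape != (model.q,):
        raise DimensionError(f"expected {model.q} responses, got shape {y_t.shape}")
    total = 0.0
    for yi, item in zip(y_t, model.items):
        yi = int(yi)
        if yi <= 0:
            continue  # missing
        if yi > item.n_categories:
            raise DataError(
                f"item {item.item_id}: category {yi} outside 1..{item.n_categories}"
            )
        x = x_t[item.state_index - 1]
        hi = _logistic(item.alpha * (x - item.beta[yi - 1])) if yi < item.n_categories else 0.0
        lo = _logistic(item.alpha * (x - item.beta[yi - 2])) if yi > 1 else 1.0
        total += np.log(max(lo - hi, 1e-300))
    return float(total)


def linear_loglik(y_t, x_t, model: MeasurementModel) -> float:
    """Log-likelihood of one timepoint's continuous responses given the states.

    NaN entries of ``y_t`` are treated as missing and skipped.
    """
    if model.kind != "linear":
        raise ParameterError("linear_loglik requires a linear measurement model")
    y_t = np.asarray(y_t, dtype=float)
    x_t = np.atleast_1d(np.asarray(x_t, dtype=float))
    if y_t.shape != (model.q,):
        raise DimensionError(f"expected {model.q} responses, got shape {y_t.shape}")
    total = 0.0
    for yi, item, ci in zip(y_t, model.items, model.center):
        if np.isnan(yi):
            continue
        resid = yi - ci - item.loading * x_t[item.state_index - 1]
        total += -0.5 * (_LOG_2PI + np.log(item.error_var) + resid * resid / item.error_var)
    return float(total)
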