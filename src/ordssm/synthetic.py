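"""Synthetic data generation for the simulation-study design.

The generating model is a 2-state VAR(1) with upper-triangular transition
matrix ``A = [[AR, CR], [0, AR]]`` (AR autoregression shared by both states,
CR the cross-regressive effect of state 1 on state 2), innovation covariance
implied by the unit-marginal-variance identification constraint, and
graded-response items with discrimination fixed at 1.

Threshold construction follows two schemes:

* *equal* — every item in a state shares the integer sequence ``1..J-1``
  centered on 0 (e.g. J=7 gives [-2.5, -1.5, -0.5, 0.5, 1.5, 2.5]);
* *offset* — item threshold sets are shifted copies of the equal set, spaced
  by ``min(n_items / (J-1), 1.25)`` and centered symmetrically about 0, so a
  scale's items cover a range of latent values.

The study grid crosses T in {100, 500}, items-per-state in {3, 6}, J in
{3, 7}, AR in {.3, .7}, CR in {0, .25} and {equal, offset} thresholds — 64
conditions.  Initial states are drawn from the exact stationary law
N(0, Gamma) (no burn-in needed), and condition x replicate -> seed is a pure
function so the whole study is re-runnable bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .dynamics import IdentifiedCovariances, identify_innovations
from .errors import DimensionError, ParameterError
from .measurement import GRMItem, LinearItem, MeasurementModel, category_probs

__all__ = [
    "SimCondition",
    "LatentTrajectory",
    "equal_thresholds",
    "offset_thresholds",
    "simulate_states",
    "simulate_measurements",
    "make_condition_dataset",
    "grm_condition_model",
    "condition_grid",
    "replicate_seed",
]


def equal_thresholds(J: int) -> np.ndarray:
    """Threshold vector for a J-category item: 1..J-1 centered on 0."""
    if J < 2:
        raise ParameterError("an ordinal item needs at least 2 categories")
    seq = np.arange(1, J, dtype=float)
    return seq - seq.mean()


def offset_thresholds(n_items: int, J: int) -> list[np.ndarray]:
    """Per-item threshold vectors offset from one another, symmetric about 0.

    The spacing between consecutive items' sets is
    ``min(n_items / (J - 1), 1.25)``.
    """
    if n_items < 1:
        raise ParameterError("n_items must be >= 1")
    base = equal_thresholds(J)
    offset = min(n_items / (J - 1), 1.25)
    centers = (np.arange(1, n_items + 1) - (n_items + 1) / 2.0) * offset
    return [base + c for c in centers]


@dataclass(frozen=True)
class SimCondition:
    """One cell of the simulation grid."""

    T: int = 100
    items_per_state: int = 3
    J: int = 7
    AR: float = 0.3
    CR: float = 0.0
    thresholds: str = "equal"
    replicate_seed: int = 0

    def __post_init__(self):
        if self.thresholds not in ("equal", "offset"):
            raise ParameterError("thresholds must be 'equal' or 'offset'")
        if self.T < 2 or self.items_per_state < 1 or self.J < 2:
            raise ParameterError("invalid condition sizes")

    @property
    def A(self) -> np.ndarray:
        return np.array([[self.AR, self.CR], [0.0, self.AR]])

    @property
    def label(self) -> str:
        return (
            f"T{self.T}_AR{self.AR:g}_CR{self.CR:g}_{self.thresholds}"
            f"_i{self.items_per_state}_J{self.J}"
        )


@dataclass(frozen=True)
class LatentTrajectory:
    """A simulated state path plus the truth that generated it."""

    states: np.ndarray  # (T, p)
    A_true: np.ndarray
    covs: IdentifiedCovariances
    seed: int

    @property
    def T(self) -> int:
        return self.states.shape[0]

    @property
    def p(self) -> int:
        return self.states.shape[1]


def condition_grid() -> list[SimCondition]:
    """The fully crossed default grid (64 conditions)."""
    cells = []
    for T, n_items, J, AR, CR, thr in product(
        (100, 500), (3, 6), (3, 7), (0.3, 0.7), (0.0, 0.25), ("equal", "offset")
    ):
        cells.append(SimCondition(T=T, items_per_state=n_items, J=J, AR=AR, CR=CR, thresholds=thr))
    return cells


def replicate_seed(base_seed: int, condition_index: int, replicate: int) -> int:
    """Pure (base, condition, replicate) -> seed map, < 2**31."""
    ss = np.random.SeedSequence([int(base_seed), int(condition_index), int(replicate)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def simulate_states(A, T: int, seed: int) -> LatentTrajectory:
    """Simulate a stationary VAR(1) trajectory under the identification
    constraint.

    The first state is drawn from the exact stationary law N(0, Gamma), so
    every marginal has unit variance from t=1 on.
    """
    A = np.asarray(A, dtype=float)
    covs = identify_innovations(A)
    p = A.shape[0]
    if T < 1:
        raise DimensionError("T must be >= 1")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(covs.Gamma)
    sd = np.sqrt(covs.sigma_diag)
    x = np.empty((T, p))
    x[0] = chol @ rng.standard_normal(p)
    eps = rng.standard_normal((T - 1, p)) * sd
    for t in range(1, T):
        x[t] = A @ x[t - 1] + eps[t - 1]
    return LatentTrajectory(states=x, A_true=A, covs=covs, seed=int(seed))


def draw_measurements(states: np.ndarray, model: MeasurementModel, rng: np.random.Generator) -> np.ndarray:
    """Draw one observation table conditional on a given state path."""
    states = np.asarray(states, dtype=float)
    T = states.shape[0]
    if model.p > states.shape[1]:
        raise DimensionError(
            f"measurement model references state {model.p} but path has p={states.shape[1]}"
        )
    if model.kind == "grm":
        out = np.empty((T, model.q), dtype=np.int64)
        u = rng.random((T, model.q))
        for i, item in enumerate(model.items):
            xs = states[:, item.state_index - 1]
            # vectorized inverse-cdf draw over the category distribution
            exc = 1.0 / (1.0 + np.exp(-item.alpha * (xs[:, None] - item.beta[None, :])))
            cum = 1.0 - np.concatenate([np.ones((T, 1)), exc], axis=1)  # P(y <= j)
            out[:, i] = 1 + np.sum(u[:, i : i + 1] > cum[:, 1:], axis=1)
        return out
    out = np.empty((T, model.q))
    for i, item in enumerate(model.items):
        xs = states[:, item.state_index - 1]
        out[:, i] = (
            model.center[i]
            + item.loading * xs
            + np.sqrt(item.error_var) * rng.standard_normal(T)
        )
    return out


def simulate_measurements(traj: LatentTrajectory, model: MeasurementModel, seed: int) -> np.ndarray:
    """Draw an observation table conditional on a latent trajectory.

    Returns a (T, q) array: integer categories 1..J for the grm kind, reals
    for the linear kind.
    """
    return draw_measurements(traj.states, model, np.random.default_rng(seed))


def grm_condition_model(items_per_state: int, J: int, thresholds: str, p: int = 2) -> MeasurementModel:
    """Build the study's measurement model: identical item sets per state,
    alpha = 1, thresholds per the equal/offset scheme."""
    if thresholds == "equal":
        betas = [equal_thresholds(J)] * items_per_state
    else:
        betas = offset_thresholds(items_per_state, J)
    items = []
    for s in range(1, p + 1):
        for k, beta in enumerate(betas, start=1):
            items.append(GRMItem(item_id=f"s{s}i{k}", state_index=s, alpha=1.0, beta=beta))
    return MeasurementModel(kind="grm", items=tuple(items))


def make_condition_dataset(cond: SimCondition):
    """Generate one replicate of a study cell.

    Returns
    -------
    (LatentTrajectory, (T, q) int array, MeasurementModel)
        The trajectory carries A_true and the identified (Gamma, Sigma);
        the model carries the true thresholds.
    """
    model = grm_condition_model(cond.items_per_state, cond.J, cond.thresholds)
    ss = np.random.SeedSequence([cond.replicate_seed, 7])
    s_states, s_meas = (int(v % (2**31 - 1)) for v in ss.generate_state(2, dtype=np.uint32))
    traj = simulate_states(cond.A, cond.T, s_states)
    y = simulate_measurements(traj, model, s_meas)
    return traj, y, model


def marginal_category_probs(item: GRMItem, n_nodes: int = 201) -> np.ndarray:
    """Marginal category distribution when the state is standard normal
    (the stationary law of an identified state), by Gauss-Hermite-free
    trapezoid quadrature.  Used as an oracle for generated category
    frequencies."""
    xs = np.linspace(-8, 8, n_nodes)
    w = np.exp(-0.5 * xs**2) / np.sqrt(2 * np.pi)
    probs = np.array([category_probs(item, x) for x in xs])  # (n, J)
    vals = np.trapezoid(probs * w[:, None], xs, axis=0)
    return vals / vals.sum()
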