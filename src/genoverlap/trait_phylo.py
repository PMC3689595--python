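"""Dependent vs independent evolution of two binary traits on a phylogeny.

Continuous-time Markov models over the combined state space {00, 01, 10, 11}
(state index = 2*trait1 + trait2).  The independent model has four rates
(gain/loss per trait) and its 4-state generator is the Kronecker sum of two
2-state generators; the dependent model has eight free single-change rates
(dual transitions fixed at zero).  Likelihoods by post-order pruning with
P(t) = exp(Qt); the two models are compared by a likelihood-ratio test with
4 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .annotation_io import Phylogeny
from .errors import ValidationError
from .stats_kit import TestResult, likelihood_ratio_test

RATE_MIN = 1e-8
RATE_MAX = 100.0

# dependent-model rate order: (from_state, to_state) single-trait changes
DEP_TRANSITIONS = (
    (0, 1),  # trait2 gain while trait1=0
    (0, 2),  # trait1 gain while trait2=0
    (1, 0),  # trait2 loss while trait1=0
    (1, 3),  # trait1 gain while trait2=1
    (2, 0),  # trait1 loss while trait2=0
    (2, 3),  # trait2 gain while trait1=1
    (3, 1),  # trait1 loss while trait2=1
    (3, 2),  # trait2 loss while trait1=1
)


def _two_state_generator(alpha: float, beta: float) -> np.ndarray:
    return np.array([[-alpha, alpha], [beta, -beta]], dtype=float)


@dataclass(frozen=True)
class IndependentModel:
    """Gain/loss rates for two independently evolving binary traits."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float

    def __post_init__(self) -> None:
        for r in (self.alpha1, self.beta1, self.alpha2, self.beta2):
            if r < 0:
                raise ValidationError("rates must be non-negative")

    def generator(self) -> np.ndarray:
        q1 = _two_state_generator(self.alpha1, self.beta1)
        q2 = _two_state_generator(self.alpha2, self.beta2)
        eye = np.eye(2)
        return np.kron(q1, eye) + np.kron(eye, q2)

    def as_dependent_rates(self) -> np.ndarray:
        a1, b1, a2, b2 = self.alpha1, self.beta1, self.alpha2, self.beta2
        return np.array([a2, a1, b2, a1, b1, a2, b1, b2], dtype=float)


@dataclass(frozen=True)
class DependentModel:
    """Eight single-change rates among the combined states {00,01,10,11}."""

    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.rates) != 8:
            raise ValidationError("dependent model needs exactly 8 rates")
        if any(r < 0 for r in self.rates):
            raise ValidationError("rates must be non-negative")

    def generator(self) -> np.ndarray:
        q = np.zeros((4, 4))
        for rate, (i, j) in zip(self.rates, DEP_TRANSITIONS):
            q[i, j] = rate
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    @classmethod
    def from_independent(cls, model: IndependentModel) -> "DependentModel":
        return cls(rates=tuple(model.as_dependent_rates()))


@dataclass(frozen=True)
class PagelFit:
    independent: IndependentModel
    ll_independent: float
    dependent: DependentModel
    ll_dependent: float
    lrt: TestResult

    def __post_init__(self) -> None:
        if self.ll_dependent < self.ll_independent - 1e-6:
            raise ValidationError("nesting violated: ll_dependent < ll_independent")

    @property
    def p_value(self) -> float:
        return self.lrt.p_value


class TreeIndex:
    """Flattened post-order view of a phylogeny for fast pruning."""

    def __init__(self, phylogeny: Phylogeny):
        nodes = list(phylogeny.tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        idx = {id(n): i for i, n in enumerate(nodes)}
        self.children: list[list[tuple[int, float]]] = [[] for _ in nodes]
        self.leaf_index: dict[str, int] = {}
        for i, n in enumerate(nodes):
            for c in n.child_nodes():
                self.children[i].append((idx[id(c)], float(c.edge.length or 0.0)))
            if n.is_leaf():
                self.leaf_index[n.taxon.label] = i
        self.root = self.n_nodes - 1
        self.edge_lengths = np.array(
            [bl for ch in self.children for (_, bl) in ch], dtype=float
        )

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_index)


def transition_matrices(Q: np.ndarray, times: np.ndarray) -> np.ndarray:
    """P(t) = exp(Qt) for a batch of times, via eigendecomposition with an
    expm fallback when Q is near-defective."""
    times = np.asarray(times, dtype=float)
    try:
        lam, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        with np.errstate(over="raise"):
            ex = np.exp(np.outer(times, lam))
        P = np.real((V[None, :, :] * ex[:, None, :]) @ Vinv)
        tmax = float(times.max()) if times.size else 0.0
        check = np.real((V * np.exp(lam * tmax)) @ Vinv)
        if not np.allclose(check, expm(Q * tmax), atol=1e-8):
            raise np.linalg.LinAlgError
    except (np.linalg.LinAlgError, FloatingPointError):
        P = np.stack([expm(Q * t) for t in times])
    return np.clip(P, 0.0, None)


def _states_from_traits(traits, leaf_labels) -> dict[str, int]:
    """Normalize trait input to {leaf: combined state 0..3}."""
    states = {}
    for label in leaf_labels:
        if label not in traits:
            raise ValidationError(f"missing trait states for leaf {label!r}")
        t1, t2 = traits[label]
        if t1 not in (0, 1) or t2 not in (0, 1):
            raise ValidationError(f"traits must be binary, got {(t1, t2)} for {label!r}")
        states[label] = 2 * int(t1) + int(t2)
    return states


def _prune_loglik(index: TreeIndex, leaf_partials: np.ndarray,
                  P_by_edge: list[np.ndarray], root_prior: np.ndarray) -> float:
    nstate = root_prior.size
    partials = np.zeros((index.n_nodes, nstate))
    logscale = 0.0
    edge_cursor = 0
    for i in range(index.n_nodes):
        ch = index.children[i]
        if not ch:
            partials[i] = leaf_partials[i]
            continue
        acc = np.ones(nstate)
        for (ci, _bl) in ch:
            acc = acc * (P_by_edge[edge_cursor] @ partials[ci])
            edge_cursor += 1
        mx = acc.max()
        if mx <= 0:
            return -np.inf
        partials[i] = acc / mx
        logscale += np.log(mx)
    lik = float(root_prior @ partials[index.root])
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + logscale)


def _edge_matrices(index: TreeIndex, Q: np.ndarray) -> list[np.ndarray]:
    P = transition_matrices(Q, index.edge_lengths)
    return list(P)


def combined_loglik(
    tree: Phylogeny | TreeIndex,
    traits: dict,
    model: IndependentModel | DependentModel,
    root_prior: str | np.ndarray = "uniform",
) -> float:
    """Log-likelihood of two binary leaf traits under a 4-state CTMC.

    ``traits`` maps leaf label -> (trait1, trait2).  Root states are weighted
    by a uniform prior (1/4 each) unless a custom prior vector or
    ``"stationary"`` is given.
    """
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    states = _states_from_traits(traits, index.leaf_index)
    Q = model.generator()
    prior = _resolve_prior(root_prior, Q, 4)
    leaf_partials = np.zeros((index.n_nodes, 4))
    for label, node_i in index.leaf_index.items():
        leaf_partials[node_i, states[label]] = 1.0
    return _prune_loglik(index, leaf_partials, _edge_matrices(index, Q), prior)


def _resolve_prior(root_prior, Q: np.ndarray, nstate: int) -> np.ndarray:
    if isinstance(root_prior, str):
        if root_prior == "uniform":
            return np.full(nstate, 1.0 / nstate)
        if root_prior == "stationary":
            return stationary_distribution(Q)
        raise ValidationError(f"unknown root prior {root_prior!r}")
    prior = np.asarray(root_prior, dtype=float)
    if prior.shape != (nstate,) or abs(prior.sum() - 1.0) > 1e-8:
        raise ValidationError("root prior must be a probability vector")
    return prior


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return np.clip(pi, 0, None) / np.clip(pi, 0, None).sum()


# ---------------------------------------------------------------------------
# single-trait closed-form pruning (independent-model fast path)
# ---------------------------------------------------------------------------


def _two_state_P(alpha: float, beta: float, times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    r = alpha + beta
    P = np.empty((times.size, 2, 2))
    if r == 0:
        P[:] = np.eye(2)
        return P
    decay = np.exp(-r * times)
    p01 = (alpha / r) * (1 - decay)
    p10 = (beta / r) * (1 - decay)
    P[:, 0, 0] = 1 - p01
    P[:, 0, 1] = p01
    P[:, 1, 0] = p10
    P[:, 1, 1] = 1 - p10
    return P


def single_trait_loglik(index: TreeIndex, leaf_states: dict[str, int],
                        alpha: float, beta: float) -> float:
    P = list(_two_state_P(alpha, beta, index.edge_lengths))
    leaf_partials = np.zeros((index.n_nodes, 2))
    for label, node_i in index.leaf_index.items():
        leaf_partials[node_i, leaf_states[label]] = 1.0
    return _prune_loglik(index, leaf_partials, P, np.array([0.5, 0.5]))


def _fit_single_trait(index: TreeIndex, leaf_states: dict[str, int],
                      rng: np.random.Generator, n_starts: int) -> tuple[float, float, float]:
    """ML (alpha, beta) for one binary trait; returns (alpha, beta, ll)."""

    def neg(params):
        return -single_trait_loglik(index, leaf_states, params[0], params[1])

    height = max(float(index.edge_lengths.sum()) / max(index.n_leaves, 1), 1e-3)
    starts = [np.array([1.0 / height, 1.0 / height])]
    for _ in range(max(0, n_starts - 1)):
        starts.append(10.0 ** rng.uniform(-2, 1, size=2))
    best = None
    for s0 in starts:
        res = minimize(neg, np.clip(s0, RATE_MIN, RATE_MAX), method="L-BFGS-B",
                       bounds=[(RATE_MIN, RATE_MAX)] * 2)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ValidationError("single-trait optimization failed on all starts")
    return float(best.x[0]), float(best.x[1]), -float(best.fun)


def fit_pagel(
    tree: Phylogeny | TreeIndex,
    traits: dict,
    n_starts: int = 4,
    seed: int | None = None,
    root_prior: str = "uniform",
) -> PagelFit:
    """Fit independent and dependent models by bounded multi-start ML.

    The dependent optimization always includes the mapped independent MLE as
    a start, which guarantees the nesting invariant ll_dep >= ll_indep up to
    optimizer tolerance.  Deterministic under a fixed seed.
    """
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    if index.n_leaves < 4:
        import logging

        logging.getLogger(__name__).warning(
            "fewer than 4 leaves: likelihood surface will be very flat"
        )
    states = _states_from_traits(traits, index.leaf_index)
    rng = np.random.default_rng(seed)

    if root_prior == "uniform":
        # the 4-state likelihood factorizes: fit each trait with 2-state pruning
        t1_states = {lab: s >> 1 for lab, s in states.items()}
        t2_states = {lab: s & 1 for lab, s in states.items()}
        a1, b1, ll1 = _fit_single_trait(index, t1_states, rng, n_starts)
        a2, b2, ll2 = _fit_single_trait(index, t2_states, rng, n_starts)
        indep = IndependentModel(a1, b1, a2, b2)
        ll_indep = ll1 + ll2
    else:
        indep, ll_indep = _fit_independent_joint(index, states, rng, n_starts, root_prior)

    leaf_partials = np.zeros((index.n_nodes, 4))
    for label, node_i in index.leaf_index.items():
        leaf_partials[node_i, states[label]] = 1.0

    def neg_dep(rates):
        q = np.zeros((4, 4))
        for rate, (i, j) in zip(rates, DEP_TRANSITIONS):
            q[i, j] = rate
        np.fill_diagonal(q, -q.sum(axis=1))
        prior = _resolve_prior(root_prior, q, 4)
        return -_prune_loglik(index, leaf_partials, _edge_matrices(index, q), prior)

    starts = [np.clip(indep.as_dependent_rates(), RATE_MIN, RATE_MAX)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(10.0 ** rng.uniform(-2, 1, size=8))
    best = None
    for s0 in starts:
        res = minimize(neg_dep, s0, method="L-BFGS-B",
                       bounds=[(RATE_MIN, RATE_MAX)] * 8)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ValidationError("dependent-model optimization failed on all starts")
    ll_dep = -float(best.fun)
    dep_rates = np.asarray(best.x, dtype=float)
    ll_at_indep = -float(neg_dep(starts[0]))
    if ll_at_indep > ll_dep:  # optimizer strayed below its nested start
        ll_dep = ll_at_indep
        dep_rates = starts[0]
    dep = DependentModel(rates=tuple(dep_rates))
    lrt = likelihood_ratio_test(ll_indep, ll_dep, df=4)
    return PagelFit(independent=indep, ll_independent=ll_indep,
                    dependent=dep, ll_dependent=ll_dep, lrt=lrt)


def _fit_independent_joint(index, states, rng, n_starts, root_prior):
    leaf_partials = np.zeros((index.n_nodes, 4))
    for label, node_i in index.leaf_index.items():
        leaf_partials[node_i, states[label]] = 1.0

    def neg(params):
        model = IndependentModel(*params)
        q = model.generator()
        prior = _resolve_prior(root_prior, q, 4)
        return -_prune_loglik(index, leaf_partials, _edge_matrices(index, q), prior)

    starts = [np.ones(4)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(10.0 ** rng.uniform(-2, 1, size=4))
    best = None
    for s0 in starts:
        res = minimize(neg, np.clip(s0, RATE_MIN, RATE_MAX), method="L-BFGS-B",
                       bounds=[(RATE_MIN, RATE_MAX)] * 4)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ValidationError("independent-model optimization failed on all starts")
    return IndependentModel(*best.x), -float(best.fun)


def simulate_traits(
    tree: Phylogeny | TreeIndex,
    model: IndependentModel | DependentModel,
    seed: int | None = None,
    root_prior: str | np.ndarray = "uniform",
) -> dict[str, tuple[int, int]]:
    """Simulate two binary traits: root state from the prior, then exact
    CTMC endpoint sampling along every branch."""
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    rng = np.random.default_rng(seed)
    Q = model.generator()
    prior = _resolve_prior(root_prior, Q, 4)
    P_cache: dict[float, np.ndarray] = {}

    def P_of(t: float) -> np.ndarray:
        if t not in P_cache:
            P = transition_matrices(Q, np.array([t]))[0]
            P = np.clip(P, 0, None)
            P_cache[t] = P / P.sum(axis=1, keepdims=True)
        return P_cache[t]

    states = np.empty(index.n_nodes, dtype=int)
    states[index.root] = rng.choice(4, p=prior)
    for i in range(index.n_nodes - 1, -1, -1):  # reverse post-order = pre-order
        for (ci, bl) in index.children[i]:
            states[ci] = rng.choice(4, p=P_of(bl)[states[i]])
    leaf_to_label = {v: k for k, v in index.leaf_index.items()}
    return {
        leaf_to_label[i]: (states[i] >> 1, states[i] & 1)
        for i in leaf_to_label
    }
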