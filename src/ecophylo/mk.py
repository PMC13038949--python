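"""Equal-rates Markov (Mk1) model for discrete characters.

The Mk1 model has ``k`` states and a single instantaneous rate ``q`` for
every ordered state pair, giving the closed-form transition probability

    P(t)[i,i] = 1/k + (1 - 1/k) * exp(-k q t)
    P(t)[i,j] = 1/k - (1/k)     * exp(-k q t)      (i != j)

with a uniform stationary distribution.  The module provides the pruning
log-likelihood, maximum-likelihood estimation of ``q``, marginal ancestral
state probabilities under a uniform root prior, and stochastic character
mapping with endpoint-conditioned path sampling by uniformization.

The modelling surface follows the Model/Results idiom: build
:class:`Mk1Model` from a tree and tip states, call :meth:`Mk1Model.fit`,
and use the returned :class:`Mk1Results` for ancestral states and maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .trees import Phylogeny

__all__ = [
    "MkModel",
    "Mk1Model",
    "Mk1Results",
    "AsrResult",
    "StochasticMapSummary",
    "mk_transition_matrix",
    "mk_likelihood",
    "fit_mk1",
    "marginal_asr",
    "stochastic_maps",
]


@dataclass(frozen=True)
class MkModel:
    """Mk1 parameters: ``k`` states, per-pair rate ``q`` (off-diagonals equal)."""

    k: int
    q: float

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"Mk model needs k >= 2 states, got {self.k}")
        if self.q < 0:
            raise ValueError(f"rate q must be >= 0, got {self.q}")


def mk_transition_matrix(model: MkModel, t: float) -> np.ndarray:
    """Closed-form ``P(t) = exp(Qt)`` for the equal-rates model."""
    k = model.k
    e = np.exp(-k * model.q * t)
    off = (1.0 - e) / k
    P = np.full((k, k), off)
    np.fill_diagonal(P, off + e)
    return P


def _check_states(tree: Phylogeny, states: np.ndarray, k: int) -> np.ndarray:
    states = np.asarray(states)
    if states.shape != (tree.n_tips,):
        raise ValueError(
            f"need one state per tip ({tree.n_tips}), got shape {states.shape}"
        )
    st = states.astype(np.intp)
    if not np.array_equal(st, states):
        raise ValueError("tip states must be integer codes")
    bad = (st < 0) | (st >= k)
    if bad.any():
        tips = [tree.tip_labels[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"state outside 0..{k - 1} at tip(s) {tips}")
    return st


def _partials(tree: Phylogeny, states: np.ndarray, model: MkModel):
    """Upward (Felsenstein) partial likelihoods and per-edge P matrices."""
    k = model.k
    n = tree.n_nodes
    L = np.zeros((n, k))
    L[np.arange(tree.n_tips), states] = 1.0
    P = np.empty((n, k, k))
    for node in tree.postorder():
        if tree.parent[node] >= 0:
            P[node] = mk_transition_matrix(model, tree.edge_length[node])
        if not tree.is_tip(node):
            prod = np.ones(k)
            for child in tree.children[node]:
                prod *= P[child] @ L[child]
            L[node] = prod
    return L, P


def mk_likelihood(tree: Phylogeny, states: np.ndarray, model: MkModel) -> float:
    """Pruning log-likelihood under Mk1 with a uniform root prior.

    Returns ``-inf`` for data impossible under the model (e.g. ``q = 0``
    with tips in different states).
    """
    st = _check_states(tree, states, model.k)
    L, _ = _partials(tree, st, model)
    lik = L[tree.root].sum() / model.k
    if lik <= 0:
        return -np.inf
    return float(np.log(lik))


@dataclass
class AsrResult:
    """Fitted rate, log-likelihood, and marginal node state probabilities."""

    model: MkModel
    loglik: float
    node_probs: dict[int, np.ndarray]  # internal node id -> length-k vector


@dataclass
class StochasticMapSummary:
    """Aggregates over a set of sampled character histories."""

    n_maps: int
    transition_mean: np.ndarray  # (k, k) mean count of i->j transitions per map
    transition_sd: np.ndarray
    origin_counts: np.ndarray  # per-map number of independent origins of focal state
    focal_state: int
    node_state_freq: dict[int, np.ndarray]  # node id -> sampled-state frequencies
    seed: int


def fit_mk1(tree: Phylogeny, states: np.ndarray, k: int) -> tuple[MkModel, float, bool]:
    """Maximum-likelihood ``q`` by bounded scalar search on log q.

    Returns ``(model, loglik, boundary)`` where ``boundary`` flags a
    monomorphic trait (q-hat pinned to 0).
    """
    st = _check_states(tree, states, k)
    if len(np.unique(st)) < 2:
        model = MkModel(k=k, q=0.0)
        return model, mk_likelihood(tree, st, model), True
    height = tree.height
    lo, hi = np.log(1e-8), np.log(100.0 / height)

    def nll(logq: float) -> float:
        return -mk_likelihood(tree, st, MkModel(k=k, q=float(np.exp(logq))))

    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    q_hat = float(np.exp(res.x))
    ll = -float(res.fun)
    # guard: the optimum must beat both bounds
    for b in (lo, hi):
        if -nll(b) > ll + 1e-9:
            q_hat = float(np.exp(b))
            ll = -nll(b)
    return MkModel(k=k, q=q_hat), ll, False


def marginal_asr(tree: Phylogeny, states: np.ndarray, model: MkModel) -> AsrResult:
    """Marginal ancestral state probabilities at every internal node.

    For each node the marginal posterior is the normalized product of the
    node's upward partial likelihood and the likelihood of the rest of the
    tree (downward pass), under the uniform root prior.
    """
    st = _check_states(tree, states, model.k)
    k = model.k
    L, P = _partials(tree, st, model)
    root = tree.root
    if L[root].sum() <= 0:
        raise ValueError("data have zero likelihood under this model")
    # downward ("outside") pass
    out = np.zeros_like(L)
    out[root] = 1.0 / k  # root prior
    for node in tree.preorder():
        if tree.is_tip(node):
            continue
        kids = tree.children[node]
        # per-child message from the node: outside * product of siblings
        msgs = [P[c] @ L[c] for c in kids]
        for idx, child in enumerate(kids):
            rest = out[node].copy()
            for jdx, m in enumerate(msgs):
                if jdx != idx:
                    rest *= m
            out[child] = P[child].T @ rest
    node_probs: dict[int, np.ndarray] = {}
    for node in range(tree.n_tips, tree.n_nodes):
        w = L[node] * out[node]
        node_probs[node] = w / w.sum()
    return AsrResult(model=model, loglik=mk_likelihood(tree, st, model),
                     node_probs=node_probs)


# --------------------------------------------------------------- stochastic maps

def _uniform_jump_prob(k: int, m: int, same: bool) -> float:
    """m-step probability of the uniform jump chain R (zero diagonal).

    ``R^m[x,y] = 1/k + (d_xy - 1/k) * (-1/(k-1))^m``.
    """
    lam = (-1.0 / (k - 1)) ** m
    if same:
        return 1.0 / k + (1.0 - 1.0 / k) * lam
    return 1.0 / k - lam / k


def _sample_path(k: int, q: float, t: float, a: int, b: int,
                 rng: np.random.Generator, max_n: int = 500) -> list[int]:
    """States visited on a branch of length t conditioned on endpoints (a, b).

    Uniformization at rate ``(k-1) q`` makes the auxiliary jump chain the
    true jump chain (zero self-loops), so every sampled jump is a real
    substitution.  Returns the state sequence ``[a, ..., b]``.
    """
    if q == 0.0 or t == 0.0:
        if a != b:
            raise ValueError("endpoint change impossible with q*t == 0")
        return [a]
    rate = (k - 1) * q * t
    # P(N = n | a, b) proportional to Poisson(rate, n) * R^n[a,b]
    weights = []
    logpois = -rate
    n = 0
    while True:
        rn = _uniform_jump_prob(k, n, a == b)
        weights.append(np.exp(logpois) * max(rn, 0.0))
        n += 1
        logpois += np.log(rate) - np.log(n)
        if n > max_n or (n > rate + 10 * np.sqrt(rate) + 10 and n >= 3):
            break
    w = np.array(weights)
    total = w.sum()
    if total <= 0:
        raise RuntimeError("degenerate jump-count distribution")
    n_jumps = int(rng.choice(len(w), p=w / total))
    # sample intermediate states given n_jumps and endpoints
    path = [a]
    cur = a
    for step in range(n_jumps):
        remaining = n_jumps - step - 1
        probs = np.empty(k)
        for s in range(k):
            probs[s] = (0.0 if s == cur else 1.0 / (k - 1)) * \
                _uniform_jump_prob(k, remaining, s == b)
        probs /= probs.sum()
        cur = int(rng.choice(k, p=probs))
        path.append(cur)
    if path[-1] != b:
        raise RuntimeError("path sampler failed to hit the endpoint")
    return path


def stochastic_maps(tree: Phylogeny, states: np.ndarray, model: MkModel,
                    n_maps: int, seed: int, focal_state: int = 1) -> StochasticMapSummary:
    """Sample character histories conditional on the tip data.

    Each map draws joint node states exactly (root from its posterior,
    children given their parent), then a substitution path on every branch
    conditioned on its endpoints.  Transitions are tallied per ordered
    state pair; "independent origins" of ``focal_state`` are the maximal
    regions painted with it whose entry edge transitions from another
    state, plus one if the root itself is in the focal state.
    """
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    st = _check_states(tree, states, model.k)
    k = model.k
    rng = np.random.default_rng(seed)
    L, P = _partials(tree, st, model)
    root = tree.root
    if L[root].sum() <= 0:
        raise ValueError("data have zero likelihood under this model")
    root_post = L[root] / L[root].sum()

    trans_counts = np.zeros((n_maps, k, k))
    origins = np.zeros(n_maps, dtype=np.intp)
    node_tally = np.zeros((tree.n_nodes, k))
    preord = tree.preorder()

    for m in range(n_maps):
        node_state = np.empty(tree.n_nodes, dtype=np.intp)
        node_state[: tree.n_tips] = st
        node_state[root] = rng.choice(k, p=root_post)
        for node in preord:
            for child in tree.children[node]:
                w = P[child][node_state[node]] * L[child]
                if tree.is_tip(child):
                    node_state[child] = st[child]
                else:
                    node_state[child] = rng.choice(k, p=w / w.sum())
        n_org = 1 if node_state[root] == focal_state else 0
        for node in range(tree.n_nodes):
            if node == root:
                continue
            path = _sample_path(k, model.q, float(tree.edge_length[node]),
                                int(node_state[tree.parent[node]]),
                                int(node_state[node]), rng)
            for a, b in zip(path[:-1], path[1:]):
                trans_counts[m, a, b] += 1
                if b == focal_state:
                    n_org += 1
        origins[m] = n_org
        node_tally[np.arange(tree.n_nodes), node_state] += 1

    node_freq = {node: node_tally[node] / n_maps
                 for node in range(tree.n_tips, tree.n_nodes)}
    return StochasticMapSummary(
        n_maps=n_maps,
        transition_mean=trans_counts.mean(axis=0),
        transition_sd=trans_counts.std(axis=0, ddof=0),
        origin_counts=origins,
        focal_state=focal_state,
        node_state_freq=node_freq,
        seed=seed,
    )


# ----------------------------------------------------------- Model/Results API

class Mk1Model:
    """Mk1 discrete-character model bound to a tree and tip states.

    Parameters
    ----------
    tree : Phylogeny
    states : integer codes, one per tip (order = ``tree.tip_labels``)
    k : number of states; default ``max(states) + 1``
    """

    def __init__(self, tree: Phylogeny, states, k: int | None = None):
        self.tree = tree
        states = np.asarray(states)
        self.k = int(states.max()) + 1 if k is None else int(k)
        self.states = _check_states(tree, states, self.k)

    @classmethod
    def from_dataframe(cls, tree: Phylogeny, table, column: str,
                       k: int | None = None) -> "Mk1Model":
        """Build from a tip-indexed DataFrame column of integer codes."""
        vals = np.array([table.loc[lab, column] for lab in tree.tip_labels])
        return cls(tree, vals, k=k)

    def loglike(self, q: float) -> float:
        return mk_likelihood(self.tree, self.states, MkModel(k=self.k, q=q))

    def fit(self) -> "Mk1Results":
        model, ll, boundary = fit_mk1(self.tree, self.states, self.k)
        return Mk1Results(self, model, ll, boundary)


@dataclass
class Mk1Results:
    """Fitted Mk1 model: rate estimate, likelihood, ASR and mapping methods."""

    model_spec: Mk1Model
    model: MkModel
    loglik: float
    at_boundary: bool
    _asr: AsrResult | None = field(default=None, repr=False)

    @property
    def q(self) -> float:
        return self.model.q

    def ancestral_states(self) -> AsrResult:
        if self._asr is None:
            self._asr = marginal_asr(self.model_spec.tree, self.model_spec.states,
                                     self.model)
        return self._asr

    def stochastic_maps(self, n_maps: int, seed: int,
                        focal_state: int = 1) -> StochasticMapSummary:
        return stochastic_maps(self.model_spec.tree, self.model_spec.states,
                               self.model, n_maps, seed, focal_state)

    def summary(self) -> str:
        lines = [
            "Mk1 model fit",
            "=============",
            f"states (k):        {self.model.k}",
            f"rate q (ML):       {self.model.q:.6g}"
            + ("  [boundary: monomorphic trait]" if self.at_boundary else ""),
            f"log-likelihood:    {self.loglik:.6f}",
            f"tips:              {self.model_spec.tree.n_tips}",
        ]
        return "\n".join(lines)
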