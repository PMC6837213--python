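"""Discrete character history on a phylogeny.

Reconstructs the history of an unordered multistate character (here the
four locomotor types) with:

* Fitch parsimony — minimum number of state changes, the full set of
  most-parsimonious states (MPR) per node, and a deterministic transition
  list along branches;
* the retention index RI = (g − s)/(g − m), measuring how much of the
  potential homoplasy the tree avoids (1 = perfect fit);
* maximum-likelihood fitting of the equal-rates (ER) Mk model by
  Felsenstein pruning with a uniform root prior;
* stochastic character mapping: sampling full histories conditional on the
  tip states under the fitted ER model, summarised as per-node posterior
  state probabilities.

Parsimony is computed by dynamic programming with uniform (Fitch) costs,
which yields exact minimum step counts and exact MPR sets; ties in the
reported single reconstruction are broken toward the parent's state, then
by lexicographic rank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .phylo import Phylogeny, _as_phylogeny

__all__ = [
    "CharacterStates",
    "ParsimonyReconstruction",
    "StochasticMapSet",
    "fitch_parsimony",
    "retention_index",
    "fit_mk_er",
    "stochastic_maps",
]


@dataclass
class ParsimonyReconstruction:
    """Most-parsimonious ancestral states for one character."""

    steps: int
    node_states: dict[int, frozenset]  # node id -> MPR state set
    chosen_states: dict[int, str]  # deterministic single reconstruction
    transitions: list[tuple[str, str, str]]  # (child clade label, from, to)
    ambiguous: bool


@dataclass
class StochasticMapSet:
    """Summary of simulated character histories under the ER Mk model."""

    rate: float
    n_sim: int
    seed: int
    node_posteriors: dict[str, dict[str, float]]  # node key -> state -> prob
    change_counts: np.ndarray  # changes per simulated map
    n_rejection_failures: int = 0


def _tree_arrays(tree) -> tuple:
    """Flatten a (rooted, binary) dendropy tree into parent/child arrays in
    postorder.  Returns nodes list, children ids, parent id, branch length,
    and a stable label per node (tip label, or sorted tip set digest)."""
    phy = _as_phylogeny(tree) if not isinstance(tree, Phylogeny) else tree
    t = phy.tree
    nodes = list(t.postorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    children: list[list[int]] = []
    blen: list[float] = []
    labels: list[str] = []
    for n in nodes:
        kids = n.child_nodes()
        if kids and len(kids) != 2:
            raise ValueError("tree must be binary-resolved (polytomy found)")
        children.append([index[id(k)] for k in kids])
        blen.append(float(n.edge.length or 0.0))
        if n.is_leaf():
            labels.append(n.taxon.label)
        else:
            tips = sorted(lf.taxon.label for lf in n.leaf_iter())
            labels.append("mrca(" + ",".join(tips[:2]) + (",..." if len(tips) > 2 else "") + ")")
    return phy, nodes, children, blen, labels


def _validate_states(labels_at_tips: list[str], states: dict[str, str]) -> list[str]:
    missing = [l for l in labels_at_tips if l not in states]
    if missing:
        raise ValueError(f"tip(s) missing a character state: {missing}")
    return sorted(set(states[l] for l in labels_at_tips))


def fitch_parsimony(tree, states: dict[str, str]) -> ParsimonyReconstruction:
    """Unordered-character parsimony with exact MPR sets.

    ``states`` maps tip label to state.  Down-pass DP cost vectors give the
    minimum change count (identical to Fitch's count for uniform costs);
    the up-pass marginalises to the exact set of states each node takes in
    at least one most-parsimonious reconstruction.  The single reported
    reconstruction picks, top-down, the parent's state when optimal and the
    lexicographically smallest optimal state otherwise.
    """
    phy, nodes, children, blen, labels = _tree_arrays(tree)
    tip_labels = [labels[i] for i, ch in enumerate(children) if not ch]
    state_names = _validate_states(tip_labels, states)
    k = len(state_names)
    sidx = {s: i for i, s in enumerate(state_names)}
    INF = 10**9
    n = len(nodes)
    down = np.full((n, k), INF, dtype=np.int64)
    for i, ch in enumerate(children):
        if not ch:
            down[i, :] = INF
            down[i, sidx[states[labels[i]]]] = 0
        else:
            # cost of subtree if node i is in state s
            for s in range(k):
                total = 0
                for c in ch:
                    total += min(down[c, u] + (0 if u == s else 1) for u in range(k))
                down[i, s] = total
    root = n - 1
    steps = int(down[root].min())
    # up-pass: up[i, s] = cost of the rest of the tree if node i has state s
    up = np.zeros((n, k), dtype=np.int64)
    for i in reversed(range(n)):
        for c in children[i]:
            sib_cost = np.empty(k, dtype=np.int64)
            siblings = [c2 for c2 in children[i] if c2 != c]
            for s in range(k):
                tot = up[i, s]
                for c2 in siblings:
                    tot += min(down[c2, u] + (0 if u == s else 1) for u in range(k))
                sib_cost[s] = tot
            for s in range(k):
                up[c, s] = min(sib_cost[u] + (0 if u == s else 1) for u in range(k))
    node_sets: dict[int, frozenset] = {}
    for i in range(n):
        total = down[i] + up[i]
        best = total.min()
        node_sets[i] = frozenset(state_names[s] for s in range(k) if total[s] == best)
    # deterministic single reconstruction, parent-first then lexicographic
    chosen: dict[int, str] = {}
    order = list(reversed(range(n)))  # preorder
    parent = [-1] * n
    for i, ch in enumerate(children):
        for c in ch:
            parent[c] = i
    for i in order:
        if parent[i] == -1:
            opts = sorted(node_sets[i])
            chosen[i] = opts[0]
        else:
            ps = chosen[parent[i]]
            cost_if = {s: down[i, sidx[s]] + (0 if s == ps else 1) for s in state_names}
            best = min(cost_if.values())
            opts = sorted(s for s, c in cost_if.items() if c == best)
            chosen[i] = ps if ps in opts else opts[0]
    transitions = [
        (labels[i], chosen[parent[i]], chosen[i])
        for i in range(n)
        if parent[i] != -1 and chosen[i] != chosen[parent[i]]
    ]
    internal_ambiguous = any(len(node_sets[i]) > 1 for i, ch in enumerate(children) if ch)
    return ParsimonyReconstruction(
        steps=steps,
        node_states={i: node_sets[i] for i in range(n)},
        chosen_states=chosen,
        transitions=transitions,
        ambiguous=internal_ambiguous,
    )


def retention_index(tree, states: dict[str, str]) -> float:
    """RI = (g − s)/(g − m) for one unordered character.

    s = parsimony steps, m = (number of observed states) − 1 (minimum
    conceivable steps), g = n_tips − max state frequency (steps on the
    worst-case star-like tree).  Undefined (nan) for an invariant
    character, where g = m = 0.
    """
    phy, nodes, children, blen, labels = _tree_arrays(tree)
    tip_labels = [labels[i] for i, ch in enumerate(children) if not ch]
    observed = [states[l] for l in tip_labels]
    names = sorted(set(observed))
    if len(names) < 2:
        return float("nan")
    s = fitch_parsimony(tree, states).steps
    m = len(names) - 1
    g = len(tip_labels) - max(observed.count(x) for x in names)
    if g == m:
        return 1.0 if s == m else 0.0
    return (g - s) / (g - m)


# ---------------------------------------------------------------------------
# Mk equal-rates model


def _er_transition(k: int, rate: float, t: float) -> tuple[float, float]:
    """(P_same, P_diff) for a k-state ER chain over time t."""
    e = math.exp(-k * rate * t)
    return 1.0 / k + (k - 1) / k * e, 1.0 / k - 1.0 / k * e


def mk_er_loglik(tree, states: dict[str, str], rate: float,
                 state_space: list[str] | None = None) -> float:
    """Felsenstein-pruning log-likelihood of the ER Mk model.

    Uniform root prior.  The state space defaults to the observed states;
    pass ``state_space`` to include unobserved states in k.
    """
    phy, nodes, children, blen, labels = _tree_arrays(tree)
    tip_labels = [labels[i] for i, ch in enumerate(children) if not ch]
    names = state_space or _validate_states(tip_labels, states)
    _validate_states(tip_labels, states)
    k = len(names)
    sidx = {s: i for i, s in enumerate(names)}
    n = len(nodes)
    L = np.zeros((n, k))
    scale = 0.0
    for i, ch in enumerate(children):
        if not ch:
            L[i, sidx[states[labels[i]]]] = 1.0
            continue
        L[i, :] = 1.0
        for c in ch:
            ps, pd = _er_transition(k, rate, blen[c])
            # prob of child subtree given parent state s
            msg = np.array([ps * L[c, s] + pd * (L[c].sum() - L[c, s]) for s in range(k)])
            L[i, :] *= msg
        m = L[i].max()
        if m <= 0:
            return -np.inf
        L[i, :] /= m
        scale += math.log(m)
    root = n - 1
    return float(scale + math.log(L[root].mean()))


def fit_mk_er(tree, states: dict[str, str], bracket: tuple[float, float] = (1e-8, 100.0),
              state_space: list[str] | None = None) -> float:
    """ML rate of the equal-rates Mk model (events per unit branch length).

    1-D bounded search over log-rate, tolerance 1e-8 on the rate.
    """
    from scipy import optimize

    phy, nodes, children, blen, labels = _tree_arrays(tree)
    if sum(blen) <= 0:
        raise ValueError("tree has zero total branch length")
    tip_labels = [labels[i] for i, ch in enumerate(children) if not ch]
    names = _validate_states(tip_labels, states)
    if len(names) < 2:
        raise ValueError("need at least two observed states to fit a rate")
    def nll(log_rate: float) -> float:
        return -mk_er_loglik(tree, states, math.exp(log_rate), state_space=state_space)

    res = optimize.minimize_scalar(
        nll, bounds=(math.log(bracket[0]), math.log(bracket[1])), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(math.exp(res.x))


# ---------------------------------------------------------------------------
# Stochastic character mapping


def _simulate_branch(
    rng: np.random.Generator, k: int, rate: float, t: float, start: int, end: int,
    max_tries: int = 1000,
) -> list[tuple[float, int]] | None:
    """Rejection-sample an ER trajectory on a branch conditioned on its
    endpoint states.  Returns a list of (time, new_state) changes, or None
    when every attempt failed."""
    total_rate = (k - 1) * rate
    for _ in range(max_tries):
        state = start
        tau = 0.0
        changes: list[tuple[float, int]] = []
        if start == end:
            pass
        else:
            # force at least one event for unequal endpoints
            if total_rate * t <= 0:
                return None
            u = rng.random()
            tau = -math.log(1 - u * (1 - math.exp(-total_rate * t))) / total_rate
            state = int(rng.choice([s for s in range(k) if s != state]))
            changes.append((tau, state))
        while True:
            tau += rng.exponential(1.0 / total_rate) if total_rate > 0 else float("inf")
            if tau >= t:
                break
            state = int(rng.choice([s for s in range(k) if s != state]))
            changes.append((tau, state))
        if state == end:
            return changes
    return None


def stochastic_maps(
    tree,
    states: dict[str, str],
    rate: float | None = None,
    n_sim: int = 1000,
    seed: int = 0,
    state_space: list[str] | None = None,
) -> StochasticMapSet:
    """Stochastic character mapping under the ER Mk model.

    Node states are drawn root-down from their conditional distributions
    (pruning partial likelihoods), then branch histories are rejection-
    sampled conditional on the endpoint states.  Node posteriors are the
    frequencies of sampled states over ``n_sim`` maps.  A branch whose
    rejection sampling fails after bounded attempts triggers a redraw of
    that map's node states (counted in ``n_rejection_failures``).
    """
    if rate is None:
        rate = fit_mk_er(tree, states, state_space=state_space)
    if not rate > 0:
        raise ValueError("rate must be positive")
    phy, nodes, children, blen, labels = _tree_arrays(tree)
    tip_labels = [labels[i] for i, ch in enumerate(children) if not ch]
    names = state_space or _validate_states(tip_labels, states)
    _validate_states(tip_labels, states)
    k = len(names)
    sidx = {s: i for i, s in enumerate(names)}
    n = len(nodes)
    # partial likelihoods (unscaled per node, scaled overall)
    L = np.zeros((n, k))
    for i, ch in enumerate(children):
        if not ch:
            L[i, sidx[states[labels[i]]]] = 1.0
        else:
            L[i, :] = 1.0
            for c in ch:
                ps, pd = _er_transition(k, rate, blen[c])
                msg = ps * L[c] + pd * (L[c].sum(axis=-1, keepdims=False) - L[c])
                L[i, :] *= msg
            m = L[i].max()
            if m > 0:
                L[i, :] /= m
    parent = [-1] * n
    for i, ch in enumerate(children):
        for c in ch:
            parent[c] = i
    root = n - 1
    rng = np.random.default_rng(seed)
    counts = np.zeros((n, k), dtype=np.int64)
    change_counts = np.zeros(n_sim, dtype=np.int64)
    failures = 0
    preorder = list(reversed(range(n)))
    for m_i in range(n_sim):
        while True:
            draw = np.empty(n, dtype=np.int64)
            pr = L[root] / L[root].sum()
            draw[root] = rng.choice(k, p=pr)
            for i in preorder:
                if i == root:
                    continue
                ps, pd = _er_transition(k, rate, blen[i])
                trans = np.full(k, pd)
                trans[draw[parent[i]]] = ps
                w = trans * L[i]
                w /= w.sum()
                draw[i] = rng.choice(k, p=w)
            # branch histories
            n_changes = 0
            ok = True
            for i in range(n):
                if parent[i] == -1:
                    continue
                hist = _simulate_branch(rng, k, rate, blen[i], draw[parent[i]], draw[i])
                if hist is None:
                    failures += 1
                    ok = False
                    break
                n_changes += len(hist)
            if ok:
                break
        counts[np.arange(n), draw] += 1
        change_counts[m_i] = n_changes
    posteriors = {
        labels[i]: {names[s]: counts[i, s] / n_sim for s in range(k)}
        for i in range(n)
    }
    return StochasticMapSet(
        rate=float(rate), n_sim=n_sim, seed=seed,
        node_posteriors=posteriors, change_counts=change_counts,
        n_rejection_failures=failures,
    )
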