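"""Policies over the PEEP x FiO2 action lattice.

Greedy and "king-knight"-restricted policies are derived from a trained
Q-model; the physician behaviour policy is estimated by k-nearest neighbours
on the z-scored state space. The king-knight restriction confines each
recommendation to the 3x3 Chebyshev neighbourhood of the previous action;
cessation of ventilation (NV) may only be recommended from configured
low-support actions, and from NV any action is permissible.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .q_agent import QModel
from .trajectory_builder import ActionGrid


@dataclass(frozen=True)
class RestrictionConfig:
    """King-knight restriction parameters.

    radius is the Chebyshev neighbourhood on the (i_peep, i_fio2) lattice
    (the king move, fixed to 1 in the study design). nv_allowed_from is the
    set of ventilated actions from which NV (extubation) may be recommended;
    the default is the lowest PEEP bin combined with the two lowest FiO2
    bins — the clinically low-support corner.
    """
    radius: int = 1
    nv_allowed_from: tuple = ((0, 0), (0, 1))   # (i_peep, i_fio2) coords

    def nv_allowed_indices(self, grid: ActionGrid) -> frozenset:
        idx = frozenset(grid.index(ip, if2) for ip, if2 in self.nv_allowed_from)
        if any(i == grid.nv_index for i in idx):
            raise ValueError("nv_allowed_from must contain ventilated actions only")
        return idx


def king_knight_mask(previous_action: int, cfg: RestrictionConfig | None = None,
                     grid: ActionGrid | None = None) -> np.ndarray:
    """Boolean allowed-action vector given the previous action.

    Previous NV: everything is allowed. Previous ventilated: all ventilated
    actions within Chebyshev distance <= radius, plus NV iff the previous
    action is in the configured extubation set. The previous action is always
    in its own mask, so the mask is never empty.
    """
    cfg = cfg or RestrictionConfig()
    grid = grid or ActionGrid()
    n = grid.n_actions
    if not 0 <= previous_action < n:
        raise ValueError(f"invalid previous action {previous_action}")
    mask = np.zeros(n, dtype=bool)
    if previous_action == grid.nv_index:
        mask[:] = True
        return mask
    for a in range(grid.nv_index):
        mask[a] = grid.chebyshev(previous_action, a) <= cfg.radius
    if previous_action in cfg.nv_allowed_indices(grid):
        mask[grid.nv_index] = True
    return mask


def mask_table(cfg: RestrictionConfig | None = None,
               grid: ActionGrid | None = None) -> list[dict]:
    """Full audit table: for every previous action, the allowed set."""
    cfg = cfg or RestrictionConfig()
    grid = grid or ActionGrid()
    rows = []
    for prev in range(grid.n_actions):
        m = king_knight_mask(prev, cfg, grid)
        rows.append({
            "previous_action": prev,
            "previous_label": grid.label(prev),
            "n_allowed": int(m.sum()),
            "allowed": [grid.label(a) for a in np.flatnonzero(m)],
        })
    return rows


@dataclass
class Policy:
    """A mapping (state, previous action) -> probability vector over actions."""
    kind: str
    n_actions: int
    _probs: Callable = None
    _probs_batch: Callable = None
    metadata: dict = field(default_factory=dict)

    def probs(self, state, previous_action: int) -> np.ndarray:
        p = np.asarray(self._probs(np.asarray(state, dtype=float),
                                   int(previous_action)), dtype=float)
        return p

    def probs_batch(self, states, previous_actions) -> np.ndarray:
        """(n, n_actions) matrix of action probabilities."""
        states = np.asarray(states, dtype=float)
        previous_actions = np.asarray(previous_actions, dtype=int)
        if self._probs_batch is not None:
            return self._probs_batch(states, previous_actions)
        return np.stack([self.probs(s, a) for s, a in zip(states, previous_actions)])

    def action(self, state, previous_action: int) -> int:
        """Deterministic recommendation: argmax probability, ties to lowest index."""
        return int(np.argmax(self.probs(state, previous_action)))

    def __call__(self, state, previous_action: int) -> np.ndarray:
        return self.probs(state, previous_action)


def _onehot(i: int, n: int) -> np.ndarray:
    v = np.zeros(n)
    v[i] = 1.0
    return v


def greedy_policy(model: QModel) -> Policy:
    """Deterministic argmax of Q over the full action set (ties to lowest
    index); ignores the previous action."""
    n = model.spec.n_actions

    def probs(state, prev):
        q = model.evaluate(state)
        return _onehot(int(np.argmax(q)), n)

    def probs_batch(states, prevs):
        Q = model.evaluate(states)
        P = np.zeros_like(Q)
        P[np.arange(len(Q)), np.argmax(Q, axis=1)] = 1.0
        return P

    return Policy("greedy", n, probs, probs_batch,
                  metadata={"model_hash": model.content_hash()})


def restricted_policy(model: QModel, cfg: RestrictionConfig | None = None,
                      grid: ActionGrid | None = None) -> Policy:
    """Argmax of Q over the king-knight mask of the previous action."""
    cfg = cfg or RestrictionConfig()
    grid = grid or ActionGrid()
    if grid.n_actions != model.spec.n_actions:
        raise ValueError("grid and model action counts disagree")
    n = grid.n_actions
    masks = np.stack([king_knight_mask(p, cfg, grid) for p in range(n)])

    def probs(state, prev):
        q = np.where(masks[prev], model.evaluate(state), -np.inf)
        return _onehot(int(np.argmax(q)), n)

    def probs_batch(states, prevs):
        Q = np.where(masks[prevs], model.evaluate(states), -np.inf)
        P = np.zeros_like(Q)
        P[np.arange(len(Q)), np.argmax(Q, axis=1)] = 1.0
        return P

    return Policy("king_knight", n, probs, probs_batch,
                  metadata={"model_hash": model.content_hash(),
                            "restriction": {"radius": cfg.radius,
                                            "nv_allowed_from": list(cfg.nv_allowed_from)}})


def soften(policy: Policy, eps: float, cfg: RestrictionConfig | None = None,
           grid: ActionGrid | None = None) -> Policy:
    """epsilon-soften a deterministic policy for finite importance ratios.

    Probability 1 - eps stays on the deterministic choice; eps is spread
    uniformly over the remaining *allowed* actions (the king-knight mask for
    restricted policies, everything otherwise). eps = 0 is the identity.
    """
    if not 0 <= eps < 1:
        raise ValueError("eps must lie in [0, 1)")
    if eps == 0:
        return policy
    n = policy.n_actions
    if policy.kind == "king_knight":
        grid = grid or ActionGrid()
        cfg = cfg or RestrictionConfig()
        masks = np.stack([king_knight_mask(p, cfg, grid) for p in range(n)])
    else:
        masks = np.ones((n, n), dtype=bool)

    def soft(P, prevs):
        M = masks[prevs]
        out = P * (1 - eps)
        k = M.sum(axis=1, keepdims=True) - 1          # remaining allowed
        spread = np.where(k > 0, eps / np.maximum(k, 1), 0.0)
        out = out + np.where(M & (P < 1.0), spread, 0.0)
        # degenerate single-action mask: keep all mass on the choice
        out[(k == 0).ravel()] = P[(k == 0).ravel()]
        return out / out.sum(axis=1, keepdims=True)

    def probs(state, prev):
        return soft(policy.probs(state, prev)[None, :], np.array([prev]))[0]

    def probs_batch(states, prevs):
        return soft(policy.probs_batch(states, prevs), np.asarray(prevs, dtype=int))

    return Policy(policy.kind + "_soft", n, probs, probs_batch,
                  metadata={**policy.metadata, "eps": eps})


def knn_behaviour_policy(train_states, train_actions, k: int = 100,
                         alpha_s: float = 0.5, n_actions: int = 17) -> Policy:
    """Physician behaviour estimate by exact k-nearest-neighbour voting.

    pi_b(a | s) = (count of a among the k Euclidean-nearest training states
    + alpha_s) / (k + n_actions * alpha_s); alpha_s > 0 keeps every action's
    probability strictly positive, as the importance-sampling estimators
    require. States must be z-scored (the training-split statistics).
    """
    X = np.asarray(train_states, dtype=float)
    y = np.asarray(train_actions, dtype=int)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(X):
        raise ValueError(f"k={k} exceeds the {len(X)} training states")
    nn = NearestNeighbors(n_neighbors=k, algorithm="auto").fit(X)
    denom = k + n_actions * alpha_s

    def probs_batch(states, prevs):
        states = np.atleast_2d(np.asarray(states, dtype=float))
        _, idx = nn.kneighbors(states)
        counts = np.zeros((len(states), n_actions))
        for j in range(n_actions):
            counts[:, j] = (y[idx] == j).sum(axis=1)
        return (counts + alpha_s) / denom

    def probs(state, prev):
        return probs_batch(state[None, :], np.array([prev]))[0]

    return Policy("behaviour", n_actions, probs, probs_batch,
                  metadata={"k": k, "alpha_s": alpha_s, "n_train": len(X)})
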