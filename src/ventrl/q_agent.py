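"""Dueling double-deep Q-network trained offline with prioritised replay.

The network is a fully-connected trunk (3-5 hidden layers, 32/64/128 units)
feeding two linear heads: a scalar state value V(s) and per-action advantages
A(s, a), combined as Q = V + A - mean(A). Targets use the double-Q rule (the
online network selects the next action, the target network evaluates it) and
minibatches are drawn by proportional prioritised replay with importance
weighting. Everything is plain deterministic NumPy — single-threaded matmuls
with hand-written gradients and Adam — so identical seeds give identical
parameters and loss traces.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

ALLOWED_LAYERS = (3, 4, 5)
ALLOWED_WIDTHS = (32, 64, 128)


@dataclass(frozen=True)
class QNetworkSpec:
    n_hidden_layers: int = 3
    width: int = 64
    n_actions: int = 17
    activation: str = "relu"
    dueling: bool = True
    input_dim: int | None = None        # set when training starts
    prev_action_onehot: bool = False    # append a_{t-1} one-hot to the input

    def __post_init__(self):
        if self.n_hidden_layers not in ALLOWED_LAYERS:
            raise ValueError(f"hidden layers must be one of {ALLOWED_LAYERS}")
        if self.width not in ALLOWED_WIDTHS:
            raise ValueError(f"layer width must be one of {ALLOWED_WIDTHS}")
        if not self.dueling:
            raise ValueError("this architecture is always dueling")

    @property
    def net_input_dim(self) -> int:
        d = self.input_dim or 0
        return d + (self.n_actions if self.prev_action_onehot else 0)


@dataclass(frozen=True)
class TrainConfig:
    gamma: float = 0.99
    lr: float = 1e-3
    lr_schedule: str = "step"           # step | plateau
    lr_step_size: int = 1000            # updates between step decays
    lr_decay: float = 0.5
    plateau_patience: int = 300         # updates without improvement
    plateau_factor: float = 0.5
    batch_size: int = 64
    target_sync: int = 250              # updates between target-network syncs
    replay_capacity: int = 100_000
    alpha: float = 0.6                  # priority exponent
    beta0: float = 0.4                  # importance exponent, annealed to 1
    eps_priority: float = 1e-3
    grad_clip: float = 10.0
    n_updates: int = 2000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must lie in (0, 1]")
        for name in ("lr", "batch_size", "target_sync", "replay_capacity",
                     "eps_priority", "n_updates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.alpha < 0 or not 0 <= self.beta0 <= 1:
            raise ValueError("alpha >= 0 and beta0 in [0, 1] required")


# ---------------------------------------------------------------------------
# dueling combination and double-Q target (exact, array-level primitives)
# ---------------------------------------------------------------------------

def dueling_combine(V, A):
    """Q(s, a) = V + A(a) - mean_a' A(a'); V (B,) or scalar, A (B, n) or (n,)."""
    A = np.asarray(A, dtype=float)
    V = np.asarray(V, dtype=float)
    if A.ndim == 1:
        return V + A - A.mean()
    return V[:, None] + A - A.mean(axis=1, keepdims=True)


def double_q_target(r, q_next_online, q_next_target, terminal, gamma,
                    allowed=None):
    """r + gamma * Q_target(s', argmax_a Q_online(s', a)), 0 bootstrap at
    terminals; argmax ties broken toward the lowest action index.

    `allowed` (optional boolean mask per row) restricts the argmax to a
    subset of actions — used for restricted-policy backups, where
    bootstrapping only over actions reachable from the logged context also
    tames overestimation of actions the data never covers.
    """
    r = np.asarray(r, dtype=float)
    terminal = np.asarray(terminal, dtype=bool)
    qo = np.atleast_2d(np.asarray(q_next_online, dtype=float))
    qt = np.atleast_2d(np.asarray(q_next_target, dtype=float))
    if allowed is not None:
        qo = np.where(np.atleast_2d(allowed), qo, -np.inf)
    a_star = np.argmax(qo, axis=1)          # first occurrence = lowest index
    boot = qt[np.arange(len(qt)), a_star]
    out = r + gamma * np.where(terminal, 0.0, boot)
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# prioritised replay
# ---------------------------------------------------------------------------

def per_sample(priorities, alpha, beta, batch_size, rng):
    """Proportional prioritised sampling with replacement.

    P(i) proportional to p_i^alpha; importance weights (N * P(i))^-beta,
    normalised by the batch maximum. Returns (indices, weights).
    """
    p = np.asarray(priorities, dtype=float)
    if p.size == 0:
        raise ValueError("replay buffer is empty")
    if np.any(p <= 0):
        raise ValueError("priorities must be strictly positive")
    probs = p ** alpha
    probs = probs / probs.sum()
    idx = rng.choice(p.size, size=batch_size, replace=True, p=probs)
    w = (p.size * probs[idx]) ** (-beta)
    w = w / w.max()
    return idx, w


class ReplayBuffer:
    """Offline transition store with per-transition priorities."""

    def __init__(self, states, actions, rewards, next_states, terminals,
                 capacity=None, eps=1e-3):
        n = len(actions)
        if capacity is not None and n > capacity:
            states, actions, rewards = states[:capacity], actions[:capacity], rewards[:capacity]
            next_states, terminals = next_states[:capacity], terminals[:capacity]
            n = capacity
        self.s = np.asarray(states, dtype=float)
        self.a = np.asarray(actions, dtype=int)
        self.r = np.asarray(rewards, dtype=float)
        self.s2 = np.asarray(next_states, dtype=float)
        self.term = np.asarray(terminals, dtype=bool)
        self.priorities = np.ones(n)
        self.eps = eps

    def __len__(self):
        return len(self.a)

    def update_priorities(self, idx, td_errors):
        self.priorities[idx] = np.abs(td_errors) + self.eps


def transitions_from_trajectories(trajectories, rewards):
    """Flatten shaped trajectories into (s, a, r, s', terminal, a_prev)
    arrays (a_prev is the action context of s', i.e. the logged action).

    The terminal flag marks each admission's last step; its s' is a copy of
    s (never bootstrapped from).
    """
    S, A, R, S2, T = [], [], [], [], []
    for traj, r in zip(trajectories, rewards):
        X = traj.states
        n = traj.T
        if len(r) != n:
            raise ValueError("reward sequence length must equal T")
        S.append(X)
        A.append(traj.actions)
        R.append(np.asarray(r, dtype=float))
        nxt = np.vstack([X[1:], X[-1:]])
        S2.append(nxt)
        t = np.zeros(n, dtype=bool)
        t[-1] = True
        T.append(t)
    return (np.vstack(S), np.concatenate(A), np.concatenate(R), np.vstack(S2),
            np.concatenate(T))


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class _DuelingMLP:
    """Parameters + forward/backward of the dueling network."""

    def __init__(self, spec: QNetworkSpec, rng):
        d = spec.net_input_dim
        if d <= 0:
            raise ValueError("input_dim must be set on the spec before init")
        w = spec.width
        dims = [d] + [w] * spec.n_hidden_layers
        self.spec = spec
        self.W, self.b = [], []
        for din, dout in zip(dims[:-1], dims[1:]):
            self.W.append(rng.normal(0, np.sqrt(2.0 / din), size=(din, dout)))
            self.b.append(np.zeros(dout))
        self.Wv = rng.normal(0, np.sqrt(2.0 / w), size=(w, 1))
        self.bv = np.zeros(1)
        self.Wa = rng.normal(0, np.sqrt(2.0 / w), size=(w, spec.n_actions))
        self.ba = np.zeros(spec.n_actions)

    def params(self):
        return self.W + self.b + [self.Wv, self.bv, self.Wa, self.ba]

    def set_params(self, params):
        k = len(self.W)
        self.W = [p.copy() for p in params[:k]]
        self.b = [p.copy() for p in params[k:2 * k]]
        self.Wv, self.bv, self.Wa, self.ba = (p.copy() for p in params[2 * k:])

    def copy(self):
        import copy as _c
        new = _c.copy(self)
        new.W = [w.copy() for w in self.W]
        new.b = [b.copy() for b in self.b]
        new.Wv, new.bv = self.Wv.copy(), self.bv.copy()
        new.Wa, new.ba = self.Wa.copy(), self.ba.copy()
        return new

    def forward(self, X, want_cache=False):
        H = [np.asarray(X, dtype=float)]
        h = H[0]
        for W, b in zip(self.W, self.b):
            h = np.maximum(h @ W + b, 0.0)
            H.append(h)
        V = (h @ self.Wv + self.bv)[:, 0]
        A = h @ self.Wa + self.ba
        Q = dueling_combine(V, A)
        if want_cache:
            return Q, (H, V, A)
        return Q

    def backward(self, cache, dQ):
        """Gradients of a scalar loss given dL/dQ (B, n_actions)."""
        H, V, A = cache
        h = H[-1]
        dV = dQ.sum(axis=1)                                   # (B,)
        # the -mean(A) term makes dL/dA = dQ - (1/n_actions) * sum_a dQ
        dA = dQ - dQ.sum(axis=1, keepdims=True) / self.spec.n_actions
        gWv = h.T @ dV[:, None]
        gbv = dV.sum(keepdims=True)
        gWa = h.T @ dA
        gba = dA.sum(axis=0)
        dh = dV[:, None] @ self.Wv.T + dA @ self.Wa.T
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        for k in range(len(self.W) - 1, -1, -1):
            dh = dh * (H[k + 1] > 0)
            gW[k] = H[k].T @ dh
            gb[k] = dh.sum(axis=0)
            dh = dh @ self.W[k].T
        return gW + gb + [gWv, gbv, gWa, gba]


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _clip_grads(grads, max_norm):
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
    if total > max_norm > 0:
        scale = max_norm / (total + 1e-12)
        grads = [g * scale for g in grads]
    return grads


# ---------------------------------------------------------------------------
# trained-model container
# ---------------------------------------------------------------------------

@dataclass
class QModel:
    """A trained Q(s, a) evaluator with its provenance metadata."""
    spec: QNetworkSpec
    net: _DuelingMLP
    train_config: TrainConfig | None = None
    reward_version: str | None = None
    loss_trace: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def evaluate(self, states) -> np.ndarray:
        X = np.asarray(states, dtype=float)
        one = X.ndim == 1
        if one:
            X = X[None, :]
        Q = self.net.forward(X)
        return Q[0] if one else Q

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for p in self.net.params():
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()[:16]

    def save(self, path) -> None:
        params = self.net.params()
        np.savez(path, *params)
        side = {
            "spec": dataclasses.asdict(self.spec),
            "train_config": dataclasses.asdict(self.train_config) if self.train_config else None,
            "reward_version": self.reward_version,
            "content_hash": self.content_hash(),
            "metadata": self.metadata,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(side, fh, indent=2)

    @classmethod
    def load(cls, path) -> "QModel":
        with open(str(path) + ".json") as fh:
            side = json.load(fh)
        spec = QNetworkSpec(**side["spec"])
        net = _DuelingMLP(spec, np.random.default_rng(0))
        with np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz") as z:
            params = [z[k] for k in z.files]
        net.set_params(params)
        tc = TrainConfig(**side["train_config"]) if side["train_config"] else None
        return cls(spec, net, tc, side["reward_version"], None, side.get("metadata", {}))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_q(trajectories, rewards, spec: QNetworkSpec, cfg: TrainConfig,
            reward_version: str | None = None,
            backup_mask_by_prev: np.ndarray | None = None) -> QModel:
    """Offline dueling double-DQN training on shaped trajectories.

    Fills the replay buffer with every (s, a, r, s', terminal) transition,
    then runs cfg.n_updates prioritised minibatch updates against a
    periodically-synced target network. Priorities track |TD error| + eps.
    Raises on NaN loss with a diagnostic.

    backup_mask_by_prev, an (n_actions, n_actions) boolean lookup of allowed
    next actions given the logged action, restricts the bootstrap argmax
    (restricted-policy backup; also curbs value overestimation for actions
    the logged data never supports).
    """
    S, A, R, S2, T = transitions_from_trajectories(trajectories, rewards)
    return train_q_transitions(S, A, R, S2, T, spec, cfg, reward_version,
                               backup_mask_by_prev)


def train_q_transitions(S, A, R, S2, T, spec: QNetworkSpec, cfg: TrainConfig,
                        reward_version: str | None = None,
                        backup_mask_by_prev: np.ndarray | None = None) -> QModel:
    if spec.input_dim is None:
        spec = dataclasses.replace(spec, input_dim=S.shape[1])
    rng = np.random.default_rng(cfg.seed)
    net = _DuelingMLP(spec, rng)
    target = net.copy()
    buf = ReplayBuffer(S, A, R, S2, T, cfg.replay_capacity, cfg.eps_priority)
    opt = _Adam(net.params(), cfg.lr)
    losses = np.empty(cfg.n_updates)
    best_loss, stale = np.inf, 0
    n_act = spec.n_actions

    for u in range(cfg.n_updates):
        beta = cfg.beta0 + (1.0 - cfg.beta0) * (u / max(cfg.n_updates - 1, 1))
        idx, w = per_sample(buf.priorities, cfg.alpha, beta, cfg.batch_size, rng)
        s, a, r = buf.s[idx], buf.a[idx], buf.r[idx]
        s2, term = buf.s2[idx], buf.term[idx]

        q2o = net.forward(s2)
        q2t = target.forward(s2)
        allowed = (backup_mask_by_prev[buf.a[idx]]
                   if backup_mask_by_prev is not None else None)
        y = double_q_target(r, q2o, q2t, term, cfg.gamma, allowed)

        Q, cache = net.forward(s, want_cache=True)
        q_sa = Q[np.arange(len(a)), a]
        td = q_sa - y
        loss = float(np.mean(w * td * td) / 2.0)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"NaN/inf loss at update {u}: |td|max={np.abs(td).max():g}, "
                f"lr={opt.lr:g} — training aborted")
        losses[u] = loss

        dQ = np.zeros_like(Q)
        dQ[np.arange(len(a)), a] = w * td / len(a)
        grads = net.backward(cache, dQ)
        grads = _clip_grads(grads, cfg.grad_clip)
        opt.step(net.params(), grads)
        buf.update_priorities(idx, td)

        if cfg.lr_schedule == "step":
            if (u + 1) % cfg.lr_step_size == 0:
                opt.lr *= cfg.lr_decay
        elif cfg.lr_schedule == "plateau":
            if loss < best_loss - 1e-6:
                best_loss, stale = loss, 0
            else:
                stale += 1
                if stale >= cfg.plateau_patience:
                    opt.lr *= cfg.plateau_factor
                    stale = 0

        if (u + 1) % cfg.target_sync == 0:
            target = net.copy()

    return QModel(spec, net, cfg, reward_version, losses,
                  metadata={"n_transitions": len(buf), "n_actions": n_act})
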