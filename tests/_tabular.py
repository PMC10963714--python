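"""Tabular MDP utilities: exact dynamic-programming oracles and trajectory
simulation, independent of the estimators they are used to check."""
from __future__ import annotations

import numpy as np


class TabularMDP:
    """Finite MDP with explicit transition tensor P[s, a, s'] and reward
    R[s, a]; episodes end on entering a terminal state or at max_steps."""

    def __init__(self, P, R, terminal, init_dist, max_steps=25):
        self.P = np.asarray(P, dtype=float)
        self.R = np.asarray(R, dtype=float)
        self.terminal = np.asarray(terminal, dtype=bool)
        self.init = np.asarray(init_dist, dtype=float)
        self.max_steps = max_steps
        self.S, self.A = self.R.shape

    # ---- exact oracles -------------------------------------------------
    def value_iteration(self, gamma, tol=1e-12, max_iter=100_000):
        Q = np.zeros((self.S, self.A))
        for _ in range(max_iter):
            V = Q.max(axis=1) * (~self.terminal)
            Qn = self.R + gamma * self.P @ V
            Qn[self.terminal] = 0.0
            if np.abs(Qn - Q).max() < tol:
                return Qn
            Q = Qn
        return Q

    def policy_q(self, pi, gamma, tol=1e-12, max_iter=100_000):
        """Q^pi for a stochastic policy pi[s, a] (exact policy evaluation)."""
        pi = np.asarray(pi, dtype=float)
        Q = np.zeros((self.S, self.A))
        for _ in range(max_iter):
            V = (pi * Q).sum(axis=1) * (~self.terminal)
            Qn = self.R + gamma * self.P @ V
            Qn[self.terminal] = 0.0
            if np.abs(Qn - Q).max() < tol:
                return Qn
            Q = Qn
        return Q

    def policy_value(self, pi, gamma):
        """Expected discounted return of pi from the initial distribution.

        Episode truncation at max_steps is accounted for exactly by rolling
        the state-occupancy vector forward step by step.
        """
        pi = np.asarray(pi, dtype=float)
        occ = self.init.copy()
        total = 0.0
        for t in range(self.max_steps):
            live = occ * (~self.terminal)
            total += gamma ** t * float((live[:, None] * pi * self.R).sum())
            step = np.einsum("s,sa,sat->t", live, pi, self.P)
            occ = step
        return total

    # ---- simulation ----------------------------------------------------
    def simulate(self, pi, n_episodes, rng):
        """Episodes under pi: list of (states, actions, rewards) arrays."""
        pi = np.asarray(pi, dtype=float)
        out = []
        for _ in range(n_episodes):
            s = rng.choice(self.S, p=self.init)
            ss, aa, rr = [], [], []
            for _ in range(self.max_steps):
                if self.terminal[s]:
                    break
                a = rng.choice(self.A, p=pi[s])
                ss.append(s)
                aa.append(a)
                rr.append(self.R[s, a])
                s = rng.choice(self.S, p=self.P[s, a])
            if not ss:     # started terminal; re-draw
                continue
            out.append((np.array(ss), np.array(aa), np.array(rr, dtype=float)))
        return out


def chain_mdp(n_states=5, step_cost=-0.01, goal_reward=1.0):
    """Deterministic corridor: action 1 moves right, action 0 moves left
    (stuck at the wall); entering the last state pays the goal reward and
    terminates. Optimal policy: always right."""
    S, A = n_states, 2
    P = np.zeros((S, A, S))
    R = np.full((S, A), step_cost)
    terminal = np.zeros(S, dtype=bool)
    terminal[-1] = True
    for s in range(S - 1):
        P[s, 0, max(s - 1, 0)] = 1.0
        P[s, 1, s + 1] = 1.0
        if s + 1 == S - 1:
            R[s, 1] = goal_reward
    P[S - 1, :, S - 1] = 1.0
    init = np.zeros(S)
    init[0] = 1.0
    return TabularMDP(P, R, terminal, init, max_steps=3 * n_states)


def random_mdp(n_states, n_actions, rng, max_steps=20):
    """A small ergodic MDP with one absorbing terminal state."""
    S = n_states
    P = rng.dirichlet(np.ones(S), size=(S, n_actions))
    # send a slice of every transition to the terminal state S-1
    term_mass = 0.08
    P = P * (1 - term_mass)
    P[:, :, S - 1] += term_mass
    P[S - 1, :, :] = 0.0
    P[S - 1, :, S - 1] = 1.0
    R = rng.normal(0, 1, size=(S, n_actions))
    R[S - 1, :] = 0.0
    terminal = np.zeros(S, dtype=bool)
    terminal[S - 1] = True
    init = np.ones(S) / (S - 1)
    init[S - 1] = 0.0
    return TabularMDP(P, R, terminal, init, max_steps=max_steps)


def episodes_to_ope_dataset(episodes, pi_b, pi_e, q=None, gamma=None):
    """Pack simulated tabular episodes into the padded OPEDataset arrays.

    q (S, A), if given, supplies the model values q_hat and
    v_hat(s) = sum_a pi_e(a|s) q(s, a).
    """
    from ventrl.ope_engine import OPEDataset
    pi_b = np.asarray(pi_b, dtype=float)
    pi_e = np.asarray(pi_e, dtype=float)
    n = len(episodes)
    lengths = np.array([len(a) for _, a, _ in episodes])
    Tmax = int(lengths.max())
    Pb = np.ones((n, Tmax))
    Pe = np.ones((n, Tmax))
    R = np.zeros((n, Tmax))
    Qh = np.zeros((n, Tmax))
    Vh = np.zeros((n, Tmax))
    for i, (ss, aa, rr) in enumerate(episodes):
        T = len(aa)
        Pb[i, :T] = pi_b[ss, aa]
        Pe[i, :T] = pi_e[ss, aa]
        R[i, :T] = rr
        if q is not None:
            Qh[i, :T] = q[ss, aa]
            Vh[i, :T] = (pi_e[ss] * q[ss]).sum(axis=1)
    return OPEDataset(Pb, Pe, R, Qh, Vh, lengths)
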