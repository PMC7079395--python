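"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles — scalar
closed forms, explicit case matrices, exhaustive enumeration over hidden
states and truncated power series — and never calls the implementation
paths it is used to check.
"""

import math
from itertools import product

import numpy as np
from scipy import integrate, stats

MISSING = 3


def sse_prob(i, j, pi, R, dt):
    """Scalar closed-form transition probability of the three-state SSE process."""
    e = math.exp(-R * dt)
    return (1.0 - e) * pi[j] + (e if i == j else 0.0)


def series_expm(Q, dt, terms=80):
    """Truncated power series for expm(Q*dt)."""
    A = np.asarray(Q, dtype=float) * dt
    out = np.eye(A.shape[0])
    term = np.eye(A.shape[0])
    for k in range(1, terms):
        term = term @ A / k
        out = out + term
    return out


def iwe_case_matrix(pi_old, pi_new, tol=1e-13):
    """The two w.l.o.g. IWE case matrices, assembled by explicit case analysis."""
    pi_old = np.asarray(pi_old, dtype=float)
    pi_new = np.asarray(pi_new, dtype=float)
    d = pi_new - pi_old
    inc = [s for s in range(3) if d[s] > tol]
    dec = [s for s in range(3) if d[s] < -tol]
    M = np.eye(3)
    if not inc:
        return M
    if len(inc) == 1:
        g = inc[0]
        for a in dec:
            M[a, a] = pi_new[a] / pi_old[a]
            M[a, g] = (pi_old[a] - pi_new[a]) / pi_old[a]
    else:
        assert len(dec) == 1
        a = dec[0]
        M[a, a] = pi_new[a] / pi_old[a]
        for g in inc:
            M[a, g] = (pi_new[g] - pi_old[g]) / pi_old[a]
    return M


def branch_prob(z_par, z_child, events, pi_start, R, length):
    """Transition probability across a branch, enumerating states at each IWE."""

    def rec(state, idx, t_prev, pi):
        if idx == len(events):
            return sse_prob(state, z_child, pi, R, length - t_prev)
        pos, tri = events[idx]
        M = iwe_case_matrix(pi, tri)
        total = 0.0
        for before in range(3):
            p1 = sse_prob(state, before, pi, R, pos - t_prev)
            if p1 == 0.0:
                continue
            for after in range(3):
                if M[before, after] > 0.0:
                    total += p1 * M[before, after] * rec(after, idx + 1, pos, tri)
        return total

    return rec(z_par, 0, 0.0, pi_start)


def _triples_in_force(tree, config):
    out = {}
    out[tree.root] = np.asarray(config.root_triple, dtype=float)
    for node in tree.preorder:
        node = int(node)
        if node == tree.root:
            continue
        evs = config.events_on(node)
        out[node] = np.asarray(evs[-1].triple) if evs else out[int(tree.parent[node])]
    return out


def site_loglik_bruteforce(tree, config, theta, site_states):
    """Exhaustive site likelihood: sum over rate categories and hidden node states."""
    from iwesse.model_core import discretize_gamma

    rates = np.concatenate([[0.0], discretize_gamma(theta.alpha)])
    weights = np.concatenate([[theta.r], np.full(3, (1.0 - theta.r) / 3.0)])
    in_force = _triples_in_force(tree, config)
    hidden = [n for n in range(tree.n_nodes) if site_states[n] == MISSING]
    total = 0.0
    for x in range(4):
        R = float(rates[x])
        if weights[x] == 0.0:
            continue
        cat_sum = 0.0
        for assignment in product(range(3), repeat=len(hidden)):
            z = np.array(site_states, dtype=int)
            z[hidden] = assignment
            p = in_force[tree.root][z[tree.root]]
            for node in tree.preorder:
                node = int(node)
                if node == tree.root:
                    continue
                par = int(tree.parent[node])
                evs = [(e.position, np.asarray(e.triple)) for e in config.events_on(node)]
                p *= branch_prob(
                    z[par], z[node], evs, in_force[par], R, float(tree.lengths[node])
                )
                if p == 0.0:
                    break
            cat_sum += p
        total += weights[x] * cat_sum
    return math.log(total) if total > 0 else -math.inf


def gamma_slice_means(alpha, K=3):
    """Conditional means of Gamma(alpha, mean 1) on K equal-probability slices
    via numerical integration."""
    dist = stats.gamma(alpha, scale=1.0 / alpha)
    bounds = dist.ppf(np.arange(K + 1) / K)
    means = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        val, _ = integrate.quad(lambda x: x * dist.pdf(x), a, b, limit=200)
        means.append(val * K)
    return np.asarray(means)
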