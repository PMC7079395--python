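"""Numba sweep kernel for the reversible-jump MCMC sampler.

All sampler state lives in flat numpy arrays so the whole sweep loop runs in
nopython mode.  IWE configurations are stored in fixed-capacity per-branch
arrays; when a birth move would overflow the capacity the kernel returns
early with a resize status and the Python wrapper grows the arrays and
resumes (the interrupted sweep is restarted, which is harmless since every
move individually preserves the target distribution).

Layout conventions
------------------
* nodes are indexed 0..n_nodes-1; a branch is identified by its child node;
* ``ev_count[i, b]`` is island ``i``'s IWE count on branch ``b``; positions
  ``ev_pos[i, b, :count]`` are sorted offsets from the parent node and
  ``ev_tri[i, b, k, :]`` the associated equilibrium triples;
* rate categories are ``rates[0] == 0`` (invariant) plus three
  discretized-gamma values; ``weights = (r, (1-r)/3, ...)``;
* the observed data enter as per-island *site patterns*: unique site columns
  with multiplicities (the data are fixed during a run).

Performance structure: for islands whose every node is observed the site
likelihood factorizes over branches given the rate category, so the kernel
caches, per island, the per-branch per-category transition-probability
factor of every pattern.  Moves that touch a single branch without changing
the equilibrium triple in force below it (branch-length updates, and event
birth/death/triple updates that do not alter the branch's last event) then
recompose one branch instead of the whole tree, and invariant-fraction
updates reuse the factors entirely.  Islands with unobserved entries go
through full pruning each time.

The likelihood matches :func:`iwesse.likelihood.island_log_likelihood`; the
test suite asserts agreement to 1e-9.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ._special import discretize_gamma_rates

STATUS_OK = 0
STATUS_RESIZE = 1

_MISSING = 3
_NEG_INF = -np.inf


@njit(cache=True)
def _sse_fill(P, pi, R, dt):
    e = math.exp(-R * dt)
    for a in range(3):
        for b in range(3):
            P[a, b] = (1.0 - e) * pi[b]
        P[a, a] += e


@njit(cache=True)
def _iwe_fill(M, pi_old, pi_new):
    total_gain = 0.0
    for s in range(3):
        g = pi_new[s] - pi_old[s]
        if g > 0.0:
            total_gain += g
    for a in range(3):
        for b in range(3):
            M[a, b] = 1.0 if a == b else 0.0
    if total_gain <= 0.0:
        return
    for a in range(3):
        if pi_new[a] < pi_old[a]:
            move = (pi_old[a] - pi_new[a]) / pi_old[a]
            M[a, a] = pi_new[a] / pi_old[a]
            for b in range(3):
                g = pi_new[b] - pi_old[b]
                if b != a and g > 0.0:
                    M[a, b] = move * (g / total_gain)


@njit(cache=True)
def _matmul3(A, B, C):
    for a in range(3):
        for b in range(3):
            s = 0.0
            for k in range(3):
                s += A[a, k] * B[k, b]
            C[a, b] = s


@njit(cache=True)
def _copy3x3(src, dst):
    for a in range(3):
        for b in range(3):
            dst[a, b] = src[a, b]


@njit(cache=True)
def _compose_branch(i, node, trip_par, l, ev_count, ev_pos, ev_tri, rates,
                    comp_node, A, B, Ms):
    """Fill ``comp_node[x]`` with the composed branch transition matrix per category."""
    h = ev_count[i, node]
    ncat = rates.shape[0]
    for k in range(h):
        if k == 0:
            _iwe_fill(Ms[0], trip_par, ev_tri[i, node, 0])
        else:
            _iwe_fill(Ms[k], ev_tri[i, node, k - 1], ev_tri[i, node, k])
    for x in range(ncat):
        R = rates[x]
        if R == 0.0:
            # Invariant sites: SSE segments are identities, only IWEs act.
            if h == 0:
                for a in range(3):
                    for b in range(3):
                        comp_node[x, a, b] = 1.0 if a == b else 0.0
            else:
                _copy3x3(Ms[0], comp_node[x])
                for k in range(1, h):
                    _matmul3(comp_node[x], Ms[k], B)
                    _copy3x3(B, comp_node[x])
            continue
        d0 = ev_pos[i, node, 0] if h > 0 else l
        _sse_fill(comp_node[x], trip_par, R, d0)
        for k in range(h):
            d = (ev_pos[i, node, k + 1] if k + 1 < h else l) - ev_pos[i, node, k]
            _matmul3(comp_node[x], Ms[k], B)
            _sse_fill(A, ev_tri[i, node, k], R, d)
            _matmul3(B, A, comp_node[x])


@njit(cache=True)
def _island_full(
    i,
    preorder,
    parent,
    root,
    children_off,
    children_flat,
    blens,
    states,
    poffsets,
    island_fast,
    pmult,
    root_triples,
    ev_count,
    ev_pos,
    ev_tri,
    rates,
    weights,
    # caches written for fast-path islands (proposal side)
    fprop,  # (n_isl, n_nodes, ncat, pmax)
    baseprop,  # (n_isl, pmax)
    tripprop,  # (n_isl, n_nodes, 3)
    # scratch
    comp,  # (n_nodes, ncat, 3, 3)
    A,
    B,
    Ms,
    w,
    sc,
    terms,
):
    """Full island log-likelihood; fills the per-branch factor caches."""
    p0 = poffsets[i]
    p1 = poffsets[i + 1]
    if p1 == p0:
        return 0.0
    n_nodes = parent.shape[0]
    ncat = rates.shape[0]
    trip = tripprop[i]

    for idx in range(n_nodes):
        node = preorder[idx]
        if node == root:
            for s in range(3):
                trip[node, s] = root_triples[i, s]
            continue
        par = parent[node]
        _compose_branch(i, node, trip[par], blens[node], ev_count, ev_pos, ev_tri,
                        rates, comp[node], A, B, Ms)
        h = ev_count[i, node]
        if h > 0:
            for s in range(3):
                trip[node, s] = ev_tri[i, node, h - 1, s]
        else:
            for s in range(3):
                trip[node, s] = trip[par, s]

    if island_fast[i] == 1:
        ll = 0.0
        for pat in range(p0, p1):
            j = pat - p0
            baseprop[i, j] = root_triples[i, states[root, pat]]
            tot = 0.0
            for x in range(ncat):
                p = baseprop[i, j]
                for idx in range(n_nodes):
                    node = preorder[idx]
                    if node == root:
                        continue
                    f = comp[node, x, states[parent[node], pat], states[node, pat]]
                    fprop[i, node, x, j] = f
                    p *= f
                tot += weights[x] * p
            if tot <= 0.0:
                return _NEG_INF
            ll += pmult[pat] * math.log(tot)
        return ll

    # General pruning with per-node rescaling (unobserved entries present).
    ll = 0.0
    for pat in range(p0, p1):
        for x in range(ncat):
            for idx in range(n_nodes - 1, -1, -1):
                node = preorder[idx]
                st = states[node, pat]
                for a in range(3):
                    w[node, a] = 1.0 if (st == _MISSING or st == a) else 0.0
                sc[node] = 0.0
                for ci in range(children_off[node], children_off[node + 1]):
                    c = children_flat[ci]
                    for a in range(3):
                        y = 0.0
                        for b in range(3):
                            y += comp[c, x, a, b] * w[c, b]
                        A[0, a] = y
                    for a in range(3):
                        w[node, a] *= A[0, a]
                    sc[node] += sc[c]
                mx = w[node, 0]
                if w[node, 1] > mx:
                    mx = w[node, 1]
                if w[node, 2] > mx:
                    mx = w[node, 2]
                if mx > 0.0:
                    for a in range(3):
                        w[node, a] /= mx
                    sc[node] += math.log(mx)
                else:
                    sc[node] = _NEG_INF
            L = 0.0
            for z in range(3):
                L += root_triples[i, z] * w[root, z]
            if L <= 0.0 or sc[root] == _NEG_INF:
                terms[x] = _NEG_INF
            else:
                terms[x] = math.log(weights[x]) if weights[x] > 0.0 else _NEG_INF
                if terms[x] > _NEG_INF:
                    terms[x] += math.log(L) + sc[root]
        mx = terms[0]
        for x in range(1, ncat):
            if terms[x] > mx:
                mx = terms[x]
        if mx == _NEG_INF:
            return _NEG_INF
        tot = 0.0
        for x in range(ncat):
            tot += math.exp(terms[x] - mx)
        ll += pmult[pat] * (mx + math.log(tot))
    return ll


@njit(cache=True)
def _island_only_branch(
    i,
    bnode,
    preorder,
    parent,
    root,
    blens,
    states,
    poffsets,
    pmult,
    root_triples,
    ev_count,
    ev_pos,
    ev_tri,
    rates,
    weights,
    fcache,
    base,
    tripc,
    fprop,
    comp,
    A,
    B,
    Ms,
):
    """Fast-path likelihood when only branch ``bnode`` changed.

    Requires that the triple in force at the branch's parent and child are
    unchanged (callers guarantee this) and that ``fcache``/``base`` are
    current for this island.  Writes the branch's new factors to
    ``fprop[i, bnode]``.
    """
    p0 = poffsets[i]
    p1 = poffsets[i + 1]
    if p1 == p0:
        return 0.0
    n_nodes = parent.shape[0]
    ncat = rates.shape[0]
    par = parent[bnode]
    _compose_branch(i, bnode, tripc[i, par], blens[bnode], ev_count, ev_pos, ev_tri,
                    rates, comp[bnode], A, B, Ms)
    ll = 0.0
    for pat in range(p0, p1):
        j = pat - p0
        tot = 0.0
        for x in range(ncat):
            fprop[i, bnode, x, j] = comp[
                bnode, x, states[par, pat], states[bnode, pat]
            ]
            p = base[i, j]
            for idx in range(n_nodes):
                node = preorder[idx]
                if node == root:
                    continue
                if node == bnode:
                    p *= fprop[i, node, x, j]
                else:
                    p *= fcache[i, node, x, j]
            tot += weights[x] * p
        if tot <= 0.0:
            return _NEG_INF
        ll += pmult[pat] * math.log(tot)
    return ll


@njit(cache=True)
def _island_from_cache(i, preorder, root, poffsets, pmult, weights, fcache, base, parent):
    """Likelihood from cached factors (used when only the mixture weights move)."""
    p0 = poffsets[i]
    p1 = poffsets[i + 1]
    if p1 == p0:
        return 0.0
    n_nodes = parent.shape[0]
    ncat = weights.shape[0]
    ll = 0.0
    for pat in range(p0, p1):
        j = pat - p0
        tot = 0.0
        for x in range(ncat):
            p = base[i, j]
            for idx in range(n_nodes):
                node = preorder[idx]
                if node != root:
                    p *= fcache[i, node, x, j]
            tot += weights[x] * p
        if tot <= 0.0:
            return _NEG_INF
        ll += pmult[pat] * math.log(tot)
    return ll


@njit(cache=True)
def _dirichlet3(out):
    for s in range(3):
        u = np.random.random()
        while u <= 0.0:
            u = np.random.random()
        out[s] = -math.log(u)
    t = out[0] + out[1] + out[2]
    for s in range(3):
        out[s] /= t


@njit(cache=True)
def _norm_lp(x, m, s):
    d = (x - m) / s
    return -0.5 * d * d


@njit(cache=True)
def run_sweeps(
    seed,
    n_sweeps,
    start_sweep,
    record_from,
    thin,
    # tree / data (read-only)
    preorder,
    parent,
    root,
    children_off,
    children_flat,
    branch_nodes,
    states,
    poffsets,
    island_fast,
    pmult,
    # sampler state (mutated in place)
    blens,
    scalars,  # [r, log_alpha, log_mu]
    root_triples,
    ev_count,
    ev_pos,
    ev_tri,
    island_ll,
    rates,
    weights,
    # configuration
    priors,  # [m_l, s_l, m_a, s_a, m_mu, s_mu]
    prop,  # [len_w1, len_s1, len_s2, r_step, a_step, mu_step]
    flags,  # [null_mode, do_iwe, do_freq, do_lengths, do_r, do_alpha, do_mu, lik_on]
    # outputs
    rec_ll,
    rec_r,
    rec_alpha,
    rec_mu,
    rec_blens,
    rec_counts,
    rec_islcount,
):
    np.random.seed(seed)
    n_isl = poffsets.shape[0] - 1
    n_branches = branch_nodes.shape[0]
    n_nodes = parent.shape[0]
    ncat = rates.shape[0]
    maxev = ev_pos.shape[2]
    pmax = 0
    for i in range(n_isl):
        if poffsets[i + 1] - poffsets[i] > pmax:
            pmax = poffsets[i + 1] - poffsets[i]
    null_mode = flags[0] == 1
    do_iwe = flags[1] == 1 and not null_mode
    do_freq = flags[2] == 1
    do_lengths = flags[3] == 1
    do_r = flags[4] == 1
    do_alpha = flags[5] == 1
    do_mu = flags[6] == 1 and not null_mode
    lik_on = flags[7] == 1

    tri_new = np.empty(3)
    tri_old = np.empty(3)
    ll_prop = np.empty(n_isl)
    save_pos = np.empty((n_isl, maxev))
    new_rates = np.empty(3)
    comp = np.empty((n_nodes, ncat, 3, 3))
    A = np.empty((3, 3))
    B = np.empty((3, 3))
    Ms = np.empty((max(maxev, 1), 3, 3))
    wbuf = np.empty((n_nodes, 3))
    scbuf = np.empty(n_nodes)
    terms = np.empty(ncat)
    # Factor caches (current state) and proposal-side buffers.
    fcache = np.empty((n_isl, n_nodes, ncat, max(pmax, 1)))
    base = np.empty((n_isl, max(pmax, 1)))
    tripc = np.empty((n_isl, n_nodes, 3))
    fprop = np.empty((n_isl, n_nodes, ncat, max(pmax, 1)))
    baseprop = np.empty((n_isl, max(pmax, 1)))
    tripprop = np.empty((n_isl, n_nodes, 3))

    def _full(i):
        if not lik_on:
            return 0.0
        return _island_full(
            i, preorder, parent, root, children_off, children_flat, blens,
            states, poffsets, island_fast, pmult, root_triples,
            ev_count, ev_pos, ev_tri, rates, weights,
            fprop, baseprop, tripprop, comp, A, B, Ms, wbuf, scbuf, terms,
        )

    def _only_branch(i, b):
        if not lik_on:
            return 0.0
        if island_fast[i] != 1:
            return _full(i)
        return _island_only_branch(
            i, b, preorder, parent, root, blens, states, poffsets, pmult,
            root_triples, ev_count, ev_pos, ev_tri, rates, weights,
            fcache, base, tripc, fprop, comp, A, B, Ms,
        )

    def _adopt_full(i):
        if island_fast[i] == 1:
            np_ = poffsets[i + 1] - poffsets[i]
            for node in range(n_nodes):
                for x in range(ncat):
                    for j in range(np_):
                        fcache[i, node, x, j] = fprop[i, node, x, j]
                for s in range(3):
                    tripc[i, node, s] = tripprop[i, node, s]
            for j in range(np_):
                base[i, j] = baseprop[i, j]

    def _adopt_branch(i, b):
        if island_fast[i] == 1:
            np_ = poffsets[i + 1] - poffsets[i]
            for x in range(ncat):
                for j in range(np_):
                    fcache[i, b, x, j] = fprop[i, b, x, j]

    # Initialize likelihoods and caches from the current state.
    if lik_on:
        for i in range(n_isl):
            island_ll[i] = _full(i)
            _adopt_full(i)
    else:
        for i in range(n_isl):
            island_ll[i] = 0.0

    for sweep in range(start_sweep, n_sweeps):
        mu = math.exp(scalars[2]) if not null_mode else 0.0

        # -- per-island reversible-jump and frequency moves ---------------
        for i in range(n_isl):
            if do_iwe:
                b = branch_nodes[int(np.random.random() * n_branches) % n_branches]
                l = blens[b]
                n = ev_count[i, b]
                if np.random.random() < 0.5:
                    # birth
                    if n >= maxev:
                        return STATUS_RESIZE, sweep
                    if mu * l > 0.0:
                        pos = np.random.random() * l
                        _dirichlet3(tri_new)
                        k = 0
                        while k < n and ev_pos[i, b, k] < pos:
                            k += 1
                        for j in range(n, k, -1):
                            ev_pos[i, b, j] = ev_pos[i, b, j - 1]
                            for s in range(3):
                                ev_tri[i, b, j, s] = ev_tri[i, b, j - 1, s]
                        ev_pos[i, b, k] = pos
                        for s in range(3):
                            ev_tri[i, b, k, s] = tri_new[s]
                        ev_count[i, b] = n + 1
                        last = k == n  # new event is the branch's last: in-force triple below changes
                        ll_new = _full(i) if last else _only_branch(i, b)
                        log_acc = (ll_new - island_ll[i]) + math.log(mu * l) - math.log(n + 1.0)
                        if math.log(np.random.random() + 1e-320) < log_acc:
                            island_ll[i] = ll_new
                            if last:
                                _adopt_full(i)
                            else:
                                _adopt_branch(i, b)
                        else:
                            for j in range(k, n):
                                ev_pos[i, b, j] = ev_pos[i, b, j + 1]
                                for s in range(3):
                                    ev_tri[i, b, j, s] = ev_tri[i, b, j + 1, s]
                            ev_count[i, b] = n
                else:
                    # death
                    if n > 0 and mu * l > 0.0:
                        k = int(np.random.random() * n) % n
                        pos = ev_pos[i, b, k]
                        for s in range(3):
                            tri_old[s] = ev_tri[i, b, k, s]
                        for j in range(k, n - 1):
                            ev_pos[i, b, j] = ev_pos[i, b, j + 1]
                            for s in range(3):
                                ev_tri[i, b, j, s] = ev_tri[i, b, j + 1, s]
                        ev_count[i, b] = n - 1
                        last = k == n - 1
                        ll_new = _full(i) if last else _only_branch(i, b)
                        log_acc = (ll_new - island_ll[i]) + math.log(float(n)) - math.log(mu * l)
                        if math.log(np.random.random() + 1e-320) < log_acc:
                            island_ll[i] = ll_new
                            if last:
                                _adopt_full(i)
                            else:
                                _adopt_branch(i, b)
                        else:
                            for j in range(n - 1, k, -1):
                                ev_pos[i, b, j] = ev_pos[i, b, j - 1]
                                for s in range(3):
                                    ev_tri[i, b, j, s] = ev_tri[i, b, j - 1, s]
                            ev_pos[i, b, k] = pos
                            for s in range(3):
                                ev_tri[i, b, k, s] = tri_old[s]
                            ev_count[i, b] = n

            if do_freq:
                # Update the root triple or one event triple, proposed from
                # the Dirichlet(1,1,1) prior (prior and proposal cancel).
                m = 1
                for bi in range(n_branches):
                    m += ev_count[i, branch_nodes[bi]]
                j = int(np.random.random() * m) % m
                _dirichlet3(tri_new)
                if j == 0:
                    for s in range(3):
                        tri_old[s] = root_triples[i, s]
                        root_triples[i, s] = tri_new[s]
                    ll_new = _full(i)
                    if math.log(np.random.random() + 1e-320) < ll_new - island_ll[i]:
                        island_ll[i] = ll_new
                        _adopt_full(i)
                    else:
                        for s in range(3):
                            root_triples[i, s] = tri_old[s]
                else:
                    j -= 1
                    b = -1
                    k = -1
                    for bi in range(n_branches):
                        cnt = ev_count[i, branch_nodes[bi]]
                        if j < cnt:
                            b = branch_nodes[bi]
                            k = j
                            break
                        j -= cnt
                    for s in range(3):
                        tri_old[s] = ev_tri[i, b, k, s]
                        ev_tri[i, b, k, s] = tri_new[s]
                    last = k == ev_count[i, b] - 1
                    ll_new = _full(i) if last else _only_branch(i, b)
                    if math.log(np.random.random() + 1e-320) < ll_new - island_ll[i]:
                        island_ll[i] = ll_new
                        if last:
                            _adopt_full(i)
                        else:
                            _adopt_branch(i, b)
                    else:
                        for s in range(3):
                            ev_tri[i, b, k, s] = tri_old[s]

        # -- branch length moves ------------------------------------------
        if do_lengths:
            for bi in range(n_branches):
                b = branch_nodes[bi]
                l = blens[b]
                ell = math.log(l)
                scale = prop[1] if np.random.random() < prop[0] else prop[2]
                ell2 = ell + np.random.normal() * scale
                l2 = math.exp(ell2)
                n_tot = 0
                for i in range(n_isl):
                    n_tot += ev_count[i, b]
                # rescale event positions proportionally
                ratio = l2 / l
                for i in range(n_isl):
                    for k in range(ev_count[i, b]):
                        save_pos[i, k] = ev_pos[i, b, k]
                        ev_pos[i, b, k] = ev_pos[i, b, k] * ratio
                blens[b] = l2
                dll = 0.0
                for i in range(n_isl):
                    ll_prop[i] = _only_branch(i, b)
                    dll += ll_prop[i] - island_ll[i]
                log_acc = (
                    dll
                    + n_tot * (ell2 - ell)
                    - mu * n_isl * (l2 - l)
                    + _norm_lp(ell2, priors[0], priors[1])
                    - _norm_lp(ell, priors[0], priors[1])
                )
                if math.log(np.random.random() + 1e-320) < log_acc:
                    for i in range(n_isl):
                        island_ll[i] = ll_prop[i]
                        _adopt_branch(i, b)
                else:
                    blens[b] = l
                    for i in range(n_isl):
                        for k in range(ev_count[i, b]):
                            ev_pos[i, b, k] = save_pos[i, k]

        # -- global parameter moves ---------------------------------------
        if do_r:
            r = scalars[0]
            r2 = r + (2.0 * np.random.random() - 1.0) * prop[3]
            while r2 < 0.0 or r2 > 1.0:
                if r2 < 0.0:
                    r2 = -r2
                if r2 > 1.0:
                    r2 = 2.0 - r2
            w0 = weights[0]
            weights[0] = r2
            for x in range(1, ncat):
                weights[x] = (1.0 - r2) / (ncat - 1.0)
            dll = 0.0
            for i in range(n_isl):
                if not lik_on:
                    ll_prop[i] = 0.0
                elif island_fast[i] == 1:
                    ll_prop[i] = _island_from_cache(
                        i, preorder, root, poffsets, pmult, weights, fcache, base, parent
                    )
                else:
                    ll_prop[i] = _full(i)
                dll += ll_prop[i] - island_ll[i]
            if math.log(np.random.random() + 1e-320) < dll:
                scalars[0] = r2
                for i in range(n_isl):
                    island_ll[i] = ll_prop[i]
            else:
                weights[0] = w0
                for x in range(1, ncat):
                    weights[x] = (1.0 - w0) / (ncat - 1.0)

        if do_alpha:
            la = scalars[1]
            la2 = la + np.random.normal() * prop[4]
            discretize_gamma_rates(math.exp(la2), new_rates)
            old1 = rates[1]
            old2 = rates[2]
            old3 = rates[3]
            rates[1] = new_rates[0]
            rates[2] = new_rates[1]
            rates[3] = new_rates[2]
            dll = 0.0
            for i in range(n_isl):
                ll_prop[i] = _full(i)
                dll += ll_prop[i] - island_ll[i]
            log_acc = dll + _norm_lp(la2, priors[2], priors[3]) - _norm_lp(la, priors[2], priors[3])
            if math.log(np.random.random() + 1e-320) < log_acc:
                scalars[1] = la2
                for i in range(n_isl):
                    island_ll[i] = ll_prop[i]
                    _adopt_full(i)
            else:
                rates[1] = old1
                rates[2] = old2
                rates[3] = old3

        if do_mu:
            lm = scalars[2]
            lm2 = lm + np.random.normal() * prop[5]
            mu2 = math.exp(lm2)
            n_tot_all = 0
            L_tot = 0.0
            for bi in range(n_branches):
                b = branch_nodes[bi]
                L_tot += blens[b]
                for i in range(n_isl):
                    n_tot_all += ev_count[i, b]
            log_acc = (
                n_tot_all * (lm2 - lm)
                - n_isl * L_tot * (mu2 - mu)
                + _norm_lp(lm2, priors[4], priors[5])
                - _norm_lp(lm, priors[4], priors[5])
            )
            if math.log(np.random.random() + 1e-320) < log_acc:
                scalars[2] = lm2

        # -- record --------------------------------------------------------
        if sweep >= record_from and (sweep - record_from) % thin == 0:
            row = (sweep - record_from) // thin
            tot = 0.0
            for i in range(n_isl):
                tot += island_ll[i]
            rec_ll[row] = tot
            rec_r[row] = scalars[0]
            rec_alpha[row] = math.exp(scalars[1])
            rec_mu[row] = math.exp(scalars[2]) if not null_mode else 0.0
            for bi in range(n_branches):
                b = branch_nodes[bi]
                rec_blens[row, bi] = blens[b]
                cnt = 0
                isl = 0
                for i in range(n_isl):
                    c = ev_count[i, b]
                    cnt += c
                    if c > 0:
                        isl += 1
                rec_counts[row, bi] = cnt
                rec_islcount[row, bi] = isl

    return STATUS_OK, n_sweeps


@njit(cache=True)
def island_loglik(
    i,
    preorder,
    parent,
    root,
    children_off,
    children_flat,
    blens,
    states,
    poffsets,
    island_fast,
    pmult,
    root_triples,
    ev_count,
    ev_pos,
    ev_tri,
    rates,
    weights,
):
    """Standalone island log-likelihood (allocates its own scratch; for checks)."""
    n_isl = poffsets.shape[0] - 1
    n_nodes = parent.shape[0]
    ncat = rates.shape[0]
    maxev = ev_pos.shape[2]
    pmax = 0
    for k in range(n_isl):
        if poffsets[k + 1] - poffsets[k] > pmax:
            pmax = poffsets[k + 1] - poffsets[k]
    fprop = np.empty((n_isl, n_nodes, ncat, max(pmax, 1)))
    baseprop = np.empty((n_isl, max(pmax, 1)))
    tripprop = np.empty((n_isl, n_nodes, 3))
    comp = np.empty((n_nodes, ncat, 3, 3))
    A = np.empty((3, 3))
    B = np.empty((3, 3))
    Ms = np.empty((max(maxev, 1), 3, 3))
    wbuf = np.empty((n_nodes, 3))
    scbuf = np.empty(n_nodes)
    terms = np.empty(ncat)
    return _island_full(
        i, preorder, parent, root, children_off, children_flat, blens,
        states, poffsets, island_fast, pmult, root_triples,
        ev_count, ev_pos, ev_tri, rates, weights,
        fprop, baseprop, tripprop, comp, A, B, Ms, wbuf, scbuf, terms,
    )
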