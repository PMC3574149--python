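"""Compiled Metropolis-Hastings kernel for the MSC sampler.

Everything here operates on flat padded arrays so numba can compile the
whole generation loop; :mod:`cardcoal.mcmc` owns packing/unpacking and all
user-facing behaviour.  The reference (slow, readable) implementations of
the coalescent density and the pruning likelihood live in
:mod:`cardcoal.core`; tests cross-check the two.

Array conventions
-----------------
Species tree: nodes ``0..S-1``, tips first; ``spar/sleft/sright`` parent and
child indices (-1 absent); ``tau``/``theta`` per node; ``anc[i, j]`` true
when i is ancestor-or-self of j.

Per locus ``l`` (padded to the largest locus): tips ``0..nt[l]-1``; arrays
``gpar/gl/gr/gage``; ``gbase`` species-MRCA of each node's tip populations;
``gpop`` the species branch currently containing each node; ``groot[l]``
the root; ``pat[l]`` integer site patterns (4 = missing) with weights
``patw[l]``.

Incremental caches
------------------
The coalescent log-density decomposes per population p into
``nc * log(2/theta') - A / theta'`` with ``nc`` the coalescence count and
``A`` the integral of j(j-1) dt, so theta updates are O(1), an age slide
touches only the populations on the moved node's chain, and the mixing
move rescales every ``A`` analytically.  Pruning partials are persistent
per node; an age slide re-peels only the path to the root, while topology,
tau and mixing moves recompute the affected loci in full.  All caches are
resynchronized from scratch every 1024 generations.

Invalid states evaluate to ``-1e300`` so the MH step rejects them; moves
are constraint-preserving by construction, so this is a guard only.
"""

import math

import numpy as np
from numba import njit

INVALID = -1.0e300


@njit(cache=True, inline="always")
def _gamma_lpdf(x, a, b):
    return a * math.log(b) - math.lgamma(a) + (a - 1.0) * math.log(x) - b * x


@njit(cache=True)
def _log_prior(tau, theta, ta_a, ta_b, th_a, th_b, sleft, S):
    lp = 0.0
    for i in range(S):
        lp += _gamma_lpdf(theta[i], th_a[i], th_b[i])
        if sleft[i] >= 0:
            lp += _gamma_lpdf(tau[i], ta_a[i], ta_b[i])
    return lp


@njit(cache=True, inline="always")
def _mrca(spar, anc, a, b):
    p = a
    while not anc[p, b]:
        p = spar[p]
    return p


@njit(cache=True, inline="always")
def _pop_of(spar, tau, base, age):
    p = base
    while spar[p] >= 0 and age >= tau[spar[p]]:
        p = spar[p]
    return p


@njit(cache=True)
def _postorder(gl, gr, groot, ng, nt, order, stack):
    sp = 0
    stack[sp] = groot
    sp += 1
    k = ng
    while sp > 0:
        sp -= 1
        v = stack[sp]
        k -= 1
        order[k] = v
        if v >= nt:
            stack[sp] = gl[v]
            sp += 1
            stack[sp] = gr[v]
            sp += 1


@njit(cache=True)
def _recompute_base_pop(gl, gr, gpar, gage, tipop, groot, ng, nt,
                        spar, tau, anc, gbase, gpop, order, stack):
    _postorder(gl, gr, groot, ng, nt, order, stack)
    for i in range(ng):
        v = order[i]
        if v < nt:
            gbase[v] = tipop[v]
        else:
            gbase[v] = _mrca(spar, anc, gbase[gl[v]], gbase[gr[v]])
        gpop[v] = _pop_of(spar, tau, gbase[v], gage[v])


@njit(cache=True)
def _coal_pop(gpar, gage, gpop, ng, nt, spar, tau, anc, p, evbuf):
    """(nc, A, ok) for population p: coalescence count and j(j-1)dt integral."""
    t0 = tau[p]
    pa = spar[p]
    j = 0
    for v in range(ng):
        u = gpar[v]
        if u < 0:
            continue
        if gage[v] <= t0 and gage[u] > t0 and anc[p, gpop[v]]:
            j += 1
    ne = 0
    for v in range(nt, ng):
        if gpop[v] == p:
            evbuf[ne] = gage[v]
            ne += 1
    for i in range(1, ne):
        key = evbuf[i]
        k = i - 1
        while k >= 0 and evbuf[k] > key:
            evbuf[k + 1] = evbuf[k]
            k -= 1
        evbuf[k + 1] = key
    A = 0.0
    t = t0
    for i in range(ne):
        if j < 2:
            return 0, 0.0, False
        te = evbuf[i]
        A += j * (j - 1) * (te - t)
        j -= 1
        t = te
    if pa >= 0:
        A += j * (j - 1) * (tau[pa] - t)
    elif j > 1:
        return 0, 0.0, False
    return ne, A, True


@njit(cache=True, inline="always")
def _contrib(nc, A, theta_eff):
    return nc * math.log(2.0 / theta_eff) - A / theta_eff


@njit(cache=True)
def _peel_node(gl, gr, gage, part, pat, npat, nt, mult, v):
    """Recompute the pruning partial of one node from its children."""
    if v < nt:
        for p in range(npat):
            c = pat[v, p]
            if c == 4:
                for s in range(4):
                    part[v, p, s] = 1.0
            else:
                for s in range(4):
                    part[v, p, s] = 0.0
                part[v, p, c] = 1.0
        return
    for ci in range(2):
        c = gl[v] if ci == 0 else gr[v]
        d = (gage[v] - gage[c]) * mult
        e = math.exp(-4.0 * d / 3.0)
        pd = 0.25 - 0.25 * e
        for p in range(npat):
            tot = (part[c, p, 0] + part[c, p, 1]
                   + part[c, p, 2] + part[c, p, 3])
            if ci == 0:
                for s in range(4):
                    part[v, p, s] = e * part[c, p, s] + pd * tot
            else:
                for s in range(4):
                    part[v, p, s] *= e * part[c, p, s] + pd * tot


@njit(cache=True)
def _root_loglik(part, patw, npat, groot):
    ll = 0.0
    for p in range(npat):
        s4 = (part[groot, p, 0] + part[groot, p, 1]
              + part[groot, p, 2] + part[groot, p, 3])
        if s4 <= 0.0:
            return INVALID
        ll += patw[p] * math.log(0.25 * s4)
    return ll


@njit(cache=True)
def _loglik_full(gl, gr, gage, groot, ng, nt, pat, patw, npat, mult,
                 part, order, stack):
    _postorder(gl, gr, groot, ng, nt, order, stack)
    for i in range(ng):
        _peel_node(gl, gr, gage, part, pat, npat, nt, mult, order[i])
    return _root_loglik(part, patw, npat, groot)


@njit(cache=True, inline="always")
def _reflect(x, lo, hi):
    for _ in range(200):
        if x < lo:
            x = 2.0 * lo - x
        elif x > hi:
            x = 2.0 * hi - x
        else:
            return x
    return lo - 1.0  # signals failure; caller rejects


@njit(cache=True)
def run_chain(spar, sleft, sright, tau, theta, anc,
              ta_a, ta_b, th_a, th_b,
              nt, gpar, gl, gr, gage, gbase, groot, tipop,
              pat, patw, npat, scaler, mult,
              int_nodes, use_lik,
              n_gens, burnin, thin,
              w, w_exp, tune,
              rng, trace, acc_out):
    """Run the sampler in place; fills `trace` and `acc_out`.

    w = [w_age, w_tau, w_logtheta, w_mix]; tuned during the first 80% of
    burn-in when `tune`, then frozen.  Trace columns: internal-node taus in
    `int_nodes` order, then all thetas, then the log posterior.
    """
    S = spar.shape[0]
    L = nt.shape[0]
    Gmax = gpar.shape[1]
    Pmax = pat.shape[2]
    n_int = int_nodes.shape[0]

    # scratch buffers
    evbuf = np.empty(Gmax, dtype=np.float64)
    order = np.empty(Gmax, dtype=np.int64)
    stack = np.empty(Gmax, dtype=np.int64)
    part = np.zeros((L, Gmax, Pmax, 4), dtype=np.float64)
    partS = np.empty((Gmax, Pmax, 4), dtype=np.float64)
    pathid = np.empty(Gmax, dtype=np.int64)
    pathsave = np.empty((Gmax, Pmax, 4), dtype=np.float64)
    bpar = np.empty(Gmax, dtype=np.int64)
    bl_ = np.empty(Gmax, dtype=np.int64)
    br_ = np.empty(Gmax, dtype=np.int64)
    bbase = np.empty(Gmax, dtype=np.int64)
    bpop = np.empty(Gmax, dtype=np.int64)
    bpart = np.empty((Gmax, Pmax, 4), dtype=np.float64)
    bage = np.empty((L, Gmax), dtype=np.float64)
    btau = np.empty(S, dtype=np.float64)
    btheta = np.empty(S, dtype=np.float64)
    gpop = np.empty((L, Gmax), dtype=np.int64)

    coal_nc = np.zeros((L, S), dtype=np.int64)
    coal_A = np.zeros((L, S), dtype=np.float64)
    contrib = np.zeros((L, S), dtype=np.float64)
    coal = np.zeros(L, dtype=np.float64)
    lik = np.zeros(L, dtype=np.float64)
    # per-move save slots for affected populations (chain along species tree)
    sv_nc = np.empty(S, dtype=np.int64)
    sv_A = np.empty(S, dtype=np.float64)
    sv_ct = np.empty(S, dtype=np.float64)
    sv_p = np.empty(S, dtype=np.int64)
    b_nc = np.empty((L, S), dtype=np.int64)
    b_A = np.empty((L, S), dtype=np.float64)
    b_ct = np.empty((L, S), dtype=np.float64)
    b_lik = np.empty(L, dtype=np.float64)

    # ---- full (re)synchronization of all caches ----------------------
    for l in range(L):
        ng = 2 * nt[l] - 1
        _recompute_base_pop(gl[l], gr[l], gpar[l], gage[l], tipop[l],
                            groot[l], ng, nt[l], spar, tau, anc,
                            gbase[l], gpop[l], order, stack)
        tot = 0.0
        for p in range(S):
            ncp, Ap, ok = _coal_pop(gpar[l], gage[l], gpop[l], ng, nt[l],
                                    spar, tau, anc, p, evbuf)
            coal_nc[l, p] = ncp
            coal_A[l, p] = Ap
            contrib[l, p] = _contrib(ncp, Ap, theta[p] * scaler[l])
            tot += contrib[l, p]
        coal[l] = tot
        if use_lik:
            lik[l] = _loglik_full(gl[l], gr[l], gage[l], groot[l], ng, nt[l],
                                  pat[l], patw[l], npat[l], mult[l],
                                  part[l], order, stack)
    prior = _log_prior(tau, theta, ta_a, ta_b, th_a, th_b, sleft, S)

    att = np.zeros(5, dtype=np.int64)
    acc = np.zeros(5, dtype=np.int64)
    att_tot = np.zeros(5, dtype=np.int64)
    acc_tot = np.zeros(5, dtype=np.int64)
    tune_end = (burnin * 4) // 5
    isample = 0

    for gen in range(n_gens):
        # ---- periodic cache resync (numerical hygiene) ---------------
        if gen > 0 and gen % 1024 == 0:
            for l in range(L):
                ng = 2 * nt[l] - 1
                _recompute_base_pop(gl[l], gr[l], gpar[l], gage[l], tipop[l],
                                    groot[l], ng, nt[l], spar, tau, anc,
                                    gbase[l], gpop[l], order, stack)
                tot = 0.0
                for p in range(S):
                    ncp, Ap, ok = _coal_pop(gpar[l], gage[l], gpop[l], ng,
                                            nt[l], spar, tau, anc, p, evbuf)
                    coal_nc[l, p] = ncp
                    coal_A[l, p] = Ap
                    contrib[l, p] = _contrib(ncp, Ap, theta[p] * scaler[l])
                    tot += contrib[l, p]
                coal[l] = tot
                if use_lik:
                    lik[l] = _loglik_full(gl[l], gr[l], gage[l], groot[l],
                                          ng, nt[l], pat[l], patw[l],
                                          npat[l], mult[l], part[l],
                                          order, stack)
            prior = _log_prior(tau, theta, ta_a, ta_b, th_a, th_b, sleft, S)

        # ---- per-locus genealogy moves -------------------------------
        for l in range(L):
            if nt[l] < 2:
                continue
            ng = 2 * nt[l] - 1
            n_age = 1 + nt[l] // 6
            for _rep in range(n_age):
                att[0] += 1
                v = nt[l] + int(rng.integers(0, nt[l] - 1))
                lb = gage[l, gl[l, v]]
                if gage[l, gr[l, v]] > lb:
                    lb = gage[l, gr[l, v]]
                if tau[gbase[l, v]] > lb:
                    lb = tau[gbase[l, v]]
                up = gpar[l, v]
                ub = gage[l, up] if up >= 0 else math.inf
                y = _reflect(gage[l, v] + (rng.random() * 2.0 - 1.0) * w[0],
                             lb, ub)
                if y <= lb:
                    continue
                old_age = gage[l, v]
                pold = gpop[l, v]
                pnew = _pop_of(spar, tau, gbase[l, v], y)
                gage[l, v] = y
                gpop[l, v] = pnew
                # affected populations: chain between pold and pnew
                lo_p = pnew if anc[pold, pnew] else pold
                hi_p = pold if anc[pold, pnew] else pnew
                nsv = 0
                dcoal = 0.0
                okm = True
                pp = lo_p
                while True:
                    ncp, Ap, ok = _coal_pop(gpar[l], gage[l], gpop[l], ng,
                                            nt[l], spar, tau, anc, pp, evbuf)
                    if not ok:
                        okm = False
                        break
                    sv_p[nsv] = pp
                    sv_nc[nsv] = coal_nc[l, pp]
                    sv_A[nsv] = coal_A[l, pp]
                    sv_ct[nsv] = contrib[l, pp]
                    nsv += 1
                    newct = _contrib(ncp, Ap, theta[pp] * scaler[l])
                    dcoal += newct - contrib[l, pp]
                    coal_nc[l, pp] = ncp
                    coal_A[l, pp] = Ap
                    contrib[l, pp] = newct
                    if pp == hi_p:
                        break
                    pp = spar[pp]
                # likelihood: re-peel the path from v to the root
                dlik = 0.0
                npath = 0
                if okm and use_lik:
                    wnode = v
                    while wnode >= 0:
                        pathid[npath] = wnode
                        for p in range(npat[l]):
                            for s in range(4):
                                pathsave[npath, p, s] = part[l, wnode, p, s]
                        npath += 1
                        wnode = gpar[l, wnode]
                    for i in range(npath):
                        _peel_node(gl[l], gr[l], gage[l], part[l], pat[l],
                                   npat[l], nt[l], mult[l], pathid[i])
                    newlik = _root_loglik(part[l], patw[l], npat[l], groot[l])
                    dlik = newlik - lik[l]
                logr = dcoal + dlik
                if okm and (logr >= 0.0 or rng.random() < math.exp(logr)):
                    coal[l] += dcoal
                    lik[l] += dlik
                    acc[0] += 1
                else:
                    gage[l, v] = old_age
                    gpop[l, v] = pold
                    for i in range(nsv):
                        pp = sv_p[i]
                        coal_nc[l, pp] = sv_nc[i]
                        coal_A[l, pp] = sv_A[i]
                        contrib[l, pp] = sv_ct[i]
                    if use_lik:
                        for i in range(npath):
                            wnode = pathid[i]
                            for p in range(npat[l]):
                                for s in range(4):
                                    part[l, wnode, p, s] = pathsave[i, p, s]

            # ---- lineage regraft (Wilson-Balding style) --------------
            if nt[l] >= 3 and rng.random() < 0.4:
                att[1] += 1
                root = groot[l]
                c = int(rng.integers(0, ng - 1))
                if c >= root:
                    c += 1
                p_ = gpar[l, c]
                s_ = gr[l, p_] if gl[l, p_] == c else gl[l, p_]
                gparent = gpar[l, p_]
                j = int(rng.integers(0, ng))
                ok = j != c and j != p_
                if ok:
                    x = j
                    while x >= 0:
                        if x == c:
                            ok = False
                            break
                        x = gpar[l, x]
                if ok:
                    pj = gpar[l, j]
                    if pj == p_:
                        pj = gparent
                    m = _mrca(spar, anc, gbase[l, c], gbase[l, j])
                    lo = gage[l, c]
                    if gage[l, j] > lo:
                        lo = gage[l, j]
                    if tau[m] > lo:
                        lo = tau[m]
                    m2 = _mrca(spar, anc, gbase[l, c], gbase[l, s_])
                    lo_rev = gage[l, c]
                    if gage[l, s_] > lo_rev:
                        lo_rev = gage[l, s_]
                    if tau[m2] > lo_rev:
                        lo_rev = tau[m2]
                    t_old = gage[l, p_]
                    t_new = 0.0
                    lq_fwd = 0.0
                    if pj >= 0:
                        ubj = gage[l, pj]
                        if ubj <= lo:
                            ok = False
                        else:
                            t_new = lo + rng.random() * (ubj - lo)
                            lq_fwd = -math.log(ubj - lo)
                    else:
                        t_new = lo - math.log(1.0 - rng.random()) * w_exp
                        lq_fwd = -math.log(w_exp) - (t_new - lo) / w_exp
                    if ok:
                        if gparent >= 0:
                            lq_rev = -math.log(gage[l, gparent] - lo_rev)
                        else:
                            lq_rev = (-math.log(w_exp)
                                      - (t_old - lo_rev) / w_exp)
                        # save full locus state
                        for v2 in range(ng):
                            bpar[v2] = gpar[l, v2]
                            bl_[v2] = gl[l, v2]
                            br_[v2] = gr[l, v2]
                            bbase[v2] = gbase[l, v2]
                            bpop[v2] = gpop[l, v2]
                            bage[l, v2] = gage[l, v2]
                        if use_lik:
                            for v2 in range(ng):
                                for p in range(npat[l]):
                                    for s in range(4):
                                        bpart[v2, p, s] = part[l, v2, p, s]
                        broot = root
                        for p in range(S):
                            sv_nc[p] = coal_nc[l, p]
                            sv_A[p] = coal_A[l, p]
                            sv_ct[p] = contrib[l, p]
                        # detach p_ (lift s_ into its place)
                        if gparent >= 0:
                            if gl[l, gparent] == p_:
                                gl[l, gparent] = s_
                            else:
                                gr[l, gparent] = s_
                            gpar[l, s_] = gparent
                        else:
                            gpar[l, s_] = -1
                            root = s_
                        # attach p_ on the branch above j
                        if pj >= 0:
                            if gl[l, pj] == j:
                                gl[l, pj] = p_
                            else:
                                gr[l, pj] = p_
                            gpar[l, p_] = pj
                        else:
                            gpar[l, p_] = -1
                            root = p_
                        gl[l, p_] = c
                        gr[l, p_] = j
                        gpar[l, j] = p_
                        gpar[l, c] = p_
                        gage[l, p_] = t_new
                        groot[l] = root
                        _recompute_base_pop(gl[l], gr[l], gpar[l], gage[l],
                                            tipop[l], root, ng, nt[l], spar,
                                            tau, anc, gbase[l], gpop[l],
                                            order, stack)
                        newcoal = 0.0
                        okm = True
                        for p in range(S):
                            ncp, Ap, okp = _coal_pop(gpar[l], gage[l],
                                                     gpop[l], ng, nt[l],
                                                     spar, tau, anc, p,
                                                     evbuf)
                            if not okp:
                                okm = False
                                break
                            coal_nc[l, p] = ncp
                            coal_A[l, p] = Ap
                            contrib[l, p] = _contrib(ncp, Ap,
                                                     theta[p] * scaler[l])
                            newcoal += contrib[l, p]
                        nl = lik[l]
                        if okm and use_lik:
                            nl = _loglik_full(gl[l], gr[l], gage[l], root,
                                              ng, nt[l], pat[l], patw[l],
                                              npat[l], mult[l], part[l],
                                              order, stack)
                        logr = ((newcoal - coal[l]) + (nl - lik[l])
                                + (lq_rev - lq_fwd))
                        if okm and (logr >= 0.0
                                    or rng.random() < math.exp(logr)):
                            coal[l] = newcoal
                            lik[l] = nl
                            acc[1] += 1
                        else:
                            for v2 in range(ng):
                                gpar[l, v2] = bpar[v2]
                                gl[l, v2] = bl_[v2]
                                gr[l, v2] = br_[v2]
                                gbase[l, v2] = bbase[v2]
                                gpop[l, v2] = bpop[v2]
                                gage[l, v2] = bage[l, v2]
                            groot[l] = broot
                            for p in range(S):
                                coal_nc[l, p] = sv_nc[p]
                                coal_A[l, p] = sv_A[p]
                                contrib[l, p] = sv_ct[p]
                            if use_lik:
                                for v2 in range(ng):
                                    for p in range(npat[l]):
                                        for s in range(4):
                                            part[l, v2, p, s] = bpart[v2, p, s]

        # ---- theta updates (log scale, O(1) via nc/A cache) ----------
        for i in range(S):
            att[2] += 1
            fac = math.exp(w[2] * (rng.random() - 0.5))
            old_th = theta[i]
            new_th = old_th * fac
            dprior = (_gamma_lpdf(new_th, th_a[i], th_b[i])
                      - _gamma_lpdf(old_th, th_a[i], th_b[i]))
            dcoal = 0.0
            for l in range(L):
                newct = _contrib(coal_nc[l, i], coal_A[l, i],
                                 new_th * scaler[l])
                dcoal += newct - contrib[l, i]
            logr = dprior + dcoal + math.log(fac)
            if logr >= 0.0 or rng.random() < math.exp(logr):
                theta[i] = new_th
                for l in range(L):
                    newct = _contrib(coal_nc[l, i], coal_A[l, i],
                                     new_th * scaler[l])
                    coal[l] += newct - contrib[l, i]
                    contrib[l, i] = newct
                prior += dprior
                acc[2] += 1

        # ---- tau rubber-band update (one node per generation) --------
        if n_int > 0:
            att[3] += 1
            k = int_nodes[int(rng.integers(0, n_int))]
            lo_t = tau[sleft[k]]
            if tau[sright[k]] > lo_t:
                lo_t = tau[sright[k]]
            pa = spar[k]
            up_t = tau[pa] if pa >= 0 else math.inf
            t_old = tau[k]
            t_new = _reflect(t_old + (rng.random() * 2.0 - 1.0) * w[1],
                             lo_t, up_t)
            if t_new > lo_t and t_old > lo_t and (pa < 0 or
                                                  (up_t > t_old
                                                   and up_t > t_new)):
                r_low = (t_new - lo_t) / (t_old - lo_t)
                bounded = pa >= 0
                r_up = ((up_t - t_new) / (up_t - t_old)) if bounded else 1.0
                nb = 0
                na = 0
                for l in range(L):
                    ng = 2 * nt[l] - 1
                    for v in range(ng):
                        bage[l, v] = gage[l, v]
                    for v in range(nt[l], ng):
                        ppv = gpop[l, v]
                        a = gage[l, v]
                        if (ppv == sleft[k] or ppv == sright[k]) and a > lo_t:
                            gage[l, v] = lo_t + (a - lo_t) * r_low
                            nb += 1
                        elif ppv == k:
                            if bounded:
                                gage[l, v] = up_t - (up_t - a) * r_up
                                na += 1
                            else:
                                gage[l, v] = a + (t_new - t_old)
                tau[k] = t_new
                dprior = (_gamma_lpdf(t_new, ta_a[k], ta_b[k])
                          - _gamma_lpdf(t_old, ta_a[k], ta_b[k]))
                lhast = nb * math.log(r_low)
                if bounded:
                    lhast += na * math.log(r_up)
                # coal: only k and its two children change; lik: full
                for l in range(L):
                    for i3 in range(3):
                        pp = k if i3 == 0 else (sleft[k] if i3 == 1
                                                else sright[k])
                        b_nc[l, i3] = coal_nc[l, pp]
                        b_A[l, i3] = coal_A[l, pp]
                        b_ct[l, i3] = contrib[l, pp]
                dpost = 0.0
                okm = True
                for l in range(L):
                    ng = 2 * nt[l] - 1
                    for i3 in range(3):
                        pp = k if i3 == 0 else (sleft[k] if i3 == 1
                                                else sright[k])
                        ncp, Ap, okp = _coal_pop(gpar[l], gage[l], gpop[l],
                                                 ng, nt[l], spar, tau, anc,
                                                 pp, evbuf)
                        if not okp:
                            okm = False
                            break
                        newct = _contrib(ncp, Ap, theta[pp] * scaler[l])
                        dpost += newct - contrib[l, pp]
                        coal_nc[l, pp] = ncp
                        coal_A[l, pp] = Ap
                        contrib[l, pp] = newct
                    if not okm:
                        break
                    if use_lik:
                        nl = _loglik_full(gl[l], gr[l], gage[l], groot[l],
                                          ng, nt[l], pat[l], patw[l],
                                          npat[l], mult[l], partS,
                                          order, stack)
                        b_lik[l] = nl
                        dpost += nl - lik[l]
                logr = dprior + dpost + lhast
                if okm and (logr >= 0.0 or rng.random() < math.exp(logr)):
                    for l in range(L):
                        ng = 2 * nt[l] - 1
                        coal[l] += (contrib[l, k] - b_ct[l, 0]
                                    + contrib[l, sleft[k]] - b_ct[l, 1]
                                    + contrib[l, sright[k]] - b_ct[l, 2])
                        if use_lik:
                            lik[l] = b_lik[l]
                            _loglik_full(gl[l], gr[l], gage[l], groot[l],
                                         ng, nt[l], pat[l], patw[l],
                                         npat[l], mult[l], part[l],
                                         order, stack)
                    prior += dprior
                    acc[3] += 1
                else:
                    tau[k] = t_old
                    for l in range(L):
                        ng = 2 * nt[l] - 1
                        for v in range(ng):
                            gage[l, v] = bage[l, v]
                        for i3 in range(3):
                            pp = k if i3 == 0 else (sleft[k] if i3 == 1
                                                    else sright[k])
                            coal_nc[l, pp] = b_nc[l, i3]
                            coal_A[l, pp] = b_A[l, i3]
                            contrib[l, pp] = b_ct[l, i3]

        # ---- mixing move: scale everything (every other generation) --
        if gen % 2 == 0:
            att[4] += 1
            cmul = math.exp(w[3] * (rng.random() - 0.5))
            ndim = n_int + S
            for i in range(S):
                btheta[i] = theta[i]
                btau[i] = tau[i]
                theta[i] *= cmul
            for ik in range(n_int):
                tau[int_nodes[ik]] *= cmul
            for l in range(L):
                ng = 2 * nt[l] - 1
                ndim += nt[l] - 1
                for v in range(ng):
                    bage[l, v] = gage[l, v]
                    gage[l, v] *= cmul
            new_prior = _log_prior(tau, theta, ta_a, ta_b, th_a, th_b,
                                   sleft, S)
            # coalescent cache: A scales by cmul, nc unchanged
            dpost = 0.0
            for l in range(L):
                for p in range(S):
                    # theta is already scaled in place; A scales by cmul
                    newct = _contrib(coal_nc[l, p], coal_A[l, p] * cmul,
                                     theta[p] * scaler[l])
                    dpost += newct - contrib[l, p]
                if use_lik:
                    ng = 2 * nt[l] - 1
                    nl = _loglik_full(gl[l], gr[l], gage[l], groot[l], ng,
                                      nt[l], pat[l], patw[l], npat[l],
                                      mult[l], partS, order, stack)
                    b_lik[l] = nl
                    dpost += nl - lik[l]
            logr = (new_prior - prior) + dpost + ndim * math.log(cmul)
            if logr >= 0.0 or rng.random() < math.exp(logr):
                for l in range(L):
                    ng = 2 * nt[l] - 1
                    for p in range(S):
                        coal_A[l, p] *= cmul
                        newct = _contrib(coal_nc[l, p], coal_A[l, p],
                                         theta[p] * scaler[l])
                        coal[l] += newct - contrib[l, p]
                        contrib[l, p] = newct
                    if use_lik:
                        lik[l] = b_lik[l]
                        _loglik_full(gl[l], gr[l], gage[l], groot[l], ng,
                                     nt[l], pat[l], patw[l], npat[l],
                                     mult[l], part[l], order, stack)
                prior = new_prior
                acc[4] += 1
            else:
                for i in range(S):
                    theta[i] = btheta[i]
                    tau[i] = btau[i]
                for l in range(L):
                    ng = 2 * nt[l] - 1
                    for v in range(ng):
                        gage[l, v] = bage[l, v]

        # ---- adaptive widths during early burn-in --------------------
        if tune and gen < tune_end and (gen + 1) % 250 == 0:
            for pair in ((0, 0), (3, 1), (2, 2), (4, 3)):
                cls = pair[0]
                wi = pair[1]
                if att[cls] > 0:
                    rate = acc[cls] / att[cls]
                    if rate > 0.4:
                        w[wi] *= 1.4
                    elif rate < 0.2:
                        w[wi] /= 1.4
                    if w[wi] < 1e-9:
                        w[wi] = 1e-9
                    elif w[wi] > 1e3:
                        w[wi] = 1e3
            for i5 in range(5):
                att_tot[i5] += att[i5]
                acc_tot[i5] += acc[i5]
                att[i5] = 0
                acc[i5] = 0

        # ---- record ---------------------------------------------------
        if gen >= burnin and (gen - burnin) % thin == 0:
            for ik in range(n_int):
                trace[isample, ik] = tau[int_nodes[ik]]
            for i in range(S):
                trace[isample, n_int + i] = theta[i]
            tot = prior
            for l in range(L):
                tot += coal[l] + lik[l]
            trace[isample, n_int + S] = tot
            isample += 1

    for i5 in range(5):
        acc_out[i5, 0] = acc_tot[i5] + acc[i5]
        acc_out[i5, 1] = att_tot[i5] + att[i5]
    return isample
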