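"""Compiled inner loop of the quartet MSC-I sampler.

The species tree is (((A,B)T, C)S, O)R with populations indexed
0=A, 1=B, 2=C, 3=O, 4=T, 5=S, 6=R, each with its own theta; one pulse
introgression edge connects the nonsister tip branches B and C at time
tau_X (0 < tau_X < tau_T), with probability phi.  Latent state per locus:
gene-tree topology (parent array, tips 0..k-1, internals k..2k-2), node
ages, and a path flag per gene-tree edge that is present in the recipient
population at tau_X (1 = traced into the donor).

Moves whose proposal changes which edges carry a path flag draw the new
flags from Bernoulli(phi); those proposal probabilities cancel the matching
phi factors of the target density, so the Hastings ratio only keeps the phi
terms of edges whose flag status is unchanged.
"""

import numpy as np
from numba import njit

# parameter vector layout
I_TAUT, I_TAUS, I_TAUR, I_TAUX, I_PHI, I_TH0 = 0, 1, 2, 3, 4, 5
NPOP = 7
NEG_INF = -1.0e308


@njit(cache=True)
def _children(parent, ch1, ch2):
    nn = parent.shape[0]
    for i in range(nn):
        ch1[i] = -1
        ch2[i] = -1
    for i in range(nn):
        p = parent[i]
        if p >= 0:
            if ch1[p] < 0:
                ch1[p] = i
            else:
                ch2[p] = i


@njit(cache=True)
def _internal_order(age, k, order):
    """Internal node indices sorted by age ascending (insertion sort)."""
    nn = age.shape[0]
    m = nn - k
    for j in range(m):
        order[j] = k + j
    for j in range(1, m):
        key = order[j]
        aj = age[key]
        i = j - 1
        while i >= 0 and age[order[i]] > aj:
            order[i + 1] = order[i]
            i -= 1
        order[i + 1] = key
    return m


@njit(cache=True)
def _pop_at(pop, flg, t0, t, tauX, tauT, tauS, tauR, donor, recipient):
    """Population of a lineage at time t, given it started in ``pop`` at
    time t0 with path flag ``flg``; boundaries apply in increasing order
    tauX < tauT <= tauS <= tauR."""
    if t0 < tauX and tauX <= t and pop == recipient and flg == 1:
        pop = donor
    if tauT <= t and pop <= 1:
        pop = 4
    if tauS <= t and (pop == 4 or pop == 2):
        pop = 5
    if tauR <= t and (pop == 5 or pop == 3):
        pop = 6
    return pop


@njit(cache=True)
def _cross_mask(parent, age, tip_pop, k, tauX, recipient, ch1, ch2, order, allrec):
    """Bitmask of edges in the recipient branch spanning tau_X.

    An edge above node i crosses iff age[i] < tauX <= age[parent[i]] and
    every tip below i belongs to the recipient species (below tau_X no
    other boundary exists, so such a clade sits in the recipient branch)."""
    nn = parent.shape[0]
    _children(parent, ch1, ch2)
    m = _internal_order(age, k, order)
    for i in range(k):
        allrec[i] = 1 if tip_pop[i] == recipient else 0
    for j in range(m):
        i = order[j]
        allrec[i] = allrec[ch1[i]] * allrec[ch2[i]]
    mask = np.int64(0)
    for i in range(nn):
        p = parent[i]
        if p >= 0 and allrec[i] == 1 and age[i] < tauX and tauX <= age[p]:
            mask |= np.int64(1) << i
    return mask


@njit(cache=True)
def _locus_stats(parent, age, flag, tip_pop, k, params, donor, recipient,
                 c_out, A_out, startpop, ch1, ch2, order,
                 seg_pop, seg_a, seg_b):
    """Sufficient statistics of the coalescent density for one locus.

    Fills per-population coalescence counts ``c_out`` and waiting-time
    integrals ``A_out`` (sum over intervals of n(n-1)*dt), and returns
    (valid, n1, n0) where n1/n0 count flagged/unflagged edges crossing
    tau_X in the recipient branch."""
    tauT, tauS, tauR, tauX = params[I_TAUT], params[I_TAUS], params[I_TAUR], params[I_TAUX]
    nn = parent.shape[0]
    _children(parent, ch1, ch2)
    m = _internal_order(age, k, order)
    for p in range(NPOP):
        c_out[p] = 0.0
        A_out[p] = 0.0
    for i in range(k):
        startpop[i] = tip_pop[i]
    for j in range(m):
        i = order[j]
        c1, c2 = ch1[i], ch2[i]
        p1 = _pop_at(startpop[c1], flag[c1], age[c1], age[i],
                     tauX, tauT, tauS, tauR, donor, recipient)
        p2 = _pop_at(startpop[c2], flag[c2], age[c2], age[i],
                     tauX, tauT, tauS, tauR, donor, recipient)
        if p1 != p2:
            return False, 0, 0
        startpop[i] = p1
        c_out[p1] += 1.0
    # decompose every edge into population segments
    ns = 0
    for i in range(nn):
        p = parent[i]
        if p < 0:
            continue
        t0 = age[i]
        te = age[p]
        pop = startpop[i]
        flg = flag[i]
        cur = t0
        for b_idx in range(4):
            if b_idx == 0:
                b = tauX
            elif b_idx == 1:
                b = tauT
            elif b_idx == 2:
                b = tauS
            else:
                b = tauR
            if b <= cur:
                # boundary at or below the segment start is already baked
                # into startpop
                continue
            if b >= te:
                break
            seg_pop[ns] = pop
            seg_a[ns] = cur
            seg_b[ns] = b
            ns += 1
            # apply this single boundary
            if b_idx == 0:
                if pop == recipient and flg == 1:
                    pop = donor
            elif b_idx == 1:
                if pop <= 1:
                    pop = 4
            elif b_idx == 2:
                if pop == 4 or pop == 2:
                    pop = 5
            else:
                if pop == 5 or pop == 3:
                    pop = 6
            cur = b
        seg_pop[ns] = pop
        seg_a[ns] = cur
        seg_b[ns] = te
        ns += 1
    # pairwise overlaps: sum_k n(n-1) dt = sum over ordered pairs of overlap*2
    for a in range(ns):
        pa = seg_pop[a]
        for b in range(a + 1, ns):
            if seg_pop[b] == pa:
                lo = seg_a[a] if seg_a[a] > seg_a[b] else seg_a[b]
                hi = seg_b[a] if seg_b[a] < seg_b[b] else seg_b[b]
                if hi > lo:
                    A_out[pa] += 2.0 * (hi - lo)
    # crossing-edge flag counts
    n1 = 0
    n0 = 0
    for i in range(nn):
        p = parent[i]
        if p >= 0 and age[i] < tauX and tauX <= age[p] and startpop[i] == recipient:
            if flag[i] == 1:
                n1 += 1
            else:
                n0 += 1
    return True, n1, n0


@njit(cache=True)
def _ld_from_stats(c, A, params, n1, n0):
    """Coalescent log density from sufficient stats, including phi terms."""
    phi = params[I_PHI]
    ld = 0.0
    for p in range(NPOP):
        th = params[I_TH0 + p]
        if c[p] > 0.0:
            ld += c[p] * np.log(2.0 / th)
        ld -= A[p] / th
    if n1 > 0:
        if phi <= 0.0:
            return NEG_INF
        ld += n1 * np.log(phi)
    if n0 > 0:
        if phi >= 1.0:
            return NEG_INF
        ld += n0 * np.log(1.0 - phi)
    return ld


@njit(cache=True)
def _flag_adjust(mask, flag, phi):
    """Sum of log phi-factors over the edges in ``mask`` (these cancel
    against Bernoulli(phi) proposal draws in Hastings ratios)."""
    tot = 0.0
    i = 0
    m = mask
    while m != 0:
        if m & np.int64(1):
            if flag[i] == 1:
                tot += np.log(phi) if phi > 0.0 else NEG_INF
            else:
                tot += np.log(1.0 - phi) if phi < 1.0 else NEG_INF
        m >>= 1
        i += 1
    return tot


@njit(cache=True)
def _jc_loglik(parent, age, k, tip_pat, npat, w, order, partial):
    """Felsenstein pruning under JC over compressed site patterns."""
    nn = parent.shape[0]
    for i in range(k):
        for s in range(npat):
            m = tip_pat[i, s]
            for x in range(4):
                partial[i, s, x] = 1.0 if (m >> x) & 1 == 1 else 0.0
    nm = _internal_order(age, k, order)
    for j in range(nm):
        i = order[j]
        for s in range(npat):
            for x in range(4):
                partial[i, s, x] = 1.0
    root = order[nm - 1] if nm > 0 else 0
    # propagate children into parents in ascending-age order
    for i in range(k):
        p = parent[i]
        if p < 0:
            continue
        d = age[p] - age[i]
        e = np.exp(-4.0 * d / 3.0)
        pd = 0.25 * (1.0 - e)
        for s in range(npat):
            tot = (partial[i, s, 0] + partial[i, s, 1]
                   + partial[i, s, 2] + partial[i, s, 3])
            for x in range(4):
                partial[p, s, x] *= pd * tot + e * partial[i, s, x]
    for j in range(nm):
        i = order[j]
        p = parent[i]
        if p < 0:
            continue
        d = age[p] - age[i]
        e = np.exp(-4.0 * d / 3.0)
        pd = 0.25 * (1.0 - e)
        for s in range(npat):
            tot = (partial[i, s, 0] + partial[i, s, 1]
                   + partial[i, s, 2] + partial[i, s, 3])
            for x in range(4):
                partial[p, s, x] *= pd * tot + e * partial[i, s, x]
    ll = 0.0
    for s in range(npat):
        tot = 0.25 * (partial[root, s, 0] + partial[root, s, 1]
                      + partial[root, s, 2] + partial[root, s, 3])
        ll += w[s] * np.log(tot)
    return ll


@njit(cache=True)
def _reflect(x, lo, hi):
    """Reflect x into the open interval (lo, hi)."""
    span = hi - lo
    if span <= 0.0:
        return lo
    y = (x - lo) % (2.0 * span)
    if y < 0.0:
        y += 2.0 * span
    if y > span:
        y = 2.0 * span - y
    return lo + y


@njit(cache=True)
def run_chain(parent, age, flag, tip_pop, tip_pat, pat_w, pat_n,
              donor, recipient,
              a_tau, b_tau, a_th, b_th, phi_a, phi_b,
              params0, n_burn, n_rec, thin, seed):
    """Metropolis-within-Gibbs sampler for the quartet MSC-I model.

    Per sweep: one node-age move, one nearest-neighbour-interchange and one
    path-flag flip per locus; a Gibbs draw for phi; log-scale random-walk
    updates for each theta; a reflected slide for tau_X; rubber-band moves
    for tau_T and tau_S (gene-tree ages between the neighbouring divergence
    times are remapped piecewise-linearly, with the Jacobian in the
    Hastings ratio); and a multiplier move for tau_R that rescales all ages
    above tau_S.  Records every ``thin`` sweeps after ``n_burn`` burn-in
    sweeps, during which proposal windows are tuned toward ~30% acceptance.
    """
    np.random.seed(seed)
    L = parent.shape[0]
    nn = parent.shape[1]
    k = (nn + 1) // 2
    maxpat = tip_pat.shape[2] if L > 0 else 1
    p = params0.copy()

    # scratch
    startpop = np.empty(nn, np.int64)
    ch1 = np.empty(nn, np.int64)
    ch2 = np.empty(nn, np.int64)
    order = np.empty(nn, np.int64)
    allrec = np.empty(nn, np.int64)
    seg_pop = np.empty(160, np.int64)
    seg_a = np.empty(160, np.float64)
    seg_b = np.empty(160, np.float64)
    c_tmp = np.empty(NPOP, np.float64)
    A_tmp = np.empty(NPOP, np.float64)
    partial = np.empty((nn, maxpat, 4), np.float64)
    flag_bak = np.empty(nn, np.uint8)
    p_try = np.empty_like(p)

    stats_c = np.zeros((L, NPOP), np.float64)
    stats_A = np.zeros((L, NPOP), np.float64)
    n1s = np.zeros(L, np.int64)
    n0s = np.zeros(L, np.int64)
    seq_ll = np.zeros(L, np.float64)
    c2 = np.zeros((L, NPOP), np.float64)
    A2 = np.zeros((L, NPOP), np.float64)
    n1_2 = np.zeros(L, np.int64)
    n0_2 = np.zeros(L, np.int64)
    ll2 = np.zeros(L, np.float64)
    changed = np.zeros(L, np.uint8)
    age_bak = np.zeros((L, nn), np.float64)
    flagall_bak = np.zeros((L, nn), np.uint8)

    for l in range(L):
        ok, n1, n0 = _locus_stats(parent[l], age[l], flag[l], tip_pop, k, p,
                                  donor, recipient, c_tmp, A_tmp, startpop,
                                  ch1, ch2, order, seg_pop, seg_a, seg_b)
        if not ok:
            raise ValueError("initial gene tree incompatible with the model")
        for q in range(NPOP):
            stats_c[l, q] = c_tmp[q]
            stats_A[l, q] = A_tmp[q]
        n1s[l] = n1
        n0s[l] = n0
        seq_ll[l] = _jc_loglik(parent[l], age[l], k, tip_pat[l], pat_n[l],
                               pat_w[l], order, partial)

    # proposal windows: age, tauX, tauT, tauS, tauR(log), theta(log)
    th_mean = a_th / b_th
    w = np.empty(6, np.float64)
    w[0] = th_mean
    w[1] = 0.5 * p[I_TAUX] + 1e-6
    w[2] = 0.5 * th_mean
    w[3] = 0.5 * th_mean
    w[4] = 0.3
    w[5] = 0.6
    acc = np.zeros(6, np.int64)
    att = np.zeros(6, np.int64)
    wacc = np.zeros(6, np.float64)
    watt = np.zeros(6, np.float64)

    trace = np.empty((n_rec, 14), np.float64)
    total = n_burn + n_rec * thin
    rec = 0

    for sweep in range(total):
        burn = sweep < n_burn
        phi = p[I_PHI]
        tauX = p[I_TAUX]

        for l in range(L):
            pl = parent[l]
            al = age[l]
            fl = flag[l]

            # ---- node-age move ----
            watt[0] += 1.0
            _children(pl, ch1, ch2)
            i = k + np.random.randint(0, nn - k)
            lb = al[ch1[i]] if al[ch1[i]] > al[ch2[i]] else al[ch2[i]]
            pi = pl[i]
            old_t = al[i]
            prop = old_t + np.random.uniform(-w[0], w[0])
            if pi >= 0:
                t_new = _reflect(prop, lb, al[pi])
            else:
                t_new = lb + abs(prop - lb)
            old_mask = _cross_mask(pl, al, tip_pop, k, tauX, recipient,
                                   ch1, ch2, order, allrec)
            al[i] = t_new
            new_mask = _cross_mask(pl, al, tip_pop, k, tauX, recipient,
                                   ch1, ch2, order, allrec)
            newbits = new_mask & ~old_mask
            oldbits = old_mask & ~new_mask
            m = newbits
            j = 0
            while m != 0:
                if m & np.int64(1):
                    flag_bak[j] = fl[j]
                    fl[j] = 1 if np.random.random() < phi else 0
                m >>= 1
                j += 1
            ok, n1, n0 = _locus_stats(pl, al, fl, tip_pop, k, p, donor,
                                      recipient, c_tmp, A_tmp, startpop,
                                      ch1, ch2, order, seg_pop, seg_a, seg_b)
            accept = False
            lln = 0.0
            if ok:
                ld_new = _ld_from_stats(c_tmp, A_tmp, p, n1, n0)
                ld_old = _ld_from_stats(stats_c[l], stats_A[l], p, n1s[l], n0s[l])
                lln = _jc_loglik(pl, al, k, tip_pat[l], pat_n[l], pat_w[l],
                                 order, partial)
                logr = (ld_new - _flag_adjust(newbits, fl, phi)) \
                    - (ld_old - _flag_adjust(oldbits, fl, phi)) \
                    + lln - seq_ll[l]
                if logr >= 0.0 or np.log(np.random.random()) < logr:
                    accept = True
            if accept:
                for q in range(NPOP):
                    stats_c[l, q] = c_tmp[q]
                    stats_A[l, q] = A_tmp[q]
                n1s[l] = n1
                n0s[l] = n0
                seq_ll[l] = lln
                wacc[0] += 1.0
                if not burn:
                    acc[0] += 1
            else:
                al[i] = old_t
                m = newbits
                j = 0
                while m != 0:
                    if m & np.int64(1):
                        fl[j] = flag_bak[j]
                    m >>= 1
                    j += 1
            if not burn:
                att[0] += 1

            # ---- NNI move ----
            if nn - k >= 2:
                _children(pl, ch1, ch2)
                r = np.random.randint(0, nn - k - 1)
                pnode = -1
                cnt = 0
                for q in range(k, nn):
                    if pl[q] >= 0:
                        if cnt == r:
                            pnode = q
                            break
                        cnt += 1
                if pnode >= 0:
                    g = pl[pnode]
                    u = ch2[g] if ch1[g] == pnode else ch1[g]
                    a_child = ch1[pnode] if np.random.random() < 0.5 else ch2[pnode]
                    if al[u] < al[pnode]:
                        old_mask = _cross_mask(pl, al, tip_pop, k, tauX,
                                               recipient, ch1, ch2, order, allrec)
                        pl[u] = pnode
                        pl[a_child] = g
                        new_mask = _cross_mask(pl, al, tip_pop, k, tauX,
                                               recipient, ch1, ch2, order, allrec)
                        newbits = new_mask & ~old_mask
                        oldbits = old_mask & ~new_mask
                        m = newbits
                        j = 0
                        while m != 0:
                            if m & np.int64(1):
                                flag_bak[j] = fl[j]
                                fl[j] = 1 if np.random.random() < phi else 0
                            m >>= 1
                            j += 1
                        ok, n1, n0 = _locus_stats(pl, al, fl, tip_pop, k, p,
                                                  donor, recipient, c_tmp, A_tmp,
                                                  startpop, ch1, ch2, order,
                                                  seg_pop, seg_a, seg_b)
                        accept = False
                        lln = 0.0
                        if ok:
                            ld_new = _ld_from_stats(c_tmp, A_tmp, p, n1, n0)
                            ld_old = _ld_from_stats(stats_c[l], stats_A[l], p,
                                                    n1s[l], n0s[l])
                            lln = _jc_loglik(pl, al, k, tip_pat[l], pat_n[l],
                                             pat_w[l], order, partial)
                            logr = (ld_new - _flag_adjust(newbits, fl, phi)) \
                                - (ld_old - _flag_adjust(oldbits, fl, phi)) \
                                + lln - seq_ll[l]
                            if logr >= 0.0 or np.log(np.random.random()) < logr:
                                accept = True
                        if accept:
                            for q in range(NPOP):
                                stats_c[l, q] = c_tmp[q]
                                stats_A[l, q] = A_tmp[q]
                            n1s[l] = n1
                            n0s[l] = n0
                            seq_ll[l] = lln
                        else:
                            pl[u] = g
                            pl[a_child] = pnode
                            m = newbits
                            j = 0
                            while m != 0:
                                if m & np.int64(1):
                                    fl[j] = flag_bak[j]
                                m >>= 1
                                j += 1

            # ---- joint flag-flip + parent-age redraw (x2) ----
            # Flipping a path flag alone is often blocked because the
            # lineage's coalescence time is only compatible with its current
            # path; redrawing the parent's age uniformly over its bracket
            # lets the chain jump between path configurations directly.
            # Path-flag mixing limits the phi effective sample size, so this
            # move and the flag scan below run twice per locus per sweep.
            for _rep_flag_move in range(2):
              mask = _cross_mask(pl, al, tip_pop, k, tauX, recipient,
                                 ch1, ch2, order, allrec)
              if mask != 0:
                nbits = 0
                m = mask
                while m != 0:
                    nbits += int(m & np.int64(1))
                    m >>= 1
                r = np.random.randint(0, nbits)
                m = mask
                j = 0
                pick = -1
                cnt = 0
                while m != 0:
                    if m & np.int64(1):
                        if cnt == r:
                            pick = j
                            break
                        cnt += 1
                    m >>= 1
                    j += 1
                _children(pl, ch1, ch2)
                pp = pl[pick]
                lb = al[ch1[pp]] if al[ch1[pp]] > al[ch2[pp]] else al[ch2[pp]]
                gpp = pl[pp]
                # the proposal box must not depend on the age being moved
                ub = al[gpp] if gpp >= 0 else lb + 8.0 * p[I_TAUR]
                old_t = al[pp]
                accept = False
                if ub > lb and old_t < ub:
                    fl[pick] ^= 1
                    al[pp] = lb + np.random.random() * (ub - lb)
                    new_mask = _cross_mask(pl, al, tip_pop, k, tauX, recipient,
                                           ch1, ch2, order, allrec)
                    pick_still_crossing = (new_mask >> pick) & np.int64(1)
                    newbits = new_mask & ~mask & ~(np.int64(1) << pick)
                    oldbits = mask & ~new_mask & ~(np.int64(1) << pick)
                    m = newbits
                    j = 0
                    while m != 0:
                        if m & np.int64(1):
                            flag_bak[j] = fl[j]
                            fl[j] = 1 if np.random.random() < phi else 0
                        m >>= 1
                        j += 1
                    ok = False
                    n1 = n0 = 0
                    if pick_still_crossing:
                        ok, n1, n0 = _locus_stats(pl, al, fl, tip_pop, k, p,
                                                  donor, recipient, c_tmp,
                                                  A_tmp, startpop, ch1, ch2,
                                                  order, seg_pop, seg_a, seg_b)
                    lln = 0.0
                    if ok:
                        nbits2 = 0
                        m = new_mask
                        while m != 0:
                            nbits2 += int(m & np.int64(1))
                            m >>= 1
                        ld_new = _ld_from_stats(c_tmp, A_tmp, p, n1, n0)
                        ld_old = _ld_from_stats(stats_c[l], stats_A[l], p,
                                                n1s[l], n0s[l])
                        lln = _jc_loglik(pl, al, k, tip_pat[l], pat_n[l],
                                         pat_w[l], order, partial)
                        logr = (ld_new - _flag_adjust(newbits, fl, phi)) \
                            - (ld_old - _flag_adjust(oldbits, fl, phi)) \
                            + lln - seq_ll[l] \
                            + np.log(nbits) - np.log(nbits2)
                        if logr >= 0.0 or np.log(np.random.random()) < logr:
                            accept = True
                    if accept:
                        for q in range(NPOP):
                            stats_c[l, q] = c_tmp[q]
                            stats_A[l, q] = A_tmp[q]
                        n1s[l] = n1
                        n0s[l] = n0
                        seq_ll[l] = lln
                    else:
                        al[pp] = old_t
                        fl[pick] ^= 1
                        m = newbits
                        j = 0
                        while m != 0:
                            if m & np.int64(1):
                                fl[j] = flag_bak[j]
                            m >>= 1
                            j += 1

            # ---- path-flag flips: sequential MH scan over crossing edges,
            # run twice per sweep (see note on the joint move above) ----
            for _rep_scan in range(2):
              mask = _cross_mask(pl, al, tip_pop, k, tauX, recipient,
                                 ch1, ch2, order, allrec)
              m = mask
              pick = 0
              while m != 0:
                if m & np.int64(1):
                    fl[pick] ^= 1
                    ok, n1, n0 = _locus_stats(pl, al, fl, tip_pop, k, p, donor,
                                              recipient, c_tmp, A_tmp, startpop,
                                              ch1, ch2, order,
                                              seg_pop, seg_a, seg_b)
                    accept = False
                    if ok:
                        ld_new = _ld_from_stats(c_tmp, A_tmp, p, n1, n0)
                        ld_old = _ld_from_stats(stats_c[l], stats_A[l], p,
                                                n1s[l], n0s[l])
                        logr = ld_new - ld_old
                        if logr >= 0.0 or np.log(np.random.random()) < logr:
                            accept = True
                    if accept:
                        for q in range(NPOP):
                            stats_c[l, q] = c_tmp[q]
                            stats_A[l, q] = A_tmp[q]
                        n1s[l] = n1
                        n0s[l] = n0
                    else:
                        fl[pick] ^= 1
                m >>= 1
                pick += 1

        # ---- phi: Gibbs (beta prior, binomial path counts) ----
        N1 = 0
        N0 = 0
        for l in range(L):
            N1 += n1s[l]
            N0 += n0s[l]
        p[I_PHI] = np.random.beta(phi_a + N1, phi_b + N0)
        phi = p[I_PHI]

        # ---- theta: log-scale random walks ----
        for pop in range(NPOP):
            watt[5] += 1.0
            if not burn:
                att[5] += 1
            Sc = 0.0
            SA = 0.0
            for l in range(L):
                Sc += stats_c[l, pop]
                SA += stats_A[l, pop]
            th = p[I_TH0 + pop]
            thn = th * np.exp(np.random.uniform(-w[5], w[5]))
            logr = Sc * (np.log(th) - np.log(thn)) - SA * (1.0 / thn - 1.0 / th) \
                + a_th * (np.log(thn) - np.log(th)) - b_th * (thn - th)
            if logr >= 0.0 or np.log(np.random.random()) < logr:
                p[I_TH0 + pop] = thn
                wacc[5] += 1.0
                if not burn:
                    acc[5] += 1

        # ---- tau_X: reflected slide; crossing sets may change ----
        watt[1] += 1.0
        if not burn:
            att[1] += 1
        txo = p[I_TAUX]
        txn = _reflect(txo + np.random.uniform(-w[1], w[1]), 0.0, p[I_TAUT])
        for q in range(p_try.shape[0]):
            p_try[q] = p[q]
        p_try[I_TAUX] = txn
        okall = True
        logr = 0.0
        for l in range(L):
            for j in range(nn):
                flagall_bak[l, j] = flag[l, j]
        for l in range(L):
            pl = parent[l]
            al = age[l]
            fl = flag[l]
            old_mask = _cross_mask(pl, al, tip_pop, k, txo, recipient,
                                   ch1, ch2, order, allrec)
            new_mask = _cross_mask(pl, al, tip_pop, k, txn, recipient,
                                   ch1, ch2, order, allrec)
            newbits = new_mask & ~old_mask
            oldbits = old_mask & ~new_mask
            m = newbits
            j = 0
            while m != 0:
                if m & np.int64(1):
                    fl[j] = 1 if np.random.random() < phi else 0
                m >>= 1
                j += 1
            ok, n1, n0 = _locus_stats(pl, al, fl, tip_pop, k, p_try, donor,
                                      recipient, c_tmp, A_tmp, startpop,
                                      ch1, ch2, order, seg_pop, seg_a, seg_b)
            if not ok:
                okall = False
                break
            for q in range(NPOP):
                c2[l, q] = c_tmp[q]
                A2[l, q] = A_tmp[q]
            n1_2[l] = n1
            n0_2[l] = n0
            ld_new = _ld_from_stats(c2[l], A2[l], p_try, n1, n0)
            ld_old = _ld_from_stats(stats_c[l], stats_A[l], p, n1s[l], n0s[l])
            logr += (ld_new - _flag_adjust(newbits, fl, phi)) \
                - (ld_old - _flag_adjust(oldbits, flagall_bak[l], phi))
        if okall and (logr >= 0.0 or np.log(np.random.random()) < logr):
            p[I_TAUX] = txn
            for l in range(L):
                for q in range(NPOP):
                    stats_c[l, q] = c2[l, q]
                    stats_A[l, q] = A2[l, q]
                n1s[l] = n1_2[l]
                n0s[l] = n0_2[l]
            wacc[1] += 1.0
            if not burn:
                acc[1] += 1
        else:
            for l in range(L):
                for j in range(nn):
                    flag[l, j] = flagall_bak[l, j]

        # ---- tau_T and tau_S: rubber-band moves (alternate sweeps: they
        # rescale gene-tree ages and re-evaluate most locus likelihoods,
        # dominating sweep cost when applied every sweep) ----
        for which in range(2 if sweep % 2 == 0 else 0):
            widx = 2 + which
            watt[widx] += 1.0
            if not burn:
                att[widx] += 1
            if which == 0:
                lb = p[I_TAUX]
                ub = p[I_TAUS]
                told = p[I_TAUT]
            else:
                lb = p[I_TAUT]
                ub = p[I_TAUR]
                told = p[I_TAUS]
            tnew = _reflect(told + np.random.uniform(-w[widx], w[widx]), lb, ub)
            s1 = (tnew - lb) / (told - lb)
            s2 = (ub - tnew) / (ub - told)
            logJ = 0.0
            for l in range(L):
                changed[l] = 0
                for j in range(nn):
                    age_bak[l, j] = age[l, j]
                    t = age[l, j]
                    if lb < t < ub:
                        if t <= told:
                            age[l, j] = lb + (t - lb) * s1
                            logJ += np.log(s1)
                        else:
                            age[l, j] = ub - (ub - t) * s2
                            logJ += np.log(s2)
                        changed[l] = 1
            for q in range(p_try.shape[0]):
                p_try[q] = p[q]
            p_try[I_TAUT if which == 0 else I_TAUS] = tnew
            okall = True
            logr = logJ
            if which == 0:
                # tau_X | tau_T is uniform on (0, tau_T)
                logr += np.log(told) - np.log(tnew)
            for l in range(L):
                ok, n1, n0 = _locus_stats(parent[l], age[l], flag[l], tip_pop,
                                          k, p_try, donor, recipient, c_tmp,
                                          A_tmp, startpop, ch1, ch2, order,
                                          seg_pop, seg_a, seg_b)
                if not ok:
                    okall = False
                    break
                for q in range(NPOP):
                    c2[l, q] = c_tmp[q]
                    A2[l, q] = A_tmp[q]
                n1_2[l] = n1
                n0_2[l] = n0
                ld_new = _ld_from_stats(c2[l], A2[l], p_try, n1, n0)
                ld_old = _ld_from_stats(stats_c[l], stats_A[l], p, n1s[l], n0s[l])
                logr += ld_new - ld_old
                if changed[l] == 1:
                    ll2[l] = _jc_loglik(parent[l], age[l], k, tip_pat[l],
                                        pat_n[l], pat_w[l], order, partial)
                    logr += ll2[l] - seq_ll[l]
                else:
                    ll2[l] = seq_ll[l]
            if okall and (logr >= 0.0 or np.log(np.random.random()) < logr):
                p[I_TAUT if which == 0 else I_TAUS] = tnew
                for l in range(L):
                    for q in range(NPOP):
                        stats_c[l, q] = c2[l, q]
                        stats_A[l, q] = A2[l, q]
                    n1s[l] = n1_2[l]
                    n0s[l] = n0_2[l]
                    seq_ll[l] = ll2[l]
                wacc[widx] += 1.0
                if not burn:
                    acc[widx] += 1
            else:
                for l in range(L):
                    for j in range(nn):
                        age[l, j] = age_bak[l, j]

        # ---- tau_R: multiplier rescaling all ages above tau_S ----
        rold = p[I_TAUR]
        lb = p[I_TAUS]
        mult = np.exp(np.random.uniform(-w[4], w[4]))
        rnew = rold * mult
        if sweep % 2 == 0 and rnew > lb:
            watt[4] += 1.0
            if not burn:
                att[4] += 1
            s = (rnew - lb) / (rold - lb)
            logJ = 0.0
            for l in range(L):
                changed[l] = 0
                for j in range(nn):
                    age_bak[l, j] = age[l, j]
                    t = age[l, j]
                    if t > lb:
                        age[l, j] = lb + (t - lb) * s
                        logJ += np.log(s)
                        changed[l] = 1
            for q in range(p_try.shape[0]):
                p_try[q] = p[q]
            p_try[I_TAUR] = rnew
            okall = True
            # gamma prior on tau_R, flat-simplex prior on (tau_T, tau_S)
            # contributing 2/tau_R^2, plus the multiplier Jacobian
            logr = logJ + (a_tau - 1.0) * (np.log(rnew) - np.log(rold)) \
                - b_tau * (rnew - rold) - 2.0 * (np.log(rnew) - np.log(rold)) \
                + np.log(mult)
            for l in range(L):
                ok, n1, n0 = _locus_stats(parent[l], age[l], flag[l], tip_pop,
                                          k, p_try, donor, recipient, c_tmp,
                                          A_tmp, startpop, ch1, ch2, order,
                                          seg_pop, seg_a, seg_b)
                if not ok:
                    okall = False
                    break
                for q in range(NPOP):
                    c2[l, q] = c_tmp[q]
                    A2[l, q] = A_tmp[q]
                n1_2[l] = n1
                n0_2[l] = n0
                ld_new = _ld_from_stats(c2[l], A2[l], p_try, n1, n0)
                ld_old = _ld_from_stats(stats_c[l], stats_A[l], p, n1s[l], n0s[l])
                logr += ld_new - ld_old
                if changed[l] == 1:
                    ll2[l] = _jc_loglik(parent[l], age[l], k, tip_pat[l],
                                        pat_n[l], pat_w[l], order, partial)
                    logr += ll2[l] - seq_ll[l]
                else:
                    ll2[l] = seq_ll[l]
            if okall and (logr >= 0.0 or np.log(np.random.random()) < logr):
                p[I_TAUR] = rnew
                for l in range(L):
                    for q in range(NPOP):
                        stats_c[l, q] = c2[l, q]
                        stats_A[l, q] = A2[l, q]
                    n1s[l] = n1_2[l]
                    n0s[l] = n0_2[l]
                    seq_ll[l] = ll2[l]
                wacc[4] += 1.0
                if not burn:
                    acc[4] += 1
            else:
                for l in range(L):
                    for j in range(nn):
                        age[l, j] = age_bak[l, j]

        # ---- adaptive tuning during burn-in ----
        if burn and (sweep + 1) % 100 == 0:
            for q in range(6):
                if watt[q] > 0.0:
                    rate = wacc[q] / watt[q]
                    fac = np.exp(1.5 * (rate - 0.3))
                    if fac < 0.5:
                        fac = 0.5
                    if fac > 2.0:
                        fac = 2.0
                    w[q] *= fac
                    if w[q] < 1e-9:
                        w[q] = 1e-9
                wacc[q] = 0.0
                watt[q] = 0.0

        # ---- record ----
        if not burn and (sweep - n_burn) % thin == 0:
            for q in range(12):
                trace[rec, q] = p[q]
            ldt = 0.0
            llt = 0.0
            for l in range(L):
                ldt += _ld_from_stats(stats_c[l], stats_A[l], p, n1s[l], n0s[l])
                llt += seq_ll[l]
            trace[rec, 12] = ldt
            trace[rec, 13] = llt
            rec += 1

    return trace, acc, att
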