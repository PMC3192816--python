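"""Continuous-time Monte Carlo kernel (numba-compiled).

One flat event loop over the whole system.  Per event the kernel makes two
identical passes over all reaction channels (lattice initiations, ribosome
moves, recharging channels): the first accumulates the total rate, the
second locates the sampled channel.  Floating-point accumulation order is
identical in both passes, so sampling is exactly proportional to the
current rates.

Observables are accumulated as time integrals over the measurement window
only, using a "flush on change" scheme: a ribosome's dwell time at a site
is added to the occupancy integral when it leaves the site, and a species'
charged count is integrated up to each instant its pool changes.  Integrals
are split over equal-length blocks of the measurement window for block
standard errors.
"""

import numpy as np
from numba import njit

# event kind codes
_NONE, _INIT, _ELONG, _TERM, _RECHARGE = 0, 1, 2, 3, 4


@njit(cache=True)
def _add_span_2d(arr, col, weight, t0, t1, t_burn, blk_len, n_blocks):
    """arr[blk, col] += weight * (overlap of [t0,t1] with each block)."""
    if t1 <= t_burn or weight == 0.0 or t1 <= t0:
        return
    lo = t0 if t0 > t_burn else t_burn
    b0 = int((lo - t_burn) / blk_len)
    b1 = int((t1 - t_burn) / blk_len)
    if b0 >= n_blocks:
        return
    if b1 >= n_blocks:
        b1 = n_blocks - 1
    for b in range(b0, b1 + 1):
        e0 = t_burn + b * blk_len
        e1 = e0 + blk_len
        a = lo if lo > e0 else e0
        z = t1 if t1 < e1 else e1
        if z > a:
            arr[b, col] += weight * (z - a)


@njit(cache=True)
def _scan(
    thresh,
    pos,
    nrib,
    lat_spec,
    seq,
    seq_off,
    Ls,
    a,
    b,
    Tint,
    V,
    K,
    kappa,
    alpha,
    beta,
    w,
    term_consumes,
    inf_recharge,
):
    """Walk all channels in fixed order.  With thresh < 0 returns the total
    rate; otherwise returns the channel in which the threshold falls."""
    nl = lat_spec.size
    S = a.size
    acc = 0.0
    for l in range(nl):
        r = lat_spec[l]
        off = seq_off[r]
        L = Ls[r]
        n = nrib[l]
        # initiation: entry codon always holds a ribosome ready to enter;
        # blocked while any reader sits at position <= w
        if n == 0 or pos[l, n - 1] > w:
            acc += alpha
            if thresh >= 0.0 and acc > thresh:
                return acc, _INIT, l, -1, -1
        for k2 in range(n):
            p = pos[l, k2]
            s = seq[off + p - 1]
            if p == L:
                rate = beta
                if term_consumes == 1 and inf_recharge == 0 and a[s] < 1:
                    rate = 0.0
                acc += rate
                if thresh >= 0.0 and acc > thresh:
                    return acc, _TERM, l, k2, s
            else:
                # exclusion: next reader ahead must leave a w-gap
                if k2 == 0 or pos[l, k2 - 1] >= p + 1 + w:
                    avail = Tint[s] if inf_recharge == 1 else a[s]
                    if avail > 0:
                        acc += kappa * avail
                        if thresh >= 0.0 and acc > thresh:
                            return acc, _ELONG, l, k2, s
    if inf_recharge == 0:
        for i in range(S):
            if b[i] > 0:
                acc += V[i] * b[i] / (K[i] + b[i])
                if thresh >= 0.0 and acc > thresh:
                    return acc, _RECHARGE, -1, -1, i
    return acc, _NONE, -1, -1, -1


@njit(cache=True)
def run_kernel(
    seed,
    lat_spec,
    seq,
    seq_off,
    Ls,
    Tint,
    V,
    K,
    kappa,
    alpha,
    beta,
    w,
    term_consumes,
    inf_recharge,
    t_burn,
    t_meas,
    n_blocks,
    max_events,
):
    np.random.seed(seed)
    nl = lat_spec.size
    S = Tint.size
    seq_total = seq.size
    t_end = t_burn + t_meas
    blk_len = t_meas / n_blocks

    cap = 0
    for r in range(Ls.size):
        c = Ls[r] // w + 2
        if c > cap:
            cap = c
    pos = np.zeros((nl, cap), dtype=np.int64)  # front (largest position) first
    arr = np.zeros((nl, cap), dtype=np.float64)  # arrival time at current site
    nrib = np.zeros(nl, dtype=np.int64)

    a = Tint.copy()  # charged
    b = np.zeros(S, dtype=np.int64)  # bare
    last_a_t = np.zeros(S, dtype=np.float64)

    occ = np.zeros((n_blocks, seq_total), dtype=np.float64)
    hops = np.zeros((n_blocks, seq_total), dtype=np.float64)
    term = np.zeros((n_blocks, Ls.size), dtype=np.float64)
    charge_int = np.zeros((n_blocks, S), dtype=np.float64)
    rib_int = np.zeros((n_blocks, 1), dtype=np.float64)
    consumed = np.zeros((n_blocks, S), dtype=np.float64)

    t = 0.0
    total_rib = 0
    n_events = 0
    while t < t_end and n_events < max_events:
        rtot, _, _, _, _ = _scan(
            -1.0, pos, nrib, lat_spec, seq, seq_off, Ls, a, b, Tint, V, K,
            kappa, alpha, beta, w, term_consumes, inf_recharge,
        )
        if rtot <= 0.0:
            _add_span_2d(rib_int, 0, float(total_rib), t, t_end, t_burn, blk_len, n_blocks)
            t = t_end
            break
        u = np.random.random()
        while u <= 0.0:
            u = np.random.random()
        dt = -np.log(u) / rtot
        tn = t + dt
        tcap = tn if tn < t_end else t_end
        _add_span_2d(rib_int, 0, float(total_rib), t, tcap, t_burn, blk_len, n_blocks)
        if tn >= t_end:
            t = t_end
            break
        x = np.random.random() * rtot
        _, kind, l, k2, s = _scan(
            x, pos, nrib, lat_spec, seq, seq_off, Ls, a, b, Tint, V, K,
            kappa, alpha, beta, w, term_consumes, inf_recharge,
        )
        blk = -1
        if tn >= t_burn:
            blk = int((tn - t_burn) / blk_len)
            if blk >= n_blocks:
                blk = n_blocks - 1
        if kind == _NONE:
            # threshold fell past the last channel by round-off: retry
            t = tn
            continue
        if kind == _INIT:
            n = nrib[l]
            pos[l, n] = 1
            arr[l, n] = tn
            nrib[l] = n + 1
            total_rib += 1
        elif kind == _ELONG:
            r = lat_spec[l]
            g = seq_off[r] + pos[l, k2] - 1
            _add_span_2d(occ, g, 1.0, arr[l, k2], tn, t_burn, blk_len, n_blocks)
            if blk >= 0:
                hops[blk, g] += 1.0
            pos[l, k2] += 1
            arr[l, k2] = tn
            if inf_recharge == 0:
                _add_span_2d(charge_int, s, float(a[s]), last_a_t[s], tn, t_burn, blk_len, n_blocks)
                last_a_t[s] = tn
                a[s] -= 1
                b[s] += 1
                if blk >= 0:
                    consumed[blk, s] += 1.0
        elif kind == _TERM:
            r = lat_spec[l]
            L = Ls[r]
            g = seq_off[r] + L - 1
            _add_span_2d(occ, g, 1.0, arr[l, k2], tn, t_burn, blk_len, n_blocks)
            if blk >= 0:
                hops[blk, g] += 1.0
                term[blk, r] += 1.0
            n = nrib[l]
            for j in range(k2, n - 1):
                pos[l, j] = pos[l, j + 1]
                arr[l, j] = arr[l, j + 1]
            nrib[l] = n - 1
            total_rib -= 1
            if term_consumes == 1 and inf_recharge == 0:
                _add_span_2d(charge_int, s, float(a[s]), last_a_t[s], tn, t_burn, blk_len, n_blocks)
                last_a_t[s] = tn
                a[s] -= 1
                b[s] += 1
                if blk >= 0:
                    consumed[blk, s] += 1.0
        else:  # recharge
            i = s
            _add_span_2d(charge_int, i, float(a[i]), last_a_t[i], tn, t_burn, blk_len, n_blocks)
            last_a_t[i] = tn
            b[i] -= 1
            a[i] += 1
        t = tn
        n_events += 1

    # final flush
    for l in range(nl):
        r = lat_spec[l]
        off = seq_off[r]
        for k2 in range(nrib[l]):
            g = off + pos[l, k2] - 1
            _add_span_2d(occ, g, 1.0, arr[l, k2], t, t_burn, blk_len, n_blocks)
    if inf_recharge == 0:
        for i in range(S):
            _add_span_2d(charge_int, i, float(a[i]), last_a_t[i], t, t_burn, blk_len, n_blocks)
    else:
        for i in range(S):
            for blkk in range(n_blocks):
                charge_int[blkk, i] = float(Tint[i]) * blk_len

    # final state snapshot
    final_pos = np.full((nl, cap), -1, dtype=np.int64)
    for l in range(nl):
        for k2 in range(nrib[l]):
            final_pos[l, k2] = pos[l, k2]

    return occ, hops, term, charge_int, rib_int, consumed, final_pos, nrib, a, b, t, n_events
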