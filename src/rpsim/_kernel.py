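"""Compiled single-step update of the whole world.

The scheduler executes, per discrete step of length dt:

1. compaction of the entity arrays and a rebuild of the uniform-grid
   neighbor index (deterministic: done at every step start, so results do
   not depend on how many steps a caller batches together);
2. clock decrements and decay removals (free-molecule lifetimes; complex
   dissociation clocks; in "ticking" mode also the lifetimes of molecules
   bound inside complexes, whose expiry frees the surviving partner);
3. a random processing order over all entities (free molecules and
   complexes alike);
4. per entity, in that order: overdue complexes dissociate; otherwise the
   entity takes a pre-move neighbor census (strict center distance <
   collision radius, complexes counted as single points), is removed if
   crowded beyond n_max, moves by one Brownian increment, and then either
   (complex) counts down its replication clock and on expiry replicates
   and releases its components, or (free molecule) tries the shuffled
   census in order for a partner that passes the omega = a*(1-l) test,
   forming a complex at the pair midpoint with the first that does.

Entities created during a step occupy space immediately (they are seen by
later censuses within the same step) but take no actions until the next
step.  Every random decision consumes, in a fixed documented order, from
the single xorshift64* stream in ``rpsim._rng``.

Entity storage is a set of parallel arrays; float fields live in the
columns of one (capacity, 10) array indexed by the F_* constants below.
For a free molecule the A/L/RLT columns are its own attributes and
lifetime; for a complex they are the *template's* (with SP the template
species), the CA/CL/CRLT columns the catalyst's, and TTR/DISS the
replication and dissociation clocks.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ._rng import normal_pair, open_uniform, randint, shuffle, uniform

# float field columns
F_X, F_Y, F_A, F_L, F_RLT, F_TTR, F_DISS, F_CA, F_CL, F_CRLT = range(10)
NF = 10

KIND_FREE = 0
KIND_CPLX = 1
SP_R = 0
SP_P = 1

INF = 1.0e300
NBR_CAP = 256

# per-step output slots
O_NRF, O_NPF, O_NRR, O_NRP = 0, 1, 2, 3
O_SAR, O_SAR2, O_SLR, O_SLR2 = 4, 5, 6, 7
O_SAP, O_SAP2, O_SLP, O_SLP2 = 8, 9, 10, 11
O_DECF, O_DECC, O_DISS, O_REPL, O_FORM, O_OVE, O_OVM = 12, 13, 14, 15, 16, 17, 18
O_NALIVE, O_ERR = 19, 20
OUT_LEN = 21


@njit(cache=True)
def _wrap1(v, L):
    v = v - L * math.floor(v / L)
    if v >= L:
        v = 0.0
    return v


@njit(cache=True)
def _mi1(d, L):
    return d - L * math.floor(d / L + 0.5)


@njit(cache=True)
def _cell_of(x, y, gw, gh, csx, csy):
    cx = int(x / csx)
    cy = int(y / csy)
    if cx >= gw:
        cx = gw - 1
    if cy >= gh:
        cy = gh - 1
    return cy * gw + cx


@njit(cache=True)
def _grid_insert(i, c, head, nxt, prv, cellof):
    j = head[c]
    nxt[i] = j
    prv[i] = -1
    cellof[i] = c
    if j != -1:
        prv[j] = i
    head[c] = i


@njit(cache=True)
def _grid_remove(i, head, nxt, prv, cellof):
    p = prv[i]
    n = nxt[i]
    if p != -1:
        nxt[p] = n
    else:
        head[cellof[i]] = n
    if n != -1:
        prv[n] = p


@njit(cache=True)
def _kill(i, alive, head, nxt, prv, cellof):
    alive[i] = 0
    _grid_remove(i, head, nxt, prv, cellof)


@njit(cache=True)
def _append_free(slot, species, a, l, rlt, ident, x, y,
                 ent, alive, kind, sp, mid, cid,
                 head, nxt, prv, cellof, gw, gh, csx, csy, out):
    if slot >= ent.shape[0]:
        out[O_ERR] = 1.0
        return slot
    ent[slot, F_X] = x
    ent[slot, F_Y] = y
    ent[slot, F_A] = a
    ent[slot, F_L] = l
    ent[slot, F_RLT] = rlt
    ent[slot, F_TTR] = 0.0
    ent[slot, F_DISS] = 0.0
    ent[slot, F_CA] = 0.0
    ent[slot, F_CL] = 0.0
    ent[slot, F_CRLT] = 0.0
    alive[slot] = 1
    kind[slot] = KIND_FREE
    sp[slot] = species
    mid[slot] = ident
    cid[slot] = -1
    _grid_insert(slot, _cell_of(x, y, gw, gh, csx, csy), head, nxt, prv, cellof)
    return slot + 1


@njit(cache=True)
def _dissociate(i, n_top,
                ent, alive, kind, sp, mid, cid,
                head, nxt, prv, cellof, gw, gh, csx, csy, out):
    """Release catalyst then template as free molecules at the complex
    position, carrying their current stored lifetime clocks."""
    x = ent[i, F_X]
    y = ent[i, F_Y]
    n_top = _append_free(n_top, SP_R, ent[i, F_CA], ent[i, F_CL], ent[i, F_CRLT],
                         cid[i], x, y, ent, alive, kind, sp, mid, cid,
                         head, nxt, prv, cellof, gw, gh, csx, csy, out)
    n_top = _append_free(n_top, sp[i], ent[i, F_A], ent[i, F_L], ent[i, F_RLT],
                         mid[i], x, y, ent, alive, kind, sp, mid, cid,
                         head, nxt, prv, cellof, gw, gh, csx, csy, out)
    _kill(i, alive, head, nxt, prv, cellof)
    return n_top


@njit(cache=True)
def _census(i, ent, alive, head, nxt, cellof, gw, gh, csx, csy, W, H, rc,
            nbr, limit):
    """Pre-move neighbor census: indices of all other live entities with
    center-to-center minimal-image distance strictly below rc.  Stops as
    soon as the count exceeds ``limit`` (the crowding threshold): the
    caller then removes the entity and never consumes the set."""
    x = ent[i, F_X]
    y = ent[i, F_Y]
    cx = int(x / csx)
    cy = int(y / csy)
    if cx >= gw:
        cx = gw - 1
    if cy >= gh:
        cy = gh - 1
    rc2 = rc * rc
    nn = 0
    for dy in range(-1, 2):
        ccy = (cy + dy) % gh
        for dx in range(-1, 2):
            ccx = (cx + dx) % gw
            j = head[ccy * gw + ccx]
            while j != -1:
                if j != i and alive[j]:
                    ddx = _mi1(ent[j, F_X] - x, W)
                    ddy = _mi1(ent[j, F_Y] - y, H)
                    if ddx * ddx + ddy * ddy < rc2:
                        if nn < NBR_CAP:
                            nbr[nn] = j
                        nn += 1
                        if nn > limit:
                            return nn
                j = nxt[j]
    return nn


@njit(cache=True)
def record_kernel(ent, alive, kind, sp, n_top, out):
    """Exact counts and attribute sums/sum-of-squares per species over the
    whole living population, complexed members included."""
    for k in range(O_NRF, O_SLP2 + 1):
        out[k] = 0.0
    out[O_NALIVE] = 0.0
    for i in range(n_top):
        if alive[i] == 0:
            continue
        out[O_NALIVE] += 1.0
        if kind[i] == KIND_FREE:
            if sp[i] == SP_R:
                out[O_NRF] += 1.0
                out[O_SAR] += ent[i, F_A]
                out[O_SAR2] += ent[i, F_A] * ent[i, F_A]
                out[O_SLR] += ent[i, F_L]
                out[O_SLR2] += ent[i, F_L] * ent[i, F_L]
            else:
                out[O_NPF] += 1.0
                out[O_SAP] += ent[i, F_A]
                out[O_SAP2] += ent[i, F_A] * ent[i, F_A]
                out[O_SLP] += ent[i, F_L]
                out[O_SLP2] += ent[i, F_L] * ent[i, F_L]
        else:
            # catalyst is always a replicase
            out[O_SAR] += ent[i, F_CA]
            out[O_SAR2] += ent[i, F_CA] * ent[i, F_CA]
            out[O_SLR] += ent[i, F_CL]
            out[O_SLR2] += ent[i, F_CL] * ent[i, F_CL]
            if sp[i] == SP_R:
                out[O_NRR] += 1.0
                out[O_SAR] += ent[i, F_A]
                out[O_SAR2] += ent[i, F_A] * ent[i, F_A]
                out[O_SLR] += ent[i, F_L]
                out[O_SLR2] += ent[i, F_L] * ent[i, F_L]
            else:
                out[O_NRP] += 1.0
                out[O_SAP] += ent[i, F_A]
                out[O_SAP2] += ent[i, F_A] * ent[i, F_A]
                out[O_SLP] += ent[i, F_L]
                out[O_SLP2] += ent[i, F_L] * ent[i, F_L]


@njit(cache=True)
def rebuild_grid(ent, alive, n_top, head, nxt, prv, cellof, gw, gh, csx, csy):
    for c in range(gw * gh):
        head[c] = -1
    for i in range(n_top):
        if alive[i]:
            _grid_insert(i, _cell_of(ent[i, F_X], ent[i, F_Y], gw, gh, csx, csy),
                         head, nxt, prv, cellof)


@njit(cache=True)
def step_kernel(ent, alive, kind, sp, mid, cid,
                head, nxt, prv, cellof, gw, gh,
                W, H,
                dt, d_rate, D_free, D_cplx, K_rate, rc, n_max,
                mu_aR, mu_lR, mu_aP, mu_lP, delta, off_dist,
                ticking,
                n_top, next_id, do_compact,
                order, nbr, rng, out):
    """Advance the world by one step of length dt.  Returns the new entity
    high-water mark and the next unused molecule id.

    ``do_compact`` squeezes dead rows out of the arrays and rebuilds the
    grid before the step; the caller requests it on a fixed, state-derived
    schedule so that trajectories are a function of (config, seed) only.
    """
    csx = W / gw
    csy = H / gh
    for k in range(OUT_LEN):
        out[k] = 0.0

    # --- compaction (stable) -------------------------------------------
    if do_compact:
        m = 0
        for i in range(n_top):
            if alive[i]:
                if m != i:
                    for f in range(NF):
                        ent[m, f] = ent[i, f]
                    kind[m] = kind[i]
                    sp[m] = sp[i]
                    mid[m] = mid[i]
                    cid[m] = cid[i]
                    alive[m] = 1
                    alive[i] = 0
                m += 1
        n_top = m
        rebuild_grid(ent, alive, n_top, head, nxt, prv, cellof, gw, gh, csx, csy)
    n_start = n_top

    # --- clock decrements and decay ------------------------------------
    for i in range(n_start):
        if alive[i] == 0:
            continue
        if kind[i] == KIND_FREE:
            ent[i, F_RLT] -= dt
            if ent[i, F_RLT] <= 0.0:
                _kill(i, alive, head, nxt, prv, cellof)
                out[O_DECF] += 1.0
        else:
            ent[i, F_DISS] -= dt
            if ticking:
                ent[i, F_CRLT] -= dt
                ent[i, F_RLT] -= dt
                cat_dead = ent[i, F_CRLT] <= 0.0
                tpl_dead = ent[i, F_RLT] <= 0.0
                if cat_dead and tpl_dead:
                    _kill(i, alive, head, nxt, prv, cellof)
                    out[O_DECC] += 2.0
                elif cat_dead:
                    n_top = _append_free(n_top, sp[i], ent[i, F_A], ent[i, F_L],
                                         ent[i, F_RLT], mid[i],
                                         ent[i, F_X], ent[i, F_Y],
                                         ent, alive, kind, sp, mid, cid,
                                         head, nxt, prv, cellof, gw, gh, csx, csy, out)
                    _kill(i, alive, head, nxt, prv, cellof)
                    out[O_DECC] += 1.0
                elif tpl_dead:
                    n_top = _append_free(n_top, SP_R, ent[i, F_CA], ent[i, F_CL],
                                         ent[i, F_CRLT], cid[i],
                                         ent[i, F_X], ent[i, F_Y],
                                         ent, alive, kind, sp, mid, cid,
                                         head, nxt, prv, cellof, gw, gh, csx, csy, out)
                    _kill(i, alive, head, nxt, prv, cellof)
                    out[O_DECC] += 1.0

    # --- random processing order over all entities ----------------------
    n_ord = 0
    for i in range(n_top):
        if alive[i]:
            order[n_ord] = i
            n_ord += 1
    shuffle(order, n_ord, rng)

    # --- per-entity actions ---------------------------------------------
    for oi in range(n_ord):
        i = order[oi]
        if alive[i] == 0:
            continue

        if kind[i] == KIND_CPLX and ent[i, F_DISS] <= 0.0:
            n_top = _dissociate(i, n_top, ent, alive, kind, sp, mid, cid,
                                head, nxt, prv, cellof, gw, gh, csx, csy, out)
            out[O_DISS] += 1.0
            continue

        nn = _census(i, ent, alive, head, nxt, cellof, gw, gh, csx, csy,
                     W, H, rc, nbr, n_max)
        if nn > n_max:
            out[O_OVE] += 1.0
            out[O_OVM] += 2.0 if kind[i] == KIND_CPLX else 1.0
            _kill(i, alive, head, nxt, prv, cellof)
            continue
        if kind[i] == KIND_FREE:
            # reaction partners are tried in random order; complexes never
            # consume their neighbor set, so no draw is spent on them
            shuffle(nbr, nn, rng)

        # Brownian move (pre-move census already taken)
        coef = D_cplx if kind[i] == KIND_CPLX else D_free
        g1, g2 = normal_pair(rng)
        s = math.sqrt(2.0 * coef * dt)
        nx = _wrap1(ent[i, F_X] + s * g1, W)
        ny = _wrap1(ent[i, F_Y] + s * g2, H)
        c_old = cellof[i]
        c_new = _cell_of(nx, ny, gw, gh, csx, csy)
        ent[i, F_X] = nx
        ent[i, F_Y] = ny
        if c_new != c_old:
            _grid_remove(i, head, nxt, prv, cellof)
            _grid_insert(i, c_new, head, nxt, prv, cellof)

        if kind[i] == KIND_CPLX:
            ent[i, F_TTR] -= dt
            if ent[i, F_TTR] <= 0.0:
                # replicate: offspring copies the template, then mutates
                osp = sp[i]
                oa = ent[i, F_A]
                ol = ent[i, F_L]
                mua = mu_aR if osp == SP_R else mu_aP
                mul = mu_lR if osp == SP_R else mu_lP
                if mua > 0.0 and uniform(rng) < mua:
                    oa = oa + (2.0 * uniform(rng) - 1.0) * delta
                    oa = min(1.0, max(0.0, oa))
                if mul > 0.0 and uniform(rng) < mul:
                    ol = ol + (2.0 * uniform(rng) - 1.0) * delta
                    ol = min(1.0, max(0.0, ol))
                orlt = INF if d_rate <= 0.0 else -math.log(open_uniform(rng)) / d_rate
                th = 2.0 * math.pi * uniform(rng)
                ox = _wrap1(ent[i, F_X] + off_dist * math.cos(th), W)
                oy = _wrap1(ent[i, F_Y] + off_dist * math.sin(th), H)
                n_top = _append_free(n_top, osp, oa, ol, orlt, next_id, ox, oy,
                                     ent, alive, kind, sp, mid, cid,
                                     head, nxt, prv, cellof, gw, gh, csx, csy, out)
                next_id += 1
                out[O_REPL] += 1.0
                # immediate post-replication release (not a clock dissociation)
                n_top = _dissociate(i, n_top, ent, alive, kind, sp, mid, cid,
                                    head, nxt, prv, cellof, gw, gh, csx, csy, out)
        else:
            xi_sp = sp[i]
            for kk in range(nn):
                j = nbr[kk]
                if alive[j] == 0 or kind[j] == KIND_CPLX:
                    continue
                if xi_sp == SP_P and sp[j] == SP_P:
                    continue
                # template selection: a parasite is always the template;
                # between two replicases the non-initiator is
                if xi_sp == SP_P:
                    t_idx, c_idx = i, j
                elif sp[j] == SP_P:
                    t_idx, c_idx = j, i
                else:
                    t_idx, c_idx = j, i
                w = ent[t_idx, F_A] * (1.0 - ent[t_idx, F_L])
                if uniform(rng) < w:
                    dx = _mi1(ent[j, F_X] - ent[i, F_X], W)
                    dy = _mi1(ent[j, F_Y] - ent[i, F_Y], H)
                    mx = _wrap1(ent[i, F_X] + 0.5 * dx, W)
                    my = _wrap1(ent[i, F_Y] + 0.5 * dy, H)
                    ttr0 = -math.log(open_uniform(rng)) / K_rate
                    ad = 1.0 - ent[t_idx, F_A]
                    diss0 = INF if ad <= 0.0 else -math.log(open_uniform(rng)) / ad
                    slot = n_top
                    if slot >= ent.shape[0]:
                        out[O_ERR] = 1.0
                        break
                    ent[slot, F_X] = mx
                    ent[slot, F_Y] = my
                    ent[slot, F_A] = ent[t_idx, F_A]
                    ent[slot, F_L] = ent[t_idx, F_L]
                    ent[slot, F_RLT] = ent[t_idx, F_RLT]
                    ent[slot, F_TTR] = ttr0
                    ent[slot, F_DISS] = diss0
                    ent[slot, F_CA] = ent[c_idx, F_A]
                    ent[slot, F_CL] = ent[c_idx, F_L]
                    ent[slot, F_CRLT] = ent[c_idx, F_RLT]
                    alive[slot] = 1
                    kind[slot] = KIND_CPLX
                    sp[slot] = sp[t_idx]
                    mid[slot] = mid[t_idx]
                    cid[slot] = mid[c_idx]
                    _grid_insert(slot, _cell_of(mx, my, gw, gh, csx, csy),
                                 head, nxt, prv, cellof)
                    n_top = slot + 1
                    _kill(i, alive, head, nxt, prv, cellof)
                    _kill(j, alive, head, nxt, prv, cellof)
                    out[O_FORM] += 1.0
                    break

    record_kernel(ent, alive, kind, sp, n_top, out)
    return n_top, next_id


@njit(cache=True)
def census_all(ent, alive, kind, n_top, head, nxt, prv, cellof, gw, gh,
               W, H, rc, nbr):
    """Neighbor count for every live entity (diagnostic; used to check the
    grid census against an independent neighbor search)."""
    counts = np.full(n_top, -1, dtype=np.int64)
    for i in range(n_top):
        if alive[i]:
            counts[i] = _census(i, ent, alive, head, nxt, cellof, gw, gh,
                                W / gw, H / gh, W, H, rc, nbr, NBR_CAP)
    return counts
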