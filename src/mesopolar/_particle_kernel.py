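"""Compiled Brownian-dynamics core (λ-ρ reactions, periodic 2D square).

Per time step: Euler-Maruyama displacement of every molecule, independent
Bernoulli trials for first-order reactions (P = 1-exp(-k·Δt)), then
bimolecular attempts over all reactant pairs within their reactive radius
(P = 1-exp(-λ·Δt)).  Pair candidates come from a cell list (or an all-pairs
scan for small N); the candidate list is shuffled and processed sequentially,
a molecule reacting at most once per step.  Dissociation places one product
at the complex position and the other at distance ρ+ε in a uniformly random
direction.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _wrap(x, L):
    if x >= L:
        return x - L
    if x < 0.0:
        return x + L
    return x


@njit(cache=True, inline="always")
def _mi(d, L):
    # minimum-image displacement on the circle of circumference L
    if d > 0.5 * L:
        return d - L
    if d < -0.5 * L:
        return d + L
    return d


@njit(cache=True)
def _collect_pairs_brute(
    pos, spec, alive, n_hi, pairmap, b_rho2, L, pair_i, pair_j, pair_r
):
    cnt = 0
    cap = pair_i.shape[0]
    for i in range(n_hi):
        if not alive[i]:
            continue
        for j in range(i + 1, n_hi):
            if not alive[j]:
                continue
            r = pairmap[spec[i], spec[j]]
            if r < 0:
                continue
            dx = _mi(pos[i, 0] - pos[j, 0], L)
            dy = _mi(pos[i, 1] - pos[j, 1], L)
            if dx * dx + dy * dy <= b_rho2[r]:
                if cnt >= cap:
                    return -1
                pair_i[cnt] = i
                pair_j[cnt] = j
                pair_r[cnt] = r
                cnt += 1
    return cnt


@njit(cache=True)
def _collect_pairs_cells(
    pos, spec, alive, n_hi, pairmap, b_rho2, L,
    ncell, head, nxt, pair_i, pair_j, pair_r,
):
    cell = L / ncell
    for c in range(ncell * ncell):
        head[c] = -1
    for i in range(n_hi):
        if not alive[i]:
            continue
        cx = np.int64(pos[i, 0] / cell)
        cy = np.int64(pos[i, 1] / cell)
        if cx >= ncell:
            cx = ncell - 1
        if cy >= ncell:
            cy = ncell - 1
        c = cy * ncell + cx
        nxt[i] = head[c]
        head[c] = i
    cnt = 0
    cap = pair_i.shape[0]
    for cy in range(ncell):
        for cx in range(ncell):
            c = cy * ncell + cx
            i = head[c]
            while i >= 0:
                for oy in range(-1, 2):
                    for ox in range(-1, 2):
                        nc = ((cy + oy) % ncell) * ncell + (cx + ox) % ncell
                        j = head[nc]
                        while j >= 0:
                            if j > i:
                                r = pairmap[spec[i], spec[j]]
                                if r >= 0:
                                    dx = _mi(pos[i, 0] - pos[j, 0], L)
                                    dy = _mi(pos[i, 1] - pos[j, 1], L)
                                    if dx * dx + dy * dy <= b_rho2[r]:
                                        if cnt >= cap:
                                            return -1
                                        pair_i[cnt] = i
                                        pair_j[cnt] = j
                                        pair_r[cnt] = r
                                        cnt += 1
                            j = nxt[j]
                i = nxt[i]
    return cnt


@njit(cache=True)
def _run_particles(
    pos, spec, alive, n_hi0,
    sigma,  # per-species step scale sqrt(2 D dt)
    u_off, u_idx, u_p, u_nprod, u_prod, u_sep,
    pairmap, b_p, b_rho2, b_nprod, b_prod, b_at,
    L, nsteps, rec_every,
    totals_out, pos_out, spec_out, record_positions,
    ncell,
):
    """Advance nsteps; record totals (and optionally positions) every
    rec_every steps, starting with the initial state.  Returns (n_hi, flag);
    flag = -1 signals pair-buffer overflow."""
    cap = pos.shape[0]
    S = sigma.shape[0]
    n_hi = n_hi0
    free = np.empty(cap, dtype=np.int64)
    n_free = 0
    maxp = max(8 * cap, 4096)
    pair_i = np.empty(maxp, dtype=np.int64)
    pair_j = np.empty(maxp, dtype=np.int64)
    pair_r = np.empty(maxp, dtype=np.int64)
    head = np.empty(ncell * ncell, dtype=np.int64)
    nxt = np.empty(cap, dtype=np.int64)
    used = np.zeros(cap, dtype=np.uint8)
    rec_i = 0

    for step in range(nsteps + 1):
        if step % rec_every == 0:
            for s in range(S):
                totals_out[rec_i, s] = 0
            for i in range(n_hi):
                if alive[i]:
                    totals_out[rec_i, spec[i]] += 1
            if record_positions:
                for i in range(cap):
                    if i < n_hi and alive[i]:
                        spec_out[rec_i, i] = spec[i]
                        pos_out[rec_i, i, 0] = pos[i, 0]
                        pos_out[rec_i, i, 1] = pos[i, 1]
                    else:
                        spec_out[rec_i, i] = -1
            rec_i += 1
        if step == nsteps:
            break

        # 1. Brownian displacement
        for i in range(n_hi):
            if not alive[i]:
                continue
            sg = sigma[spec[i]]
            if sg > 0.0:
                pos[i, 0] = _wrap(pos[i, 0] + sg * np.random.standard_normal(), L)
                pos[i, 1] = _wrap(pos[i, 1] + sg * np.random.standard_normal(), L)

        # 2. first-order reactions
        for i in range(n_hi):
            if not alive[i]:
                continue
            s = spec[i]
            for k in range(u_off[s], u_off[s + 1]):
                r = u_idx[k]
                if np.random.random() < u_p[r]:
                    npd = u_nprod[r]
                    if npd == 0:
                        alive[i] = False
                        free[n_free] = i
                        n_free += 1
                    elif npd == 1:
                        spec[i] = u_prod[r, 0]
                    else:
                        spec[i] = u_prod[r, 0]
                        if n_free > 0:
                            n_free -= 1
                            inew = free[n_free]
                        else:
                            inew = n_hi
                            n_hi += 1
                        theta = 2.0 * np.pi * np.random.random()
                        sep = u_sep[r]
                        pos[inew, 0] = _wrap(pos[i, 0] + sep * np.cos(theta), L)
                        pos[inew, 1] = _wrap(pos[i, 1] + sep * np.sin(theta), L)
                        spec[inew] = u_prod[r, 1]
                        alive[inew] = True
                    break

        # 3. bimolecular attempts
        if ncell >= 3 and n_hi > 64:
            npairs = _collect_pairs_cells(
                pos, spec, alive, n_hi, pairmap, b_rho2, L,
                ncell, head, nxt, pair_i, pair_j, pair_r,
            )
        else:
            npairs = _collect_pairs_brute(
                pos, spec, alive, n_hi, pairmap, b_rho2, L,
                pair_i, pair_j, pair_r,
            )
        if npairs < 0:
            return n_hi, -1
        # Fisher-Yates shuffle of the candidate list
        for k in range(npairs - 1, 0, -1):
            m = np.int64(np.random.random() * (k + 1))
            if m > k:
                m = k
            pair_i[k], pair_i[m] = pair_i[m], pair_i[k]
            pair_j[k], pair_j[m] = pair_j[m], pair_j[k]
            pair_r[k], pair_r[m] = pair_r[m], pair_r[k]
        for k in range(npairs):
            i = pair_i[k]
            j = pair_j[k]
            if used[i] or used[j]:
                continue
            r = pair_r[k]
            if np.random.random() >= b_p[r]:
                continue
            used[i] = 1
            used[j] = 1
            # orient: a is the molecule whose species is reactant_a
            # (reactant species are always distinct, so this is unambiguous)
            a = i
            b = j
            if spec[i] != b_at[r, 0]:
                a = j
                b = i
            if b_nprod[r] == 1:
                keep = a if b_at[r, 1] == 0 else b
                drop = b if keep == a else a
                spec[keep] = b_prod[r, 0]
                alive[drop] = False
                free[n_free] = drop
                n_free += 1
            else:
                m0 = a if b_at[r, 2] == 0 else b
                m1 = a if b_at[r, 3] == 0 else b
                s0 = b_prod[r, 0]
                s1 = b_prod[r, 1]
                spec[m0] = s0
                spec[m1] = s1
        for k in range(npairs):
            used[pair_i[k]] = 0
            used[pair_j[k]] = 0

    return n_hi, 0


@njit(cache=True)
def _pair_first_passage(n_trials, L, d_tot, rho2, p_react, dt, max_steps):
    """First-reaction times for an isolated A-B pair on the periodic square.

    Uses the relative coordinate (diffusivity D_A + D_B); reaction is tested
    each step when the minimum-image separation is within the reactive
    radius.  Returns NaN where no reaction occurred within max_steps."""
    out = np.empty(n_trials)
    sg = np.sqrt(2.0 * d_tot * dt)
    for trial in range(n_trials):
        dx = np.random.random() * L
        dy = np.random.random() * L
        t = np.nan
        for step in range(max_steps):
            dxm = _mi(dx, L)
            dym = _mi(dy, L)
            if dxm * dxm + dym * dym <= rho2:
                if np.random.random() < p_react:
                    t = (step + 1) * dt
                    break
            dx = _wrap(dx + sg * np.random.standard_normal(), L)
            dy = _wrap(dy + sg * np.random.standard_normal(), L)
        out[trial] = t
    return out


@njit(cache=True)
def _seed(seed):
    np.random.seed(seed)


@njit(cache=True)
def _place_uniform(pos, n0, L):
    for i in range(n0):
        pos[i, 0] = np.random.random() * L
        pos[i, 1] = np.random.random() * L
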