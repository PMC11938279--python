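"""Low-level face-spiral routines.

Two parallel implementations live here.  The pure-Python functions are the
readable reference used for single windups/unwinds and as a cross-check; the
numba kernels repeat the same semantics on flat arrays and power the
backtracking enumerator, the canonicity filter and the acceptance-rejection
sampler, which would otherwise dominate every desk-scale experiment.

Windup semantics (shared by both implementations)
-------------------------------------------------
Dual-side spiral: vertex ``j`` of the triangulation has target degree
``caps[j]`` (5 or 6).  The open boundary of the partial patch is a list of
unsaturated vertices in spiral order.  Each new vertex connects to the
boundary head (previous vertex) and tail (earliest open vertex), cascading
over saturated ends; the last vertex must close every remaining open vertex
exactly.  Any double edge, degree overflow, premature closure or pinched
spiral is a rejection.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# --------------------------------------------------------------------------
# pure-Python reference
# --------------------------------------------------------------------------


def windup_adj_py(caps):
    """Wind a face-size sequence into dual-triangulation adjacency sets.

    Returns a list of neighbour sets (vertex ids = spiral positions) or
    ``None`` when the spiral does not close.
    """
    m = len(caps)
    if m < 4:
        return None
    adj = [set() for _ in range(m)]
    used = [0] * m

    def connect(a, b):
        if a == b or b in adj[a]:
            return False
        if used[a] >= caps[a] or used[b] >= caps[b]:
            return False
        adj[a].add(b)
        adj[b].add(a)
        used[a] += 1
        used[b] += 1
        return True

    bnd = [0]
    for j in range(1, m):
        if j == m - 1:
            for x in list(bnd):
                if not connect(j, x):
                    return None
            if used[j] != caps[j]:
                return None
            if any(used[v] != caps[v] for v in range(m)):
                return None
            return adj
        if not connect(j, bnd[-1]):
            return None
        while used[bnd[-1]] == caps[bnd[-1]]:
            bnd.pop()
            if not bnd:
                return None
            if not connect(j, bnd[-1]):
                return None
        if bnd[0] not in adj[j]:
            if not connect(j, bnd[0]):
                return None
        while used[bnd[0]] == caps[bnd[0]]:
            bnd.pop(0)
            if not bnd:
                return None
            if bnd[0] in adj[j]:
                continue
            if not connect(j, bnd[0]):
                return None
        if used[j] >= caps[j]:  # pinched spiral: new face already closed
            return None
        bnd.append(j)
    return None


def spiral_walk_py(adj, degs, a, b, c):
    """Unwind one spiral from start faces ``a, b, c`` (c fixes the direction).

    Returns the visit order (length ``m``) or ``None`` when the tight spiral
    breaks.  The walk mirrors the windup rule: the next face is the unvisited
    common neighbour of the boundary head and tail.
    """
    m = len(degs)
    if b not in adj[a] or c not in adj[a] or c not in adj[b]:
        return None
    visited = bytearray(m)
    order = [a, b, c]
    for v in order:
        visited[v] = 1
    usedw = [0] * m
    usedw[a] = usedw[b] = usedw[c] = 2
    ob = [a, b, c]
    f = 0
    while len(order) < m:
        while f < len(ob) and usedw[ob[f]] == degs[ob[f]]:
            f += 1
        while len(ob) > f and usedw[ob[-1]] == degs[ob[-1]]:
            ob.pop()
        if len(ob) <= f:
            return None
        h, t = ob[-1], ob[f]
        if h == t:
            cands = [x for x in adj[h] if not visited[x]]
        else:
            if t not in adj[h]:
                return None
            cands = [x for x in adj[h] & adj[t] if not visited[x]]
        if len(cands) != 1:
            return None
        s = cands[0]
        visited[s] = 1
        order.append(s)
        ob.append(s)
        cnt = 0
        for y in adj[s]:
            if visited[y]:
                usedw[y] += 1
                cnt += 1
        usedw[s] = cnt
    return order


def all_spiral_codes_py(adj, degs):
    """Every successful spiral size-sequence of a dual triangulation.

    Iterates all ordered adjacent start pairs in both winding directions; each
    completed walk is verified by windup before being accepted.
    """
    m = len(degs)
    seen = set()
    for a in range(m):
        for b in adj[a]:
            for c in adj[a] & adj[b]:
                order = spiral_walk_py(adj, degs, a, b, c)
                if order is None:
                    continue
                seq = tuple(degs[v] for v in order)
                if seq in seen:
                    continue
                if windup_adj_py(seq) is not None:
                    seen.add(seq)
    return sorted(seen)


def canonical_code_py(adj, degs):
    """Lexicographically smallest successful spiral sequence, or ``None``."""
    codes = all_spiral_codes_py(adj, degs)
    return codes[0] if codes else None


# --------------------------------------------------------------------------
# numba kernels
# --------------------------------------------------------------------------


@njit(cache=True)
def _windup_full(caps, adj, used, bnd):
    """Array windup of a complete sequence; returns success flag.

    ``adj`` (m*m uint8), ``used`` (m int32) and ``bnd`` (>= m+2 int32) are
    caller-provided scratch, zeroed here.
    """
    m = caps.shape[0]
    if m < 4:
        return False
    for i in range(m):
        used[i] = 0
        for k in range(m):
            adj[i, k] = 0
    f = 0
    b = 0
    bnd[b] = 0
    b += 1
    for j in range(1, m):
        if j == m - 1:
            for p in range(f, b):
                x = bnd[p]
                if adj[j, x] == 1 or used[x] >= caps[x] or used[j] >= caps[j]:
                    return False
                adj[j, x] = 1
                adj[x, j] = 1
                used[j] += 1
                used[x] += 1
            if used[j] != caps[j]:
                return False
            for v in range(m):
                if used[v] != caps[v]:
                    return False
            return True
        # connect to head
        h = bnd[b - 1]
        if adj[j, h] == 1 or used[h] >= caps[h] or used[j] >= caps[j]:
            return False
        adj[j, h] = 1
        adj[h, j] = 1
        used[j] += 1
        used[h] += 1
        while used[bnd[b - 1]] == caps[bnd[b - 1]]:
            b -= 1
            if b == f:
                return False
            h = bnd[b - 1]
            if adj[j, h] == 1 or used[h] >= caps[h] or used[j] >= caps[j]:
                return False
            adj[j, h] = 1
            adj[h, j] = 1
            used[j] += 1
            used[h] += 1
        t = bnd[f]
        if adj[j, t] == 0:
            if j == t or used[t] >= caps[t] or used[j] >= caps[j]:
                return False
            adj[j, t] = 1
            adj[t, j] = 1
            used[j] += 1
            used[t] += 1
        while used[bnd[f]] == caps[bnd[f]]:
            f += 1
            if f == b:
                return False
            t = bnd[f]
            if adj[j, t] == 1:
                continue
            if used[t] >= caps[t] or used[j] >= caps[j]:
                return False
            adj[j, t] = 1
            adj[t, j] = 1
            used[j] += 1
            used[t] += 1
        if used[j] >= caps[j]:
            return False
        bnd[b] = j
        b += 1
    return False


@njit(cache=True)
def _is_canonical(adj, caps, wadj, wused, wbnd, visited, usedw, ob, seq, nbrs, ndeg):
    """True iff ``caps`` is the lex-min successful spiral of its own graph.

    ``adj``/``caps`` describe the completed triangulation (vertex degrees equal
    ``caps``).  Remaining arguments are scratch arrays: ``wadj, wused, wbnd``
    for verification windups, ``visited/usedw/ob`` (sizes m, m, 2m+4), ``seq``
    (m) for walks and ``nbrs``/``ndeg`` ((m, 6) and m) for neighbour lists.
    """
    m = caps.shape[0]
    for v in range(m):
        k = 0
        for x in range(m):
            if adj[v, x] == 1:
                nbrs[v, k] = x
                k += 1
        ndeg[v] = k
    for a in range(m):
        if caps[a] > caps[0]:
            continue
        state_a = 0
        if caps[a] < caps[0]:
            state_a = 1
        for bi in range(ndeg[a]):
            b = nbrs[a, bi]
            state_b = state_a
            if state_b == 0:
                if caps[b] > caps[1]:
                    continue
                if caps[b] < caps[1]:
                    state_b = 1
            for ci in range(ndeg[a]):
                c = nbrs[a, ci]
                if c == b or adj[b, c] == 0:
                    continue
                # walk the spiral from (a, b, c); state 0 = equal so far,
                # 1 = strictly smaller than the candidate.
                state = state_b
                if state == 0:
                    if caps[c] > caps[2]:
                        continue
                    if caps[c] < caps[2]:
                        state = 1
                for v in range(m):
                    visited[v] = 0
                    usedw[v] = 0
                visited[a] = 1
                visited[b] = 1
                visited[c] = 1
                usedw[a] = 2
                usedw[b] = 2
                usedw[c] = 2
                seq[0] = caps[a]
                seq[1] = caps[b]
                seq[2] = caps[c]
                ob[0] = a
                ob[1] = b
                ob[2] = c
                f = 0
                bk = 3
                cnt_vis = 3
                failed = False
                while cnt_vis < m:
                    while f < bk and usedw[ob[f]] == caps[ob[f]]:
                        f += 1
                    while bk > f and usedw[ob[bk - 1]] == caps[ob[bk - 1]]:
                        bk -= 1
                    if bk <= f:
                        failed = True
                        break
                    h = ob[bk - 1]
                    t = ob[f]
                    s = -1
                    ncand = 0
                    if h == t:
                        for xi in range(ndeg[h]):
                            x = nbrs[h, xi]
                            if visited[x] == 0:
                                ncand += 1
                                s = x
                    else:
                        if adj[h, t] == 0:
                            failed = True
                            break
                        for xi in range(ndeg[h]):
                            x = nbrs[h, xi]
                            if adj[t, x] == 1 and visited[x] == 0:
                                ncand += 1
                                s = x
                    if ncand != 1:
                        failed = True
                        break
                    if state == 0:
                        if caps[s] > caps[cnt_vis]:
                            failed = True
                            break
                        if caps[s] < caps[cnt_vis]:
                            state = 1
                    visited[s] = 1
                    seq[cnt_vis] = caps[s]
                    cnt_vis += 1
                    ob[bk] = s
                    bk += 1
                    c2 = 0
                    for yi in range(ndeg[s]):
                        y = nbrs[s, yi]
                        if visited[y] == 1:
                            usedw[y] += 1
                            c2 += 1
                    usedw[s] = c2
                if failed:
                    continue
                if state == 1:
                    if _windup_full(seq, wadj, wused, wbnd):
                        return False
    return True


@njit(cache=True, inline="always")
def _apply_step(j, caps, adj, used, bnd, fb, elog, snap):
    """Incremental windup step for vertex ``j`` (not the last vertex).

    ``fb = [f, b, ep]`` boundary window and edge-log pointers; ``elog`` the
    undo log of added edges; ``snap`` receives (f0, b0, ep0, slot, slotval).
    Rolls itself back and returns False on failure.
    """
    f0 = fb[0]
    b0 = fb[1]
    ep0 = fb[2]
    snap[0] = f0
    snap[1] = b0
    snap[2] = ep0
    snap[3] = -1
    snap[4] = -1
    if j == 0:
        bnd[fb[1]] = 0
        fb[1] += 1
        return True
    f = fb[0]
    b = fb[1]
    ep = fb[2]
    ok = True
    # connect to head
    h = bnd[b - 1]
    if adj[j, h] == 1 or used[h] >= caps[h] or used[j] >= caps[j]:
        ok = False
    else:
        adj[j, h] = 1
        adj[h, j] = 1
        used[j] += 1
        used[h] += 1
        elog[ep, 0] = j
        elog[ep, 1] = h
        ep += 1
    while ok and used[bnd[b - 1]] == caps[bnd[b - 1]]:
        b -= 1
        if b == f:
            ok = False
            break
        h = bnd[b - 1]
        if adj[j, h] == 1 or used[h] >= caps[h] or used[j] >= caps[j]:
            ok = False
            break
        adj[j, h] = 1
        adj[h, j] = 1
        used[j] += 1
        used[h] += 1
        elog[ep, 0] = j
        elog[ep, 1] = h
        ep += 1
    if ok:
        t = bnd[f]
        if adj[j, t] == 0:
            if j == t or used[t] >= caps[t] or used[j] >= caps[j]:
                ok = False
            else:
                adj[j, t] = 1
                adj[t, j] = 1
                used[j] += 1
                used[t] += 1
                elog[ep, 0] = j
                elog[ep, 1] = t
                ep += 1
    while ok and used[bnd[f]] == caps[bnd[f]]:
        f += 1
        if f == b:
            ok = False
            break
        t = bnd[f]
        if adj[j, t] == 1:
            continue
        if used[t] >= caps[t] or used[j] >= caps[j]:
            ok = False
            break
        adj[j, t] = 1
        adj[t, j] = 1
        used[j] += 1
        used[t] += 1
        elog[ep, 0] = j
        elog[ep, 1] = t
        ep += 1
    if ok and used[j] >= caps[j]:
        ok = False
    if not ok:
        while ep > ep0:
            ep -= 1
            x = elog[ep, 0]
            y = elog[ep, 1]
            adj[x, y] = 0
            adj[y, x] = 0
            used[x] -= 1
            used[y] -= 1
        fb[0] = f0
        fb[1] = b0
        fb[2] = ep0
        return False
    snap[3] = b
    snap[4] = bnd[b]
    bnd[b] = j
    b += 1
    fb[0] = f
    fb[1] = b
    fb[2] = ep
    return True


@njit(cache=True, inline="always")
def _apply_final(j, caps, adj, used, bnd, fb, elog, snap):
    """Close the spiral with the last vertex; self-rollback on failure."""
    f0 = fb[0]
    b0 = fb[1]
    ep0 = fb[2]
    snap[0] = f0
    snap[1] = b0
    snap[2] = ep0
    snap[3] = -1
    snap[4] = -1
    ep = ep0
    ok = True
    for p in range(f0, b0):
        x = bnd[p]
        if adj[j, x] == 1 or used[x] >= caps[x] or used[j] >= caps[j]:
            ok = False
            break
        adj[j, x] = 1
        adj[x, j] = 1
        used[j] += 1
        used[x] += 1
        elog[ep, 0] = j
        elog[ep, 1] = x
        ep += 1
    if ok and used[j] != caps[j]:
        ok = False
    if ok:
        m = caps.shape[0]
        for v in range(m):
            if used[v] != caps[v]:
                ok = False
                break
    if not ok:
        while ep > ep0:
            ep -= 1
            x = elog[ep, 0]
            y = elog[ep, 1]
            adj[x, y] = 0
            adj[y, x] = 0
            used[x] -= 1
            used[y] -= 1
        return False
    fb[2] = ep
    return True


@njit(cache=True, inline="always")
def _undo_step(caps, adj, used, bnd, fb, elog, snap):
    ep0 = snap[2]
    ep = fb[2]
    while ep > ep0:
        ep -= 1
        x = elog[ep, 0]
        y = elog[ep, 1]
        adj[x, y] = 0
        adj[y, x] = 0
        used[x] -= 1
        used[y] -= 1
    if snap[3] >= 0 and snap[4] >= 0:
        bnd[snap[3]] = snap[4]
    fb[0] = snap[0]
    fb[1] = snap[1]
    fb[2] = snap[2]


@njit(cache=True)
def _enumerate_kernel(m, reverse, limit):
    """Backtracking spiral enumeration with canonicity filtering.

    Returns ``(codes, count, stats)`` where ``codes`` is an int32 array of
    1-based pentagon positions, one row per canonical code, in the DFS
    emission order (lexicographically ascending for ``reverse=False``,
    descending for ``reverse=True``); ``limit < 0`` means unlimited.
    ``stats = [nodes, successful steps, complete spirals, canonical]``.
    """
    stats = np.zeros(4, np.int64)
    first = 5
    second = 6
    if reverse:
        first = 6
        second = 5
    caps = np.zeros(m, np.int32)
    adj = np.zeros((m, m), np.uint8)
    used = np.zeros(m, np.int32)
    bnd = np.zeros(2 * m + 4, np.int32)
    fb = np.zeros(3, np.int64)
    elog = np.zeros((4 * m + 16, 2), np.int32)
    snaps = np.zeros((m, 5), np.int64)
    option = np.zeros(m, np.int32)
    fives_before = np.zeros(m, np.int32)
    deficit_before = np.zeros(m, np.int64)
    # canonicity scratch
    wadj = np.zeros((m, m), np.uint8)
    wused = np.zeros(m, np.int32)
    wbnd = np.zeros(2 * m + 4, np.int32)
    visited = np.zeros(m, np.uint8)
    usedw = np.zeros(m, np.int32)
    ob = np.zeros(2 * m + 4, np.int32)
    seq = np.zeros(m, np.int32)
    nbrs = np.zeros((m, 6), np.int32)
    ndeg = np.zeros(m, np.int32)

    cap_res = 4096
    results = np.zeros((cap_res, 12), np.int32)
    nres = 0
    fives = 0
    deficit = 0
    j = 0
    option[0] = 0
    fives_before[0] = 0
    deficit_before[0] = 0
    while j >= 0:
        if option[j] >= 2:
            option[j] = 0
            j -= 1
            if j >= 0:
                fives = fives_before[j]
                deficit = deficit_before[j]
                _undo_step(caps, adj, used, bnd, fb, elog, snaps[j])
            continue
        if option[j] == 0:
            s = first
        else:
            s = second
        option[j] += 1
        nf = fives
        if s == 5:
            nf += 1
        if nf > 12:
            continue
        if 12 - nf > m - 1 - j:
            continue
        caps[j] = s
        fives_before[j] = fives
        stats[0] += 1
        if j == m - 1:
            if _apply_final(j, caps, adj, used, bnd, fb, elog, snaps[j]):
                stats[2] += 1
                if _is_canonical(
                    adj, caps, wadj, wused, wbnd, visited, usedw, ob, seq, nbrs, ndeg
                ):
                    stats[3] += 1
                    if nres == cap_res:
                        cap_res *= 2
                        bigger = np.zeros((cap_res, 12), np.int32)
                        bigger[:nres] = results
                        results = bigger
                    k = 0
                    for p in range(m):
                        if caps[p] == 5:
                            results[nres, k] = p + 1
                            k += 1
                    nres += 1
                    if limit >= 0 and nres >= limit:
                        return results[:nres].copy(), nres, stats
                _undo_step(caps, adj, used, bnd, fb, elog, snaps[j])
            continue
        if not _apply_step(j, caps, adj, used, bnd, fb, elog, snaps[j]):
            continue
        stats[1] += 1
        # Branch-and-bound on the open boundary's missing degree: the R
        # remaining faces supply at most 6R - (pentagons left) edge-endpoints,
        # of which at least 2(R - 1) are spent on edges among themselves.
        newdef = deficit + s - 2 * used[j]
        rem = m - 1 - j
        if newdef > 4 * rem + 2 - (12 - nf):
            _undo_step(caps, adj, used, bnd, fb, elog, snaps[j])
            continue
        fives_before[j] = fives
        deficit_before[j] = deficit
        fives = nf
        deficit = newdef
        j += 1
        option[j] = 0
    return results[:nres].copy(), nres, stats


@njit(cache=True)
def _windup_positions(m, positions):
    """Windup from 1-based pentagon positions; returns (success, adj matrix)."""
    caps = np.full(m, 6, np.int32)
    for p in positions:
        caps[p - 1] = 5
    adj = np.zeros((m, m), np.uint8)
    used = np.zeros(m, np.int32)
    bnd = np.zeros(2 * m + 4, np.int32)
    ok = _windup_full(caps, adj, used, bnd)
    return ok, adj


@njit(cache=True)
def _sample_kernel(m, n_accepts, seed, max_trials):
    """Acceptance-rejection sampling of canonical pentagon-position vectors.

    Draws uniform 12-subsets of {1..m}, winds them up and accepts exactly the
    canonical ones.  Returns (codes, trials, accepted).
    """
    np.random.seed(seed)
    caps = np.zeros(m, np.int32)
    adj = np.zeros((m, m), np.uint8)
    used = np.zeros(m, np.int32)
    bnd = np.zeros(2 * m + 4, np.int32)
    wadj = np.zeros((m, m), np.uint8)
    wused = np.zeros(m, np.int32)
    wbnd = np.zeros(2 * m + 4, np.int32)
    visited = np.zeros(m, np.uint8)
    usedw = np.zeros(m, np.int32)
    ob = np.zeros(2 * m + 4, np.int32)
    seq = np.zeros(m, np.int32)
    nbrs = np.zeros((m, 6), np.int32)
    ndeg = np.zeros(m, np.int32)
    pool = np.zeros(m, np.int32)
    out = np.zeros((n_accepts, 12), np.int32)
    accepted = 0
    trials = 0
    while accepted < n_accepts and trials < max_trials:
        trials += 1
        for i in range(m):
            pool[i] = i
        for i in range(12):
            k = i + np.random.randint(0, m - i)
            tmp = pool[i]
            pool[i] = pool[k]
            pool[k] = tmp
        sel = np.sort(pool[:12])
        for i in range(m):
            caps[i] = 6
        for i in range(12):
            caps[sel[i]] = 5
        if not _windup_full(caps, adj, used, bnd):
            continue
        if not _is_canonical(
            adj, caps, wadj, wused, wbnd, visited, usedw, ob, seq, nbrs, ndeg
        ):
            continue
        for i in range(12):
            out[accepted, i] = sel[i] + 1
        accepted += 1
    return out[:accepted].copy(), trials, accepted
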