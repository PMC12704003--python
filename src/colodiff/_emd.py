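"""Exact earth mover's distance via the transportation simplex.

Solves min_T <T, C> s.t. T >= 0, T 1 = a, T^T 1 = b for dense cost
matrices.  This is the classical primal (MODI / u-v) simplex specialised to
the transportation polytope: the basis is a spanning forest of the bipartite
supply/demand graph, duals are recovered by a forest traversal, and entering
arcs are found by cyclic block pricing (a standard device in network-simplex
codes that avoids a full O(mn) scan per pivot).  The initial basic feasible
solution comes from the least-cost greedy rule.

The solver is exact up to floating point: on random instances it agrees
with an LP solver to ~1e-15 (see the oracle-equivalence tests).  If the
pivot cap is ever hit (pathological degeneracy), the caller falls back to
scipy's HiGHS LP.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _solve(a, b, C, max_iter):  # pragma: no cover - exercised via emd()
    m = a.shape[0]
    n = b.shape[0]
    N = m + n
    maxE = N + 1
    ei = np.empty(maxE, np.int64)
    ej = np.empty(maxE, np.int64)
    ef = np.empty(maxE)  # flow carried by each basic arc
    basic = np.zeros((m, n), np.uint8)

    # least-cost greedy initial feasible solution (a forest; possibly with
    # fewer than m+n-1 arcs when a placement exhausts a row and a column)
    ra = a.copy()
    rb = b.copy()
    B = 0
    order = np.argsort(C.ravel())
    for t in range(order.shape[0]):
        idx = order[t]
        i = idx // n
        j = idx - i * n
        if ra[i] <= 0.0 or rb[j] <= 0.0:
            continue
        amt = ra[i] if ra[i] < rb[j] else rb[j]
        ei[B] = i
        ej[B] = j
        ef[B] = amt
        basic[i, j] = 1
        B += 1
        ra[i] -= amt
        rb[j] -= amt
        if B == N - 1:
            break

    u = np.empty(m)
    v = np.empty(n)
    mn = m * n
    bs = mn // 16 + 64  # pricing block size
    if bs > mn:
        bs = mn
    pptr = 0
    tol = 1e-11

    deg = np.empty(N, np.int64)
    ptr = np.empty(N + 1, np.int64)
    adj_e = np.empty(2 * maxE, np.int64)
    stack = np.empty(N, np.int64)
    prev_e = np.empty(N, np.int64)
    prev_n = np.empty(N, np.int64)
    seen = np.empty(N, np.uint8)
    pathe = np.empty(N, np.int64)

    converged = False
    for _ in range(max_iter):
        # CSR adjacency of the basis forest; nodes = rows [0,m) + cols m+[0,n)
        for x in range(N):
            deg[x] = 0
        for e in range(B):
            deg[ei[e]] += 1
            deg[m + ej[e]] += 1
        ptr[0] = 0
        for x in range(N):
            ptr[x + 1] = ptr[x] + deg[x]
            deg[x] = 0
        for e in range(B):
            x = ei[e]
            y = m + ej[e]
            adj_e[ptr[x] + deg[x]] = e
            deg[x] += 1
            adj_e[ptr[y] + deg[y]] = e
            deg[y] += 1

        # duals u_i + v_j = C_ij on basic arcs, by DFS over each tree
        for x in range(N):
            seen[x] = 0
        for root in range(N):
            if seen[root] == 1:
                continue
            if root < m:
                u[root] = 0.0
            else:
                v[root - m] = 0.0
            seen[root] = 1
            top = 0
            stack[top] = root
            top = 1
            while top > 0:
                top -= 1
                x = stack[top]
                for t in range(ptr[x], ptr[x + 1]):
                    e = adj_e[t]
                    if x < m:
                        y = m + ej[e]
                        if seen[y] == 0:
                            v[ej[e]] = C[ei[e], ej[e]] - u[ei[e]]
                            seen[y] = 1
                            stack[top] = y
                            top += 1
                    else:
                        y = ei[e]
                        if seen[y] == 0:
                            u[ei[e]] = C[ei[e], ej[e]] - v[ej[e]]
                            seen[y] = 1
                            stack[top] = y
                            top += 1

        # cyclic block pricing: most negative reduced cost in the first
        # block that contains one
        best = -tol
        bi = -1
        bj = -1
        scanned = 0
        while scanned < mn:
            for _s in range(bs):
                ii = pptr // n
                jj = pptr - ii * n
                if basic[ii, jj] == 0:
                    d = C[ii, jj] - u[ii] - v[jj]
                    if d < best:
                        best = d
                        bi = ii
                        bj = jj
                pptr += 1
                if pptr == mn:
                    pptr = 0
            scanned += bs
            if bi >= 0:
                break
        if bi < 0:
            converged = True
            break

        # unique cycle = entering arc (bi,bj) + tree path from row bi to col bj
        for x in range(N):
            seen[x] = 0
        qh = 0
        qt = 0
        stack[qt] = bi
        qt += 1
        seen[bi] = 1
        prev_e[bi] = -1
        target = m + bj
        found = False
        while qh < qt:
            x = stack[qh]
            qh += 1
            if x == target:
                found = True
                break
            for t in range(ptr[x], ptr[x + 1]):
                e = adj_e[t]
                y = m + ej[e] if x < m else ei[e]
                if seen[y] == 0:
                    seen[y] = 1
                    prev_e[y] = e
                    prev_n[y] = x
                    stack[qt] = y
                    qt += 1
        if not found:
            # entering arc joins two trees: no cycle, adopt with zero flow
            ei[B] = bi
            ej[B] = bj
            ef[B] = 0.0
            basic[bi, bj] = 1
            B += 1
            continue
        plen = 0
        x = target
        while x != bi:
            e = prev_e[x]
            pathe[plen] = e
            plen += 1
            x = prev_n[x]
        # walking back from the column end, path arcs alternate -,+,-,...
        theta = np.inf
        leave = -1
        for t in range(plen):
            if t % 2 == 0:
                e = pathe[t]
                if ef[e] < theta:
                    theta = ef[e]
                    leave = e
        for t in range(plen):
            e = pathe[t]
            if t % 2 == 0:
                ef[e] -= theta
            else:
                ef[e] += theta
        ei[B] = bi
        ej[B] = bj
        ef[B] = theta
        basic[bi, bj] = 1
        B += 1
        basic[ei[leave], ej[leave]] = 0
        B -= 1
        ei[leave] = ei[B]
        ej[leave] = ej[B]
        ef[leave] = ef[B]

    total = 0.0
    for e in range(B):
        total += ef[e] * C[ei[e], ej[e]]
    return total, converged


def _emd_linprog(a: np.ndarray, b: np.ndarray, C: np.ndarray) -> float:
    from scipy.optimize import linprog
    from scipy.sparse import coo_matrix

    m, n = len(a), len(b)
    ii = np.repeat(np.arange(m), n)
    jj = np.tile(np.arange(n), m)
    var = np.arange(m * n)
    A = coo_matrix(
        (np.ones(2 * m * n), (np.concatenate([ii, m + jj]), np.concatenate([var, var]))),
        shape=(m + n, m * n),
    )
    res = linprog(C.ravel(), A_eq=A, b_eq=np.concatenate([a, b]), method="highs")
    if not res.success:
        raise RuntimeError(f"LP fallback failed: {res.message}")
    return float(res.fun)


def emd(a: np.ndarray, b: np.ndarray, C: np.ndarray) -> float:
    """Exact optimal-transport cost between histograms ``a`` and ``b``.

    ``a`` and ``b`` are renormalized to sum exactly to one before solving,
    which guarantees feasibility under floating point.
    """
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    C = np.ascontiguousarray(C, dtype=np.float64)
    if a.ndim != 1 or b.ndim != 1 or C.shape != (a.size, b.size):
        raise ValueError("need a (m,), b (n,) and C (m, n)")
    if np.any(a < 0) or np.any(b < 0) or a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("histograms must be non-negative with positive mass")
    a = a / a.sum()
    b = b / b.sum()
    if a.size == 1:
        return float(np.dot(b, C[0]))
    if b.size == 1:
        return float(np.dot(a, C[:, 0]))
    max_iter = 200 * (a.size + b.size)
    total, converged = _solve(a, b, C, max_iter)
    if not converged:
        return _emd_linprog(a, b, C)
    return total
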