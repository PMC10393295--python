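"""Exact network-simplex solver for the dense transportation problem.

Primal network simplex on the complete bipartite graph with ``n1`` supply
nodes and ``n2`` demand nodes, all real arcs uncapacitated.  Arc ``e`` with
``0 <= e < n1*n2`` runs from supply node ``e // n2`` to demand node
``e % n2``; arcs ``n1*n2 + k`` are the artificial arcs tying node ``k`` to
the root that form the initial strongly feasible spanning tree.  The
leaving-arc rule keeps the tree strongly feasible, which prevents cycling
even with floating-point supplies.

Only the solver lives here; problem setup, thresholding and the public API
are in :mod:`lamcsd.transport`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["solve_transport"]


@njit(cache=True)
def _solve(a, b, C):  # pragma: no cover - exercised via solve_transport
    n1 = a.shape[0]
    n2 = b.shape[0]
    n = n1 + n2          # real nodes; the root is node n
    m = n1 * n2          # real arcs; artificial arcs are m..m+n-1

    # node demands: supplies negative (they send flow), demands positive
    demand = np.empty(n, dtype=np.float64)
    for i in range(n1):
        demand[i] = -a[i]
    for j in range(n2):
        demand[n1 + j] = b[j]

    sum_w = 0.0
    for e in range(m):
        w = C[e]
        sum_w += w if w >= 0.0 else -w
    sum_d = 0.0
    for k in range(n):
        sum_d += demand[k] if demand[k] >= 0.0 else -demand[k]
    faux_inf = 3.0 * max(sum_w, sum_d)
    if faux_inf == 0.0:
        faux_inf = 1.0

    # artificial-arc orientation: demand > 0 -> root->node, else node->root
    art_to_root = np.empty(n, dtype=np.bool_)
    for k in range(n):
        art_to_root[k] = demand[k] <= 0.0

    flow = np.zeros(m + n, dtype=np.float64)
    for k in range(n):
        flow[m + k] = demand[k] if demand[k] >= 0.0 else -demand[k]

    potential = np.empty(n + 1, dtype=np.float64)
    for k in range(n):
        potential[k] = faux_inf if demand[k] <= 0.0 else -faux_inf
    potential[n] = 0.0

    parent = np.empty(n + 1, dtype=np.int64)
    parent_edge = np.empty(n + 1, dtype=np.int64)
    subtree_size = np.empty(n + 1, dtype=np.int64)
    next_dft = np.empty(n + 1, dtype=np.int64)
    prev_dft = np.empty(n + 1, dtype=np.int64)
    last_dft = np.empty(n + 1, dtype=np.int64)
    for k in range(n):
        parent[k] = n
        parent_edge[k] = m + k
        subtree_size[k] = 1
        next_dft[k] = k + 1 if k + 1 < n else -1
        prev_dft[k] = k - 1 if k > 0 else n
        last_dft[k] = k
    next_dft[n - 1] = n
    parent[n] = -1
    parent_edge[n] = -1
    subtree_size[n] = n + 1
    next_dft[n] = 0
    prev_dft[n] = n - 1
    last_dft[n] = n - 1

    # basic-arc state for real arcs; tree arcs are never entering candidates
    # (their reduced cost is 0 only up to rounding, and a tree arc picked as
    # "entering" because of a -1e-15 rounding residue sends the pivot loop
    # into a flow-doubling spiral)
    in_tree = np.zeros(m, dtype=np.bool_)

    # scratch buffers for the pivot cycle (cycle length <= n + 2)
    cyc_nodes = np.empty(n + 2, dtype=np.int64)
    cyc_edges = np.empty(n + 2, dtype=np.int64)
    ancestors = np.empty(n + 2, dtype=np.int64)

    # only real arcs are candidates for entering (artificial arcs keep a
    # reduced cost of ~faux_inf once they leave the basis)
    block = int(np.ceil(np.sqrt(m)))
    n_edges = m
    n_blocks = (n_edges + block - 1) // block

    def _src(e):
        if e < m:
            return e // n2
        k = e - m
        return k if art_to_root[k] else n

    def _tgt(e):
        if e < m:
            return n1 + (e % n2)
        k = e - m
        return n if art_to_root[k] else k

    def _weight(e):
        return C[e] if e < m else faux_inf

    f_start = 0  # first edge of the next pivot block (persists across pivots)
    misses = 0
    while misses < n_blocks:
        # ---- entering arc: Dantzig within a block, Bland over blocks ----
        best_e = -1
        best_c = 0.0
        for off in range(block):
            e = f_start + off
            if e >= n_edges:
                e -= n_edges
            if in_tree[e]:
                continue
            src = e // n2
            tgt = n1 + (e % n2)
            c = C[e] - potential[src] + potential[tgt]
            if c < best_c:
                best_c = c
                best_e = e
        f_start += block
        if f_start >= n_edges:
            f_start -= n_edges
        if best_e < 0:
            misses += 1
            continue
        misses = 0
        e_in = best_e
        p = _src(e_in)  # nonbasic arcs carry zero flow: enter in arc direction
        q = _tgt(e_in)

        # ---- cycle containing the entering arc (oriented p -> q) ----
        # find apex (lowest common ancestor by subtree sizes)
        u = p
        v = q
        su = subtree_size[u]
        sv = subtree_size[v]
        while True:
            while su < sv:
                u = parent[u]
                su = subtree_size[u]
            while su > sv:
                v = parent[v]
                sv = subtree_size[v]
            if su == sv:
                if u != v:
                    u = parent[u]
                    su = subtree_size[u]
                    v = parent[v]
                    sv = subtree_size[v]
                else:
                    break
        apex = u

        # path p -> apex, reversed, then entering arc, then apex <- q
        n_cyc = 0
        u = p
        while u != apex:
            cyc_nodes[n_cyc] = u
            cyc_edges[n_cyc] = parent_edge[u]
            n_cyc += 1
            u = parent[u]
        cyc_nodes[n_cyc] = apex
        # reverse nodes/edges so they run apex -> p
        for idx in range((n_cyc + 1) // 2):
            jdx = n_cyc - idx
            tmp = cyc_nodes[idx]
            cyc_nodes[idx] = cyc_nodes[jdx]
            cyc_nodes[jdx] = tmp
        for idx in range(n_cyc // 2):
            jdx = n_cyc - 1 - idx
            tmp = cyc_edges[idx]
            cyc_edges[idx] = cyc_edges[jdx]
            cyc_edges[jdx] = tmp
        # entering arc (between p and q); mirror networkx: skip if already sole
        pos_in = n_cyc
        cyc_edges[n_cyc] = e_in
        n_nodes_cyc = n_cyc + 1
        n_edges_cyc = n_cyc + 1
        v = q
        while v != apex:
            cyc_nodes[n_nodes_cyc] = v
            cyc_edges[n_edges_cyc] = parent_edge[v]
            n_nodes_cyc += 1
            n_edges_cyc += 1
            v = parent[v]

        # ---- leaving arc: min residual, scanned from the cycle's end ----
        # residual of edge e away from node u: inf if u is the arc's source
        # (uncapacitated), else flow[e]
        leave_pos = -1
        min_res = np.inf
        for idx in range(n_edges_cyc - 1, -1, -1):
            e = cyc_edges[idx]
            u = cyc_nodes[idx]
            if _src(e) == u:
                res = np.inf
            else:
                res = flow[e]
            if res < min_res:
                min_res = res
                leave_pos = idx
        e_out = cyc_edges[leave_pos]
        s_node = cyc_nodes[leave_pos]
        t_node = _tgt(e_out) if _src(e_out) == s_node else _src(e_out)

        # ---- augment along the cycle ----
        if min_res > 0.0 and np.isfinite(min_res):
            for idx in range(n_edges_cyc):
                e = cyc_edges[idx]
                u = cyc_nodes[idx]
                if _src(e) == u:
                    flow[e] += min_res
                else:
                    flow[e] -= min_res

        if e_in == e_out:
            continue
        in_tree[e_in] = True
        if e_out < m:
            in_tree[e_out] = False

        # ensure s_node is the parent of t_node
        if parent[t_node] != s_node:
            tmp = s_node
            s_node = t_node
            t_node = tmp
        # ensure q lies in the subtree rooted at t_node
        if pos_in > leave_pos:
            tmp = p
            p = q
            q = tmp

        # ---- remove (s_node, t_node) from the tree ----
        size_t = subtree_size[t_node]
        prev_t = prev_dft[t_node]
        last_t = last_dft[t_node]
        next_last_t = next_dft[last_t]
        parent[t_node] = -1
        parent_edge[t_node] = -1
        next_dft[prev_t] = next_last_t
        prev_dft[next_last_t] = prev_t
        next_dft[last_t] = t_node
        prev_dft[t_node] = last_t
        u = s_node
        while u != -1:
            subtree_size[u] -= size_t
            if last_dft[u] == last_t:
                last_dft[u] = prev_t
            u = parent[u]

        # ---- re-root the detached subtree at q ----
        n_anc = 0
        u = q
        while u != -1:
            ancestors[n_anc] = u
            n_anc += 1
            u = parent[u]
        for idx in range(n_anc - 1, 0, -1):
            pp = ancestors[idx]
            qq = ancestors[idx - 1]
            size_p = subtree_size[pp]
            last_p = last_dft[pp]
            prev_q = prev_dft[qq]
            last_q = last_dft[qq]
            next_last_q = next_dft[last_q]
            parent[pp] = qq
            parent[qq] = -1
            parent_edge[pp] = parent_edge[qq]
            parent_edge[qq] = -1
            subtree_size[pp] = size_p - subtree_size[qq]
            subtree_size[qq] = size_p
            next_dft[prev_q] = next_last_q
            prev_dft[next_last_q] = prev_q
            next_dft[last_q] = qq
            prev_dft[qq] = last_q
            if last_p == last_q:
                last_dft[pp] = prev_q
                last_p = prev_q
            prev_dft[pp] = last_q
            next_dft[last_q] = pp
            next_dft[last_p] = qq
            prev_dft[qq] = last_p
            last_dft[qq] = last_p

        # ---- attach the subtree rooted at q below p via the entering arc ----
        last_p = last_dft[p]
        next_last_p = next_dft[last_p]
        size_q = subtree_size[q]
        last_q = last_dft[q]
        parent[q] = p
        parent_edge[q] = e_in
        next_dft[last_p] = q
        prev_dft[q] = last_p
        prev_dft[next_last_p] = last_q
        next_dft[last_q] = next_last_p
        u = p
        while u != -1:
            subtree_size[u] += size_q
            if last_dft[u] == last_p:
                last_dft[u] = last_q
            u = parent[u]

        # ---- update potentials over the re-attached subtree ----
        if q == _tgt(e_in):
            d = potential[p] - _weight(e_in) - potential[q]
        else:
            d = potential[p] + _weight(e_in) - potential[q]
        u = q
        potential[u] += d
        last_q = last_dft[q]
        while u != last_q:
            u = next_dft[u]
            potential[u] += d

    # feasibility: artificial arcs must be (numerically) empty
    art_resid = 0.0
    for k in range(n):
        f = flow[m + k]
        if f < 0.0:
            f = -f
        if f > art_resid:
            art_resid = f
    feasible = art_resid <= 1e-9 * sum_d

    cost = 0.0
    for e in range(m):
        if flow[e] != 0.0:
            cost += C[e] * flow[e]
    return cost, flow[:m], feasible


def solve_transport(
    a: np.ndarray, b: np.ndarray, cost: np.ndarray, return_plan: bool = False
):
    """Solve ``min <P, cost>`` over transport plans with marginals ``a``, ``b``.

    Parameters
    ----------
    a, b
        Nonnegative weight vectors with (numerically) equal sums.
    cost
        Cost matrix of shape ``(len(a), len(b))``.
    return_plan
        If True also return the optimal plan as a dense matrix.

    Returns
    -------
    cost : float, or ``(float, ndarray)`` when ``return_plan`` is set.
    """
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    cost = np.ascontiguousarray(cost, dtype=np.float64)
    if cost.shape != (a.size, b.size):
        raise ValueError(
            f"cost matrix shape {cost.shape} does not match marginals "
            f"({a.size}, {b.size})"
        )
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("marginals must be nonnegative")
    sa, sb = a.sum(), b.sum()
    if sa <= 0 or sb <= 0:
        raise ValueError("marginals must have positive total mass")
    if abs(sa - sb) > 1e-6 * max(sa, sb):
        raise ValueError(f"marginal mass mismatch: {sa} vs {sb}")
    # rebalance to float-exact equality so no residual sticks to the root arcs
    b = b * (sa / sb)
    b[np.argmax(b)] += sa - b.sum()

    total, flow, feasible = _solve(a, b, cost.ravel())
    if not feasible:
        raise RuntimeError("network simplex terminated with infeasible basis")
    if return_plan:
        return total, flow.reshape(a.size, b.size)
    return total
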