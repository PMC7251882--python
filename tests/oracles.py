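"""Independent reference implementations used only to cross-check the
package: truncated matrix-exponential birth-death transitions, exhaustive
chain enumeration on small grids, brute-force LCA pair grouping, a minimal
Markov-clustering iteration, and Nei-Gojobori-style counting via Biopython.

These deliberately avoid the code paths they validate.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm


# -- birth-death via truncated generator exponential -------------------------


def bd_expm_matrix(lam: float, mu: float, t: float, K: int = 300) -> np.ndarray:
    """P(n -> m) for n, m <= K via expm of the truncated BD generator."""
    G = np.zeros((K + 1, K + 1))
    for i in range(K + 1):
        if i > 0:
            G[i, i - 1] = i * mu
        if i < K:
            G[i, i + 1] = i * lam
        G[i, i] = -(i * (lam + mu)) if i < K else -(i * mu)
    return expm(G * t)


def enumeration_family_loglik(tree, counts, lam, mu, eta, K_root=250, K_mid=80):
    """Brute-force DL likelihood (no WGD) by explicit summation over root and
    internal-node states, using matrix-exponential transitions.

    ``tree`` is a DatedSpeciesTree; ``counts`` maps leaf label -> count.
    Conditioned on at least one survivor in each root clade.
    """
    Ps = {}
    for node in tree.postorder():
        if node != tree.root:
            Ps[node] = bd_expm_matrix(lam, mu, tree.length[node], K=max(K_root, K_mid))

    def subtree_prob(node, n_start):
        """P(observed counts below `node` | n_start lineages at node)."""
        if tree.is_leaf(node):
            raise AssertionError("called on leaf")
        total = 1.0
        for child in tree.children(node):
            P = Ps[child]
            if tree.is_leaf(child):
                total *= P[n_start, counts[tree.label[child]]]
            else:
                total *= sum(
                    P[n_start, k] * subtree_prob(child, k) for k in range(K_mid + 1)
                )
        return total

    def subtree_extinct(node, n_start, empty_leaves):
        total = 1.0
        for child in tree.children(node):
            P = Ps[child]
            if tree.is_leaf(child):
                if tree.label[child] in empty_leaves:
                    total *= P[n_start, 0]
            else:
                total *= sum(
                    P[n_start, k] * subtree_extinct(child, k, empty_leaves)
                    for k in range(K_mid + 1)
                )
        return total

    clade1, clade2 = tree.root_clades()
    lab1 = {tree.label[i] for i in clade1}
    lab2 = {tree.label[i] for i in clade2}
    ns = np.arange(1, K_root + 1)
    prior = eta * (1 - eta) ** (ns - 1)
    num = sum(g * subtree_prob(tree.root, n) for n, g in zip(ns, prior))
    p1 = sum(g * subtree_extinct(tree.root, n, lab1) for n, g in zip(ns, prior))
    p2 = sum(g * subtree_extinct(tree.root, n, lab2) for n, g in zip(ns, prior))
    p12 = sum(g * subtree_extinct(tree.root, n, lab1 | lab2) for n, g in zip(ns, prior))
    incl = 1.0 - p1 - p2 + p12
    return np.log(num / incl)


# -- exhaustive chain enumeration --------------------------------------------


def _legal(p, q, max_gap):
    return p[0] < q[0] and p[1] < q[1] and (q[0] - p[0]) + (q[1] - p[1]) <= max_gap


def _chain_score(chain_pts, match, gap_pen):
    s = match * len(chain_pts)
    for a, b in zip(chain_pts, chain_pts[1:]):
        s -= gap_pen * ((b[0] - a[0]) + (b[1] - a[1]) - 2)
    return s


def best_chain_bruteforce(hits, max_gap, match, gap_pen, inverted):
    """All-chains enumeration; returns (score, [keys]) with the same
    tie-break as the dynamic programme: maximum score, then lexicographically
    smallest index sequence compared from the chain's end backwards."""
    if not hits:
        return None
    pts = sorted((q, -t if inverted else t, key) for q, t, key in hits)
    n = len(pts)
    best = None  # ((score, neg reversed index tuple), chain indices)
    # iterative DFS over all chains
    frontier = [(i,) for i in range(n)]
    while frontier:
        chain = frontier.pop()
        score = _chain_score([pts[i][:2] for i in chain], match, gap_pen)
        rev = tuple(reversed(chain))
        cand = (score, tuple(-i for i in rev))  # larger is better on both
        if best is None or cand > best[0]:
            best = (cand, chain)
        last = pts[chain[-1]][:2]
        for j in range(n):
            if j not in chain and _legal(last, pts[j][:2], max_gap):
                frontier.append(chain + (j,))
    (score, _), chain = best
    return score, [pts[i][2] for i in chain]


def chain_blocks_bruteforce(hits, seed_size, max_gap, match, gap_pen):
    """Greedy best-chain extraction mirroring the production policy, with
    each best chain found by exhaustive enumeration."""
    pool = list(hits)
    blocks = []
    while pool:
        candidates = []
        for inverted in (False, True):
            res = best_chain_bruteforce(pool, max_gap, match, gap_pen, inverted)
            if res is not None:
                score, chain = res
                candidates.append((score, len(chain), not inverted, chain))
        if not candidates:
            break
        score, length, is_par, chain = max(candidates, key=lambda c: (c[0], c[1], c[2]))
        used = {id(k) for k in chain}
        pool = [h for h in pool if id(h[2]) not in used]
        if length >= seed_size:
            blocks.append((score, "parallel" if is_par else "inverted",
                           [k for k in chain]))
    return blocks


# -- brute-force LCA pair grouping -------------------------------------------


def lca_groups_bruteforce(newick: str):
    """Group all leaf pairs by their LCA using leaf-set containment on a
    dendropy parse (independent of the Bio.Phylo-based implementation)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    internal = []
    for nd in tree.preorder_node_iter():
        if not nd.is_leaf():
            leaves = frozenset(l.taxon.label.replace(" ", "_")
                               for l in nd.leaf_iter())
            internal.append(leaves)
    leaves_all = sorted(set().union(*internal))
    groups = {}
    for a, b in itertools.combinations(leaves_all, 2):
        containing = [s for s in internal if a in s and b in s]
        lca = min(containing, key=len)
        groups.setdefault(lca, set()).add(frozenset((a, b)))
    return groups


# -- minimal independent Markov clustering -----------------------------------


def mcl_reference(adj: np.ndarray, inflation: float = 2.0, iters: int = 200):
    """Plain power-iteration MCL on a dense adjacency; clusters from the
    connected components of the limit matrix's support."""
    n = adj.shape[0]
    M = adj.astype(float).copy()
    np.fill_diagonal(M, np.where(adj.max(axis=0) > 0, adj.max(axis=0), 1.0))
    M /= M.sum(axis=0)
    for _ in range(iters):
        M = np.linalg.matrix_power(M, 2)
        M = M**inflation
        M[M < 1e-8] = 0
        colsum = M.sum(axis=0)
        colsum[colsum == 0] = 1
        M /= colsum
    support = (M + M.T) > 1e-6
    seen = [False] * n
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        comp, stack = [], [i]
        seen[i] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in range(n):
                if support[v, w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(sorted(comp))
    return comps
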