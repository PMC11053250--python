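"""Independent brute-force oracles, deliberately sharing no code with the
package: pure-Python enumeration of the ECDF/rank/KS-walk score definition
and a definitional Benjamini-Hochberg computation."""
from __future__ import annotations


def brute_set_scores(matrix, set_idx, tau=1.0, es_mode="diff"):
    """Enumerate the per-spot set score for a dense spots x genes matrix.

    matrix: nested lists (S x N); set_idx: collection of gene indices.
    """
    S = len(matrix)
    N = len(matrix[0])
    in_set = set(set_idx)
    m = len(in_set)
    assert 1 <= m < N

    # stage 1: averaged-tie rank of each spot per gene, / S
    e = [[0.0] * N for _ in range(S)]
    for j in range(N):
        col = [matrix[i][j] for i in range(S)]
        for i in range(S):
            less = sum(1 for v in col if v < col[i])
            eq = sum(1 for v in col if v == col[i])
            e[i][j] = (less + (eq + 1) / 2) / S

    scores = []
    for i in range(S):
        # stage 2: order genes by e descending, ties by gene index ascending
        order = sorted(range(N), key=lambda j: (-e[i][j], j))
        weights = [abs(N / 2 - r) for r in range(1, N + 1)]
        wsum = sum(weights[r] ** tau for r, j in enumerate(order) if j in in_set)
        # stage 3: weighted KS walk
        nu = []
        cum_in = 0.0
        cum_out = 0
        for r, j in enumerate(order):
            if j in in_set:
                if wsum > 0:
                    cum_in += weights[r] ** tau / wsum
                else:  # all set weights zero: unweighted step function
                    cum_in += 1.0 / m
            else:
                cum_out += 1
            nu.append(cum_in - cum_out / (N - m))
        if es_mode == "diff":
            es = max(max(nu), 0.0) + min(min(nu), 0.0)
        else:
            es = max(nu, key=abs)
        scores.append(es)
    return scores


def brute_bh(pvals):
    """Definitional BH step-up: padj_i = min over thresholds t = p_j >= p_i
    of m * t / #{k : p_k <= t}, capped at 1."""
    m = len(pvals)
    out = []
    for p_i in pvals:
        candidates = [
            min(1.0, m * t / sum(1 for q in pvals if q <= t))
            for t in pvals if t >= p_i
        ]
        out.append(min(candidates))
    return out


def brute_rank_sum_p(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    from itertools import combinations

    pooled = list(x) + list(y)
    n1, n = len(x), len(pooled)
    ranks = []
    for v in pooled:
        less = sum(1 for w in pooled if w < v)
        eq = sum(1 for w in pooled if w == v)
        ranks.append(less + (eq + 1) / 2)
    mu = n1 * (n - n1) / 2
    u_obs = sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    hits = total = 0
    for idx in combinations(range(n), n1):
        u = sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            hits += 1
    return hits / total
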