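"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the alignment oracle
enumerates every global alignment recursively, and the MCL oracle iterates
the dense matrix with explicit Python loops.
"""

from panbgc.homology import MCLParams


def brute_force_alignment(a: str, b: str):
    """Enumerate every global alignment under match +1/mismatch −1/gap −1.

    Returns (best score, set of identity fractions achieved by
    optimal-score alignments).
    """
    outcomes = []

    def rec(i, j, score, ident, length):
        if i == len(a) and j == len(b):
            outcomes.append((score, ident, length))
            return
        if i < len(a) and j < len(b):
            m = 1 if a[i] == b[j] else -1
            rec(i + 1, j + 1, score + m, ident + (m == 1), length + 1)
        if i < len(a):
            rec(i + 1, j, score - 1, ident, length + 1)
        if j < len(b):
            rec(i, j + 1, score - 1, ident, length + 1)

    rec(0, 0, 0, 0, 0)
    best = max(s for s, _, _ in outcomes)
    return best, {i / l for s, i, l in outcomes if s == best}


def mcl_oracle(nodes, weights, params: MCLParams):
    """Dense-matrix MCL with explicit loops, straight from the definition.

    ``nodes`` is an ordered list; ``weights`` maps (i, j) index pairs to
    edge weights.  Returns the partition as a set of frozensets.
    """
    n = len(nodes)
    m = [[0.0] * n for _ in range(n)]
    for (i, j), w in weights.items():
        m[i][j] = m[j][i] = w
    for j in range(n):
        loop = max(m[i][j] for i in range(n)) or 1.0
        m[j][j] = loop
    for j in range(n):
        s = sum(m[i][j] for i in range(n))
        for i in range(n):
            m[i][j] /= s
    for _ in range(params.max_iterations):
        prev = [row[:] for row in m]
        for _ in range(params.expansion - 1):
            nxt = [[0.0] * n for _ in range(n)]
            for i in range(n):
                for j in range(n):
                    nxt[i][j] = sum(m[i][k] * m[k][j] for k in range(n))
            m = nxt
        for j in range(n):
            col = [m[i][j] ** params.inflation for i in range(n)]
            s = sum(col)
            col = [c / s for c in col]
            col = [0.0 if c < params.prune_threshold else c for c in col]
            s = sum(col)
            for i in range(n):
                m[i][j] = col[i] / s
        if (
            max(abs(m[i][j] - prev[i][j]) for i in range(n) for j in range(n))
            < params.convergence_tol
        ):
            break
    attractors = [i for i in range(n) if m[i][i] > 0]
    owner = {}
    for j in range(n):
        owner[j] = max(attractors, key=lambda i: (m[i][j], -i))
    parent = {a: a for a in attractors}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for a in attractors:
        ra, rb = find(a), find(owner[a])
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    clusters = {}
    for j in range(n):
        clusters.setdefault(find(owner[j]), []).append(nodes[j])
    return {frozenset(c) for c in clusters.values()}
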