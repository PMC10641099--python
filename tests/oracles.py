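"""Independent brute-force oracles for small graphs.

These deliberately avoid networkx/scipy graph routines: distances come from
a hand-written Floyd–Warshall, and betweenness from explicit enumeration of
all simple paths.  Only feasible for a handful of nodes — which is the
point: they are ground truth for the fast implementations.
"""

from itertools import combinations

INF = float("inf")


def floyd_warshall(A):
    n = len(A)
    D = [[0 if i == j else (1 if A[i][j] else INF) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i][k] + D[k][j] < D[i][j]:
                    D[i][j] = D[i][k] + D[k][j]
    return D


def _simple_paths(A, s, t):
    n = len(A)
    stack = [(s, (s,))]
    while stack:
        u, path = stack.pop()
        if u == t:
            yield path
            continue
        for w in range(n):
            if A[u][w] and w not in path:
                stack.append((w, path + (w,)))


def brute_betweenness(A):
    """Raw betweenness: each unordered pair contributes its fractional
    shortest-path dependency once."""
    n = len(A)
    D = floyd_warshall(A)
    bc = [0.0] * n
    for s, t in combinations(range(n), 2):
        if D[s][t] == INF:
            continue
        shortest = [p for p in _simple_paths(A, s, t) if len(p) - 1 == D[s][t]]
        sigma = len(shortest)
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            bc[v] += through / sigma
    return bc


def brute_closeness(A):
    """(raw, normalized) closeness with Wasserman–Faust component scaling."""
    n = len(A)
    D = floyd_warshall(A)
    raw, norm = [0.0] * n, [0.0] * n
    for i in range(n):
        reach = [j for j in range(n) if j != i and D[i][j] < INF]
        if not reach:
            continue
        total = sum(D[i][j] for j in reach)
        nc = len(reach) + 1
        raw[i] = (nc - 1) / total
        norm[i] = raw[i] * (nc - 1) / (n - 1) if n > 1 else raw[i]
    return raw, norm


def brute_degree(A):
    return [sum(row) for row in A]


def set_partitions(items):
    """All partitions of a sequence (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part
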