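"""Independent brute-force oracles for the structural metrics.

Pure-python reimplementations straight from the definitions, operating on
(n, edge list, type list) with no shared code or graph library, used to
cross-check the package implementations by enumeration.
"""

from fractions import Fraction


def brute_density(n, edges):
    return Fraction(len(set(edges)), n * (n - 1))


def brute_in_centralization(n, edges):
    indeg = [0] * n
    for _, b in set(edges):
        indeg[b] += 1
    dmax = max(indeg)
    return Fraction(sum(dmax - d for d in indeg), (n - 1) ** 2)


def brute_clustering(n, edges):
    und = set()
    for a, b in edges:
        und.add(frozenset((a, b)))
    neigh = {i: set() for i in range(n)}
    for pair in und:
        a, b = tuple(pair)
        neigh[a].add(b)
        neigh[b].add(a)
    total = Fraction(0)
    for i in range(n):
        ns = sorted(neigh[i])
        k = len(ns)
        if k < 2:
            continue
        links = sum(
            1
            for x in range(k)
            for y in range(x + 1, k)
            if frozenset((ns[x], ns[y])) in und
        )
        total += Fraction(links, k * (k - 1) // 2)
    return total / n


def brute_reciprocity(edges):
    es = set(edges)
    return Fraction(sum(1 for (a, b) in es if (b, a) in es), len(es))


def brute_coleman(n, edges, types, group):
    members = [i for i in range(n) if types[i] == group]
    n_g = len(members)
    if n_g == 0 or n_g == n:
        return None
    out = [(a, b) for (a, b) in set(edges) if types[a] == group]
    if not out:
        return None
    w = Fraction(sum(1 for (_, b) in out if types[b] == group), len(out))
    e = Fraction(n_g - 1, n - 1)
    if w >= e:
        return (w - e) / (1 - e)
    return (w - e) / e
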