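"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: centralities come
from exhaustive simple-path enumeration, and haplotype-frequency maxima from
direct numerical maximization of the multilocus genotype likelihood started
from a lattice of points on the simplex.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import scipy.optimize


def brute_force_centralities(adj: np.ndarray):
    """Betweenness, geodesic distances, harmonic closeness and farness by
    exhaustive enumeration of every simple path (feasible for n <= 8).
    """
    n = adj.shape[0]
    neighbors = [set(np.flatnonzero(adj[v])) for v in range(n)]

    def all_simple_paths(s, t):
        paths = []
        stack = [(s, [s])]
        while stack:
            v, path = stack.pop()
            if v == t:
                paths.append(path)
                continue
            for w in neighbors[v]:
                if w not in path:
                    stack.append((w, path + [w]))
        return paths

    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    betweenness = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = all_simple_paths(s, t)
            if not paths:
                continue
            d = min(len(p) - 1 for p in paths)
            dist[s, t] = dist[t, s] = d
            shortest = [p for p in paths if len(p) - 1 == d]
            sigma = len(shortest)
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in shortest if v in p)
                betweenness[v] += through / sigma

    off = dist.copy()
    np.fill_diagonal(off, np.inf)
    reach = np.isfinite(off)
    with np.errstate(divide="ignore"):
        harmonic = np.where(reach, 1.0 / off, 0.0).sum(axis=1)
    counts = reach.sum(axis=1)
    farness = np.full(n, np.nan)
    has = counts > 0
    farness[has] = np.where(reach, off, 0.0).sum(axis=1)[has] / counts[has]
    return betweenness, dist, harmonic, farness


def random_graph(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    adj = np.zeros((n, n), dtype=bool)
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(len(iu)) < p
    adj[iu[mask], ju[mask]] = True
    adj[ju[mask], iu[mask]] = True
    return adj


# ---------------------------------------------------------------------------
# haplotype-likelihood oracle

def _parse(genotype_row, alphabets):
    out = []
    for value, alleles in zip(genotype_row, alphabets):
        if value is None or str(value) in ("", ".", "./.", "nan"):
            out.append(None)
        else:
            a, b = str(value).split("/")
            out.append((a, b))
    return out


def _compatible_pairs(parsed, alphabets):
    per_marker = []
    for g, alleles in zip(parsed, alphabets):
        if g is None:
            per_marker.append([(a, b) for a in alleles for b in alleles])
        elif g[0] == g[1]:
            per_marker.append([(g[0], g[1])])
        else:
            per_marker.append([(g[0], g[1]), (g[1], g[0])])
    pairs = set()
    for combo in itertools.product(*per_marker):
        h1 = tuple(c[0] for c in combo)
        h2 = tuple(c[1] for c in combo)
        pairs.add((h1, h2) if h1 <= h2 else (h2, h1))
    return sorted(pairs)


def maximize_genotype_likelihood(genotype_rows, alphabets, seed: int = 0):
    """Global maximum of the unphased-genotype likelihood over haplotype
    frequencies, by L-BFGS on softmax coordinates from a deterministic
    lattice of simplex starting points plus seeded random restarts.

    Returns ``(freq_dict, max_log_likelihood)``.
    """
    parsed = [_parse(row, alphabets) for row in genotype_rows]
    pair_lists = [_compatible_pairs(p, alphabets) for p in parsed]
    haps = sorted({h for pl in pair_lists for pair in pl for h in pair})
    index = {h: i for i, h in enumerate(haps)}
    k = len(haps)
    i1 = [np.array([index[a] for a, b in pl]) for pl in pair_lists]
    i2 = [np.array([index[b] for a, b in pl]) for pl in pair_lists]
    mult = [np.array([2.0 if a != b else 1.0 for a, b in pl]) for pl in pair_lists]

    def neg_ll(theta):
        w = np.exp(theta - theta.max())
        f = w / w.sum()
        total = 0.0
        for a, b, m in zip(i1, i2, mult):
            p = float((m * f[a] * f[b]).sum())
            if p <= 0:
                return 1e9
            total += math.log(p)
        return -total

    rng = np.random.default_rng(seed)
    starts = [np.zeros(k)]
    for j in range(k):
        e = np.full(k, -2.0)
        e[j] = 2.0
        starts.append(e)
    starts.extend(np.log(rng.dirichlet(np.ones(k)) + 1e-9) for _ in range(8))

    best = None
    for x0 in starts:
        res = scipy.optimize.minimize(neg_ll, x0, method="L-BFGS-B",
                                      options={"maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    # polish the winner with a derivative-free refinement
    res = scipy.optimize.minimize(neg_ll, best.x, method="Nelder-Mead",
                                  options={"maxiter": 6000, "xatol": 1e-12,
                                           "fatol": 1e-13})
    if res.fun <= best.fun:
        best = res
    w = np.exp(best.x - best.x.max())
    f = w / w.sum()
    return {h: float(f[index[h]]) for h in haps}, -float(best.fun)
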