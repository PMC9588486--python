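"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: persistence is
recomputed from persistent Betti numbers via F2 linear algebra on every
sub-level complex, and the bottleneck distance by exhaustive enumeration of
partial matchings.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np

INF = float("inf")


def gf2_rank(M) -> int:
    M = (np.asarray(M, dtype=np.int8) % 2).copy()
    if M.size == 0:
        return 0
    r = 0
    rows, cols = M.shape
    for c in range(cols):
        piv = next((i for i in range(r, rows) if M[i, c]), None)
        if piv is None:
            continue
        M[[r, piv]] = M[[piv, r]]
        for i in range(rows):
            if i != r and M[i, c]:
                M[i] ^= M[r]
        r += 1
    return r


def gf2_kernel(M) -> np.ndarray:
    M = (np.asarray(M, dtype=np.int8) % 2).copy()
    rows, cols = M.shape
    R = M.copy()
    pivots: list[int] = []
    r = 0
    for c in range(cols):
        piv = next((i for i in range(r, rows) if R[i, c]), None)
        if piv is None:
            continue
        R[[r, piv]] = R[[piv, r]]
        for i in range(rows):
            if i != r and R[i, c]:
                R[i] ^= R[r]
        pivots.append(c)
        r += 1
    free = [c for c in range(cols) if c not in pivots]
    basis = []
    for f in free:
        v = np.zeros(cols, dtype=np.int8)
        v[f] = 1
        for ri, pc in enumerate(pivots):
            if R[ri, f]:
                v[pc] = 1
        basis.append(v)
    return np.array(basis).T if basis else np.zeros((cols, 0), dtype=np.int8)


def boundary_matrix(simplices, k):
    """F2 boundary map from k-simplices to (k-1)-simplices (zero for k=0)."""
    sk = [s for s in simplices if len(s) == k + 1]
    if k == 0:
        return np.zeros((0, len(sk)), dtype=np.int8), sk
    sk1 = [s for s in simplices if len(s) == k]
    idx = {s: i for i, s in enumerate(sk1)}
    M = np.zeros((len(sk1), len(sk)), dtype=np.int8)
    for j, s in enumerate(sk):
        for f in combinations(s, k):
            M[idx[tuple(sorted(f))], j] = 1
    return M, sk


def persistent_betti(filt, k: int, li: float, lj: float) -> int:
    """Rank of H_k(K_li) -> H_k(K_lj): cycles of K_li modulo boundaries of
    K_lj, all over F2."""
    vals = filt.values
    Ki = [s for s in filt.complex.simplices if vals[s] <= li]
    Kj = [s for s in filt.complex.simplices if vals[s] <= lj]
    Mi, ski = boundary_matrix(Ki, k)
    if not ski:
        return 0
    ker = np.eye(len(ski), dtype=np.int8) if k == 0 else gf2_kernel(Mi)
    zi = ker.shape[1]
    if zi == 0:
        return 0
    kj_list = [s for s in Kj if len(s) == k + 1]
    idx = {s: i for i, s in enumerate(kj_list)}
    Zi = np.zeros((len(kj_list), zi), dtype=np.int8)
    for c in range(zi):
        for a, s in zip(ker[:, c], ski):
            if a:
                Zi[idx[s], c] = 1
    Mj, _ = boundary_matrix(Kj, k + 1)
    bj = gf2_rank(Mj)
    dim_sum = gf2_rank(np.hstack([Zi, Mj]) if Mj.size else Zi)
    intersection = zi + bj - dim_sum
    return zi - intersection


def brute_barcode(filt, k: int) -> list:
    """Interval decomposition from persistent Betti numbers by
    inclusion-exclusion over the critical values."""
    vals = sorted(set(filt.values.values()))
    T = len(vals)
    P = {
        (i, j): persistent_betti(filt, k, vals[i], vals[j])
        for i in range(T)
        for j in range(i, T)
    }

    def getP(i, j):
        return 0 if i < 0 else P[(min(i, j), j)]

    bars = []
    for i in range(T):
        for j in range(i + 1, T):
            mu = (getP(i, j - 1) - getP(i, j)) - (
                getP(i - 1, j - 1) - getP(i - 1, j)
            )
            bars.extend([(vals[i], vals[j])] * mu)
        ess = getP(i, T - 1) - getP(i - 1, T - 1)
        bars.extend([(vals[i], INF)] * ess)
    return sorted(bars)


def _pair_cost(a, b) -> float:
    if a[1] == INF and b[1] == INF:
        return abs(a[0] - b[0])
    if a[1] == INF or b[1] == INF:
        return INF
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]))


def _skip_cost(bar) -> float:
    return INF if bar[1] == INF else (bar[1] - bar[0]) / 2.0


def brute_bottleneck(bars_a, bars_b) -> float:
    """Exhaustive minimum over all partial injections (small barcodes only)."""
    na, nb = len(bars_a), len(bars_b)
    best = INF
    for size in range(min(na, nb) + 1):
        for dom in combinations(range(na), size):
            rest_a = [i for i in range(na) if i not in dom]
            for img in permutations(range(nb), size):
                cost = 0.0
                for i, j in zip(dom, img):
                    cost = max(cost, _pair_cost(bars_a[i], bars_b[j]))
                for i in rest_a:
                    cost = max(cost, _skip_cost(bars_a[i]))
                for j in set(range(nb)) - set(img):
                    cost = max(cost, _skip_cost(bars_b[j]))
                best = min(best, cost)
    return best
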