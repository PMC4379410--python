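"""Numba kernels for the hot inner loops of the recombination statistics."""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _find(parent, x):
    while parent[x] != x:
        parent[x] = parent[parent[x]]
        x = parent[x]
    return x


@njit(cache=True)
def pair_incompatibility(col_a, col_b):
    """Refined incompatibility score of two nucleotide site patterns.

    The score is the cyclomatic number (edges - vertices + components) of the
    partition intersection graph: vertices are the observed states of each
    site, edges the observed joint states.  It equals the minimum number of
    extra parsimony steps ("homoplasies") the pair forces on any tree; 0 means
    the pair is compatible.  Rows with a negative (missing) state in either
    column are skipped.
    """
    amap = np.full(4, -1, dtype=np.int64)
    bmap = np.full(4, -1, dtype=np.int64)
    seen = np.zeros((4, 4), dtype=np.uint8)
    parent = np.arange(8)
    na = 0
    nb = 0
    n_edges = 0
    for r in range(col_a.shape[0]):
        a = col_a[r]
        b = col_b[r]
        if a < 0 or b < 0:
            continue
        if amap[a] < 0:
            amap[a] = na
            na += 1
        if bmap[b] < 0:
            bmap[b] = nb
            nb += 1
        if seen[a, b] == 0:
            seen[a, b] = 1
            n_edges += 1
            ra = _find(parent, amap[a])
            rb = _find(parent, 4 + bmap[b])
            if ra != rb:
                parent[ra] = rb
    n_vertices = na + nb
    n_comp = 0
    for v in range(4):
        if amap[v] >= 0 and _find(parent, amap[v]) == amap[v]:
            n_comp += 1
        if bmap[v] >= 0 and _find(parent, 4 + bmap[v]) == 4 + bmap[v]:
            n_comp += 1
    return n_edges - n_vertices + n_comp


@njit(cache=True)
def seed_rng(seed):
    """Seed numba's per-thread Mersenne Twister state."""
    np.random.seed(seed)


@njit(cache=True)
def evolve_codon_sites(seq, duration, site_rate, exit_rates, cum_trans):
    """Exact jump-chain sampling of independent codon-site CTMCs on a branch.

    ``seq`` is modified in place.  ``site_rate`` already includes the overall
    theta/(2L) factor and per-site multipliers; ``exit_rates``/``cum_trans``
    come from the normalised rate matrix.  Uses numba's thread-local RNG
    (seed via :func:`seed_rng`).
    """
    for s in range(seq.shape[0]):
        state = seq[s]
        r = site_rate[s] * exit_rates[state]
        if r <= 0.0:
            continue
        t = np.random.exponential() / r
        while t < duration:
            u = np.random.random()
            row = cum_trans[state]
            state = np.searchsorted(row, u, side="right")
            if state > 60:
                state = 60
            r = site_rate[s] * exit_rates[state]
            if r <= 0.0:
                break
            t += np.random.exponential() / r
        seq[s] = state


@njit(cache=True)
def maxchi_scan(sub, half_window):
    """Max 2x2 chi-squared over all sequence pairs and candidate breakpoints.

    ``sub`` is (n_seq, n_polymorphic_columns) with -1 for missing states.
    For each pair, columns valid in both sequences are scored match/mismatch
    and every boundary between consecutive columns is contrasted with a
    window of ``half_window`` columns each side (truncated at the ends).
    """
    n, s_all = sub.shape
    best = 0.0
    d = np.empty(s_all, dtype=np.int64)
    for i in range(n - 1):
        for j in range(i + 1, n):
            s = 0
            for c in range(s_all):
                a = sub[i, c]
                b = sub[j, c]
                if a >= 0 and b >= 0:
                    d[s] = 1 if a != b else 0
                    s += 1
            if s < 2:
                continue
            cum = np.empty(s + 1, dtype=np.int64)
            cum[0] = 0
            for c in range(s):
                cum[c + 1] = cum[c] + d[c]
            for bp in range(1, s):
                lo = bp - half_window
                if lo < 0:
                    lo = 0
                hi = bp + half_window
                if hi > s:
                    hi = s
                a1 = cum[bp] - cum[lo]
                n1 = bp - lo
                a2 = cum[hi] - cum[bp]
                n2 = hi - bp
                tot = n1 + n2
                c1 = a1 + a2
                c2 = tot - c1
                denom = n1 * n2 * c1 * c2
                if denom > 0:
                    num = tot * float(a1 * (n2 - a2) - (n1 - a1) * a2) ** 2
                    chi = num / denom
                    if chi > best:
                        best = chi
    return best


@njit(cache=True)
def phi_mean_score(cols, positions, window):
    """Mean refined incompatibility over informative-site pairs within
    ``window`` nucleotides of each other.  ``cols`` is (n_sites, n_seqs)."""
    s = cols.shape[0]
    total = 0.0
    count = 0
    for i in range(s):
        for j in range(i + 1, s):
            if positions[j] - positions[i] > window:
                break
            total += pair_incompatibility(cols[i], cols[j])
            count += 1
    if count == 0:
        return 0.0
    return total / count
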