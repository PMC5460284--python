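"""Independent brute-force oracles the implementation is checked against.

Everything here is deliberately naive (all-pairs union-find, exhaustive
candidate scans, exact combinatorics) and shares no code path with the
package.
"""

from __future__ import annotations

import math

import numpy as np


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri

    def groups(self):
        out = {}
        for i in range(len(self.parent)):
            out.setdefault(self.find(i), []).append(i)
        return list(out.values())


def ppm(m1, m2):
    return 1e6 * abs(m1 - m2) / min(m1, m2)


def umc_partition_oracle(masses, scans, mass_tol_ppm, max_scan_gap):
    """All-pairs single linkage in mass, then in scan within mass groups.

    Returns the partition as a set of frozensets of row positions.
    """
    n = len(masses)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if ppm(masses[i], masses[j]) <= mass_tol_ppm:
                uf.union(i, j)
    partition = set()
    for comp in uf.groups():
        sub = _UnionFind(len(comp))
        for a in range(len(comp)):
            for b in range(a + 1, len(comp)):
                if abs(scans[comp[a]] - scans[comp[b]]) <= max_scan_gap:
                    sub.union(a, b)
        for g in sub.groups():
            partition.add(frozenset(comp[k] for k in g))
    return partition


def match_oracle(umc_mass, umc_net, db_masses, db_nets, mass_tol_ppm, net_tol):
    """Exhaustive nearest-candidate AMT match; None if no/ambiguous match."""
    best, best_d, n_best = None, None, 0
    for k in range(len(db_masses)):
        dppm = ppm(umc_mass, db_masses[k])
        dnet = abs(umc_net - db_nets[k])
        if dppm > mass_tol_ppm or dnet > net_tol:
            continue
        d = (dppm / mass_tol_ppm) ** 2 + (dnet / net_tol) ** 2
        if best_d is None or d < best_d:
            best, best_d, n_best = k, d, 1
        elif d == best_d:
            n_best += 1
    if best is None or n_best > 1:
        return None
    return best


def hypergeom_upper_tail(N, K, n, overlap):
    """Exact P(X >= overlap) for X ~ Hypergeom(N, K, n), as a float."""
    total = math.comb(N, n)
    acc = 0
    for x in range(overlap, min(K, n) + 1):
        acc += math.comb(K, x) * math.comb(N - K, n - x)
    return acc / total


def venn_regions_oracle(sets):
    """Region counts via explicit per-item membership vectors."""
    union = set().union(*sets.values()) if sets else set()
    regions = {}
    for item in union:
        key = frozenset(n for n, s in sets.items() if item in s)
        regions[key] = regions.get(key, 0) + 1
    return regions


def gaussian_match_recall_bound(mass_sd_ppm, net_sd, mass_tol_ppm, net_tol):
    """Lower bound on AMT-match recall when both errors are Gaussian.

    The UMC-vs-entry differences are at most sqrt(2) times the single-
    observation error sd in each dimension (averaging over repeated
    observations only shrinks them), so the probability that a truly
    present peptide falls inside both tolerance windows is at least the
    product of the two central probabilities.
    """
    from scipy.stats import norm

    p_mass = 1.0 if mass_sd_ppm == 0 else (
        2 * norm.cdf(mass_tol_ppm / (math.sqrt(2) * mass_sd_ppm)) - 1)
    p_net = 1.0 if net_sd == 0 else (
        2 * norm.cdf(net_tol / (math.sqrt(2) * net_sd)) - 1)
    return p_mass * p_net
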