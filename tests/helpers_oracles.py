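"""Independent brute-force oracles used to validate the implementations.

Each oracle is deliberately naive (recursion, exhaustive enumeration)
and shares no code with the package.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations
from math import comb

import numpy as np


def levenshtein_oracle(a: str, b: str) -> int:
    """Edit distance by memoized recursion."""

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            d(i - 1, j) + 1,
            d(i, j - 1) + 1,
            d(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    result = d(len(a), len(b))
    d.cache_clear()
    return result


def fisher_twosided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x: int) -> float:
        y = c1 - x
        if x < 0 or x > r1 or y < 0 or y > r2:
            return 0.0
        return comb(r1, x) * comb(r2, y) / denom

    p_obs = prob(a)
    total = 0.0
    for x in range(0, min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def hypergeom_tail_oracle(overlap: int, universe: int, n_a: int, n_b: int) -> float:
    """P(overlap >= observed) by exact combinatorial summation."""
    denom = comb(universe, n_b)
    s = 0
    for k in range(overlap, min(n_a, n_b) + 1):
        if 0 <= n_b - k <= universe - n_a:
            s += comb(n_a, k) * comb(universe - n_a, n_b - k)
    return s / denom


def _ks_stat(x: np.ndarray, y: np.ndarray) -> float:
    allv = np.sort(np.concatenate([x, y]))
    cdfx = np.searchsorted(np.sort(x), allv, side="right") / len(x)
    cdfy = np.searchsorted(np.sort(y), allv, side="right") / len(y)
    return float(np.max(np.abs(cdfx - cdfy)))


def ks_exact_oracle(x, y) -> tuple[float, float]:
    """Exact two-sample KS statistic and p by enumerating all splits."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d_obs = _ks_stat(x, y)
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    idx = np.arange(n + m)
    hits = 0
    total = 0
    for chosen in combinations(idx, n):
        total += 1
        mask = np.zeros(n + m, dtype=bool)
        mask[list(chosen)] = True
        if _ks_stat(pooled[mask], pooled[~mask]) >= d_obs - 1e-12:
            hits += 1
    return d_obs, hits / total


def contact_set_oracle(chains: dict, cutoff: float) -> set[tuple[str, int]]:
    """All-pairs distance scan over residue atom coordinates."""
    pep_atoms = [xyz for res in chains["peptide"] for xyz in res.coords]
    out = set()
    for role in ("TRA", "TRB"):
        for res in chains.get(role, ()):
            best = min(
                float(np.sqrt(((np.array(p) - np.array(q)) ** 2).sum()))
                for p in res.coords
                for q in pep_atoms
            )
            if best < cutoff:
                out.add((role, res.residue_index))
    return out
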