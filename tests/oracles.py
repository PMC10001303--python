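"""Independent brute-force oracles used to freeze expected values.

Each oracle recomputes a statistic by naive enumeration or sorting, sharing
no code path with the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def exact_rank_sum_p(x, y) -> float:
    """Two-sided rank-sum p by full enumeration of group assignments.

    Average ranks at ties; p = min(1, 2 * min(P(W <= w), P(W >= w))) over the
    uniform distribution of assignments of the pooled values to group sizes.
    """
    x = list(x)
    pooled = np.asarray(list(x) + list(y), dtype=float)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    observed = ranks[: len(x)].sum()
    sums = np.fromiter(
        (ranks[list(c)].sum() for c in itertools.combinations(range(len(pooled)), len(x))),
        dtype=float,
    )
    p_le = float(np.mean(sums <= observed + 1e-9))
    p_ge = float(np.mean(sums >= observed - 1e-9))
    return min(1.0, 2.0 * min(p_le, p_ge))


def naive_percentage_rank(values, gene_index: int) -> float | None:
    """Percentage-rank by explicit sorting of the cell's non-zero values."""
    values = list(map(float, values))
    if values[gene_index] == 0.0:
        return None
    nonzero = sorted(v for v in values if v != 0.0)
    target = values[gene_index]
    positions = [i + 1 for i, v in enumerate(nonzero) if v == target]
    rank = sum(positions) / len(positions)
    return 100.0 * rank / len(nonzero)


def hypergeom_upper_tail(k: int, background: int, n_signature: int, n_drawn: int) -> float:
    """P(overlap >= k) when n_drawn genes are drawn without replacement."""
    total = math.comb(background, n_drawn)
    acc = 0
    for i in range(k, min(n_signature, n_drawn) + 1):
        acc += math.comb(n_signature, i) * math.comb(background - n_signature, n_drawn - i)
    return acc / total
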