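"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: entropy bounds come
from exhaustive enumeration of all integer matrices with given
marginals, and Delta from a literal transcription of its defining
double sum over individuals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def integer_matrices_with_marginals(rows: tuple[int, ...], cols: tuple[int, ...]):
    """Yield every non-negative integer matrix with the given marginals."""
    assert sum(rows) == sum(cols)
    n_rows, n_cols = len(rows), len(cols)

    def fill(row_idx: int, remaining_cols: tuple[int, ...], acc: list):
        if row_idx == n_rows:
            if all(c == 0 for c in remaining_cols):
                yield np.array(acc, dtype=np.int64).reshape(n_rows, n_cols)
            return
        target = rows[row_idx]
        # all compositions of `target` into n_cols parts bounded by remaining_cols
        def comps(j: int, left: int, row: list):
            if j == n_cols:
                if left == 0:
                    yield list(row)
                return
            hi = min(left, remaining_cols[j])
            for v in range(hi + 1):
                row.append(v)
                yield from comps(j + 1, left - v, row)
                row.pop()

        for row in comps(0, target, []):
            new_remaining = tuple(c - v for c, v in zip(remaining_cols, row))
            yield from fill(row_idx + 1, new_remaining, acc + row)

    yield from fill(0, tuple(cols), [])


def entropy_of_counts(mat: np.ndarray) -> float:
    m = mat.sum()
    h = 0.0
    for v in mat.ravel():
        if v > 0:
            p = v / m
            h -= p * math.log(p)
    return h


def entropy_bounds_oracle(rows: tuple[int, ...], cols: tuple[int, ...]) -> tuple[float, float]:
    """(min, max) entropy over all integer matrices with these marginals."""
    ents = [entropy_of_counts(mat) for mat in integer_matrices_with_marginals(rows, cols)]
    return min(ents), max(ents)


def h2_prime_oracle(mat: np.ndarray) -> float:
    """H2' of an integer matrix via exhaustive entropy bounds."""
    rows = tuple(int(v) for v in mat.sum(axis=1))
    cols = tuple(int(v) for v in mat.sum(axis=0))
    h_min, h_max = entropy_bounds_oracle(rows, cols)
    h_obs = entropy_of_counts(mat)
    if h_max - h_min <= 1e-12:
        return 0.0
    return (h_max - h_obs) / (h_max - h_min)


def marginal_pairs(max_total: int, max_dim: int = 3):
    """All canonical (sorted-descending) marginal pairs with total <= max_total.

    Row/column permutations leave entropy bounds unchanged, so sorted
    marginals cover every case up to symmetry.
    """
    def partitions_into_parts(total: int, max_parts: int):
        # positive, non-increasing compositions
        def rec(left: int, max_part: int, parts: list):
            if left == 0:
                yield tuple(parts)
                return
            if len(parts) == max_parts:
                return
            for v in range(min(left, max_part), 0, -1):
                parts.append(v)
                yield from rec(left - v, v, parts)
                parts.pop()

        yield from rec(total, total, [])

    for total in range(1, max_total + 1):
        rows_options = list(partitions_into_parts(total, max_dim))
        for rows in rows_options:
            for cols in rows_options:
                yield rows, cols


def delta_oracle(omega: np.ndarray, x: np.ndarray) -> float:
    """Taxonomic diversity via the defining sum over individual pairs."""
    n = x.sum()
    num = 0.0
    k = len(x)
    for i, j in itertools.combinations(range(k), 2):
        num += omega[i, j] * x[i] * x[j]
    return num / (n * (n - 1) / 2.0)
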