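"""Weighted metrics of quantitative bipartite network structure.

The five Shannon-based descriptors and the network-level
specialisation index H2' follow the standard definitions for
quantitative webs:

* generality G — mean effective number of host species per parasitoid,
  weighted by parasitoid marginal totals: ``G = sum_j (a_.j/m) exp(H_j)``
  where ``H_j`` is the Shannon entropy of column j's interaction
  frequencies.
* vulnerability V — the row-wise analogue: mean effective number of
  parasitoid species per host, weighted by host marginals.  All-zero
  host rows carry weight 0 and so contribute nothing, but they do
  count towards S below.
* linkage density LD = (G + V) / 2 — weighted diversity of
  interactions per species.
* weighted connectance Cw = LD / S with S = R + C, counting
  unparasitised hosts in R.
* H2' — the observed interaction entropy rescaled between the maximum
  and minimum entropies attainable under the network's fixed marginal
  totals: ``H2' = (H2_max - H2_obs) / (H2_max - H2_min)``, so 0 means
  interactions match the independence expectation and 1 means maximal
  specialisation.  Only defined for integer count data, because the
  extremal entropies are taken over integer matrices.
* modularity Q — delegated to :mod:`quantweb.modularity`.

Entropies are computed in nats; effective numbers via ``exp`` are
identical to the base-2 formulation.  ``0 * ln 0 == 0`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import QuantNetwork

__all__ = [
    "MetricVector",
    "EntropyBounds",
    "UndefinedMetricError",
    "generality",
    "vulnerability",
    "linkage_density",
    "weighted_connectance",
    "h2_observed",
    "h2_bounds",
    "h2_prime",
    "compute_all_metrics",
    "collection_metrics",
    "METRIC_NAMES",
]

#: canonical metric column names, in reporting order
METRIC_NAMES = (
    "linkage_density",
    "connectance",
    "generality",
    "vulnerability",
    "h2prime",
    "modularity",
)


class UndefinedMetricError(ValueError):
    """The requested metric is not defined for this network."""


@dataclass
class MetricVector:
    """The six structural metrics for one network (NaN where undefined)."""

    network_id: str
    study_id: str
    m: float
    n_hosts: int
    n_parasitoids: int
    linkage_density: float
    connectance: float
    generality: float
    vulnerability: float
    h2prime: float
    modularity: float

    def as_dict(self) -> dict:
        return {
            "network_id": self.network_id,
            "study_id": self.study_id,
            "m": self.m,
            "n_hosts": self.n_hosts,
            "n_parasitoids": self.n_parasitoids,
            "linkage_density": self.linkage_density,
            "connectance": self.connectance,
            "generality": self.generality,
            "vulnerability": self.vulnerability,
            "h2prime": self.h2prime,
            "modularity": self.modularity,
        }


@dataclass
class EntropyBounds:
    """Observed and extremal interaction entropies (nats) for fixed marginals."""

    h2_obs: float
    h2_min: float
    h2_max: float


def _check_nonempty(net: QuantNetwork) -> None:
    if net.m <= 0:
        raise UndefinedMetricError("metric undefined for an empty network")


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats with the 0 ln 0 = 0 convention."""
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _marginal_weighted_diversity(a: np.ndarray, axis: int) -> float:
    """Marginal-weighted mean of exp(entropy) along ``axis``.

    ``axis=0`` collapses rows -> per-column effective numbers
    (generality); ``axis=1`` -> per-row (vulnerability).  Zero
    marginals get weight zero.
    """
    m = a.sum()
    marg = a.sum(axis=axis)
    total = 0.0
    vectors = a.T if axis == 0 else a
    for k, tot in enumerate(marg):
        if tot <= 0:
            continue
        h = _entropy(vectors[k] / tot)
        total += (tot / m) * np.exp(h)
    return float(total)


def generality(net: QuantNetwork) -> float:
    """Weighted mean effective number of host species per parasitoid."""
    _check_nonempty(net)
    return _marginal_weighted_diversity(np.asarray(net.a, dtype=float), axis=0)


def vulnerability(net: QuantNetwork) -> float:
    """Weighted mean effective number of parasitoid species per host."""
    _check_nonempty(net)
    return _marginal_weighted_diversity(np.asarray(net.a, dtype=float), axis=1)


def linkage_density(net: QuantNetwork) -> float:
    """Weighted diversity of interactions per species: (G + V) / 2."""
    return 0.5 * (generality(net) + vulnerability(net))


def weighted_connectance(net: QuantNetwork) -> float:
    """Linkage density divided by species count S = R + C (zero rows in R)."""
    return linkage_density(net) / net.n_species


def h2_observed(net: QuantNetwork) -> float:
    """Shannon entropy (nats) of the observed interaction frequencies."""
    _check_nonempty(net)
    a = np.asarray(net.a, dtype=float)
    return _entropy(a.ravel() / a.sum())


def _entropy_counts(counts: np.ndarray, m: int) -> float:
    """Entropy of an integer matrix given its total, via sum n ln n."""
    n = counts[counts > 0].astype(float)
    return float(np.log(m) - (n * np.log(n)).sum() / m)


def _pack_largest(r: np.ndarray, c: np.ndarray, match_first: bool) -> np.ndarray:
    """Greedy packing of marginals into few large cells.

    Place ``min(remaining row, remaining col)`` into the cell at the
    currently largest remaining totals; with ``match_first``, a row and
    column with exactly equal remainders are consumed together first
    (one placement can then empty both, which concentrates harder).
    Ties break to the lowest row index, then lowest column index.
    """
    r = r.copy()
    c = c.copy()
    out = np.zeros((len(r), len(c)), dtype=np.int64)
    while True:
        i = j = -1
        if match_first:
            live_r = np.flatnonzero(r > 0)
            live_c = np.flatnonzero(c > 0)
            if live_r.size and live_c.size:
                eq = r[live_r][:, None] == c[live_c][None, :]
                if eq.any():
                    pairs = np.argwhere(eq)
                    best = pairs[np.argmax(r[live_r[pairs[:, 0]]])]
                    i, j = int(live_r[best[0]]), int(live_c[best[1]])
        if i < 0:
            i = int(np.argmax(r))
            j = int(np.argmax(c))
        amount = min(r[i], c[j])
        if amount <= 0:
            break
        out[i, j] += amount
        r[i] -= amount
        c[j] -= amount
    return out


def _h2_min_counts(r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Most-concentrated integer matrix with marginals (r, c).

    Best of two deterministic greedy packings (plain largest-totals, and
    exact-match-first), judged by entropy.
    """
    candidates = [_pack_largest(r, c, match_first=False),
                  _pack_largest(r, c, match_first=True)]
    m = int(r.sum())
    return min(candidates, key=lambda mat: _entropy_counts(mat, m))


def _h2_max_counts(r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Integer matrix with marginals (r, c) closest to independence.

    Start from the floor of the expected cell values ``r_i c_j / m``,
    then distribute the remaining units one at a time into the feasible
    cell (positive remaining row and column capacity) with the largest
    remainder of the expectation, breaking ties toward the smallest
    current count (which maximises the entropy gain), then row-major.
    A final local-exchange pass repairs rounding choices that a
    same-row/column swap can improve.
    """
    m = int(r.sum())
    expected = np.outer(r, c) / m
    out = np.floor(expected).astype(np.int64)
    rem = expected - out
    row_cap = r - out.sum(axis=1)
    col_cap = c - out.sum(axis=0)
    deficit = int(m - out.sum())
    n_rows, n_cols = out.shape
    # sweep cells once per pass in descending remainder order (largest-
    # remainder apportionment under marginal caps); later passes prefer the
    # cells with the smallest current count, which maximises entropy
    while deficit > 0:
        score = (rem - 1e-4 * np.log1p(out)).ravel()
        order = np.argsort(-score, kind="stable")
        placed = 0
        for flat in order:
            if deficit == 0:
                break
            i, j = divmod(int(flat), n_cols)
            if row_cap[i] > 0 and col_cap[j] > 0:
                out[i, j] += 1
                row_cap[i] -= 1
                col_cap[j] -= 1
                deficit -= 1
                placed += 1
        if placed == 0:  # pragma: no cover - marginal sums guarantee progress
            raise RuntimeError("infeasible marginal repair")
    # exchange repair is quartic in matrix dimensions; on larger webs the
    # remainder fill is already within rounding noise of independence
    if out.size <= 100:
        _improve_entropy_swaps(out)
    return out


def _improve_entropy_swaps(out: np.ndarray, max_sweeps: int = 20) -> None:
    """2x2 exchange moves (preserve marginals) while entropy increases.

    Moving one unit around a rectangle (i1,j1),(i1,j2),(i2,j1),(i2,j2)
    keeps all marginals; accept the move when it lowers sum(n ln n).
    """

    def nlogn(x: np.int64) -> float:
        return 0.0 if x <= 0 else float(x) * np.log(float(x))

    n_rows, n_cols = out.shape
    for _ in range(max_sweeps):
        improved = False
        for i1 in range(n_rows):
            for i2 in range(n_rows):
                if i1 == i2:
                    continue
                for j1 in range(n_cols):
                    if out[i1, j1] <= 0:
                        continue
                    for j2 in range(n_cols):
                        if j1 == j2 or out[i2, j2] <= 0:
                            continue
                        # move a unit from (i1,j1),(i2,j2) to (i1,j2),(i2,j1)
                        before = (
                            nlogn(out[i1, j1]) + nlogn(out[i2, j2])
                            + nlogn(out[i1, j2]) + nlogn(out[i2, j1])
                        )
                        after = (
                            nlogn(out[i1, j1] - 1) + nlogn(out[i2, j2] - 1)
                            + nlogn(out[i1, j2] + 1) + nlogn(out[i2, j1] + 1)
                        )
                        if after < before - 1e-12:
                            out[i1, j1] -= 1
                            out[i2, j2] -= 1
                            out[i1, j2] += 1
                            out[i2, j1] += 1
                            improved = True
        if not improved:
            break


def _exact_entropy_bounds(r: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """Exact (min, max) entropy by depth-first enumeration of all integer
    matrices with marginals (r, c).  Only for small problems."""
    m = int(r.sum())
    n_rows, n_cols = len(r), len(c)
    best = [np.inf, -np.inf]

    def fill_row(i: int, cols_left: tuple[int, ...], nlogn: float) -> None:
        if i == n_rows:
            if all(v == 0 for v in cols_left):
                h = float(np.log(m) - nlogn / m)
                best[0] = min(best[0], h)
                best[1] = max(best[1], h)
            return
        target = int(r[i])

        def comps(j: int, left: int, cols: list, acc: float) -> None:
            if j == n_cols:
                if left == 0:
                    fill_row(i + 1, tuple(cols), nlogn + acc)
                return
            for v in range(min(left, cols_left[j]), -1, -1):
                cols.append(cols_left[j] - v)
                comps(j + 1, left - v, cols, acc + (v * np.log(v) if v > 0 else 0.0))
                cols.pop()

        comps(0, target, [], 0.0)

    fill_row(0, tuple(int(v) for v in c), 0.0)
    return best[0], best[1]


#: above this size the extremal entropies come from heuristics, not enumeration
_EXACT_BOUND_CELLS = 12
_EXACT_BOUND_EVENTS = 14


def h2_bounds(net: QuantNetwork) -> EntropyBounds:
    """Extremal interaction entropies attainable under fixed marginal totals.

    Requires integer count data: the bounds are taken over non-negative
    integer matrices sharing the network's row and column totals.  Small
    problems are solved exactly by enumeration; larger ones by the
    greedy packing (minimum) and capped largest-remainder apportionment
    with exchange repair (maximum).
    """
    _check_nonempty(net)
    if not net.is_integer:
        raise UndefinedMetricError(
            "H2' requires integer count data; this network has non-integer weights"
        )
    counts = net.counts()
    m = int(counts.sum())
    r = counts.sum(axis=1)
    c = counts.sum(axis=0)
    # zero marginals contribute nothing to any entropy
    r_pos = r[r > 0]
    c_pos = c[c > 0]
    h_obs = _entropy_counts(counts, m)
    if len(r_pos) * len(c_pos) <= _EXACT_BOUND_CELLS and m <= _EXACT_BOUND_EVENTS:
        h_min, h_max = _exact_entropy_bounds(r_pos, c_pos)
    else:
        h_min = _entropy_counts(_h2_min_counts(r_pos, c_pos), m)
        h_max = _entropy_counts(_h2_max_counts(r_pos, c_pos), m)
        # heuristic bounds must bracket the observed entropy
        h_min = min(h_min, h_obs)
        h_max = max(h_max, h_obs)
    return EntropyBounds(h2_obs=h_obs, h2_min=h_min, h2_max=h_max)


def h2_prime(net: QuantNetwork, degenerate: float = 0.0) -> float:
    """Network-level specialisation index in [0, 1].

    ``(H2_max - H2_obs) / (H2_max - H2_min)``.  When the marginals
    leave no freedom (H2_max == H2_min) the index carries no
    information; the reported value is then ``degenerate`` — 0 by
    convention for a single network ("no deviation from expectation"),
    while replicate averaging passes NaN to drop such draws.
    """
    b = h2_bounds(net)
    denom = b.h2_max - b.h2_min
    if denom <= 1e-12:
        return degenerate
    return float(np.clip((b.h2_max - b.h2_obs) / denom, 0.0, 1.0))


def compute_all_metrics(
    net: QuantNetwork,
    include_modularity: bool = False,
    seed: int | None = None,
    chains: int = 3,
) -> MetricVector:
    """Assemble the full metric vector for one network.

    H2' is NaN for non-integer networks; modularity is NaN unless
    ``include_modularity`` (it needs a stochastic optimiser, seeded by
    ``seed``).
    """
    g = generality(net)
    v = vulnerability(net)
    ld = 0.5 * (g + v)
    h2p = h2_prime(net) if net.is_integer else float("nan")
    q = float("nan")
    if include_modularity:
        from .modularity import optimise_modularity

        q = optimise_modularity(net, seed=0 if seed is None else seed, chains=chains).q
    return MetricVector(
        network_id=net.network_id,
        study_id=net.study_id,
        m=net.m,
        n_hosts=net.n_hosts,
        n_parasitoids=net.n_parasitoids,
        linkage_density=ld,
        connectance=ld / net.n_species,
        generality=g,
        vulnerability=v,
        h2prime=h2p,
        modularity=q,
    )


def collection_metrics(
    collection,
    include_modularity: bool = False,
    seed: int = 0,
    chains: int = 3,
) -> "pd.DataFrame":
    """One metrics row per network of a collection, with its metadata.

    Columns: identifiers, m, R, C, the six metrics, plus latitude,
    absolute latitude and guild where present — the observation table
    every analysis stage starts from.
    """
    import pandas as pd

    rows = []
    for k, net in enumerate(collection.networks):
        mv = compute_all_metrics(
            net, include_modularity=include_modularity,
            seed=seed + k, chains=chains,
        )
        row = mv.as_dict()
        row["latitude"] = net.latitude
        row["abs_latitude"] = net.abs_latitude
        row["guild"] = net.guild
        row["is_integer"] = net.is_integer
        rows.append(row)
    return pd.DataFrame(rows)
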