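"""Rarefaction of interaction matrices.

A quantitative integer network is a multiset of individual parasitism
events; subsampling n of them without replacement (multivariate
hypergeometric on the cells) yields a smaller network drawn under pure
sampling effects.  The machinery here expands networks into events,
subsamples them to target sizes, averages metrics over replicates along
a size grid, and standardises whole collections to a common size so
that across-network comparisons are freed from sampling-effort
artefacts.

A species enters a subsampled network the same way it entered the
original one: through recorded events.  Hosts and parasitoids whose
events are all sampled out are therefore dropped; hosts that were
all-zero rows in the *original* network are study-design records
(deliberately surveyed, never parasitised) and are carried through to
every subsample.  This makes the species count S of a subsample shrink
with the sample, which is what drives weighted connectance downward at
small sizes, and it makes the full-size subsample reproduce the
original network exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .network import NetworkValidationError, QuantNetwork, StudyCollection

__all__ = [
    "RarefactionResult",
    "expand_events",
    "subsample",
    "rarefaction_curve",
    "standardise",
    "empirical_tercile",
    "geometric_size_grid",
    "DEFAULT_REPS",
    "DEFAULT_REPS_MODULARITY",
    "DEFAULT_STD_SIZE",
]

#: replicate subsamples per target size for the Shannon metrics
DEFAULT_REPS = 100
#: replicate subsamples for modularity (costlier, half the replicates)
DEFAULT_REPS_MODULARITY = 50
#: default standardisation size: the second tercile of typical
#: compilation matrix sizes
DEFAULT_STD_SIZE = 65


class NotSubsamplableError(NetworkValidationError):
    """Rarefaction needs integer count data."""


def expand_events(net: QuantNetwork) -> list[tuple[str, str]]:
    """List the network's m individual parasitism events in row-major order."""
    if not net.is_integer:
        raise NotSubsamplableError(
            f"network {net.network_id!r} has non-integer weights; "
            "only event-count networks can be subsampled"
        )
    counts = net.counts()
    events = []
    for i, host in enumerate(net.hosts):
        for j, par in enumerate(net.parasitoids):
            events.extend([(host, par)] * int(counts[i, j]))
    return events


def _subsample_counts(counts: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n events without replacement from an integer cell-count matrix."""
    flat = counts.ravel()
    taken = rng.multivariate_hypergeometric(flat, n)
    return taken.reshape(counts.shape)


def subsample(net: QuantNetwork, n: int, seed: int | np.random.Generator = 0) -> QuantNetwork:
    """A network of n events drawn uniformly without replacement.

    Hosts and parasitoids with no sampled event are dropped, except
    hosts that were all-zero rows in the original network (deliberate
    study-design records, retained in every subsample).  Sampling all
    m events reproduces the original network exactly.
    """
    if not net.is_integer:
        raise NotSubsamplableError(
            f"network {net.network_id!r} has non-integer weights"
        )
    counts = net.counts()
    m = int(counts.sum())
    if not 1 <= n <= m:
        raise NetworkValidationError(f"subsample size {n} outside [1, m={m}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    taken = _subsample_counts(counts, n, rng)
    keep_rows = np.flatnonzero((taken.sum(axis=1) > 0) | (counts.sum(axis=1) == 0))
    keep_cols = np.flatnonzero(taken.sum(axis=0) > 0)
    return QuantNetwork(
        network_id=net.network_id,
        study_id=net.study_id,
        hosts=[net.hosts[i] for i in keep_rows],
        parasitoids=[net.parasitoids[j] for j in keep_cols],
        a=taken[np.ix_(keep_rows, keep_cols)],
        latitude=net.latitude,
        guild=net.guild,
    )


def geometric_size_grid(m: int, n_points: int = 25, start: int = 2) -> list[int]:
    """Up to ``n_points`` geometrically spaced integer sizes in [start, m]."""
    if m < start:
        raise NetworkValidationError(f"network too small for grid start {start}")
    raw = np.geomspace(start, m, num=n_points)
    return sorted(set(int(round(v)) for v in raw))


@dataclass
class RarefactionResult:
    """Replicate-mean metrics of one network along a size grid."""

    network_id: str
    study_id: str
    original_m: int
    target_sizes: list[int]
    means: pd.DataFrame  # index: size, columns: metric names
    reps: int
    reps_modularity: int
    seed: int
    latitude: float | None = None
    guild: str | None = None

    def to_frame(self) -> pd.DataFrame:
        df = self.means.reset_index(names="size")
        df.insert(0, "network_id", self.network_id)
        df.insert(1, "study_id", self.study_id)
        df.insert(2, "original_m", self.original_m)
        return df


def _replicate_seed(master: int, *parts: int) -> np.random.Generator:
    """Independent generator for a (network, size, replicate) cell."""
    return np.random.default_rng(np.random.SeedSequence(master, spawn_key=tuple(parts)))


def _mean_metrics_at_size(
    net: QuantNetwork,
    size: int,
    reps: int,
    reps_modularity: int,
    include_modularity: bool,
    master_seed: int,
    size_index: int,
    net_index: int,
) -> dict[str, float]:
    n_reps = max(reps, reps_modularity if include_modularity else 0)
    sums: dict[str, float] = {name: 0.0 for name in _metrics.METRIC_NAMES}
    counts: dict[str, int] = {name: 0 for name in _metrics.METRIC_NAMES}
    for rep in range(n_reps):
        rng = _replicate_seed(master_seed, net_index, size_index, rep)
        sub = subsample(net, size, rng)
        if rep < reps:
            g = _metrics.generality(sub)
            v = _metrics.vulnerability(sub)
            ld = 0.5 * (g + v)
            sums["generality"] += g
            sums["vulnerability"] += v
            sums["linkage_density"] += ld
            sums["connectance"] += ld / sub.n_species
            for name in ("generality", "vulnerability", "linkage_density", "connectance"):
                counts[name] += 1
            # degenerate-marginal draws carry no specialisation signal and
            # are excluded from the replicate mean (all-degenerate sizes
            # fall back to the network-level 0 convention)
            h2p = _metrics.h2_prime(sub, degenerate=float("nan"))
            if np.isfinite(h2p):
                sums["h2prime"] += h2p
                counts["h2prime"] += 1
        if include_modularity and rep < reps_modularity:
            from .modularity import optimise_modularity

            q = optimise_modularity(sub, seed=int(rng.integers(2**31)), chains=1).q
            sums["modularity"] += q
            counts["modularity"] += 1
    out = {
        name: (sums[name] / counts[name]) if counts[name] else float("nan")
        for name in _metrics.METRIC_NAMES
    }
    if counts["h2prime"] == 0 and reps > 0 and size == int(net.m):
        # the full-size draw is the original network: keep its convention
        out["h2prime"] = _metrics.h2_prime(net)
    return out


def rarefaction_curve(
    net: QuantNetwork,
    sizes: list[int] | None = None,
    reps: int = DEFAULT_REPS,
    reps_modularity: int = DEFAULT_REPS_MODULARITY,
    include_modularity: bool = False,
    seed: int = 0,
    net_index: int = 0,
) -> RarefactionResult:
    """Replicate-mean metrics of subsamples along a size grid.

    At the full size m the subsample is the original network, so the
    curve endpoint reproduces the original metrics exactly.
    """
    if not net.is_integer:
        raise NotSubsamplableError(f"network {net.network_id!r} has non-integer weights")
    m = int(net.m)
    if sizes is None:
        sizes = geometric_size_grid(m)
    for s in sizes:
        if not 2 <= s <= m:
            raise NetworkValidationError(f"target size {s} outside [2, m={m}]")
    rows = {}
    for k, size in enumerate(sorted(sizes)):
        rows[size] = _mean_metrics_at_size(
            net, size, reps, reps_modularity, include_modularity, seed, k, net_index
        )
    means = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    means.index.name = "size"
    return RarefactionResult(
        network_id=net.network_id,
        study_id=net.study_id,
        original_m=m,
        target_sizes=sorted(sizes),
        means=means,
        reps=reps,
        reps_modularity=reps_modularity,
        seed=seed,
        latitude=net.latitude,
        guild=net.guild,
    )


def standardise(
    collection: StudyCollection,
    std_size: int = DEFAULT_STD_SIZE,
    reps: int = DEFAULT_REPS,
    reps_modularity: int = DEFAULT_REPS_MODULARITY,
    include_modularity: bool = True,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Mean metrics of every eligible network subsampled to a common size.

    Integer networks with ``m >= std_size`` are subsampled to exactly
    ``std_size`` events; the replicate means are returned together with
    each network's original m (for regressions of standardised metrics
    on original size).  Returns ``(table, excluded_ids)`` where the
    excluded list names networks too small or non-integer.
    """
    rows = []
    excluded: list[str] = []
    net_index = 0
    for net in collection.networks:
        if (not net.is_integer) or net.m < std_size:
            excluded.append(net.network_id)
            continue
        means = _mean_metrics_at_size(
            net, std_size, reps, reps_modularity, include_modularity, seed, 0, net_index
        )
        rows.append(
            {
                "network_id": net.network_id,
                "study_id": net.study_id,
                "original_m": int(net.m),
                "std_size": std_size,
                "latitude": net.latitude,
                "guild": net.guild,
                **means,
            }
        )
        net_index += 1
    if not rows:
        raise NetworkValidationError(
            f"no network is eligible for standardisation to {std_size} events"
        )
    return pd.DataFrame(rows), excluded


def empirical_tercile(collection: StudyCollection, which: int = 2) -> float:
    """The first or second tercile of the matrix-size distribution.

    Empirical quantile at ``which / 3`` with linear interpolation; used
    to pick a standardisation size representative of the compilation.
    """
    if which not in (1, 2):
        raise ValueError("which must be 1 or 2")
    sizes = np.array([net.m for net in collection.networks], dtype=float)
    if len(sizes) < 3:
        raise NetworkValidationError("need at least 3 networks for terciles")
    # interpolated inverse of the empirical CDF: a mass point carrying the
    # p-th quantile is returned exactly (e.g. sizes {30, 65, 200} -> 65)
    return float(np.quantile(sizes, which / 3.0, method="interpolated_inverted_cdf"))
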