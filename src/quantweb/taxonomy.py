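"""Taxonomic diversity of the hosts in a network.

The index Delta is the abundance-weighted mean taxonomic path distance
between pairs of individuals drawn from different host species:

    Delta = [sum_{i<j} omega_ij x_i x_j] / [N (N - 1) / 2]

where omega_ij is the number of equal-length rank steps separating
hosts i and j (distance to their lowest shared rank, counting an
implicit root above the highest rank), linearly rescaled so the
largest realised pairwise distance is 100; x_i is the abundance of
host i and N = sum x_i.  Abundances default to the host marginal
totals of the network (zero rows then contribute nothing); a
presence/absence mode (x_i = 1) is also provided since compilations
rarely state which was used.

Host-side taxonomy only: rearing-based sampling of host-parasitoid
webs is host-focused, so the parasitoid side is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import NetworkValidationError, QuantNetwork

__all__ = [
    "TaxonomyTable",
    "DeltaResult",
    "taxonomic_distances",
    "delta",
    "collection_delta",
]


@dataclass
class TaxonomyTable:
    """Hierarchical classification of hosts, finest rank first.

    ``ranks`` orders the levels from species upward (e.g. species,
    genus, family, order); ``assignment`` maps each host label to its
    tuple of rank values in that order.  Nesting must be consistent:
    two hosts sharing a rank value must share all coarser ranks.
    """

    ranks: list[str]
    assignment: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        k = len(self.ranks)
        for host, tup in self.assignment.items():
            if len(tup) != k:
                raise NetworkValidationError(
                    f"host {host!r}: expected {k} rank values, got {len(tup)}"
                )
        self._check_nesting()

    def _check_nesting(self) -> None:
        # a value at rank r must always sit under the same value at rank r+1
        for level in range(len(self.ranks) - 1):
            parent_of: dict[str, str] = {}
            for host, tup in self.assignment.items():
                child, parent = tup[level], tup[level + 1]
                if child in parent_of and parent_of[child] != parent:
                    raise NetworkValidationError(
                        f"inconsistent nesting: {self.ranks[level]} {child!r} appears "
                        f"under both {self.ranks[level + 1]} {parent_of[child]!r} and {parent!r}"
                    )
                parent_of[child] = parent

    @classmethod
    def from_frame(cls, df: pd.DataFrame, host_column: str = "host") -> "TaxonomyTable":
        """Build from a table with a host column and rank columns finest-first."""
        ranks = [c for c in df.columns if c != host_column]
        if df[host_column].duplicated().any():
            raise NetworkValidationError("duplicate host rows in taxonomy table")
        assignment = {
            str(row[host_column]): tuple(str(row[r]) for r in ranks)
            for _, row in df.iterrows()
        }
        return cls(ranks=ranks, assignment=assignment)

    @classmethod
    def read_csv(cls, path: str, host_column: str = "host") -> "TaxonomyTable":
        return cls.from_frame(pd.read_csv(path), host_column=host_column)

    def to_frame(self, host_column: str = "host") -> pd.DataFrame:
        rows = [
            {host_column: host, **dict(zip(self.ranks, tup))}
            for host, tup in self.assignment.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class DeltaResult:
    """Taxonomic diversity Delta (0-100 scale) and its ingredients."""

    delta: float
    n_hosts: int
    total_abundance: float


def _step_matrix(tax: TaxonomyTable, hosts: list[str]) -> np.ndarray:
    """Unscaled pairwise step counts to the lowest shared rank.

    A pair whose classifications first agree at rank index ``r``
    (0-based, species = 0) is ``r`` steps apart: conspecifics 0,
    congeners 1, and so on; pairs sharing no listed rank meet at an
    implicit root ``k`` steps up, one above the top rank.
    """
    k = len(tax.ranks)
    tuples = []
    for h in hosts:
        if h not in tax.assignment:
            raise NetworkValidationError(f"host {h!r} missing from taxonomy table")
        tuples.append(tax.assignment[h])
    n = len(hosts)
    steps = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            level = k  # implicit shared root
            for r in range(k):
                if tuples[i][r] == tuples[j][r]:
                    level = r
                    break
            steps[i, j] = steps[j, i] = level
    return steps


def taxonomic_distances(tax: TaxonomyTable, hosts: list[str] | None = None) -> pd.DataFrame:
    """Pairwise taxonomic distances omega scaled so the realised maximum is 100.

    Equal step lengths between successive ranks; ``omega_ii = 0``.  When
    every pair is conspecific the distances are all zero.
    """
    if hosts is None:
        hosts = list(tax.assignment)
    steps = _step_matrix(tax, hosts)
    top = steps.max()
    omega = steps * (100.0 / top) if top > 0 else steps
    return pd.DataFrame(omega, index=hosts, columns=hosts)


def delta(
    net: QuantNetwork,
    tax: TaxonomyTable,
    abundance_mode: str = "host-marginals",
) -> DeltaResult:
    """Taxonomic diversity Delta of the hosts of one network.

    ``abundance_mode='host-marginals'`` weights each host by its row
    total (the number of parasitism events it supplied); ``'presence'``
    weights every host equally.
    """
    if abundance_mode not in ("host-marginals", "presence"):
        raise ValueError(f"unknown abundance_mode {abundance_mode!r}")
    hosts = net.hosts
    missing = [h for h in hosts if h not in tax.assignment]
    if missing:
        raise NetworkValidationError(
            f"host(s) missing from taxonomy table: {', '.join(missing)}"
        )
    # scale distances over the whole classification, then subset, so that
    # omega (and hence Delta) is comparable across networks sharing a taxonomy
    omega = taxonomic_distances(tax).loc[hosts, hosts].to_numpy()
    if abundance_mode == "host-marginals":
        x = np.asarray(net.a, dtype=float).sum(axis=1)
    else:
        x = np.ones(len(hosts))
    n_total = x.sum()
    if n_total <= 1:
        raise NetworkValidationError(
            f"Delta undefined: total host abundance {n_total:g} <= 1"
        )
    num = 0.0
    for i in range(len(hosts)):
        for j in range(i + 1, len(hosts)):
            num += omega[i, j] * x[i] * x[j]
    value = num / (n_total * (n_total - 1) / 2.0)
    return DeltaResult(delta=float(value), n_hosts=len(hosts), total_abundance=float(n_total))


def collection_delta(
    collection,
    tax: TaxonomyTable,
    abundance_mode: str = "host-marginals",
) -> pd.DataFrame:
    """Delta for every network of a collection, one row per network."""
    rows = []
    for net in collection.networks:
        res = delta(net, tax, abundance_mode=abundance_mode)
        rows.append(
            {"network_id": net.network_id, "study_id": net.study_id,
             "delta": res.delta, "n_hosts": res.n_hosts,
             "total_abundance": res.total_abundance}
        )
    return pd.DataFrame(rows)
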