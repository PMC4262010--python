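"""Core data model for quantitative bipartite host-parasitoid networks.

A quantitative network records, for one sampled community, how many
individual parasitism events were observed between each host species
(rows) and each parasitoid species (columns).  The row/column weights
``a[i, j]`` are non-negative; for most rearing studies they are integer
counts of reared individuals, but some studies report densities or
rates, which are stored opaquely and flagged via ``is_integer``.

Hosts that were sampled but never parasitised are legitimate network
members and are kept as all-zero rows ("empty web" handling).  A
parasitoid, by contrast, can only enter a rearing study through at
least one interaction, so all-zero columns are rejected on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QuantNetwork",
    "StudyCollection",
    "NetworkValidationError",
    "MalformedDataError",
    "matrix_size",
]


class NetworkValidationError(ValueError):
    """A matrix violates the structural contract of a quantitative network."""


class MalformedDataError(ValueError):
    """A data file contains values that cannot form a valid network."""


#: relative tolerance for deciding that a float-typed cell is integral
_INTEGER_RTOL = 1e-9


def _integrality(a: np.ndarray) -> bool:
    if np.issubdtype(a.dtype, np.integer):
        return True
    nearest = np.round(a)
    scale = np.maximum(np.abs(a), 1.0)
    return bool(np.all(np.abs(a - nearest) <= _INTEGER_RTOL * scale))


@dataclass
class QuantNetwork:
    """A labelled non-negative host x parasitoid interaction matrix.

    Parameters
    ----------
    network_id, study_id
        Identity of the network and of the study it belongs to; the
        study is the grouping unit for random effects downstream.
    hosts, parasitoids
        Ordered species labels for the rows / columns of ``a``.
    a
        ``(R, C)`` array of non-negative interaction weights.
    latitude
        Signed decimal degrees; models use ``abs(latitude)``.
    guild
        Host feeding guild label (aphids, gallers, leaf chewers,
        leaf miners, trap nesters, or a free label).
    """

    network_id: str
    study_id: str
    hosts: list[str]
    parasitoids: list[str]
    a: np.ndarray
    latitude: float | None = None
    guild: str | None = None
    is_integer: bool = field(init=False)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a)
        if self.a.ndim != 2:
            raise NetworkValidationError("interaction matrix must be 2-D")
        if self.a.shape != (len(self.hosts), len(self.parasitoids)):
            raise NetworkValidationError(
                f"matrix shape {self.a.shape} does not match "
                f"{len(self.hosts)} hosts x {len(self.parasitoids)} parasitoids"
            )
        if len(set(self.hosts)) != len(self.hosts):
            raise NetworkValidationError("duplicate host labels")
        if len(set(self.parasitoids)) != len(self.parasitoids):
            raise NetworkValidationError("duplicate parasitoid labels")
        neg = np.argwhere(self.a < 0)
        if neg.size:
            i, j = neg[0]
            raise MalformedDataError(
                f"negative weight at host {self.hosts[i]!r} / "
                f"parasitoid {self.parasitoids[j]!r}"
            )
        if not np.any(self.a > 0):
            raise NetworkValidationError("network has no interactions")
        empty_cols = np.flatnonzero(self.a.sum(axis=0) == 0)
        if empty_cols.size:
            raise NetworkValidationError(
                "all-zero parasitoid column(s): "
                + ", ".join(self.parasitoids[j] for j in empty_cols)
            )
        self.is_integer = _integrality(self.a)

    # -- derived quantities -------------------------------------------------

    @property
    def n_hosts(self) -> int:
        return len(self.hosts)

    @property
    def n_parasitoids(self) -> int:
        return len(self.parasitoids)

    @property
    def n_species(self) -> int:
        """S = hosts + parasitoids, counting unparasitised hosts."""
        return self.n_hosts + self.n_parasitoids

    @property
    def m(self) -> float:
        """Matrix size: total number of interaction events, sum of all cells."""
        return float(self.a.sum())

    @property
    def abs_latitude(self) -> float | None:
        return None if self.latitude is None else abs(self.latitude)

    def counts(self) -> np.ndarray:
        """The matrix as exact integer counts (requires ``is_integer``)."""
        if not self.is_integer:
            raise NetworkValidationError(
                f"network {self.network_id!r} has non-integer weights"
            )
        return np.round(self.a).astype(np.int64)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"QuantNetwork({self.network_id!r}, study={self.study_id!r}, "
            f"R={self.n_hosts}, C={self.n_parasitoids}, m={self.m:g})"
        )


def matrix_size(net: QuantNetwork) -> float:
    """Total number of interactions in the matrix, m = sum over all cells."""
    return net.m


@dataclass
class StudyCollection:
    """Networks grouped into studies — the replication unit of a compilation."""

    studies: list[tuple[str, list[QuantNetwork]]]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for study_id, nets in self.studies:
            if study_id in seen:
                raise NetworkValidationError(f"duplicate study id {study_id!r}")
            seen.add(study_id)
            if not nets:
                raise NetworkValidationError(f"study {study_id!r} has no networks")
            for net in nets:
                if net.study_id != study_id:
                    raise NetworkValidationError(
                        f"network {net.network_id!r} claims study "
                        f"{net.study_id!r} but is filed under {study_id!r}"
                    )

    @classmethod
    def from_networks(cls, nets: list[QuantNetwork], provenance: str = "") -> "StudyCollection":
        order: dict[str, list[QuantNetwork]] = {}
        for net in nets:
            order.setdefault(net.study_id, []).append(net)
        return cls(studies=list(order.items()), provenance=provenance)

    @property
    def networks(self) -> list[QuantNetwork]:
        return [net for _, nets in self.studies for net in nets]

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    def __len__(self) -> int:
        return len(self.networks)
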