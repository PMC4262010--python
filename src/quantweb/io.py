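"""Readers and writers for network matrices, edge lists, taxonomy and metadata.

All formats are plain delimited text (CSV by default, TSV detected by
extension).  Matrix files carry parasitoid labels in the first row and
host labels in the first column; edge lists are long-format
``host,parasitoid,weight`` tables, optionally accompanied by a roster
file declaring hosts with no parasitism.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .network import MalformedDataError, NetworkValidationError, QuantNetwork, StudyCollection

__all__ = [
    "read_network_matrix",
    "write_network_matrix",
    "read_edge_list",
    "read_metadata",
    "read_collection",
    "write_collection",
]


def _sep_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_network_matrix(
    path: str,
    network_id: str,
    study_id: str,
    latitude: float | None = None,
    guild: str | None = None,
) -> QuantNetwork:
    """Read a host x parasitoid matrix file into a :class:`QuantNetwork`.

    First row holds parasitoid labels, first column host labels; every
    cell must be a non-negative number.  Integer-typed files yield
    ``is_integer=True`` exactly; float files are tested cell-by-cell.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise MalformedDataError(f"{path}: empty matrix")
    try:
        a = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise MalformedDataError(f"{path}: non-numeric cell ({exc})") from exc
    if np.isnan(a).any():
        i, j = np.argwhere(np.isnan(a))[0]
        raise MalformedDataError(
            f"{path}: missing value at row {df.index[i]!r} / column {df.columns[j]!r}"
        )
    neg = np.argwhere(a < 0)
    if neg.size:
        i, j = neg[0]
        raise MalformedDataError(
            f"{path}: negative weight at row {df.index[i]!r} / column {df.columns[j]!r}"
        )
    # preserve exact integer typing when the file parses as integers
    if np.all(a == np.round(a)) and (df.dtypes == np.int64).all():
        a = a.astype(np.int64)
    return QuantNetwork(
        network_id=network_id,
        study_id=study_id,
        hosts=[str(h) for h in df.index],
        parasitoids=[str(p) for p in df.columns],
        a=a,
        latitude=latitude,
        guild=guild,
    )


def write_network_matrix(net: QuantNetwork, path: str) -> None:
    a = net.counts() if net.is_integer else net.a
    df = pd.DataFrame(a, index=net.hosts, columns=net.parasitoids)
    df.to_csv(path, sep=_sep_for(path))


def read_edge_list(
    path: str,
    network_id: str,
    study_id: str,
    roster_path: str | None = None,
    latitude: float | None = None,
    guild: str | None = None,
) -> QuantNetwork:
    """Read a long-format ``host,parasitoid,weight`` file.

    Duplicate (host, parasitoid) rows are summed.  A roster file (one
    host label per line) may declare additional hosts with no edges,
    which become all-zero rows.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"host", "parasitoid", "weight"}
    if not required.issubset(df.columns):
        raise MalformedDataError(
            f"{path}: edge list must have columns host,parasitoid,weight "
            f"(found {list(df.columns)})"
        )
    df = df.astype({"host": str, "parasitoid": str})
    hosts = list(dict.fromkeys(df["host"]))
    if roster_path is not None:
        with open(roster_path) as fh:
            roster = [line.strip() for line in fh if line.strip()]
        for h in roster:
            if h not in hosts:
                hosts.append(h)
    parasitoids = list(dict.fromkeys(df["parasitoid"]))
    weights = df["weight"].to_numpy()
    integer_typed = np.issubdtype(weights.dtype, np.integer)
    a = np.zeros((len(hosts), len(parasitoids)), dtype=np.int64 if integer_typed else float)
    hi = {h: i for i, h in enumerate(hosts)}
    pj = {p: j for j, p in enumerate(parasitoids)}
    for h, p, w in zip(df["host"], df["parasitoid"], weights):
        if w < 0:
            raise MalformedDataError(f"{path}: negative weight for ({h}, {p})")
        a[hi[h], pj[p]] += w
    return QuantNetwork(
        network_id=network_id,
        study_id=study_id,
        hosts=hosts,
        parasitoids=parasitoids,
        a=a,
        latitude=latitude,
        guild=guild,
    )


def read_metadata(path: str) -> pd.DataFrame:
    """Read per-network metadata: ``study_id,network_id,latitude,guild``."""
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"study_id", "network_id", "latitude", "guild"}
    missing = required - set(df.columns)
    if missing:
        raise MalformedDataError(f"{path}: metadata missing columns {sorted(missing)}")
    return df.astype({"study_id": str, "network_id": str, "guild": str})


def read_collection(directory: str, metadata: str = "metadata.csv") -> StudyCollection:
    """Load every network listed in a metadata file from matrix CSVs.

    Each network ``<network_id>`` is read from ``<directory>/<network_id>.csv``.
    """
    meta = read_metadata(os.path.join(directory, metadata))
    nets = []
    for row in meta.itertuples(index=False):
        path = os.path.join(directory, f"{row.network_id}.csv")
        nets.append(
            read_network_matrix(
                path,
                network_id=row.network_id,
                study_id=row.study_id,
                latitude=float(row.latitude),
                guild=row.guild,
            )
        )
    return StudyCollection.from_networks(nets, provenance=directory)


def write_collection(collection: StudyCollection, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    rows = []
    for net in collection.networks:
        write_network_matrix(net, os.path.join(directory, f"{net.network_id}.csv"))
        rows.append(
            {
                "study_id": net.study_id,
                "network_id": net.network_id,
                "latitude": net.latitude,
                "guild": net.guild,
            }
        )
    pd.DataFrame(rows).to_csv(os.path.join(directory, "metadata.csv"), index=False)
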