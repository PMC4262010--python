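"""Synthetic multi-study collections of quantitative host-parasitoid networks.

The generator emulates the kind of literature compilation the analysis
pipeline is built for: a few dozen studies, each contributing one to
many rearing-based networks, with total interaction counts spanning
three orders of magnitude, latitudes from the southern subtropics to
the High Arctic, and five host guilds.

Each network is built mechanistically: host availability weights are
lognormal, each parasitoid draws a host-preference vector from a
Dirichlet whose concentration theta sets its niche breadth (small
theta = specialised parasitoids, large theta = generalists), and the
matrix is m multinomial event draws over the host x parasitoid cell
probabilities — so matrix size is exactly controllable, as the
rarefaction contracts require.  Hosts that attract no event are kept
as zero rows; parasitoid columns that receive no event are dropped.

Latitude and guild effects are NOT baked into network mechanics.  They
are injected post hoc on the metric scale (:func:`apply_injected_effects`),
which gives exact known truth for recovery tests of the residual
analysis; the generating values are returned in a ledger alongside
every collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .network import QuantNetwork, StudyCollection
from .taxonomy import TaxonomyTable

__all__ = [
    "GeneratorConfig",
    "GUILDS",
    "generate_taxonomy",
    "generate_network",
    "generate_collection",
    "apply_injected_effects",
]

#: the five host guilds of rearing-based compilations
GUILDS = ("aphids", "gallers", "leaf chewers", "leaf miners", "trap nesters")


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic compilation.

    Defaults mirror a literature compilation of ~28 studies whose
    matrix sizes span three orders of magnitude and whose latitudes
    run from -35 to +75 decimal degrees.
    """

    n_studies: int = 28
    networks_per_study: tuple[int, int] = (1, 15)
    n_hosts_range: tuple[int, int] = (4, 30)
    n_parasitoids_range: tuple[int, int] = (3, 20)
    m_range: tuple[int, int] = (10, 10_000)  # log-uniform
    theta: float = 0.5  # Dirichlet concentration of parasitoid preferences
    host_abundance_sd: float = 1.0  # lognormal sigma of host weights
    richness_size_coupling: float = 0.7  # 0 = richness independent of m,
    # 1 = fully set by m; studies recording more events sample more species
    latitude_range: tuple[float, float] = (-35.0, 75.0)
    taxonomy_ranks: tuple[str, ...] = ("species", "genus", "family", "order")
    taxonomy_branching: tuple[int, ...] = (3, 3, 4)  # children per node, coarse->fine
    study_intercept_sd: float = 0.0  # multiplicative study effect on theta (log scale)
    taxonomic_clustering: bool = False  # bias preferences toward related hosts
    shared_structure: bool = False  # all networks share one cell-probability matrix
    latitude_effects: dict = field(default_factory=dict)  # metric -> slope per degree
    guild_effects: dict = field(default_factory=dict)  # metric -> {guild: offset}
    seed: int = 0


def generate_taxonomy(config: GeneratorConfig, rng: np.random.Generator,
                      n_hosts: int | None = None) -> TaxonomyTable:
    """A nested random host classification with the configured shape.

    Ranks are ordered finest-first (species upward); branching factors
    give the number of children per node from the top rank downward.
    Nesting is consistent by construction.
    """
    ranks = list(config.taxonomy_ranks)
    branching = list(config.taxonomy_branching)
    n_levels = len(ranks)
    if len(branching) not in (n_levels - 1, n_levels):
        raise ValueError(
            f"need {n_levels - 1} (unique species per host) or {n_levels} "
            f"(last factor = species per genus) branching factors for {n_levels} ranks"
        )
    species_branching = len(branching) == n_levels
    if n_hosts is None:
        n_hosts = int(np.prod(branching))
    assignment: dict[str, tuple[str, ...]] = {}
    for h in range(n_hosts):
        # walk down from the single root, choosing a child at each level;
        # the path prefix of length d names the rank at depth d, which
        # makes nesting consistent by construction
        path = [int(rng.integers(b)) for b in branching]
        if species_branching:
            labels = [f"{ranks[0]}_{'.'.join(map(str, path))}"]
        else:
            labels = [f"sp_{h}"]  # each host its own species
        for level in range(1, n_levels):
            # coarser rank = shorter path prefix; the top rank uses path[:1]
            depth = len(branching) - level + (0 if species_branching else 1)
            prefix = ".".join(map(str, path[:depth]))
            labels.append(f"{ranks[level]}_{prefix}")
        assignment[f"host_{h}"] = tuple(labels)
    return TaxonomyTable(ranks=ranks, assignment=assignment)


#: total Dirichlet preference mass at theta = 1; theta scales this budget
_NICHE_MASS = 10.0


def _cell_probabilities(
    n_hosts: int,
    n_parasitoids: int,
    theta: float,
    host_abundance_sd: float,
    rng: np.random.Generator,
    host_groups: np.ndarray | None = None,
    clustering_strength: float = 4.0,
) -> np.ndarray:
    """Host x parasitoid event probabilities from weights and preferences.

    Each parasitoid's preference vector is Dirichlet with total
    concentration ``10 * theta`` spread evenly over the host pool, so
    theta controls niche breadth independently of host richness: as
    theta -> 0 every parasitoid collapses onto a single host, as
    theta -> infinity preferences become uniform.
    """
    w = rng.lognormal(mean=0.0, sigma=host_abundance_sd, size=n_hosts)
    alpha = np.full(n_hosts, theta * _NICHE_MASS / n_hosts)
    p = np.empty((n_hosts, n_parasitoids))
    for j in range(n_parasitoids):
        a_j = alpha.copy()
        if host_groups is not None:
            # concentrate this parasitoid's prior on one taxonomic group
            focal = rng.choice(np.unique(host_groups))
            a_j = np.where(host_groups == focal, alpha * clustering_strength, alpha)
        q = rng.dirichlet(a_j)
        p[:, j] = w * q
    total = p.sum()
    return p / total


def generate_network(
    n_hosts: int,
    n_parasitoids: int,
    m: int,
    theta: float,
    rng: np.random.Generator,
    network_id: str = "net",
    study_id: str = "study",
    host_abundance_sd: float = 1.0,
    taxonomy: TaxonomyTable | None = None,
    taxonomic_clustering: bool = False,
    latitude: float | None = None,
    guild: str | None = None,
    cell_probabilities: np.ndarray | None = None,
    keep_empty_hosts: bool = True,
) -> QuantNetwork:
    """One integer network of exactly m events.

    ``theta`` controls parasitoid niche breadth: in the theta -> 0
    limit every parasitoid uses a single host (H2' near 1); in the
    theta -> infinity limit preferences are uniform and, at large m,
    H2' approaches 0.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if cell_probabilities is None:
        host_groups = None
        if taxonomic_clustering and taxonomy is not None:
            hosts = list(taxonomy.assignment)[:n_hosts]
            genus_level = 1 if len(taxonomy.ranks) > 1 else 0
            genera = [taxonomy.assignment[h][genus_level] for h in hosts]
            _, host_groups = np.unique(genera, return_inverse=True)
        p = _cell_probabilities(
            n_hosts, n_parasitoids, theta, host_abundance_sd, rng, host_groups
        )
    else:
        p = np.asarray(cell_probabilities, dtype=float)
        p = p / p.sum()
        n_hosts, n_parasitoids = p.shape
    counts = rng.multinomial(m, p.ravel()).reshape(p.shape)
    keep = np.flatnonzero(counts.sum(axis=0) > 0)
    rows = np.arange(n_hosts)
    if not keep_empty_hosts:
        # emulate studies whose data are interaction records only, with
        # no roster of surveyed-but-unparasitised hosts
        rows = np.flatnonzero(counts.sum(axis=1) > 0)
    return QuantNetwork(
        network_id=network_id,
        study_id=study_id,
        hosts=[f"host_{i}" for i in rows],
        parasitoids=[f"par_{j}" for j in keep],
        a=counts[np.ix_(rows, keep)],
        latitude=latitude,
        guild=guild,
    )


def _coupled_richness(
    bounds: tuple[int, int], frac_m: float, coupling: float, rng: np.random.Generator
) -> int:
    """Species richness blended between a size-driven and a uniform draw."""
    lo, hi = bounds
    frac = coupling * np.clip(frac_m, 0.0, 1.0) + (1.0 - coupling) * rng.uniform()
    return int(np.clip(round(lo + frac * (hi - lo)), lo, hi))


def generate_collection(
    config: GeneratorConfig,
) -> tuple[StudyCollection, TaxonomyTable, dict]:
    """A full synthetic compilation plus its true-parameter ledger.

    Studies get a latitude, a guild, and (optionally) a multiplicative
    random effect on theta; each study contributes a random number of
    networks whose sizes are log-uniform over ``m_range``.  The ledger
    records every generating value needed by recovery tests, including
    the injected latitude/guild effects (which are applied to metric
    tables separately, see :func:`apply_injected_effects`).
    """
    rng = np.random.default_rng(config.seed)
    max_hosts = config.n_hosts_range[1]
    taxonomy = generate_taxonomy(config, rng, n_hosts=max_hosts)
    shared_p = None
    if config.shared_structure:
        shared_p = _cell_probabilities(
            config.n_hosts_range[1],
            config.n_parasitoids_range[1],
            config.theta,
            config.host_abundance_sd,
            rng,
        )
    nets: list[QuantNetwork] = []
    study_rows = []
    lo, hi = config.latitude_range
    for s in range(config.n_studies):
        study_id = f"study_{s:02d}"
        latitude = float(rng.uniform(lo, hi))
        guild = GUILDS[int(rng.integers(len(GUILDS)))]
        study_log_theta = float(rng.normal(0.0, config.study_intercept_sd))
        theta_s = config.theta * np.exp(study_log_theta)
        n_nets = int(rng.integers(config.networks_per_study[0],
                                  config.networks_per_study[1] + 1))
        study_rows.append(
            {"study_id": study_id, "latitude": latitude, "guild": guild,
             "theta": theta_s, "n_networks": n_nets}
        )
        for k in range(n_nets):
            m = int(round(np.exp(rng.uniform(np.log(config.m_range[0]),
                                             np.log(config.m_range[1])))))
            net_kwargs = dict(
                rng=rng,
                network_id=f"{study_id}_net_{k:02d}",
                study_id=study_id,
                latitude=latitude,
                guild=guild,
            )
            if shared_p is not None:
                net = generate_network(0, 0, m, theta_s,
                                       cell_probabilities=shared_p, **net_kwargs)
            else:
                # species accumulation: studies that record more events also
                # sample more host and parasitoid species
                frac_m = (np.log(m) - np.log(config.m_range[0])) / (
                    np.log(config.m_range[1]) - np.log(config.m_range[0]))
                w = config.richness_size_coupling
                n_h = _coupled_richness(config.n_hosts_range, frac_m, w, rng)
                n_p = _coupled_richness(config.n_parasitoids_range, frac_m, w, rng)
                net = generate_network(
                    n_h, n_p, m, theta_s,
                    host_abundance_sd=config.host_abundance_sd,
                    taxonomy=taxonomy,
                    taxonomic_clustering=config.taxonomic_clustering,
                    **net_kwargs,
                )
            nets.append(net)
    collection = StudyCollection.from_networks(nets, provenance="synthetic generator")
    ledger = {
        "config": asdict(config),
        "studies": study_rows,
        "latitude_effects": dict(config.latitude_effects),
        "guild_effects": {k: dict(v) for k, v in config.guild_effects.items()},
        "seed": config.seed,
    }
    return collection, taxonomy, ledger


def apply_injected_effects(
    metrics_table: pd.DataFrame,
    config: GeneratorConfig,
    latitude_column: str = "abs_latitude",
) -> pd.DataFrame:
    """Shift metric columns by the configured latitude and guild effects.

    ``latitude_effects[metric]`` is a slope per degree applied to the
    metric on its own scale (using the table's latitude column);
    ``guild_effects[metric]`` maps guild labels to additive offsets.
    Returns a copy; a no-op under the null configuration.
    """
    out = metrics_table.copy()
    for metric, slope in config.latitude_effects.items():
        out[metric] = out[metric] + slope * out[latitude_column]
    for metric, offsets in config.guild_effects.items():
        shift = out["guild"].map(lambda g: offsets.get(g, 0.0))
        out[metric] = out[metric] + shift
    return out
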