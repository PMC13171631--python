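"""Synthetic worlds with known ground truth for every pipeline input.

The generators emulate the structure of a cross-habitat marker-gene census
— long-tailed species occupancy across samples, hierarchical provenance
(isolate reference / reference catalogue / study MAG / unbinned contig),
controllable cluster-to-species splitting, pure-birth gene trees with
planted rank labels, and preferential-attachment clade-size samples — so
every downstream stage can be tested against parameters it must recover.
No sequence-level realism is attempted: no nucleotides are generated and
no assembly artefacts are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from microcensus.census import GeneClusterTable
from microcensus.cladelaws import CladeSizeDistribution
from microcensus.rarefaction import RarefactionCurve

DEFAULT_RANK_FRACTIONS = {
    "phylum": 0.20,
    "class": 0.35,
    "order": 0.50,
    "family": 0.65,
    "genus": 0.80,
}


# ---------------------------------------------------------------------------
# Simon preferential-attachment process
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimonProcessParams:
    """Parameters of the Simon innovation/attachment process.

    At each step a new species either founds a new clade (probability
    ``p_innovation``) or joins an existing clade chosen proportionally to
    its current size.  For p < 1 the stationary clade-size law is
    Yule-Simon with rho = 1 / (1 - p).
    """

    n_steps: int
    p_innovation: float
    seed: int | None = None

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1 (empty process)")
        if not 0.0 <= self.p_innovation <= 1.0:
            raise ValueError("p_innovation must lie in [0, 1]")

    @property
    def expected_rho(self) -> float:
        if self.p_innovation >= 1.0:
            return float("inf")
        return 1.0 / (1.0 - self.p_innovation)


def simulate_simon_clades(params: SimonProcessParams) -> CladeSizeDistribution:
    """Run the Simon process and return the clade-size histogram.

    The first step always founds a clade (the seeded clade, which makes the
    p -> 0 limit well defined).  Size-proportional attachment is realized
    by joining the clade of a uniformly chosen earlier species.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_steps
    innovate = rng.random(n) < params.p_innovation
    innovate[0] = True
    clade_of = np.empty(n, dtype=np.int64)
    pick = rng.integers(1, np.iinfo(np.int64).max, size=n)  # uniform draws, mod below
    n_clades = 0
    for t in range(n):
        if innovate[t]:
            clade_of[t] = n_clades
            n_clades += 1
        else:
            clade_of[t] = clade_of[pick[t] % t]
    sizes = np.bincount(clade_of, minlength=n_clades)
    return CladeSizeDistribution.from_sizes(
        sizes, parent_rank="simon-clade", child_unit="species-tip"
    )


# ---------------------------------------------------------------------------
# Pure-birth (Yule) gene trees with planted rank labels
# ---------------------------------------------------------------------------


@dataclass
class YuleTreeResult:
    """A simulated gene tree plus its planted taxonomy.

    ``labels`` is indexed by tip name with one column per rank; planted
    clades were cut from the *true* chronology (node times as fractions of
    tree height), not from RED, so RED-based calibration against them is a
    non-circular test.  ``rank_cut_times`` records the absolute cut time
    per rank and ``planted_counts`` the number of planted clades per rank.
    """

    tree: dendropy.Tree
    labels: pd.DataFrame
    height: float
    rank_cut_times: dict[str, float]
    planted_counts: dict[str, int]
    seed: int | None = None


def simulate_yule_tree(
    n_tips: int,
    seed: int | None = None,
    birth_rate: float = 1.0,
    rank_fractions: Mapping[str, float] | None = None,
) -> YuleTreeResult:
    """Simulate a pure-birth tree and plant rank labels by chronology.

    A single lineage born at time 0 splits after Exp(birth_rate); with k
    extant lineages the next split follows Exp(k * birth_rate) on a
    uniformly chosen lineage, until ``n_tips`` lineages exist; a final
    Exp(n_tips * birth_rate) interval separates the last split from the
    present, so all tips are contemporaneous and branch lengths are time.
    Ranks are planted by cutting the chronology at fixed fractions of the
    root-split-to-present interval (phylum shallowest, genus deepest):
    every lineage crossing the cut founds one planted clade, and each tip
    inherits the labels of its enclosing clades, which are nested by
    construction.  Because the cut sits above the first split, every rank
    plants at least two clades.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if rank_fractions is None:
        rank_fractions = DEFAULT_RANK_FRACTIONS
    rng = np.random.default_rng(seed)
    # lineage records: id -> (parent_node_id, birth_time); node records for splits
    parent: dict[int, int | None] = {}
    node_time: dict[int, float] = {}
    children: dict[int, list[int]] = {}
    t = float(rng.exponential(1.0 / birth_rate))
    root = 0
    node_time[root] = t
    parent[root] = None
    children[root] = []
    active = [root]  # ids of lineages open to the future
    # root immediately splits into two daughters
    next_id = 1
    dA, dB = next_id, next_id + 1
    next_id += 2
    for d in (dA, dB):
        parent[d] = root
        children[root].append(d)
        children[d] = []
    active = [dA, dB]
    while len(active) < n_tips:
        k = len(active)
        t += float(rng.exponential(1.0 / (k * birth_rate)))
        i = int(rng.integers(k))
        lineage = active[i]
        node_time[lineage] = t
        c1, c2 = next_id, next_id + 1
        next_id += 2
        for c in (c1, c2):
            parent[c] = lineage
            children[lineage].append(c)
            children[c] = []
        active[i] = c1
        active.append(c2)
    T = t + float(rng.exponential(1.0 / (len(active) * birth_rate)))
    for tip_id in active:
        node_time[tip_id] = T

    tip_name = {
        tip_id: f"t{i:05d}" for i, tip_id in enumerate(sorted(active))
    }
    # build dendropy tree
    taxon_ns = dendropy.TaxonNamespace()
    dnodes: dict[int, dendropy.Node] = {}
    for nid in sorted(node_time, key=lambda x: node_time[x]):
        node = dendropy.Node()
        p = parent[nid]
        node.edge.length = node_time[nid] - (node_time[p] if p is not None else 0.0)
        if nid in tip_name:
            node.taxon = taxon_ns.new_taxon(tip_name[nid])
        dnodes[nid] = node
    for nid, p in parent.items():
        if p is not None:
            dnodes[p].add_child(dnodes[nid])
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = dnodes[root]
    tree.is_rooted = True

    # plant ranks by cutting the chronology
    tips_sorted = sorted(tip_name.values())
    labels = pd.DataFrame(index=tips_sorted)
    rank_cut_times: dict[str, float] = {}
    planted_counts: dict[str, int] = {}
    t_root = node_time[root]
    for rank, frac in rank_fractions.items():
        # cut fractions span the root-split-to-present interval, so every
        # rank plants at least the two basal clades
        t_cut = t_root + frac * (T - t_root)
        rank_cut_times[rank] = t_cut
        # clade founders: lineages alive at t_cut = nodes with time >= t_cut
        # whose parent's time < t_cut (parent of the root is the origin, time 0)
        founders = []
        for nid, tm in node_time.items():
            p = parent[nid]
            p_time = node_time[p] if p is not None else 0.0
            if tm >= t_cut and p_time < t_cut:
                founders.append(nid)
        if not founders:  # cut below the first split: one clade holds everything
            founders = [root]
        founders.sort()
        col = {}
        for j, f_id in enumerate(founders):
            label = f"{rank.upper()}{j + 1:04d}"
            stack = [f_id]
            while stack:
                nid = stack.pop()
                if nid in tip_name:
                    col[tip_name[nid]] = label
                stack.extend(children[nid])
        labels[rank] = pd.Series(col)
        planted_counts[rank] = len(founders)
    return YuleTreeResult(
        tree=tree,
        labels=labels,
        height=T,
        rank_cut_times=rank_cut_times,
        planted_counts=planted_counts,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Census generator
# ---------------------------------------------------------------------------


@dataclass
class SyntheticWorld:
    """Ground-truth parameters of a synthetic marker-gene census.

    ``source_probs`` is a categorical over provenance tiers per species:
    a PROGENOMES- or GTDB-tier species contributes genome records (and its
    metagenomic occurrences surface as unbinned contigs), a SPIRE_MAG-tier
    species surfaces as study-MAG sequences in samples, and an
    UNBINNED-tier species only ever appears on unbinned contigs.
    ``cluster_split_rate`` is the expected number of gene clusters per
    species (ground-truth inverse conversion factor).
    """

    n_species: int = 2000
    occupancy_law: str = "lognormal"
    occupancy_params: dict = field(
        default_factory=lambda: {"mu": -6.0, "sigma": 2.0}
    )
    n_samples_per_habitat: dict = field(
        default_factory=lambda: {"human gut": 250, "soil": 250}
    )
    source_probs: dict = field(
        default_factory=lambda: {
            "PROGENOMES": 0.10,
            "GTDB": 0.10,
            "SPIRE_MAG": 0.20,
            "UNBINNED": 0.60,
        }
    )
    n_markers: int = 3
    marker_dropout: float = 0.1
    cluster_split_rate: float = 1.0
    genomes_per_species_mean: float = 20.0
    habitat_leakage: float = 0.1
    seed: int | None = None

    def __post_init__(self):
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not self.n_samples_per_habitat:
            raise ValueError("habitat map must not be empty")
        if self.cluster_split_rate <= 0:
            raise ValueError("cluster_split_rate must be positive")
        if not 0.0 <= self.marker_dropout <= 1.0:
            raise ValueError("marker_dropout must lie in [0, 1]")
        probs = np.array(list(self.source_probs.values()), dtype=float)
        if np.any(probs < 0) or np.any(probs > 1) or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("source_probs must be probabilities summing to 1")
        if self.occupancy_law not in ("log_series", "lognormal"):
            raise ValueError("occupancy_law must be 'log_series' or 'lognormal'")


@dataclass
class SyntheticCensus:
    """A generated census table plus its ground truth."""

    table: GeneClusterTable
    species_labels: dict[str, str]  # seq_id -> species, genome-derived records
    species_tier: dict[str, str]  # species -> provenance tier
    presence: np.ndarray  # species x samples boolean occurrence matrix
    samples: list[str]
    sample_habitat: dict[str, str]
    n_sample_sequences: int  # records emitted from samples (not genomes)
    world: SyntheticWorld


def _occupancy_probs(world: SyntheticWorld, rng: np.random.Generator, n_samples: int):
    if world.occupancy_law == "lognormal":
        mu = world.occupancy_params.get("mu", -3.0)
        sigma = world.occupancy_params.get("sigma", 1.5)
        return np.clip(np.exp(rng.normal(mu, sigma, world.n_species)), 0.0, 1.0)
    theta = world.occupancy_params.get("theta", 0.95)
    k = stats.logser.rvs(theta, size=world.n_species, random_state=rng)
    return np.clip(k / n_samples, 0.0, 1.0)


def simulate_census(world: SyntheticWorld) -> SyntheticCensus:
    """Generate a sequence-level census table from a synthetic world.

    Species occupancy follows the chosen long-tailed law, modulated by a
    home-habitat preference (occupancy off the home habitat is scaled by
    ``habitat_leakage``).  Each present species contributes one sequence
    per marker per sample unless dropped out; reference-tier species
    additionally contribute genome-derived records.  Output is
    deterministic under a fixed seed.
    """
    rng = np.random.default_rng(world.seed)
    habitats = sorted(world.n_samples_per_habitat)
    samples = []
    sample_habitat = {}
    for hab in habitats:
        for i in range(world.n_samples_per_habitat[hab]):
            sid = f"{hab.replace(' ', '_')}_s{i:04d}"
            samples.append(sid)
            sample_habitat[sid] = hab
    n_samples = len(samples)
    species = [f"sp{i:05d}" for i in range(world.n_species)]
    tiers = list(world.source_probs)
    tier_idx = rng.choice(
        len(tiers), size=world.n_species, p=list(world.source_probs.values())
    )
    species_tier = {sp: tiers[t] for sp, t in zip(species, tier_idx)}

    base_p = _occupancy_probs(world, rng, n_samples)
    home = rng.integers(len(habitats), size=world.n_species)
    hab_of_sample = np.array([habitats.index(sample_habitat[s]) for s in samples])
    # occupancy matrix: base occupancy at home habitat, leakage elsewhere
    scale = np.where(
        home[:, None] == hab_of_sample[None, :], 1.0, world.habitat_leakage
    )
    presence = rng.random((world.n_species, n_samples)) < base_p[:, None] * scale

    markers = [f"marker{m:02d}" for m in range(world.n_markers)]
    # species -> clusters per marker
    rate = world.cluster_split_rate
    cluster_ids: dict[tuple[str, str], list[str]] = {}
    for mk in markers:
        if rate >= 1.0:
            n_clusters = 1 + rng.poisson(rate - 1.0, size=world.n_species)
            idx = 0
            for si, sp in enumerate(species):
                cluster_ids[(sp, mk)] = [
                    f"{mk}_c{idx + j:06d}" for j in range(n_clusters[si])
                ]
                idx += int(n_clusters[si])
        else:
            # lumping regime: species share cluster slots
            n_slots = max(1, int(round(rate * world.n_species)))
            slot = rng.integers(n_slots, size=world.n_species)
            for si, sp in enumerate(species):
                cluster_ids[(sp, mk)] = [f"{mk}_c{slot[si]:06d}"]

    rows = []
    species_labels: dict[str, str] = {}
    counter = 0

    def emit(marker, cluster, source, sample_id, contig_id, habitat, label=None):
        nonlocal counter
        sid = f"seq{counter:08d}"
        counter += 1
        rows.append(
            {
                "seq_id": sid,
                "marker_gene": marker,
                "cluster_id": cluster,
                "source": source,
                "sample_id": sample_id,
                "contig_id": contig_id,
                "habitat": habitat,
            }
        )
        if label is not None:
            species_labels[sid] = label

    # genome-derived records for reference-tier and MAG-tier species
    for si, sp in enumerate(species):
        tier = species_tier[sp]
        if tier not in ("PROGENOMES", "GTDB"):
            continue
        # heavy-tailed genome counts (few deeply sequenced species, many
        # rare ones), floored so every gene cluster of a species is
        # represented by at least one genome
        n_genomes = int(rng.geometric(1.0 / world.genomes_per_species_mean))
        for mk in markers:
            clusters = cluster_ids[(sp, mk)]
            for g in range(max(n_genomes, len(clusters))):
                emit(mk, clusters[g % len(clusters)], tier, "", "", "", label=sp)

    # sample-derived records
    n_sample_sequences = 0
    sp_idx, sm_idx = np.nonzero(presence)
    dropout = rng.random((len(sp_idx), world.n_markers)) < world.marker_dropout
    for row_i, (si, smi) in enumerate(zip(sp_idx, sm_idx)):
        sp = species[si]
        tier = species_tier[sp]
        sid = samples[smi]
        hab = sample_habitat[sid]
        for mi, mk in enumerate(markers):
            if dropout[row_i, mi]:
                continue
            clusters = cluster_ids[(sp, mk)]
            cl = clusters[rng.integers(len(clusters))]
            if tier == "SPIRE_MAG":
                emit(mk, cl, "SPIRE_MAG", sid, "", hab, label=sp)
            else:
                contig = f"{sid}_ctg{si:05d}"
                emit(mk, cl, "UNBINNED", sid, contig, hab)
            n_sample_sequences += 1

    table = GeneClusterTable(pd.DataFrame(rows), habitats=habitats)
    return SyntheticCensus(
        table=table,
        species_labels=species_labels,
        species_tier=species_tier,
        presence=presence,
        samples=samples,
        sample_habitat=sample_habitat,
        n_sample_sequences=n_sample_sequences,
        world=world,
    )


# ---------------------------------------------------------------------------
# Synthetic discovery curves
# ---------------------------------------------------------------------------


def simulate_discovery_curve(
    k: float,
    gamma: float,
    grid,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> RarefactionCurve:
    """Cumulative discovery curve whose marginal gains follow k * N^-gamma.

    Between consecutive grid points the marginal gain, evaluated at the
    geometric midpoint m = sqrt(N_i * N_{i+1}), is k * m^-gamma times
    multiplicative lognormal noise exp(noise_sd * Z); with ``noise_sd=0``
    the law is exact and the fitted gamma recovers the input to machine
    precision.  The curve starts from the integrated power law at the
    first grid point.
    """
    grid = np.asarray(grid, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    if len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing with >= 2 points")
    rng = np.random.default_rng(seed)
    mids = np.sqrt(grid[:-1] * grid[1:])
    gains = k * mids ** (-gamma)
    if noise_sd > 0:
        gains = gains * np.exp(noise_sd * rng.standard_normal(len(gains)))
    if np.any(gains < 0):
        raise ValueError("marginal gains must be nonnegative (curve would decrease)")
    if gamma < 1.0:
        s0 = k * grid[0] ** (1.0 - gamma) / (1.0 - gamma)
    else:
        s0 = k * np.log(grid[0]) if gamma == 1.0 else k * grid[0] ** (1 - gamma)
    S = np.concatenate([[s0], s0 + np.cumsum(gains * np.diff(grid))])
    series = pd.Series(S, index=grid.astype(int))
    return RarefactionCurve.from_series(series, marker_gene="synthetic")
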