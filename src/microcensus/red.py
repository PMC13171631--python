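"""Relative evolutionary divergence (RED) and taxonomy-free clade delineation.

RED interpolates between 0 at the root of a phylogeny and 1 at its tips:
for a node with parent P connected by a branch of length d,

    RED(node) = RED(P) + (d / u) * (1 - RED(P)),

where u is the mean branch-length distance from P to all tips descending
through the node.  Cutting a tree where root-to-tip paths first reach a
given RED value yields rank-comparable clades without relying on taxon
names; cutoffs per rank are calibrated by scanning RED values and scoring
the resulting partitions against reference taxonomic labels with adjusted
mutual information (AMI), optionally averaging RED over alternative
rootings that use each recognized phylum in turn as an outgroup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_mutual_info_score

from microcensus.census import GeneClusterTable, SourceLabel

RANKS = ["phylum", "class", "order", "family", "genus"]

#: Rank cutoffs of the GTDB reference taxonomy, shipped as defaults for
#: Bacteria-mode runs; Archaea-mode runs calibrate cutoffs from data.
GTDB_REFERENCE_CUTOFFS = {
    "phylum": 0.32,
    "class": 0.46,
    "order": 0.61,
    "family": 0.77,
    "genus": 0.92,
}


def _validate_tree(tree: dendropy.Tree) -> None:
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 tips")
    if len(set(leaves)) != len(leaves):
        raise ValueError("tip names must be unique")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("all branches must carry lengths")
        if edge.length < 0:
            raise ValueError("negative branch length")


@dataclass
class REDAnnotatedTree:
    """A rooted phylogeny plus per-node RED values.

    ``red`` maps each node's descendant-tip frozenset to its RED value
    (tips are keyed by singleton sets); ``n_rootings`` records over how
    many root positions each value was averaged.
    """

    tree: dendropy.Tree
    red: dict[frozenset, float]
    n_rootings: dict[frozenset, int] = field(default_factory=dict)
    _node_red: dict[int, float] = field(default_factory=dict, repr=False)

    def node_red(self, node: dendropy.Node) -> float:
        if id(node) in self._node_red:
            return self._node_red[id(node)]
        return self.red[_tipset(node)]

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "tips": ";".join(sorted(k)),
                "n_tips": len(k),
                "red": v,
                "n_rootings": self.n_rootings.get(k, 1),
            }
            for k, v in self.red.items()
        ]
        return pd.DataFrame(rows).sort_values(["n_tips", "tips"]).reset_index(drop=True)


def _tipset(node: dendropy.Node) -> frozenset:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def compute_red(tree: dendropy.Tree) -> REDAnnotatedTree:
    """Annotate every node of a rooted tree with its RED value.

    Tips are fixed at 1 and the root at 0.  Zero-length branches inherit
    the parental RED; multifurcations are handled natively.
    """
    _validate_tree(tree)
    # mean distance from each node to its descendant tips (postorder)
    n_tips: dict[int, int] = {}
    sum_dist: dict[int, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            n_tips[id(node)] = 1
            sum_dist[id(node)] = 0.0
        else:
            n_tips[id(node)] = sum(n_tips[id(c)] for c in node.child_nodes())
            sum_dist[id(node)] = sum(
                sum_dist[id(c)] + (c.edge.length or 0.0) * n_tips[id(c)]
                for c in node.child_nodes()
            )
    red: dict[frozenset, float] = {}
    node_red: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            value = 0.0
        elif node.is_leaf():
            value = 1.0
        else:
            d = node.edge.length or 0.0
            parent_red = node_red[id(node.parent_node)]
            # u: mean distance from the parent to tips descending through node
            u = d + sum_dist[id(node)] / n_tips[id(node)]
            value = parent_red + (d / u) * (1.0 - parent_red) if u > 0 else parent_red
        node_red[id(node)] = value
        red[_tipset(node)] = value
    return REDAnnotatedTree(
        tree=tree, red=red, n_rootings={k: 1 for k in red}, _node_red=node_red
    )


def _reroot_at_outgroup(
    tree: dendropy.Tree, outgroup: frozenset
) -> dendropy.Tree:
    """Clone and reroot so the outgroup is one side of the basal split.

    The root is placed at the midpoint of the branch subtending the
    outgroup's MRCA (or, if the outgroup is paraphyletic from the current
    rooting but its complement is clean, the complement's MRCA).
    """
    t = tree.clone(depth=1)
    t.is_rooted = True
    taxa = [t.taxon_namespace.get_taxon(l) for l in sorted(outgroup)]
    if any(x is None for x in taxa):
        raise ValueError("outgroup contains unknown tips")
    all_tips = frozenset(l.taxon.label for l in t.leaf_node_iter())
    if outgroup == all_tips:
        raise ValueError("outgroup cannot equal the entire tip set")
    mrca = t.mrca(taxa=taxa)
    if _tipset(mrca) != outgroup:
        comp = all_tips - outgroup
        taxa = [t.taxon_namespace.get_taxon(l) for l in sorted(comp)]
        mrca = t.mrca(taxa=taxa)
        if _tipset(mrca) != comp:
            raise ValueError("outgroup is not attachable by a bipartition")
    if mrca.parent_node is None:
        return t  # already the basal split
    L = mrca.edge.length or 0.0
    t.reroot_at_edge(mrca.edge, length1=L / 2.0, length2=L / 2.0)
    return t


def average_red_over_rootings(
    tree: dendropy.Tree, outgroup_sets: Sequence[Iterable[str]]
) -> REDAnnotatedTree:
    """Average per-node RED over alternative rootings.

    For each outgroup the tree is re-rooted on the branch subtending it and
    RED recomputed; nodes are matched across rootings by their descendant
    tip set, and a node contributes to the average only in rootings where
    it exists and does not sit inside the current outgroup.  Nodes of the
    original tree never seen under any alternative rooting keep their
    original-rooting RED.
    """
    base = compute_red(tree)
    if not outgroup_sets:
        return base
    sums: dict[frozenset, float] = {}
    counts: dict[frozenset, int] = {}
    for og in outgroup_sets:
        og = frozenset(og)
        rerooted = _reroot_at_outgroup(tree, og)
        red = compute_red(rerooted)
        for tipset, value in red.red.items():
            if tipset <= og:
                continue  # inside the current outgroup
            sums[tipset] = sums.get(tipset, 0.0) + value
            counts[tipset] = counts.get(tipset, 0) + 1
    avg: dict[frozenset, float] = {}
    n_rootings: dict[frozenset, int] = {}
    for tipset, value in base.red.items():
        if tipset in sums:
            avg[tipset] = sums[tipset] / counts[tipset]
            n_rootings[tipset] = counts[tipset]
        else:
            avg[tipset] = value
            n_rootings[tipset] = 0
    node_red = {
        node_id: avg[tipset]
        for tipset, node_id in (
            (_tipset(n), id(n)) for n in tree.preorder_node_iter()
        )
    }
    return REDAnnotatedTree(
        tree=tree, red=avg, n_rootings=n_rootings, _node_red=node_red
    )


@dataclass
class CladePartition:
    """Result of cutting a RED-annotated tree at one rank cutoff."""

    rank: str
    cutoff: float
    clades: list[dict]  # {"clade_id", "tips": frozenset, "provenance": str|None}

    @property
    def n_clades(self) -> int:
        return len(self.clades)

    def tip_labels(self) -> dict[str, str]:
        """Map tip -> clade_id (a labelling of all tips)."""
        out: dict[str, str] = {}
        for clade in self.clades:
            for tip in clade["tips"]:
                out[tip] = clade["clade_id"]
        return out


def cut_at_red(
    red_tree: REDAnnotatedTree, cutoff: float, rank: str = "unranked"
) -> CladePartition:
    """Cut a tree into clades at a RED cutoff (first-crossing rule).

    Clade roots are the maximal nodes with RED >= cutoff, i.e. the first
    node crossing the cutoff along each root-to-tip path; because tips have
    RED 1 every tip belongs to exactly one clade, so the clades partition
    the tip set (tips not under an internal crossing become singletons).
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    clades: list[dict] = []
    stack: list[tuple[dendropy.Node, float | None]] = [
        (red_tree.tree.seed_node, None)
    ]
    while stack:
        node, parent_red = stack.pop()
        value = red_tree.node_red(node)
        if value >= cutoff and (parent_red is None or parent_red < cutoff):
            clades.append({"tips": _tipset(node)})
        else:
            stack.extend((child, value) for child in node.child_nodes())
    clades.sort(key=lambda c: sorted(c["tips"])[0])
    for i, clade in enumerate(clades):
        clade["clade_id"] = f"{rank}_{i:05d}"
        clade["provenance"] = None
    return CladePartition(rank=rank, cutoff=cutoff, clades=clades)


def adjusted_mutual_information(
    part_a: Mapping[str, str] | Sequence, part_b: Mapping[str, str] | Sequence
) -> float:
    """Chance-corrected agreement between two labellings of the same items.

    AMI with arithmetic-mean normalization and the hypergeometric model of
    expected mutual information; 1 for identical partitions up to
    relabelling, about 0 for independent ones.
    """
    if isinstance(part_a, Mapping) or isinstance(part_b, Mapping):
        if set(part_a) != set(part_b):
            raise ValueError("partitions must label the same element set")
        keys = sorted(part_a)
        a = [part_a[k] for k in keys]
        b = [part_b[k] for k in keys]
    else:
        a, b = list(part_a), list(part_b)
        if len(a) != len(b):
            raise ValueError("partitions must label the same element set")
    return float(adjusted_mutual_info_score(a, b, average_method="arithmetic"))


@dataclass
class CalibrationResult:
    """AMI scan of RED cutoffs against reference labels at one rank."""

    rank: str
    grid: np.ndarray
    ami: np.ndarray
    cutoff: float
    tolerance: float = 0.1

    @property
    def peak_ami(self) -> float:
        return float(self.ami.max())


def calibrate_cutoffs(
    red_tree: REDAnnotatedTree,
    labels: Mapping[str, str],
    rank: str,
    grid_step: float = 0.01,
) -> CalibrationResult:
    """Find the RED cutoff whose partition best matches reference labels.

    Scans a cutoff grid (a uniform grid of step ``grid_step`` augmented
    with the observed node RED values, so that every achievable partition
    is visited) restricted to the labelled tips, scoring each partition by
    AMI against the labels; the selected cutoff attains the peak AMI (ties
    broken toward the smallest cutoff).
    """
    labelled = set(labels) & {
        l.taxon.label for l in red_tree.tree.leaf_node_iter()
    }
    if len(labelled) < 2 or len({labels[t] for t in labelled}) < 2:
        raise ValueError("need at least 2 distinct labels at this rank")
    uniform = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    observed = np.array(sorted(set(red_tree.red.values())))
    grid = np.unique(np.clip(np.concatenate([uniform, observed]), 0.0, 1.0))
    ref = {t: labels[t] for t in labelled}
    scores = np.empty(len(grid))
    # cutoffs between consecutive observed RED values induce identical
    # partitions, so score each distinct partition only once
    cache: dict[float, float] = {}
    for i, c in enumerate(grid):
        j = int(np.searchsorted(observed, c, side="left"))
        key = float(observed[j]) if j < len(observed) else float(c)
        if key not in cache:
            part = cut_at_red(red_tree, float(key), rank=rank)
            pred = {
                t: cid for t, cid in part.tip_labels().items() if t in labelled
            }
            cache[key] = adjusted_mutual_information(pred, ref)
        scores[i] = cache[key]
    best = int(np.argmax(scores))  # argmax takes the first (smallest) maximizer
    return CalibrationResult(
        rank=rank, grid=grid, ami=scores, cutoff=float(grid[best])
    )


def label_clade_sources(
    partition: CladePartition, table: GeneClusterTable, marker: str
) -> CladePartition:
    """Attach a provenance class to every clade.

    A clade is ``reference`` if any tip's cluster contains an isolate or
    catalogue genome sequence, ``mag_only`` if none do but at least one
    contains a study MAG, and ``unbinned_only`` otherwise.  Tips are
    cluster identifiers of the given marker.
    """
    sources = table.cluster_sources(marker)
    for clade in partition.clades:
        tip_sources: set[str] = set()
        for tip in clade["tips"]:
            if tip not in sources:
                raise ValueError(f"tip {tip!r} has no cluster mapping")
            tip_sources |= sources[tip]
        if tip_sources & {SourceLabel.PROGENOMES.value, SourceLabel.GTDB.value}:
            clade["provenance"] = "reference"
        elif SourceLabel.SPIRE_MAG.value in tip_sources:
            clade["provenance"] = "mag_only"
        else:
            clade["provenance"] = "unbinned_only"
    return partition


PROVENANCE_CLASSES = ["reference", "mag_only", "unbinned_only"]


def count_clades_by_level(
    partitions: Mapping[str, Mapping[str, CladePartition]]
) -> pd.DataFrame:
    """Median and s.d. of clade counts across markers, per rank and class.

    ``partitions`` maps marker -> rank -> labelled partition.  The s.d. is
    the sample standard deviation across markers (0 for a single marker).
    """
    if not partitions:
        raise ValueError("need at least one marker")
    rows = []
    ranks = sorted({r for per_rank in partitions.values() for r in per_rank})
    for rank in ranks:
        for cls in PROVENANCE_CLASSES + ["total"]:
            counts = []
            for marker in sorted(partitions):
                part = partitions[marker].get(rank)
                if part is None:
                    continue
                if cls == "total":
                    counts.append(part.n_clades)
                else:
                    counts.append(
                        sum(1 for c in part.clades if c["provenance"] == cls)
                    )
            arr = np.array(counts, dtype=float)
            sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
            rows.append(
                {
                    "rank": rank,
                    "provenance": cls,
                    "median": float(np.median(arr)),
                    "sd": sd,
                    "n_markers": len(arr),
                }
            )
    return pd.DataFrame(rows)


def profile_phylum_subtrees(
    red_tree: REDAnnotatedTree,
    phylum_labels: Mapping[str, str],
    table: GeneClusterTable,
    marker: str,
    n_rep: int = 5,
    frac: float = 0.8,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-phylum subtree profile of unbinned-to-genome-backed tip ratios.

    For each labelled phylum, the MRCA of a random ``frac`` subset of its
    genome-backed tips is located ``n_rep`` times; each MRCA subtree is
    profiled for the ratio of tips representing only unbinned sequences to
    tips backed by a genome, and values are averaged over repetitions.
    """
    sources = table.cluster_sources(marker)
    genome_backed = {
        tip
        for tip in (l.taxon.label for l in red_tree.tree.leaf_node_iter())
        if sources.get(tip, set())
        & {SourceLabel.PROGENOMES.value, SourceLabel.GTDB.value, SourceLabel.SPIRE_MAG.value}
    }
    rng = np.random.default_rng(seed)
    taxon_ns = red_tree.tree.taxon_namespace
    rows = []
    phyla = sorted(set(phylum_labels.values()))
    for phylum in phyla:
        tips = sorted(
            t for t, p in phylum_labels.items() if p == phylum and t in genome_backed
        )
        if len(tips) < 2:
            raise ValueError(f"phylum {phylum!r} has fewer than 2 genome-backed tips")
        ratios, n_tips_list = [], []
        for _ in range(n_rep):
            k = max(2, int(round(frac * len(tips))))
            chosen = sorted(rng.choice(tips, size=min(k, len(tips)), replace=False))
            mrca = red_tree.tree.mrca(
                taxa=[taxon_ns.get_taxon(t) for t in chosen]
            )
            sub_tips = _tipset(mrca)
            n_genome = len(sub_tips & genome_backed)
            n_unbinned = len(sub_tips - genome_backed)
            ratios.append(n_unbinned / n_genome if n_genome else float("inf"))
            n_tips_list.append(len(sub_tips))
        rows.append(
            {
                "phylum": phylum,
                "unbinned_ratio": float(np.mean(ratios)),
                "mean_subtree_tips": float(np.mean(n_tips_list)),
                "n_rep": n_rep,
            }
        )
    return pd.DataFrame(rows)
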