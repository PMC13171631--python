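"""RED values, rooting averages, cutting, AMI calibration and clade labelling."""

import numpy as np
import pytest

from microcensus import (
    GeneClusterTable,
    adjusted_mutual_information,
    average_red_over_rootings,
    calibrate_cutoffs,
    compute_red,
    count_clades_by_level,
    cut_at_red,
    label_clade_sources,
    profile_phylum_subtrees,
    simulate_yule_tree,
)
from microcensus.red import RANKS

from conftest import records, tree_from_newick


def red_by_tips(red_tree):
    return {";".join(sorted(k)): v for k, v in red_tree.red.items()}


class TestComputeRed:
    def test_balanced_tree_closed_form(self, balanced_red):
        red = red_by_tips(balanced_red)
        assert red["A;B;C;D"] == 0.0
        # children of the root: d=1, mean root-to-tip distance through child 2
        assert red["A;B"] == pytest.approx(0.5)
        assert red["C;D"] == pytest.approx(0.5)
        for tip in "ABCD":
            assert red[tip] == 1.0

    def test_caterpillar_against_independent_recursion(self):
        newick = "(A:0.5,(B:1.5,(C:0.3,(D:2.0,(E:0.7,F:1.1):0.4):0.6):0.9):0.2):0;"
        tree = tree_from_newick(newick)
        got = red_by_tips(compute_red(tree))

        # independent oracle: explicit adjacency + direct formula application
        children = {
            "R": [("A", 0.5), ("N1", 0.2)],
            "N1": [("B", 1.5), ("N2", 0.9)],
            "N2": [("C", 0.3), ("N3", 0.6)],
            "N3": [("D", 2.0), ("N4", 0.4)],
            "N4": [("E", 0.7), ("F", 1.1)],
        }

        def tips_below(n):
            if n not in children:
                return [(n, 0.0)]
            out = []
            for c, d in children[n]:
                out.extend((t, d + dist) for t, dist in tips_below(c))
            return out

        expected = {}

        def walk(node, parent_red):
            for child, d in children.get(node, []):
                if child not in children:
                    expected[child] = 1.0
                    continue
                dists = [d + dist for _, dist in tips_below(child)]
                u = sum(dists) / len(dists)
                value = parent_red + (d / u) * (1.0 - parent_red)
                expected[";".join(sorted(t for t, _ in tips_below(child)))] = value
                walk(child, value)

        expected["A;B;C;D;E;F"] = 0.0
        walk("R", 0.0)
        for key, val in expected.items():
            assert got[key] == pytest.approx(val), key

    def test_root_zero_tips_one_everywhere(self):
        sim = simulate_yule_tree(30, seed=5)
        red = compute_red(sim.tree)
        tips = {l.taxon.label for l in sim.tree.leaf_node_iter()}
        assert red.red[frozenset(tips)] == 0.0
        for t in tips:
            assert red.red[frozenset([t])] == 1.0

    def test_monotone_along_root_to_tip_paths(self):
        for seed in range(25):
            sim = simulate_yule_tree(20, seed=seed)
            red = compute_red(sim.tree)
            for node in sim.tree.preorder_node_iter():
                if node.parent_node is not None:
                    assert red.node_red(node) >= red.node_red(node.parent_node) - 1e-12

    def test_zero_length_branch_inherits_parent_red(self):
        tree = tree_from_newick("((A:1,B:1):0.0,(C:1,D:1):1):0;")
        red = red_by_tips(compute_red(tree))
        assert red["A;B"] == 0.0

    def test_negative_branch_rejected(self):
        tree = tree_from_newick("((A:1,B:1):-1,(C:1,D:1):1):0;")
        with pytest.raises(ValueError, match="negative"):
            compute_red(tree)


class TestRootingAverage:
    def test_no_outgroups_identical_to_single_rooting(self, balanced_tree):
        base = compute_red(balanced_tree)
        avg = average_red_over_rootings(balanced_tree, [])
        assert base.red == avg.red

    def test_symmetric_tree_symmetric_outgroups(self, balanced_tree):
        avg = average_red_over_rootings(balanced_tree, [{"A", "B"}, {"C", "D"}])
        red = red_by_tips(avg)
        assert red["A;B"] == pytest.approx(red["C;D"])

    def test_brute_force_average(self):
        sim = simulate_yule_tree(20, seed=9)
        phyla = sorted(set(sim.labels["phylum"]))
        ogs = [
            frozenset(sim.labels.index[sim.labels["phylum"] == p]) for p in phyla
        ]
        avg = average_red_over_rootings(sim.tree, ogs)
        from microcensus.red import _reroot_at_outgroup

        sums, counts = {}, {}
        for og in ogs:
            red = compute_red(_reroot_at_outgroup(sim.tree, og))
            for ts, v in red.red.items():
                if ts <= og:
                    continue
                sums[ts] = sums.get(ts, 0.0) + v
                counts[ts] = counts.get(ts, 0) + 1
        for ts, v in avg.red.items():
            if ts in sums:
                assert v == pytest.approx(sums[ts] / counts[ts])

    def test_outgroup_equal_to_all_tips_rejected(self, balanced_tree):
        with pytest.raises(ValueError, match="entire"):
            average_red_over_rootings(balanced_tree, [{"A", "B", "C", "D"}])


class TestCutAtRed:
    @pytest.mark.parametrize("cutoff,n_clades", [(0.0, 1), (0.25, 2), (0.75, 4)])
    def test_balanced_tree_cuts(self, balanced_red, cutoff, n_clades):
        assert cut_at_red(balanced_red, cutoff).n_clades == n_clades

    def test_partition_property_random_trees(self):
        for seed in range(10):
            sim = simulate_yule_tree(40, seed=seed)
            red = compute_red(sim.tree)
            tips = frozenset(l.taxon.label for l in sim.tree.leaf_node_iter())
            for cutoff in (0.0, 0.2, 0.5, 0.8, 1.0):
                part = cut_at_red(red, cutoff)
                seen = [t for c in part.clades for t in c["tips"]]
                assert len(seen) == len(tips)
                assert frozenset(seen) == tips

    def test_clade_count_monotone_in_cutoff(self):
        sim = simulate_yule_tree(60, seed=2)
        red = compute_red(sim.tree)
        counts = [cut_at_red(red, c).n_clades for c in np.linspace(0, 1, 21)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_cutoff_out_of_range(self, balanced_red):
        with pytest.raises(ValueError):
            cut_at_red(balanced_red, 1.5)


class TestAMI:
    def test_identical_partitions(self):
        labels = {f"e{i}": f"g{i % 5}" for i in range(50)}
        assert adjusted_mutual_information(labels, labels) == pytest.approx(1.0)

    def test_invariant_to_relabelling(self):
        a = {f"e{i}": f"g{i % 5}" for i in range(50)}
        b = {k: f"renamed-{v}" for k, v in a.items()}
        assert adjusted_mutual_information(a, b) == pytest.approx(1.0)

    def test_independent_partitions_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(10, size=10_000)
        b = rng.integers(10, size=10_000)
        assert abs(adjusted_mutual_information(a, b)) < 0.01

    def test_self_ami_one_for_random_partitions(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            labels = rng.integers(rng.integers(2, 20), size=200)
            assert adjusted_mutual_information(labels, labels) == pytest.approx(1.0)

    def test_mismatched_elements_rejected(self):
        with pytest.raises(ValueError):
            adjusted_mutual_information({"a": 1}, {"b": 1})


class TestCalibration:
    def test_planted_ranks_recovered_exactly(self):
        sim = simulate_yule_tree(300, seed=7)
        red = compute_red(sim.tree)
        cutoffs = {}
        for rank in RANKS:
            labels = dict(sim.labels[rank])
            result = calibrate_cutoffs(red, labels, rank)
            assert result.peak_ami == pytest.approx(1.0)
            part = cut_at_red(red, result.cutoff, rank=rank)
            assert part.n_clades == sim.planted_counts[rank]
            cutoffs[rank] = result.cutoff
        ordered = [cutoffs[r] for r in RANKS]
        assert all(b > a for a, b in zip(ordered, ordered[1:]))

    def test_all_distinct_labels_peak_at_singletons(self):
        sim = simulate_yule_tree(30, seed=3)
        labels = {t: t for t in sim.labels.index}
        result = calibrate_cutoffs(compute_red(sim.tree), labels, "genus")
        part = cut_at_red(compute_red(sim.tree), result.cutoff)
        assert part.n_clades == 30
        assert result.peak_ami == pytest.approx(1.0)

    def test_single_label_rejected(self):
        sim = simulate_yule_tree(10, seed=0)
        labels = {t: "only" for t in sim.labels.index}
        with pytest.raises(ValueError, match="distinct"):
            calibrate_cutoffs(compute_red(sim.tree), labels, "phylum")


def provenance_table(tip_sources):
    rows = []
    for i, (tip, source) in enumerate(tip_sources):
        sample = "" if source in ("PROGENOMES", "GTDB") else f"smp{i}"
        contig = f"ctg{i}" if source == "UNBINNED" else ""
        habitat = "" if not sample else "soil"
        rows.append((f"s{i}", "mk", tip, source, sample, contig, habitat))
    return GeneClusterTable(records(rows))


class TestCladeLabelling:
    def test_provenance_rules(self, balanced_red):
        table = provenance_table(
            [("A", "PROGENOMES"), ("B", "UNBINNED"), ("C", "SPIRE_MAG"), ("D", "UNBINNED")]
        )
        part = cut_at_red(balanced_red, 0.25)
        part = label_clade_sources(part, table, "mk")
        by_tips = {min(c["tips"]): c["provenance"] for c in part.clades}
        assert by_tips["A"] == "reference"
        assert by_tips["C"] == "mag_only"

    def test_unbinned_only(self, balanced_red):
        table = provenance_table([(t, "UNBINNED") for t in "ABCD"])
        part = label_clade_sources(cut_at_red(balanced_red, 0.25), table, "mk")
        assert all(c["provenance"] == "unbinned_only" for c in part.clades)

    def test_missing_mapping_rejected(self, balanced_red):
        table = provenance_table([("A", "UNBINNED"), ("B", "UNBINNED"), ("C", "UNBINNED")])
        with pytest.raises(ValueError, match="mapping"):
            label_clade_sources(cut_at_red(balanced_red, 0.25), table, "mk")


class TestCladeCounts:
    def test_single_marker_sd_zero(self, balanced_red):
        table = provenance_table([(t, "UNBINNED") for t in "ABCD"])
        part = label_clade_sources(cut_at_red(balanced_red, 0.25, rank="genus"), table, "mk")
        out = count_clades_by_level({"mk": {"genus": part}})
        total = out[(out["rank"] == "genus") & (out["provenance"] == "total")]
        assert total["median"].iloc[0] == 2
        assert total["sd"].iloc[0] == 0.0

    def test_median_across_markers(self, balanced_red):
        table = provenance_table([(t, "UNBINNED") for t in "ABCD"])
        parts = {}
        for marker, cutoff in [("m1", 0.25), ("m2", 0.75), ("m3", 0.0)]:
            parts[marker] = {
                "genus": label_clade_sources(
                    cut_at_red(balanced_red, cutoff, rank="genus"), table, "mk"
                )
            }
        out = count_clades_by_level(parts)
        total = out[(out["rank"] == "genus") & (out["provenance"] == "total")]
        assert total["median"].iloc[0] == 2.0  # counts {2, 4, 1}

    def test_class_sums_match_total(self, small_census):
        # conservation: provenance classes partition each marker's clades
        from microcensus import simulate_yule_tree as syt

        table = small_census.table
        marker = table.markers[0]
        clusters = sorted(table.subset(marker)["cluster_id"].unique())[:50]
        sim = syt(50, seed=1)
        mapping = {f"t{i:05d}": clusters[i] for i in range(50)}
        for leaf in sim.tree.leaf_node_iter():
            leaf.taxon.label = mapping[leaf.taxon.label]
        red = compute_red(sim.tree)
        part = label_clade_sources(cut_at_red(red, 0.5, rank="family"), table, marker)
        out = count_clades_by_level({marker: {"family": part}})
        sub = out[out["rank"] == "family"].set_index("provenance")["median"]
        assert sub[["reference", "mag_only", "unbinned_only"]].sum() == sub["total"]


class TestPhylumProfile:
    def test_all_genome_backed_ratio_zero(self, balanced_red):
        table = provenance_table([(t, "GTDB") for t in "ABCD"])
        labels = {"A": "P1", "B": "P1", "C": "P2", "D": "P2"}
        prof = profile_phylum_subtrees(balanced_red, labels, table, "mk", seed=0)
        assert (prof["unbinned_ratio"] == 0.0).all()

    def test_planted_mixed_clade_ratio_one(self):
        # a phylum clade holding 3 unbinned and 3 genome-backed tips
        newick = "(((A:1,B:1):1,(C:1,(D:1,(E:1,F:1):1):1):1):1,(G:1,H:1):2):0;"
        tree = tree_from_newick(newick)
        red = compute_red(tree)
        sources = [(t, "GTDB") for t in "ACE"] + [(t, "UNBINNED") for t in "BDF"] + [
            (t, "GTDB") for t in "GH"
        ]
        table = provenance_table(sources)
        labels = {t: "P1" for t in "ACE"} | {t: "P2" for t in "GH"}
        prof = profile_phylum_subtrees(
            red, labels, table, "mk", n_rep=1, frac=1.0, seed=0
        )
        row = prof[prof["phylum"] == "P1"].iloc[0]
        assert row["unbinned_ratio"] == pytest.approx(1.0)

    def test_small_phylum_rejected(self, balanced_red):
        table = provenance_table([(t, "GTDB") for t in "ABCD"])
        labels = {"A": "P1", "B": "P2", "C": "P2", "D": "P2"}
        with pytest.raises(ValueError, match="fewer than 2"):
            profile_phylum_subtrees(balanced_red, labels, table, "mk", seed=0)
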