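"""Strain-sharing inference: distances, thresholds, events, rates, transmissibility."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from socialstrains.strainshare import (
    analyze,
    detect_events,
    normalized_leaf_distances,
    pair_categories,
    read_distance_table,
    sharing_rate,
    species_inclusion_filter,
    strain_threshold,
    transmissibility,
)
from socialstrains.synthdata import SimulationConfig, simulate_all


def tree_of(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def random_binary_tree(rng, n_leaves: int) -> dendropy.Tree:
    """Random topology with uniform branch lengths, built bottom-up."""
    nodes = [f"L{i}:{rng.uniform(0.1, 2.0):.6f}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.1, 2.0):.6f}"
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [merged]
    return tree_of(nodes[0] + ";")


def naive_normalized_distances(tree: dendropy.Tree) -> dict:
    """Independent oracle: root-to-leaf path sums minus twice the LCA depth."""
    depth = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depth[node] = (depth[parent] if parent else 0.0) + (node.edge.length or 0.0)
    ancestors = {}
    for leaf in tree.leaf_node_iter():
        chain, node = [], leaf
        while node is not None:
            chain.append(node)
            node = node.parent_node
        ancestors[leaf] = chain
    total = sum(e.length or 0.0 for e in tree.preorder_edge_iter())
    out = {}
    leaves = list(tree.leaf_node_iter())
    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            lca = next(x for x in ancestors[a] if x in set(ancestors[b]))
            d = depth[a] + depth[b] - 2 * depth[lca]
            out[tuple(sorted((a.taxon.label, b.taxon.label)))] = d / total
    return out


class TestNormalizedDistances:
    def test_three_leaf_star_path_arithmetic(self):
        dist = normalized_leaf_distances(tree_of("(A:1,B:1,C:2);"))
        assert dist.at["A", "B"] == pytest.approx(0.5)
        assert dist.at["A", "C"] == pytest.approx(0.75)
        assert dist.at["B", "C"] == pytest.approx(0.75)

    def test_two_leaf_tree_is_unit_distance(self):
        dist = normalized_leaf_distances(tree_of("(A:1,B:1);"))
        assert dist.at["A", "B"] == pytest.approx(1.0)

    def test_matches_naive_traversal_oracle(self, rng):
        tree = random_binary_tree(rng, 20)
        dist = normalized_leaf_distances(tree)
        for (a, b), expected in naive_normalized_distances(tree).items():
            assert dist.at[a, b] == pytest.approx(expected, abs=1e-12)

    def test_all_distances_bounded_by_one(self, rng):
        for n in (3, 7, 15):
            dist = normalized_leaf_distances(random_binary_tree(rng, n))
            arr = dist.to_numpy()
            assert arr.max() <= 1.0 + 1e-12
            assert np.allclose(arr, arr.T) and np.all(np.diag(arr) == 0)

    def test_degenerate_zero_length_tree_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalized_leaf_distances(tree_of("(A:0,B:0);"))

    def test_duplicate_leaf_labels_rejected(self):
        # duplicate sample labels are an input error, raised at parse time
        with pytest.raises(Exception, match="[Dd]uplicate"):
            normalized_leaf_distances(tree_of("(A:1,A:1);"))


def roster_frame(samples: dict[str, str]) -> pd.DataFrame:
    """sample -> dataset mapping to a minimal roster."""
    return pd.DataFrame(
        {
            "individual_id": [s.replace("S_", "") for s in samples],
            "sample_id": list(samples),
            "social_group": "1MZ",
            "sex": "F",
            "age_class": "adult",
            "role": "NA",
            "dataset": list(samples.values()),
        }
    )


class TestInclusionFilter:
    @pytest.mark.parametrize(
        "n_total,n_primary,kept",
        [(5, 2, True), (6, 1, False), (4, 4, False), (7, 3, True)],
    )
    def test_sample_count_boundaries(self, n_total, n_primary, kept):
        samples = {
            f"S_{i}": ("primary" if i < n_primary else "secondary") for i in range(n_total)
        }
        newick = "(" + ",".join(f"S_{i}:1" for i in range(n_total)) + ");"
        trees = {"s__SGB0001": tree_of(newick)}
        out = species_inclusion_filter(trees, roster_frame(samples))
        assert (out == ["s__SGB0001"]) is kept

    def test_unknown_leaf_names_sample(self):
        trees = {"sp": tree_of("(S_0:1,S_mystery:1);")}
        with pytest.raises(ValueError, match="S_mystery"):
            species_inclusion_filter(trees, roster_frame({"S_0": "primary"}))


class TestThreshold:
    def test_constant_distribution(self):
        d = pd.DataFrame(0.3 * (1 - np.eye(4)), index=list("abcd"), columns=list("abcd"))
        assert strain_threshold(d) == pytest.approx(0.3)

    def test_single_pair(self):
        d = pd.DataFrame([[0, 0.2], [0.2, 0]], index=list("ab"), columns=list("ab"))
        assert strain_threshold(d) == pytest.approx(0.2)

    def test_matches_sorted_interpolation_oracle(self):
        values = np.arange(0.01, 1.001, 0.01)  # 100 off-diagonal values
        # embed into a symmetric matrix over 15 leaves (105 pairs, pad with 1.0)
        n = 15
        arr = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        padded = np.concatenate([values, np.full(len(iu[0]) - len(values), 1.0)])
        arr[iu] = padded
        arr = arr + arr.T
        d = pd.DataFrame(arr, index=range(n), columns=range(n))
        # independent sorted-interpolation computation
        srt = np.sort(padded)
        rank = 0.05 * (len(srt) - 1)
        lo, hi = int(np.floor(rank)), int(np.ceil(rank))
        expected = srt[lo] + (rank - lo) * (srt[hi] - srt[lo])
        assert strain_threshold(d, 5) == pytest.approx(expected, abs=1e-15)

    def test_empty_distribution_rejected(self):
        d = pd.DataFrame([[0.0]], index=["a"], columns=["a"])
        with pytest.raises(ValueError):
            strain_threshold(d)


class TestEvents:
    def test_strictly_below_threshold(self):
        d = pd.DataFrame(
            [[0, 0.05, 0.2], [0.05, 0, 0.15], [0.2, 0.15, 0]],
            index=list("ABC"), columns=list("ABC"),
        )
        assert detect_events(d, 0.1) == {("A", "B")}
        assert detect_events(d, 0.05) == set()  # boundary is not an event
        assert detect_events(d, 0.01) == set()

    def test_raising_percentile_never_loses_events(self, bundle):
        from socialstrains.strainshare import normalized_leaf_distances

        tree = next(iter(bundle["trees"].values()))
        dist = normalized_leaf_distances(tree)
        counts = [
            len(detect_events(dist, strain_threshold(dist, pct))) for pct in (1, 5, 10, 25)
        ]
        assert counts == sorted(counts)


class TestRatesAndTransmissibility:
    def _fixture(self, n_species, n_events_for_pair):
        leaves = {f"sp{i}": {"S_a", "S_b"} for i in range(n_species)}
        events = {
            f"sp{i}": ({("S_a", "S_b")} if i < n_events_for_pair else set())
            for i in range(n_species)
        }
        roster = pd.DataFrame(
            {
                "individual_id": ["a", "b"],
                "sample_id": ["S_a", "S_b"],
                "social_group": "1MZ",
                "sex": ["F", "M"],
                "age_class": "adult",
                "role": ["mother", "father"],
                "dataset": "primary",
            }
        )
        return events, leaves, roster

    @pytest.mark.parametrize(
        "n_species,n_events,rate,retained",
        [(6, 3, 0.5, True), (4, 4, 1.0, False), (5, 0, 0.0, True)],
    )
    def test_rate_and_retention(self, n_species, n_events, rate, retained):
        events, leaves, roster = self._fixture(n_species, n_events)
        out = sharing_rate(events, leaves, roster)
        assert len(out) == 1
        assert out.at[0, "rate"] == pytest.approx(rate)
        assert bool(out.at[0, "retained"]) is retained
        assert out.at[0, "n_shared_strains"] <= out.at[0, "n_shared_species"]

    def test_transmissibility_counts_potential_pairs(self):
        roster = pd.DataFrame(
            {
                "individual_id": list("abcd"),
                "sample_id": [f"S_{i}" for i in "abcd"],
                "social_group": "1MZ",
                "sex": "F",
                "age_class": "adult",
                "role": "NA",
                "dataset": "primary",
            }
        )
        leaves = {"sp": {f"S_{i}" for i in "abcd"}}
        events = {"sp": {("S_a", "S_b"), ("S_a", "S_c"), ("S_b", "S_c")}}
        out = transmissibility(events, leaves, roster)
        assert out.at[0, "n_potential"] == 6  # C(4,2)
        assert out.at[0, "value"] == pytest.approx(0.5)
        assert bool(out.at[0, "retained"])

    def test_too_few_potential_pairs_not_retained(self):
        roster = pd.DataFrame(
            {
                "individual_id": list("abc"),
                "sample_id": [f"S_{i}" for i in "abc"],
                "social_group": "1MZ",
                "sex": "F",
                "age_class": "adult",
                "role": "NA",
                "dataset": "primary",
            }
        )
        leaves = {"sp": {"S_a", "S_b", "S_c"}}
        out = transmissibility({"sp": set()}, leaves, roster)
        assert out.at[0, "n_potential"] == 3
        assert not bool(out.at[0, "retained"])
        assert out.at[0, "value"] == 0.0


class TestPairCategories:
    def test_exactly_one_category_per_pair(self, bundle):
        primary = bundle["roster"][bundle["roster"]["dataset"] == "primary"]
        pairs = pair_categories(primary)
        n = len(primary)
        assert len(pairs) == n * (n - 1) // 2
        assert pairs[["individual_a", "individual_b"]].duplicated().sum() == 0


class TestEndToEndRecovery:
    def test_within_group_rates_dominate_between_group(self):
        cfg = SimulationConfig(seed=5, p_within=0.9, p_between=0.02, p_vertical=0.9)
        b = simulate_all(cfg)
        res = analyze(b["trees"], b["roster"])
        rates = res["rates"]
        kept = rates[rates["retained"] & rates["rate"].notna()]
        assert kept.loc[kept["same_group"], "rate"].median() >= 0.8
        assert kept.loc[~kept["same_group"], "rate"].median() <= 0.1

    def test_distance_table_reader_round_trip(self, tmp_path, bundle):
        tree = next(iter(bundle["trees"].values()))
        dist = normalized_leaf_distances(tree)
        rows = []
        labels = list(dist.index)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                rows.append({"species": "sp1", "sample_a": a, "sample_b": b, "distance": dist.at[a, b]})
        pd.DataFrame(rows).to_csv(tmp_path / "d.tsv", sep="\t", index=False)
        back = read_distance_table(tmp_path / "d.tsv")["sp1"]
        assert np.allclose(back.loc[labels, labels].to_numpy(), dist.to_numpy())
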