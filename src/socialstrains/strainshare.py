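"""Strain-sharing inference from per-species strain phylogenies.

For every microbial species profiled at the strain level, leaf-to-leaf
patristic distances are normalized by the tree's total branch length, a
species-specific strain identity threshold is set at a low percentile
(default the 5th) of that species' distance distribution, and pairs of
samples strictly below the threshold count as strain sharing events. Events
aggregate into two statistics:

* the pairwise **strain sharing rate** — shared strains between two
  individuals over the species both carry with a strain-level profile,
  retained only when the pair shares at least ``min_shared`` species;
* per-species **transmissibility** — observed events over potential events
  (all in-scope sample pairs carrying the species), retained only with at
  least ``min_potential`` potential events.
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "pair_categories",
    "read_metadata",
    "read_trees",
    "read_distance_table",
    "normalized_leaf_distances",
    "species_inclusion_filter",
    "strain_threshold",
    "detect_events",
    "sharing_rate",
    "transmissibility",
    "analyze",
]

CATEGORIES = (
    "mother-offspring",
    "father-offspring",
    "siblings",
    "partners",
    "same-group-other",
    "different-group",
)

_REQUIRED_META = ["individual_id", "sample_id", "social_group", "role", "dataset"]


def read_metadata(path: Path | str) -> pd.DataFrame:
    # keep literal "NA" category labels (unknown sex/role) as strings
    roster = pd.read_csv(path, sep="\t", dtype={"social_group": str}, keep_default_na=False)
    missing = [c for c in _REQUIRED_META if c not in roster.columns]
    if missing:
        raise ValueError(f"metadata file {path} is missing columns: {missing}")
    if roster["individual_id"].duplicated().any():
        raise ValueError("one sample per individual: duplicated individual_id in metadata")
    return roster


def pair_categories(roster: pd.DataFrame) -> pd.DataFrame:
    """Unordered pair relations derived from group membership and family roles."""

    def categorize(a, b) -> str:
        if a.social_group != b.social_group:
            return "different-group"
        roles = {a.role, b.role}
        if roles == {"mother", "progeny"}:
            return "mother-offspring"
        if roles == {"father", "progeny"}:
            return "father-offspring"
        if roles == {"progeny"}:
            return "siblings"
        if roles == {"mother", "father"}:
            return "partners"
        return "same-group-other"

    rows = [
        {
            "individual_a": a.individual_id,
            "individual_b": b.individual_id,
            "category": categorize(a, b),
            "same_group": a.social_group == b.social_group,
        }
        for a, b in combinations(
            sorted(roster.itertuples(), key=lambda r: r.individual_id), 2
        )
    ]
    return pd.DataFrame(rows, columns=["individual_a", "individual_b", "category", "same_group"])


def read_trees(treedir: Path | str) -> dict[str, dendropy.Tree]:
    """Load a directory of per-species Newick files (species id = file stem)."""
    treedir = Path(treedir)
    trees = {}
    for p in sorted(treedir.glob("*.nwk")) + sorted(treedir.glob("*.tre")):
        trees[p.stem] = dendropy.Tree.get(
            path=str(p), schema="newick", preserve_underscores=True
        )
    if not trees:
        raise ValueError(f"no Newick files found under {treedir}")
    return trees


def normalized_leaf_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Leaf-to-leaf patristic distances normalized by the total branch length.

    Entries lie in [0, 1] since no simple path can exceed the sum of all
    branch lengths; the result is symmetric with a zero diagonal. Rooting is
    irrelevant: patristic distance is a property of the unrooted tree metric.
    """
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("strain tree needs at least 2 leaves")
    if len(set(leaves)) != len(leaves):
        raise ValueError("duplicate leaf labels in strain tree")
    total = tree.length()
    if total <= 0:
        raise ValueError("degenerate tree: total branch length is 0")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    labels = sorted(leaves)
    mat = np.zeros((len(labels), len(labels)))
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            d = pdm.patristic_distance(taxa[a], taxa[labels[j]]) / total
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


def read_distance_table(path: Path | str) -> dict[str, pd.DataFrame]:
    """Long-format TSV (species, sample_a, sample_b, distance) -> per-species matrices."""
    long = pd.read_csv(path, sep="\t")
    out = {}
    for species, grp in long.groupby("species"):
        samples = sorted(set(grp["sample_a"]) | set(grp["sample_b"]))
        mat = pd.DataFrame(0.0, index=samples, columns=samples)
        for row in grp.itertuples():
            mat.at[row.sample_a, row.sample_b] = row.distance
            mat.at[row.sample_b, row.sample_a] = row.distance
        out[str(species)] = mat
    return out


def species_inclusion_filter(
    trees: dict[str, dendropy.Tree],
    roster: pd.DataFrame,
    min_samples: int = 5,
    min_primary: int = 2,
) -> list[str]:
    """Species kept iff profiled in >= min_samples samples, >= min_primary primary ones."""
    dataset_of = dict(zip(roster["sample_id"], roster["dataset"]))
    kept = []
    for species, tree in trees.items():
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        unknown = [s for s in leaves if s not in dataset_of]
        if unknown:
            raise ValueError(f"{species}: leaf sample(s) not in metadata: {unknown[:3]}")
        n_primary = sum(dataset_of[s] == "primary" for s in leaves)
        if len(leaves) >= min_samples and n_primary >= min_primary:
            kept.append(species)
    return kept


def strain_threshold(
    dist: pd.DataFrame, percentile: float = 5.0, method: str = "linear"
) -> float:
    """Strain identity threshold: percentile of the off-diagonal distance distribution.

    ``method`` follows numpy's percentile conventions ('linear' interpolation
    by default; 'lower' gives a nearest-rank-below variant).
    """
    arr = dist.to_numpy()
    iu = np.triu_indices(arr.shape[0], k=1)
    values = arr[iu]
    if values.size == 0:
        raise ValueError("empty distance distribution")
    return float(np.percentile(values, percentile, method=method))


def detect_events(dist: pd.DataFrame, threshold: float) -> set[tuple[str, str]]:
    """Unordered sample pairs with distance strictly below the threshold."""
    events = set()
    labels = list(dist.index)
    arr = dist.to_numpy()
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if arr[i, j] < threshold:
                events.add(tuple(sorted((labels[i], labels[j]))))
    return events


def sharing_rate(
    events_by_species: dict[str, set[tuple[str, str]]],
    leaves_by_species: dict[str, set[str]],
    roster: pd.DataFrame,
    min_shared: int = 5,
) -> pd.DataFrame:
    """Pairwise strain sharing rates with the minimum-shared-species retention flag.

    For each pair of individuals, ``n_shared_species`` counts species whose
    tree holds both samples and ``n_shared_strains`` those with a sharing
    event for the pair; ``rate`` is their ratio. Pairs sharing fewer than
    ``min_shared`` species are flagged not retained. Rates are computed among
    primary-dataset individuals (secondary samples only augment the trees).
    """
    sample_of = dict(zip(roster["individual_id"], roster["sample_id"]))
    pairs = pair_categories(roster[roster["dataset"] == "primary"])
    rows = []
    for row in pairs.itertuples():
        sa, sb = sample_of[row.individual_a], sample_of[row.individual_b]
        key = tuple(sorted((sa, sb)))
        n_species = sum(
            1 for sp, leaves in leaves_by_species.items() if sa in leaves and sb in leaves
        )
        n_strains = sum(
            1
            for sp, leaves in leaves_by_species.items()
            if sa in leaves and sb in leaves and key in events_by_species.get(sp, set())
        )
        rows.append(
            {
                "individual_a": row.individual_a,
                "individual_b": row.individual_b,
                "category": row.category,
                "same_group": row.same_group,
                "n_shared_species": n_species,
                "n_shared_strains": n_strains,
                "rate": (n_strains / n_species) if n_species else np.nan,
                "retained": n_species >= min_shared,
            }
        )
    return pd.DataFrame(rows)


def transmissibility(
    events_by_species: dict[str, set[tuple[str, str]]],
    leaves_by_species: dict[str, set[str]],
    roster: pd.DataFrame,
    min_potential: int = 5,
    scope: str = "primary",
    within_group_only: bool = True,
) -> pd.DataFrame:
    """Per-species transmissibility: observed over potential sharing events.

    A potential event is an in-scope sample pair in which both samples carry
    a strain-level profile of the species. ``scope='primary'`` restricts to
    primary-dataset samples; by default pairs are further restricted to
    members of the same social group, so the value reads "when two group
    members had the species in common, how often did they share the strain".
    """
    if scope == "primary":
        in_scope = set(roster.loc[roster["dataset"] == "primary", "sample_id"])
    elif scope == "all":
        in_scope = set(roster["sample_id"])
    else:
        raise ValueError("scope must be 'primary' or 'all'")
    group_of = dict(zip(roster["sample_id"], roster["social_group"]))

    def eligible(a: str, b: str) -> bool:
        if a not in in_scope or b not in in_scope:
            return False
        return not within_group_only or group_of.get(a) == group_of.get(b)

    rows = []
    for species in sorted(leaves_by_species):
        carriers = sorted(leaves_by_species[species] & in_scope)
        n_potential = sum(
            1 for a, b in combinations(carriers, 2) if eligible(a, b)
        )
        n_events = sum(
            1 for a, b in events_by_species.get(species, set()) if eligible(a, b)
        )
        rows.append(
            {
                "species_id": species,
                "n_events": n_events,
                "n_potential": n_potential,
                "value": (n_events / n_potential) if n_potential else np.nan,
                "retained": n_potential >= min_potential,
            }
        )
    return pd.DataFrame(rows)


def analyze(
    trees: dict[str, dendropy.Tree],
    roster: pd.DataFrame,
    percentile: float = 5.0,
    min_samples: int = 5,
    min_primary: int = 2,
    min_shared: int = 5,
    min_potential: int = 5,
    scope: str = "primary",
    within_group_only: bool = True,
) -> dict:
    """Full strain-sharing analysis over a set of per-species trees.

    Applies the species inclusion filter, computes per-species normalized
    distances, thresholds and events, then the pairwise sharing rates and
    species transmissibilities. Returns a dict of DataFrames/sets keyed by
    'retained_species', 'thresholds', 'events', 'rates', 'transmissibility'.
    """
    retained = species_inclusion_filter(trees, roster, min_samples, min_primary)
    thresholds = {}
    events_by_species: dict[str, set] = {}
    leaves_by_species: dict[str, set] = {}
    warn_zero = []
    for species in retained:
        dist = normalized_leaf_distances(trees[species])
        thr = strain_threshold(dist, percentile=percentile)
        if thr == 0.0:
            warn_zero.append(species)
        thresholds[species] = {
            "threshold": thr,
            "n_leaves": dist.shape[0],
            "n_primary_leaves": int(
                roster.set_index("sample_id")
                .reindex(dist.index)["dataset"]
                .eq("primary")
                .sum()
            ),
        }
        events_by_species[species] = detect_events(dist, thr)
        leaves_by_species[species] = set(dist.index)
    thresholds_df = (
        pd.DataFrame.from_dict(thresholds, orient="index")
        .rename_axis("species_id")
        .reset_index()
    )
    return {
        "retained_species": retained,
        "zero_threshold_species": warn_zero,
        "thresholds": thresholds_df,
        "events": events_by_species,
        "leaves": leaves_by_species,
        "rates": sharing_rate(events_by_species, leaves_by_species, roster, min_shared),
        "transmissibility": transmissibility(
            events_by_species, leaves_by_species, roster, min_potential, scope, within_group_only
        ),
    }
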