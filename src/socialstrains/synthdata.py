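"""Synthetic cohorts, strain trees, abundance tables, GPS tracks and MASH matrices.

The generator emulates the structure of a social-transmission microbiome study
in a group-living host: small stable social groups built around a reproductive
pair, per-species strain phylogenies in which socially linked individuals carry
near-identical strains, a large core set of species present in nearly every
individual, group-clustered GPS territories, and block-structured genome
distance matrices with a nested species/genus/family hierarchy. Every generator
is deterministic given the master seed, and ships its ground truth so the
downstream inference can be scored.

Sharing structure
-----------------
Arbitrary per-pair sharing indicators cannot be realized as leaf distances of a
tree (two short distances and one long one between three leaves violate the
triangle inequality), so strain sharing is generated as an equivalence relation
over strain *labels*:

* each (group, species) has a group strain; carriers adopt it with probability
  ``q = sqrt(p_within)``, otherwise they carry a private strain;
* each group adopts, for each species, a region-wide strain instead of its own
  with probability ``s = sqrt(p_between / p_within)``;
* progeny copy their mother's label with probability ``p_vertical``.

Two same-group individuals without a vertical link then share with marginal
probability exactly ``p_within``; a cross-group pair with exactly
``p_between``; mother-offspring pairs with ``p_vertical + (1 - p_vertical) *
p_within``; sibling sharing is elevated through the common mother, as observed
in real social cohorts.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import projection

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_strain_trees",
    "simulate_abundance_table",
    "simulate_gps_tracks",
    "simulate_mash_matrix",
    "simulate_all",
    "write_trees",
    "write_metadata",
    "write_abundance",
    "write_gps",
    "write_mash",
]

# Anchor of the synthetic study area (lon, lat): an evergreen-rainforest site
# inside UTM zone 39 in the southern hemisphere.
_ANCHOR_LON = 48.47
_ANCHOR_LAT = -18.96


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-generator substream of the master seed."""
    return np.random.default_rng([int(seed), zlib.crc32(stream.encode())])


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the field situation the package targets: six social groups
    of two to five individuals each (the reproductive pair plus progeny), a
    species pool in which ~60% of species are core (present in every
    individual), strong vertical (mother-to-offspring) and horizontal
    (within-group) transmission, rare between-group transmission, and small
    exclusive territories a few hundred meters apart.

    ``n_secondary`` unrelated context individuals (dataset="secondary",
    mirroring samples pooled in from other studies) carry private strains:
    they thicken each species' distance distribution so that genuinely shared
    pairs sit in its extreme low tail, which is what makes a low-percentile
    identity threshold conservative.
    """

    n_groups: int = 6
    group_size_range: tuple[int, int] = (2, 5)
    n_secondary: int = 40
    n_species: int = 30
    core_fraction: float = 0.6
    p_vertical: float = 0.85
    p_within: float = 0.7
    p_between: float = 0.02
    shared_divergence: float = 0.01
    unshared_divergence: float = 0.5
    territory_spacing_m: float = 500.0
    points_per_group: int = 40
    gps_jitter_m: float = 150.0
    noncore_prevalence: float = 0.6
    group_effect_scale: float = 1.0
    mean_reads: float = 4.7e7
    seed: int = 0
    # optional per-species overrides (arrays of length n_species); used to
    # simulate species that differ in transmissibility
    p_within_per_species: np.ndarray | None = None
    p_vertical_per_species: np.ndarray | None = None

    def __post_init__(self) -> None:
        lo, hi = self.group_size_range
        if lo < 2:
            raise ValueError("group_size_range minimum must be >= 2 (a reproductive pair)")
        if hi < lo:
            raise ValueError("group_size_range must be (min, max) with max >= min")
        if not (0.0 <= self.p_between <= self.p_within <= 1.0):
            raise ValueError("require 0 <= p_between <= p_within <= 1")
        if not 0.0 <= self.p_vertical <= 1.0:
            raise ValueError("p_vertical must be in [0, 1]")
        if not self.shared_divergence < self.unshared_divergence:
            raise ValueError("shared_divergence must be < unshared_divergence")
        if min(self.n_groups, self.n_species, self.points_per_group) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0.0 <= self.core_fraction <= 1.0:
            raise ValueError("core_fraction must be in [0, 1]")
        for name in ("p_within_per_species", "p_vertical_per_species"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (self.n_species,):
                    raise ValueError(f"{name} must have length n_species")
                if arr.min() < 0 or arr.max() > 1:
                    raise ValueError(f"{name} values must be in [0, 1]")
                setattr(self, name, arr)

    def species_ids(self) -> list[str]:
        return [f"s__SGB{k + 1:04d}" for k in range(self.n_species)]


@dataclass
class GroundTruth:
    """What the generators actually seeded, for scoring downstream inference."""

    true_shared_pairs: set = field(default_factory=set)  # {(species_id, (ind_a, ind_b))}
    species_carriers: dict = field(default_factory=dict)  # species_id -> [individual_id]
    true_bin_labels: pd.DataFrame | None = None  # genome_id, sgb, ggb, fgb
    true_group_effects: pd.DataFrame | None = None  # group x species

    def to_json(self) -> str:
        payload = {
            "true_shared_pairs": sorted(
                [sp, list(pair)] for sp, pair in self.true_shared_pairs
            ),
            "species_carriers": {k: sorted(v) for k, v in sorted(self.species_carriers.items())},
            "true_bin_labels": (
                None
                if self.true_bin_labels is None
                else self.true_bin_labels.to_dict(orient="list")
            ),
            "true_group_effects": (
                None
                if self.true_group_effects is None
                else json.loads(self.true_group_effects.to_json())
            ),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# cohort


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the roster of individuals and the derived pair-relation table.

    Each group holds exactly one mother and one father (the reproductive pair)
    and zero or more progeny. Returns ``(roster, pair_relations)``; the roster
    has one sample per individual.
    """
    rng = _rng(config.seed, "cohort")
    lo, hi = config.group_size_range
    rows = []
    for g in range(1, config.n_groups + 1):
        group = f"{g}MZ"
        size = int(rng.integers(lo, hi + 1))
        members = [("mother", "F", "adult"), ("father", "M", "adult")]
        for _ in range(size - 2):
            age = rng.choice(["infant", "yearling", "adult"], p=[0.2, 0.3, 0.5])
            sex = rng.choice(["F", "M", "NA"], p=[0.4, 0.4, 0.2]) if age != "infant" else "NA"
            members.append(("progeny", sex, age))
        for j, (role, sex, age) in enumerate(members):
            ind = f"I{g:02d}{chr(ord('A') + j)}"
            rows.append(
                {
                    "individual_id": ind,
                    "sample_id": f"S_{ind}",
                    "social_group": group,
                    "sex": sex,
                    "age_class": age,
                    "role": role,
                    "dataset": "primary",
                    "n_reads": int(rng.lognormal(np.log(config.mean_reads), 0.4)),
                }
            )
    for j in range(1, config.n_secondary + 1):
        ind = f"X{j:03d}"
        rows.append(
            {
                "individual_id": ind,
                "sample_id": f"S_{ind}",
                "social_group": f"EXT{j:03d}",
                "sex": rng.choice(["F", "M"]),
                "age_class": "adult",
                "role": "NA",
                "dataset": "secondary",
                "n_reads": int(rng.lognormal(np.log(config.mean_reads), 0.4)),
            }
        )
    roster = pd.DataFrame(rows)
    from .strainshare import pair_categories

    return roster, pair_categories(roster[roster["dataset"] == "primary"])


# ---------------------------------------------------------------------------
# strain trees


def _strain_labels(
    roster: pd.DataFrame,
    carriers: list[str],
    p_within: float,
    p_between: float,
    p_vertical: float,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Assign a strain label to every carrier (see module docstring)."""
    q = np.sqrt(p_within)
    s = np.sqrt(p_between / p_within) if p_within > 0 else 0.0
    by_ind = roster.set_index("individual_id")
    groups = sorted(by_ind.loc[carriers, "social_group"].unique())
    group_base = {g: ("REGIONAL" if rng.random() < s else f"G::{g}") for g in groups}
    mother_of = {
        row.social_group: row.individual_id
        for row in roster.itertuples()
        if row.role == "mother"
    }
    labels: dict[str, str] = {}
    carrier_set = set(carriers)
    # parents and unroled individuals first, progeny after (they may copy the mother)
    ordered = sorted(carriers, key=lambda i: (by_ind.at[i, "role"] == "progeny", i))
    for ind in ordered:
        g = by_ind.at[ind, "social_group"]
        if by_ind.at[ind, "role"] == "progeny":
            mom = mother_of.get(g)
            if mom in carrier_set and rng.random() < p_vertical:
                labels[ind] = labels[mom]
                continue
        labels[ind] = group_base[g] if rng.random() < q else f"P::{ind}"
    return labels


def _cluster_tree(
    clusters: list[list[str]],
    sample_of: dict[str, str],
    shared_div: float,
    unshared_div: float,
    rng: np.random.Generator,
) -> dendropy.Tree:
    """Build a star-of-clusters tree realizing the seeded sharing structure.

    Leaves of one cluster hang off a shared internal node; the leaf-to-leaf
    distance inside a cluster is on the ``shared_divergence`` scale and across
    clusters on the ``unshared_divergence`` scale (before normalization by
    total branch length, which preserves their ratio).
    """
    eps = 0.5 * shared_div
    height = 0.5 * (unshared_div - shared_div)
    parts = []
    for members in clusters:
        pendants = [f"{sample_of[m]}:{eps * rng.uniform(0.5, 1.5):.10f}" for m in sorted(members)]
        if len(clusters) == 1:
            parts.extend(pendants)
        elif len(members) == 1:
            h = height * rng.uniform(0.75, 1.25)
            m = sorted(members)[0]
            parts.append(f"{sample_of[m]}:{h + eps * rng.uniform(0.5, 1.5):.10f}")
        else:
            h = height * rng.uniform(0.75, 1.25)
            parts.append(f"({','.join(pendants)}):{h:.10f}")
    newick = f"({','.join(parts)});"
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def simulate_strain_trees(
    roster: pd.DataFrame, config: SimulationConfig
) -> tuple[dict[str, dendropy.Tree], GroundTruth]:
    """One strain phylogeny per species plus the seeded sharing ground truth.

    Species presence is drawn with ``core_fraction`` (core species carried by
    everyone, others by a Bernoulli draw); species with fewer than two
    carriers yield no tree. Leaf labels are sample ids.
    """
    if roster.empty:
        raise ValueError("roster is empty")
    rng = _rng(config.seed, "trees")
    individuals = list(roster["individual_id"])
    primary_set = set(roster.loc[roster["dataset"] == "primary", "individual_id"])
    sample_of = dict(zip(roster["individual_id"], roster["sample_id"]))
    n_core = int(round(config.core_fraction * config.n_species))
    truth = GroundTruth()
    trees: dict[str, dendropy.Tree] = {}
    for k, species in enumerate(config.species_ids()):
        if k < n_core:
            carriers = list(individuals)
        else:
            mask = rng.random(len(individuals)) < config.noncore_prevalence
            carriers = [i for i, keep in zip(individuals, mask) if keep]
        truth.species_carriers[species] = carriers
        if len(carriers) < 2:
            continue
        p_w = (
            float(config.p_within_per_species[k])
            if config.p_within_per_species is not None
            else config.p_within
        )
        p_v = (
            float(config.p_vertical_per_species[k])
            if config.p_vertical_per_species is not None
            else config.p_vertical
        )
        p_b = min(config.p_between, p_w)
        primary_carriers = [c for c in carriers if c in primary_set]
        labels = _strain_labels(roster, primary_carriers, p_w, p_b, p_v, rng)
        # secondary context samples carry private strains
        labels.update({c: f"P::{c}" for c in carriers if c not in primary_set})
        by_label: dict[str, list[str]] = {}
        for ind, lab in labels.items():
            by_label.setdefault(lab, []).append(ind)
        clusters = [sorted(v) for _, v in sorted(by_label.items())]
        for members in clusters:
            for a_i in range(len(members)):
                for b_i in range(a_i + 1, len(members)):
                    pair = tuple(sorted((members[a_i], members[b_i])))
                    truth.true_shared_pairs.add((species, pair))
        trees[species] = _cluster_tree(
            clusters, sample_of, config.shared_divergence, config.unshared_divergence, rng
        )
    return trees, truth


# ---------------------------------------------------------------------------
# abundance


def simulate_abundance_table(
    roster: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Samples x species relative-abundance table (rows sum to 1).

    Core species are present in every sample; the rest follow a Bernoulli
    presence draw. Log-normal abundances carry an additive per-(group,
    species) log-scale effect of magnitude ``group_effect_scale`` (0 disables
    group structure, yielding a null table). Returns ``(table, group_effects)``.
    """
    if roster.empty:
        raise ValueError("roster is empty")
    rng = _rng(config.seed, "abundance")
    roster = roster[roster["dataset"] == "primary"].reset_index(drop=True)
    species = config.species_ids()
    n_core = int(round(config.core_fraction * config.n_species))
    groups = sorted(roster["social_group"].unique())
    base = rng.normal(0.0, 1.5, size=config.n_species)
    effects = pd.DataFrame(
        rng.normal(0.0, config.group_effect_scale, size=(len(groups), config.n_species)),
        index=groups,
        columns=species,
    )
    rows = []
    for row in roster.itertuples():
        logab = base + effects.loc[row.social_group].to_numpy() + rng.normal(0.0, 0.5, config.n_species)
        present = np.ones(config.n_species, dtype=bool)
        present[n_core:] = rng.random(config.n_species - n_core) < config.noncore_prevalence
        ab = np.where(present, np.exp(logab), 0.0)
        rows.append(ab / ab.sum())
    table = pd.DataFrame(rows, index=list(roster["sample_id"]), columns=species)
    return table, effects


# ---------------------------------------------------------------------------
# GPS


def simulate_gps_tracks(roster: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Group-clustered stationary GPS points.

    Group centers sit on a grid with ``territory_spacing_m`` spacing; points
    scatter uniformly within ``gps_jitter_m`` of the center. Coordinates are
    emitted both as projected meters (UTM zone 39S) and as back-projected
    WGS84 degrees.
    """
    if roster.empty:
        raise ValueError("roster is empty")
    rng = _rng(config.seed, "gps")
    groups = sorted(roster.loc[roster["dataset"] == "primary", "social_group"].unique())
    anchor_e, anchor_n = projection.geographic_to_utm(
        np.array([_ANCHOR_LON]), np.array([_ANCHOR_LAT]), zone=39, south=True
    )
    ncol = int(np.ceil(np.sqrt(len(groups))))
    rows = []
    for gi, group in enumerate(groups):
        ce = anchor_e[0] + (gi % ncol) * config.territory_spacing_m
        cn = anchor_n[0] + (gi // ncol) * config.territory_spacing_m
        for _ in range(config.points_per_group):
            e = ce + rng.uniform(-config.gps_jitter_m, config.gps_jitter_m)
            n = cn + rng.uniform(-config.gps_jitter_m, config.gps_jitter_m)
            rows.append({"group_id": group, "easting": e, "northing": n})
    pts = pd.DataFrame(rows)
    lon, lat = projection.utm_to_geographic(
        pts["easting"].to_numpy(), pts["northing"].to_numpy(), zone=39, south=True
    )
    pts["lon"] = lon
    pts["lat"] = lat
    return pts


# ---------------------------------------------------------------------------
# MASH matrix


def simulate_mash_matrix(
    n_per_sgb: int = 3,
    n_sgb_per_ggb: int = 2,
    n_ggb_per_fgb: int = 2,
    n_fgb: int = 2,
    level_distances: tuple[float, float, float, float] = (0.02, 0.10, 0.22, 0.40),
    noise: float = 0.005,
    seed: int = 0,
    cutoffs: tuple[float, float, float] = (0.05, 0.15, 0.30),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Block-structured genome distance matrix with a nested 3-level hierarchy.

    ``level_distances`` are the characteristic distances within an SGB, within
    a GGB (across its SGBs), within an FGB (across its GGBs) and across FGBs;
    they must be strictly increasing and, after maximal ``noise``, stay on the
    correct side of the clustering cutoffs. Returns ``(matrix, labels)`` where
    labels holds the true (sgb, ggb, fgb) integer assignment per genome.
    """
    d = np.asarray(level_distances, dtype=float)
    if not np.all(np.diff(d) > 0):
        raise ValueError("level_distances must be strictly increasing")
    bounds = (0.0, *cutoffs, 1.0)
    for lvl in range(4):
        lo, hi = bounds[lvl], bounds[lvl + 1]
        if not (lo < d[lvl] - noise and d[lvl] + noise < hi):
            raise ValueError(
                f"level distance {d[lvl]} +/- {noise} straddles the ({lo}, {hi}) band"
            )
    rng = np.random.default_rng([int(seed), zlib.crc32(b"mash")])
    recs = []
    gid = 0
    for f in range(n_fgb):
        for g in range(n_ggb_per_fgb):
            for s in range(n_sgb_per_ggb):
                for _ in range(n_per_sgb):
                    recs.append(
                        {
                            "genome_id": f"MAG{gid:04d}",
                            "sgb": f * n_ggb_per_fgb * n_sgb_per_ggb + g * n_sgb_per_ggb + s,
                            "ggb": f * n_ggb_per_fgb + g,
                            "fgb": f,
                        }
                    )
                    gid += 1
    labels = pd.DataFrame(recs)
    n = len(labels)
    sgb = labels["sgb"].to_numpy()
    ggb = labels["ggb"].to_numpy()
    fgb = labels["fgb"].to_numpy()
    level = np.full((n, n), 3)
    level[fgb[:, None] == fgb[None, :]] = 2
    level[ggb[:, None] == ggb[None, :]] = 1
    level[sgb[:, None] == sgb[None, :]] = 0
    mat = d[level] + rng.uniform(-noise, noise, size=(n, n))
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 0.0)
    matrix = pd.DataFrame(mat, index=labels["genome_id"], columns=labels["genome_id"])
    return matrix, labels


# ---------------------------------------------------------------------------
# writers


def write_metadata(roster: pd.DataFrame, path: Path | str) -> None:
    roster.to_csv(path, sep="\t", index=False)


def write_trees(trees: dict[str, dendropy.Tree], outdir: Path | str) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for species, tree in sorted(trees.items()):
        p = outdir / f"{species}.nwk"
        p.write_text(
            tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
        )
        paths.append(p)
    return paths


def write_abundance(table: pd.DataFrame, path: Path | str) -> None:
    """MetaPhlAn-style merged table: rank-prefixed species rows, sample columns."""
    out = table.T.copy()
    out.index = [f"k__Bacteria|{s}" for s in out.index]
    out.index.name = "clade_name"
    out.to_csv(path, sep="\t")


def write_gps(points: pd.DataFrame, path: Path | str) -> None:
    points[["group_id", "lon", "lat"]].to_csv(path, index=False)


def write_mash(matrix: pd.DataFrame, path: Path | str) -> None:
    """mash-dist 5-column tabular: ref query distance pvalue shared-hashes."""
    with open(path, "w") as fh:
        ids = list(matrix.index)
        for a in ids:
            for b in ids:
                fh.write(f"{a}\t{b}\t{matrix.at[a, b]:.8f}\t0.0\t1000/1000\n")


def simulate_all(config: SimulationConfig, outdir: Path | str | None = None) -> dict:
    """Run every generator; optionally write the full file bundle."""
    roster, pairs = simulate_cohort(config)
    trees, truth = simulate_strain_trees(roster, config)
    abundance, effects = simulate_abundance_table(roster, config)
    truth.true_group_effects = effects
    gps = simulate_gps_tracks(roster, config)
    mash, bin_labels = simulate_mash_matrix(seed=config.seed)
    truth.true_bin_labels = bin_labels
    bundle = {
        "roster": roster,
        "pairs": pairs,
        "trees": trees,
        "abundance": abundance,
        "gps": gps,
        "mash": mash,
        "ground_truth": truth,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_metadata(roster, outdir / "metadata.tsv")
        write_trees(trees, outdir / "trees")
        write_abundance(abundance, outdir / "abundance.tsv")
        write_gps(gps, outdir / "gps.csv")
        write_mash(mash, outdir / "mash.tsv")
        (outdir / "ground_truth.json").write_text(truth.to_json())
    return bundle
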