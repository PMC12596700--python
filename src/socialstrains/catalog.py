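"""Genome cataloging: quality classes, SGB/GGB/FGB binning, taxonomy, coreness.

Metagenome-assembled genomes (MAGs) are screened on CheckM-style completeness
and contamination, assigned to existing species/genus/family-level genome bins
(SGB/GGB/FGB) by genetic distance to bin representatives, or clustered de novo
with average linkage on all-versus-all MASH distances cut at 5% / 15% / 30%.
Taxonomy follows a majority rule over reference genomes with a fallback
cascade (species -> genus -> family -> phylum of nearest references), and
uncharacterized bins (uSGBs) are retained by host provenance and quality.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "GenomeRecord",
    "classify_quality",
    "quality_score",
    "assign_to_existing",
    "GenomeBinClusterer",
    "cluster_unassigned",
    "assign_taxonomy",
    "retain_usgbs",
    "select_representative",
    "compute_coreness",
    "read_mash",
    "read_quality",
    "build_catalog",
]

DEFAULT_CUTOFFS = (0.05, 0.15, 0.30)  # SGB, GGB, FGB genetic-distance cutoffs

_RANKS = ("k", "p", "c", "o", "f", "g", "s")


@dataclass(frozen=True)
class GenomeRecord:
    genome_id: str
    completeness: float  # percent, 0-100
    contamination: float  # percent, >= 0
    host_label: str = "unknown"
    is_reference: bool = False
    reference_taxonomy: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError(f"{self.genome_id}: completeness must be in [0, 100]")
        if self.contamination < 0.0:
            raise ValueError(f"{self.genome_id}: contamination must be >= 0")
        if self.is_reference and not self.reference_taxonomy:
            raise ValueError(f"{self.genome_id}: reference genome needs a taxonomy")


def classify_quality(genome: GenomeRecord) -> str:
    """'HQ' (completeness >=90, contamination <=5), 'MQ' (>=50, <=5), else 'fail'."""
    if genome.contamination <= 5.0:
        if genome.completeness >= 90.0:
            return "HQ"
        if genome.completeness >= 50.0:
            return "MQ"
    return "fail"


def quality_score(genome: GenomeRecord) -> float:
    """CheckM-style quality value: completeness - 3 x contamination."""
    return genome.completeness - 3.0 * genome.contamination


def assign_to_existing(
    genome_id: str,
    sgb_distances: dict[str, float],
    ggb_distances: dict[str, float],
    fgb_distances: dict[str, float],
    cutoffs: tuple[float, float, float] = DEFAULT_CUTOFFS,
) -> dict | None:
    """Assign one genome to the existing catalog by the nearest-representative cascade.

    Nearest SGB representative within the SGB cutoff wins; otherwise a new SGB
    inside the nearest GGB within the GGB cutoff; otherwise a new GGB inside
    the nearest FGB within the FGB cutoff; otherwise ``None`` (de novo
    clustering). Cutoff comparisons are inclusive.
    """
    for dists in (sgb_distances, ggb_distances, fgb_distances):
        for bin_id, d in dists.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"{genome_id}: distance to {bin_id} outside [0, 1]")

    def nearest(dists: dict[str, float]) -> tuple[str, float] | None:
        if not dists:
            return None
        # min distance; lexicographically smallest id on ties
        return min(dists.items(), key=lambda kv: (kv[1], kv[0]))

    hit = nearest(sgb_distances)
    if hit and hit[1] <= cutoffs[0]:
        return {"genome_id": genome_id, "novelty": "known-SGB", "sgb": hit[0]}
    hit = nearest(ggb_distances)
    if hit and hit[1] <= cutoffs[1]:
        return {"genome_id": genome_id, "novelty": "new-SGB-known-GGB", "ggb": hit[0]}
    hit = nearest(fgb_distances)
    if hit and hit[1] <= cutoffs[2]:
        return {"genome_id": genome_id, "novelty": "new-GGB-known-FGB", "fgb": hit[0]}
    return None


class GenomeBinClusterer(ClusterMixin, BaseEstimator):
    """Average-linkage clustering of genomes into nested SGB/GGB/FGB bins.

    scikit-learn style clusterer over a precomputed square distance matrix.
    The average-linkage dendrogram is cut at the three genetic-distance
    cutoffs; cuts at increasing heights are nested by construction, so the
    SGB partition refines the GGB partition, which refines the FGB partition.

    Parameters
    ----------
    cutoffs : (float, float, float)
        Dendrogram cut heights for the species, genus, and family level
        (inclusive: a pair exactly at a cutoff co-clusters).

    Attributes
    ----------
    labels_ : ndarray
        SGB labels (0-based, order of first appearance).
    ggb_labels_, fgb_labels_ : ndarray
        Genus- and family-level labels.
    """

    def __init__(self, cutoffs: tuple[float, float, float] = DEFAULT_CUTOFFS):
        self.cutoffs = cutoffs

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != X.shape[1]:
            raise ValueError("X must be a square distance matrix")
        if not np.allclose(X, X.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        c = tuple(self.cutoffs)
        if not (0 < c[0] < c[1] < c[2]):
            raise ValueError("cutoffs must be strictly increasing and positive")
        n = X.shape[0]
        if n == 1:
            self.labels_ = np.array([0])
            self.ggb_labels_ = np.array([0])
            self.fgb_labels_ = np.array([0])
            return self
        Z = linkage(squareform(X, checks=False), method="average")
        labels = []
        for cutoff in c:
            flat = fcluster(Z, t=cutoff, criterion="distance")
            labels.append(_canonical(flat))
        self.labels_, self.ggb_labels_, self.fgb_labels_ = labels
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def _canonical(flat: np.ndarray) -> np.ndarray:
    """Relabel clusters by order of first appearance (input-order stable)."""
    mapping: dict[int, int] = {}
    out = np.empty(len(flat), dtype=int)
    for i, lab in enumerate(flat):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def cluster_unassigned(
    mash: pd.DataFrame, cutoffs: tuple[float, float, float] = DEFAULT_CUTOFFS
) -> pd.DataFrame:
    """De novo SGB/GGB/FGB assignment for genomes absent from the catalog.

    ``mash`` is a square genome-by-genome distance DataFrame. Returns one row
    per genome with integer sgb/ggb/fgb labels satisfying the nesting
    invariant.
    """
    if list(mash.index) != list(mash.columns):
        raise ValueError("mash matrix index and columns must match")
    est = GenomeBinClusterer(cutoffs=cutoffs).fit(mash.to_numpy())
    return pd.DataFrame(
        {
            "genome_id": list(mash.index),
            "sgb": est.labels_,
            "ggb": est.ggb_labels_,
            "fgb": est.fgb_labels_,
        }
    )


def _majority(labels: list[str]) -> tuple[str, bool]:
    """Majority label; ties broken lexicographically and flagged."""
    counts = pd.Series(labels).value_counts()
    top = counts.max()
    winners = sorted(counts[counts == top].index)
    return winners[0], len(winners) > 1


def _rank_value(taxonomy: str, rank: str) -> str | None:
    for part in taxonomy.split("|"):
        if part.startswith(f"{rank}__") and len(part) > 3:
            return part[3:]
    return None


def _prefixed(upto_rank: str, values: dict[str, str]) -> str:
    parts = []
    for r in _RANKS:
        parts.append(f"{r}__{values.get(r, '')}")
        if r == upto_rank:
            break
    # pad remaining ranks blank
    idx = _RANKS.index(upto_rank)
    for r in _RANKS[idx + 1 :]:
        parts.append(f"{r}__")
    return "|".join(parts)


def assign_taxonomy(
    sgb_reference_taxa: list[str],
    ggb_reference_taxa: list[str],
    fgb_reference_taxa: list[str],
    nearest_reference_taxa: list[str] | None = None,
) -> dict:
    """Majority-rule taxonomy with the kSGB/uSGB fallback cascade.

    References inside the SGB give a species-level call (kSGB); otherwise
    references in the parent GGB give genus, in the parent FGB family, and
    failing all that, the phylum majority over up to 100 nearest reference
    genomes. Returns ``{'taxonomy', 'level', 'tie'}``.
    """

    def call(taxa: list[str], rank: str) -> dict | None:
        values = [v for v in (_rank_value(t, rank) for t in taxa) if v]
        if not values:
            return None
        winner, tie = _majority(values)
        # carry the winner's higher ranks from the first taxon that matches
        ranks = {}
        for t in taxa:
            if _rank_value(t, rank) == winner:
                ranks = {r: (_rank_value(t, r) or "") for r in _RANKS}
                break
        ranks[rank] = winner
        return {"taxonomy": _prefixed(rank, ranks), "level": rank, "tie": tie}

    for taxa, rank in ((sgb_reference_taxa, "s"), (ggb_reference_taxa, "g"), (fgb_reference_taxa, "f")):
        result = call(taxa, rank)
        if result:
            return result
    nearest = (nearest_reference_taxa or [])[:100]
    result = call(nearest, "p")
    if result:
        return result
    return {"taxonomy": "unclassified", "level": None, "tie": False}


def retain_usgbs(
    usgb_members: dict[int, list[GenomeRecord]], target_host: str = "I. indri"
) -> set[int]:
    """uSGBs kept iff any member comes from the target host, or the bin has
    at least 1 HQ member or at least 3 members."""
    kept = set()
    for sgb, members in usgb_members.items():
        if any(m.host_label == target_host for m in members):
            kept.add(sgb)
        elif any(classify_quality(m) == "HQ" for m in members):
            kept.add(sgb)
        elif len(members) >= 3:
            kept.add(sgb)
    return kept


def select_representative(members: list[GenomeRecord]) -> str:
    """Genome with the highest quality score; lexicographic id on ties."""
    if not members:
        raise ValueError("empty cluster")
    return min(members, key=lambda m: (-quality_score(m), m.genome_id)).genome_id


def compute_coreness(
    presence: pd.DataFrame, quality_scores: pd.Series, top_n: int = 2000
) -> pd.Series:
    """Per-gene-family coreness: prevalence within the top-quality genomes.

    ``presence`` is a gene-family x genome boolean matrix; prevalence is
    computed over the ``min(top_n, n_genomes)`` genomes with the highest
    quality score (ties broken by genome id for determinism).
    """
    missing = [g for g in presence.columns if g not in quality_scores.index]
    if missing:
        raise ValueError(f"quality scores missing for genomes: {missing[:5]}")
    order = sorted(presence.columns, key=lambda g: (-quality_scores[g], g))
    top = order[: min(top_n, len(order))]
    return presence[top].astype(bool).mean(axis=1)


# ---------------------------------------------------------------------------
# file interfaces


def read_mash(path: Path | str) -> pd.DataFrame:
    """Read a mash-dist 5-column table or a square-matrix TSV into a square DataFrame."""
    path = Path(path)
    first = path.read_text().splitlines()[0]
    if len(first.split("\t")) == 5 and not first.startswith("genome_id"):
        long = pd.read_csv(
            path, sep="\t", header=None, names=["ref", "query", "distance", "pvalue", "hashes"]
        )
        mat = long.pivot(index="ref", columns="query", values="distance")
        mat = mat.loc[sorted(mat.index), sorted(mat.index)]
    else:
        mat = pd.read_csv(path, sep="\t", index_col=0)
    if list(mat.index) != list(mat.columns):
        raise ValueError("mash matrix is not square over the same genome ids")
    arr = mat.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=1e-9):
        raise ValueError("mash matrix is not symmetric")
    return mat


def read_quality(path: Path | str) -> list[GenomeRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples():
        records.append(
            GenomeRecord(
                genome_id=str(row.genome_id),
                completeness=float(row.completeness),
                contamination=float(row.contamination),
                host_label=str(getattr(row, "host", "unknown")),
                is_reference=bool(getattr(row, "is_reference", False)),
                reference_taxonomy=(
                    str(row.taxonomy)
                    if getattr(row, "taxonomy", None) and pd.notna(getattr(row, "taxonomy"))
                    else None
                ),
            )
        )
    return records


def build_catalog(
    genomes: list[GenomeRecord],
    mash: pd.DataFrame,
    target_host: str = "I. indri",
    cutoffs: tuple[float, float, float] = DEFAULT_CUTOFFS,
) -> pd.DataFrame:
    """Full de novo cataloging of quality-passing genomes.

    Quality-fail genomes are excluded; the rest are clustered into nested
    bins, uSGB retention is applied (all bins are uSGBs here since no
    reference catalog is supplied), and each retained SGB gets a
    representative. Returns the assignment table.
    """
    by_id = {g.genome_id: g for g in genomes}
    passing = [g.genome_id for g in genomes if classify_quality(g) != "fail"]
    if not passing:
        return pd.DataFrame(
            columns=["genome_id", "sgb", "ggb", "fgb", "quality_class", "quality_score", "retained", "representative"]
        )
    sub = mash.loc[passing, passing]
    assign = cluster_unassigned(sub, cutoffs=cutoffs)
    assign["quality_class"] = [classify_quality(by_id[g]) for g in assign["genome_id"]]
    assign["quality_score"] = [quality_score(by_id[g]) for g in assign["genome_id"]]
    members = {
        sgb: [by_id[g] for g in grp["genome_id"]] for sgb, grp in assign.groupby("sgb")
    }
    kept = retain_usgbs(members, target_host=target_host)
    reps = {sgb: select_representative(m) for sgb, m in members.items()}
    assign["retained"] = assign["sgb"].isin(kept)
    assign["representative"] = [reps[s] == g for s, g in zip(assign["sgb"], assign["genome_id"])]
    return assign
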