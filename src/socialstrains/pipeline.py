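"""End-to-end run: simulate/load -> catalog -> strains -> network -> spatial -> diversity.

A single RunConfig carries every threshold of the analysis (strain-identity
percentile, species inclusion minima, retention filters, bin cutoffs, quality
rules, abundance filter, permutation count, master seed) and is echoed
verbatim into the JSON summary for provenance. Identical config + seed yields
a byte-identical summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import catalog, community, geospatial, socialnet, strainshare, synthdata

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run."""

    # inputs; None means "generate synthetically with `simulation`"
    metadata: str | None = None
    trees: str | None = None
    abundance: str | None = None
    gps: str | None = None
    mash: str | None = None
    quality: str | None = None
    # thresholds
    percentile: float = 5.0
    min_samples: int = 5
    min_primary: int = 2
    min_shared_sgbs: int = 5
    min_potential: int = 5
    sgb_cutoff: float = 0.05
    ggb_cutoff: float = 0.15
    fgb_cutoff: float = 0.30
    min_completeness_mq: float = 50.0
    min_completeness_hq: float = 90.0
    max_contamination: float = 5.0
    min_mean_abundance: float = 0.001
    min_reads: int = 1_000_000
    permutations: int = 999
    utm_zone: int = 39
    seed: int = 0
    target_host: str = "I. indri"
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _round(x, nd=6):
    if isinstance(x, float):
        return round(x, nd)
    return x


def run_pipeline(config: RunConfig, outdir: Path | str) -> dict:
    """Execute every analysis stage and write the consolidated report bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    # ----- inputs (files, or the synthetic bundle when paths are absent)
    if config.metadata is None:
        sim = synthdata.SimulationConfig(seed=config.seed, **config.simulation)
        bundle = synthdata.simulate_all(sim, outdir / "inputs")
        roster = bundle["roster"]
        trees = bundle["trees"]
        abundance = bundle["abundance"]
        gps = bundle["gps"]
        mash = bundle["mash"]
        quality = None
        log.append(f"simulated cohort: {len(roster)} individuals in {sim.n_groups} groups")
    else:
        roster = strainshare.read_metadata(config.metadata)
        trees = strainshare.read_trees(config.trees) if config.trees else {}
        abundance = community.read_abundance(config.abundance) if config.abundance else None
        gps = geospatial.read_gps(config.gps) if config.gps else None
        mash = catalog.read_mash(config.mash) if config.mash else None
        quality = catalog.read_quality(config.quality) if config.quality else None

    # read-count sample filter (strict >)
    if "n_reads" in roster.columns:
        before = len(roster)
        roster = roster[roster["n_reads"] > config.min_reads].reset_index(drop=True)
        log.append(f"read-count filter (> {config.min_reads}): {before} -> {len(roster)} samples")

    summary: dict = {"config": asdict(config), "log": log}

    # ----- genome catalog
    if mash is not None:
        cutoffs = (config.sgb_cutoff, config.ggb_cutoff, config.fgb_cutoff)
        if quality is not None:
            assignments = catalog.build_catalog(
                quality, mash, target_host=config.target_host, cutoffs=cutoffs
            )
        else:
            assignments = catalog.cluster_unassigned(mash, cutoffs=cutoffs)
        assignments.to_csv(outdir / "catalog_assignments.tsv", sep="\t", index=False)
        summary["catalog"] = {
            "n_genomes": int(len(assignments)),
            "n_sgb": int(assignments["sgb"].nunique()),
            "n_ggb": int(assignments["ggb"].nunique()),
            "n_fgb": int(assignments["fgb"].nunique()),
        }
        log.append(f"catalog: {len(assignments)} genomes -> {assignments['sgb'].nunique()} SGBs")

    # ----- strain sharing
    keep_samples = set(roster["sample_id"])
    trees = {
        sp: t
        for sp, t in trees.items()
        if all(lf.taxon.label in keep_samples for lf in t.leaf_node_iter())
    }
    strains = strainshare.analyze(
        trees,
        roster,
        percentile=config.percentile,
        min_samples=config.min_samples,
        min_primary=config.min_primary,
        min_shared=config.min_shared_sgbs,
        min_potential=config.min_potential,
    )
    rates = strains["rates"]
    trans = strains["transmissibility"]
    strains["thresholds"].to_csv(outdir / "strain_thresholds.tsv", sep="\t", index=False)
    rates.to_csv(outdir / "sharing_rates.tsv", sep="\t", index=False)
    trans.to_csv(outdir / "transmissibility.tsv", sep="\t", index=False)
    log.append(
        f"strain inclusion: {len(trees)} trees -> {len(strains['retained_species'])} species retained"
    )
    kept_rates = rates[rates["retained"] & rates["rate"].notna()]
    summary["sharing"] = {
        "n_species_retained": len(strains["retained_species"]),
        "n_pairs_retained": int(len(kept_rates)),
        "median_rate_by_category": {
            cat: _round(float(grp["rate"].median()))
            for cat, grp in kept_rates.groupby("category")
        },
        "median_rate_same_group": _round(
            float(kept_rates.loc[kept_rates["same_group"], "rate"].median())
        )
        if kept_rates["same_group"].any()
        else None,
        "median_rate_different_group": _round(
            float(kept_rates.loc[~kept_rates["same_group"], "rate"].median())
        )
        if (~kept_rates["same_group"]).any()
        else None,
    }
    kept_trans = trans[trans["retained"] & trans["value"].notna()]
    summary["transmissibility"] = {
        "n_species": int(len(kept_trans)),
        "median": _round(float(kept_trans["value"].median())) if len(kept_trans) else None,
        "min": _round(float(kept_trans["value"].min())) if len(kept_trans) else None,
        "max": _round(float(kept_trans["value"].max())) if len(kept_trans) else None,
    }

    # ----- network
    net = socialnet.build_network(rates, roster)
    cents = socialnet.centralities(net)
    cents.to_csv(outdir / "centralities.tsv", sep="\t", index=False)
    nx.write_graphml(net, outdir / "network.graphml")
    pd.DataFrame(
        [
            {"a": a, "b": b, "n_shared_strains": d["weight"]}
            for a, b, d in net.edges(data=True)
        ]
    ).to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
    summary["network"] = {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "n_components": nx.number_connected_components(net),
    }

    # ----- spatial
    if gps is not None:
        pts = geospatial.project_to_utm(gps, zone=config.utm_zone, south=True)
        terr = geospatial.territories_from_points(pts)
        terr_df = pd.DataFrame(
            [
                {
                    "group_id": t.group_id,
                    "area_ha": t.area_ha,
                    "centroid_e": t.centroid[0],
                    "centroid_n": t.centroid[1],
                    "degenerate": t.degenerate,
                }
                for t in terr.values()
            ]
        ).sort_values("group_id")
        terr_df.to_csv(outdir / "territories.tsv", sep="\t", index=False)
        geospatial.centroid_distances(terr).to_csv(outdir / "centroid_distances.tsv", sep="\t")
        sampled_groups = set(roster["social_group"])
        if sampled_groups <= set(terr):
            geo = geospatial.sharing_vs_distance(rates, terr, roster)
        else:
            geo = {"rho": None, "p": None, "degenerate": True, "n_pairs": 0}
        summary["spatial"] = {
            "territories": {
                row.group_id: {"area_ha": _round(row.area_ha)} for row in terr_df.itertuples()
            },
            "sharing_vs_distance_rho": _round(geo["rho"]) if geo["rho"] is not None else None,
            "sharing_vs_distance_p": _round(geo["p"], 8) if geo["p"] is not None else None,
        }

    # ----- diversity
    if abundance is not None:
        filtered = community.filter_species(abundance, min_mean=config.min_mean_abundance)
        log.append(
            f"abundance filter (mean >= {config.min_mean_abundance}): "
            f"{abundance.shape[1]} -> {filtered.shape[1]} species"
        )
        clr = community.clr_transform(filtered)
        alpha = community.alpha_metrics(filtered)
        alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
        dist = community.aitchison_distance(clr)
        dist.to_csv(outdir / "aitchison_distance.tsv", sep="\t")
        ord_res = community.pcoa(dist, n_axes=2)
        ord_res["coordinates"].to_csv(outdir / "pcoa_coordinates.tsv", sep="\t")
        labels = roster.set_index("sample_id").loc[list(dist.index), "social_group"]
        perm = community.permanova(
            dist, labels.to_numpy(), n_perm=config.permutations, seed=config.seed
        )
        core = community.prevalence_core_summary(filtered)
        summary["diversity"] = {
            "permanova_social_group": {key: _round(val) for key, val in perm.items()},
            "core_classes": core["classes"],
            "core_fractions": {key: _round(val) for key, val in core["fractions"].items()},
            "alpha_median_observed": _round(float(alpha["observed"].median())),
            "alpha_median_simpson": _round(float(alpha["simpson"].median())),
        }

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
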