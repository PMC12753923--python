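"""End-to-end pipeline: diversity -> networks -> nulls -> inoculant tracking.

One flat config drives the whole four-treatment analysis so a run is fully
reproducible from a single file and seed.  Every stage logs the counts that
matter (OTUs retained, pairs tested, edges kept, boundary ties excluded) and
the consolidated JSON report records the exact thresholds used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diversity as div
from . import network as net
from . import null_models as nulls
from . import inoculant_tracking as track
from .data_model import (
    OtuTable,
    PgpbDatabase,
    SampleMetadata,
    TaxonomyTable,
    load_packaged_pgpb_database,
    read_fasta,
    read_genus_list,
    read_metadata,
    read_otu_table,
    read_taxonomy,
    to_relative_abundance,
)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs and tunables of one pipeline run.

    Thresholds default to the analysis conventions this package targets:
    mean relative abundance > 0.05% for the network filter, |rho| > 0.6 and
    BH-adjusted q < 0.05 for edges, 10,000 G(n,m) null replicates, 99.5%
    16S identity for inoculant matching, 999 ANOSIM permutations.  The seed
    is mandatory; nothing is seeded from the wall clock.
    """

    counts: str
    metadata: str
    taxonomy: str
    out_dir: str
    seed: int
    sequences: str | None = None
    inoculant_refs: str | None = None
    pgpb_list: str | None = None
    treatments: tuple[str, ...] = ("S6-1", "UW4", "NC", "CK")
    orientation: str = "samples_as_rows"
    abundance_threshold: float = 0.0005
    rho_threshold: float = 0.6
    q_threshold: float = 0.05
    null_replicates: int = 10_000
    identity_threshold: float = 99.5
    anosim_permutations: int = 999
    rarefy_to: int | None = None
    louvain_restarts: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.abundance_threshold < 1:
            raise ValueError("abundance_threshold must be in [0, 1)")
        if not 0 < self.rho_threshold < 1:
            raise ValueError("rho_threshold must be in (0, 1)")
        if not 0 < self.q_threshold <= 1:
            raise ValueError("q_threshold must be in (0, 1]")
        if not 0 < self.identity_threshold <= 100:
            raise ValueError("identity_threshold must be in (0, 100]")
        if self.null_replicates < 1 or self.anosim_permutations < 1:
            raise ValueError("replicate/permutation counts must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "treatments" in raw:
            raw["treatments"] = tuple(raw["treatments"])
        return cls(**raw)


def _json_default(obj):
    import numpy as np
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, frozenset):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _metrics_dict(metrics: net.NetworkMetrics) -> dict:
    d = dataclasses.asdict(metrics)
    d["partition"] = [sorted(p) for p in metrics.partition]
    return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write the report bundle under ``config.out_dir``.

    Returns the machine-readable summary that is also written to
    ``summary.json``.  Identical configs produce byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage: load inputs")
    try:
        table = read_otu_table(config.counts, orientation=config.orientation)
        metadata = read_metadata(config.metadata)
        taxonomy = read_taxonomy(config.taxonomy)
        metadata.validate_against(table)
        taxonomy.validate_against(table)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'load inputs' failed: {exc}") from exc
    pgpb: PgpbDatabase = (read_genus_list(config.pgpb_list)
                          if config.pgpb_list else load_packaged_pgpb_database())

    summary: dict = {"config": dataclasses.asdict(config), "stages": {}}

    # --- diversity -------------------------------------------------------
    logger.info("stage: diversity")
    alpha = div.alpha_diversity(table, rarefy_to=config.rarefy_to, seed=config.seed)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", index_label="sample_id")
    rel = to_relative_abundance(table)
    distances = div.bray_curtis(rel)
    distances.to_csv(out / "distances.tsv", sep="\t", index_label="sample_id")
    ordination = div.pcoa(distances)
    ordination.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t",
                                  index_label="sample_id")
    (out / "dendrogram.nwk").write_text(div.upgma_dendrogram(distances) + "\n")

    meta_df = metadata.to_dataframe().loc[list(table.sample_ids)]
    anosim_results = {}
    for name, grouping in (("compartment", meta_df["compartment"]),
                           ("treatment", meta_df["treatment"])):
        if grouping.value_counts().min() >= 2 and grouping.nunique() >= 2:
            res = div.anosim(distances, grouping,
                             n_permutations=config.anosim_permutations,
                             seed=config.seed, grouping_name=name)
            anosim_results[name] = {"R": res.r, "p": res.p_value,
                                    "n_permutations": res.n_permutations}
    pd.DataFrame(anosim_results).T.to_csv(out / "anosim.tsv", sep="\t",
                                          index_label="grouping")

    group_stats = {}
    for metric in ("shannon", "simpson_gini", "chao1"):
        res = div.group_tests(alpha[metric], metadata)
        group_stats[metric] = {
            "anova": res.anova.to_dict(orient="records"),
            "duncan": res.duncan.to_dict(orient="records"),
            "ttests": res.ttests.to_dict(orient="records"),
        }
    summary["stages"]["diversity"] = {
        "explained_variance": list(ordination.explained[:4]),
        "anosim": anosim_results,
        "group_tests": group_stats,
    }

    # --- networks and nulls ---------------------------------------------
    networks: dict[str, net.CooccurrenceNetwork] = {}
    summary["stages"]["networks"] = {}
    for treatment in config.treatments:
        logger.info("stage: network for treatment %s", treatment)
        try:
            network = net.build_treatment_network(
                table, taxonomy, metadata, treatment,
                abundance_threshold=config.abundance_threshold,
                rho_threshold=config.rho_threshold,
                q_threshold=config.q_threshold)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage 'network' failed for treatment "
                f"{treatment!r}: {exc}") from exc
        networks[treatment] = network
        metrics = (net.compute_metrics(network, seed=config.seed,
                                       restarts=config.louvain_restarts)
                   if network.n_nodes > 0 else None)
        tdir = out / f"network_{treatment}"
        tdir.mkdir(exist_ok=True)
        edges = pd.DataFrame(
            [{"otu_a": a, "otu_b": b, "rho": d["rho"], "q": d["q"], "sign": d["sign"]}
             for a, b, d in network.graph.edges(data=True)],
            columns=["otu_a", "otu_b", "rho", "q", "sign"])
        edges.to_csv(tdir / "edges.tsv", sep="\t", index=False)
        pd.DataFrame([{"otu_id": v, **net_attrs} for v, net_attrs
                      in network.graph.nodes(data=True)],
                     columns=["otu_id", "phylum", "mean_abundance"]).to_csv(
            tdir / "nodes.tsv", sep="\t", index=False)
        net.phylum_edge_matrix(network, taxonomy).to_csv(
            tdir / "phylum_edges.tsv", sep="\t", index_label="phylum")
        net.write_graphml(network, tdir / "network.graphml")

        entry = {"metrics": _metrics_dict(metrics) if metrics is not None
                 else {"n_nodes": 0, "n_edges": 0},
                 "boundary_ties": network.boundary_ties}
        if metrics is not None and network.n_nodes >= 3 \
                and 1 <= network.n_edges <= network.n_nodes * (network.n_nodes - 1) // 2:
            logger.info("stage: null ensemble for %s (%d replicates)",
                        treatment, config.null_replicates)
            ensemble = nulls.er_ensemble(
                metrics.n_nodes, metrics.n_edges,
                replicates=config.null_replicates, seed=config.seed,
                restarts=config.louvain_restarts)
            verdict = nulls.small_world_assessment(metrics, ensemble)
            entry["null_ensemble"] = {"mean": ensemble.mean, "sd": ensemble.sd,
                                      "ensemble_size": ensemble.ensemble_size}
            entry["small_world"] = dataclasses.asdict(verdict)
        with open(tdir / "metrics.json", "w") as fh:
            json.dump(entry, fh, indent=2, default=_json_default, sort_keys=True)
        summary["stages"]["networks"][treatment] = entry

    # --- inoculant tracking ---------------------------------------------
    if config.inoculant_refs and config.sequences:
        logger.info("stage: inoculant tracking")
        refs = read_fasta(config.inoculant_refs)
        reps = read_fasta(config.sequences)
        tracking = {}
        for name, ref_seq in refs.items():
            match = track.match_inoculant(name, ref_seq, reps,
                                          threshold=config.identity_threshold)
            abundance, _tests = track.track_abundance(match.otu_id, table, metadata)
            egos = {}
            for treatment, network in networks.items():
                ego = track.ego_summary(network, match.otu_id, taxonomy, pgpb)
                egos[treatment] = {
                    "degree": ego.degree,
                    "positive_count": ego.positive_count,
                    "negative_count": ego.negative_count,
                    "phylum_counts": ego.phylum_counts,
                    "phylum_percentages": ego.phylum_percentages(),
                    "n_pgpb_partners": ego.n_pgpb_partners,
                    "pgpb_partners": [p.otu_id for p in ego.partners if p.is_pgpb],
                }
            tracking[name] = {
                "match": dataclasses.asdict(match),
                "abundance": abundance.to_dict(orient="records"),
                "ego": egos,
            }
        summary["stages"]["tracking"] = tracking

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default, sort_keys=True)
    _write_report(summary, out / "report.md")
    logger.info("pipeline complete: %s", out)
    return summary


def _write_report(summary: dict, path: Path) -> None:
    lines = ["# Pipeline report", ""]
    cfg = summary["config"]
    lines += ["## Parameters", ""]
    for key in ("abundance_threshold", "rho_threshold", "q_threshold",
                "null_replicates", "identity_threshold", "anosim_permutations",
                "seed"):
        lines.append(f"- {key}: {cfg[key]}")
    lines += ["", "## Networks", ""]
    for treatment, entry in summary["stages"].get("networks", {}).items():
        m = entry["metrics"]
        if m.get("n_nodes", 0) == 0:
            lines.append(f"- {treatment}: no edges passed the thresholds")
            continue
        lines.append(
            f"- {treatment}: {m['n_nodes']} nodes, {m['n_edges']} edges, "
            f"avg degree {m['average_degree']:.2f}, density {m['density']:.4f}, "
            f"C {m['clustering']:.3f}, L {m['path_length']:.3f}, "
            f"Q {m['modularity']:.3f}")
        if "small_world" in entry:
            verdict = entry["small_world"]
            lines.append(f"    - small-world-like: "
                         f"{'yes' if verdict['small_world'] else 'no'}; "
                         f"modular (Q > 0.4): {'yes' if verdict['modular'] else 'no'}")
    if "tracking" in summary["stages"]:
        lines += ["", "## Inoculant tracking", ""]
        for name, entry in summary["stages"]["tracking"].items():
            match = entry["match"]
            lines.append(f"- {name}: best hit {match['otu_id']} at "
                         f"{match['percent_identity']:.2f}% identity "
                         f"(pass: {match['passed']})")
            for treatment, ego in entry["ego"].items():
                lines.append(f"    - {treatment}: degree {ego['degree']}, "
                             f"{ego['n_pgpb_partners']} PGPB partners")
    path.write_text("\n".join(lines) + "\n")
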