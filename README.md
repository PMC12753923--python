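# inocunet

Analysis pipeline for studying how bacterial inoculants reshape an
indigenous soil bacterial community, built around 16S rRNA amplicon OTU
count tables from inoculation experiments (four treatments — two plant
growth-promoting strains, one non-PGPB strain, one uninoculated control —
sampled in bulk and rhizosphere soil).

It is aimed at microbial ecologists who want the full chain from counts to
conclusions as tested, scriptable code:

- **Diversity** — Shannon (nats), both Simpson variants, bias-corrected
  Chao1, Good's coverage, seeded rarefaction; Bray–Curtis dissimilarity,
  PCoA, UPGMA dendrograms, ANOSIM; one-way ANOVA with Duncan's
  multiple-range letters and Welch t-tests for treatment/compartment
  comparisons.
- **Co-occurrence networks** — per treatment: keep OTUs with mean relative
  abundance > 0.05%, compute all pairwise Spearman rank correlations,
  adjust p-values with the Benjamini–Hochberg step-up, and keep edges with
  |ρ| > 0.6 and q < 0.05 (both strict). Topology: average degree, density,
  clustering coefficient C, average path length L (connected pairs only),
  modularity Q by seeded Leiden-family maximization, signed-edge fractions
  and a phylum × phylum edge matrix; GraphML export.
- **Null models** — G(n, m) Erdős–Rényi ensembles of equal size (default
  10,000 replicates) with identical metric computation; a network is called
  small-world-like when Q, C and L all exceed the ensemble means, and
  modular when Q > 0.4.
- **Inoculant tracking** — end-gap-free global alignment of each
  inoculant's 16S reference against the OTU representative sequences
  (≥ 99.5% identity to call colonization), abundance tracking across
  treatments, and ego-network summaries with partners flagged against a
  PGPB genus database.
- **Synthetic communities** — a Gaussian-copula generator (latent
  multivariate normal → log-normal marginals → multinomial counts) that
  plants rank-correlation blocks, a spiked inoculant OTU with signed
  partners, and a known ground-truth edge set, so the whole cascade is
  testable without sequencing data.

## Worked example

```python
from inocunet import (SyntheticSpec, CorrelationBlock, InoculantSpike,
                      generate_community, to_relative_abundance,
                      filter_abundant_otus, spearman_all_pairs, build_network,
                      compute_metrics, er_ensemble, small_world_assessment,
                      match_inoculant, ego_summary, load_packaged_pgpb_database)

spec = SyntheticSpec(
    seed=7,
    correlation_blocks=(CorrelationBlock(members=tuple(range(8)), r=0.85),),
    inoculant_spike=InoculantSpike(
        focal=20, target_treatments=("S6-1", "UW4", "NC", "CK"),
        positive_partners=(21, 22, 23), negative_partners=(24,), partner_r=0.9),
)
community = generate_community(spec)

rel = to_relative_abundance(community.table)
kept = filter_abundant_otus(rel)                      # mean abundance > 0.05%
corr = spearman_all_pairs(rel, otu_ids=kept)          # all pairs + BH q-values
net = build_network(corr, community.taxonomy)         # |rho| > 0.6, q < 0.05
metrics = compute_metrics(net, seed=7, restarts=3)
print(f"network: {metrics.n_nodes} nodes, {metrics.n_edges} edges, "
      f"Q = {metrics.modularity:.3f}")

ens = er_ensemble(metrics.n_nodes, metrics.n_edges, replicates=1000, seed=7,
                  restarts=3)
verdict = small_world_assessment(metrics, ens)
print(f"modular (Q > 0.4): {verdict.modular}")

match = match_inoculant("S6-1", community.reference_sequences["inoculant"],
                        community.sequences)
print(f"inoculant best hit: {match.otu_id} at {match.percent_identity:.2f}%")
ego = ego_summary(net, match.otu_id, community.taxonomy,
                  load_packaged_pgpb_database())
print(f"ego degree: {ego.degree} ({ego.positive_count}+/{ego.negative_count}-)")
```

prints

```
network: 19 nodes, 39 edges, Q = 0.440
modular (Q > 0.4): True
inoculant best hit: OTU21 at 99.56%
ego degree: 4 (3+/1-)
```

The 19-node network recovers the planted 8-OTU correlation block and the
inoculant's neighborhood; the focal OTU's representative sequence carries 2
substitutions over the 450-nt amplicon (99.56% identity, a colonization
call), and its ego network finds exactly the planted 3 positive and 1
negative partners.

## Command line

Every stage is also a subcommand of the `inocunet` CLI
(`simulate`, `diversity`, `network`, `nulls`, `track`), and
`inocunet run --config config.yaml` drives the whole four-treatment
pipeline from one YAML file, writing TSV/JSON/GraphML/newick outputs plus a
consolidated `summary.json` and `report.md`. Runs are byte-reproducible
for a fixed config and seed.

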