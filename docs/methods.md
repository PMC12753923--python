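# Methods

This note records the statistical conventions, the synthetic-community
model, the numerical choices, and the limitations of the package. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Diversity statistics

Alpha diversity is computed per sample from raw (or seeded-rarefied)
counts:

- Shannon H' = −Σ pᵢ ln pᵢ over non-zero proportions, in nats (the mothur
  convention).
- Simpson is reported in both directions — dominance D = Σ pᵢ² and
  Gini–Simpson 1 − D — because "Simpson diversity" is used for either in
  the literature; outputs label both explicitly.
- Chao1 uses the bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)), which is
  finite when no doubletons exist; with no singletons it equals observed
  richness.
- Good's coverage = 1 − F₁/N (F₁ singletons, N reads in the sample).
- Rarefaction subsamples without replacement via a multivariate
  hypergeometric draw; curves are means over a configurable number of
  seeded replicates and the full-depth point recovers observed richness
  exactly.

Whether to rarefy before diversity/ordination is left to the caller
(`rarefy_to`); both paths are supported and the pipeline records which was
used. Bray–Curtis d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) on relative abundances; it
is a semi-metric, so the triangle inequality is not asserted anywhere.

PCoA is classical scaling: double-center −½D², eigendecompose, scale
eigenvectors by √λ. Negative eigenvalues (expected for Bray–Curtis input)
are dropped from the axes and from the explained-variance denominator; no
Lingoes/Cailliez correction is applied. Axis signs are fixed by making
each axis's largest-magnitude loading positive, so coordinates are
reproducible across runs.

UPGMA processes samples in lexicographic label order so that merge
tie-breaks are deterministic; the newick output is ultrametric (each leaf
at merge height / 2).

ANOSIM ranks all n(n−1)/2 dissimilarities once, computes
R = (r̄_between − r̄_within)/(M/2), and estimates p with the add-one
permutation estimator (default 999 seeded permutations);
`n_permutations="all"` enumerates every label permutation instead, in
which case p is the exact null fraction with R ≥ R_obs. With 6 samples in
two groups of three, the exact p can never go below 0.1 — small designs
simply cannot reach conventional significance by label permutation.

Group comparisons follow the standard two-factor reporting convention:
one-way ANOVA across treatments within each compartment, Duncan's
multiple-range letters at α = 0.05 (studentized-range critical values at
protection level 1−(1−α)^(p−1), harmonic-mean group size for unbalanced
designs), and a Welch t-test with Satterthwaite df between compartments
within each treatment. Groups with zero error variance fall back to
exact-tie letter assignment rather than NaN.

## Co-occurrence networks

The cascade per treatment pools bulk and rhizosphere samples of that
treatment, then:

1. **Abundance filter** — retain OTUs whose *mean* relative abundance over
   the samples in scope is strictly > 0.05% (a max-over-samples variant is
   available via `mode="max"`).
2. **Correlation** — Spearman ρ with midrank ties for every retained pair.
   p-values use the exact permutation distribution when n ≤ 9 samples
   (the t-approximation is unreliable there; note the granularity caveat
   above) and the t-approximation otherwise. Zero-variance OTU vectors
   make ρ undefined; such pairs are excluded from testing and recorded.
3. **FDR** — Benjamini–Hochberg step-up across all tested pairs.
4. **Threshold** — edge iff |ρ| > 0.6 AND q < 0.05, both strict; pairs
   exactly at a boundary are excluded and counted in the build log. The
   adjusted q is authoritative where a raw-p convention might be expected;
   thresholds are configurable for sensitivity analysis.

Node sets default to filtered OTUs carrying at least one edge; a config
flag adds isolated filtered OTUs.

Metrics: average degree 2m/n; density 2m/(n(n−1)); C is the mean local
clustering with degree-<2 nodes contributing 0; L averages shortest-path
lengths over connected pairs only (component count is reported alongside —
conventions differ between igraph and Gephi here, so the choice is
explicit). Q comes from seeded Leiden modularity maximization
(`leidenalg.ModularityVertexPartition`, resolution 1) with a configurable
number of restarts keeping the best partition, re-scored with the standard
partition modularity Σ(e_ii − a_i²) **on the unsigned, unweighted graph**
(edge signs never enter Q, C or L). The test suite verifies the found Q
against exhaustive partition search on graphs of ≤ 8 nodes.

## Erdős–Rényi null model

"Random networks of equal size" is implemented as G(n, m) — uniform simple
graphs with exactly the real network's node and edge counts — rather than
G(n, p), so degree and density match by construction. Metrics, including
community detection with the same algorithm and restart policy, are
computed identically for real and null graphs. The small-world verdict is
the qualitative rule: modularity, clustering and path length all strictly
greater than the ensemble means; z = (real − mean)/sd is reported per
metric as additional context (undefined, not infinite, when sd = 0), and a
separate flag marks modular structure at Q > 0.4 (strict). Default
ensemble size is 10,000; the test suite runs 300–1,000 replicates with
tolerances scaled accordingly. A single ER draw judged against its own
ensemble exceeds all three means with non-trivial probability, so checks
of the "not small-world" direction use a majority verdict over independent
draws.

## Inoculant tracking

Reference 16S sequences are aligned to every representative sequence with
an end-gap-free global alignment (match +1, mismatch −1, gap −2; terminal
gaps free), since V3–V4 amplicons and references cover the same region and
a local alignment could inflate identity on partial overlaps. Identity =
matches / aligned columns, excluding terminal-overhang columns. Unrelated
sequences can produce an optimal end-gap-free alignment whose overlap is
only a few (matching) columns; when the overlap covers less than half of
the shorter sequence, matches are counted over the shorter sequence's full
length instead, which sends unrelated pairs toward 0% while leaving
co-covering amplicons exact. The colonization threshold is 99.5% — about
two substitutions over a 450-nt amplicon; best identity wins, ties break
to the lexicographically smallest OTU id, and a best hit below threshold
is reported with `passed=False` rather than raised.

Ego networks are extracted from the treatment networks (not recomputed
subgraphs). Per-phylum percentages are rounded half-up to 2 decimals for
display; exact fractions remain available. PGPB flags are genus-membership
lookups against a case-normalized genus set. The packaged list
(`data/pgpb_genera_synthetic.txt`) is a stand-in snapshot assembled from
genera widely reported to carry plant-growth-promoting traits; any
analysis intended for publication should substitute a curated database via
the `--pgpb` option / `pgpb_list` config key.

## Synthetic communities

The generator emulates the structure the correlation cascade assumes:
abundant OTUs with monotone co-variation across samples, compositional
closure, and multinomial sampling noise.

Per sample, a latent vector z ~ N(0, Σ) is drawn; Σ is the identity plus
(a) equicorrelated blocks at the requested r and (b) an inoculant spike in
target-treatment samples, built as a rank-one factor (focal loading 1,
partner loadings ±r), which plants corr(focal, partner) = ±r and keeps Σ
positive semi-definite by construction. Σ is still explicitly
eigenvalue-checked before sampling and infeasible requests (e.g. five
equicorrelated variables at r = −0.5) error out. z is pushed through the
common log-normal marginal (mean_log 0, sd_log 1 by default) via the
Gaussian copula, closed to proportions, and sampled as multinomial counts
at the sequencing depth. Because every per-OTU step after the latent draw
is monotone, planted signs survive as rank correlations — which is exactly
what Spearman-based edge detection should recover. The focal OTU's latent
mean is shifted by ln(multiplier)/sd_log in target treatments, multiplying
its median propensity by the requested factor.

Defaults mirror the targeted study design: 4 treatments × 2 compartments
× 3 replicates (24 samples), 150 OTUs, 50,000 reads/sample. The spike's
partner correlation (`partner_r`, default 0.8) has no empirical anchor —
real effect sizes for inter-OTU correlations are unknown — so recovery
settings are chosen for testability, not fidelity.

Representative sequences are uniform random 450-nt ACGT strings except the
focal OTU, which carries 0–2 substitutions (no indels, keeping
percent-identity arithmetic exact) from a generated reference.

What the generator does **not** emulate: phylogenetic signal in sequences
or abundances, overdispersion beyond the log-normal/multinomial hierarchy,
PCR/chimera artifacts, and spatial or temporal autocorrelation between
replicates. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not performance on real
sequencing data.

Two frozen calibration properties tie the generator to the cascade:

- **Null calibration** — with no planted structure, the fraction of OTU
  pairs called as edges (q < 0.05 ∧ |ρ| > 0.6) over 50 seeds stays within
  0.05 + 3·SE; in practice BH under the global null yields a rate near
  zero, and compositional closure's weak negative background does not
  inflate it.
- **Planted-edge recovery** — one 8-OTU block at r = 0.85 (24 samples,
  depth 50,000): mean F1 against ground truth over 10 seeds ≥ 0.8, a bound
  frozen from an independent brute-force run of the same cascade.
  Per-seed F1 varies substantially (roughly 0.5–1.0), so the bound is on
  the mean, not on each seed.

## Problem sizes and reproducibility

Every stochastic routine takes an explicit integer seed; nothing seeds
from the wall clock, and identical configs reproduce byte-identical
outputs. Test and acceptance runs use scaled-down problem sizes chosen as
reasonable desk-scale settings: 20–50 generator seeds for calibration
properties, 300–1,000 null replicates (vs the 10,000 default), Leiden
restarts 2–3 in ensembles (10 for single networks), and exact ANOSIM /
modularity enumeration only where the design is small enough (≤ 6 samples,
≤ 8 nodes).

## Known limitations

- Spearman-threshold networks ignore compositionality; closure induces
  weak negative background correlation (bounded by the null-calibration
  property but not removed). SparCC/SPIEC-EASI-style compositional
  inference is deliberately out of scope.
- With 6 samples, exact-permutation Spearman p-values have granularity
  2/720 ≈ 0.0028, and BH across thousands of pairs then rarely admits any
  edge; per-treatment networks from 3 + 3 replicates are expected to be
  sparse or empty. This is surfaced, not smoothed.
- UniFrac (weighted or unweighted) and phylogenetic alpha diversity are
  unsupported: no phylogenetic tree is modeled.
- The small-world rule is the qualitative "greater than the null mean"
  comparison; no significance test is attached to the verdict.
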