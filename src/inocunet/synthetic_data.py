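"""Synthetic compositional communities with planted correlation structure.

Counts are generated through a Gaussian copula: a latent multivariate normal
vector per sample (its correlation matrix carries the planted block and
inoculant-spike structure), pushed through a common log-normal marginal to
give per-OTU propensities, closed to proportions, and sampled as multinomial
reads at a fixed sequencing depth.  Rank (Spearman) correlations of the
planted sign survive this pipeline because every step after the latent draw
is monotone per OTU, which is exactly what the downstream co-occurrence
stage tests for.

The ground-truth edge set returned with each community lists every planted
pair with its sign, enabling parameter-recovery tests of the full
filter -> correlation -> FDR -> threshold cascade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    COMPARTMENTS,
    TREATMENTS,
    Lineage,
    OtuTable,
    SampleMetadata,
    SampleInfo,
    TaxonomyTable,
    load_packaged_pgpb_database,
    write_fasta,
    write_metadata,
    write_otu_table,
    write_taxonomy,
)

__all__ = [
    "CorrelationBlock",
    "InoculantSpike",
    "SyntheticSpec",
    "SyntheticCommunity",
    "generate_community",
    "write_community",
    "DEFAULT_GROUPS",
    "PHYLA",
]

# the nine phyla that dominate heavy-metal soil 16S surveys
PHYLA = (
    "Actinobacteria", "Proteobacteria", "Chloroflexi", "Patescibacteria",
    "Acidobacteria", "Firmicutes", "Bacteroidetes", "Planctomycetes", "WPS-2",
)

_FILLER_GENERA = (
    "Dyella", "Saccharimonadales_ge", "Frankia", "Gaiella", "Singulisphaera",
    "Rhodanobacter", "Tumebacillus", "Conexibacter", "Bryobacter", "Jatrophihabitans",
)

DEFAULT_GROUPS = tuple((t, c) for t in TREATMENTS for c in COMPARTMENTS)

_ALPHABET = np.array(list("ACGT"))
_SEQ_LENGTH = 450


@dataclass(frozen=True)
class CorrelationBlock:
    """A set of OTU indices sharing a within-block latent correlation r."""

    members: tuple[int, ...]
    r: float

    def __post_init__(self) -> None:
        if not -1 < self.r < 1:
            raise ValueError(f"block correlation must satisfy |r| < 1, got {self.r}")
        if len(set(self.members)) != len(self.members) or len(self.members) < 2:
            raise ValueError("a block needs >= 2 distinct member indices")


@dataclass(frozen=True)
class InoculantSpike:
    """A focal inoculant OTU spiked into target treatments.

    The focal OTU's latent mean is shifted so its expected propensity is
    multiplied by ``multiplier`` in samples of ``target_treatments``; listed
    partners receive latent correlation ``+partner_r`` / ``-partner_r`` with
    the focal OTU in those samples, via a rank-one factor so the assembled
    correlation matrix stays positive semi-definite.
    """

    focal: int
    target_treatments: tuple[str, ...] = ("S6-1",)
    multiplier: float = 10.0
    positive_partners: tuple[int, ...] = ()
    negative_partners: tuple[int, ...] = ()
    partner_r: float = 0.8
    reference_mismatches: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.partner_r < 1:
            raise ValueError("partner_r must be in (0, 1)")
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")
        if not 0 <= self.reference_mismatches <= 2:
            raise ValueError("reference_mismatches must be 0, 1 or 2")
        overlap = set(self.positive_partners) & set(self.negative_partners)
        if overlap or self.focal in set(self.positive_partners) | set(self.negative_partners):
            raise ValueError("spike partner index sets must be disjoint and exclude the focal OTU")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of a simulated inoculation experiment.

    Defaults emulate the study design this package targets: 3 replicate pots
    per treatment x compartment cell (4 treatments x 2 compartments = 24
    samples), 150 OTUs, 50,000 reads per sample, log-normal base abundances.
    """

    n_samples_per_group: int = 3
    groups: tuple[tuple[str, str], ...] = DEFAULT_GROUPS
    n_otus: int = 150
    sequencing_depth: int = 50_000
    correlation_blocks: tuple[CorrelationBlock, ...] = ()
    inoculant_spike: InoculantSpike | None = None
    pgpb_genus_fraction: float = 0.15
    mean_log: float = 0.0
    sd_log: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_otus < 2 or self.n_samples_per_group < 1:
            raise ValueError("need n_otus >= 2 and n_samples_per_group >= 1")
        if self.sd_log <= 0:
            raise ValueError("sd_log must be positive")
        if not 0 <= self.pgpb_genus_fraction <= 1:
            raise ValueError("pgpb_genus_fraction must be in [0, 1]")
        for t, c in self.groups:
            if t not in TREATMENTS or c not in COMPARTMENTS:
                raise ValueError(f"unknown group ({t!r}, {c!r})")
        seen: set[int] = set()
        for block in self.correlation_blocks:
            if max(block.members) >= self.n_otus:
                raise ValueError("block member index out of range")
            if seen & set(block.members):
                raise ValueError("correlation blocks must be disjoint")
            seen |= set(block.members)
        if self.inoculant_spike is not None:
            spike = self.inoculant_spike
            involved = {spike.focal, *spike.positive_partners, *spike.negative_partners}
            if max(involved) >= self.n_otus:
                raise ValueError("spike OTU index out of range")
            if seen & involved:
                raise ValueError("spike OTUs must not belong to correlation blocks")
        if self.sequencing_depth < 10 * self.n_otus:
            warnings.warn(
                "sequencing_depth below 10x n_otus: multinomial noise will "
                "attenuate planted correlations", stacklevel=2)


@dataclass(frozen=True)
class SyntheticCommunity:
    table: OtuTable
    taxonomy: TaxonomyTable
    metadata: SampleMetadata
    sequences: dict[str, str]
    reference_sequences: dict[str, str]
    ground_truth_edges: tuple[tuple[str, str, int], ...]
    spec: SyntheticSpec


def _otu_id(i: int) -> str:
    return f"OTU{i + 1}"


def _assemble_sigma(spec: SyntheticSpec, spiked: bool) -> np.ndarray:
    """Explicit latent correlation matrix; eigenvalue-checked before use."""
    k = spec.n_otus
    sigma = np.eye(k)
    for block in spec.correlation_blocks:
        for a in block.members:
            for b in block.members:
                if a != b:
                    sigma[a, b] = block.r
    if spiked and spec.inoculant_spike is not None:
        spike = spec.inoculant_spike
        r = spike.partner_r
        partners = [(i, +1) for i in spike.positive_partners] + \
                   [(i, -1) for i in spike.negative_partners]
        # one-factor construction: focal loads 1 on the shared factor scale,
        # partner i loads s_i * r, giving corr(focal, i) = s_i * r and
        # corr(i, j) = s_i * s_j * r^2 (PSD by construction).
        for i, si in partners:
            sigma[spike.focal, i] = sigma[i, spike.focal] = si * r
        for i, si in partners:
            for j, sj in partners:
                if i != j:
                    sigma[i, j] = si * sj * r * r
    eigvals = np.linalg.eigvalsh(sigma)
    if eigvals.min() < -1e-10:
        raise ValueError(
            f"assembled latent correlation matrix is not positive "
            f"semi-definite (min eigenvalue {eigvals.min():.3g})")
    return sigma


def _cholesky_psd(sigma: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        # semi-definite boundary: tiny jitter on the diagonal
        return np.linalg.cholesky(sigma + 1e-10 * np.eye(sigma.shape[0]))


def _make_taxonomy(spec: SyntheticSpec, rng: np.random.Generator) -> TaxonomyTable:
    pgpb_pool = sorted(load_packaged_pgpb_database().genera)
    n_pgpb = int(round(spec.pgpb_genus_fraction * spec.n_otus))
    is_pgpb = np.zeros(spec.n_otus, dtype=bool)
    if n_pgpb:
        is_pgpb[rng.choice(spec.n_otus, size=n_pgpb, replace=False)] = True
    lineages = {}
    for i in range(spec.n_otus):
        phylum = PHYLA[i % len(PHYLA)]
        if is_pgpb[i]:
            genus = pgpb_pool[int(rng.integers(len(pgpb_pool)))]
        else:
            genus = _FILLER_GENERA[i % len(_FILLER_GENERA)]
        lineages[_otu_id(i)] = Lineage(
            kingdom="Bacteria", phylum=phylum, class_=f"{phylum}_class",
            order=f"{phylum}_order", family=f"{phylum}_family", genus=genus)
    return TaxonomyTable(lineages)


def _random_sequence(rng: np.random.Generator, length: int = _SEQ_LENGTH) -> str:
    return "".join(_ALPHABET[rng.integers(0, 4, size=length)])


def _mutate(seq: str, n_mismatches: int, rng: np.random.Generator) -> str:
    if n_mismatches == 0:
        return seq
    positions = rng.choice(len(seq), size=n_mismatches, replace=False)
    chars = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(3))]
    return "".join(chars)


def generate_community(spec: SyntheticSpec) -> SyntheticCommunity:
    """Draw one community; identical spec (incl. seed) gives identical output."""
    rng = np.random.default_rng(spec.seed)

    sample_ids, infos = [], {}
    for treatment, compartment in spec.groups:
        for rep in range(1, spec.n_samples_per_group + 1):
            sid = f"{treatment}-{'B' if compartment == 'bulk' else 'R'}{rep}"
            sample_ids.append(sid)
            infos[sid] = SampleInfo(treatment, compartment, rep)
    metadata = SampleMetadata(infos)
    n_samples = len(sample_ids)

    sigma_base = _assemble_sigma(spec, spiked=False)
    chol = {False: _cholesky_psd(sigma_base)}
    spike = spec.inoculant_spike
    if spike is not None:
        chol[True] = _cholesky_psd(_assemble_sigma(spec, spiked=True))

    z = np.empty((n_samples, spec.n_otus))
    for i, sid in enumerate(sample_ids):
        in_target = spike is not None and infos[sid].treatment in spike.target_treatments
        z[i] = chol[in_target] @ rng.standard_normal(spec.n_otus)
        if in_target:
            # latent shift that multiplies the log-normal propensity
            z[i, spike.focal] += np.log(spike.multiplier) / spec.sd_log

    u = stats.norm.cdf(z)
    propensity = stats.lognorm.ppf(u, s=spec.sd_log, scale=np.exp(spec.mean_log))
    probs = propensity / propensity.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(spec.sequencing_depth, p) for p in probs])

    table = OtuTable(tuple(sample_ids), tuple(_otu_id(i) for i in range(spec.n_otus)),
                     counts)
    taxonomy = _make_taxonomy(spec, rng)

    sequences = {_otu_id(i): _random_sequence(rng) for i in range(spec.n_otus)}
    reference_sequences: dict[str, str] = {}
    if spike is not None:
        reference = _random_sequence(rng)
        reference_sequences["inoculant"] = reference
        sequences[_otu_id(spike.focal)] = _mutate(
            reference, spike.reference_mismatches, rng)

    edges: list[tuple[str, str, int]] = []
    for block in spec.correlation_blocks:
        sign = 1 if block.r > 0 else -1
        members = sorted(block.members)
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                edges.append((_otu_id(members[ai]), _otu_id(members[bi]), sign))
    if spike is not None:
        for p in spike.positive_partners:
            edges.append((_otu_id(spike.focal), _otu_id(p), 1))
        for p in spike.negative_partners:
            edges.append((_otu_id(spike.focal), _otu_id(p), -1))

    return SyntheticCommunity(table, taxonomy, metadata, sequences,
                              reference_sequences, tuple(edges), spec)


def write_community(community: SyntheticCommunity, outdir: str | Path) -> dict[str, Path]:
    """Write the community in the pipeline's on-disk formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "metadata": outdir / "metadata.tsv",
        "sequences": outdir / "rep_seqs.fasta",
        "ground_truth": outdir / "ground_truth_edges.tsv",
    }
    write_otu_table(community.table, paths["counts"])
    write_taxonomy(community.taxonomy, paths["taxonomy"])
    write_metadata(community.metadata, paths["metadata"])
    write_fasta(community.sequences, paths["sequences"])
    pd.DataFrame(community.ground_truth_edges,
                 columns=["otu_a", "otu_b", "sign"]).to_csv(
        paths["ground_truth"], sep="\t", index=False)
    if community.reference_sequences:
        paths["reference"] = outdir / "inoculant_ref.fasta"
        write_fasta(community.reference_sequences, paths["reference"])
    return paths
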