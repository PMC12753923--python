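"""Inoculant colonization tracking and ego-network characterization.

An inoculated strain is located in the community by aligning its reference
16S sequence (V3-V4 amplicon, ~450 nt) against every OTU representative
sequence with an end-gap-free global alignment; identity is counted over
aligned columns excluding terminal overhangs, and a hit at >= 99.5%
identity (roughly <= 2 substitutions over the amplicon) is treated as the
inoculant's OTU.  The matched OTU's relative abundance is then tracked
across treatments and compartments, and its ego network — the focal node,
its direct co-occurrence partners, and the incident signed edges — is
summarized per phylum, with partners flagged when their genus appears in
the PGPB database.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from Bio import Align

from .data_model import (
    OtuTable,
    PgpbDatabase,
    SampleMetadata,
    TaxonomyTable,
    to_relative_abundance,
)
from .diversity import GroupTestResult, group_tests
from .network import CooccurrenceNetwork

__all__ = [
    "InoculantMatch",
    "EgoPartner",
    "EgoSummary",
    "percent_identity",
    "match_inoculant",
    "track_abundance",
    "ego_summary",
]

IDENTITY_THRESHOLD = 99.5


@dataclass(frozen=True)
class InoculantMatch:
    inoculant: str
    otu_id: str
    percent_identity: float
    alignment_length: int
    passed: bool
    threshold: float = IDENTITY_THRESHOLD


@dataclass(frozen=True)
class EgoPartner:
    otu_id: str
    sign: int
    rho: float
    phylum: str
    genus: str
    is_pgpb: bool


@dataclass(frozen=True)
class EgoSummary:
    focal_otu: str
    degree: int
    positive_count: int
    negative_count: int
    phylum_counts: dict[str, int]
    partners: tuple[EgoPartner, ...]

    @property
    def positive_fraction(self) -> float | None:
        return self.positive_count / self.degree if self.degree else None

    @property
    def negative_fraction(self) -> float | None:
        return self.negative_count / self.degree if self.degree else None

    @property
    def n_pgpb_partners(self) -> int:
        return sum(1 for p in self.partners if p.is_pgpb)

    def phylum_percentages(self) -> dict[str, float]:
        """Per-phylum edge percentages, rounded half-up to 2 decimals for
        display (exact fractions stay available via phylum_counts/degree)."""
        if self.degree == 0:
            return {}
        return {phylum: _round_half_up(100.0 * count / self.degree)
                for phylum, count in self.phylum_counts.items()}


def _round_half_up(value: float, decimals: int = 2) -> float:
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_internal_gap_score = -2
    aligner.extend_internal_gap_score = -2
    # end-gap-free: terminal overhangs are not penalized
    aligner.open_end_gap_score = 0
    aligner.extend_end_gap_score = 0
    return aligner


MIN_OVERLAP_FRACTION = 0.5


def percent_identity(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Identity of the best end-gap-free global alignment of two sequences.

    Returns (percent identity, aligned columns).  Terminal overhang columns
    (leading/trailing positions where either sequence has a gap running to
    its end) are excluded from both the match and the column count, so two
    sequences covering the same amplicon region compare on that region only.

    Unrelated sequences can produce an optimal end-gap-free alignment whose
    overlap is only a handful of (matching) columns; an identity over such
    an overlap is meaningless.  When the overlap covers less than half of
    the shorter sequence, matches are therefore counted over the shorter
    sequence's full length instead, which drives the identity of unrelated
    pairs toward zero while leaving genuinely co-covering amplicons exact.
    """
    for name, seq in (("first", seq_a), ("second", seq_b)):
        if not seq:
            raise ValueError(f"{name} sequence is empty")
        if set(seq) - set("ACGTN"):
            raise ValueError(f"{name} sequence has characters outside ACGTN")
    alignment = _make_aligner().align(seq_a, seq_b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])

    start = 0
    while start < len(row_a) and (row_a[start] == "-" or row_b[start] == "-"):
        start += 1
    end = len(row_a)
    while end > start and (row_a[end - 1] == "-" or row_b[end - 1] == "-"):
        end -= 1
    columns = end - start
    if columns == 0:
        return 0.0, 0
    matches = sum(1 for i in range(start, end) if row_a[i] == row_b[i])
    shorter = min(len(seq_a), len(seq_b))
    if columns < MIN_OVERLAP_FRACTION * shorter:
        return 100.0 * matches / shorter, columns
    return 100.0 * matches / columns, columns


def match_inoculant(inoculant: str, reference_seq: str,
                    representative_seqs: dict[str, str],
                    threshold: float = IDENTITY_THRESHOLD) -> InoculantMatch:
    """Best-identity OTU for one inoculant reference sequence.

    Ties on identity break to the lexicographically smallest OTU id.  A best
    hit below the threshold is still reported, with ``passed=False``.
    """
    if not representative_seqs:
        raise ValueError("no representative sequences supplied")
    best: tuple[float, str, int] | None = None
    for otu_id in sorted(representative_seqs):
        identity, columns = percent_identity(reference_seq,
                                             representative_seqs[otu_id])
        if best is None or identity > best[0] + 1e-12:
            best = (identity, otu_id, columns)
    identity, otu_id, columns = best
    return InoculantMatch(inoculant=inoculant, otu_id=otu_id,
                          percent_identity=identity, alignment_length=columns,
                          passed=identity >= threshold, threshold=threshold)


def track_abundance(otu_id: str, table: OtuTable, metadata: SampleMetadata
                    ) -> tuple[pd.DataFrame, GroupTestResult]:
    """Relative abundance of one OTU per treatment x compartment group.

    Returns the summary table (mean, sd, n per group, deterministically
    ordered) plus the treatment/compartment statistics from
    :func:`inocunet.diversity.group_tests` on the per-sample values.
    """
    if otu_id not in table.otu_ids:
        raise ValueError(f"OTU {otu_id!r} not present in the count table")
    rel = to_relative_abundance(table).to_dataframe()[otu_id]
    meta = metadata.to_dataframe().loc[list(rel.index)]
    grouped = rel.groupby([meta["treatment"], meta["compartment"]])
    summary = grouped.agg(["mean", "std", "count"]).reset_index()
    summary.columns = ["treatment", "compartment", "mean", "sd", "n"]
    summary = summary.sort_values(["treatment", "compartment"]).reset_index(drop=True)
    tests = group_tests(rel, metadata)
    return summary, tests


def ego_summary(net: CooccurrenceNetwork, focal_otu: str,
                taxonomy: TaxonomyTable, pgpb: PgpbDatabase) -> EgoSummary:
    """Signed, phylum-resolved summary of one OTU's direct neighborhood.

    A focal OTU absent from the network yields a degree-0 summary rather
    than an error (an inoculant may simply not integrate into a network).
    """
    if focal_otu not in net.graph:
        return EgoSummary(focal_otu=focal_otu, degree=0, positive_count=0,
                          negative_count=0, phylum_counts={}, partners=())
    partners = []
    for neighbor in sorted(net.graph.neighbors(focal_otu)):
        data = net.graph.edges[focal_otu, neighbor]
        genus = taxonomy.genus(neighbor)
        partners.append(EgoPartner(
            otu_id=neighbor, sign=int(data["sign"]), rho=float(data["rho"]),
            phylum=taxonomy.phylum(neighbor), genus=genus,
            is_pgpb=genus in pgpb))
    phylum_counts: dict[str, int] = {}
    for p in partners:
        phylum_counts[p.phylum] = phylum_counts.get(p.phylum, 0) + 1
    positive = sum(1 for p in partners if p.sign > 0)
    return EgoSummary(
        focal_otu=focal_otu, degree=len(partners), positive_count=positive,
        negative_count=len(partners) - positive, phylum_counts=phylum_counts,
        partners=tuple(partners))
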