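"""Core containers and file I/O for OTU-table based community analysis.

The pipeline's root input is an integer OTU count table (samples x OTUs),
accompanied by a six-rank taxonomy, sample metadata describing the inoculation
design (four treatments x two soil compartments), representative 16S
sequences, and a list of plant growth-promoting bacterial (PGPB) genera.
All tabular formats are UTF-8 TSV with one header row; lines starting with
``#`` are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "RANKS",
    "TREATMENTS",
    "COMPARTMENTS",
    "UNCLASSIFIED",
    "OtuTable",
    "RelativeAbundanceMatrix",
    "Lineage",
    "TaxonomyTable",
    "SampleInfo",
    "SampleMetadata",
    "PgpbDatabase",
    "read_otu_table",
    "write_otu_table",
    "to_relative_abundance",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "read_fasta",
    "write_fasta",
    "read_genus_list",
    "load_packaged_pgpb_database",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
TREATMENTS = ("S6-1", "UW4", "NC", "CK")
COMPARTMENTS = ("bulk", "rhizosphere")
UNCLASSIFIED = "unclassified"


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def _check_unique(ids: Iterable[str], what: str) -> tuple[str, ...]:
    ids = tuple(str(i).strip() for i in ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if list(ids).count(i) > 1})
        raise ValidationError(f"duplicate {what} identifiers: {dupes[:5]}")
    return ids


@dataclass(frozen=True)
class OtuTable:
    """Non-negative integer read counts, samples on rows, OTUs on columns."""

    sample_ids: tuple[str, ...]
    otu_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", _check_unique(self.sample_ids, "sample"))
        object.__setattr__(self, "otu_ids", _check_unique(self.otu_ids, "OTU"))
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValidationError("an OTU table needs at least 2 samples and 2 OTUs")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                bad = np.argwhere(np.mod(counts, 1) != 0)[0]
                raise ValidationError(
                    f"non-integer count at sample {self.sample_ids[bad[0]]!r}, "
                    f"OTU {self.otu_ids[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            bad = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, "
                f"OTU {self.otu_ids[bad[1]]!r}"
            )
        counts = counts.astype(np.int64, copy=False)
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.sample_ids),
                            columns=list(self.otu_ids))

    def select_samples(self, sample_ids: Iterable[str]) -> "OtuTable":
        keep = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(tuple(self.sample_ids[i] for i in keep), self.otu_ids,
                        self.counts[keep, :])


@dataclass(frozen=True)
class RelativeAbundanceMatrix:
    """Per-sample proportions on the same axes as the source OtuTable."""

    sample_ids: tuple[str, ...]
    otu_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError("values shape does not match identifier axes")
        if (values < 0).any() or (values > 1).any():
            raise ValidationError("relative abundances must lie in [0, 1]")
        rowsums = values.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            bad = self.sample_ids[int(np.argmax(np.abs(rowsums - 1.0)))]
            raise ValidationError(f"sample {bad!r} abundances do not sum to 1")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sample_ids),
                            columns=list(self.otu_ids))

    def mean_abundance(self) -> pd.Series:
        """Mean relative abundance of each OTU across the samples held."""
        return pd.Series(self.values.mean(axis=0), index=list(self.otu_ids))


@dataclass(frozen=True)
class Lineage:
    kingdom: str = UNCLASSIFIED
    phylum: str = UNCLASSIFIED
    class_: str = UNCLASSIFIED
    order: str = UNCLASSIFIED
    family: str = UNCLASSIFIED
    genus: str = UNCLASSIFIED

    def as_dict(self) -> dict[str, str]:
        return {"kingdom": self.kingdom, "phylum": self.phylum,
                "class": self.class_, "order": self.order,
                "family": self.family, "genus": self.genus}


@dataclass(frozen=True)
class TaxonomyTable:
    """OTU -> six-rank lineage; missing ranks carry the explicit
    ``unclassified`` marker rather than being empty."""

    lineages: Mapping[str, Lineage]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lineages", dict(self.lineages))

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.lineages

    def __getitem__(self, otu_id: str) -> Lineage:
        return self.lineages[otu_id]

    def phylum(self, otu_id: str) -> str:
        return self.lineages[otu_id].phylum if otu_id in self.lineages else UNCLASSIFIED

    def genus(self, otu_id: str) -> str:
        return self.lineages[otu_id].genus if otu_id in self.lineages else UNCLASSIFIED

    def validate_against(self, table: OtuTable) -> None:
        missing = [o for o in table.otu_ids if o not in self.lineages]
        if missing:
            raise ValidationError(f"OTUs without taxonomy entries: {missing[:5]}")


@dataclass(frozen=True)
class SampleInfo:
    treatment: str
    compartment: str
    replicate: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"unknown treatment {self.treatment!r}; expected one of {TREATMENTS}")
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"unknown compartment {self.compartment!r}; expected one of {COMPARTMENTS}")


@dataclass(frozen=True)
class SampleMetadata:
    samples: Mapping[str, SampleInfo]

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", dict(self.samples))

    def __getitem__(self, sample_id: str) -> SampleInfo:
        return self.samples[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.samples

    def validate_against(self, table: OtuTable) -> None:
        missing = [s for s in table.sample_ids if s not in self.samples]
        if missing:
            raise ValidationError(f"samples without metadata entries: {missing[:5]}")

    def samples_for(self, treatment: str | None = None,
                    compartment: str | None = None) -> list[str]:
        """Sample ids matching the given factor levels, in insertion order."""
        out = []
        for sid, info in self.samples.items():
            if treatment is not None and info.treatment != treatment:
                continue
            if compartment is not None and info.compartment != compartment:
                continue
            out.append(sid)
        return out

    def treatment_of(self, sample_id: str) -> str:
        return self.samples[sample_id].treatment

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"sample_id": s, "treatment": i.treatment,
                 "compartment": i.compartment, "replicate": i.replicate}
                for s, i in self.samples.items()]
        return pd.DataFrame(rows).set_index("sample_id")


@dataclass(frozen=True)
class PgpbDatabase:
    """Case-normalized set of plant growth-promoting bacterial genus names.

    Genera are stored in title case so that lineages from different
    taxonomy pipelines (which disagree on casing) compare equal.
    """

    genera: frozenset[str] = field(default_factory=frozenset)

    @staticmethod
    def normalize(genus: str) -> str:
        return genus.strip().title()

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "PgpbDatabase":
        normalized = {cls.normalize(n) for n in names if n.strip()}
        return cls(frozenset(normalized))

    def __contains__(self, genus: str) -> bool:
        return self.normalize(genus) in self.genera

    def __len__(self) -> int:
        return len(self.genera)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", header=0, index_col=0,
                       dtype=str, keep_default_na=False)


def read_otu_table(path: str | Path, orientation: str = "samples_as_rows") -> OtuTable:
    """Read a tab-separated count table.

    ``orientation`` must be ``"samples_as_rows"`` or ``"otus_as_rows"``; the
    result is always normalized to samples x OTUs.  Guessing the orientation
    from the file is deliberately not attempted.
    """
    if orientation not in ("samples_as_rows", "otus_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_tsv(path)
    if orientation == "otus_as_rows":
        df = df.T
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                v = int(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"non-integer count {raw!r} at row {df.index[i]!r}, "
                    f"column {col!r} in {path}") from None
            values[i, j] = v
    return OtuTable(tuple(str(i).strip() for i in df.index),
                    tuple(str(c).strip() for c in df.columns), values)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")


def to_relative_abundance(table: OtuTable) -> RelativeAbundanceMatrix:
    """Divide each sample's counts by its total; errors on empty samples."""
    totals = table.sample_totals()
    if (totals == 0).any():
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise ValidationError(f"sample {bad!r} has zero total count")
    values = table.counts / totals[:, None]
    return RelativeAbundanceMatrix(table.sample_ids, table.otu_ids, values)


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    df = _read_tsv(path)
    cols = {c.lower(): c for c in df.columns}
    lineages: dict[str, Lineage] = {}
    for otu_id, row in df.iterrows():
        kwargs = {}
        for rank in RANKS:
            col = cols.get(rank)
            value = str(row[col]).strip() if col is not None else ""
            key = "class_" if rank == "class" else rank
            kwargs[key] = value if value else UNCLASSIFIED
        lineages[str(otu_id).strip()] = Lineage(**kwargs)
    if not lineages:
        raise ValidationError(f"empty taxonomy table: {path}")
    return TaxonomyTable(lineages)


def write_taxonomy(taxonomy: TaxonomyTable, path: str | Path) -> None:
    rows = [{"otu_id": o, **lin.as_dict()} for o, lin in taxonomy.lineages.items()]
    pd.DataFrame(rows).set_index("otu_id").to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = _read_tsv(path)
    cols = {c.lower(): c for c in df.columns}
    for required in ("treatment", "compartment", "replicate"):
        if required not in cols:
            raise ValidationError(f"metadata file lacks a {required!r} column: {path}")
    samples = {}
    for sid, row in df.iterrows():
        samples[str(sid).strip()] = SampleInfo(
            treatment=str(row[cols["treatment"]]).strip(),
            compartment=str(row[cols["compartment"]]).strip(),
            replicate=int(row[cols["replicate"]]),
        )
    if not samples:
        raise ValidationError(f"empty metadata file: {path}")
    return SampleMetadata(samples)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> ordered map of record id to uppercase nucleotide string."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id.strip()
        if rid in records:
            raise ValidationError(f"duplicate FASTA identifier {rid!r} in {path}")
        records[rid] = str(rec.seq).upper()
    if not records:
        raise ValidationError(f"no FASTA records found in {path}")
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in sequences.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def read_genus_list(path: str | Path) -> PgpbDatabase:
    """Plain text, one genus per line; '#' lines ignored; case-insensitive."""
    names = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                names.append(line)
    db = PgpbDatabase.from_names(names)
    if len(db) == 0:
        raise ValidationError(f"genus list {path} contains no genera")
    return db


def load_packaged_pgpb_database() -> PgpbDatabase:
    """The PGPB genus snapshot shipped with the package (user-replaceable)."""
    from importlib.resources import files

    path = files("inocunet").joinpath("data/pgpb_genera_synthetic.txt")
    names = [ln.strip() for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    return PgpbDatabase.from_names(names)
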