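"""Readers and writers for the pipeline's on-disk artifacts.

Protein sequences travel as FASTA; everything tabular (motif/cassette
occurrence tables, catalogs, sharing summaries, Ct tables) is
tab-separated with a fixed header so that every stage of the pipeline can
be re-run from its files alone.

Coordinates are 0-based, half-open everywhere in memory and on disk;
1-based closed coordinates appear only in human-readable reports
(``reports`` adds +1 to the start and leaves the end).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino acids plus 'X' (unknown / assembly-gap residue).
ALLOWED_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: The seven canonical silk classes, named for their producing glands.
CANONICAL_CLASSES = ("AcSp", "AgSp", "FLAG", "MaSp", "MiSp", "PySp", "TuSp")

#: Valid class labels for a gene: the canonical seven, spidroin-like, or none.
CLASS_LABELS = CANONICAL_CLASSES + ("SpL", "unclassified")

OCCURRENCE_COLUMNS = ["species", "gene_id", "feature_kind", "feature_id", "start", "end"]
CT_COLUMNS = ["sample", "tissue", "target", "replicate", "ct"]


@dataclass(frozen=True)
class ProteinRecord:
    """One translated spidroin or spidroin-like gene.

    Parameters
    ----------
    gene_id:
        Unique identifier within a dataset (first whitespace-delimited
        token of the FASTA header).
    species:
        Caller-supplied species tag, e.g. ``"Cdar"`` or ``"Tcla"``.
    residues:
        Uppercase amino-acid string over the 20 canonical letters plus X.
    class_label:
        Optional silk-class tag (one of :data:`CLASS_LABELS`).
    description:
        Free text after the first header token, retained verbatim.
    """

    gene_id: str
    species: str
    residues: str
    class_label: Optional[str] = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"gene {self.gene_id!r}: empty residue string")
        for pos, ch in enumerate(self.residues):
            if ch not in ALLOWED_RESIDUES:
                raise ValueError(
                    f"gene {self.gene_id!r}: illegal residue {ch!r} at position {pos}"
                )
        if self.class_label is not None and self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"gene {self.gene_id!r}: unknown class label {self.class_label!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ReferenceDomainEntry:
    """One curated terminal-domain reference sequence with its class label."""

    domain_id: str
    domain_kind: str  # "NTD" or "CTD"
    class_label: str
    residues: str

    def __post_init__(self) -> None:
        if self.domain_kind not in ("NTD", "CTD"):
            raise ValueError(f"{self.domain_id!r}: domain_kind must be NTD or CTD")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"{self.domain_id!r}: unknown class label {self.class_label!r}")


@dataclass(frozen=True)
class ReferenceDomainLibrary:
    """Curated library of spidroin N-/C-terminal domains used for homology calls."""

    entries: tuple[ReferenceDomainEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def by_kind(self, kind: str) -> list[ReferenceDomainEntry]:
        return [e for e in self.entries if e.domain_kind == kind]

    @property
    def total_length(self) -> int:
        return sum(len(e.residues) for e in self.entries)


# ---------------------------------------------------------------------------
# protein FASTA


def read_protein_fasta(path, species_tag: str, labels: Optional[Mapping[str, str]] = None) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    The first whitespace-delimited header token becomes ``gene_id``;
    the remainder is kept as the description. Sequences are uppercased and
    trailing ``*`` stop symbols are stripped (from the end only). An empty
    file yields an empty list.
    """
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id {gene_id!r} in {path}")
        seen.add(gene_id)
        residues = str(rec.seq).upper().rstrip("*")
        description = rec.description[len(rec.id):].strip()
        records.append(
            ProteinRecord(
                gene_id=gene_id,
                species=species_tag,
                residues=residues,
                class_label=(labels or {}).get(gene_id),
                description=description,
            )
        )
    return records


def write_protein_fasta(records: Iterable[ProteinRecord], path) -> None:
    """Write records as FASTA (60-column wrap), header = ``gene_id description``."""
    seqs = [
        SeqRecord(Seq(r.residues), id=r.gene_id, description=r.description)
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_reference_library(fasta_path, labels_path) -> ReferenceDomainLibrary:
    """Read a terminal-domain reference library.

    ``fasta_path`` holds the domain sequences; ``labels_path`` is a TSV with
    columns ``domain_id``, ``domain_kind`` (NTD/CTD) and ``class_label``.
    """
    labels = pd.read_csv(labels_path, sep="\t", dtype=str)
    required = {"domain_id", "domain_kind", "class_label"}
    missing = required - set(labels.columns)
    if missing:
        raise ValueError(
            f"{labels_path}: missing columns {sorted(missing)}; expected {sorted(required)}"
        )
    meta = labels.set_index("domain_id")
    entries = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in meta.index:
            raise ValueError(f"reference {rec.id!r} has no row in {labels_path}")
        row = meta.loc[rec.id]
        entries.append(
            ReferenceDomainEntry(
                domain_id=rec.id,
                domain_kind=str(row["domain_kind"]),
                class_label=str(row["class_label"]),
                residues=str(rec.seq).upper().rstrip("*"),
            )
        )
    return ReferenceDomainLibrary(entries=tuple(entries))


def write_reference_library(library: ReferenceDomainLibrary, fasta_path, labels_path) -> None:
    seqs = [
        SeqRecord(Seq(e.residues), id=e.domain_id, description="")
        for e in library.entries
    ]
    SeqIO.write(seqs, str(fasta_path), "fasta")
    pd.DataFrame(
        {
            "domain_id": [e.domain_id for e in library.entries],
            "domain_kind": [e.domain_kind for e in library.entries],
            "class_label": [e.class_label for e in library.entries],
        }
    ).to_csv(labels_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# occurrence tables


def sort_occurrence_table(table: pd.DataFrame) -> pd.DataFrame:
    """Canonical row order: (species, gene_id, start, feature_id)."""
    return (
        table[OCCURRENCE_COLUMNS]
        .sort_values(["species", "gene_id", "start", "feature_id"], kind="mergesort")
        .reset_index(drop=True)
    )


def validate_occurrence_table(table: pd.DataFrame, lengths: Optional[Mapping[str, int]] = None) -> None:
    """Check schema and 0 <= start < end (<= gene length when known)."""
    missing = [c for c in OCCURRENCE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"occurrence table missing columns {missing}; expected {OCCURRENCE_COLUMNS}"
        )
    for idx, row in table.iterrows():
        start, end = int(row["start"]), int(row["end"])
        bound = lengths.get(row["gene_id"]) if lengths else None
        if start < 0 or start >= end or (bound is not None and end > bound):
            raise ValueError(
                f"occurrence table row {idx} ({row['gene_id']}, {row['feature_id']}): "
                f"coordinates [{start}, {end}) out of bounds"
            )


def write_occurrence_table(table: pd.DataFrame, path, lengths: Optional[Mapping[str, int]] = None) -> None:
    """Write an occurrence table as TSV in canonical row order."""
    validate_occurrence_table(table, lengths)
    sort_occurrence_table(table).to_csv(path, sep="\t", index=False)


def read_occurrence_table(path) -> pd.DataFrame:
    table = pd.read_csv(
        path,
        sep="\t",
        dtype={c: str for c in OCCURRENCE_COLUMNS[:4]},
    )
    missing = [c for c in OCCURRENCE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"{path}: missing columns {missing}; expected {OCCURRENCE_COLUMNS}"
        )
    table["start"] = table["start"].astype(int)
    table["end"] = table["end"].astype(int)
    return sort_occurrence_table(table)


def occurrence_table_from_rows(rows: Sequence[tuple]) -> pd.DataFrame:
    """Build an occurrence DataFrame from (species, gene_id, kind, id, start, end) tuples."""
    return pd.DataFrame(rows, columns=OCCURRENCE_COLUMNS).astype(
        {"start": int, "end": int}
    )


# ---------------------------------------------------------------------------
# catalog tables


def write_motif_catalog(variants, path) -> None:
    """Write a motif catalog TSV: variant_id, pattern, group_id, subgroup_id."""
    pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in variants],
            "pattern": [v.pattern for v in variants],
            "group_id": [v.group_id for v in variants],
            "subgroup_id": [v.subgroup_id if v.subgroup_id is not None else "" for v in variants],
        }
    ).to_csv(path, sep="\t", index=False)


def read_motif_catalog(path):
    from .motif_catalog import MotifVariant

    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"variant_id", "pattern"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        MotifVariant(
            variant_id=row["variant_id"],
            pattern=row["pattern"],
            group_id=row.get("group_id", "unassigned") or "unassigned",
            subgroup_id=row.get("subgroup_id") or None,
        )
        for _, row in table.iterrows()
    ]


# ---------------------------------------------------------------------------
# Ct tables


def read_ct_table(path):
    """Read a qPCR Ct table into :class:`~silkmotif.qpcr_expression.CtRecord` lists.

    Expected columns: ``sample``, ``tissue``, ``target``, ``replicate``,
    ``ct`` (an optional boolean ``is_nrt`` column marks no-RT controls).
    ``Undetermined`` or empty Ct cells are parsed as censored values
    (``None`` in the replicate list); rows are grouped per
    (sample, tissue, target, is_nrt) in replicate order, so shuffled input
    rows yield identical records.
    """
    from .qpcr_expression import CtRecord

    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}; expected {CT_COLUMNS}")
    if "is_nrt" not in table.columns:
        table["is_nrt"] = "False"
    table["is_nrt"] = table["is_nrt"].fillna("False").map(
        lambda v: str(v).strip().lower() in ("true", "1", "yes")
    )

    def parse_ct(value) -> Optional[float]:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        text = str(value).strip()
        if text == "" or text.lower() in ("undetermined", "nan", "na"):
            return None
        return float(text)

    table["_ct"] = table["ct"].map(parse_ct)
    table["_rep"] = table["replicate"].astype(int)
    records = []
    grouped = table.sort_values(["sample", "tissue", "target", "is_nrt", "_rep"]).groupby(
        ["sample", "tissue", "target", "is_nrt"], sort=True
    )
    for (sample, tissue, target, is_nrt), grp in grouped:
        records.append(
            CtRecord(
                sample_id=str(sample),
                tissue=str(tissue),
                target_gene=str(target),
                replicate_cts=tuple(
                    None if pd.isna(v) else float(v) for v in grp["_ct"]
                ),
                is_nrt_control=bool(is_nrt),
            )
        )
    return records


def write_ct_table(records, path) -> None:
    rows = []
    for rec in records:
        for rep, ct in enumerate(rec.replicate_cts, start=1):
            rows.append(
                {
                    "sample": rec.sample_id,
                    "tissue": rec.tissue,
                    "target": rec.target_gene,
                    "replicate": rep,
                    "ct": "Undetermined" if ct is None else f"{ct:.4f}",
                    "is_nrt": rec.is_nrt_control,
                }
            )
    pd.DataFrame(rows, columns=CT_COLUMNS + ["is_nrt"]).to_csv(path, sep="\t", index=False)


def to_one_based_closed(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open span to 1-based closed for display."""
    return start + 1, end
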