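"""Cross-gene, cross-class and cross-species sharing tallies.

Given the motif (or cassette) occurrence tables of two species, a feature
*type* is shared when it has at least one occurrence in each species and
private otherwise. Type identity across species is pattern-string
equality after wildcard collapse (collapse first, then compare), so the
caller normally maps variant ids to collapsed descriptions before
summarizing. Percentages are recomputed from the raw counts and rounded
half-up to one decimal.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import pandas as pd

from .sequence_io import OCCURRENCE_COLUMNS


def percentage(count: int, total: int) -> float:
    """100 * count / total, rounded half-up to one decimal (0.0 when total=0)."""
    if total == 0:
        return 0.0
    value = Decimal(count) * 100 / Decimal(total)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SharingSummary:
    """Per-species private / shared tallies for one feature kind."""

    feature_kind: str
    species_a: str
    species_b: str
    total_types: int
    private_a: int
    private_b: int
    shared: int
    pct_private_a: float
    pct_private_b: float
    pct_shared: float
    occurrences_a: int
    occurrences_b: int
    pct_occurrences_a: float
    n_genes_a: int
    n_genes_b: int
    # type-key sets backing the counts (not part of the printed table)
    private_types_a: frozenset = frozenset()
    private_types_b: frozenset = frozenset()
    shared_types: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.private_a + self.private_b + self.shared != self.total_types:
            raise ValueError("private_a + private_b + shared != total_types")


@dataclass(frozen=True)
class OriginBreakdown:
    """How a species' private types distribute over genes and classes."""

    species: str
    private_types: int
    single_gene_private_types: int
    pct_single_gene: float
    within_class_shared: int
    across_class_shared: int


def summary_from_counts(
    feature_kind: str,
    private_a: int,
    private_b: int,
    shared: int,
    occurrences_a: int,
    occurrences_b: int,
    n_genes_a: int = 0,
    n_genes_b: int = 0,
    species_a: str = "a",
    species_b: str = "b",
    **type_sets,
) -> SharingSummary:
    """Build a summary from raw counts, re-deriving every percentage."""
    total = private_a + private_b + shared
    return SharingSummary(
        feature_kind=feature_kind,
        species_a=species_a,
        species_b=species_b,
        total_types=total,
        private_a=private_a,
        private_b=private_b,
        shared=shared,
        pct_private_a=percentage(private_a, total),
        pct_private_b=percentage(private_b, total),
        pct_shared=percentage(shared, total),
        occurrences_a=occurrences_a,
        occurrences_b=occurrences_b,
        pct_occurrences_a=percentage(occurrences_a, occurrences_a + occurrences_b),
        n_genes_a=n_genes_a,
        n_genes_b=n_genes_b,
        **type_sets,
    )


def _check_table(table: pd.DataFrame, name: str) -> None:
    missing = [c for c in OCCURRENCE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"occurrence table {name!r} missing columns {missing}")


def summarize_sharing(
    occurrences_a: pd.DataFrame,
    occurrences_b: pd.DataFrame,
    feature_kind: str,
) -> SharingSummary:
    """Tally private/shared types and occurrence splits for two species.

    Both inputs follow the occurrence-table schema; ``feature_id`` is the
    type key (use collapsed descriptions for cross-species motif identity).
    The operation is symmetric: swapping the inputs swaps the a/b fields.
    """
    _check_table(occurrences_a, "a")
    _check_table(occurrences_b, "b")
    species_a = set(occurrences_a["species"].unique())
    species_b = set(occurrences_b["species"].unique())
    if species_a & species_b:
        raise ValueError(f"species tags overlap between tables: {species_a & species_b}")
    types_a = set(occurrences_a["feature_id"])
    types_b = set(occurrences_b["feature_id"])
    shared = types_a & types_b
    private_a = types_a - types_b
    private_b = types_b - types_a
    return summary_from_counts(
        feature_kind=feature_kind,
        private_a=len(private_a),
        private_b=len(private_b),
        shared=len(shared),
        occurrences_a=len(occurrences_a),
        occurrences_b=len(occurrences_b),
        n_genes_a=occurrences_a["gene_id"].nunique(),
        n_genes_b=occurrences_b["gene_id"].nunique(),
        species_a=(sorted(species_a)[0] if species_a else "a"),
        species_b=(sorted(species_b)[0] if species_b else "b"),
        private_types_a=frozenset(private_a),
        private_types_b=frozenset(private_b),
        shared_types=frozenset(shared),
    )


def origin_breakdown(
    occurrences: pd.DataFrame,
    private_types: frozenset,
    class_labels: Mapping[str, str],
    species: str,
) -> OriginBreakdown:
    """Split one species' private types by gene origin and class sharing.

    A private type is single-gene when all its occurrences lie in one
    gene; the remainder split into within-class (all carrier genes share
    one class) versus across-class. Genes without a label count as
    ``unclassified``. single_gene + within_class + across_class equals the
    private-type total.
    """
    genes_per_type: dict[str, set[str]] = defaultdict(set)
    for _, row in occurrences.iterrows():
        if row["feature_id"] in private_types:
            genes_per_type[row["feature_id"]].add(row["gene_id"])
    single = within = across = 0
    for type_key in private_types:
        genes = genes_per_type.get(type_key, set())
        if len(genes) <= 1:
            single += 1
        else:
            classes = {class_labels.get(g, "unclassified") for g in genes}
            if len(classes) == 1:
                within += 1
            else:
                across += 1
    return OriginBreakdown(
        species=species,
        private_types=len(private_types),
        single_gene_private_types=single,
        pct_single_gene=percentage(single, len(private_types)),
        within_class_shared=within,
        across_class_shared=across,
    )


@dataclass(frozen=True)
class RankedMotif:
    type_key: str
    total_occurrences: int
    classes_a: frozenset
    classes_b: frozenset

    @property
    def cross_class(self) -> bool:
        """Shared but used in disjoint silk classes across the two species."""
        return bool(self.classes_a) and bool(self.classes_b) and not (
            self.classes_a & self.classes_b
        )


def rank_top_motifs(
    occurrences_a: pd.DataFrame,
    occurrences_b: pd.DataFrame,
    sharing: SharingSummary,
    class_labels_a: Mapping[str, str],
    class_labels_b: Mapping[str, str],
    k: int = 15,
) -> dict[str, list[RankedMotif]]:
    """Top-k most frequent private (per species) and shared types.

    Ranking is by total occurrence count, ties broken lexicographically by
    pattern. Shared entries carry the classes of use per species; entries
    whose class sets are disjoint are cross-class flagged.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    counts_a = Counter(occurrences_a["feature_id"])
    counts_b = Counter(occurrences_b["feature_id"])

    def classes_of(table: pd.DataFrame, labels: Mapping[str, str], type_key: str) -> frozenset:
        genes = set(table.loc[table["feature_id"] == type_key, "gene_id"])
        return frozenset(labels.get(g, "unclassified") for g in genes)

    def ranked(type_keys, count_fn) -> list[RankedMotif]:
        items = sorted(type_keys, key=lambda t: (-count_fn(t), t))[:k]
        return [
            RankedMotif(
                type_key=type_key,
                total_occurrences=count_fn(type_key),
                classes_a=classes_of(occurrences_a, class_labels_a, type_key)
                if counts_a[type_key]
                else frozenset(),
                classes_b=classes_of(occurrences_b, class_labels_b, type_key)
                if counts_b[type_key]
                else frozenset(),
            )
            for type_key in items
        ]

    return {
        "private_a": ranked(sharing.private_types_a, lambda t: counts_a[t]),
        "private_b": ranked(sharing.private_types_b, lambda t: counts_b[t]),
        "shared": ranked(sharing.shared_types, lambda t: counts_a[t] + counts_b[t]),
    }
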