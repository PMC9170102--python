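"""Assemble the pipeline's summary outputs into one bundle.

The bundle mirrors the shape of a silk-gene study's headline tables: a
two-species sharing table per feature kind, top-k motif listings (private
per species and shared, with cross-class flags), and a targets x tissues
relative-expression matrix. Every number is re-derived from the
referenced input tables — percentages are recomputed from counts, never
copied — and rendering is pure: the same inputs yield identical bytes.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import sequence_io
from .qpcr_expression import RelativeQuantity, relative_quantities
from .sharing_stats import (
    OriginBreakdown,
    RankedMotif,
    SharingSummary,
    origin_breakdown,
    rank_top_motifs,
    summarize_sharing,
)


@dataclass(frozen=True)
class ReportBundle:
    sharing: dict  # feature_kind -> SharingSummary
    origins: dict  # feature_kind -> {species: OriginBreakdown}
    top_motifs: dict  # "private_a" | "private_b" | "shared" -> list[RankedMotif]
    expression_matrix: Optional[pd.DataFrame]  # targets x tissues of RQ
    metadata: dict


def build_report(
    inputs: Mapping[str, str],
    class_labels_a: Optional[Mapping[str, str]] = None,
    class_labels_b: Optional[Mapping[str, str]] = None,
    top_k: int = 15,
    reference_gene: str = "RPL13a",
    calibrator_tissue: str = "legs",
    metadata: Optional[Mapping] = None,
) -> ReportBundle:
    """Build a report from upstream TSV paths.

    Recognized ``inputs`` keys: ``motif_occurrences_a`` / ``_b``,
    ``cassette_occurrences_a`` / ``_b`` (occurrence-table TSVs) and ``ct``
    (a Ct table TSV). Schema errors name the offending file and column.
    """
    sharing: dict = {}
    origins: dict = {}
    top: dict = {"private_a": [], "private_b": [], "shared": []}
    kinds = {
        "motif": ("motif_occurrences_a", "motif_occurrences_b"),
        "cassette": ("cassette_occurrences_a", "cassette_occurrences_b"),
    }
    for kind, (key_a, key_b) in kinds.items():
        if key_a not in inputs or key_b not in inputs:
            continue
        try:
            occ_a = sequence_io.read_occurrence_table(inputs[key_a])
        except ValueError as err:
            raise ValueError(f"{inputs[key_a]}: {err}") from err
        try:
            occ_b = sequence_io.read_occurrence_table(inputs[key_b])
        except ValueError as err:
            raise ValueError(f"{inputs[key_b]}: {err}") from err
        summary = summarize_sharing(occ_a, occ_b, feature_kind=kind)
        sharing[kind] = summary
        origins[kind] = {
            summary.species_a: origin_breakdown(
                occ_a, summary.private_types_a, class_labels_a or {}, summary.species_a
            ),
            summary.species_b: origin_breakdown(
                occ_b, summary.private_types_b, class_labels_b or {}, summary.species_b
            ),
        }
        if kind == "motif":
            top = rank_top_motifs(
                occ_a,
                occ_b,
                summary,
                class_labels_a or {},
                class_labels_b or {},
                k=top_k,
            )

    expression = None
    if "ct" in inputs:
        records = sequence_io.read_ct_table(inputs["ct"])
        rqs = relative_quantities(
            records, reference_gene=reference_gene, calibrator_tissue=calibrator_tissue
        )
        rows = [
            {"target": q.target_gene, "tissue": q.tissue, "rq": q.rq}
            for q in rqs
            if q.quantifiable
        ]
        if rows:
            expression = (
                pd.DataFrame(rows)
                .pivot_table(index="target", columns="tissue", values="rq")
                .sort_index()
            )

    return ReportBundle(
        sharing=sharing,
        origins=origins,
        top_motifs=top,
        expression_matrix=expression,
        metadata=dict(metadata or {}),
    )


def _sharing_rows(summary: SharingSummary) -> list[tuple[str, str]]:
    return [
        ("Feature kind", summary.feature_kind),
        ("Types detected", str(summary.total_types)),
        (
            f"Types private to {summary.species_a} (%)",
            f"{summary.private_a} ({summary.pct_private_a})",
        ),
        (
            f"Types private to {summary.species_b} (%)",
            f"{summary.private_b} ({summary.pct_private_b})",
        ),
        ("Shared types (%)", f"{summary.shared} ({summary.pct_shared})"),
        (
            f"Occurrences in {summary.species_a} (n = {summary.n_genes_a} genes)",
            str(summary.occurrences_a),
        ),
        (
            f"Occurrences in {summary.species_b} (n = {summary.n_genes_b} genes)",
            str(summary.occurrences_b),
        ),
        (f"% occurrences in {summary.species_a}", str(summary.pct_occurrences_a)),
    ]


def render_text(bundle: ReportBundle) -> str:
    """Deterministic plain-text rendering of the bundle."""
    lines: list[str] = ["# silkmotif report", ""]
    for key in sorted(bundle.metadata):
        lines.append(f"{key}: {bundle.metadata[key]}")
    if bundle.metadata:
        lines.append("")
    for kind in sorted(bundle.sharing):
        lines.append(f"## {kind} sharing")
        for name, value in _sharing_rows(bundle.sharing[kind]):
            lines.append(f"{name}\t{value}")
        for species, origin in sorted(bundle.origins.get(kind, {}).items()):
            lines.append(
                f"{species} private: {origin.private_types} "
                f"(single-gene {origin.single_gene_private_types}, "
                f"{origin.pct_single_gene}%; within-class {origin.within_class_shared}; "
                f"across-class {origin.across_class_shared})"
            )
        lines.append("")
    for section in ("private_a", "private_b", "shared"):
        ranked = bundle.top_motifs.get(section) or []
        if not ranked:
            continue
        lines.append(f"## top motifs: {section}")
        for motif in ranked:
            flag = " [cross-class]" if motif.cross_class else ""
            lines.append(f"{motif.type_key}\t{motif.total_occurrences}{flag}")
        lines.append("")
    if bundle.expression_matrix is not None:
        lines.append("## relative expression (RQ = 2^-ddCt)")
        lines.append(bundle.expression_matrix.round(4).to_csv(sep="\t").rstrip("\n"))
        lines.append("")
    return "\n".join(lines) + "\n"


def render_html(bundle: ReportBundle) -> str:
    """Self-contained HTML rendering (no external assets)."""
    body = html.escape(render_text(bundle))
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        "<title>silkmotif report</title></head>"
        f"<body><pre>{body}</pre></body></html>\n"
    )
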