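"""Spidroin candidate screening.

Identifies spidroin candidates among input proteins by local homology of
their termini against a curated library of N-/C-terminal domains (NTD/CTD),
annotates sequence signatures typical of spidroins (the MAFAS anchor near
the N terminus, repetitive GPGQQ, poly-alanine tracts), places incomplete
candidates into one of five fragment categories, and assigns each gene a
silk class from the combined evidence.

Local alignment is Smith–Waterman with affine gaps (BLOSUM62, gap open 11,
extend 1: a gap of length k costs 11 + (k-1)) via Bio.Align.PairwiseAligner.
Significance uses a Karlin–Altschul-style expectation
``E = K * m * n * exp(-lambda * S)`` with the standard gapped BLOSUM62
parameters (lambda = 0.267, K = 0.041), where ``m`` is the query length and
``n`` the summed library length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import math

from Bio.Align import PairwiseAligner, substitution_matrices

from .sequence_io import (
    CANONICAL_CLASSES,
    ProteinRecord,
    ReferenceDomainLibrary,
)

GAPPED_LAMBDA = 0.267
GAPPED_K = 0.041

#: Terminal search window: when a query exceeds 300 aa, NTD hits are sought
#: in the first 150 residues and CTD hits in the last 150; shorter queries
#: are searched whole. Terminal domains are ~100 aa, so this avoids
#: repetitive-core false positives on long spidroins.
TERMINAL_SEARCH_WINDOW = 150

#: Silk-gland tissue -> silk class, used when expression is the only evidence.
TISSUE_CLASS = {
    "MA": "MaSp",
    "MI": "MiSp",
    "FL": "FLAG",
    "AG": "AgSp",
    "tubuliform": "TuSp",
}


class FragmentCategory(str, Enum):
    """The five completeness categories of a spidroin candidate."""

    COMPLETE = "complete"
    INTERNAL_GAP = "internal_gap"
    FIVE_PRIME_END = "five_prime_end"
    THREE_PRIME_END = "three_prime_end"
    REPETITIVE = "repetitive"


@dataclass(frozen=True)
class TerminalDomainHit:
    gene_id: str
    domain_kind: str  # "NTD" | "CTD"
    start: int
    end: int
    best_reference_id: str
    best_class_label: str
    alignment_score: float
    e_value: float


@dataclass(frozen=True)
class SignatureAnnotation:
    """Spidroin sequence signatures found in one gene."""

    gene_id: str
    mafas_present: bool
    gpgqq_repeat_count: int
    polya_runs: tuple[tuple[int, int], ...]  # (start, length), length >= 4


@dataclass(frozen=True)
class ClassAssignment:
    gene_id: str
    class_label: str
    evidence: frozenset[str]  # subset of {ntd_homology, ctd_homology, internal_motifs, expression}


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def e_value(score: float, query_length: int, database_length: int) -> float:
    """Karlin–Altschul-style expectation for a local alignment score."""
    return GAPPED_K * query_length * database_length * math.exp(-GAPPED_LAMBDA * score)


def local_homology_search(
    queries: Sequence[ProteinRecord],
    library: ReferenceDomainLibrary,
    e_threshold: float = 1e-6,
) -> list[TerminalDomainHit]:
    """Best NTD and CTD hit per query at expectation <= ``e_threshold``.

    For each query and domain kind, every library entry of that kind is
    aligned locally; the single best hit (highest score, ties broken by
    lowest e-value then lexicographic reference id) is retained if its
    expectation passes the threshold. At most one NTD and one CTD hit are
    reported per query.
    """
    if len(library) == 0:
        raise ValueError("reference library is empty")
    if len(queries) < 1:
        raise ValueError("need at least one query")
    aligner = _make_aligner()
    db_len = library.total_length
    hits: list[TerminalDomainHit] = []
    for query in queries:
        seq = query.residues
        length = len(seq)
        for kind in ("NTD", "CTD"):
            if length > 2 * TERMINAL_SEARCH_WINDOW:
                if kind == "NTD":
                    region, offset = seq[:TERMINAL_SEARCH_WINDOW], 0
                else:
                    region, offset = seq[-TERMINAL_SEARCH_WINDOW:], length - TERMINAL_SEARCH_WINDOW
            else:
                region, offset = seq, 0
            best = None  # (-score, e, ref_id, entry)
            for entry in library.by_kind(kind):
                score = aligner.score(region, entry.residues)
                if score <= 0:
                    continue
                expect = e_value(score, length, db_len)
                if expect > e_threshold:
                    continue
                key = (-score, expect, entry.domain_id)
                if best is None or key < best[0]:
                    best = (key, entry, score, expect)
            if best is None:
                continue
            _, entry, score, expect = best
            alignment = aligner.align(region, entry.residues)[0]
            blocks = alignment.aligned[0]
            span_start = int(blocks[0][0]) + offset
            span_end = int(blocks[-1][1]) + offset
            hits.append(
                TerminalDomainHit(
                    gene_id=query.gene_id,
                    domain_kind=kind,
                    start=span_start,
                    end=span_end,
                    best_reference_id=entry.domain_id,
                    best_class_label=entry.class_label,
                    alignment_score=float(score),
                    e_value=float(expect),
                )
            )
    return hits


_POLYA = re.compile(r"A{4,}")


def detect_signatures(record: ProteinRecord, ntd_window: int = 100) -> SignatureAnnotation:
    """Locate MAFAS (within the N-terminal window), GPGQQ repeats, poly-A runs."""
    seq = record.residues
    mafas_pos = seq.find("MAFAS")
    gpgqq = len(re.findall("GPGQQ", seq))  # non-overlapping scan
    runs = tuple((m.start(), m.end() - m.start()) for m in _POLYA.finditer(seq))
    return SignatureAnnotation(
        gene_id=record.gene_id,
        mafas_present=0 <= mafas_pos < ntd_window,
        gpgqq_repeat_count=gpgqq,
        polya_runs=runs,
    )


def has_internal_gap(record: ProteinRecord, min_run: int = 10) -> bool:
    """Assembly-gap evidence: a run of >= ``min_run`` X residues strictly inside."""
    for m in re.finditer("X{%d,}" % min_run, record.residues):
        if m.start() > 0 and m.end() < len(record.residues):
            return True
    return False


def repetitive_evidence(
    signatures: SignatureAnnotation, motif_coverage: float = 0.0
) -> bool:
    """Repetitive-core evidence: >=3 GPGQQ repeats, a poly-A run >= 6, or
    >=30% of residues covered by catalog motifs (when a catalog was painted)."""
    if signatures.gpgqq_repeat_count >= 3:
        return True
    if any(length >= 6 for _, length in signatures.polya_runs):
        return True
    return motif_coverage >= 0.30


def categorize_fragment(
    record: ProteinRecord,
    hits: Sequence[TerminalDomainHit],
    gap_evidence: bool,
    signatures: Optional[SignatureAnnotation] = None,
    motif_coverage: float = 0.0,
) -> FragmentCategory:
    """Place a candidate into one of the five completeness categories.

    complete: both termini, no gap evidence; internal_gap: both termini with
    gap evidence; five_prime_end: NTD only; three_prime_end: CTD only;
    repetitive: neither terminus (candidates reaching this stage without
    terminal homology carry repetitive-core evidence upstream).
    """
    own = [h for h in hits if h.gene_id == record.gene_id]
    has_ntd = any(h.domain_kind == "NTD" for h in own)
    has_ctd = any(h.domain_kind == "CTD" for h in own)
    if has_ntd and has_ctd:
        return FragmentCategory.INTERNAL_GAP if gap_evidence else FragmentCategory.COMPLETE
    if has_ntd:
        return FragmentCategory.FIVE_PRIME_END
    if has_ctd:
        return FragmentCategory.THREE_PRIME_END
    if signatures is None:
        signatures = detect_signatures(record)
    # evidence thresholds are computed for the record of it; a candidate with
    # neither terminus is a repetitive fragment either way
    repetitive_evidence(signatures, motif_coverage)
    return FragmentCategory.REPETITIVE


def assign_class(
    gene_id: str,
    hits: Sequence[TerminalDomainHit],
    motif_class_votes: Optional[Mapping[str, int]] = None,
    expression_top_tissue: Optional[str] = None,
) -> ClassAssignment:
    """Assign a silk class from terminal homology, internal motifs, expression.

    Precedence: concordant NTD/CTD homology outranks internal-motif votes,
    which outrank expression. Conflicting NTD/CTD labels fall through to the
    weaker evidence as a tiebreaker; if none resolves the conflict the gene
    is ``unclassified`` with its evidence recorded.
    """
    own = [h for h in hits if h.gene_id == gene_id]
    ntd = next((h for h in own if h.domain_kind == "NTD"), None)
    ctd = next((h for h in own if h.domain_kind == "CTD"), None)
    evidence: set[str] = set()
    if ntd:
        evidence.add("ntd_homology")
    if ctd:
        evidence.add("ctd_homology")

    motif_label = None
    if motif_class_votes:
        ranked = sorted(motif_class_votes.items(), key=lambda kv: (-kv[1], kv[0]))
        if ranked and ranked[0][1] > 0:
            motif_label = ranked[0][0]

    expr_label = TISSUE_CLASS.get(expression_top_tissue) if expression_top_tissue else None

    if ntd and ctd:
        if ntd.best_class_label == ctd.best_class_label:
            return ClassAssignment(gene_id, ntd.best_class_label, frozenset(evidence))
        # conflicting termini: let internal motifs, then expression, arbitrate
        candidates = {ntd.best_class_label, ctd.best_class_label}
        if motif_label in candidates:
            evidence.add("internal_motifs")
            return ClassAssignment(gene_id, motif_label, frozenset(evidence))
        if expr_label in candidates:
            evidence.add("expression")
            return ClassAssignment(gene_id, expr_label, frozenset(evidence))
        return ClassAssignment(gene_id, "unclassified", frozenset(evidence))
    if ntd or ctd:
        hit = ntd or ctd
        return ClassAssignment(gene_id, hit.best_class_label, frozenset(evidence))
    if motif_label is not None:
        evidence.add("internal_motifs")
        return ClassAssignment(gene_id, motif_label, frozenset(evidence))
    if expr_label is not None:
        evidence.add("expression")
        return ClassAssignment(gene_id, expr_label, frozenset(evidence))
    return ClassAssignment(gene_id, "unclassified", frozenset())
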