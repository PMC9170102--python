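"""Higher-order repeat (cassette / ensemble) detection and grouping.

A cassette is an ordered run of 2-6 adjacent motif occurrences whose
inter-motif gaps never exceed 20 residues. Detection chains the painted
motif occurrences of each gene, segments the chains into windows of at
most 6 components (leftmost, longest-window-first), and promotes a
component tuple to a cassette *type* when it recurs at least
``min_type_support`` times across the dataset. Curation removes
occurrences that stray outside the repetitive core or violate the gap
bound, then re-applies the support threshold so no type dangles.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

from .motif_catalog import CoreSpan, MotifOccurrence

MAX_INTER_MOTIF_GAP = 20
MIN_COMPONENTS = 2
MAX_COMPONENTS = 6


@dataclass(frozen=True)
class CassetteType:
    cassette_id: str
    components: tuple[str, ...]  # ordered motif variant_ids
    description: str
    group_id: str = "ungrouped"

    def __post_init__(self) -> None:
        if not (MIN_COMPONENTS <= len(self.components) <= MAX_COMPONENTS):
            raise ValueError(
                f"{self.cassette_id}: {len(self.components)} components outside "
                f"[{MIN_COMPONENTS}, {MAX_COMPONENTS}]"
            )


@dataclass(frozen=True)
class CassetteOccurrence:
    species: str
    gene_id: str
    cassette_id: str
    start: int
    end: int
    component_occurrences: tuple[MotifOccurrence, ...]
    gaps: tuple[int, ...]  # inter-component gaps, residues


@dataclass(frozen=True)
class CassetteGroup:
    group_id: str
    description: str
    member_cassette_ids: tuple[str, ...]


def _chain_gene_occurrences(
    occurrences: Sequence[MotifOccurrence], max_gap: int
) -> list[list[MotifOccurrence]]:
    """Maximal adjacency chains for one gene's sorted occurrences.

    Occurrences are consumed in (start, longer-first) order; one that
    overlaps the tail of the growing chain is skipped entirely, since
    cassette occurrences may not share motif occurrences.
    """
    ordered = sorted(occurrences, key=lambda o: (o.start, -(o.end - o.start), o.variant_id))
    chains: list[list[MotifOccurrence]] = []
    current: list[MotifOccurrence] = []
    for occ in ordered:
        if not current:
            current = [occ]
            continue
        tail = current[-1]
        if occ.start < tail.end:
            continue  # overlap: not usable as an adjacent component
        if occ.start - tail.end <= max_gap:
            current.append(occ)
        else:
            chains.append(current)
            current = [occ]
    if current:
        chains.append(current)
    return chains


def _segment_chain(chain: Sequence[MotifOccurrence], min_components: int, max_components: int):
    """Split a chain into leftmost, longest-first windows of <= max_components."""
    windows = []
    for i in range(0, len(chain), max_components):
        window = chain[i : i + max_components]
        if len(window) >= min_components:
            windows.append(window)
    return windows


def detect_cassettes(
    occurrences: Sequence[MotifOccurrence],
    max_gap: int = MAX_INTER_MOTIF_GAP,
    min_components: int = MIN_COMPONENTS,
    max_components: int = MAX_COMPONENTS,
    min_type_support: int = 2,
) -> tuple[list[CassetteType], list[CassetteOccurrence]]:
    """Detect cassette types and their occurrences from painted motifs.

    A component tuple becomes a :class:`CassetteType` only when its total
    occurrence count across the dataset reaches ``min_type_support``
    ("enriched across spidroins"). Both outputs are deterministic given
    the inputs: types are ordered by (component count descending, tuple),
    occurrences by (species, gene, start).
    """
    if min_components < MIN_COMPONENTS:
        raise ValueError(f"min_components must be >= {MIN_COMPONENTS}")
    if max_components < min_components:
        raise ValueError("max_components < min_components")

    per_gene: dict[tuple[str, str], list[MotifOccurrence]] = defaultdict(list)
    for occ in occurrences:
        per_gene[(occ.species, occ.gene_id)].append(occ)

    windows: list[tuple[str, str, tuple[MotifOccurrence, ...]]] = []
    for (species, gene_id), gene_occs in sorted(per_gene.items()):
        for chain in _chain_gene_occurrences(gene_occs, max_gap):
            for window in _segment_chain(chain, min_components, max_components):
                windows.append((species, gene_id, tuple(window)))

    support = Counter(tuple(o.variant_id for o in window) for _, _, window in windows)
    kept_tuples = sorted(
        (t for t, n in support.items() if n >= min_type_support),
        key=lambda t: (-len(t), t),
    )
    type_ids = {t: f"c{idx:04d}" for idx, t in enumerate(kept_tuples, 1)}
    types = [
        CassetteType(cassette_id=type_ids[t], components=t, description="+".join(t))
        for t in kept_tuples
    ]

    cassette_occurrences = []
    for species, gene_id, window in windows:
        key = tuple(o.variant_id for o in window)
        if key not in type_ids:
            continue
        gaps = tuple(b.start - a.end for a, b in zip(window, window[1:]))
        cassette_occurrences.append(
            CassetteOccurrence(
                species=species,
                gene_id=gene_id,
                cassette_id=type_ids[key],
                start=window[0].start,
                end=window[-1].end,
                component_occurrences=window,
                gaps=gaps,
            )
        )
    cassette_occurrences.sort(key=lambda c: (c.species, c.gene_id, c.start))
    return types, cassette_occurrences


def curate_cassettes(
    types: Sequence[CassetteType],
    occurrences: Sequence[CassetteOccurrence],
    core_spans: Mapping[str, CoreSpan],
    max_gap: int = MAX_INTER_MOTIF_GAP,
    min_type_support: int = 2,
) -> tuple[list[CassetteType], list[CassetteOccurrence]]:
    """Drop occurrences violating the gap bound or straddling a core boundary,
    then drop types whose support falls below ``min_type_support`` (and any
    occurrences of a dropped type, preserving referential integrity)."""
    retained = []
    for occ in occurrences:
        span = core_spans.get(occ.gene_id)
        in_core = span is not None and span.start <= occ.start and occ.end <= span.end
        if in_core and all(g <= max_gap for g in occ.gaps):
            retained.append(occ)
    support = Counter(occ.cassette_id for occ in retained)
    kept_types = [t for t in types if support[t.cassette_id] >= min_type_support]
    kept_ids = {t.cassette_id for t in kept_types}
    return kept_types, [occ for occ in retained if occ.cassette_id in kept_ids]


def group_cassettes(
    types: Sequence[CassetteType],
    occurrences: Sequence[CassetteOccurrence],
    variant_groups: Mapping[str, str],
    collapsed_descriptions: Optional[Mapping[str, str]] = None,
) -> tuple[list[CassetteGroup], list[CassetteType]]:
    """Group cassette types whose components map to the same ordered tuple of
    motif groups.

    The group description joins the components' collapsed motif
    descriptions with ``_`` at junctions where any member occurrence shows
    a positive gap (``xGG_GGx`` style); junctions whose gap is always zero
    are concatenated directly. Tuples of different lengths never share a
    group, so grouping partitions the types.
    """
    if not types:
        raise ValueError("no cassette types to group")
    by_group_tuple: dict[tuple[str, ...], list[CassetteType]] = defaultdict(list)
    for ctype in types:
        key = tuple(variant_groups.get(v, "unassigned") for v in ctype.components)
        by_group_tuple[key].append(ctype)

    occ_by_type: dict[str, list[CassetteOccurrence]] = defaultdict(list)
    for occ in occurrences:
        occ_by_type[occ.cassette_id].append(occ)

    groups: list[CassetteGroup] = []
    updated: dict[str, CassetteType] = {t.cassette_id: t for t in types}
    for idx, key in enumerate(sorted(by_group_tuple, key=lambda k: (-len(k), k)), 1):
        members = by_group_tuple[key]
        group_id = f"cg{idx:03d}"
        representative = min(members, key=lambda t: t.cassette_id)
        n_junctions = len(representative.components) - 1
        gap_seen = [False] * n_junctions
        for member in members:
            for occ in occ_by_type[member.cassette_id]:
                for j, gap in enumerate(occ.gaps):
                    if gap > 0:
                        gap_seen[j] = True
        parts = []
        for j, vid in enumerate(representative.components):
            label = (collapsed_descriptions or {}).get(vid, vid)
            parts.append(label)
            if j < n_junctions and gap_seen[j]:
                parts.append("_")
        description = "".join(parts)
        groups.append(
            CassetteGroup(
                group_id=group_id,
                description=description,
                member_cassette_ids=tuple(sorted(t.cassette_id for t in members)),
            )
        )
        for member in members:
            updated[member.cassette_id] = replace(member, group_id=group_id)
    return groups, [updated[t.cassette_id] for t in types]
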