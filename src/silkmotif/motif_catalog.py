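"""Repetitive motif discovery, painting, grouping and description collapse.

Spidroin cores (the sequence between the ~100-residue terminal domains)
are built almost entirely from short repeated motifs, 4-41 residues long.
This module

* masks the terminal windows (:func:`mask_terminal_domains`),
* enumerates repeated substrings of the cores as candidate motif variants
  (:func:`discover_motifs`) using a level-wise extension of repeated
  k-mers with subsumption pruning — a variant fully contained in a longer
  variant with the identical occurrence set is dropped,
* paints a catalog back onto sequences (:func:`paint_sequences`),
  i.e. locates every variant's leftmost-greedy non-overlapping matches,
* clusters variants into residue-composition groups and edit-distance
  subgroups (:func:`group_motifs`), and
* collapses near-identical variant descriptions into wildcard patterns
  (:func:`collapse_variant_descriptions`), e.g. APGPQ/GPGPQ/SPGPQ -> xPGPQ.

Wildcards: lowercase ``x`` matches any residue; a second symbol ``z``
(also any residue) only distinguishes independent wildcard positions in
one description, as in ``DTxSYzTGEY``.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import edlib

from .sequence_io import ProteinRecord

WILDCARDS = ("x", "z")

#: Default bounds on motif variant length (residues).
MIN_MOTIF_LEN = 4
MAX_MOTIF_LEN = 41

#: Default hard cutoff masking the terminal domains (residues).
TERMINAL_CUTOFF = 100

#: Normalized edit distance threshold for single-linkage subgrouping.
EDIT_DISTANCE_THRESHOLD = 0.25


@dataclass(frozen=True)
class CoreSpan:
    """Repetitive core of one gene after terminal masking (0-based half-open)."""

    gene_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(f"{self.gene_id}: invalid core span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MotifVariant:
    """A curated repetitive motif pattern (possibly with wildcard positions)."""

    variant_id: str
    pattern: str
    group_id: str = "unassigned"
    subgroup_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (MIN_MOTIF_LEN <= len(self.pattern) <= MAX_MOTIF_LEN):
            raise ValueError(
                f"{self.variant_id}: pattern length {len(self.pattern)} outside "
                f"[{MIN_MOTIF_LEN}, {MAX_MOTIF_LEN}]"
            )
        n_wild = sum(self.pattern.count(w) for w in WILDCARDS)
        if 2 * n_wild > len(self.pattern):
            raise ValueError(f"{self.variant_id}: wildcard density exceeds 50%")


@dataclass(frozen=True)
class MotifOccurrence:
    species: str
    gene_id: str
    variant_id: str
    start: int
    end: int


@dataclass(frozen=True)
class MotifGroup:
    """A cluster of motif variants by residue composition and sequence."""

    group_id: str
    description: str
    member_variant_ids: tuple[str, ...]
    subgroups: tuple[tuple[str, ...], ...]  # partition of the members


@dataclass(frozen=True)
class CollapsedDescription:
    description: str
    subgroup_id: str
    member_variant_ids: tuple[str, ...]


def mask_terminal_domains(record: ProteinRecord, cutoff: int = TERMINAL_CUTOFF) -> CoreSpan:
    """Core span after masking ``cutoff`` residues at each terminus.

    For a gene of length L the core is ``[min(cutoff, L), max(L - cutoff,
    min(cutoff, L)))`` — empty when the sequence is shorter than two windows.
    """
    length = len(record.residues)
    start = min(cutoff, length)
    end = max(length - cutoff, start)
    return CoreSpan(gene_id=record.gene_id, start=start, end=end)


# ---------------------------------------------------------------------------
# discovery


def _nonoverlap_count(positions: Sequence[tuple[int, int]], length: int) -> int:
    """Greedy leftmost non-overlapping count of matches given (core, pos) pairs."""
    count = 0
    last_core, last_end = None, -1
    for core_idx, pos in positions:  # positions are generated in sorted order
        if core_idx != last_core or pos >= last_end:
            count += 1
            last_core, last_end = core_idx, pos + length
    return count


def discover_motifs(
    cores: Sequence[tuple[str, str]],
    min_len: int = MIN_MOTIF_LEN,
    max_len: int = MAX_MOTIF_LEN,
    min_total_occurrences: int = 3,
) -> list[MotifVariant]:
    """Enumerate repeated substrings of the cores as motif variants.

    Returns right-maximal repeated substrings with length in
    ``[min_len, max_len]`` whose leftmost-greedy non-overlapping occurrence
    total across all cores is at least ``min_total_occurrences``, after
    subsumption pruning: a candidate fully contained in a longer candidate
    with the identical (all-match) occurrence set is dropped. Variant ids
    are assigned deterministically by (length descending, pattern).

    ``cores`` is a list of ``(gene_id, core_residues)`` pairs; empty cores
    are ignored.
    """
    if min_len < 1 or max_len < min_len:
        raise ValueError(f"invalid length bounds [{min_len}, {max_len}]")
    seqs = [s for _, s in cores]
    if not any(seqs):
        raise ValueError("need at least one non-empty core")

    # level-wise (a-priori) enumeration of repeated substrings: a repeated
    # (L+1)-mer always extends a repeated L-mer
    levels: dict[int, dict[str, list[tuple[int, int]]]] = {}
    current: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for core_idx, seq in enumerate(seqs):
        for i in range(len(seq) - min_len + 1):
            current[seq[i : i + min_len]].append((core_idx, i))
    current = {p: v for p, v in current.items() if len(v) >= 2}
    levels[min_len] = current
    for length in range(min_len, max_len):
        nxt: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for positions in current.values():
            for core_idx, i in positions:
                seq = seqs[core_idx]
                if i + length < len(seq):
                    nxt[seq[i : i + length + 1]].append((core_idx, i))
        current = {p: v for p, v in nxt.items() if len(v) >= 2}
        if not current:
            break
        levels[length + 1] = current

    def all_count(pattern: str) -> int:
        level = levels.get(len(pattern))
        if level is None or pattern not in level:
            return 0
        return len(level[pattern])

    candidates: dict[str, int] = {}  # pattern -> non-overlapping count
    for length, level in levels.items():
        for pattern, positions in level.items():
            n = _nonoverlap_count(positions, length)
            if n >= min_total_occurrences:
                candidates[pattern] = n

    # subsumption pruning: a candidate contained in a longer candidate with
    # the identical occurrence set is dropped (equal all-match count plus
    # containment implies identical sets)
    by_count: dict[int, list[str]] = defaultdict(list)
    for pattern in candidates:
        by_count[all_count(pattern)].append(pattern)

    def subsumed(pattern: str) -> bool:
        return any(
            len(other) > len(pattern) and pattern in other
            for other in by_count[all_count(pattern)]
        )

    kept = [p for p in candidates if not subsumed(p)]
    kept.sort(key=lambda p: (-len(p), p))
    return [MotifVariant(variant_id=f"m{idx:04d}", pattern=p) for idx, p in enumerate(kept, 1)]


# ---------------------------------------------------------------------------
# painting


def pattern_regex(pattern: str) -> re.Pattern:
    """Compile a motif pattern to a regex; wildcards x/z match any residue."""
    return re.compile("".join("." if ch in WILDCARDS else re.escape(ch) for ch in pattern))


def paint_sequences(
    records: Sequence[ProteinRecord],
    catalog: Sequence[MotifVariant],
    core_spans: Mapping[str, CoreSpan],
) -> list[MotifOccurrence]:
    """Locate every catalog variant along each gene's repetitive core.

    Matching is exact up to wildcards; per variant the matches are
    leftmost-greedy and non-overlapping (tandem copies are not
    double-counted at shifted offsets), while overlaps *between* different
    variants are allowed. Occurrences are sorted by
    (gene, start, longer variant first).
    """
    occurrences: list[MotifOccurrence] = []
    if not catalog:
        return occurrences
    compiled = [(v, pattern_regex(v.pattern)) for v in catalog]
    for record in records:
        span = core_spans[record.gene_id]
        core = record.residues[span.start : span.end]
        for variant, rx in compiled:
            for m in rx.finditer(core):  # finditer is leftmost non-overlapping
                occurrences.append(
                    MotifOccurrence(
                        species=record.species,
                        gene_id=record.gene_id,
                        variant_id=variant.variant_id,
                        start=span.start + m.start(),
                        end=span.start + m.end(),
                    )
                )
    occurrences.sort(key=lambda o: (o.species, o.gene_id, o.start, -(o.end - o.start), o.variant_id))
    return occurrences


# ---------------------------------------------------------------------------
# grouping


def _concrete(pattern: str) -> str:
    return "".join(ch for ch in pattern if ch not in WILDCARDS)


def composition_class(pattern: str) -> Optional[str]:
    """Fixed residue-composition classes used as the first grouping tier.

    In precedence order: poly-A (>=80% alanine), GA-dinucleotide-like
    (only G and A, both present), glycine-rich (>=1/3 G), Ser/Thr/Val-rich
    (>=60% S+T+V). Patterns fitting none return ``None``.
    """
    concrete = _concrete(pattern)
    if not concrete:
        return None
    n = len(concrete)
    frac_a = concrete.count("A") / n
    if frac_a >= 0.8:
        return "poly_A"
    if set(concrete) <= {"G", "A"} and "G" in concrete and "A" in concrete:
        return "GA_dinucleotide"
    if concrete.count("G") / n >= 1 / 3:
        return "glycine_rich"
    if sum(concrete.count(ch) for ch in "STV") / n >= 0.6:
        return "ser_thr_val_rich"
    return None


def normalized_edit_distance(a: str, b: str) -> float:
    """Levenshtein distance divided by the longer pattern length."""
    if a == b:
        return 0.0
    dist = edlib.align(_concrete(a) or a, _concrete(b) or b, task="distance")["editDistance"]
    return dist / max(len(a), len(b))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _single_linkage(patterns: Sequence[str], threshold: float) -> list[list[int]]:
    uf = _UnionFind(len(patterns))
    for i in range(len(patterns)):
        for j in range(i + 1, len(patterns)):
            if normalized_edit_distance(patterns[i], patterns[j]) <= threshold:
                uf.union(i, j)
    clusters: dict[int, list[int]] = defaultdict(list)
    for i in range(len(patterns)):
        clusters[uf.find(i)].append(i)
    return [clusters[r] for r in sorted(clusters)]


def group_motifs(
    catalog: Sequence[MotifVariant],
    edit_threshold: float = EDIT_DISTANCE_THRESHOLD,
) -> tuple[list[MotifGroup], list[MotifVariant]]:
    """Cluster variants into groups and subgroups.

    Variants first bucket by :func:`composition_class`; within a bucket,
    single-linkage clustering at normalized edit distance
    <= ``edit_threshold`` yields the subgroups. Variants matching no
    composition class cluster by edit distance alone: multi-member clusters
    become their own groups, singletons are designated ``unassigned``.
    Groups partition the non-unassigned variants.
    """
    if not catalog:
        raise ValueError("catalog is empty")
    buckets: dict[Optional[str], list[MotifVariant]] = defaultdict(list)
    for variant in catalog:
        buckets[composition_class(variant.pattern)].append(variant)

    groups: list[MotifGroup] = []
    updated: dict[str, MotifVariant] = {v.variant_id: v for v in catalog}

    def add_group(group_id: str, members: list[MotifVariant], clusters: list[list[int]]) -> None:
        subgroup_members = []
        for k, idxs in enumerate(clusters, 1):
            subgroup_id = f"{group_id}.{k}"
            ids = tuple(sorted(members[i].variant_id for i in idxs))
            subgroup_members.append(ids)
            for vid in ids:
                updated[vid] = replace(updated[vid], group_id=group_id, subgroup_id=subgroup_id)
        description = min(v.pattern for v in members)
        groups.append(
            MotifGroup(
                group_id=group_id,
                description=description,
                member_variant_ids=tuple(sorted(v.variant_id for v in members)),
                subgroups=tuple(subgroup_members),
            )
        )

    for comp in sorted(k for k in buckets if k is not None):
        members = sorted(buckets[comp], key=lambda v: v.variant_id)
        clusters = _single_linkage([v.pattern for v in members], edit_threshold)
        add_group(f"G_{comp}", members, clusters)

    leftovers = sorted(buckets.get(None, []), key=lambda v: v.variant_id)
    if leftovers:
        clusters = _single_linkage([v.pattern for v in leftovers], edit_threshold)
        seq_group = 0
        for idxs in clusters:
            members = [leftovers[i] for i in idxs]
            if len(members) == 1:
                vid = members[0].variant_id
                updated[vid] = replace(updated[vid], group_id="unassigned", subgroup_id=None)
                continue
            seq_group += 1
            add_group(f"G_seq{seq_group:03d}", members, [list(range(len(members)))])

    return groups, [updated[v.variant_id] for v in catalog]


# ---------------------------------------------------------------------------
# description collapse


def _merge_pair(a: str, b: str) -> Optional[str]:
    """Merge two equal-length descriptions differing at <= 1 concrete position."""
    if len(a) != len(b):
        return None
    diffs = 0
    merged = []
    for ca, cb in zip(a, b):
        if ca == cb:
            merged.append(ca)
        elif ca in WILDCARDS or cb in WILDCARDS:
            merged.append("x")
        else:
            diffs += 1
            merged.append("x")
    if diffs > 1:
        return None
    n_wild = sum(1 for ch in merged if ch == "x")
    if 2 * n_wild > len(merged):  # keep the <=50% wildcard-density invariant
        return None
    return "".join(merged)


def _relabel_wildcards(pattern: str) -> str:
    """Alternate x/z over wildcard positions to mark them as independent."""
    out, k = [], 0
    for ch in pattern:
        if ch in WILDCARDS:
            out.append(WILDCARDS[k % 2])
            k += 1
        else:
            out.append(ch)
    return "".join(out)


def collapse_variant_descriptions(
    groups: Sequence[MotifGroup],
    catalog: Sequence[MotifVariant],
) -> list[CollapsedDescription]:
    """Collapse near-identical descriptions within each subgroup to fixpoint.

    Within a subgroup, variants of equal length that differ at a single
    position merge into one wildcard description; merging repeats until no
    pair merges. The collapse is idempotent and never increases the number
    of descriptions. Unassigned variants pass through unchanged (one
    description each, subgroup ``unassigned``).
    """
    by_id = {v.variant_id: v for v in catalog}
    collapsed: list[CollapsedDescription] = []
    grouped_ids: set[str] = set()
    for group in groups:
        for k, subgroup in enumerate(group.subgroups, 1):
            subgroup_id = f"{group.group_id}.{k}"
            grouped_ids.update(subgroup)
            pool: list[tuple[str, tuple[str, ...]]] = sorted(
                ((by_id[vid].pattern, (vid,)) for vid in subgroup)
            )
            changed = True
            while changed:
                changed = False
                for i in range(len(pool)):
                    for j in range(i + 1, len(pool)):
                        merged = _merge_pair(pool[i][0], pool[j][0])
                        if merged is not None:
                            members = tuple(sorted(set(pool[i][1] + pool[j][1])))
                            del pool[j], pool[i]
                            pool.append((merged, members))
                            pool.sort()
                            changed = True
                            break
                    if changed:
                        break
            for description, members in pool:
                collapsed.append(
                    CollapsedDescription(
                        description=_relabel_wildcards(description),
                        subgroup_id=subgroup_id,
                        member_variant_ids=members,
                    )
                )
    for variant in catalog:
        if variant.variant_id not in grouped_ids:
            collapsed.append(
                CollapsedDescription(
                    description=variant.pattern,
                    subgroup_id="unassigned",
                    member_variant_ids=(variant.variant_id,),
                )
            )
    collapsed.sort(key=lambda c: (c.subgroup_id, c.description))
    return collapsed


def collapsed_pattern_map(collapsed: Sequence[CollapsedDescription]) -> dict[str, str]:
    """Map each member variant_id to its collapsed description."""
    mapping: dict[str, str] = {}
    for desc in collapsed:
        for vid in desc.member_variant_ids:
            mapping[vid] = desc.description
    return mapping
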