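"""Synthetic spidroin datasets with full ground truth.

Real spidroins are ~100-residue conserved N-/C-terminal domains (the NTD
carrying the MAFAS anchor) flanking a long repetitive core built from
short motifs arranged into higher-order cassettes. The generator emulates
exactly that architecture from an explicit grammar, records every planted
motif and cassette occurrence, and so gives every pipeline stage a known
answer: truncation produces the five fragment categories, a paired
two-species draw plants a configurable motif-sharing fraction, and a Ct
table generator plants gland-specific fold changes with replicate noise.

Spacer (linker) residues are drawn from an alphabet disjoint from the
motif alphabet, so planted occurrences are exactly the occurrences a
painter can find: motifs can match neither inside spacers nor across
motif/spacer junctions.

All generators are reproducible: identical seeds give byte-identical
output. Independent random streams (template choice, spacer lengths,
spacer residues, noise) are spawned from one master seed, so changing one
grammar knob perturbs only its own stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .qpcr_expression import CtRecord
from .sequence_io import (
    CANONICAL_CLASSES,
    ProteinRecord,
    ReferenceDomainEntry,
    ReferenceDomainLibrary,
    occurrence_table_from_rows,
)
from .spidroin_screen import FragmentCategory

#: Residues used for spacers/linkers between motifs — disjoint from the
#: motif alphabet so spurious motif matches cannot arise.
SPACER_ALPHABET = "DEKR"

#: Residues allowed inside randomly drawn motif patterns.
MOTIF_ALPHABET = "GPASQYT"

# The NTD, CTD, spacer and motif alphabets are chosen to be mutually
# low-scoring under BLOSUM62, so a terminal-domain reference cannot hit
# the repetitive core (or the opposite terminus) by chance and truncation
# ground truth stays clean.
_NTD_ALPHABET = "ILVM"
_CTD_ALPHABET = "HNC"


def _fixed_residues(alphabet: str, length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(alphabet), size=length))


#: Default ~100-aa terminal-domain templates (NTD anchored by MAFAS).
DEFAULT_NTD = "MAFAS" + _fixed_residues(_NTD_ALPHABET, 95, seed=1902)
DEFAULT_CTD = _fixed_residues(_CTD_ALPHABET, 100, seed=2063)

#: Paper-inspired default motif pool: GPGPQGPS tandem-repeat unit, GPGQQ,
#: a poly-A tract, glycine-rich motifs, GGSGGGL, [GGP]3, and an S/T/V-rich
#: spacer-like motif.
DEFAULT_MOTIF_POOL = (
    "GPGPQGPS",
    "GPGQQ",
    "AAAAAA",
    "GYGGQ",
    "GGSGGGL",
    "GGPGGPGGP",
    "SVSVVSTTIS",
    "GGAGQGGY",
)

DEFAULT_CASSETTE_TEMPLATES = ((2, 0), (1, 0), (3, 4), (5, 3), (7, 6), (0, 1, 2))


@dataclass(frozen=True)
class SpidroinGrammar:
    """Generative grammar for one species' spidroin-like proteins."""

    ntd_template: str = DEFAULT_NTD
    ctd_template: str = DEFAULT_CTD
    motif_pool: tuple[str, ...] = DEFAULT_MOTIF_POOL
    cassette_templates: tuple[tuple[int, ...], ...] = DEFAULT_CASSETTE_TEMPLATES
    spacer_length_range: tuple[int, int] = (2, 12)  # within-cassette, <= 20
    inter_cassette_spacer_range: tuple[int, int] = (25, 40)  # > 20: separates cassettes
    repeats_per_gene: tuple[int, int] = (6, 12)  # cassette instances per gene
    background_alphabet: str = SPACER_ALPHABET
    class_label: str = "MaSp"

    def __post_init__(self) -> None:
        if "MAFAS" not in self.ntd_template[:100]:
            raise ValueError("NTD template must contain the MAFAS anchor")
        for motif in self.motif_pool:
            if not (4 <= len(motif) <= 41):
                raise ValueError(f"motif {motif!r} length outside [4, 41]")
        for template in self.cassette_templates:
            if not (2 <= len(template) <= 6):
                raise ValueError(f"cassette template {template} needs 2-6 motifs")
            if any(i >= len(self.motif_pool) for i in template):
                raise ValueError(f"cassette template {template} indexes outside pool")
        lo, hi = self.spacer_length_range
        if not (0 <= lo <= hi <= 20):
            raise ValueError("within-cassette spacers must lie in [0, 20]")
        lo, hi = self.inter_cassette_spacer_range
        if not (20 < lo <= hi):
            raise ValueError("inter-cassette spacers must exceed 20")
        if self.repeats_per_gene[0] < 0 or self.repeats_per_gene[0] > self.repeats_per_gene[1]:
            raise ValueError("invalid repeats_per_gene range")


@dataclass(frozen=True)
class PlantedMotif:
    pattern: str
    start: int
    end: int


@dataclass(frozen=True)
class PlantedCassette:
    component_patterns: tuple[str, ...]
    start: int
    end: int
    gaps: tuple[int, ...]


@dataclass(frozen=True)
class GroundTruthSlice:
    """Planted structure of one generated gene."""

    motif_occurrences: tuple[PlantedMotif, ...]
    cassette_occurrences: tuple[PlantedCassette, ...]
    class_label: str


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a paired two-species dataset."""

    slices: Mapping[str, GroundTruthSlice]  # gene_id -> slice
    species_of: Mapping[str, str]
    class_labels: Mapping[str, str]
    pool_a: tuple[str, ...]
    pool_b: tuple[str, ...]
    shared_types: frozenset
    planted_shared_fraction: float

    @property
    def realized_shared_fraction(self) -> float:
        total = len(set(self.pool_a) | set(self.pool_b))
        return len(self.shared_types) / total if total else 0.0

    def occurrence_table(self, species: str) -> pd.DataFrame:
        """Planted motif occurrences of one species as an occurrence table
        (``feature_id`` is the motif pattern)."""
        rows = []
        for gene_id, sl in self.slices.items():
            if self.species_of[gene_id] != species:
                continue
            for occ in sl.motif_occurrences:
                rows.append((species, gene_id, "motif", occ.pattern, occ.start, occ.end))
        return occurrence_table_from_rows(rows)


def generate_spidroin(
    grammar: SpidroinGrammar,
    seed: int,
    gene_id: str = "gene1",
    species: str = "SynA",
    template_indices: Optional[Sequence[int]] = None,
) -> tuple[ProteinRecord, GroundTruthSlice]:
    """Generate one spidroin: NTD + cassette instances with spacers + CTD.

    ``template_indices`` optionally fixes which cassette template each
    repeat instantiates (its length overrides ``repeats_per_gene``);
    otherwise templates are sampled uniformly. Every planted occurrence is
    checked against the emitted sequence before returning.
    """
    streams = np.random.SeedSequence(seed).spawn(3)
    rng_template = np.random.default_rng(streams[0])
    rng_spacer_len = np.random.default_rng(streams[1])
    rng_spacer_res = np.random.default_rng(streams[2])

    if template_indices is None:
        lo, hi = grammar.repeats_per_gene
        n_repeats = int(rng_template.integers(lo, hi + 1))
        template_indices = [
            int(rng_template.integers(0, len(grammar.cassette_templates)))
            for _ in range(n_repeats)
        ]

    def spacer(lo: int, hi: int) -> str:
        length = int(rng_spacer_len.integers(lo, hi + 1))
        return "".join(rng_spacer_res.choice(list(grammar.background_alphabet), size=length))

    parts = [grammar.ntd_template]
    pos = len(grammar.ntd_template)
    motifs: list[PlantedMotif] = []
    cassettes: list[PlantedCassette] = []
    for k, t_idx in enumerate(template_indices):
        if k > 0:
            gap = spacer(*grammar.inter_cassette_spacer_range)
            parts.append(gap)
            pos += len(gap)
        template = grammar.cassette_templates[t_idx]
        start = pos
        gaps: list[int] = []
        patterns: list[str] = []
        for j, m_idx in enumerate(template):
            if j > 0:
                link = spacer(*grammar.spacer_length_range)
                parts.append(link)
                pos += len(link)
                gaps.append(len(link))
            motif = grammar.motif_pool[m_idx]
            motifs.append(PlantedMotif(pattern=motif, start=pos, end=pos + len(motif)))
            patterns.append(motif)
            parts.append(motif)
            pos += len(motif)
        cassettes.append(
            PlantedCassette(
                component_patterns=tuple(patterns),
                start=start,
                end=pos,
                gaps=tuple(gaps),
            )
        )
    parts.append(grammar.ctd_template)
    residues = "".join(parts)

    for occ in motifs:  # substring consistency of the ground truth
        assert residues[occ.start : occ.end] == occ.pattern

    record = ProteinRecord(
        gene_id=gene_id,
        species=species,
        residues=residues,
        class_label=grammar.class_label
        if grammar.class_label in CANONICAL_CLASSES + ("SpL",)
        else None,
    )
    return record, GroundTruthSlice(
        motif_occurrences=tuple(motifs),
        cassette_occurrences=tuple(cassettes),
        class_label=grammar.class_label,
    )


def _draw_motif_pool(rng: np.random.Generator, n_types: int) -> list[str]:
    """Draw distinct random motif patterns, none a substring of another."""
    pool: list[str] = []
    while len(pool) < n_types:
        length = int(rng.integers(4, 11))
        pattern = "".join(rng.choice(list(MOTIF_ALPHABET), size=length))
        if any(pattern in other or other in pattern for other in pool):
            continue
        pool.append(pattern)
    return pool


def _pair_templates(n: int) -> tuple[tuple[int, ...], ...]:
    templates = [(i, i + 1) for i in range(0, n - 1, 2)]
    if n % 2:
        templates.append((n - 1, 0))
    return tuple(templates)


def generate_two_species(
    grammar_a: SpidroinGrammar,
    grammar_b: SpidroinGrammar,
    shared_fraction: float,
    n_genes: int,
    seed: int,
    n_motif_types: int = 60,
    species_a: str = "SynA",
    species_b: str = "SynB",
) -> tuple[list[ProteinRecord], list[ProteinRecord], GroundTruth]:
    """Paired datasets whose motif pools share an expected fraction of types.

    A universe of ``n_motif_types`` random patterns is drawn; each type is
    shared between the species with probability ``shared_fraction``
    (Bernoulli per type), the rest alternate between species. Each
    species' cassette templates pair up its pool and the per-gene repeats
    cycle through them, so every pooled type is realized at least once —
    planted presence equals pool membership.
    """
    if not (0.0 <= shared_fraction <= 1.0):
        raise ValueError("shared_fraction must lie in [0, 1]")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(4)
    rng_pool = np.random.default_rng(streams[0])
    rng_assign = np.random.default_rng(streams[1])
    gene_seed_root = streams[2]
    rng_order = np.random.default_rng(streams[3])

    universe = _draw_motif_pool(rng_pool, n_motif_types)
    shared_flags = rng_assign.random(n_motif_types) < shared_fraction
    pool_a: list[str] = []
    pool_b: list[str] = []
    shared_types: list[str] = []
    toggle = True
    for pattern, is_shared in zip(universe, shared_flags):
        if is_shared:
            pool_a.append(pattern)
            pool_b.append(pattern)
            shared_types.append(pattern)
        elif toggle:
            pool_a.append(pattern)
            toggle = False
        else:
            pool_b.append(pattern)
            toggle = True

    slices: dict[str, GroundTruthSlice] = {}
    species_of: dict[str, str] = {}
    class_labels: dict[str, str] = {}
    records_a: list[ProteinRecord] = []
    records_b: list[ProteinRecord] = []

    gene_seeds = gene_seed_root.spawn(2 * n_genes)
    for side, (species, grammar, pool, out) in enumerate(
        [
            (species_a, grammar_a, pool_a, records_a),
            (species_b, grammar_b, pool_b, records_b),
        ]
    ):
        templates = _pair_templates(len(pool))
        grammar_s = replace(
            grammar, motif_pool=tuple(pool), cassette_templates=templates
        )
        lo, _ = grammar_s.repeats_per_gene
        if n_genes * lo < len(templates):
            raise ValueError(
                "n_genes * min repeats_per_gene too small to realize every motif type"
            )
        order = list(rng_order.permutation(len(templates)))
        cursor = 0
        rng_rep = np.random.default_rng(rng_order.integers(0, 2**31 - 1))
        for g in range(n_genes):
            lo, hi = grammar_s.repeats_per_gene
            n_rep = int(rng_rep.integers(lo, hi + 1))
            idxs = []
            for _ in range(n_rep):
                idxs.append(order[cursor % len(order)])
                cursor += 1
            gene_id = f"{species}_g{g:03d}"
            label = CANONICAL_CLASSES[g % len(CANONICAL_CLASSES)]
            seed_g = int(gene_seeds[side * n_genes + g].generate_state(1)[0] % (2**31 - 1))
            record, sl = generate_spidroin(
                replace(grammar_s, class_label=label),
                seed=seed_g,
                gene_id=gene_id,
                species=species,
                template_indices=idxs,
            )
            out.append(record)
            slices[gene_id] = sl
            species_of[gene_id] = species
            class_labels[gene_id] = label

    truth = GroundTruth(
        slices=slices,
        species_of=species_of,
        class_labels=class_labels,
        pool_a=tuple(pool_a),
        pool_b=tuple(pool_b),
        shared_types=frozenset(shared_types),
        planted_shared_fraction=shared_fraction,
    )
    return records_a, records_b, truth


# ---------------------------------------------------------------------------
# fragment truncation harness


def truncate_for_fragments(
    record: ProteinRecord,
    mode: str,
    seed: int,
    cutoff: int = 100,
    margin: int = 10,
) -> tuple[ProteinRecord, FragmentCategory, bool]:
    """Truncate/obscure a complete gene and return the expected category.

    ``five_prime`` keeps the NTD and loses the CTD; ``three_prime`` the
    reverse; ``internal_gap`` keeps both termini and blanks >= 10 residues
    of the core with X; ``repetitive`` keeps only a middle slice of the
    core. Cut points stay at least ``margin`` residues away from the
    terminal windows. Returns ``(record, expected_category, gap_evidence)``.
    """
    length = len(record.residues)
    lo = cutoff + margin
    hi = length - cutoff - margin
    if hi - lo < 40:
        raise ValueError(f"gene {record.gene_id!r} too short to truncate (length {length})")
    rng = np.random.default_rng(seed)

    def rebuild(residues: str) -> ProteinRecord:
        return ProteinRecord(
            gene_id=record.gene_id,
            species=record.species,
            residues=residues,
            class_label=record.class_label,
            description=record.description,
        )

    if mode == "five_prime":
        cut = int(rng.integers(lo, hi + 1))
        return rebuild(record.residues[:cut]), FragmentCategory.FIVE_PRIME_END, False
    if mode == "three_prime":
        cut = int(rng.integers(lo, hi + 1))
        return rebuild(record.residues[cut:]), FragmentCategory.THREE_PRIME_END, False
    if mode == "internal_gap":
        gap_len = 12
        start = int(rng.integers(lo, hi - gap_len + 1))
        residues = record.residues[:start] + "X" * gap_len + record.residues[start + gap_len :]
        return rebuild(residues), FragmentCategory.INTERNAL_GAP, True
    if mode == "repetitive":
        p1 = int(rng.integers(lo, hi - 40 + 1))
        p2 = int(rng.integers(p1 + 40, hi + 1))
        return rebuild(record.residues[p1:p2]), FragmentCategory.REPETITIVE, False
    raise ValueError(f"unknown truncation mode {mode!r}")


# ---------------------------------------------------------------------------
# qPCR table generation


def generate_ct_table(
    targets: Sequence[str],
    tissues: Sequence[str],
    fold_changes: Mapping[str, Mapping[str, float]],
    noise_sd: float,
    seed: int,
    reference_gene: str = "RPL13a",
    calibrator_tissue: str = "legs",
    n_replicates: int = 3,
    base_ct_target: float = 24.0,
    base_ct_reference: float = 18.0,
    sample_id: str = "S1",
) -> list[CtRecord]:
    """Plant gland-specific fold changes into a replicate Ct table.

    ``Ct(target, tissue) = base - log2(fold) + N(0, noise_sd)`` per
    replicate; the reference gene is flat across tissues up to noise and
    the calibrator tissue's fold is fixed at 1 for every target.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    for target, per_tissue in fold_changes.items():
        for tissue, fold in per_tissue.items():
            if fold <= 0:
                raise ValueError(f"fold change for ({target}, {tissue}) must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    all_tissues = list(tissues)
    if calibrator_tissue not in all_tissues:
        all_tissues.append(calibrator_tissue)
    records = []
    for target in list(targets) + [reference_gene]:
        for tissue in all_tissues:
            if target == reference_gene:
                fold = 1.0
                base = base_ct_reference
            else:
                base = base_ct_target
                fold = 1.0 if tissue == calibrator_tissue else (
                    fold_changes.get(target, {}).get(tissue, 1.0)
                )
            clean = base - float(np.log2(fold))
            cts = tuple(
                float(np.clip(clean + rng.normal(0.0, noise_sd), 1e-3, 40.0))
                if noise_sd > 0
                else clean
                for _ in range(n_replicates)
            )
            records.append(
                CtRecord(
                    sample_id=sample_id,
                    tissue=tissue,
                    target_gene=target,
                    replicate_cts=cts,
                )
            )
    return records


# ---------------------------------------------------------------------------
# reference library derived from grammar templates


def class_templates(class_label: str) -> tuple[str, str]:
    """Class-specific NTD/CTD templates: the defaults with a 20-residue
    class-diagnostic block, so terminal homology can tell classes apart."""
    index = CANONICAL_CLASSES.index(class_label)
    ntd_block = _fixed_residues(_NTD_ALPHABET, 20, seed=7000 + index)
    ctd_block = _fixed_residues(_CTD_ALPHABET, 20, seed=8000 + index)
    ntd = DEFAULT_NTD[:40] + ntd_block + DEFAULT_NTD[60:]
    ctd = DEFAULT_CTD[:40] + ctd_block + DEFAULT_CTD[60:]
    return ntd, ctd


def grammar_for_class(class_label: str, **overrides) -> SpidroinGrammar:
    """Default grammar wired to one silk class's terminal templates."""
    ntd, ctd = class_templates(class_label)
    return SpidroinGrammar(
        ntd_template=ntd, ctd_template=ctd, class_label=class_label, **overrides
    )


def default_reference_library() -> ReferenceDomainLibrary:
    """Synthetic terminal-domain library: one NTD + CTD per canonical class.

    This is a synthetic stand-in built from the generator's templates, for
    screening generated data; it contains no real spidroin sequences.
    """
    entries = []
    for label in CANONICAL_CLASSES:
        ntd, ctd = class_templates(label)
        entries.append(ReferenceDomainEntry(f"{label}_NTD", "NTD", label, ntd))
        entries.append(ReferenceDomainEntry(f"{label}_CTD", "CTD", label, ctd))
    return ReferenceDomainLibrary(entries=tuple(entries))
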