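import numpy as np
import pytest

from silkmotif import motif_catalog as mc
from silkmotif.sequence_io import ProteinRecord

from conftest import random_core


def _record(gene_id, residues):
    return ProteinRecord(gene_id=gene_id, species="Cdar", residues=residues)


class TestMaskTerminalDomains:
    @pytest.mark.parametrize(
        "length, expected",
        [(300, (100, 200)), (150, (100, 100)), (201, (100, 101)), (50, (50, 50))],
    )
    def test_core_span(self, length, expected):
        record = _record("g", "L" * length)
        span = mc.mask_terminal_domains(record)
        assert (span.start, span.end) == expected

    def test_span_invariant_holds_for_any_length(self):
        for length in range(1, 400, 7):
            span = mc.mask_terminal_domains(_record("g", "L" * length))
            assert 0 <= span.start <= span.end <= length


class TestMotifVariantInvariants:
    def test_length_bounds(self):
        with pytest.raises(ValueError):
            mc.MotifVariant(variant_id="v", pattern="GPG")
        with pytest.raises(ValueError):
            mc.MotifVariant(variant_id="v", pattern="G" * 42)

    def test_wildcard_density_bound(self):
        with pytest.raises(ValueError):
            mc.MotifVariant(variant_id="v", pattern="xxxG")
        mc.MotifVariant(variant_id="v", pattern="xPxQ")  # exactly 50% is allowed


def discovery_oracle(cores, min_len, max_len, min_total):
    """Exhaustive enumeration of repeated substrings: every substring with
    enough leftmost-greedy non-overlapping hits, minus any pattern contained
    in a longer kept candidate with the identical occurrence set."""
    all_pos = {}
    for core_idx, (_, seq) in enumerate(cores):
        for length in range(min_len, max_len + 1):
            for i in range(len(seq) - length + 1):
                all_pos.setdefault(seq[i : i + length], []).append((core_idx, i))

    def nonoverlap(pattern):
        count, last_core, last_end = 0, None, -1
        for core_idx, i in sorted(all_pos[pattern]):
            if core_idx != last_core or i >= last_end:
                count += 1
                last_core, last_end = core_idx, i + len(pattern)
        return count

    candidates = {p for p in all_pos if nonoverlap(p) >= min_total}
    return {
        p
        for p in candidates
        if not any(
            len(q) > len(p) and p in q and len(all_pos[p]) == len(all_pos[q])
            for q in candidates
        )
    }


class TestDiscoverMotifs:
    def test_tandem_unit_is_discovered(self):
        cores = [("g", "GPGPQGPS" * 20)]
        patterns = {v.pattern for v in mc.discover_motifs(cores)}
        assert "GPGPQGPS" in patterns

    def test_repetition_free_core_gives_empty_catalog(self):
        cores = [("g", "ACDEFGHIKLMNPQRSTVWY")]  # no repeated 4-mer
        assert mc.discover_motifs(cores) == []

    def test_invalid_length_bounds_rejected(self):
        with pytest.raises(ValueError):
            mc.discover_motifs([("g", "GPGP" * 5)], min_len=0)
        with pytest.raises(ValueError):
            mc.discover_motifs([("g", "GPGP" * 5)], min_len=6, max_len=5)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle_on_random_cores(self, seed):
        rng = np.random.default_rng(seed)
        cores = [(f"g{i}", random_core(rng, 60)) for i in range(3)]
        found = {v.pattern for v in mc.discover_motifs(cores, min_len=4, max_len=8)}
        assert found == discovery_oracle(cores, 4, 8, 3)

    def test_raising_min_occurrences_never_enlarges_catalog(self):
        rng = np.random.default_rng(99)
        cores = [("g", random_core(rng, 120))]
        previous = None
        for min_total in (3, 4, 5, 6):
            patterns = {
                v.pattern
                for v in mc.discover_motifs(cores, max_len=8, min_total_occurrences=min_total)
            }
            if previous is not None:
                assert patterns <= previous
            previous = patterns

    def test_variant_ids_deterministic_by_length_then_pattern(self):
        cores = [("g", "GPGPQGPS" * 10 + "D" * 5 + "AAAA" * 6)]
        catalog = mc.discover_motifs(cores, max_len=10)
        keys = [(-len(v.pattern), v.pattern) for v in catalog]
        assert keys == sorted(keys)
        assert [v.variant_id for v in catalog] == [
            f"m{i:04d}" for i in range(1, len(catalog) + 1)
        ]


def painting_oracle(records, catalog, spans):
    """Naive per-variant sliding-window scan with greedy non-overlap."""
    hits = set()
    for record in records:
        span = spans[record.gene_id]
        core = record.residues[span.start : span.end]
        for variant in catalog:
            pattern = variant.pattern
            i = 0
            while i + len(pattern) <= len(core):
                window = core[i : i + len(pattern)]
                if all(
                    p in mc.WILDCARDS or p == c for p, c in zip(pattern, window)
                ):
                    hits.add((record.gene_id, variant.variant_id, span.start + i))
                    i += len(pattern)
                else:
                    i += 1
    return hits


class TestPaintSequences:
    def test_empty_catalog_gives_no_occurrences(self):
        record = _record("g", "L" * 300)
        span = mc.mask_terminal_domains(record)
        assert mc.paint_sequences([record], [], {"g": span}) == []

    def test_tandem_occurrences_at_expected_offsets(self):
        core = "GPGPQ" * 3
        record = _record("g", "L" * 100 + core + "L" * 100)
        span = mc.mask_terminal_domains(record)
        catalog = [mc.MotifVariant(variant_id="m1", pattern="GPGPQ")]
        occurrences = mc.paint_sequences([record], catalog, {"g": span})
        assert [(o.start, o.end) for o in occurrences] == [
            (100, 105),
            (105, 110),
            (110, 115),
        ]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sliding_window_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        records = [
            _record(f"g{i}", "L" * 100 + random_core(rng, 150) + "L" * 100)
            for i in range(3)
        ]
        spans = {r.gene_id: mc.mask_terminal_domains(r) for r in records}
        patterns = set()
        while len(patterns) < 6:
            pattern = random_core(rng, int(rng.integers(4, 7)))
            if int(rng.integers(0, 2)):
                i = int(rng.integers(0, len(pattern)))
                pattern = pattern[:i] + "x" + pattern[i + 1 :]
            patterns.add(pattern)
        catalog = [
            mc.MotifVariant(variant_id=f"m{i}", pattern=p)
            for i, p in enumerate(sorted(patterns))
        ]
        occurrences = mc.paint_sequences(records, catalog, spans)
        got = {(o.gene_id, o.variant_id, o.start) for o in occurrences}
        assert got == painting_oracle(records, catalog, spans)

    def test_no_occurrence_enters_masked_terminal_window(self, small_dataset):
        records, _ = small_dataset
        spans = {r.gene_id: mc.mask_terminal_domains(r) for r in records}
        cores = [
            (r.gene_id, r.residues[spans[r.gene_id].start : spans[r.gene_id].end])
            for r in records
        ]
        catalog = mc.discover_motifs(cores, max_len=12)
        for occ in mc.paint_sequences(records, catalog, spans):
            span = spans[occ.gene_id]
            assert span.start <= occ.start < occ.end <= span.end


class TestGroupMotifs:
    def _variants(self, patterns):
        return [
            mc.MotifVariant(variant_id=f"m{i}", pattern=p)
            for i, p in enumerate(patterns)
        ]

    def test_glycine_rich_patterns_group_together(self):
        groups, updated = mc.group_motifs(self._variants(["GYGGQ", "GGYG"]))
        by_id = {v.variant_id: v for v in updated}
        assert by_id["m0"].group_id == by_id["m1"].group_id == "G_glycine_rich"

    def test_identical_patterns_share_group_and_subgroup(self):
        _, updated = mc.group_motifs(self._variants(["SVSVV", "SVSVV"]))
        assert updated[0].group_id == updated[1].group_id
        assert updated[0].subgroup_id == updated[1].subgroup_id

    def test_grouping_is_a_partition(self):
        rng = np.random.default_rng(17)
        patterns = set()
        while len(patterns) < 25:
            patterns.add(random_core(rng, int(rng.integers(4, 12)), "GPASQYTVAL"))
        catalog = self._variants(sorted(patterns))
        groups, updated = mc.group_motifs(catalog)
        grouped = [vid for g in groups for vid in g.member_variant_ids]
        assert len(grouped) == len(set(grouped))  # no variant in two groups
        unassigned = {v.variant_id for v in updated if v.group_id == "unassigned"}
        assert set(grouped) | unassigned == {v.variant_id for v in catalog}
        assert set(grouped) & unassigned == set()
        for group in groups:  # subgroups partition each group
            in_subgroups = [vid for sub in group.subgroups for vid in sub]
            assert sorted(in_subgroups) == sorted(group.member_variant_ids)

    def test_empty_catalog_is_an_error(self):
        with pytest.raises(ValueError):
            mc.group_motifs([])


class TestCollapseDescriptions:
    def _collapse(self, patterns):
        catalog = [
            mc.MotifVariant(variant_id=f"m{i}", pattern=p)
            for i, p in enumerate(patterns)
        ]
        group = mc.MotifGroup(
            group_id="G_test",
            description=patterns[0],
            member_variant_ids=tuple(v.variant_id for v in catalog),
            subgroups=(tuple(v.variant_id for v in catalog),),
        )
        return mc.collapse_variant_descriptions([group], catalog)

    def test_single_position_family_collapses_to_wildcard(self):
        collapsed = self._collapse(["APGPQ", "GPGPQ", "SPGPQ"])
        assert [c.description for c in collapsed] == ["xPGPQ"]

    def test_single_member_subgroup_unchanged(self):
        collapsed = self._collapse(["GPGQQ"])
        assert [c.description for c in collapsed] == ["GPGQQ"]

    def test_collapse_is_idempotent(self):
        first = self._collapse(["APGPQ", "GPGPQ", "SPGPQ", "GAGAS", "GAGAT"])
        again = self._collapse([c.description for c in first])
        assert sorted(c.description for c in again) == sorted(
            c.description for c in first
        )

    def test_two_wildcards_use_independent_symbols(self):
        collapsed = self._collapse(["GAGPQ", "GTGPQ", "GAGPS"])
        (description,) = [c.description for c in collapsed]
        assert description == "GxGPz"
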