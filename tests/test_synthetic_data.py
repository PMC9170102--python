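import dataclasses

import numpy as np
import pytest

from silkmotif import cassette_catalog as cc
from silkmotif import motif_catalog as mc
from silkmotif import sharing_stats as sh
from silkmotif import spidroin_screen as scr
from silkmotif import synthetic_data as sd


class TestGenerateSpidroin:
    def test_identical_seeds_are_byte_identical(self, grammar):
        rec1, truth1 = sd.generate_spidroin(grammar, seed=5)
        rec2, truth2 = sd.generate_spidroin(grammar, seed=5)
        assert rec1.residues == rec2.residues
        assert truth1 == truth2
        rec3, _ = sd.generate_spidroin(grammar, seed=6)
        assert rec3.residues != rec1.residues

    def test_zero_repeats_gives_bare_termini(self, grammar):
        record, truth = sd.generate_spidroin(grammar, seed=1, template_indices=[])
        assert record.residues == grammar.ntd_template + grammar.ctd_template
        assert truth.motif_occurrences == () and truth.cassette_occurrences == ()

    @pytest.mark.parametrize("seed", range(0, 100, 7))
    def test_planted_occurrences_match_sequence_slices(self, grammar, seed):
        record, truth = sd.generate_spidroin(grammar, seed=seed)
        for occ in truth.motif_occurrences:
            assert record.residues[occ.start : occ.end] == occ.pattern
        for cassette in truth.cassette_occurrences:
            assert all(gap <= 20 for gap in cassette.gaps)

    def test_tandem_grammar_paints_twenty_copies(self):
        grammar = sd.SpidroinGrammar(
            motif_pool=("GPGPQGPS",),
            cassette_templates=((0, 0),),
            spacer_length_range=(0, 0),
            repeats_per_gene=(10, 10),
        )
        record, truth = sd.generate_spidroin(grammar, seed=3, gene_id="g")
        span = mc.mask_terminal_domains(record)
        catalog = [mc.MotifVariant(variant_id="m1", pattern="GPGPQGPS")]
        painted = mc.paint_sequences([record], catalog, {"g": span})
        assert len(painted) == len(truth.motif_occurrences) == 20

    def test_grammar_bounds_are_enforced(self):
        with pytest.raises(ValueError):
            sd.SpidroinGrammar(motif_pool=("GPG",))  # motif below 4 residues
        with pytest.raises(ValueError):
            sd.SpidroinGrammar(cassette_templates=((0,),))  # 1-motif cassette
        with pytest.raises(ValueError):
            sd.SpidroinGrammar(spacer_length_range=(0, 25))  # spacer > 20
        with pytest.raises(ValueError):
            sd.SpidroinGrammar(ntd_template="L" * 100)  # missing MAFAS anchor


class TestPaintingRecoversPlantedTruth:
    def test_painting_equals_planted_occurrence_set(self, small_dataset, grammar):
        records, truths = small_dataset
        spans = {r.gene_id: mc.mask_terminal_domains(r) for r in records}
        catalog = [
            mc.MotifVariant(variant_id=f"m{i}", pattern=p)
            for i, p in enumerate(grammar.motif_pool)
        ]
        painted = mc.paint_sequences(records, catalog, spans)
        pattern_of = {v.variant_id: v.pattern for v in catalog}
        got = {(o.gene_id, pattern_of[o.variant_id], o.start, o.end) for o in painted}
        planted = {
            (gene_id, occ.pattern, occ.start, occ.end)
            for gene_id, truth in truths.items()
            for occ in truth.motif_occurrences
        }
        assert got == planted

    def test_cassette_detection_recovers_planted_cassettes(self, small_dataset):
        records, truths = small_dataset
        occurrences = [
            mc.MotifOccurrence("SynA", gene_id, occ.pattern, occ.start, occ.end)
            for gene_id, truth in truths.items()
            for occ in truth.motif_occurrences
        ]
        _, found = cc.detect_cassettes(occurrences, min_type_support=2)
        planted = {
            (gene_id, cassette.start, cassette.end, cassette.component_patterns)
            for gene_id, truth in truths.items()
            for cassette in truth.cassette_occurrences
        }
        got = {
            (o.gene_id, o.start, o.end, tuple(m.variant_id for m in o.component_occurrences))
            for o in found
        }
        # every detected cassette is planted, and every planted cassette whose
        # template recurs at least twice is detected
        assert got <= planted
        from collections import Counter

        support = Counter(p[3] for p in planted)
        expected = {p for p in planted if support[p[3]] >= 2}
        assert got == expected


class TestTwoSpecies:
    def test_forced_full_sharing_has_no_private_types(self, grammar):
        _, _, truth = sd.generate_two_species(grammar, grammar, 1.0, 6, seed=2, n_motif_types=30)
        summary = sh.summarize_sharing(
            truth.occurrence_table("SynA"), truth.occurrence_table("SynB"), "motif"
        )
        assert summary.private_a == summary.private_b == 0
        assert summary.shared == summary.total_types

    def test_zero_sharing_has_no_shared_types(self, grammar):
        _, _, truth = sd.generate_two_species(grammar, grammar, 0.0, 6, seed=2, n_motif_types=30)
        summary = sh.summarize_sharing(
            truth.occurrence_table("SynA"), truth.occurrence_table("SynB"), "motif"
        )
        assert summary.shared == 0

    def test_planted_fraction_recovered_within_binomial_error(self, grammar):
        _, _, truth = sd.generate_two_species(
            grammar, grammar, 0.3, 20, seed=11, n_motif_types=200
        )
        summary = sh.summarize_sharing(
            truth.occurrence_table("SynA"), truth.occurrence_table("SynB"), "motif"
        )
        recovered = summary.shared / summary.total_types
        se = np.sqrt(0.3 * 0.7 / 200)
        assert abs(recovered - 0.3) <= 3 * se
        # planted presence equals pool membership
        assert summary.total_types == 200

    def test_invalid_parameters_rejected(self, grammar):
        with pytest.raises(ValueError):
            sd.generate_two_species(grammar, grammar, 1.5, 6, seed=1)
        with pytest.raises(ValueError):
            sd.generate_two_species(grammar, grammar, 0.5, 0, seed=1)

    def test_reproducible_given_seed(self, grammar):
        a1, b1, t1 = sd.generate_two_species(grammar, grammar, 0.4, 4, seed=9, n_motif_types=24)
        a2, b2, t2 = sd.generate_two_species(grammar, grammar, 0.4, 4, seed=9, n_motif_types=24)
        assert [r.residues for r in a1] == [r.residues for r in a2]
        assert [r.residues for r in b1] == [r.residues for r in b2]
        assert t1.shared_types == t2.shared_types


class TestTruncation:
    @pytest.mark.parametrize("mode, expected", [
        ("five_prime", scr.FragmentCategory.FIVE_PRIME_END),
        ("three_prime", scr.FragmentCategory.THREE_PRIME_END),
        ("internal_gap", scr.FragmentCategory.INTERNAL_GAP),
        ("repetitive", scr.FragmentCategory.REPETITIVE),
    ])
    def test_expected_category_is_reported(self, grammar, mode, expected):
        record, _ = sd.generate_spidroin(grammar, seed=4, gene_id="g")
        truncated, category, gap = sd.truncate_for_fragments(record, mode, seed=1)
        assert category == expected
        assert gap == (mode == "internal_gap")
        if mode == "internal_gap":
            assert scr.has_internal_gap(truncated)

    def test_too_short_sequence_is_an_error(self, grammar):
        record, _ = sd.generate_spidroin(grammar, seed=4, template_indices=[0])
        with pytest.raises(ValueError):
            sd.truncate_for_fragments(record, "five_prime", seed=1)

    def test_unknown_mode_is_an_error(self, grammar):
        record, _ = sd.generate_spidroin(grammar, seed=4)
        with pytest.raises(ValueError):
            sd.truncate_for_fragments(record, "sideways", seed=1)

    def test_end_to_end_categorization_matches_expected(self, grammar, reference_library):
        classes = list(sd.CANONICAL_CLASSES)
        correct = total = 0
        for i in range(10):
            record, _ = sd.generate_spidroin(
                sd.grammar_for_class(classes[i % 7]), seed=300 + i, gene_id=f"g{i}"
            )
            for mode in ("five_prime", "three_prime", "internal_gap", "repetitive"):
                truncated, expected, _ = sd.truncate_for_fragments(record, mode, seed=13 * i + 1)
                hits = scr.local_homology_search([truncated], reference_library)
                got = scr.categorize_fragment(
                    truncated, hits, scr.has_internal_gap(truncated)
                )
                total += 1
                correct += got == expected
        assert correct == total


class TestCtGenerator:
    def test_flat_fold_without_noise_gives_unit_rq_everywhere(self):
        from silkmotif import qpcr_expression as qp

        records = sd.generate_ct_table(["tgt"], ["MA", "FL", "legs"], {}, noise_sd=0.0, seed=1)
        for q in qp.relative_quantities(records):
            assert q.rq == pytest.approx(1.0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            sd.generate_ct_table(["tgt"], ["MA"], {}, noise_sd=-0.1, seed=1)

    def test_non_positive_fold_rejected(self):
        with pytest.raises(ValueError):
            sd.generate_ct_table(["tgt"], ["MA"], {"tgt": {"MA": 0.0}}, noise_sd=0.1, seed=1)

    def test_reproducible_given_seed(self):
        a = sd.generate_ct_table(["tgt"], ["MA", "legs"], {"tgt": {"MA": 2.0}}, 0.2, seed=7)
        b = sd.generate_ct_table(["tgt"], ["MA", "legs"], {"tgt": {"MA": 2.0}}, 0.2, seed=7)
        assert a == b
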