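import math

import numpy as np
import pytest

from loopcraft.errors import DesignError
from loopcraft.hotspots import LoopRegion
from loopcraft.io_formats import AlignmentRecord, ProteinRecord
from loopcraft.library_design import (
    LINKER_SETS,
    alanine_scan,
    amino_acid_coverage,
    clones_for_coverage,
    consensus_library,
    fillup_insertions,
    lili_library,
    nested_deletions,
    nnk_coverage,
    nnk_saturation,
)
from loopcraft.variant_model import parse_variant_name


class TestAlanineScan:
    def test_both_loops_give_42_variants(self, cdo_ref, loops):
        lib = alanine_scan(cdo_ref, loops)
        assert len(lib) == sum(len(r) for r in loops) == 42
        assert "H240A" in lib.names

    def test_wildtype_alanine_goes_to_glycine(self, cdo_ref, loops):
        lib = alanine_scan(cdo_ref, loops)
        for v in lib:
            assert v.alt == ("G" if v.ref == "A" else "A")
        assert "A283G" in lib.names

    def test_single_residue_ala_region(self):
        ref = ProteinRecord(id="r", sequence="MAV")
        lib = alanine_scan(ref, [LoopRegion("x", 2, 2)])
        assert lib.names == ["A2G"]

    def test_size_always_equals_region_length(self, cdo_ref):
        rng = np.random.default_rng(1)
        for _ in range(10):
            start = int(rng.integers(1, 400))
            end = start + int(rng.integers(0, 30))
            lib = alanine_scan(cdo_ref, [LoopRegion("x", start, end)])
            assert len(lib) == end - start + 1


class TestNnkCoverage:
    def test_boundaries(self):
        assert nnk_coverage(32, 0) == 0.0
        assert nnk_coverage(1, 5) == 1.0

    def test_92_clones_almost_95_percent(self):
        assert nnk_coverage(32, 92) == pytest.approx(1 - (31 / 32) ** 92, abs=1e-12)
        assert nnk_coverage(32, 92) == pytest.approx(0.946, abs=1e-3)

    def test_monotone_concave_to_one(self):
        vals = [nnk_coverage(32, n) for n in range(0, 400)]
        diffs = np.diff(vals)
        assert (diffs > 0).all()
        assert (np.diff(diffs) < 0).all()
        assert nnk_coverage(32, 5000) == pytest.approx(1.0, abs=1e-12)

    def test_clones_for_coverage_is_exact_inverse(self):
        for target in (0.5, 0.9, 0.946, 0.95, 0.99):
            n = clones_for_coverage(32, target)
            assert nnk_coverage(32, n) >= target
            assert nnk_coverage(32, n - 1) < target

    def test_known_inverses(self):
        assert clones_for_coverage(32, 0.95) == 95  # ln(0.05)/ln(31/32) ~ 94.4
        assert clones_for_coverage(32, 0.946) <= 92
        assert clones_for_coverage(2, 0.5) == 1

    def test_target_out_of_domain(self):
        with pytest.raises(ValueError):
            clones_for_coverage(32, 1.0)

    def test_amino_acid_coverage_exceeds_codon_coverage(self):
        # NNK codon multiplicities make residue-level coverage ~99% at N=92
        assert amino_acid_coverage(92) > 0.99 > nnk_coverage(32, 92)

    def test_saturation_designs(self, cdo_ref):
        designs = nnk_saturation(cdo_ref, [282, 278], clones=92)
        assert [d.position for d in designs] == [278, 282]
        assert all(d.codons == 32 and d.stop_codons == 1 for d in designs)
        sized = nnk_saturation(cdo_ref, [282], target_coverage=0.95)
        assert sized[0].clones == 95


class TestConsensusLibrary:
    def test_engineered_mismatch_and_gap_rules(self, family):
        reference, alignment, regions = family
        lib = consensus_library(alignment, reference.id, regions)
        kinds = {v.name: v.kind for v in lib}
        # positions engineered in the family fixture: 236/278 shared-residue
        # mismatches, 251 homolog-gapped
        assert {v.start for v in lib} == {236, 251, 278}
        assert kinds[[n for n in lib.names if n.startswith("E251")][0]] == "deletion"
        for v in lib:
            parse_variant_name(v.name, reference)

    def test_reference_matching_consensus_yields_nothing(self):
        rows = tuple((f"s{i}", "MKVLTAPLEA") for i in range(6))
        aln = AlignmentRecord(records=rows)
        lib = consensus_library(aln, "s0", [LoopRegion("x", 2, 9)])
        assert len(lib) == 0

    def test_single_engineered_mismatch(self):
        # all homologs share G where the reference has F
        rows = (("ref", "MKVFTAPLEA"),) + tuple(
            (f"h{i}", "MKVGTAPLEA") for i in range(8)
        )
        aln = AlignmentRecord(records=rows)
        lib = consensus_library(aln, "ref", [LoopRegion("x", 1, 10)])
        assert lib.names == ["F4G"]


class TestFillupInsertions:
    def _aln(self):
        # reference has a 4-column gap after N279-like position; donor_a fills
        # all 4 (ADKE), donor_b fills 2 (AD)
        return AlignmentRecord(
            records=(
                ("ref", "MKVN----DPLE"),
                ("donor_a", "MKVNADKEDPLE"),
                ("donor_b", "MKVNAD--DPLE"),
                ("thin", "MKVN----DPLE"),
            )
        )

    def test_stepwise_pairs_from_best_donor(self):
        aln = self._aln()
        lib = fillup_insertions(aln, "ref", LoopRegion("loop", 3, 6), n_donors=1, step=2)
        assert lib.names == ["N4_D5insAD", "N4_D5insADKE"]

    def test_two_donors_deduplicated(self):
        aln = self._aln()
        lib = fillup_insertions(aln, "ref", LoopRegion("loop", 3, 6), n_donors=2, step=2)
        assert lib.names == ["N4_D5insAD", "N4_D5insADKE"]  # donor_b's AD collapses

    def test_odd_total_gets_final_full_variant(self):
        aln = AlignmentRecord(
            records=(("ref", "MKVN---DPLE"), ("donor", "MKVNADKDPLE"))
        )
        lib = fillup_insertions(aln, "ref", LoopRegion("loop", 3, 5), n_donors=1, step=2)
        assert lib.names == ["N4_D5insAD", "N4_D5insADK"]

    def test_step_one_produces_single_residue_insertion(self):
        aln = AlignmentRecord(
            records=(("ref", "MKVN-DPLE"), ("donor", "MKVNEDPLE"))
        )
        lib = fillup_insertions(aln, "ref", LoopRegion("loop", 3, 5), step=1)
        assert "N4_D5insE" in lib.names

    def test_no_gap_columns_gives_empty_library(self, caplog):
        aln = AlignmentRecord(records=(("ref", "MKVLTA"), ("h", "MKVLTA")))
        lib = fillup_insertions(aln, "ref", LoopRegion("loop", 2, 5))
        assert len(lib) == 0


class TestNestedDeletions:
    def test_nine_variants_with_printed_names(self, cdo_ref):
        lib = nested_deletions(cdo_ref, [251, 257, 283])
        assert len(lib) == 9
        assert {"A283del", "F282_L284del", "D280_Q286del"} <= set(lib.names)

    def test_deletion_lengths_match_half_widths(self, cdo_ref):
        lib = nested_deletions(cdo_ref, [251, 283], half_widths=(0, 2))
        lengths = sorted({v.end - v.start + 1 for v in lib})
        assert lengths == [1, 5]

    def test_out_of_bounds_window_names_center(self, cdo_ref):
        with pytest.raises(DesignError, match="center 2"):
            nested_deletions(cdo_ref, [2], half_widths=(3,))


class TestLili:
    def test_default_enumeration_60_unique(self, cdo_ref):
        lib = lili_library(cdo_ref, [257, 278, 286])
        assert len(lib) == 60 == len(set(lib.names))
        assert {"Q286_A287insGSGSG", "F278_N279insPAPAPA", "F278_N279insGP"} <= set(lib.names)

    def test_linker_prefix_property(self):
        for lset in LINKER_SETS:
            for L in range(1, 8):
                assert lset.linker(L + 1).startswith(lset.linker(L))

    def test_all_generator_outputs_validate_and_round_trip(self, cdo_ref, family, loops):
        reference, alignment, regions = family
        libs = [
            alanine_scan(cdo_ref, loops),
            nested_deletions(cdo_ref, [251, 257, 283]),
            lili_library(cdo_ref, [257, 278, 286]),
            consensus_library(alignment, reference.id, regions),
            fillup_insertions(alignment, reference.id, regions[1], step=1),
        ]
        for lib in libs:
            for v in lib:
                v.validate(cdo_ref)
                assert parse_variant_name(v.name, cdo_ref) == v
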