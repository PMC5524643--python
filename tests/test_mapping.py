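import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crisprcoev.catalog import build_global_catalog
from crisprcoev.io import DatedSequenceRecord, OrfAnnotation
from crisprcoev.mapping import (
    PfsEligibilityError,
    ProtospacerHit,
    build_motif,
    classify_hit,
    extract_pam,
    extract_pfs,
    find_protospacers,
    match_counts,
    phage_targeting_labels,
)
from crisprcoev.sequtils import random_dna, revcomp

rng0 = np.random.default_rng(0)


def _plant(genome, pos0, insert):
    return genome[:pos0] + insert + genome[pos0 + len(insert):]


class TestFindProtospacers:
    def test_absent_spacer_yields_no_hits(self):
        rng = np.random.default_rng(1)
        genome = random_dna(rng, 1000)
        spacer = "A" * 30  # long homopolymer absent from this draw
        assert find_protospacers(spacer, genome.replace("AAAA", "ACGT"), 0) == []

    def test_forward_plant_recovered_with_exact_coordinates(self):
        rng = np.random.default_rng(2)
        genome, spacer = random_dna(rng, 1000), random_dna(rng, 30)
        genome = _plant(genome, 100, spacer)  # 0-based 100 -> 1-based 101
        (hit,) = find_protospacers(spacer, genome, 0)
        assert (hit.start, hit.end, hit.strand, hit.mismatches) == (101, 130, "+", 0)

    def test_reverse_complement_plant_reported_on_minus_strand(self):
        rng = np.random.default_rng(3)
        genome, spacer = random_dna(rng, 1000), random_dna(rng, 30)
        genome = _plant(genome, 199, revcomp(spacer))
        (hit,) = find_protospacers(spacer, genome, 0)
        assert (hit.start, hit.end, hit.strand) == (200, 229, "-")

    def test_genome_shorter_than_spacer_is_empty_not_error(self):
        assert find_protospacers("ACGTACGTACGTACGTACGT", "ACGT", 0) == []

    def test_mismatch_budget_reports_hamming_distance(self):
        rng = np.random.default_rng(4)
        genome, spacer = random_dna(rng, 500), random_dna(rng, 30)
        mutated = "T" + spacer[1:] if spacer[0] != "T" else "A" + spacer[1:]
        genome = _plant(genome, 50, mutated)
        hits = find_protospacers(spacer, genome, 2)
        assert any(h.start == 51 and h.mismatches == 1 for h in hits)

    def test_no_spurious_hits_for_spacers_drawn_from_random_genome(self):
        # ~4^10-unique regime: every 30-mer drawn from a random genome should
        # map back only to its own planted footprint
        rng = np.random.default_rng(5)
        genome = random_dna(rng, 50_000)
        starts = rng.choice(50_000 - 30, size=20, replace=False)
        for s0 in starts:
            spacer = genome[s0 : s0 + 30]
            hits = find_protospacers(spacer, genome, 0)
            assert [(h.start, h.strand) for h in hits] == [(int(s0) + 1, "+")]

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), budget=st.integers(0, 2))
    def test_strand_symmetry_under_genome_reverse_complement(self, seed, budget):
        rng = np.random.default_rng(seed)
        genome = random_dna(rng, 300)
        s0 = int(rng.integers(0, 300 - 20))
        spacer = genome[s0 : s0 + 20]
        fwd = find_protospacers(spacer, genome, budget)
        rev = find_protospacers(spacer, revcomp(genome), budget)
        L = len(genome)
        mirrored = {
            (L - h.end + 1, L - h.start + 1, "-" if h.strand == "+" else "+", h.mismatches)
            for h in fwd
        }
        assert {(h.start, h.end, h.strand, h.mismatches) for h in rev} == mirrored


class TestFlankExtraction:
    def test_pam_downstream_of_forward_hit(self):
        rng = np.random.default_rng(6)
        genome, spacer = random_dna(rng, 300), random_dna(rng, 30)
        genome = _plant(genome, 100, spacer + "ACGTGTAAAA")
        (hit,) = find_protospacers(spacer, genome, 0)
        assert extract_pam(hit, genome, 10) == "ACGTGTAAAA"

    def test_pam_of_minus_hit_is_revcomp_of_upstream(self):
        rng = np.random.default_rng(7)
        genome, spacer = random_dna(rng, 300), random_dna(rng, 30)
        flank = "ACGTGTAAAA"
        genome = _plant(genome, 100, revcomp(flank) + revcomp(spacer))
        (hit,) = find_protospacers(spacer, genome, 0)
        assert hit.strand == "-"
        assert extract_pam(hit, genome, 10) == flank

    def test_pam_truncated_at_genome_end(self):
        rng = np.random.default_rng(8)
        spacer = random_dna(rng, 30)
        genome = random_dna(rng, 50) + spacer + "ACGT"
        (hit,) = find_protospacers(spacer, genome, 0)
        assert extract_pam(hit, genome, 10) == "ACGT"

    def test_pfs_from_plus_strand_orf_reads_forward_sense(self):
        rng = np.random.default_rng(9)
        genome, spacer = random_dna(rng, 400), random_dna(rng, 30)
        genome = _plant(genome, 150, spacer)
        orf = OrfAnnotation("genome", "orfA", 101, 300, "+")
        (hit,) = find_protospacers(spacer, genome, 0)
        up, down = extract_pfs(hit, genome, [orf], 5, 5)
        assert up == genome[145:150] and down == genome[180:185]

    def test_pfs_from_minus_strand_orf_reads_revcomp_sense(self):
        rng = np.random.default_rng(10)
        genome = random_dna(rng, 400)
        orf = OrfAnnotation("genome", "orfB", 101, 300, "-")
        mrna = revcomp(genome[100:300])
        spacer = mrna[60:90]  # spacer matches the mRNA sense
        (hit,) = find_protospacers(spacer, genome, 0)
        assert hit.strand == "-"
        up, down = extract_pfs(hit, genome, [orf], 5, 5)
        assert up == mrna[55:60] and down == mrna[90:95]

    def test_intergenic_hit_is_not_pfs_eligible(self):
        rng = np.random.default_rng(11)
        genome, spacer = random_dna(rng, 400), random_dna(rng, 30)
        genome = _plant(genome, 150, spacer)
        (hit,) = find_protospacers(spacer, genome, 0)
        with pytest.raises(PfsEligibilityError):
            extract_pfs(hit, genome, [OrfAnnotation("genome", "o", 350, 390, "+")])


class TestMotif:
    def test_planted_suffix_recovered_as_consensus(self):
        rng = np.random.default_rng(12)
        flanks = [random_dna(rng, 5) + "TAAAA" for _ in range(20)]
        assert build_motif(flanks, 0.8).consensus == "NNNNNTAAAA"

    def test_single_flank_is_its_own_consensus(self):
        m = build_motif(["AAAAAAAAAA"])
        assert m.consensus == "AAAAAAAAAA" and m.n_flanks == 1

    def test_total_disagreement_gives_all_n(self):
        assert build_motif(["ACACA", "CACAC"], 0.8).consensus == "NNNNN"

    def test_column_sums_equal_contributing_flanks(self):
        rng = np.random.default_rng(13)
        flanks = [random_dna(rng, 8) for _ in range(17)]
        m = build_motif(flanks)
        assert (m.counts.sum(axis=0) == 17).all()

    def test_short_boundary_flank_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            m = build_motif(["ACGTACGTAC", "ACG"])
        assert m.n_flanks == 1

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            build_motif([])


class TestClassifyHit:
    def _hit(self, start, end, strand="+"):
        return ProtospacerHit("s", "g", start, end, strand, 0)

    def test_terminal_midpoint_lands_in_fourth_quadrant(self):
        hit = classify_hit(self._hit(39_986, 40_014), 50_666, [])
        assert hit.quadrant == 4 and hit.region == "intergenic"

    def test_hit_between_orfs_is_intergenic(self):
        orfs = [OrfAnnotation("g", "a", 1, 90, "+"), OrfAnnotation("g", "b", 200, 300, "-")]
        assert classify_hit(self._hit(100, 129), 1000, orfs).region == "intergenic"

    def test_overlap_tie_goes_to_larger_overlap(self):
        # footprint 100..129: 5 nt inside orf a (ends 104), 25 nt inside orf b
        orfs = [OrfAnnotation("g", "a", 50, 104, "+"), OrfAnnotation("g", "b", 105, 300, "-")]
        hit = classify_hit(self._hit(100, 129), 1000, orfs)
        assert hit.orf_overlap == "b" and hit.region == "ORF"

    def test_coding_strand_flag_tracks_orf_sense(self):
        orfs = [OrfAnnotation("g", "a", 50, 300, "-")]
        assert classify_hit(self._hit(100, 129, "-"), 1000, orfs).coding_strand_hit
        assert not classify_hit(self._hit(100, 129, "+"), 1000, orfs).coding_strand_hit

    @pytest.mark.parametrize(
        "mid,expected", [(1, 1), (12_666, 1), (12_667, 2), (25_333, 2), (37_999, 3), (50_666, 4)]
    )
    def test_quadrant_arithmetic(self, mid, expected):
        hit = classify_hit(self._hit(mid, mid), 50_666, [])
        assert hit.quadrant == expected


class TestMatchCounts:
    def _setup(self):
        rng = np.random.default_rng(14)
        genome = random_dna(rng, 2000)
        in_phage = [genome[100:130], genome[500:530]]
        elsewhere = random_dna(rng, 30)  # targets a different phage only
        other_genome = _plant(random_dna(rng, 2000), 50, elsewhere)
        backbone = random_dna(rng, 30)
        cat = build_global_catalog(
            [("B1", 2009, {"C1": [backbone] + in_phage + [elsewhere]}),
             ("B2", 2010, {"C1": [backbone]})]
        )
        phages = [
            DatedSequenceRecord("P", genome, 2009),
            DatedSequenceRecord("Q", other_genome, 2010),
        ]
        return cat, phages

    def test_counts_against_one_phage_and_dataset(self):
        cat, phages = self._setup()
        targeting = phage_targeting_labels(cat, phages)
        assert match_counts(cat, "B1", phages[0], targeting) == (2, 3)

    def test_bacterium_without_targeting_spacers_is_zero_zero(self):
        cat, phages = self._setup()
        targeting = phage_targeting_labels(cat, phages)
        assert match_counts(cat, "B2", phages[0], targeting) == (0, 0)

    def test_second_number_invariant_across_phages(self):
        cat, phages = self._setup()
        targeting = phage_targeting_labels(cat, phages)
        seconds = {match_counts(cat, "B1", p, targeting)[1] for p in phages}
        assert seconds == {3}
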