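import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crisprcoev.catalog import (
    build_global_catalog,
    classify_conserved_variable,
    extract_array,
)
from crisprcoev.sequtils import random_dna

REPEAT = "GTTGTAGTTCCCTATCTCATTTCGCAGTGCTACAAT"


def _array_seq(spacers, repeat=REPEAT):
    return repeat + "".join(s + repeat for s in spacers)


class TestExtractArray:
    def test_planted_spacers_recovered_in_order(self):
        rng = np.random.default_rng(0)
        s1, s2 = random_dna(rng, 30), random_dna(rng, 30)
        assert extract_array(_array_seq([s1, s2]), REPEAT) == [s1, s2]

    def test_repeat_with_one_mismatch_still_found(self):
        rng = np.random.default_rng(1)
        s1, s2 = random_dna(rng, 30), random_dna(rng, 30)
        degenerate = "A" + REPEAT[1:] if REPEAT[0] != "A" else "C" + REPEAT[1:]
        seq = REPEAT + s1 + degenerate + s2 + REPEAT
        assert extract_array(seq, REPEAT, max_repeat_mismatch=1) == [s1, s2]

    def test_degenerate_segment_outside_range_is_skipped(self):
        # mirrors a 114-nt stretch of degenerate repeats mid-array: the
        # segment is skipped with a warning and numbering resumes after it
        rng = np.random.default_rng(2)
        s1, s2 = random_dna(rng, 30), random_dna(rng, 30)
        junk = random_dna(rng, 114)
        seq = REPEAT + s1 + REPEAT + junk + REPEAT + s2 + REPEAT
        with pytest.warns(UserWarning, match="114 nt"):
            spacers = extract_array(seq, REPEAT, spacer_len_range=(20, 50))
        assert spacers == [s1, s2]

    def test_no_repeat_occurrence_is_an_error(self):
        with pytest.raises(ValueError, match="no repeat"):
            extract_array("ACGT" * 30, REPEAT)

    def test_short_repeat_rejected(self):
        with pytest.raises(ValueError, match="18"):
            extract_array("ACGT" * 30, "ACGTACGT")


class TestGlobalCatalog:
    def test_oldest_strain_numbered_from_conserved_end(self):
        rng = np.random.default_rng(3)
        spacers = [random_dna(rng, 30) for _ in range(37)]
        cat = build_global_catalog([("B425", 2007, {"C1": spacers})])
        assert list(cat.pools["C1"]) == [f"C1s{i}" for i in range(1, 38)]
        assert cat.pools["C1"]["C1s1"] == spacers[0]
        assert cat.pools["C1"]["C1s37"] == spacers[-1]

    def test_identical_second_isolate_adds_no_labels(self):
        rng = np.random.default_rng(4)
        spacers = [random_dna(rng, 30) for _ in range(5)]
        cat = build_global_catalog(
            [("old", 2007, {"C1": spacers}), ("new", 2010, {"C1": spacers})]
        )
        assert len(cat.pools["C1"]) == 5
        assert cat.arrays["old"]["C1"] == cat.arrays["new"]["C1"]

    def test_shared_core_then_unique_additions_in_year_order(self):
        rng = np.random.default_rng(5)
        core = [random_dna(rng, 30) for _ in range(3)]
        uniq = {y: random_dna(rng, 30) for y in (2009, 2010, 2011)}
        isolates = [
            (f"iso{y}", y, {"C1": core + [uniq[y]]}) for y in (2011, 2009, 2010)
        ]
        cat = build_global_catalog(isolates)
        # brute-force oracle: core labelled 1..3 by the oldest, uniques 4..6 in year order
        assert [cat.pools["C1"][f"C1s{i}"] for i in (1, 2, 3)] == core
        assert cat.pools["C1"]["C1s4"] == uniq[2009]
        assert cat.pools["C1"]["C1s5"] == uniq[2010]
        assert cat.pools["C1"]["C1s6"] == uniq[2011]

    def test_rerun_is_deterministic(self, sim):
        a = build_global_catalog(sim.isolate_arrays())
        b = build_global_catalog(sim.isolate_arrays())
        assert a.pools == b.pools and a.arrays == b.arrays

    def test_duplicate_spacer_in_one_array_kept_under_one_label(self):
        rng = np.random.default_rng(6)
        s = random_dna(rng, 30)
        with pytest.warns(UserWarning, match="duplicated"):
            cat = build_global_catalog([("iso", 2009, {"C1": [s, s]})])
        assert cat.arrays["iso"]["C1"] == ["C1s1", "C1s1"]

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.data())
    def test_appending_youngest_isolate_never_relabels(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        pool = [random_dna(rng, 20) for _ in range(8)]
        n_old = data.draw(st.integers(1, 4))
        olds = []
        for i in range(n_old):
            picks = data.draw(
                st.lists(st.integers(0, 7), min_size=1, max_size=6)
            )
            olds.append((f"iso{i}", 2007 + i, {"C1": [pool[j] for j in picks]}))
        young_picks = data.draw(st.lists(st.integers(0, 7), min_size=1, max_size=6))
        young = (f"iso{n_old}", 2007 + n_old, {"C1": [pool[j] for j in young_picks]})
        before = build_global_catalog(olds)
        after = build_global_catalog(olds + [young])
        for label, seq in before.pools["C1"].items():
            assert after.pools["C1"][label] == seq


class TestConservedVariable:
    def test_presence_in_every_isolate_is_conserved(self):
        rng = np.random.default_rng(7)
        shared, private = random_dna(rng, 30), random_dna(rng, 30)
        isolates = [(f"i{k}", 2007 + k, {"C1": [shared]}) for k in range(16)]
        isolates.append(("i16", 2023, {"C1": [shared, private]}))
        cat = classify_conserved_variable(build_global_catalog(isolates))
        assert cat.label_for("C1", shared) in cat.conserved["C1"]
        assert cat.label_for("C1", private) in cat.variable["C1"]

    def test_conserved_set_equals_planted_backbone(self, sim, sim_catalog):
        for locus in ("C1", "C2"):
            conserved_seqs = {
                sim_catalog.pools[locus][l] for l in sim_catalog.conserved[locus]
            }
            assert conserved_seqs == set(sim.truth.backbone[locus])
            assert sim_catalog.conserved[locus] | sim_catalog.variable[locus] == set(
                sim_catalog.pools[locus]
            )
            assert not sim_catalog.conserved[locus] & sim_catalog.variable[locus]
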